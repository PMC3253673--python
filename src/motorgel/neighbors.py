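"""Monomer pair list with a verlet skin, built on a k-d tree.

Flat monomer index ``i = fil*M + mon``.  The list is rebuilt every
``kinetics_interval`` BD steps (the skin absorbs motion in between) and is
shared by the excluded-volume force loop and the motor-attachment sweep.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["PairList", "build_pair_list"]


class PairList:
    def __init__(self, pairs: np.ndarray, M: int, cutoff: float, skin: float):
        self.pairs = pairs            # (P, 2) flat monomer indices, i < j
        self.M = M
        self.cutoff = cutoff
        self.skin = skin

    def unpack(self):
        """Return (fil_i, mon_i, fil_j, mon_j) arrays."""
        i, j = self.pairs[:, 0], self.pairs[:, 1]
        return i // self.M, i % self.M, j // self.M, j % self.M


def build_pair_list(positions: np.ndarray, cutoff: float, skin: float = 0.3) -> PairList:
    """All monomer pairs within ``cutoff + skin``, excluding directly bonded
    (same-filament adjacent) pairs.  ``positions`` is (N, M, 3)."""
    N, M, _ = positions.shape
    flat = positions.reshape(N * M, 3)
    tree = cKDTree(flat)
    pairs = tree.query_pairs(cutoff + skin, output_type="ndarray")
    if len(pairs):
        same_fil = pairs[:, 0] // M == pairs[:, 1] // M
        adjacent = np.abs(pairs[:, 0] - pairs[:, 1]) == 1
        pairs = pairs[~(same_fil & adjacent)]
    else:
        pairs = np.empty((0, 2), dtype=np.int64)
    return PairList(pairs, M, cutoff, skin)
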