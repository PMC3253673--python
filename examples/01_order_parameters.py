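"""Classify ideal polarity fields by their angular mode amplitudes.

Builds each ideal polarity field (aster, semi-aster, spindle, nematic) on a
ring, runs the Fourier-mode decomposition and nearest-target classification,
and prints the amplitudes Q_0..Q_3.  Q_1 = 1 is the perfect aster; all
modes vanish for the apolar nematic.

Two target sets are available: "printed" (the tuples in common circulation)
and "derived" (direct quadrature of the ideal fields).  They disagree for
the spindle, where the printed Q_1, Q_3 are twice the quadrature values —
large enough that a field generated from the stated ideal spindle form is
classified as nematic under the printed targets but correctly as spindle
under the derived ones.
"""

import numpy as np

from motorgel import analysis, fixtures

rng = np.random.default_rng(0)
printed = analysis.ideal_state_targets("printed")
derived = analysis.ideal_state_targets("derived")

print(f"{'state':>12}  {'Q0':>7} {'Q1':>7} {'Q2':>7} {'Q3':>7}  printed    derived")
for name in ("aster", "semi-aster", "spindle", "nematic"):
    pos, pol = fixtures.gen_ideal_field(name, 50_000, noise=0.05, rng=rng)
    Q = analysis.mode_amplitudes(pos, pol, n_bins=200).Q
    lab_p = analysis.classify_state(Q, printed)
    lab_d = analysis.classify_state(Q, derived)
    print(f"{name:>12}  " + " ".join(f"{q:7.4f}" for q in Q)
          + f"  {lab_p:<10} {lab_d}")

print("\nEach field carries 0.05 rad of angular noise.  Under the derived")
print("targets every field is recovered as itself; under the printed set the")
print("spindle sits midway between the printed spindle tuple and the nematic.")
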