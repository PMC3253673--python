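"""Fixed-volume protocol: rigid wall with a sudden radius step.

Runs a small gel in a rigid circular box whose radius is suddenly reduced
by b/2 partway through the run, then extracts sign changes of the
transverse-velocity series (direction-switching intervals).  In the full
model this protocol turns an aster into a persistent vortex whose rotation
direction reverses aperiodically.
"""

import numpy as np

import motorgel as mg
from motorgel import analysis
from motorgel.dynamics import Schedule

params = mg.ModelParams(N=24, M=8, R0=12.0, volume_mode="fixed",
                        k_A=15.0, k_D=1.0, k_M=10.0,
                        t_end=20.0, seed=4)
schedule = Schedule.from_params(params, frame_interval=500,
                                radius_schedule=[(10.0, params.R0 - 0.5)])
traj = mg.run_simulation(params, schedule, store_frames=False)
obs = traj.observables

print(obs[["t_over_tau_b", "R", "n_mot", "Q1", "vxp"]].to_string(index=False))

vxp = obs["vxp"].to_numpy()
t = obs["t"].to_numpy()
ok = np.isfinite(vxp)
intervals, mean, se = analysis.switching_times(t[ok], vxp[ok], window=3)
print(f"\nimposed radius follows the schedule exactly (step at t=10).")
if len(intervals):
    print(f"direction-switch intervals: {np.round(intervals, 1)}; "
          f"mean {mean:.1f} +- {se if np.isfinite(se) else float('nan'):.1f}")
else:
    print("no direction switch resolved in this short run (expected at this "
          "scale; switching statistics need runs ~1000x longer).")
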