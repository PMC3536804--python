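"""Infer the potential and diffusivity field from one trajectory.

A 1D double-well landscape (3 kBT barrier, minima 200 nm apart) is
simulated and handed to the MAP estimator; the script prints the fitted
landscape at a few positions and the per-cell diffusivities.
"""

import numpy as np

import raftmap as rm

pot = rm.make_double_well(3.0, half_separation=0.1, dim=1)
traj = rm.simulate(pot, diffusivity=0.025, n_frames=2000, frame_dt=0.025,
                   substeps=20, seed=1, r0=-0.1)

result = rm.infer_map(traj, rm.RunConfig(sigma=0.0))
print(f"converged: {result.diagnostics['converged']}, "
      f"{result.diagnostics['n_estimated_cells']} estimated cells, "
      f"mean occupancy {result.diagnostics['mean_occupancy']:.0f}")

print("\n   x (um)   V_hat (kBT)   V_true (kBT)")
for x in (-0.15, -0.1, -0.05, 0.0, 0.05, 0.1, 0.15):
    vh = result.potential.value(np.array([[x]]))[0]
    vt = pot.value(np.array([[x]]))[0]
    print(f"  {x:+.2f}     {vh:6.2f}        {vt:6.2f}")
# The fitted polynomial reproduces the two wells and the ~3 kBT barrier;
# values are gauged so the lowest visited cell sits at 0.

print(f"\noccupancy-weighted D-hat: {rm.average_diffusivity(result):.4f} "
      "um^2/s (the per-step apparent diffusivity of confined motion at "
      "25 ms frames is below the generating 0.025; the drift term "
      "compensates in the landscape)")
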