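"""Extract the hopping energy between two confinement domains.

Simulates a receptor hopping between two wells, infers the landscape,
locates the minima, measures the barrier along the straight inter-minima
path and classifies the record as multi-hop or single-hop.
"""

import numpy as np

import raftmap as rm

pot = rm.make_double_well(2.0, half_separation=0.1, dim=2, lateral_k=150.0)
traj = rm.simulate(pot, diffusivity=0.025, n_frames=2000, frame_dt=0.025,
                   substeps=20, seed=3, r0=(-0.1, 0.0))

result = rm.infer_map(traj, rm.RunConfig(sigma=0.0))
minima = rm.find_minima(result)
print(f"{len(minima)} potential minima:")
for p, v in minima:
    print(f"  at ({p[0]:+.3f}, {p[1]:+.3f}) um, V = {v:.2f} kBT")

est = rm.classify_hopping(traj, rm.hopping_energy_two_wells(result))
print(f"\nhopping energy: {est.e_h:.2f} kBT (input 2.0)")
print(f"barrier at {np.round(est.barrier_position, 3)} um")
print(f"{est.n_crossings} mid-plane crossings -> {est.event_class}")
# Many back-and-forth crossings mark exchange between sub-structures of
# one large domain (low barriers); one or few crossings mark a rare jump
# between distinct domains (higher barriers).  Single records scatter by
# several tenths of a kBT, and at 25 ms frames 2D estimates read
# systematically low (see docs/methods.md on finite-frame-rate bias).
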