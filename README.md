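# raftmap

Bayesian inference of diffusivity and potential fields from
single-particle-tracking (SPT) trajectories of membrane proteins
confined in lipid-raft-like domains.

A receptor moving in the plasma membrane experiences both friction and
direct interactions with its lipid environment. Its recorded trajectory
**r**₀, **r**₁, … is modelled as overdamped Langevin motion

    dr = -D(r) ∇V(r) dt + √(2 D(r)) dW        (k_BT = 1)

with a diffusivity field *D*(**r**) (µm²/s) and an interaction potential
*V*(**r**) (k_BT). `raftmap` estimates both fields from a single
trajectory: the visited area is split into a regular mesh with cells
twice the mean displacement, each cell carries its own diffusivity
*D₍ᵢⱼ₎*, the potential is a single polynomial of order *C* (default 4)
about the trajectory's centre of mass, and each recorded step
contributes the short-time Gaussian transition density

    r_{μ+1} | r_μ ~ N( r_μ − D ∇V dt ,  2 (D + σ²/dt) dt per axis )

where σ is the static localisation noise. With a flat prior, the
maximum-a-posteriori (MAP) point of the product of these densities gives
the fields. On top of the core estimator the package provides:

- a Langevin **simulator** (Euler–Maruyama with substeps, camera blur and
  localisation noise, enzyme-treatment schedules, rough-potential
  overlays) used both as fixture generator and benchmark ground truth;
- **sliding-window inference** for slowly varying fields (k(t), D(t)
  traces during cholesterol-oxidase / sphingomyelinase-like raft
  destabilisation), with drift correction, timescale checks and an
  inferred-vs-input harmonic calibration;
- **hopping-energy extraction** for two-well and well-to-escape
  geometries, event classification, and a replicate benchmark harness
  with empirical bias calibration;
- **Boltzmann thermodynamics** of inferred landscapes: occupancy maps,
  partition functions and free-energy differences.

## Worked example

```python
import raftmap as rm

pot = rm.make_double_well(3.0, half_separation=0.1, dim=1)   # 3 kBT barrier
traj = rm.simulate(pot, diffusivity=0.025, n_frames=2000,
                   frame_dt=0.025, substeps=20, seed=1, r0=-0.1)
result = rm.infer_map(traj, rm.RunConfig(sigma=0.0))
est = rm.hopping_energy_two_wells(result)
print(f"hopping energy: {est.e_h:.2f} kBT")
```

prints

```
hopping energy: 3.65 kBT
```

for this particular record; over 20 replicate simulations the mean is
3.08 ± 0.10 (SEM) k_BT — the estimator recovers the 3 k_BT barrier that
separates the two wells. The example scripts in `examples/` walk through
each capability (simulation and camera noise, potential maps,
hopping energies, enzyme-treatment time series, free energies) and print
the numbers they compute alongside the generating truth.

A thin command-line interface wraps the same functions:

```sh
raftmap simulate --form double_well --e-h 3 --separation 0.2 --out traj.csv
raftmap infer traj.csv --sigma 0.0 --out result.json
raftmap hop traj.csv --sigma 0.0 --out hop.json
```

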