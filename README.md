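# dnacaliper

Analysis toolkit for **DNA nanoswitch caliper (DNC)** single-molecule force
spectroscopy. A caliper is a looped DNA construct that closes through a
target molecule via hybridised handles; mechanically opening ("unlooping")
the loop under force releases a discrete extension step ΔL that reports an
intramolecular distance, and slowly ramping the force unfolds the target
along the pulling axis defined by the grabbed handle. This package turns
raw `(time, force, extension)` traces into:

- **intramolecular distances** — step detection at constant force,
  per-molecule Gaussian multi-peak fitting, per-molecule averaging,
  parametric bootstrap uncertainties, and conversion of unlooping lengths
  into absolute distances through a calibrated effective loop length,
  `d = L0 − ΔL`;
- **conformation assignments** — comparison of measured per-site values to
  candidate folded structures (e.g. G-quadruplex parallel / antiparallel /
  hybrid forms) by RMSD with propagated errors and by a Gaussian-mixture
  maximum-likelihood model (uniform site prior, fixed σ = 0.5 nm);
- **direction-dependent mechanical stability** — worm-like-chain
  contour-length differencing for ramp unfolding events (ΔL_unfold),
  pulling-axis identification from the subsequent unlooping step
  (ΔL_unloop), and per-axis unfolding-force statistics.

A first-class simulator generates synthetic caliper experiments (force-jump
cycles at 1400 Hz, ~6 pN/s ramps, Bell-model unfolding kinetics, Gaussian
measurement noise) with exact ground-truth event logs, so every analysis
stage is tested against a generative model it does not share code with.

## The model in brief

Tether elasticity is the Marko–Siggia worm-like chain,
`F(x) = (kBT/Lp)·[1/(4(1−x/Lc)²) − 1/4 + x/Lc]`, composed in series for
dsDNA handle + ssDNA elements. Unfolding during a linear force ramp at rate
`r` follows the Bell model `k(F) = k0·exp(F·Δx/kBT)`, giving the
first-passage force density
`p(F) = (k0/r)·exp(FΔx/kBT)·exp(−(k0·kBT)/(r·Δx)·(exp(FΔx/kBT) − 1))`;
the simulator samples it by inverse CDF and the calibration helper solves
`(k0, Δx)` for a target mean force by quadrature plus root finding. Steps at
constant force are located with a two-sided CUSUM statistic and sized as
differences of plateau means; ramp events are sized as the difference in
fitted WLC contour length before and after the event.

## Worked example

Simulate a potassium-buffer end-to-end assay (10 molecules × 30 shear/rebind
cycles), detect the unlooping steps, fit the ΔL population, calibrate the
loop length and convert to an absolute distance:

```python
from dnacaliper import RunConfig, run_conformation_pipeline

cfg = RunConfig(experiment="k_endtoend", seed=1, n_molecules=10,
                cycles_per_molecule=30, bootstrap_iters=1000)
report = run_conformation_pipeline(cfg)
peak = report["stages"]["infer"]["population_peaks"][0]
cal = report["stages"]["calibrate"]
dist = report["stages"]["distance"]
print(f"dL peak: {peak['mean_nm']:.2f} +/- {peak['sem_nm']:.2f} nm")
print(f"L0: {cal['L0_nm']:.2f} +/- {cal['se_L0_nm']:.2f} nm")
print(f"end-to-end distance: {dist['d_nm']:.2f} +/- {dist['se_nm']:.2f} nm")
```

prints

```
dL peak: 27.01 +/- 0.04 nm
L0: 28.14 +/- 0.09 nm
end-to-end distance: 1.13 +/- 0.10 nm
```

i.e. the single unlooping population sits at ≈27 nm; regressing a
known-length analyte ladder back to zero length gives an effective loop
length L0 ≈ 28 nm, so the folded target holds its labeled ends ≈1 nm apart
— the potassium-conformer geometry the simulation was generated with.

The same pipeline with `experiment="na_endtoend"` resolves the three
sodium-buffer populations (~6 nm unfolding, ~20 nm unlooping from the
unfolded state, ~26 nm unlooping from the folded state) and a ~2 nm
end-to-end distance; `run_unfolding_pipeline` analyses multidirectional
ramp experiments and reports per-axis unfolding forces.

A CLI mirrors the library: `dnc simulate | detect | calibrate | infer |
assign | unfold | report | fixtures` (see `dnc --help`).

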