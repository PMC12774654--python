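# Methods

This note documents the models, parameter choices and numerical decisions
behind `dnacaliper`, and what the synthetic experiments do and do not
establish about real data.

## Physical model

**Tether elasticity.** Every tether element is an inextensible worm-like
chain in the Marko–Siggia interpolation; elements in series share tension,
so the construct extension is the sum of per-segment extensions at the
common force. The interpolation is inverted by a damped Newton iteration on
the reduced force (machine precision in < 30 steps, vectorised), which the
simulator, the composite-extension model and the contour-length fitting all
share. An extensible-WLC correction (`x → x + Lc·F/K`) is available per
segment but off by default: the analysis forces stay below ~55 pN where the
inextensible form is adequate, and the ~65 pN overstretching plateau enters
only as a tether-QC flag, never as elasticity.

Fixed constants (all overridable): kBT = 4.114 pN·nm (23 °C), dsDNA
Lp = 50 nm and rise 0.34 nm/bp, ssDNA Lp = 1.0 nm and rise 0.59 nm/nt.
These are field-standard values; the original instrument fits did not
publish their elasticity parameters, so they are declared defaults rather
than inferred quantities.

**Contour-length fitting.** `fit_contour_length` minimises *extension*
residuals at the measured forces (extension is the noisy channel in an
optical-tweezers trace) with Lc as the only free parameter; the standard
error comes from the Gauss–Newton Jacobian and residual variance. ΔL_unfold
is the difference of the contour lengths fitted to the pre- and post-event
branches of a ramp, with SEs combined in quadrature.

**Unfolding kinetics.** Each transition is a two-state Bell process,
`k(F) = k0·exp(F·Δx/kBT)`. Under a linear ramp the first-passage force has
a closed-form CDF, which the simulator inverts exactly for sampling; the
mean force is computed by quadrature of the survival function, and
`calibrate_bell_k0` root-finds k0 (log-scale Brent) so the mean matches a
target at a given ramp rate. Handle rebinding at the low force is modelled
as deterministic success per cycle.

## Synthetic experiments (study conditions)

The presets pin the generating conditions the analysis is tested under:

- **Geometry.** Effective loop length L0 = 28.0 nm at the 10 pN shearing
  force for the distance assays. End-to-end distance 2.0 nm
  (sodium/antiparallel-like, with a 6.0 nm unfolding release → ΔL classes
  6/20/26 nm), 1.0 nm (potassium-conformer, single 27 nm class), and a
  four-site hybrid-1-like table ΔL = {18, 21, 24, 27} nm. Directional
  presets use per-axis ΔL_unloop = {48, 58, 63, 68} nm and releases
  {1.0, 6.0, 8.0, 8.5} nm; the 1.0 nm axis is deliberately below the 2 nm
  detection floor.
- **Protocols.** Force-jump: 0.5 pN rebind hold 1 s, 10 pN shear hold 2 s,
  1400 Hz (hold durations are declared defaults; the acquisition paper
  trail does not state them). Ramp: 6 pN/s from 1 to 45 pN, then a jump to
  58 pN held 2 s to unloop.
- **Kinetics.** Shearing at 10 pN: k = 2 s⁻¹ (Δx = 2 nm). Sodium-like
  holds add unfolding at k = 0.8 s⁻¹ (Δx = 1.5 nm), so unfolding precedes
  unlooping in ~29% of cycles; potassium-like holds have no unfolding.
  Ramp unfolding kinetics are Bell-calibrated per axis to mean forces of
  21 pN (end-to-end) and 22–23.5 pN (loop axes) at 6 pN/s, reproducing the
  loops-stiffer-than-ends ordering.
- **Noise.** Per-sample extension noise σ_x = 2 nm at 1400 Hz
  (instrument-level choice) plus per-event ΔL jitter σ = 0.5 nm, the
  observed cycle-to-cycle spread of caliper measurements. Drift is
  available but defaults to 0.
- **Randomness.** One seed feeds named CRC-split `SeedSequence` streams
  (sites / kinetics / noise, per molecule), so any stage can be rerun in
  isolation bit-identically.

What the simulator does **not** emulate: bead/trap hydrodynamics and
low-pass filtering, slow instrumental drift, mixed ssDNA/dsDNA compliance
of the released segment during a ramp (the released length is added to the
same WLC family, making "contour-length difference" exactly the generating
quantity), static conformational heterogeneity between molecules, and
missed-rebinding cycles. Passing tests therefore demonstrate correctness
of the estimators under the stated statistical structure, not robustness
to every instrumental artefact of real traces.

## Event detection

Steps at constant force are found by two-sided CUSUM binary segmentation
with the threshold expressed in units of plateau noise (robustly estimated
from the median absolute first difference; default 8σ). Change points are
localised with a 5-sample minimum segment; step heights are differences of
plateau means excluding a 50 ms guard around each change point. When an
event sits close to a hold boundary the guard shrinks so at least 30
plateau samples remain; below a hard floor of 10 usable samples the event
is dropped rather than reported with a biased height (in the axis-
identification pipeline the floor is raised to 30, since a mis-sized
unlooping step could select the wrong axis window while a dropped one only
costs a cycle). The default minimum step is 2 nm, matching the smallest
reported unfolding release.

Ramp events are located on the residual of extension against a WLC fitted
to the early ramp, then sized by pre/post contour-length fits; events whose
release falls below the detection floor return type `none`, which is what
makes the sub-threshold pulling axis genuinely unobservable rather than an
error.

## Inference

Per-molecule ΔL histograms seed Gaussian-mixture fits
(`sklearn.mixture.GaussianMixture`, full covariance, σ floor 0.05 nm via
`reg_covar`). Bin width is Freedman–Diaconis with a 0.2 nm floor, capped so
a k-modal histogram keeps ≥ 4 bins per expected component (plain FD is a
unimodal rule and merges well-separated peaks). The component count comes
from the experiment design (1 end-to-end, 3 sodium classes, 4 multi-site),
is capped at one component per 5 observations, or is selected by BIC in
`auto` mode; components whose means coincide within 0.1 nm are merged and
the fit repeated with k−1.

Per-molecule peak means are pooled and fitted again (the per-molecule
average distribution); population peaks report mean ± SEM over
contributing molecules. The parametric bootstrap (default 10,000
iterations, seeded) redraws each molecule mean from its fitted population
component N(μ, σ) and refits every replicate with a warm-started,
replicate-batched EM; reported are per-peak SD and percentile 95% CIs, with
replicates whose refit collapses dropped and a > 20% drop rate flagged.
Degenerate inputs (zero spread) propagate to zero-width CIs.

Loop calibration is ordinary least squares of ΔL against known analyte
length; the intercept is L0 and `d = L0 − ΔL` with calibration and
measurement errors combined in quadrature. Conversion to absolute distance
applies only to the single-site end-to-end assay; multi-site and
directional results stay in ΔL space because L0 differs between loop-region
and end handles.

## Conformation assignment

Candidates carry expected per-site values in a declared space (ΔL or
distance; distance-space tables can be built from PDB coordinates via
gemmi, first NMR model by default or averaged, with per-site linker
offsets). RMSD uses first-order error propagation
(∂RMSD/∂mᵢ = eᵢ/(n·RMSD)); at RMSD = 0, where the delta method
degenerates, the per-site SE quadratic mean is reported as an upper bound.
The likelihood model is exactly the uniform mixture
`p(x) = (1/k)·Σ N(x; μ_site, 0.5 nm)` evaluated on raw measurements (no
binning or fitting), normalised across candidates per molecule and
averaged over molecules. Mixture weights are fixed uniform — sampling is
by design equiprobable across sites — and σ is fixed, not fitted. The
bundled four-candidate table is a synthetic stand-in consistent with the
generating geometry; real analyses should derive tables from deposited
coordinates and supply them as editable YAML.

When pairing unlabeled population peaks with candidate sites for RMSD, the
sorted measured peaks are matched to each candidate's sites sorted by
expected value (rank pairing); this is unambiguous for the well-separated
tables used here.

## Directional statistics

Axis windows default to ±2.5 nm around the expected ΔL_unloop
(non-overlapping at the ~5 nm spacings used); assignment requires a unique
window, raises on overlap, and cross-checks the paired ΔL_unfold against
the axis's expected range (±30%), flagging mismatches without discarding
them. Axes whose expected release lies entirely below the detection floor
are excluded from statistics with an explicit note. The optional linear
trend of per-axis force is regressed against cycle index and labeled
exploratory — the appropriate abscissa for such trends is not settled.

## Problem sizes

The default test and acceptance scales are the study scales: 16 (sodium)
and 10 (potassium) molecules × 30 cycles, 21 molecules × 4 sites for the
multi-site assay, ≥ 200 ramp cycles for force recovery, and 100-replicate
classification sweeps. The bootstrap runs at 1,000 iterations in the test
suite and acceptance script (the 10,000-iteration default is the library
setting); the replicate-batched EM makes the full 10,000 equally feasible.

## Known limitations

- Step detection assumes piecewise-constant plateaus; slow drift beyond a
  linear term would need detrending upstream.
- The ramp detector fits a single event per ramp (the strongest change
  point); multi-intermediate unfolding pathways are out of scope.
- Between-molecule heterogeneity is supported in the fast ΔL-dataset
  generator but not in the trace-level simulator.
- Bell-parameter *estimation* from measured force distributions is out of
  scope; the package only reports empirical per-axis force statistics.
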