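"""Loop calibration, dL-to-distance conversion, and peak inference.

The caliper reports an intramolecular distance d indirectly: unlooping at
the shearing force releases dL = L0 - d, where L0 is the effective loop
length at that force. L0 is calibrated by measuring dL for analytes of
known length and extrapolating a linear regression to zero analyte length
(the intercept is L0); d = L0 - dL then converts the unlooping peak into an
absolute distance.

Peak positions are estimated hierarchically, the way single-molecule data
demand: Gaussian multi-peak fitting is applied per molecule first (initial
means seeded from histogram peaks), the per-molecule peak means are pooled
into a per-molecule average distribution which is fitted again, and the
uncertainty of the population peaks is quantified by a seeded parametric
bootstrap (default 10,000 iterations) that resamples molecule means from
the fitted population components and refits every replicate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.special import logsumexp
from scipy.stats import linregress
from sklearn.mixture import GaussianMixture

from .errors import ArgumentError, DomainError, FitError
from .rng import rng_stream
from .simulator import MoleculeObservations

__all__ = [
    "PeakEstimate",
    "MoleculePeaks",
    "PopulationFit",
    "CalibrationResult",
    "BootstrapResult",
    "calibrate_loop_length",
    "deltaL_to_distance",
    "fit_molecule_peaks",
    "per_molecule_average_distribution",
    "bootstrap_peak_uncertainty",
]

SIGMA_FLOOR_NM = 0.05
MERGE_TOL_NM = 0.1
BIN_FLOOR_NM = 0.2


@dataclass(frozen=True)
class PeakEstimate:
    """One fitted Gaussian component."""

    mean: float
    sigma: float
    weight: float
    stderr: float
    n: int

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ArgumentError("sigma must be > 0")
        if self.stderr < 0:
            raise ArgumentError("stderr must be >= 0")


@dataclass
class MoleculePeaks:
    """Per-molecule multi-peak fit."""

    molecule_id: str
    peaks: list[PeakEstimate]
    converged: bool
    n_observations: int


@dataclass
class PopulationFit:
    """Population-level fit over per-molecule peak means.

    ``member_means`` are the pooled per-molecule means, ``assignments``
    their component indices (aligned with ``peaks``); both are retained so
    the parametric bootstrap can resample the exact fitted structure.
    """

    peaks: list[PeakEstimate]
    member_means: np.ndarray = field(repr=False)
    assignments: np.ndarray = field(repr=False)
    converged: bool = True


@dataclass(frozen=True)
class CalibrationResult:
    """Linear-regression loop calibration: dL = L0 - slope * length."""

    L0: float
    slope: float
    se_L0: float
    se_slope: float
    residual_rms: float
    n: int

    def __post_init__(self) -> None:
        if not (self.L0 > 0):
            raise ArgumentError("calibrated L0 must be > 0")


@dataclass
class BootstrapResult:
    peak_se: np.ndarray
    peak_ci: np.ndarray  # shape (k, 2): 2.5 / 97.5 percentiles
    n_iter: int
    failure_rate: float
    flagged: bool


# ---------------------------------------------------------------------------
# Calibration and conversion
# ---------------------------------------------------------------------------

def calibrate_loop_length(known_analytes) -> CalibrationResult:
    """Ordinary least squares of observed dL against known analyte length.

    The intercept extrapolates to a zero-length analyte and is the
    effective loop length L0; the (positive) slope is the extension per
    analyte nucleotide at the measurement force.
    """
    pts = np.asarray(known_analytes, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ArgumentError("need >= 2 (length, dL) pairs")
    length, dl = pts[:, 0], pts[:, 1]
    if np.ptp(length) <= 0:
        raise FitError(
            "rank-deficient calibration: all analyte lengths identical"
        )
    fit = linregress(length, dl)
    resid = dl - (fit.intercept + fit.slope * length)
    return CalibrationResult(
        L0=float(fit.intercept),
        slope=float(-fit.slope),
        se_L0=float(fit.intercept_stderr),
        se_slope=float(fit.stderr),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n=len(pts),
    )


def deltaL_to_distance(
    deltaL: float, cal: CalibrationResult, deltaL_se: float = 0.0
) -> tuple[float, float]:
    """Convert an unlooping length into an absolute distance: d = L0 - dL.

    The returned standard error combines the calibration and measurement
    errors in quadrature. dL exceeding L0 by more than 3 calibration SEs is
    a physically negative distance and raises :class:`DomainError`.
    """
    if deltaL > cal.L0 + 3.0 * cal.se_L0:
        raise DomainError(
            f"dL = {deltaL:.2f} nm exceeds L0 = {cal.L0:.2f} nm "
            "beyond calibration error: negative distance"
        )
    d = cal.L0 - deltaL
    se = float(np.hypot(cal.se_L0, deltaL_se))
    return float(d), se


# ---------------------------------------------------------------------------
# Gaussian multi-peak fitting
# ---------------------------------------------------------------------------

def _histogram_seeds(values: np.ndarray, k: int) -> np.ndarray:
    """Initial component means from histogram peak positions.

    Freedman-Diaconis bin width with a floor keeps narrow single-molecule
    histograms from over-binning; when fewer peaks than components are
    found the remaining seeds come from evenly spaced quantiles.
    """
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    width = 2.0 * iqr / max(len(values), 1) ** (1.0 / 3.0)
    # FD assumes a unimodal histogram; cap the width so a k-modal one keeps
    # at least ~4 bins per expected component, with the floor against
    # over-binning narrow single-molecule data
    span_raw = np.ptp(values)
    if span_raw > 0:
        width = min(width, span_raw / max(4 * k, 8))
    width = max(width, BIN_FLOOR_NM)
    span = max(span_raw, width)
    nbins = max(int(np.ceil(span / width)), 1)
    counts, edges = np.histogram(values, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx, props = find_peaks(np.concatenate([[0], counts, [0]]), height=1)
    idx = idx - 1
    order = np.argsort(props["peak_heights"])[::-1]
    seeds = list(centers[idx[order][:k]])
    while len(seeds) < k:
        q = (len(seeds) + 0.5) / k
        seeds.append(float(np.quantile(values, q)))
    return np.sort(np.array(seeds[:k]))


def _gmm_fit(
    values: np.ndarray,
    k: int,
    seed: int,
    means_init: np.ndarray | None = None,
    max_iter: int = 200,
):
    gmm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        reg_covar=SIGMA_FLOOR_NM**2,
        means_init=None if means_init is None else means_init.reshape(-1, 1),
        random_state=seed & 0x7FFFFFFF,
        max_iter=max_iter,
        n_init=1,
    )
    gmm.fit(values.reshape(-1, 1))
    return gmm


def _gmm_to_peaks(gmm, values: np.ndarray) -> tuple[list[PeakEstimate], np.ndarray]:
    means = gmm.means_.ravel()
    sigmas = np.sqrt(gmm.covariances_.reshape(-1))
    weights = gmm.weights_.ravel()
    order = np.argsort(means)
    assign_raw = gmm.predict(values.reshape(-1, 1))
    remap = np.empty_like(order)
    remap[order] = np.arange(len(order))
    assignments = remap[assign_raw]
    peaks = []
    for rank, i in enumerate(order):
        n_i = int(np.sum(assignments == rank))
        sig = max(float(sigmas[i]), SIGMA_FLOOR_NM)
        peaks.append(
            PeakEstimate(
                mean=float(means[i]),
                sigma=sig,
                weight=float(weights[i]),
                stderr=float(sig / np.sqrt(max(n_i, 1))),
                n=n_i,
            )
        )
    return peaks, assignments


def _fit_mixture(
    values: np.ndarray, expected_k, k_max: int, seed: int
) -> tuple[list[PeakEstimate], np.ndarray, bool]:
    """Shared 1-D mixture fit with degenerate handling, BIC auto-k and
    merging of coincident components."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        raise ArgumentError("no observations to fit")
    if np.ptp(values) < 1e-12:
        peak = PeakEstimate(float(values[0]), SIGMA_FLOOR_NM, 1.0, 0.0, n)
        return [peak], np.zeros(n, dtype=int), True

    if expected_k == "auto":
        best = None
        for k in range(1, max(min(k_max, n // 5), 1) + 1):
            gmm = _gmm_fit(values, k, seed, _histogram_seeds(values, k))
            bic = gmm.bic(values.reshape(-1, 1))
            if best is None or bic < best[0]:
                best = (bic, gmm)
        gmm = best[1]
    else:
        k = int(expected_k)
        if k < 1:
            raise ArgumentError("component count must be >= 1")
        k = max(min(k, n // 5), 1)  # need >= 5 observations per component
        gmm = _gmm_fit(values, k, seed, _histogram_seeds(values, k))

    # merge components whose means coincide and refit with k-1
    while gmm.n_components > 1:
        means = np.sort(gmm.means_.ravel())
        if np.min(np.diff(means)) >= MERGE_TOL_NM:
            break
        gmm = _gmm_fit(
            values, gmm.n_components - 1, seed,
            _histogram_seeds(values, gmm.n_components - 1),
        )
    peaks, assignments = _gmm_to_peaks(gmm, values)
    return peaks, assignments, bool(gmm.converged_)


def fit_molecule_peaks(
    mol: MoleculeObservations | np.ndarray,
    expected_k="auto",
    k_max: int = 4,
    seed: int = 0,
) -> MoleculePeaks:
    """Multi-peak Gaussian fit of one molecule's dL observations.

    Initial means come from histogram peak finding; ``expected_k`` fixes
    the component count (capped so each component keeps >= 5 observations)
    or ``"auto"`` selects it by BIC up to ``k_max``. Components closer than
    0.1 nm are merged and the fit repeated with one fewer component.
    Non-convergence is flagged on the result, never raised.
    """
    if isinstance(mol, MoleculeObservations):
        values = mol.deltaL
        mol_id = mol.molecule_id
    else:
        values = np.asarray(mol, dtype=float)
        mol_id = ""
    peaks, _, converged = _fit_mixture(values, expected_k, k_max, seed)
    return MoleculePeaks(mol_id, peaks, converged, len(values))


def per_molecule_average_distribution(
    mol_fits: Sequence[MoleculePeaks],
    expected_k="auto",
    k_max: int = 4,
    seed: int = 0,
) -> PopulationFit:
    """Fit the distribution of per-molecule peak means.

    Pools every molecule's fitted peak means and applies the same Gaussian
    multi-peak fit; the reported uncertainty of each population peak is the
    standard error of the mean over contributing molecules. With a single
    molecule the fit is passed through with a warning (no averaging is
    possible).
    """
    if len(mol_fits) == 0:
        raise ArgumentError("no molecule fits supplied")
    means = np.concatenate([[p.mean for p in mf.peaks] for mf in mol_fits])
    if len(mol_fits) < 2:
        warnings.warn(
            "population fit over a single molecule: passthrough of its peaks",
            stacklevel=2,
        )
        peaks = [
            PeakEstimate(p.mean, p.sigma, p.weight, 0.0, 1)
            for p in mol_fits[0].peaks
        ]
        return PopulationFit(peaks, means, np.arange(len(means)), True)
    peaks, assignments, converged = _fit_mixture(means, expected_k, k_max, seed)
    return PopulationFit(peaks, means, assignments, converged)


def _em_refit_batch(
    draws: np.ndarray,
    mu0: np.ndarray,
    sig0: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started 1-D Gaussian-mixture EM, vectorised over replicates.

    ``draws`` has shape (R, n); every replicate is refitted from the same
    initial component means/sigmas. Returns sorted component means of
    shape (R, k) and a boolean failure mask (collapsed or non-finite
    components).
    """
    R, n = draws.shape
    k = len(mu0)
    mu = np.broadcast_to(mu0, (R, k)).copy()
    var = np.broadcast_to(np.maximum(sig0, SIGMA_FLOOR_NM) ** 2, (R, k)).copy()
    w = np.full((R, k), 1.0 / k)
    for _ in range(max_iter):
        log_p = (
            np.log(w[:, None, :])
            - 0.5 * np.log(2 * np.pi * var[:, None, :])
            - 0.5 * (draws[:, :, None] - mu[:, None, :]) ** 2 / var[:, None, :]
        )
        log_norm = logsumexp(log_p, axis=2)
        resp = np.exp(log_p - log_norm[:, :, None])  # (R, n, k)
        nk = resp.sum(axis=1)  # (R, k)
        new_mu = (resp * draws[:, :, None]).sum(axis=1) / np.maximum(nk, 1e-12)
        new_var = (resp * (draws[:, :, None] - new_mu[:, None, :]) ** 2).sum(
            axis=1
        ) / np.maximum(nk, 1e-12)
        new_var = np.maximum(new_var, SIGMA_FLOOR_NM**2)
        w = nk / n
        shift = np.max(np.abs(new_mu - mu))
        mu, var = new_mu, new_var
        if shift < tol:
            break
    failed = (
        ~np.all(np.isfinite(mu), axis=1)
        | (np.min(w, axis=1) < 1e-6)
    )
    return np.sort(mu, axis=1), failed


def bootstrap_peak_uncertainty(
    fit: PopulationFit,
    n_iter: int = 10_000,
    seed: int = 0,
    max_failure_rate: float = 0.2,
) -> BootstrapResult:
    """Parametric bootstrap of the population peak positions.

    Each replicate redraws every contributing molecule mean from its fitted
    population component N(mean, sigma), refits the multi-peak model with
    warm-started means (batched EM across replicates), and records the
    sorted component means. Reported are the per-peak SD and percentile
    95% CI. Replicates whose refit collapses are dropped; a drop rate
    above ``max_failure_rate`` flags the result.
    """
    if n_iter < 100:
        raise ArgumentError("n_iter must be >= 100")
    k = len(fit.peaks)
    mu = np.array([p.mean for p in fit.peaks])
    # component spread; degenerate components (stderr 0) resample with zero
    # width so the CI collapses as it should
    sig = np.array(
        [0.0 if p.stderr == 0.0 else p.sigma for p in fit.peaks]
    )
    comp = fit.assignments
    rng = rng_stream(seed, "bootstrap")
    if np.all(sig == 0.0):
        ci = np.column_stack([mu, mu])
        return BootstrapResult(np.zeros(k), ci, n_iter, 0.0, False)

    draws = mu[comp] + rng.standard_normal((n_iter, len(comp))) * sig[comp]
    if k == 1:
        replicates = draws.mean(axis=1, keepdims=True)
        failures = 0
    else:
        replicates, failed = _em_refit_batch(draws, mu, sig)
        failures = int(failed.sum())
        replicates = replicates[~failed]
    if len(replicates) == 0:
        raise FitError("all bootstrap replicates failed to converge")
    se = (np.std(replicates, axis=0, ddof=1)
          if len(replicates) > 1 else np.zeros(k))
    ci = np.percentile(replicates, [2.5, 97.5], axis=0).T
    rate = failures / n_iter
    return BootstrapResult(se, ci, n_iter, rate, rate > max_failure_rate)
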