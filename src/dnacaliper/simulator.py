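"""Synthetic caliper experiments with ground-truth event logs.

The generator reproduces the statistical structure the analysis assumes:

* force-jump cycles between a shearing force (~10 pN) and a rebinding force
  (~0 pN) sampled at 1400 Hz, with one labeled site grabbed uniformly at
  random per cycle and stochastic unlooping (and, in sodium-like
  conditions, prior unfolding) during the high-force hold;
* slow force ramps (~6 pN/s) to ~45 pN with unfolding forces drawn from the
  Bell-model first-passage distribution, followed by a jump above 55 pN
  whose unlooping step identifies the pulling axis;
* a fast path that draws per-molecule dL datasets directly from a Gaussian
  mixture, bypassing trace synthesis for inference tests.

Every trace is paired with a ground-truth log (one row per emitted event)
so detectors and estimators can be scored exactly. All randomness derives
from one seed through named sub-streams.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from .constants import DS_PERSISTENCE_NM, KBT, SS_PERSISTENCE_NM, SS_RISE_NM_PER_NT
from .errors import ArgumentError, ConfigurationError, DomainError
from .polymer_mechanics import (
    ConstructDesign,
    PolymerSegment,
    composite_extension,
    construct_contour_length,
    wlc_extension,
)
from .rng import rng_stream
from .trace_analysis import Trace

__all__ = [
    "ConformationGeometry",
    "ForceProtocol",
    "BellTransition",
    "KineticModel",
    "NoiseSpec",
    "effective_loop_length",
    "simulate_force_jump_trace",
    "simulate_ramp_trace",
    "simulate_deltaL_dataset",
    "sample_unfolding_force",
    "bell_unfolding_pdf",
    "bell_unfolding_cdf",
    "bell_mean_unfolding_force",
    "calibrate_bell_k0",
    "sample_sites",
    "MoleculeObservations",
]

LOG_COLUMNS = ["cycle", "site", "event_type", "time_s", "force_pN", "deltaL_true"]


@dataclass(frozen=True)
class ConformationGeometry:
    """True geometry of the folded target as seen by the caliper.

    ``site_distance`` maps each grabbed site to the folded-state distance d
    (nm) between the grabbing point and that site. ``loop_extension_nm``
    pins the effective loop length L0 at the shearing force; when absent it
    is computed from the loop ssDNA WLC. ``unfold_release`` is the length
    released by unfolding when pulled through a site: interpreted as an
    extension gain during constant-force holds and as a contour-length
    release during ramps (both are the quantity the respective detector
    reports). ``unloop_deltaL`` overrides the unlooping step per site; when
    absent it is ``L0 - d`` (the distance-measurement identity).
    """

    name: str
    site_distance: Mapping[str, float]
    linker_offset: Mapping[str, float] | None = None
    loop_extension_nm: float | None = None
    unfold_release: Mapping[str, float] | None = None
    unloop_deltaL: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.site_distance.values()):
            raise ArgumentError("site distances must be >= 0")


@dataclass(frozen=True)
class ForceProtocol:
    mode: str  # "force_jump" | "ramp_then_jump"
    low_force: float = 0.5
    high_force: float = 10.0
    ramp_rate: float = 6.0
    ramp_start: float = 1.0
    ramp_ceiling: float = 45.0
    jump_force: float = 58.0
    hold_high_s: float = 2.0
    hold_low_s: float = 1.0
    jump_hold_s: float = 1.0
    n_cycles: int = 30
    sampling_rate: float = 1400.0

    def __post_init__(self) -> None:
        if self.mode not in ("force_jump", "ramp_then_jump"):
            raise ArgumentError(f"unknown protocol mode {self.mode!r}")
        if self.sampling_rate <= 0:
            raise ArgumentError("sampling_rate must be > 0")
        for name in ("low_force", "high_force", "jump_force", "ramp_start",
                     "ramp_ceiling"):
            if getattr(self, name) < 0:
                raise ArgumentError(f"{name} must be >= 0")
        if self.mode == "ramp_then_jump" and self.ramp_rate <= 0:
            raise ArgumentError("ramp_rate must be > 0 in ramp mode")
        if self.n_cycles < 1:
            raise ArgumentError("n_cycles must be >= 1")


@dataclass(frozen=True)
class BellTransition:
    """Two-state Bell transition: rate k(F) = k0 * exp(F dx / kBT)."""

    k0: float
    dx: float

    def __post_init__(self) -> None:
        if not (self.k0 > 0 and self.dx > 0):
            raise DomainError("Bell parameters k0 and dx must be > 0")

    def rate(self, F: float, kBT: float = KBT) -> float:
        return self.k0 * math.exp(F * self.dx / kBT)


@dataclass(frozen=True)
class KineticModel:
    """Transitions of one construct.

    ``unfold`` maps sites/axes to their unfolding transitions (empty means
    no unfolding, the potassium-like case); ``unloop`` governs shearing of
    the grabbed handle. Rebinding at the low force is treated as
    deterministic success each cycle.
    """

    unfold: Mapping[str, BellTransition] = field(default_factory=dict)
    unloop: BellTransition = BellTransition(1e-4, 2.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model: per-sample extension noise, per-event dL
    jitter (the 0.5 nm scale observed across caliper measurements), and an
    optional linear drift."""

    sigma_x: float = 2.0
    sigma_deltaL: float = 0.5
    drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_x < 0 or self.sigma_deltaL < 0:
            raise ArgumentError("noise sigmas must be >= 0")


@dataclass
class MoleculeObservations:
    """dL observations of one molecule, grouped by cycle."""

    molecule_id: str
    condition: str
    cycles: np.ndarray
    deltaL: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=int)
        self.deltaL = np.asarray(self.deltaL, dtype=float)
        if len(self.deltaL) < 1:
            raise ArgumentError("a molecule needs >= 1 observation")
        if not np.all(np.isfinite(self.deltaL)):
            raise ArgumentError("dL observations must be finite")


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def sample_sites(
    sites: Sequence[str],
    n: int,
    rng: np.random.Generator,
    weights: Sequence[float] | None = None,
) -> list[str]:
    """Draw the grabbed site for each cycle (uniform unless weighted)."""
    p = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ArgumentError("site weights must be >= 0 with positive sum")
        p = w / w.sum()
    return list(rng.choice(list(sites), size=n, p=p))


def effective_loop_length(
    design: ConstructDesign,
    geometry: ConformationGeometry,
    force: float,
    kBT: float = KBT,
) -> float:
    """Effective loop length L0 (nm) at the measurement force.

    The override on the geometry wins; otherwise the loop ssDNA extension
    at the shearing force is computed from the WLC.
    """
    if geometry.loop_extension_nm is not None:
        return float(geometry.loop_extension_nm)
    loop = PolymerSegment(
        "single-stranded", design.loop_nt * design.rise_per_nt, SS_PERSISTENCE_NM
    )
    return float(wlc_extension(force, loop, kBT))


def _base_segments(design: ConstructDesign) -> list[PolymerSegment]:
    """Tether segments common to looped and unlooped states."""
    segs = [
        PolymerSegment(
            "double-stranded",
            design.dsdna_handle_bp * design.rise_per_bp,
            DS_PERSISTENCE_NM,
        )
    ]
    if design.grabbing_handle_nt > 0:
        segs.append(
            PolymerSegment(
                "single-stranded",
                design.grabbing_handle_nt * design.rise_per_nt,
                SS_PERSISTENCE_NM,
            )
        )
    return segs


def _check_geometry(design: ConstructDesign, geometry: ConformationGeometry) -> None:
    extra = set(geometry.site_distance) - set(design.labeled_sites)
    if extra:
        raise ConfigurationError(
            f"geometry sites not present in construct design: {sorted(extra)}"
        )


def _true_unloop(geometry, site: str, L0: float) -> float:
    if geometry.unloop_deltaL is not None and site in geometry.unloop_deltaL:
        return float(geometry.unloop_deltaL[site])
    return L0 - float(geometry.site_distance[site])


# ---------------------------------------------------------------------------
# Force-jump simulation
# ---------------------------------------------------------------------------

def simulate_force_jump_trace(
    design: ConstructDesign,
    geometry: ConformationGeometry,
    protocol: ForceProtocol,
    kinetics: KineticModel,
    noise: NoiseSpec,
    molecule_id: str = "mol",
    site_weights: Sequence[float] | None = None,
    kBT: float = KBT,
) -> tuple[Trace, pd.DataFrame]:
    """Simulate repeated shear/rebind cycles of one tethered caliper.

    Each cycle holds the rebinding force, then jumps to the shearing force.
    During the high hold, unlooping (and, when the kinetic model allows,
    prior unfolding) occurs at exponential first-passage times; each event
    adds its dL (with per-event jitter ``sigma_deltaL``) to the extension.
    Returns the trace plus a ground-truth log whose rows match the emitted
    steps exactly.
    """
    if protocol.mode != "force_jump":
        raise ArgumentError("protocol.mode must be 'force_jump'")
    _check_geometry(design, geometry)
    rng_site = rng_stream(noise.seed, "sites", molecule_id)
    rng_kin = rng_stream(noise.seed, "kinetics", molecule_id)
    rng_noise = rng_stream(noise.seed, "noise", molecule_id)

    fs = protocol.sampling_rate
    n_lo = int(round(protocol.hold_low_s * fs))
    n_hi = int(round(protocol.hold_high_s * fs))
    n_cyc = n_lo + n_hi
    n_total = n_cyc * protocol.n_cycles

    segs = _base_segments(design)
    x_lo_base = float(composite_extension(protocol.low_force, segs, kBT))
    x_hi_base = float(composite_extension(protocol.high_force, segs, kBT))
    L0 = effective_loop_length(design, geometry, protocol.high_force, kBT)
    k_unloop = kinetics.unloop.rate(protocol.high_force, kBT)

    sites = sample_sites(design.labeled_sites, protocol.n_cycles, rng_site,
                         site_weights)
    force = np.empty(n_total)
    ext = np.empty(n_total)
    segments: list[dict] = []
    rows: list[dict] = []

    for c in range(protocol.n_cycles):
        i0 = c * n_cyc
        site = sites[c]
        d = float(geometry.site_distance[site])
        force[i0 : i0 + n_lo] = protocol.low_force
        ext[i0 : i0 + n_lo] = x_lo_base + d
        segments.append({"cycle": c, "phase": "low", "i0": i0, "i1": i0 + n_lo,
                         "force": protocol.low_force})
        j0 = i0 + n_lo
        force[j0 : j0 + n_hi] = protocol.high_force
        segments.append({"cycle": c, "phase": "high", "i0": j0, "i1": j0 + n_hi,
                         "force": protocol.high_force})

        hold = np.full(n_hi, x_hi_base + d)
        t_hold0 = j0 / fs
        # competing unfold/unloop during the hold
        tr_unfold = kinetics.unfold.get(site) if kinetics.unfold else None
        t_unloop = rng_kin.exponential(1.0 / k_unloop)
        t_unfold = (
            rng_kin.exponential(1.0 / tr_unfold.rate(protocol.high_force, kBT))
            if tr_unfold is not None
            else np.inf
        )
        events: list[tuple[float, str, float]] = []  # (t_rel, type, dL_true)
        if t_unloop <= t_unfold:
            dl = _true_unloop(geometry, site, L0)
            events.append((t_unloop, "unloop_folded", dl))
        else:
            gain = float((geometry.unfold_release or {}).get(site, 0.0))
            events.append((t_unfold, "unfold", gain))
            t2 = t_unfold + rng_kin.exponential(1.0 / k_unloop)
            dl2 = _true_unloop(geometry, site, L0) - gain
            events.append((t2, "unloop_unfolded", dl2))
        for t_rel, etype, dl_true in events:
            k = int(t_rel * fs)
            if k >= n_hi:
                continue
            dl_real = dl_true + (
                rng_kin.normal(0.0, noise.sigma_deltaL)
                if noise.sigma_deltaL > 0
                else 0.0
            )
            hold[k:] += dl_real
            rows.append(
                {
                    "cycle": c,
                    "site": site,
                    "event_type": etype,
                    "time_s": t_hold0 + k / fs,
                    "force_pN": protocol.high_force,
                    "deltaL_true": dl_real,
                }
            )
        ext[j0 : j0 + n_hi] = hold

    t = np.arange(n_total) / fs
    if noise.sigma_x > 0:
        ext = ext + rng_noise.normal(0.0, noise.sigma_x, size=n_total)
    if noise.drift != 0.0:
        ext = ext + noise.drift * t
    trace = Trace(
        t, force, ext, fs,
        meta={
            "mode": "force_jump",
            "molecule_id": molecule_id,
            "seed": noise.seed,
            "geometry": geometry.name,
            "L0_nm": L0,
        },
        segments=segments,
    )
    log = pd.DataFrame(rows, columns=LOG_COLUMNS)
    return trace, log


# ---------------------------------------------------------------------------
# Ramp-then-jump simulation
# ---------------------------------------------------------------------------

def simulate_ramp_trace(
    design: ConstructDesign,
    geometry: ConformationGeometry,
    protocol: ForceProtocol,
    kinetics: KineticModel,
    noise: NoiseSpec,
    molecule_id: str = "mol",
    site_weights: Sequence[float] | None = None,
    kBT: float = KBT,
) -> tuple[Trace, pd.DataFrame]:
    """Simulate ramp-probe / jump-unloop cycles for directional unfolding.

    Each cycle ramps the force linearly from ``ramp_start`` to
    ``ramp_ceiling`` at ``ramp_rate``; the grabbed axis's unfolding force is
    drawn from the Bell first-passage distribution, and the event releases
    that axis's dL_unfold as extra contour length (so contour-length
    differencing recovers it). The subsequent jump above the unlooping
    threshold produces the axis-specific dL_unloop as an extension step at
    constant force. Both events are logged.
    """
    if protocol.mode != "ramp_then_jump":
        raise ArgumentError("protocol.mode must be 'ramp_then_jump'")
    _check_geometry(design, geometry)
    rng_site = rng_stream(noise.seed, "sites", molecule_id)
    rng_kin = rng_stream(noise.seed, "kinetics", molecule_id)
    rng_noise = rng_stream(noise.seed, "noise", molecule_id)

    fs = protocol.sampling_rate
    n_lo = int(round(protocol.hold_low_s * fs))
    ramp_span = protocol.ramp_ceiling - protocol.ramp_start
    n_ramp = int(round(ramp_span / protocol.ramp_rate * fs))
    n_jump = int(round(protocol.jump_hold_s * fs))
    n_cyc = n_lo + n_ramp + n_jump
    n_total = n_cyc * protocol.n_cycles

    lc_base = (
        design.dsdna_handle_bp * design.rise_per_bp
        + design.grabbing_handle_nt * design.rise_per_nt
    )
    template_lp = DS_PERSISTENCE_NM
    L0 = effective_loop_length(design, geometry, protocol.jump_force, kBT)
    k_unloop_jump = kinetics.unloop.rate(protocol.jump_force, kBT)

    sites = sample_sites(design.labeled_sites, protocol.n_cycles, rng_site,
                         site_weights)
    force = np.empty(n_total)
    ext = np.empty(n_total)
    segments: list[dict] = []
    rows: list[dict] = []

    f_ramp = protocol.ramp_start + protocol.ramp_rate * np.arange(n_ramp) / fs

    for c in range(protocol.n_cycles):
        i0 = c * n_cyc
        site = sites[c]
        release = float((geometry.unfold_release or {}).get(site, 0.0))
        force[i0 : i0 + n_lo] = protocol.low_force
        seg_lo = PolymerSegment("double-stranded", lc_base, template_lp)
        ext[i0 : i0 + n_lo] = wlc_extension(protocol.low_force, seg_lo, kBT)
        segments.append({"cycle": c, "phase": "low", "i0": i0, "i1": i0 + n_lo,
                         "force": protocol.low_force})

        j0 = i0 + n_lo
        force[j0 : j0 + n_ramp] = f_ramp
        segments.append({"cycle": c, "phase": "ramp", "i0": j0,
                         "i1": j0 + n_ramp, "force": None})
        tr = kinetics.unfold.get(site) if kinetics.unfold else None
        f_unfold = (
            sample_unfolding_force(tr, protocol.ramp_rate, kBT, rng_kin)
            if tr is not None
            else np.inf
        )
        unfolded_in_ramp = f_unfold < protocol.ramp_ceiling and release > 0
        seg_pre = PolymerSegment("double-stranded", lc_base, template_lp)
        if unfolded_in_ramp:
            k_ev = int(
                np.clip((f_unfold - protocol.ramp_start) / ramp_span * n_ramp,
                        0, n_ramp - 1)
            )
            seg_post = PolymerSegment(
                "double-stranded", lc_base + release, template_lp
            )
            ext[j0 : j0 + k_ev] = wlc_extension(f_ramp[:k_ev], seg_pre, kBT)
            ext[j0 + k_ev : j0 + n_ramp] = wlc_extension(
                f_ramp[k_ev:], seg_post, kBT
            )
            rows.append(
                {
                    "cycle": c,
                    "site": site,
                    "event_type": "unfold",
                    "time_s": (j0 + k_ev) / fs,
                    "force_pN": float(f_ramp[k_ev]),
                    "deltaL_true": release,
                }
            )
        else:
            ext[j0 : j0 + n_ramp] = wlc_extension(f_ramp, seg_pre, kBT)

        # jump phase: any still-folded structure opens within the jump
        # transient; only the unlooping step is observable here.
        m0 = j0 + n_ramp
        force[m0 : m0 + n_jump] = protocol.jump_force
        segments.append({"cycle": c, "phase": "jump", "i0": m0,
                         "i1": m0 + n_jump, "force": protocol.jump_force})
        seg_jump = PolymerSegment(
            "double-stranded", lc_base + release, template_lp
        )
        base_jump = float(wlc_extension(protocol.jump_force, seg_jump, kBT))
        hold = np.full(n_jump, base_jump)
        t_unloop = rng_kin.exponential(1.0 / k_unloop_jump)
        k_ul = int(t_unloop * fs)
        if k_ul < n_jump:
            dl_true = _true_unloop(geometry, site, L0)
            dl_real = dl_true + (
                rng_kin.normal(0.0, noise.sigma_deltaL)
                if noise.sigma_deltaL > 0
                else 0.0
            )
            hold[k_ul:] += dl_real
            rows.append(
                {
                    "cycle": c,
                    "site": site,
                    "event_type": "unloop",
                    "time_s": (m0 + k_ul) / fs,
                    "force_pN": protocol.jump_force,
                    "deltaL_true": dl_real,
                }
            )
        ext[m0 : m0 + n_jump] = hold

    t = np.arange(n_total) / fs
    if noise.sigma_x > 0:
        ext = ext + rng_noise.normal(0.0, noise.sigma_x, size=n_total)
    if noise.drift != 0.0:
        ext = ext + noise.drift * t
    trace = Trace(
        t, force, ext, fs,
        meta={
            "mode": "ramp_then_jump",
            "molecule_id": molecule_id,
            "seed": noise.seed,
            "geometry": geometry.name,
            "L0_nm": L0,
        },
        segments=segments,
    )
    log = pd.DataFrame(rows, columns=LOG_COLUMNS)
    return trace, log


# ---------------------------------------------------------------------------
# Fast dL dataset path
# ---------------------------------------------------------------------------

def simulate_deltaL_dataset(
    components: Sequence[tuple[float, float, float]],
    n_molecules: int,
    cycles_per_molecule: int,
    seed: int,
    between_sigma: float = 0.0,
    condition: str = "synthetic",
) -> list[MoleculeObservations]:
    """Draw per-molecule dL observations from a Gaussian mixture.

    ``components`` is a list of (mean nm, sigma nm, weight). Molecules can
    additionally carry a shared offset drawn from N(0, between_sigma) to
    emulate molecule-to-molecule variability. Fully reproducible under
    ``seed``; weight-zero components are never sampled.
    """
    if len(components) == 0:
        raise ArgumentError("component list must be non-empty")
    if n_molecules < 1:
        raise ArgumentError("n_molecules must be >= 1")
    means = np.array([c[0] for c in components], dtype=float)
    sigmas = np.array([c[1] for c in components], dtype=float)
    weights = np.array([c[2] for c in components], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ArgumentError("weights must be >= 0 with positive sum")
    if np.any(sigmas < 0):
        raise ArgumentError("component sigmas must be >= 0")
    p = weights / weights.sum()

    out: list[MoleculeObservations] = []
    for m in range(n_molecules):
        rng = rng_stream(seed, "deltaL", m)
        offset = rng.normal(0.0, between_sigma) if between_sigma > 0 else 0.0
        comp = rng.choice(len(means), size=cycles_per_molecule, p=p)
        vals = means[comp] + offset + rng.standard_normal(cycles_per_molecule) * sigmas[comp]
        out.append(
            MoleculeObservations(
                molecule_id=f"mol{m:03d}",
                condition=condition,
                cycles=np.arange(cycles_per_molecule),
                deltaL=vals,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Bell-model first passage under a linear ramp
# ---------------------------------------------------------------------------

def _bell_scale(tr: BellTransition, ramp_rate: float, kBT: float) -> float:
    return tr.k0 * kBT / (ramp_rate * tr.dx)


def bell_unfolding_pdf(F, tr: BellTransition, ramp_rate: float, kBT: float = KBT):
    """First-passage density of the unfolding force under a linear ramp:
    p(F) = (k0/r) exp(F dx/kBT) exp(-(k0 kBT)/(r dx) (exp(F dx/kBT) - 1))."""
    if ramp_rate <= 0:
        raise DomainError("ramp_rate must be > 0")
    F = np.asarray(F, dtype=float)
    a = _bell_scale(tr, ramp_rate, kBT)
    e = np.exp(F * tr.dx / kBT)
    return (tr.k0 / ramp_rate) * e * np.exp(-a * (e - 1.0))


def bell_unfolding_cdf(F, tr: BellTransition, ramp_rate: float, kBT: float = KBT):
    """Analytic CDF of the linear-ramp first-passage force."""
    if ramp_rate <= 0:
        raise DomainError("ramp_rate must be > 0")
    F = np.asarray(F, dtype=float)
    a = _bell_scale(tr, ramp_rate, kBT)
    return 1.0 - np.exp(-a * np.expm1(F * tr.dx / kBT))


def sample_unfolding_force(
    tr: BellTransition,
    ramp_rate: float,
    kBT: float = KBT,
    rng: np.random.Generator | int = 0,
    size: int | None = None,
):
    """Draw unfolding forces by inverting the analytic first-passage CDF."""
    if ramp_rate <= 0:
        raise DomainError("ramp_rate must be > 0")
    if not isinstance(rng, np.random.Generator):
        rng = rng_stream(int(rng), "unfolding_force")
    u = rng.uniform(size=size)
    a = _bell_scale(tr, ramp_rate, kBT)
    out = (kBT / tr.dx) * np.log1p(-np.log1p(-u) / a)
    return float(out) if size is None else out


def bell_mean_unfolding_force(
    tr: BellTransition, ramp_rate: float, kBT: float = KBT
) -> float:
    """Mean first-passage force by quadrature of the survival function."""
    a = _bell_scale(tr, ramp_rate, kBT)

    def survival(F: float) -> float:
        return math.exp(-a * math.expm1(F * tr.dx / kBT))

    # upper limit: survival below 1e-14
    hi = (kBT / tr.dx) * math.log1p(32.0 / a)
    val, _ = quad(survival, 0.0, hi, limit=200)
    return float(val)


def calibrate_bell_k0(
    target_mean_force: float,
    dx: float,
    ramp_rate: float,
    kBT: float = KBT,
) -> BellTransition:
    """Find k0 so the linear-ramp mean unfolding force equals the target.

    The mean is strictly decreasing in k0, so the root is bracketed on a
    log scale and found by Brent's method against the quadrature mean.
    """
    if target_mean_force <= 0:
        raise DomainError("target mean force must be > 0")

    def f(log10_k0: float) -> float:
        tr = BellTransition(10.0**log10_k0, dx)
        return bell_mean_unfolding_force(tr, ramp_rate, kBT) - target_mean_force

    lo, hi = -14.0, 8.0
    if f(lo) < 0 or f(hi) > 0:
        raise DomainError(
            "target mean force not reachable with this dx/ramp rate"
        )
    root = brentq(f, lo, hi, xtol=1e-10)
    return BellTransition(10.0**root, dx)
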