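"""Event detection in force-spectroscopy traces.

Turns raw (time, force, extension) series into event records:

* sliding-window averaging for display and noise reduction,
* step (unlooping) detection during constant-force holds via a two-sided
  CUSUM change-point statistic, with step heights taken as differences of
  plateau means,
* unfolding detection during force ramps via change points on the residual
  to a WLC prediction, with dL_unfold obtained as the difference in fitted
  contour length before and after the event,
* per-cycle event classification into magnitude bands,
* single-tether quality control from whole-construct contour length, the
  dsDNA overstretching plateau, and rupture counting.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import KBT, DS_PERSISTENCE_NM, OVERSTRETCH_PLATEAU_PN
from .errors import ArgumentError, FitError, PreconditionError
from .polymer_mechanics import (
    ConstructDesign,
    ContourFit,
    PolymerSegment,
    construct_contour_length,
    fit_contour_length,
    wlc_extension,
)

__all__ = [
    "Trace",
    "EventRecord",
    "QCReport",
    "sliding_window_average",
    "detect_constant_force_steps",
    "detect_ramp_unfolding",
    "classify_cycle_events",
    "validate_tether",
    "events_to_frame",
]

EVENT_TYPES = ("unfold", "unloop", "rupture", "step", "none")


@dataclass
class Trace:
    """Uniformly sampled (time, force, extension) record.

    ``segments`` is the protocol annotation: a list of dicts with keys
    ``cycle``, ``phase`` (low/high/ramp/jump), ``i0``, ``i1`` (sample span,
    half-open) and, for constant phases, ``force``. ``meta`` carries
    protocol parameters, seed and design hash for provenance.
    """

    time: np.ndarray
    force: np.ndarray
    extension: np.ndarray
    sampling_rate: float
    meta: dict = field(default_factory=dict)
    segments: list[dict] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        n = len(self.time)
        if not (len(self.force) == len(self.extension) == n):
            raise ArgumentError("time/force/extension must have equal length")
        if n > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ArgumentError("time must be strictly increasing")
            if abs(np.median(dt) * self.sampling_rate - 1.0) > 0.01:
                raise ArgumentError("sampling_rate inconsistent with time grid")

    def __len__(self) -> int:
        return len(self.time)

    def view(self, i0: int, i1: int) -> "Trace":
        """Sub-trace over samples [i0, i1); segment annotation dropped."""
        return Trace(
            self.time[i0:i1],
            self.force[i0:i1],
            self.extension[i0:i1],
            self.sampling_rate,
            meta=self.meta,
            segments=None,
        )


@dataclass
class EventRecord:
    """One detected transition in a trace."""

    molecule_id: str
    cycle: int
    event_type: str
    deltaL: float
    force: float
    time: float
    label: str | None = None
    stderr: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ArgumentError(f"unknown event type {self.event_type!r}")
        if self.force < 0:
            raise ArgumentError("event force must be >= 0")


def events_to_frame(events: Sequence[EventRecord]) -> pd.DataFrame:
    """EventRecords as a DataFrame with the stable on-disk column names."""
    return pd.DataFrame(
        {
            "molecule_id": [e.molecule_id for e in events],
            "cycle": [e.cycle for e in events],
            "type": [e.event_type for e in events],
            "deltaL_nm": [e.deltaL for e in events],
            "force_pN": [e.force for e in events],
            "time_s": [e.time for e in events],
            "label": [e.label if e.label is not None else "" for e in events],
        }
    )


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def sliding_window_average(data, window: int):
    """Centered moving mean with shrunken edge windows.

    Accepts a 1-D array or a :class:`Trace` (extension channel smoothed,
    other channels untouched). Output length equals input length; the edges
    use however many samples fall inside the centered window, which keeps
    the trace length and avoids phase shift.
    """
    if window < 1:
        raise ArgumentError("window must be >= 1")
    if isinstance(data, Trace):
        if window > len(data):
            raise ArgumentError("window exceeds trace length")
        sm = sliding_window_average(data.extension, window)
        out = replace(data)
        out.extension = sm
        return out
    x = np.asarray(data, dtype=float)
    if window > len(x):
        raise ArgumentError("window exceeds series length")
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


# ---------------------------------------------------------------------------
# Change-point machinery (shared by hold and ramp detection)
# ---------------------------------------------------------------------------

def _noise_sigma(x: np.ndarray) -> float:
    """Robust per-sample noise from the median absolute first difference."""
    d = np.abs(np.diff(x))
    if len(d) == 0:
        return 0.0
    return float(1.4826 * np.median(d) / np.sqrt(2.0))


def _cusum_stat(x: np.ndarray, min_size: int):
    """Two-sided mean-shift statistic for every admissible split point.

    For split k the statistic is |mean(x[:k]) - mean(x[k:])| weighted by
    sqrt(k (n-k) / n); under white noise with std sigma its maximum stays
    near sigma * sqrt(2 log log n), so thresholds are expressed in units of
    plateau noise.
    """
    n = len(x)
    if n < 2 * min_size:
        return None, 0.0
    c = np.cumsum(x)
    k = np.arange(min_size, n - min_size + 1)
    mean_l = c[k - 1] / k
    mean_r = (c[-1] - c[k - 1]) / (n - k)
    stat = np.abs(mean_l - mean_r) * np.sqrt(k * (n - k) / n)
    j = int(np.argmax(stat))
    return int(k[j]), float(stat[j])


def _find_changepoints(
    x: np.ndarray, sigma: float, threshold: float, min_size: int
) -> list[int]:
    """Binary segmentation: recursively split while the statistic exceeds
    ``threshold * sigma``."""
    out: list[int] = []

    def recurse(i0: int, i1: int) -> None:
        k, s = _cusum_stat(x[i0:i1], min_size)
        if k is None or s < threshold * max(sigma, 1e-12):
            return
        cp = i0 + k
        recurse(i0, cp)
        out.append(cp)
        recurse(cp, i1)

    recurse(0, len(x))
    return sorted(out)


# ---------------------------------------------------------------------------
# Constant-force step detection (dL_unloop)
# ---------------------------------------------------------------------------

def detect_constant_force_steps(
    trace: Trace,
    hold: tuple[int, int] | None = None,
    min_step: float = 2.0,
    force_tol: float = 1.0,
    threshold_sigma: float = 8.0,
    guard_s: float = 0.05,
    min_plateau: int = 30,
    min_plateau_floor: int = 10,
    molecule_id: str = "",
    cycle: int = 0,
) -> list[EventRecord]:
    """Detect discrete extension steps during a constant-force hold.

    Each step's dL is the difference of plateau means flanking the change
    point; steps with |dL| below ``min_step`` are ignored. Plateau means
    exclude samples within ``guard_s`` of the change point; when an event
    sits close to a hold boundary (or to a neighbouring event) the guard
    shrinks so that at least ``min_plateau`` samples remain, and an event
    whose flanking plateau still has fewer than ``min_plateau_floor``
    usable samples is dropped rather than reported with a biased
    magnitude. The returned dL is signed (positive for extension
    increases); classification enforces positivity downstream.

    Raises
    ------
    PreconditionError
        If the force inside the hold is not constant to ``force_tol``; the
        message names the violating sample indices.
    """
    i0, i1 = hold if hold is not None else (0, len(trace))
    F = trace.force[i0:i1]
    x = trace.extension[i0:i1]
    t = trace.time[i0:i1]
    if len(x) < 4:
        return []
    fref = float(np.median(F))
    bad = np.nonzero(np.abs(F - fref) > force_tol)[0]
    if len(bad):
        head = ", ".join(str(i0 + b) for b in bad[:10])
        raise PreconditionError(
            f"force not constant within +/-{force_tol} pN in hold "
            f"[{i0}, {i1}): {len(bad)} samples deviate (first: {head})"
        )
    guard = max(int(round(guard_s * trace.sampling_rate)), 1)
    sigma = _noise_sigma(x)
    # fine-grained localization; the guard only protects the sizing windows
    cps = _find_changepoints(x, sigma, threshold_sigma, min_size=5)

    events: list[EventRecord] = []
    bounds = [0] + cps + [len(x)]
    for j, cp in enumerate(cps):
        left, right = bounds[j], bounds[j + 2]
        gap_pre, gap_post = cp - left, right - cp
        g_pre = guard if gap_pre >= guard + min_plateau else max(
            gap_pre - min_plateau, 3
        )
        g_post = guard if gap_post >= guard + min_plateau else max(
            gap_post - min_plateau, 3
        )
        pre = x[left : cp - g_pre]
        post = x[cp + g_post : right]
        if len(pre) < min_plateau_floor or len(post) < min_plateau_floor:
            continue
        dl = float(np.mean(post) - np.mean(pre))
        if abs(dl) < min_step:
            continue
        se = float(
            np.sqrt(sigma**2 / max(len(pre), 1) + sigma**2 / max(len(post), 1))
        )
        events.append(
            EventRecord(
                molecule_id=molecule_id,
                cycle=cycle,
                event_type="step",
                deltaL=dl,
                force=fref,
                time=float(t[cp]),
                stderr=se,
            )
        )
    return events


# ---------------------------------------------------------------------------
# Ramp unfolding detection (dL_unfold)
# ---------------------------------------------------------------------------

def detect_ramp_unfolding(
    trace: Trace,
    ramp: tuple[int, int] | None = None,
    template: PolymerSegment | None = None,
    kBT: float = KBT,
    min_deltaL: float = 2.0,
    threshold_sigma: float = 8.0,
    guard_s: float = 0.05,
    molecule_id: str = "",
    cycle: int = 0,
) -> EventRecord:
    """Locate an unfolding event on a force ramp and size it by WLC fits.

    The change point is found on the residual of extension against a WLC
    prediction fitted to the early ramp. dL_unfold is the difference of
    contour lengths fitted to the pre- and post-event branches, with the
    standard errors combined in quadrature; the event force is the force at
    the change-point sample. Returns a record of type ``"none"`` when no
    event exceeds the detection threshold or the sized release falls below
    ``min_deltaL`` (sub-threshold axes are genuinely unobservable, not an
    error); fit failures are returned flagged rather than raised.
    """
    if ramp is None:
        seg = next(
            (s for s in (trace.segments or []) if s.get("phase") == "ramp"), None
        )
        if seg is None:
            raise ArgumentError("no ramp annotation and no explicit ramp span")
        ramp = (seg["i0"], seg["i1"])
    i0, i1 = ramp
    F = trace.force[i0:i1]
    x = trace.extension[i0:i1]
    t = trace.time[i0:i1]
    if template is None:
        template = PolymerSegment("double-stranded", 1000.0, DS_PERSISTENCE_NM)

    none_record = EventRecord(
        molecule_id=molecule_id, cycle=cycle, event_type="none",
        deltaL=0.0, force=0.0, time=float(t[0]) if len(t) else 0.0,
    )
    if len(x) < 50:
        return none_record

    n_init = max(int(0.4 * len(x)), 25)
    try:
        pre0 = fit_contour_length(np.column_stack([F[:n_init], x[:n_init]]), template, kBT)
    except FitError as exc:
        return replace(none_record, flags=("fit_failed", str(exc)))
    seg0 = PolymerSegment(
        template.kind, pre0.contour_length, template.persistence_length,
        template.stretch_modulus,
    )
    resid = x - wlc_extension(F, seg0, kBT)
    guard = max(int(round(guard_s * trace.sampling_rate)), 2)
    sigma = _noise_sigma(resid)
    cp, stat = _cusum_stat(resid, min_size=5)
    if cp is None or stat < threshold_sigma * max(sigma, 1e-12):
        return none_record

    pre_sl = slice(0, max(cp - guard, 5))
    post_sl = slice(min(cp + guard, len(x) - 5), len(x))
    try:
        fit_pre = fit_contour_length(
            np.column_stack([F[pre_sl], x[pre_sl]]), template, kBT
        )
        fit_post = fit_contour_length(
            np.column_stack([F[post_sl], x[post_sl]]), template, kBT,
            lc_init=fit_pre.contour_length + 10.0,
        )
    except FitError as exc:
        return replace(
            none_record, event_type="unfold", time=float(t[cp]),
            force=float(F[cp]), flags=("fit_failed", str(exc)),
        )
    dl = fit_post.contour_length - fit_pre.contour_length
    se = float(np.hypot(fit_pre.stderr, fit_post.stderr))
    if dl < min_deltaL:
        return none_record
    return EventRecord(
        molecule_id=molecule_id, cycle=cycle, event_type="unfold",
        deltaL=float(dl), force=float(F[cp]), time=float(t[cp]), stderr=se,
    )


# ---------------------------------------------------------------------------
# Cycle-level classification
# ---------------------------------------------------------------------------

def classify_cycle_events(
    events: Sequence[EventRecord],
    bands: Mapping[str, tuple[float, float]],
) -> list[EventRecord]:
    """Label time-ordered events of one cycle by dL magnitude band.

    ``bands`` maps labels (e.g. ``unfold``, ``unloop_folded``,
    ``unloop_unfolded``) to inclusive (lo, hi) dL windows. An event whose
    dL falls in no band (or whose dL is negative) is labeled ``ambiguous``
    rather than dropped. Event types are rewritten to ``unfold``/``unloop``
    according to the matched label; the unloop-after-unfold vs
    unloop-from-folded distinction is carried in ``label``.
    """
    ordered = sorted(events, key=lambda e: e.time)
    out: list[EventRecord] = []
    for ev in ordered:
        matches = [
            name for name, (lo, hi) in bands.items() if lo <= ev.deltaL <= hi
        ]
        if len(matches) != 1 or ev.deltaL < 0:
            out.append(replace(ev, label="ambiguous"))
            continue
        label = matches[0]
        etype = "unfold" if label.startswith("unfold") else "unloop"
        out.append(replace(ev, label=label, event_type=etype))
    return out


# ---------------------------------------------------------------------------
# Tether QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCReport:
    status: str  # pass | fail | indeterminate
    fitted_Lc: float | None
    expected_Lc: float
    plateau_detected: bool
    rupture_count: int
    detail: str = ""


def validate_tether(
    trace: Trace,
    design: ConstructDesign,
    kBT: float = KBT,
    tolerance: float = 0.15,
    min_force: float = 15.0,
) -> QCReport:
    """Single-tether check against the expected whole-caliper length.

    Fits one WLC to the 5-55 pN portion of the trace and compares the
    contour length to the design value within ``tolerance`` (default 15%,
    generous enough for the folded-structure offset and linker compliance).
    Also flags an overstretching plateau near 65 pN and counts abrupt force
    collapses (ruptures). Returns ``indeterminate`` when the trace never
    reaches ``min_force``.
    """
    expected = construct_contour_length(design)
    F, x = trace.force, trace.extension
    if len(F) == 0 or float(np.max(F)) < min_force:
        return QCReport("indeterminate", None, expected, False, 0,
                        "insufficient force range for contour estimate")
    sel = (F >= 5.0) & (F <= 55.0)
    template = PolymerSegment("double-stranded", expected, DS_PERSISTENCE_NM)
    fitted = None
    detail = ""
    status = "indeterminate"
    if sel.sum() >= 5 and np.ptp(F[sel]) > 1.0:
        try:
            fit = fit_contour_length(np.column_stack([F[sel], x[sel]]), template, kBT)
            fitted = fit.contour_length
            ok = abs(fitted - expected) <= tolerance * expected
            status = "pass" if ok else "fail"
            detail = f"fitted Lc = {fitted:.1f} nm vs expected {expected:.1f} nm"
        except FitError as exc:
            detail = f"contour fit failed: {exc}"
    plateau = bool(
        np.sum(np.abs(F - OVERSTRETCH_PLATEAU_PN) < 3.0) >= 0.02 * trace.sampling_rate
    )
    dF = np.diff(F)
    ruptures = int(np.sum(dF < -20.0))
    return QCReport(status, fitted, expected, plateau, ruptures, detail)
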