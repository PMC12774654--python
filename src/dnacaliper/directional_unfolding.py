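"""Axis assignment and per-axis mechanical-stability statistics.

In a directional-unfolding cycle the ramp-detected unfolding event does not
by itself say which handle the caliper had grabbed; the subsequent
unlooping step at high force does, because each pulling axis has a distinct
expected dL_unloop (~58-68 nm, set by the handle linkers). Assignment is
window-based and deterministic: an observed dL_unloop must fall inside
exactly one axis window, and the paired dL_unfold is cross-checked against
that axis's expected range. Axes whose expected unfolding release sits
below the detection floor are flagged unobservable and excluded from
statistics with an explicit note.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import linregress

from .errors import ArgumentError, AxisAmbiguityError
from .trace_analysis import EventRecord

__all__ = [
    "AxisSpec",
    "AxisMap",
    "AxisAssignment",
    "AxisStats",
    "assign_axis",
    "per_axis_force_stats",
    "observability_check",
]


@dataclass(frozen=True)
class AxisSpec:
    """Expected signature of one pulling axis."""

    expected_unloop: float
    tolerance: float = 2.5
    unfold_range: tuple[float, float] = (2.0, 9.0)
    observable: bool = True

    def __post_init__(self) -> None:
        if not (self.tolerance > 0):
            raise ArgumentError("tolerance must be > 0")

    @property
    def window(self) -> tuple[float, float]:
        return (self.expected_unloop - self.tolerance,
                self.expected_unloop + self.tolerance)


@dataclass(frozen=True)
class AxisMap:
    """Axis label -> expected dL_unloop window and dL_unfold range."""

    axes: Mapping[str, AxisSpec]

    def __post_init__(self) -> None:
        if len(self.axes) < 1:
            raise ArgumentError("axis map must contain >= 1 axis")

    def overlapping_pairs(self) -> list[tuple[str, str]]:
        names = list(self.axes)
        out = []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                lo_a, hi_a = self.axes[a].window
                lo_b, hi_b = self.axes[b].window
                if max(lo_a, lo_b) < min(hi_a, hi_b):
                    out.append((a, b))
        return out

    def validate_windows(self) -> None:
        bad = self.overlapping_pairs()
        if bad:
            raise ArgumentError(f"overlapping axis windows: {bad}")


@dataclass
class AxisAssignment:
    """Outcome of assigning one cycle's event pair to an axis."""

    axis: str | None
    status: str  # assigned | unassigned | mismatch
    unfold: EventRecord | None
    unloop: EventRecord


@dataclass(frozen=True)
class AxisStats:
    axis: str
    n: int
    mean_force: float
    se_force: float | None
    mean_deltaL_unfold: float
    se_deltaL_unfold: float | None
    trend_slope: float | None = None
    trend_se: float | None = None


def assign_axis(
    unfold: EventRecord | None,
    unloop: EventRecord,
    axes: AxisMap,
) -> AxisAssignment:
    """Label one cycle's unfolding event by its unlooping signature.

    The axis is the unique map entry whose dL_unloop window contains the
    observed value. A value inside two windows raises
    :class:`AxisAmbiguityError` (never an arbitrary pick); outside all
    windows the cycle is retained as ``unassigned``. When an unfolding
    event is present and its dL falls outside the matched axis's expected
    range the assignment is kept but flagged ``mismatch``.
    """
    if unfold is not None and unfold.time > unloop.time:
        raise ArgumentError("unloop must follow unfold within the cycle")
    hits = [
        name for name, spec in axes.axes.items()
        if spec.window[0] <= unloop.deltaL <= spec.window[1]
    ]
    if len(hits) > 1:
        raise AxisAmbiguityError(
            f"dL_unloop = {unloop.deltaL:.2f} nm falls in windows of {hits}"
        )
    if not hits:
        return AxisAssignment(None, "unassigned", unfold, unloop)
    axis = hits[0]
    spec = axes.axes[axis]
    status = "assigned"
    if unfold is not None:
        lo, hi = spec.unfold_range
        if not (lo <= unfold.deltaL <= hi):
            status = "mismatch"
        unfold = replace(unfold, label=axis)
    return AxisAssignment(axis, status, unfold, replace(unloop, label=axis))


def per_axis_force_stats(
    assignments: Sequence[AxisAssignment],
    fit_trend: bool = False,
) -> list[AxisStats]:
    """Mean +/- SE of unfolding force and dL_unfold per assigned axis.

    Cycles without an unfolding event or without an assigned axis are
    skipped (they remain in the assignment list for audit). SEs are absent
    (None) for single-event axes. ``fit_trend`` adds an exploratory linear
    fit of force against cycle index per axis.
    """
    if len(assignments) < 1:
        raise ArgumentError("need >= 1 assignment")
    by_axis: dict[str, list[AxisAssignment]] = {}
    for a in assignments:
        if a.axis is not None and a.status == "assigned" and a.unfold is not None:
            by_axis.setdefault(a.axis, []).append(a)
    out = []
    for axis in sorted(by_axis):
        group = by_axis[axis]
        forces = np.array([a.unfold.force for a in group])
        dls = np.array([a.unfold.deltaL for a in group])
        n = len(group)
        se_f = float(np.std(forces, ddof=1) / np.sqrt(n)) if n > 1 else None
        se_d = float(np.std(dls, ddof=1) / np.sqrt(n)) if n > 1 else None
        slope = slope_se = None
        if fit_trend and n > 2:
            cycles = np.array([a.unfold.cycle for a in group], dtype=float)
            if np.ptp(cycles) > 0:
                fit = linregress(cycles, forces)
                slope, slope_se = float(fit.slope), float(fit.stderr)
        out.append(
            AxisStats(
                axis, n, float(np.mean(forces)), se_f,
                float(np.mean(dls)), se_d, slope, slope_se,
            )
        )
    return out


def observability_check(axes: AxisMap, detection_floor: float) -> AxisMap:
    """Flag axes whose expected unfolding release cannot be detected.

    An axis whose entire expected dL_unfold range lies below the detection
    floor produces no resolvable ramp event (the physical situation for a
    pulling direction with near-zero length release); downstream statistics
    exclude such axes explicitly rather than reporting empty bins.
    """
    if not (detection_floor > 0):
        raise ArgumentError("detection_floor must be > 0")
    new = {
        name: replace(spec, observable=spec.unfold_range[1] >= detection_floor)
        for name, spec in axes.axes.items()
    }
    return AxisMap(new)
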