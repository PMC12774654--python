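"""Experiment presets: study conditions for the synthetic experiments.

Each preset bundles a construct design, folded-target geometry, force
protocol and kinetic model that together reproduce the phenomenology of
one caliper experiment class:

* ``na_endtoend`` - sodium buffer, short (9-nt) shearing handle at the 3'
  end; three dL classes (~6 nm unfolding, ~20 nm unlooping from the
  unfolded state, ~26 nm unlooping from the folded state) with an
  end-to-end distance of 2.0 nm under an effective loop length of 28 nm.
* ``k_endtoend`` - potassium buffer: no unfolding at the shearing force and
  a single unlooping class at 27 nm (end-to-end distance 1.0 nm).
* ``k_multisite`` - four labeled sites with well-separated dL classes
  (27/24/21/18 nm), the hybrid-1-like generating geometry.
* ``na_directional`` - long (16-nt) shearing handles; 6 pN/s ramps to 45 pN
  followed by a 58 pN unlooping jump; four axes with distinct
  dL_unloop signatures (48/58/63/68 nm), one of which releases too little
  length on unfolding to be observable.

Kinetic rates are not observables of the distance measurements; the hold
rates are chosen so unlooping completes well within the 2-s shearing hold
and, in sodium, unfolding precedes unlooping in roughly a third of cycles.
Ramp unfolding kinetics are calibrated by root finding so the Bell-model
mean unfolding force at 6 pN/s equals the per-axis target (21 pN along the
end-to-end axis, slightly higher through the loops).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .constants import KBT, SS_PERSISTENCE_NM
from .errors import ArgumentError
from .conformation_assignment import ConformationModel
from .directional_unfolding import AxisMap, AxisSpec
from .polymer_mechanics import ConstructDesign, PolymerSegment, wlc_extension
from .rng import rng_stream
from .simulator import (
    BellTransition,
    ConformationGeometry,
    ForceProtocol,
    KineticModel,
    NoiseSpec,
    calibrate_bell_k0,
)

__all__ = [
    "ExperimentPreset",
    "get_preset",
    "PRESET_NAMES",
    "ladder_slope_per_nt",
    "simulate_calibration_ladder",
    "builtin_candidates",
    "make_mini_pdb",
    "directional_axis_map",
]

LOOP_L0_NM = 28.0  # effective loop length at the 10 pN shearing force


def _bell_with_rate_at(force: float, rate: float, dx: float,
                       kBT: float = KBT) -> BellTransition:
    """Bell transition with a prescribed rate at a given force."""
    return BellTransition(rate * math.exp(-force * dx / kBT), dx)


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------

def design_endtoend() -> ConstructDesign:
    return ConstructDesign(
        dsdna_handle_bp=2820, loop_nt=73, grabbing_handle_nt=30,
        shearing_handle_nt={"3p": 9}, labeled_sites=("3p",),
    )


def design_multisite() -> ConstructDesign:
    return ConstructDesign(
        dsdna_handle_bp=2820, loop_nt=73, grabbing_handle_nt=30,
        shearing_handle_nt={"3p": 9, "loop1": 9, "loop2": 9, "loop3": 9},
        labeled_sites=("3p", "loop1", "loop2", "loop3"),
    )


def design_directional() -> ConstructDesign:
    return ConstructDesign(
        dsdna_handle_bp=2820, loop_nt=120, grabbing_handle_nt=30,
        shearing_handle_nt={"end_3p": 16, "loop_mid": 16, "loop_3p": 16,
                            "loop_5p": 16},
        labeled_sites=("end_3p", "loop_mid", "loop_3p", "loop_5p"),
    )


# ---------------------------------------------------------------------------
# Preset bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentPreset:
    name: str
    design: ConstructDesign
    geometry: ConformationGeometry
    protocol: ForceProtocol
    kinetics: KineticModel
    bands: Mapping[str, tuple[float, float]]
    expected_k: int
    n_molecules: int
    axis_map: AxisMap | None = None
    #: generating truths the simulator guarantees (for scoring only)
    truth: Mapping[str, float] = field(default_factory=dict)


def _preset_na_endtoend(n_molecules=16, cycles=30) -> ExperimentPreset:
    geometry = ConformationGeometry(
        name="antiparallel-like",
        site_distance={"3p": 2.0},
        loop_extension_nm=LOOP_L0_NM,
        unfold_release={"3p": 6.0},
    )
    kinetics = KineticModel(
        unfold={"3p": _bell_with_rate_at(10.0, 0.8, 1.5)},
        unloop=_bell_with_rate_at(10.0, 2.0, 2.0),
    )
    protocol = ForceProtocol(mode="force_jump", n_cycles=cycles)
    bands = {"unfold": (2.0, 9.0), "unloop_unfolded": (17.0, 23.0),
             "unloop_folded": (23.5, 29.0)}
    return ExperimentPreset(
        "na_endtoend", design_endtoend(), geometry, protocol, kinetics,
        bands, expected_k=3, n_molecules=n_molecules,
        truth={"deltaL_folded": 26.0, "distance": 2.0, "L0": LOOP_L0_NM},
    )


def _preset_k_endtoend(n_molecules=10, cycles=30) -> ExperimentPreset:
    geometry = ConformationGeometry(
        name="potassium-conformer",
        site_distance={"3p": 1.0},
        loop_extension_nm=LOOP_L0_NM,
    )
    kinetics = KineticModel(unloop=_bell_with_rate_at(10.0, 2.0, 2.0))
    protocol = ForceProtocol(mode="force_jump", n_cycles=cycles)
    bands = {"unloop_folded": (23.5, 30.0)}
    return ExperimentPreset(
        "k_endtoend", design_endtoend(), geometry, protocol, kinetics,
        bands, expected_k=1, n_molecules=n_molecules,
        truth={"deltaL_folded": 27.0, "distance": 1.0, "L0": LOOP_L0_NM},
    )


MULTISITE_DELTAL = {"3p": 27.0, "loop1": 18.0, "loop2": 21.0, "loop3": 24.0}


def _preset_k_multisite(n_molecules=21, cycles=30) -> ExperimentPreset:
    geometry = ConformationGeometry(
        name="hybrid1-like",
        site_distance={s: LOOP_L0_NM - dl for s, dl in MULTISITE_DELTAL.items()},
        loop_extension_nm=LOOP_L0_NM,
    )
    kinetics = KineticModel(unloop=_bell_with_rate_at(10.0, 2.0, 2.0))
    protocol = ForceProtocol(mode="force_jump", n_cycles=cycles)
    bands = {"unloop_folded": (15.0, 30.0)}
    return ExperimentPreset(
        "k_multisite", design_multisite(), geometry, protocol, kinetics,
        bands, expected_k=4, n_molecules=n_molecules,
        truth=dict(MULTISITE_DELTAL),
    )


DIRECTIONAL_UNLOOP = {"end_3p": 58.0, "loop_mid": 63.0, "loop_3p": 68.0,
                      "loop_5p": 48.0}
DIRECTIONAL_RELEASE = {"end_3p": 6.0, "loop_mid": 8.0, "loop_3p": 8.5,
                       "loop_5p": 1.0}
DIRECTIONAL_MEAN_FORCE = {"end_3p": 21.0, "loop_mid": 23.0, "loop_3p": 23.5,
                          "loop_5p": 22.0}


def directional_axis_map(tolerance: float = 2.5) -> AxisMap:
    axes = {}
    for name, dl in DIRECTIONAL_UNLOOP.items():
        rel = DIRECTIONAL_RELEASE[name]
        # +/-30% covers detection scatter while keeping the sub-threshold
        # axis's expected range honestly below the detection floor
        axes[name] = AxisSpec(
            expected_unloop=dl, tolerance=tolerance,
            unfold_range=(0.7 * rel, 1.3 * rel),
        )
    return AxisMap(axes)


def _preset_na_directional(n_molecules=3, cycles=40) -> ExperimentPreset:
    geometry = ConformationGeometry(
        name="antiparallel-like-directional",
        site_distance={"end_3p": 2.0, "loop_mid": 5.0, "loop_3p": 6.0,
                       "loop_5p": 3.0},
        unloop_deltaL=dict(DIRECTIONAL_UNLOOP),
        unfold_release=dict(DIRECTIONAL_RELEASE),
        loop_extension_nm=70.0,
    )
    unfold = {
        axis: calibrate_bell_k0(mean, dx=1.5, ramp_rate=6.0)
        for axis, mean in DIRECTIONAL_MEAN_FORCE.items()
    }
    kinetics = KineticModel(
        unfold=unfold,
        unloop=_bell_with_rate_at(58.0, 2.0, 2.0),
    )
    protocol = ForceProtocol(
        mode="ramp_then_jump", low_force=0.5, hold_low_s=0.3,
        ramp_start=1.0, ramp_ceiling=45.0, ramp_rate=6.0,
        jump_force=58.0, jump_hold_s=2.0, n_cycles=cycles,
    )
    bands = {"unfold": (2.0, 12.0)}
    return ExperimentPreset(
        "na_directional", design_directional(), geometry, protocol, kinetics,
        bands, expected_k=3, n_molecules=n_molecules,
        axis_map=directional_axis_map(),
        truth={**{f"unloop_{k}": v for k, v in DIRECTIONAL_UNLOOP.items()},
               **{f"force_{k}": v for k, v in DIRECTIONAL_MEAN_FORCE.items()}},
    )


_PRESETS: dict[str, Callable[..., ExperimentPreset]] = {
    "na_endtoend": _preset_na_endtoend,
    "k_endtoend": _preset_k_endtoend,
    "k_multisite": _preset_k_multisite,
    "na_directional": _preset_na_directional,
}
PRESET_NAMES = tuple(_PRESETS)


def get_preset(name: str, n_molecules: int | None = None,
               cycles: int | None = None) -> ExperimentPreset:
    if name not in _PRESETS:
        raise ArgumentError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    kwargs = {}
    if n_molecules is not None:
        kwargs["n_molecules"] = n_molecules
    if cycles is not None:
        kwargs["cycles"] = cycles
    return _PRESETS[name](**kwargs)


def default_noise(seed: int, sigma_x: float = 2.0,
                  sigma_deltaL: float = 0.5) -> NoiseSpec:
    return NoiseSpec(sigma_x=sigma_x, sigma_deltaL=sigma_deltaL, seed=seed)


# ---------------------------------------------------------------------------
# Calibration ladder
# ---------------------------------------------------------------------------

def ladder_slope_per_nt(force: float = 10.0, kBT: float = KBT) -> float:
    """Extension per analyte nucleotide at the measurement force (nm/nt)."""
    per_nt = PolymerSegment("single-stranded", 0.59, SS_PERSISTENCE_NM)
    return float(wlc_extension(force, per_nt, kBT))


def simulate_calibration_ladder(
    seed: int,
    L0: float = LOOP_L0_NM,
    lengths_nt=(10, 20, 30, 40, 50),
    reps: int = 10,
    sigma: float = 0.3,
    force: float = 10.0,
) -> np.ndarray:
    """Known-length analyte ladder: (length nt, observed dL nm) pairs.

    The generating law is dL = L0 - slope*length with the per-nucleotide
    slope from ssDNA elasticity at the measurement force, plus Gaussian
    measurement noise; regression of these pairs back to zero length is
    the L0 calibration the pipeline uses.
    """
    rng = rng_stream(seed, "ladder")
    slope = ladder_slope_per_nt(force)
    rows = []
    for n in lengths_nt:
        dl = L0 - slope * n + rng.normal(0.0, sigma, size=reps)
        rows.extend((float(n), float(v)) for v in dl)
    return np.array(rows)


# ---------------------------------------------------------------------------
# Candidate conformation tables
# ---------------------------------------------------------------------------

def builtin_candidates(sigma: float = 0.5) -> list[ConformationModel]:
    """Four candidate conformations in dL space for the multi-site assay.

    These are synthetic stand-in tables consistent with the generating
    multi-site geometry (``hybrid1-like`` is the generating one); real
    analyses should derive expectations from deposited coordinates via
    :func:`dnacaliper.conformation_assignment.expected_sites_from_structure`
    and supply them as editable config.
    """
    tables = {
        "hybrid1-like": {"3p": 27.0, "loop1": 18.0, "loop2": 21.0,
                         "loop3": 24.0},
        "hybrid2-like": {"3p": 27.0, "loop1": 20.0, "loop2": 23.5,
                         "loop3": 22.0},
        "parallel-like": {"3p": 25.0, "loop1": 19.5, "loop2": 21.0,
                          "loop3": 26.0},
        "antiparallel-like": {"3p": 26.0, "loop1": 16.5, "loop2": 22.5,
                              "loop3": 24.0},
    }
    return [ConformationModel(name, exp, "deltaL", sigma, "synthetic table")
            for name, exp in tables.items()]


# ---------------------------------------------------------------------------
# Synthetic coordinate fixture
# ---------------------------------------------------------------------------

MINI_PDB_SITES = {  # Angstrom coordinates; reference at the origin
    "ref": (0.0, 0.0, 0.0),
    "site1": (0.0, 0.0, 20.0),
    "site2": (40.0, 0.0, 0.0),
    "site3": (0.0, 70.0, 0.0),
    "site4": (60.0, 0.0, 80.0),
}


def make_mini_pdb(path) -> dict[str, float]:
    """Write a synthetic mini-PDB of labeled sites with known distances.

    One phosphorus atom per site on chain A; returns the site -> distance
    (nm) truth table implied by the coordinates.
    """
    import gemmi

    st = gemmi.Structure()
    st.name = "synthetic mini caliper target"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, (name, pos) in enumerate(MINI_PDB_SITES.items(), start=1):
        res = gemmi.Residue()
        res.name = "DT"
        res.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = "P"
        atom.element = gemmi.Element("P")
        atom.pos = gemmi.Position(*pos)
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
    ref = np.array(MINI_PDB_SITES["ref"])
    return {
        name: float(np.linalg.norm(np.array(p) - ref) / 10.0)
        for name, p in MINI_PDB_SITES.items()
        if name != "ref"
    }
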