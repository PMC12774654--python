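"""End-to-end pipeline drivers and fixture generation.

``run_conformation_pipeline`` executes the distance-measurement chain
(simulate or load traces -> step detection -> per-cycle classification ->
per-molecule Gaussian fitting -> per-molecule averaging -> bootstrap ->
loop calibration and d = L0 - dL conversion -> candidate assignment) and
returns a machine-readable report. ``run_unfolding_pipeline`` does the
same for the directional-unfolding chain (ramp detection -> unloop step ->
axis assignment -> per-axis force statistics). Both are deterministic
under a fixed seed; a stage failure produces a report naming the stage and
carrying whatever partial outputs exist.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .conformation_assignment import (
    aggregate_structure_probability,
    molecule_structure_likelihood,
    rmsd_to_candidate,
)
from .directional_unfolding import (
    assign_axis,
    observability_check,
    per_axis_force_stats,
)
from .distance_inference import (
    bootstrap_peak_uncertainty,
    calibrate_loop_length,
    deltaL_to_distance,
    fit_molecule_peaks,
    per_molecule_average_distribution,
)
from .errors import ConfigurationError, DncError
from .io import RunConfig, config_hash, read_trace, write_trace
from .presets import (
    builtin_candidates,
    default_noise,
    get_preset,
    make_mini_pdb,
    simulate_calibration_ladder,
)
from .simulator import (
    MoleculeObservations,
    simulate_force_jump_trace,
    simulate_ramp_trace,
)
from .trace_analysis import (
    classify_cycle_events,
    detect_constant_force_steps,
    detect_ramp_unfolding,
    events_to_frame,
)

log = logging.getLogger("dnacaliper")

__all__ = [
    "run_conformation_pipeline",
    "run_unfolding_pipeline",
    "generate_fixtures",
    "detect_and_classify_trace",
]

FIXTURE_PRESETS = ("na_endtoend", "k_endtoend", "k_multisite",
                   "na_directional", "calibration_ladder", "mini_pdb")


def _peak_dict(p) -> dict:
    return {"mean_nm": p.mean, "sigma_nm": p.sigma, "weight": p.weight,
            "sem_nm": p.stderr, "n": p.n}


def _versions() -> dict:
    import sklearn
    import scipy

    return {
        "dnacaliper": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
    }


def detect_and_classify_trace(trace, bands, min_step=2.0, molecule_id=""):
    """Step detection + band classification over every high-force hold."""
    events = []
    for seg in trace.segments or []:
        if seg.get("phase") not in ("high", "jump"):
            continue
        found = detect_constant_force_steps(
            trace, (seg["i0"], seg["i1"]), min_step=min_step,
            molecule_id=molecule_id or trace.meta.get("molecule_id", ""),
            cycle=seg["cycle"],
        )
        events.extend(classify_cycle_events(found, bands))
    return events


def _simulate_molecules(preset, config: RunConfig):
    """One (trace, log) pair per molecule; molecule streams are independent."""
    out = []
    noise = default_noise(config.seed, config.sigma_x_nm, config.sigma_deltaL_nm)
    for m in range(preset.n_molecules):
        mol_id = f"mol{m:03d}"
        if preset.protocol.mode == "force_jump":
            tr, gt = simulate_force_jump_trace(
                preset.design, preset.geometry, preset.protocol,
                preset.kinetics, noise, molecule_id=mol_id, kBT=config.kBT,
            )
        else:
            tr, gt = simulate_ramp_trace(
                preset.design, preset.geometry, preset.protocol,
                preset.kinetics, noise, molecule_id=mol_id, kBT=config.kBT,
            )
        out.append((mol_id, tr, gt))
    return out


# ---------------------------------------------------------------------------
# Conformation / distance pipeline
# ---------------------------------------------------------------------------

def run_conformation_pipeline(config: RunConfig) -> dict:
    """Run the distance-measurement chain and return the run report."""
    report: dict = {
        "status": "ok",
        "pipeline": "conformation",
        "config": asdict(config),
        "config_hash": config_hash(config),
        "versions": _versions(),
        "stages": {},
        "warnings": [],
    }
    stages = report["stages"]
    stage = "setup"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            stage = "ingest"
            log.info("[%s] stage=%s", report["config_hash"], stage)
            if config.experiment == "files":
                traces = []
                for i, p in enumerate(config.trace_paths):
                    tr = read_trace(p)
                    traces.append((tr.meta.get("molecule_id", f"mol{i:03d}"),
                                   tr, None))
                if not traces:
                    raise ConfigurationError("no input traces")
                preset = get_preset("k_endtoend")  # bands/k fallback
            else:
                preset = get_preset(config.experiment,
                                    n_molecules=config.n_molecules,
                                    cycles=config.cycles_per_molecule)
                traces = _simulate_molecules(preset, config)
            stages["ingest"] = {"n_molecules": len(traces),
                                "n_cycles": preset.protocol.n_cycles}

            stage = "detect"
            log.info("[%s] stage=%s", report["config_hash"], stage)
            molecules = []
            n_events = n_ambig = 0
            for mol_id, tr, _gt in traces:
                events = detect_and_classify_trace(
                    tr, preset.bands, config.min_step_nm, mol_id
                )
                keep = [e for e in events if e.label != "ambiguous"]
                n_events += len(events)
                n_ambig += len(events) - len(keep)
                if keep:
                    molecules.append(
                        MoleculeObservations(
                            molecule_id=mol_id,
                            condition=preset.name,
                            cycles=np.array([e.cycle for e in keep]),
                            deltaL=np.array([e.deltaL for e in keep]),
                            labels=[e.label or "" for e in keep],
                        )
                    )
            stages["detect"] = {"n_events": n_events, "n_ambiguous": n_ambig,
                                "n_molecules_with_events": len(molecules)}
            if not molecules:
                raise ConfigurationError("no events detected in any trace")

            stage = "infer"
            log.info("[%s] stage=%s", report["config_hash"], stage)
            k = (preset.expected_k if config.expected_k == "auto"
                 else config.expected_k)
            mol_fits = [
                fit_molecule_peaks(m, expected_k=k, seed=config.seed)
                for m in molecules
            ]
            pop = per_molecule_average_distribution(
                mol_fits, expected_k=k, seed=config.seed
            )
            boot = bootstrap_peak_uncertainty(
                pop, n_iter=config.bootstrap_iters, seed=config.seed
            )
            stages["infer"] = {
                "k": k,
                "molecule_peaks": {
                    mf.molecule_id: [_peak_dict(p) for p in mf.peaks]
                    for mf in mol_fits
                },
                "population_peaks": [_peak_dict(p) for p in pop.peaks],
                "bootstrap": {
                    "n_iter": boot.n_iter,
                    "peak_se_nm": boot.peak_se.tolist(),
                    "peak_ci_nm": boot.peak_ci.tolist(),
                    "failure_rate": boot.failure_rate,
                    "flagged": boot.flagged,
                },
            }

            if config.calibrate and config.experiment in ("na_endtoend",
                                                          "k_endtoend"):
                stage = "calibrate"
                log.info("[%s] stage=%s", report["config_hash"], stage)
                ladder = simulate_calibration_ladder(config.seed)
                cal = calibrate_loop_length(ladder)
                stages["calibrate"] = {
                    "L0_nm": cal.L0, "se_L0_nm": cal.se_L0,
                    "slope_nm_per_nt": cal.slope, "se_slope": cal.se_slope,
                    "residual_rms_nm": cal.residual_rms, "n": cal.n,
                }
                stage = "distance"
                folded = max(pop.peaks, key=lambda p: p.mean)
                d, se = deltaL_to_distance(folded.mean, cal, folded.stderr)
                stages["distance"] = {
                    "deltaL_folded_nm": folded.mean,
                    "deltaL_sem_nm": folded.stderr,
                    "d_nm": d, "se_nm": se,
                }

            if config.experiment == "k_multisite":
                stage = "assign"
                log.info("[%s] stage=%s", report["config_hash"], stage)
                if config.candidates_path:
                    from .conformation_assignment import candidates_from_yaml

                    candidates = candidates_from_yaml(config.candidates_path)
                else:
                    candidates = builtin_candidates()
                per_mol = [
                    molecule_structure_likelihood(m.deltaL, candidates)
                    for m in molecules
                ]
                measured_sorted = sorted(p.mean for p in pop.peaks)
                ses_sorted = [p.stderr for p in
                              sorted(pop.peaks, key=lambda p: p.mean)]
                rmsd = {}
                for cand in candidates:
                    ordered_sites = sorted(cand.expected,
                                           key=cand.expected.get)
                    measured = {
                        s: (measured_sorted[i], ses_sorted[i])
                        for i, s in enumerate(ordered_sites)
                        if i < len(measured_sorted)
                    }
                    rmsd[cand.name] = rmsd_to_candidate(measured, cand)
                assignment = aggregate_structure_probability(per_mol, rmsd)
                stages["assign"] = {
                    "averaged_probability": assignment.averaged_probability,
                    "best_candidate": assignment.best_candidate,
                    "lowest_rmsd": min(rmsd, key=lambda n: rmsd[n][0]),
                    "rmsd_nm": {n: list(v) for n, v in rmsd.items()},
                }

            report["warnings"] = [str(w.message) for w in caught]
    except (DncError, ValueError, RuntimeError, OSError) as exc:
        report["status"] = "failed"
        report["stage_failed"] = stage
        report["error"] = str(exc)
    return report


# ---------------------------------------------------------------------------
# Directional-unfolding pipeline
# ---------------------------------------------------------------------------

def run_unfolding_pipeline(config: RunConfig) -> dict:
    """Run the multidirectional-unfolding chain and return the run report."""
    report: dict = {
        "status": "ok",
        "pipeline": "unfolding",
        "config": asdict(config),
        "config_hash": config_hash(config),
        "versions": _versions(),
        "stages": {},
        "warnings": [],
    }
    stages = report["stages"]
    stage = "setup"
    try:
        if config.experiment != "na_directional":
            raise ConfigurationError(
                "unfolding pipeline requires the na_directional experiment"
            )
        preset = get_preset(config.experiment,
                            n_molecules=config.n_molecules,
                            cycles=config.cycles_per_molecule)
        axes = observability_check(preset.axis_map, config.detection_floor_nm)
        axes.validate_windows()

        stage = "ingest"
        log.info("[%s] stage=%s", report["config_hash"], stage)
        traces = _simulate_molecules(preset, config)
        stages["ingest"] = {"n_molecules": len(traces),
                            "n_cycles": preset.protocol.n_cycles}

        stage = "detect"
        log.info("[%s] stage=%s", report["config_hash"], stage)
        assignments = []
        counts = {"assigned": 0, "unassigned": 0, "mismatch": 0,
                  "no_unloop": 0, "no_unfold": 0}
        for mol_id, tr, _gt in traces:
            ramps = {s["cycle"]: (s["i0"], s["i1"])
                     for s in tr.segments if s["phase"] == "ramp"}
            jumps = {s["cycle"]: (s["i0"], s["i1"])
                     for s in tr.segments if s["phase"] == "jump"}
            for cycle, span in ramps.items():
                unfold = detect_ramp_unfolding(
                    tr, span, kBT=config.kBT,
                    min_deltaL=config.detection_floor_nm,
                    molecule_id=mol_id, cycle=cycle,
                )
                # strict plateau requirement: a mis-sized unloop step could
                # put the cycle in the wrong axis window, while a dropped
                # one only costs a cycle
                steps = detect_constant_force_steps(
                    tr, jumps[cycle], min_step=config.min_step_nm,
                    min_plateau_floor=30, molecule_id=mol_id, cycle=cycle,
                )
                if not steps:
                    counts["no_unloop"] += 1
                    continue
                unloop = max(steps, key=lambda e: abs(e.deltaL))
                if unfold.event_type != "unfold":
                    counts["no_unfold"] += 1
                    continue
                a = assign_axis(unfold, unloop, axes)
                counts[a.status] = counts.get(a.status, 0) + 1
                assignments.append(a)
        stages["detect"] = dict(counts)
        if not assignments:
            raise ConfigurationError("no unfolding/unlooping pairs detected")

        stage = "stats"
        log.info("[%s] stage=%s", report["config_hash"], stage)
        stats = per_axis_force_stats(assignments)
        observable = {name: spec.observable for name, spec in axes.axes.items()}
        excluded = sorted(n for n, obs in observable.items() if not obs)
        stats = [s for s in stats if observable.get(s.axis, True)]
        stages["stats"] = {
            "axes": [
                {
                    "axis": s.axis, "n": s.n,
                    "mean_force_pN": s.mean_force,
                    "se_force_pN": s.se_force,
                    "mean_deltaL_unfold_nm": s.mean_deltaL_unfold,
                    "se_deltaL_unfold_nm": s.se_deltaL_unfold,
                }
                for s in stats
            ],
            "n_observed_axes": len(stats),
            "observability": observable,
            "note": (f"axes excluded as unobservable below "
                     f"{config.detection_floor_nm} nm: {excluded}"
                     if excluded else ""),
        }
    except (DncError, ValueError, RuntimeError, OSError) as exc:
        report["status"] = "failed"
        report["stage_failed"] = stage
        report["error"] = str(exc)
    return report


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def generate_fixtures(preset_name: str, seed: int, out_dir) -> list[Path]:
    """Write small synthetic datasets for a named preset.

    Traces and ground-truth logs for the simulation presets, a known-L0
    analyte ladder for ``calibration_ladder``, and a synthetic coordinate
    file with its distance truth table for ``mini_pdb``.
    """
    if preset_name not in FIXTURE_PRESETS:
        raise ConfigurationError(
            f"unknown fixture preset {preset_name!r}; "
            f"choose from {FIXTURE_PRESETS}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if preset_name == "calibration_ladder":
        ladder = simulate_calibration_ladder(seed)
        path = out / "calibration_ladder.tsv"
        pd.DataFrame(ladder, columns=["length_nt", "deltaL_nm"]).to_csv(
            path, sep="\t", index=False
        )
        truth = out / "calibration_ladder.truth.yaml"
        from .presets import LOOP_L0_NM, ladder_slope_per_nt

        truth.write_text(yaml.safe_dump(
            {"L0_nm": LOOP_L0_NM, "slope_nm_per_nt": ladder_slope_per_nt()}
        ))
        return [path, truth]

    if preset_name == "mini_pdb":
        path = out / "mini_sites.pdb"
        distances = make_mini_pdb(path)
        truth = out / "mini_sites.truth.tsv"
        pd.DataFrame(
            {"site": list(distances), "distance_nm": list(distances.values())}
        ).to_csv(truth, sep="\t", index=False)
        return [path, truth]

    n_mol, cycles = (1, 6) if preset_name == "na_directional" else (2, 8)
    preset = get_preset(preset_name, n_molecules=n_mol, cycles=cycles)
    config = RunConfig(experiment=preset_name, seed=seed,
                       n_molecules=n_mol, cycles_per_molecule=cycles)
    for mol_id, tr, gt in _simulate_molecules(preset, config):
        tpath = out / f"{preset_name}_{mol_id}.trace.tsv"
        write_trace(tr, tpath)
        gpath = out / f"{preset_name}_{mol_id}.truth.tsv"
        gt.to_csv(gpath, sep="\t", index=False)
        written.extend([tpath, gpath])
    return written
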