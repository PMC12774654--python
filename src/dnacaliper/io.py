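"""File formats and run configuration.

On-disk conventions (bit-stable across platforms): tab-separated values,
'#'-prefixed metadata header, UTF-8, '.' decimal separator. Units are fixed
at the interface: nm, pN, s, Hz; coordinate files are in Angstrom and
converted at the boundary (0.1 nm/A).
"""
from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError
from .trace_analysis import Trace

__all__ = [
    "RunConfig",
    "write_trace",
    "read_trace",
    "write_events",
    "read_events",
    "read_structure_coords",
    "load_config",
    "config_hash",
    "trace_meta_hash",
]

TRACE_COLUMNS = ["time_s", "force_pN", "extension_nm"]
EVENT_COLUMNS = ["molecule_id", "cycle", "type", "deltaL_nm", "force_pN",
                 "time_s", "label"]


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

def trace_meta_hash(meta: dict) -> str:
    """Stable hash of trace metadata (used to tie files to their runs)."""
    payload = json.dumps(meta, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_trace(trace: Trace, path) -> None:
    """Write a trace as TSV with a '#' metadata header."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("# dnc-trace v1\n")
        fh.write(f"# sampling_rate_hz: {trace.sampling_rate!r}\n")
        meta = dict(trace.meta)
        fh.write(f"# meta: {json.dumps(meta, sort_keys=True, default=str)}\n")
        fh.write(f"# meta_hash: {trace_meta_hash(meta)}\n")
        if trace.segments is not None:
            fh.write(f"# segments: {json.dumps(trace.segments)}\n")
        fh.write("\t".join(TRACE_COLUMNS) + "\n")
        np.savetxt(fh, np.column_stack([trace.time, trace.force,
                                        trace.extension]),
                   fmt="%.9g", delimiter="\t")


def read_trace(path) -> Trace:
    """Parse a trace TSV, validating header, columns and the time grid.

    Malformed data rows are reported with their 1-based line numbers;
    missing columns and non-monotone time raise :class:`FormatError`.
    """
    path = Path(path)
    header: dict[str, str] = {}
    data_lines: list[str] = []
    first_data_line = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    header[key.strip()] = val.strip()
                continue
            if first_data_line is None:
                first_data_line = lineno
            data_lines.append(line)
    if not data_lines:
        raise FormatError(f"{path}: no data rows")
    if "sampling_rate_hz" not in header:
        raise FormatError(f"{path}: header missing sampling_rate_hz")
    cols = data_lines[0].split("\t")
    missing = [c for c in TRACE_COLUMNS if c not in cols]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    try:
        df = pd.read_csv(
            _io.StringIO("\n".join(data_lines)), sep="\t", dtype=float,
        )
    except ValueError as exc:
        raise FormatError(f"{path}: malformed rows near line "
                          f"{first_data_line}: {exc}") from exc
    bad = df[TRACE_COLUMNS].isna().any(axis=1)
    if bad.any():
        lines = [first_data_line + 1 + int(i) for i in np.nonzero(bad.to_numpy())[0][:10]]
        raise FormatError(f"{path}: malformed rows at lines {lines}")
    t = df["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: time is not strictly increasing")
    meta = json.loads(header.get("meta", "{}"))
    segments = json.loads(header["segments"]) if "segments" in header else None
    return Trace(
        t, df["force_pN"].to_numpy(), df["extension_nm"].to_numpy(),
        float(header["sampling_rate_hz"]), meta=meta, segments=segments,
    )


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

def write_events(frame: pd.DataFrame, path) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"event table missing columns {missing}")
    frame.to_csv(path, sep="\t", index=False, columns=EVENT_COLUMNS)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df["label"] = df["label"].fillna("")
    return df


# ---------------------------------------------------------------------------
# Coordinates
# ---------------------------------------------------------------------------

def read_structure_coords(path):
    """Read atomic coordinates (PDB/mmCIF via gemmi), preserving MODEL blocks.

    Returns a ``gemmi.Structure``; raises :class:`FormatError` when the
    file contains no atoms.
    """
    import gemmi

    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse coordinates: {exc}") from exc
    n_atoms = sum(m.count_atom_sites() for m in st)
    if n_atoms == 0:
        raise FormatError(f"{path}: no ATOM/HETATM records")
    return st


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one pipeline run.

    ``experiment`` selects a simulation preset (or ``"files"`` to analyse
    supplied traces). Every numeric field is checked against the
    preconditions of the module that consumes it; unknown keys in a config
    file are rejected outright.
    """

    experiment: str
    seed: int = 0
    n_molecules: int | None = None
    cycles_per_molecule: int | None = None
    expected_k: int | str = "auto"
    bootstrap_iters: int = 10_000
    min_step_nm: float = 2.0
    detection_floor_nm: float = 2.0
    sigma_x_nm: float = 2.0
    sigma_deltaL_nm: float = 0.5
    kBT: float = 4.114
    axis_tolerance_nm: float = 2.5
    calibrate: bool = True
    trace_paths: tuple[str, ...] = ()
    candidates_path: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        known = {
            "na_endtoend", "k_endtoend", "k_multisite", "na_directional",
            "files",
        }
        if self.experiment not in known:
            raise ConfigurationError(
                f"unknown experiment {self.experiment!r}; choose from {sorted(known)}"
            )
        if self.bootstrap_iters < 100:
            raise ConfigurationError("bootstrap_iters must be >= 100")
        for name in ("min_step_nm", "detection_floor_nm", "axis_tolerance_nm",
                     "kBT"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("sigma_x_nm", "sigma_deltaL_nm"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_molecules is not None and self.n_molecules < 1:
            raise ConfigurationError("n_molecules must be >= 1")
        if self.cycles_per_molecule is not None and self.cycles_per_molecule < 1:
            raise ConfigurationError("cycles_per_molecule must be >= 1")
        if self.expected_k != "auto":
            if not isinstance(self.expected_k, int) or self.expected_k < 1:
                raise ConfigurationError("expected_k must be 'auto' or int >= 1")
        if self.experiment == "files" and not self.trace_paths:
            raise ConfigurationError("experiment 'files' requires trace_paths")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    allowed = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - allowed)
    if unknown:
        raise ConfigurationError(f"{path}: unknown config keys {unknown}")
    if "trace_paths" in raw:
        raw["trace_paths"] = tuple(raw["trace_paths"])
    return RunConfig(**raw)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
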