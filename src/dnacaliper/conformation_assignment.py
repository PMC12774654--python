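"""Candidate-structure comparison: RMSD and mixture-likelihood assignment.

Measured peak positions (one per labeled site) are compared with the
distances expected for each candidate folded conformation, either by RMSD
with first-order error propagation, or by a per-molecule Gaussian-mixture
likelihood: each candidate defines a density that is a uniform mixture of
Gaussians centered on its expected per-site values with a fixed width
(0.5 nm, the observed spread of caliper measurements). Likelihoods are
normalised across candidates per molecule and averaged over molecules to
give a population-level probability per structure.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import ArgumentError, DomainError

__all__ = [
    "ConformationModel",
    "AssignmentReport",
    "expected_sites_from_structure",
    "candidates_from_yaml",
    "rmsd_to_candidate",
    "molecule_structure_likelihood",
    "aggregate_structure_probability",
]

LIKELIHOOD_SIGMA_NM = 0.5


@dataclass(frozen=True)
class ConformationModel:
    """A named candidate structure with expected per-site values.

    ``space`` declares whether the expectations are absolute distances or
    dL values; candidates being compared must share the space. ``sigma``
    is the fixed Gaussian width of the likelihood model.
    """

    name: str
    expected: Mapping[str, float]
    space: str = "deltaL"  # "deltaL" | "distance"
    sigma: float = LIKELIHOOD_SIGMA_NM
    source: str = "user table"

    def __post_init__(self) -> None:
        if len(self.expected) < 1:
            raise ArgumentError("candidate needs >= 1 site")
        if not (self.sigma > 0):
            raise DomainError("likelihood sigma must be > 0")
        if self.space not in ("deltaL", "distance"):
            raise ArgumentError(f"unknown space {self.space!r}")

    def mapped_to_deltaL(self, site_offsets: Mapping[str, float]) -> "ConformationModel":
        """Map distance-space expectations into dL space.

        ``site_offsets`` gives, per site, the effective loop length plus
        linker contribution at the measurement force; the expected dL is
        offset - distance.
        """
        if self.space != "distance":
            raise ArgumentError("model is already in dL space")
        missing = set(self.expected) - set(site_offsets)
        if missing:
            raise ArgumentError(f"missing offsets for sites: {sorted(missing)}")
        new = {s: site_offsets[s] - v for s, v in self.expected.items()}
        return ConformationModel(self.name, new, "deltaL", self.sigma, self.source)


@dataclass
class AssignmentReport:
    """Aggregated structure assignment across molecules."""

    candidates: tuple[str, ...]
    averaged_probability: dict[str, float]
    best_candidate: str
    per_molecule: pd.DataFrame
    rmsd: dict[str, tuple[float, float]] | None = None


# ---------------------------------------------------------------------------
# Expected distances from atomic coordinates
# ---------------------------------------------------------------------------

def expected_sites_from_structure(
    structure,
    reference: tuple[str, int, str],
    sites: Mapping[str, tuple[str, int, str]],
    linker_offsets: Mapping[str, float] | None = None,
    model: str = "first",
    name: str | None = None,
    sigma: float = LIKELIHOOD_SIGMA_NM,
) -> ConformationModel:
    """Build a distance-space candidate from atomic coordinates.

    ``structure`` is a ``gemmi.Structure`` (see :func:`dnacaliper.io.
    read_structure_coords`). ``reference`` and each site selection are
    (chain, residue seqnum, atom name) triples; distances are Euclidean,
    converted from Angstrom to nm, with an optional per-site linker offset
    added. For multi-model (NMR) files the first model is used by default;
    ``model="average"`` averages the distance over models.

    Raises :class:`ArgumentError` naming the selection when an atom is
    absent.
    """
    import gemmi  # local import keeps the module importable without coords

    if len(structure) == 0:
        raise ArgumentError("structure contains no models")
    models = [structure[0]] if model == "first" else list(structure)
    if model not in ("first", "average"):
        raise ArgumentError(f"unknown model handling {model!r}")

    def atom_pos(mdl, sel):
        chain_name, seqnum, atom_name = sel
        chain = mdl.find_chain(chain_name)
        if chain is None:
            raise ArgumentError(f"chain {chain_name!r} not found for {sel}")
        for res in chain:
            if res.seqid.num == seqnum:
                atom = res.find_atom(atom_name, "*")
                if atom is None:
                    raise ArgumentError(f"atom {atom_name!r} not found for {sel}")
                return np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        raise ArgumentError(f"residue {seqnum} not found for {sel}")

    expected: dict[str, float] = {}
    for site, sel in sites.items():
        dists = []
        for mdl in models:
            r = atom_pos(mdl, reference)
            p = atom_pos(mdl, sel)
            dists.append(np.linalg.norm(p - r) / 10.0)  # A -> nm
        d = float(np.mean(dists))
        if linker_offsets and site in linker_offsets:
            d += float(linker_offsets[site])
        expected[site] = d
    return ConformationModel(
        name or structure.name or "structure", expected, "distance", sigma,
        source="PDB coordinates",
    )


def candidates_from_yaml(path) -> list["ConformationModel"]:
    """Load an editable candidate table from YAML.

    The file is a list of entries with ``name``, ``expected`` (site ->
    value in nm) and optional ``space`` (default dL), ``sigma`` and
    ``source`` (e.g. the PDB id the expectations were derived from).
    """
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise ArgumentError(f"{path}: candidate table must be a non-empty list")
    out = []
    for entry in raw:
        unknown = set(entry) - {"name", "expected", "space", "sigma", "source"}
        if unknown:
            raise ArgumentError(
                f"{path}: unknown candidate keys {sorted(unknown)}"
            )
        out.append(
            ConformationModel(
                name=str(entry["name"]),
                expected={str(k): float(v)
                          for k, v in entry["expected"].items()},
                space=entry.get("space", "deltaL"),
                sigma=float(entry.get("sigma", LIKELIHOOD_SIGMA_NM)),
                source=str(entry.get("source", "user table")),
            )
        )
    return out


# ---------------------------------------------------------------------------
# RMSD with propagated error
# ---------------------------------------------------------------------------

def rmsd_to_candidate(
    measured: Mapping[str, tuple[float, float]],
    model: ConformationModel,
) -> tuple[float, float]:
    """RMSD between measured per-site peaks and a candidate's expectations.

    ``measured`` maps site -> (value, standard error). The error of the
    RMSD follows from the first-order delta method,
    ``d RMSD / d m_i = e_i / (n RMSD)``; at RMSD = 0 the delta method
    degenerates and the per-site SEs give an upper bound
    ``sqrt(mean SE_i^2)`` instead.
    """
    common = [s for s in measured if s in model.expected]
    if not common:
        raise ArgumentError("no common sites between measurement and candidate")
    e = np.array([measured[s][0] - model.expected[s] for s in common])
    se = np.array([measured[s][1] for s in common])
    n = len(common)
    rmsd = float(np.sqrt(np.mean(e**2)))
    if rmsd == 0.0:
        return 0.0, float(np.sqrt(np.mean(se**2)))
    grad = e / (n * rmsd)
    return rmsd, float(np.sqrt(np.sum((grad * se) ** 2)))


# ---------------------------------------------------------------------------
# Mixture likelihood
# ---------------------------------------------------------------------------

def _check_candidates(candidates: Sequence[ConformationModel]) -> None:
    if len(candidates) < 2:
        raise ArgumentError("need >= 2 candidate structures")
    spaces = {c.space for c in candidates}
    if len(spaces) != 1:
        raise ArgumentError("candidates mix dL and distance spaces")


def molecule_structure_likelihood(
    measurements: np.ndarray,
    candidates: Sequence[ConformationModel],
) -> dict[str, float]:
    """Normalised probability of each candidate given one molecule's data.

    Each candidate's density is a uniform mixture over its sites,
    ``p(x) = (1/k) sum_s N(x; mu_s, sigma)``; the per-candidate
    log-likelihood sums over measurements, and probabilities are the
    likelihoods normalised across candidates. Order of measurements and
    candidate labelling are immaterial.
    """
    x = np.asarray(measurements, dtype=float)
    if x.size < 1:
        raise ArgumentError("need >= 1 measurement")
    _check_candidates(candidates)
    logls = []
    for cand in candidates:
        mus = np.array(list(cand.expected.values()))
        s = cand.sigma
        # log of (1/k) sum_s N(x; mu_s, s), summed over measurements
        z = -0.5 * ((x[:, None] - mus[None, :]) / s) ** 2
        log_density = (
            logsumexp(z, axis=1)
            - np.log(len(mus))
            - 0.5 * np.log(2 * np.pi)
            - np.log(s)
        )
        logls.append(np.sum(log_density))
    logls = np.array(logls)
    p = np.exp(logls - logsumexp(logls))
    p = p / p.sum()
    return {c.name: float(pi) for c, pi in zip(candidates, p)}


def aggregate_structure_probability(
    per_molecule: Sequence[Mapping[str, float]],
    rmsd: Mapping[str, tuple[float, float]] | None = None,
) -> AssignmentReport:
    """Average per-molecule candidate probabilities into a final call.

    All molecules must have been scored against the same candidate set.
    The best candidate is the argmax of the averaged probabilities; an
    RMSD table (candidate -> (rmsd, propagated error)) can be attached for
    the dual-route comparison.
    """
    if len(per_molecule) < 1:
        raise ArgumentError("need >= 1 molecule")
    names = tuple(sorted(per_molecule[0]))
    for probs in per_molecule:
        if tuple(sorted(probs)) != names:
            raise ArgumentError("candidate sets differ across molecules")
    table = pd.DataFrame(
        [{n: probs[n] for n in names} for probs in per_molecule]
    )
    avg = table.mean(axis=0)
    avg = avg / avg.sum()
    best = str(avg.idxmax())
    return AssignmentReport(
        candidates=names,
        averaged_probability={n: float(avg[n]) for n in names},
        best_candidate=best,
        per_molecule=table,
        rmsd=dict(rmsd) if rmsd is not None else None,
    )
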