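"""RMSD and mixture-likelihood structure assignment."""
import math

import numpy as np
import pytest

from dnacaliper.conformation_assignment import (
    ConformationModel,
    aggregate_structure_probability,
    expected_sites_from_structure,
    molecule_structure_likelihood,
    rmsd_to_candidate,
)
from dnacaliper.errors import ArgumentError, DomainError
from dnacaliper.presets import builtin_candidates, make_mini_pdb
from dnacaliper.simulator import simulate_deltaL_dataset
from dnacaliper.io import read_structure_coords


def brute_force_probabilities(values, candidates):
    """Independent oracle: explicit scalar-loop density computation."""
    liks = []
    for cand in candidates:
        mus = list(cand.expected.values())
        s = cand.sigma
        logl = 0.0
        for x in values:
            dens = sum(
                math.exp(-0.5 * ((x - mu) / s) ** 2)
                / (s * math.sqrt(2 * math.pi))
                for mu in mus
            ) / len(mus)
            logl += math.log(dens)
        liks.append(logl)
    mx = max(liks)
    w = [math.exp(v - mx) for v in liks]
    return {c.name: wi / sum(w) for c, wi in zip(candidates, w)}


class TestExpectedSitesFromStructure:
    def test_mini_pdb_distances_match_truth(self, tmp_path):
        path = tmp_path / "mini.pdb"
        truth = make_mini_pdb(path)
        st = read_structure_coords(path)
        model = expected_sites_from_structure(
            st, reference=("A", 1, "P"),
            sites={"site1": ("A", 2, "P"), "site2": ("A", 3, "P"),
                   "site3": ("A", 4, "P"), "site4": ("A", 5, "P")},
        )
        for site, d in truth.items():
            assert model.expected[site] == pytest.approx(d, abs=1e-6)

    def test_two_atoms_20A_apart_give_2nm(self, tmp_path):
        path = tmp_path / "mini.pdb"
        make_mini_pdb(path)
        st = read_structure_coords(path)
        model = expected_sites_from_structure(
            st, ("A", 1, "P"), {"s": ("A", 2, "P")}
        )
        assert model.expected["s"] == pytest.approx(2.0)

    def test_missing_residue_named_in_error(self, tmp_path):
        path = tmp_path / "mini.pdb"
        make_mini_pdb(path)
        st = read_structure_coords(path)
        with pytest.raises(ArgumentError, match="99"):
            expected_sites_from_structure(
                st, ("A", 1, "P"), {"s": ("A", 99, "P")}
            )

    def test_linker_offsets_added(self, tmp_path):
        path = tmp_path / "mini.pdb"
        make_mini_pdb(path)
        st = read_structure_coords(path)
        model = expected_sites_from_structure(
            st, ("A", 1, "P"), {"s": ("A", 2, "P")},
            linker_offsets={"s": 0.5},
        )
        assert model.expected["s"] == pytest.approx(2.5)


class TestRmsd:
    model = ConformationModel("c", {"a": 10.0, "b": 12.0, "c": 14.0,
                                    "d": 16.0})

    def test_perfect_match_zero_rmsd_with_se_upper_bound(self):
        measured = {s: (v, 0.2) for s, v in self.model.expected.items()}
        rmsd, err = rmsd_to_candidate(measured, self.model)
        assert rmsd == 0.0
        assert err == pytest.approx(0.2)

    def test_uniform_offset(self):
        measured = {s: (v + 1.0, 0.1) for s, v in self.model.expected.items()}
        rmsd, _ = rmsd_to_candidate(measured, self.model)
        assert rmsd == pytest.approx(1.0)

    def test_hand_computed_mixed_offsets(self):
        offs = {"a": 1.0, "b": -1.0, "c": 2.0, "d": 0.0}
        measured = {s: (self.model.expected[s] + offs[s], 0.1)
                    for s in self.model.expected}
        rmsd, _ = rmsd_to_candidate(measured, self.model)
        assert rmsd == pytest.approx(math.sqrt(6.0 / 4.0))

    def test_no_common_sites_rejected(self):
        with pytest.raises(ArgumentError):
            rmsd_to_candidate({"zz": (1.0, 0.1)}, self.model)


class TestLikelihood:
    def test_symmetric_candidates_split_evenly(self):
        a = ConformationModel("a", {"s": 9.0})
        b = ConformationModel("b", {"s": 11.0})
        p = molecule_structure_likelihood(np.array([10.0]), [a, b])
        assert p["a"] == pytest.approx(0.5, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        candidates = builtin_candidates()
        gen = candidates[0]
        values = rng.choice(list(gen.expected.values()), size=20) + \
            rng.normal(0, 0.5, 20)
        p = molecule_structure_likelihood(values, candidates)
        oracle = brute_force_probabilities(values, candidates)
        for name in p:
            assert p[name] == pytest.approx(oracle[name], abs=1e-9)

    def test_clear_generator_wins_decisively(self, rng):
        a = ConformationModel("a", {"s1": 10.0, "s2": 14.0, "s3": 18.0,
                                    "s4": 22.0})
        b = ConformationModel("b", {"s1": 12.0, "s2": 16.0, "s3": 20.0,
                                    "s4": 24.0})
        values = np.tile([10.0, 14.0, 18.0, 22.0], 5)
        p = molecule_structure_likelihood(values, [a, b])
        assert p["a"] > 0.99

    def test_identical_candidates_uniform(self):
        a = ConformationModel("a", {"s": 10.0})
        b = ConformationModel("b", {"s": 10.0})
        c = ConformationModel("c", {"s": 10.0})
        p = molecule_structure_likelihood(np.array([9.0, 10.5]), [a, b, c])
        for v in p.values():
            assert v == pytest.approx(1 / 3, abs=1e-12)

    def test_invariance_to_order_and_labeling(self, rng):
        candidates = builtin_candidates()
        values = rng.normal(22.0, 2.0, 15)
        p1 = molecule_structure_likelihood(values, candidates)
        p2 = molecule_structure_likelihood(values[::-1], candidates[::-1])
        for name in p1:
            assert p1[name] == pytest.approx(p2[name], abs=1e-12)

    def test_probabilities_sum_to_one(self, rng):
        p = molecule_structure_likelihood(
            rng.normal(20, 3, 10), builtin_candidates()
        )
        assert sum(p.values()) == pytest.approx(1.0, abs=1e-9)

    def test_sigma_must_be_positive(self):
        with pytest.raises(DomainError):
            ConformationModel("a", {"s": 1.0}, sigma=0.0)


class TestAggregate:
    def test_single_molecule_passthrough(self):
        report = aggregate_structure_probability([{"a": 0.8, "b": 0.2}])
        assert report.averaged_probability == {"a": 0.8, "b": 0.2}
        assert report.best_candidate == "a"

    def test_generating_candidate_wins_21_molecules(self):
        candidates = builtin_candidates()
        gen = candidates[0]  # hybrid1-like
        comps = [(v, 0.5, 1.0) for v in gen.expected.values()]
        mols = simulate_deltaL_dataset(comps, 21, 20, seed=17)
        per_mol = [molecule_structure_likelihood(m.deltaL, candidates)
                   for m in mols]
        report = aggregate_structure_probability(per_mol)
        assert report.best_candidate == gen.name
        assert sum(report.averaged_probability.values()) == pytest.approx(1.0)

    def test_even_split_between_two_generators(self):
        a = ConformationModel("a", {"s": 10.0})
        b = ConformationModel("b", {"s": 20.0})
        mols_a = simulate_deltaL_dataset([(10.0, 0.5, 1.0)], 10, 20, seed=1)
        mols_b = simulate_deltaL_dataset([(20.0, 0.5, 1.0)], 10, 20, seed=2)
        per_mol = [molecule_structure_likelihood(m.deltaL, [a, b])
                   for m in mols_a + mols_b]
        report = aggregate_structure_probability(per_mol)
        assert report.averaged_probability["a"] == pytest.approx(0.5, abs=0.05)

    def test_differing_candidate_sets_rejected(self):
        with pytest.raises(ArgumentError):
            aggregate_structure_probability(
                [{"a": 1.0}, {"b": 1.0}]
            )


class TestCandidateYaml:
    def test_round_trip_and_unknown_key_rejection(self, tmp_path):
        import yaml

        from dnacaliper.conformation_assignment import candidates_from_yaml

        path = tmp_path / "cands.yaml"
        path.write_text(yaml.safe_dump([
            {"name": "antiparallel", "source": "143D",
             "expected": {"3p": 26.0, "loop1": 16.5}},
            {"name": "hybrid1", "source": "2HY9", "sigma": 0.5,
             "expected": {"3p": 27.0, "loop1": 18.0}},
        ]))
        cands = candidates_from_yaml(path)
        assert [c.name for c in cands] == ["antiparallel", "hybrid1"]
        assert cands[0].expected["3p"] == 26.0
        path.write_text(yaml.safe_dump(
            [{"name": "x", "expected": {"s": 1.0}, "bogus": 2}]
        ))
        with pytest.raises(ArgumentError, match="bogus"):
            candidates_from_yaml(path)
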