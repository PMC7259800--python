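import numpy as np
import pandas as pd
import pytest

from glypheno.errors import ValidationError
from glypheno.ranking import (
    DockingModel,
    conservation_parameter,
    constrained_rescore,
    distance_parameter,
    interface_residues,
    normalize_and_rank,
    parse_models,
    score_models,
)
from glypheno.simulate import simulate_docking_set


def _toy_model(coords_a, coords_b, model_id="m"):
    rows = []
    for i, xyz in enumerate(coords_a):
        rows.append(dict(chain="A", resnum=i + 1, resname="ALA", atom_name="CA",
                         x=xyz[0], y=xyz[1], z=xyz[2]))
    for i, xyz in enumerate(coords_b):
        rows.append(dict(chain="B", resnum=i + 1, resname="GLY", atom_name="CA",
                         x=xyz[0], y=xyz[1], z=xyz[2]))
    return DockingModel(model_id, pd.DataFrame(rows))


class TestParseModels:
    def test_multi_model_file(self, docking_set):
        sim, models = docking_set
        assert len(models) == 15
        assert models[0].model_id == sim.planted_model_id
        assert set(models[0].atoms["chain"]) == {"A", "B"}

    def test_single_chain_rejected(self, tmp_path):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A   2       3.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        p = tmp_path / "one_chain.pdb"
        p.write_text(text)
        with pytest.raises(ValidationError, match="chains"):
            parse_models(p)

    def test_waters_dropped(self, tmp_path):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLY B   1       3.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    3  O   HOH A 100       9.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        p = tmp_path / "waters.pdb"
        p.write_text(text)
        (model,) = parse_models(p)
        assert "HOH" not in set(model.atoms["resname"])


class TestInterfaceResidues:
    def test_below_cutoff_pair(self):
        m = _toy_model([(0, 0, 0)], [(3.9, 0, 0)])
        res_a, res_b = interface_residues(m, "A", "B")
        assert res_a == {1} and res_b == {1}

    def test_far_apart_chains(self):
        m = _toy_model([(0, 0, 0)], [(25.0, 0, 0)])
        assert interface_residues(m, "A", "B") == (set(), set())

    def test_matches_brute_force_on_random_decoys(self, rng):
        """KD-tree detection equals the all-pairs O(n²) definition."""
        for _ in range(10):
            ca = rng.uniform(-10, 10, size=(25, 3))
            cb = rng.uniform(-10, 10, size=(25, 3))
            m = _toy_model(ca, cb)
            got_a, got_b = interface_residues(m, "A", "B", cutoff=4.0)
            exp_a, exp_b = set(), set()
            for i, pa in enumerate(ca):
                for j, pb in enumerate(cb):
                    if np.linalg.norm(pa - pb) <= 4.0:
                        exp_a.add(i + 1)
                        exp_b.add(j + 1)
            assert (got_a, got_b) == (exp_a, exp_b)


class TestConservationParameter:
    def test_uniform_grades(self):
        assert conservation_parameter({1, 2}, {1: 9, 2: 9}) == 9.0

    def test_mean_of_grades(self):
        assert conservation_parameter({1, 2}, {1: 9, 2: 5}) == 7.0

    def test_empty_set_is_missing(self):
        assert conservation_parameter(set(), {1: 9}) is None

    def test_missing_residues_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            assert conservation_parameter({1, 99}, {1: 9}) == 9.0

    def test_median_aggregator(self):
        assert conservation_parameter({1, 2, 3}, {1: 1, 2: 8, 3: 9}, np.median) == 8.0


class TestDistanceParameter:
    def test_ligand_at_centroid(self):
        m = _toy_model([(0, 0, 0), (2, 0, 0)], [(1, 0, 0)])
        assert distance_parameter(m, ("B", 1, "CA"), {1, 2}, "A") == pytest.approx(0.0)

    def test_three_four_five(self):
        m = _toy_model([(0, 0, 0)], [(3, 4, 0)])
        assert distance_parameter(m, ("B", 1, "CA"), {1}, "A") == pytest.approx(5.0)

    def test_missing_ligand_atom_warns(self):
        m = _toy_model([(0, 0, 0)], [(3, 4, 0)])
        with pytest.warns(UserWarning):
            assert distance_parameter(m, ("B", 1, "NZ"), {1}, "A") is None


class TestNormalizeAndRank:
    def _raw(self, **cols):
        n = len(next(iter(cols.values())))
        return pd.DataFrame({"model_id": [f"m{i}" for i in range(n)], **cols})

    def test_best_in_all_parameters_totals_three(self):
        raw = self._raw(
            raw_cons_a=[9.0, 4.0, 5.0],
            raw_cons_b=[8.0, 3.0, 4.0],
            raw_distance=[2.0, 20.0, 15.0],
        )
        out = normalize_and_rank(raw)
        top = out.iloc[0]
        assert top["model_id"] == "m0" and top["total"] == pytest.approx(3.0)
        assert out["total"].between(0, 3).all()

    def test_two_models_normalize_to_zero_and_one(self):
        raw = self._raw(raw_cons_a=[9.0, 4.0], raw_cons_b=[3.0, 8.0])
        out = normalize_and_rank(raw, use_distance=False)
        assert set(out["norm_cons_a"]) == {0.0, 1.0}
        assert set(out["norm_cons_b"]) == {0.0, 1.0}

    def test_affine_invariance_of_normalized_scores(self, rng):
        vals = rng.uniform(1, 9, 6)
        raw1 = self._raw(raw_cons_a=vals, raw_cons_b=vals[::-1].copy())
        raw2 = self._raw(raw_cons_a=3.0 * vals + 7.0, raw_cons_b=vals[::-1].copy())
        out1 = normalize_and_rank(raw1, use_distance=False)
        out2 = normalize_and_rank(raw2, use_distance=False)
        assert np.allclose(out1["norm_cons_a"], out2["norm_cons_a"])

    def test_input_order_invariance(self, rng):
        raw = self._raw(
            raw_cons_a=rng.uniform(1, 9, 8),
            raw_cons_b=rng.uniform(1, 9, 8),
            raw_distance=rng.uniform(5, 40, 8),
        )
        out1 = normalize_and_rank(raw)
        out2 = normalize_and_rank(raw.sample(frac=1, random_state=0))
        pd.testing.assert_frame_equal(
            out1.reset_index(drop=True), out2.reset_index(drop=True)
        )

    def test_constant_parameter_dropped_with_warning(self):
        raw = self._raw(raw_cons_a=[5.0, 5.0, 5.0], raw_cons_b=[1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="degenerate"):
            out = normalize_and_rank(raw, use_distance=False)
        assert "norm_cons_a" not in out.columns
        assert out["total"].max() == pytest.approx(1.0)

    def test_fewer_than_two_models_rejected(self):
        with pytest.raises(ValidationError):
            normalize_and_rank(self._raw(raw_cons_a=[1.0], raw_cons_b=[2.0]))

    def test_bounds_on_many_random_sets(self, rng):
        """Totals stay within [0, #parameters] across 1000 random decoy sets."""
        for _ in range(1000):
            n = int(rng.integers(2, 12))
            raw = self._raw(
                raw_cons_a=rng.uniform(0, 9, n),
                raw_cons_b=rng.uniform(0, 9, n),
                raw_distance=rng.uniform(1, 50, n),
            )
            out = normalize_and_rank(raw)
            k = len(out.attrs["parameters_used"])
            assert out["total"].between(-1e-12, k + 1e-12).all()
            assert list(out["rank"]) == list(range(1, n + 1))


class TestPlantedPose:
    def test_planted_pose_wins_every_parameter(self, docking_set):
        sim, models = docking_set
        raw = score_models(
            models, sim.cons_a, sim.cons_b,
            ligand=sim.ligand, site_residues=sim.site_residues,
        )
        planted = raw[raw["model_id"] == sim.planted_model_id].iloc[0]
        others = raw[raw["model_id"] != sim.planted_model_id]
        assert planted["raw_cons_a"] > others["raw_cons_a"].max()
        assert planted["raw_cons_b"] > others["raw_cons_b"].max()
        assert planted["raw_distance"] < others["raw_distance"].min()

    def test_planted_pose_ranks_first_with_total_three(self, docking_set):
        sim, models = docking_set
        raw = score_models(
            models, sim.cons_a, sim.cons_b,
            ligand=sim.ligand, site_residues=sim.site_residues,
        )
        ranked = normalize_and_rank(raw)
        assert ranked.iloc[0]["model_id"] == sim.planted_model_id
        assert ranked.iloc[0]["total"] == pytest.approx(3.0)


class TestConstrainedRescore:
    def test_infinite_radius_reproduces_round_one(self, docking_set):
        sim, models = docking_set
        raw = score_models(models, sim.cons_a, sim.cons_b,
                           ligand=sim.ligand, site_residues=sim.site_residues)
        round1 = normalize_and_rank(raw)
        round2 = constrained_rescore(models, raw, sim.planted_model_id, radius=np.inf)
        assert list(round1["model_id"]) == list(round2["model_id"])

    def test_zero_radius_keeps_only_anchor(self, docking_set):
        sim, models = docking_set
        raw = score_models(models, sim.cons_a, sim.cons_b)
        with pytest.warns(UserWarning, match="unranked"):
            out = constrained_rescore(models, raw, sim.planted_model_id, radius=0.0)
        assert list(out["model_id"]) == [sim.planted_model_id]

    def test_subset_renormalized(self, docking_set):
        """Normalization constants are recomputed on the constrained subset."""
        sim, models = docking_set
        raw = score_models(models, sim.cons_a, sim.cons_b,
                           ligand=sim.ligand, site_residues=sim.site_residues)
        round2 = constrained_rescore(models, raw, sim.planted_model_id, radius=60.0)
        assert 2 <= len(round2) <= len(models)
        for col in round2.attrs["parameters_used"]:
            assert round2[col].min() == pytest.approx(0.0)
            assert round2[col].max() == pytest.approx(1.0)

    def test_unknown_anchor_rejected(self, docking_set):
        sim, models = docking_set
        raw = score_models(models, sim.cons_a, sim.cons_b)
        with pytest.raises(ValidationError):
            constrained_rescore(models, raw, "nope")
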