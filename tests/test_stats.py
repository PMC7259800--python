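import itertools
import warnings
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from glypheno.errors import ValidationError
from glypheno.stats import (
    concordance_counts,
    enrichment_table,
    hypergeom_enrichment,
    mutation_survey,
    phi_coefficient,
    phi_matrix,
    region_mutation_rate,
    severity_separation_ttest,
)
from glypheno import io


class TestRegionMutationRate:
    def test_fraction_of_region_mutated(self):
        region = set(range(1, 31))
        mutated = set(range(1, 11)) | {500, 600}
        assert region_mutation_rate(region, mutated) == pytest.approx(1 / 3)

    def test_no_mutations(self):
        assert region_mutation_rate({1, 2, 3}, set()) == 0.0

    def test_whole_protein_baseline(self):
        assert region_mutation_rate(
            set(range(1, 1021)), set(range(1, 214))
        ) == pytest.approx(0.209, abs=5e-4)

    def test_empty_region_rejected(self):
        with pytest.raises(ValidationError):
            region_mutation_rate(set(), {1})


class TestHypergeomEnrichment:
    @pytest.mark.parametrize(
        "n, k, printed",
        [(30, 10, 0.08), (20, 6, 0.22), (17, 6, 0.12)],
    )
    def test_region_census_pvalues(self, n, k, printed):
        """Upper-tail p-values for the mutated-residue census round to the
        published two-decimal values."""
        assert round(hypergeom_enrichment(1020, 213, n, k), 2) == printed

    def test_k_zero_is_certain(self):
        assert hypergeom_enrichment(100, 10, 5, 0) == 1.0

    def test_small_exact_value(self):
        # P(X >= 4) for N=10, K=5, n=4: only C(5,4)*C(5,0) of C(10,4) draws
        assert hypergeom_enrichment(10, 5, 4, 4) == pytest.approx(5 / 210)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_enrichment(10, 5, 4, 5)

    def test_matches_independent_tail_for_all_small_problems(self):
        """Exhaustive agreement with scipy's survival function for N <= 25."""
        for N in range(1, 26):
            for K in range(0, N + 1, 3):
                for n in range(0, N + 1, 3):
                    for k in range(0, min(K, n) + 1):
                        ours = hypergeom_enrichment(N, K, n, k)
                        ref = sps.hypergeom.sf(k - 1, N, K, n)
                        assert ours == pytest.approx(ref, abs=1e-12)

    def test_matches_brute_force_enumeration(self):
        """Direct enumeration of draws for a tiny urn."""
        N, K, n, k = 9, 4, 3, 2
        marked = set(range(K))
        hits = sum(
            1
            for draw in itertools.combinations(range(N), n)
            if len(marked & set(draw)) >= k
        )
        assert hypergeom_enrichment(N, K, n, k) == pytest.approx(hits / comb(N, n))

    def test_monotone_in_k(self):
        ps = [hypergeom_enrichment(50, 20, 10, k) for k in range(0, 11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestPhiCoefficient:
    def test_identical_vectors(self):
        x = np.array([1, 0, 1, 1, 0])
        assert phi_coefficient(x, x) == pytest.approx(1.0)

    def test_complementary_vectors(self):
        x = np.array([1, 0, 1, 0])
        assert phi_coefficient(x, 1 - x) == pytest.approx(-1.0)

    def test_half_scores_binarized(self):
        x = np.array([0.5, 0.0, 1.0, 0.5])
        y = np.array([1, 0, 1, 1])
        assert phi_coefficient(x, y) == pytest.approx(1.0)

    def test_constant_vector_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isnan(phi_coefficient([1, 1, 1], [0, 1, 0]))

    @given(
        data=st.lists(
            st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=4, max_size=30
        )
    )
    @settings(derandomize=True, max_examples=60)
    def test_symmetry_and_label_swap_invariance(self, data):
        x = np.array([a for a, _ in data])
        y = np.array([b for _, b in data])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p1 = phi_coefficient(x, y)
            p2 = phi_coefficient(y, x)
            p3 = phi_coefficient(1 - x, 1 - y)
        if np.isnan(p1):
            assert np.isnan(p2) and np.isnan(p3)
        else:
            assert p1 == pytest.approx(p2)
            assert p1 == pytest.approx(p3)

    def test_matches_pearson_on_binary_data(self, rng):
        x = (rng.random(100) < 0.4).astype(float)
        y = np.where(rng.random(100) < 0.7, x, 1 - x)
        assert phi_coefficient(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1])


class TestSeverityTtest:
    def test_identical_groups(self):
        scores = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        classes = ["severe"] * 3 + ["attenuated"] * 3
        res = severity_separation_ttest(scores, classes)
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_known_effect_simulation(self, rng):
        scores = np.r_[rng.normal(0, 1, 20), rng.normal(3, 1, 20)]
        classes = ["attenuated"] * 20 + ["severe"] * 20
        res = severity_separation_ttest(scores, classes)
        assert res.p < 1e-6
        assert res.means["severe"] > res.means["attenuated"]

    def test_matches_closed_form_for_two_by_two(self):
        """Pooled two-sample t with n1=n2=2, checked against the t CDF."""
        a, b = np.array([0.0, 2.0]), np.array([3.0, 5.0])
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 2 + 1 / 2))
        p = 2 * sps.t.sf(abs(t), df=2)
        res = severity_separation_ttest(
            np.r_[b, a], ["severe", "severe", "attenuated", "attenuated"]
        )
        assert res.t == pytest.approx(abs(t))
        assert res.p == pytest.approx(p)

    def test_small_class_rejected(self):
        with pytest.raises(ValidationError, match="severe"):
            severity_separation_ttest([1.0, 2.0, 3.0], ["severe", "attenuated", "attenuated"])


class TestConcordance:
    def test_homozygous_cohort_table(self):
        t6 = io.load_fixture("table6_homozygous_mms").astype({"cos": float, "mms": float})
        counts = concordance_counts(t6)
        # 14 of the 16 low-COS cases carry a low MMS
        assert counts.loc["cos_low"].sum() == 16
        assert counts.loc["cos_low", "mms_low"] == 14

    def test_heterozygous_cohort_table(self):
        t7 = io.load_fixture("table7_heterozygous_mms").astype({"cos": float, "mms": float})
        counts = concordance_counts(t7)
        assert counts.loc["cos_low", "mms_low"] == 27
        assert counts.loc["cos_low"].sum() == 29
        assert counts.loc["cos_severe", "mms_high"] == 2
        assert counts.loc["cos_severe"].sum() == 21

    def test_empty_cohort(self):
        import pandas as pd

        counts = concordance_counts(pd.DataFrame({"cos": [], "mms": []}))
        assert counts.to_numpy().sum() == 0

    def test_missing_column_rejected(self):
        import pandas as pd

        with pytest.raises(ValidationError):
            concordance_counts(pd.DataFrame({"cos": [1]}))


class TestMutationSurvey:
    def test_single_mutation(self):
        out = mutation_survey([(515, "R", "S")])
        assert out["n_mutations"] == 1 and out["n_residues"] == 1
        assert out["top_positions"][0] == (515, 1)

    def test_two_substitutions_one_residue(self):
        out = mutation_survey([(515, "R", "S"), (515, "R", "L")])
        assert out["n_mutations"] == 2 and out["n_residues"] == 1

    def test_duplicates_collapse_and_ties_break_by_position(self):
        muts = [(7, "A", "V"), (7, "A", "V"), (3, "G", "R"), (3, "G", "E"), (9, "L", "P")]
        out = mutation_survey(muts, top_k=3)
        assert out["n_mutations"] == 4
        assert out["top_positions"] == [(3, 2), (7, 1), (9, 1)]


def test_enrichment_table_layout():
    regions = {"site": set(range(1, 31))}
    table = enrichment_table(regions, set(range(1, 11)), protein_length=100)
    row = table[table["region"] == "site"].iloc[0]
    assert row["rate"] == pytest.approx(1 / 3)
    assert 0 < row["p_upper"] <= 1


def test_phi_matrix_is_symmetric_with_unit_diagonal(rng):
    import pandas as pd

    X = pd.DataFrame((rng.random((60, 5)) < 0.5).astype(float), columns=list("abcde"))
    M = phi_matrix(X)
    assert np.allclose(M, M.T, equal_nan=True)
    assert np.allclose(np.diag(M), 1.0)
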