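"""Normalization, the exact NB test, BH adjustment, fold-change conventions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

import bcngdose as b
from bcngdose.diffexpr import DegenerateDataError

# TMM factors for the fixture matrix below, frozen from an independent run
# of the reference TMM implementation (R/Bioconductor edgeR 4.0.16,
# calcNormFactors(method="TMM")).
EDGER_TMM_FACTORS = [0.1329797992, 2.0041295141, 1.9186439670, 1.9556635928]


def tmm_fixture_matrix():
    rng = np.random.default_rng(7)
    mat = rng.negative_binomial(10, 10 / (10 + 50.0), size=(30, 4)).astype(float)
    mat[0, 0] = 20000  # one dominant transcript distorts sample S1's composition
    return pd.DataFrame(mat.astype(int), columns=["S1", "S2", "S3", "S4"],
                        index=[f"T{i}" for i in range(30)])


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([10, 50, 200, 1000, 5, 80])
        counts = pd.DataFrame({f"S{i}": col for i in range(3)})
        assert np.allclose(b.tmm_factors(counts), 1.0)

    def test_pure_library_size_scaling_leaves_factors_unchanged(self):
        # M-values absorb library size exactly; the precision weights
        # depend weakly on depth, so the weighted variant is only
        # approximately invariant
        rng = np.random.default_rng(3)
        base = rng.poisson(100, size=(50, 3))
        counts = pd.DataFrame(base, columns=["A", "B", "C"])
        scaled = counts.copy()
        scaled["B"] = scaled["B"] * 5
        assert np.allclose(b.tmm_factors(counts, weighted=False),
                           b.tmm_factors(scaled, weighted=False), atol=1e-12)
        assert np.allclose(b.tmm_factors(counts), b.tmm_factors(scaled), atol=1e-2)

    def test_matches_reference_implementation_on_fixture(self):
        factors = b.tmm_factors(tmm_fixture_matrix())
        assert np.allclose(factors.to_numpy(), EDGER_TMM_FACTORS, atol=1e-8)

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"A": [1, 2], "B": [0, 0]})
        with pytest.raises(DegenerateDataError):
            b.tmm_factors(counts)


class TestSignedLinearFc:
    @pytest.mark.parametrize("log2fc, expected", [(-1.0, -2.0), (1.0, 2.0), (0.0, 1.0)])
    def test_reporting_convention(self, log2fc, expected):
        assert b.signed_linear_fc(log2fc) == pytest.approx(expected)

    @given(st.floats(min_value=-20, max_value=20, allow_nan=False))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_odd_symmetry_and_forbidden_band(self, x):
        fwd, rev = b.signed_linear_fc(x), b.signed_linear_fc(-x)
        assert abs(fwd) == pytest.approx(abs(rev), rel=1e-9)
        assert abs(fwd) >= 1.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            b.signed_linear_fc(float("nan"))


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(b.bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert b.bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones_capped(self):
        assert np.allclose(b.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            b.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=1, max_size=60))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_agrees_with_reference_step_up(self, pvals):
        ours = b.bh_adjust(pvals)
        theirs = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)
        assert np.all(ours >= np.asarray(pvals) - 1e-15)  # FDR >= raw p


class TestTpm:
    def test_equal_counts_and_lengths_split_evenly(self):
        counts = pd.DataFrame({"S": [7, 7]}, index=["a", "b"])
        lengths = pd.Series([100, 100], index=["a", "b"])
        assert np.allclose(b.compute_tpm(counts, lengths)["S"], [500000, 500000])

    def test_three_transcript_arithmetic(self):
        counts = pd.DataFrame({"S": [10, 20, 30]}, index=["a", "b", "c"])
        lengths = pd.Series([1000, 1000, 2000], index=["a", "b", "c"])
        tpm = b.compute_tpm(counts, lengths)["S"]
        assert np.allclose(tpm, [222222.2222, 444444.4444, 333333.3333], atol=0.01)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(50, size=(20, 4)) + 1)
        lengths = pd.Series(rng.integers(200, 5000, size=20))
        assert np.allclose(b.compute_tpm(counts, lengths).sum(axis=0), 1e6)

    def test_zero_length_rejected(self):
        counts = pd.DataFrame({"S": [1, 2]}, index=["a", "b"])
        with pytest.raises(ValueError):
            b.compute_tpm(counts, pd.Series([100, 0], index=["a", "b"]))


def simulate_two_groups(rng, n_genes, n_per_group, mu, phi, effect=None):
    mu_vec = np.full(n_genes, float(mu)) if np.isscalar(mu) else mu
    mu_a = mu_vec * (effect if effect is not None else 1.0)
    a = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu_a[:, None]), size=(n_genes, n_per_group))
    bb = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu_vec[:, None]), size=(n_genes, n_per_group))
    df = pd.DataFrame(np.hstack([a, bb]), index=[f"T{i}" for i in range(n_genes)],
                      columns=[f"S{i}" for i in range(2 * n_per_group)])
    return df, list(df.columns[:n_per_group]), list(df.columns[n_per_group:])


class TestExactTest:
    def test_two_fold_effect_is_recovered(self):
        # 40 transcripts at a true 2x effect among 400, 30 vs 30 samples
        rng = np.random.default_rng(5)
        effect = np.ones(400)
        effect[:40] = 2.0
        mu = np.exp(rng.normal(4.0, 1.0, size=400))
        counts, ga, gb = simulate_two_groups(rng, 400, 30, mu, 0.1, effect)
        res = b.de_test(counts, ga, gb)
        hits = res.table.iloc[:40]
        assert (hits["fdr"] < 0.05).mean() >= 0.8
        assert 1.7 <= hits["signed_fc"].median() <= 2.3
        rel_err = (hits["signed_fc"] - 2.0).abs() / 2.0
        assert rel_err.median() < 0.10

    def test_all_zero_transcript_absent_from_results(self):
        rng = np.random.default_rng(8)
        counts, ga, gb = simulate_two_groups(rng, 50, 5, 100, 0.1)
        counts.iloc[10] = 0
        with pytest.warns(UserWarning, match="all-zero"):
            res = b.de_test(counts, ga, gb, transcripts=counts.index)
        assert "T10" not in res.table.index

    def test_group_too_small_rejected(self):
        rng = np.random.default_rng(9)
        counts, ga, gb = simulate_two_groups(rng, 20, 3, 100, 0.1)
        with pytest.raises(DegenerateDataError):
            b.de_test(counts, ga[:1], gb)

    def test_overlapping_groups_rejected(self):
        rng = np.random.default_rng(9)
        counts, ga, gb = simulate_two_groups(rng, 20, 3, 100, 0.1)
        with pytest.raises(DegenerateDataError):
            b.de_test(counts, ga, ga)


class TestContrastSet:
    def test_normals_never_on_a_tumour_side(self):
        with pytest.raises(DegenerateDataError):
            b.ContrastSet(selected=["a", "b"], control=["c"], normals=["a", "n"])

    def test_contrast_layout(self):
        cs = b.ContrastSet(selected=["s1", "s2"], control=["c1", "c2"], normals=["n1", "n2"])
        c = cs.contrasts()
        assert c["FC1"].numerator == ["s1", "s2", "c1", "c2"]
        assert c["FC2"].numerator == ["s1", "s2"] and c["FC2"].denominator == ["c1", "c2"]
        assert c["FC3"].numerator == ["c1", "c2"] and c["FC3"].denominator == ["n1", "n2"]
        assert c["FC4"].numerator == ["s1", "s2"] and c["FC4"].denominator == ["n1", "n2"]
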