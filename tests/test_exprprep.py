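import numpy as np
import pandas as pd
import pytest

from immunophen import exprprep, simdata


def _matrix(values, genes=None, samples=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)


class TestFilterLowExpression:
    def test_all_zero_gene_removed(self):
        counts = _matrix([[0, 0, 0], [10, 20, 30]])
        out = exprprep.filter_low_expression(counts)
        assert list(out.index) == ["g1"]

    def test_boundary_fraction_removes(self):
        # 10 samples, library size 10^6 each; gene has CPM 0.2 (< 0.25)
        # in exactly one sample (10% of samples) -> removed
        n = 10
        lib_target = 1_000_000
        g = np.full(n, 300)
        g[0] = 0  # CPM 0 < 0.25 in exactly 1/10 samples
        filler = lib_target - g
        counts = _matrix(np.vstack([g, filler]), genes=["G", "rest"])
        out = exprprep.filter_low_expression(counts, cpm_cutoff=0.25, frac_cutoff=0.10)
        assert "G" not in out.index

    def test_high_cpm_gene_retained(self):
        counts = _matrix([[100, 100, 100], [900, 900, 900]])
        out = exprprep.filter_low_expression(counts)
        assert set(out.index) == {"g0", "g1"}

    def test_all_removed_is_error(self):
        # every gene is zero (CPM 0 < 0.25) in exactly one of 10 samples
        vals = np.full((10, 10), 100)
        np.fill_diagonal(vals, 0)
        with pytest.raises(ValueError, match="every gene"):
            exprprep.filter_low_expression(_matrix(vals))

    def test_idempotent(self, small_cohort):
        counts, _, _ = small_cohort
        once = exprprep.filter_low_expression(counts)
        twice = exprprep.filter_low_expression(once)
        assert once.equals(twice)


def _tmm_oracle(obs, ref, logratio_trim=0.30, abs_trim=0.05):
    """Independent brute-force trimmed weighted mean of M-values."""
    obs, ref = np.asarray(obs, float), np.asarray(ref, float)
    no, nr = obs.sum(), ref.sum()
    pos = (obs > 0) & (ref > 0)
    o, r = obs[pos], ref[pos]
    m = np.log2((o / no) / (r / nr))
    a = 0.5 * np.log2((o / no) * (r / nr))
    w = (no - o) / (no * o) + (nr - r) / (nr * r)
    n = len(m)
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
    lo_a, hi_a = np.floor(n * abs_trim) + 1, n - np.floor(n * abs_trim)
    rm = np.argsort(np.argsort(m)) + 1
    ra = np.argsort(np.argsort(a)) + 1
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    return 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


class TestTmmFactors:
    def test_identical_columns(self):
        col = np.array([5, 50, 500, 5000, 100])
        counts = _matrix(np.column_stack([col, col, col]))
        f = exprprep.tmm_factors(counts)
        np.testing.assert_allclose(f.to_numpy(), 1.0, atol=1e-12)

    def test_pure_depth_difference(self):
        gen = np.random.default_rng(1)
        col = gen.integers(1, 1000, 200)
        counts = _matrix(np.column_stack([col, 2 * col]))
        f = exprprep.tmm_factors(counts)
        np.testing.assert_allclose(f.to_numpy(), 1.0, atol=1e-9)

    def test_composition_bias_matches_oracle(self):
        # jittered counts so M/A values carry no exact ties, making the
        # ordinal-rank trimming of the oracle equivalent to average ranks
        gen = np.random.default_rng(2)
        base = gen.integers(50, 2000, 400).astype(float)
        biased = np.round(base * gen.uniform(0.95, 1.05, 400))
        biased[:160] = np.round(biased[:160] * 2)  # 40% of genes doubled
        counts = _matrix(np.column_stack([base, biased]))
        # mirror the documented reference choice with independent code
        lib = counts.sum(axis=0).to_numpy()
        uq = np.array([np.quantile(counts.iloc[:, j] / lib[j], 0.75) for j in (0, 1)])
        ref = int(np.argmin(np.abs(uq - uq.mean())))
        obs = 1 - ref
        raw = np.ones(2)
        raw[obs] = _tmm_oracle(counts.iloc[:, obs], counts.iloc[:, ref])
        raw /= np.exp(np.mean(np.log(raw)))
        f = exprprep.tmm_factors(counts)
        np.testing.assert_allclose(f.to_numpy(), raw, rtol=1e-10)

    def test_doubled_minority_shrinks_factor(self):
        # doubling a minority of genes inflates sample j's library; the
        # unchanged majority's log-ratios therefore pull factor_j < 1
        gen = np.random.default_rng(7)
        base = gen.integers(50, 2000, 400).astype(float)
        biased = np.round(base * gen.uniform(0.97, 1.03, 400))
        biased[:120] = np.round(biased[:120] * 2)
        f = exprprep.tmm_factors(_matrix(np.column_stack([base, biased])))
        assert f.iloc[1] < 1.0 < f.iloc[0]

    def test_geometric_mean_one(self, small_cohort):
        counts, _, _ = small_cohort
        f = exprprep.tmm_factors(exprprep.filter_low_expression(counts))
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_support_error(self):
        counts = _matrix([[10, 0], [20, 0], [0, 7], [0, 9]])
        with pytest.raises(ValueError, match="s1"):
            exprprep.tmm_factors(counts)

    def test_permutation_invariance(self, small_cohort):
        counts, _, _ = small_cohort
        counts = exprprep.filter_low_expression(counts)
        f = exprprep.tmm_factors(counts)
        perm = list(reversed(counts.columns))
        f_perm = exprprep.tmm_factors(counts[perm])
        np.testing.assert_allclose(f.loc[perm].to_numpy(), f_perm.to_numpy(), rtol=1e-12)


class TestLog2Cpm:
    def test_closed_form_zero_count(self):
        counts = _matrix([[0, 0], [999_999, 999_999]])
        counts.iloc[1] = 1_000_000  # lib size exactly 10^6
        counts.iloc[0] = 0
        out = exprprep.log2_cpm(counts, pd.Series(1.0, index=counts.columns), prior=0.5)
        expected = np.log2(0.5 / (1e6 + 1) * 1e6)  # oracle: direct formula
        assert out.iloc[0, 0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-1.0000014, abs=1e-6)

    def test_doubling_cpm_argument_adds_one(self):
        # doubling count + prior at fixed effective library size adds
        # exactly 1.0 on the log2 scale
        lib = 10**9
        counts = _matrix([[100.0, 100.0], [lib - 100.0, lib - 100.0]])
        counts2 = _matrix([[200.5, 200.5], [lib - 200.5, lib - 200.5]])
        f = pd.Series(1.0, index=["s0", "s1"])
        a = exprprep.log2_cpm(counts, f).iloc[0, 0]
        b = exprprep.log2_cpm(counts2, f).iloc[0, 0]
        assert b - a == pytest.approx(1.0, abs=1e-12)

    def test_equal_columns_identical(self):
        counts = _matrix([[3, 3], [7, 7], [11, 11]])
        out = exprprep.log2_cpm(counts)
        np.testing.assert_array_equal(out.iloc[:, 0], out.iloc[:, 1])

    def test_monotone_in_count(self):
        counts = _matrix([[1, 1], [2, 2], [400, 400]])
        out = exprprep.log2_cpm(counts)
        assert out.iloc[1, 0] > out.iloc[0, 0]


class TestIdentifyHousekeeping:
    def test_constant_high_gene_selected(self):
        gen = np.random.default_rng(3)
        mat = pd.DataFrame(gen.normal(5, 1, size=(20, 8)))
        mat.iloc[0] = 12.0  # constant, variance 0
        sel = exprprep.identify_housekeeping(mat, mean_cutoff=10)
        assert 0 in sel

    def test_mean_below_threshold_excluded(self):
        mat = pd.DataFrame(np.vstack([np.full(8, 9.9), np.random.default_rng(4).normal(5, 1, (10, 8))]))
        sel = exprprep.identify_housekeeping(mat, mean_cutoff=10)
        assert 0 not in sel

    def test_recovers_planted_housekeeping(self, small_cohort):
        counts, _, truth = small_cohort
        logmat = exprprep.log2_cpm(counts, exprprep.tmm_factors(counts))
        sel = set(exprprep.identify_housekeeping(logmat))
        planted = set(truth.gene_module[truth.gene_module == "housekeeping"].index)
        signal = set(
            truth.gene_module[
                truth.gene_module.isin(
                    ["cytotoxic", "antigen_presentation", "tgfb_stroma", "desert_program"]
                )
            ].index
        )
        assert planted <= sel
        assert not (sel & signal)

    def test_empty_result_warns(self):
        mat = pd.DataFrame(np.random.default_rng(5).normal(2, 1, (10, 6)))
        with pytest.warns(UserWarning):
            out = exprprep.identify_housekeeping(mat, mean_cutoff=50)
        assert out == []


class TestHousekeepingNormalize:
    def _mat(self, hk_value):
        gen = np.random.default_rng(6)
        mat = pd.DataFrame(
            gen.normal(5, 1, size=(6, 3)),
            index=["ACTB", "ACTG1", "HSP90AB1", "UBC", "x1", "x2"],
        )
        mat.iloc[:4] = hk_value
        return mat

    def test_unit_mean_unchanged(self):
        mat = self._mat(1.0)
        out = exprprep.housekeeping_normalize(mat)
        np.testing.assert_allclose(out.values.to_numpy(), mat.to_numpy())

    def test_mean_ten_divides(self):
        mat = self._mat(10.0)
        out = exprprep.housekeeping_normalize(mat)
        np.testing.assert_allclose(out.values.to_numpy(), mat.to_numpy() / 10.0)

    def test_default_gene_list(self):
        assert exprprep.DEFAULT_HK_GENES == ("ACTB", "ACTG1", "HSP90AB1", "UBC")

    def test_missing_gene_error(self):
        mat = self._mat(1.0).drop(index="UBC")
        with pytest.raises(ValueError, match="UBC"):
            exprprep.housekeeping_normalize(mat)

    def test_scale_consistency(self):
        # adding c to every log2 value of a sample maps (v + c) / (m + c)
        mat = self._mat(2.0)
        out = exprprep.housekeeping_normalize(mat)
        shifted = mat.copy()
        shifted.iloc[:, 0] += 3.0
        out2 = exprprep.housekeeping_normalize(shifted)
        np.testing.assert_allclose(
            out2.values.iloc[:, 0].to_numpy(),
            (mat.iloc[:, 0].to_numpy() + 3.0) / (2.0 + 3.0),
        )
        np.testing.assert_allclose(
            out2.values.iloc[:, 1].to_numpy(), out.values.iloc[:, 1].to_numpy()
        )


class TestPrepPipeline:
    def test_provenance_and_shapes(self, small_cohort):
        counts, _, _ = small_cohort
        norm = exprprep.prep_pipeline(counts)
        assert norm.values.shape[1] == counts.shape[1]
        names = [t["name"] for t in norm.provenance["transforms"]]
        assert names == [
            "filter_low_expression", "tmm", "log2_cpm", "housekeeping_normalize",
        ]
        assert norm.provenance["hk_genes"] == list(exprprep.DEFAULT_HK_GENES)
        assert len(norm.provenance["pca_variance_explained"]) == 5

    def test_worked_fixture_cpm_definition(self):
        counts, _, _ = simdata.worked_fixture()
        c = exprprep.cpm(counts)
        # CPM definition: count 1 in a library of 10^6 is exactly 1.0
        one = _matrix([[1], [999_999]])
        assert exprprep.cpm(one).iloc[0, 0] == pytest.approx(1.0)
        # and on the fixture: cpm * lib / 1e6 reproduces counts
        lib = counts.sum(axis=0)
        np.testing.assert_allclose((c * lib / 1e6).to_numpy(), counts.to_numpy())
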