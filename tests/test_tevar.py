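import numpy as np
import pandas as pd
import pytest

from ribevol import normalization
from ribevol.io import CountMatrix
from ribevol.synthetic import SimConfig, simulate_counts
from ribevol.tevar import (TEError, TEMatrix, compute_te, downsample_group_ci,
                           group_median, resample_group_pvalue, te_var,
                           zero_filter_mask)

from conftest import paired_sample_table, te_matrix_from_frame


def _norm_identity(df: pd.DataFrame) -> normalization.NormalizedMatrix:
    return normalization.NormalizedMatrix(
        df, pd.Series(1.0, index=df.columns))


class TestComputeTe:
    def test_ratio_examples(self):
        samples = paired_sample_table({"a": 2, "b": 2})
        rna = _norm_identity(pd.DataFrame(
            {s: [5.0] for s in samples.samples_for("RNA")}, index=["g"]))
        ribo = _norm_identity(pd.DataFrame(
            {s: [10.0] for s in samples.samples_for("RIBO")}, index=["g"]))
        lin = compute_te(rna, ribo, samples, scale="linear", pseudocount=0.0)
        assert np.allclose(lin.values.to_numpy(), 2.0)
        log = compute_te(rna, ribo, samples, scale="log2", pseudocount=0.0)
        assert np.allclose(log.values.to_numpy(), 1.0)

    def test_zero_rule_three_zeros_excluded(self):
        counts = pd.DataFrame([[0, 0, 0, 8, 9]], index=["g"],
                              columns=[f"s{i}" for i in range(5)])
        species = pd.Series("a", index=counts.columns)
        assert not zero_filter_mask(counts, species).loc["g"]

    def test_zero_rule_median_positive_retained(self):
        counts = pd.DataFrame([[0, 5, 6, 7, 8]], index=["g"],
                              columns=[f"s{i}" for i in range(5)])
        species = pd.Series("a", index=counts.columns)
        assert zero_filter_mask(counts, species).loc["g"]

    def test_zero_rule_median_zero_excluded(self):
        counts = pd.DataFrame([[0, 0, 0, 7, 8, 9]], index=["g"],
                              columns=[f"s{i}" for i in range(6)])
        # median is (0+7)/2 = 3.5 but three zeros -> excluded
        species = pd.Series("a", index=counts.columns)
        assert not zero_filter_mask(counts, species).loc["g"]

    def test_filtered_gene_dropped_globally(self):
        samples = paired_sample_table({"a": 5, "b": 5})
        rna_cols = {}
        for i, s in enumerate(samples.samples_for("RNA")):
            rna_cols[s] = [10.0, 0.0 if i < 3 else 10.0]
        ribo_cols = {s: [10.0, 10.0] for s in samples.samples_for("RIBO")}
        te = compute_te(_norm_identity(pd.DataFrame(rna_cols, index=["keep", "drop"])),
                        _norm_identity(pd.DataFrame(ribo_cols, index=["keep", "drop"])),
                        samples)
        assert list(te.values.index) == ["keep"]
        assert te.dropped_genes == ["drop"]

    def test_all_filtered_errors(self):
        samples = paired_sample_table({"a": 3})
        zeros = _norm_identity(pd.DataFrame(
            {s: [0.0] for s in samples.samples_for("RNA")}, index=["g"]))
        ribo = _norm_identity(pd.DataFrame(
            {s: [5.0] for s in samples.samples_for("RIBO")}, index=["g"]))
        with pytest.raises(TEError, match="zero-count filter"):
            compute_te(zeros, ribo, samples)


class TestTeVar:
    def test_constant_te_gives_zero(self):
        frame = pd.DataFrame([[1.5] * 6], index=["g"],
                             columns=[f"c{i}" for i in range(6)])
        te = te_matrix_from_frame(frame, {f"c{i}": ["a", "b", "c"][i // 2]
                                          for i in range(6)})
        res = te_var(te)
        assert res.loc["g", "te_var"] == pytest.approx(0.0)
        assert res.loc["g", "across_species_variance"] == pytest.approx(0.0)

    def test_hand_computed_between_species_variance(self):
        # per-species means (0,0,0,0,2), zero within-variance:
        # sample variance with n-1=4 denominator = 0.8
        cols = [f"{sp}{r}" for sp in "abcde" for r in range(2)]
        vals = [0.0] * 8 + [2.0] * 2
        frame = pd.DataFrame([vals], index=["g"], columns=cols)
        te = te_matrix_from_frame(frame, {c: c[0] for c in cols})
        res = te_var(te)
        assert res.loc["g", "te_var"] == pytest.approx(0.8)
        assert res.loc["g", "avg_sampling_variance"] == pytest.approx(0.0)

    def test_decomposition_identity_exact(self, small_te):
        res = te_var(small_te)
        assert np.array_equal(
            res["te_var"].to_numpy(),
            (res["across_species_variance"]
             - res["avg_sampling_variance"]).to_numpy())

    def test_null_mean_close_to_zero(self):
        # no between-species signal: mean te_var over many genes ~ 0
        rng = np.random.default_rng(12)
        G, n_sp, n = 10000, 5, 5
        sigma_w = 0.5
        vals = rng.normal(0, sigma_w, size=(G, n_sp * n))
        cols = [f"s{i}" for i in range(n_sp * n)]
        te = te_matrix_from_frame(
            pd.DataFrame(vals, columns=cols,
                         index=[f"g{i}" for i in range(G)]),
            {c: f"sp{i // n}" for i, c in enumerate(cols)})
        res = te_var(te)
        se = res["te_var"].std() / np.sqrt(G)
        assert abs(res["te_var"].mean()) < 3 * se

    def test_single_sample_species_excluded(self):
        cols = ["a1", "a2", "b1", "b2", "c1"]
        frame = pd.DataFrame([[0, 0, 1, 1, 99]], index=["g"], columns=cols,
                             dtype=float)
        te = te_matrix_from_frame(frame, {c: c[0] for c in cols})
        res = te_var(te)
        # species c (one sample) ignored: Var([0,1]) with ddof 1 = 0.5
        assert res.loc["g", "across_species_variance"] == pytest.approx(0.5)
        assert res.loc["g", "n_species_used"] == 2

    def test_fewer_than_two_species_errors(self):
        frame = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"],
                             columns=["a1", "a2", "b1"])
        te = te_matrix_from_frame(frame, {"a1": "a", "a2": "a", "b1": "b"})
        with pytest.raises(TEError, match=">=2 species"):
            te_var(te)

    def test_doubling_ribo_leaves_te_var_unchanged(self, small_sim):
        rna, ribo, samples, _ = small_sim
        te1 = compute_te(normalization.normalize(rna),
                         normalization.normalize(ribo), samples,
                         pseudocount=0.0)
        doubled = CountMatrix(ribo.counts * 2)
        te2 = compute_te(normalization.normalize(rna),
                         normalization.normalize(doubled), samples,
                         pseudocount=0.0)
        # joint renormalization absorbs the global factor entirely
        r1, r2 = te_var(te1), te_var(te2)
        assert np.allclose(r1["te_var"], r2["te_var"], atol=1e-10)


class TestGroupMedian:
    def test_examples(self, small_te):
        res = te_var(small_te)
        one = [res.index[0]]
        assert group_median(res, one) == pytest.approx(res["te_var"].iloc[0])
        sub = res.iloc[:3].copy()
        sub["te_var"] = [0.1, 0.2, 0.9]
        assert group_median(sub, list(sub.index)) == pytest.approx(0.2)
        assert group_median(sub, list(sub.index) + ["missing_gene"]) == \
            pytest.approx(0.2)

    def test_empty_intersection_errors(self, small_te):
        with pytest.raises(TEError, match="no genes"):
            group_median(te_var(small_te), ["not_a_gene"])


class TestResampling:
    def test_observed_larger_than_all_permuted_gives_zero(self):
        rng = np.random.default_rng(0)
        cols = [f"s{i}" for i in range(20)]
        vals = rng.normal(0, 0.05, size=(50, 20))
        vals[:10, :4] += 50.0  # huge species-specific shift for group genes
        te = te_matrix_from_frame(
            pd.DataFrame(vals, columns=cols,
                         index=[f"g{i}" for i in range(50)]),
            {c: f"sp{i // 4}" for i, c in enumerate(cols)})
        out = resample_group_pvalue(te, {"grp": [f"g{i}" for i in range(10)]},
                                    iterations=200, seed=1)
        assert out.loc["grp", "p_one_sided"] == 0.0

    def test_relabeling_species_invariance(self, small_te):
        groups = {"grp": list(small_te.values.index[:20])}
        out1 = resample_group_pvalue(small_te, groups, iterations=100, seed=5)
        relabel = {"sp1": "spB", "sp2": "spC", "sp3": "spA"}
        te2 = TEMatrix(small_te.values.copy(),
                       small_te.species_of.map(relabel), small_te.scale)
        out2 = resample_group_pvalue(te2, groups, iterations=100, seed=5)
        assert out1.loc["grp", "observed_median"] == \
            pytest.approx(out2.loc["grp", "observed_median"])
        assert out1.loc["grp", "p_one_sided"] == \
            pytest.approx(out2.loc["grp", "p_one_sided"])

    def test_absent_group_errors(self, small_te):
        with pytest.raises(TEError, match="absent"):
            resample_group_pvalue(small_te, {"bad": ["nope"]}, iterations=10)


class TestDownsampling:
    def test_degenerate_ci_equals_observed(self, small_te):
        res = te_var(small_te)
        group = list(res.index[:15])
        lo, hi = downsample_group_ci(small_te, group, k_samples=4,
                                     iterations=50, seed=2)
        obs = group_median(res, group)
        assert lo == pytest.approx(obs)
        assert hi == pytest.approx(obs)

    def test_bounds_ordered(self, small_te):
        lo, hi = downsample_group_ci(small_te, list(small_te.values.index[:15]),
                                     k_samples=3, iterations=100, seed=3)
        assert lo <= hi

    def test_k_exceeding_smallest_species_errors(self, small_te):
        with pytest.raises(TEError, match="exceeds"):
            downsample_group_ci(small_te, list(small_te.values.index[:5]),
                                k_samples=10, iterations=10)

    def test_ci_narrows_with_more_samples(self):
        config = SimConfig(n_species=4, samples_per_species=[8] * 4,
                           n_genes=150, sigma_between=0.5, sigma_within=0.4,
                           seed=21)
        rna, ribo, samples, _ = simulate_counts(config)
        te = compute_te(normalization.normalize(rna),
                        normalization.normalize(ribo), samples)
        group = list(te.values.index[:40])
        lo3, hi3 = downsample_group_ci(te, group, k_samples=3,
                                       iterations=300, seed=4)
        lo6, hi6 = downsample_group_ci(te, group, k_samples=6,
                                       iterations=300, seed=4)
        assert (hi6 - lo6) < (hi3 - lo3)
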