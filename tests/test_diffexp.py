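import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import serosom
from serosom import diffexp
from serosom.diffexp import (
    NegativeBinomialDE,
    bh_adjust,
    call_degs,
    estimate_dispersions,
    nb_wald_test,
)
from serosom.quantnorm import CountMatrix, size_factors_median_of_ratios


def bh_bruteforce(p):
    """O(m^2) transcription of the step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for i in range(m):
        candidates = [p[order[j]] * m / (j + 1) for j in range(i, m)]
        out[order[i]] = min(1.0, min(candidates))
    return out


class TestBH:
    def test_closed_form(self):
        assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(bh_adjust(np.ones(5)), 1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_bruteforce_definition(self, p):
        assert np.allclose(bh_adjust(np.array(p)), bh_bruteforce(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    def test_monotone_in_p_rank(self, rng):
        p = rng.uniform(size=200)
        fdr = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(fdr[order]) >= -1e-12).all()


def two_group_cm(counts):
    counts = np.asarray(counts)
    n = counts.shape[1] // 2
    cols = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
    genes = [f"g{i}" for i in range(counts.shape[0])]
    return (
        CountMatrix(pd.DataFrame(counts, index=genes, columns=cols),
                    pd.Series(1000, index=genes)),
        cols[:n],
        cols[n:],
    )


class TestDispersions:
    def test_poisson_counts_give_near_zero_raw_alpha(self, rng):
        counts = rng.poisson(200.0, size=(2000, 6))
        cm, a, b = two_group_cm(counts)
        fit = estimate_dispersions(cm, groups={"a": a, "b": b})
        assert abs(fit.alpha_raw.median()) < 0.01

    def test_constant_counts_give_exactly_zero_raw_alpha(self):
        cm, a, b = two_group_cm(np.full((10, 6), 37))
        fit = estimate_dispersions(cm, groups={"a": a, "b": b})
        assert (fit.alpha_raw == 0).all()

    def test_recovery_at_many_replicates(self, rng):
        # alpha = 0.2 at mu = 500 with 50 replicates per group
        counts = serosom.nb_counts(np.full((2000, 100), 500.0), 0.2, rng)
        cm, a, b = two_group_cm(counts)
        fit = estimate_dispersions(cm, groups={"a": a, "b": b})
        assert abs(fit.alpha_final.median() / 0.2 - 1) < 0.2

    def test_single_replicate_group_rejected(self, rng):
        cm, a, b = two_group_cm(rng.poisson(50, size=(10, 4)))
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersions(cm, groups={"a": a[:1], "b": b})

    def test_trend_bounds_final_from_below(self, rng):
        counts = serosom.nb_counts(np.full((3000, 6), 300.0), 0.1, rng)
        cm, a, b = two_group_cm(counts)
        fit = estimate_dispersions(cm, groups={"a": a, "b": b})
        assert (fit.alpha_final >= fit.alpha_trend - 1e-12).all()


class TestWald:
    def test_identical_groups_zero_lfc(self, rng):
        half = rng.poisson(100, size=(50, 3))
        cm, a, b = two_group_cm(np.hstack([half, half]))
        f = size_factors_median_of_ratios(cm)
        fit = estimate_dispersions(cm, f, {"a": a, "b": b})
        res = nb_wald_test(cm, f, fit, a, b)
        assert np.allclose(res["log2FC"], 0.0)

    def test_label_swap_negates_lfc_and_keeps_p(self, rng):
        counts = rng.poisson(rng.uniform(20, 400, size=(100, 1)), size=(100, 6))
        cm, a, b = two_group_cm(counts)
        f = size_factors_median_of_ratios(cm)
        fit = estimate_dispersions(cm, f, {"a": a, "b": b})
        r1 = nb_wald_test(cm, f, fit, a, b)
        r2 = nb_wald_test(cm, f, fit, b, a)
        assert np.allclose(r1["log2FC"], -r2["log2FC"])
        assert np.allclose(r1["p"], r2["p"])

    def test_scaling_invariance(self, rng):
        counts = rng.poisson(100, size=(80, 6)).astype(float)
        cm, a, b = two_group_cm(counts)
        f = size_factors_median_of_ratios(cm)
        scaled = counts.copy()
        scaled[:, 0] *= 3.0
        cm2, _, _ = two_group_cm(scaled)
        f2 = f.copy()
        f2.iloc[0] *= 3.0
        fit = estimate_dispersions(cm, f, {"a": a, "b": b})
        fit2 = estimate_dispersions(cm2, f2, {"a": a, "b": b})
        r1 = nb_wald_test(cm, f, fit, a, b)
        r2 = nb_wald_test(cm2, f2, fit2, a, b)
        assert np.allclose(r1["log2FC"], r2["log2FC"])
        assert np.allclose(r1["p"], r2["p"])

    def test_all_zero_gene_flagged(self, rng):
        counts = rng.poisson(50, size=(20, 6))
        counts[0] = 0
        cm, a, b = two_group_cm(counts)
        f = size_factors_median_of_ratios(cm)
        fit = estimate_dispersions(cm, f, {"a": a, "b": b})
        res = nb_wald_test(cm, f, fit, a, b)
        assert res["allzero"].iloc[0]
        assert res["p"].iloc[0] == 1.0 and res["log2FC"].iloc[0] == 0.0

    def test_planted_lfc_recovered(self):
        cm, truth = serosom.simulate_two_group(
            3000, 3, frac_de=0.1, lfc=2.0, dispersion=0.05, seed=11
        )
        a = [c for c in cm.sample_ids if "grpA" in c]
        b = [c for c in cm.sample_ids if "grpB" in c]
        f = size_factors_median_of_ratios(cm)
        fit = estimate_dispersions(cm, f, {"a": a, "b": b})
        res = nb_wald_test(cm, f, fit, b, a)  # B over A
        strong = (truth == 2.0) & (res["baseMean"] >= 100)
        assert abs(res.loc[strong, "log2FC"].median() - 2.0) < 0.3

    def test_overlapping_groups_rejected(self, rng):
        cm, a, b = two_group_cm(rng.poisson(50, size=(10, 6)))
        with pytest.raises(ValueError, match="disjoint"):
            f = size_factors_median_of_ratios(cm)
            fit = estimate_dispersions(cm, f, {"a": a, "b": b})
            nb_wald_test(cm, f, fit, a, a)


class TestCallsAndEstimator:
    def test_call_degs_empty(self):
        up, down = call_degs(pd.DataFrame(columns=["log2FC", "fdr"]))
        assert up == [] and down == []

    def test_call_degs_all_ns(self):
        res = pd.DataFrame({"log2FC": [1.0, -1.0], "fdr": [0.5, 0.9]}, index=["a", "b"])
        assert call_degs(res, 0.01) == ([], [])

    def test_estimator_api(self):
        cm, truth = serosom.simulate_two_group(400, 3, frac_de=0.2, seed=3)
        X = cm.counts.T
        y = cm.samples["condition"].to_numpy()
        est = NegativeBinomialDE().fit(X, y)
        res = est.results_
        assert set(res["call"].unique()) <= {"up", "down", "ns"}
        expected_sig = (res["fdr"] < 0.01) & (res["log2FC"] != 0)
        assert ((res["call"] != "ns") == expected_sig).all()
        assert sorted(est.up_ + est.down_) == sorted(res.index[res["call"] != "ns"])
        params = est.get_params()
        assert params["fdr_threshold"] == 0.01
        est.set_params(fdr_threshold=0.2)
        assert est.fdr_threshold == 0.2

    def test_estimator_rejects_bad_labels(self):
        X = np.random.default_rng(0).poisson(50, size=(6, 20))
        with pytest.raises(ValueError, match="two group"):
            NegativeBinomialDE().fit(X, ["a"] * 6)

    def test_fit_from_counts_contrast_direction(self, small_sim):
        cm = small_sim[0]
        est = NegativeBinomialDE().fit_from_counts(cm, "D.HS", "D.24")
        # cytosolic HSPs must come out strongly up in the heat shock
        truth = small_sim[1]
        assert (est.results_.loc[truth.hsp_genes, "log2FC"] > 3).all()
        assert est.results_.loc["SAG-51D", "log2FC"] < -3


def test_matches_pydeseq2_direction_and_magnitude():
    """Independent cross-check against DESeq2's Python implementation."""
    import warnings

    cm, truth = serosom.simulate_two_group(300, 3, frac_de=0.2, lfc=2.0, seed=5)
    a = [c for c in cm.sample_ids if "grpA" in c]
    b = [c for c in cm.sample_ids if "grpB" in c]
    f = size_factors_median_of_ratios(cm)
    fit = estimate_dispersions(cm, f, {"a": a, "b": b})
    mine = nb_wald_test(cm, f, fit, b, a)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        dds = DeseqDataSet(
            counts=cm.counts.T,
            metadata=cm.samples[["condition"]],
            design="~condition",
            quiet=True,
        )
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["condition", "grpB", "grpA"], quiet=True)
        stats.summary()
        ref = stats.results_df

    both = mine.join(ref[["log2FoldChange"]], how="inner").dropna()
    rho = both["log2FC"].corr(both["log2FoldChange"], method="spearman")
    assert rho > 0.9
    planted = truth != 0
    sign_ok = np.sign(both.loc[planted, "log2FC"]) == np.sign(
        both.loc[planted, "log2FoldChange"]
    )
    assert sign_ok.mean() > 0.95
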