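"""Negative-binomial two-group differential expression.

Counts are modelled as NB with Var = mu + alpha * mu^2.  Per-gene
dispersions are estimated by method of moments on size-factor-normalized
counts, a log-log linear mean-dispersion trend is fitted across genes,
and the trend acts as a lower bound on each gene's final dispersion: a
raw estimate above the trend is kept (optionally shrunk geometrically
toward it), one below the trend is replaced by it.  At typical replicate
numbers the raw moment estimate is extremely noisy and its low tail,
taken at face value, makes the Wald test anti-conservative; bounding by
the trend restores near-nominal type-I error.  Group differences
are tested with a Wald statistic, log2 fold change over its delta-method
standard error, against the standard normal; Benjamini-Hochberg step-up
correction yields FDRs and genes below the threshold (0.01 by default)
are called up or down by fold-change sign.

This is intentionally a minimal, fully specified NB pipeline — no
Cox-Reid adjustment, no fold-change shrinkage, no independent filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .quantnorm import CountMatrix, size_factors_median_of_ratios

__all__ = [
    "DispersionFit",
    "NegativeBinomialDE",
    "estimate_dispersions",
    "nb_wald_test",
    "bh_adjust",
    "call_degs",
]

_LN2 = np.log(2.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (classic definition).

    fdr(i) = min_{j >= i} p(j) * m / j on the sorted p-values, capped at
    1; ties are handled stably by the sort.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    fdr_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(fdr_sorted, 1.0)
    return out


@dataclass
class DispersionFit:
    """Raw, trend and final (shrunk) per-gene NB dispersions."""

    alpha_raw: pd.Series
    alpha_trend: pd.Series
    alpha_final: pd.Series
    base_mean: pd.Series
    trend_coef: tuple[float, float]  # intercept, slope of log alpha ~ log mean

    def __post_init__(self) -> None:
        for s in (self.alpha_raw, self.alpha_trend, self.alpha_final):
            if (s < 0).any():
                raise ValueError("dispersions must be non-negative")


_ALPHA_FLOOR = 1e-8


def _group_arrays(cm: CountMatrix, factors: pd.Series, groups: dict[str, list[str]]):
    norm = cm.counts.div(factors, axis=1)
    return {g: norm[cols].to_numpy(dtype=float) for g, cols in groups.items()}


def estimate_dispersions(
    cm: CountMatrix,
    factors: pd.Series | None = None,
    groups: dict[str, list[str]] | None = None,
    trend_weight: float = 0.0,
) -> DispersionFit:
    """Method-of-moments dispersions, lower-bounded by a fitted trend.

    Raw per-gene alpha = max(0, (s^2 - mu) / mu^2) on normalized counts,
    pooling within-group variance when ``groups`` is given (so condition
    effects do not inflate the estimate).  The trend is an OLS fit of
    log(alpha) on log(mean) over genes with positive raw alpha.  Final
    alpha equals the trend where the raw estimate falls below it;
    otherwise the raw estimate, shrunk geometrically toward the trend by
    ``trend_weight`` (0 keeps the raw value, 1 collapses to the trend).
    """
    if factors is None:
        factors = size_factors_median_of_ratios(cm)
    if groups is None:
        groups = {"all": list(cm.sample_ids)}
    for g, cols in groups.items():
        if len(cols) < 2:
            raise ValueError(
                f"group {g!r} has {len(cols)} sample(s); dispersion estimation "
                "requires at least 2 replicates per group"
            )
    arrays = list(_group_arrays(cm, factors, groups).values())
    n_total = sum(a.shape[1] for a in arrays)
    mu = sum(a.sum(axis=1) for a in arrays) / n_total
    # pooled within-group variance
    ss = sum(((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for a in arrays)
    df = n_total - len(arrays)
    var = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, np.maximum(0.0, (var - mu) / mu**2), 0.0)

    ok = (raw > 0) & (mu > 0)
    if ok.sum() >= 10:
        x = np.log(mu[ok])
        y = np.log(raw[ok])
        slope, intercept = np.polyfit(x, y, 1)
    else:  # too few informative genes: flat trend at the median raw alpha
        intercept = np.log(max(np.median(raw[raw > 0]), _ALPHA_FLOOR)) if ok.any() else np.log(_ALPHA_FLOOR)
        slope = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        trend = np.where(mu > 0, np.exp(intercept + slope * np.log(np.maximum(mu, 1e-12))), 0.0)
    trend = np.maximum(trend, _ALPHA_FLOOR)

    w = float(trend_weight)
    if not 0.0 <= w <= 1.0:
        raise ValueError("trend_weight must be in [0, 1]")
    raw_f = np.maximum(raw, _ALPHA_FLOOR)
    lifted = np.exp(w * np.log(trend) + (1 - w) * np.log(raw_f))
    final = np.where(raw_f > trend, lifted, trend)
    final = np.where(mu > 0, final, 0.0)

    idx = cm.gene_ids
    return DispersionFit(
        alpha_raw=pd.Series(raw, index=idx, name="alpha_raw"),
        alpha_trend=pd.Series(np.where(mu > 0, trend, 0.0), index=idx, name="alpha_trend"),
        alpha_final=pd.Series(final, index=idx, name="alpha_final"),
        base_mean=pd.Series(mu, index=idx, name="base_mean"),
        trend_coef=(float(intercept), float(slope)),
    )


def nb_wald_test(
    cm: CountMatrix,
    factors: pd.Series,
    fit: DispersionFit,
    group_a: list[str],
    group_b: list[str],
    lfc_offset: float = 0.5,
) -> pd.DataFrame:
    """Per-gene Wald test of group A versus group B.

    log2FC is log2((mean_A + offset) / (mean_B + offset)) of normalized
    counts (positive = higher in A); its standard error comes from the NB
    variance, SE^2 = [(1/mA + alpha)/nA + (1/mB + alpha)/nB] / ln(2)^2
    with the offset applied to the means.  Genes that are all-zero in
    both groups get p = 1, log2FC = 0 and an ``allzero`` flag.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    norm = cm.counts.div(factors, axis=1)
    a = norm[list(group_a)].to_numpy(dtype=float)
    b = norm[list(group_b)].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    m_a, m_b = a.mean(axis=1), b.mean(axis=1)
    alpha = fit.alpha_final.to_numpy()

    off = float(lfc_offset)
    lfc = np.log2(m_a + off) - np.log2(m_b + off)
    se2 = ((1.0 / (m_a + off) + alpha) / n_a + (1.0 / (m_b + off) + alpha) / n_b) / _LN2**2
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    allzero = (m_a == 0) & (m_b == 0)
    lfc[allzero] = 0.0
    z[allzero] = 0.0
    p[allzero] = 1.0

    res = pd.DataFrame(
        {
            "baseMean": (m_a * n_a + m_b * n_b) / (n_a + n_b),
            "log2FC": lfc,
            "SE": se,
            "stat": z,
            "p": np.clip(p, 0.0, 1.0),
            "allzero": allzero,
        },
        index=cm.gene_ids,
    )
    res["fdr"] = bh_adjust(res["p"].to_numpy())
    return res


def call_degs(
    results: pd.DataFrame, fdr_threshold: float = 0.01
) -> tuple[list[str], list[str]]:
    """Partition significant genes (fdr < threshold) by fold-change sign."""
    if len(results) == 0:
        return [], []
    sig = results["fdr"] < fdr_threshold
    up = list(results.index[sig & (results["log2FC"] > 0)])
    down = list(results.index[sig & (results["log2FC"] < 0)])
    return up, down


class NegativeBinomialDE(BaseEstimator):
    """Two-group NB differential expression as a scikit-learn estimator.

    Parameters
    ----------
    fdr_threshold : float
        FDR below which a gene is called differentially expressed.
    lfc_offset : float
        Pseudo-mean added to group means before the log ratio.
    trend_weight : float
        Geometric shrinkage toward the trend for raw dispersions above
        it (the trend always bounds the final dispersion from below).
    contrast : tuple of (str, str), optional
        (group_a, group_b); log2FC is A over B.  Defaults to the two
        labels in sorted order.

    ``fit(X, y)`` takes X with shape (n_samples, n_genes) and y a label
    per sample with exactly two levels.  Fitted attributes:
    ``size_factors_``, ``dispersion_`` (a :class:`DispersionFit`),
    ``results_`` (per-gene table with ``call``), ``up_``, ``down_``.
    """

    def __init__(
        self,
        fdr_threshold: float = 0.01,
        lfc_offset: float = 0.5,
        trend_weight: float = 0.0,
        contrast: tuple[str, str] | None = None,
    ):
        self.fdr_threshold = fdr_threshold
        self.lfc_offset = lfc_offset
        self.trend_weight = trend_weight
        self.contrast = contrast

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            genes = X.columns
            sample_ids = [str(s) for s in X.index]
            mat = X.to_numpy().T
        else:
            mat = np.asarray(X).T
            genes = pd.Index([f"g{i}" for i in range(mat.shape[0])])
            sample_ids = [f"s{i}" for i in range(mat.shape[1])]
        y = np.asarray(y)
        if y.shape[0] != mat.shape[1]:
            raise ValueError("y must have one label per sample")
        levels = sorted(pd.unique(y).tolist())
        if len(levels) != 2:
            raise ValueError(f"need exactly two group labels, got {levels}")
        if self.contrast is not None:
            a, b = self.contrast
            if sorted((a, b)) != levels:
                raise ValueError(f"contrast {self.contrast} does not match labels {levels}")
        else:
            a, b = levels
        counts = pd.DataFrame(mat, index=genes, columns=sample_ids)
        lengths = pd.Series(1000, index=genes)  # lengths unused by the NB test
        cm = CountMatrix(counts, lengths)
        groups = {
            a: [s for s, lab in zip(sample_ids, y) if lab == a],
            b: [s for s, lab in zip(sample_ids, y) if lab == b],
        }
        self.size_factors_ = size_factors_median_of_ratios(cm)
        self.dispersion_ = estimate_dispersions(
            cm, self.size_factors_, groups, trend_weight=self.trend_weight
        )
        res = nb_wald_test(
            cm, self.size_factors_, self.dispersion_,
            groups[a], groups[b], lfc_offset=self.lfc_offset,
        )
        call = np.where(
            res["fdr"] < self.fdr_threshold,
            np.where(res["log2FC"] > 0, "up", "down"),
            "ns",
        )
        # a zero log2FC can never be called
        call[(res["log2FC"] == 0).to_numpy() & (call != "ns")] = "ns"
        res["call"] = call
        self.results_ = res
        self.up_, self.down_ = call_degs(res, self.fdr_threshold)
        self.contrast_ = (a, b)
        return self

    def fit_from_counts(
        self, cm: CountMatrix, condition_a: str, condition_b: str
    ) -> "NegativeBinomialDE":
        """Convenience: fit from a CountMatrix with a sample sheet."""
        cols_a = cm.condition_samples(condition_a)
        cols_b = cm.condition_samples(condition_b)
        sub = cm.counts[cols_a + cols_b].T
        y = [condition_a] * len(cols_a) + [condition_b] * len(cols_b)
        self.contrast = (condition_a, condition_b)
        return self.fit(sub, y)
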