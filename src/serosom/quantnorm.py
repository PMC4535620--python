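"""Expression-unit conversions and between-sample normalization.

Counts are held in a :class:`CountMatrix` (genes x samples, with gene
lengths and a sample sheet).  Unit conversions produce an
:class:`ExpressionMatrix` that records its unit (TPM, RPKM, their log10
forms, or normalized counts) and the pseudocount used for log transforms.

RPKM(g, s) = 1e9 * count(g, s) / (length(g) * colsum(s)); TPM rescales
length-normalized rates so every column sums to 1e6.  Between-sample
normalization uses the median-of-ratios size factors of the DESeq family:
factor(s) = median over universally expressed genes of
count(g, s) / geometric-mean_g(count(g, .)).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "to_rpkm",
    "to_tpm",
    "log_transform",
    "size_factors_median_of_ratios",
    "normalized_counts",
]


@dataclass
class CountMatrix:
    """Gene x sample integer count matrix with gene lengths.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts, genes as rows, samples as columns.
    lengths : pandas.Series
        Gene lengths in bases, indexed like ``counts``.
    samples : pandas.DataFrame, optional
        Sample sheet indexed by sample id; typical columns are
        ``condition``, ``replicate``, ``temperature``, ``serotype``,
        ``parent``.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()][:3].tolist()
            raise ValueError(f"missing gene lengths, e.g. {missing}")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("counts must be finite")
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if self.samples is not None:
            self.samples = self.samples.reindex(self.counts.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def condition_samples(self, condition: str) -> list[str]:
        """Sample ids belonging to one condition (needs a sample sheet)."""
        if self.samples is None:
            raise ValueError("no sample sheet attached")
        mask = self.samples["condition"] == condition
        if not mask.any():
            raise KeyError(f"unknown condition {condition!r}")
        return list(self.samples.index[mask])

    # -- plain-text IO -------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, samples: pd.DataFrame | None = None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        lengths = df.pop("length")
        return cls(df, lengths, samples)


@dataclass
class ExpressionMatrix:
    """Real-valued expression matrix with a recorded unit."""

    values: pd.DataFrame
    unit: str
    pseudocount: float = 0.0

    _UNITS = {"TPM", "RPKM", "log-TPM", "log-RPKM", "normalized-counts"}

    def __post_init__(self) -> None:
        if self.unit not in self._UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# unit={self.unit} pseudocount={self.pseudocount:g}\n")
            self.values.to_csv(fh, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        with open(path) as fh:
            header = fh.readline().strip()
            body = fh.read()
        meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split())
        values = pd.read_csv(io.StringIO(body), sep="\t", index_col="gene_id")
        return cls(values, meta["unit"], float(meta.get("pseudocount", 0.0)))


def _check_colsums(cm: CountMatrix) -> pd.Series:
    colsums = cm.counts.sum(axis=0)
    zero = colsums.index[colsums == 0]
    if len(zero):
        raise ValueError(f"zero total count in sample(s): {list(zero)}")
    return colsums


def to_rpkm(cm: CountMatrix) -> ExpressionMatrix:
    """Reads per kilobase per million mapped reads."""
    colsums = _check_colsums(cm)
    vals = 1e9 * cm.counts.div(cm.lengths, axis=0).div(colsums, axis=1)
    return ExpressionMatrix(vals, "RPKM")


def to_tpm(cm: CountMatrix) -> ExpressionMatrix:
    """Transcripts per million: columns each sum to 1e6."""
    _check_colsums(cm)
    rates = cm.counts.div(cm.lengths, axis=0)
    rate_sums = rates.sum(axis=0)
    if (rate_sums == 0).any():
        zero = list(rate_sums.index[rate_sums == 0])
        raise ValueError(f"zero total count in sample(s): {zero}")
    return ExpressionMatrix(1e6 * rates.div(rate_sums, axis=1), "TPM")


def log_transform(em: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log10(x + pseudocount), recording the pseudocount in the unit."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if em.unit.startswith("log-"):
        raise ValueError(f"matrix already log-scaled ({em.unit})")
    unit = "log-" + em.unit if em.unit in ("TPM", "RPKM") else em.unit
    if unit == em.unit:
        raise ValueError(f"cannot log-transform unit {em.unit!r}")
    return ExpressionMatrix(np.log10(em.values + pseudocount), unit, pseudocount)


def size_factors_median_of_ratios(cm: CountMatrix) -> pd.Series:
    """DESeq-style median-of-ratios size factors.

    Genes with a zero count in any sample are excluded from the reference
    gene set; at least one universally expressed gene is required.
    """
    counts = cm.counts.to_numpy(dtype=float)
    expressed = (counts > 0).all(axis=1)
    if not expressed.any():
        raise ValueError(
            "no gene expressed in every sample; filter the matrix or "
            "check for failed libraries before computing size factors"
        )
    sub = counts[expressed]
    log_geomean = np.log(sub).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(sub) - log_geomean)
    return pd.Series(np.median(ratios, axis=0), index=cm.sample_ids, name="size_factor")


def normalized_counts(cm: CountMatrix, factors: pd.Series | None = None) -> ExpressionMatrix:
    """Counts divided by per-sample size factors."""
    if factors is None:
        factors = size_factors_median_of_ratios(cm)
    vals = cm.counts.div(factors, axis=1)
    return ExpressionMatrix(vals, "normalized-counts")
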