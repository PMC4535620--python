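"""Self-organizing-map transcriptome landscapes and regulated spots.

Genes (observations, one feature per sample) are mapped onto a 20x20
Kohonen lattice.  Each lattice unit is a *metagene*: a codebook vector
whose member genes are those for which it is the best-matching unit.  A
sample's *landscape* assigns each unit the mean expression of its member
genes in that sample.  Units are classified per sample by the extremum
band rule: a metagene with expression de is over-expressed when
de > MaxEXP * 0.9 and under-expressed when de < MinEXP * 0.9 (strict
inequalities), where MaxEXP/MinEXP are the landscape's extreme metagene
values.  Connected groups of same-class units form *regulated spots*.

Training is classic online Kohonen: Gaussian neighbourhood, geometric
decay of learning rate and radius, codebook initialized from random data
rows, fully determined by ``random_state``.  By default genes are
mean-centered across samples and then saturated at +/- ``clip``
(winsorized portraits).  The bound matters for the extremum rule: on
unbounded centered data a single gene of extreme dynamic range (an
active surface-antigen gene, say) forms its own unit, monopolizes MaxEXP
and collapses the band to that one unit, whereas with saturation every
strongly over-expressed unit sits at the ceiling and the band selects
the whole co-regulated set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SOMLandscape",
    "MetageneLandscape",
    "RegulatedSpot",
    "classify_metagenes",
    "detect_spots",
    "spot_summary",
]

OVER, NONE, UNDER = 1, 0, -1


@dataclass
class MetageneLandscape:
    """Per-sample metagene expression on the lattice.

    ``grid`` holds the mean scaled expression of each unit's member genes
    in one sample; empty units carry the codebook value and are flagged
    in ``empty`` (they are excluded from MaxEXP/MinEXP and from
    classification).
    """

    sample: str
    grid: np.ndarray          # rows x cols
    empty: np.ndarray         # rows x cols bool
    max_exp: float = field(init=False)
    min_exp: float = field(init=False)

    def __post_init__(self) -> None:
        occupied = self.grid[~self.empty]
        if occupied.size == 0:
            raise ValueError("landscape has no occupied units")
        self.max_exp = float(occupied.max())
        self.min_exp = float(occupied.min())


@dataclass
class RegulatedSpot:
    """A maximal connected set of same-class units plus its member genes."""

    sample: str
    spot_class: str            # "over" | "under"
    units: frozenset[tuple[int, int]]
    genes: frozenset[str]
    anchor: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        self.anchor = min(self.units)

    @property
    def size(self) -> int:
        return len(self.genes)


class SOMLandscape(BaseEstimator, TransformerMixin):
    """Kohonen SOM over genes, exposing landscapes and spot detection.

    Parameters
    ----------
    rows, cols : int
        Lattice dimensions (default 20 x 20).
    n_epochs : int
        Passes over the genes during online training.
    learning_rate : (float, float)
        Initial and final learning rate, decayed linearly.
    radius : (float or None, float)
        Initial and final Gaussian neighbourhood radius in lattice units;
        ``None`` starts at max(rows, cols) / 2.
    scale : {"center", "zscore", "none"}
        Per-gene preprocessing across samples before training.
    clip : float or None
        Saturation bound applied after scaling (None disables).  With the
        default centered scale this bounds each gene's portrait to
        [-clip, clip], which pins MaxEXP to the ceiling and makes the
        extremum band a co-regulation selector instead of an
        outlier-amplitude selector.
    extremum_scope : {"sample", "global"}
        Whether MaxEXP/MinEXP are taken per sample landscape (default) or
        over all samples at once.
    spot_factor : float
        The extremum-band factor (default 0.9).
    adjacency : {4, 8}
        Lattice connectivity for spot detection.
    random_state : int or None
        Seed for codebook init and presentation order.

    ``fit(X)`` takes X of shape (n_genes, n_samples).  Fitted attributes:
    ``codebook_`` (units x samples), ``labels_`` (best-matching unit per
    gene), ``quantization_error_``, ``initial_quantization_error_``,
    ``empty_units_``, ``gene_ids_``, ``sample_ids_``.
    """

    def __init__(
        self,
        rows: int = 20,
        cols: int = 20,
        n_epochs: int = 10,
        learning_rate: tuple[float, float] = (0.5, 0.01),
        radius: tuple[float | None, float] = (None, 0.3),
        decay: str = "exponential",
        scale: str = "center",
        clip: float | None = 0.35,
        extremum_scope: str = "sample",
        spot_factor: float = 0.9,
        adjacency: int = 8,
        random_state: int | None = None,
    ):
        self.rows = rows
        self.cols = cols
        self.n_epochs = n_epochs
        self.learning_rate = learning_rate
        self.radius = radius
        self.decay = decay
        self.scale = scale
        self.clip = clip
        self.extremum_scope = extremum_scope
        self.spot_factor = spot_factor
        self.adjacency = adjacency
        self.random_state = random_state

    # -- internals -----------------------------------------------------
    def _validate(self, X):
        if isinstance(X, pd.DataFrame):
            genes = pd.Index(X.index)
            samples = list(X.columns)
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            genes = pd.Index([f"g{i}" for i in range(arr.shape[0])])
            samples = [f"s{j}" for j in range(arr.shape[1])]
        if arr.ndim != 2:
            raise ValueError("X must be 2-dimensional (genes x samples)")
        if not np.isfinite(arr).all():
            raise ValueError("X contains NaN or infinite values")
        if arr.shape[1] < 2:
            raise ValueError("need at least 2 samples to train a landscape")
        return arr, genes, samples

    def _scaled(self, arr: np.ndarray) -> np.ndarray:
        if self.scale == "none":
            out = arr
        elif self.scale in ("center", "zscore"):
            out = arr - arr.mean(axis=1, keepdims=True)
            if self.scale == "zscore":
                sd = arr.std(axis=1, keepdims=True)
                sd[sd == 0] = 1.0  # flat genes stay at zero
                out = out / sd
        else:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.clip is not None:
            if self.clip <= 0:
                raise ValueError("clip must be positive")
            out = np.clip(out, -self.clip, self.clip)
        return out

    def _lattice_dist2(self) -> np.ndarray:
        r, c = np.divmod(np.arange(self.rows * self.cols), self.cols)
        dr = r[:, None] - r[None, :]
        dc = c[:, None] - c[None, :]
        return (dr**2 + dc**2).astype(float)

    # -- estimator API -------------------------------------------------
    def fit(self, X, y=None):
        if self.rows * self.cols < 4:
            raise ValueError("lattice must have at least 4 units")
        if self.adjacency not in (4, 8):
            raise ValueError("adjacency must be 4 or 8")
        arr, genes, samples = self._validate(X)
        n_units = self.rows * self.cols
        if arr.shape[0] < n_units:
            warnings.warn(
                f"{arr.shape[0]} genes for {n_units} units; many units will be empty",
                stacklevel=2,
            )
        data = self._scaled(arr)
        rng = np.random.default_rng(self.random_state)
        n = data.shape[0]

        codebook = data[rng.integers(0, n, size=n_units)].copy()
        self.initial_quantization_error_ = self._qe(data, codebook)

        lr0, lr1 = self.learning_rate
        rad0 = self.radius[0] if self.radius[0] is not None else max(self.rows, self.cols) / 2.0
        rad1 = self.radius[1]
        if lr0 < lr1 or rad0 < rad1 or min(lr1, rad1) <= 0:
            raise ValueError("learning rate and radius must be positive and non-increasing")
        d2 = self._lattice_dist2()

        total = self.n_epochs * n
        t = 0
        for _ in range(self.n_epochs):
            for i in rng.permutation(n):
                frac = t / max(total - 1, 1)
                if self.decay == "linear":
                    lr = lr0 + (lr1 - lr0) * frac
                    rad = rad0 + (rad1 - rad0) * frac
                else:  # geometric: most of training runs at small radius
                    lr = lr0 * (lr1 / lr0) ** frac
                    rad = rad0 * (rad1 / rad0) ** frac
                x = data[i]
                bmu = int(np.argmin(((codebook - x) ** 2).sum(axis=1)))
                h = np.exp(-d2[bmu] / (2.0 * rad * rad))
                codebook += (lr * h)[:, None] * (x - codebook)
                t += 1

        self.codebook_ = codebook
        self.gene_ids_ = genes
        self.sample_ids_ = samples
        self._train_data = data
        self.labels_ = self._assign(data)
        self.quantization_error_ = self._qe(data, codebook)
        counts = np.bincount(self.labels_, minlength=n_units)
        self.empty_units_ = counts == 0
        self.unit_counts_ = counts
        return self

    @staticmethod
    def _dist2(data: np.ndarray, codebook: np.ndarray) -> np.ndarray:
        d2 = (
            (data**2).sum(axis=1)[:, None]
            + (codebook**2).sum(axis=1)[None, :]
            - 2.0 * data @ codebook.T
        )
        return np.maximum(d2, 0.0)

    @classmethod
    def _qe(cls, data: np.ndarray, codebook: np.ndarray) -> float:
        return float(np.sqrt(cls._dist2(data, codebook).min(axis=1)).mean())

    def _assign(self, data: np.ndarray) -> np.ndarray:
        # argmin breaks ties toward the lowest unit index
        return self._dist2(data, self.codebook_).argmin(axis=1)

    def predict(self, X) -> np.ndarray:
        """Best-matching unit index for each gene (row) of X."""
        arr, _, _ = self._validate(X)
        return self._assign(self._scaled(arr))

    def transform(self, X) -> np.ndarray:
        """Metagene landscapes for each sample: (n_samples, rows*cols).

        Column j of X is summarized as the per-unit mean of its member
        genes (membership from the training assignment); empty units
        carry the codebook value.
        """
        arr, _, _ = self._validate(X)
        data = self._scaled(arr)
        if arr.shape[0] != len(self.gene_ids_):
            raise ValueError("X must contain the training genes (same rows)")
        n_units = self.rows * self.cols
        out = np.empty((data.shape[1], n_units))
        for j in range(data.shape[1]):
            sums = np.bincount(self.labels_, weights=data[:, j], minlength=n_units)
            with np.errstate(invalid="ignore"):
                means = sums / self.unit_counts_
            means[self.empty_units_] = self.codebook_[self.empty_units_, j] if j < self.codebook_.shape[1] else 0.0
            out[j] = means
        return out

    # -- landscapes and spots ------------------------------------------
    def landscape(self, sample: str) -> MetageneLandscape:
        """The fitted landscape of one training sample."""
        if sample not in self.sample_ids_:
            raise KeyError(f"unknown sample {sample!r}")
        j = self.sample_ids_.index(sample)
        grid = self.transform_training()[j].reshape(self.rows, self.cols)
        return MetageneLandscape(sample, grid, self.empty_units_.reshape(self.rows, self.cols))

    def transform_training(self) -> np.ndarray:
        n_units = self.rows * self.cols
        data = self._train_data
        out = np.empty((data.shape[1], n_units))
        for j in range(data.shape[1]):
            sums = np.bincount(self.labels_, weights=data[:, j], minlength=n_units)
            with np.errstate(invalid="ignore"):
                means = np.where(self.unit_counts_ > 0, sums / np.maximum(self.unit_counts_, 1), 0.0)
            means[self.empty_units_] = self.codebook_[self.empty_units_, j]
            out[j] = means
        return out

    def landscapes(self) -> list[MetageneLandscape]:
        return [self.landscape(s) for s in self.sample_ids_]

    def unit_genes(self, unit: int) -> list[str]:
        return list(self.gene_ids_[self.labels_ == unit])

    def spots(self, sample: str) -> list[RegulatedSpot]:
        """Regulated spots of one training sample under the fitted config."""
        ls = self.landscape(sample)
        bounds = self._global_bounds() if self.extremum_scope == "global" else None
        classified = classify_metagenes(ls, factor=self.spot_factor, bounds=bounds)
        return detect_spots(classified, self, sample, adjacency=self.adjacency)

    def _global_bounds(self) -> tuple[float, float]:
        grids = self.transform_training()
        occ = ~self.empty_units_
        return float(grids[:, occ].max()), float(grids[:, occ].min())

    def all_spots(self) -> list[RegulatedSpot]:
        return [s for sample in self.sample_ids_ for s in self.spots(sample)]


def classify_metagenes(
    ls: MetageneLandscape,
    factor: float = 0.9,
    bounds: tuple[float, float] | None = None,
) -> np.ndarray:
    """Classify units as over (+1), under (-1) or none (0).

    A unit is over-expressed iff de > MaxEXP * factor and under-expressed
    iff de < MinEXP * factor, with strict inequalities.  The rule bounds
    a proper extreme band only when MaxEXP > 0 and MinEXP < 0 (generic
    after gene-wise centering or z-scoring); in other sign regimes all
    units are classified none with a warning.  ``bounds`` overrides
    (MaxEXP, MinEXP), e.g. with global extremes across samples.
    """
    max_exp, min_exp = bounds if bounds is not None else (ls.max_exp, ls.min_exp)
    out = np.zeros(ls.grid.shape, dtype=np.int8)
    if max_exp == min_exp:
        return out
    if max_exp <= 0 or min_exp >= 0:
        warnings.warn(
            f"extremum rule ill-posed for sample {ls.sample!r} "
            f"(MaxEXP={max_exp:.3g}, MinEXP={min_exp:.3g}); classifying none",
            stacklevel=2,
        )
        return out
    out[ls.grid > max_exp * factor] = OVER
    out[ls.grid < min_exp * factor] = UNDER
    out[ls.empty] = NONE
    return out


_STRUCTS = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]),
    8: np.ones((3, 3), dtype=int),
}


def detect_spots(
    classified: np.ndarray,
    model: SOMLandscape,
    sample: str,
    adjacency: int = 8,
) -> list[RegulatedSpot]:
    """Maximal connected components of same-class units.

    Components are found separately for the over and under classes with
    the requested 4- or 8-neighbour lattice connectivity; spots are
    ordered by gene count descending, then row-major anchor.
    """
    if adjacency not in _STRUCTS:
        raise ValueError("adjacency must be 4 or 8")
    spots: list[RegulatedSpot] = []
    for cls_val, cls_name in ((OVER, "over"), (UNDER, "under")):
        labels, n = ndimage.label(classified == cls_val, structure=_STRUCTS[adjacency])
        for comp in range(1, n + 1):
            coords = np.argwhere(labels == comp)
            units = frozenset((int(r), int(c)) for r, c in coords)
            genes: set[str] = set()
            for r, c in units:
                genes.update(model.unit_genes(r * model.cols + c))
            spots.append(RegulatedSpot(sample, cls_name, units, frozenset(genes)))
    spots.sort(key=lambda s: (-s.size, s.anchor))
    return spots


def spot_summary(
    spots: list[RegulatedSpot], gene_ids=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate spots and build a gene x (sample, class) incidence matrix.

    The incidence entry is True when the gene belongs to any spot of that
    sample and class; row sums therefore count each gene's spot
    memberships across landscapes.
    """
    rows = [
        {
            "sample": s.sample,
            "class": s.spot_class,
            "n_units": len(s.units),
            "n_genes": s.size,
            "anchor_row": s.anchor[0],
            "anchor_col": s.anchor[1],
        }
        for s in spots
    ]
    table = pd.DataFrame(
        rows, columns=["sample", "class", "n_units", "n_genes", "anchor_row", "anchor_col"]
    )
    if gene_ids is None:
        gene_ids = sorted({g for s in spots for g in s.genes})
    cols = sorted({(s.sample, s.spot_class) for s in spots})
    incidence = pd.DataFrame(
        False,
        index=pd.Index(gene_ids, name="gene_id"),
        columns=pd.MultiIndex.from_tuples(cols, names=["sample", "class"])
        if cols
        else pd.MultiIndex.from_arrays([[], []], names=["sample", "class"]),
    )
    for s in spots:
        incidence.loc[list(s.genes), (s.sample, s.spot_class)] = True
    return table, incidence
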