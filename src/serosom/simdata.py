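"""Seeded synthetic multi-condition RNA-seq datasets with ground truth.

The default design emulates a serotype-expression study in *Paramecium*:
seven culture conditions with three biological replicates each, an
eight-gene surface-antigen (SAg) family under mutually exclusive
expression (one dominant gene per serotype), a planted module of genes
co-regulated with each serotype's active SAg, condition programs (cold
adaptation, starvation, and a heat shock that activates cytosolic HSP70
genes while decaying the SAg and its module), gene-wise NB dispersions
(Var = mu + alpha * mu^2) and unequal library sizes.

Everything downstream is tested against the returned :class:`SimTruth`.
All magnitudes beyond the design's structure (activation/decay factors,
perturbed fractions, dispersion and baseline distributions) are
configurable defaults of this generator, not measured values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .goenrich import GODataset
from .quantnorm import CountMatrix
from .tpescan import Scaffold, SubtelomereMap

__all__ = [
    "ConditionSpec",
    "SimConfig",
    "SimTruth",
    "simulate_dataset",
    "simulate_null",
    "simulate_two_group",
    "simulate_subtelomere",
    "nb_counts",
    "write_dataset",
]


@dataclass(frozen=True)
class ConditionSpec:
    """One culture condition: name, temperature, serotype and program."""

    name: str
    temperature: float
    serotype: str
    parent: str | None = None
    program: str = "baseline"

    def __post_init__(self) -> None:
        if self.program not in {"baseline", "cold", "starve", "heatshock"}:
            raise ValueError(f"unknown program {self.program!r}")


def default_conditions() -> list[ConditionSpec]:
    """Seven conditions: four serotype-pure cultures plus a cold-adapted,
    a starved and a heat-shocked derivative."""
    return [
        ConditionSpec("A.31", 31, "A"),
        ConditionSpec("B.24", 24, "B"),
        ConditionSpec("D.24", 24, "D"),
        ConditionSpec("H.14", 14, "H"),
        ConditionSpec("B.6", 6, "B", parent="B.24", program="cold"),
        ConditionSpec("D.starv", 24, "D", parent="D.24", program="starve"),
        ConditionSpec("D.HS", 39, "D", parent="D.24", program="heatshock"),
    ]


_SAG_NAMES = ["SAG-51A", "SAG-51B", "SAG-51D", "SAG-51H",
              "SAG-51E", "SAG-51F", "SAG-51G", "SAG-51I"]


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset.

    Defaults: 6000 genes, 8 SAg genes, 7 conditions x 3 replicates,
    one 500-gene co-regulated module per serotype at log2 effect 2.
    """

    n_genes: int = 6000
    n_sag: int = 8
    n_hsp: int = 6
    conditions: list[ConditionSpec] = field(default_factory=default_conditions)
    n_replicates: int = 3
    module_sizes: dict[str, int] | None = None  # serotype -> size; default 500 each
    lfc_module: float = 2.0
    # gene-wise dispersion alpha ~ lognormal(meanlog, sdlog); clonal culture
    # replicates are tightly controlled, so alpha centres on 0.02
    dispersion_shape: tuple[float, float] = (float(np.log(0.02)), 0.5)
    # baseline gene means ~ lognormal(meanlog, sdlog), count scale
    baseline_shape: tuple[float, float] = (4.0, 1.0)
    # co-regulated module genes are well expressed, so their baselines are
    # drawn from a higher, tighter distribution
    module_baseline_shape: tuple[float, float] = (4.7, 0.6)
    libsize_range: tuple[float, float] = (0.5, 2.0)
    sag_on_mean: float = 3.0e4
    sag_off_mean: float = 30.0
    starve_sag_factor: float = 0.8   # slightly reduced under starvation
    # Heat shock interpolates the serotype program geometrically toward the
    # silent state: HS mean = inactive * (active / inactive) ** hs_residual,
    # applied with the same residual to the SAg and its module so both decay
    # by the same fraction of their log-scale activation.  The default keeps
    # the decayed SAg ~16-fold below its active level (a drastic reduction)
    # while still >=50-fold above the silent family members, preserving
    # mutual exclusion in every condition.
    hs_residual: float = 0.6
    # per-replicate shock intensity lambda ~ U(range): a weaker shock both
    # activates the HSPs less (activation^lambda) and decays the serotype
    # program less, producing the replicate-level inverse correlation
    # between HSP induction and SAg loss; the range is kept narrow enough
    # that even the weakest shock still destroys the module spot
    hs_intensity_range: tuple[float, float] = (0.75, 1.0)
    # the SAg family is epigenetically locked and extremely abundant, so its
    # replicate-to-replicate dispersion is far below the genome-wide draw
    sag_dispersion: float = 0.005
    hsp_activation: float = 32.0     # cytosolic HSP70 induction
    hsp_base_mean: float = 200.0
    perturb_frac: dict[str, float] = field(
        default_factory=lambda: {"cold": 0.15, "starve": 0.20}
    )
    perturb_lfc_range: tuple[float, float] = (1.0, 2.5)
    # subtelomeric layout attached to the dataset
    scaffold_neighbours: int = 11    # genes per scaffold besides the focal SAg
    focal_rank: int = 2              # genes between the focal SAg and the EOS
    # flat GO ontology with one planted enriched term
    n_go_terms: int = 30
    go_term_size: tuple[int, int] = (30, 120)
    planted_term_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_sag, self.n_hsp, self.n_replicates) < 1:
            raise ValueError("all sizes must be >= 1")
        if self.n_sag > len(_SAG_NAMES):
            raise ValueError(f"n_sag must be <= {len(_SAG_NAMES)}")
        serotypes = []
        for c in self.conditions:
            if c.serotype not in serotypes:
                serotypes.append(c.serotype)
        if len(serotypes) > self.n_sag:
            raise ValueError("more serotypes than SAg genes")
        self.serotypes = serotypes
        if self.module_sizes is None:
            self.module_sizes = {s: 500 for s in serotypes}
        if any(v < 1 for v in self.module_sizes.values()):
            raise ValueError("module sizes must be >= 1")
        unknown = set(self.module_sizes) - set(serotypes)
        if unknown:
            raise ValueError(f"module for unknown serotype(s) {sorted(unknown)}")
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate condition names")
        for c in self.conditions:
            if c.parent is not None and c.parent not in names:
                raise ValueError(f"unknown parent condition {c.parent!r}")
        reserved = self.n_sag + self.n_hsp + sum(self.module_sizes.values())
        n_scaff_genes = len(serotypes) * self.scaffold_neighbours
        if reserved + n_scaff_genes > self.n_genes:
            raise ValueError(
                f"planted sets ({reserved} genes) plus scaffold neighbours "
                f"({n_scaff_genes}) exceed n_genes={self.n_genes}"
            )
        if self.focal_rank > self.scaffold_neighbours:
            raise ValueError("focal_rank exceeds genes on scaffold")

    @property
    def sag_genes(self) -> list[str]:
        return _SAG_NAMES[: self.n_sag]

    @property
    def sag_of_serotype(self) -> dict[str, str]:
        # serotype X -> the SAg gene named after it
        mapping = {}
        for s in self.serotypes:
            name = f"SAG-51{s}"
            mapping[s] = name if name in self.sag_genes else self.sag_genes[
                self.serotypes.index(s)
            ]
        return mapping

    @property
    def hsp_genes(self) -> list[str]:
        return [f"HSP70CY-{i + 1:02d}" for i in range(self.n_hsp)]


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    condition_means: pd.DataFrame          # genes x conditions, expected counts
    mean_matrix: pd.DataFrame              # genes x samples (library factors applied)
    sag_active: dict[str, str]             # condition -> active SAg gene
    module_members: dict[str, list[str]]   # serotype -> planted module genes
    sag_genes: list[str]
    hsp_genes: list[str]
    dispersions: pd.Series                 # per-gene alpha
    libsize_factors: pd.Series             # per-sample multiplicative factor
    hs_intensity: pd.Series | None = None  # per-sample shock intensity (1 = full)
    planted_go_term: str | None = None

    def true_log2fc(self, cond_a: str, cond_b: str) -> pd.Series:
        """Exact log2 ratio of condition means (0 where means are equal)."""
        a = self.condition_means[cond_a]
        b = self.condition_means[cond_b]
        out = np.where(a.to_numpy() == b.to_numpy(), 0.0, np.log2(a / b))
        return pd.Series(out, index=a.index, name=f"lfc[{cond_a}/{cond_b}]")

    def de_flags(self, cond_a: str, cond_b: str) -> pd.Series:
        return self.true_log2fc(cond_a, cond_b)

    def to_json(self, path) -> None:
        payload = {
            "sag_active": self.sag_active,
            "module_members": self.module_members,
            "sag_genes": self.sag_genes,
            "hsp_genes": self.hsp_genes,
            "planted_go_term": self.planted_go_term,
            "libsize_factors": self.libsize_factors.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def nb_counts(mean, alpha, rng: np.random.Generator) -> np.ndarray:
    """NB(mu, alpha) draws with Var = mu + alpha mu^2 (gamma-Poisson mixture).

    alpha = 0 reduces to Poisson.  ``mean`` and ``alpha`` broadcast.
    """
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    if (mean < 0).any() or (alpha < 0).any():
        raise ValueError("mean and alpha must be non-negative")
    lam = np.array(mean, copy=True)
    pos = alpha > 0
    if pos.any():
        shape = 1.0 / alpha[pos]
        lam[pos] = rng.gamma(shape, alpha[pos] * mean[pos])
    return rng.poisson(lam)


def _gene_ids(cfg: SimConfig) -> tuple[list[str], dict[str, list[str]], list[str]]:
    """All gene ids plus module membership and background ids."""
    n_other = cfg.n_genes - cfg.n_sag - cfg.n_hsp
    generic = [f"G{i + 1:05d}" for i in range(n_other)]
    modules: dict[str, list[str]] = {}
    cursor = 0
    for s in cfg.serotypes:
        size = cfg.module_sizes[s]
        modules[s] = generic[cursor : cursor + size]
        cursor += size
    background = generic[cursor:]
    all_ids = cfg.sag_genes + cfg.hsp_genes + generic
    return all_ids, modules, background


def _condition_means(cfg: SimConfig, rng: np.random.Generator):
    all_ids, modules, background = _gene_ids(cfg)
    n = len(all_ids)
    cond_names = [c.name for c in cfg.conditions]
    idx = pd.Index(all_ids, name="gene_id")

    baseline = pd.Series(
        rng.lognormal(cfg.baseline_shape[0], cfg.baseline_shape[1], size=n), index=idx
    )
    for s in cfg.serotypes:
        baseline.loc[modules[s]] = rng.lognormal(
            cfg.module_baseline_shape[0], cfg.module_baseline_shape[1], size=len(modules[s])
        )
    baseline.loc[cfg.sag_genes] = cfg.sag_off_mean
    baseline.loc[cfg.hsp_genes] = cfg.hsp_base_mean

    means = pd.DataFrame(
        np.tile(baseline.to_numpy()[:, None], (1, len(cond_names))),
        index=idx,
        columns=cond_names,
    )
    sag_of = cfg.sag_of_serotype
    sag_active: dict[str, str] = {}
    module_lfc = 2.0**cfg.lfc_module

    # scaffold neighbours are kept free of program perturbations so that,
    # by construction, their expression is independent of the SAg state
    n_scaff = len(cfg.serotypes) * cfg.scaffold_neighbours
    scaffold_pool = background[:n_scaff]
    perturbable = np.array(background[n_scaff:])

    for c in cfg.conditions:
        sag = sag_of[c.serotype]
        sag_active[c.name] = sag
        means.loc[sag, c.name] = cfg.sag_on_mean
        means.loc[modules[c.serotype], c.name] = (
            baseline.loc[modules[c.serotype]] * module_lfc
        )
        if c.program == "starve":
            means.loc[sag, c.name] = cfg.sag_on_mean * cfg.starve_sag_factor
        elif c.program == "heatshock":
            rho = cfg.hs_residual
            means.loc[sag, c.name] = cfg.sag_off_mean * (
                cfg.sag_on_mean / cfg.sag_off_mean
            ) ** rho
            base_mod = baseline.loc[modules[c.serotype]]
            means.loc[modules[c.serotype], c.name] = base_mod * module_lfc**rho
            means.loc[cfg.hsp_genes, c.name] = cfg.hsp_base_mean * cfg.hsp_activation
        if c.program in cfg.perturb_frac and c.parent is not None:
            n_pert = int(round(cfg.perturb_frac[c.program] * len(perturbable)))
            chosen = rng.choice(perturbable, size=n_pert, replace=False)
            lo, hi = cfg.perturb_lfc_range
            lfc = rng.uniform(lo, hi, size=n_pert) * rng.choice([-1.0, 1.0], size=n_pert)
            means.loc[chosen, c.name] = means.loc[chosen, c.parent] * 2.0**lfc

    return means, sag_active, modules, background, scaffold_pool


def _subtelomere_map(cfg: SimConfig, scaffold_pool: list[str]) -> SubtelomereMap:
    """One scaffold per serotype; the focal SAg sits ``focal_rank`` genes
    from the right EOS, with an internal telomeric site near the left end."""
    sag_of = cfg.sag_of_serotype
    n_nb = cfg.scaffold_neighbours
    scaffolds: dict[str, Scaffold] = {}
    gene_len, gap = 1500, 500
    for i, s in enumerate(cfg.serotypes):
        neighbours = scaffold_pool[i * n_nb : (i + 1) * n_nb]
        order = list(neighbours)
        order.insert(len(order) - cfg.focal_rank, sag_of[s])
        rows = []
        for j, gid in enumerate(order):
            start = 1 + gap + j * (gene_len + gap)
            rows.append((gid, start, start + gene_len - 1, "+" if j % 2 == 0 else "-"))
        genes = pd.DataFrame(
            rows, columns=["gene_id", "start", "end", "strand"]
        ).set_index("gene_id")
        length = int(genes["end"].max() + gap)
        internal = [int(genes["start"].iloc[1] - gap // 2)]
        scaffolds[f"scaffold_{s}"] = Scaffold(f"scaffold_{s}", length, genes, internal)
    return SubtelomereMap(scaffolds)


def _go_dataset(cfg: SimConfig, all_ids: list[str],
                modules: dict[str, list[str]], rng: np.random.Generator) -> GODataset:
    """Flat ontology: every term a child of the root, one planted term
    drawn from the first serotype's module (enriched in that module's
    differential set by construction)."""
    root = "GO:0000000"
    graph = nx.DiGraph()
    graph.add_node(root)
    names = {root: "biological_process"}
    annotations: dict[str, set[str]] = {g: {root} for g in all_ids}
    lo, hi = cfg.go_term_size
    for t in range(cfg.n_go_terms):
        term = f"GO:{t + 1:07d}"
        graph.add_edge(term, root)
        names[term] = f"process_{t + 1}"
        size = int(rng.integers(lo, hi + 1))
        for g in rng.choice(all_ids, size=size, replace=False):
            annotations[g].add(term)
    planted = "GO:0000999"
    graph.add_edge(planted, root)
    names[planted] = "planted_coregulated_process"
    first_module = modules[cfg.serotypes[0]]
    k = min(cfg.planted_term_size, len(first_module))
    for g in rng.choice(first_module, size=k, replace=False):
        annotations[g].add(planted)
    return GODataset(graph, {g: frozenset(t) for g, t in annotations.items()}, names)


def simulate_dataset(
    cfg: SimConfig | None = None,
) -> tuple[CountMatrix, SimTruth, SubtelomereMap, GODataset]:
    """Generate the full synthetic study: counts, truth, layout, ontology."""
    if cfg is None:
        cfg = SimConfig()
    rng = np.random.default_rng(cfg.seed)
    means, sag_active, modules, background, scaffold_pool = _condition_means(cfg, rng)
    all_ids = list(means.index)

    sample_rows = []
    for c in cfg.conditions:
        for r in range(1, cfg.n_replicates + 1):
            sample_rows.append(
                {
                    "sample": f"{c.name}-{r}",
                    "condition": c.name,
                    "replicate": r,
                    "temperature": c.temperature,
                    "serotype": c.serotype,
                    "parent": c.parent or "",
                }
            )
    samples = pd.DataFrame(sample_rows).set_index("sample")

    lo, hi = cfg.libsize_range
    libsize = pd.Series(
        rng.uniform(lo, hi, size=len(samples)), index=samples.index, name="libsize"
    )
    alpha = pd.Series(
        rng.lognormal(cfg.dispersion_shape[0], cfg.dispersion_shape[1], size=len(all_ids)),
        index=means.index,
        name="alpha",
    )
    alpha.loc[cfg.sag_genes] = cfg.sag_dispersion

    mean_matrix = pd.DataFrame(
        means[samples["condition"]].to_numpy() * libsize.to_numpy()[None, :],
        index=means.index,
        columns=samples.index,
    )

    # per-replicate heat-shock intensity modulates HSP activation and the
    # serotype-program decay in opposite directions (lambda = 1 is the full
    # shock encoded in the condition means)
    hs_intensity = pd.Series(1.0, index=samples.index, name="hs_intensity")
    program = {c.name: c.program for c in cfg.conditions}
    sag_of = cfg.sag_of_serotype
    sero_of = {c.name: c.serotype for c in cfg.conditions}
    # intensities are evenly spaced across a condition's replicates (order
    # shuffled), so the replicates always differ cleanly in shock strength
    for c in cfg.conditions:
        if c.program != "heatshock":
            continue
        cols = samples.index[samples["condition"] == c.name]
        lo, hi = cfg.hs_intensity_range
        lams = np.linspace(lo, hi, len(cols)) if len(cols) > 1 else np.array([hi])
        hs_intensity[cols] = rng.permutation(lams)
    for s in samples.index:
        cond = samples.loc[s, "condition"]
        if program[cond] != "heatshock":
            continue
        lam = float(hs_intensity[s])
        expo = 1.0 - (1.0 - cfg.hs_residual) * lam
        lib = libsize[s]
        sag = sag_of[sero_of[cond]]
        mean_matrix.loc[sag, s] = (
            cfg.sag_off_mean * (cfg.sag_on_mean / cfg.sag_off_mean) ** expo * lib
        )
        members = modules[sero_of[cond]]
        base_mod = mean_matrix.loc[members, s] / (
            lib * (2.0**cfg.lfc_module) ** cfg.hs_residual
        )
        mean_matrix.loc[members, s] = base_mod * (2.0**cfg.lfc_module) ** expo * lib
        mean_matrix.loc[cfg.hsp_genes, s] = (
            cfg.hsp_base_mean * cfg.hsp_activation**lam * lib
        )
    counts = pd.DataFrame(
        nb_counts(mean_matrix.to_numpy(), alpha.to_numpy()[:, None], rng),
        index=means.index,
        columns=samples.index,
    )
    lengths = pd.Series(
        rng.integers(500, 5000, size=len(all_ids)), index=means.index, name="length"
    )
    cm = CountMatrix(counts, lengths, samples)

    smap = _subtelomere_map(cfg, scaffold_pool)
    go = _go_dataset(cfg, all_ids, modules, rng)
    truth = SimTruth(
        condition_means=means,
        mean_matrix=mean_matrix,
        sag_active=sag_active,
        module_members={s: list(v) for s, v in modules.items()},
        sag_genes=list(cfg.sag_genes),
        hsp_genes=list(cfg.hsp_genes),
        dispersions=alpha,
        libsize_factors=libsize,
        hs_intensity=hs_intensity,
        planted_go_term="GO:0000999",
    )
    return cm, truth, smap, go


def simulate_null(
    n_genes: int,
    n_samples_per_group: int,
    dispersion: float | tuple[float, float],
    seed: int,
    baseline_shape: tuple[float, float] = (4.0, 1.0),
) -> CountMatrix:
    """Two exchangeable groups with identical per-gene means (NB noise only)."""
    if n_genes < 1 or n_samples_per_group < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"G{i + 1:05d}" for i in range(n_genes)], name="gene_id")
    mu = rng.lognormal(baseline_shape[0], baseline_shape[1], size=n_genes)
    if isinstance(dispersion, tuple):
        alpha = rng.lognormal(dispersion[0], dispersion[1], size=n_genes)
    else:
        alpha = np.full(n_genes, float(dispersion))
    n_s = 2 * n_samples_per_group
    counts = nb_counts(np.tile(mu[:, None], (1, n_s)), alpha[:, None], rng)
    cols = [f"grp{g}-{r + 1}" for g in ("A", "B") for r in range(n_samples_per_group)]
    samples = pd.DataFrame(
        {
            "condition": ["grpA"] * n_samples_per_group + ["grpB"] * n_samples_per_group,
            "replicate": list(range(1, n_samples_per_group + 1)) * 2,
        },
        index=pd.Index(cols, name="sample"),
    )
    return CountMatrix(
        pd.DataFrame(counts, index=idx, columns=cols),
        pd.Series(1000, index=idx),
        samples,
    )


def simulate_two_group(
    n_genes: int,
    n_samples_per_group: int,
    frac_de: float = 0.1,
    lfc: float = 2.0,
    dispersion: float | tuple[float, float] = (float(np.log(0.05)), 0.8),
    seed: int = 0,
    baseline_shape: tuple[float, float] = (4.0, 1.0),
) -> tuple[CountMatrix, pd.Series]:
    """Two groups with a planted fraction of genes at +/- ``lfc`` in group B.

    Returns the counts and the per-gene true log2 fold change (B over A).
    """
    if not 0 <= frac_de <= 1:
        raise ValueError("frac_de must be in [0, 1]")
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"G{i + 1:05d}" for i in range(n_genes)], name="gene_id")
    mu = rng.lognormal(baseline_shape[0], baseline_shape[1], size=n_genes)
    if isinstance(dispersion, tuple):
        alpha = rng.lognormal(dispersion[0], dispersion[1], size=n_genes)
    else:
        alpha = np.full(n_genes, float(dispersion))
    n_de = int(round(frac_de * n_genes))
    true_lfc = np.zeros(n_genes)
    if n_de:
        which = rng.choice(n_genes, size=n_de, replace=False)
        true_lfc[which] = lfc * rng.choice([-1.0, 1.0], size=n_de)
    mu_b = mu * 2.0**true_lfc
    n = n_samples_per_group
    mean_mat = np.concatenate(
        [np.tile(mu[:, None], (1, n)), np.tile(mu_b[:, None], (1, n))], axis=1
    )
    counts = nb_counts(mean_mat, alpha[:, None], rng)
    cols = [f"grp{g}-{r + 1}" for g in ("A", "B") for r in range(n)]
    samples = pd.DataFrame(
        {"condition": ["grpA"] * n + ["grpB"] * n, "replicate": list(range(1, n + 1)) * 2},
        index=pd.Index(cols, name="sample"),
    )
    cm = CountMatrix(
        pd.DataFrame(counts, index=idx, columns=cols), pd.Series(1000, index=idx), samples
    )
    return cm, pd.Series(true_lfc, index=idx, name="true_lfc")


def simulate_subtelomere(
    n_scaffolds: int = 4,
    focal_rank: int = 4,
    k_upstream: int = 8,
    spreading: bool = False,
    decay: float = 0.5,
    n_on: int = 5,
    n_off: int = 5,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> tuple[SubtelomereMap, pd.DataFrame, dict[str, list[str]]]:
    """Standalone subtelomeric layouts with log-expression under an
    explicit spreading model.

    Each scaffold carries a focal SAg ``focal_rank`` genes from the right
    EOS plus ``k_upstream`` genes on the far side; ``focal_rank`` must
    stay below ``k_upstream`` so the right EOS is the focal gene's
    nearest telomere.  With
    ``spreading=True``, downstream neighbours (between the SAg and the
    telomere) lose expression in SAg-OFF conditions by ``decay`` per gene
    step toward the telomere; with ``spreading=False`` neighbour
    expression is independent of the SAg state and of distance.

    Returns (map, log10-expression table genes x samples, condition ->
    sample columns with ON conditions named ON1.. and OFF conditions
    OFF1..).
    """
    if n_scaffolds < 1 or focal_rank < 1:
        raise ValueError("dimensions must be positive")
    if focal_rank >= k_upstream:
        raise ValueError(
            "focal_rank must be < k_upstream so the decayed side is the "
            "focal gene's nearest telomere"
        )
    rng = np.random.default_rng(seed)
    gene_len, gap = 1500, 500
    scaffolds: dict[str, Scaffold] = {}
    base_log: dict[str, float] = {}
    is_focal: dict[str, bool] = {}
    decay_steps: dict[str, int] = {}
    for s in range(n_scaffolds):
        n_genes = k_upstream + 1 + focal_rank
        ids = [f"SC{s + 1:02d}_{j + 1:02d}" for j in range(n_genes)]
        focal = f"SAG-SC{s + 1:02d}"
        ids[k_upstream] = focal
        rows = []
        for j, gid in enumerate(ids):
            start = 1 + gap + j * (gene_len + gap)
            rows.append((gid, start, start + gene_len - 1, "+"))
            is_focal[gid] = gid == focal
            base_log[gid] = 3.5 if gid == focal else float(rng.normal(2.0, 0.3))
            # steps toward the right-end telomere, counted from the focal
            j_from_end = n_genes - 1 - j
            decay_steps[gid] = (
                focal_rank - j_from_end if 0 <= j_from_end < focal_rank else 0
            )
        genes = pd.DataFrame(
            rows, columns=["gene_id", "start", "end", "strand"]
        ).set_index("gene_id")
        length = int(genes["end"].max() + gap)
        scaffolds[f"sim_scaffold_{s + 1}"] = Scaffold(
            f"sim_scaffold_{s + 1}", length, genes
        )
    smap = SubtelomereMap(scaffolds)

    conditions = {f"ON{i + 1}": [f"ON{i + 1}"] for i in range(n_on)}
    conditions.update({f"OFF{i + 1}": [f"OFF{i + 1}"] for i in range(n_off)})
    cols = [c for cs in conditions.values() for c in cs]
    all_genes = [g for sc in scaffolds.values() for g in sc.genes.index]
    expr = pd.DataFrame(index=pd.Index(all_genes, name="gene_id"), columns=cols, dtype=float)
    log_decay = np.log10(1.0 / decay)
    for g in all_genes:
        for c in cols:
            on = c.startswith("ON")
            v = base_log[g]
            if is_focal[g]:
                v = 3.5 if on else 1.0
            elif spreading and not on and decay_steps[g] > 0:
                v = v - decay_steps[g] * log_decay
            expr.loc[g, c] = v + rng.normal(0.0, noise_sd)
    return smap, expr, conditions


def write_dataset(outdir, cm: CountMatrix, truth: SimTruth,
                  smap: SubtelomereMap, go: GODataset) -> dict[str, str]:
    """Write the simulated study as plain-text files; returns name -> path."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "truth": out / "truth.json",
        "annotation": out / "annotation.gff3",
        "ontology": out / "ontology.obo",
        "associations": out / "associations.tsv",
    }
    cm.to_tsv(paths["counts"])
    cm.samples.to_csv(paths["samples"], sep="\t")
    truth.to_json(paths["truth"])
    smap.to_gff3(paths["annotation"])
    go.to_obo(paths["ontology"])
    go.to_association_tsv(paths["associations"])
    return {k: str(v) for k, v in paths.items()}
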