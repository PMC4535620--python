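"""GO term enrichment: term-for-term hypergeometric and parent-child-union.

The term-for-term test asks whether a study set is enriched for genes
annotated to a term, relative to the whole annotated population.  The
parent-child-union variant conditions on the term's parents: the
population is restricted to genes annotated to the union of the parents,
and the study set likewise, so a term is only called enriched when its
genes are over-represented *given* that its parents' genes already are.
On a flat ontology (every term a child of the root) the two coincide.

Annotations are propagated to ancestors on load (the true-path rule), so
a gene annotated to a term counts for every ancestor of that term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust

__all__ = [
    "GODataset",
    "hypergeom_term_test",
    "parent_child_union_test",
    "enrich",
]


@dataclass
class GODataset:
    """A rooted is-a DAG plus gene -> term annotations.

    ``graph`` stores one edge child -> parent per is-a link.  Annotations
    passed to the constructor are propagated to all ancestors; the
    annotated-gene universe is the population for enrichment tests.
    """

    graph: nx.DiGraph
    annotations: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("GO graph contains a cycle")
        roots = [t for t in self.graph if self.graph.out_degree(t) == 0]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root term, found {roots}")
        self.root = roots[0]
        # true-path propagation: gene annotated to t => to all ancestors of t
        closure: dict[str, frozenset[str]] = {}
        anc_cache: dict[str, frozenset[str]] = {}
        for gene, terms in self.annotations.items():
            full: set[str] = set()
            for t in terms:
                if t not in self.graph:
                    raise KeyError(f"annotation to unknown term {t!r}")
                if t not in anc_cache:
                    anc_cache[t] = frozenset(nx.descendants(self.graph, t)) | {t}
                full |= anc_cache[t]
            closure[gene] = frozenset(full)
        self.annotations = closure
        self._term2genes: dict[str, set[str]] = {t: set() for t in self.graph}
        for gene, terms in self.annotations.items():
            for t in terms:
                self._term2genes[t].add(gene)

    @property
    def population(self) -> set[str]:
        return set(self.annotations)

    def genes_of(self, term: str) -> set[str]:
        return self._term2genes[term]

    def parents(self, term: str) -> list[str]:
        return list(self.graph.successors(term))

    # -- plain-text IO -------------------------------------------------
    def to_obo(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("format-version: 1.2\n")
            for t in nx.topological_sort(self.graph):
                fh.write(f"\n[Term]\nid: {t}\nname: {self.names.get(t, t)}\n")
                for p in self.parents(t):
                    fh.write(f"is_a: {p} ! {self.names.get(p, p)}\n")

    def to_association_tsv(self, path) -> None:
        rows = [
            {"gene_id": g, "term": t}
            for g, terms in sorted(self.annotations.items())
            for t in sorted(terms)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_files(cls, obo_path, assoc_path) -> "GODataset":
        import obonet

        g = obonet.read_obo(obo_path)
        graph = nx.DiGraph()
        names = {}
        for t, data in g.nodes(data=True):
            graph.add_node(t)
            if "name" in data:
                names[t] = data["name"]
        for child, parent, key in g.edges(keys=True):
            if key == "part_of":
                warnings.warn(
                    f"part_of edge {child}->{parent} treated as is_a", stacklevel=2
                )
            graph.add_edge(child, parent)
        assoc = pd.read_csv(assoc_path, sep="\t")
        ann: dict[str, set[str]] = {}
        for rec in assoc.itertuples(index=False):
            ann.setdefault(rec.gene_id, set()).add(rec.term)
        return cls(graph, {g_: frozenset(t) for g_, t in ann.items()}, names)


def _check_study(dataset: GODataset, study: set[str]) -> set[str]:
    study = set(study)
    if not study:
        raise ValueError("empty study set")
    extra = study - dataset.population
    if extra:
        raise ValueError(
            f"study genes outside annotated population, e.g. {sorted(extra)[:3]}"
        )
    return study


def hypergeom_term_test(dataset: GODataset, study: set[str], term: str) -> float:
    """Upper-tail hypergeometric p for term enrichment in the study set."""
    study = _check_study(dataset, study)
    pop = dataset.population
    term_genes = dataset.genes_of(term)
    k = len(study & term_genes)
    return float(stats.hypergeom.sf(k - 1, len(pop), len(term_genes), len(study)))


def parent_child_union_test(dataset: GODataset, study: set[str], term: str) -> float:
    """Parent-child-union enrichment p-value.

    Population and study are restricted to genes annotated to the union
    of the term's parents; the root (which has no parents) gets p = 1.
    """
    study = _check_study(dataset, study)
    parents = dataset.parents(term)
    if not parents:
        return 1.0
    pop_star: set[str] = set()
    for p in parents:
        pop_star |= dataset.genes_of(p)
    study_star = study & pop_star
    term_genes = dataset.genes_of(term)  # subset of pop_star by true-path rule
    k = len(study_star & term_genes)
    return float(
        stats.hypergeom.sf(k - 1, len(pop_star), len(term_genes), len(study_star))
    )


_METHODS = {
    "term_for_term": hypergeom_term_test,
    "parent_child_union": parent_child_union_test,
}


def enrich(
    dataset: GODataset,
    up: set[str],
    down: set[str],
    method: str = "parent_child_union",
    fdr_threshold: float = 0.02,
) -> pd.DataFrame:
    """Test every annotated term against the up and down study sets.

    BH correction is applied across terms within each direction.  Returns
    a tidy frame sorted by fdr with a ``significant`` flag at the given
    threshold (0.02 by default, the reporting threshold used downstream).
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
    test = _METHODS[method]
    terms = [t for t in dataset.graph if dataset.genes_of(t)]
    frames = []
    for direction, study in (("up", up), ("down", down)):
        if not study:
            continue
        study = _check_study(dataset, set(study))
        rows = []
        for t in terms:
            rows.append(
                {
                    "term": t,
                    "name": dataset.names.get(t, t),
                    "direction": direction,
                    "study_count": len(study & dataset.genes_of(t)),
                    "population_count": len(dataset.genes_of(t)),
                    "p": test(dataset, study, t),
                    "method": method,
                }
            )
        df = pd.DataFrame(rows)
        df["fdr"] = bh_adjust(df["p"].to_numpy())
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=[
                "term", "name", "direction", "study_count",
                "population_count", "p", "method", "fdr", "significant",
            ]
        )
    out = pd.concat(frames, ignore_index=True)
    out["significant"] = out["fdr"] < fdr_threshold
    return out.sort_values(["direction", "fdr", "p", "term"]).reset_index(drop=True)
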