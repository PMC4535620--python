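"""Serotype-level synthesis over SOM landscapes.

Identifies the active surface-antigen (SAg) gene of each condition (the
family member with dominant mean TPM — the family is under mutually
exclusive expression, so the runner-up should be far below), locates the
regulated spot containing it, extracts the group of genes co-regulated
with it (identical spot-incidence pattern across all samples), and
quantifies spot persistence between a parent condition and its
derivatives as the Jaccard similarity of spot gene sets.  The expected
picture: a cold-adapted or starved derivative retains the parent's
SAg spot, while a heat shock destroys it while activating cytosolic
HSP70 genes — an inverse correlation visible per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .somscape import RegulatedSpot

__all__ = [
    "SAgPanel",
    "active_sag",
    "sag_spot",
    "coregulation_group",
    "spot_persistence",
    "heat_shock_contrast",
    "hs_spot_loss",
    "coreg_report",
]


@dataclass
class SAgPanel:
    """The SAg family gene ids, optionally with user serotype labels."""

    genes: list[str]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("empty SAg panel")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in SAg panel")


def active_sag(
    tpm: pd.DataFrame,
    panel: SAgPanel,
    condition_samples: list[str],
    min_ratio: float = 10.0,
) -> tuple[str, float]:
    """Dominant family member in a condition and its exclusivity ratio.

    Returns (gene, mean TPM ratio to the runner-up); warns when the ratio
    falls below ``min_ratio``, i.e. when mutual exclusion looks violated.
    A single-gene panel is trivially active with infinite ratio.
    """
    means = tpm.loc[panel.genes, condition_samples].mean(axis=1).sort_values(
        ascending=False
    )
    best = str(means.index[0])
    if len(means) == 1:
        return best, float("inf")
    runner = float(means.iloc[1])
    ratio = float("inf") if runner == 0 else float(means.iloc[0]) / runner
    if ratio < min_ratio:
        warnings.warn(
            f"weak SAg exclusivity: {best} only {ratio:.2f}x above "
            f"{means.index[1]} (threshold {min_ratio})",
            stacklevel=2,
        )
    return best, ratio


def sag_spot(spots: list[RegulatedSpot], active: str) -> RegulatedSpot | None:
    """The over-class spot containing the active SAg, or None.

    Spots of one sample and class are disjoint, so at most one matches.
    If the SAg sits in an under-class spot a warning is raised and None
    is returned.
    """
    for s in spots:
        if active in s.genes:
            if s.spot_class == "over":
                return s
            warnings.warn(
                f"active SAg {active} lies in an under-expressed spot of "
                f"{s.sample}; no over-spot reported",
                stacklevel=2,
            )
            return None
    return None


def coregulation_group(incidence: pd.DataFrame, reference_gene: str) -> set[str]:
    """Genes whose spot-incidence pattern equals the reference's, everywhere.

    ``incidence`` is the gene x (sample, class) boolean matrix from
    :func:`serosom.somscape.spot_summary`; the reference gene (typically
    the active SAg) is always a member of its own group.
    """
    if reference_gene not in incidence.index:
        raise KeyError(f"{reference_gene!r} has no spot membership")
    ref = incidence.loc[reference_gene].to_numpy()
    match = (incidence.to_numpy() == ref).all(axis=1)
    return set(incidence.index[match])


def spot_persistence(
    parent_spot: RegulatedSpot, derived_spots: list[RegulatedSpot]
) -> float:
    """Max Jaccard similarity of the parent spot's gene set with any
    over-class spot of the derived sample (0 when none exists)."""
    if not parent_spot.genes:
        raise ValueError("parent spot has no member genes")
    parent = set(parent_spot.genes)
    best = 0.0
    for s in derived_spots:
        if s.spot_class != "over":
            continue
        inter = len(parent & set(s.genes))
        union = len(parent | set(s.genes))
        best = max(best, inter / union)
    return best


def heat_shock_contrast(
    tpm: pd.DataFrame,
    samples: pd.DataFrame,
    parent_condition: str,
    hs_condition: str,
    hsp_panel: list[str],
    sag_panel: SAgPanel,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, float]:
    """Per-replicate log2 fold changes of HSP genes and the active SAg.

    Replicates are paired by replicate index (unpaired ones are dropped
    with a warning).  Returns the per-replicate LFC table and the
    Spearman correlation, across replicates, between mean HSP activation
    and SAg fold change (expected negative: the stronger the shock, the
    deeper the SAg decay).  With a single replicate pair the correlation
    is undefined and reported as NaN.
    """
    parent_cols = samples.index[samples["condition"] == parent_condition]
    hs_cols = samples.index[samples["condition"] == hs_condition]
    if len(parent_cols) == 0 or len(hs_cols) == 0:
        raise KeyError("unknown parent or heat-shock condition")
    sag, _ = active_sag(tpm, sag_panel, list(parent_cols))

    par_rep = {int(samples.loc[s, "replicate"]): s for s in parent_cols}
    hs_rep = {int(samples.loc[s, "replicate"]): s for s in hs_cols}
    common = sorted(set(par_rep) & set(hs_rep))
    if set(par_rep) != set(hs_rep):
        warnings.warn(
            "unpaired replicates between parent and heat-shock conditions; "
            f"pairing by index on {common}",
            stacklevel=2,
        )
    rows = []
    for r in common:
        ref, shocked = par_rep[r], hs_rep[r]
        rec = {"replicate": r}
        for g in list(hsp_panel) + [sag]:
            rec[g] = float(
                np.log2(tpm.loc[g, shocked] + pseudocount)
                - np.log2(tpm.loc[g, ref] + pseudocount)
            )
        rows.append(rec)
    table = pd.DataFrame(rows).set_index("replicate")
    table.attrs["active_sag"] = sag
    if len(table) < 2:
        warnings.warn("single replicate pair: correlation undefined", stacklevel=2)
        return table, float("nan")
    hsp_mean = table[list(hsp_panel)].mean(axis=1)
    rho = stats.spearmanr(hsp_mean, table[sag]).statistic
    return table, float(rho)


def coreg_report(
    per_condition_spots: dict[str, list[RegulatedSpot]],
    active: dict[str, str],
    persistence: dict[tuple[str, str], float],
    hs_loss: dict[tuple[str, str], float],
) -> dict:
    """Assemble the serotype co-regulation report as a JSON-able dict."""
    conditions = {}
    for cond, spots in per_condition_spots.items():
        spot = sag_spot(spots, active[cond]) if cond in active else None
        conditions[cond] = {
            "active_sag": active.get(cond),
            "sag_spot_units": len(spot.units) if spot else 0,
            "sag_spot_genes": spot.size if spot else 0,
        }
    for v in persistence.values():
        if not 0.0 <= v <= 1.0:
            raise ValueError("persistence must lie in [0, 1]")
    for v in hs_loss.values():
        if not 0.0 <= v <= 1.0:
            raise ValueError("hs_loss must lie in [0, 1]")
    return {
        "conditions": conditions,
        "persistence": {f"{a}->{b}": v for (a, b), v in persistence.items()},
        "hs_loss": {f"{a}->{b}": v for (a, b), v in hs_loss.items()},
    }


def hs_spot_loss(parent_spot: RegulatedSpot, hs_spots: list[RegulatedSpot]) -> float:
    """Fraction of the parent spot's units no longer over-expressed in the
    heat-shock landscape."""
    if not parent_spot.units:
        raise ValueError("parent spot has no units")
    hs_over_units = set()
    for s in hs_spots:
        if s.spot_class == "over":
            hs_over_units |= set(s.units)
    kept = len(set(parent_spot.units) & hs_over_units)
    return 1.0 - kept / len(parent_spot.units)
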