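"""End-to-end orchestration: simulate/load -> normalize -> DE -> SOM ->
spots -> co-regulation -> clustering -> TPE scan -> GO enrichment.

A run is driven by a :class:`RunConfig` (constructible from YAML), is
fully seeded (stage seeds derive from the global seed via
``numpy.random.SeedSequence(seed).spawn``), writes every output as plain
text under the output directory, and records a manifest with SHA-256
content hashes so that a rerun with the same config and seed can be
checked for byte-level reproducibility of the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coreg, diffexp, goenrich, quantnorm, similarity, simdata, somscape, tpescan

logger = logging.getLogger("serosom.pipeline")

__all__ = ["RunConfig", "run_pipeline", "write_report"]

_STAGES = ("normalize", "de", "som", "coreg", "cluster", "tpe", "go")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``simulate`` holds keyword arguments for
    :class:`serosom.simdata.SimConfig`, or ``data`` holds paths
    (``counts``, ``samples``, optional ``gff``, ``obo``, ``associations``,
    ``sag_panel``, ``hsp_panel``).  Stage parameters mirror the analysis
    defaults: DE FDR 0.01, 20x20 lattice, extremum factor 0.9,
    8-neighbour adjacency, GO reporting FDR 0.02.
    """

    outdir: str = "serosom_run"
    seed: int = 0
    simulate: dict | None = field(default_factory=dict)
    data: dict | None = None
    stages: dict = field(default_factory=dict)
    de: dict = field(default_factory=lambda: {"fdr": 0.01, "contrasts": "auto"})
    som: dict = field(
        default_factory=lambda: {
            "rows": 20, "cols": 20, "n_epochs": 10,
            "spot_factor": 0.9, "adjacency": 8, "scale": "center", "clip": 0.35,
        }
    )
    cluster: dict = field(default_factory=lambda: {"metrics": list(similarity.METRICS)})
    tpe: dict = field(default_factory=lambda: {"k": 5, "n_perm": 999})
    go: dict = field(default_factory=lambda: {"method": "parent_child_union", "fdr": 0.02})

    def __post_init__(self) -> None:
        if self.simulate is None and self.data is None:
            raise ValueError("either 'simulate' or 'data' must be given")
        if self.data is not None:
            self.simulate = None
            for key in ("counts", "samples"):
                if key not in self.data:
                    raise ValueError(f"data config requires {key!r}")
                if not Path(self.data[key]).exists():
                    raise FileNotFoundError(self.data[key])
        for name in self.stages:
            if name not in _STAGES:
                raise ValueError(f"unknown stage {name!r}")

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _parent_of(samples: pd.DataFrame, condition: str) -> str:
    row = samples.loc[samples["condition"] == condition]
    if "parent" not in row.columns or row.empty:
        return ""
    v = row["parent"].iloc[0]
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return ""
    return str(v)


def _auto_contrasts(samples: pd.DataFrame) -> list[tuple[str, str]]:
    """Derived-vs-parent pairs plus all pairs of parentless conditions."""
    conditions = list(dict.fromkeys(samples["condition"]))
    contrasts = []
    base = []
    for cond in conditions:
        parent = _parent_of(samples, cond)
        if parent:
            contrasts.append((cond, parent))
        else:
            base.append(cond)
    for i, a in enumerate(base):
        for b in base[i + 1 :]:
            contrasts.append((a, b))
    return contrasts


def run_pipeline(cfg: RunConfig) -> tuple[dict, dict]:
    """Execute all enabled stages in dependency order.

    Returns (manifest, results): the manifest lists parameters and output
    files with SHA-256 hashes; results holds the in-memory stage outputs
    (DE tables, spots, reports) for programmatic use.  A stage failure
    aborts with the stage name; files already written are kept and the
    manifest flags the run as partial.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {
        name: int(ss.generate_state(1)[0] % 2**31)
        for name, ss in zip(
            ("simulate", *_STAGES), np.random.SeedSequence(cfg.seed).spawn(len(_STAGES) + 1)
        )
    }
    manifest: dict = {"seed": cfg.seed, "stage_seeds": seeds, "stages": {}, "partial": False}
    results: dict = {}
    current = "setup"
    try:
        # -- inputs ----------------------------------------------------
        if cfg.simulate is not None:
            current = "simulate"
            sim_cfg = simdata.SimConfig(**{**cfg.simulate, "seed": seeds["simulate"]})
            cm, truth, smap, go_ds = simdata.simulate_dataset(sim_cfg)
            paths = simdata.write_dataset(out / "data", cm, truth, smap, go_ds)
            manifest["stages"]["simulate"] = {
                "params": {"n_genes": sim_cfg.n_genes, "seed": seeds["simulate"]},
                "outputs": {k: _sha256(Path(p)) for k, p in paths.items()},
            }
            results["truth"] = truth
            sag_panel = coreg.SAgPanel(truth.sag_genes)
            hsp_panel = truth.hsp_genes
        else:
            current = "load"
            samples = pd.read_csv(cfg.data["samples"], sep="\t", index_col=0)
            cm = quantnorm.CountMatrix.from_tsv(cfg.data["counts"], samples)
            smap = (
                tpescan.SubtelomereMap.from_gff3(cfg.data["gff"])
                if "gff" in cfg.data
                else None
            )
            go_ds = (
                goenrich.GODataset.from_files(cfg.data["obo"], cfg.data["associations"])
                if "obo" in cfg.data and "associations" in cfg.data
                else None
            )
            sag_panel = (
                coreg.SAgPanel(list(pd.read_csv(cfg.data["sag_panel"], sep="\t")["gene_id"]))
                if "sag_panel" in cfg.data
                else None
            )
            hsp_panel = (
                list(pd.read_csv(cfg.data["hsp_panel"], sep="\t")["gene_id"])
                if "hsp_panel" in cfg.data
                else None
            )
        results["counts"] = cm

        # -- normalize ---------------------------------------------------
        current = "normalize"
        tpm = quantnorm.to_tpm(cm)
        logtpm = quantnorm.log_transform(tpm, pseudocount=1.0)
        factors = quantnorm.size_factors_median_of_ratios(cm)
        results.update(tpm=tpm, logtpm=logtpm, size_factors=factors)
        if cfg.enabled("normalize"):
            logtpm.to_tsv(out / "log_tpm.tsv")
            factors.to_csv(out / "size_factors.tsv", sep="\t")
            manifest["stages"]["normalize"] = {
                "params": {"unit": "log-TPM", "pseudocount": 1.0},
                "outputs": {
                    "log_tpm": _sha256(out / "log_tpm.tsv"),
                    "size_factors": _sha256(out / "size_factors.tsv"),
                },
            }

        # -- differential expression ------------------------------------
        if cfg.enabled("de"):
            current = "de"
            contrasts = cfg.de.get("contrasts", "auto")
            if contrasts == "auto":
                contrasts = _auto_contrasts(cm.samples)
            fdr = float(cfg.de.get("fdr", 0.01))
            de_results, deg_counts = {}, {}
            for a, b in contrasts:
                est = diffexp.NegativeBinomialDE(fdr_threshold=fdr).fit_from_counts(cm, a, b)
                de_results[(a, b)] = est.results_
                deg_counts[(a, b)] = {"up": len(est.up_), "down": len(est.down_)}
                est.results_.to_csv(out / f"de_{a}_vs_{b}.tsv", sep="\t")
                logger.info("DE %s vs %s: %d up, %d down (fdr<%g)",
                            a, b, len(est.up_), len(est.down_), fdr)
            results["de"] = de_results
            results["deg_counts"] = deg_counts
            manifest["stages"]["de"] = {
                "params": {"fdr": fdr, "contrasts": [list(c) for c in contrasts]},
                "outputs": {
                    f"de_{a}_vs_{b}": _sha256(out / f"de_{a}_vs_{b}.tsv")
                    for a, b in contrasts
                },
            }

        # -- SOM landscapes and spots ------------------------------------
        som_model = None
        if cfg.enabled("som"):
            current = "som"
            som_params = dict(cfg.som)
            som_model = somscape.SOMLandscape(
                rows=int(som_params.get("rows", 20)),
                cols=int(som_params.get("cols", 20)),
                n_epochs=int(som_params.get("n_epochs", 10)),
                scale=som_params.get("scale", "center"),
                clip=som_params.get("clip", 0.35),
                spot_factor=float(som_params.get("spot_factor", 0.9)),
                adjacency=int(som_params.get("adjacency", 8)),
                random_state=seeds["som"],
            ).fit(logtpm.values)
            spots = som_model.all_spots()
            table, incidence = somscape.spot_summary(spots, gene_ids=list(cm.gene_ids))
            table.to_csv(out / "spots.tsv", sep="\t", index=False)
            results.update(som=som_model, spots=spots, spot_table=table, incidence=incidence)
            manifest["stages"]["som"] = {
                "params": {k: som_params.get(k) for k in ("rows", "cols", "spot_factor", "adjacency")},
                "outputs": {"spots": _sha256(out / "spots.tsv")},
            }

        # -- serotype co-regulation --------------------------------------
        if cfg.enabled("coreg") and som_model is not None and sag_panel is not None:
            current = "coreg"
            samples = cm.samples
            conditions = list(dict.fromkeys(samples["condition"]))
            active, cond_spots = {}, {}
            for cond in conditions:
                cols = cm.condition_samples(cond)
                active[cond], _ = coreg.active_sag(tpm.values, sag_panel, cols)
                cond_spots[cond] = som_model.spots(cols[0])  # representative replicate
            persistence, hs_loss = {}, {}
            for cond in conditions:
                parent = _parent_of(samples, cond)
                if not parent:
                    continue
                pspot = coreg.sag_spot(cond_spots[parent], active[parent])
                if pspot is None:
                    continue
                persistence[(parent, cond)] = coreg.spot_persistence(pspot, cond_spots[cond])
                hs_loss[(parent, cond)] = coreg.hs_spot_loss(pspot, cond_spots[cond])
            report = coreg.coreg_report(cond_spots, active, persistence, hs_loss)
            if hsp_panel:
                hs_conds = [
                    c for c in conditions
                    if _parent_of(samples, c)
                    and float(samples.loc[samples["condition"] == c, "temperature"].iloc[0])
                    >= 37.0
                ]
                for hs in hs_conds:
                    parent = _parent_of(samples, hs)
                    tab, rho = coreg.heat_shock_contrast(
                        tpm.values, samples, parent, hs, hsp_panel, sag_panel
                    )
                    report.setdefault("heat_shock", {})[hs] = {
                        "hsp_sag_rank_correlation": None if np.isnan(rho) else rho,
                        "active_sag": tab.attrs["active_sag"],
                    }
                    tab.to_csv(out / f"hs_contrast_{hs}.tsv", sep="\t")
            (out / "coreg_report.json").write_text(json.dumps(report, indent=1))
            results["coreg"] = report
            manifest["stages"]["coreg"] = {
                "params": {},
                "outputs": {"report": _sha256(out / "coreg_report.json")},
            }

        # -- transcriptome clustering -------------------------------------
        if cfg.enabled("cluster"):
            current = "cluster"
            outputs = {}
            results["cluster"] = {}
            for metric in cfg.cluster.get("metrics", similarity.METRICS):
                dend = similarity.average_linkage(
                    similarity.distance_matrix(logtpm.values, metric)
                )
                nwk = similarity.export_newick(dend)
                path = out / f"dendrogram_{metric}.nwk"
                path.write_text(nwk + "\n")
                outputs[metric] = _sha256(path)
                results["cluster"][metric] = dend
            manifest["stages"]["cluster"] = {"params": dict(cfg.cluster), "outputs": outputs}

        # -- subtelomeric position-effect scan ----------------------------
        if cfg.enabled("tpe") and smap is not None and sag_panel is not None:
            current = "tpe"
            conds = {
                c: cm.condition_samples(c) for c in dict.fromkeys(cm.samples["condition"])
            }
            tpe_results = {}
            profiles = []
            k = int(cfg.tpe.get("k", 5))
            for sc in smap.scaffolds.values():
                focal = next((g for g in sc.genes.index if g in sag_panel.genes), None)
                if focal is None:
                    continue
                profiles.append(
                    tpescan.neighbour_profile(smap, logtpm.values, focal, k, conds)
                )
            if profiles:
                for prof in profiles:
                    on = [
                        c for c in conds
                        if results["tpm"].values.loc[prof.focal, conds[c]].mean()
                        > results["tpm"].values.loc[prof.focal].mean()
                    ]
                    off = [c for c in conds if c not in on]
                    if not on or not off:
                        continue
                    stat, p = tpescan.spreading_test(
                        [prof], on, off,
                        n_perm=int(cfg.tpe.get("n_perm", 999)), seed=seeds["tpe"],
                    )
                    tpe_results[prof.focal] = {"statistic": stat, "p": p}
                    prof.table.to_csv(out / f"tpe_profile_{prof.focal}.tsv", sep="\t")
            (out / "tpe_results.json").write_text(json.dumps(tpe_results, indent=1))
            results["tpe"] = tpe_results
            manifest["stages"]["tpe"] = {
                "params": dict(cfg.tpe),
                "outputs": {"tpe_results": _sha256(out / "tpe_results.json")},
            }

        # -- GO enrichment -------------------------------------------------
        if cfg.enabled("go") and go_ds is not None and results.get("de"):
            current = "go"
            (a, b) = next(iter(results["de"]))
            up, down = diffexp.call_degs(results["de"][(a, b)], float(cfg.de.get("fdr", 0.01)))
            pop = go_ds.population
            enr = goenrich.enrich(
                go_ds,
                set(up) & pop,
                set(down) & pop,
                method=cfg.go.get("method", "parent_child_union"),
                fdr_threshold=float(cfg.go.get("fdr", 0.02)),
            )
            enr.to_csv(out / "go_enrichment.tsv", sep="\t", index=False)
            results["go"] = enr
            manifest["stages"]["go"] = {
                "params": {**cfg.go, "contrast": [a, b]},
                "outputs": {"go_enrichment": _sha256(out / "go_enrichment.tsv")},
            }
    except Exception:
        manifest["partial"] = True
        manifest["failed_stage"] = current
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        logger.exception("pipeline aborted in stage %s", current)
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest, results


def write_report(manifest: dict, results: dict, path) -> str:
    """Human-readable run summary (markdown); idempotent for fixed inputs."""
    lines = ["# serosom run report", ""]
    lines.append(f"Global seed: {manifest.get('seed')}")
    if manifest.get("partial"):
        lines.append(f"**Partial run** — failed in stage `{manifest.get('failed_stage')}`.")
    if "deg_counts" in results:
        lines += ["", "## Differentially expressed genes"]
        for (a, b), c in results["deg_counts"].items():
            lines.append(f"- {a} vs {b}: {c['up']} up, {c['down']} down")
    if "spot_table" in results and len(results["spot_table"]):
        lines += ["", "## Regulated spots (top 10 by gene count)", "",
                  results["spot_table"].head(10).to_string(index=False)]
    if "coreg" in results:
        lines += ["", "## Serotype co-regulation"]
        for cond, rec in results["coreg"]["conditions"].items():
            lines.append(
                f"- {cond}: active SAg {rec['active_sag']}, spot of "
                f"{rec['sag_spot_genes']} genes / {rec['sag_spot_units']} units"
            )
        for key, v in results["coreg"]["persistence"].items():
            lines.append(f"- persistence {key}: Jaccard {v:.3f}")
        for key, v in results["coreg"]["hs_loss"].items():
            lines.append(f"- spot loss {key}: {v:.3f}")
    if "tpe" in results:
        lines += ["", "## Subtelomeric spreading scan"]
        for focal, rec in results["tpe"].items():
            lines.append(f"- {focal}: statistic {rec['statistic']:.3f}, p = {rec['p']:.4f}")
    if "go" in results and len(results["go"]):
        top = results["go"].head(5)
        lines += ["", "## Top GO terms", "", top.to_string(index=False)]
    text = "\n".join(lines) + "\n"
    Path(path).write_text(text)
    return text
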