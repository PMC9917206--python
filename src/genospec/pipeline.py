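"""End-to-end orchestration: matrices -> contrasts -> calls -> cross-omics ->
enrichment -> term networks -> qPCR validation -> summary.

A run is driven by a :class:`PipelineConfig` holding either file paths to
real inputs or a simulation block (exactly one of the two).  Every artefact
is written under the output directory together with a content-hash manifest
and the resolved configuration; the summary JSON is byte-identical across
runs with the same seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from genospec import crossomics, differential, enrichment, qpcr, simulate, term_network
from genospec.matrices import (
    CountMatrix,
    ExpressionMatrix,
    consolidate_features,
    filter_low_expression,
    log_transform,
    read_counts_tsv,
    read_lengths_tsv,
    read_matrix_tsv,
    rpkm,
    screen_outliers,
)

log = logging.getLogger("genospec")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class Thresholds:
    min_count: int = 100
    min_samples: int = 3
    summed_q_rna: float = 0.15
    summed_q_protein: float = 0.3
    specificity_alpha: float = 0.05
    enrichment_min_score: float = 4.0
    require_uniform_direction: bool = True
    log_pseudocount: float = 1.0
    outlier_mad_k: float = 3.0


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "genospec_out"
    simulation: dict | None = None
    inputs: dict | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    screen_outliers: bool = True

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("config must provide exactly one of 'simulation' or 'inputs'")
        if isinstance(self.thresholds, dict):
            self.thresholds = Thresholds(**self.thresholds)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def resolved(self) -> dict:
        d = asdict(self)
        return d


def demo_config(seed: int = 0, outdir: str = "genospec_demo") -> PipelineConfig:
    """The bundled synthetic study: four groups of six, planted 2-7-fold
    Z+-only suppression plus an up-regulated set, weak protein coupling."""
    return PipelineConfig(
        seed=seed,
        outdir=outdir,
        simulation={"n_genes": 6000, "n_proteins": 4000, "n_planted_down": 100, "n_planted_up": 100},
    )


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, float)):
        v = float(x)
        return None if np.isnan(v) else round(v, 6)
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the result bundle (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    bundle: dict = {"outdir": str(out)}
    timings: dict[str, float] = {}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s ...", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self.t0
                if exc is not None:
                    raise PipelineError(name, exc) from exc
                log.info("stage %s done in %.2fs", name, timings[name])

        return _Ctx()

    # ------------------------------------------------------------------ inputs
    with stage("inputs"):
        truth = None
        feature_map = None
        qpcr_table = None
        if config.simulation is not None:
            sim_kwargs = dict(config.simulation)
            sim_kwargs.setdefault("seed", config.seed)
            if {"n_planted_down", "n_planted_up"} & set(sim_kwargs):
                sim_cfg = simulate.default_config(**sim_kwargs)
            else:
                sim_cfg = simulate.SimulationConfig(**sim_kwargs)
            ds = simulate.simulate_dataset(sim_cfg)
            simulate.write_dataset(ds, out / "synthetic")
            counts, lengths = ds.counts, ds.lengths
            proteins, protein_to_gene = ds.proteins, ds.protein_to_gene
            ortholog_map, annotations = ds.ortholog_map, ds.annotations
            qpcr_table, truth = ds.qpcr, ds.truth
        else:
            paths = config.inputs
            counts = read_counts_tsv(paths["counts"], paths["metadata"])
            lengths = read_lengths_tsv(paths["lengths"])
            proteins = read_matrix_tsv(paths["intensities"]) if "intensities" in paths else None
            protein_to_gene = (
                pd.read_csv(paths["protein_to_gene"], sep="\t", index_col=0).iloc[:, 0].to_dict()
                if "protein_to_gene" in paths
                else {}
            )
            ortholog_map = (
                pd.read_csv(paths["ortholog_map"], sep="\t", index_col=0).iloc[:, 0].to_dict()
                if "ortholog_map" in paths
                else None
            )
            annotations = {}
            for category, gmt_path in (paths.get("annotations") or {}).items():
                annotations[category] = enrichment.read_gmt(gmt_path, category=category)
            if "feature_map" in paths:
                feature_map = (
                    pd.read_csv(paths["feature_map"], sep="\t", index_col=0).iloc[:, 0].to_dict()
                )
            if "qpcr" in paths:
                qpcr_table = qpcr.read_qpcr_tsv(paths["qpcr"])

    # ------------------------------------------------------------- matrix prep
    with stage("matrix_prep"):
        if feature_map is not None:
            counts = consolidate_features(counts, feature_map)
        if config.screen_outliers:
            counts, outlier_report = screen_outliers(counts, k=thr.outlier_mad_k)
            outlier_report.to_csv(out / "outlier_report.tsv", sep="\t")
        library_sizes = counts.library_sizes()  # pre-filter depth
        filtered = filter_low_expression(counts, thr.min_count, thr.min_samples)
        expr = log_transform(rpkm(filtered, lengths, library_sizes), thr.log_pseudocount)
        bundle["n_genes_tested"] = int(filtered.counts.shape[0])

    # ------------------------------------------------------------ differential
    with stage("differential_rna"):
        ct_rna = differential.run_contrasts(expr)
        calls_rna = differential.call_degs(ct_rna, thr.summed_q_rna, thr.specificity_alpha)
        differential.write_results_tsv(ct_rna, calls_rna, out / "differential_rna.tsv")
        degs = calls_rna[calls_rna["is_deg"]]
        bundle["degs_up"] = int((degs["direction"] == "up").sum())
        bundle["degs_down"] = int((degs["direction"] == "down").sum())
        bundle["contrasts_rna"] = ct_rna
        bundle["calls_rna"] = calls_rna

    with stage("differential_protein"):
        calls_prot = None
        if proteins is not None and proteins.shape[0]:
            active = counts.outlier.reindex(proteins.columns).fillna(False)
            # same detection rule as transcripts: > min_count in >= min_samples
            keep = (proteins.loc[:, ~active.to_numpy()] > thr.min_count).sum(axis=1) >= thr.min_samples
            prot_filtered = proteins.loc[keep]
            prot_log = ExpressionMatrix(
                values=np.log2(prot_filtered.astype(float) + 1.0),
                unit="log2intensity",
                genotypes=counts.genotypes.reindex(proteins.columns),
                outlier=active,
            )
            ct_prot = differential.run_contrasts(prot_log)
            calls_prot = differential.call_degs(ct_prot, thr.summed_q_protein, thr.specificity_alpha)
            differential.write_results_tsv(ct_prot, calls_prot, out / "differential_protein.tsv")
            deps = calls_prot[calls_prot["is_deg"]]
            bundle["deps_up"] = int((deps["direction"] == "up").sum())
            bundle["deps_down"] = int((deps["direction"] == "down").sum())
            bundle["n_proteins_tested"] = int(prot_filtered.shape[0])
        else:
            bundle["deps_up"] = bundle["deps_down"] = 0
            bundle["n_proteins_tested"] = 0
        bundle["calls_protein"] = calls_prot

    # -------------------------------------------------------------- crossomics
    with stage("crossomics"):
        bundle["crossomics"] = None
        if proteins is not None and proteins.shape[0]:
            prot_log_all = np.log2(proteins.astype(float) + 1.0)
            pairs = crossomics.match_features(expr, prot_log_all, protein_to_gene)
            if pairs.pairs.shape[0] >= 3:
                r, p, n_points = crossomics.correlate_omics(pairs)
            else:
                r, p, n_points = float("nan"), float("nan"), 0
            deg_ids = list(calls_rna.index[calls_rna["is_deg"]])
            dep_ids = (
                list(calls_prot.index[calls_prot["is_deg"]]) if calls_prot is not None else []
            )
            inter = crossomics.intersect_calls(deg_ids, dep_ids, protein_to_gene)
            crossomics.write_correlation_json(r, p, n_points, out / "crossomics_correlation.json")
            bundle["crossomics"] = {
                "pearson_r": r,
                "pearson_p": p,
                "n_points": n_points,
                "overlap": pairs.overlap,
                "deg_dep_shared": inter["n_shared"],
                "deg_dep_jaccard": inter["jaccard"],
            }

    # -------------------------------------------------------------- enrichment
    with stage("enrichment"):
        deg_dirs = {
            g: d for g, d in calls_rna.loc[calls_rna["is_deg"], "direction"].items()
        }
        dep_dirs = {}
        if calls_prot is not None:
            for pid, d in calls_prot.loc[calls_prot["is_deg"], "direction"].items():
                gid = protein_to_gene.get(pid, pid)
                dep_dirs[gid] = d
        enrich_results: dict[str, dict[str, list]] = {"deg": {}, "dep": {}}
        mapping_rates: dict[str, dict[str, float]] = {"deg": {}, "dep": {}}
        for category, db in annotations.items():
            for layer, dirs in (("deg", deg_dirs), ("dep", dep_dirs)):
                _, _, rate = enrichment.map_to_annotations(dirs.keys(), ortholog_map, db)
                mapping_rates[layer][category] = rate
                res = enrichment.score_all_terms(dirs, db, ortholog_map, with_p=True)
                enrich_results[layer][category] = res
                enrichment.write_results_tsv(res, out / f"enrichment_{layer}_{category}.tsv")
        bundle["enrichment"] = enrich_results
        bundle["mapping_rates"] = mapping_rates
        over_counts = {
            layer: {c: sum(r.over_represented for r in res) for c, res in by_cat.items()}
            for layer, by_cat in enrich_results.items()
        }
        bundle["over_represented_counts"] = over_counts

    # ------------------------------------------------------------ term network
    with stage("term_network"):
        networks = {}
        for layer, min_score in (("deg", thr.enrichment_min_score), ("dep", 0.0)):
            for category, res in bundle["enrichment"][layer].items():
                kept = term_network.filter_terms(
                    res, min_score=min_score,
                    require_uniform_direction=thr.require_uniform_direction,
                )
                g = term_network.build_network(kept)
                term_network.export_network(g, out / f"network_{layer}_{category}.graphml")
                term_network.export_network(
                    g, out / f"network_{layer}_{category}_edges.tsv", fmt="edge_tsv"
                )
                networks[f"{layer}_{category}"] = {
                    "nodes": g.number_of_nodes(),
                    "edges": g.number_of_edges(),
                }
        bundle["networks"] = networks

    # -------------------------------------------------------------------- qPCR
    with stage("qpcr_validation"):
        bundle["qpcr"] = None
        if qpcr_table is not None and len(qpcr_table):
            qpcr_lfcs = qpcr.qpcr_fold_changes(qpcr_table)
            rnaseq_lfcs = calls_rna["lfc_Z+_vs_A+"].to_dict()
            shared = set(qpcr_lfcs) & set(rnaseq_lfcs)
            if len(shared) >= 3:
                rho, p, table = qpcr.validate_against_rnaseq(qpcr_lfcs, rnaseq_lfcs)
                table.to_csv(out / "qpcr_validation.tsv", sep="\t", index=False)
                bundle["qpcr"] = {"spearman_rho": rho, "p": p, "n_genes": len(table)}

    # ----------------------------------------------------------------- summary
    with stage("summary"):
        summary = summarize(bundle)
        (out / "summary.json").write_text(
            json.dumps(_jsonable(summary), sort_keys=True, indent=2) + "\n"
        )
        resolved = _jsonable(config.resolved())
        (out / "config_resolved.json").write_text(
            json.dumps(resolved, sort_keys=True, indent=2) + "\n"
        )
        manifest = {
            p.relative_to(out).as_posix(): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        }
        (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")
        bundle["summary"] = summary
        bundle["truth"] = truth
    bundle["timings"] = timings
    return bundle


def summarize(bundle: dict) -> dict:
    """Headline statistics of a completed run."""
    for key in ("degs_up", "degs_down", "mapping_rates", "networks"):
        if key not in bundle:
            raise ValueError(f"bundle is missing stage output {key!r}")
    return {
        "n_genes_tested": bundle["n_genes_tested"],
        "n_proteins_tested": bundle["n_proteins_tested"],
        "degs_up": bundle["degs_up"],
        "degs_down": bundle["degs_down"],
        "deps_up": bundle["deps_up"],
        "deps_down": bundle["deps_down"],
        "mapping_rates_percent": bundle["mapping_rates"],
        "over_represented_counts": bundle["over_represented_counts"],
        "crossomics": bundle.get("crossomics"),
        "networks": bundle["networks"],
        "qpcr": bundle.get("qpcr"),
    }
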