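"""End-to-end pipeline driver.

Runs simulate -> preprocess -> differential expression -> classification ->
SVD -> over-representation -> network construction on one configuration,
writes every intermediate artifact under the output directory, and returns a
JSON-serializable RunReport with per-stage parameters and file checksums.
A single global seed fans out to per-stage seeds by fixed offsets so stages
can be rerun in isolation.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diffexpr, enrich, netbuild, preprocess, simulate, svd
from .classify import (
    ClassifierConfig,
    aggregate_model_features,
    classification_frequencies,
    cross_study_classify,
    repeated_cv,
)

STAGES = ("simulate", "preprocess", "diffexpr", "classify", "svd", "enrich", "netbuild")

# fixed per-stage seed offsets
_SEED_OFFSETS = {"simulate": 0, "classify": 40_000, "holdout": 70_000}


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "laborsig_run"
    seed: int = 0
    sim: simulate.SimConfig | None = None
    #: fixture manifest path when running on pre-existing files instead
    manifest: str | None = None
    max_zero_samples: int = 3
    de_q_max: float = 0.05
    de_fc_min: float = 1.5
    clf_algorithm: str = "lasso"
    clf_n_runs: int = 20
    clf_inner_folds: int = 5
    run_cross_study: bool = True
    n_sinks: int = 10
    retain_fraction: float = 0.5
    schemes: tuple = ("general", "non_labor", "labor")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_block = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_block is not None:
            if "samples_per_study" in sim_block:
                sim_block["samples_per_study"] = tuple(
                    tuple(g) for g in sim_block["samples_per_study"]
                )
            if "platform_per_study" in sim_block:
                sim_block["platform_per_study"] = tuple(sim_block["platform_per_study"])
            cfg.sim = simulate.SimConfig(**sim_block)
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _study_k(n_samples: int) -> int:
    """k = 3 for very small studies (~10 samples), else 5."""
    return 3 if n_samples <= 10 else 5


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the RunReport dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "seed": config.seed, "out_dir": str(out)}
    files: dict[str, str] = {}
    t0 = time.time()

    def finish(stage: str, params: dict, written: dict) -> None:
        files.update({k: str(v) for k, v in written.items()})
        report["stages"][stage] = {
            "status": "completed",
            "params": params,
            "files": {k: str(v) for k, v in written.items()},
            "elapsed_s": round(time.time() - t0, 3),
        }

    # -- simulate ---------------------------------------------------------
    stage = "simulate"
    try:
        if config.sim is not None:
            sim_cfg = simulate.SimConfig(
                **{**config.sim.__dict__, "seed": config.seed + _SEED_OFFSETS["simulate"]}
            )
            studies, truth = simulate.generate_study_collection(sim_cfg)
            gene_sets = simulate.generate_gene_sets(sim_cfg, truth)
            graph = simulate.generate_signaling_network(sim_cfg, truth)
            manifest = simulate.write_fixtures(studies, truth, gene_sets, graph, out / "fixtures")
            finish(stage, {"sim": {k: str(v) for k, v in sim_cfg.__dict__.items()}},
                   {"manifest": manifest["manifest"]})
        elif config.manifest is not None:
            from . import io as wio

            manifest = wio.read_manifest(config.manifest)
            studies = wio.read_study_collection(manifest)
            truth = None
            gene_sets = enrich.read_gmt(manifest["gene_sets"]) if "gene_sets" in manifest else None
            graph = (
                netbuild.load_signaling_network(manifest["network_edges"], manifest["tf_edges"])
                if "network_edges" in manifest
                else None
            )
            finish(stage, {"manifest": config.manifest}, {})
        else:
            raise ValueError("config needs either a sim block or a manifest path")
    except Exception as exc:  # noqa: BLE001 - abort with stage name
        raise StageError(stage, str(exc)) from exc

    # -- preprocess -------------------------------------------------------
    stage = "preprocess"
    try:
        processed = [
            preprocess.log_transform(
                preprocess.filter_genes(s, max_zero_samples=config.max_zero_samples)
            )
            for s in studies
        ]
        combined = preprocess.merge_studies(processed)
        comb_path = out / "combined_matrix.tsv"
        combined.values.to_csv(comb_path, sep="\t", float_format="%.10g")
        ann_path = out / "combined_samples.tsv"
        combined.samples.to_csv(ann_path, sep="\t")
        finish(
            stage,
            {
                "max_zero_samples": config.max_zero_samples,
                "normalization_log": combined.normalization_log,
                "shape": list(combined.values.shape),
            },
            {"combined_matrix": comb_path, "combined_samples": ann_path},
        )
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -- differential expression -----------------------------------------
    stage = "diffexpr"
    try:
        comparisons = diffexpr.standard_comparisons(processed)
        sig_sets = []
        written = {}
        for study, ga, gb in comparisons:
            table = diffexpr.differential_expression(study, ga, gb)
            cid = table["comparison_id"].iloc[0].replace(":", "_")
            path = out / f"de_{cid}.tsv"
            table.to_csv(path, sep="\t", float_format="%.10g")
            written[f"de_{cid}"] = path
            sig_sets.append(
                diffexpr.significant_genes(table, q_max=config.de_q_max, fc_min=config.de_fc_min)
            )
        high_conf = diffexpr.high_confidence_intersection(sig_sets)
        hc_path = out / "high_confidence_genes.tsv"
        high_conf.to_csv(hc_path, sep="\t", float_format="%.10g")
        written["high_confidence"] = hc_path
        finish(
            stage,
            {
                "q_max": config.de_q_max,
                "fc_min": config.de_fc_min,
                "n_comparisons": len(comparisons),
                "n_significant_per_comparison": [int(len(s)) for s in sig_sets],
                "n_high_confidence": int(len(high_conf)),
                "n_up": int((high_conf["direction"] == "up").sum()),
                "n_down": int((high_conf["direction"] == "down").sum()),
            },
            written,
        )
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -- classification ---------------------------------------------------
    stage = "classify"
    try:
        written = {}
        auc_summary = {}
        clf_seed = config.seed + _SEED_OFFSETS["classify"]
        for study in processed:
            groups = set(study.labels().unique())
            family = "multinomial" if {"ILEa", "ILEs"} <= groups else "binomial"
            cfg = ClassifierConfig(
                algorithm=config.clf_algorithm,
                k_folds=_study_k(len(study.samples)),
                n_runs=config.clf_n_runs,
                family=family,
                inner_folds=config.clf_inner_folds,
                seed=clf_seed,
            )
            rep = repeated_cv(study, cfg)
            freq = classification_frequencies(rep)
            fpath = out / f"cv_frequencies_{study.study_id}.tsv"
            freq.to_csv(fpath, sep="\t", float_format="%.10g")
            written[f"cv_frequencies_{study.study_id}"] = fpath
            feats = aggregate_model_features(rep)
            gpath = out / f"cv_model_genes_{study.study_id}.tsv"
            feats.to_csv(gpath, sep="\t", index=False, float_format="%.10g")
            written[f"cv_model_genes_{study.study_id}"] = gpath
            auc_summary[rep.task_id] = rep.mean_auc
        cross_tasks = 0
        if config.run_cross_study:
            for tr in processed:
                for te in processed:
                    if tr.study_id == te.study_id:
                        continue
                    cfg = ClassifierConfig(
                        algorithm=config.clf_algorithm,
                        k_folds=5,
                        n_runs=config.clf_n_runs,
                        family="binomial",
                        inner_folds=config.clf_inner_folds,
                        seed=clf_seed + 17 * cross_tasks,
                    )
                    rep = cross_study_classify(tr, te, cfg)
                    freq = classification_frequencies(rep)
                    fpath = out / f"cross_frequencies_{tr.study_id}_to_{te.study_id}.tsv"
                    freq.to_csv(fpath, sep="\t", float_format="%.10g")
                    written[f"cross_{tr.study_id}_to_{te.study_id}"] = fpath
                    auc_summary[rep.task_id] = rep.mean_auc
                    cross_tasks += 1
        auc_path = out / "classification_auc.json"
        with open(auc_path, "w") as fh:
            json.dump(auc_summary, fh, indent=1, sort_keys=True)
        written["classification_auc"] = auc_path
        finish(
            stage,
            {
                "algorithm": config.clf_algorithm,
                "n_runs": config.clf_n_runs,
                "n_cross_study_tasks": cross_tasks,
                "mean_auc": auc_summary,
            },
            written,
        )
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -- SVD --------------------------------------------------------------
    stage = "svd"
    try:
        result = svd.run_svd(combined)
        written = dict(svd.write_svd_result(result, out, tag="global"))
        energies = {"global": svd.energy(result, 1)}
        if gene_sets is not None:
            for name in ("labor_program", "quiescence_program", "mixed_program"):
                if name in gene_sets.sets:
                    sub = svd.pathway_svd(combined, gene_sets[name])
                    energies[name] = svd.energy(sub, 1)
        epath = out / "svd_energies.json"
        with open(epath, "w") as fh:
            json.dump(energies, fh, indent=1, sort_keys=True)
        written["energies"] = epath
        ranking = svd.top_loadings(result, axis="gene", n=25)
        rank_path = out / "svd_top_loadings.tsv"
        pd.DataFrame(
            [("positive", g, v) for g, v in ranking.positive]
            + [("negative", g, v) for g, v in ranking.negative],
            columns=["block", "gene", "loading"],
        ).to_csv(rank_path, sep="\t", index=False, float_format="%.10g")
        written["top_loadings"] = rank_path
        finish(stage, {"energies": energies}, written)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -- over-representation ---------------------------------------------
    stage = "enrich"
    try:
        written = {}
        if gene_sets is not None and len(high_conf):
            universe = set(combined.genes)
            query = set(high_conf.index) & universe
            table = enrich.ora(query, universe, gene_sets)
            opath = out / "ora_high_confidence.tsv"
            table.to_csv(opath, sep="\t", float_format="%.10g")
            written["ora"] = opath
            top = table.index[0] if len(table) else None
            finish(stage, {"n_query": len(query), "top_set": top}, written)
        else:
            finish(stage, {"skipped": "no gene sets or empty query"}, written)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # -- network construction --------------------------------------------
    stage = "netbuild"
    try:
        written = {}
        net_summary = {}
        if graph is not None:
            loadings = result.eigensample(1).to_dict()
            sources = graph.sources or sorted(
                n for n in graph.nodes if graph.graph.in_degree(n) == 0
            )
            for scheme in config.schemes:
                costed = netbuild.assign_node_costs(graph, loadings, scheme)
                sinks, uncoverable = netbuild.select_sink_genes(
                    {g: l for g, l in loadings.items() if g in graph.nodes},
                    n_per_side=config.n_sinks,
                    scheme=scheme,
                    graph=graph,
                )
                net = netbuild.build_parturition_network(
                    costed, sources, sinks, scheme, retain_fraction=config.retain_fraction
                )
                written.update(
                    {f"{scheme}_{k}": v for k, v in netbuild.export_network(net, out).items()}
                )
                net_summary[scheme] = {
                    "n_nodes": net.graph.number_of_nodes(),
                    "n_edges": net.graph.number_of_edges(),
                    "n_retained_paths": len(net.retained_paths),
                    "n_uncoverable_sinks": len(uncoverable),
                }
        finish(
            stage,
            {"n_sinks": config.n_sinks, "retain_fraction": config.retain_fraction,
             "networks": net_summary},
            written,
        )
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    report["checksums"] = {k: _sha256(v) for k, v in sorted(files.items())}
    report["elapsed_s"] = round(time.time() - t0, 3)
    report_path = out / "run_report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
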