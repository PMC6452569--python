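"""Synthetic multi-study expression data with a planted labor signature.

The generator emulates the structure of the real integration problem: three
myometrial studies of unequal size (defaults 10 / 22 / 39 samples), mixed
platforms (negative-binomial counts for RNA-seq-like studies, Gaussian
log-scale intensities for the microarray-like study), a shared set of
labor-responsive genes planted with a common direction in every study,
study-specific batch shifts, one three-group study (NL / ILEa / ILEs) whose
early-labor samples carry an attenuated signature, and a small number of
mislabeled ("ambiguous") labor samples drawn from the non-labor expectation.

Everything is driven by a single integer seed; identical configuration gives
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionStudy
from .enrich import GeneSetCollection
from .netbuild import SignalingGraph
from . import io as wio


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Study design and noise model for the synthetic collection.

    Defaults reproduce the three-study design the pipeline targets:
    a small two-group count study (5 NL / 5 IL), a three-group count study
    (8 NL / 8 ILEa / 6 ILEs), and a larger two-group intensity study
    (20 NL / 19 IL).
    """

    seed: int = 0
    samples_per_study: tuple = ((5, 5), (8, 8, 6), (20, 19))
    n_genes_total: int = 2000
    n_shared_genes: int = 1500
    n_up: int = 100
    n_down: int = 30
    effect_log2fc_mean: float = 1.2
    effect_log2fc_sd: float = 0.3
    platform_per_study: tuple = ("count", "count", "intensity")
    batch_scale_sd: float = 0.3
    dispersion: float = 0.2
    intensity_sd: float = 0.4
    n_ambiguous: int = 1
    ilea_effect_scale: float = 0.7

    @property
    def n_studies(self) -> int:
        return len(self.samples_per_study)

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_shared_genes:
            raise ConfigurationError("planted genes exceed shared gene count")
        if self.n_shared_genes > self.n_genes_total:
            raise ConfigurationError("shared genes exceed total gene count")
        if len(self.platform_per_study) != self.n_studies:
            raise ConfigurationError("one platform tag required per study")
        for tag in self.platform_per_study:
            if tag not in ("count", "intensity"):
                raise ConfigurationError(f"unknown platform tag {tag!r}")
        for sizes in self.samples_per_study:
            if len(sizes) not in (2, 3):
                raise ConfigurationError("each study needs 2 or 3 groups")
            if any(n < 2 for n in sizes):
                raise ConfigurationError("every group needs >= 2 samples")
        if self.effect_log2fc_mean <= 0 or self.effect_log2fc_sd <= 0:
            raise ConfigurationError("effect sizes must be positive")
        if self.dispersion < 0 or self.intensity_sd <= 0:
            raise ConfigurationError("noise parameters must be positive")
        if self.n_ambiguous < 0:
            raise ConfigurationError("n_ambiguous must be >= 0")


@dataclass
class GroundTruth:
    """What was planted: signature genes, effects, mislabeled samples, paths."""

    up_genes: set
    down_genes: set
    #: signed log2 fold change (IL vs NL) per shared gene; 0 for unplanted
    base_log2fc: pd.Series = None
    #: per-study signed true log2FC vector (IL-vs-NL contrast)
    study_log2fc: dict = field(default_factory=dict)
    ambiguous_sample_ids: set = field(default_factory=set)
    planted_active_paths: list = field(default_factory=list)
    #: baseline log2 expression of shared genes (used for hold-out samples)
    base_log2: pd.Series = None

    def __post_init__(self) -> None:
        if self.up_genes & self.down_genes:
            raise ConfigurationError("up and down gene sets overlap")


def _shared_gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:05d}" for i in range(n)]


def _group_layout(sizes: tuple) -> list[str]:
    """Phenotype label per sample, in column order, for one study."""
    if len(sizes) == 2:
        groups = ("NL", "IL")
    else:
        groups = ("NL", "ILEa", "ILEs")
    labels = []
    for g, n in zip(groups, sizes):
        labels.extend([g] * n)
    return labels


def _effect_scale(label: str, ilea_scale: float) -> float:
    if label == "NL":
        return 0.0
    if label == "ILEa":
        return ilea_scale
    return 1.0


def _sample_matrix(rng, platform, mean_log2, dispersion, intensity_sd):
    """Draw one study's matrix given per-cell expected log2 expression."""
    if platform == "count":
        mu = np.exp2(mean_log2)
        if dispersion == 0:
            return rng.poisson(mu).astype(float)
        r = 1.0 / dispersion
        p = r / (r + mu)
        return rng.negative_binomial(r, p).astype(float)
    return mean_log2 + rng.normal(0.0, intensity_sd, size=mean_log2.shape)


def _generate_one_study(
    config: SimConfig,
    rng: np.random.Generator,
    study_idx: int,
    study_id: str,
    sizes: tuple,
    platform: str,
    shared_base: pd.Series,
    effect: pd.Series,
    n_private: int,
) -> tuple[ExpressionStudy, list[str]]:
    shared_genes = list(shared_base.index)
    private_genes = [f"S{study_idx + 1}_P{i + 1:04d}" for i in range(n_private)]
    genes = shared_genes + private_genes
    labels = _group_layout(sizes)
    samples = []
    counters: dict[str, int] = {}
    for lab in labels:
        counters[lab] = counters.get(lab, 0) + 1
        samples.append(f"S{study_idx + 1}-{lab}{counters[lab]}")

    # ambiguous: labor-labeled samples drawn from the NL expectation; pick the
    # last samples of the most variable labor group (ILEa if present, else IL)
    amb_group = "ILEa" if len(sizes) == 3 else "IL"
    amb_candidates = [s for s, l in zip(samples, labels) if l == amb_group]
    ambiguous = amb_candidates[len(amb_candidates) - config.n_ambiguous:] if config.n_ambiguous else []

    # private genes span low to high expression so the zero-filter has work to do
    private_base = pd.Series(rng.uniform(1.0, 9.0, size=n_private), index=private_genes)
    base = pd.concat([shared_base, private_base])
    eff = effect.reindex(genes).fillna(0.0)

    # study-specific multiplicative (log-scale additive) batch effect per gene
    batch = rng.normal(0.0, config.batch_scale_sd, size=len(genes))

    mean_log2 = np.empty((len(genes), len(samples)))
    for j, (s, lab) in enumerate(zip(samples, labels)):
        scale = 0.0 if s in ambiguous else _effect_scale(lab, config.ilea_effect_scale)
        mean_log2[:, j] = base.to_numpy() + batch + scale * eff.to_numpy()

    values = _sample_matrix(rng, platform, mean_log2, config.dispersion, config.intensity_sd)
    frame = pd.DataFrame(values, index=genes, columns=samples)
    study = ExpressionStudy(
        study_id=study_id,
        platform=platform,
        values=frame,
        phenotype=dict(zip(samples, labels)),
    )
    return study, ambiguous


def generate_study_collection(config: SimConfig) -> tuple[list[ExpressionStudy], GroundTruth]:
    """Generate one ExpressionStudy per configured study plus ground truth.

    Count-platform studies hold nonnegative negative-binomial counts whose
    log2 means differ by the planted effect between labor and NL samples;
    intensity studies are Gaussian on the log2 scale with additive effects.
    All studies share the first ``n_shared_genes`` identifiers; the remainder
    are study-private.
    """
    rng = np.random.default_rng(config.seed)
    shared = _shared_gene_ids(config.n_shared_genes)
    shared_base = pd.Series(rng.uniform(3.0, 9.0, size=len(shared)), index=shared)

    planted = list(rng.choice(shared, size=config.n_up + config.n_down, replace=False))
    up = planted[: config.n_up]
    down = planted[config.n_up:]
    magnitudes = np.clip(
        rng.normal(config.effect_log2fc_mean, config.effect_log2fc_sd, size=len(planted)),
        0.1,
        None,
    )
    effect = pd.Series(0.0, index=shared)
    effect[up] = magnitudes[: config.n_up]
    effect[down] = -magnitudes[config.n_up:]

    n_private = config.n_genes_total - config.n_shared_genes
    studies: list[ExpressionStudy] = []
    truth = GroundTruth(
        up_genes=set(up),
        down_genes=set(down),
        base_log2fc=effect.copy(),
        base_log2=shared_base.copy(),
    )
    for i, (sizes, platform) in enumerate(
        zip(config.samples_per_study, config.platform_per_study)
    ):
        study_id = f"study{i + 1}"
        study, ambiguous = _generate_one_study(
            config, rng, i, study_id, sizes, platform, shared_base, effect, n_private
        )
        studies.append(study)
        truth.ambiguous_sample_ids.update(ambiguous)
        truth.study_log2fc[study_id] = effect.reindex(study.genes).fillna(0.0)
    return studies, truth


def generate_holdout_study(
    config: SimConfig,
    truth: GroundTruth,
    n_nl: int,
    n_il: int,
    platform: str = "count",
    seed: int = 10_000,
    study_id: str = "holdout",
) -> ExpressionStudy:
    """Extra samples carrying the same planted signature, for evaluation.

    Shares the planted effect vector and baseline with ``truth`` but uses an
    independent random stream, so downstream stages can score genuinely
    held-out samples.
    """
    rng = np.random.default_rng(seed)
    cfg = SimConfig(
        seed=seed,
        samples_per_study=((n_nl, n_il),),
        n_genes_total=config.n_shared_genes,
        n_shared_genes=config.n_shared_genes,
        n_up=config.n_up,
        n_down=config.n_down,
        effect_log2fc_mean=config.effect_log2fc_mean,
        effect_log2fc_sd=config.effect_log2fc_sd,
        platform_per_study=(platform,),
        batch_scale_sd=config.batch_scale_sd,
        dispersion=config.dispersion,
        intensity_sd=config.intensity_sd,
        n_ambiguous=0,
        ilea_effect_scale=config.ilea_effect_scale,
    )
    shared_effect = truth.base_log2fc
    study, _ = _generate_one_study(
        cfg, rng, 98, study_id, (n_nl, n_il), platform, truth.base_log2, shared_effect, 0
    )
    return ExpressionStudy(
        study_id=study_id,
        platform=platform,
        values=study.values,
        phenotype=study.phenotype,
    )


def generate_gene_sets(
    config: SimConfig,
    truth: GroundTruth,
    labor_set_size: int = 50,
    quiescence_set_size: int = 30,
    mixed_set_size: int = 40,
    planted_fraction: float = 0.8,
    n_decoy_sets: int = 10,
    decoy_size_range: tuple = (10, 60),
) -> GeneSetCollection:
    """Gene-set collection with program sets enriched for the planted genes.

    Produces a ``labor_program`` set enriched for up-genes, a
    ``quiescence_program`` set enriched for down-genes, a ``mixed_program``
    containing both directions, and random decoy sets from unplanted genes.
    """
    for size in (labor_set_size, quiescence_set_size, mixed_set_size, *decoy_size_range):
        if not 5 <= size <= 500:
            raise ConfigurationError("gene-set sizes must lie in [5, 500]")
    rng = np.random.default_rng(config.seed + 101)
    shared = _shared_gene_ids(config.n_shared_genes)
    up = sorted(truth.up_genes)
    down = sorted(truth.down_genes)
    unplanted = [g for g in shared if g not in truth.up_genes and g not in truth.down_genes]

    def pick(pool, n):
        n = min(n, len(pool))
        return list(rng.choice(pool, size=n, replace=False))

    sets: dict[str, list[str]] = {}
    n_up_in = int(round(planted_fraction * labor_set_size))
    sets["labor_program"] = pick(up, n_up_in) + pick(unplanted, labor_set_size - n_up_in)
    n_down_in = int(round(planted_fraction * quiescence_set_size))
    sets["quiescence_program"] = pick(down, n_down_in) + pick(
        unplanted, quiescence_set_size - n_down_in
    )
    third = mixed_set_size // 3
    sets["mixed_program"] = (
        pick(up, third) + pick(down, third) + pick(unplanted, mixed_set_size - 2 * third)
    )
    for i in range(n_decoy_sets):
        size = int(rng.integers(decoy_size_range[0], decoy_size_range[1] + 1))
        sets[f"decoy_{i + 1:02d}"] = pick(unplanted, size)

    return GeneSetCollection(
        {name: sorted(set(members)) for name, members in sets.items()},
        descriptions={name: "synthetic" for name in sets},
    )


def generate_signaling_network(
    config: SimConfig,
    truth: GroundTruth,
    n_receptors: int = 3,
    n_signaling: int = 30,
    n_tfs: int = 10,
    n_targets: int = 50,
    n_planted_paths: int = 10,
) -> SignalingGraph:
    """Synthetic directed interactome with recoverable planted paths.

    Layered topology: receptors -> signaling proteins -> transcription
    factors -> target genes (targets are expression gene identifiers so SVD
    loadings map onto them). Every target has at least one incoming TF edge
    and every signaling/TF node is reachable from a receptor, so each target
    is reachable from some source through a TF-terminated path. Planted
    paths receive inflated edge confidences (0.99, against decoys capped at
    0.9) and the minimum possible hop count, which makes them the unique
    cheapest TF-terminated route to their targets; they are recorded in
    ``truth.planted_active_paths``.
    """
    rng = np.random.default_rng(config.seed + 202)
    receptors = [f"REC{i + 1}" for i in range(n_receptors)]
    signaling = [f"SIG{i + 1:02d}" for i in range(n_signaling)]
    tfs = [f"TF{i + 1:02d}" for i in range(n_tfs)]

    up = sorted(truth.up_genes)
    down = sorted(truth.down_genes)
    shared = _shared_gene_ids(config.n_shared_genes)
    unplanted = [g for g in shared if g not in truth.up_genes and g not in truth.down_genes]
    n_up_t = min(len(up), n_targets // 2)
    n_down_t = min(len(down), max(0, n_targets // 3 - 5))
    targets = (
        list(rng.choice(up, size=n_up_t, replace=False))
        + list(rng.choice(down, size=n_down_t, replace=False))
        + list(rng.choice(unplanted, size=n_targets - n_up_t - n_down_t, replace=False))
    )

    def decoy_conf() -> float:
        return float(np.clip(rng.beta(2.0, 4.0), 0.05, 0.9))

    edges: dict[tuple, float] = {}
    tf_edges: set[tuple] = set()

    def add_edge(tail, head, conf, tf=False):
        key = (tail, head)
        edges[key] = max(edges.get(key, 0.0), conf)
        if tf:
            tf_edges.add(key)

    for s in signaling:  # every signaling node hangs off >= 1 receptor
        for r in rng.choice(receptors, size=int(rng.integers(1, 3)), replace=False):
            add_edge(r, s, decoy_conf())
    for s in signaling:  # sparse signaling -> signaling cross-talk
        for t in rng.choice(signaling, size=2, replace=False):
            if t != s:
                add_edge(s, t, decoy_conf())
    for t in tfs:  # every TF reachable from the signaling layer
        for s in rng.choice(signaling, size=int(rng.integers(1, 4)), replace=False):
            add_edge(s, t, decoy_conf())
    for g in targets:  # every target has >= 1 incoming TF edge
        for t in rng.choice(tfs, size=int(rng.integers(1, 4)), replace=False):
            add_edge(t, g, decoy_conf(), tf=True)

    truth.planted_active_paths = []
    # disjoint interior nodes per planted path: inflated (0.99) edges from
    # different planted paths can then never chain into an equal-cost rival,
    # so each planted path is the unique cheapest route to its target
    n_planted_paths = min(n_planted_paths, len(targets), n_signaling, n_tfs)
    planted_targets = list(rng.choice(targets, size=n_planted_paths, replace=False))
    planted_sig = list(rng.choice(signaling, size=n_planted_paths, replace=False))
    planted_tfs = list(rng.choice(tfs, size=n_planted_paths, replace=False))
    for g, s, t in zip(planted_targets, planted_sig, planted_tfs):
        r = receptors[int(rng.integers(0, n_receptors))]
        add_edge(r, s, 0.99)
        add_edge(s, t, 0.99)
        add_edge(t, g, 0.99, tf=True)
        truth.planted_active_paths.append([r, s, t, g])

    edge_records = [(tail, head, conf) for (tail, head), conf in sorted(edges.items())]
    graph = SignalingGraph.from_edges(edge_records, sorted(tf_edges), sources=receptors)
    return graph


def write_fixtures(
    studies: list[ExpressionStudy],
    truth: GroundTruth,
    gene_sets: GeneSetCollection,
    graph: SignalingGraph,
    out_dir,
) -> dict:
    """Write every synthetic artifact as plain text and return a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"expression": {}, "n_studies": len(studies)}

    pheno_rows = []
    for study in studies:
        path = out / f"expression_{study.study_id}.tsv"
        wio.write_expression_tsv(study, path)
        manifest["expression"][study.study_id] = str(path)
        for s in study.samples:
            pheno_rows.append((s, study.study_id, study.phenotype[s], study.platform))
    pheno = pd.DataFrame(pheno_rows, columns=["sample_id", "study_id", "phenotype", "platform"])
    pheno_path = out / "phenotypes.tsv"
    pheno.to_csv(pheno_path, sep="\t", index=False)
    manifest["phenotypes"] = str(pheno_path)

    gmt_path = out / "gene_sets.gmt"
    gene_sets.write_gmt(gmt_path)
    manifest["gene_sets"] = str(gmt_path)

    edges_path = out / "network_edges.tsv"
    tf_path = out / "tf_edges.tsv"
    graph.write_edge_lists(edges_path, tf_path)
    manifest["network_edges"] = str(edges_path)
    manifest["tf_edges"] = str(tf_path)

    truth_path = out / "ground_truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "up_genes": sorted(truth.up_genes),
                "down_genes": sorted(truth.down_genes),
                "base_log2fc": {g: float(v) for g, v in truth.base_log2fc.items() if v != 0.0},
                "ambiguous_sample_ids": sorted(truth.ambiguous_sample_ids),
                "planted_active_paths": truth.planted_active_paths,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    manifest["ground_truth"] = str(truth_path)

    # the on-disk manifest stores paths relative to its own directory so a
    # fixture tree is relocatable and byte-reproducible
    relative = {
        k: ({s: Path(p).name for s, p in v.items()} if isinstance(v, dict) else
            Path(v).name if isinstance(v, str) else v)
        for k, v in manifest.items()
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(relative, fh, indent=1, sort_keys=True)
    manifest["manifest"] = str(manifest_path)
    return manifest
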