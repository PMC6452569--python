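"""Two-group differential expression and multi-comparison intersection.

Each comparison is a Welch two-sample t-test per gene on log2-scale values,
with Benjamini-Hochberg adjustment across all tested genes. A gene is called
significant when q < 0.05 and fold change > 1.5 (both strict), where fold
change is the ratio of geometric means, 2^|Δ mean log2|. The high-confidence
set is the direction-consistent intersection of the significant sets from
every configured comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionStudy

DE_COLUMNS = ["log2fc", "fold_change", "p_raw", "q_value", "direction", "comparison_id"]


class DesignError(ValueError):
    """Invalid group specification for a two-group test."""


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def differential_expression(
    study: ExpressionStudy,
    group_a: str | list[str],
    group_b: str | list[str],
    comparison_id: str | None = None,
) -> pd.DataFrame:
    """Per-gene Welch test of ``group_b`` vs ``group_a`` on log2 values.

    ``group_a`` is the baseline (e.g. NL) and ``group_b`` the condition
    (e.g. IL); positive log2fc means higher expression in ``group_b``.
    Groups may be given as a single phenotype label or a list of labels.
    Genes constant in both groups get p_raw = 1. Returns a DataFrame indexed
    by gene with columns log2fc, fold_change, p_raw, q_value, direction,
    comparison_id.
    """
    labels = study.labels()
    ga = [group_a] if isinstance(group_a, str) else list(group_a)
    gb = [group_b] if isinstance(group_b, str) else list(group_b)
    known = set(labels.unique())
    for g in ga + gb:
        if g not in known:
            raise DesignError(f"unknown group label {g!r} in {study.study_id}")
    a_cols = labels.index[labels.isin(ga)]
    b_cols = labels.index[labels.isin(gb)]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise DesignError("each group needs >= 2 samples")

    a = study.values[a_cols].to_numpy(dtype=float)
    b = study.values[b_cols].to_numpy(dtype=float)
    log2fc = b.mean(axis=1) - a.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        _, p_raw = stats.ttest_ind(b, a, axis=1, equal_var=False)
    # genes with zero variance in both groups: Welch statistic is undefined;
    # no evidence against the null, so p = 1
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)
    q_value = bh_adjust(p_raw)

    cid = comparison_id or f"{study.study_id}:{'+'.join(gb)}_vs_{'+'.join(ga)}"
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fold_change": np.exp2(np.abs(log2fc)),
            "p_raw": p_raw,
            "q_value": q_value,
            "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none")),
            "comparison_id": cid,
        },
        index=study.genes,
    )
    return table


def significant_genes(
    table: pd.DataFrame, q_max: float = 0.05, fc_min: float = 1.5
) -> pd.DataFrame:
    """Rows with q_value < q_max and fold_change > fc_min (strict), tagged
    up/down by the sign of log2fc."""
    mask = (table["q_value"] < q_max) & (table["fold_change"] > fc_min)
    out = table.loc[mask, DE_COLUMNS].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


def high_confidence_intersection(
    directed_sets: list[pd.DataFrame], require_direction: bool = True
) -> pd.DataFrame:
    """Genes significant in every comparison with a consistent direction.

    ``directed_sets`` are outputs of :func:`significant_genes`. Returns a
    DataFrame indexed by gene with columns direction, median_log2fc,
    median_q, n_comparisons, sorted by |median_log2fc| descending. With
    ``require_direction=False`` the intersection ignores direction (kept for
    comparison; the default matches the consistent-direction contract).
    """
    if len(directed_sets) < 2:
        raise ValueError("intersection requires >= 2 comparisons")
    common = set(directed_sets[0].index)
    for s in directed_sets[1:]:
        common &= set(s.index)
    records = []
    for gene in sorted(common):
        directions = {s.loc[gene, "direction"] for s in directed_sets}
        if require_direction and len(directions) > 1:
            continue
        log2fcs = [s.loc[gene, "log2fc"] for s in directed_sets]
        qs = [s.loc[gene, "q_value"] for s in directed_sets]
        records.append(
            (
                gene,
                directed_sets[0].loc[gene, "direction"] if len(directions) == 1 else "mixed",
                float(np.median(log2fcs)),
                float(np.median(qs)),
                len(directed_sets),
            )
        )
    out = pd.DataFrame(
        records, columns=["gene", "direction", "median_log2fc", "median_q", "n_comparisons"]
    ).set_index("gene")
    return out.sort_values("median_log2fc", key=lambda s: s.abs(), ascending=False)


def standard_comparisons(studies: list[ExpressionStudy]) -> list[tuple]:
    """The labor-vs-NL contrast list for a study collection.

    Two-group studies contribute IL vs NL; a three-group study contributes
    ILEa vs NL and ILEs vs NL, mirroring the four-comparison design of a
    collection with one three-group study.
    """
    comparisons = []
    for study in studies:
        groups = set(study.labels().unique())
        if "IL" in groups:
            comparisons.append((study, "NL", "IL"))
        if "ILEa" in groups:
            comparisons.append((study, "NL", "ILEa"))
        if "ILEs" in groups:
            comparisons.append((study, "NL", "ILEs"))
    return comparisons
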