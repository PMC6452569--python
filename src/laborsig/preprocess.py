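"""Per-study filtering, log transformation, and cross-platform merging.

The merge strategy reconciles count (RNA-seq-like) and intensity
(microarray-like) platforms by (1) log2(x+1)-transforming count studies,
(2) restricting every study to the genes measured in all of them, and
(3) z-scoring each study's genes (rows) and then samples (columns) before
concatenation, so that each study contributes comparably scaled columns to
the combined matrix used by classification and SVD.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CombinedMatrix, ExpressionStudy


class EmptyResultError(ValueError):
    """A filtering or merging step removed everything."""


def filter_genes(study: ExpressionStudy, max_zero_samples: int = 3) -> ExpressionStudy:
    """Drop genes with zero expression in more than ``max_zero_samples`` samples.

    Duplicate gene rows are collapsed first, keeping the duplicate with the
    highest mean expression. Genes with zeros in exactly ``max_zero_samples``
    samples are retained (the rule is a strict inequality).
    """
    values = study.values
    if values.index.duplicated().any():
        # keep, per gene id, the duplicate row with the highest mean expression
        order = values.mean(axis=1)
        pos = np.argsort(-order.to_numpy(), kind="stable")
        seen: set = set()
        keep_pos = []
        for p in pos:
            g = values.index[p]
            if g not in seen:
                seen.add(g)
                keep_pos.append(p)
        keep_pos.sort()
        values = values.iloc[keep_pos]
    zero_counts = (values == 0).sum(axis=1)
    kept = values.loc[zero_counts <= max_zero_samples]
    if kept.shape[0] == 0:
        raise EmptyResultError(f"{study.study_id}: all genes removed by zero filter")
    out = study.copy()
    out.values = kept
    out.log.append(f"filter_genes(max_zero_samples={max_zero_samples}): {len(values)} -> {len(kept)} genes")
    return out


def log_transform(study: ExpressionStudy) -> ExpressionStudy:
    """log2(x+1) for count studies; intensity studies pass through unchanged."""
    out = study.copy()
    if study.platform == "intensity":
        out.log.append("log_transform: no-op (already on log scale)")
        return out
    if (study.values.to_numpy() < 0).any():
        raise ValueError(f"{study.study_id}: negative values on count platform")
    out.values = np.log2(study.values + 1.0)
    out.platform = "intensity"
    out.log.append("log_transform: log2(x+1)")
    return out


def _zscore(arr: np.ndarray, axis: int) -> np.ndarray:
    """Standardize along ``axis`` with sample (n-1) sd; constants map to 0."""
    mean = arr.mean(axis=axis, keepdims=True)
    sd = arr.std(axis=axis, ddof=1, keepdims=True)
    out = np.zeros_like(arr, dtype=float)
    np.divide(arr - mean, sd, out=out, where=sd > 0)
    return out


def normalize_rows_columns(matrix):
    """One pass of row standardization followed by one pass of column
    standardization (z-score, sample sd). Constant rows/columns map to zeros.

    Accepts and returns either a DataFrame or an ndarray.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    arr = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    arr = _zscore(arr, axis=1)
    arr = _zscore(arr, axis=0)
    if is_frame:
        return pd.DataFrame(arr, index=matrix.index, columns=matrix.columns)
    return arr


def merge_studies(studies: list[ExpressionStudy]) -> CombinedMatrix:
    """Restrict to shared genes, normalize each study, and concatenate samples.

    Studies must already be filtered and log-transformed. Each study is row-
    then column-standardized over the shared genes before concatenation, so
    every column of the combined matrix has mean 0 and sd 1.
    """
    if len(studies) < 2:
        raise ValueError("merging requires at least two studies")
    shared = studies[0].genes
    for study in studies[1:]:
        shared = shared.intersection(study.genes)
    if len(shared) == 0:
        raise EmptyResultError("no genes shared by all studies")
    shared = sorted(shared)

    blocks = []
    annotations = []
    log = [f"merge: {len(shared)} shared genes across {len(studies)} studies"]
    for study in studies:
        block = normalize_rows_columns(study.values.loc[shared])
        blocks.append(block)
        log.append(f"{study.study_id}: z-score rows then columns over shared genes")
        for s in study.samples:
            annotations.append((s, study.study_id, study.phenotype[s]))
    values = pd.concat(blocks, axis=1)
    samples = pd.DataFrame(
        annotations, columns=["sample_id", "study_id", "phenotype"]
    ).set_index("sample_id")
    return CombinedMatrix(values=values, samples=samples, normalization_log=log)
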