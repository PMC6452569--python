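"""Eigen-pattern extraction from the combined expression matrix.

The combined matrix M (genes x samples) is decomposed as M = U diag(s) V^T.
Terminology follows the transcriptomics convention: a column of U is an
*eigen-sample* (one value per gene: each gene's contribution to a pattern)
and a row of V^T — equivalently a column of V — is an *eigen-gene* (one
value per sample: the pattern's activity in each sample). The *energy* of a
component is its share of total squared singular-value mass, s_i^2 / sum s^2.

Sign convention: singular vectors are defined up to a joint sign flip. The
first component is oriented so the mean eigen-gene loading over labor-labeled
samples is nonnegative (labor positive, quiescence negative); without labels
the largest-|loading| gene entry is made positive. Higher components use the
label-free rule. The convention makes loadings reproducible across runs and
column permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import LABOR_LABELS, CombinedMatrix


class CoverageError(ValueError):
    """Too little gene overlap to carry out the requested projection."""


@dataclass
class SVDResult:
    U: pd.DataFrame  # genes x r, columns are eigen-samples
    singular_values: np.ndarray  # nonincreasing, length r
    V: pd.DataFrame  # samples x r, columns are eigen-genes
    sign_convention: list[str] = field(default_factory=list)

    @property
    def source_matrix_shape(self) -> tuple[int, int]:
        return (self.U.shape[0], self.V.shape[0])

    @property
    def energy_fractions(self) -> np.ndarray:
        sq = self.singular_values**2
        return sq / sq.sum()

    def eigensample(self, component: int = 1) -> pd.Series:
        """Gene-indexed loadings of one component (column of U); 1-based."""
        return self.U.iloc[:, component - 1]

    def eigengene(self, component: int = 1) -> pd.Series:
        """Sample-indexed loadings of one component (column of V); 1-based."""
        return self.V.iloc[:, component - 1]


@dataclass
class LoadingRanking:
    axis: str  # "gene" or "sample"
    component: int
    positive: list[tuple]  # (identifier, loading), descending loading
    negative: list[tuple]  # (identifier, loading), ascending loading


def _decompose(values: pd.DataFrame, labor_mask: np.ndarray | None) -> SVDResult:
    if values.size == 0:
        raise ValueError("empty matrix")
    u, s, vt = np.linalg.svd(values.to_numpy(dtype=float), full_matrices=False)
    v = vt.T
    convention = []
    for j in range(len(s)):
        flip = False
        if j == 0 and labor_mask is not None and labor_mask.any():
            mean_labor = v[labor_mask, 0].mean()
            flip = mean_labor < 0
            convention.append("component 1: mean labor-sample loading >= 0")
        else:
            k = int(np.argmax(np.abs(u[:, j])))
            flip = u[k, j] < 0
            if j == 0:
                convention.append("component 1: largest-|loading| gene positive (no labels)")
        if flip:
            u[:, j] = -u[:, j]
            v[:, j] = -v[:, j]
    if len(convention) < 2 and len(s) > 1:
        convention.append("components >= 2: largest-|loading| gene positive")
    return SVDResult(
        U=pd.DataFrame(u, index=values.index),
        singular_values=s,
        V=pd.DataFrame(v, index=values.columns),
        sign_convention=convention,
    )


def run_svd(combined: CombinedMatrix) -> SVDResult:
    """Full SVD of the combined matrix with the labor-positive orientation."""
    labor = combined.phenotype.isin(LABOR_LABELS).to_numpy()
    return _decompose(combined.values, labor)


def svd_of_matrix(values: pd.DataFrame, labor_mask=None) -> SVDResult:
    """SVD of a bare genes x samples DataFrame (no annotations required)."""
    mask = None if labor_mask is None else np.asarray(labor_mask, dtype=bool)
    return _decompose(values, mask)


def energy(result: SVDResult, component: int = 1) -> float:
    """Fraction of total squared singular-value mass in one component."""
    if not 1 <= component <= len(result.singular_values):
        raise IndexError(f"component {component} out of range")
    return float(result.energy_fractions[component - 1])


def top_loadings(
    result: SVDResult, axis: str = "gene", component: int = 1, n: int = 25
) -> LoadingRanking:
    """The n largest-positive and n largest-negative loadings of one vector."""
    if axis == "gene":
        vec = result.eigensample(component)
    elif axis == "sample":
        vec = result.eigengene(component)
    else:
        raise ValueError("axis must be 'gene' or 'sample'")
    if n > len(vec):
        import warnings

        warnings.warn(f"n={n} exceeds dimension {len(vec)}; truncating", stacklevel=2)
        n = len(vec)
    ordered = vec.sort_values(kind="stable")
    negative = [(i, float(v)) for i, v in ordered.iloc[:n].items()]
    positive = [(i, float(v)) for i, v in ordered.iloc[::-1].iloc[:n].items()]
    return LoadingRanking(axis=axis, component=component, positive=positive, negative=negative)


def pathway_svd(combined: CombinedMatrix, gene_set) -> SVDResult:
    """SVD of the combined matrix restricted to one gene set's rows."""
    present = [g for g in combined.genes if g in set(gene_set)]
    if len(present) < 2:
        raise CoverageError(f"only {len(present)} gene(s) of the set are measured")
    restricted = CombinedMatrix(
        values=combined.values.loc[present],
        samples=combined.samples,
        normalization_log=list(combined.normalization_log),
    )
    return run_svd(restricted)


def svd_phenotype_score(
    result: SVDResult, expression_profile: pd.Series, min_overlap: float = 0.5
) -> tuple[float, str]:
    """Unsupervised phenotype call for one sample profile.

    The profile (gene-indexed, normalized like the combined matrix rows) is
    projected onto the first eigen-sample; a positive score calls labor (IL),
    otherwise NL (ties go to the quiescent baseline). Requires gene overlap
    with U of at least ``min_overlap``.
    """
    u1 = result.eigensample(1)
    shared = u1.index.intersection(expression_profile.index)
    if len(shared) < min_overlap * len(u1):
        raise CoverageError(
            f"profile covers {len(shared)}/{len(u1)} genes, below {min_overlap:.0%}"
        )
    score = float(u1.loc[shared] @ expression_profile.loc[shared])
    return score, ("IL" if score > 0 else "NL")


def write_svd_result(result: SVDResult, out_dir, tag: str = "global") -> dict:
    """Persist U, singular values, and V as TSVs plus JSON metadata."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    u_path = out / f"svd_{tag}_U.tsv"
    result.U.to_csv(u_path, sep="\t", float_format="%.10g")
    files["U"] = str(u_path)
    s_path = out / f"svd_{tag}_singular_values.tsv"
    pd.Series(result.singular_values, name="sigma").to_csv(s_path, sep="\t", float_format="%.10g")
    files["singular_values"] = str(s_path)
    v_path = out / f"svd_{tag}_V.tsv"
    result.V.to_csv(v_path, sep="\t", float_format="%.10g")
    files["V"] = str(v_path)
    meta = {
        "shape": list(result.source_matrix_shape),
        "sign_convention": result.sign_convention,
        "energy_fractions": [float(x) for x in result.energy_fractions],
    }
    meta_path = out / f"svd_{tag}_meta.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1)
    files["meta"] = str(meta_path)
    return files
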