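"""Core in-memory containers shared across the pipeline.

Expression data is carried as pandas DataFrames (genes in rows, samples in
columns) wrapped with the per-sample phenotype annotation that every stage
needs. Phenotype labels follow the clinical convention: NL (non-labor),
IL (in labor), and for the three-group study ILEa / ILEs (early / established
labor, split at 3 cm cervical dilation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHENOTYPES = ("NL", "ILEa", "ILEs", "IL")
#: labels counted as "in labor" when a binary contrast is needed
LABOR_LABELS = frozenset({"IL", "ILEa", "ILEs"})


@dataclass
class ExpressionStudy:
    """One study's genes x samples matrix plus platform and phenotype labels.

    Parameters
    ----------
    study_id
        Short identifier, e.g. ``"study1"``.
    platform
        ``"count"`` for raw count-like data (RNA-seq abundance estimates) or
        ``"intensity"`` for data already on a log-like scale (microarray).
    values
        DataFrame, rows indexed by gene identifier, columns by sample
        identifier.
    phenotype
        Mapping sample id -> phenotype label.
    """

    study_id: str
    platform: str
    values: pd.DataFrame
    phenotype: dict[str, str]
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.platform not in ("count", "intensity"):
            raise ValueError(f"unknown platform {self.platform!r}")
        missing = [s for s in self.values.columns if s not in self.phenotype]
        if missing:
            raise ValueError(f"samples without phenotype label: {missing[:5]}")
        bad = set(self.phenotype.values()) - set(PHENOTYPES)
        if bad:
            raise ValueError(f"unknown phenotype labels: {sorted(bad)}")
        if self.platform == "count" and (self.values.to_numpy() < 0).any():
            raise ValueError("count platform requires nonnegative values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def labels(self, samples=None) -> pd.Series:
        cols = self.values.columns if samples is None else samples
        return pd.Series([self.phenotype[s] for s in cols], index=cols, name="phenotype")

    def binary_labor(self) -> pd.Series:
        """0/1 series: 1 where the sample label denotes labor."""
        lab = self.labels()
        return (lab.isin(LABOR_LABELS)).astype(int)

    def copy(self) -> "ExpressionStudy":
        return ExpressionStudy(
            study_id=self.study_id,
            platform=self.platform,
            values=self.values.copy(),
            phenotype=dict(self.phenotype),
            log=list(self.log),
        )


@dataclass
class CombinedMatrix:
    """Normalized concatenation of several studies over their shared genes.

    ``values`` is the matrix M handed to the SVD stage (genes x samples);
    ``samples`` is an annotation table with columns ``study_id`` and
    ``phenotype`` indexed by sample id; ``normalization_log`` records the
    ordered normalization steps that produced ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    normalization_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample annotation index must match matrix columns")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("combined matrix contains NaN/Inf")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def phenotype(self) -> pd.Series:
        return self.samples["phenotype"]

    def binary_labor(self) -> pd.Series:
        return self.phenotype.isin(LABOR_LABELS).astype(int)
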