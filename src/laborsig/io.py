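"""Readers and writers for the plain-text formats used across the pipeline.

Expression TSV: first column is the gene identifier, remaining columns are
samples. Phenotype TSV: columns ``sample_id``, ``study_id``, ``phenotype``
(and optionally ``platform``). Expression values are serialized with 17
significant digits, which round-trips IEEE doubles exactly; derived report
tables use 10 significant digits for cross-platform diffability.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import ExpressionStudy

FLOAT_FORMAT = "%.17g"


class ParseError(ValueError):
    """Malformed input file; the message names the offending location."""


def write_expression_tsv(study: ExpressionStudy, path) -> None:
    frame = study.values.copy()
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_expression_tsv(
    path,
    study_id: str,
    platform: str,
    phenotype: dict[str, str],
) -> ExpressionStudy:
    """Load one study matrix; fails loudly on ragged rows or duplicate samples."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    seen: set = set()
    for col in header[1:]:  # pandas would silently mangle duplicates
        if col in seen:
            raise ParseError(f"{path}: duplicate sample column {col!r}")
        seen.add(col)
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip").astype(float)
    frame.index.name = None  # round-trip: the header label is not data
    if frame.isna().any().any():
        rows = frame.index[frame.isna().any(axis=1)].tolist()[:5]
        raise ParseError(f"{path}: missing/ragged values in rows {rows}")
    return ExpressionStudy(
        study_id=study_id,
        platform=platform,
        values=frame,
        phenotype={s: phenotype[s] for s in frame.columns},
    )


def read_phenotype_tsv(path) -> pd.DataFrame:
    """Phenotype table indexed by sample_id with study_id/phenotype columns."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "study_id", "phenotype"}
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if table["sample_id"].duplicated().any():
        dups = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()[:5]
        raise ParseError(f"{path}: duplicate sample ids {dups}")
    return table.set_index("sample_id")


def read_manifest(path) -> dict:
    """Load a fixture manifest file, resolving paths against its directory."""
    import json

    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    base = path.parent

    def resolve(v):
        if isinstance(v, dict):
            return {k: resolve(x) for k, x in v.items()}
        if isinstance(v, str):
            return str(base / v)
        return v

    return {k: resolve(v) if k != "n_studies" else v for k, v in raw.items()}


def read_study_collection(manifest: dict) -> list[ExpressionStudy]:
    """Rebuild the study list from a fixture manifest (see write_fixtures)."""
    pheno = read_phenotype_tsv(manifest["phenotypes"])
    studies = []
    for study_id, path in sorted(manifest["expression"].items()):
        rows = pheno[pheno["study_id"] == study_id]
        platform = rows["platform"].iloc[0] if "platform" in rows else "intensity"
        studies.append(
            read_expression_tsv(
                path,
                study_id=study_id,
                platform=platform,
                phenotype=rows["phenotype"].to_dict(),
            )
        )
    return studies
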