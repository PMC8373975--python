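"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices are gene-by-sample TSV (first column gene id, header =
sample ids); annotations and assay tables are CSV; gene sets use the
MSigDB GMT dialect (tab-separated name, description, then members); results
and ground truth serialize as JSON. Read then write is the identity on all
emitted artifacts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .core import DataError, ExpressionMatrix
from .syndata import GroundTruth

logger = logging.getLogger(__name__)


class GeneSetCollection(dict):
    """Named gene sets: maps set name -> list of gene ids.

    Descriptions are kept in :attr:`descriptions` keyed by set name.
    """

    def __init__(self, sets=None, descriptions=None):
        super().__init__(sets or {})
        self.descriptions: dict[str, str] = dict(descriptions or {})
        for name, members in self.items():
            if not members:
                raise DataError(f"gene set '{name}' is empty")


def read_expression(path, orientation: str = "genes_by_samples", layer: str = "counts") -> ExpressionMatrix:
    """Read a delimited expression matrix.

    ``orientation`` is ``genes_by_samples`` (default) or ``samples_by_genes``
    (the matrix is transposed on read). Duplicate gene or sample ids raise
    with the offending ids named; non-numeric cells and ragged rows raise.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise DataError(f"malformed expression file {path}: {exc}") from exc
    if orientation == "samples_by_genes":
        df = df.T
    elif orientation != "genes_by_samples":
        raise DataError(f"unknown orientation '{orientation}'")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise DataError(f"non-numeric values in columns: {non_numeric[:10]}")
    if df.isna().any().any():
        raise DataError(f"missing/ragged values in expression file {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = "gene_id"
    df.columns.name = None
    return ExpressionMatrix(df, layer=layer)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep=sep)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"layer": matrix.layer}) + "\n")


def read_annotation(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a sample annotation CSV indexed by its first column (sample id)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    for col in required:
        if col not in df.columns:
            raise DataError(f"annotation {path} is missing required column '{col}'")
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise DataError(f"duplicate sample ids in {path}: {dups}")
    return df


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, members per tab-separated line).

    Trailing empty fields are dropped; duplicate members within a set are
    deduplicated (first occurrence kept) with a logged warning.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DataError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
        name, desc, *members = fields
        members = [m for m in members if m != ""]
        if not members:
            raise DataError(f"{path}:{lineno}: gene set '{name}' has no members")
        if name in sets:
            raise DataError(f"{path}:{lineno}: duplicate set name '{name}'")
        seen: dict[str, None] = {}
        for m in members:
            if m in seen:
                logger.warning("set '%s': duplicate member '%s' dropped", name, m)
            else:
                seen[m] = None
        sets[name] = list(seen)
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = [
        "\t".join([name, collection.descriptions.get(name, "")] + list(members))
        for name, members in collection.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "de_log2fc": truth.de_log2fc,
        "base_log2": truth.base_log2,
        "batch_shift": truth.batch_shift,
        "batch_scale": truth.batch_scale,
        "lda_frequencies": truth.lda_frequencies,
        "meta_mu": truth.meta_mu,
        "meta_tau2": truth.meta_tau2,
        "hazard_ratio": truth.hazard_ratio,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(**payload)


def read_lda_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"arm", "dose", "n_tested", "n_response"}
    missing = needed - set(df.columns)
    if missing:
        raise DataError(f"LDA table {path} missing columns: {sorted(missing)}")
    return df


def read_meta_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "effect" not in df.columns:
        raise DataError(f"meta-analysis table {path} missing 'effect' column")
    return df


def read_survival_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"time", "event"} - set(df.columns)
    if missing:
        raise DataError(f"survival table {path} missing columns: {sorted(missing)}")
    return df
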