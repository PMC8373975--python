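"""Shared in-memory containers for the pipeline.

Expression data travel as a genes-by-samples :class:`pandas.DataFrame`
wrapped in :class:`ExpressionMatrix`, which carries a ``layer`` tag naming
the transformation state of the values (raw counts, log2-RPM, batch-adjusted,
centered). Sample metadata travel as a plain DataFrame indexed by sample id;
:func:`validate_annotation` enforces the contract between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Recognised layer tags, in the order the pipeline produces them.
LAYERS = ("counts", "log2rpm", "adjusted", "averaged", "centered")


class CmsShiftError(Exception):
    """Base class for user-facing errors raised by this package."""


class ConfigError(CmsShiftError):
    """An invalid configuration value; the message names the field."""


class DataError(CmsShiftError):
    """Malformed or inconsistent input data."""


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with a layer tag.

    Parameters
    ----------
    values
        DataFrame with gene ids as the index and sample ids as columns.
    layer
        One of :data:`LAYERS` (free-form tags are tolerated but the
        pipeline stages check for the tag they require).
    """

    values: pd.DataFrame
    layer: str = "counts"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise DataError(f"duplicate gene ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = sorted(self.values.columns[self.values.columns.duplicated()].unique())
            raise DataError(f"duplicate sample ids: {dups}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: pd.DataFrame, layer: str) -> "ExpressionMatrix":
        return replace(self, values=values, layer=layer)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = pd.Index(genes).difference(self.values.index)
        if len(missing):
            raise DataError(f"genes absent from matrix: {sorted(missing)[:10]}")
        return replace(self, values=self.values.loc[list(genes)])


def validate_annotation(
    annotation: pd.DataFrame,
    matrix: ExpressionMatrix | None = None,
    required: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Check an annotation table against a matrix and required columns.

    The annotation is joined to matrices by sample id (its index), never by
    row position, so row order is irrelevant. Returns the annotation
    reindexed to the matrix's column order when a matrix is given.
    """
    for col in required:
        if col not in annotation.columns:
            raise DataError(f"annotation is missing required column '{col}'")
    if annotation.index.has_duplicates:
        dups = sorted(annotation.index[annotation.index.duplicated()].unique())
        raise DataError(f"duplicate sample ids in annotation: {dups}")
    if matrix is not None:
        ann_ids = set(annotation.index)
        mat_ids = set(matrix.samples)
        if ann_ids != mat_ids:
            diff = sorted(ann_ids.symmetric_difference(mat_ids))
            raise DataError(
                "annotation and matrix sample ids disagree; "
                f"symmetric difference: {diff[:20]}"
            )
        return annotation.loc[matrix.samples]
    return annotation


def check_counts(matrix: ExpressionMatrix) -> None:
    """Raise unless the matrix holds non-negative integer counts."""
    vals = matrix.values.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise DataError("count matrix contains non-numeric values")
    if (vals < 0).any():
        raise DataError("count matrix contains negative values")
    if not np.allclose(vals, np.round(vals)):
        raise DataError("count matrix contains non-integer values")
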