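"""Data preparation: low-expression filter, log transform, sample alignment.

The rules mirror standard RNA-seq survival practice: features whose total
FPKM across all samples (both subtypes combined) is below a threshold are
deleted; retained values are transformed to log2(FPKM + 1); samples
missing any required clinical field are discarded before modelling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import (
    DataError,
    ExpressionMatrix,
    LOG2P1,
    RAW,
    validate_clinical,
)

#: Fields a sample must have to enter the screen.
DEFAULT_REQUIRED = ("os_time", "os_event", "subtype")

#: Warn (not fail) when a subtype has fewer samples than this after
#: alignment; tiny minority arms are analysable but unstable.
MIN_SUBTYPE_WARN = 10


def filter_low_expression(
    matrix: ExpressionMatrix, threshold: float = 4.0
) -> ExpressionMatrix:
    """Delete features whose FPKM row sum over all samples is < threshold.

    The boundary is literal: a row sum exactly equal to the threshold is
    retained.  Defined on raw FPKM only.
    """
    if matrix.scale_tag != RAW:
        raise DataError(
            "low-expression filter is defined on raw FPKM; "
            f"matrix is on the {matrix.scale_tag!r} scale"
        )
    keep = matrix.values.sum(axis=1) >= threshold
    return matrix.subset_features(keep)


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Map each FPKM value v to log2(v + 1)."""
    if matrix.scale_tag != RAW:
        raise DataError("matrix is already log-transformed")
    if matrix.values.size and np.any(matrix.values < 0):
        raise DataError("negative FPKM value")
    return ExpressionMatrix(
        matrix.feature_ids,
        matrix.sample_ids,
        np.log2(matrix.values + 1.0),
        LOG2P1,
    )


def align_samples(
    matrix: ExpressionMatrix,
    clinical: pd.DataFrame,
    require=DEFAULT_REQUIRED,
):
    """Intersect matrix columns with complete clinical rows.

    Drops samples missing any field in ``require`` (empty string / NA /
    "[Not Available]" tokens count as missing when read through
    :func:`coxfilter.containers.read_clinical_tsv`), then restricts both
    inputs to the shared sample ids.  The returned matrix column order and
    clinical row order are identical (matrix order wins).
    """
    validate_clinical(clinical)
    missing = [c for c in require if c not in clinical.columns]
    if missing:
        raise DataError(f"clinical table lacks required columns {missing}")
    complete = clinical.dropna(subset=list(require))
    shared = set(matrix.sample_ids) & set(complete["sample_id"])
    if not shared:
        raise DataError("no samples shared between matrix and clinical table")
    order = [s for s in matrix.sample_ids if s in shared]
    out_matrix = matrix.subset_samples(order)
    out_clinical = (
        complete.set_index("sample_id").loc[order].reset_index()
    )
    counts = out_clinical["subtype"].value_counts()
    for level, n in counts.items():
        if n < MIN_SUBTYPE_WARN:
            warnings.warn(
                f"subtype {level!r} has only {n} samples after alignment",
                UserWarning,
                stacklevel=2,
            )
    return out_matrix, out_clinical


def prepare(
    matrix: ExpressionMatrix,
    clinical: pd.DataFrame,
    fpkm_threshold: float = 4.0,
    require=DEFAULT_REQUIRED,
):
    """Full preparation: filter (raw mode only) -> log transform -> align.

    A matrix already on the log2 scale skips the filter and transform.
    """
    if matrix.scale_tag == RAW:
        matrix = filter_low_expression(matrix, fpkm_threshold)
        matrix = log_transform(matrix)
    return align_samples(matrix, clinical, require)
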