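"""Expression filtering and transformation.

Three steps, applied per cohort: flag sub-floor RPKM values as missing and
drop rows with too many of them, impute the remaining flagged values at the
floor and log2-transform, then drop low-variability rows by (unscaled)
median absolute deviation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from spongescout.matrix import EmptyMatrixError, ExpressionMatrix

DEFAULT_RPKM_FLOOR = 0.05
DEFAULT_MAX_MISSING_FRACTION = 0.20
DEFAULT_MIN_MAD = 0.5


def missingness_filter(
    m: ExpressionMatrix,
    rpkm_floor: float = DEFAULT_RPKM_FLOOR,
    max_missing_fraction: float = DEFAULT_MAX_MISSING_FRACTION,
    max_missing_count: int | None = None,
) -> ExpressionMatrix:
    """Drop rows with too many sub-floor (missing) values.

    Values strictly below ``rpkm_floor`` are treated as missing and set to
    NaN so the later imputation step can see them.  A row is dropped when
    its missing fraction exceeds ``max_missing_fraction``; pass
    ``max_missing_count`` instead to use an absolute-count rule (a row is
    dropped when more than that many values are missing).
    """
    if m.log_scale:
        raise ValueError("missingness_filter expects raw RPKM values")
    vals = m.values.where(m.values >= rpkm_floor)
    n_missing = vals.isna().sum(axis=1)
    if max_missing_count is not None:
        keep = n_missing <= max_missing_count
    else:
        keep = n_missing / m.n_samples <= max_missing_fraction
    if not keep.any():
        raise EmptyMatrixError("no rows survive the missingness filter")
    return ExpressionMatrix(
        values=vals.loc[keep],
        rna_class=m.rna_class.loc[keep],
        subtype=m.subtype,
        log_scale=False,
    )


def log2_transform(
    m: ExpressionMatrix, rpkm_floor: float = DEFAULT_RPKM_FLOOR
) -> ExpressionMatrix:
    """Impute missing entries at the floor, then log2 every entry."""
    vals = m.values.fillna(rpkm_floor)
    if (vals <= 0).any().any():
        raise ValueError("non-positive expression values cannot be log2-transformed")
    return ExpressionMatrix(
        values=np.log2(vals),
        rna_class=m.rna_class,
        subtype=m.subtype,
        log_scale=True,
    )


def row_mad(values: pd.DataFrame) -> pd.Series:
    """Unscaled MAD per row: median of |x - median(x)|."""
    med = values.median(axis=1)
    return (values.sub(med, axis=0)).abs().median(axis=1)


def mad_filter(
    m: ExpressionMatrix, min_mad: float = DEFAULT_MIN_MAD
) -> ExpressionMatrix:
    """Drop rows whose unscaled MAD is below ``min_mad``."""
    keep = row_mad(m.values) >= min_mad
    if not keep.any():
        raise EmptyMatrixError("no rows survive the MAD filter")
    return ExpressionMatrix(
        values=m.values.loc[keep],
        rna_class=m.rna_class.loc[keep],
        subtype=m.subtype,
        log_scale=m.log_scale,
    )


def preprocess(
    m: ExpressionMatrix,
    rpkm_floor: float = DEFAULT_RPKM_FLOOR,
    max_missing_fraction: float = DEFAULT_MAX_MISSING_FRACTION,
    max_missing_count: int | None = None,
    min_mad: float = DEFAULT_MIN_MAD,
) -> ExpressionMatrix:
    """Full chain: missingness filter -> log2 -> MAD filter.

    Idempotent in the sense that re-running the chain on an already
    preprocessed cohort (after undoing the log) removes nothing further.
    """
    m = missingness_filter(m, rpkm_floor, max_missing_fraction, max_missing_count)
    m = log2_transform(m, rpkm_floor)
    return mad_filter(m, min_mad)
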