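"""Inter-reader reproducibility filtering via intraclass correlation.

Radiomic features are only useful if they survive segmentation
variability: the same lesion contoured by two readers should yield nearly
the same value.  Features are scored with the intraclass correlation
coefficient across a reader study and those below a threshold (default
0.9) are excluded from all downstream analysis.

The default ICC form is ICC(2,1) — two-way random effects, absolute
agreement, single measures — the conservative standard for reader
studies, computed from the classic two-way ANOVA mean squares.  ICC(3,1)
(consistency) is available via ``variant="consistency"``; only the
consistency variant is invariant to a reader-specific affine shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from radsurv.errors import ValidationError

ICC_THRESHOLD_DEFAULT = 0.9


@dataclass(frozen=True)
class ReaderPairedFeatures:
    """Per-subject feature tables from two readers over the same images."""

    reader_a: pd.DataFrame
    reader_b: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.reader_a.index.equals(self.reader_b.index):
            raise ValidationError("reader tables must cover identical subjects")
        if list(self.reader_a.columns) != list(self.reader_b.columns):
            raise ValidationError("reader tables must have identical feature columns")
        if len(self.reader_a) < 3:
            raise ValidationError("ICC requires at least 3 subjects")

    @property
    def features(self) -> list[str]:
        return list(self.reader_a.columns)


def icc_from_matrix(data: np.ndarray, variant: str = "agreement") -> float:
    """Single-measure ICC of an (n subjects x k raters) matrix.

    ``variant="agreement"`` gives ICC(2,1) (two-way random, absolute
    agreement); ``variant="consistency"`` gives ICC(3,1).
    """
    data = np.asarray(data, dtype=float)
    if np.isnan(data).any():
        raise ValidationError("missing values in ICC input")
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if ss_rows <= 1e-12 * max(ss_total, 1e-300):
        warnings.warn("zero between-subject variance; ICC defined as 0")
        return 0.0
    if variant == "agreement":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif variant == "consistency":
        denom = msr + (k - 1) * mse
    else:
        raise ValidationError(f"unknown ICC variant {variant!r}")
    if denom <= 0:
        warnings.warn("degenerate variance decomposition; ICC defined as 0")
        return 0.0
    return float((msr - mse) / denom)


def icc(
    paired: ReaderPairedFeatures, feature: str | None = None, variant: str = "agreement"
) -> float:
    """Inter-reader ICC of one feature (may be omitted for a 1-feature table)."""
    if feature is None:
        if len(paired.features) != 1:
            raise ValidationError("feature name required for multi-feature tables")
        feature = paired.features[0]
    a = paired.reader_a[feature].to_numpy(dtype=float)
    b = paired.reader_b[feature].to_numpy(dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError(f"missing values for feature {feature!r}")
    if np.var(np.concatenate([a, b])) < 1e-300:
        warnings.warn("zero between-subject variance; ICC defined as 0")
        return 0.0
    return icc_from_matrix(np.column_stack([a, b]), variant=variant)


def filter_unstable(
    features: list[str],
    paired: ReaderPairedFeatures,
    threshold: float = ICC_THRESHOLD_DEFAULT,
    variant: str = "agreement",
) -> tuple[list[str], pd.DataFrame]:
    """Split features into stable (ICC >= threshold) and excluded.

    Returns the retained feature list (input order preserved) and a report
    with one row per feature: its ICC and whether it was retained.
    """
    rows = []
    retained = []
    for feat in features:
        value = icc(paired, feat, variant=variant)
        keep = value >= threshold
        rows.append({"feature": feat, "icc": value, "retained": keep})
        if keep:
            retained.append(feat)
    report = pd.DataFrame(rows).set_index("feature")
    return retained, report
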