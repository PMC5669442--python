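"""First-order (histogram) features of the ROI intensity distribution.

Moment statistics (mean, SD, variance, skewness, kurtosis) and the
percentiles C5..C95 are computed on the raw HU values; entropy,
homogeneity and energy follow in-house texture-software conventions:
entropy and homogeneity on the discretized grey-level histogram
(``-sum p log2 p`` and ``sum p^2``), energy as the sum of squared raw
intensities.  Skewness and kurtosis use population (biased) moments with
kurtosis in non-excess form; both are defined as 0 for a zero-variance ROI.
"""

from __future__ import annotations

import numpy as np

from radsurv.errors import DegenerateInputError
from radsurv.features.discretize import BinningSpec, DiscretizedROI, discretize
from radsurv.io import ImageVolume, SegmentationMask

FIRST_ORDER_NAMES = (
    "mean",
    "standard deviation",
    "variance",
    "skewness",
    "kurtosis",
    "entropy",
    "homogeneity",
    "energy",
    "C5",
    "C10",
    "C25",
    "C50",
    "C75",
    "C90",
    "C95",
)

_PERCENTILES = (5, 10, 25, 50, 75, 90, 95)


def histogram_probabilities(droi: DiscretizedROI) -> np.ndarray:
    """Probability of each grey level 1..n_levels inside the mask."""
    counts = np.bincount(droi.foreground_levels, minlength=droi.n_levels + 1)[1:]
    return counts / counts.sum()


def first_order_features(
    volume: ImageVolume,
    mask: SegmentationMask,
    binning: BinningSpec | None = None,
    droi: DiscretizedROI | None = None,
) -> dict[str, float]:
    """The 15 first-order features of a volume+mask pair."""
    if droi is None:
        droi = discretize(volume, mask, binning)
    values = droi.intensities
    if values.size < 2:
        raise DegenerateInputError("first-order features require >= 2 foreground voxels")

    mu = float(values.mean())
    m2 = float(np.mean((values - mu) ** 2))
    sd = float(np.sqrt(m2))
    if m2 > 0:
        skew = float(np.mean((values - mu) ** 3) / m2 ** 1.5)
        kurt = float(np.mean((values - mu) ** 4) / m2 ** 2)
    else:
        skew = 0.0
        kurt = 0.0

    p = histogram_probabilities(droi)
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    homogeneity = float((p ** 2).sum())
    energy = float((values ** 2).sum())

    out = {
        "mean": mu,
        "standard deviation": sd,
        "variance": m2,
        "skewness": skew,
        "kurtosis": kurt,
        "entropy": entropy,
        "homogeneity": homogeneity,
        "energy": energy,
    }
    pct = np.percentile(values, _PERCENTILES)  # linear interpolation
    for q, v in zip(_PERCENTILES, pct):
        out[f"C{q}"] = float(v)
    return out
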