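"""Grey-level discretization of a masked region of interest.

Texture matrices (co-occurrence, run-length) are built on integer grey
levels 1..N_g.  Two standard binning modes are supported:

* ``fixed_count`` (default, N_g = 64): the ROI min-max range is split into
  a fixed number of equal bins, making texture features invariant to
  constant HU offsets.
* ``fixed_width`` (default 25 HU): bins of constant width anchored at the
  ROI minimum, preserving absolute contrast scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from radsurv.errors import ConfigError, ValidationError
from radsurv.io import ImageVolume, SegmentationMask


@dataclass(frozen=True)
class BinningSpec:
    """How ROI intensities are mapped to grey levels."""

    mode: str = "fixed_count"  # "fixed_count" | "fixed_width"
    n_bins: int = 64
    bin_width: float = 25.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_count", "fixed_width"):
            raise ConfigError(f"unknown binning mode {self.mode!r}")
        if self.mode == "fixed_count" and self.n_bins < 1:
            raise ConfigError(f"n_bins must be >= 1, got {self.n_bins}")
        if self.mode == "fixed_width" and self.bin_width <= 0:
            raise ConfigError(f"bin_width must be > 0, got {self.bin_width}")


@dataclass(frozen=True)
class DiscretizedROI:
    """Integer grey levels over the mask; 0 marks background.

    ``levels`` has the full grid shape with level 0 outside the mask and
    levels 1..n_levels inside.
    """

    levels: np.ndarray
    n_levels: int
    binning: BinningSpec
    intensities: np.ndarray  # raw HU of foreground voxels, flattened
    mask: np.ndarray

    @property
    def foreground_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def discretize_array(
    values: np.ndarray, mask: np.ndarray, binning: BinningSpec
) -> DiscretizedROI:
    """Discretize an arbitrary scalar field within a mask."""
    if not mask.any():
        raise ValidationError("cannot discretize an empty mask")
    fg = values[mask].astype(float)
    vmin = fg.min()
    vmax = fg.max()
    levels = np.zeros(values.shape, dtype=np.int32)
    if vmax == vmin:
        levels[mask] = 1
        n_levels = 1
    elif binning.mode == "fixed_count":
        width = (vmax - vmin) / binning.n_bins
        lv = np.floor((fg - vmin) / width).astype(np.int32) + 1
        np.clip(lv, 1, binning.n_bins, out=lv)
        levels[mask] = lv
        n_levels = binning.n_bins
    else:  # fixed_width
        lv = np.floor((fg - vmin) / binning.bin_width).astype(np.int32) + 1
        levels[mask] = lv
        n_levels = int(lv.max())
    return DiscretizedROI(
        levels=levels, n_levels=n_levels, binning=binning, intensities=fg, mask=mask
    )


def discretize(
    volume: ImageVolume, mask: SegmentationMask, binning: BinningSpec | None = None
) -> DiscretizedROI:
    """Discretize the HU values of a volume within a segmentation mask."""
    binning = binning or BinningSpec()
    mask.check_compatible(volume)
    return discretize_array(volume.intensities, mask.voxels, binning)
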