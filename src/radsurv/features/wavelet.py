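"""Wavelet-decomposed grey-level nonuniformity.

The masked bounding box of the volume undergoes a single-level 3D
undecimated (stationary) wavelet transform with Coiflet-1 filters,
yielding 8 sub-bands labelled by the filter applied along each axis:
``LLL`` (low-pass along x, y and z) through ``HHH``.  The undecimated
transform keeps every sub-band on the original grid, so the segmentation
mask applies unchanged; each sub-band is re-discretized within the mask
and its grey-level nonuniformity computed.
"""

from __future__ import annotations

import numpy as np
import pywt

from radsurv.errors import ValidationError
from radsurv.features.discretize import BinningSpec, discretize_array
from radsurv.features.texture import glrl, grey_level_nonuniformity
from radsurv.io import ImageVolume, SegmentationMask

#: sub-band names: letter i is the filter (L=low, H=high) along x, y, z
SUBBAND_NAMES = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

WAVELET_NAMES = tuple(f"wavelet GLN {b}" for b in SUBBAND_NAMES)


def _subband_key(name: str) -> str:
    """Map an x,y,z sub-band name to the pywt key (axis 0 = z first)."""
    trans = {"L": "a", "H": "d"}
    fx, fy, fz = name
    return trans[fz] + trans[fy] + trans[fx]


def swt3(data: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """Single-level 3D stationary wavelet transform -> 8 named sub-bands.

    Input axes are (z, y, x); each dimension must be >= 2 and is padded to
    even length internally (the pad is trimmed from the output).
    """
    if min(data.shape) < 2:
        raise ValidationError(f"each axis must have >= 2 samples, got shape {data.shape}")
    pad = [(0, s % 2) for s in data.shape]
    padded = np.pad(data, pad, mode="edge")
    coeffs = pywt.swtn(padded, wavelet, level=1)[0]
    trim = tuple(slice(0, s) for s in data.shape)
    return {name: coeffs[_subband_key(name)][trim] for name in SUBBAND_NAMES}


def wavelet_gln(
    volume: ImageVolume,
    mask: SegmentationMask,
    binning: BinningSpec | None = None,
    wavelet: str = "coif1",
) -> dict[str, float]:
    """GLN of each of the 8 stationary-wavelet sub-bands within the mask."""
    binning = binning or BinningSpec()
    mask.check_compatible(volume)
    vox = mask.voxels
    zz, yy, xx = np.nonzero(vox)
    # bounding box with a margin of 1 voxel (clipped to the grid) so the
    # wavelet filters see some context around the lesion
    lo = [max(int(c.min()) - 1, 0) for c in (zz, yy, xx)]
    hi = [min(int(c.max()) + 2, s) for c, s in zip((zz, yy, xx), vox.shape)]
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub_vol = volume.intensities[box]
    sub_mask = vox[box]
    if min(sub_vol.shape) < 2:
        pad = [(0, max(0, 2 - s)) for s in sub_vol.shape]
        sub_vol = np.pad(sub_vol, pad, mode="edge")
        sub_mask = np.pad(sub_mask, pad, mode="edge")
    out: dict[str, float] = {}
    for name, band in swt3(sub_vol, wavelet).items():
        droi = discretize_array(band, sub_mask, binning)
        out[f"wavelet GLN {name}"] = grey_level_nonuniformity(glrl(droi))
    return out
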