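"""The 37 canonical 3D radiomic features.

Five families: 15 first-order statistics, 8 size-and-shape descriptors,
5 grey-level co-occurrence (GLCM) features, grey-level nonuniformity
(GLN) from the run-length matrix, and GLN of the 8 sub-bands of a
single-level stationary wavelet decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from radsurv.features.discretize import (
    BinningSpec,
    DiscretizedROI,
    discretize,
    discretize_array,
)
from radsurv.features.firstorder import FIRST_ORDER_NAMES, first_order_features
from radsurv.features.shape import SHAPE_NAMES, shape_features
from radsurv.features.texture import (
    DIRECTIONS_13,
    GLCM,
    GLCM_NAMES,
    GLRLMatrix,
    glcm,
    glcm_features,
    glrl,
    grey_level_nonuniformity,
)
from radsurv.features.wavelet import SUBBAND_NAMES, WAVELET_NAMES, swt3, wavelet_gln
from radsurv.io import ImageVolume, SegmentationMask

#: canonical ordering of all 37 feature names
FEATURE_NAMES: tuple[str, ...] = (
    FIRST_ORDER_NAMES
    + SHAPE_NAMES
    + GLCM_NAMES
    + ("grey-level nonuniformity",)
    + WAVELET_NAMES
)

assert len(FEATURE_NAMES) == 37


@dataclass(frozen=True)
class FeatureConfig:
    """Configuration of the feature engine (recorded with every output)."""

    binning: BinningSpec = field(default_factory=BinningSpec)
    glcm_distance: int = 1
    glcm_moment_order: int = 1
    wavelet: str = "coif1"
    surface_mode: str = "mesh"  # "mesh" | "voxel_faces"


def extract_all(
    volume: ImageVolume,
    mask: SegmentationMask,
    config: FeatureConfig | None = None,
) -> dict[str, float]:
    """Compute all 37 features for one volume+mask pair.

    Returns a dict keyed by canonical feature name, in
    :data:`FEATURE_NAMES` order.  Deterministic: repeated calls on the
    same inputs are bit-identical.
    """
    config = config or FeatureConfig()
    mask.check_compatible(volume)
    droi = discretize(volume, mask, config.binning)

    out: dict[str, float] = {}
    out.update(first_order_features(volume, mask, droi=droi))
    out.update(shape_features(mask, surface_mode=config.surface_mode))
    out.update(glcm_features(glcm(droi, distance=config.glcm_distance),
                             moment_order=config.glcm_moment_order))
    out["grey-level nonuniformity"] = grey_level_nonuniformity(glrl(droi))
    out.update(wavelet_gln(volume, mask, config.binning, config.wavelet))
    return {name: out[name] for name in FEATURE_NAMES}


__all__ = [
    "FEATURE_NAMES",
    "FeatureConfig",
    "BinningSpec",
    "DiscretizedROI",
    "discretize",
    "discretize_array",
    "first_order_features",
    "FIRST_ORDER_NAMES",
    "shape_features",
    "SHAPE_NAMES",
    "glcm",
    "glcm_features",
    "GLCM",
    "GLCM_NAMES",
    "glrl",
    "GLRLMatrix",
    "grey_level_nonuniformity",
    "wavelet_gln",
    "swt3",
    "SUBBAND_NAMES",
    "WAVELET_NAMES",
    "DIRECTIONS_13",
    "extract_all",
]
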