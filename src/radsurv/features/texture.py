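"""Grey-level co-occurrence and run-length texture features.

Both matrices are fully three-dimensional: voxel pairs (GLCM) and maximal
runs (GLRL) are accumulated over the 13 unique 3D directions at distance
1 (the 26-neighbourhood modulo central symmetry).  The GLCM is summed
over directions, symmetrized and normalized to probabilities; run-length
matrices are summed over directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from radsurv.errors import ContractError, DegenerateInputError
from radsurv.features.discretize import DiscretizedROI

#: the 13 unique direction vectors (dz, dy, dx) of the 3D 26-neighbourhood
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)

GLCM_NAMES = (
    "GLCM moments",
    "GLCM angular second moment",
    "GLCM inverse difference moment",
    "GLCM contrast",
    "GLCM entropy",
)


@dataclass(frozen=True)
class GLCM:
    """Normalized, symmetric grey-level co-occurrence matrix."""

    P: np.ndarray
    distance: int = 1
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13

    def __post_init__(self) -> None:
        if not np.isclose(self.P.sum(), 1.0):
            raise ContractError("GLCM probabilities must sum to 1")
        if not np.allclose(self.P, self.P.T):
            raise ContractError("GLCM must be symmetric")


@dataclass(frozen=True)
class GLRLMatrix:
    """Run-length matrix R[g, l-1] = number of runs of level g+1, length l."""

    R: np.ndarray
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13

    @property
    def total_runs(self) -> float:
        return float(self.R.sum())


def _shifted_views(arr: np.ndarray, d: tuple[int, int, int]):
    """Views (a, b) such that b is arr shifted by +d, over the overlap."""
    slices_a, slices_b = [], []
    for dim, off in zip(arr.shape, d):
        if off >= 0:
            slices_a.append(slice(0, dim - off))
            slices_b.append(slice(off, dim))
        else:
            slices_a.append(slice(-off, dim))
            slices_b.append(slice(0, dim + off))
    return arr[tuple(slices_a)], arr[tuple(slices_b)]


def glcm(
    droi: DiscretizedROI,
    distance: int = 1,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> GLCM:
    """Co-occurrence matrix over all given directions, symmetrized and normalized."""
    n = droi.n_levels
    levels = droi.levels
    counts = np.zeros((n, n), dtype=np.int64)
    for d in directions:
        step = tuple(distance * c for c in d)
        a, b = _shifted_views(levels, step)
        valid = (a > 0) & (b > 0)
        if valid.any():
            np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1)
    sym = counts + counts.T
    total = sym.sum()
    if total == 0:
        # single voxel / no neighbouring pairs: degenerate uniform matrix
        sym = np.zeros((n, n), dtype=float)
        fg = droi.foreground_levels
        sym[fg[0] - 1, fg[0] - 1] = 1.0
        total = 1.0
    return GLCM(P=sym / total, distance=distance, directions=directions)


def glcm_features(M: GLCM, moment_order: int = 1) -> dict[str, float]:
    """GLCM moments, ASM, inverse difference moment, contrast, entropy.

    "Moments" is the grey-level moment of the co-occurrence distribution,
    sum_ij i^k p(i, j) with k = ``moment_order`` (default the GLCM mean).
    """
    P = M.P
    n = P.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    moments = float(((ii ** moment_order) * P).sum())
    asm = float((P ** 2).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())
    contrast = float((((ii - jj) ** 2) * P).sum())
    nz = P[P > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return {
        "GLCM moments": moments,
        "GLCM angular second moment": asm,
        "GLCM inverse difference moment": idm,
        "GLCM contrast": contrast,
        "GLCM entropy": entropy,
    }


def glrl(
    droi_or_levels: DiscretizedROI | np.ndarray,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
    n_levels: int | None = None,
) -> GLRLMatrix:
    """Run-length matrix of maximal same-level runs, summed over directions.

    Background voxels (level 0) break runs.  Accepts either a
    :class:`DiscretizedROI` or a raw integer level array.
    """
    if isinstance(droi_or_levels, DiscretizedROI):
        levels = droi_or_levels.levels
        n = droi_or_levels.n_levels
    else:
        levels = droi_or_levels
        n = n_levels if n_levels is not None else int(levels.max())
    if n < 1:
        raise DegenerateInputError("run-length matrix of an empty ROI")
    max_len = max(levels.shape)
    R = np.zeros((n, max_len), dtype=np.int64)
    coords = np.argwhere(levels > 0)
    flat_levels = levels
    for d in directions:
        d_arr = np.array(d)
        # a run starts at v if v-d is out of bounds or has a different level
        prev = coords - d_arr
        in_bounds = np.all((prev >= 0) & (prev < levels.shape), axis=1)
        same = np.zeros(len(coords), dtype=bool)
        pb = prev[in_bounds]
        cb = coords[in_bounds]
        same[in_bounds] = (
            flat_levels[pb[:, 0], pb[:, 1], pb[:, 2]]
            == flat_levels[cb[:, 0], cb[:, 1], cb[:, 2]]
        )
        starts = coords[~same]
        if len(starts) == 0:
            continue
        run_level = flat_levels[starts[:, 0], starts[:, 1], starts[:, 2]]
        pos = starts.copy()
        active = np.arange(len(starts))
        length = np.ones(len(starts), dtype=np.int64)
        while len(active):
            nxt = pos[active] + d_arr
            ok = np.all((nxt >= 0) & (nxt < levels.shape), axis=1)
            cont = np.zeros(len(active), dtype=bool)
            nb = nxt[ok]
            cont[ok] = (
                flat_levels[nb[:, 0], nb[:, 1], nb[:, 2]] == run_level[active[ok]]
            )
            pos[active[cont]] += d_arr
            length[active[cont]] += 1
            active = active[cont]
        np.add.at(R, (run_level - 1, length - 1), 1)
    return GLRLMatrix(R=R, directions=directions)


def grey_level_nonuniformity(R: GLRLMatrix) -> float:
    """GLN = sum_g (sum_l R[g, l])^2 / total runs.

    Large when runs concentrate in few grey levels (many runs of similar
    intensity), small when runs spread evenly over many levels.
    """
    total = R.total_runs
    if total == 0:
        raise DegenerateInputError("empty run-length matrix")
    per_level = R.R.sum(axis=1).astype(float)
    return float((per_level ** 2).sum() / total)
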