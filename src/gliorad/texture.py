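"""Second-order 3D texture statistics: GLCM and GLRLM.

Both matrix families are accumulated per spatial direction over the 13
unique directions of 3D 26-connectivity (one representative per +/- pair),
restricted to voxel pairs lying entirely inside the VOI mask.  GLCM
statistics can then be aggregated across directions by arithmetic mean or
by sample standard deviation; the directional SD is the anisotropy readout
that the prognostic feature `T2_core_GLCMhomogeniety_3_SD` is built from.

Gray levels are the 256-level quantized values used directly, with no
re-binning.  The GLCM offset multiplies the unit direction componentwise
(Chebyshev convention), so offset 3 in direction (1, 1, 0) pairs voxels
(x, y, z) and (x+3, y+3, z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .preprocess import N_GRAY_LEVELS, QuantizedVolume, VoiMask

# one representative of each +/- pair of 26-connectivity offsets, in fixed
# lexicographic order: first nonzero component positive
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS_3D) == 13

GLCM_STATS = ("contrast", "correlation", "energy", "homogeniety", "entropy")
GLRLM_STATS = ("SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRHGE")


def _shifted_pairs(levels: np.ndarray, mask: np.ndarray, vec: tuple[int, int, int]):
    """Gray levels of ordered voxel pairs (x, x+vec) with both inside the mask."""
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, d in enumerate(vec):
        n = levels.shape[ax]
        if abs(d) >= n:
            return None
        if d >= 0:
            src[ax] = slice(0, n - d)
            dst[ax] = slice(d, n)
        else:
            src[ax] = slice(-d, n)
            dst[ax] = slice(0, n + d)
    src_t, dst_t = tuple(src), tuple(dst)
    both = mask[src_t] & mask[dst_t]
    if not both.any():
        return None
    return levels[src_t][both], levels[dst_t][both]


@dataclass
class _SparseGlcm:
    """Nonzero entries (i, j, p) of one symmetric normalized GLCM."""

    ii: np.ndarray
    jj: np.ndarray
    p: np.ndarray

    def dense(self) -> np.ndarray:
        m = np.zeros((N_GRAY_LEVELS, N_GRAY_LEVELS))
        m[self.ii, self.jj] = self.p
        return m


@dataclass
class GlcmSet:
    """One symmetric, normalized 256x256 co-occurrence matrix per direction.

    Matrices are held sparsely; directions with no valid voxel pair are
    ``None`` (empty).  Per-direction statistics are computed lazily and
    cached, since every statistic is read twice (mean and SD aggregation).
    """

    matrices: dict[tuple[int, int, int], _SparseGlcm | None]
    offset: int

    def __post_init__(self) -> None:
        self._stat_cache: dict[str, list[float]] = {}

    @property
    def nonempty_directions(self) -> list[tuple[int, int, int]]:
        return [d for d, m in self.matrices.items() if m is not None]

    def direction_stats(self, stat: str) -> list[float]:
        if stat not in self._stat_cache:
            self._stat_cache[stat] = [
                _glcm_stat_one(m, stat) for m in self.matrices.values() if m is not None
            ]
        return self._stat_cache[stat]


def compute_glcm_set(q: QuantizedVolume, mask: VoiMask, offset: int) -> GlcmSet:
    """Co-occurrence matrices at a voxel offset for all 13 directions.

    For each direction ``d`` the ordered pairs (x, x + offset*d) with both
    voxels in the mask are counted, the count matrix is symmetrized, and
    normalized to a probability distribution.
    """
    if offset < 1:
        raise ValueError("offset must be >= 1")
    levels = np.asarray(q.levels)
    m = mask.mask
    # compact the gray levels present in the mask so the per-direction
    # count array is nu^2 instead of 256^2
    uvals = np.unique(levels[m]) if m.any() else np.empty(0, dtype=levels.dtype)
    nu = len(uvals)
    lut = np.zeros(N_GRAY_LEVELS, dtype=np.int64)
    lut[uvals] = np.arange(nu)
    ranks = lut[levels]
    out: dict[tuple[int, int, int], _SparseGlcm | None] = {}
    for d in DIRECTIONS_3D:
        vec = tuple(offset * c for c in d)
        pairs = _shifted_pairs(ranks, m, vec)
        if pairs is None:
            out[d] = None
            continue
        ri, rj = pairs
        # symmetrize by counting each ordered pair both ways
        code = np.concatenate([ri * nu + rj, rj * nu + ri])
        uniq, counts = np.unique(code, return_counts=True)
        p = counts / counts.sum()
        out[d] = _SparseGlcm(ii=uvals[uniq // nu].astype(np.int64),
                             jj=uvals[uniq % nu].astype(np.int64), p=p)
    return GlcmSet(matrices=out, offset=offset)


def _glcm_stat_one(m: _SparseGlcm, stat: str) -> float:
    ii, jj, pv = m.ii, m.jj, m.p
    if stat == "homogeniety":
        return float(np.sum(pv / (1.0 + (ii - jj) ** 2)))
    if stat == "contrast":
        return float(np.sum((ii - jj) ** 2 * pv))
    if stat == "energy":
        return float(np.sum(pv**2))
    if stat == "entropy":
        return float(-np.sum(pv * np.log2(pv)))
    if stat == "correlation":
        # symmetric matrix: both marginals coincide
        mu = float(np.sum(ii * pv))
        var = float(np.sum((ii - mu) ** 2 * pv))
        if var == 0:  # constant region: correlation undefined, reported as 0
            return 0.0
        return float((np.sum(ii * jj * pv) - mu * mu) / var)
    raise ValueError(f"unknown GLCM statistic '{stat}'")


def glcm_feature(glcm: GlcmSet, stat: str, agg: str) -> float:
    """A GLCM statistic aggregated across directions by mean or sample SD.

    Returns NaN (a missing value, feeding listwise deletion) when no
    direction has a valid pair, or when SD is requested with fewer than two
    nonempty directions.
    """
    vals = glcm.direction_stats(stat)
    if not vals:
        return float("nan")
    if agg == "mean":
        return float(np.mean(vals))
    if agg == "SD":
        if len(vals) < 2:
            return float("nan")
        return float(np.std(vals, ddof=1))
    raise ValueError(f"unknown aggregation '{agg}'")


@njit(cache=True)
def _runs_kernel(levels, mask, dx, dy, dz):
    """Walk every line of direction (dx,dy,dz): emit (gray, length) per
    maximal same-level run inside the mask."""
    nx, ny, nz = levels.shape
    cap = nx * ny * nz
    grays = np.empty(cap, dtype=np.int64)
    lens = np.empty(cap, dtype=np.int64)
    cnt = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                g = levels[x, y, z]
                px, py, pz = x - dx, y - dy, z - dz
                if (
                    0 <= px < nx and 0 <= py < ny and 0 <= pz < nz
                    and mask[px, py, pz] and levels[px, py, pz] == g
                ):
                    continue  # interior of a run, not its start
                length = 0
                cx, cy, cz = x, y, z
                while (
                    0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz
                    and mask[cx, cy, cz] and levels[cx, cy, cz] == g
                ):
                    length += 1
                    cx += dx
                    cy += dy
                    cz += dz
                grays[cnt] = g
                lens[cnt] = length
                cnt += 1
    return grays[:cnt], lens[:cnt]


def _runs_one_direction(levels: np.ndarray, mask: np.ndarray, d: tuple[int, int, int]):
    """Gray level and length of every maximal same-level run along direction d.

    A run is broken by a level change, a mask boundary, or the grid edge.
    Returns (gray_levels, run_lengths) arrays; empty mask gives empty arrays.
    """
    return _runs_kernel(
        np.ascontiguousarray(levels, dtype=np.int64),
        np.ascontiguousarray(mask),
        d[0], d[1], d[2],
    )


def glrlm_features(q: QuantizedVolume, mask: VoiMask) -> dict[str, float]:
    """Run-length statistics averaged over the 13 directions.

    Per direction the run-length matrix R(g, l) counts maximal runs of gray
    level g and length l inside the mask; the ten standard statistics use
    the 1-based gray index g+1 (levels start at 0) and are averaged across
    directions.  An empty mask yields NaN for every statistic.
    """
    n_vox = mask.n_voxels
    if n_vox == 0:
        return {s: float("nan") for s in GLRLM_STATS}
    levels = np.ascontiguousarray(q.levels, dtype=np.int64)
    cmask = np.ascontiguousarray(mask.mask)
    acc: dict[str, list[float]] = {s: [] for s in GLRLM_STATS}
    for d in DIRECTIONS_3D:
        grays, lengths = _runs_kernel(levels, cmask, d[0], d[1], d[2])
        if len(grays) == 0:
            continue
        nr = float(len(grays))
        g = grays.astype(float) + 1.0  # 1-based gray index
        ln = lengths.astype(float)
        gl_counts = np.bincount(grays)  # runs per gray level
        rl_counts = np.bincount(lengths)  # runs per length
        acc["SRE"].append(np.sum(1.0 / ln**2) / nr)
        acc["LRE"].append(np.sum(ln**2) / nr)
        acc["GLN"].append(np.sum(gl_counts.astype(float) ** 2) / nr)
        acc["RLN"].append(np.sum(rl_counts.astype(float) ** 2) / nr)
        acc["RP"].append(nr / n_vox)
        acc["LGRE"].append(np.sum(1.0 / g**2) / nr)
        acc["HGRE"].append(np.sum(g**2) / nr)
        acc["SRLGE"].append(np.sum(1.0 / (g**2 * ln**2)) / nr)
        acc["SRHGE"].append(np.sum(g**2 / ln**2) / nr)
        acc["LRHGE"].append(np.sum(g**2 * ln**2) / nr)
    return {
        s: (float(np.mean(v)) if v else float("nan")) for s, v in acc.items()
    }
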