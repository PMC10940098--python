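"""Gray-level texture matrices and their statistics on masked 3D regions.

Implements the five classical texture families on an integer-quantized
region: co-occurrence (GLCM), run length (GLRLM), size zone (GLSZM),
dependence (GLDM) and neighborhood gray-tone difference (NGTDM).

Conventions (fixed for the reference inventory):

* GLCM: distance 1, the 13 unique 3D directions, symmetric accumulation.
  Each of the 13 Haralick-type statistics is reported three ways — mean over
  directions, range over directions, and on the merged (direction-summed)
  matrix — giving 39 features.
* GLRLM: runs along the same 13 directions, counts merged into one matrix.
* GLSZM: zones are 26-connected components of equal gray level.
* GLDM: neighborhood = 26-neighbors, dependence threshold alpha = 0
  (a neighbor counts iff its level equals the centre level).
* NGTDM: neighborhood = 26-neighbors restricted to the mask.

Degenerate regions (a single voxel has no neighborhood) yield all-zero
texture features and a warning; constant regions are handled without NaNs
(entropy 0, energy 1, correlation 1 by convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import ImageVolume, VoxelMask

__all__ = ["QuantizedRegion", "discretize", "texture_features",
           "glcm_matrix", "glrlm_matrix", "glszm_matrix", "gldm_matrix",
           "ngtdm_table", "OFFSETS_13", "GLCM_STATS", "GLRLM_STATS",
           "GLSZM_STATS", "GLDM_STATS", "NGTDM_STATS", "texture_feature_names"]

# one representative of each +/- pair of the 26 neighbor offsets
OFFSETS_13: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

GLCM_STATS = (
    "autocorrelation", "cluster_prominence", "cluster_shade",
    "cluster_tendency", "contrast", "correlation", "difference_entropy",
    "dissimilarity", "homogeneity", "joint_energy", "joint_entropy",
    "maximum_probability", "sum_average",
)
GLRLM_STATS = (
    "short_run_emphasis", "long_run_emphasis", "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized", "run_length_nonuniformity",
    "run_length_nonuniformity_normalized", "run_percentage",
    "gray_level_variance", "run_variance", "run_entropy",
    "low_gray_level_run_emphasis", "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis", "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis", "long_run_high_gray_level_emphasis",
)
GLSZM_STATS = (
    "small_area_emphasis", "large_area_emphasis", "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized", "size_zone_nonuniformity",
    "size_zone_nonuniformity_normalized", "zone_percentage",
    "gray_level_variance", "zone_variance", "zone_entropy",
    "low_gray_level_zone_emphasis", "high_gray_level_zone_emphasis",
    "small_area_low_gray_level_emphasis", "small_area_high_gray_level_emphasis",
    "large_area_low_gray_level_emphasis", "large_area_high_gray_level_emphasis",
)
GLDM_STATS = (
    "small_dependence_emphasis", "large_dependence_emphasis",
    "gray_level_nonuniformity", "dependence_nonuniformity",
    "dependence_nonuniformity_normalized", "gray_level_variance",
    "dependence_variance", "dependence_entropy", "low_gray_level_emphasis",
    "high_gray_level_emphasis", "small_dependence_low_gray_level_emphasis",
    "small_dependence_high_gray_level_emphasis",
    "large_dependence_low_gray_level_emphasis",
    "large_dependence_high_gray_level_emphasis",
)
NGTDM_STATS = ("coarseness", "contrast", "busyness", "complexity", "strength")


@dataclass
class QuantizedRegion:
    """Integer gray levels 1..n_bins over a masked voxel set (0 outside)."""

    levels: np.ndarray   # int array, 0 outside mask
    mask: np.ndarray     # bool array, same shape
    n_bins: int

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.levels.shape != self.mask.shape:
            raise ValueError("levels/mask shape mismatch")
        inmask = self.levels[self.mask]
        if inmask.size and (inmask.min() < 1 or inmask.max() > self.n_bins):
            raise ValueError("levels outside [1, n_bins]")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def discretize(volume: ImageVolume, mask: VoxelMask, bins: int) -> QuantizedRegion:
    """Equal-width fixed-bin-count discretization over the in-mask range.

    Bins span [min, max] of the masked intensities; a constant region maps
    every voxel to level 1.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if mask.is_empty():
        raise ValueError("empty mask")
    m = mask.values
    vals = volume.values[m]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(volume.shape, dtype=np.int64)
    if hi == lo:
        levels[m] = 1
    else:
        width = (hi - lo) / bins
        lv = np.floor((vals - lo) / width).astype(np.int64) + 1
        np.clip(lv, 1, bins, out=lv)
        levels[m] = lv
    return QuantizedRegion(levels, m, bins)


def _shift(a: np.ndarray, off, fill=0) -> np.ndarray:
    """Return b with b[x] = a[x + off], padding with ``fill``."""
    out = np.full_like(a, fill)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    for ax, o in enumerate(off):
        if o > 0:
            src[ax], dst[ax] = slice(o, None), slice(None, -o)
        elif o < 0:
            src[ax], dst[ax] = slice(None, o), slice(-o, None)
    out[tuple(dst)] = a[tuple(src)]
    return out


# ---------------------------------------------------------------- matrices

def glcm_matrix(q: QuantizedRegion, offset) -> np.ndarray:
    """Symmetric co-occurrence count matrix for one offset (not normalized)."""
    G = q.n_bins
    a, mask = q.levels, q.mask
    b = _shift(a, offset)
    valid = mask & _shift(mask, offset, False)
    P = np.zeros((G, G))
    if valid.any():
        i = a[valid] - 1
        j = b[valid] - 1
        np.add.at(P, (i, j), 1.0)
        np.add.at(P, (j, i), 1.0)
    return P


def glrlm_matrix(q: QuantizedRegion, offsets=OFFSETS_13) -> np.ndarray:
    """Run-length count matrix merged over directions; shape (G, max_run)."""
    G = q.n_bins
    a, mask = q.levels, q.mask
    maxlen = max(a.shape)
    R = np.zeros((G, maxlen))
    for off in offsets:
        same_next = mask & _shift(mask, off, False) & (_shift(a, off) == a)
        rl = np.ones(a.shape, dtype=np.int64)
        for _ in range(maxlen):
            new = np.where(same_next, 1 + _shift(rl, off), 1)
            if np.array_equal(new, rl):
                break
            rl = new
        neg = tuple(-o for o in off)
        start = mask & ~_shift(same_next, neg, False)
        np.add.at(R, (a[start] - 1, rl[start] - 1), 1.0)
    return R


def glszm_matrix(q: QuantizedRegion) -> np.ndarray:
    """Size-zone count matrix; zones are 26-connected equal-level components."""
    G = q.n_bins
    structure = np.ones((3, 3, 3), dtype=bool)
    max_size = q.voxel_count
    S = np.zeros((G, max(max_size, 1)))
    for g in range(1, G + 1):
        lv = q.levels == g
        if not lv.any():
            continue
        lab, n = ndimage.label(lv, structure=structure)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            np.add.at(S, (g - 1, sizes - 1), 1.0)
    return S


def _neighbor_offsets_26():
    offs = list(OFFSETS_13) + [tuple(-o for o in off) for off in OFFSETS_13]
    return offs


def gldm_matrix(q: QuantizedRegion) -> np.ndarray:
    """Dependence count matrix; column k = k equal-level 26-neighbors."""
    G = q.n_bins
    a, mask = q.levels, q.mask
    dep = np.zeros(a.shape, dtype=np.int64)
    for off in _neighbor_offsets_26():
        dep += (mask & _shift(mask, off, False) & (_shift(a, off) == a))
    D = np.zeros((G, 27))
    np.add.at(D, (a[mask] - 1, dep[mask]), 1.0)
    return D


def ngtdm_table(q: QuantizedRegion) -> tuple[np.ndarray, np.ndarray]:
    """Return (n_i, s_i) for levels i = 1..G.

    n_i counts voxels of level i; s_i sums |i - A(x)| where A(x) is the mean
    level of the in-mask 26-neighbors of x (voxels with no in-mask neighbor
    contribute 0).
    """
    G = q.n_bins
    a, mask = q.levels, q.mask
    nb_sum = np.zeros(a.shape, dtype=float)
    nb_cnt = np.zeros(a.shape, dtype=np.int64)
    for off in _neighbor_offsets_26():
        valid = _shift(mask, off, False)
        nb_sum += np.where(valid, _shift(a, off), 0)
        nb_cnt += valid
    n = np.zeros(G)
    s = np.zeros(G)
    has_nb = mask & (nb_cnt > 0)
    diffs = np.zeros(a.shape)
    diffs[has_nb] = np.abs(a[has_nb] - nb_sum[has_nb] / nb_cnt[has_nb])
    np.add.at(n, a[mask] - 1, 1.0)
    np.add.at(s, a[mask] - 1, diffs[mask])
    return n, s


# -------------------------------------------------------------- statistics

def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_statistics(P: np.ndarray) -> dict[str, float]:
    """13 Haralick-type statistics of a (count or probability) GLCM."""
    total = P.sum()
    if total == 0:
        return {k: 0.0 for k in GLCM_STATS}
    p = P / total
    G = p.shape[0]
    lv = np.arange(1, G + 1, dtype=float)
    i = lv[:, None]
    j = lv[None, :]
    px = p.sum(axis=1)
    mu_x = float((lv * px).sum())
    var_x = float(((lv - mu_x) ** 2 * px).sum())
    out: dict[str, float] = {}
    out["autocorrelation"] = float((i * j * p).sum())
    out["cluster_prominence"] = float(((i + j - 2 * mu_x) ** 4 * p).sum())
    out["cluster_shade"] = float(((i + j - 2 * mu_x) ** 3 * p).sum())
    out["cluster_tendency"] = float(((i + j - 2 * mu_x) ** 2 * p).sum())
    out["contrast"] = float(((i - j) ** 2 * p).sum())
    if var_x > 0:
        out["correlation"] = float(((i - mu_x) * (j - mu_x) * p).sum() / var_x)
    else:
        out["correlation"] = 1.0
    # difference distribution p_{|i-j|}
    k = np.abs(i - j).astype(int)
    pdiff = np.zeros(G)
    np.add.at(pdiff, k.ravel(), p.ravel())
    out["difference_entropy"] = _entropy2(pdiff)
    out["dissimilarity"] = float((np.abs(i - j) * p).sum())
    out["homogeneity"] = float((p / (1.0 + (i - j) ** 2)).sum())
    out["joint_energy"] = float((p ** 2).sum())
    out["joint_entropy"] = _entropy2(p.ravel())
    out["maximum_probability"] = float(p.max())
    ksum = (i + j).astype(int)
    psum = np.zeros(2 * G + 1)
    np.add.at(psum, ksum.ravel(), p.ravel())
    out["sum_average"] = float((np.arange(2 * G + 1) * psum).sum())
    return out


def _rl_style_statistics(M: np.ndarray, n_voxels: int, names) -> dict[str, float]:
    """Shared statistic set for run-length / size-zone matrices.

    Row index = gray level i (1-based), column index = run length / zone
    size j (1-based).
    """
    N = M.sum()
    if N == 0:
        return {k: 0.0 for k in names}
    G, L = M.shape
    iv = np.arange(1, G + 1, dtype=float)[:, None]
    jv = np.arange(1, L + 1, dtype=float)[None, :]
    p = M / N
    row = M.sum(axis=1)
    col = M.sum(axis=0)
    mu_i = float((iv * p).sum())
    mu_j = float((jv * p).sum())
    vals = [
        float((M / jv ** 2).sum() / N),                    # short emphasis
        float((M * jv ** 2).sum() / N),                    # long emphasis
        float((row ** 2).sum() / N),                       # GLN
        float((row ** 2).sum() / N ** 2),                  # GLNN
        float((col ** 2).sum() / N),                       # RLN / SZN
        float((col ** 2).sum() / N ** 2),                  # normalized
        float(N / n_voxels),                               # percentage
        float(((iv - mu_i) ** 2 * p).sum()),               # GL variance
        float(((jv - mu_j) ** 2 * p).sum()),               # run/zone variance
        _entropy2(p.ravel()),                              # entropy
        float((M / iv ** 2).sum() / N),                    # LGL emphasis
        float((M * iv ** 2).sum() / N),                    # HGL emphasis
        float((M / (iv ** 2 * jv ** 2)).sum() / N),        # short+low
        float((M * iv ** 2 / jv ** 2).sum() / N),          # short+high
        float((M * jv ** 2 / iv ** 2).sum() / N),          # long+low
        float((M * iv ** 2 * jv ** 2).sum() / N),          # long+high
    ]
    return dict(zip(names, vals))


def gldm_statistics(D: np.ndarray, n_voxels: int) -> dict[str, float]:
    N = D.sum()
    if N == 0:
        return {k: 0.0 for k in GLDM_STATS}
    G, K = D.shape
    iv = np.arange(1, G + 1, dtype=float)[:, None]
    jv = np.arange(1, K + 1, dtype=float)[None, :]   # dependence j = count + 1
    p = D / N
    row = D.sum(axis=1)
    col = D.sum(axis=0)
    mu_i = float((iv * p).sum())
    mu_j = float((jv * p).sum())
    return dict(zip(GLDM_STATS, [
        float((D / jv ** 2).sum() / N),
        float((D * jv ** 2).sum() / N),
        float((row ** 2).sum() / N),
        float((col ** 2).sum() / N),
        float((col ** 2).sum() / N ** 2),
        float(((iv - mu_i) ** 2 * p).sum()),
        float(((jv - mu_j) ** 2 * p).sum()),
        _entropy2(p.ravel()),
        float((D / iv ** 2).sum() / N),
        float((D * iv ** 2).sum() / N),
        float((D / (iv ** 2 * jv ** 2)).sum() / N),
        float((D * iv ** 2 / jv ** 2).sum() / N),
        float((D * jv ** 2 / iv ** 2).sum() / N),
        float((D * iv ** 2 * jv ** 2).sum() / N),
    ]))


def ngtdm_statistics(n: np.ndarray, s: np.ndarray) -> dict[str, float]:
    N = n.sum()
    if N == 0:
        return {k: 0.0 for k in NGTDM_STATS}
    G = len(n)
    iv = np.arange(1, G + 1, dtype=float)
    p = n / N
    present = p > 0
    Ngp = int(present.sum())
    ps = float((p * s).sum())
    out: dict[str, float] = {}
    out["coarseness"] = float(1.0 / ps) if ps > 0 else 1e6
    if Ngp > 1:
        ii = iv[present][:, None]
        jj = iv[present][None, :]
        pi = p[present][:, None]
        pj = p[present][None, :]
        out["contrast"] = float(
            (pi * pj * (ii - jj) ** 2).sum() / (Ngp * (Ngp - 1)) * s.sum() / N)
        denom = float(np.abs(ii * pi - jj * pj).sum())
        out["busyness"] = float(ps / denom) if denom > 0 else 0.0
        si = s[present][:, None]
        sj = s[present][None, :]
        out["complexity"] = float(
            (np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum() / N)
        ssum = float(s.sum())
        out["strength"] = (float(((pi + pj) * (ii - jj) ** 2).sum() / ssum)
                           if ssum > 0 else 0.0)
    else:
        out["contrast"] = 0.0
        out["busyness"] = 0.0
        out["complexity"] = 0.0
        out["strength"] = 0.0
    return out


# ------------------------------------------------------------ full family

def texture_feature_names() -> list[str]:
    """Deterministic order of the 90 texture feature names."""
    names = []
    for stat in GLCM_STATS:
        for agg in ("mean", "range", "merged"):
            names.append(f"glcm_{stat}_{agg}")
    names += [f"glrlm_{s}" for s in GLRLM_STATS]
    names += [f"glszm_{s}" for s in GLSZM_STATS]
    names += [f"gldm_{s}" for s in GLDM_STATS]
    names += [f"ngtdm_{s}" for s in NGTDM_STATS]
    return names


def texture_features(q: QuantizedRegion) -> dict[str, float]:
    """The 90 texture statistics of a quantized region.

    Single-voxel regions have no neighborhood: every feature is returned as
    0.0 and a degenerate-region warning is emitted.
    """
    if q.voxel_count == 0:
        raise ValueError("empty quantized region")
    if q.voxel_count == 1:
        warnings.warn("degenerate single-voxel region: texture features set to 0",
                      stacklevel=2)
        return {name: 0.0 for name in texture_feature_names()}

    out: dict[str, float] = {}
    per_dir = [glcm_statistics(glcm_matrix(q, off)) for off in OFFSETS_13]
    merged = np.sum([glcm_matrix(q, off) for off in OFFSETS_13], axis=0)
    merged_stats = glcm_statistics(merged)
    for stat in GLCM_STATS:
        vals = np.array([d[stat] for d in per_dir])
        out[f"glcm_{stat}_mean"] = float(vals.mean())
        out[f"glcm_{stat}_range"] = float(vals.max() - vals.min())
        out[f"glcm_{stat}_merged"] = merged_stats[stat]

    nvox = q.voxel_count
    rl = _rl_style_statistics(glrlm_matrix(q), nvox, GLRLM_STATS)
    out.update({f"glrlm_{k}": v for k, v in rl.items()})
    sz = _rl_style_statistics(glszm_matrix(q), nvox, GLSZM_STATS)
    out.update({f"glszm_{k}": v for k, v in sz.items()})
    out.update({f"gldm_{k}": v
                for k, v in gldm_statistics(gldm_matrix(q), nvox).items()})
    n, s = ngtdm_table(q)
    out.update({f"ngtdm_{k}": v for k, v in ngtdm_statistics(n, s).items()})
    return out
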