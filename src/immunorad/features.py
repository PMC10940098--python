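"""The radiomics feature inventory: 8 shape + 14 first-order + 270 texture
statistics per region, 292 per region and 584 per patient for the reference
configuration (texture computed at bin counts 16, 32 and 64).

Feature names encode region, family, statistic and quantization level, e.g.
``intra_glcm32_contrast_mean`` or ``peri_shape_sphericity``, and the order
of the vector is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import kurtosis, skew
from skimage.measure import marching_cubes, mesh_surface_area

from .geometry import validate_region_pair
from .grids import ImageVolume, RegionPair, VoxelMask
from .texture import discretize, texture_feature_names, texture_features

__all__ = ["shape_features", "first_order_features", "extract_feature_vector",
           "FeatureConfig", "feature_names", "SHAPE_NAMES", "FIRSTORDER_NAMES"]

SHAPE_NAMES = (
    "volume", "surface_area", "surface_to_volume_ratio", "sphericity",
    "maximum_3d_diameter", "major_axis_length", "elongation", "flatness",
)
FIRSTORDER_NAMES = (
    "mean", "median", "minimum", "maximum", "range", "interquartile_range",
    "variance", "skewness", "kurtosis", "energy", "entropy", "uniformity",
    "robust_mean_absolute_deviation", "root_mean_squared",
)


@dataclass
class FeatureConfig:
    """Extraction configuration.

    The reference settings reproduce the printed inventory: texture at bin
    counts (16, 32, 64) gives 8 + 14 + 3 x 90 = 292 features per region and
    584 for the intratumoral/peritumoral pair.
    """

    texture_bins: tuple[int, ...] = (16, 32, 64)
    firstorder_bins: int = 32
    region_prefixes: tuple[str, str] = ("intra", "peri")

    def features_per_region(self) -> int:
        return (len(SHAPE_NAMES) + len(FIRSTORDER_NAMES)
                + 90 * len(self.texture_bins))


def shape_features(mask: VoxelMask) -> dict[str, float]:
    """Eight 3D shape descriptors of a binary mask, in mm-consistent units.

    Principal extents come from the eigenvalues of the voxel-centre
    covariance; elongation = sqrt(l2/l1) and flatness = sqrt(l3/l1) with
    l1 >= l2 >= l3.
    """
    if mask.is_empty():
        raise ValueError("empty mask")
    n = mask.voxel_count
    volume = n * mask.voxel_volume
    coords = mask.coordinates_mm()

    # surface area from a marching-cubes mesh of the padded mask; a light
    # Gaussian (0.8 voxel) removes the staircase overestimate so digital
    # spheres mesh close to their analytic area
    padded = np.pad(mask.values.astype(float), 1)
    if n == 1:
        area = _box_surface_area(mask)
    else:
        smoothed = gaussian_filter(padded, sigma=0.8)
        level_set = smoothed if smoothed.max() > 0.5 else padded
        try:
            verts, faces, _, _ = marching_cubes(level_set, level=0.5,
                                                spacing=mask.spacing)
            area = float(mesh_surface_area(verts, faces))
        except (ValueError, RuntimeError):
            area = _box_surface_area(mask)

    sphericity = float(np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / area)

    diam = _max_diameter(coords, mask.spacing)

    if n > 1:
        cov = np.cov(coords.T)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
        major = 4.0 * np.sqrt(eig[0])
        elong = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0
        flat = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0
    else:
        major, elong, flat = 0.0, 0.0, 0.0

    return dict(zip(SHAPE_NAMES, (
        float(volume), float(area), float(area / volume), sphericity,
        float(diam), float(major), elong, flat,
    )))


def _box_surface_area(mask: VoxelMask) -> float:
    """Exposed-face surface area; fallback for meshes the mesher rejects."""
    m = mask.values
    sz, sy, sx = mask.spacing
    face = {0: sy * sx, 1: sz * sx, 2: sz * sy}
    area = 0.0
    for ax in range(3):
        pad = np.pad(m, [(1, 1) if a == ax else (0, 0) for a in range(3)])
        diff = np.abs(np.diff(pad.astype(np.int8), axis=ax))
        area += diff.sum() * face[ax]
    return float(area)


def _max_diameter(coords: np.ndarray, spacing) -> float:
    """Maximum pairwise distance between voxel centres, plus one voxel
    diagonal so a single voxel has the diameter of its own cell."""
    if len(coords) == 1:
        return float(np.linalg.norm(spacing))
    pts = coords
    if len(pts) > 400:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def first_order_features(volume: ImageVolume, mask: VoxelMask,
                         bins: int = 32) -> dict[str, float]:
    """Fourteen histogram/intensity statistics of the in-mask voxels.

    Entropy and uniformity use a fixed ``bins``-level min-max
    discretization.  Constant regions use the zero-variance conventions:
    skewness = kurtosis = 0, entropy = 0, uniformity = 1.
    """
    if mask.is_empty():
        raise ValueError("empty mask")
    x = volume.values[mask.values].astype(float)
    q25, q75 = np.percentile(x, [25, 75])
    var = float(np.var(x))
    if var > 0:
        sk = float(skew(x))
        ku = float(kurtosis(x, fisher=False))
    else:
        sk, ku = 0.0, 0.0

    if x.max() > x.min():
        hist, _ = np.histogram(x, bins=bins, range=(x.min(), x.max()))
        p = hist / hist.sum()
        p = p[p > 0]
        entropy = float(-(p * np.log2(p)).sum())
        uniformity = float((p ** 2).sum())
    else:
        entropy, uniformity = 0.0, 1.0

    p10, p90 = np.percentile(x, [10, 90])
    mid = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(mid - mid.mean()).mean()) if mid.size else 0.0

    return dict(zip(FIRSTORDER_NAMES, (
        float(x.mean()), float(np.median(x)), float(x.min()), float(x.max()),
        float(x.max() - x.min()), float(q75 - q25), var, sk, ku,
        float((x ** 2).sum()), entropy, uniformity, rmad,
        float(np.sqrt((x ** 2).mean())),
    )))


def feature_names(config: FeatureConfig | None = None) -> list[str]:
    """Deterministic full inventory order (584 names for the reference)."""
    config = config or FeatureConfig()
    names: list[str] = []
    tex = texture_feature_names()
    for region in config.region_prefixes:
        names += [f"{region}_shape_{s}" for s in SHAPE_NAMES]
        names += [f"{region}_firstorder_{s}" for s in FIRSTORDER_NAMES]
        for b in config.texture_bins:
            names += [f"{region}_{t.replace('_', str(b) + '_', 1)}" for t in tex]
    return names


def extract_feature_vector(volume: ImageVolume, pair: RegionPair,
                           config: FeatureConfig | None = None) -> dict[str, float]:
    """Extract the full inventory for one patient (both regions).

    Returns an ordered mapping with exactly
    ``2 * config.features_per_region()`` entries (584 for the reference
    configuration).
    """
    config = config or FeatureConfig()
    report = validate_region_pair(pair, volume)
    if not report.passed:
        raise ValueError(f"invalid region pair: {report.messages}")

    out: dict[str, float] = {}
    regions = dict(zip(config.region_prefixes,
                       (pair.intratumoral, pair.peritumoral)))
    for prefix, mask in regions.items():
        if mask.is_empty():
            raise ValueError(f"empty {prefix} region")
        sh = shape_features(mask)
        out.update({f"{prefix}_shape_{k}": v for k, v in sh.items()})
        fo = first_order_features(volume, mask, bins=config.firstorder_bins)
        out.update({f"{prefix}_firstorder_{k}": v for k, v in fo.items()})
        for b in config.texture_bins:
            q = discretize(volume, mask, b)
            tx = texture_features(q)
            out.update({f"{prefix}_{k.replace('_', str(b) + '_', 1)}": v
                        for k, v in tx.items()})
    return out
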