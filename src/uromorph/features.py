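"""Per-nucleus morphometry: the canonical 40-feature catalog.

Features fall in the four families a pathologist's grading intuition draws
on: geometry (size and shape), color intensity (hyperchromasia), texture
(chromatin granularity) and neighborhood (crowding and the distance to the
closest nuclei).  All geometric quantities are reported in physical units
(µm / µm²) via the image's microns-per-pixel calibration; intensity uses
the luminance convention where lower values mean darker staining.

Features that are undefined for a nucleus (texture on a < 4-pixel speck,
nearest-neighbor statistics in a near-empty field) are reported as NaN,
the catalog's undefined sentinel; aggregation skips sentinels rather than
imputing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.measure import regionprops

from .segmentation import CalibratedImage, hematoxylin_density

__all__ = [
    "FEATURE_CATALOG",
    "FEATURE_NAMES",
    "extract_features",
    "neighborhood_features",
]

logger = logging.getLogger(__name__)

#: (name, family) for the fixed 40-column feature schema, in column order.
FEATURE_CATALOG: tuple[tuple[str, str], ...] = (
    # geometry (14)
    ("area_um2", "geometry"),
    ("perimeter_um", "geometry"),
    ("equivalent_diameter_um", "geometry"),
    ("major_axis_um", "geometry"),
    ("minor_axis_um", "geometry"),
    ("aspect_ratio", "geometry"),
    ("eccentricity", "geometry"),
    ("circularity", "geometry"),
    ("solidity", "geometry"),
    ("extent", "geometry"),
    ("convex_area_um2", "geometry"),
    ("bbox_area_um2", "geometry"),
    ("orientation_rad", "geometry"),
    ("radial_sd_um", "geometry"),
    # color intensity (12)
    ("mean_R", "color"),
    ("mean_G", "color"),
    ("mean_B", "color"),
    ("sd_R", "color"),
    ("sd_G", "color"),
    ("sd_B", "color"),
    ("mean_intensity", "color"),
    ("sd_intensity", "color"),
    ("min_intensity", "color"),
    ("max_intensity", "color"),
    ("mean_hematoxylin_od", "color"),
    ("integrated_od", "color"),
    # texture (8)
    ("granulometry_residual_1", "texture"),
    ("granulometry_residual_2", "texture"),
    ("granulometry_residual_3", "texture"),
    ("glcm_contrast", "texture"),
    ("glcm_homogeneity", "texture"),
    ("glcm_energy", "texture"),
    ("glcm_entropy", "texture"),
    ("intensity_entropy", "texture"),
    # neighborhood (6)
    ("nn1_distance_um", "neighborhood"),
    ("nn3_mean_distance_um", "neighborhood"),
    ("nn5_mean_distance_um", "neighborhood"),
    ("count_within_50um", "neighborhood"),
    ("crowding_fraction_within_50um", "neighborhood"),
    ("nn1_boundary_gap_um", "neighborhood"),
)

FEATURE_NAMES: tuple[str, ...] = tuple(name for name, _ in FEATURE_CATALOG)
assert len(FEATURE_NAMES) == 40 and len(set(FEATURE_NAMES)) == 40

#: granulometry structuring-element radii, µm
GRANULOMETRY_SCALES_UM = (0.5, 1.0, 2.0)
GLCM_LEVELS = 32
NEIGHBORHOOD_RADIUS_UM = 50.0

_GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def _luminance(rgb: np.ndarray) -> np.ndarray:
    return (
        0.299 * rgb[..., 0].astype(float)
        + 0.587 * rgb[..., 1].astype(float)
        + 0.114 * rgb[..., 2].astype(float)
    )


def _disk(radius: int) -> np.ndarray:
    r = max(int(radius), 1)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= r * r


def _boundary_radial_sd(m: np.ndarray, cy: float, cx: float) -> float:
    interior = ndimage.binary_erosion(m)
    bd = m & ~interior
    if not bd.any():
        bd = m
    ys, xs = np.nonzero(bd)
    d = np.hypot(ys - cy, xs - cx)
    return float(d.std())


def _glcm_stats(levels: np.ndarray, m: np.ndarray) -> tuple[float, float, float, float]:
    """Contrast / homogeneity / energy / entropy of the masked, symmetric,
    direction-averaged co-occurrence matrix (distance 1, 4 directions)."""
    P = np.zeros((GLCM_LEVELS, GLCM_LEVELS), dtype=float)
    h, w = m.shape
    total = 0
    for dy, dx in _GLCM_OFFSETS:
        a_sl = (slice(max(0, -dy), h - max(0, dy)), slice(max(0, -dx), w - max(0, dx)))
        b_sl = (slice(max(0, dy), h + min(0, dy) or h), slice(max(0, dx), w + min(0, dx) or w))
        a_m = m[a_sl]
        b_m = m[b_sl]
        valid = a_m & b_m
        if not valid.any():
            continue
        a = levels[a_sl][valid]
        b = levels[b_sl][valid]
        np.add.at(P, (a, b), 1.0)
        np.add.at(P, (b, a), 1.0)
        total += 2 * a.size
    if total == 0:
        return (np.nan,) * 4
    P /= total
    i, j = np.indices(P.shape)
    contrast = float(np.sum(P * (i - j) ** 2))
    homogeneity = float(np.sum(P / (1.0 + np.abs(i - j))))
    energy = float(np.sum(P * P))
    nz = P[P > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    return contrast, homogeneity, energy, entropy


def _texture_features(patch_lum: np.ndarray, m: np.ndarray, mpp: float) -> dict:
    out: dict[str, float] = {}
    inv = 255.0 - patch_lum  # chromatin-dark is high signal
    for k, scale_um in enumerate(GRANULOMETRY_SCALES_UM, start=1):
        r = max(int(round(scale_um / mpp)), 1)
        opened = ndimage.grey_opening(inv, footprint=_disk(r))
        out[f"granulometry_residual_{k}"] = float(np.mean((inv - opened)[m]))
    levels = np.clip((patch_lum / (256.0 / GLCM_LEVELS)).astype(int), 0, GLCM_LEVELS - 1)
    contrast, homogeneity, energy, entropy = _glcm_stats(levels, m)
    out["glcm_contrast"] = contrast
    out["glcm_homogeneity"] = homogeneity
    out["glcm_energy"] = energy
    out["glcm_entropy"] = entropy
    vals = patch_lum[m]
    hist, _ = np.histogram(vals, bins=GLCM_LEVELS, range=(0, 256))
    p = hist[hist > 0] / vals.size
    out["intensity_entropy"] = float(-np.sum(p * np.log2(p)))
    return out


def neighborhood_features(
    centroids_um: np.ndarray, equivalent_radii_um: np.ndarray | None = None
) -> pd.DataFrame:
    """Neighborhood statistics from nucleus centroids (µm coordinates).

    For fields with fewer than ``k + 1`` nuclei the ``nn-k`` features are
    NaN.  ``nn1_boundary_gap_um`` is the center distance to the nearest
    neighbor minus both equivalent radii (negative when equal-area circles
    would overlap); it requires ``equivalent_radii_um``.
    """
    pts = np.asarray(centroids_um, dtype=float).reshape(-1, 2)
    n = len(pts)
    cols = [name for name, fam in FEATURE_CATALOG if fam == "neighborhood"]
    if n == 0:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(np.nan, index=np.arange(n), columns=cols)
    if n >= 2:
        tree = cKDTree(pts)
        k = min(6, n)
        dists, idx = tree.query(pts, k=k)
        out["nn1_distance_um"] = dists[:, 1]
        if n >= 4:
            out["nn3_mean_distance_um"] = dists[:, 1:4].mean(axis=1)
        if n >= 6:
            out["nn5_mean_distance_um"] = dists[:, 1:6].mean(axis=1)
        counts = np.array(
            [len(c) - 1 for c in tree.query_ball_point(pts, NEIGHBORHOOD_RADIUS_UM)]
        )
        out["count_within_50um"] = counts.astype(float)
        out["crowding_fraction_within_50um"] = counts / (n - 1)
        if equivalent_radii_um is not None:
            r = np.asarray(equivalent_radii_um, dtype=float)
            out["nn1_boundary_gap_um"] = dists[:, 1] - r - r[idx[:, 1]]
    return out


def extract_features(
    image: CalibratedImage,
    mask: np.ndarray,
    image_id: str = "image",
    class_truth: pd.Series | None = None,
) -> pd.DataFrame:
    """One record per label with all 40 catalog features.

    ``class_truth`` optionally maps labels to ground-truth classes (tumor /
    inflammatory) for generator-produced fields.  Nuclei smaller than 4
    pixels get NaN texture features (and a log line); every other feature
    is always computed.
    """
    mask = np.asarray(mask)
    if mask.shape != image.rgb.shape[:2]:
        raise ValueError("mask and image shapes disagree")
    mpp = image.microns_per_pixel
    px_area = mpp * mpp

    lum = _luminance(image.rgb)
    density = hematoxylin_density(image)
    rgb = image.rgb.astype(float)

    rows = []
    props = regionprops(mask)
    for rp in props:
        lab = int(rp.label)
        sl = rp.slice
        m = rp.image
        area_px = float(rp.area)
        cy, cx = rp.centroid

        row: dict[str, float] = {"label": lab}
        row["centroid_x_um"] = cx * mpp
        row["centroid_y_um"] = cy * mpp

        perimeter_px = float(rp.perimeter)
        row["area_um2"] = area_px * px_area
        row["perimeter_um"] = perimeter_px * mpp
        row["equivalent_diameter_um"] = 2.0 * np.sqrt(area_px / np.pi) * mpp
        row["major_axis_um"] = float(rp.axis_major_length) * mpp
        row["minor_axis_um"] = float(rp.axis_minor_length) * mpp
        row["aspect_ratio"] = (
            float(rp.axis_major_length) / float(rp.axis_minor_length)
            if rp.axis_minor_length > 0
            else np.nan
        )
        row["eccentricity"] = float(rp.eccentricity)
        row["circularity"] = (
            4.0 * np.pi * area_px / (perimeter_px**2) if perimeter_px > 0 else np.nan
        )
        row["solidity"] = float(rp.solidity)
        row["extent"] = float(rp.extent)
        row["convex_area_um2"] = float(rp.area_convex) * px_area
        row["bbox_area_um2"] = float(rp.area_bbox) * px_area
        row["orientation_rad"] = float(rp.orientation)
        row["radial_sd_um"] = (
            _boundary_radial_sd(m, cy - sl[0].start, cx - sl[1].start) * mpp
        )

        lum_patch = lum[sl]
        vals_lum = lum_patch[m]
        for c, name in enumerate("RGB"):
            vals = rgb[sl][..., c][m]
            row[f"mean_{name}"] = float(vals.mean())
            row[f"sd_{name}"] = float(vals.std())
        row["mean_intensity"] = float(vals_lum.mean())
        row["sd_intensity"] = float(vals_lum.std())
        row["min_intensity"] = float(vals_lum.min())
        row["max_intensity"] = float(vals_lum.max())
        dens_vals = density[sl][m]
        row["mean_hematoxylin_od"] = float(dens_vals.mean())
        row["integrated_od"] = float(dens_vals.sum()) * px_area

        if area_px < 4:
            logger.warning(
                "%s: label %d has %d px; texture features set to NaN",
                image_id, lab, int(area_px),
            )
            for name, fam in FEATURE_CATALOG:
                if fam == "texture":
                    row[name] = np.nan
        else:
            row.update(_texture_features(lum_patch, m, mpp))
        rows.append(row)

    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(
            columns=["label", "centroid_x_um", "centroid_y_um", *FEATURE_NAMES]
        )
    nb = neighborhood_features(
        df[["centroid_x_um", "centroid_y_um"]].to_numpy() if len(df) else np.empty((0, 2)),
        equivalent_radii_um=(df["equivalent_diameter_um"] / 2.0).to_numpy()
        if len(df)
        else None,
    )
    for col in nb.columns:
        df[col] = nb[col].to_numpy() if len(df) else pd.Series(dtype=float)

    df.insert(0, "image_id", image_id)
    if class_truth is not None and len(df):
        df["class_truth"] = df["label"].map(class_truth)
    ordered = ["image_id", "label", "centroid_x_um", "centroid_y_um", *FEATURE_NAMES]
    if "class_truth" in df.columns:
        ordered.append("class_truth")
    return df[ordered]
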