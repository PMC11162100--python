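"""Nucleus segmentation for H&E-like RGB fields.

Classical, weight-free pipeline: Beer–Lambert hematoxylin density →
Gaussian smoothing → automatic (Otsu) threshold → hole filling →
distance-transform watershed with a ridge-merge guard → physical-unit
area/border filtering.  Deterministic for a fixed input.

The ridge-merge guard exists because the distance transform of an elongated
ellipse has a ridge of near-equal maxima along its major axis; naive
peak-marker watershed would shatter single elongated or very large nuclei.
Two candidate markers are merged when the distance transform along the
straight line between them never drops much below the shallower peak —
true for points on one ridge, false across the neck of a touching pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import relabel_sequential, watershed

from .synthetic import HEMATOXYLIN_OD_VECTOR

__all__ = [
    "CalibratedImage",
    "SegmentationParams",
    "hematoxylin_density",
    "segment",
    "filter_labels",
]


@dataclass(frozen=True)
class CalibratedImage:
    """An 8-bit RGB field with its physical pixel size."""

    rgb: np.ndarray
    microns_per_pixel: float

    def __post_init__(self):
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be an (H, W, 3) array")


@dataclass(frozen=True)
class SegmentationParams:
    """Physical-unit parameters of the segmentation pipeline.

    ``min_area_um2`` defaults to 10 µm², small enough to retain
    inflammatory (lymphocyte/neutrophil) nuclei — the grade signal this
    pipeline exists to measure lives in small nuclei.  ``min_contrast`` is
    the minimum optical-density spread below which an image is treated as
    featureless (degenerate images yield an empty mask, not an exception).
    """

    smoothing_um: float = 0.5
    min_area_um2: float = 10.0
    max_area_um2: float = 20000.0
    border_policy: str = "keep"  # "keep" | "drop"
    split_min_distance_um: float = 6.0
    ridge_merge_ratio: float = 0.6
    min_contrast: float = 0.15
    refine_boundaries: bool = True
    refine_level: float = 0.5

    def __post_init__(self):
        if self.min_area_um2 >= self.max_area_um2:
            raise ValueError("min_area_um2 must be below max_area_um2")
        if min(self.smoothing_um, self.min_area_um2, self.split_min_distance_um) <= 0:
            raise ValueError("physical parameters must be positive")
        if self.border_policy not in ("keep", "drop"):
            raise ValueError("border_policy must be 'keep' or 'drop'")
        if not 0.0 < self.ridge_merge_ratio < 1.0:
            raise ValueError("ridge_merge_ratio must lie in (0, 1)")


def hematoxylin_density(image: CalibratedImage) -> np.ndarray:
    """Per-pixel hematoxylin optical density (Beer–Lambert projection).

    Each channel's OD is ``-log10(I / 255)``; the OD vector is projected
    onto the fixed reference hematoxylin stain direction.  A pure white
    pixel has zero density; dimming any channel strictly raises it.
    """
    # od_c = -log10(I_c / 255) = (ln 255 - ln I_c) / ln 10, projected on the
    # stain vector; accumulated channel-wise in float32 for speed
    rgb = np.maximum(image.rgb.astype(np.float32), np.float32(1.0))
    acc = np.zeros(rgb.shape[:2], dtype=np.float32)
    for c in range(3):
        acc += np.float32(HEMATOXYLIN_OD_VECTOR[c]) * np.log(rgb[..., c])
    const = np.float32(np.log(255.0) * HEMATOXYLIN_OD_VECTOR.sum())
    return (const - acc) / np.float32(np.log(10.0))


def _ridge_connected(dist: np.ndarray, p: np.ndarray, q: np.ndarray, ratio: float) -> bool:
    """True when the distance transform along segment p→q stays high."""
    length = int(np.ceil(np.hypot(*(p.astype(float) - q)))) + 1
    rr = np.linspace(p[0], q[0], length).round().astype(int)
    cc = np.linspace(p[1], q[1], length).round().astype(int)
    saddle = dist[rr, cc].min()
    return saddle >= ratio * min(dist[tuple(p)], dist[tuple(q)])


def _split_markers(
    binary: np.ndarray, dist: np.ndarray, min_distance_px: int, ratio: float
) -> np.ndarray:
    """Watershed markers: distance-transform peaks, ridge-merged per component."""
    comps, n_comp = ndimage.label(binary)
    markers = np.zeros_like(comps)
    if n_comp == 0:
        return markers
    coords = peak_local_max(
        dist, min_distance=max(min_distance_px, 1), labels=comps, exclude_border=False
    )
    peaks_by_comp: dict[int, list[np.ndarray]] = {}
    for rc in coords:
        peaks_by_comp.setdefault(int(comps[tuple(rc)]), []).append(rc)

    # components whose peak was suppressed entirely still need one marker
    present = set(peaks_by_comp)
    missing = [c for c in range(1, n_comp + 1) if c not in present]
    if missing:
        maxima = ndimage.maximum_position(dist, labels=comps, index=missing)
        for c, pos in zip(missing, maxima):
            peaks_by_comp[c] = [np.asarray(pos)]

    next_label = 1
    for c, peaks in sorted(peaks_by_comp.items()):
        k = len(peaks)
        parent = list(range(k))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(k):
            for j in range(i + 1, k):
                if find(i) != find(j) and _ridge_connected(
                    dist, peaks[i], peaks[j], ratio
                ):
                    parent[find(i)] = find(j)
        groups: dict[int, int] = {}
        for i, rc in enumerate(peaks):
            root = find(i)
            if root not in groups:
                groups[root] = next_label
                next_label += 1
            markers[tuple(rc)] = groups[root]
    return markers


def segment(image: CalibratedImage, params: SegmentationParams | None = None) -> np.ndarray:
    """Segment all nuclei into a labeled mask (0 = background).

    Pipeline: hematoxylin density → Gaussian smoothing → Otsu threshold →
    hole filling → distance-transform watershed split → area/border filter.
    A degenerate (near-uniform) image yields an empty mask.
    """
    if params is None:
        params = SegmentationParams()
    mpp = image.microns_per_pixel

    density = hematoxylin_density(image)
    sigma = params.smoothing_um / mpp
    smooth = ndimage.gaussian_filter(density, sigma)

    lo, hi = np.percentile(smooth, [1, 99])
    if hi - lo < params.min_contrast:
        return np.zeros(smooth.shape, dtype=np.int32)
    thresh = threshold_otsu(smooth)
    binary = smooth > thresh
    binary = ndimage.binary_fill_holes(binary)

    # drop sub-threshold specks early so the distance transform is cheap
    min_px = int(np.floor(params.min_area_um2 / (mpp * mpp)))
    comps, _ = ndimage.label(binary)
    sizes = np.bincount(comps.ravel())
    too_small = sizes < max(min_px, 1)
    too_small[0] = False
    binary[too_small[comps]] = False

    dist = ndimage.distance_transform_edt(binary)
    dist_s = ndimage.gaussian_filter(dist, 1.0)
    dist_s[~binary] = 0.0
    markers = _split_markers(
        binary, dist_s, int(round(params.split_min_distance_um / mpp)),
        params.ridge_merge_ratio,
    )
    if markers.max() == 0:
        return np.zeros(smooth.shape, dtype=np.int32)
    labels = watershed(-dist_s, markers=markers, mask=binary)
    if params.refine_boundaries:
        labels = _refine_boundaries(labels, smooth, binary, params.refine_level)
    return filter_labels(labels.astype(np.int32), params, microns_per_pixel=mpp)


def _refine_boundaries(
    labels: np.ndarray, smooth: np.ndarray, binary: np.ndarray, level: float
) -> np.ndarray:
    """Re-cut each nucleus at its own half-height density level.

    A single global (Otsu) threshold sits at one density for all nuclei, so
    darker nuclei are captured wider than paler ones.  For an edge blurred
    by a symmetric kernel the unbiased boundary is the mid level between
    local background and the nucleus plateau; each label is therefore
    shrunk to pixels above ``bg + level * (plateau - bg)``.
    """
    bg = float(np.median(smooth[~binary])) if (~binary).any() else 0.0
    out = labels.copy()
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        sub = smooth[sl]
        m = labels[sl] == lab
        plateau = float(np.median(sub[m]))
        if plateau <= bg:
            continue
        refined = m & (sub >= bg + level * (plateau - bg))
        refined = ndimage.binary_fill_holes(refined)
        region = out[sl]
        region[m & ~refined] = 0
    return out


def filter_labels(
    mask: np.ndarray,
    params: SegmentationParams | None = None,
    *,
    microns_per_pixel: float,
) -> np.ndarray:
    """Remove out-of-bounds-area components (and border-touchers under
    ``drop``) and relabel consecutively from 1.  Idempotent."""
    if params is None:
        params = SegmentationParams()
    mask = np.asarray(mask)
    if mask.max() == 0:
        return np.zeros_like(mask, dtype=np.int32)
    px_area = microns_per_pixel * microns_per_pixel
    sizes = np.bincount(mask.ravel())
    areas_um2 = sizes * px_area
    keep = (areas_um2 >= params.min_area_um2) & (areas_um2 <= params.max_area_um2)
    keep[0] = False
    if params.border_policy == "drop":
        edge = np.concatenate([mask[0, :], mask[-1, :], mask[:, 0], mask[:, -1]])
        for lab in np.unique(edge):
            if lab != 0:
                keep[lab] = False
    filtered = np.where(keep[mask], mask, 0)
    out, _, _ = relabel_sequential(filtered)
    return out.astype(np.int32)
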