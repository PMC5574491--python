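"""Plane-wise cyst segmentation with vertical linking across the z-stack.

Cysts are detected independently on every focal plane (smooth -> threshold ->
fill the dim lumen -> size-filter), then objects on adjacent planes are linked
by mask overlap.  Each linked group becomes one cyst whose defining plane is
the plane of maximal area (best focus, the sphere's equator); cysts that
overlap in x,y but live on non-adjacent planes stay distinct — the situation
a single whole-stack projection would collapse into one object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_multiotsu, threshold_otsu
from skimage.feature import peak_local_max
from skimage.measure import label as sk_label, perimeter as sk_perimeter
from skimage.morphology import disk

from .stacks import ImageStack, max_projection

__all__ = [
    "SegmentationParams", "NucleiParams", "CystObject",
    "segment_plane", "detect_cysts", "measure_wall", "count_nuclei",
    "max_projection", "ImageStack",
]


@dataclass
class SegmentationParams:
    """Tunables of the plane segmentation and vertical linking.

    The default threshold is the upper split of a three-class Otsu
    (background / lumen / wall), which places the foreground boundary at the
    wall edge rather than at the dim lumen level; ``threshold_method="otsu"``
    selects the classical two-class split.  Histogram thresholds are
    meaningless on a plane that holds no object — they split the noise — so
    the effective threshold is floored at the plane median plus
    ``noise_floor_sigmas`` robust standard deviations (1.4826 * MAD of the
    smoothed plane) and at the absolute ``threshold_floor``.  Both floors
    are inert on planes with real foreground and on noise-free images.
    ``link_overlap_fraction`` is the minimum overlap, as a fraction of the
    smaller mask, for two objects on adjacent planes to be the same cyst.
    """

    smoothing_sigma: float = 0.8
    threshold_method: str = "multiotsu"
    threshold_floor: float = 0.0
    noise_floor_sigmas: float = 6.0
    min_area_px: int = 30
    max_area_px: int | None = None
    link_overlap_fraction: float = 0.5
    exclude_border: bool = True
    wall_margin_px: int = 1
    wall_contrast_fraction: float = 0.5


@dataclass
class NucleiParams:
    smoothing_sigma: float = 1.5
    threshold_floor: float = 0.0
    noise_floor_sigmas: float = 6.0
    min_distance_px: int = 3
    min_spot_area_px: int = 4


@dataclass
class CystObject:
    """One segmented cyst, defined on its best-focus plane."""

    object_id: int
    plane_index: int
    pixels: tuple[np.ndarray, np.ndarray]  # (rows, cols) of the filled mask
    image_shape: tuple[int, int]
    area_px: int
    perimeter_px: float
    centroid: tuple[float, float]
    wall_pixels: tuple[np.ndarray, np.ndarray]
    wall_area_px: int
    wall_mean_thickness_px: float
    touches_border: bool = False
    degenerate: bool = False
    n_planes_spanned: int = 1

    def mask_array(self) -> np.ndarray:
        m = np.zeros(self.image_shape, dtype=bool)
        m[self.pixels] = True
        return m

    def wall_mask_array(self) -> np.ndarray:
        m = np.zeros(self.image_shape, dtype=bool)
        m[self.wall_pixels] = True
        return m


def _noise_floor(smoothed: np.ndarray, n_sigmas: float) -> float:
    """Background level + ``n_sigmas`` robust SDs of the smoothed image."""
    med = float(np.median(smoothed))
    mad_sd = 1.4826 * float(np.median(np.abs(smoothed - med)))
    return med + n_sigmas * mad_sd


def _label_plane(plane: np.ndarray, params: SegmentationParams):
    """Smooth, threshold, fill holes and size-filter one plane.

    Returns ``(labels, areas, border_labels)``; ``labels`` is 0-background.
    A constant plane yields an empty labelling rather than an error.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.size == 0:
        raise ValueError("empty plane")
    if np.ptp(plane) == 0:
        return np.zeros(plane.shape, dtype=np.int32), np.zeros(1, dtype=np.int64), set()
    sm = gaussian(plane, sigma=params.smoothing_sigma, preserve_range=True) \
        if params.smoothing_sigma > 0 else plane
    if params.threshold_method == "multiotsu":
        try:
            thr = float(threshold_multiotsu(sm, classes=3)[-1])
        except ValueError:  # too few distinct grey levels for 3 classes
            thr = float(threshold_otsu(sm))
    elif params.threshold_method == "otsu":
        thr = float(threshold_otsu(sm))
    else:
        raise ValueError(f"unknown threshold method {params.threshold_method!r}")
    thr = max(thr, params.threshold_floor, _noise_floor(sm, params.noise_floor_sigmas))
    fg = sm > thr
    fg = ndi.binary_fill_holes(fg)
    labels = sk_label(fg, connectivity=2)
    areas = np.bincount(labels.ravel())
    keep = areas >= params.min_area_px
    if params.max_area_px is not None:
        keep &= areas <= params.max_area_px
    keep[0] = False
    relabel = np.zeros_like(areas, dtype=np.int32)
    relabel[keep] = np.arange(1, int(keep.sum()) + 1)
    labels = relabel[labels]
    areas = np.bincount(labels.ravel())
    border = set(np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])))
    border.discard(0)
    return labels, areas, border


def segment_plane(plane: np.ndarray, params: SegmentationParams | None = None
                  ) -> list[np.ndarray]:
    """Segment one plane into disjoint filled object masks (boolean arrays)."""
    params = params or SegmentationParams()
    labels, areas, _ = _label_plane(plane, params)
    return [labels == l for l in range(1, len(areas))]


def measure_wall(mask: np.ndarray, plane: np.ndarray,
                 params: SegmentationParams | None = None):
    """Extract the actin-dense wall band of a cyst mask.

    The wall is the set of pixels, within the mask dilated by
    ``wall_margin_px``, whose intensity exceeds a threshold interpolated
    between the object's interior (lumen) median and the regional maximum.
    The mean thickness is the wall area divided by the object perimeter, so a
    uniform-intensity object (no actin-dense band) gets thickness ~0.

    Returns ``(wall_mask, wall_mean_thickness_px, degenerate_flag)``.
    """
    params = params or SegmentationParams()
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area < params.min_area_px:
        return np.zeros_like(mask), 0.0, True
    plane = np.asarray(plane, dtype=np.float64)
    r_eq = np.sqrt(area / np.pi)
    erode_r = max(2, int(round(r_eq / 3.0)))
    core = ndi.binary_erosion(mask, structure=disk(erode_r))
    if not core.any():
        core = mask
    region = ndi.binary_dilation(mask, structure=disk(params.wall_margin_px))
    interior_med = float(np.median(plane[core]))
    peak = float(plane[region].max())
    thr = interior_med + params.wall_contrast_fraction * (peak - interior_med)
    wall = region & (plane > thr)
    perim = sk_perimeter(mask)
    thickness = float(wall.sum() / perim) if perim > 0 else 0.0
    return wall, thickness, False


def _pair_overlaps(lab_a: np.ndarray, lab_b: np.ndarray) -> dict:
    """Pixel-overlap counts between labels of two registered planes."""
    both = (lab_a > 0) & (lab_b > 0)
    if not both.any():
        return {}
    a, b = lab_a[both].astype(np.int64), lab_b[both].astype(np.int64)
    key = a * (lab_b.max() + 1) + b
    uniq, counts = np.unique(key, return_counts=True)
    kb = int(lab_b.max() + 1)
    return {(int(k // kb), int(k % kb)): int(c) for k, c in zip(uniq, counts)}


def detect_cysts(stack: ImageStack, params: SegmentationParams | None = None
                 ) -> list[CystObject]:
    """Detect individual cysts in an actin z-stack.

    Per-plane objects are linked across adjacent planes when their overlap is
    at least ``link_overlap_fraction`` of the smaller mask; each object links
    to at most one object on the previous plane (the largest-overlap
    candidate, ties to the lower label).  Every linked group yields one
    :class:`CystObject` whose defining plane is its maximal-area plane (ties
    to the lower plane index).
    """
    params = params or SegmentationParams()
    if stack.n_planes < 1:
        raise ValueError("need at least one plane")
    per_plane = [_label_plane(p, params) for p in stack.planes]
    smoothed = [gaussian(np.asarray(p, dtype=np.float64),
                         sigma=params.smoothing_sigma, preserve_range=True)
                if params.smoothing_sigma > 0 else np.asarray(p, dtype=np.float64)
                for p in stack.planes]

    # union-find over (plane, label) nodes
    parent: dict[tuple[int, int], tuple[int, int]] = {}

    def find(x):
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for p in range(stack.n_planes):
        for l in range(1, len(per_plane[p][1])):
            parent.setdefault((p, l), (p, l))
    for p in range(stack.n_planes - 1):
        lab_a, areas_a, _ = per_plane[p]
        lab_b, areas_b, _ = per_plane[p + 1]
        overlaps = _pair_overlaps(lab_a, lab_b)
        by_b: dict[int, list[tuple[int, int]]] = {}
        for (la, lb), c in overlaps.items():
            if c >= params.link_overlap_fraction * min(areas_a[la], areas_b[lb]):
                by_b.setdefault(lb, []).append((la, c))
        for lb, cands in by_b.items():
            la = max(cands, key=lambda t: (t[1], -t[0]))[0]
            union((p, la), (p + 1, lb))

    groups: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for node in parent:
        groups.setdefault(find(node), []).append(node)

    objects: list[CystObject] = []
    for members in groups.values():
        best = min(members, key=lambda pl: (-per_plane[pl[0]][1][pl[1]], pl[0]))
        p, l = best
        labels = per_plane[p][0]
        mask = labels == l
        rows, cols = np.nonzero(mask)
        area = rows.size
        wall, thickness, degen = measure_wall(mask, smoothed[p], params)
        wr, wc = np.nonzero(wall)
        touches = any(lab in per_plane[pp][2] for pp, lab in members)
        objects.append(CystObject(
            object_id=-1, plane_index=p, pixels=(rows, cols),
            image_shape=mask.shape, area_px=int(area),
            perimeter_px=float(sk_perimeter(mask)),
            centroid=(float(rows.mean()), float(cols.mean())),
            wall_pixels=(wr, wc), wall_area_px=int(wr.size),
            wall_mean_thickness_px=thickness, touches_border=bool(touches),
            degenerate=degen, n_planes_spanned=len(members)))
    objects.sort(key=lambda o: (o.plane_index, o.centroid))
    for i, o in enumerate(objects):
        o.object_id = i
    return objects


def count_nuclei(stack: ImageStack, params: NucleiParams | None = None) -> int:
    """Count nuclear spots in the maximum intensity projection.

    The projection is smoothed and thresholded (Otsu, with an absolute
    floor); merged spots are split by local intensity maxima at
    ``min_distance_px``.  Deterministic for fixed input and parameters.
    """
    params = params or NucleiParams()
    mip = max_projection(stack)
    if np.ptp(mip) == 0:
        return 0
    sm = gaussian(mip, sigma=params.smoothing_sigma, preserve_range=True) \
        if params.smoothing_sigma > 0 else mip.astype(np.float64)
    thr = max(threshold_otsu(sm), params.threshold_floor,
              _noise_floor(sm, params.noise_floor_sigmas))
    fg = sm > thr
    labels = sk_label(fg, connectivity=2)
    areas = np.bincount(labels.ravel())
    small = areas < params.min_spot_area_px
    small[0] = True
    fg[small[labels]] = False
    if not fg.any():
        return 0
    labels = sk_label(fg, connectivity=2)
    peaks = peak_local_max(sm, min_distance=params.min_distance_px,
                           labels=labels, exclude_border=False)
    return int(len(peaks))
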