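"""Fiber segmentation from the laminin channel, plus cell/vessel detection.

Muscle fibers are polygonal profiles wrapped in a laminin-positive basal
lamina, so in a transverse section the laminin channel draws the fiber
outlines.  Segmentation here is a deterministic classical pipeline
(smooth → threshold → connected interiors → watershed), replacing the
original workflow's external deep-learning model:

1. Gaussian-smooth the laminin channel (``smooth_sigma_um``).
2. Boundary mask = smoothed laminin ≥ ``boundary_threshold``
   (Otsu within the ROI when not set).
3. Candidate fiber interiors = connected components of ROI ∖ boundary.
4. Watershed on the smoothed laminin landscape resolves any non-boundary
   pixels left unassigned; by default the laminin wall itself stays out of
   the fibers, so the reported cross-sectional area is the area *inside*
   the basal-lamina ring (``assign_boundary=True`` absorbs the wall).
5. Drop fibers below ``min_fiber_area_um2`` or above ``max_fiber_area_um2``
   (large laminin-free regions are stroma, not fibers); optionally drop
   fibers touching the ROI border.  Labels are canonicalized 1..n in raster
   order of each fiber's first pixel.

Cells (satellite cells, macrophages) are counted as connected components of
a thresholded cell-marker channel, size-gated and required to overlap the
nuclei channel; capillaries and larger vessels are connected components of
the thresholded CD31 channel partitioned by area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import watershed

__all__ = [
    "SegmentationParams",
    "CellObject",
    "VesselObject",
    "segment_fibers",
    "stroma_mask",
    "detect_cells",
    "classify_macrophages",
    "detect_capillaries",
    "nearest_structure_distance",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable gates for fiber, cell, and vessel detection (all in µm/µm²)."""

    smooth_sigma_um: float = 1.0
    boundary_threshold: float | None = None  # None → Otsu within the ROI
    min_fiber_area_um2: float = 100.0
    max_fiber_area_um2: float = 20000.0
    exclude_border: bool = False
    assign_boundary: bool = False
    cell_min_area_um2: float = 25.0
    cell_max_area_um2: float = 500.0
    capillary_min_area_um2: float = 10.0
    capillary_max_area_um2: float = 300.0
    nucleus_overlap_min_px: int = 1

    def __post_init__(self) -> None:
        for lo, hi, what in (
            (self.min_fiber_area_um2, self.max_fiber_area_um2, "fiber area"),
            (self.cell_min_area_um2, self.cell_max_area_um2, "cell area"),
            (self.capillary_min_area_um2, self.capillary_max_area_um2, "capillary area"),
        ):
            if lo <= 0 or hi <= 0:
                raise ValueError(f"{what} bounds must be > 0")
            if lo >= hi:
                raise ValueError(f"{what} min must be < max ({lo} vs {hi})")
        if self.smooth_sigma_um < 0:
            raise ValueError("smooth_sigma_um must be ≥ 0")
        if self.nucleus_overlap_min_px < 1:
            raise ValueError("nucleus_overlap_min_px must be ≥ 1")

    def with_(self, **kwargs) -> "SegmentationParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CellObject:
    """A counted cell: marker-positive, size-gated, nucleus-gated component."""

    centroid: tuple[float, float]  # (x, y) µm
    area_um2: float
    marker_name: str
    has_nucleus: bool
    coords: np.ndarray = field(repr=False, compare=False, default=None)


@dataclass(frozen=True)
class VesselObject:
    centroid: tuple[float, float]  # (x, y) µm
    area_um2: float
    kind: str  # "capillary" | "large_vessel"


def _canonical_relabel(labels: np.ndarray) -> np.ndarray:
    """Relabel 1..n by raster order of each label's first pixel (deterministic)."""
    flat = labels.ravel()
    first_seen = {}
    order = []
    for v in flat[flat > 0]:
        if v not in first_seen:
            first_seen[v] = True
            order.append(v)
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        lut[old] = new
    return lut[labels]


def segment_fibers(
    laminin: np.ndarray,
    roi: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> np.ndarray:
    """Segment muscle fibers from the laminin channel within an ROI.

    Returns an H×W int32 label map (0 = background/stroma); labels are
    contiguous 1..n in raster order.  Deterministic for identical inputs.
    """
    roi = np.asarray(roi, dtype=bool)
    laminin = np.asarray(laminin, dtype=np.float64)
    if laminin.shape != roi.shape:
        raise ValueError(f"laminin shape {laminin.shape} != ROI shape {roi.shape}")
    if not roi.any():
        raise ValueError("ROI is empty")

    if params.smooth_sigma_um > 0:
        smoothed = gaussian(laminin, sigma=params.smooth_sigma_um, preserve_range=True)
    else:
        smoothed = laminin

    if params.boundary_threshold is None:
        vals = smoothed[roi]
        if vals.min() == vals.max():
            t = vals.max() + 1.0  # nothing is boundary
        else:
            t = float(threshold_otsu(vals))
    else:
        t = float(params.boundary_threshold)
    boundary = (smoothed >= t) & roi

    interiors = cc_label(roi & ~boundary, connectivity=1)
    if interiors.max() > 0:
        ws = watershed(smoothed, markers=interiors, mask=roi)
        labels = ws.astype(np.int32)
        if not params.assign_boundary:
            labels[boundary] = 0
    else:
        labels = np.zeros_like(interiors, dtype=np.int32)

    # area gates
    if labels.max() > 0:
        counts = np.bincount(labels.ravel())
        bad = (counts < params.min_fiber_area_um2) | (counts > params.max_fiber_area_um2)
        bad[0] = False
        labels[bad[labels]] = 0

    # border exclusion: fibers touching pixels on the ROI's own edge
    if params.exclude_border and labels.max() > 0:
        from scipy.ndimage import binary_erosion

        edge = roi & ~binary_erosion(roi, border_value=0)
        drop = np.unique(labels[edge])
        drop = drop[drop > 0]
        if drop.size:
            mask = np.isin(labels, drop)
            labels[mask] = 0

    labels = _canonical_relabel(labels)
    if labels.max() == 0:
        warnings.warn("no fibers found in ROI", stacklevel=2)
    return labels


def stroma_mask(roi: np.ndarray, fibers: np.ndarray) -> np.ndarray:
    """Stroma = ROI ∖ fiber labels; stroma and fibers partition the ROI exactly."""
    roi = np.asarray(roi, dtype=bool)
    fibers = np.asarray(fibers)
    if fibers.shape != roi.shape:
        raise ValueError(f"label shape {fibers.shape} != ROI shape {roi.shape}")
    return roi & (fibers == 0)


def _components(mask: np.ndarray):
    lab = cc_label(np.asarray(mask, dtype=bool), connectivity=1)
    return regionprops(lab)


def detect_cells(
    marker_mask: np.ndarray,
    nuclei_mask: np.ndarray,
    params: SegmentationParams,
    marker_name: str = "cell_marker",
) -> list[CellObject]:
    """Count cells: marker-positive components, size- and nucleus-gated.

    A component is a cell iff cell_min ≤ area ≤ cell_max and it overlaps the
    thresholded nuclei channel in ≥ nucleus_overlap_min_px pixels.  Oversized
    components are logged as diffuse signal and dropped.
    """
    marker_mask = np.asarray(marker_mask, dtype=bool)
    nuclei_mask = np.asarray(nuclei_mask, dtype=bool)
    if marker_mask.shape != nuclei_mask.shape:
        raise ValueError("marker and nuclei masks must share a shape")
    cells: list[CellObject] = []
    for rp in _components(marker_mask):
        if rp.area > params.cell_max_area_um2:
            warnings.warn(
                f"{marker_name}: {rp.area:.0f} µm² component exceeds the cell size "
                "gate; treated as diffuse signal",
                stacklevel=2,
            )
            continue
        if rp.area < params.cell_min_area_um2:
            continue
        rr, cc = rp.coords[:, 0], rp.coords[:, 1]
        n_overlap = int(nuclei_mask[rr, cc].sum())
        if n_overlap < params.nucleus_overlap_min_px:
            continue
        r, c = rp.centroid
        cells.append(
            CellObject(
                centroid=(float(c), float(r)),
                area_um2=float(rp.area),
                marker_name=marker_name,
                has_nucleus=True,
                coords=rp.coords.copy(),
            )
        )
    return cells


def classify_macrophages(
    cd68_cells: list[CellObject],
    cd206_mask: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> dict[str, int]:
    """Partition CD68+ macrophages into M2 (CD206-co-positive) and non-M2.

    A CD68 cell is M2 when its pixels overlap the thresholded CD206 channel
    in ≥ nucleus_overlap_min_px pixels; the M2 population proper (all
    CD206+ cells) is counted separately by :func:`detect_cells` on CD206.
    """
    cd206_mask = np.asarray(cd206_mask, dtype=bool)
    m2 = 0
    for cell in cd68_cells:
        if cell.coords is None:
            raise ValueError("cells must carry pixel coords for overlap classification")
        rr, cc = cell.coords[:, 0], cell.coords[:, 1]
        if int(cd206_mask[rr, cc].sum()) >= params.nucleus_overlap_min_px:
            m2 += 1
    return {"m2": m2, "non_m2": len(cd68_cells) - m2}


def detect_capillaries(
    cd31_mask: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> list[VesselObject]:
    """Partition CD31+ components by area into capillaries and large vessels.

    Components below the capillary range are discarded as noise.
    """
    vessels: list[VesselObject] = []
    for rp in _components(cd31_mask):
        if rp.area < params.capillary_min_area_um2:
            continue
        kind = "capillary" if rp.area <= params.capillary_max_area_um2 else "large_vessel"
        r, c = rp.centroid
        vessels.append(
            VesselObject(centroid=(float(c), float(r)), area_um2=float(rp.area), kind=kind)
        )
    return vessels


def nearest_structure_distance(
    cells: list[CellObject], vessels: list[VesselObject]
) -> np.ndarray:
    """Per-cell Euclidean distance (µm) to the nearest vessel centroid."""
    if not vessels:
        raise ValueError(
            "no vessels to measure against; report the distance as undefined"
        )
    if not cells:
        return np.zeros(0, dtype=np.float64)
    tree = cKDTree(np.asarray([v.centroid for v in vessels], dtype=np.float64))
    d, _ = tree.query(np.asarray([c.centroid for c in cells], dtype=np.float64))
    return np.atleast_1d(np.asarray(d, dtype=np.float64))
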