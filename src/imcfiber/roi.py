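"""Region-of-interest polygons, rasterization, and mask algebra.

ROIs are drawn in an annotation tool (QuPath-style GeoJSON export) in pixel
coordinates, where 1 px = 1 µm².  They are rasterized with a pixel-center
containment rule: pixel (r, c) belongs to the ROI iff its center
(c + 0.5, r + 0.5) is covered by the polygon, boundary included.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
import tifffile
from shapely.geometry import Polygon, shape as shapely_shape

__all__ = [
    "ROI_KINDS",
    "RoiPolygon",
    "import_rois",
    "rasterize",
    "mask_subtract",
    "mask_area",
    "erode_margin",
    "write_mask",
]

ROI_KINDS = ("whole_section", "fibrotic_focus", "nonfibrotic_area")

# Annotation-tool class names mapped onto the three analysis kinds.
_KIND_ALIASES = {
    "whole_section": "whole_section",
    "whole section": "whole_section",
    "fibrotic_focus": "fibrotic_focus",
    "fibrotic focus": "fibrotic_focus",
    "fibrosis": "fibrotic_focus",
    "fibrotic": "fibrotic_focus",
    "nonfibrotic_area": "nonfibrotic_area",
    "non-fibrotic": "nonfibrotic_area",
    "nonfibrotic": "nonfibrotic_area",
    "non-fibrotic area": "nonfibrotic_area",
    "non_fibrotic_area": "nonfibrotic_area",
}


@dataclass(frozen=True)
class RoiPolygon:
    """A simple polygon ROI in pixel (µm) coordinates, x = column, y = row.

    ``holes`` are interior rings subtracted from the outer ring.
    """

    roi_id: str
    kind: str
    vertices: tuple[tuple[float, float], ...]
    holes: tuple[tuple[tuple[float, float], ...], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ROI_KINDS:
            raise ValueError(f"unknown ROI kind {self.kind!r}; expected one of {ROI_KINDS}")
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        # normalize: drop an explicit closing vertex, shapely closes rings itself
        if len(verts) > 1 and verts[0] == verts[-1]:
            verts = verts[:-1]
        if len(verts) < 3:
            raise ValueError(f"ROI {self.roi_id!r}: polygon needs ≥ 3 vertices")
        object.__setattr__(self, "vertices", verts)
        poly = Polygon(verts, [list(h) for h in self.holes])
        if not poly.is_valid:
            raise ValueError(f"ROI {self.roi_id!r}: polygon is self-intersecting or invalid")
        if poly.area == 0:
            raise ValueError(f"ROI {self.roi_id!r}: polygon has zero area")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices, [list(h) for h in self.holes])

    @property
    def area_um2(self) -> float:
        return self.polygon.area


def _feature_kind(props: dict) -> str:
    """QuPath dialect: properties.classification.name; plain 'kind' also honoured."""
    name = None
    if isinstance(props.get("classification"), dict):
        name = props["classification"].get("name")
    if name is None:
        name = props.get("kind")
    if name is None:
        return "whole_section"
    return _KIND_ALIASES.get(str(name).strip().lower(), "whole_section")


def import_rois(path: str | Path) -> list[RoiPolygon]:
    """Import a GeoJSON FeatureCollection of polygon ROIs.

    Non-polygon geometries are skipped with a warning; MultiPolygon features
    are split into one ROI per part, sharing the id with a ``/k`` suffix.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed GeoJSON in {path}: {exc}") from exc
    features = doc.get("features", [doc] if doc.get("type") != "FeatureCollection" else [])
    rois: list[RoiPolygon] = []
    for i, feat in enumerate(features):
        geom = feat.get("geometry") or {}
        props = feat.get("properties") or {}
        roi_id = str(props.get("name", props.get("id", f"roi_{i}")))
        kind = _feature_kind(props)
        gtype = geom.get("type")
        if gtype == "Polygon":
            g = shapely_shape(geom)
            rois.append(
                RoiPolygon(
                    roi_id=roi_id,
                    kind=kind,
                    vertices=tuple(g.exterior.coords),
                    holes=tuple(tuple(r.coords) for r in g.interiors),
                )
            )
        elif gtype == "MultiPolygon":
            g = shapely_shape(geom)
            for k, part in enumerate(g.geoms):
                rois.append(
                    RoiPolygon(
                        roi_id=f"{roi_id}/{k}",
                        kind=kind,
                        vertices=tuple(part.exterior.coords),
                        holes=tuple(tuple(r.coords) for r in part.interiors),
                    )
                )
        else:
            warnings.warn(
                f"{path}: feature {roi_id!r} has non-polygon geometry "
                f"{gtype!r}; skipped",
                stacklevel=2,
            )
    if not rois:
        raise ValueError(f"{path}: no polygon ROIs found")
    return rois


def rasterize(roi: RoiPolygon, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize an ROI to a boolean mask over an (H, W) frame.

    A pixel is in the mask iff its center is covered by the polygon
    (boundary-inclusive).  Raises if the polygon misses the frame entirely.
    """
    h, w = int(shape[0]), int(shape[1])
    if h <= 0 or w <= 0:
        raise ValueError(f"frame shape must be positive, got {(h, w)}")
    poly = roi.polygon
    mask = np.zeros((h, w), dtype=bool)
    # restrict the covers test to the polygon's bounding box
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(int(np.floor(minx - 0.5)), 0)
    c1 = min(int(np.ceil(maxx + 0.5)), w)
    r0 = max(int(np.floor(miny - 0.5)), 0)
    r1 = min(int(np.ceil(maxy + 0.5)), h)
    if c1 > c0 and r1 > r0:
        cols = np.arange(c0, c1)
        rows = np.arange(r0, r1)
        xx, yy = np.meshgrid(cols + 0.5, rows + 0.5)
        pts = shapely.points(xx.ravel(), yy.ravel())
        inside = shapely.covers(poly, pts).reshape(r1 - r0, c1 - c0)
        mask[r0:r1, c0:c1] = inside
    if not mask.any():
        raise ValueError(
            f"ROI {roi.roi_id!r} rasterizes to an empty mask on a {h}×{w} frame "
            "(polygon outside the frame or thinner than a pixel)"
        )
    return mask


def mask_area(mask: np.ndarray) -> float:
    """Mask area in µm² (pixel count × 1 µm²)."""
    return float(np.count_nonzero(mask))


def mask_subtract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Set difference a ∖ b of two same-shape boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a & ~b


def erode_margin(mask: np.ndarray, margin_um: int) -> np.ndarray:
    """Morphologically erode a mask by ``margin_um`` µm (edge exclusion)."""
    from scipy.ndimage import binary_erosion

    if margin_um < 0:
        raise ValueError("margin must be ≥ 0")
    if margin_um == 0:
        return np.asarray(mask, dtype=bool).copy()
    return binary_erosion(np.asarray(mask, dtype=bool), iterations=int(margin_um))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Export a mask as an 8-bit single-page TIFF (0/255) for inspection."""
    tifffile.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))
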