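"""Synthetic IMC-like muscle sections with full ground truth.

The generator emulates a transverse skeletal-muscle section as seen by
imaging mass cytometry at 1 px = 1 µm²: a mosaic of polygonal myofibers
(jittered hexagonal-lattice Voronoi cells) wrapped in laminin-positive
walls, an interstitial stroma compartment (wall network plus endomysial/
perimysial patches) painted with ECM and cytokine signal, planted
capillaries and one larger vessel (CD31), perivascular fat vacuoles
(perilipin rings), and marker-positive cells (CD56 satellite cells, CD68 /
CD206 macrophages) with nuclear dots.  Per-channel images are expected ion
counts (background + signal × mask) with Poisson noise, clipped to 16 bit.

Every planted structure is recorded in a :class:`GroundTruth` bundle so
each pipeline stage has a recoverable target.  Five stage presets follow
the disease spectrum from healthy muscle to advanced fibro-fatty
replacement: stroma coverage rises, capillaries and satellite cells fall,
M2 macrophages rise, and perilipin is essentially absent outside the
fat-replacement stage.  The preset magnitudes are the generator's own
choices; only the direction of each trend is modelled.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.draw import disk as draw_disk
from skimage.filters import gaussian
from skimage.measure import label as cc_label
from skimage.morphology import binary_dilation, disk as disk_footprint

from .panel import ChannelStack, Panel, default_panel
from .roi import ROI_KINDS, RoiPolygon
from .segment import _canonical_relabel

__all__ = [
    "FatFocus",
    "SynthParams",
    "GroundTruth",
    "generate_section",
    "generate_lattice",
    "stage_preset",
    "generate_cohort",
    "focus_windows",
    "STAGE_ORDER",
]

STAGE_ORDER = ("control", "mild", "moderate", "advanced_fibrosis", "advanced_fat")

_RETRY_CAP = 2000


@dataclass(frozen=True)
class FatFocus:
    count: int = 0
    radius_um: float = 9.0
    near_large_vessel: bool = True


def _default_fiber_pos() -> dict:
    return {"MYH3": 0.02, "CD56": 0.04, "CTGF": 0.02, "PDGFA": 0.02, "TGFb": 0.02}


def _default_coverage() -> dict:
    return {
        "Collagen I": 0.15,
        "Collagen III": 0.80,
        "Collagen VI": 0.20,
        "TE7": 0.25,
        "PDGFRa": 0.10,
        "CTGF": 0.05,
        "PDGFA": 0.05,
        "TGFb": 0.05,
    }


@dataclass(frozen=True)
class SynthParams:
    """Generator knobs; lengths in µm, areas in µm², signals in ion counts."""

    frame: tuple[int, int] = (400, 400)
    fiber_csa_median_um2: float = 2300.0
    fiber_csa_sigma: float = 0.35
    boundary_width_um: float = 3.0
    stroma_fraction: float = 0.10  # target coverage of stroma *patches*
    fat_focus: FatFocus = field(default_factory=FatFocus)
    n_satellite_cells: int = 20
    n_cd68: int = 5
    n_m2: int = 5
    n_capillaries: int = 40
    m2_cd68_coexpression: float = 0.5
    cell_near_vessel_prob: float = 0.8
    fiber_positive_fraction: dict = field(default_factory=_default_fiber_pos)
    stroma_coverage: dict = field(default_factory=_default_coverage)
    signal_level: float = 120.0
    laminin_level: float = 150.0
    background_level: float = 0.2
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.stroma_fraction < 1.0:
            raise ValueError(
                f"stroma_fraction must be in [0, 1), got {self.stroma_fraction}"
            )
        for name in ("n_satellite_cells", "n_cd68", "n_m2", "n_capillaries"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if self.signal_level <= self.background_level:
            raise ValueError("signal must exceed background")
        if not 0.0 <= self.cell_near_vessel_prob <= 1.0:
            raise ValueError("cell_near_vessel_prob must be in [0, 1]")

    def with_(self, **kwargs) -> "SynthParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery scoring."""

    fiber_labels: np.ndarray
    stroma_mask: np.ndarray
    channel_masks: dict
    objects: pd.DataFrame
    csa_um2: np.ndarray
    stroma_fraction: float
    counts: dict
    positive_fiber_ids: dict
    params: SynthParams
    interior_fiber_ids: np.ndarray = field(default_factory=lambda: np.zeros(0, int))

    @property
    def csa_interior_um2(self) -> np.ndarray:
        """CSA of fibers not truncated by the frame edge.

        Frame-cut profiles are incomplete cross-sections; size-distribution
        targets (the lognormal mean) apply to the interior fibers only.
        """
        if self.interior_fiber_ids.size == 0:
            return self.csa_um2
        return self.csa_um2[self.interior_fiber_ids - 1]


def _paint_disk(mask: np.ndarray, center_rc: tuple[float, float], radius: float) -> None:
    rr, cc = draw_disk(center_rc, radius, shape=mask.shape)
    mask[rr, cc] = True


def _paint_ring(
    mask: np.ndarray, center_rc: tuple[float, float], r_out: float, r_in: float
) -> None:
    tmp = np.zeros_like(mask)
    _paint_disk(tmp, center_rc, r_out)
    inner = np.zeros_like(mask)
    _paint_disk(inner, center_rc, r_in)
    mask |= tmp & ~inner

def _hex_seeds(frame: tuple[int, int], pitch: float, jitter_sd: float, rng) -> np.ndarray:
    """Jittered hexagonal lattice covering the frame with one pitch of margin."""
    h, w = frame
    dy = pitch * math.sqrt(3) / 2
    pts = []
    row = 0
    y = -pitch
    while y < h + pitch:
        offset = (pitch / 2) if (row % 2) else 0.0
        x = -pitch + offset
        while x < w + pitch:
            pts.append((y, x))
            x += pitch
        y += dy
        row += 1
    pts = np.asarray(pts, dtype=np.float64)
    return pts + rng.normal(0.0, jitter_sd, size=pts.shape)


def _sample_separated(
    rng,
    candidates_rc: np.ndarray,
    n: int,
    min_sep: float,
    taken: list | None = None,
    what: str = "objects",
) -> list[tuple[float, float]]:
    """Pick n points from candidate pixels with pairwise (and vs taken) separation."""
    placed: list[tuple[float, float]] = []
    existing = list(taken or [])
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > _RETRY_CAP * max(n, 1):
            raise RuntimeError(
                f"could not place {n} {what} at separation {min_sep} µm; "
                "use a larger frame or fewer objects"
            )
        r, c = candidates_rc[rng.integers(len(candidates_rc))]
        ok = all(
            (r - pr) ** 2 + (c - pc) ** 2 >= min_sep**2 for pr, pc in placed + existing
        )
        if ok:
            placed.append((float(r), float(c)))
    return placed


def _coverage_mask(rng, region: np.ndarray, coverage: float, sigma: float = 8.0) -> np.ndarray:
    """Random smooth subset of ``region`` covering ≈ ``coverage`` of its area."""
    if coverage <= 0 or not region.any():
        return np.zeros_like(region)
    if coverage >= 1:
        return region.copy()
    fld = gaussian(rng.standard_normal(region.shape), sigma=sigma, preserve_range=True)
    thr = np.quantile(fld[region], 1.0 - coverage)
    return region & (fld >= thr)


def generate_section(params: SynthParams, panel: Panel | None = None,
                     sample_id: str = "synthetic") -> tuple[ChannelStack, GroundTruth]:
    """Generate one synthetic section and its ground truth (seeded, deterministic)."""
    panel = panel or default_panel()
    rng = np.random.default_rng(params.seed)
    h, w = params.frame
    if h < 64 or w < 64:
        raise ValueError("frame must be at least 64×64 µm")

    # ---- stroma patches -------------------------------------------------
    if params.stroma_fraction > 0:
        fld = gaussian(rng.standard_normal((h, w)), sigma=30.0, preserve_range=True)
        patches = fld >= np.quantile(fld, 1.0 - params.stroma_fraction)
    else:
        rng.standard_normal((h, w))  # keep the stream layout stable across settings
        patches = np.zeros((h, w), dtype=bool)

    # ---- fiber mosaic ---------------------------------------------------
    bw = params.boundary_width_um
    mean_csa = params.fiber_csa_median_um2 * math.exp(params.fiber_csa_sigma**2 / 2)
    # hexagon eroded by bw/2: sqrt(area) shrinks by ~0.93·bw
    cell_area = (math.sqrt(mean_csa) + 0.93 * bw) ** 2
    pitch = math.sqrt(cell_area / (math.sqrt(3) / 2))
    seeds = _hex_seeds((h, w), pitch, jitter_sd=0.5 * params.fiber_csa_sigma * pitch, rng=rng)
    tree = cKDTree(seeds)
    rr, cc = np.mgrid[0:h, 0:w]
    _, vor = tree.query(np.column_stack([rr.ravel() + 0.5, cc.ravel() + 0.5]))
    vor = vor.reshape(h, w).astype(np.int32) + 1

    edges = np.zeros((h, w), dtype=bool)
    edges[:, :-1] |= vor[:, :-1] != vor[:, 1:]
    edges[:-1, :] |= vor[:-1, :] != vor[1:, :]
    r_wall = max(1, int(round((bw - 1) / 2)))
    wall = binary_dilation(edges, disk_footprint(r_wall))

    fiber_mask = ~wall & ~patches
    labels = cc_label(fiber_mask, connectivity=1)
    counts = np.bincount(labels.ravel())
    small = counts < 100  # slivers cut off by patches are stroma, not fibers
    small[0] = False
    labels[small[labels]] = 0
    labels = _canonical_relabel(labels)
    fiber_mask = labels > 0
    n_fibers = int(labels.max())
    csa = np.bincount(labels.ravel())[1:].astype(np.float64)
    edge_ids = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    interior_ids = np.setdiff1d(np.arange(1, n_fibers + 1), edge_ids)

    stroma = ~fiber_mask
    stroma_fraction_true = float(stroma.sum() / stroma.size)
    stroma_rc = np.column_stack(np.nonzero(stroma))

    # laminin: basal-lamina shell around every fiber
    r_sh = max(1, math.ceil(bw / 2))
    laminin_mask = binary_dilation(fiber_mask, disk_footprint(r_sh)) & ~fiber_mask

    masks: dict[str, np.ndarray] = {m: np.zeros((h, w), dtype=bool) for m in panel.marker_names}
    masks["Laminin"] = laminin_mask

    objects: list[dict] = []

    # ---- fiber-level marker positivity ---------------------------------
    positive_ids: dict[str, np.ndarray] = {}
    frac = params.fiber_positive_fraction
    n_cd56 = int(round(frac.get("CD56", 0.0) * n_fibers))
    cd56_ids = rng.choice(n_fibers, size=n_cd56, replace=False) + 1 if n_cd56 else np.zeros(0, int)
    positive_ids["CD56"] = np.sort(cd56_ids)
    n_myh3 = int(round(frac.get("MYH3", 0.0) * n_fibers))
    # regenerating (MYH3+) fibers mostly co-express CD56
    from_cd56 = min(n_myh3 * 4 // 5, cd56_ids.size)
    myh3_ids = list(rng.choice(cd56_ids, size=from_cd56, replace=False)) if from_cd56 else []
    others = np.setdiff1d(np.arange(1, n_fibers + 1), myh3_ids)
    extra = n_myh3 - len(myh3_ids)
    if extra > 0 and others.size:
        myh3_ids += list(rng.choice(others, size=min(extra, others.size), replace=False))
    positive_ids["MYH3"] = np.sort(np.asarray(myh3_ids, dtype=int))
    for marker in ("CTGF", "PDGFA", "TGFb"):
        k = int(round(frac.get(marker, 0.0) * n_fibers))
        ids = rng.choice(n_fibers, size=k, replace=False) + 1 if k else np.zeros(0, int)
        positive_ids[marker] = np.sort(ids)
    for marker, ids in positive_ids.items():
        if ids.size:
            masks[marker] |= np.isin(labels, ids)

    # ---- vessels --------------------------------------------------------
    lv_r = 13.0
    lv_center = _sample_separated(rng, stroma_rc, 1, min_sep=1.0, what="large vessel")[0]
    _paint_disk(masks["CD31"], lv_center, lv_r)
    _paint_ring(masks["aSMA"], lv_center, lv_r + 3, lv_r)
    objects.append(
        {"kind": "large_vessel", "marker": "CD31", "x": lv_center[1], "y": lv_center[0],
         "area_um2": float(math.pi * lv_r**2)}
    )
    cap_r = 3.0
    cap_centers = _sample_separated(
        rng, stroma_rc, params.n_capillaries, min_sep=10.0,
        taken=[(lv_center[0], lv_center[1])], what="capillaries",
    )
    # keep capillaries clear of the large vessel so components stay distinct
    cap_centers = [
        c for c in cap_centers
        if (c[0] - lv_center[0]) ** 2 + (c[1] - lv_center[1]) ** 2 >= (lv_r + 12) ** 2
    ]
    deficit = params.n_capillaries - len(cap_centers)
    if deficit:
        far = stroma_rc[
            (stroma_rc[:, 0] - lv_center[0]) ** 2 + (stroma_rc[:, 1] - lv_center[1]) ** 2
            >= (lv_r + 12) ** 2
        ]
        cap_centers += _sample_separated(
            rng, far, deficit, min_sep=10.0, taken=cap_centers, what="capillaries"
        )
    for r, c in cap_centers:
        _paint_disk(masks["CD31"], (r, c), cap_r)
        objects.append(
            {"kind": "capillary", "marker": "CD31", "x": c, "y": r,
             "area_um2": float(math.pi * cap_r**2)}
        )

    # ---- fat vacuoles (perilipin rings), perivascular when configured ----
    fat = params.fat_focus
    fat_centers: list[tuple[float, float]] = []
    if fat.count:
        tries = 0
        while len(fat_centers) < fat.count:
            tries += 1
            if tries > _RETRY_CAP * fat.count:
                raise RuntimeError(
                    "could not place fat vacuoles; use a larger frame or fewer foci"
                )
            if fat.near_large_vessel:
                ang = rng.uniform(0, 2 * math.pi)
                d = rng.uniform(lv_r + fat.radius_um + 4, lv_r + fat.radius_um + 60)
                r, c = lv_center[0] + d * math.sin(ang), lv_center[1] + d * math.cos(ang)
            else:
                r, c = stroma_rc[rng.integers(len(stroma_rc))]
            if not (fat.radius_um < r < h - fat.radius_um and fat.radius_um < c < w - fat.radius_um):
                continue
            if all(
                (r - pr) ** 2 + (c - pc) ** 2 >= (2 * fat.radius_um + 2) ** 2
                for pr, pc in fat_centers
            ):
                fat_centers.append((float(r), float(c)))
        for r, c in fat_centers:
            _paint_ring(masks["Perilipin"], (r, c), fat.radius_um, fat.radius_um - 2.0)
            objects.append(
                {"kind": "fat_vacuole", "marker": "Perilipin", "x": c, "y": r,
                 "area_um2": float(math.pi * (fat.radius_um**2 - (fat.radius_um - 2) ** 2))}
            )

    # ---- cells ----------------------------------------------------------
    nuclei = masks[panel.nuclei_marker]

    def _place_cells(n: int, marker: str, kind: str, avoid_mask: np.ndarray | None,
                     taken: list) -> list[tuple[float, float]]:
        placed: list[tuple[float, float]] = []
        tries = 0
        while len(placed) < n:
            tries += 1
            if tries > _RETRY_CAP * max(n, 1):
                raise RuntimeError(
                    f"could not place {n} {kind} cells; use a larger frame"
                )
            if cap_centers and rng.random() < params.cell_near_vessel_prob:
                vr, vc = cap_centers[rng.integers(len(cap_centers))]
                ang = rng.uniform(0, 2 * math.pi)
                d = rng.uniform(cap_r + 2, cap_r + 9)
                r, c = vr + d * math.sin(ang), vc + d * math.cos(ang)
                if not (0 <= int(r) < h and 0 <= int(c) < w) or not stroma[int(r), int(c)]:
                    continue
            else:
                r, c = stroma_rc[rng.integers(len(stroma_rc))]
                r, c = float(r), float(c)
            if not (5 <= r < h - 5 and 5 <= c < w - 5):
                continue
            if not all((r - pr) ** 2 + (c - pc) ** 2 >= 10.0**2 for pr, pc in placed + taken):
                continue
            radius = rng.uniform(3.0, 3.9)
            stamp = np.zeros((h, w), dtype=bool)
            _paint_disk(stamp, (r, c), radius)
            if avoid_mask is not None and (stamp & avoid_mask).any():
                continue  # would merge with a marker-positive fiber
            masks[marker] |= stamp
            _paint_disk(nuclei, (r, c), 2.0)
            placed.append((r, c))
            objects.append(
                {"kind": kind, "marker": marker, "x": c, "y": r,
                 "area_um2": float(stamp.sum())}
            )
        return placed

    cd56_fiber_mask = masks["CD56"].copy()
    all_cells: list[tuple[float, float]] = []
    all_cells += _place_cells(
        params.n_satellite_cells, "CD56", "satellite_cell", cd56_fiber_mask, all_cells
    )
    m2_centers = _place_cells(params.n_m2, "CD206", "m2_macrophage", None, all_cells)
    all_cells += m2_centers
    n_co = int(round(params.m2_cd68_coexpression * len(m2_centers)))
    for r, c in m2_centers[:n_co]:  # CD68+CD206+ double-positive macrophages
        _paint_disk(masks["CD68"], (r, c), 3.4)
    all_cells += _place_cells(params.n_cd68, "CD68", "non_m2_macrophage", None, all_cells)

    # scattered marker-negative nuclei (myonuclei, endothelial nuclei)
    n_extra = 60
    any_rc = np.column_stack(np.nonzero(np.ones((h, w), dtype=bool)))
    for _ in range(n_extra):
        r, c = any_rc[rng.integers(len(any_rc))]
        _paint_disk(nuclei, (float(r), float(c)), 2.0)

    # ---- ECM / cytokine stroma coverage ---------------------------------
    for marker, cov in params.stroma_coverage.items():
        masks[marker] |= _coverage_mask(rng, stroma, cov)

    # ---- emit counts ----------------------------------------------------
    pixels = np.zeros((h, w, panel.n_channels), dtype=np.uint16)
    for m in panel.marker_names:
        level = params.laminin_level if m == "Laminin" else params.signal_level
        expected = params.background_level + level * masks[m].astype(np.float64)
        if params.poisson_noise:
            img = rng.poisson(expected)
        else:
            img = np.round(expected).astype(np.int64)
        pixels[:, :, panel.index_of(m)] = np.clip(img, 0, 65535).astype(np.uint16)

    stack = ChannelStack(pixels=pixels, panel=panel, sample_id=sample_id)
    gt = GroundTruth(
        fiber_labels=labels,
        stroma_mask=stroma,
        channel_masks=masks,
        objects=pd.DataFrame(objects),
        csa_um2=csa,
        stroma_fraction=stroma_fraction_true,
        counts={
            "fibers": n_fibers,
            "capillaries": len(cap_centers),
            "large_vessels": 1,
            "satellite_cells": params.n_satellite_cells,
            "m2": len(m2_centers),
            "non_m2": params.n_cd68,
            "cd68_total": params.n_cd68 + n_co,
            "fat_vacuoles": len(fat_centers),
        },
        positive_fiber_ids=positive_ids,
        params=params,
        interior_fiber_ids=interior_ids,
    )
    return stack, gt


def generate_lattice(
    n: int = 4,
    fiber_size_um: int = 40,
    wall_um: int = 3,
    n_cells: int = 3,
    n_capillaries: int = 10,
    cell_area_um2: float = 60.0,
    signal_level: float = 120.0,
    laminin_level: float = 150.0,
    background_level: float = 0.2,
    poisson_noise: bool = True,
    seed: int = 0,
    panel: Panel | None = None,
) -> tuple[ChannelStack, GroundTruth]:
    """A regular n×n grid of square fibers separated by laminin walls.

    The simplest recoverable geometry: n² fibers of exactly
    ``fiber_size_um²`` µm² with walls of ``wall_um`` µm; CD68 cells (with
    nuclei) and CD31 capillaries are planted at grid-interior positions.
    """
    panel = panel or default_panel()
    rng = np.random.default_rng(seed)
    f, wl = int(fiber_size_um), int(wall_um)
    size = n * f + (n + 1) * wl
    labels = np.zeros((size, size), dtype=np.int32)
    fid = 0
    for i in range(n):
        for j in range(n):
            fid += 1
            r0 = wl + i * (f + wl)
            c0 = wl + j * (f + wl)
            labels[r0 : r0 + f, c0 : c0 + f] = fid
    fiber_mask = labels > 0
    laminin_mask = ~fiber_mask

    masks = {m: np.zeros((size, size), dtype=bool) for m in panel.marker_names}
    masks["Laminin"] = laminin_mask
    objects: list[dict] = []
    nuclei = masks[panel.nuclei_marker]

    # plant cells and capillaries inside fiber interiors, well separated
    interior_rc = np.column_stack(np.nonzero(fiber_mask))
    margin = 8
    interior_rc = interior_rc[
        (interior_rc[:, 0] > margin) & (interior_rc[:, 0] < size - margin)
        & (interior_rc[:, 1] > margin) & (interior_rc[:, 1] < size - margin)
    ]
    cell_r = math.sqrt(cell_area_um2 / math.pi)
    centers = _sample_separated(
        rng, interior_rc, n_cells + n_capillaries, min_sep=14.0, what="planted objects"
    )
    for r, c in centers[:n_cells]:
        _paint_disk(masks["CD68"], (r, c), cell_r)
        _paint_disk(nuclei, (r, c), 2.0)
        objects.append({"kind": "non_m2_macrophage", "marker": "CD68", "x": c, "y": r,
                        "area_um2": float(math.pi * cell_r**2)})
    for r, c in centers[n_cells:]:
        _paint_disk(masks["CD31"], (r, c), 3.0)
        objects.append({"kind": "capillary", "marker": "CD31", "x": c, "y": r,
                        "area_um2": float(math.pi * 9.0)})

    pixels = np.zeros((size, size, panel.n_channels), dtype=np.uint16)
    for m in panel.marker_names:
        level = laminin_level if m == "Laminin" else signal_level
        expected = background_level + level * masks[m].astype(np.float64)
        img = rng.poisson(expected) if poisson_noise else np.round(expected).astype(np.int64)
        pixels[:, :, panel.index_of(m)] = np.clip(img, 0, 65535).astype(np.uint16)

    params = SynthParams(
        frame=(size, size),
        fiber_csa_median_um2=float(f * f),
        fiber_csa_sigma=0.0 if f else 0.0,
        boundary_width_um=float(wl),
        stroma_fraction=0.0,
        n_satellite_cells=0,
        n_cd68=n_cells,
        n_m2=0,
        n_capillaries=n_capillaries,
        signal_level=signal_level,
        laminin_level=laminin_level,
        background_level=background_level,
        poisson_noise=poisson_noise,
        seed=seed,
    )
    gt = GroundTruth(
        fiber_labels=labels,
        stroma_mask=~fiber_mask,
        channel_masks=masks,
        objects=pd.DataFrame(objects),
        csa_um2=np.full(n * n, float(f * f)),
        stroma_fraction=float((~fiber_mask).sum() / fiber_mask.size),
        counts={
            "fibers": n * n,
            "capillaries": n_capillaries,
            "large_vessels": 0,
            "satellite_cells": 0,
            "m2": 0,
            "non_m2": n_cells,
            "cd68_total": n_cells,
            "fat_vacuoles": 0,
        },
        positive_fiber_ids={},
        params=params,
    )
    return ChannelStack(pixels=pixels, panel=panel, sample_id=f"lattice_{n}x{n}"), gt


# ---------------------------------------------------------------------------
# stage presets

_PRESETS: dict[str, dict] = {
    "control": dict(
        stroma_fraction=0.03, fiber_csa_median_um2=2295.0, fiber_csa_sigma=0.30,
        n_capillaries=60, n_satellite_cells=25, n_m2=2, n_cd68=3,
        fat_focus=FatFocus(count=0), cell_near_vessel_prob=0.8,
        fiber_positive_fraction={"MYH3": 0.01, "CD56": 0.03, "CTGF": 0.02,
                                 "PDGFA": 0.02, "TGFb": 0.02},
        stroma_coverage={"Collagen I": 0.15, "Collagen III": 0.80, "Collagen VI": 0.20,
                         "TE7": 0.25, "PDGFRa": 0.10, "CTGF": 0.05, "PDGFA": 0.05,
                         "TGFb": 0.05},
    ),
    "mild": dict(
        stroma_fraction=0.12, fiber_csa_median_um2=2600.0, fiber_csa_sigma=0.50,
        n_capillaries=45, n_satellite_cells=18, n_m2=6, n_cd68=5,
        fat_focus=FatFocus(count=1), cell_near_vessel_prob=0.3,
        fiber_positive_fraction={"MYH3": 0.08, "CD56": 0.12, "CTGF": 0.05,
                                 "PDGFA": 0.06, "TGFb": 0.03},
        stroma_coverage={"Collagen I": 0.35, "Collagen III": 0.70, "Collagen VI": 0.35,
                         "TE7": 0.40, "PDGFRa": 0.25, "CTGF": 0.15, "PDGFA": 0.12,
                         "TGFb": 0.08},
    ),
    "moderate": dict(
        stroma_fraction=0.25, fiber_csa_median_um2=2800.0, fiber_csa_sigma=0.60,
        n_capillaries=30, n_satellite_cells=12, n_m2=12, n_cd68=8,
        fat_focus=FatFocus(count=2), cell_near_vessel_prob=0.3,
        fiber_positive_fraction={"MYH3": 0.15, "CD56": 0.22, "CTGF": 0.10,
                                 "PDGFA": 0.10, "TGFb": 0.04},
        stroma_coverage={"Collagen I": 0.55, "Collagen III": 0.60, "Collagen VI": 0.50,
                         "TE7": 0.55, "PDGFRa": 0.40, "CTGF": 0.25, "PDGFA": 0.20,
                         "TGFb": 0.10},
    ),
    "advanced_fibrosis": dict(
        stroma_fraction=0.42, fiber_csa_median_um2=3000.0, fiber_csa_sigma=0.70,
        n_capillaries=18, n_satellite_cells=7, n_m2=20, n_cd68=10,
        fat_focus=FatFocus(count=3), cell_near_vessel_prob=0.3,
        fiber_positive_fraction={"MYH3": 0.25, "CD56": 0.35, "CTGF": 0.15,
                                 "PDGFA": 0.15, "TGFb": 0.05},
        stroma_coverage={"Collagen I": 0.80, "Collagen III": 0.50, "Collagen VI": 0.70,
                         "TE7": 0.75, "PDGFRa": 0.60, "CTGF": 0.35, "PDGFA": 0.30,
                         "TGFb": 0.12},
    ),
    "advanced_fat": dict(
        stroma_fraction=0.46, fiber_csa_median_um2=3200.0, fiber_csa_sigma=0.70,
        n_capillaries=10, n_satellite_cells=4, n_m2=26, n_cd68=12,
        fat_focus=FatFocus(count=14), cell_near_vessel_prob=0.3,
        fiber_positive_fraction={"MYH3": 0.30, "CD56": 0.40, "CTGF": 0.35,
                                 "PDGFA": 0.18, "TGFb": 0.12},
        stroma_coverage={"Collagen I": 0.80, "Collagen III": 0.45, "Collagen VI": 0.70,
                         "TE7": 0.75, "PDGFRa": 0.65, "CTGF": 0.50, "PDGFA": 0.35,
                         "TGFb": 0.12},
    ),
}


def stage_preset(name: str, frame: tuple[int, int] = (400, 400), seed: int = 0) -> SynthParams:
    """Parameters for one disease stage; trends follow the stage spectrum."""
    if name not in _PRESETS:
        raise ValueError(f"unknown stage {name!r}; options: {', '.join(STAGE_ORDER)}")
    return SynthParams(frame=frame, seed=seed, **_PRESETS[name])


def generate_cohort(
    n_per_group: int,
    base_seed: int = 0,
    frame: tuple[int, int] = (400, 400),
    panel: Panel | None = None,
) -> list[tuple[str, str, ChannelStack, GroundTruth]]:
    """One synthetic cohort: n_per_group samples per stage, seeded from base_seed.

    Returns (sample_id, group, stack, ground_truth) tuples; sample seeds are
    derived deterministically and kept below 2³¹.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be ≥ 1")
    panel = panel or default_panel()
    out = []
    for gi, group in enumerate(STAGE_ORDER):
        for j in range(n_per_group):
            seed = int(
                np.random.SeedSequence([int(base_seed), gi, j]).generate_state(1)[0]
                & 0x7FFFFFFF
            )
            sid = f"{group}_{j + 1}"
            params = stage_preset(group, frame=frame, seed=seed)
            stack, gt = generate_section(params, panel=panel, sample_id=sid)
            out.append((sid, group, stack, gt))
    return out


def focus_windows(
    gt: GroundTruth, size_um: int = 120, n_each: int = 1
) -> list[RoiPolygon]:
    """Construct fibrotic-focus and non-fibrotic sub-ROIs from ground truth.

    Square windows of ``size_um`` are ranked by true stroma coverage; the
    top windows become ``fibrotic_focus`` ROIs and the bottom windows
    ``nonfibrotic_area`` ROIs (greedy, non-overlapping).  This stands in
    for the annotator's manual sub-region selection.
    """
    h, w = gt.stroma_mask.shape
    s = int(size_um)
    if s > min(h, w):
        raise ValueError("window larger than the frame")
    integ = np.pad(np.cumsum(np.cumsum(gt.stroma_mask, 0), 1), ((1, 0), (1, 0)))
    # stroma pixel count of every s×s window anchored at (r, c)
    win = (
        integ[s:, s:] - integ[:-s, s:] - integ[s:, :-s] + integ[:-s, :-s]
    ).astype(np.float64) / (s * s)

    def _greedy(order_rc: np.ndarray, n: int, taken: list) -> list[tuple[int, int]]:
        picked: list[tuple[int, int]] = []
        for r, c in order_rc:
            if len(picked) >= n:
                break
            if all(abs(r - pr) >= s or abs(c - pc) >= s for pr, pc in picked + taken):
                picked.append((int(r), int(c)))
        return picked

    flat_order = np.argsort(win, axis=None)
    rc = np.column_stack(np.unravel_index(flat_order, win.shape))
    low = _greedy(rc, n_each, [])
    high = _greedy(rc[::-1], n_each, low)
    rois: list[RoiPolygon] = []
    for k, (r, c) in enumerate(high):
        rois.append(
            RoiPolygon(
                roi_id=f"fibrotic_{k}",
                kind="fibrotic_focus",
                vertices=((c, r), (c + s, r), (c + s, r + s), (c, r + s)),
            )
        )
    for k, (r, c) in enumerate(low):
        rois.append(
            RoiPolygon(
                roi_id=f"nonfibrotic_{k}",
                kind="nonfibrotic_area",
                vertices=((c, r), (c + s, r), (c + s, r + s), (c, r + s)),
            )
        )
    return rois
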