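"""Per-fiber tables: cross-sectional area, marker fractions, positivity.

Each segmented fiber contributes one record holding its cross-sectional
area (CSA, pixel count × 1 µm²) and, per marker, the fraction of its pixels
at/above the channel threshold.  A fiber is called positive for a marker
when that fraction reaches the marker's area rule — 10% of the fiber area
by default, 5% for CTGF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import ChannelStack
from .quantify import ThresholdSet

__all__ = [
    "GROUPS",
    "DEFAULT_RULE",
    "DEFAULT_RULES",
    "FiberRecord",
    "FiberTable",
    "build_fiber_table",
    "score_positivity",
    "class_percentages",
    "csa_summary",
]

#: Disease-stage vocabulary, ordered by severity.
GROUPS = ("control", "mild", "moderate", "advanced_fibrosis", "advanced_fat")

DEFAULT_RULE = 0.10
#: Marker-specific positivity rules (fraction of fiber area); CTGF uses 5%.
DEFAULT_RULES = {"CTGF": 0.05}


def _rule_for(marker: str, rules: dict[str, float] | None) -> float:
    table = DEFAULT_RULES if rules is None else rules
    return table.get(marker, DEFAULT_RULE)


def score_positivity(fraction: float, rule: float) -> bool:
    """Positive iff the fiber's positive-area fraction reaches the rule.

    Inclusive comparison: a fiber positive for *at least* 10% of its area
    (5% for CTGF) is called positive.
    """
    if not 0.0 < rule <= 1.0:
        raise ValueError(f"rule must be in (0, 1], got {rule}")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    return fraction >= rule


@dataclass(frozen=True)
class FiberRecord:
    fiber_id: int
    roi_id: str
    csa_um2: float
    centroid: tuple[float, float]  # (x, y) µm
    fractions: dict  # marker → positive-area fraction in [0, 1]
    flags: dict  # marker → positivity flag

    def fraction(self, marker: str) -> float:
        if marker not in self.fractions:
            raise KeyError(f"marker {marker!r} not scored on fiber {self.fiber_id}")
        return self.fractions[marker]

    def positive(self, marker: str) -> bool:
        if marker not in self.flags:
            raise KeyError(f"marker {marker!r} not scored on fiber {self.fiber_id}")
        return self.flags[marker]


@dataclass
class FiberTable:
    records: list[FiberRecord]
    sample_id: str = "sample"
    group: str = "control"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        ids = [r.fiber_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("fiber_ids are not unique")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def csa(self) -> np.ndarray:
        return np.asarray([r.csa_um2 for r in self.records], dtype=np.float64)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "sample_id": self.sample_id,
                "group": self.group,
                "roi_id": r.roi_id,
                "fiber_id": r.fiber_id,
                "csa_um2": r.csa_um2,
                "centroid_x": r.centroid[0],
                "centroid_y": r.centroid[1],
            }
            for m, f in r.fractions.items():
                row[f"frac_{m}"] = f
                row[f"pos_{m}"] = r.flags[m]
            rows.append(row)
        return pd.DataFrame(rows)


def build_fiber_table(
    fibers: np.ndarray,
    stack: ChannelStack,
    thresholds: ThresholdSet,
    roi_id: str = "roi",
    group: str = "control",
    rules: dict[str, float] | None = None,
) -> FiberTable:
    """Extract the per-fiber table from a label map and the channel stack.

    CSA is the label's pixel count; the per-marker fraction is the share of
    the fiber's pixels at/above the marker threshold (same thresholds as the
    ROI metrics).  An empty label map yields an empty (valid) table.
    """
    fibers = np.asarray(fibers)
    if fibers.shape != stack.shape:
        raise ValueError(f"label shape {fibers.shape} != stack shape {stack.shape}")
    n = int(fibers.max())
    if n == 0:
        return FiberTable([], sample_id=stack.sample_id, group=group)

    flat = fibers.ravel()
    csa = np.bincount(flat, minlength=n + 1).astype(np.float64)  # index 0 = background
    rr, cc = np.nonzero(fibers)
    lab = fibers[rr, cc]
    cx = np.bincount(lab, weights=cc + 0.5, minlength=n + 1)
    cy = np.bincount(lab, weights=rr + 0.5, minlength=n + 1)

    pos_counts = {}
    for marker in stack.panel.marker_names:
        t = thresholds.get(stack.sample_id, marker)
        pos = (stack.plane(marker) >= t.value).ravel().astype(np.float64)
        pos_counts[marker] = np.bincount(flat, weights=pos, minlength=n + 1)

    records = []
    for fid in range(1, n + 1):
        if csa[fid] == 0:
            raise ValueError(f"label map not contiguous: label {fid} has no pixels")
        fractions = {m: float(pos_counts[m][fid] / csa[fid]) for m in pos_counts}
        flags = {m: score_positivity(f, _rule_for(m, rules)) for m, f in fractions.items()}
        records.append(
            FiberRecord(
                fiber_id=fid,
                roi_id=roi_id,
                csa_um2=float(csa[fid]),
                centroid=(float(cx[fid] / csa[fid]), float(cy[fid] / csa[fid])),
                fractions=fractions,
                flags=flags,
            )
        )
    return FiberTable(records, sample_id=stack.sample_id, group=group)


#: Fiber classes reported as percentages of all fibers.  "MYH3-CD56+" means
#: MYH3-negative AND CD56-positive (immature fibers not expressing neonatal
#: myosin).
FIBER_CLASSES = (
    ("MYH3+", lambda r: r.positive("MYH3")),
    ("CD56+", lambda r: r.positive("CD56")),
    ("MYH3-CD56+", lambda r: (not r.positive("MYH3")) and r.positive("CD56")),
    ("CTGF+", lambda r: r.positive("CTGF")),
    ("PDGFA+", lambda r: r.positive("PDGFA")),
    ("TGFb+", lambda r: r.positive("TGFb")),
)


def class_percentages(table: FiberTable) -> dict[str, float]:
    """Percentage of fibers in each positivity class (of all fibers)."""
    if len(table) == 0:
        raise ValueError("fiber table is empty")
    n = len(table)
    return {
        name: 100.0 * sum(pred(r) for r in table.records) / n
        for name, pred in FIBER_CLASSES
    }


def csa_summary(
    tables: list[FiberTable], bin_width_um2: float = 250.0
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Per-group CSA statistics, relative-frequency histogram, and ECDF.

    Returns ``(stats, hist, ecdf)`` where *stats* has one row per group with
    mean and sample (n−1) SD, *hist* holds relative frequencies on a shared
    binning (summing to 1 per group), and *ecdf* maps each group to its
    (sorted CSA, cumulative fraction) arrays over the pooled per-group CSAs.
    Groups with no fibers are skipped with a warning.
    """
    if bin_width_um2 <= 0:
        raise ValueError("bin width must be > 0")
    pooled: dict[str, np.ndarray] = {}
    for g in GROUPS:
        vals = np.concatenate(
            [t.csa for t in tables if t.group == g] or [np.zeros(0)]
        )
        if vals.size == 0:
            if any(t.group == g for t in tables):
                warnings.warn(f"group {g!r} has no fibers; skipped", stacklevel=2)
            continue
        pooled[g] = np.sort(vals)
    if not pooled:
        raise ValueError("no fibers in any group")

    stats = pd.DataFrame(
        [
            {
                "group": g,
                "n_fibers": v.size,
                "csa_mean_um2": float(v.mean()),
                "csa_sd_um2": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
            }
            for g, v in pooled.items()
        ]
    )

    top = max(v.max() for v in pooled.values())
    edges = np.arange(0.0, top + bin_width_um2, bin_width_um2)
    if edges[-1] <= top:
        edges = np.append(edges, edges[-1] + bin_width_um2)
    rows = []
    for g, v in pooled.items():
        counts, _ = np.histogram(v, bins=edges)
        rel = counts / v.size
        for lo, hi, f in zip(edges[:-1], edges[1:], rel):
            rows.append({"group": g, "bin_lo_um2": lo, "bin_hi_um2": hi, "rel_freq": f})
    hist = pd.DataFrame(rows)

    ecdf = {
        g: (v, np.arange(1, v.size + 1, dtype=np.float64) / v.size)
        for g, v in pooled.items()
    }
    return stats, hist, ecdf
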