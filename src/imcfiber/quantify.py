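"""Per-ROI channel metrics: positive fraction, mean intensities, densities.

The core readout per (ROI, marker) is the *positive fraction* — the
percentage of ROI pixels at or above the channel threshold — together with
the mean intensity over all ROI pixels and over the positive pixels only.
Thresholds are raw ion-count values, set per sample and marker (manually or
by a reproducible automatic rule) and carried with their provenance.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import ChannelStack

__all__ = [
    "Threshold",
    "ThresholdSet",
    "RoiChannelMetrics",
    "apply_threshold",
    "auto_threshold",
    "roi_metrics",
    "metrics_frame",
    "object_density",
]

#: wildcard sample id used for panel-wide default thresholds
ANY_SAMPLE = "*"


@dataclass(frozen=True)
class Threshold:
    value: float
    provenance: str = "manual"  # "manual" | "auto"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"threshold must be ≥ 0, got {self.value}")
        if self.provenance not in ("manual", "auto"):
            raise ValueError(f"unknown threshold provenance {self.provenance!r}")


class ThresholdSet:
    """Per (sample_id, marker_name) thresholds in raw counts.

    The sample id ``"*"`` acts as a fallback for all samples, so a single
    panel-wide threshold table can be declared once.
    """

    def __init__(self) -> None:
        self._table: dict[tuple[str, str], Threshold] = {}

    def set(
        self, sample_id: str, marker_name: str, value: float, provenance: str = "manual"
    ) -> None:
        self._table[(sample_id, marker_name)] = Threshold(float(value), provenance)

    def get(self, sample_id: str, marker_name: str) -> Threshold:
        for key in ((sample_id, marker_name), (ANY_SAMPLE, marker_name)):
            if key in self._table:
                return self._table[key]
        raise KeyError(
            f"no threshold for sample {sample_id!r}, marker {marker_name!r}"
        )

    def __contains__(self, key: tuple[str, str]) -> bool:
        try:
            self.get(*key)
            return True
        except KeyError:
            return False

    def __len__(self) -> int:
        return len(self._table)

    @classmethod
    def uniform(cls, markers, value: float, provenance: str = "manual") -> "ThresholdSet":
        """One common threshold for every marker (wildcard sample)."""
        ts = cls()
        for m in markers:
            ts.set(ANY_SAMPLE, m, value, provenance)
        return ts

    @classmethod
    def from_csv(cls, path: str | Path) -> "ThresholdSet":
        ts = cls()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                ts.set(
                    row["sample_id"],
                    row["marker_name"],
                    float(row["threshold"]),
                    row.get("provenance", "manual"),
                )
        return ts

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["sample_id", "marker_name", "threshold", "provenance"])
            for (sid, m), t in sorted(self._table.items()):
                w.writerow([sid, m, t.value, t.provenance])


def apply_threshold(plane: np.ndarray, t: float) -> np.ndarray:
    """Positive-pixel mask: value ≥ t (inclusive; t = 0 marks everything)."""
    if t < 0:
        raise ValueError(f"threshold must be ≥ 0, got {t}")
    return np.asarray(plane) >= t


def auto_threshold(
    plane: np.ndarray,
    roi: np.ndarray,
    method: str = "otsu",
    quantile: float = 0.95,
) -> float:
    """Reproducible automatic threshold from ROI pixels only.

    ``otsu`` runs two-class Otsu on the ROI histogram; on a constant plane it
    falls back to max+1 (nothing positive) with a warning.  ``quantile``
    returns the given upper quantile of ROI pixel values.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    vals = np.asarray(plane)[roi]
    if method == "otsu":
        from skimage.filters import threshold_otsu

        if vals.min() == vals.max():
            warnings.warn(
                "constant plane under otsu; falling back to max+1 (nothing positive)",
                stacklevel=2,
            )
            return float(vals.max() + 1)
        return float(threshold_otsu(vals))
    if method == "quantile":
        if not 0.0 < quantile < 1.0:
            raise ValueError(f"quantile must be in (0, 1), got {quantile}")
        return float(np.quantile(vals, quantile))
    raise ValueError(f"unknown auto-threshold method {method!r}")


@dataclass(frozen=True)
class RoiChannelMetrics:
    """HIPO-style per-(ROI, marker) metrics.

    ``positive_mean_intensity`` is None when no pixel reaches threshold —
    missing, never zero.
    """

    roi_id: str
    marker_name: str
    threshold: float
    threshold_provenance: str
    roi_area_um2: float
    positive_fraction: float  # percent, 0–100
    mean_intensity: float
    positive_mean_intensity: float | None


def roi_metrics(
    stack: ChannelStack,
    roi: np.ndarray,
    thresholds: ThresholdSet,
    roi_id: str = "roi",
) -> list[RoiChannelMetrics]:
    """Compute the per-marker ROI metrics for one region.

    positive_fraction = 100 · |{p ∈ ROI : v(p) ≥ t}| / |ROI|.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != stack.shape:
        raise ValueError(f"ROI shape {roi.shape} does not match stack {stack.shape}")
    n_roi = int(np.count_nonzero(roi))
    if n_roi == 0:
        raise ValueError(f"ROI {roi_id!r} is empty")
    out: list[RoiChannelMetrics] = []
    for marker in stack.panel.marker_names:
        t = thresholds.get(stack.sample_id, marker)
        vals = stack.plane(marker)[roi].astype(np.float64)
        pos = vals >= t.value
        n_pos = int(pos.sum())
        out.append(
            RoiChannelMetrics(
                roi_id=roi_id,
                marker_name=marker,
                threshold=t.value,
                threshold_provenance=t.provenance,
                roi_area_um2=float(n_roi),
                positive_fraction=100.0 * n_pos / n_roi,
                mean_intensity=float(vals.sum() / n_roi),
                positive_mean_intensity=(
                    float(vals[pos].sum() / n_pos) if n_pos else None
                ),
            )
        )
    return out


def metrics_frame(metrics: list[RoiChannelMetrics]) -> pd.DataFrame:
    """Tidy DataFrame view (one row per ROI × marker)."""
    return pd.DataFrame([vars(m) for m in metrics])


def object_density(n: int, roi: np.ndarray) -> float:
    """Objects per mm² of ROI (ROI area in µm² / 1e6)."""
    if n < 0:
        raise ValueError("object count must be ≥ 0")
    area = float(np.count_nonzero(np.asarray(roi, dtype=bool)))
    if area == 0:
        raise ValueError("ROI is empty")
    return n / (area / 1e6)
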