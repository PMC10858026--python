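"""End-to-end orchestration: quantify → segment → fiber table → statistics.

A run analyzes a cohort of samples (either synthetic sections generated on
the fly or stacks + ROI files from disk), producing tidy CSVs: per-ROI
channel metrics, the fiber table, detected objects, one summary row per
sample, CSA distribution summaries, the Spearman/Bonferroni correlation
family, and the fibrotic-vs-non-fibrotic region comparison.

All randomness flows from the single config seed.  Outputs are written
with canonical ordering and float formatting so a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fibers import (
    DEFAULT_RULES,
    FiberTable,
    GROUPS,
    build_fiber_table,
    class_percentages,
    csa_summary,
)
from .panel import ChannelStack, Panel, default_panel, load_panel, read_stack
from .quantify import ThresholdSet, apply_threshold, metrics_frame, object_density, roi_metrics
from .roi import RoiPolygon, import_rois, mask_area, rasterize
from .segment import (
    SegmentationParams,
    detect_capillaries,
    detect_cells,
    classify_macrophages,
    segment_fibers,
    stroma_mask,
)
from .stats import ALPHA, compare_groups, correlation_frame, ks_compare, spearman_family
from .synth import GroundTruth, focus_windows, generate_cohort

logger = logging.getLogger("imcfiber")

__all__ = [
    "RunConfig",
    "SampleResult",
    "analyze_sample",
    "run_quantify",
    "run_compare_regions",
    "run_full",
    "DEFAULT_CORRELATION_PAIRS",
    "slug",
]

_FLOAT_FMT = "%.6g"

#: Area-readout markers summarized as "% positive area of the ROI".
AREA_MARKERS = (
    "Collagen I",
    "Collagen III",
    "Collagen VI",
    "TE7",
    "Perilipin",
    "PDGFRa",
    "CTGF",
    "PDGFA",
    "TGFb",
)

#: Default Spearman family: the marker associations tracked across severity.
DEFAULT_CORRELATION_PAIRS = [
    ("stroma_pct", "capillary_density_mm2"),
    ("stroma_pct", "n_satellite_cells"),
    ("stroma_pct", "n_m2"),
    ("stroma_pct", "collagen_i_pct"),
    ("collagen_i_pct", "te7_pct"),
    ("collagen_vi_pct", "te7_pct"),
    ("perilipin_pct", "stroma_pct"),
    ("stroma_pct", "pct_myh3_pos"),
    ("n_satellite_cells", "n_capillaries"),
    ("n_m2", "pdgfra_pct"),
]


def slug(marker: str) -> str:
    """CSV-safe column stem for a marker name."""
    return re.sub(r"[^a-z0-9]+", "_", marker.lower()).strip("_")


@dataclass
class RunConfig:
    """One run: inputs, thresholds, gates, statistics options, output paths."""

    output_dir: Path = Path("imcfiber_out")
    seed: int = 0
    mode: str = "synthetic"  # "synthetic" | "files"
    # synthetic mode
    n_per_group: int = 2
    frame: tuple[int, int] = (400, 400)
    # files mode
    panel_path: Path | None = None
    samples: list[dict] = field(default_factory=list)  # {sample_id, group, stack, rois}
    # thresholds: a uniform raw-count value, a CSV path, or "auto:otsu"/"auto:quantile"
    thresholds: float | str = 5.0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    positivity_rules: dict = field(default_factory=lambda: dict(DEFAULT_RULES))
    ecm_fiber_exclusion: bool = True
    alpha: float = ALPHA
    equal_var: bool = False
    correlation_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_CORRELATION_PAIRS)
    )
    csa_bin_um2: float = 250.0
    subroi_size_um: int = 120
    subroi_n_each: int = 1

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.frame = (int(self.frame[0]), int(self.frame[1]))
        if isinstance(self.segmentation, dict):
            self.segmentation = SegmentationParams(**self.segmentation)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate_paths()
        return cfg

    def validate_paths(self) -> None:
        """Fail before any compute if referenced inputs are missing."""
        if self.mode == "files":
            if self.panel_path is not None and not Path(self.panel_path).exists():
                raise FileNotFoundError(f"panel file not found: {self.panel_path}")
            if not self.samples:
                raise ValueError("files mode requires a non-empty samples list")
            for s in self.samples:
                for key in ("stack",):
                    if not Path(s[key]).exists():
                        raise FileNotFoundError(
                            f"sample {s.get('sample_id')}: missing {key} file {s[key]}"
                        )
                if s.get("group") not in GROUPS:
                    raise ValueError(
                        f"sample {s.get('sample_id')}: group must be one of {GROUPS}"
                    )
        if isinstance(self.thresholds, str) and not self.thresholds.startswith("auto:"):
            if not Path(self.thresholds).exists():
                raise FileNotFoundError(f"threshold CSV not found: {self.thresholds}")


def _resolve_thresholds(config: RunConfig, panel: Panel, stack: ChannelStack,
                        roi: np.ndarray) -> ThresholdSet:
    t = config.thresholds
    if isinstance(t, (int, float)):
        return ThresholdSet.uniform(panel.marker_names, float(t))
    if isinstance(t, str) and t.startswith("auto:"):
        from .quantify import auto_threshold

        method = t.split(":", 1)[1]
        ts = ThresholdSet()
        for m in panel.marker_names:
            ts.set(stack.sample_id, m, auto_threshold(stack.plane(m), roi, method=method),
                   provenance="auto")
        return ts
    return ThresholdSet.from_csv(t)


@dataclass
class SampleResult:
    sample_id: str
    group: str
    roi_id: str
    metrics: pd.DataFrame
    fiber_table: FiberTable
    labels: np.ndarray
    stroma: np.ndarray
    objects: pd.DataFrame
    summary: dict


def _ecm_exclusion(labels: np.ndarray, stack: ChannelStack, thresholds: ThresholdSet,
                   max_ecm_fraction: float = 0.5) -> np.ndarray:
    """Reclassify candidate fibers dominated by ECM signal as stroma.

    The laminin channel alone cannot distinguish a fiber interior from a
    laminin-free stroma patch; a true fiber is not collagen-filled, so
    candidates whose interior ECM-positive fraction exceeds the cutoff are
    dropped back into the stroma compartment.
    """
    from .segment import _canonical_relabel

    n = int(labels.max())
    if n == 0:
        return labels
    ecm = np.zeros(stack.shape, dtype=bool)
    for m in ("Collagen I", "Collagen III", "Collagen VI", "TE7"):
        t = thresholds.get(stack.sample_id, m)
        ecm |= stack.plane(m) >= t.value
    flat = labels.ravel()
    area = np.bincount(flat, minlength=n + 1)
    pos = np.bincount(flat, weights=ecm.ravel().astype(np.float64), minlength=n + 1)
    frac = np.divide(pos, area, out=np.zeros_like(pos), where=area > 0)
    drop = frac > max_ecm_fraction
    drop[0] = False
    out = labels.copy()
    out[drop[out]] = 0
    return _canonical_relabel(out)


def analyze_sample(
    stack: ChannelStack,
    roi: np.ndarray,
    config: RunConfig,
    group: str,
    roi_id: str = "whole_section",
) -> SampleResult:
    """Full single-ROI analysis: metrics, fibers, cells, vessels, summary row."""
    panel = stack.panel
    thresholds = _resolve_thresholds(config, panel, stack, roi)
    metrics = metrics_frame(roi_metrics(stack, roi, thresholds, roi_id=roi_id))
    metrics.insert(0, "sample_id", stack.sample_id)
    metrics.insert(1, "group", group)

    labels = segment_fibers(stack.plane("Laminin"), roi, config.segmentation)
    if config.ecm_fiber_exclusion:
        labels = _ecm_exclusion(labels, stack, thresholds)
    stroma = stroma_mask(roi, labels)

    fiber_table = build_fiber_table(
        labels, stack, thresholds, roi_id=roi_id, group=group,
        rules=config.positivity_rules,
    )

    seg = config.segmentation
    nuclei = apply_threshold(
        stack.plane(panel.nuclei_marker),
        thresholds.get(stack.sample_id, panel.nuclei_marker).value,
    )

    def _mask(marker: str) -> np.ndarray:
        t = thresholds.get(stack.sample_id, marker).value
        return apply_threshold(stack.plane(marker), t) & roi

    sc = detect_cells(_mask("CD56"), nuclei, seg, marker_name="CD56")
    cd68 = detect_cells(_mask("CD68"), nuclei, seg, marker_name="CD68")
    m2_cells = detect_cells(_mask("CD206"), nuclei, seg, marker_name="CD206")
    macro = classify_macrophages(cd68, _mask("CD206"), seg)
    vessels = detect_capillaries(_mask("CD31"), seg)
    caps = [v for v in vessels if v.kind == "capillary"]
    large = [v for v in vessels if v.kind == "large_vessel"]

    obj_rows = []
    for kind, objs in (
        ("satellite_cell", sc),
        ("cd68_macrophage", cd68),
        ("m2_macrophage", m2_cells),
    ):
        for o in objs:
            obj_rows.append(
                {"sample_id": stack.sample_id, "roi_id": roi_id, "kind": kind,
                 "marker": o.marker_name, "x": o.centroid[0], "y": o.centroid[1],
                 "area_um2": o.area_um2}
            )
    for v in vessels:
        obj_rows.append(
            {"sample_id": stack.sample_id, "roi_id": roi_id, "kind": v.kind,
             "marker": "CD31", "x": v.centroid[0], "y": v.centroid[1],
             "area_um2": v.area_um2}
        )
    objects = pd.DataFrame(
        obj_rows, columns=["sample_id", "roi_id", "kind", "marker", "x", "y", "area_um2"]
    )

    roi_area = mask_area(roi)
    summary = {
        "sample_id": stack.sample_id,
        "group": group,
        "roi_id": roi_id,
        "roi_area_um2": roi_area,
        "stroma_pct": 100.0 * mask_area(stroma) / roi_area,
        "fiber_area_pct": 100.0 * mask_area(labels > 0) / roi_area,
        "n_fibers": len(fiber_table),
        "fiber_density_mm2": object_density(len(fiber_table), roi),
        "n_capillaries": len(caps),
        "capillary_density_mm2": object_density(len(caps), roi),
        "n_large_vessels": len(large),
        "n_satellite_cells": len(sc),
        "n_cd68": len(cd68),
        "n_m2": len(m2_cells),
        "n_cd68_m2": macro["m2"],
        "n_cd68_nonm2": macro["non_m2"],
    }
    by_marker = metrics.set_index("marker_name")
    for m in AREA_MARKERS:
        summary[f"{slug(m)}_pct"] = float(by_marker.loc[m, "positive_fraction"])
    if len(fiber_table):
        for name, pct in class_percentages(fiber_table).items():
            key = "pct_" + slug(name.replace("-", "neg_").replace("+", "_pos"))
            summary[key] = pct
        summary["csa_mean_um2"] = float(fiber_table.csa.mean())
    return SampleResult(
        sample_id=stack.sample_id, group=group, roi_id=roi_id, metrics=metrics,
        fiber_table=fiber_table, labels=labels, stroma=stroma, objects=objects,
        summary=summary,
    )


def _load_samples(config: RunConfig):
    """Yield (sample_id, group, stack, ground_truth_or_None, sub_rois)."""
    if config.mode == "synthetic":
        for sid, group, stack, gt in generate_cohort(
            config.n_per_group, base_seed=config.seed, frame=config.frame
        ):
            sub = focus_windows(gt, size_um=config.subroi_size_um,
                                n_each=config.subroi_n_each)
            yield sid, group, stack, gt, sub
    else:
        panel = load_panel(config.panel_path) if config.panel_path else default_panel()
        for s in config.samples:
            stack = read_stack(s["stack"], panel, sample_id=s["sample_id"])
            sub: list[RoiPolygon] = []
            rois = []
            if s.get("rois"):
                rois = import_rois(s["rois"])
                sub = [r for r in rois if r.kind != "whole_section"]
            yield s["sample_id"], s["group"], stack, None, sub


def _whole_section_roi(stack: ChannelStack) -> np.ndarray:
    return np.ones(stack.shape, dtype=bool)


def _write_csv(df: pd.DataFrame, path: Path, sort_by: list[str]) -> None:
    df = df.sort_values(sort_by, kind="stable").reset_index(drop=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_quantify(config: RunConfig) -> pd.DataFrame:
    """Per-ROI channel metrics only (one row per sample × ROI × marker)."""
    config.validate_paths()
    config.output_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for sid, group, stack, _gt, _sub in _load_samples(config):
        roi = _whole_section_roi(stack)
        thresholds = _resolve_thresholds(config, stack.panel, stack, roi)
        df = metrics_frame(roi_metrics(stack, roi, thresholds, roi_id="whole_section"))
        df.insert(0, "sample_id", sid)
        df.insert(1, "group", group)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    _write_csv(out, config.output_dir / "roi_metrics.csv",
               ["sample_id", "roi_id", "marker_name"])
    return out


#: Quantities compared between fibrotic and non-fibrotic regions.
REGION_QUANTITIES = (
    ["stroma_pct"]
    + [f"{slug(m)}_pct" for m in AREA_MARKERS]
    + ["n_satellite_cells", "n_fibers", "n_capillaries", "n_m2"]
)

REGION_CLASSES = ("control_nonfibrotic", "dystrophic_nonfibrotic", "dystrophic_fibrotic")


def _region_class(group: str, kind: str) -> str | None:
    if kind == "fibrotic_focus":
        return None if group == "control" else "dystrophic_fibrotic"
    if kind == "nonfibrotic_area":
        return "control_nonfibrotic" if group == "control" else "dystrophic_nonfibrotic"
    return None


def run_compare_regions(config: RunConfig, region_rows: pd.DataFrame | None = None
                        ) -> pd.DataFrame:
    """Compare fibrotic foci against non-fibrotic areas across sample groups.

    Produces per-quantity means ± SD for the three region classes plus
    pairwise unpaired t-tests.  ``region_rows`` (one summary row per
    sub-ROI) may be passed in from a full run; otherwise they are computed.
    """
    config.validate_paths()
    if region_rows is None:
        rows = []
        for sid, group, stack, _gt, sub in _load_samples(config):
            for r in sub:
                mask = rasterize(r, stack.shape)
                res = analyze_sample(stack, mask, config, group, roi_id=r.roi_id)
                res.summary["roi_kind"] = r.kind
                rows.append(res.summary)
        region_rows = pd.DataFrame(rows)
    if region_rows.empty:
        raise ValueError("no sub-ROIs of kind fibrotic_focus / nonfibrotic_area found")
    region_rows = region_rows.copy()
    region_rows["region_class"] = [
        _region_class(g, k) for g, k in zip(region_rows["group"], region_rows["roi_kind"])
    ]
    region_rows = region_rows.dropna(subset=["region_class"])
    present = [c for c in REGION_CLASSES if (region_rows["region_class"] == c).any()]
    if len(present) < 2:
        raise ValueError("region comparison needs ≥ 2 region classes present")

    out_rows = []
    contrasts = [
        (a, b) for i, a in enumerate(present) for b in present[i + 1:]
    ]
    for q in REGION_QUANTITIES:
        if q not in region_rows.columns:
            continue
        by = {c: region_rows.loc[region_rows["region_class"] == c, q].dropna().to_numpy()
              for c in present}
        row = {"quantity": q}
        for c in present:
            row[f"{c}_mean"] = float(by[c].mean()) if by[c].size else np.nan
            row[f"{c}_sd"] = float(by[c].std(ddof=1)) if by[c].size > 1 else np.nan
            row[f"{c}_n"] = int(by[c].size)
        for a, b in contrasts:
            if by[a].size >= 2 and by[b].size >= 2:
                res = compare_groups(by[a], by[b], equal_var=config.equal_var,
                                     alpha=config.alpha)
                row[f"p_{a}_vs_{b}"] = res.p
                row[f"sig_{a}_vs_{b}"] = res.significant
            else:
                logger.warning("contrast %s vs %s skipped for %s (too few regions)",
                               a, b, q)
        out_rows.append(row)
    out = pd.DataFrame(out_rows)
    config.output_dir.mkdir(parents=True, exist_ok=True)
    _write_csv(out, config.output_dir / "region_comparison.csv", ["quantity"])
    return out


def run_full(config: RunConfig) -> dict:
    """The whole workflow; returns the result tables and writes the bundle.

    Outputs in ``output_dir``: roi_metrics.csv, fibers.csv, objects.csv,
    sample_summary.csv, csa_summary.csv, correlations.csv,
    region_comparison.csv, run_log.txt.
    """
    config.validate_paths()
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        metrics_frames, fiber_frames, object_frames = [], [], []
        summaries, region_rows = [], []
        fiber_tables: list[FiberTable] = []
        for sid, group, stack, _gt, sub in _load_samples(config):
            stage = f"sample {sid}"
            roi = _whole_section_roi(stack)
            res = analyze_sample(stack, roi, config, group, roi_id="whole_section")
            metrics_frames.append(res.metrics)
            fiber_frames.append(res.fiber_table.to_frame())
            object_frames.append(res.objects)
            summaries.append(res.summary)
            fiber_tables.append(res.fiber_table)
            for r in sub:
                mask = rasterize(r, stack.shape)
                rres = analyze_sample(stack, mask, config, group, roi_id=r.roi_id)
                rres.summary["roi_kind"] = r.kind
                region_rows.append(rres.summary)

        stage = "summaries"
        roi_metrics_df = pd.concat(metrics_frames, ignore_index=True)
        fibers_df = pd.concat([f for f in fiber_frames if not f.empty], ignore_index=True)
        objects_df = pd.concat(object_frames, ignore_index=True)
        summary_df = pd.DataFrame(summaries)

        csa_stats, csa_hist, _ = csa_summary(fiber_tables, bin_width_um2=config.csa_bin_um2)
        control_csa = np.concatenate(
            [t.csa for t in fiber_tables if t.group == "control"] or [np.zeros(0)]
        )
        dys_csa = np.concatenate(
            [t.csa for t in fiber_tables if t.group != "control"] or [np.zeros(0)]
        )
        ks_d = ks_p = float("nan")
        if control_csa.size and dys_csa.size:
            ks_d, ks_p = ks_compare(control_csa, dys_csa)

        stage = "statistics"
        corr = spearman_family(summary_df, config.correlation_pairs)
        corr_df = correlation_frame(corr)

        stage = "region comparison"
        region_df = pd.DataFrame(region_rows)
        comparison = None
        if not region_df.empty:
            comparison = run_compare_regions(config, region_rows=region_df)

        stage = "write"
        _write_csv(roi_metrics_df, out / "roi_metrics.csv",
                   ["sample_id", "roi_id", "marker_name"])
        _write_csv(fibers_df, out / "fibers.csv", ["sample_id", "roi_id", "fiber_id"])
        _write_csv(objects_df, out / "objects.csv",
                   ["sample_id", "roi_id", "kind", "x", "y"])
        _write_csv(summary_df, out / "sample_summary.csv", ["sample_id"])
        _write_csv(csa_stats, out / "csa_summary.csv", ["group"])
        _write_csv(csa_hist, out / "csa_histogram.csv", ["group", "bin_lo_um2"])
        if not corr_df.empty:
            _write_csv(corr_df, out / "correlations.csv", ["quantity_a", "quantity_b"])
        else:
            corr_df.to_csv(out / "correlations.csv", index=False)

        log_lines = [
            f"imcfiber {__version__}",
            f"seed: {config.seed}",
            f"mode: {config.mode}",
            f"segmentation: {dataclasses.asdict(config.segmentation)}",
            f"positivity_rules: default 0.10 with overrides {config.positivity_rules}",
            f"thresholds: {config.thresholds}",
            f"alpha: {config.alpha}",
            f"correlation family m = {len(config.correlation_pairs)}",
            f"csa ks: D = {ks_d:.6g}, p = {ks_p:.6g} (control vs dystrophic, "
            f"n = {control_csa.size} / {dys_csa.size})",
            "schema v1: roi_metrics, fibers, objects, sample_summary, csa_summary, "
            "csa_histogram, correlations, region_comparison",
        ]
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        return {
            "roi_metrics": roi_metrics_df,
            "fibers": fibers_df,
            "objects": objects_df,
            "sample_summary": summary_df,
            "csa_summary": csa_stats,
            "csa_histogram": csa_hist,
            "correlations": corr_df,
            "region_comparison": comparison,
            "ks": (ks_d, ks_p),
        }
    except Exception:
        (out / "FAILED").write_text(f"failed during stage: {stage}\n")
        logger.exception("run failed during stage: %s", stage)
        raise
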