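"""Marker panel definitions and multi-channel pseudoimage I/O.

An IMC acquisition produces one raster of ion counts per metal-conjugated
antibody; exports are multi-page 16-bit TIFF stacks, one page per channel,
at 1 pixel per 1 µm².  A :class:`Panel` binds page indices to marker names
so downstream code can ask for "the laminin channel" instead of "page 4".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "MarkerDef",
    "Panel",
    "ChannelStack",
    "PanelError",
    "TARGET_CLASSES",
    "load_panel",
    "default_panel",
    "read_stack",
    "write_stack",
]

#: Allowed biological target classes for a panel entry.
TARGET_CLASSES = frozenset(
    {"fiber_marker", "ecm", "cell_marker", "cytokine", "nuclei", "vessel", "fat"}
)

MAX_UINT16 = np.iinfo(np.uint16).max


class PanelError(ValueError):
    """Raised when a panel table violates its invariants."""


@dataclass(frozen=True)
class MarkerDef:
    """One panel entry: a marker bound to a metal tag and a stack page."""

    marker_name: str
    metal_tag: str
    channel_index: int
    target_class: str

    def __post_init__(self) -> None:
        if self.target_class not in TARGET_CLASSES:
            raise PanelError(
                f"unknown target_class {self.target_class!r} for marker "
                f"{self.marker_name!r}; expected one of {sorted(TARGET_CLASSES)}"
            )


@dataclass(frozen=True)
class Panel:
    """Ordered marker panel; validates uniqueness and channel contiguity."""

    markers: tuple[MarkerDef, ...]

    def __post_init__(self) -> None:
        if not self.markers:
            raise PanelError("panel has no markers")
        tags = [m.metal_tag for m in self.markers]
        dupes = {t for t in tags if tags.count(t) > 1}
        if dupes:
            raise PanelError(f"duplicate metal tag: {', '.join(sorted(dupes))}")
        names = [m.marker_name for m in self.markers]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise PanelError(f"duplicate marker name: {', '.join(sorted(dupes))}")
        idx = sorted(m.channel_index for m in self.markers)
        if idx != list(range(len(self.markers))):
            raise PanelError(
                f"channel_index values must be unique and contiguous 0..{len(self.markers) - 1}, "
                f"got {idx}"
            )
        n_nuc = sum(m.target_class == "nuclei" for m in self.markers)
        if n_nuc != 1:
            raise PanelError(f"panel must contain exactly one nuclei entry, found {n_nuc}")

    @property
    def n_channels(self) -> int:
        return len(self.markers)

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(m.marker_name for m in self.markers)

    @property
    def nuclei_marker(self) -> str:
        return next(m.marker_name for m in self.markers if m.target_class == "nuclei")

    def __iter__(self):
        return iter(self.markers)

    def __getitem__(self, name: str) -> MarkerDef:
        for m in self.markers:
            if m.marker_name == name:
                return m
        raise KeyError(f"marker {name!r} not in panel {self.marker_names}")

    def index_of(self, name: str) -> int:
        return self[name].channel_index

    def markers_of_class(self, target_class: str) -> tuple[str, ...]:
        return tuple(
            m.marker_name for m in self.markers if m.target_class == target_class
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_name": [m.marker_name for m in self.markers],
                "metal_tag": [m.metal_tag for m in self.markers],
                "channel_index": [m.channel_index for m in self.markers],
                "target_class": [m.target_class for m in self.markers],
            }
        )


def load_panel(path: str | Path) -> Panel:
    """Load a marker panel from a CSV with the four canonical columns.

    Required columns: ``marker_name``, ``metal_tag``, ``channel_index``,
    ``target_class``.  Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"panel file not found: {path}")
    df = pd.read_csv(path)
    required = {"marker_name", "metal_tag", "channel_index", "target_class"}
    missing = required - set(df.columns)
    if missing:
        raise PanelError(f"panel file {path} missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise PanelError("panel has no markers")
    markers = tuple(
        MarkerDef(
            marker_name=str(r.marker_name),
            metal_tag=str(r.metal_tag),
            channel_index=int(r.channel_index),
            target_class=str(r.target_class),
        )
        for r in df.itertuples()
    )
    return Panel(markers)


def default_panel() -> Panel:
    """The packaged default panel (16 recoverable antibodies + iridium nuclei)."""
    with resources.as_file(
        resources.files("imcfiber.data") / "default_panel.csv"
    ) as p:
        return load_panel(p)


@dataclass
class ChannelStack:
    """An H×W×C stack of raw ion counts at 1 px = 1 µm².

    Values are non-negative integers exactly as exported; no rescaling is
    ever applied.
    """

    pixels: np.ndarray
    panel: Panel
    sample_id: str = "sample"
    pixel_area_um2: float = field(default=1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError(f"stack must be H×W×C, got shape {self.pixels.shape}")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValueError(f"stack must hold integer counts, got {self.pixels.dtype}")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("stack contains negative counts")
        if self.pixels.shape[2] != self.panel.n_channels:
            raise ValueError(
                f"stack has {self.pixels.shape[2]} channels but panel defines "
                f"{self.panel.n_channels}"
            )
        if self.pixel_area_um2 != 1.0:
            raise ValueError("pixel_area_um2 must be 1.0 (1 px = 1 µm²)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def plane(self, marker: str | int) -> np.ndarray:
        """Return one channel image, addressed by marker name or page index."""
        if isinstance(marker, str):
            marker = self.panel.index_of(marker)
        return self.pixels[:, :, marker]


def read_stack(path: str | Path, panel: Panel, sample_id: str | None = None) -> ChannelStack:
    """Read a multi-page TIFF stack and bind it to ``panel``.

    The page count must equal the panel's channel count and pixels must be
    integer-typed; values are returned exactly as stored.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    pages = np.asarray(pages)
    if pages.ndim == 2:
        pages = pages[None, :, :]
    if pages.ndim != 3:
        raise ValueError(f"{path}: expected a multi-page 2-D TIFF, got shape {pages.shape}")
    if pages.shape[0] != panel.n_channels:
        raise ValueError(
            f"{path}: file has {pages.shape[0]} pages but panel defines "
            f"{panel.n_channels} channels"
        )
    if not np.issubdtype(pages.dtype, np.integer):
        raise ValueError(f"{path}: non-integer pixel type {pages.dtype}")
    return ChannelStack(
        pixels=np.moveaxis(pages, 0, 2),
        panel=panel,
        sample_id=sample_id if sample_id is not None else path.stem,
    )


def write_stack(path: str | Path, stack: ChannelStack) -> None:
    """Write a stack as a multi-page 16-bit TIFF (one page per channel).

    Values above the 16-bit range are clipped with a warning to match the
    declared export format.
    """
    pages = np.moveaxis(stack.pixels, 2, 0)
    if pages.max(initial=0) > MAX_UINT16:
        warnings.warn(
            f"{stack.sample_id}: clipping {int((pages > MAX_UINT16).sum())} pixels "
            f"above the 16-bit range at write time",
            stacklevel=2,
        )
        pages = np.clip(pages, 0, MAX_UINT16)
    tifffile.imwrite(Path(path), pages.astype(np.uint16), photometric="minisblack")
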