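"""Convert a four-lead ECG panel into stacked-lead grayscale images.

Pipeline for one patient (10 s, 5000 samples/lead):

1. each lead is split into ``segments`` contiguous time segments
   (default 3, so 5000 samples become 1667 + 1667 + 1666);
2. each segment is rasterized at native resolution — one pixel column per
   sample, ``native_strip_height_px`` rows — as a 1-px connected polyline
   (linear interpolation between samples), black trace on white background;
3. each native strip is reduced with Lanczos windowed-sinc resampling to
   ``out_size`` x ``strip_height_px``;
4. the four reduced strips are stacked top-to-bottom in the fixed order
   II, V3, V5, aVR with ``inter_lead_gap_px`` background rows between
   them, giving one ``out_size`` x ``out_size`` 8-bit image per segment.

Amplitude is mapped linearly from a fixed symmetric physical range
(default +/-2 mV; values outside are clipped to the edge rows), so pixel
row carries the same voltage meaning in every segment and every patient.
The whole pipeline is deterministic: identical inputs give byte-identical
PNG files.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from functools import lru_cache
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import (
    DimensionError,
    EmptyInputError,
    PartitionError,
    ShapeError,
)
from .leads import PANEL_ORDER, LeadPanel


@dataclass(frozen=True)
class RenderConfig:
    """Geometry and intensity parameters of the image encoding.

    The default layout is the only integer solution to stacking four
    strips with 40-px gaps in a 224-px image: 4*26 + 3*40 = 224.
    """

    segments: int = 3
    out_size: int = 224
    strip_height_px: int = 26
    inter_lead_gap_px: int = 40
    amp_range_mv: float = 2.0
    native_strip_height_px: int = 256
    trace_intensity: int = 0
    background_intensity: int = 255
    lanczos_taps: int = 3

    def __post_init__(self) -> None:
        if self.trace_intensity == self.background_intensity:
            raise ShapeError("trace and background intensities must differ")
        if self.segments < 1 or self.out_size < 1 or self.strip_height_px < 1:
            raise DimensionError("segments, out_size and strip_height_px must be >= 1")
        if self.amp_range_mv <= 0:
            raise DimensionError("amp_range_mv must be positive")

    @property
    def n_leads(self) -> int:
        return len(PANEL_ORDER)

    def strip_row_bands(self) -> list[tuple[int, int]]:
        """Half-open row intervals [start, stop) occupied by each strip."""
        pitch = self.strip_height_px + self.inter_lead_gap_px
        return [(k * pitch, k * pitch + self.strip_height_px)
                for k in range(self.n_leads)]


@dataclass(frozen=True)
class ECGImagePanel:
    """The per-patient stack of segment images (8-bit grayscale)."""

    patient_id: str
    images: tuple[np.ndarray, ...]
    label: int | None = None

    def __post_init__(self) -> None:
        for img in self.images:
            if img.ndim != 2 or img.dtype != np.uint8:
                raise ShapeError("panel images must be 2-D uint8 grids")

    @property
    def segment_indices(self) -> tuple[int, ...]:
        return tuple(range(len(self.images)))


def render_config_from_file(path: str | Path) -> RenderConfig:
    """Load a RenderConfig from a YAML or JSON file of its fields."""
    import json

    import yaml

    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = (json.loads(text) if path.suffix.lower() == ".json"
            else yaml.safe_load(text)) or {}
    valid = {f.name for f in fields(RenderConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ShapeError(f"unknown RenderConfig fields in {path}: "
                         f"{sorted(unknown)}")
    return RenderConfig(**data)


def split_segments(samples: np.ndarray, n: int) -> list[np.ndarray]:
    """Split a sequence into ``n`` contiguous segments of near-equal length.

    Segments are ordered, disjoint and cover the input exactly; lengths
    differ by at most one, with earlier segments taking the extra sample
    (5000 -> 1667, 1667, 1666).
    """
    arr = np.asarray(samples)
    if n < 1:
        raise PartitionError(f"segment count must be >= 1, got {n}")
    if arr.shape[0] < n:
        raise PartitionError(
            f"cannot split {arr.shape[0]} samples into {n} segments")
    base, extra = divmod(arr.shape[0], n)
    out, start = [], 0
    for k in range(n):
        size = base + (1 if k < extra else 0)
        out.append(arr[start:start + size])
        start += size
    return out


def render_strip(samples: np.ndarray, width_px: int, height_px: int,
                 config: RenderConfig) -> np.ndarray:
    """Rasterize one lead segment as a 1-px connected polyline.

    Samples are placed uniformly over x in [0, width_px-1]; amplitude maps
    linearly so +amp_range_mv is row 0 (top) and -amp_range_mv is the
    bottom row, with out-of-range values clipped to the edge rows. Every
    column receives the linearly interpolated trace value, and consecutive
    columns are joined vertically so the trace is connected.
    """
    v = np.asarray(samples, dtype=np.float64)
    if v.size == 0:
        raise EmptyInputError("cannot render an empty segment")
    if width_px < 2 or height_px < 2:
        raise DimensionError("strip dimensions must be >= 2 px")

    r = config.amp_range_mv
    if v.size == 1:
        x = np.array([0.0])
    else:
        x = np.arange(v.size) * (width_px - 1) / (v.size - 1)
    cols = np.arange(width_px, dtype=np.float64)
    amp = np.interp(cols, x, v)
    amp = np.clip(amp, -r, r)
    y = (r - amp) / (2.0 * r) * (height_px - 1)
    rows = np.clip(np.floor(y + 0.5).astype(np.int64), 0, height_px - 1)

    lo = rows.copy()
    hi = rows.copy()
    # join consecutive columns vertically for a connected trace
    np.minimum(lo[1:], rows[:-1], out=lo[1:])
    np.maximum(hi[1:], rows[:-1], out=hi[1:])
    rr = np.arange(height_px)[:, None]
    mask = (rr >= lo[None, :]) & (rr <= hi[None, :])
    grid = np.full((height_px, width_px), config.background_intensity,
                   dtype=np.uint8)
    grid[mask] = config.trace_intensity
    return grid


def _lanczos_kernel(x: np.ndarray, a: int) -> np.ndarray:
    out = np.sinc(x) * np.sinc(x / a)
    out[np.abs(x) >= a] = 0.0
    return out


def lanczos_weights(n_in: int, n_out: int, taps: int) -> np.ndarray:
    """Dense (n_out, n_in) resampling matrix for one axis.

    Pixel centers follow the half-pixel convention; on downscale the
    kernel is widened by the scale factor (antialiasing); source indices
    outside the grid are clamped to the edge; each row is normalized to
    unit sum so constants are preserved.
    """
    if n_out < 1 or n_in < 1:
        raise DimensionError("resample dimensions must be >= 1")
    scale = n_in / n_out
    support = max(scale, 1.0)
    w = np.zeros((n_out, n_in), dtype=np.float64)
    for j in range(n_out):
        center = (j + 0.5) * scale - 0.5
        left = int(np.ceil(center - taps * support))
        right = int(np.floor(center + taps * support))
        idx = np.arange(left, right + 1)
        k = _lanczos_kernel((idx - center) / support, taps)
        np.add.at(w[j], np.clip(idx, 0, n_in - 1), k)
        w[j] /= w[j].sum()
    return w


@lru_cache(maxsize=64)
def _cached_weights(n_in: int, n_out: int, taps: int) -> np.ndarray:
    w = lanczos_weights(n_in, n_out, taps)
    w.flags.writeable = False
    return w


def resize_lanczos(grid: np.ndarray, out_w: int, out_h: int,
                   taps: int = 3) -> np.ndarray:
    """Resize a 2-D intensity grid with separable Lanczos resampling.

    The result is clamped to [0, 255] and rounded to 8 bits.
    """
    if out_w < 1 or out_h < 1:
        raise DimensionError(f"output dims must be >= 1, got {out_w}x{out_h}")
    g = np.asarray(grid, dtype=np.float64)
    if g.ndim != 2:
        raise ShapeError("resize_lanczos expects a 2-D grid")
    wr = _cached_weights(g.shape[0], out_h, taps)
    wc = _cached_weights(g.shape[1], out_w, taps)
    out = wr @ g @ wc.T
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def compose_panel(strips: list[np.ndarray], config: RenderConfig) -> np.ndarray:
    """Stack four reduced strips into one out_size x out_size image.

    Strips are placed top-to-bottom in the given (fixed lead) order with
    ``inter_lead_gap_px`` background rows between consecutive strips.
    """
    n = config.n_leads
    if len(strips) != n:
        raise ShapeError(f"expected {n} strips, got {len(strips)}")
    expected = (config.strip_height_px, config.out_size)
    for k, s in enumerate(strips):
        if s.shape != expected:
            raise ShapeError(
                f"strip {k} has shape {s.shape}, expected {expected}")
    total = n * config.strip_height_px + (n - 1) * config.inter_lead_gap_px
    if total != config.out_size:
        raise ShapeError(
            f"layout {n}x{config.strip_height_px} + "
            f"{n - 1}x{config.inter_lead_gap_px} = {total} px does not fill "
            f"out_size {config.out_size}")
    img = np.full((config.out_size, config.out_size),
                  config.background_intensity, dtype=np.uint8)
    for (start, stop), strip in zip(config.strip_row_bands(), strips):
        img[start:stop, :] = strip
    return img


def encode_patient(panel: LeadPanel,
                   config: RenderConfig | None = None) -> ECGImagePanel:
    """Run the full lead-panel -> image-stack encoding for one patient."""
    config = config or RenderConfig()
    per_lead_segments = [split_segments(lead, config.segments)
                         for lead in panel.leads_in_order]
    images = []
    for s in range(config.segments):
        strips = []
        for lead_segments in per_lead_segments:
            seg = lead_segments[s]
            native = render_strip(seg, width_px=len(seg),
                                  height_px=config.native_strip_height_px,
                                  config=config)
            strips.append(resize_lanczos(native, config.out_size,
                                         config.strip_height_px,
                                         config.lanczos_taps))
        images.append(compose_panel(strips, config))
    return ECGImagePanel(patient_id=panel.patient_id, images=tuple(images),
                         label=panel.label)


def save_panel_png(panel: ECGImagePanel, outdir: str | Path) -> list[Path]:
    """Write each segment image as ``<patient_id>_seg<k>.png`` (8-bit gray)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, img in enumerate(panel.images):
        p = outdir / f"{panel.patient_id}_seg{k}.png"
        Image.fromarray(img, mode="L").save(p, format="PNG")
        paths.append(p)
    return paths


def load_image_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG back as a 2-D uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)
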