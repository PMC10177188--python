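"""Surface detection, en face attenuation mapping, rendering and stitching.

An en face map is the per-A-scan mean of the valid attenuation voxels over a
fixed depth window measured from the detected tissue surface (default
105-630 um below it, the range giving the most contrasted tissue maps).
Rendering uses a fixed absolute color scale of 0-7 mm^-1 running
blue -> cyan -> yellow -> red so that maps from different volumes are
directly comparable; pixels with no valid voxel are black.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy.ndimage import median_filter

from .attenuation import AttenuationVolume, NoiseModel, _smooth3
from .io import CHANNELS, OCTVolume, channel_index

#: default depth window below the surface, mm
DEFAULT_WINDOW = (0.105, 0.630)

#: fixed rendering scale, mm^-1
COLOR_SCALE = (0.0, 7.0)

MISSING = -1  # surface-index value for A-scans with no detected surface


def detect_surface(
    vol: OCTVolume,
    noise: NoiseModel | None = None,
    k: float = 4.0,
    channel: str = "co",
    flat: int | None = None,
    median_px: int = 5,
) -> np.ndarray:
    """Per-A-scan tissue-surface index map.

    The surface is the first axial index where the 3x3x3-smoothed signal
    exceeds ``k * <N>``, followed by ``median_px`` x ``median_px`` lateral
    median filtering.  A-scans that never cross the threshold are marked
    :data:`MISSING`.  ``flat`` overrides detection with a constant index
    (contact-probe geometry gives a near-flat surface).

    When no noise model is given, a provisional floor is taken from the top
    10 axial planes (probe stand-off region).
    """
    nz, nx, ny = vol.data.shape[1:]
    if flat is not None:
        if not (0 <= flat < nz):
            raise ValueError(f"flat surface index {flat} outside [0, {nz})")
        return np.full((nx, ny), int(flat), dtype=int)
    sm = _smooth3(vol.channel(channel))
    if noise is None:
        n_mean = float(vol.channel(channel)[: min(10, nz)].mean())
    else:
        n_mean = noise[channel]
    above = sm > k * n_mean
    hit = above.any(axis=0)
    idx = np.argmax(above, axis=0)
    surf = np.where(hit, idx, MISSING)
    if hit.any():
        filled = np.where(hit, idx, np.median(idx[hit])).astype(float)
        smoothed = median_filter(filled, size=median_px, mode="nearest")
        surf = np.where(hit, np.round(smoothed).astype(int), MISSING)
    return surf


@dataclass
class EnFaceMap:
    """Depth-averaged attenuation map for one channel (NaN = missing)."""

    values: np.ndarray
    channel: str
    window_mm: tuple
    pitch_xy: float
    scale: tuple = COLOR_SCALE
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("en face map values must be 2D")

    @property
    def shape(self) -> tuple:
        return self.values.shape


def window_indices(window_mm, delta_z: float) -> tuple:
    """Depth window as pixel offsets below the surface (half-open)."""
    z_min, z_max = window_mm
    if not (0 <= z_min < z_max):
        raise ValueError(f"bad depth window {window_mm}")
    return int(round(z_min / delta_z)), int(round(z_max / delta_z))


def enface_average(
    attvol: AttenuationVolume,
    surface: np.ndarray | None = None,
    window_mm=DEFAULT_WINDOW,
    channel: str = "cross",
) -> EnFaceMap:
    """Mean of valid attenuation voxels over a surface-relative depth window."""
    ci = channel_index(channel)
    surf = attvol.surface if surface is None else np.asarray(surface)
    mu = attvol.mu_att[ci].astype(np.float64)
    valid = attvol.valid[ci]
    nz, nx, ny = mu.shape
    o0, o1 = window_indices(window_mm, attvol.delta_z)

    have_surface = surf >= 0
    if not have_surface.any():
        raise ValueError("no A-scan has a detected surface; en face map would be empty")
    i0 = np.clip(surf + o0, 0, nz)
    i1 = np.clip(surf + o1, 0, nz)
    if (i0[have_surface] >= nz).all():
        raise ValueError("depth window lies entirely below the volume bottom")

    contrib = np.where(valid, mu, 0.0)
    csum = np.concatenate([np.zeros((1, nx, ny)), np.cumsum(contrib, axis=0)], axis=0)
    ccnt = np.concatenate(
        [np.zeros((1, nx, ny), dtype=np.int64), np.cumsum(valid, axis=0)], axis=0
    )
    gx, gy = np.ogrid[:nx, :ny]
    total = csum[i1, gx, gy] - csum[i0, gx, gy]
    count = ccnt[i1, gx, gy] - ccnt[i0, gx, gy]
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(count > 0, total / count, np.nan)
    vals = np.where(have_surface, vals, np.nan)
    return EnFaceMap(
        values=vals,
        channel=channel,
        window_mm=tuple(window_mm),
        pitch_xy=attvol.pitch_xy,
        meta={"depth_window_px": (o0, o1)},
    )


def enface_maps(attvol: AttenuationVolume, window_mm=DEFAULT_WINDOW):
    """Both channels' en face maps as a dict."""
    return {ch: enface_average(attvol, window_mm=window_mm, channel=ch) for ch in CHANNELS}


# fixed colormap anchors (value in mm^-1 -> color), matching the verbal bands:
# < 2 blue shades, 2-3 cyan, 4-5 yellow, > 6 red.
_CMAP_ANCHORS = [
    (0.0, "#000080"),
    (1.0, "#0000ff"),
    (2.0, "#00a8ff"),
    (3.0, "#00ffff"),
    (4.0, "#ffff00"),
    (5.0, "#ffc800"),
    (6.0, "#ff0000"),
    (7.0, "#8b0000"),
]


def attenuation_colormap():
    """The fixed blue->cyan->yellow->red colormap over 0-7 mm^-1."""
    from matplotlib.colors import LinearSegmentedColormap

    lo, hi = COLOR_SCALE
    anchors = [((v - lo) / (hi - lo), c) for v, c in _CMAP_ANCHORS]
    return LinearSegmentedColormap.from_list("attenuation", anchors, N=256)


def map_to_rgb(emap: EnFaceMap) -> np.ndarray:
    """8-bit RGB render of a map on the fixed scale; missing pixels black."""
    cmap = attenuation_colormap()
    lo, hi = emap.scale
    vals = np.clip((emap.values - lo) / (hi - lo), 0.0, 1.0)
    rgb = (cmap(np.nan_to_num(vals, nan=0.0))[:, :, :3] * 255).round().astype(np.uint8)
    rgb[np.isnan(emap.values)] = 0
    return rgb


def render_map(emap: EnFaceMap, path, upscale: int = 4) -> None:
    """Write a deterministic PNG of the map with a color bar on the right.

    The color bar runs from the scale minimum (bottom) to the maximum (top)
    and is separated from the image by a 2-px black gutter.
    """
    rgb = np.repeat(np.repeat(map_to_rgb(emap), upscale, axis=0), upscale, axis=1)
    h = rgb.shape[0]
    cmap = attenuation_colormap()
    ramp = cmap(np.linspace(1.0, 0.0, h))[:, :3]
    bar = (np.tile(ramp[:, None, :], (1, 8 * upscale, 1)) * 255).round().astype(np.uint8)
    gutter = np.zeros((h, 2 * upscale, 3), dtype=np.uint8)
    img = np.concatenate([rgb, gutter, bar], axis=1)
    Image.fromarray(img).save(path, format="PNG")


def stitch_maps(maps, offsets) -> EnFaceMap:
    """Offset-grid stitching; overlapping pixels are averaged.

    ``offsets`` are (dx, dy) lateral pixel offsets, one per tile; no
    registration is attempted.  All tiles must share channel, pitch and depth
    window.
    """
    maps = list(maps)
    offsets = [tuple(int(v) for v in o) for o in offsets]
    if len(maps) != len(offsets):
        raise ValueError("need one offset per map")
    if not maps:
        raise ValueError("no maps to stitch")
    ref = maps[0]
    for m in maps[1:]:
        if m.channel != ref.channel:
            raise ValueError("cannot stitch maps from different channels")
        if not np.isclose(m.pitch_xy, ref.pitch_xy):
            raise ValueError("cannot stitch maps with different pixel pitch")
        if tuple(m.window_mm) != tuple(ref.window_mm):
            raise ValueError("cannot stitch maps with different depth windows")
    x0 = min(o[0] for o in offsets)
    y0 = min(o[1] for o in offsets)
    x1 = max(o[0] + m.shape[0] for m, o in zip(maps, offsets))
    y1 = max(o[1] + m.shape[1] for m, o in zip(maps, offsets))
    total = np.zeros((x1 - x0, y1 - y0))
    count = np.zeros((x1 - x0, y1 - y0), dtype=int)
    for m, (dx, dy) in zip(maps, offsets):
        sx, sy = dx - x0, dy - y0
        vals = m.values
        ok = np.isfinite(vals)
        total[sx:sx + vals.shape[0], sy:sy + vals.shape[1]] += np.where(ok, vals, 0.0)
        count[sx:sx + vals.shape[0], sy:sy + vals.shape[1]] += ok
    with np.errstate(invalid="ignore"):
        out = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return EnFaceMap(
        values=out,
        channel=ref.channel,
        window_mm=tuple(ref.window_mm),
        pitch_xy=ref.pitch_xy,
        meta={"stitched_tiles": len(maps)},
    )
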