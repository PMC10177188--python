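"""Calibrated CP-OCT phantom generator.

Every downstream stage of the pipeline is testable without instrument data:
this module synthesises two-channel volumes whose mean signal decays
exponentially with depth at class-specific attenuation rates, modulated by
fully developed speckle (unit-mean exponential, multiplicative on intensity)
on top of an additive detection-noise floor.  The five breast-tissue classes
(adipose tissue AT, non-tumorous fibrous connective tissue NCT, hyalinized
tumor stroma HTS, low- and high-density tumor cells LDTC/HDTC) are calibrated
to published median [Q1; Q3] attenuation values per polarization channel.

Between-sample variability of the attenuation coefficient is modelled as a
truncated normal around the class median with sd = IQR/1.349 (the normal-theory
conversion, since only quartiles are published), truncated at median ± 3 sd and
at zero.  The co- and cross-channel values of one sample share a single
standard-normal deviate (comonotone coupling) so each sample's two-channel
pair is coherent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .attenuation import NoiseModel
from .io import CHANNELS, CLASS_LABELS, OCTVolume, ROISet

#: IQR of a normal distribution in units of its standard deviation.
IQR_TO_SD = 1.349

#: Half-width of the truncation interval in standard deviations.
TRUNC_SD = 3.0


@dataclass(frozen=True)
class TissueClassModel:
    """Per-class attenuation calibration and phantom signal parameters.

    Attenuation medians/quartiles are in mm^-1; backscatter values are the
    relative mean surface signal (dimensionless, linear intensity scale).
    """

    label: str
    mu_co_median: float
    mu_co_q1: float
    mu_co_q3: float
    mu_cross_median: float
    mu_cross_q1: float
    mu_cross_q3: float
    backscatter_co: float
    backscatter_cross: float
    roi_count_default: int

    def __post_init__(self) -> None:
        for ch in CHANNELS:
            q1, me, q3 = (self.quartiles(ch)[k] for k in range(3))
            if not (0 < q1 < me < q3):
                raise ValueError(
                    f"{self.label}/{ch}: need 0 < q1 < median < q3, got "
                    f"[{q1}; {me}; {q3}]"
                )

    def quartiles(self, channel: str) -> tuple:
        if channel == "co":
            return (self.mu_co_q1, self.mu_co_median, self.mu_co_q3)
        if channel == "cross":
            return (self.mu_cross_q1, self.mu_cross_median, self.mu_cross_q3)
        raise KeyError(f"unknown channel {channel!r}; expected one of {CHANNELS}")

    def median(self, channel: str) -> float:
        return self.quartiles(channel)[1]

    def sd(self, channel: str) -> float:
        q1, _, q3 = self.quartiles(channel)
        return (q3 - q1) / IQR_TO_SD

    def backscatter(self, channel: str) -> float:
        return self.backscatter_co if channel == "co" else self.backscatter_cross


def default_class_table() -> "dict[str, TissueClassModel]":
    """The five-class calibration table (median [Q1; Q3] per channel, mm^-1)."""
    rows = [
        # label, co: me q1 q3, cross: me q1 q3, backscatter co/cross, n
        ("AT", 3.9, 3.5, 4.2, 0.9, 0.7, 1.2, 0.6, 0.25, 33),
        ("NCT", 5.3, 4.9, 5.8, 3.7, 3.4, 4.2, 1.0, 0.90, 36),
        ("HTS", 5.1, 5.0, 5.4, 4.7, 4.6, 5.1, 1.0, 1.00, 27),
        ("LDTC", 5.0, 4.7, 5.3, 2.2, 1.9, 2.5, 0.9, 0.50, 34),
        ("HDTC", 4.3, 4.1, 4.4, 1.0, 0.7, 1.2, 0.8, 0.30, 35),
    ]
    return {
        label: TissueClassModel(
            label=label,
            mu_co_median=co_me, mu_co_q1=co_q1, mu_co_q3=co_q3,
            mu_cross_median=cr_me, mu_cross_q1=cr_q1, mu_cross_q3=cr_q3,
            backscatter_co=b_co, backscatter_cross=b_cr,
            roi_count_default=n,
        )
        for (label, co_me, co_q1, co_q3, cr_me, cr_q1, cr_q3, b_co, b_cr, n) in rows
    }


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _truncnorm_bounds(cls: TissueClassModel, channels: Sequence[str]) -> tuple:
    """Standard-unit truncation bounds shared by the requested channels.

    The interval is median ± 3 sd, additionally truncated at zero so that
    attenuation draws are always positive.
    """
    lo = -TRUNC_SD
    for ch in channels:
        me, sd = cls.median(ch), cls.sd(ch)
        lo = max(lo, -me / sd)
    return lo, TRUNC_SD


def _sample_std_deviate(lo: float, hi: float, n: int, rng: np.random.Generator):
    # inverse-CDF sampling of the truncated standard normal
    from scipy.stats import norm

    u = rng.uniform(norm.cdf(lo), norm.cdf(hi), size=n)
    return norm.ppf(u)


def sample_roi_mu(cls: TissueClassModel, channel: str, n: int, seed) -> np.ndarray:
    """Draw ``n`` per-sample attenuation values (mm^-1) for one class/channel."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    lo, hi = _truncnorm_bounds(cls, [channel])
    z = _sample_std_deviate(lo, hi, n, rng)
    return cls.median(channel) + cls.sd(channel) * z


def sample_roi_mu_pair(cls: TissueClassModel, n: int, seed) -> "dict[str, np.ndarray]":
    """Comonotone (co, cross) attenuation pairs from a shared deviate."""
    rng = _as_rng(seed)
    lo, hi = _truncnorm_bounds(cls, CHANNELS)
    z = _sample_std_deviate(lo, hi, n, rng)
    return {ch: cls.median(ch) + cls.sd(ch) * z for ch in CHANNELS}


#: Default lateral layout (x0, y0, width, height) on the 128 x 128 grid:
#: an adipose band across the top, the remaining four classes in quadrants.
DEFAULT_LAYOUT = (
    ("AT", (0, 0, 128, 43)),
    ("NCT", (0, 43, 64, 43)),
    ("HTS", (64, 43, 64, 43)),
    ("LDTC", (0, 86, 64, 42)),
    ("HDTC", (64, 86, 64, 42)),
)

#: Truncation-bias bound: exp(-2 mu_min (depth - surface)) must stay below this.
TAIL_TRUNCATION_BOUND = 0.02


@dataclass
class PhantomSpec:
    """Geometry, layout and noise model of one synthetic CP-OCT volume.

    Defaults give a (2, 800, 128, 128) volume: 4 mm deep at 5 um axial pixels
    (deep enough that the unobserved signal tail is negligible for the weakest
    attenuator in the default class table), 1.2 x 1.2 mm lateral field at
    9.375 um pitch, flat tissue surface 0.25 mm below the probe.
    """

    depth_mm: float = 4.0
    delta_z_mm: float = 0.005
    nx: int = 128
    ny: int = 128
    pitch_xy_mm: float = 0.009375
    surface_depth_mm: float = 0.25
    layout: tuple = DEFAULT_LAYOUT
    heterogeneity: str = "patch"  # "patch": per-patch mu draws; "uniform": class medians
    patch_px: int = 32
    speckle: bool = True
    noise_floor_frac: float = 0.01  # of mean surface signal of the brightest class
    seed: int = 0

    @property
    def n_z(self) -> int:
        return int(round(self.depth_mm / self.delta_z_mm))

    @property
    def surface_index(self) -> int:
        return int(round(self.surface_depth_mm / self.delta_z_mm))

    def validate(self, table: Mapping[str, TissueClassModel]) -> None:
        if self.heterogeneity not in ("patch", "uniform"):
            raise ValueError("heterogeneity must be 'patch' or 'uniform'")
        occupied = np.zeros((self.nx, self.ny), dtype=bool)
        mus = []
        for label, (x0, y0, w, h) in self.layout:
            if label not in table:
                raise KeyError(f"layout class {label!r} not in class table")
            if x0 < 0 or y0 < 0 or x0 + w > self.nx or y0 + h > self.ny:
                raise ValueError(f"layout rectangle for {label} out of bounds")
            if occupied[x0:x0 + w, y0:y0 + h].any():
                raise ValueError(f"layout rectangle for {label} overlaps another")
            occupied[x0:x0 + w, y0:y0 + h] = True
            mus += [table[label].median(ch) for ch in CHANNELS]
        mu_min = min(mus)
        tail = np.exp(-2.0 * mu_min * (self.depth_mm - self.surface_depth_mm))
        if tail >= TAIL_TRUNCATION_BOUND:
            raise ValueError(
                f"phantom too shallow: residual signal fraction {tail:.3g} at the "
                f"bottom exceeds {TAIL_TRUNCATION_BOUND} for mu = {mu_min} mm^-1; "
                f"increase depth_mm"
            )


def _split_edges(start: int, size: int, patch: int) -> np.ndarray:
    """Edges of a near-even partition of [start, start+size) into ~patch-px bins."""
    n = max(1, int(round(size / patch)))
    return start + np.round(np.linspace(0, size, n + 1)).astype(int)


def _mu_backscatter_maps(spec, table, rng):
    """Per-column ground-truth attenuation and backscatter maps per channel."""
    mu = {ch: np.full((spec.nx, spec.ny), np.nan) for ch in CHANNELS}
    bsc = {ch: np.zeros((spec.nx, spec.ny)) for ch in CHANNELS}
    for label, (x0, y0, w, h) in spec.layout:
        cls = table[label]
        for ch in CHANNELS:
            bsc[ch][x0:x0 + w, y0:y0 + h] = cls.backscatter(ch)
        if spec.heterogeneity == "uniform":
            for ch in CHANNELS:
                mu[ch][x0:x0 + w, y0:y0 + h] = cls.median(ch)
        else:
            xe = _split_edges(x0, w, spec.patch_px)
            ye = _split_edges(y0, h, spec.patch_px)
            n_patch = (len(xe) - 1) * (len(ye) - 1)
            draws = sample_roi_mu_pair(cls, n_patch, rng)
            k = 0
            for i in range(len(xe) - 1):
                for j in range(len(ye) - 1):
                    for ch in CHANNELS:
                        mu[ch][xe[i]:xe[i + 1], ye[j]:ye[j + 1]] = draws[ch][k]
                    k += 1
    return mu, bsc


def synthesize_volume(
    spec: PhantomSpec,
    table: Mapping[str, TissueClassModel] | None = None,
):
    """Generate one phantom volume.

    Returns
    -------
    vol : OCTVolume
        Observed signal ``S * speckle + <N> * noise_deviate`` with
        ``S(z) = backscatter * exp(-2 mu (z - z_surface))`` below the surface
        and 0 above it.
    truth : dict of 2D arrays
        Per-channel ground-truth attenuation actually used per A-scan column.
    noise : NoiseModel
        The true noise floor <N> per channel fed into the generator.
    """
    table = table if table is not None else default_class_table()
    spec.validate(table)
    rng = np.random.default_rng(spec.seed)
    mu, bsc = _mu_backscatter_maps(spec, table, rng)

    noise_mean = {}
    for ch in CHANNELS:
        brightest = max(table[label].backscatter(ch) for label, _ in spec.layout)
        noise_mean[ch] = spec.noise_floor_frac * brightest

    nz = spec.n_z
    z = (np.arange(nz) * spec.delta_z_mm).astype(np.float64)
    rel_depth = z - spec.surface_depth_mm
    below = rel_depth >= 0

    data = np.empty((len(CHANNELS), nz, spec.nx, spec.ny), dtype=np.float32)
    for ci, ch in enumerate(CHANNELS):
        # columns outside every layout rectangle carry no tissue signal
        # (backscatter 0); their truth-map entries stay NaN
        mu_filled = np.nan_to_num(mu[ch], nan=0.0)
        decay = np.exp(
            -2.0 * mu_filled[None, :, :] * np.where(below, rel_depth, 0.0)[:, None, None]
        )
        signal = np.where(below[:, None, None], bsc[ch][None, :, :] * decay, 0.0)
        if spec.speckle:
            signal = signal * rng.exponential(1.0, size=signal.shape)
        if noise_mean[ch] > 0:
            signal = signal + noise_mean[ch] * rng.exponential(1.0, size=signal.shape)
        data[ci] = signal.astype(np.float32)

    vol = OCTVolume(
        data=data,
        delta_z=spec.delta_z_mm,
        pitch_xy=spec.pitch_xy_mm,
        meta={
            "generator": "cpoct.synth",
            "seed": spec.seed,
            "heterogeneity": spec.heterogeneity,
            "surface_depth_mm": spec.surface_depth_mm,
        },
    )
    noise = NoiseModel(
        mean_noise=noise_mean, region="generator ground truth (additive floor)"
    )
    return vol, mu, noise


def roi_window_px(spec: PhantomSpec, size_mm: float = 0.3) -> int:
    """Window edge in pixels for a given physical ROI size (default 300 um)."""
    return int(round(size_mm / spec.pitch_xy_mm))


def default_fixture_rois(
    spec: PhantomSpec,
    table: Mapping[str, TissueClassModel] | None = None,
    seed: int | None = None,
) -> ROISet:
    """Place the default per-class ROI counts inside their layout rectangles.

    Windows are 300 x 300 um (32 x 32 px at the default pitch).  Non-overlapping
    grid positions are used first; once a region's disjoint capacity is
    exhausted, the remaining windows are placed at seeded uniform positions
    inside the rectangle (windows may then overlap, but each stays fully inside
    its class region).
    """
    table = table if table is not None else default_class_table()
    spec.validate(table)
    present = {label for label, _ in spec.layout}
    missing = set(CLASS_LABELS) - present
    if missing:
        raise ValueError(f"layout lacks class(es) {sorted(missing)}")
    win = roi_window_px(spec)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed if seed is None else seed), 1017])
    )
    rows = []
    rects_by_label: dict[str, list] = {}
    for label, rect in spec.layout:
        rects_by_label.setdefault(label, []).append(rect)
    for label in CLASS_LABELS:
        count = table[label].roi_count_default
        rects = rects_by_label[label]
        for x0, y0, w, h in rects:
            if w < win or h < win:
                raise ValueError(
                    f"region for {label} ({w}x{h} px) cannot host a {win}x{win} px ROI"
                )
        # split the count across this label's rectangles proportionally to area
        areas = np.array([w * h for _, _, w, h in rects], dtype=float)
        alloc = np.floor(count * areas / areas.sum()).astype(int)
        alloc[: count - alloc.sum()] += 1
        k = 0
        for (x0, y0, w, h), n_here in zip(rects, alloc):
            grid = [
                (x, y)
                for x in range(x0, x0 + w - win + 1, win)
                for y in range(y0, y0 + h - win + 1, win)
            ]
            for i in range(n_here):
                if i < len(grid):
                    x, y = grid[i]
                else:
                    x = int(rng.integers(x0, x0 + w - win + 1))
                    y = int(rng.integers(y0, y0 + h - win + 1))
                rows.append(
                    {
                        "roi_id": f"{label}-{k:03d}",
                        "class": label,
                        "x0": x,
                        "y0": y,
                        "width": win,
                        "height": win,
                    }
                )
                k += 1
    import pandas as pd

    return ROISet(table=pd.DataFrame(rows), provenance="generated")


def simulate_class_medians(
    table: Mapping[str, TissueClassModel] | None = None,
    counts: Mapping[str, int] | None = None,
    seed: int = 0,
) -> "dict[str, dict[str, np.ndarray]]":
    """Distribution-level per-sample medians for every class, both channels.

    Draws ``counts[label]`` comonotone (co, cross) pairs per class from the
    calibrated truncated-normal laws; this is the sampling model behind the
    ROC-level simulation.
    """
    table = table if table is not None else default_class_table()
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, np.ndarray]] = {}
    for label, cls in table.items():
        n = cls.roi_count_default if counts is None else counts[label]
        out[label] = sample_roi_mu_pair(cls, n, rng)
    return out
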