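"""ROI median extraction, class summary statistics and inter-group testing.

Each region of interest (a 300 x 300 um window on an en face attenuation map)
is summarised by the median attenuation over its valid pixels; classes are
summarised as Me [Q1; Q3] (linear-interpolation quartiles) plus the mean, and
compared pairwise with two-sided Mann-Whitney U tests under a Bonferroni
correction over the number of pairs tested per channel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .enface import EnFaceMap

logger = logging.getLogger(__name__)

#: an ROI is excluded when fewer than this fraction of its pixels are valid
MIN_VALID_FRAC = 0.5


@dataclass(frozen=True)
class ClassStats:
    """Me [Q1; Q3], mean and count for one class/channel (mm^-1)."""

    class_label: str
    channel: str
    n: int
    median: float
    q1: float
    q3: float
    mean: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("need q1 <= median <= q3")

    def __str__(self) -> str:
        return (
            f"{self.class_label}/{self.channel}: "
            f"{self.median:.3f} [{self.q1:.3f}; {self.q3:.3f}] mm^-1 (n={self.n})"
        )


def _roi_window(roi):
    """(roi_id, x0, y0, width, height) from a row-like ROI record."""
    get = roi.get if isinstance(roi, dict) else lambda k, d=None: getattr(roi, k, d)
    return (
        get("roi_id", "<unnamed>"),
        int(get("x0")),
        int(get("y0")),
        int(get("width")),
        int(get("height")),
    )


def roi_median(emap: EnFaceMap, roi, min_valid_frac: float = MIN_VALID_FRAC) -> float:
    """Median attenuation over the valid pixels of one ROI window.

    Returns NaN when fewer than ``min_valid_frac`` of the window's pixels are
    valid (the ROI is then excluded from class statistics); raises if the
    window is not fully inside the map.
    """
    roi_id, x0, y0, w, h = _roi_window(roi)
    nx, ny = emap.shape
    if x0 < 0 or y0 < 0 or x0 + w > nx or y0 + h > ny:
        raise ValueError(
            f"ROI {roi_id!r} window [{x0},{x0 + w})x[{y0},{y0 + h}) exceeds "
            f"map bounds {nx}x{ny}"
        )
    patch = emap.values[x0:x0 + w, y0:y0 + h]
    valid = np.isfinite(patch)
    if valid.mean() < min_valid_frac:
        return float("nan")
    return float(np.median(patch[valid]))


def extract_roi_medians(maps: Mapping[str, EnFaceMap], rois) -> pd.DataFrame:
    """Long-format table of per-ROI medians for every channel.

    Columns: roi_id, class, channel, median, excluded, reason.
    """
    records = rois.table.to_dict("records") if hasattr(rois, "table") else list(rois)
    rows = []
    for roi in records:
        for ch, emap in maps.items():
            med = roi_median(emap, roi)
            excluded = not np.isfinite(med)
            rows.append(
                {
                    "roi_id": roi["roi_id"],
                    "class": roi["class"],
                    "channel": ch,
                    "median": med,
                    "excluded": excluded,
                    "reason": "" if not excluded else
                    f"fewer than {MIN_VALID_FRAC:.0%} of window pixels valid",
                }
            )
            if excluded:
                logger.info(
                    "ROI %s/%s excluded: insufficient valid pixels", roi["roi_id"], ch
                )
    return pd.DataFrame(rows)


def summarize_class(values, class_label: str = "", channel: str = "") -> ClassStats:
    """Me [Q1; Q3] and mean of a class's per-ROI medians.

    Quartiles use the inclusive linear-interpolation convention (the same one
    that converts published IQRs into the synthetic calibration).
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite values to summarise")
    q1, me, q3 = np.percentile(vals, [25, 50, 75], method="linear")
    return ClassStats(
        class_label=class_label,
        channel=channel,
        n=int(vals.size),
        median=float(me),
        q1=float(q1),
        q3=float(q3),
        mean=float(vals.mean()),
    )


def mann_whitney_p(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact distribution when both samples have n <= 8 and there are no ties;
    otherwise the normal approximation with tie correction and continuity
    correction.  Degenerate all-tied inputs give p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both groups; p = 1", stacklevel=2)
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def compare_groups(groups: Mapping[str, "np.ndarray"]) -> pd.DataFrame:
    """All pairwise Mann-Whitney tests with Bonferroni adjustment.

    ``p_adj = min(1, p * m)`` where m is the number of pairs tested (10 for
    five classes); significance is declared at p_adj < 0.05.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    pairs = list(combinations(labels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        p = mann_whitney_p(groups[a], groups[b])
        p_adj = min(1.0, p * m)
        rows.append(
            {
                "group1": a,
                "group2": b,
                "n1": len(groups[a]),
                "n2": len(groups[b]),
                "p_raw": p,
                "p_adj": p_adj,
                "significant": p_adj < 0.05,
            }
        )
    return pd.DataFrame(rows)


def class_stats_table(roi_medians: pd.DataFrame) -> pd.DataFrame:
    """ClassStats rows for every (class, channel) pair in a medians table."""
    rows = []
    for (label, ch), grp in roi_medians.groupby(["class", "channel"], sort=False):
        vals = grp.loc[~grp["excluded"], "median"]
        cs = summarize_class(vals, class_label=label, channel=ch)
        rows.append(
            {
                "class": cs.class_label,
                "channel": cs.channel,
                "n": cs.n,
                "median": round(cs.median, 3),
                "q1": round(cs.q1, 3),
                "q3": round(cs.q3, 3),
                "mean": round(cs.mean, 3),
            }
        )
    return pd.DataFrame(rows)
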