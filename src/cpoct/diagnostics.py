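"""ROC analysis of ROI medians for tumor/non-tumor discrimination.

Three class-pair comparisons are evaluated per polarization channel, with the
pooled tumor-cell classes (low- plus high-density, "TC") as the clinically
relevant positive group:

* TC vs adipose tissue (tumor takes *higher* attenuation),
* TC vs non-tumorous fibrous connective tissue (tumor takes *lower* values),
* hyalinized tumor stroma vs non-tumorous connective tissue
  (stroma higher in cross, lower in co).

AUC is the trapezoidal area under the empirical ROC staircase (equal to the
pairwise concordance probability with ties counted 1/2); the optimal cutoff
maximises Youden's Se + Sp - 1, reported as the midpoint between adjacent
observed values.  95% CIs: stratified bootstrap for AUC, Wilson for Se/Sp/Ac.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

from .io import CHANNELS

DIRECTIONS = ("lower", "higher")

#: (label, positive class(es), negative class, direction per channel)
PAPER_COMPARISONS = (
    ("TC_vs_AT", ("LDTC", "HDTC"), "AT", {"co": "higher", "cross": "higher"}),
    ("TC_vs_NCT", ("LDTC", "HDTC"), "NCT", {"co": "lower", "cross": "lower"}),
    ("HTS_vs_NCT", ("HTS",), "NCT", {"co": "lower", "cross": "higher"}),
)


def _scores(values, direction: str) -> np.ndarray:
    """Map raw values to scores where larger means more positive-like."""
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    v = np.asarray(values, dtype=float)
    return -v if direction == "lower" else v


def roc_curve(pos, neg, direction: str = "lower"):
    """Empirical ROC staircase.

    Returns (fpr, tpr, thresholds); thresholds are in the original units and
    the curve runs monotonically from (0, 0) to (1, 1).
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    s = np.concatenate([_scores(pos, direction), _scores(neg, direction)])
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    if direction == "lower":
        thr = -thr
    return fpr, tpr, thr


def _auc_concordance(pos, neg, direction: str) -> float:
    """AUC as the rank-based concordance probability (ties counted 1/2)."""
    sp = _scores(pos, direction)
    sn = _scores(neg, direction)
    allv = np.concatenate([sp, sn])
    ranks = rankdata(allv)
    u = ranks[: sp.size].sum() - sp.size * (sp.size + 1) / 2.0
    return float(u / (sp.size * sn.size))


def auc(
    pos,
    neg,
    direction: str = "lower",
    ci: bool = True,
    n_boot: int = 2000,
    seed: int = 0,
):
    """Trapezoidal AUC with an optional stratified-bootstrap 95% CI.

    Returns ``value`` or ``(value, (lo, hi))``.  The trapezoidal area equals
    the Mann-Whitney U statistic divided by n_pos * n_neg.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    fpr, tpr, _ = roc_curve(pos, neg, direction)
    value = float(np.trapezoid(tpr, fpr))
    if not ci:
        return value
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bp = pos[rng.integers(0, pos.size, pos.size)]
        bn = neg[rng.integers(0, neg.size, neg.size)]
        boot[b] = _auc_concordance(bp, bn, direction)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return value, (float(lo), float(hi))


def _confusion_rates(pos, neg, pth: float, direction: str):
    """(se, sp, ac) for the rule 'positive iff value beyond pth'."""
    if direction == "lower":
        tp = int(np.sum(pos < pth))
        tn = int(np.sum(neg >= pth))
    else:
        tp = int(np.sum(pos > pth))
        tn = int(np.sum(neg <= pth))
    se = tp / pos.size
    sp = tn / neg.size
    ac = (tp + tn) / (pos.size + neg.size)
    return se, sp, ac


def optimal_cutoff(pos, neg, direction: str = "lower"):
    """Youden-optimal threshold and its operating point.

    Candidate thresholds are the midpoints between adjacent distinct observed
    values plus sentinels beyond the extremes; ties on Se + Sp break toward
    higher accuracy, then toward the smaller threshold.
    Returns (pth, se, sp, ac).
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    vals = np.unique(np.concatenate([pos, neg]))
    mids = (vals[:-1] + vals[1:]) / 2.0 if vals.size > 1 else np.array([])
    span = max(vals[-1] - vals[0], 1.0)
    cands = np.concatenate([[vals[0] - 0.05 * span], mids, [vals[-1] + 0.05 * span]])
    best = None
    for pth in cands:
        se, sp, ac = _confusion_rates(pos, neg, float(pth), direction)
        key = (se + sp, ac, -pth)
        if best is None or key > best[0]:
            best = (key, float(pth), se, sp, ac)
    _, pth, se, sp, ac = best
    return pth, se, sp, ac


def _wilson(count: int, nobs: int):
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return float(lo), float(hi)


@dataclass
class ROCResult:
    """AUC, optimal cutoff and operating characteristics for one comparison."""

    comparison: str
    channel: str
    direction: str
    auc: float
    auc_ci: tuple
    pth: float
    se: float
    se_ci: tuple
    sp: float
    sp_ci: tuple
    ac: float
    ac_ci: tuple
    n_pos: int
    n_neg: int
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "comparison": self.comparison,
            "channel": self.channel,
            "direction": self.direction,
            "auc": round(self.auc, 3),
            "auc_lo": round(self.auc_ci[0], 3),
            "auc_hi": round(self.auc_ci[1], 3),
            "pth": round(self.pth, 3),
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }
        for name in ("se", "sp", "ac"):
            d[name] = round(getattr(self, name), 3)
            lo, hi = getattr(self, f"{name}_ci")
            d[f"{name}_lo"], d[f"{name}_hi"] = round(lo, 3), round(hi, 3)
        return d


def evaluate_comparison(
    pos,
    neg,
    direction: str,
    comparison: str = "",
    channel: str = "",
    n_boot: int = 2000,
    seed: int = 0,
) -> ROCResult:
    """Full ROC work-up (AUC + CI, Youden cutoff, Se/Sp/Ac + Wilson CIs)."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    value, auc_ci = auc(pos, neg, direction, ci=True, n_boot=n_boot, seed=seed)
    pth, se, sp, ac = optimal_cutoff(pos, neg, direction)
    tp = int(round(se * pos.size))
    tn = int(round(sp * neg.size))
    return ROCResult(
        comparison=comparison,
        channel=channel,
        direction=direction,
        auc=value,
        auc_ci=auc_ci,
        pth=pth,
        se=se,
        se_ci=_wilson(tp, pos.size),
        sp=sp,
        sp_ci=_wilson(tn, neg.size),
        ac=ac,
        ac_ci=_wilson(tp + tn, pos.size + neg.size),
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


def run_paper_comparisons(
    roi_medians: pd.DataFrame, n_boot: int = 2000, seed: int = 0
):
    """The three class-pair comparisons in both channels (six ROCResults).

    ``roi_medians`` is the long-format table from
    :func:`cpoct.roistats.extract_roi_medians` (columns: class, channel,
    median, excluded); excluded ROIs are dropped.  Directions are fixed from
    the class-distribution logic, not auto-detected.
    """
    df = roi_medians
    if "excluded" in df.columns:
        df = df[~df["excluded"]]
    present = set(df["class"])
    results = []
    for label, pos_classes, neg_class, dirs in PAPER_COMPARISONS:
        missing = (set(pos_classes) | {neg_class}) - present
        if missing:
            raise ValueError(f"missing class(es) {sorted(missing)} for {label}")
        for ch in CHANNELS:
            sub = df[df["channel"] == ch]
            pos = sub.loc[sub["class"].isin(pos_classes), "median"].to_numpy()
            neg = sub.loc[sub["class"] == neg_class, "median"].to_numpy()
            results.append(
                evaluate_comparison(
                    pos,
                    neg,
                    dirs[ch],
                    comparison=label,
                    channel=ch,
                    n_boot=n_boot,
                    seed=seed,
                )
            )
    return results


def results_table(results) -> pd.DataFrame:
    """Six-row summary mirroring the AUC / Se / Sp / Ac / Pth layout."""
    return pd.DataFrame([r.to_dict() for r in results])
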