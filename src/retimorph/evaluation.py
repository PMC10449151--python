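"""Performance statistics: confusion metrics, pixelwise segmentation scoring,
width agreement (Bland-Altman), stratified width reports, detection rates.

Undefined metrics (zero denominators) are reported as ``nan`` — an explicit
missing marker, never silently 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "ConfusionCounts",
    "AgreementStats",
    "confusion_metrics",
    "pixelwise_eval",
    "width_agreement",
    "stratified_width_report",
    "match_measurements_to_truth",
    "bland_altman_plot",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman summary of two paired width sets (differences = gt - pred)."""

    mean_diff: float
    sd_diff: float       # sample (n-1) standard deviation
    pearson_r: float
    loa_low: float       # mean_diff - 1.96 * sd_diff
    loa_high: float      # mean_diff + 1.96 * sd_diff
    n: int
    mean_gt: float = float("nan")
    sd_gt: float = float("nan")
    mean_pred: float = float("nan")
    sd_pred: float = float("nan")


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) = TP/(TP+FN), TN/(TN+FP),
    (TP+TN)/(TP+TN+FP+FN).  Zero denominators yield nan."""
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    acc = _ratio(c.tp + c.tn, c.total)
    return sens, spec, acc


def pixelwise_eval(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Per-pixel 2x2 tally of two binary masks (positives = vessel)."""
    p = pred.data if (hasattr(pred, "data") and not isinstance(pred, np.ndarray)) \
        else np.asarray(pred)
    g = gt.data if (hasattr(gt, "data") and not isinstance(gt, np.ndarray)) \
        else np.asarray(gt)
    p = p.astype(bool)
    g = g.astype(bool)
    if p.shape != g.shape:
        raise ValueError("mask shapes differ")
    return ConfusionCounts(
        tp=int((p & g).sum()), fp=int((p & ~g).sum()),
        tn=int((~p & ~g).sum()), fn=int((~p & g).sum()),
    )


def width_agreement(gt_widths, pred_widths) -> AgreementStats:
    """Bland-Altman agreement between paired width sets (gt minus predicted)."""
    gt = np.asarray(gt_widths, dtype=float)
    pr = np.asarray(pred_widths, dtype=float)
    if gt.shape != pr.shape:
        raise ValueError("width vectors must be paired (equal lengths)")
    if gt.size < 2:
        raise ValueError("need at least 2 paired measurements")
    diff = gt - pr
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    if gt.std() == 0 or pr.std() == 0:
        r = float("nan") if not np.allclose(gt, pr) else 1.0
    else:
        r = float(np.corrcoef(gt, pr)[0, 1])
    return AgreementStats(
        mean_diff=mean_diff, sd_diff=sd_diff, pearson_r=r,
        loa_low=mean_diff - 1.96 * sd_diff, loa_high=mean_diff + 1.96 * sd_diff,
        n=int(gt.size),
        mean_gt=float(gt.mean()), sd_gt=float(gt.std(ddof=1)),
        mean_pred=float(pr.mean()), sd_pred=float(pr.std(ddof=1)),
    )


_EMPTY = AgreementStats(float("nan"), float("nan"), float("nan"),
                        float("nan"), float("nan"), 0)


def stratified_width_report(gt_widths, pred_widths, strata) -> pd.DataFrame:
    """Per-stratum agreement table plus an ``all`` row.

    ``strata`` is a label per pair (e.g. the profile regime).  Empty strata
    yield rows with n=0 and nan statistics.
    """
    gt = np.asarray(gt_widths, dtype=float)
    pr = np.asarray(pred_widths, dtype=float)
    st = np.asarray(strata)
    rows = []
    for name in list(pd.unique(st)) + ["all"]:
        sel = np.ones(len(gt), bool) if name == "all" else st == name
        if sel.sum() >= 2:
            s = width_agreement(gt[sel], pr[sel])
        else:
            s = _EMPTY
        rows.append({
            "stratum": name, "n": int(sel.sum()),
            "mean_gt": s.mean_gt, "sd_gt": s.sd_gt,
            "mean_pred": s.mean_pred, "sd_pred": s.sd_pred,
            "mean_diff": s.mean_diff, "sd_diff": s.sd_diff,
            "pearson_r": s.pearson_r,
            "loa_low": s.loa_low, "loa_high": s.loa_high,
        })
    return pd.DataFrame(rows)


def match_measurements_to_truth(measurements, truth, max_dist: float = 2.0) -> pd.DataFrame:
    """Pair valid width measurements with ground-truth centreline points.

    Each valid measurement is matched to the nearest ground-truth centreline
    point within ``max_dist`` px; returns a DataFrame with columns
    ``gt_width``, ``pred_width``, ``av_label``, ``segment_id``, ``row``,
    ``col``.  ``truth`` is a :class:`retimorph.synthetic.GroundTruth`.
    """
    pts = truth.centreline_array()
    if len(pts) == 0:
        return pd.DataFrame(columns=["gt_width", "pred_width", "av_label",
                                     "segment_id", "row", "col"])
    tree = cKDTree(pts)
    rows = []
    for m in measurements:
        if not m.valid:
            continue
        d, j = tree.query(m.centre)
        if d <= max_dist:
            p = truth.centreline_points[j]
            rows.append({"gt_width": p.width, "pred_width": m.width,
                         "av_label": p.av_label, "segment_id": m.segment_id,
                         "row": m.centre[0], "col": m.centre[1]})
    return pd.DataFrame(rows)


def truth_segment_labels(graph, truth, max_dist: float = 3.0) -> dict:
    """Ground-truth A/V label per centreline-graph segment.

    Each segment takes the majority label of the ground-truth centreline
    points nearest its pixels (within ``max_dist`` px); segments with no
    nearby ground truth are omitted.  Pixel-level truth comes from
    :func:`truth_pixel_labels`.
    """
    pix = truth_pixel_labels(graph, truth, max_dist)
    out = {}
    votes: dict[int, list] = {}
    for seg in graph.segments:
        votes[seg.segment_id] = [pix[(int(r), int(c))] for r, c in seg.points
                                 if (int(r), int(c)) in pix]
    for sid, v in votes.items():
        if v:
            out[sid] = "A" if sum(1 for x in v if x == "A") * 2 >= len(v) else "V"
    return out


def truth_pixel_labels(graph, truth, max_dist: float = 3.0) -> dict:
    """Ground-truth A/V label per centreline-graph pixel (nearest GT point)."""
    pts = truth.centreline_array()
    if len(pts) == 0:
        return {}
    tree = cKDTree(pts)
    out = {}
    for seg in graph.segments:
        d, j = tree.query(seg.points.astype(float))
        for (r, c), dist, jj in zip(seg.points, np.atleast_1d(d), np.atleast_1d(j)):
            if dist <= max_dist:
                out[(int(r), int(c))] = truth.centreline_points[jj].av_label
    return out


def bland_altman_plot(gt_widths, pred_widths, path):
    """Write a simple Bland-Altman scatter (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gt = np.asarray(gt_widths, float)
    pr = np.asarray(pred_widths, float)
    stats = width_agreement(gt, pr)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter((gt + pr) / 2, gt - pr, s=4, alpha=0.4)
    ax.axhline(stats.mean_diff, color="red")
    for y in (stats.loa_low, stats.loa_high):
        ax.axhline(y, color="red", linestyle="--")
    ax.set_xlabel("mean of widths (px)")
    ax.set_ylabel("difference gt - predicted (px)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return stats
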