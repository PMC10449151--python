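"""Study-style evaluation drivers on synthetic cohorts.

Each function regenerates its inputs from a seed, runs one pipeline stage at
the package defaults, and scores it against the generator's ground truth —
the synthetic analogue of validating each stage against human annotations.
Problem sizes follow the validation designs these protocols mirror where the
design is known (a 500/500 quality split, a 100-image optic-disc set,
a 50/15/35 train/validation/test split for A/V work) and desk-scale synthetic
cohorts elsewhere.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .av import (classify_pixels, aggregate_segments, extract_av_features,
                 fit_av_classifier, retention_sweep)
from .evaluation import (ConfusionCounts, confusion_metrics,
                         match_measurements_to_truth, pixelwise_eval,
                         truth_pixel_labels, truth_segment_labels,
                         width_agreement)
from .optic_disc import locate_disc
from .quality import fit_quality_classifier, quality_features
from .segmentation import segment_vessels
from .synthetic import SyntheticSpec, generate_quality_cohort, generate_retina
from .widths import extract_centrelines, measure_widths

__all__ = [
    "segmentation_benchmark",
    "width_benchmark",
    "quality_benchmark",
    "train_av_model",
    "av_benchmark",
    "disc_benchmark",
]

REGIMES = ("normal", "central_reflex", "low_contrast")


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(2 ** 31, size=n)]


def _retina(seed: int, regime: str = "normal", size: int = 512, **overrides):
    spec = dataclasses.replace(SyntheticSpec.default((size, size), seed=seed),
                               profile_regime=regime, **overrides)
    return generate_retina(spec)


def segmentation_benchmark(n_images: int = 20, seed: int = 0, size: int = 512) -> dict:
    """Pooled pixelwise segmentation scores, with and without post-processing."""
    pooled = {True: np.zeros(4, dtype=np.int64), False: np.zeros(4, dtype=np.int64)}
    post_never_adds_fp = True
    for s in _sub_seeds(seed, n_images):
        img, truth = _retina(s, size=size)
        fp_by_post = {}
        for post in (False, True):
            mask = segment_vessels(img, pre=True, post=post,
                                   fovea_centre=truth.fovea_centre)
            c = pixelwise_eval(mask.data, truth.vessel_mask)
            pooled[post] += np.array([c.tp, c.fp, c.tn, c.fn])
            fp_by_post[post] = c.fp
        if fp_by_post[True] > fp_by_post[False]:
            post_never_adds_fp = False
    out = {"n_images": n_images, "post_never_adds_fp": post_never_adds_fp}
    for post, tag in ((True, "post"), (False, "nopost")):
        tp, fp, tn, fn = (int(v) for v in pooled[post])
        sens, spec, acc = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
        out[f"sensitivity_{tag}"] = sens
        out[f"specificity_{tag}"] = spec
        out[f"accuracy_{tag}"] = acc
    return out


def width_benchmark(n_per_regime: int = 2, seed: int = 0, size: int = 512) -> pd.DataFrame:
    """Paired (ground truth, measured) widths across the three profile regimes."""
    frames = []
    seeds = _sub_seeds(seed, n_per_regime * len(REGIMES))
    for i, regime in enumerate(REGIMES):
        for j in range(n_per_regime):
            img, truth = _retina(seeds[i * n_per_regime + j], regime, size)
            mask = segment_vessels(img, fovea_centre=truth.fovea_centre)
            graph = extract_centrelines(mask)
            ms = measure_widths(img, graph, mask=mask,
                                disc_centre=truth.disc_centre,
                                disc_radius=truth.disc_radius)
            df = match_measurements_to_truth(ms, truth)
            df["regime"] = regime
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def quality_benchmark(n_train: int = 500, n_test: int = 500, seed: int = 0,
                      size: int = 256) -> dict:
    """Train/test quality classification on disjoint synthetic cohorts."""
    s_train, s_test = _sub_seeds(seed, 2)

    def featurise(n, s):
        feats, labels = [], []
        for spec in generate_quality_cohort(n, s, image_size=(size, size)):
            img, truth = generate_retina(spec)
            mask = segment_vessels(img, pre=True, post=False)
            feats.append(quality_features(mask))
            labels.append(truth.quality_label)
        return feats, labels

    ftr, ltr = featurise(n_train, s_train)
    fte, lte = featurise(n_test, s_test)
    model = fit_quality_classifier(ftr, ltr, folds=5, seed=seed)
    tp = fn = tn = fp = 0
    for f, l in zip(fte, lte):
        pred = model.classify(f).label
        if l == "inadequate":
            tp += pred == "inadequate"
            fn += pred == "adequate"
        else:
            tn += pred == "adequate"
            fp += pred == "inadequate"
    sens, spec, acc = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
    return {"model": model, "sensitivity": sens, "specificity": spec,
            "accuracy": acc, "n_test": n_test,
            "n_inadequate_test": tp + fn}


def train_av_model(n_images: int = 6, seed: int = 0, size: int = 512):
    """Fit the feature-backend A/V model on synthetic images with known labels."""
    frames, labels = [], []
    for i, s in enumerate(_sub_seeds(seed, n_images)):
        img, truth = _retina(s, REGIMES[i % len(REGIMES)], size)
        mask = segment_vessels(img, fovea_centre=truth.fovea_centre)
        graph = extract_centrelines(mask)
        feats = extract_av_features(img, graph, mask=mask)
        pix = truth_pixel_labels(graph, truth)
        lab = np.array([pix.get((r, c), "?")
                        for r, c in zip(feats.row, feats.col)])
        keep = lab != "?"
        frames.append(feats[keep])
        labels.append(lab[keep])
    return fit_av_classifier(frames, labels, seed=seed)


def av_benchmark(model, n_test: int = 6, seed: int = 1000, size: int = 512,
                 swap: bool = False) -> dict:
    """Segment- and pixel-level A/V scores plus the retention curve."""
    seg_probs_all, seg_truth_all = {}, {}
    pixel_hits = pixel_total = 0
    offset = 0
    for i, s in enumerate(_sub_seeds(seed, n_test)):
        img, truth = _retina(s, REGIMES[i % len(REGIMES)], size,
                             swap_av_intensity=swap)
        mask = segment_vessels(img, fovea_centre=truth.fovea_centre)
        graph = extract_centrelines(mask)
        probs = classify_pixels(img, graph, model, mask=mask)
        res = aggregate_segments(probs, graph, threshold=0.5)
        truth_seg = truth_segment_labels(graph, truth)
        truth_pix = truth_pixel_labels(graph, truth)
        for sid, p in res.segment_probs.items():
            if sid in truth_seg:
                seg_probs_all[offset + sid] = p
                seg_truth_all[offset + sid] = truth_seg[sid]
        offset += 1 + max(res.segment_probs, default=0)
        for k, p in probs.items():
            if k in truth_pix and p != 0.5:
                pixel_hits += ("A" if p > 0.5 else "V") == truth_pix[k]
                pixel_total += 1
    curve = retention_sweep(seg_probs_all, seg_truth_all).to_frame()
    return {
        "curve": curve,
        "segment_accuracy": float(curve.av_accuracy.iloc[0]),
        "pixel_accuracy": pixel_hits / pixel_total if pixel_total else float("nan"),
        "n_segments": len(seg_probs_all),
        "n_pixels": pixel_total,
    }


def disc_benchmark(n_images: int = 100, seed: int = 0, size: int = 512) -> dict:
    """Detection rate: predicted centre inside the true disc."""
    hits = 0
    for i, s in enumerate(_sub_seeds(seed, n_images)):
        img, truth = _retina(
            s, REGIMES[i % len(REGIMES)], size,
            degradation="uneven_illumination" if i % 4 == 0 else "none")
        loc = locate_disc(img)
        err = np.hypot(loc.centre[0] - truth.disc_centre[0],
                       loc.centre[1] - truth.disc_centre[1])
        hits += err <= truth.disc_radius
    return {"detection_rate": hits / n_images, "hits": hits, "n": n_images}
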