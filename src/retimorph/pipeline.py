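"""End-to-end pipeline: quality gate, then segmentation, optic disc,
centrelines, widths and A/V classification, with a JSON run manifest.

Inadequate-quality images stop at the gate with the quality result recorded —
downstream morphometry is only meaningful on adequate images.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .av import AVModel, aggregate_segments, classify_pixels
from .config import PipelineConfig, config_to_toml
from .io import RetinalImage, read_image, write_mask, write_widths_csv
from .optic_disc import locate_disc
from .quality import QualityModel, quality_features, label_from_probability
from .segmentation import estimate_fovea, segment_vessels
from .widths import extract_centrelines, measure_widths

logger = logging.getLogger("retimorph")

__all__ = ["RunManifest", "run_pipeline"]


@dataclasses.dataclass
class RunManifest:
    input_path: str
    config_hash: str
    version: str
    completed_stages: list
    outputs: dict           # stage -> file path
    quality: dict
    timestamps: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _hash_config(config: PipelineConfig) -> str:
    return hashlib.sha256(config_to_toml(config).encode()).hexdigest()[:16]


def run_pipeline(image_path, config: PipelineConfig, quality_model: QualityModel,
                 av_model: AVModel, out_dir,
                 fovea_centre: tuple[float, float] | None = None) -> RunManifest:
    """Run the full analysis on one image, writing artefacts to ``out_dir``.

    Stage order: quality gate -> segmentation -> optic disc -> centrelines ->
    widths -> A/V.  An inadequate image stops after the gate.  Outputs are
    deterministic for a fixed image and config (timestamps live only in the
    manifest).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timestamps = {"start": time.time()}
    manifest = RunManifest(
        input_path=str(image_path), config_hash=_hash_config(config),
        version=__version__, completed_stages=[], outputs={}, quality={},
        timestamps=timestamps,
    )

    image = read_image(image_path, config.working_long_side)
    img = image.data

    # Quality gate: features from segmentation *without* post-processing, at
    # the gate's fixed working resolution (features are resolution-dependent).
    from .quality import QUALITY_WORKING_LONG_SIDE
    gate_mask = segment_vessels(img, config.segmentation, pre=True, post=False,
                                working_long_side=QUALITY_WORKING_LONG_SIDE)
    feats = quality_features(gate_mask)
    p_bad = float(quality_model.p_inadequate(feats.as_array())[0])
    qres = label_from_probability(feats, p_bad, config.quality.threshold)
    manifest.quality = {
        "area": feats.area, "fragmentation": feats.fragmentation,
        "complexity": feats.complexity, "p_inadequate": qres.p_inadequate,
        "score": qres.score, "label": qres.label,
        "threshold": qres.threshold_used,
    }
    qpath = out / "quality.json"
    with open(qpath, "w") as fh:
        json.dump(manifest.quality, fh, indent=1)
    manifest.outputs["quality"] = str(qpath)
    manifest.completed_stages.append("quality")
    if qres.label == "inadequate":
        logger.info("image %s gated out (score %.3f)", image_path, qres.score)
        timestamps["end"] = time.time()
        manifest.save(out / "manifest.json")
        return manifest

    fovea = fovea_centre if fovea_centre is not None else estimate_fovea(img)
    mask = segment_vessels(img, config.segmentation, pre=True, post=True,
                           fovea_centre=fovea)
    mpath = out / "mask.png"
    write_mask(mask, mpath)
    manifest.outputs["mask"] = str(mpath)
    manifest.completed_stages.append("segmentation")

    disc = locate_disc(img, config.disc, fovea_centre=fovea)
    dpath = out / "disc.json"
    with open(dpath, "w") as fh:
        json.dump({"centre": list(disc.centre),
                   "radius_estimate": disc.radius_estimate,
                   "confidence": disc.confidence}, fh, indent=1)
    manifest.outputs["disc"] = str(dpath)
    manifest.completed_stages.append("optic_disc")

    graph = extract_centrelines(mask)
    measurements = measure_widths(img, graph, config.widths, mask=mask,
                                  disc_centre=disc.centre,
                                  disc_radius=disc.radius_estimate)
    wpath = out / "widths.csv"
    write_widths_csv(measurements, wpath)
    manifest.outputs["widths"] = str(wpath)
    manifest.completed_stages.append("widths")

    probs = classify_pixels(img, graph, av_model, config=config.av, mask=mask)
    av = aggregate_segments(probs, graph, threshold=0.5)
    av_rows = [{"segment_id": sid, "p_arteriole": p,
                "label": av.segment_labels[sid]}
               for sid, p in sorted(av.segment_probs.items())]
    apath = out / "av.csv"
    pd.DataFrame(av_rows, columns=["segment_id", "p_arteriole", "label"]) \
        .to_csv(apath, index=False)
    manifest.outputs["av"] = str(apath)
    manifest.completed_stages.append("av")

    timestamps["end"] = time.time()
    manifest.save(out / "manifest.json")
    return manifest
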