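# retimorph

Automated retinal vessel morphometry for colour fundus photographs: image
quality gating, unsupervised vessel segmentation, vessel width measurement,
arteriole/venule classification and optic disc localisation — plus the full
evaluation machinery (confusion metrics, Bland–Altman agreement,
threshold/retention sweeps) used to validate such pipelines against human
annotations.

Retinal vessels are the one part of the microvasculature visible
non-invasively, and their geometry (calibre, in particular) tracks
cardiovascular and neurological risk.  Epidemiological use requires turning
thousands of fundus images into per-vessel quantitative measures without a
human in the loop, and the package follows the standard architecture for that
task:

* **Quality gate** — global shape features of the segmented vessel map
  (area, fragmentation, complexity) feed an RBF-SVM whose output is flipped
  into a quality score in [0, 1]; an image is *inadequate* when
  score ≤ 0.48 and is excluded from downstream analysis.
* **Segmentation** — a multi-scale line detector (response =
  window mean − oriented line mean, maximised over 12 orientations and line
  lengths 5/9/15 px) followed by hysteresis thresholding realised as
  morphological reconstruction; pre-processing suppresses bright pixels,
  post-processing removes the fovea and small spurious objects.
* **Widths** — centrelines by thinning, per-point orientation by local PCA,
  edge points as the zero-crossings of the second derivative of the
  perpendicular intensity profile, width = ‖edge_left − edge_right‖.
* **A/V classification** — per-centreline-pixel arteriole probabilities from
  profile features encoding the graders' criteria (venules darker, reflex
  stronger in arterioles, relative calibre), averaged per vessel segment
  (between bifurcations/crossovers) and labelled with strict thresholds
  (A iff p > t, V iff 1 − p > t, else unclassified), giving the
  accuracy-vs-retention trade-off across t ∈ {0.5, …, 0.9}.
* **Optic disc** — shade correction then constrained maximum-intensity
  search; widths inside the disc zone are excluded.

No study images ship with the package.  Instead `retimorph.synthetic`
generates fundus-like images with *exact* ground truth — per-pixel vessel
masks, per-point centreline widths and A/V labels, disc/fovea positions and
quality labels — spanning three vessel-profile regimes (normal, central
reflex, low contrast) and quality degradations (blur, uneven illumination,
occlusion).  Every stage is validated against that ground truth; see
`docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import numpy as np
from retimorph import (SyntheticSpec, generate_retina, segment_vessels,
                       extract_centrelines, measure_widths,
                       match_measurements_to_truth, width_agreement, locate_disc)

img, truth = generate_retina(SyntheticSpec.default(seed=7))
mask = segment_vessels(img, fovea_centre=truth.fovea_centre)
graph = extract_centrelines(mask)
ms = measure_widths(img, graph, mask=mask,
                    disc_centre=truth.disc_centre, disc_radius=truth.disc_radius)
paired = match_measurements_to_truth(ms, truth)
stats = width_agreement(paired.gt_width, paired.pred_width)
disc = locate_disc(img)

print(f"vessel pixels: {mask.data.mean():.3f} of image")
print(f"segments: {len(graph.segments)}, valid width measurements: "
      f"{sum(m.valid for m in ms)}")
print(f"width agreement (truth - measured): {stats.mean_diff:+.2f} "
      f"({stats.sd_diff:.2f}) px, r = {stats.pearson_r:.3f}, n = {stats.n}")
print(f"limits of agreement: [{stats.loa_low:+.2f}, {stats.loa_high:+.2f}] px")
err = np.hypot(disc.centre[0] - truth.disc_centre[0],
               disc.centre[1] - truth.disc_centre[1])
print(f"optic disc error: {err:.1f} px (true radius {truth.disc_radius:.0f})")
```

prints

```
vessel pixels: 0.093 of image
segments: 321, valid width measurements: 442
width agreement (truth - measured): +0.53 (1.55) px, r = 0.839, n = 427
limits of agreement: [-2.50, +3.57] px
optic disc error: 1.8 px (true radius 40)
```

Reading: 9.3% of the image is segmented as vessel; 442 centreline sites
yielded a plausible width; the measured widths agree with the rasterised
truth to +0.53 px on average with an SD of 1.55 px (the Bland–Altman limits
bound 95% of per-profile differences), and the disc was localised to within
2 px of its true centre.

## Command line

`retimorph` exposes each stage and the full pipeline:

```sh
retimorph simulate --n 20 --seed 7 --regime central_reflex --out data/
retimorph quality-train --n 200 --seed 0 --out quality.json
retimorph av-train --n 8 --seed 0 --out av.json
retimorph segment data/retina_000.png --out mask.png
retimorph widths data/retina_000.png --mask mask.png --out widths.csv
retimorph classify-av data/retina_000.png --mask mask.png --model av.json --out av.csv
retimorph optic-disc data/retina_000.png
retimorph run data/retina_000.png --quality-model quality.json \
              --av-model av.json --out run_000/
```

`run` applies the quality gate first (inadequate images stop there with the
result recorded), then segmentation → disc → centrelines → widths → A/V,
writing a JSON manifest alongside the artefacts.  Configuration is one TOML
file (`retimorph write-config --out cfg.toml`); every subcommand with
randomness takes `--seed` and is reproducible under it.

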