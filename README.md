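# colonypat

Noninvasive, quantitative morphological monitoring of pluripotent
stem-cell colony cultures from phase-contrast images — a process
analytical technology (PAT) toolkit for colony-based cell manufacture.

## The problem

Adherent pluripotent colonies cannot be sampled destructively at the
frequency process control needs. Their morphology, however, is visible
continuously: a healthy colony shows a dark, dense **central core**, an
intermediate **core periphery**, and low-density spread **edge cells**,
and the balance of these zones shifts quickly under poor feeding or a
differentiation stimulus. This package quantifies that balance from
ordinary phase-contrast images and turns it into process metrics.

## The method

1. **Taught libraries.** Four reference libraries (default 200 patches
   each) of 64×64 example patches are "taught" — one per class:
   background, central core, core periphery, edge cells. Each patch is
   summarised by a 31-dimensional texture descriptor (intensity
   statistics, 16-bin histogram, gradient statistics, rotation-invariant
   LBP histogram), z-scored over the pooled library.
2. **Tile classification.** Each image is tiled into non-overlapping
   64×64 squares; every tile is assigned the majority class among its
   k = 5 nearest library patches (Euclidean distance on z-scored
   features). Per-class **coverage** is the percentage of analysed tiles
   per class.
3. **Statistics on coverage.** For per-image coverages x₁..xₙ,
   SEM = s/√n and the 95 % CI half-width is 1.96·s/√n, so a target
   half-width *h* maps to a required image sample size
   n = ⌈(1.96 σ/h)²⌉. Two monitored arms separate at the earliest
   timepoint where a Welch t-test gives p ≤ α for three consecutive
   frames.
4. **Per-colony analysis.** Colonies are 4-connected components of
   non-background tiles; size is the equivalent circular diameter
   d = 2√(A/π). Initial size is related to the fraction converting to
   edge morphology under a differentiation stimulus, and
   diameter-threshold triggers fire a process action when the mean
   colony diameter crosses a specification.
5. **Count regression.** Cell counts are regressed on coverage: one
   predictor (total coverage, a confluence analogue) versus three
   (core, periphery, edge separately), the latter capturing the very
   different cell densities of the zones.

A seeded synthetic scene generator (`colonypat.synthetic`) renders
colonies with these three concentric zones, growth, and outside-in edge
conversion after a stimulus — with exact per-pixel ground truth — so
every stage of the pipeline is testable end to end.

## Worked example

```python
from colonypat import (build_default_library, classify_image,
                       render_frame, SceneSpec, ColonySpec)

library = build_default_library(200, seed=1)      # teach 4 x 200 patches
spec = SceneSpec(image_height_px=768, image_width_px=768,
                 colonies=(ColonySpec(center_rc=(384, 384),
                                      initial_diameter_um=600.0),))
image, truth = render_frame(spec, time_h=0.0, seed=7)
labelmap, coverage = classify_image(image, library)
print({k: round(v, 1) for k, v in coverage.percentages.items()})
```

prints

```
{'background': 89.6, 'central_core': 2.8, 'core_periphery': 5.6, 'edge': 2.1}
```

i.e. the 600 µm colony occupies ~10 % of the 1.5 mm field, split into
its three morphological zones (the exact mask truth is 12.0 % total cell
coverage — the difference is tile quantisation at the colony rim). The numbered drivers under `analysis/` run the full
studies; for example `python analysis/04_colony_size_response.py` prints

```
Pearson r = -0.788 (slope -0.079 %/um): the smaller the colony,
the larger the fraction converting to edge cell morphology ...
trigger at 300 um fired at 20.0 h; edge response slope 5.57 %/h
trigger at 750 um fired at 4.0 h; edge response slope 1.92 %/h
```

— small colonies convert completely (100 % edge) and fast, while large
colonies retain a pluripotent-morphology core that caps their measured
conversion near 70 %.

## Layout

- `src/colonypat/` — the library: `synthetic` (scene generator),
  `library` (taught patch libraries), `classify` (tile k-NN), `stats`
  (precision/separation), `colonies` (segmentation, tracking, triggers),
  `counts` (regressions, flask CV), `scenarios` (standard study
  conditions), `cli` (`colonypat simulate` / `classify`).
- `analysis/` — numbered narrative drivers writing tables to `results/`.
- `docs/methods.md` — model, parameters, and design notes.
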