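# larvamorph

Outline morphometrics and morphospace-occupation analysis for larval
insect shapes, built around the study system of long-nosed antlion larvae
(Psychopsidae, the silky lacewings) from Cretaceous and Eocene ambers and
the modern fauna.

## The problem

Fossil insect larvae usually cannot be placed in a species-level taxonomy,
so diversity through time is instead measured on *shape*: each specimen's
outline (head capsule with stylets, head capsule alone, stylets, or the
whole body) becomes a point in a low-dimensional morphospace, and the area
a fauna occupies there is a proxy for its morphological diversity
(disparity). For long-nosed antlions this approach shows the Cretaceous
fauna occupying the largest area, the Eocene less, and the modern fauna
the least — a decline over the last ~100 million years — while specimen
accumulation curves that keep rising indicate the known Cretaceous sample
is still far from exhausting the original diversity.

`larvamorph` implements that entire analysis chain as a tested library:

1. **Outline ingestion** (`larvamorph.outlines`) — closed contours from
   CSV point lists, SVG paths (Béziers flattened), or Freeman chain
   codes; validation, counter-clockwise orientation, arc-length
   resampling.
2. **Elliptic Fourier analysis** (`larvamorph.efa`) — exact
   Kuhl–Giardina line-segment integration of closed polygons,

   x(t) = A₀ + Σₙ aₙ cos(2πnt/T) + bₙ sin(2πnt/T),
   y(t) = C₀ + Σₙ cₙ cos(2πnt/T) + dₙ sin(2πnt/T),

   with first-harmonic-ellipse normalization (size, rotation, starting
   point; optional reflection standardization) and exact inversion.
3. **Morphospace** (`larvamorph.morphospace`) — covariance PCA of the
   normalized coefficient matrix with a deterministic eigensolver,
   effective-PC rules (≥2% variance share, or Kaiser-style
   greater-than-mean), and shape reconstruction along PC axes.
4. **Occupation statistics** (`larvamorph.occupation`) — per-group convex
   hulls and areas in PC1×PC2, convex-polygon overlaps, old-vs-expanded
   subset ratios, and specimen-accumulation (rarefaction) curves with a
   normalized tail slope as the saturation statistic.
5. **Specimen metadata** (`larvamorph.specimens`) — the packaged
   98-specimen inventory (72 Cretaceous, 14 Eocene, 12 extant; 44 + 2
   newly described fossils with PED repository numbers, body lengths and
   labrum-morphotype labels), analysis-inclusion filtering, and
   head-measurement utilities.
6. **Synthetic cohorts** (`larvamorph.synthetic`) — a parametric
   generator of larva-like head+stylet outlines in six labrum morphotype
   families (triangular, pentagonal, trident, bifid trident, pentadent,
   broad) with per-epoch dispersion control, providing ground truth for
   every pipeline stage.
7. **Pipeline, figures, CLI** (`larvamorph.pipeline`, `larvamorph.viz`,
   `larvamorph` command) — an end-to-end runner with reproducible on-disk
   artifacts, morphospace/accumulation/size-panel figures, and a thin
   command-line front end (`run`, `simulate`, `rarefy`).

## A worked example

`examples/03_occupation_and_saturation.py` simulates three epochs whose
shape dispersion falls 3:2:1 from the Cretaceous to the present, fits one
shared morphospace, and quantifies occupation:

```
hull areas in PC1 x PC2 (score units^2):
  Cretaceous n= 64 area=0.3004
  Eocene     n= 13 area=0.0293
  extant     n= 12 area=0.0067
the dispersion gradient (3:2:1) makes Cretaceous occupation largest.

Eocene-within-Cretaceous overlap: 0.0293 (100% of the Eocene area)

old-subset hull 0.1733 vs full hull 0.3005 -> ratio 0.58: the added
specimens expand occupation by 42%.

accumulation tail slope (relative area gain per specimen): 0.0059
no saturation: new specimens still enlarge the morphospace
```

Reading the numbers: the Cretaceous hull is an order of magnitude larger
than the extant one (the simulated decline); the Eocene hull lies wholly
inside the Cretaceous one; a random "previously known" half of the
Cretaceous sample covers only 58% of the final area, so the other half
genuinely expanded the morphospace; and the accumulation curve's tail
slope (0.6% area gain per added specimen) is above the 0.5% saturation
label — sampling has not yet levelled off.

The other examples walk through outline ingestion and EFA
(`01_outline_and_efa.py`), morphospace construction and PC interpretation
(`02_morphospace.py`), the packaged specimen inventory
(`04_specimen_inventory.py`), and the full artifact-writing pipeline
(`05_full_pipeline.py`). Each is runnable as `python examples/<name>.py`.

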