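# minkograde

Texture-based grading of brain-tumour tissue from atomic force
microscopy (AFM) height maps, using Minkowski functionals and a
genetic-programming (GP) symbolic classifier.

## The problem

WHO grading of astrocytic tumours from histomorphology suffers from
high inter-observer variability.  AFM scans of routine histopathology
sections provide a quantitative alternative: the dense meshwork of
fine neuropil fibres seen in low-grade astrocytoma (grade II)
progressively degenerates into a pulpy mass riddled with irregular
large cavities in glioblastoma multiforme (grade IV).  The formation
of these dark, neuropil-free areas is a measurable morphological
marker.

`minkograde` implements the complete analysis chain for this marker:

1. **Preprocessing** — first-order (plane) flattening of the height
   map, then rank-based histogram equalization to the full dynamic
   range of 256 gray levels.
2. **Level-set analysis** — the equalized image is thresholded at
   every gray level *t* (foreground: pixels ≥ *t*), giving a stack of
   256 binary level sets.  For each level the three 2-D Minkowski
   functionals are computed: covered area *A(t)*, contour length
   *P(t)* (foreground/background pixel edges, exterior counted as
   background), and the Euler characteristic

   χ(t) = #(8-connected foreground objects) − #(4-connected holes),

   evaluated exactly by 2×2 quad-pattern counting,
   χ = (Q₁ − Q₃ − 2·Q_D)/4.
3. **Feature reduction** — each curve pair (χ(t), P(t)) is reduced to
   15 named scalar descriptors (extremum values and positions,
   zero-crossing, steepness, areas under the curves, FWHM, centroid).
4. **Group statistics** — per-grade mean curves with 1σ bands,
   extreme-value ratios between grades, and gray-level bands where the
   two groups' 1σ bands do not intersect (a single band-mean feature
   already separates the grades well).
5. **Classification** — a strongly-typed GP evolves Boolean expression
   trees over the 15 features (logical, comparison and arithmetic
   operators with protected division), evaluated by repeated
   stratified k-fold cross-validation and an optional 24-configuration
   parameter grid.

The clinical image set behind the method is not public, so the package
ships a seeded synthetic generator that emulates the two texture
classes (fibre meshwork + nuclei + small cavities vs. sparse pulpy
texture + large irregular cavities) and exercises the pipeline end to
end.

## Worked example

```python
from minkograde import GPConfig, PipelineConfig, run_pipeline
from minkograde.pipeline import SimulateBlock

cfg = PipelineConfig(
    out_dir="demo",
    seed=7,
    simulate=SimulateBlock(n_gradeII=12, n_gradeIV=12, image_size=128),
    gp=GPConfig(max_generations=70, max_tree_length=25,
                n_folds=6, n_runs=5, seed=7),
)
report = run_pipeline(cfg)
```

prints per-stage timings and writes `curves.csv`, `features.csv`,
`stats.csv`, `band_report.json` and `classification_report.json` into
`demo/`.  The run report contains (abridged):

```json
{
  "band": {
    "band_feature_cv_accuracy": 0.9167,
    "extreme_ratios": {"min_ratio_rounded": 1.21, "max_ratio_rounded": 1.21},
    "nonoverlap_bands": [[2, 39], [141, 186], [243, 253]]
  },
  "classification": {"best_run_accuracy": 0.9583, "mean_accuracy": 0.8667}
}
```

Reading: the grade II group's mean Euler curve dips 1.21× deeper than
grade IV's (its fine texture punches many more holes into the low
level sets), the two groups' 1σ bands are disjoint over three
gray-level windows, the mean Euler value over the widest window alone
classifies 92% of samples in 6-fold CV, and the best of five repeated
GP cross-validation runs reaches 96% test accuracy.  The best evolved
model is a readable expression over the named features, e.g.
`(euler_zero_crossing > 156.4) XOR (…)`.

The same stages are available from the shell:

```sh
minkograde simulate --grade II --n 10 --seed 1 --size 256 --out-dir imgs
minkograde preprocess --in imgs/II_000.txt --out eq.png
minkograde curves --in eq.png --out curves.csv
minkograde features --curves curves.csv --out features.csv
minkograde run --out-dir demo --seed 7
```

## Scope

Single-channel 8/16-bit PNG/TIFF and whitespace-delimited text
matrices in; CSV/JSON out.  Proprietary AFM vendor formats, 3-D
Minkowski functionals, sub-pixel (Crofton/marching-squares) boundary
measures and multi-class grading are out of scope.  See
`docs/methods.md` for the model details, parameter defaults and known
limitations.
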