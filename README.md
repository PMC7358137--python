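# simap — sentinel interaction mapping

Quantifying human gene variant function by yeast growth.  A variant of a
human gene is overexpressed in sensitized yeast deletion strains
("sentinels") whose growth is impaired in proportion to the variant's
residual activity; colony sizes on paired-control mini-arrays and rate
constants from calibrated liquid growth curves are then scaled into a
loss-of-function (LoF) score:

```
                 median(area_variant − area_paired_wt)           k_var − k_wt
lof_array  =  ─────────────────────────────────────────   lof_liquid = ────────────
                 median(area_vector − area_paired_wt)            k_vec − k_wt
```

so wt-like variants score ≈0, complete LoF variants ≈1, and
gain-of-function variants (hyperactive protein, growth defect beyond wt)
score negative.  The package is aimed at groups running growth-based
variant phenotyping screens: it implements SDL hit calling with replicate
confidence classes and control-screen filtering, 1536-spot mini-array
layout construction and paired-difference scoring, a colony-grid image
quantifier, cubic absorbance calibration and exponential rate fitting,
cross-assay agreement, and per-sentinel logistic-regression pathogenicity
prediction — plus a generative model of the entire study with planted
ground truth, so every statistic can be validated against a known answer.

## Worked example

```python
from simap import pipeline, evaluate
from simap.synthetic import SimulationConfig

study = pipeline.simulate_study(SimulationConfig(seed=1))   # 100 variants, 8 sentinels
scores = pipeline.run_miniarray(study["miniarray_spots"], study["layouts"])
liquid = pipeline.run_liquid(study["growth_curves"], study["calibration"])

best = pipeline.most_sensitive(study["sentinels"]).strain_id
matrix = evaluate.align_scores(
    [pipeline.miniarray_variant_scores(scores, best),
     pipeline.liquid_variant_scores(liquid)],
    ["miniarray", "liquid"])
r = evaluate.pearson_matrix(matrix).loc["miniarray", "liquid"]
print(f"solid vs liquid: r^2 = {r*r:.3f} over {len(matrix)} variants")

rep = evaluate.recovery_report(
    pipeline.miniarray_variant_scores(scores, best), study["truth"])
print(f"LoF recovery ({best}): RMSE = {rep['overall']['rmse']:.3f}")
```

prints

```
solid vs liquid: r^2 = 0.989 over 100 variants
LoF recovery (sent07): RMSE = 0.055
```

— the two assays agree closely on the same simulated panel, and the most
sensitive sentinel (dynamic range d = 0.6) recovers the planted
loss-of-function levels to ±0.06 on the 0–1 LoF scale.

The same workflow is available as numbered drivers (`analysis/01_simulate.py`
… `05_evaluate.py`), which narrate each stage and write their tables under
`results/`, and as a CLI:

```sh
simap simulate --seed 1 --out run/data
simap sdl       --dataset run/data --out run/sdl
simap miniarray --dataset run/data --out run/ma
simap liquid    --dataset run/data --out run/lq
simap eval      --dataset run/data --miniarray-scores run/ma/miniarray_scores.tsv \
                --liquid-scores run/lq/liquid_scores.tsv --out run/eval
```

Every output directory contains a verbatim YAML echo of the configuration
(thresholds, window, seed) that produced it.

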