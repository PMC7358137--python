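# Methods

## The assay being modeled

Sentinel interaction mapping (SIM) measures the activity of a human gene
variant by how much it slows the growth of sensitized yeast deletion
strains.  A genome-scale synthetic dosage lethality (SDL) screen first finds
deletion strains whose growth is specifically impaired by overexpression of
the functional gene; those strains — *sentinels* — then act as quantitative
reporters: a variant that retains activity recapitulates the growth defect,
a loss-of-function (LoF) variant does not, and a hyperactive variant causes
a defect beyond the wild type's.

Two readouts are implemented.  On solid medium, variants are pinned as
1536-spot mini-arrays in which every variant spot sits next to a wt-control
spot; the area difference of each pair cancels plate-level size bias, and
the LoF score of a variant in a sentinel background is

```
lof_array = median(area_variant − area_paired_wt)
          ─────────────────────────────────────────
            median(area_vector − area_paired_wt)
```

In liquid culture, absorbance curves are calibrated to relative cell number,
fitted to y = a·e^{kx} over the log-phase window, and scaled as

```
lof_liquid = (k_var − k_wt) / (k_vec − k_wt)
```

Both formulas anchor the scale at 0 for wt-like variants and 1 for the
empty-vector control (complete loss); gain-of-function (GoF) variants score
negative.  These anchors are identities of the formulas and are tested as
such.

## The generative model

The synthetic study plants a known truth so every downstream estimate can be
scored against it.  Each variant carries a functional level `f` (0 complete
loss, 1 wt-like, up to 1.3 for GoF alleles).  Both assays respond linearly
to activity:

* array: expected spot area `m_plate · base_s · max(1 − d_s·f, 0.05)`,
  where `d_s` is the sentinel's dynamic range (fractional area lost at full
  activity), `m_plate` a plate-level multiplicative bias, and 0.05 a floor
  keeping GoF spots measurable;
* liquid: true rate `k(f) = k0·(1 − r·f)` per hour.

Under this model the true LoF of a variant is exactly `1 − f` in both
assays, which is what makes the noiseless-closure tests sharp.

Noise choices, and why:

* **Spot and plate noise are multiplicative lognormal** (`σ_spot`,
  `σ_plate`, both 0.1 by default).  Colony areas are positive and plate
  biases act multiplicatively — which is precisely the error structure the
  adjacent-pair design cancels.  The noise factors are mean-one
  (`exp(σz − σ²/2)`), so expected areas equal the model values and the σ=0
  limit is exactly noise-free.  Real colony-area noise structure is not
  published for this assay; lognormal is a modeling decision, not a claim.
* **A600 read noise is additive Gaussian** (`σ_a600 = 0.002`), the typical
  scale of plate-reader repeatability.
* **Reference labels flip symmetrically** with probability 0.1 by default:
  clinical annotations are imperfect in both directions, and noisy labels
  make the classifier benchmarks conservative.

Growth in liquid follows an exponential `N0·e^{kt}` capped at a carrying
capacity of 50× the inoculum.  A smooth logistic with that capacity would
bend the curve appreciably within the standard 6-h window at realistic
rates (k ≈ 0.25–0.5/h), biasing fitted rate constants by several percent
and breaking the exact `lof = 1 − f` closure that the package guarantees in
the noiseless limit; the capped-exponential form keeps the early phase
exactly exponential while still saturating long simulations.  Growth-curve
defaults follow standard practice for this assay: inoculum at A600 0.125,
readings every 4 min, 8 technical replicate wells per variant, fit window
(0, 6) h.

The calibration cubic defaults to `y = 0.5x³ + 0.2x² + x` — monotone on the
simulated range, linear at low density and super-linear at high density as
real A600/cell-number calibrations are.  Curves are generated by inverting
the cubic (bracketed root finding to ~1e-14), so the pipeline's
fit-then-evaluate path is tested against a true inverse.

What the generator does **not** emulate: colony morphology, agar and
plate-edge nutrient artifacts, condensation/evaporation in liquid, lag
phase, and any sequence-level structure in the variants.  Passing tests
therefore demonstrate correctness of the *analysis* under a plausible error
model, not robustness to every failure mode of real plates.

## Layouts

Standard SGA geometry is fixed at 32×48 = 1536 spots, 0-based row-major
coordinates.

* **mi-1** (sentinel validation): up to 45 deletion strains from a 96-well
  source dish, each well pinned to a 4×4 block; strains occupy 2 wells each
  and the neutral control 8, giving 16 replicates per (strain, query) and
  64 for the control on a full plate (44·2·16 + 2·64 = 1536, asserted by
  the constructor).  Query rows alternate wt / variant, so each variant
  spot pairs with the wt spot one row above.  One plate per variant query.
* **mi-2** (variant screening): 8 sentinels in 4-row bands; within a band,
  even columns are wt controls and odd columns queries (7 variants + the
  empty vector, cycling), giving 12 replicates per variant/sentinel and 768
  pairs per plate.  The pair is the horizontal neighbor in the same
  2-column block.

The pairing orientation differs between the two designs; it is recorded
explicitly in each layout's pairing map and scorers never assume it.  A
variant panel larger than 7 per plate is chunked across plates (100
variants → 15 plates), padding the final plate's spare query slots with
extra wt spots.

## Statistical choices

* All significance tests are **two-tailed unpaired Student's t-tests with
  pooled variance** (Welch's version available behind a flag).  Degenerate
  conventions: two constant equal samples → p = 1; constant unequal →
  p = 0.
* Mini-array p-values compare raw colony areas (variant spots vs the
  wt-control spots of the same sentinel and plate); LoF scaling uses the
  **median** of paired differences, with no further outlier handling.
* No multiple-testing correction by default — significance sets use raw
  P < 0.05, as is conventional for this assay; Benjamini–Hochberg is
  available as an option.
* Sentinel ranking uses the **arithmetic** mean of p-values across the
  chosen loss-of-function conditions (a geometric mean would order by the
  product and be dominated by the single smallest p); ties break by larger
  mean |median difference|.
* SDL hit calling is the joint criterion p < α **and** ratio below an
  experimentally defined cutoff (default 0.8, always echoed to the log);
  colony sizes are normalized per plate by the median of non-zero areas.
  Replicate-confidence classes count replicate-level calls over the 6
  replicates (2 screens × 3): 6/6 high, 4–5/6 low; a single colony pair per
  replicate supports no test statistic, so the replicate-level call is the
  ratio criterion alone.
* The liquid assay's headline rate uses the mean-normalized 8-replicate
  curve; per-well fits feed the GoF test (t-test of per-well rate constants
  vs the wt wells), declared when the variant is significantly *slower*.
* Exponential fits run nonlinear least squares on calibrated, t0-normalized
  cell numbers (normalizing raw A600 would not linearize cell number),
  initialized from the log-linear regression; non-convergence falls back to
  the log-linear estimate, flagged.  The window is fixed at (0, 6) h; a
  rolling log-linear-R² auto-detector exists behind a flag.
* Pathogenicity models are single-feature logistic regressions per sentinel
  (scikit-learn, lbfgs, C = 1), stratified 70-30 split (stratification
  avoids single-class test sets at n ≈ 80), metrics computed from the
  held-out confusion counts via the exact identities, plus mean accuracy of
  a stratified fivefold CV.  Undefined metrics (zero denominators) are
  reported as NaN, never 0.
* Pearson matrices are pairwise-complete with a 3-pair minimum;
  zero-variance columns give undefined cells.
* External fitness metrics are mapped onto the LoF scale by the unique
  affine transform through two anchors (metric value for wt-like → 0, for
  null → 1); anchors are configuration values, no clipping.

## Numerical details and degenerate inputs

* Cubic inversion: bracketed Brent root finding, xtol 1e-14; the bracket is
  expanded by doubling and monotonicity (3ax² + 2bx + c > 0) is verified on
  the final range.  Inversion followed by evaluation is an identity to
  better than 1e-6 relative (tested to ~1e-12).
* A sentinel whose realized vector-control median difference is below 1 px
  on a plate has no usable dynamic range there; scoring a single pair of
  comparisons raises a degenerate-sentinel error, while whole-study scoring
  keeps the comparison (median, p) and reports the LoF as NaN with a
  warning.  The analogous liquid guard is |k_vec − k_wt| < 1e-6.
* Strains whose −gene control colonies are all dead are excluded from SDL
  scoring (dead strains cannot report), with a warning.
* Replicate wells with a zero initial reading cannot be t0-normalized and
  are dropped; fewer than 4 surviving replicates is an error.
* Disk rendering for synthetic plate images picks a sub-pixel center offset
  and a squared-radius threshold between consecutive ranked lattice
  distances, so the rasterized pixel count matches the requested area to
  ±2% (usually exactly); quantification thresholds each grid cell at the
  midpoint of its 10th/90th intensity percentiles, which is robust to
  plate-level brightness drift but requires colonies to occupy a
  non-trivial fraction of the cell window.

## Problem sizes and reproducibility

The bundled study simulates 100 variants (¼ each complete-LoF, partial,
wt-like, GoF), 8 sentinels with dynamic ranges evenly spaced over
[0.1, 0.6], 12 array replicates, 8 liquid wells per variant, and a
2000-strain SDL screen with 20 planted defects (δ ∈ [0.3, 0.6]) in 3
replicates × 2 screens — sizes chosen to match the structure of a real
single-gene study while keeping a full end-to-end run in seconds.  Every
stochastic step draws from `numpy.random.default_rng` seeded from the
single configuration seed, so identical configurations give bit-identical
outputs; run directories include a verbatim YAML echo of the configuration.

## Known limitations

* The linear area/activity and rate/activity responses are the simplest
  model consistent with the assay's design; real sentinels saturate
  (observed in the most sensitive strains, which cannot resolve activity
  above wt) and the floor parameter only crudely captures that.
* Low-dynamic-range sentinels (d ≈ 0.1) are close to the degenerate
  boundary by construction: their LoF estimates are noisy and occasionally
  undefined on a plate, which mirrors the behaviour of insensitive
  deletion strains rather than being a defect of the scorer.
* The SDL false-positive calibration assumes approximately lognormal spot
  noise; heavy-tailed contamination (pinning failures) would inflate the
  nominal test level and is not modeled.
* The image quantifier assumes registered, pre-gridded images; no automatic
  grid detection is attempted.
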