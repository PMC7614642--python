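# Methods

## The measurement problem

The analysis asks whether the voxel pattern at an event boundary — the TR
that ends a scene of a continuous narrative — resembles the patterns of
temporally remote *past* scenes more than those of *future* scenes. A naive
correlation between boundary and scene patterns confounds three sources of
similarity: genuine reinstatement of past information, similarity between
the scenes themselves (the boundary resembles its own scene, which
resembles other scenes), and temporal autocorrelation of the fMRI signal.
The design of every statistic in this package follows from how each
confound behaves in time:

- Scene-by-scene similarity is a function of scene identity, not of
  temporal direction, so it contributes identically to the past and future
  parts of the boundary × scene similarity matrix. The reactivation index
  `mean(past cells) − mean(future cells)` cancels it exactly (the package
  asserts this with injected stable scene patterns).
- Signal autocorrelation is a function of temporal distance, and the
  boundary sits asymmetrically between its past (the scene it ends, plus a
  possible silence) and its future. After high-pass filtering the
  autocorrelation alternates in sign with lag, and the near-diagonal cells
  of the similarity matrix inherit that structure. Removing the `d`
  diagonals nearest the main diagonal (d/2 past, including the boundary's
  own scene, and d/2 future) excises the contaminated cells; `d` is
  calibrated per design by the null simulation described below.

## Pipeline conventions

- **Timing.** Scene tables are integer TRs, 1-based and inclusive;
  `boundary_tr = offset_tr`. A seconds→TR loader floors onsets and ceils
  offsets. All event timings are shifted by `hrf_shift_trs = 4` TRs (6 s at
  TR 1.5 s) to accommodate the hemodynamic delay; boundary and scene
  windows shift together so they never alias.
- **Scene interiors.** A TR contributes to a scene representation when it
  is ≥ `gap_trs = 5` TRs from the previous boundary (the TR before the
  scene's onset, for a first scene) and from the scene's own boundary,
  inclusive distances. A contiguous scene of L TRs therefore retains
  `max(0, L − 2·gap + 1)` TRs, making 10 TRs the shortest analysable scene
  at the default gap — which is exactly the movie-style exclusion
  threshold. The two anchors are one TR asymmetric (the previous boundary
  lies outside the scene, the own boundary inside), so time reversal maps
  interiors onto interiors shifted by one TR; sizes and boundary distances
  are preserved.
- **Exclusions.** Scenes shorter than the threshold, filler labels, and
  the final scene of each run are flagged, never renumbered, so diagonal
  offsets keep their meaning; their rows/columns are simply absent from the
  similarity matrix.
- **Similarity.** Pearson correlations across voxels, Fisher-z transformed
  with |r| clipped at 1 − 1e−15 so degenerate perfect correlations stay
  finite. Zero-variance patterns mask their cells with a warning. The main
  diagonal (offset 0, the just-ended scene) is always removed. Offsets are
  `row_scene − col_scene`; positive = past.
- **Diagonal removal.** `d = 10` for the movie-style design (contiguous
  scenes, median 51 s), `d = 6` for the story-style design (60–84 s scenes
  with 4.5–6 s silences). Between-participant analyses (scene patterns from
  one brain against boundary patterns averaged over the other brains, or
  vice versa) need no removal beyond the main diagonal because the two
  signals are independent. The flush-control variant additionally removes
  the post-boundary scene (offset −1) to rule out "flushing" of the
  just-ended event as the driver.
- **Congruency.** In the two-narrative design a boundary inherits its
  scene's narrative; joint-narrative scenes are congruent with everything.
  The interaction index contrasts congruent-minus-incongruent means across
  the past and future parts, with unweighted means per cell class.
- **Control timepoints.** The balanced control contrasts the boundary
  index with the average of indices computed ±`c` TRs around the boundary
  (c = 10 movie-style, 5 story-style, the latter constrained by the short
  silences). Each single control is biased; the biases are symmetric in
  time and cancel in the average.
- **Timecourses.** TR-resolved indices sample the boundary pattern at the
  literal scene-end TR plus offsets −3..+12 (no HRF shift), restricted to
  boundaries of scenes ≥ 20 TRs; the scalar summary is
  `mean(offsets +1..+6) − mean(offsets −1, 0)`.
- **Context model.** Scene texts are case-folded, punctuation-stripped,
  stop-word-filtered word counts over the stimulus-wide vocabulary,
  normalised to probability vectors. A fixed stop-word list ships in the
  package (sha256 exposed, substitutable) — results should not hinge on the
  exact list. Context similarity is `1 − JSD` with base-2 logs, so it lies
  in [0, 1] with unit diagonal. Time-bias diagnostics report the Pearson
  correlation of upper-triangle similarities with a time covariate (the
  pair-mean serial position by default — the convention is exposed because
  other choices are defensible) and a two-sample t contrasting pairs that
  involve a designated scene group. Scene-set exclusions (e.g. the first
  15 movie scenes, the last 15 story scenes) are applied to the context
  model and inherited by the neural matrix inside the modulation
  statistics.
- **Context modulation.** `atanh(r_past) − atanh(r_future)` where each r
  correlates unmasked neural cells with the matching context similarities;
  the pairwise minimum word count can be partialled out of both variables
  by residualisation (default on for the variable-scene-length movie
  design, off for the constant-length story design). The interaction form
  contrasts congruent-minus-incongruent correlation differences across
  parts. Modulation statistics use neural matrices with only the main
  diagonal removed: the index's diagonal removal exists to fix a *mean*
  bias, whereas the modulation is a correlation, and the simulations below
  show its bias is a (sign-stable, quantified) property of this convention.
- **Group inference.** One-sample t with a sign-flip null and add-one
  p-values, `p = (1 + #{null ≥ obs}) / (1 + B)` — exactly valid at finite
  B; one-tailed tests count same-direction exceedances only (used where
  the hypothesis is directional, e.g. context modulation). Cluster-mass
  correction thresholds the group t-map at the two-tailed `voxel_p`
  critical value (df = n−1), clusters by 26-connectivity (6/18 available),
  and compares cluster masses (Σ|t|) with the permutation distribution of
  the maximal mass. Fisher's method combines dataset p-values
  (−2Σln p ~ χ²(2k)); printed one-sided caps like "p < 0.001" enter as
  0.001. Cohen's D is the group mean over the sample SD. The mega-analysis
  fits dataset-indicator intercepts and tests their average with per-
  subject sign flips. Every stochastic operation requires an explicit
  seed; identical seeds give identical output.

## The synthetic-data program

The generator reproduces the structure the analysis is sensitive to, not
the physiology:

- **Noise.** Per voxel, Gaussian spectral coefficients scaled so power ∝
  1/f (DC removed), inverse-transformed and normalised to unit variance.
  Voxels are independent; there is no spatial structure, physiological
  noise, or hemodynamic model beyond the fixed 4-TR shift.
- **Filtering.** The default high-pass is a sharp spectral (DCT) cutoff.
  This was a deliberate choice over the smoother Gaussian running-line
  variant (also provided): the analysis's bias structure is driven by the
  *alternating* sign of the post-filter autocorrelation, which a hard
  cutoff produces and a Gaussian running line does not. Under the
  running-line filter the raw (main-diagonal-only) null is weakly
  *negatively* biased and the control timepoints are barely displaced; the
  documented calibration (positive raw bias, centring at d = 10/6,
  opposite-displaced controls, residual interaction bias) emerges under the
  sharp filter. Both filters are exact on constants and (running line)
  lines, and the running-line implementation is verified against an
  independent scipy.ndimage construction.
- **Timings.** Movie-style: contiguous scenes, log-normal lengths (median
  51 s, σ = 0.5 in log-space) clipped to [12, 184.5] s, 48 scenes by
  default. Story-style: lengths from a Beta(2, 4.4) scaled onto [60, 84] s
  — mean 67.5 s, matching the printed median; a uniform law on that range
  cannot fit 45 scenes plus silences into the 2,242-TR scan — with 4.5–6 s
  silences and narratives A/B alternating over scenes 1–30, JOINT after.
  The suite redraws timings until they fit the run, then applies the
  style's exclusions.
- **Scene patterns and planted signal.** Stable scene patterns (uniform,
  1/f-derived, or narrative templates plus noise) are added to every TR of
  each scene *after* filtering — they model representations in the analysed
  signal space; adding them before the sharp filter would ring each pattern
  across scene edges and manufacture a bias the construction does not
  intend. Planted reactivation adds a chosen remote past scene's
  representation at each boundary TR (+HRF shift), scaled by `weight`
  times the data SD; targets are a fixed lag or the context-most-similar
  remote past scene.
- **Scene texts.** Topic-block multinomials (same-topic scenes share
  words; a mixture topic models a joint narrative) plus an optional
  positional-vocabulary `drift` whose sliding window makes word overlap
  decay with scene lag, as the local context of a real story does. The
  canonical story-style context stimulus uses two alternating topics,
  drift 0.3, a 400-word vocabulary and 120 words per scene.

### What the null suite shows

`null_bias_suite` repeats (default 500 times; the statistics stabilise well
below that) the full within-participant pipeline on cohorts of 10 subjects
× 120 voxels of pure filtered noise and records the group index per
repetition. With the canonical configurations it reproduces, from scratch:
positively biased raw indices in both designs; distributions centred on
zero (99% Monte-Carlo CI) after removing 10/6 diagonals; ±10-TR control
indices displaced in opposite directions with a centred balanced contrast
(which direction is displaced which way depends on the realised scene
timings); an interaction-mode index that stays biased after removal in the
alternating-narrative design; and a negative mean for the context-
modulation interaction null under the canonical story-style stimulus. That
last sign is the least portable result: it reflects the interplay of the
oscillating near-diagonal artefact with the congruency-asymmetric local
word overlap of adjacent scenes, is stable across text draws under the
main-diagonal-only convention, but becomes draw-dependent if extra
diagonals are removed before correlating.

Passing these suites shows the *statistics* behave as designed under the
stated noise model; it says nothing about motion, physiology, spatial
smoothness, inter-subject registration error, or any other property of real
data the generator does not model.

## Problem sizes

The shipped tests run the two null suites at 500 repetitions (about a
minute each on one CPU), power/false-positive checks over 30 cohorts, and
sign-flip calibration over 250 simulated datasets; the acceptance script
runs one 500-repetition movie-style suite. The simulation engine is
float32 (Monte-Carlo SE ~1e−5 dwarfs single-precision error) and is
asserted, in the tests, to agree with the step-by-step float64 public API.

## Known limitations

- Within-scene TRs are averaged without per-TR normalisation; whether any
  z-scoring should precede averaging is left to the caller's preprocessing.
- The interaction index uses unweighted cell-class means; weighting by
  class size is a defensible alternative.
- The mega-analysis is a documented stand-in (dataset-dummy GLM with
  per-subject sign flips) for richer second-level designs.
- Real-data runs require deposited scene-timing tables; the package
  validates but cannot invent per-scene timings, and the printed time-bias
  correlations of real stimuli (e.g. r ≈ 0.69) are properties of those
  stimuli that synthetic texts do not target.
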