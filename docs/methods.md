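# Methods

This note records the statistical procedures, the generative model
behind the synthetic screens, the defaults and why they were chosen,
and the known limits of what the tests demonstrate.

## The analysis model

An incPRINT screen measures, for every (protein, RNA) pair, duplicate
luciferase luminescence L₁, L₂ (interaction) and duplicate ELISA
E₁, E₂ (expression), all non-negative RLU. The pipeline treats the pair
(protein, RNA) as the unit of analysis; wells and plates are carriers
of provenance only (no spatial/edge correction is applied).

**Status codes.** Every pair ends in exactly one state: 1 = analyzed,
2 = low expression, 3 = discordant replicates, 4 = single replicate
(retained and flagged; partial plates are common in practice). Filters
are idempotent because each derives its threshold from the pool of
records it could ever affect (statuses {1,2} for expression, {1,3} for
discordance), not from its own survivors.

**Expression threshold.** The summary statistic is the mean of
log₂(E + 1) over available replicates (pseudocount 1 RLU because true
zeros occur). The default *valley* policy histograms the summaries with
Freedman–Diaconis bin width (clipped to 10–200 bins), smooths with a
3-bin moving average, finds local maxima, and cuts at the minimum
between the two largest modes; if the histogram is unimodal it falls
back to a fixed quantile, default 0.20 — chosen because real screens
retain roughly 80% of the library (≈2405 of ~3000) — and a degenerate
all-zero ELISA column is an error. The exact numeric cut-off used in
published screens is not recoverable; only the policy shape is.

**Discordance.** The ratio is mean/s.d. on raw luminescence with the
sample (n−1) standard deviation of a pair, s.d. = |a−b|/√2
(`sd_ddof=0` selects the population variant). s.d. = 0 ⇒ ratio = +∞
(identical replicates are never discordant). The high-score exemption
("both duplicates high") has no published numeric definition; the
default level is the 95th percentile of replicate-averaged luminescence
within the dataset — scale-free, so the core decision is invariant
under rescaling both replicates.

**Normalization.** Common binders are the top-200 analyzed proteins by
mean luminescence in the MS2-tag-only control, ranked after the QC
filters, ties at the boundary broken lexicographically for
determinism. In each dataset the factor is the median mean-luminescence
of the binders *found* there (absent/filtered binders are skipped,
guarded by a minimum overlap of 50). Scores are plain ratios, not
log-ratios; the transform is a positive rescaling, so within-dataset
ranking is exact and the found binders' median normalized score is 1 by
construction.

**Hit calling.** Because ~97% of proteins do not interact, the analyzed
score distribution is essentially background plus a sparse upper tail.
The robust cutoff median + 5·1.4826·MAD estimates the null location and
scale without being dragged by the tail; it is computed per RNA dataset
(score dispersion differs between RNAs). MAD = 0 is an error directing
the user to manual mode. Whether published cutoffs were fixed scores or
per-dataset quantiles is unknowable; both are exposed.

**Enrichment.** Domains are presence/absence per protein. The
two-sample pooled-proportion z-test compares the hit fraction carrying
a domain with the library fraction; z² is algebraically the uncorrected
Pearson chi-square of the 2×2 table, which the tests exploit as an
oracle. The z-test treats hits and library as independent samples even
though hits ⊂ library — that is the convention of the published
"proportion test" and is kept deliberately. The correction method
behind "corrected P" is not published: Benjamini–Hochberg is the
default (many domains, FDR control is the plausible reading),
Bonferroni selectable, and the choice is recorded in output. The
enriched flag additionally requires ≥ 3 occurrences among interactors,
which suppresses the z-test's anticonservatism for rare domains — but
does not eliminate it: a rare domain carried by exactly 3 hits can
reach a nominally tiny normal-approximation p, so isolated extra flags
beside a planted signal are expected and the null false-flag rate
(measured across seeded null screens) stays well under alpha. The
library denominator defaults to the full screened library; an
expressed-only background is available since expression filtering
changes the background. Hits-vs-complement testing is antisymmetric
(swapping the samples flips z exactly).

## The synthetic screen generator

Everything multiplicative and lognormal, since plate luminescence spans
decades and real replicate scatter is log-log:

* **Expression** E is a two-mode log₂-normal mixture: low mode
  N(4.5, 1.0), expressed mode N(12.5, 2.0) (log₂ RLU), 20% low. The
  wide expressed mode reflects the decades-spanning expression of a
  3000-construct tagged library and is what makes ELISA replicate R²
  high.
* **ELISA replicate** = E·ε′, luciferase replicate =
  gain·B·A·C(E)·ε, with constant background B = 100 RLU,
  ε, ε′ lognormal with CV 0.25 (replicate_cv = 0 ⇒ a fully
  deterministic screen).
* **Capture saturation** C(E) = E/(E + K), K = 128 RLU ≈ the valley
  between the expression modes. Above threshold C ≈ 1, which decouples
  luminescence from ELISA among expressed proteins (|r| ≲ 0.16); below
  it C collapses, which is why unexpressed proteins carry no usable
  interaction signal.
* **Planted affinity** A: 20× for each test RNA's interactors; 10× for
  the 200 common binders *in the control dataset only*. The model's
  assumption is that tag binders dominate the naked-tag construct,
  where nothing competes with the MS2 stem-loops, while on a long test
  RNA the tag is a small, partly occluded feature — so in test datasets
  binders behave as background (a `binder_carryover` multiplier exposes
  intermediate behaviour). This choice makes the control's
  normalization factor ~10× the test datasets' and keeps called hits
  equal to the RNA-specific interactors, matching the 2–3% hit rate of
  real screens; with carryover the binders would dominate every hit
  list, which real screens do not show.
* **Planting rules.** Interactors and common binders are drawn among
  robustly expressed proteins (E ≥ 512 RLU); the two sets may overlap;
  the interactor count is `frac_true_interactors` (2.5%) of that
  eligible pool (~2300), giving ~58 planted per RNA ≈ 2.4% of analyzed.
* **Domains**: 120 Pfam accessions with truncated power-law library
  frequencies (min(0.3, 0.3/j)), independent Bernoulli presence. Planted
  enrichment biases interactor sampling toward carriers of one chosen
  mid-frequency domain per test RNA (weight 8); an empty `enriched`
  mapping yields a null screen for the enrichment stage.
* **Dilution series** scales the *excess* affinity,
  A_eff = 1 + (A−1)·f, so factor 1 is the identity and f → 0 converges
  to background, emulating reduced tagged-RNA vector doses.

Scale parameters were calibrated once, analytically, against the
envelope the generator must reproduce (replicate R² ≈ 0.87 luciferase /
≈ 0.98 ELISA, luminescence–ELISA independence, ~80% of the library
expressed, 2–3% hits) and then frozen; they are artifact parameters,
not estimates of any real screen's physics.

**What the generator does not emulate**: plate spatial artifacts (edge
effects, drift), heavy-tailed outlier wells, cross-well contamination,
correlated domain co-occurrence, binder/interactor affinity spread
(planted effects are single-valued), and any dependence between
interaction strength and expression beyond capture saturation. Passing
recovery tests therefore shows the pipeline is correct and well
calibrated under these idealized conditions, not that real screens have
~100% sensitivity.

## Numerical choices

* Replicate reproducibility (R²) is Pearson on log₂ median-normalized
  replicate values (non-positive values dropped); raw-scale Pearson is
  selectable but with multiplicative CV-0.25 noise it is bounded near
  0.89 and cannot reach the ELISA reproducibility seen on the log-log
  scale.
* The discordance exemption and all quantiles use NumPy's default
  linear interpolation; the expression filter flags strictly below the
  threshold, so an all-identical column flags nothing.
* Ties: binder ranking and the ranked dot-plot order break score ties
  by protein_id (stable mergesort); enrichment tables sort by corrected
  p then accession.
* Degenerate inputs raise typed errors (all-zero ELISA, zero-variance
  correlation vectors, zero MAD, zero binder median, insufficient
  binder overlap) rather than returning silent defaults.
* Comparing the z-test against its permutation null uses the pooled
  two-sample label permutation with the mid-p tie convention, the
  standard comparator for an uncorrected z on a discrete table.
* Determinism: one `numpy.random.default_rng(seed)` with a fixed draw
  order; identical (config, seed) produce byte-identical written
  datasets, and pipeline reruns into the same directory are
  checksum-identical.
* Tests and examples run the generator at 400–600 proteins where the
  property under test is scale-free, and at the full 3000-protein
  default where study-condition calibration is the point.

## Limitations

* The published screens' exact thresholds (ELISA cut-off, interaction
  cutoff) are not recoverable; the package reproduces the policy
  shapes, not the historical numbers.
* The proportion z-test is anticonservative for rare domains; the
  ≥3-occurrence rule is a blunt guard, and an exact/hypergeometric
  option would be the natural extension.
* Cross-RNA comparison requires expression in *all* compared screens;
  proteins expressed in only a subset are silently outside the matrix
  (by design, but worth remembering when comparing hit lists).
* No GO-term enrichment and no direct-vs-indirect binding distinction —
  both outside what the assay's readout can support.
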