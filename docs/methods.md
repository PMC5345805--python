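# Methods

This note records the models, the defaults and the judgment calls behind
the package, in the spirit of a statistical-software methods appendix.  It
states no empirical claim that the test suite or `scripts/acceptance.py`
does not itself compute.

## Misregulation calling

A gene is *misregulated* when |FC| clears 1.5 and the BH-adjusted p-value
is below 0.05.  Fold changes use the signed-ratio convention (ratio r ≥ 1
stored as r, r < 1 as −1/r), which makes the ±1.5 thresholds symmetric and
leaves the open interval (−1, 1) unoccupied.  Three choices needed fixing:

* **FDR procedure.** "FDR-corrected" is implemented as Benjamini–Hochberg
  step-up, the default of essentially all differential-expression tooling;
  other `statsmodels` methods can be selected.
* **Threshold boundary.** Inclusive (|FC| ≥ 1.5) by default; a strict-mode
  flag switches to strictly-greater, under which a gene sitting exactly at
  the threshold is called unchanged.  The difference has measure zero for
  continuous data but tests need one fixed rule.
* **Replicate handling.** Signed fold changes are averaged across
  replicates *before* calling, with the replicate-combined test's p-value
  taken as given (the package never re-derives differential-expression
  p-values; they are inputs).  If replicate signs disagree and the
  arithmetic mean lands in the impossible interval (−1, 1), it is snapped
  to the nearest boundary (±1.0, i.e. exactly "no change"); such genes are
  far below the calling threshold either way.

## The directional pathway test

The test statistic is the plain sum of ternary values over a pathway.  Its
null distribution is empirical: size-matched gene sets drawn uniformly
without replacement from the measured transcriptome excluding the
pathway's own genes, 100,000 draws per pathway by default.

* **Per-pathway versus size-class nulls.** Self-exclusion makes the null
  pathway-specific even for pathways of equal size.  We generate one null
  per pathway (the more specific reading of the design); a shared
  size-class mode without exclusion is available behind a flag and agrees
  closely whenever pathways are small relative to the transcriptome.
* **Sampling shortcut.** A draw's score depends only on how many +1 and −1
  genes it contains, so Monte-Carlo sampling uses the multivariate
  hypergeometric distribution over the (+1, −1, 0) counts of the eligible
  universe — exactly the distribution of subset draws, at a fraction of
  the cost.  An exhaustive mode enumerates all C(m, n) subsets when that
  count is below a cap (default 500,000) and is used as the exact oracle
  in tests.
* **Tail rule.** One-sided, conditional on the observed sign, with
  non-strict counting (≥ for positive, ≤ for negative scores); S = 0
  defines no tail and is reported as p = 1, direction "none".  p = count/N
  with no pseudocount by default (a pseudocount mode exists for users who
  need strictly positive p).  Because the tail is chosen by the observed
  sign, the procedure is a two-tailed selection evaluated one-sidedly: its
  exact type-I rate at nominal 0.05 is about 0.06 under our null generator
  (both tails contribute, partially offset by the discreteness of small
  pathways and the P(S=0) mass).  The acceptance checks measure exactly
  this: the null fraction of p ≤ 0.05 scatters around ~0.06, and the
  Spearman length-bias p-value is non-significant in most but not all
  replicates, because small pathways are intrinsically more conservative
  (coarser score grid), which induces a weak negative p-versus-length
  trend.  Users wanting strict 0.05 control should rely on the corrected
  p-values, which are conservative (multiplication by the number of
  pathways tested, capped at 1).
* **Length normalization.** Dividing S and the null by the same positive n
  is order-preserving, so the length-averaged p equals the raw p *exactly*;
  the operation exists as a run-time assertion and to report S/n.
* **Multiplicity.** Raw p-values are multiplied by the number of pathways
  actually tested after filtering (e.g. 118 when 154 curated sets shrink
  to 118 with ≥ 4 measured genes), capped at 1 — Bonferroni, as in the
  original design, not BH.
* **Reproducibility.** Each pathway's RNG stream derives from (master
  seed, SHA-256 of the pathway id), so results are independent of
  processing order and identical across runs.
* **Filtering.** Pathways are first restricted to the measured universe,
  then dropped if fewer than 4 genes remain or their category is excluded
  (the category label rides in the GMT description field; which categories
  to exclude — e.g. amino-acid or DNA biosynthesis — is the user's call).

## Variant consensus

The only variant-calling logic implemented is the consensus filter:
a variant (identified by the full contig/position/ref/alt tuple, not by
position alone) is kept when present in all provided call sets ("all",
≥ 2 sets, e.g. three growth conditions) or in exactly two ("both", e.g.
RNA versus whole-genome sequencing).  Upstream calling is out of scope.

## Fermentation kinetics

* **µ_max** comes from log-linear regressions over all contiguous windows
  of ≥ 4 points, keeping the steepest slope among windows with R² ≥ 0.98;
  if none qualifies the best window is returned flagged `degraded`.  A
  zero-variance window is defined to have R² = 1 (a constant is a perfect
  fit), so constant biomass yields µ_max = 0 rather than NaN.
* **Yields** are Δproduct/Δglucose with the product peak sought between
  inoculation and glucose exhaustion (first sample < 0.1 g/L — a robust
  detector given coarse sampling of residual glucose around 0.02 g/L).
* **OTR/CER** use the gas balance at V_m = 24.45 L/mol (25 °C, 1 atm, the
  cultivation temperature).  The inert-gas-corrected OTR is the default
  (the outlet molar flow shifts whenever RQ ≠ 1); the simple-difference
  form is a flag.  Both forms are exposed because published "mass transfer
  equation" formulations vary.
* **RQ** is the ratio of time-integrated CER to OTR over a window
  (trapezoidal); samples with OTR ≤ 0 are trimmed with a warning.
* **Switch time** is t_onset − t_exhaust, with onset defined as the start
  of two consecutive strictly decreasing ethanol samples (single-point
  noise does not trigger it), or, from the gas side, the first sustained
  CER recovery after its collapse at glucose exhaustion.
* **Correlations** are reported as R² with the sign of r carried
  separately.  The truncation rules — until the sustained decrease of the
  second variable, or until ethanol decline — follow the phase logic of
  batch fermentations: beyond those points the relation changes regime.
  Bacterial "cell death" is the running-peak log₁₀ CFU minus the current
  value, a cumulative, non-negative decline signal.

## Synthetic data

The generators define the study conditions under which the pipeline is
validated; they are first-class, tested code.

**Expression generator** (default 5,000 genes, 118 pathways of 4–30 genes
always including sizes 10 and 21 — the sizes of glycolysis and the TCA
cycle — and 1,300 background-misregulated genes): unchanged genes get
log-ratios ~N(0, 0.15) truncated below the 1.5 threshold and uniform
p-values; misregulated genes get |FC| = 1.5·exp(|N(0, 0.5)|) with random
sign and log₁₀ p uniform on [−8, −3.5], so essentially all survive BH at
the 5,000-gene scale.  Planted pathways force round(f·n) members (ties
round up) to the planted direction.  Replicates share the per-gene
direction and p-value and differ by multiplicative log-normal noise
(σ = 0.1) on the ratio.  What this does *not* emulate: count-level noise,
gene-gene correlation, library-size effects — so passing tests demonstrate
the statistics of the pipeline, not robustness to RNA-seq artefacts.

**Fermentation simulator**: fixed-step explicit Euler (dt = 0.05 h,
step-halving convergence tested; consumption fluxes are rate-limited so no
state goes negative) of Monod growth on 20 g/L glucose (µ = 0.25 h⁻¹,
K_s = 0.1 g/L), with the glucose carbon not fixed in biomass
(Y_x/s = 0.12 g/g in the fermentative regime) or excreted as
acetate/glycerol/pyruvate split φ to fermentation (2/3 of that carbon to
ethanol, 1/3 to CO₂, no O₂) and 1−φ to respiration (CO₂ with equimolar
O₂).  This makes the growth-phase RQ analytic — RQ = 1 + φ/(3(1−φ)) — and
lets φ be solved from a target ethanol yield or RQ.  After glucose
exhaustion and a configurable diauxic lag (default 3 h) the culture grows
on ethanol (Y_x/e = 0.6 g/g, O₂ by degree-of-reduction balance), then
acetate.  Cumulative CO₂/O₂ are integrated alongside the states, so carbon
balances close to machine precision by construction — the balance check
validates the bookkeeping, not the integrator.  CFU counts are reported on
log₁₀ with a detection floor at 0, using 4.6×10⁷ cfu/mL per g DW/L; the
default inoculum (5 log₁₀ cfu/mL yeast, 4 log₁₀ bacteria) makes glucose
exhaustion fall near 28 h, matching the multi-day scale of real batch
runs.

**Co-culture defaults.** The bacterial population grows on glucose at
0.1 h⁻¹ (competition-slowed) and dies at 0.3 h⁻¹ per g/L of ethanol above
0.2 g/L; its substrate consumption is negligible at plate-count scales and
is not fed back.  No quantitative death law exists for this system; the
threshold-linear form and its constants were chosen to reproduce the
qualitative co-culture trajectory of such experiments — a modest initial
rise (~0.7 log), steady decline from mid-fermentation, and decimation
coinciding with the ethanol peak.  The resulting ethanol–death correlation
(R² ≈ 0.90) is a property of that trajectory shape, not a fitted target.

## Problem sizes

The analysis drivers and acceptance script run the permutation test at
n_perm = 100,000 for single datasets and n_perm = 10,000 for the replicated
studies (400-pathway null calibration; 50 planted-recovery replicates) —
at 10,000 draws the smallest resolvable p (10⁻⁴) is still 40-fold below
the corrected significance threshold at 118 pathways, so the scaled runs
lose no decisions, only p-value resolution.

## Known limitations

* The permutation test treats genes as exchangeable; co-regulation within
  pathways (real transcriptomes) makes the null narrower than reality and
  the test anti-conservative in a way no size-matched gene permutation can
  fix.
* The simulator has no pH/DO dynamics, no OD→DW calibration, no lag phase
  at inoculation, and deterministic dynamics (no measurement noise), so
  estimator recovery tolerances (1–2%) reflect discretization, not
  measurement error.
* The DE generator's p-values are synthetic; nothing is implied about the
  upstream differential-expression test.
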