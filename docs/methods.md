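# Methods

## Design

`revmr` implements two-sample summary-data Mendelian randomization with
a binary disease liability as the exposure and continuous traits as
outcomes. The package assumes the three instrumental-variable
conditions for each instrument (association with liability,
independence from confounders, exclusion restriction), relaxes the
third through its sensitivity estimators, and works entirely on
summary statistics: per-variant effect sizes, standard errors, allele
labels, allele frequencies and p-values from two non-overlapping (or
nearly so) GWAS.

## Instrument processing

Instruments are variants associated with the disease at p < 5e-8
(strict inequality), greedily clumped so that no retained pair has
LD r² > 0.001: the variant with the smallest p-value is kept and
everything correlated above the threshold is discarded, repeating on
the remainder; p-value ties break lexicographically by rsid so results
are deterministic. The LD matrix is user-supplied — the package neither
computes LD from genotypes nor fixes a reference panel. Instrument
strength is summarised by the mean per-variant F statistic
(beta/se)², with ~10 the conventional adequacy floor. Named variants
(for example a dominant effect-gene variant one wishes to exclude in
sensitivity analysis) can be removed with `exclude_snps`.

## Harmonisation

Both tables are aligned to the exposure's effect allele: direct
matches kept; effect/other swaps negate the outcome beta and complement
its frequency; strand complements (A↔T, C↔G) are corrected before the
same rules. Palindromic variants are intrinsically strand-ambiguous and
are resolved by allele frequency only: kept when both frequencies lie
on the same side of 0.5 **and** both are outside [limit, 1 − limit]
with limit 0.42 by default (configurable); otherwise dropped, as are
palindromes with a missing frequency. Every exclusion is a recorded
disposition, not an error, and per-disposition tallies are reported.
The harmonised frame keeps a per-variant flip sign so that a second
exposure can later be co-oriented through the shared outcome (used by
multivariable MR).

Positive-exposure orientation is applied only inside MR-Egger, whose
intercept sign depends on it; the other estimators are invariant to
jointly flipping (γⱼ, Γⱼ) and see the native orientation.

## Estimators and conventions

With weights wⱼ = 1/σ_Γⱼ² and Wald ratios βⱼ = Γ̂ⱼ/γ̂ⱼ:

- **IVW**: β̂ = Σwγ̂Γ̂ / Σwγ̂² (zero-intercept WLS), algebraically the
  inverse-variance-weighted mean of the βⱼ with first-order weights
  γ̂ⱼ²/σ_Γⱼ². Default inference is multiplicative random effects: the
  fixed-effect SE is inflated by max(1, sqrt(Q/(J−2))), never deflated;
  a fixed-effect flag is available. Cochran's Q about the IVW fit is
  referred to χ²(J−1).
- **MR-Egger**: WLS with intercept on positively-oriented exposure
  effects; both SEs inflated by max(1, sqrt(Q_E/(J−2))) with Rücker's Q
  about the Egger fit, referred to χ²(J−2). The intercept p-value is
  the directional-pleiotropy test.
- **Weighted median**: order the βⱼ, form normalized weights
  wⱼ' ∝ γ̂ⱼ²/σ_Γⱼ², and linearly interpolate the ordered ratios at
  cumulative weight 0.5 (using sⱼ = Σ_{k≤j} wₖ' − wⱼ'/2). SE from a
  parametric bootstrap: (γ̂ⱼ, Γ̂ⱼ) resampled from their normal sampling
  distributions, default 1,000 draws, seed mandatory.
- **Weighted mode**: weighted normal-kernel density over the βⱼ with
  bandwidth φ × 0.9·min(sd, 1.4826·MAD)·J^(−1/5) (φ = 1 default; the
  MAD guards the plug-in scale against the very outliers the estimator
  resists), evaluated on a 512-point grid spanning [min − 3h, max + 3h];
  argmax ties break toward the grid midpoint; degenerate all-equal
  ratios short-circuit to the common value. Bootstrap SE as above.
- **Radial MR**: first-order radial weights wⱼ = γ̂ⱼ²/σ_Γⱼ² give
  per-variant Qⱼ = wⱼ(βⱼ − β̂)²; a variant is an outlier when the
  upper-tail χ²(1) probability of Qⱼ falls below the screening level
  (default 0.05, no multiplicity correction; Bonferroni and iterated
  modes available behind flags). Exclusion is a single pass by default,
  reading outlier removal as one screening step.
- **Multivariable IVW**: zero-intercept WLS of Γ̂ on (γ̂₁, γ̂₂, …) with
  the same weights; coefficients are direct effects conditional on the
  other exposures. Collinearity beyond condition number 1e8 is an
  error. Overdispersion inflation uses residual df J − max(k, 2), which
  makes the one-exposure path coincide exactly with univariable IVW.
  Conditional F diagnostics are out of scope; plain per-exposure mean F
  is reported instead.

Wald-ratio SEs are first order (σ_Γ/|γ̂|): no second-order term and no
exposure-uncertainty term. This is the main documented limitation — the
point estimates inherit a weak-instrument attenuation of roughly a
factor F̄/(F̄+1), i.e. a relative bias ≈ 1/F̄, which is negligible for
interval-scale inference at the instrument strengths simulated here
(mean F in the hundreds to thousands) but measurable when averaging
thousands of replicates; multivariable fits amplify it by the inverse
collinearity factor of the exposure columns. All p-values are two-sided
normal (not t) for comparability across estimators; 95% intervals use
the normal 0.975 quantile.

Estimates and SEs for binary-disease exposures are multiplied by
ln 2 ≈ 0.693 to read as SD difference in the outcome per doubling of
genetic liability; p-values are unchanged and double scaling is a
state error.

## Panel, strata, multiplicity, profiles

`run_panel` harmonises and runs all five labelled estimates (IVW, Egger
slope, Egger intercept, weighted median, weighted mode) per outcome;
per-outcome failures are recorded, not fatal, and each outcome draws a
child seed from the master seed in input order, so a fixed seed gives
byte-identical long-format output.

Stratum contrasts use z = (β_a − β_b)/sqrt(se_a² + se_b²) with a
two-sided normal p. This assumes independent strata — true by
construction for disjoint age tertiles of one cohort, an assumption to
verify before applying it elsewhere. The contrast is an addition over
typical per-tertile reporting and is labelled as such in output.

The correlated-trait multiplicity threshold divides α by the smallest
number of principal components of the trait correlation matrix whose
eigenvalues sum to ≥ 95% of the trait count; both the raw threshold and
its one-significant-figure rounding are emitted (0.05 over 33
components → 0.0015 → 0.002). The component count can also be set
directly in pipeline configuration when it comes from prior literature
rather than an available correlation matrix.

Profile comparison regresses exposure 2's per-trait estimates on
exposure 1's by OLS **with intercept** (the no-intercept variant
changes little on roughly centred panels) and reports slope, intercept,
R² and trait count.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
so recovery of known truth is a meaningful end-to-end test:

- True per-variant liability effects γⱼ ~ N(0.12, 0.04²) on the
  log-odds scale; allele frequencies uniform on (0.05, 0.5). Observed
  effects add noise with σ_γⱼ = 1/sqrt(2·maf·(1−maf)·n_eff),
  n_eff = 4/(1/cases + 1/controls) — the standard binary-trait
  summary-statistics approximation. Defaults mirror large consortium
  GWAS scale: 74,124 cases / 824,006 controls for the first liability,
  181,522 / 984,168 for the second, 118,466 for outcome traits
  (variance-1 continuous traits, σ_Γⱼ = 1/sqrt(2·maf·(1−maf)·n)).
  The default instrument count is J = 150 and the default panel has 20
  traits — desk-scale stand-ins for post-clumping instrument sets and
  a 249-trait metabolomics panel.
- Outcomes follow Γⱼ = θγⱼ + αⱼ (+ θ₂γ₂ⱼ with a second liability),
  with pleiotropy αⱼ on a configurable fraction of instruments: none,
  balanced (zero mean) or directional (nonzero mean). Planted outliers
  add an offset expressed in units of σ_Γⱼ. Default θ = 0.3.
- Harmonisation stressors: configurable fractions of palindromic
  variants (optionally pinned to a chosen frequency such as 0.5),
  strand-flipped and allele-swapped outcome rows; the generating
  orientation is recorded in the truth object so recovery is exactly
  checkable.
- LD is block-diagonal: a chosen number of contiguous blocks at a
  chosen within-block r², zero between blocks.
- Panels share per-variant noise across traits through a supplied or
  exchangeable trait correlation (factored by eigendecomposition, so
  duplicated traits at r = 1 are legal); the generating correlation is
  emitted for the multiplicity calculation.
- Age strata: three outcome tables with an equal split of the outcome
  sample and stratum effects θ_s = θ + m·p_s, where p_s are statin-use
  prevalences (0.05/0.17/0.29 youngest→oldest by default) and m is a
  medication modifier — the simplest additive mechanism by which
  medication taken preferentially at older ages attenuates or reverses
  an effect estimate; a sufficiently negative m reproduces the
  qualitative sign reversal of LDL-C-like traits in the oldest
  tertile. Alternatives (multiplicative damping, per-individual
  mediation) would need individual-level data the two-sample design
  does not see.
- One pseudo-random child stream per logical component (exposure,
  second exposure, outcome, panel, strata) derived from the master
  seed, so enabling strata never perturbs exposure draws; a fixed
  configuration and seed reproduce identical bytes on disk.

What the generator does **not** emulate: instrument selection effects
(winner's curse), sample-overlap correlation between exposure and
outcome errors, realistic LD from reference panels, indels or
multi-allelic variants, and non-normal effect distributions. Passing
recovery tests therefore demonstrates correctness of the estimators
and plumbing under the stated model, not robustness to those
real-data complications.

## Pipeline

`revmr run` executes simulate/ingest → instrument selection →
harmonise + estimate per outcome → radial screening → multivariable MR
→ per-stratum estimation with a youngest-vs-oldest contrast →
multiplicity threshold → two-exposure profile comparison, writing
tab-separated long-format tables and a JSON manifest with a SHA-256
digest per output. Stage failures are recorded and dependent stages
skipped; the CLI exits non-zero if any stage failed. Timestamps live
only in the manifest metadata, never in output tables, so re-running an
identical configuration reproduces identical digests. `revmr report`
sorts results, flags estimates passing the multiplicity threshold and
draws the two-exposure XY scatter (PNG date metadata suppressed for
reproducibility).

## Validation study sizes

The test suite and `scripts/acceptance.py` use these replicate studies,
chosen to finish in seconds to minutes on one CPU: no-pleiotropy
recovery and CI coverage over 2,000 replicate studies at default scale;
directional pleiotropy (30% invalid, mean α 0.02) over 200 replicates;
weighted-median breakdown at 45% vs 55% invalid (mean α 0.1, J = 100)
over 200 replicates; radial screening (3 planted outliers at +10σ_Γ)
over 200 replicates; multivariable MR with shared instruments
(J = 200, θ = 0.3/0.1, effect correlation 0.5) over 500 replicates;
single frozen studies for the age-stratification reversal,
harmonisation fidelity (200 variants, 30 strand flips, 20 swaps, 10
frequency-ambiguous palindromes) and pipeline determinism. Unit-level
recovery tests scale the outcome GWAS down to n ≈ 2–3 × 10⁴ for speed.

## Known limitations

- First-order ratio SEs and the resulting ~1/F̄ attenuation (above);
  no second-order or exposure-uncertainty corrections, no MR-PRESSO,
  contamination-mixture, debiased IVW or Steiger filtering.
- The weighted median is consistent only as outcome sampling noise
  vanishes; at any finite noise, one-sided invalid instruments just
  below 50% weight shift it to the 0.5/(1−f) quantile of the valid
  ratio cluster — visible in the breakdown study as a positive offset
  at 45% invalid that is small relative to the invalid-cluster offset
  but nonzero.
- Palindromic variants with missing frequency are always dropped;
  proxy-variant lookup is out of scope.
- The medication-mediation mechanism is an additive stratum-level
  shift; it reproduces the qualitative age distortion, not any
  particular pharmacological dose-response.
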