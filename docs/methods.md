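# Methods

## Setting

A pediatric allogeneic-HSCT cohort (default n = 49) with unmanipulated
bone-marrow grafts from matched sibling (MSD), matched family (MFD) or
matched unrelated (MUD) donors. Absolute T-cell subset counts (cells/µl)
are measured at day +15, +30, +60, +100, +180 and +240 after graft
infusion, plus one pre-conditioning sample. Clinical endpoints: acute
GvHD (modified-Glucksberg grade 0–IV, onset day, organs), EBV/CMV/ADV
infections detected by PCR surveillance (onset days), relapse (malignant
disease only), and death.

## Time-averaged relative abundance R

For subset s ∈ {γδ total, Vδ1, Vδ2} and one patient,
R = trapezoidal integral of s(t)/αβ(t) over the usable post-HSCT days,
divided by the spanned time. Choices:

* **Trapezoid over visit mean.** The schedule is unevenly spaced; an
  arithmetic mean across visits would weight day +15–+60 as heavily as
  the 140-day tail. The integral average is isolated in
  `time_average_abundance` so the convention can be swapped in one place.
* **Denominator = TCRαβ count**, not CD3.
* **Aplasia guard.** Timepoints with αβ < 1 cell/µl are skipped; early
  after conditioning the denominator is so small that ratios are noise.
  Patients with fewer than two usable timepoints are ineligible for
  stratification and are reported as such.
* Pre-conditioning samples never enter R or the recovery summaries.

## ω²-maximizing dichotomization

Eligible patients are sorted by R (ties broken by patient id; the rank
feature uses midranks so tied R values are indistinguishable). Each
patient i becomes z_i = (minmax01(R_i), minmax01(rank_i)); dissimilarity
is the weighted (Ružička) Jaccard distance 1 − Σmin/Σmax, which reduces
to the set Jaccard on binary vectors and is 0 for two all-zero vectors.
For every split size k ∈ [min_group, n − min_group] the binary grouping
is scored with a PERMANOVA-style ω² computed from the distance matrix
(between-group df = 1, clipped at 0 because the classical estimator can
be negative). The k with the largest ω² wins; ties resolve to the
smallest k; the cut-off is the midpoint of the boundary R values.

* `min_group = max(3, ⌈0.1 n⌉)` guards against 1-vs-rest splits.
* The continuous-Jaccard/ω² construction is this package's
  operationalization; it is deliberately confined to `weighted_jaccard`
  and `omega_squared`.
* Degenerate inputs (all R equal) return ω² = 0 at every k and a
  `degenerate` flag.
* The search is verified against a naive brute-force re-implementation on
  random instances (n ≤ 20) in the test suite.

## Association screens

For each cell variable (10 counts) × predictor pair, per scope (a single
day, or the per-patient time average of the count):

* binary predictors (related donor vs MUD, ATG, serotherapy, malignancy,
  sex, and the outcome flags) → Mann–Whitney/Wilcoxon rank-sum
  (midranks; exact enumeration when both n ≤ 12 and tie-free, otherwise
  tie-corrected normal approximation with continuity correction) with
  Cliff's δ;
* 3-level donor type → Kruskal–Wallis with tie correction;
* continuous predictors (donor age, graft cell doses, aGvHD grade) →
  Spearman ρ with its t-approximation test.

Benjamini–Hochberg correction spans one whole matrix per scope; q < 0.1
is significant. Each significant pair is screened for confounding:
responses are ln(1+x)-transformed (counts are heavily right-skewed early
after transplant), M0 = `response ~ focal` is compared against
M1 = `response ~ focal + c + focal:c` for every other modality variable c
with the Gaussian likelihood-ratio statistic n·ln(RSS0/RSS1) (identical
to −2Δloglik with the variance profiled out); any candidate with p < 0.05
flags the pair as confounded. The screen is a flag, not a causal
adjustment. Collinear or degenerate candidates are skipped and reported.

## Outcome analysis

Endpoint datasets use event time = onset day, death before the event as
a competing risk (EBMT-style; relapse is not a competing risk by default
but a flag exposes it), censoring at end of follow-up. The cumulative
incidence function is the Aalen–Johansen estimator; a 1−Kaplan–Meier
variant is bundled for sensitivity and coincides exactly when no
competing events occur. Strata are compared with the log-rank test and a
Cox model on the high-vs-low indicator (Breslow ties — adequate for
day-resolution ties at n ≈ 49; Newton–Raphson with step-halving,
tolerance 1e-8, ≤ 50 iterations). Monotone likelihood (separation) is
detected (|β| drifting beyond 15 or a singular information matrix) and
flagged instead of reported as a finite estimate. Patients with an event
flag but no usable onset day are excluded from that endpoint.

## Synthetic cohort generator

The generator's defaults are the study conditions; it exists so the
pipeline's operating characteristics can be measured.

**Counts.** Per day, the γδ total and the αβ count are log-normal with
medians fixed at the published reconstitution table; a single
multiplicative patient frailty (log-normal, mean 1, log-sd 0.5) is shared
by all counts and days, a persistent γδ-level effect (log-sd 0.45) and a
persistent Vδ2-share tilt (log-sd 0.5) make time-averaging meaningful.
The γδ total is split into (Vδ1, Vδ2, non-Vδ1-non-Vδ2) by a Dirichlet
whose marginal medians track the published relative concentrations
(alphas via the Beta median approximation (a−1/3)/(a+b−2/3),
concentration 4). CD3 = αβ + γδ by construction; CD4/CD8 occupy a
Beta-distributed sub-pool of CD3 with day-specific CD4 shares; HLA-DR+
cells are Beta sub-fractions. Subset-sum invariants therefore hold
exactly, with the 5% validator tolerance reserved for ingested real data.

**Planted effects.** Covariate effects are centred log-multipliers
(x^(flag − mean flag)): MUD donors suppress Vδ2 at days +30…+180,
serotherapy tilts the CD4/CD8 share at days +30…+100, donor age carries a
negative log-slope on the γδ compartment. Centring keeps cohort medians
on their anchors while group contrasts carry the planted direction.
Infection responses are sum-preserving reallocations: EBV tilts the γδ
split toward Vδ1 from day +100, CMV tilts the CD4/CD8 pair toward CD8 at
days +60…+180. Effect magnitudes are set to reproduce the published
strength of the univariate findings (near-complete Vδ2 separation by
donor type), not just their sign.

**Events.** A two-part model per endpoint: a Bernoulli indicator
p_i = min(c·m_i, 1) whose scale c is solved by bisection so the cohort
mean equals the published rate, and a truncated log-normal onset day with
the published median (truncation at follow-up, or at the death day for
deceased patients, keeps every event inside follow-up without changing
the rate). Multipliers m_i: ATG and the latent Vδ2 propensity (the
standardized log time-averaged Vδ2/αβ level) act on EBV; the Vδ2
propensity acts on the severe-aGvHD stage; a shared log-normal viral
susceptibility (sd 0.45) couples EBV/CMV/ADV so the any-viral rate falls
below the independence value, as observed. An exponential-hazard
formulation was rejected because no single exponential can match both a
46% aGvHD rate over two years and an onset median of day 17. Death is an
independent Bernoulli (0.10) with a log-normal day; panel rows after
death are absent; follow-up is log-normal (median 737 d, IQR-matched).

**Determinism.** Each patient draws from substreams keyed by
(seed, patient index, phase), so cohorts are bit-reproducible and adding
patients never perturbs existing ones. `GeneratorConfig.null()` switches
every planted effect off for null-calibration studies.

**What the generator does not emulate.** Mechanistic immunology (thymic
output, homeostatic proliferation), viral-load kinetics, graft cell-dose
effects on trajectories, inter-day autocorrelation beyond the shared
patient effects, and real missingness patterns (a per-visit dropout rate
is a knob, default 0). Passing tests therefore demonstrate that the
pipeline recovers structure *of this kind* at this sample size — not
that the clinical findings themselves replicate.

## Verification strategy and problem sizes

* Exact oracles: all-pairs enumeration for Cliff's δ, a naive
  re-implementation for the cut-off search, hand-computed toys for
  Kruskal (H = 32/7), BH, the Aalen–Johansen steps and the log-rank
  accumulation, golden-section maximization of the explicit partial
  likelihood for the Cox β, and the score-test identity between log-rank
  and Cox at β = 0. lifelines is used as an independent cross-check for
  CIF, Cox and log-rank, never as the implementation.
* Null calibration: rank-sum, Kruskal, confounder-LRT and log-rank reject
  at ≈5% over 600–1000 null replicates; BH keeps the false-discovery
  proportion at ≈0.1 on 100 null p-values.
* Generator calibration: 200 replicate cohorts (seeds derived from one
  master seed) for the event rates and count anchors.
* Effect-direction recovery: 25 replicate cohorts through the full
  pipeline.
* Cox parameter recovery: 200 replicates of n = 500 exponential data with
  a true hazard ratio of 2, checking 95% CI coverage.

These sizes keep the whole suite at a few minutes on one CPU while
leaving Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The confounder screen assumes Gaussian errors after ln(1+x); it is a
  screening heuristic, as intended, not inference.
* The Cox fit targets the one-covariate grouped comparison with Breslow
  tie handling only (adequate at day-resolution ties and n ≈ 49);
  multi-covariate use works mechanically but is not tuned.
* The ω² cut-off search is O(n²) per split evaluation — fine for
  cohort-sized n, not for thousands of patients.
* Below-detection counts are treated as measured zeros; absent rows as
  missing visits.
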