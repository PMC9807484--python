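# Methods

## Effect sizes from event counts

The analysable unit is the substudy: one study × cohort × microRNA
comparison summarised as a 2×2 table of dysregulation events. We read "one
event" as one sample exhibiting dysregulated expression of the microRNA;
this is an assumption of the encoding, stated here rather than asserted as
the only possible reading of per-study reporting. With `a` events among
`n_case` cases and `c` among `n_ctrl` controls, `b = n_case − a`,
`d = n_ctrl − c`:

    y = ln(ad / bc),    v = 1/a + 1/b + 1/c + 1/d.

If any cell is zero, 0.5 is added to all four cells (Haldane–Anscombe) and
the record is flagged. Effects are **signed** internally; reports present
`|y|` with a direction column and mirror the CI onto the absolute scale,
which is the convention of the literature this pipeline serves. Direction
is recomputed from counts; a conflict with the reported direction is
logged and the counts win, because the counts are the analysable datum.

Substudies sharing a parent publication are pooled as independent. That is
a known limitation of the design being reproduced; the parent link is kept
because the bias tests refuse microRNAs whose substudies all share one
parent.

## Random-effects model and dual τ² estimation

The random-effects model is `y_i ~ N(μ, v_i + τ²)`. τ² is estimated two
ways:

- **Empirical Bayes / Paule–Mandel**: the root of
  `Σ w_i (y_i − μ̂)² = k − 1` with `w_i = 1/(v_i + τ²)`, found by bisection
  (the function is strictly decreasing; truncation at 0 when the
  generalised Q at τ² = 0 is already below k − 1). Tolerance 1e-8.
- **REML**: bounded scalar maximisation of the restricted log-likelihood
  `−½Σln(v_i+τ²) − ½ln(Σw_i) − ½Σw_i(y_i−μ̂)²` on `[0, max(10, 100·S²_y)]`,
  with an explicit boundary check at 0.

For balanced designs (equal `v`) both coincide with `max(0, S²_y − v)`;
the suite asserts this and cross-checks an unbalanced instance against R
metafor (`rma`, methods REML and EB) with the oracle values frozen in.

Pooling is inverse-variance at the estimated τ²: `μ = Σw_i y_i / Σw_i`,
`se = (Σw_i)^{-1/2}`, Wald z CIs (quantile 1.959964 at 95%), two-sided
normal p. No Knapp–Hartung adjustment (matching the conventional default
of the toolchain being emulated). Bonferroni multiplies each raw p by the
number of microRNAs analysed **within the analysis set at hand** (the
least-surprising reading when the divisor is not stated; configurable via
`MetaConfig.m_tests`). Significance requires adjusted p < α under *both*
estimators **and** matching pooled sign; a sign mismatch with two small p
values is logged distinctly rather than silently passed.

Subgroup axes: tissue class, blood fraction, platform (PCR and sequencing
strata only; others are logged and skipped, mirroring the analysed
strata). Sensitivity cuts keep substudies with `n_case + n_ctrl ≥ t`,
inclusive, at t = 25 and 50 by default. Direction consistency across all
analysis sets classifies each microRNA as consistent (same direction in
every set where significant), inconsistent, or never significant.

## Publication bias

**Begg**: Kendall correlation between standardised deviates
`(y_i − μ_FE)/√(v_i − 1/Σ(1/v_j))` and the variances. For k ≤ 8 with no
ties the two-sided p is exact: under the permutation null the inversion
count of a random ranking is Mahonian, and `S = k(k−1)/2 − 2·inversions`,
so the tail sums directly without enumerating k! orderings (tests verify
the equivalence against full enumeration up to k = 6). With ties or k > 8
the tie-corrected normal approximation is used and labelled. A
non-positive conditional variance (possible when one weight dominates) is
clipped at 1e-12 with a warning.

**Egger**: OLS of `y_i/se_i` on `1/se_i` with intercept; reported as
z = intercept/SE with a two-sided normal p (the z convention matches how
these tests are customarily tabulated; a t form with k − 2 df would be the
alternative). A perfect fit (relative residual sum of squares ≤ 1e-10)
reports z = ±∞ with a flag; an all-equal precision design is an error.

**Trim-and-fill**: the L₀ estimator. Each pass computes the fixed-effect
centre of the non-trimmed set, ranks |deviations| over all k points, sums
the ranks of the positive deviations into `T_n`, and sets
`L₀ = (4T_n − k(k+1))/(2k−1)`; `k₀ = round(L₀)` clipped to `[0, k−1]`,
iterated to stabilisation (cap 50, error with trace beyond). Fills mirror
the k₀ most extreme observed values about the trimmed centre with their
original variances; the corrected estimate re-pools observed + filled
under REML. `side="auto"` picks the side with the larger first-pass L₀,
breaking ties by the sign of the Egger intercept (or defaulting to the
right when Egger is not computable — then k₀ = 0 anyway). R₀ and
contour-based variants are out of scope.

Bias tests require k ≥ 3 and ≥ 2 parent studies; otherwise the microRNA is
reported `not_testable` (the behaviour applied to a most-reported
microRNA whose substudies all came from one publication). Default targets
are the most-reported microRNAs overall and per direction (top 3 each).
Significance after correction compares the trim-and-fill pooled p with α
unadjusted; candidates failing it are excluded from selection.

## Interaction evidence

Ledgers carry experimental records (with PMIDs) and predicted records
(with a rank percentile). Processing order: merge (names canonicalised,
PMIDs unioned per pair×source), top-percentile cut on predictions
(inclusive at 1.4% by default — a quantile cut includes its boundary),
retraction strike, then the robustness filter: ≥ 2 distinct surviving
experimental PMIDs **and** a prediction record. Striking retractions
*before* counting support means a three-article pair losing one retraction
still passes — strict about evidence without double-penalising. The two
supporting PMIDs may come from the same experimental database; requiring
distinct databases would be a different (undocumented) rule. Filter-stage
counts are recorded and are monotonically non-increasing.

## Pathway impact

Base pathways are signed directed graphs read from edge-list TSV or
GraphML (`beta` ∈ {+1, −1}; activation-like relations map to +1,
inhibition-like to −1, unknown labels default to +1 with a warning).
Augmentation adds each robust microRNA once, with β = −1 repression edges
to its targets present in the pathway; microRNAs without a target on the
pathway are not added.

Propagation solves `(I − B)·PF = ΔE` with `B[i,j] = β(j→i)/outdeg(j)` (the
classic out-degree normalisation). If the system is ill-conditioned
(condition number > 1e12, e.g. an undamped feedback loop), all β are
scaled by 0.9 and the solve is retried with a flag; failure after damping
is an error naming the pathway. `Acc = PF − ΔE`; `tA = ΣAcc`. Because the
solve is linear, `tA = s·ΔE` for a fixed vector `s`, so the permutation
null (observed input values reassigned to entities resampled uniformly
without replacement from the measured entities on the pathway; 2000 draws
by default, seed mandatory) costs one dot product per draw.
`pAcc = (#{|t_null − med| ≥ |t_A − med|} + 1)/(n_perm + 1)` with the
median-centred two-sided tail and pseudo-count, so `pAcc ≥ 1/(n_perm+1)`.
`pORA` is the hypergeometric upper tail over the measured universe (all
microRNAs meta-analysed), with pathway size = measured entities on the
pathway. `pG = c − c·ln c`, `c = pORA·pAcc`; adjustment across pathways is
Benjamini–Hochberg by default (Bonferroni selectable) — the source
procedure states only "statistically significantly enriched", so the
choice is surfaced as configuration. A pathway with no measured entity
reports pG = 1 with a flag.

## Biomarker selection

Candidates must be significant somewhere with a consistent direction,
enter the target pathway as perturbation inputs while that pathway's
adjusted pG < α, and survive trim-and-fill correction where tested (the
gate applies only to tested microRNAs by default because bias tests run on
a most-reported subset; `apply_bias_gate_to_all` widens it). Ranking: tier
1 = blood-detectable (significant in the blood tissue subgroup or any
blood-fraction subgroup), then within tier by number of analyses
significant (desc), minimum adjusted p (asc), maximum |logOR| (desc), and
name — the last three tie-breaks make the two-key priority a total,
reproducible order; they are this package's choices, not claims about any
published ordering.

## Synthetic data

`simulate_corpus` draws, per substudy × reported microRNA, control events
~ Binomial(n_ctrl, p₀) and case events ~ Binomial(n_case, p₁) with
`logit(p₁) = logit(p₀) + δ`, `δ ~ N(true_logOR, τ²_between)` — so the
population logOR of the event indicator equals the planted value exactly,
while the *estimated* logOR carries the usual O(1/cell-count) attenuation
(see Numerical notes). Defaults: 50 microRNAs, 40 studies (70%/30% one or
two substudies), log-normal total sample size (median 50, σ = 0.6,
truncated to [10, 500], split evenly between arms), baseline event
probability 0.1, five effect microRNAs at |logOR| 2.0 with alternating
sign, τ_between = 0.3, tissue mix 75% blood (fractions ≈ the published
serum/plasma/PBMC/whole-blood proportions), platform 95% PCR. Each
substudy reports each microRNA with probability 0.35 (`report_prob`, a
field beyond the minimal spec) so per-microRNA study counts vary as they
do in real corpora. The optional `suppress_small_null` rule drops
small-|logOR| substudies of null microRNAs with a stated probability,
inducing funnel asymmetry. Three RNG streams (corpus / ledgers / pathways)
derive from the master seed, so artefacts regenerate independently and
bit-identically.

`simulate_interaction_db` gives each planted pair three experimental
PMIDs (split across two databases) and a top-percentile prediction, plus
decoys that each fail one robustness clause and qualifying decoys wiring
null microRNAs onto null-pathway genes (so null pathways carry measured
but non-dysregulated inputs). A global fraction of all PMIDs is marked
retracted. `simulate_pathways` wires the planted targets plus extra genes
into a connected signed random DAG and builds size- and density-matched
null pathways over disjoint gene sets.

What the generator does **not** emulate: correlated effects across
microRNAs, platform-specific measurement error, realistic gene symbols or
sequence content, non-human records, and within-study correlation between
substudies. Passing recovery tests therefore demonstrates that the
pipeline recovers truth under its own model assumptions, not that those
assumptions hold for any particular real corpus.

### Study conditions used by the replicated suites

- **Power / type-I suite**: the generator defaults above (the stated
  design point: 50 microRNAs, 40 studies, 5 effects at logOR 2.0,
  τ = 0.3), 100 replicates each.
- **Estimator-recovery suite**: a large-count design (baseline 0.4,
  median total n 400 in [100, 1000], planted logOR 1.0, τ = 0.3, every
  substudy reporting) over 200 replicates, so the logOR estimator is in
  its large-sample regime.
- **End-to-end suite** (`endtoend_config`): a circulating-only corpus
  (blood tissue mix 1.0) with planted |logOR| 2.5 and median total n 80,
  50 replicates, permutation null at 500 draws. These conditions make the
  planted biomarkers blood-detectable by construction and per-microRNA
  power near one, so the composite assertions (planted pathway attains the
  smallest adjusted pG; planted microRNAs occupy tier 1) isolate the
  evidence-filter / augmentation / impact / selection plumbing rather than
  re-measuring marginal power.

## Numerical notes

- τ² solvers: bisection/bounded optimisation to 1e-8; REML snaps to 0 when
  the boundary is at least as likely.
- The empirical logOR from binomial counts is attenuated toward zero by
  O(1/cell-count) (about 0.006 at 200 per arm with baseline 0.4, larger at
  small counts); recovery tests allow for this explicitly (0.015 on μ,
  0.01 on τ²) on top of Monte-Carlo error rather than pretending the
  estimator is exactly unbiased.
- Begg exactness cutoff k ≤ 8 (8! orderings enumerable via the Mahonian
  recurrence in microseconds); ties always fall back to the approximation.
- Trim-and-fill k₀ rounding is to the nearest integer; iteration cap 50.
- Propagation damping 0.9 applied only on ill-conditioning; the damped
  matrix is reused for the permutation null so observed and null
  statistics share one system.
- Ranking tie-breaks terminate in the name, so the order is total and
  deterministic for any input.

## Known limitations

Substudy independence within a parent study is assumed in pooling;
Bonferroni divisors per analysis set are a reading, not a published
constant; the exact empirical-Bayes/Paule–Mandel identification holds for
the standard implementation but the source procedure does not spell its
estimator out; KGML parsing is out of scope (edge-list TSV/GraphML carry
the same information); real-corpus headline counts depend on unpackaged
supplementary tables and external database versions and are not
reproduced here.
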