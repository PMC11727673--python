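# Methods

## The measurement problem

Object-case (case 1) best-worst scaling asks respondents to mark the most
and the least important item in repeated subsets of a master list of
candidate outcomes. Relative to direct rating it avoids the ceiling effect
(importance ratings pile up at the top of a Likert scale) and yields a
full interval-scaled ranking. `bwsprefs` implements the complete analysis
chain for such a survey in the context of total joint arthroplasty (TJA)
quality-of-care outcomes: 13 candidate outcomes (activities of daily
living, pain relief, avoiding reintervention, avoiding complications,
three "quick" time-to-achievement variants, and several care-process
items), with respondents stratified by phase of care — pre-operative,
short-term post-operative (≤ 6 months), long-term post-operative
(> 6 months).

## Questionnaire design

Choice sets come from a balanced incomplete block design (BIBD):
`v` items arranged in `b` blocks of `k` so that each item appears in `r`
blocks and each unordered pair co-occurs in `λ` blocks, with
`v·r = b·k` and `λ·(v−1) = r·(k−1)`. Balance makes raw best/worst tallies
comparable across items. The default survey design is
`(v, b, k, r, λ) = (13, 13, 4, 4, 1)`.

`generate_bibd(v, k)` scans feasible `(λ, r, b)` triples in increasing
`λ` (hence increasing `b`, so the minimal design is found first, subject
to Fisher's inequality `b ≥ v`), trying a cyclic difference-set
development when `b = v` — which produces the `(13, 4)` design and the
Fano plane `(7, 3)` instantly from the difference sets {0,1,3,9} mod 13
and {0,1,3} mod 7 — and otherwise backtracking over lexicographically
nondecreasing blocks with replication/co-occurrence pruning. The search
is fully deterministic; a configurable node budget (default 2,000,000)
bounds the backtracking, and exceeding it raises an explicit error rather
than silently returning an unbalanced layout. Presentation-order
randomisation (block order, within-block order) is isolated in
`build_questionnaire` behind an explicit layout seed and never affects
the analysis, which keys picks by design block index.

## Choice model

Latent utilities `u_i` drive both simulation and estimation through the
MaxDiff (joint ordered-pair) rule: in a block S,

    P(best = i, worst = j | S) = exp(u_i − u_j) / Σ_{l≠m ∈ S} exp(u_l − u_m).

The denominator factorises as `(Σ_l e^{u_l})(Σ_m e^{−u_m}) − k`, which
keeps the exact log-likelihood, gradient and Hessian cheap. Only utility
differences are identified, so estimation uses effects coding
(Σ u_i = 0); the reported β for an item is its utility relative to the
average item, directly comparable to published "standardized scores" that
take positive and negative values around an implicit centre.

Fitting starts at β = 0 and runs BFGS on the (v−1)-dimensional free
parametrisation with the analytic gradient, followed by up to 20 Newton
polish steps with the analytic Hessian (BFGS can stop on precision loss
with the gradient slightly above tolerance). Convergence is declared iff
the projected gradient's max-norm is ≤ `tol` (default 1e−6); an exhausted
iteration budget is reported as `converged=False` with a warning, never
polished over. Standard errors are observed-information
(inverse negative Hessian) mapped through the sum-to-zero constraint;
95% confidence intervals are Wald, β ± 1.96·SE (the published intervals
state no method; the Wald form is the conventional default at these
sample sizes). Items picked best (or worst) at every appearance are
flagged with a separation warning, since their utilities drift to ±∞.

A sequential best-then-worst likelihood — best by a standard logit over
the block, then worst by an inverse logit over the remaining items — is
available via `likelihood="sequential"` for sensitivity analysis. The
published analysis names only "a multinomial logit model"; the joint
MaxDiff form is the standard case-1 default and is what the simulator
uses, making simulation → estimation a closed parameter-recovery loop.

Alongside the logit fit, `count_scores` implements the counting
estimator: per choice set +1 for the best pick, −1 for the worst, 0
otherwise, summed and divided by the item's total availability
(`r` appearances per questionnaire × number of respondents), bounded in
[−1, 1] and summing to 0 on complete data. Whether a published
"standardized score" is count-based or likelihood-based is ambiguous in
this literature; both are provided, and at large n their rankings agree
(Kendall τ ≥ 0.9 at n = 2000 in the test suite). Ranks break ties
lexicographically by item id in both estimators.

## Synthetic respondents

No raw choice data were ever deposited for the study this package
emulates, so the simulator is a first-class module. Mean utilities are
anchored on the published coefficients where printed — overall:
ADL 1.03, pain 0.65, reintervention 0.64, complication 0.58, quick-ADL
0.29, quick-pain −0.04, negative emotions −1.29; per phase: ADL
0.96/1.06/1.05, reintervention 0.47/0.77/0.62, pain 0.66/0.57/0.71,
complication 0.76/0.50/0.56 (pre / short post / long post). The six items
without printed values (hobby, quick-hobby, communication, knowledge,
heard, positive emotions) are filled by linear interpolation of the rank
gap between the quick-ADL and negative-emotions anchors, with the
physical-outcome item (hobby) placed above the care-process items; they
are flagged `interpolated_items` on the profile and are anchors, not
ground truth. The full vector is then shifted to sum to zero: utilities
are identified only up to an additive constant, so centering preserves
every anchored difference and ordering exactly.

Respondent heterogeneity is one normal perturbation per item per
respondent, sd 0.3 by default. That value reproduces confidence-interval
widths of the published order (≈ ±0.13 at n ≈ 153) without being fitted
to them; it is configurable, and the estimand under heterogeneity is the
population-average utility, mildly attenuated relative to the latent
means (ranking structure is unaffected in expectation).

The `study_emulation` preset reproduces the emulated study's enrollment
structure: 36/55/62 complete respondents in the three phase strata plus
15 incomplete submissions (168 total), the incomplete ones generated by
missing-completely-at-random deletion of 1–3 pick pairs — the source
study states no missingness mechanism, so MCAR is the neutral choice.
A master seed fans out to per-respondent child seeds via
`numpy.random.SeedSequence.spawn`, so datasets are byte-reproducible and
any respondent can be re-simulated independently. The completeness filter
partitions submitted responses exhaustively into included (all blocks
answered) and excluded, mirroring the study's exclusion rule.

What the simulator does **not** emulate: demographic covariate effects on
utilities, informative missingness, longitudinal correlation across
phases (the design is cross-sectional), and respondent fatigue or
position effects. Passing recovery tests therefore demonstrates that the
estimator inverts the assumed choice model at the study's sample sizes —
not that the model is a complete account of real respondents.

## Pilot screen

`screen_pilot` implements the Likert ceiling screen that precedes the
BWS survey: items whose mean 1–10 importance rating falls below the
cutoff (default 8) are dropped; a mean of exactly 8 is retained, reading
the rule "below 8 is removed" literally. Missing ratings are rejected
unless an explicit available-case policy is enabled. The packaged
19-item, 20-respondent fixture is synthetic (individual pilot ratings
were never published; the six dropped candidate labels are invented
stand-ins) and mirrors only the 19 → 13 count structure and the ceiling
behaviour.

## Statistical power of rank-recovery checks

At the emulated strata sizes the per-item SE is ≈ 0.13 in the smallest
(pre-operative, n = 36) stratum. The anchored ADL-vs-complication gap
there is 0.20, so the probability that a refit ranks ADL first in that
stratum is ≈ 0.85 even with zero heterogeneity
(z = 0.20/(0.13·√2) ≈ 1.05), and the probability of recovering ADL first
in all three phases simultaneously is ≈ 0.7–0.8. Demanding near-certain
recovery of the full per-phase ranking at these sample sizes is not
statistically attainable, and the test suite's per-phase structure check
documents this: it asserts the strict recovery levels and is expected to
fail at the margin, quantifying how much of the published per-phase
ordering is resolvable at the published sample sizes. The overall fit
(n = 153) is well powered: ADL-top and top-4-set recovery succeed in
≥ 19/20 replicates and Spearman(truth, estimate) ≥ 0.9 throughout.

## Numerical and interface choices

- All file formats are delimited text with headers; designs carry a
  metadata header (v, b, k, r, λ, generator version, item order) so files
  round-trip exactly. Item ids, never positions, appear in files.
- Pipeline artifacts are stamped with a config hash (output directory
  excluded) and seed; reruns with an identical config are byte-identical.
- Degenerate inputs: `k = v` yields the single complete block; a dataset
  with one stratum makes the subgroup fit collapse to the overall fit;
  empty subgroups and incomplete responses raise named errors rather than
  being silently dropped.
- Problem sizes in the test suite (20 replicates at the study's n for
  recovery checks, n = 5000 for the 3-SE consistency check, n = 2000 for
  estimator agreement) were chosen to make sampling noise negligible
  relative to the tolerances asserted.

## Known limitations

- The MaxDiff likelihood treats each block's pair choice as independent
  within respondent given the utilities; within-respondent correlation
  beyond the shared perturbation is not modelled (no mixed logit /
  hierarchical individual estimates — out of scope).
- Confidence intervals are Wald; near the [−1, 1] bounds of the counting
  score or under separation they can be poorly calibrated.
- Interpolated utilities for the six unprinted items are assumptions;
  conclusions about those items' exact positions reflect the
  interpolation, not published evidence.
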