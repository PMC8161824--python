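# Methods

`oligocea` implements a cost-utility and budget-impact model comparing
stereotactic ablative body radiotherapy (SABR) with systemic therapy
(standard of care, SoC) for oligometastatic cancer, from the perspective
of a provincial payer, in 2018 Canadian dollars. This note records the
model, its assumptions, the numerical choices, and what the synthetic
data do and do not establish.

## Model structure

Each arm is a time-inhomogeneous Markov cohort model over mutually
exclusive health states, advanced in 3-month cycles over a 5-year
reference horizon (10 years as a sensitivity analysis). The SABR arm
starts in a single-cycle treatment state (carrying the time-zero cost of
CAD 89,696.22, which bundles amortized capital, delivery and human
resources), then moves through Stable Disease, Progression and
Supportive Care toward an absorbing Death state. The SoC arm starts in
Systemic Therapy, from which patients may stabilise, progress, or die.
Death is modelled explicitly even though the published state list omits
it: overall-survival curves force its existence.

Transition probabilities are time-dependent:

* **Death** per cycle, from every alive state, is the conditional
  probability `1 − S_OS(t+c)/S_OS(t)` of the arm's fitted overall
  survival model.
* **Progression** from states exposed to the progression hazard is
  `max(0, p_PFS − p_death)`, an additive split of the composite PFS
  event (progression or death) into its components. No decomposition is
  published; the split is isolated in one function
  (`markov.assemble_transitions`) so alternatives are local edits. When
  noisy digitized curves cross (PFS "survival" above OS), the
  progression probability is clamped at zero and logged.
* **Fixed clinical transitions** (Progression → Supportive Care,
  Systemic Therapy → Stable Disease, both 0.10 per cycle in the
  reference configuration) are conditional probabilities applied to the
  residual mass after death and progression. Treating them as absolute
  row probabilities would overflow rows late in the horizon when the
  curve-driven death probability approaches 1.
* **Within-cycle events** (toxicity tiers) modify a state's expected
  cycle cost and utility by probability weighting; a tier with a
  configured destination (major toxicity → Progression) additionally
  routes its share of the residual mass. Because the survival curves
  already embed clinical events, curve-driven probabilities take
  precedence and event routing acts only on the residual.

Costs and QALYs accrue on start-of-cycle occupancy, discounted at 1.5%
per year as `(1+r)^(−t)`; no half-cycle correction is applied by default
(a `half_cycle_correction` flag enables trapezoid accrual for
sensitivity). One-time costs are charged on the flow into a state,
discounted at the entry cycle. Life-years count occupancy of non-absorbing
states; QALYs weight it by the state utility.

## Survival extrapolation

Digitized Kaplan–Meier coordinates are fitted with a two-parameter
Weibull, `S(t) = exp(−(t/scale)^shape)` (scale in months; shape 1 is the
exponential), by weighted least squares on the complementary log-log
scale, where the model is linear: `log(−log S) = shape·log t −
shape·log scale`. Points with survival of exactly 0 or 1 are outside
the transform's domain and are dropped with a log entry.

When at-risk counts accompany the coordinates, the weights are the
inverse Greenwood variance of each coordinate mapped to the cloglog
scale. This matters: raw at-risk counts over-weight early event times,
where `|log S|` is tiny and the transform amplifies digitization and
sampling noise enormously; with inverse-variance weights the fit is
unbiased and, on censored Kaplan–Meier curves of 500 subjects, about 97%
of replicate fits recover both parameters within 10%.

The `(log shape, log scale)` covariance comes from the WLS coefficient
covariance via the delta method; it is exactly zero on noiseless input.
Per-cycle transition-probability standard deviations use the delta
method on that covariance inside the observed window. Beyond it, a
standard error of prediction adds the regression's residual variance
(anchored to the Greenwood variance at the last observed coordinate) as
a level shift of the log cumulative hazard: the sensitivity of the
conditional cycle probability to such a shift is `(S1/S0)·ln(S0/S1)`,
bounded by 1/e. Projected sds are floored at the last observed cycle's
sd, so uncertainty never shrinks when the data run out.

For the 10-year horizon the intervention arm's projected schedules
(means, sds, and PSA draws) are replaced by the comparator's beyond 60
months — a deliberately conservative non-durable-effect assumption about
treatment benefit beyond the trial window.

## Probabilistic sensitivity analysis

Second-order uncertainty: costs are gamma, utilities and probabilities
beta, both parameterised from (mean, sd) by the method of moments — the
standard construction when only summary estimates are published. Where
a source gives no dispersion, the default coefficient of variation is
25% for costs and 10% for utilities and probabilities (these published
"variance" figures are read as CVs; a literal variance of 0.25 CAD²
would be vacuous for costs). If the CV rule breaches beta feasibility
the sd is capped at `0.99·sqrt(mean(1−mean))` with a warning, so
literature utilities near 0 or 1 remain usable.

Each of the 10,000 iterations draws one joint parameter set applied to
both arms; parameters shared between arms (e.g. the Progression cost)
are drawn once per iteration, preserving their correlation — independent
draws would inflate the variance of the increments. Per-cycle schedule
probabilities are drawn from betas moment-matched at each time point,
independently across cycles and endpoints; sampled survival paths are
therefore not constrained to be monotone across cycles (a documented
property of per-time-point sampling). Event-tier probabilities are
drawn from betas and renormalised to sum to one within each state.
Randomness is organised as per-parameter substreams derived from the
master seed, so adding a parameter leaves all other draws unchanged, and
identical seeds give bit-identical results.

Outputs: per-arm means with equal-tailed 2.5/97.5 percentile intervals;
the ICER as the ratio of mean increments (not the mean of per-iteration
ratios, which is ill-defined under sign changes), with explicit
dominant/dominated/undefined labels; the CE-plane scatter; and the CEAC
as the fraction of iterations with positive net monetary benefit
`λ·ΔE − ΔC` over a WTP grid of 0–200,000 CAD in steps of 1,000 (ties
count as not cost-effective).

## Budget impact

Undiscounted, hospital perspective, centre with no existing SABR
equipment: all capital and human-resource costs are attributed to
adoption in the year incurred; each annual cohort trades SoC recurring
costs for SABR recurring costs. The reference inputs use the published
year-1 capital total (CAD 5,301,805), recurring per-patient annual costs
derived from the cost table at four cycles per year (SoC: 4 × 43,397.98;
SABR follow-up: 4 × 12,737.47), and 25 patients per year — a mid-size
centre figure chosen because no cohort size is published. Annual and
cumulative impacts are both reported.

## Synthetic trial generator

The trial data and digitized curve coordinates behind the published
analysis are not distributable, so the package generates a synthetic
trial with the statistical structure the analysis assumes: Weibull event
times under proportional hazards (treatment scale = control scale ×
HR^(−1/shape)), OS and PFS coupled through a common uniform per subject
with PFS clamped at OS (progression cannot follow death), and censoring
as exponential dropout (0.005/month) plus an administrative cutoff at 60
months, giving roughly 30% censoring.

Reference effect sizes: control median OS 28 months, OS hazard ratio
0.57, control median PFS 6 months, PFS scale doubled under treatment,
66/33 allocation (2:1 of 99 patients, a plausible trial scale that is a
stand-in, not a historical record). The OS shape 1.47 is chosen so that
HR 0.57 yields a ~13-month median OS gain; toxicity-tier probabilities
(SABR 0.71/0.20/0.09, consistent with a grade ≥ 2 rate near 29%; stable
disease 0.80/0.15/0.05) and the 0.10/cycle clinical transition rates are
fixture choices, as no values are published.

What passing tests show: the pipeline's arithmetic, contracts and
statistical behaviour (parameter recovery, conservation, determinism,
dominance of the treatment arm) under realistic structure. What they do
not show: agreement with the published headline per-arm costs and QALYs,
which depend on the unavailable digitized curves, comparator schedules
and event probabilities. Worked-example checks confirm the incremental
arithmetic and ICERs among the published per-arm summaries; the
reference-case outputs of this package are labelled synthetic throughout.

## Numerical choices and limitations

* Weibull parameterisation is fixed and tested as
  `S(t)=exp(−(t/scale)^shape)`; rate-vs-scale conventions differ across
  tools.
* Degenerate inputs: `S(cycle start)=0` defines the cycle probability as
  1 with a log entry; all-censored input yields a flat curve with a
  warning; an effect difference of exactly zero yields an explicit
  "undefined" ICER, never a division error.
* Problem sizes: the test suite runs the full 10,000-iteration reference
  PSA (seconds on one CPU); parameter-recovery checks use 200 replicates
  of 500 subjects.
* Not modelled: alternative parametric families and AIC selection,
  image digitization, individual-level microsimulation, EVPI, parameter
  correlation beyond shared draws, cancer-site-specific sub-models,
  inflation/currency conversion, equity weighting.
* OS and PFS schedules are sampled independently in the PSA; whether the
  published analysis sampled them jointly is unknown. The comparator
  accepts either a fitted curve or a direct per-cycle probability table.
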