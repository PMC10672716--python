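# Methods

## The problem

Intensive-care trials often measure efficacy as "event-free days out of
G = 28" — days alive and free of an organ-support intervention. Two
features make this endpoint awkward: an excess of zeros (death before
follow-up completion is scored 0) and right truncation at G. When the
trial also wants to learn *which* biomarker-defined patients benefit,
and biomarkers are measured inconsistently, the analysis must handle
partially observed subgroup membership. `zitpseq` implements a Bayesian
group-sequential design for exactly this setting: a zero-inflated
truncated Poisson (ZITP) outcome model, a posterior-probability efficacy
stopping rule, and SUCRA-based posterior ranking of subgroups.

## Probability model

Outcomes are ZITP: a point mass at zero with probability
φ = logit⁻¹(γ₀), mixed with a Poisson(λ) renormalized to {0, …, G}.
log λ is linear in the biomarkers, treatment, and biomarker-by-treatment
interactions; a missing biomarker contributes zero to the linear
predictor. φ is intercept-only (no covariates), so zero inflation is a
population-level nuisance, not a subgroup feature.

Two zero/truncation mechanisms coexist deliberately:

* the **likelihood** uses the renormalized truncated density
  f(y) ∝ λ^y / y! on {0, …, G};
* the **data generator** censors a plain Poisson draw at G
  (R = min(W, G)) and then zeroes it with probability φ via an
  independent uniform coin.

These coincide only when P(W > G) is negligible (true in the shipped
scenarios, where λ ≤ e^3.1 ≈ 22 gives P(W > 28) < 0.1, and the typical
λ ≈ 13.5 gives ≈ 2·10⁻⁴). Both are kept as distinct operations because
the replication studies require the generator's exact mechanism; the
goodness-of-fit test that compares them is run at a G large enough for
the two to agree.

The generator masks biomarkers *before* computing λ, so a hidden
biomarker genuinely does not influence the generated outcome. That is a
literal reading of the generating equation's zeroing rule; it is
biologically odd (measurement should not change biology) but it is the
mechanism the shipped scenarios define, and the alternative
(generate-then-hide) is not exposed as a default.

## Synthetic cohorts

Defaults mirror the shipped study conditions: two independent
Bernoulli(0.5) biomarkers (x2 prevalence is the sensitivity axis:
0.2–0.8), MCAR missingness in three equal random terciles (both
measured / only x1 / only x2 — every patient has at least one
measurement), independent 1:1 Bernoulli randomization (no blocking),
φ = 0.30, G = 28, N_max = 1800 with one interim look at 500. The full
cohort is generated up front and revealed in enrollment order, which is
statistically equivalent to sequential accrual and simplifies
bookkeeping. Six scenario coefficient sets are shipped, spanning a null,
purely prognostic, purely predictive, mixed, and two
qualitative-interaction configurations.

What the generator does **not** emulate: covariate-dependent or
informative missingness, continuous or correlated biomarkers,
staggered entry with pending outcomes at a look, dropout, or any
toxicity endpoint. Passing tests therefore certify the design's
behavior under MCAR binary-biomarker conditions, not under real-world
measurement processes.

## Inference

Priors are independent N(0, sd 10⁴) on every regression coefficient and
γ₀. The sampler is an adaptive random-walk Metropolis-within-Gibbs over
the exact mixture likelihood: one per-parameter sweep (step sizes tuned
to 0.44 acceptance during burn-in) plus one joint update whose proposal
covariance is the empirical covariance of the burn-in history
(Haario-style, tuned to 0.28 acceptance). All adaptation freezes at the
end of burn-in, so kept draws come from a fixed, valid kernel. Subjects
are collapsed to unique covariate patterns with sufficient statistics
(zero count, positive count, positive sum per pattern) — valid because
φ is intercept-only — making one likelihood evaluation O(patterns × G)
and fit cost independent of n. Chain defaults are 3 × (10,000 burn +
30,000 keep); the reduced 3 × (1,000 + 3,000) configuration is used for
desk-scale replication studies and the test suite. Split-R̂ and bulk ESS
come from arviz; typical reduced-setting fits on n = 600 give R̂ < 1.01
and ESS 500–2,500.

Correctness is enforced by tests rather than asserted: the collapsed
likelihood is checked against the plain per-subject log likelihood, and
posterior moments on a tiny intercept-only dataset (n = 20, G = 5) are
checked against deterministic 2-D grid quadrature within Monte-Carlo
error. That oracle test uses an sd-10 prior and zero-rich data: under a
nearly flat prior the γ₀ → −∞ likelihood plateau (φ → 0) carries
non-negligible integrated mass over a ±3·10⁴ range, making "the
posterior mean of γ₀" a property of the prior's extent rather than of
the data — a known pathology of noninformative priors on logit
intercepts. With ≥ 10 zeros out of 20 the plateau's relative mass is
< 10⁻⁶ and the comparison is well posed.

Degenerate inputs: an empty dataset is allowed and samples the prior
(with a warning); 0 < n < #parameters refuses to fit; a treatment model
requires ≥ 2 subjects per arm; an all-zero arm proceeds under the priors
with a warning.

## Effects, pooling, and the stopping rule

The decision scale is the λ contrast (extra event-free days implied by
the count process), per the rule's definition; the expected-outcome
contrast (1 − φ)·(truncated mean) is available as a secondary "days"
scale. Arm-level λ comes from marginal standardization: each in-scope
subject's λ is computed under T = 1 and T = 0 for every draw and
averaged, so both arms share one covariate mix and randomization noise
does not leak into the estimand.

Each look fits three models — both-biomarker on complete cases (≈ n/3),
and each single-biomarker model on everyone with that biomarker measured
(≈ 2n/3 each; these sets overlap the complete cases) — and pools their
contrasts draw-wise, weighted by analysis-set size. The draws of the
three fits are paired by index, i.e. treated as independent posteriors.
The overlap means the pooled posterior is somewhat overconfident
relative to a joint model; this is a property of the design being
studied, and reproducing its published operating characteristics
requires keeping it. Stopping is strict: the trial stops for efficacy
iff the pooled Pr(contrast > δ) strictly exceeds ε, with δ = 2 days and
ε = 0.995 (calibrated once, upstream, for a 5–10% null positive rate).
There is no futility or harm stop; a null trial runs to N_max. Realized
sample size is the enrollment at the stopping look (500 on an interim
stop), which reproduces the published average-sample-size arithmetic.

Non-finite contrast draws (possible when very short chains wander far
enough for exp() to overflow) never count as exceeding δ —
a conservative convention.

## Ranking

Per draw, subgroup effects are sorted descending and awarded ranks
1 … J; exact ties (probability ~0 for continuous draws) are broken
uniformly at random from a dedicated seed stream so results stay
deterministic. The rank matrix is doubly stochastic; SUCRA values sum to
J/2. Marginal ranking pairs the two single-biomarker fits' draws by
index (independence construction — the only one available when four
subgroups span two separate models); joint ranking uses one fit's
aligned draws. An empty joint cell falls back to the model-based
contrast at that covariate pattern, which is exact because the cell
pattern determines λ. Replication-level figures average each
replicate's rank matrix (posterior-probability averaging, not modal-rank
frequencies; per-replicate modal ranks remain accessible through the
stored summaries).

"Correct identification" is operationalized as: the subgroup with
maximal SUCRA at the stopping analysis equals the subgroup with maximal
true λ contrast, computed in closed form from the generating
coefficients by mixing over the other biomarker's prevalence and the
missingness terciles. Under the null all four contrasts tie and the
rate is undefined (reported as NaN/null).

## Replication engine

Seeding is hierarchical — master seed → per-replication SeedSequence →
per-component streams (cohort, each fit, tie-breaks) — so results are
invariant to worker count and any single replication can be replayed.
Rates carry binomial Monte-Carlo standard errors. Scaled-down defaults
(60–200 replications, reduced MCMC) characterize the design to within a
few points; the full-scale configuration (1,000 replications,
3 × 40,000 draws) sits behind the CLI's `--full` flag. Because the
likelihood is pattern-collapsed, running the full N_max = 1800 costs the
same as a small cohort, so sample sizes are never scaled down — only
replication counts and chain lengths are.

## Known limitations

* The pooled overall effect inherits the design's overlap
  overconfidence (above); it is a faithful reproduction, not a
  recommendation.
* φ is intercept-only; covariate-dependent zero inflation, hurdle and
  negative-binomial variants are out of scope.
* The trial engine's ranking step is wired for m = 2 biomarkers (the
  shipped design); cohort generation, fitting, contrasts, and ranking
  primitives accept general m.
* With near-flat priors and very small samples, γ₀'s posterior is
  dominated by the φ → 0 plateau; fits at the shipped sample sizes are
  unaffected (the plateau's relative mass is astronomically small once
  zeros number in the dozens).
* MCAR missingness only; the design's behavior under MNAR biomarker
  measurement is untested and likely worse.
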