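# Methods

This note documents the models, calibrations and numerical choices behind
`dxearly`: the suggestion-ranking law, the consultation-record semantics, the
study simulator, and the clustered analyses. It also states what the
simulator does and does not emulate, and therefore what passing tests do and
do not show about real consultations.

## 1. Evidence base and candidate filtering

The knowledge model is deliberately declarative: per reason for encounter
(RfE), a list of diagnoses with an annual incidence (per 100,000 per annum),
a sex applicability (`male`/`female`/`both`), an inclusive integer age range,
and one or more finding associations `(p_given_dx, p_given_not_dx)` — the
probability of the finding being present when the diagnosis is true
respectively false. Association probabilities are artifact-level parameters:
published primary-care data of this granularity do not exist for most
conditions, so fixtures use hand-chosen values and the simulator samples
them.

Incidence tiers partition the positive reals: common above 50/100,000 p.a.,
rare below 10, uncommon in the closed interval [10, 50]. The inclusive
reading of both boundaries is a design choice, centralized in `tier_of` so a
different convention is a one-line change.

Candidate filtering is a pure predicate (age in range, sex matches or
`both`); risk factors are modelled as findings pre-coded present so they
shift the ranking from the first screen rather than forming a separate
channel.

## 2. Ranking law

The engine scores diagnosis *d* after coded findings *f₁..f_k* as

    score(d) ∝ incidence(d) · Π_i LR_i(d)

with the likelihood ratio using `p_given_dx / p_given_not_dx` for presence,
the complement ratio for absence, and a neutral factor 1 for findings not
associated with *d*. This is the simplest law that combines diagnostic
incidence with the accumulated diagnostic information, and it has the
properties the interface needs: order-invariance (the product commutes),
informativeness of absence, and exact incremental updating. It is naive
Bayes: findings are treated as conditionally independent given the
diagnosis, and `p_given_not_dx` is a single background rate rather than a
mixture over the other candidates. Nothing in the engine depends on the
scores being calibrated probabilities; they are display weights normalized
to sum to one.

Numerics: accumulation is in log space (`log` / `log1p`) with normalization
at read-out via the max-subtraction trick, so underflow cannot occur even
for long consultations. Association probabilities are required to be
strictly inside (0, 1) so every log likelihood ratio is finite.

Display: at `n_coded = 0` the list is grouped common → uncommon → rare with
a seeded uniform shuffle inside each tier (the seed is an explicit argument;
there is no hidden global state). From the first coded finding onward the
order is purely score-descending; ties are broken by the seeded initial
order, making every trajectory deterministic given the seed. Tier grouping
is not re-imposed after coding begins, and no diagnosis is ever dropped from
the list — both deliberate choices: demoting instead of deleting keeps the
rare-but-serious candidates visible, which is the clinical point of the
tool.

## 3. Consultation record

The record is an append-only audit keyed by a 1-based sequence number;
re-coding a finding replaces its status in place (a checkbox has one state)
while keeping its original sequence position. Timestamps are intentionally
absent — a simulated consultation has no meaningful wall clock — so `seq` is
the canonical order. Finalization validates the outcome fields (certainty in
[0, 10], at least one management action, working diagnosis not duplicated in
the differential) and freezes the record. Export is a plain JSON document
designed for lossless round-tripping; import re-validates the sequence
invariants so a tampered document is rejected rather than silently
reordered.

## 4. Study simulator

### Layout

`simulate_study` draws one evidence base (3 RfEs × 18 diagnoses × 5
associations from a 30-finding per-RfE vocabulary), 12 scenarios (four per
RfE, alternating patient sex, ages 22–70), and `n_gps` virtual GPs. Scenario
finding profiles are Bernoulli draws: `p_given_dx` for findings of the true
diagnosis, the finding's mean background rate otherwise. Scenarios get
latent difficulties `d_j ~ N(0, 0.3²)` (centred), split into two sets of six
matched in mean difficulty by a sort-and-alternate pairing. Each GP does the
baseline session first and the DSS session second; with counterbalancing,
even-indexed GPs see set A unaided and set B aided, odd-indexed GPs the
reverse, so each set is seen in each role by exactly half the GPs.
Presentation order is shuffled within session; `scenario_order` runs 1–12
across the two sessions.

A default difficulty SD of 0.3 on the logit scale spreads scenario-level
accuracy over roughly ±7 percentage points around the session mean — enough
heterogeneity to make the difficulty-matching machinery non-trivial without
dominating the GP effect.

### Outcome model and calibration

Correctness of the working diagnosis is Bernoulli on the logit scale:

    logit P(correct) = μ_session + a_i + b_i·[aided] + d_j

with ability `a_i ~ N(0, σ_gp²)` and optional per-GP DSS benefit `b_i`
(default SD 0 — a common population-averaged effect). Two quantities are
solved numerically (41-node Gauss–Hermite quadrature + Brent root finding)
rather than plugged in:

* **σ_gp** such that the *binary-outcome* ICC equals the target: with
  `g(a) = mean_j expit(μ + a + d_j)` the GP-level mean probability,
  `ρ = Var_a[g] / (p̄(1−p̄))`. This is the ANOVA/latent-threshold ICC of the
  0/1 outcome — the scale on which a study reports ρ — not the latent-logit
  ICC, which would be a different (smaller-σ) calibration. Because every GP
  sees all 12 scenarios, the shared difficulty effects cancel from the
  between-GP component and this quantity is exactly what a one-way ANOVA
  moment estimator on the study table estimates.
* **μ_baseline and μ_dss** such that the *marginal* session accuracies equal
  the configured π₀ and π₁ after integrating over abilities and averaging
  the realized difficulties. A naive shift `β = logit(π₁) − logit(π₀)` would
  leave the marginals attenuated by the random effect (by <0.005 at the
  default σ_gp ≈ 0.45, but systematically); the calibrated intercepts make
  π₀/π₁ exact targets, which is what the convergence checks assert.

At the defaults (π₀ = 0.495, π₁ = 0.583, ρ = 0.05) the implied
population-averaged session odds ratio is ≈ 1.43; large simulated studies
recover it through the GEE analysis.

Secondary outcomes per consultation: correct-inclusive adds the true
diagnosis to the differential with probability 0.2 when the working
diagnosis is wrong; management is appropriate when the diagnosis is correct,
else with probability 0.2 (both chosen so the inclusive and management
accuracies sit ~7–9 points above the strict accuracy, the typical spacing in
this kind of study); items coded are Poisson with means 1.64 (unaided) and
12.35 (aided) — the aided policy codes through the consultation module, the
unaided policy emulates GPs recording little or nothing until the end;
certainty, tests ordered and consultation minutes are Normal draws truncated
at the domain bounds with per-session location/scale (7.61/1.77 vs
8.01/1.37; 2.51/2.96 vs 2.83/2.92; 13.73/4.81 vs 14.42/5.28). Truncation is
by redraw, so the *location parameter* matches the configured mean; the
realized mean of a heavily truncated variable (tests ordered) sits above it,
which only the difference-between-sessions checks care about.

All randomness flows from the single design seed through one
`numpy.random.Generator` consumed in a fixed order — evidence base seed,
difficulties, scenarios, then GPs outer / sessions / scenarios inner — so a
study table is reproducible from `(design, seed)` alone.

### What the simulator does not emulate

No actor behaviour, no dialogue, no questionnaire psychometrics, no real
clinical content: diagnosis labels and findings are synthetic and outcome
correctness is drawn from the logit model, not derived from the ranking
engine's output on the scenario profile. Passing calibration tests therefore
shows that the *statistical machinery* (clustering, counterbalancing,
effects, analyses) behaves as specified — not that the DSS would achieve any
particular accuracy gain on real patients.

## 5. Study statistics

`design_effect(n, ρ) = 1 + (n−1)ρ` exactly; `adjust_sample_size` is the
ceiling of the product (with a 1e-9 guard against binary-float dust).
Accuracy summaries report exact integer counts and percent computed in
decimal arithmetic, rounded half-up to one decimal — matching how such
tables are conventionally presented, and avoiding banker's-rounding
surprises at `.x5` boundaries.

Binary outcomes are analysed with population-averaged GEE logistic
regression (exchangeable working correlation, moment estimator for the
common correlation α, robust sandwich variance), the standard
population-averaged treatment of within-participant binary data. The
"multilevel with random intercept" phrasing sometimes used for this analysis
describes a conditional (subject-specific) model; what `xtgee`-style
estimation actually fits is the population-averaged formulation implemented
here, and the two have different estimands when the random effect is large.
The backend is statsmodels' GEE; the surface adds domain validation,
separation and singularity diagnostics (divergent coefficients raise rather
than return garbage), a non-convergence flag, and odds-ratio/CI reporting.
Convergence tolerance is 1e-8 on the coefficient change with a 100-iteration
cap. With an independence working correlation and one observation per
cluster the estimates coincide with the ordinary logistic MLE, which is the
oracle equivalence the tests exploit.

Standard errors default to the plain robust sandwich. For inference at small
cluster counts (a few dozen GPs) the sandwich is anti-conservative, so
`cov_type="bias_reduced"` exposes the Mancl–DeRouen correction; the type-I
calibration battery runs at the 34-GP design size with that correction,
where the empirical rejection rate of the 5%-level session-effect Wald test
sits at its nominal level. A cluster bootstrap (resampling GPs) is provided
as a model-free cross-check on the session OR.

Continuous outcomes use OLS with cluster-robust covariance (statsmodels,
`cov_type="cluster"`). The order-effect check regresses the outcome on
within-session presentation order (1–6) separately per session — the
training-effect diagnostic for a design in which the aided session always
comes second.

The ICC is estimated by the one-way ANOVA moment estimator with the usual
unbalanced-design `n₀`; it carries the estimator's well-known small negative
O(1/k) bias in k clusters, which is why the recovery check averages
replicate studies rather than trusting a single draw.

Power (and, under a null design, type-I error) is by simulation only:
`power_by_simulation` simulates full studies and counts rejections. No
closed-form paired-proportions power routine is offered — such a formula
needs discordance assumptions the simulation makes explicit instead.

## 6. Problem sizes used in the checks

The calibration checks run at sizes chosen to make Monte-Carlo error small
relative to the tolerances: ICC recovery at 200 GPs averaged over 5
replicate studies (SE ≈ 0.005 against a ±0.02 band); marginal-accuracy
convergence at 4,000 GPs (SE ≈ 0.003 per session against ±0.012); type-I
calibration over 1,000 simulated 34-GP studies (SE ≈ 0.7 points against ±2);
large-sample OR consistency at 500 GPs. The exhaustive
incremental-versus-batch ranking check enumerates all 2,882 coding sequences
of up to five findings over a six-diagnosis set.

## 7. Known limitations

* Conditional independence of findings given the diagnosis is assumed by
  the ranking law; correlated findings (syndromes) will over- or
  under-weight evidence.
* `p_given_not_dx` is a background rate, not the properly normalized
  mixture over competing candidates, so scores are rank-faithful rather
  than calibrated posteriors.
* The simulator's accuracy outcomes are generated by the logit model, not
  by running the ranking engine against the scenario; it validates the
  study machinery, not the engine's clinical performance.
* Generated evidence bases make every diagnosis applicable to all
  ages/sexes so candidate-list sizes are exact; age/sex filtering is
  exercised by hand-built fixtures instead.
* The GEE working correlation is exchangeable only; no autoregressive
  structure over scenario order is offered.
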