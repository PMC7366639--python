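# Methods

## The decision model

On each trial of a judgement-bias task a subject hears a tone at one of five
positions on a coded stimulus axis, `s ∈ {-2, -1, 0, 1, 2}`: `-2` is the
trained punisher-predicting reference, `+2` the reward-predicting reference,
and the three intermediate probe tones are never reinforced.  The physical
tones (2, 2.8, 4, 5.6, 8 kHz) are mapped to these idealised positions by
ordinal position on the log-frequency scale, oriented per subject so that
`+2` is always the rewarded tone; the ~0.03 deviation of 2.8/5.6 kHz from
exact log-equidistance is ignored, matching the model's abstraction.

The subject perceives `x ~ N(s, σ²)` and holds the symmetric posterior
`P(pun | x) = Φ(-x/σ)`.  Staying pays `c⁺` if the tone was the rewarded
reference and `-c⁻` if punished; going pays 0.  With `C_p/r = c⁻/c⁺` and
`α = 1/(1 + C_p/r)`, staying is optimal when `x > -σ Φ⁻¹(α)`.
Marginalising the percept and adding a lapse rate `λ` and linear
stimulus-scale shifts gives

    P_stay = (1 - λ) Φ((s + σ Φ⁻¹(α) + δ + ω R_prev + β R_s) / σ) + λ/2

where `δ` is an overall stay bias, `R_prev ∈ {-1, 0, 1}` codes the previous
trial's outcome (air-puff / nothing / sucrose), and `R_s ∈ {+1, -1}` codes
which reference tone is rewarded (`+1` = low tone).  We read the Gaussian
choice kernel as the CDF of `N(0, σ²)`, i.e. the threshold term enters as
`σ Φ⁻¹(α)`, and the additive shifts sit inside the kernel on the stimulus
scale — the only reading consistent with the threshold derivation.

Choices are Bernoulli in `P_stay`; per-trial probabilities are clamped to
`[1e-12, 1 - 1e-12]` before logging so optimisation stays finite.

### Parameters and transforms

| name      | meaning                                   | scale for fitting |
|-----------|-------------------------------------------|-------------------|
| `delta`   | stay bias (stimulus units)                | identity          |
| `c_ratio` | punisher/reward sensitivity `C_p/r`       | log               |
| `sigma`   | perceptual noise SD (stimulus units)      | log               |
| `lapse`   | stimulus-independent error rate `λ`       | logit             |
| `omega`   | shift per unit previous outcome           | identity          |
| `beta`    | shift per unit tone-assignment code       | identity          |

Models are subsets of these; parameters not fitted are pinned in natural
space (`δ=0, C=1, σ=1, λ=0, ω=0, β=0`, overridable).  The canonical
comparison space is the 16 subsets of `{delta, c_ratio, sigma, lapse}`, each
joined with `{omega, beta}`.

## The hierarchy and the EM fitter

Session-level parameter vectors are Gaussian about subject means, which are
Gaussian about a population mean:
`h_ij ~ N(μ_i, Σ)`, `μ_i ~ N(m, ν)`, with diagonal `ν` and `Σ`.  `beta`
cannot vary within a subject (the tone assignment does not), so it lives in
`μ_i` only: it has entries in `m` and `ν` but none in `Σ`, and every session
likelihood reads it from `μ_i` — a three-level structure embedded in the
four-level algebra.

Hyperparameters are estimated by empirical-Bayes EM:

* **E-step.**  Per subject, the joint MAP of `(μ_i, {h_ij})` by L-BFGS with
  an analytic gradient, starting from the prior mean plus jittered restarts
  (SD 0.5) on the first iteration and warm-starting from the previous MAP
  afterwards.  The Laplace covariance is the inverse of a Hessian obtained
  by central finite differences of the analytic gradient (step 1e-4),
  ridge-escalated (×10 from 1e-6) until positive definite.  Its blocks
  `M00` (subject), `Mjj` (session) and `M0j` (cross) feed the M-step.
* **M-step.**  Moment updates: `m` is the mean of subject MAPs;
  `ν = diag{mean(μ̄μ̄ᵀ + M00) - mmᵀ}`; `Σ` pools, over sessions, the spread
  of session MAPs about each subject's *session mean* (the centring term
  `-N_i (h̄_i - μ̄_i)(h̄_i - μ̄_i)ᵀ` is applied as specified; a config flag
  `sigma_centring_correction=False` instead measures spread about the
  subject MAP).  Diagonals are floored at 1e-6 — with one session per
  subject the centred `Σ` update can reach exactly zero.

### Convergence and the δ–C ridge

`delta` and `c_ratio` are nearly redundant: both only shift the effective
decision threshold `Φ⁻¹(α) + δ/σ`, and the data separate them only through
weak second-order structure (how the threshold co-varies with `σ` across
sessions).  With both free, naive EM iteration produces a slow parameter
walk along this near-flat ridge: each step buys a sliver of marginal
likelihood while moving the decomposition substantially.  The fitter
therefore monitors the sampled-prior marginal likelihood (600
common-random-number draws per session by default) at every iteration,
keeps the best iterate seen, and stops on whichever comes first: the
hyperparameters move less than `tol` (1e-3 on `m`, `log ν`, `log Σ`); no
new best for `monitor_patience` (10) iterations; or practical convergence —
the monitored marginal improved by less than `monitor_tol` (0.5 nats, the
order of the monitor's own resolution) over the last patience window — up
to `max_iter` (500).  The returned fit is the best-monitored iterate with a
final E-step pass at those hyperparameters.

The initial `m` comes from a single pooled MAP fit of all trials with one
parameter vector (weak `N(0, 5²)` regulariser); when both `delta` and
`c_ratio` are free, `delta` is held at its null of 0 in that pooled fit,
because the pooled likelihood cannot apportion the threshold between them.
`ν(0) = Σ(0) = 0.5·I`.

Even so, the population means of `delta` and `log C_p/r` are weakly
identified by design: their marginal-likelihood profile along the ridge is
shallow (a one-nat interval spans several tenths), so their sampling error
across simulated cohorts is several times larger than that of the
well-identified components (`log σ`, `ω`, `β`).  Parameter-recovery runs
show occasional seeds where the marginal-likelihood optimum genuinely sits
a few tenths from the generating value along the ridge.  This is a property
of the task design, and is consistent with model selection preferring the
variant without `delta`.

## Model comparison

`iBIC = N_p ln|D| - 2 ln P(D | m, ν, Σ)` with natural logarithms; `|D|` is
the total number of choices.  `N_p` counts 3 per session-level free
parameter (entries in `m`, `ν`, `Σ`) and 2 for `beta` (no `Σ` entry);
`count_variance_components=False` counts only `m` entries.  The marginal
likelihood integrates session parameters over the fitted hierarchy,
estimated per session by Monte Carlo: draw `μ ~ N(m, ν)` then
`h ~ N(μ, Σ)` (`beta` from the `μ` draw), average the K = 2,000 session
likelihoods, take the log, and sum over sessions and subjects; a delete-one
jackknife gives the MC standard error.  Identical trials within a session
share one probability evaluation (exact compaction).

## Inference

The fit never reads condition labels; condition effects are assessed post
hoc on the session-level MAPs.  Group-level nullity of a parameter uses a
two-sided sign-flip permutation test (exhaustive for n ≤ 12, else 10,000
seeded resamples including the identity, so p > 0 always).  Condition
contrasts use the standard 8-contrast family over the 2×2×2 design
(valence × task-specificity × prevalence), computed as within-subject
paired differences of condition-group means; z is the paired mean over its
empirical SE with a two-sided normal p, Holm-adjusted across the family.
A single-step multivariate-normal (Tukey-style) adjustment is deliberately
not replicated; the adjustment method is always reported with the p-values.

## The synthetic cohort generator

The generator emulates the study design the analysis assumes: 14 subjects,
8 sessions each (one per cell of the 2×2×2 pre-test condition design),
60 trials per session (21 per reference tone, 6 per probe, seeded random
order), sequential outcome feedback (`R_prev` is the realised previous
outcome, 0 on the first trial), tone assignment `R_s = +1` for half the
subjects, and the reinforcement contingency (sucrose only for stay on the
rewarded reference, air-puff only for stay on the punished reference,
probes and go never reinforced).  Pre-test schedules deliver the
manipulation 15 times (high prevalence) or once (low) at distinct 1-s grid
points in a 900-s window; they exist for design-count checks (e.g. the
36-pellet ceiling) and do not enter the likelihood.

Default generating hyperparameters (transformed scale):
`m = (δ=-0.1, log C=-1.1, log σ=-0.3, logit λ=-3, ω=-0.2, β=0.5)` and
`ν = Σ = 0.04·I` — a cohort that weighs rewards above punishers, lapses on
~5% of trials, is mildly risk-averse overall and after favourable outcomes,
and prefers the low tone; between-subject and between-session SDs of 0.2
give realistic but not extreme heterogeneity.  Condition offsets default to
zero (a condition-null cohort); effects are injected explicitly via
`condition_offsets` when studying contrast recovery.

What the generator does *not* emulate: within-session learning beyond the
one-trial `ω` term, reaction times, early session termination (supported
via `max_trials` but off by default), satiation or habituation dynamics,
and any acoustic structure of the stimuli.  Passing recovery tests
therefore certify the estimator under the model's own assumptions, not
robustness to real-data violations of them.

## Problem sizes used in the test suite

Closed-form and oracle checks run on toy data (≤ 3 trials for quadrature
comparisons, ≤ 40 trials for grid-search MAP checks).  The generative
recovery check uses the full default cohort (14×8×60) over 10 seeds.
Model-selection consistency uses 20 replicates of a reduced cohort
(6 subjects × 4 sessions) for the pairwise reduced-vs-augmented comparison
and one small cohort for the full 16-model table; these sizes keep the
selection signal (the ~3 ln|D| penalty gap) while holding the suite to
desktop runtimes.

## Known limitations

* `ν` components of weakly-informed parameters (notably `logit λ`) converge
  slowly: when the data say little, the EM fixed-point update leaves `ν`
  near its previous value, so such components should be read as
  regularisers rather than precise variance estimates.
* The Laplace covariance is local; for the δ–C ridge it understates the
  joint uncertainty of the two threshold parameters.
* The MC marginal uses the independent-session reading of the empirical
  prior (`h ~ N(m, ν + Σ)` effectively); it does not integrate the shared
  subject level jointly across a subject's sessions, matching the stated
  sampling scheme.
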