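# Methods

## The race model

A cued TOJ trial contains three racers.  The reference target appears at
(virtual) time 0, the probe at `SOA`, and the cue at `SOA - COA`.  Each
stimulus begins an exponential race toward encoding once it has been visible
for the threshold `t0` (default 0 ms): completion times are
`T_r ~ t0 + Exp(v_r)`, `T_p ~ SOA + t0 + Exp(v_p)`, and
`T_cp ~ SOA - COA + t0 + Exp(v_cp)` for the cue's "cue is the probe"
categorization.  The judgment is "probe first" when the probe or the valid
cue event completes strictly before the reference; floating-point ties count
as "not probe first" (ties have probability zero in the model).

Two refinements shape the base algorithm:

1. **Masking.** The probe masks the cue at probe onset, so the cue race is
   censored at time `SOA`: completions after that are discarded.  The
   uncensored window has length `max(COA - t0, 0)`, giving the capture
   probability `1 - exp(-v_cp (COA - t0))`.
2. **Reference-before-cue regime.** When the reference appears before the
   cue (`SOA > COA`) it cannot yet be affected by the cue and initially
   receives the neutral-condition resources.  The default implementation
   gives the reference a piecewise-constant hazard: `v_neutral` from race
   start until cue onset, `v_r` afterwards.  Because exponential races are
   memoryless this is both tractable in closed form and exactly reduces to
   "the reference raced entirely at the neutral rate" whenever it finishes
   before the cue appears.  Whether the rate actually switches at cue onset
   or stays fixed for the whole race is not empirically settled; the
   all-one-rate alternative ships behind `ModelConfig(regime_rule="fixed")`.
   The two variants differ only for cells with `SOA > COA`.

### Closed form

Writing `S_ref(x)` for the reference's survival function (piecewise
exponential with the hazard above), the two disjoint routes to a "probe
first" judgment are

    p_via_cue   = ∫ over the cue window of  v_cp e^{-v_cp(x - start)} S_ref(x) dx
    p_via_probe = (1 - capture) · ∫_probe_start^∞ v_p e^{-v_p(x - start)} S_ref(x) dx

and `P(p1st) = p_via_cue + p_via_probe`.  The factorization of
`p_via_probe` uses the independence of the cue race and the fact that the
probe cannot finish before its own onset, which is also the cue's censoring
time.  Each integral splits into at most three segments of products of
exponentials, evaluated with `expm1` for small-exponent accuracy.  The
closed form was validated against the trial-level Monte-Carlo simulator at
100 random parameter points (within 4 binomial SE at n = 1e5 draws; see
`tests/test_acceptance.py`), and the no-cue curve, all limits, continuity at
the regime boundaries (`SOA = 0`, `SOA = COA`), and monotonicity in SOA are
property-tested.

Units: interfaces take rates in Hz and times in ms; the single conversion
point (`Hz/1000`) lives next to the kernels.  A numba-compiled scalar copy
of the closed form drives the MCMC likelihood; its equivalence with the
vectorized numpy implementation (within 1e-12) is asserted in the test
suite.

## Synthetic experiments

`make_design("exp1")` reproduces a four-condition design (no-cue, COA 40,
80, 140 ms) with nine SOAs per condition and repetition counts biased toward
the shifting point of subjective simultaneity, 160 trials per condition;
`"exp2"` fixes COA = 80 ms and varies the cue's spatial displacement
(CLD 0/15/60 px), reusing the corresponding repetition rows.  CLD is
condition metadata only — the model has no spatial term; displacement acts
through the generating rates.

Subject populations are log-normal per rate: `log v ~ Normal(log median,
sd_log)`, guaranteeing positivity; defaults use `sd_log = 0.25` for target
rates and `0.5` for the more variable confusion rate.  The beneficial
phenotype's condition medians sit at the package's reference values
(neutral 29 Hz; probe 69 vs reference 22 Hz at COA 80; probe 58, reference
113, confusion 10 Hz at COA 140; the exp2 preset peaks at 83 Hz at zero
displacement and collapses to 27/32 Hz with no confusions at 60 px).  The
disadvantageous phenotype (default mixture weight 0.2) has the cue only
slowing the probe — median probe 20 vs reference 36 Hz with confusion rate
0.5 Hz; these minority-pattern values are illustrative preset choices, as no
quantitative estimates exist for it.  Responses are
`k ~ Binomial(n, P(p1st))` per subject × condition × SOA cell.

What the generator does *not* emulate: lapses/guessing, response errors,
letter identity, trial-order (learning) effects, eye movements, or any
spatial interaction beyond the rate presets.  Passing recovery tests
therefore certifies the estimation machinery under the model's own
assumptions, not robustness to such real-data features.

## Hierarchical inference

The likelihood is binomial per cell with the closed-form success rate.
Subject log-rates are partially pooled:
`log v_i ~ Normal(mu, sigma)` per parameter type and condition, with
`v_neutral` shared across conditions (it also enters cued cells in the
reference-before-cue regime) and condition-specific `v_p, v_r, v_cp`.
Variants: `full`; `rates_only` (`v_cp ≡ 0`); `confusion_only`
(`v_p = v_r = v_neutral`, only the confusion rate free).

Priors (design choice; printed in provenance logs): `mu ~ Normal(log 30,
1.5)` for target rates — weakly informative, centred in the tens of Hz with
a heavy right tail — and `Normal(log 5, 2)` for the confusion rate;
`sigma ~ HalfNormal(0.7)`.

The sampler is a purpose-built adaptive Metropolis-within-Gibbs scheme
(no general-purpose probabilistic-programming MCMC is used):

- **Subject blocks.**  Within each cued condition a subject's
  `(log v_p, log v_r, log v_cp)` are updated jointly by directional slice
  sampling, with per-subject directions drawn from a proposal covariance
  adapted over the warmup history.  The posterior carries strong curved
  ridges between `(v_p - v_r)` and `v_cp` — the same trade-off that shows up
  as their negative posterior correlation — and slice sampling's step-out
  procedure crosses the flat stretches that random-walk proposals diffuse
  along too slowly.  The shared neutral rate, which touches every
  condition's likelihood, uses a cheaper covariance-scaled Metropolis step
  with a periodic slice pass.
- **Group level.**  Means have conjugate Gaussian full conditionals (drawn
  exactly); spreads use random-walk Metropolis on `log sigma`.  Two
  non-centered moves are interleaved to cross the hierarchical funnel:
  an ancillary rescale of `(mu, sigma)` with standardized subject effects
  held fixed, and a slice version of the sigma-rescale for condition-specific
  parameters.  A directional slice translation of a condition's mean vector
  (covariance-adapted) drags all subjects along the group-level ridge.
- **Diagnostics.**  Split-chain R-hat and bulk ESS (arviz) over the group
  parameters; 4 chains by default.  The convergence flag defaults to the
  strict threshold 1.01 — at desk-scale chain lengths (800–1000 warmup +
  draws) typical fits reach worst-case group R-hat ≈ 1.05–1.15, so results
  are routinely *flagged* rather than silently accepted; recovery
  calibration (below) is the operative quality check.  All adaptation is
  frozen after warmup; every random stream derives from the user seed.

Recovery calibration: at the full first-experiment scale (30 subjects,
Table-style design, 160 trials/condition), the generating group medians fall
inside their 95% HDIs in ≈94% of (parameter × replication) checks over
seeded replications — the acceptance suite runs 5 replications at about
45 s each.  Because the fitted hierarchy is homogeneous, recovery runs
generate from the beneficial phenotype only (mixture weight 0).

An explicit, optional filter (`classify_disadvantageous`, off by default)
marks subjects whose posterior mean `v_p - v_r` is negative in every cued
condition while `v_cp` mass concentrates near zero; group summaries never
exclude anyone unless the caller applies it.

## Model comparison

Each variant is fitted and scored by PSIS-LOO expected log predictive
density (arviz) over the cued condition's cells, per condition by default
(the no-cue rows are fitted alongside to pin the neutral rate); a joint mode
scores all cued cells at once.  Ranking applies a one-standard-error
parsimony rule: a more complex nested variant outranks a simpler one only
when its ELPD advantage exceeds the paired difference SE.  Without it the
full and rates-only variants — whose predictions coincide as `v_cp → 0` —
would be ranked by Monte-Carlo noise on confusion-free data.  A fit whose
worst group R-hat exceeds the comparison gate (default 1.2) aborts that
condition's comparison with a diagnostic rather than contributing an
unreliable score.

## Psychometric summaries

PSS is the SOA at which the curve crosses 0.5 (Brent root finding on the
closed form, or linear interpolation on empirical frequencies); DL is half
the distance between the 25% and 75% points (quantiles configurable).  The
classic fit is a maximum-likelihood logistic
`P = 1/(1 + exp((SOA - alpha)/beta))` (Nelder-Mead on `(alpha, log beta)`,
two spread initializations); all-0/all-1 data are flagged as failures, not
fitted.  Note the race-model curve is not logistic: for asymmetric rates the
logistic PSS carries a small systematic offset (a few ms) relative to the
model PSS, and with confusions present the two can differ substantially —
which is precisely the concealment phenomenon the decomposition plots
visualize.

## Problem sizes and numerical choices

- Simulator oracle checks: n = 1e5 per point, 100 random points; the
  qualitative psychometric-family check uses n = 1e4 per SOA at 61 SOAs.
- MCMC defaults: 4 chains × (800 warmup + 800 draws); acceptance recovery
  uses 1000 + 1000, comparison replications 500 + 500 at 12 subjects.
- Probabilities are clipped to `[1e-12, 1 - 1e-12]` inside the likelihood;
  log-rates are clamped to `[-30, 15]` so far-out proposals cannot overflow
  (the prior rejects them regardless).
- `t0` defaults to 0 in fitted models and enters as a common onset delay;
  a per-RateSet `t0` overrides the config value when nonzero.

## Known limitations

- The sampler's worst-direction ESS (tens, on ridge-coupled group spreads)
  is adequate for 95% HDIs and rankings but not for extreme tail quantiles.
- No lapse parameter: a subject with keyboard slips at extreme SOAs would
  bias rate estimates; the classic logistic fit shares this limitation.
- The disadvantageous-phenotype presets are illustrative; conclusions about
  that minority pattern should not lean on their specific values.
- Model comparison inherits PSIS-LOO's finite-sample noise; on datasets
  where variants' predictions nearly coincide the reported ranking depends
  on the parsimony rule, and occasional Pareto-k warnings from influential
  cells are expected at these cell counts.
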