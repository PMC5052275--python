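# cuedtoj

Race-model analysis of **cued temporal-order judgments (TOJs)**, for
visual-attention psychophysicists who want process-level parameters instead
of descriptive psychometric summaries.

## The problem

In a TOJ experiment two targets — a *probe* (preceded by a peripheral cue)
and a *reference* — appear with a stimulus onset asynchrony (SOA), and the
observer reports which came first.  Peripheral cues shift the resulting
psychometric function far more than attention theory predicts.  This package
implements a model, grounded in the Theory of Visual Attention (TVA), in
which every stimulus races for encoding into visual short-term memory with an
exponential rate `v` (after a threshold `t0`), and the cue *also* races — at
rate `v_cp` — to be miscategorized as the probe.  A "probe first" judgment
occurs when the probe, or the cue-as-probe event, is encoded before the
reference:

    P(p1st | v_p, v_r, v_cp, SOA, COA)
      = P( min(T_p + SOA,  [T_cp + SOA - COA]·censored) < T_r ),
        T_x ~ Exponential(v_x)

with two refinements: the cue race is censored at probe onset (the probe
masks the cue), and a reference shown before the cue races at the neutral
no-cue rate `v` until cue onset.  Cue–target confusions (`v_cp > 0`) shift
the psychometric function rightward and grow with the cue onset asynchrony
(COA) even at constant rates — and they can *conceal* opposing rate effects
such as inhibition of return (IOR), where the reference is actually
processed faster than the cued probe.

## What the package provides

| module | contents |
| --- | --- |
| `cuedtoj.model` | closed-form `probe_first_probability`, `decompose_contributions` (cue vs probe share), `cue_capture_probability`, `overall_rate` |
| `cuedtoj.simulate` | trial-level Monte-Carlo race (`simulate_trials`, `simulate_curve`) — the brute-force oracle for the closed form |
| `cuedtoj.design` / `population` / `data` | the two bundled experiment designs (COA 40/80/140 ms; cue displacement 0/15/60 px), log-normal subject populations with beneficial/disadvantageous phenotypes, binomial dataset generation and tidy-CSV I/O |
| `cuedtoj.inference` | `HierarchicalTOJModel` — a scikit-learn-style estimator running a purpose-built adaptive MCMC sampler (Metropolis-within-Gibbs with slice moves) for partial pooling of subject rates; contrasts with 95% HDIs; posterior-predictive bands |
| `cuedtoj.compare` | nested-variant comparison (full / rates-only / confusion-only) by PSIS-LOO with a one-standard-error parsimony rule |
| `cuedtoj.psychometrics` | PSS/DL from model rates or from a classic logistic ML fit |
| `cuedtoj.reporting` | density panels with HDI brackets, normalized predictive curves, cue-contribution decomposition figures |

A `cuedtoj` command-line tool wraps the pipeline
(`generate`, `simulate`, `fit`, `compare`, `report`).

## Worked example

```python
from cuedtoj import (RateSet, TrialCondition, probe_first_probability,
                     decompose_contributions, cue_capture_probability,
                     overall_rate, pss_dl_from_rates)

# IOR-patterned rates at a long cueing interval: the reference races at
# 113 Hz, far faster than the cued probe (58 Hz), but confusions (10 Hz)
# still push judgments toward "probe first".
rates = RateSet(v_p=58, v_r=113, v_cp=10, v_neutral=29)
cond = TrialCondition(soa=0.0, coa=140.0)

print(f"P(probe first | SOA=0, COA=140) = {probe_first_probability(rates, cond):.4f}")
via_cue, via_probe = decompose_contributions(rates, cond)
print(f"  via cue-as-probe categorization: {via_cue:.4f}")
print(f"  via the probe itself:            {via_probe:.4f}")
print(f"cue capture probability (10 Hz, 140 ms): {100*cue_capture_probability(10, 140):.1f}%")
print(f"overall rate C = {overall_rate(rates):.0f} Hz")
for coa in (40.0, 80.0, 140.0):
    s = pss_dl_from_rates(RateSet(50, 50, 10, 50), coa)
    print(f"PSS at COA={coa:>5.0f} ms: {s.pss:6.1f} ms   (DL = {s.dl:.1f} ms)")
```

prints

```
P(probe first | SOA=0, COA=140) = 0.8370
  via cue-as-probe categorization: 0.7534
  via the probe itself:            0.0836
cue capture probability (10 Hz, 140 ms): 75.3%
overall rate C = 181 Hz
PSS at COA=   40 ms:   11.4 ms   (DL = 20.2 ms)
PSS at COA=   80 ms:   34.2 ms   (DL = 33.9 ms)
PSS at COA=  140 ms:   89.1 ms   (DL = 51.0 ms)
```

Reading: at simultaneity the observer says "probe first" on 84% of trials,
and 0.75 of that is carried by cue–probe confusions alone — the cue wins its
140 ms categorization window three times out of four at a mere 10 Hz.  The
last three lines show the signature rightward PSS shift that grows with the
COA even though every processing rate is held constant.

Fitting synthetic data end to end:

```python
from cuedtoj import make_design, default_population, generate_dataset, HierarchicalTOJModel

dataset = generate_dataset(make_design("exp1"), default_population("exp1"), seed=0)
model = HierarchicalTOJModel(variant="full", seed=1).fit(dataset)
print(model.summary_)                                    # group means + 95% HDIs
print(model.contrast("v_r_mu[COA=140]", "v_p_mu[COA=140]"))  # IOR contrast
bands = model.posterior_predict()                        # predictive count bands
```

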