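# mapseg

Event-segmentation agreement analysis for dynamic choropleth maps.

When people watch an animated thematic map — regions recoloring second by
second as some quantity evolves — they spontaneously divide the stream into
discrete events, pressing a key whenever "one meaningful event ends and
another begins". `mapseg` implements the full quantitative pipeline for
studying that behavior: it generates the map stimuli (Voronoi region
partitions with per-second values in [0, 1] under three experimental
designs), simulates key-press cohorts with a change-driven response model,
measures inter-viewer *segmentation agreement*, tests it against
permutation nulls and cross-stimulus baselines, and fits the factorial
mixed models — including marginal effects of the depicted trend and
Monte-Carlo power analysis. It is aimed at researchers in visualization
cognition and event perception who want a tested, reproducible reference
implementation of this analysis.

## The measure

A participant's presses on one stimulus are debounced (presses < 500 ms
after the last retained press are dropped) and binned into 1-second bins,
giving a binary vector *x* with *k* ones. The group norm *m* is the
per-bin proportion of the *other* participants who pressed in that bin.
Because the Pearson correlation of a *k*-ones indicator with *m* is
bounded by placing the ones on the *k* largest (r<sub>max</sub>) or
smallest (r<sub>min</sub>) norm values, the observed correlation
r<sub>obs</sub> is rescaled to

```
agreement = (r_obs − r_min) / (r_max − r_min)   ∈ [0, 1]
```

which removes the confound with press count. Chance level is the
permutation null of the sample-mean agreement obtained by independently
re-timing every trial's binned vector (press counts preserved);
specificity is assessed by scoring each trial against the norms of the
*other* stimuli (and, for the between-group design, the other group).
Factorial effects are estimated with linear mixed models
(`agreement ~ trend * framing * salience + (trend + framing + salience | participant)`,
REML, Satterthwaite degrees of freedom, Wald intervals), with average
marginal effects of trend per framing × salience cell.

## Worked example

```python
import mapseg as ms

designs = ms.enumerate_design(2)[:5]                # five factorial stimuli
series = {d.stimulus_id: ms.generate_series(d) for d in designs}
params = ms.ResponseModelParams(change_gain=4.0, congruence_gain=0.0,
                                participant_sd=0.2)
logs = ms.simulate_cohort(designs, series, 20, params, seed=5)

binned, audit = ms.bin_cohort(logs, {d.stimulus_id: 30 for d in designs})
table = ms.agreement_table(binned).dropna(subset=["agreement"])
obs = table.agreement.mean()
null = ms.permutation_null(binned, iterations=2000, seed=9)
print(audit)
print(f"observed mean agreement: {obs:.3f}")
print(f"null mean {null.mean:.3f} (sd {null.sd:.4f}), 95% interval "
      f"[{null.q2_5:.3f}, {null.q97_5:.3f}]")
print(f"p = {ms.two_tailed_p(null, obs):.4g}")
```

prints

```
{'total': 100, 'empty': 2, 'post_end': 0, 'retained': 98, 'saturated': 0, 'analyzable': 98}
observed mean agreement: 0.542
null mean 0.465 (sd 0.0222), 95% interval [0.422, 0.508]
p = 0.0009995
```

Twenty simulated viewers pressing preferentially where the map's global
value moves agree at 0.54 — clearly above the permutation-null chance band
around 0.47, so the two-tailed permutation p is at the resolution floor of
2000 iterations. Setting `change_gain=0` collapses the observed mean back
into the null interval.

The same machinery runs from the shell: `mapseg simulate`,
`mapseg agreement`, `mapseg null-test`, `mapseg specificity`,
`mapseg power`, and `mapseg run --config config.yaml` for the full
generate → simulate → filter → agreement → null/specificity → fit
pipeline with a written audit trail.

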