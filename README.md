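# erconvoy

**Emotion regulation convoys from experience-sampling data.**

People regulate their emotions through concrete, valence-specific
*tactics* — "enter or seek out positive situations", "hide the expression
of emotion you were feeling", "accept current emotions" — that implement
the broader process-model strategies (situation selection and
modification, attentional deployment, cognitive change, response
modulation) plus acceptance. Two people can use a tactic equally often in
absolute terms while relying on it very differently *relative to their
other tactics*. An **emotion regulation convoy** captures that relative
structure: for each person, the tactics they used are banded into three
frequency circles, by analogy to social convoys — an **inner circle** of
most-relied-on "top tactics", a **middle circle**, and an **outer
circle** of seldom-used tactics.

`erconvoy` is for researchers running experience-sampling (ESM/EMA)
studies of emotion regulation who want person-specific hierarchical
snapshots of tactic use and the group-difference and effectiveness
analyses built on them.

## The method

From a long-format ESM table (one row per survey prompt), per participant:

1. **Regulation instances.** Keep prompts where the respondent reported
   trying to influence their feelings *and* endorsed ≥ 1 of the
   codebook's tactics (default: a 17-tactic codebook split 5/5/5/2 over
   positivity-upregulating, negativity-downregulating,
   negativity-upregulating, and acceptance categories).
2. **Percentages.** Within each measurement burst, each used tactic's
   percentage is `100 · count / n_instances` (instances can endorse
   several tactics). Unused tactics are excluded from the convoy.
3. **Person-specific cut-points.** Sort the anchor burst's used-tactic
   percentages ascending; the values at the nearest-rank 67th and 33rd
   percentile positions (`⌈0.67 n⌉`, `⌈0.33 n⌉`) are the participant's
   fixed upper/lower cut-points, reused in every later burst.
4. **Circles.** A tactic with percentage *p* is **inner** if *p* ≥ upper,
   **outer** if *p* ≤ lower, otherwise **middle**.
5. **Downstream analyses.** Per-circle category shares feed an
   age × category × circle × burst factorial ANOVA with partial η² (and
   noncentral-F confidence intervals) and Games–Howell pairwise
   comparisons; instance-level top-tactic flags feed a two-level mixed
   model of post-regulation affect with within/between (person-mean)
   decomposition, REML estimation, forward selection by AIC/BIC/LRT,
   random-slope retention at p < .10, and Nakagawa marginal/conditional R².

Because real ESM datasets of this kind are rarely shareable, the package
includes a seeded synthetic generator (`erconvoy.synthetic`) that
emulates the study design — 3 bursts × 7 days × 5 prompts, ~27%
regulation prompts, age-tilted tactic propensities, latent-Gaussian
Likert affect with person random effects — and exports ground truth for
parameter-recovery studies.

## Worked example

```python
import erconvoy as ec

cfg = ec.preset_paper_like(seed=7)
cfg.n_per_group = {"YA": 10, "MA": 10, "OA": 10}
ds, truth = ec.generate_dataset(cfg)
ds = ec.filter_eligible(ec.assign_bursts(ds))

results = ec.build_convoys(ds)
print("regulation instance proportion:", round(results.instance_proportion, 3))
one = results.convoys_frame().query("participant_id == 'p0001' and burst == 1")
print(one.to_string(index=False))
cut = results.cutoffs["p0001"]
print(f"cut-points: upper={cut.upper:.2f} lower={cut.lower:.2f}")
```

prints

```
regulation instance proportion: 0.283
participant_id  burst        tactic_id  count  percentage circle
         p0001      1      acc_emotion      5        50.0  inner
         p0001      1    acc_situation      2        20.0  inner
         p0001      1    ad_attend_neg      1        10.0  outer
         p0001      1    ad_attend_pos      1        10.0  outer
         p0001      1  ad_distract_neg      1        10.0  outer
         p0001      1      cc_distance      6        60.0  inner
         ...
cut-points: upper=20.00 lower=10.00
```

This participant had 10 burst-1 regulation instances; `cc_distance`
(distancing/objective analysis) was endorsed in 6 of them (60%), at or
above the person's upper cut-point of 20%, so it sits in the inner
circle — it is one of this person's "top tactics". Tactics endorsed once
(10%) fall at the lower cut-point and band outer. The effectiveness side
then asks whether instances that used an inner-circle tactic (overall or
within a valence category) ended with higher post-regulation affect:

```python
frame = ec.build_model_frame(results.codings, ds.participants)
print("unconditional ICC:", round(ec.fit_unconditional(frame).icc, 3))
# unconditional ICC: 0.316  -> ~32% of affect variance is between persons
```

## Command line

```bash
erconvoy simulate --out runs/sim --seed 7
erconvoy run-all --esm runs/sim/esm.csv --participants runs/sim/participants.csv \
    --codebook default --gap-days 14 --min-instances 13 \
    --boundary-rule outer_wins --out runs/demo
```

`run-all` writes `convoys.csv`, `cutoffs.csv`, `shares.csv`,
`instances_coded.csv`, `person_summaries.csv`, `anova.csv`,
`pairwise.csv`, `models.json`/`models.txt`, and a `run_metadata.json`
with every option, the codebook hash and stage timings, so any run can
be re-executed exactly.

## Documentation

See `docs/methods.md` for the model details, parameter defaults and
their rationale, what the synthetic generator does and does not emulate,
and known limitations.
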