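# Methods

This note documents the models and procedures `erconvoy` implements, the
defaults it ships, the numerical choices behind them, and what the
synthetic generator does and does not emulate.

## Data model and preprocessing

The unit of observation is a survey prompt. A prompt becomes a
**regulation instance** only when the respondent both reported trying to
influence their feelings (`regulated = 1`) and endorsed at least one
tactic of the active codebook; "yes but no tactic" prompts are parsed
but excluded from all analyses. Pre- and post-regulation affect are 1–7
Likert ratings collected only on the regulation branch of the survey.

**Bursts.** ESM designs of this kind deliver prompts in week-long bursts
separated by about four weeks, but field data rarely carries clean burst
labels (restarts, delays). `assign_bursts` therefore recomputes bursts
deterministically from inter-response gaps: within a participant, a gap
of `gap_days` or more starts a new burst. The default `gap_days = 14` is
half the nominal four-week inter-burst interval — long enough that
within-burst gaps (missed days) never split a burst, short enough that a
delayed burst start is still detected. Pre-assigned burst columns are
honored when `recompute=False`. Burst assignment is invariant to input
row order (rows are sorted by timestamp within participant first).

**Eligibility.** Participants are retained when at least one of their
bursts contains `min_instances` (default 13) completed prompts — enough
observations to make a within-burst frequency ranking meaningful. The
filter is idempotent and logs removals.

## Convoy construction

Per participant × burst, each used tactic's percentage is
`100 · count / n_instances`. Multi-tactic instances are expected, so
percentages do not sum to 100. Tactics with zero uses are excluded from
that burst's convoy rather than counted as 0%.

**Cut-points (tertile bands).** The participant's used-tactic
percentages from the *anchor burst* are sorted ascending; the upper and
lower cut-points are the values at the nearest-rank positions
`⌈0.67·n⌉` and `⌈0.33·n⌉`. We use the nearest-rank order statistic
rather than an interpolated quantile because the cut-point is meant to
be the *location* of a rank in the participant's own frequency ordering,
and order statistics keep the cut-points equal to actually observed
percentages; an interpolated convention is available behind
`convention="interpolated"`. The anchor burst is the participant's first
burst with any regulation instances (normally burst 1; later-anchored
participants are flagged in the log). Cut-points are frozen at the
anchor and reused for all later bursts, so convoys are comparable within
person over time; a tactic that first appears in a later burst is banded
against the same fixed numbers.

**Circle assignment.** A tactic with percentage *p* bands inner if
*p ≥ upper*, else outer if *p ≤ lower*, else middle. The membership of a
value exactly equal to the lower cut-point is genuinely ambiguous under
a three-band ≥/≤ scheme (both the outer and the middle rule can claim
it); we resolve it with an explicit `boundary_rule` — the default
`outer_wins` gives the outer rule precedence, `middle_wins` makes the
outer comparison strict — and record the choice in output metadata.
Degenerate convoy sizes fall out of the same rules: a single used tactic
is its own inner circle (upper = lower = its value), and with two
distinct values the top bands inner and the bottom outer. Equal
percentages always share a circle, since assignment is by value against
cut-points, never by rank-slot splitting.

**Category shares and top-tactic coding.** Within each non-empty circle,
a category's share is the fraction of that circle's tactics belonging to
the category (shares sum to 1 per circle; empty circles produce no
rows). At the instance level, `top_any = 1` when the instance endorsed
at least one inner-circle ("top") tactic, and `top_<category> = 1` when
it endorsed an inner-circle tactic of that category; the flags are
independent ORs over the endorsed inner tactics, so one instance can
raise several. Negativity-upregulating flags are computed but excluded
from the default model formulas: NEG_UP tactics are rare and the flag's
distribution is extremely skewed, so its within-person deviations carry
almost no information.

## Group-difference statistics

The circle-composition analysis is a factorial ANOVA on category shares
with one observation per participant × burst × circle × category.
Sums of squares are sequential (Type I) by default, matching the base-R
`aov` workflow this analysis style comes from; Type III is available via
`ss_type=3`, and the choice is recorded in the output because the design
is unbalanced whenever circles are empty or participants miss bursts.
Partial η² is `SS_effect / (SS_effect + SS_error)`; its 95% CI inverts
the noncentral-F CDF in the noncentrality parameter (bisection via
`scipy.stats.ncf`) and maps λ to η² by `λ / (λ + df1 + df2 + 1)`.
Numerically-zero effects (e.g. a constant response) are reported as
F = 0, p = 1 rather than a 0/0 ratio.

Games–Howell pairwise comparisons use Welch-type standard errors
`√(s²ᵃ/nᵃ + s²ᵇ/nᵇ)`, Welch–Satterthwaite degrees of freedom, and the
studentized-range distribution with k groups
(`scipy.stats.studentized_range`); at k = 2 the procedure reduces
exactly to the Welch t-test, which the test suite verifies to 1e-6.
Zero-variance or single-observation groups are an error, not a silent
NaN.

## Effectiveness models

Post-regulation affect is modelled with two levels: instances (L1)
nested in persons (L2), fit with `statsmodels` MixedLM. Time-varying
predictors are person-mean-decomposed: the `_b` column is the person
mean (between), the `_w` column the occasion deviation (within, mean
zero per person by construction). Age enters as YA/OA dummies with the
middle-aged group as reference; burst is centered to the first burst.

The reported sequence is: unconditional model (ICC = τ₀₀/(τ₀₀+σ²));
Model 1 adds burst, age, and pre-affect (within and between); Model 2
adds top-tactic use overall and by category (within and between);
Model 3 adds age × within-person top-tactic interactions; the final
model keeps only interactions significant at α = .05 plus random slopes
retained by LRT at p < .10, fitted per candidate against the model
without it (boundary estimates with near-zero slope variance count as
non-improving). Reported fits use REML; forward selection across
fixed-effect blocks refits with ML, since REML likelihoods are not
comparable across different fixed-effect structures. Fixed-effect p
values use the normal (Wald) approximation — with thousands of L1
observations the difference from Satterthwaite is negligible, and the
choice is documented rather than hidden. Marginal/conditional R² follow
the Nakagawa variance-partition formulas, with the random-effect
variance computed as the average of zᵢᵀĜzᵢ over observations so random
slopes are handled uniformly.

**Variance heterogeneity.** MixedLM assumes one residual variance, so
the age-group-heterogeneity check is fit directly: the unconditional
model's per-person likelihood is compound-symmetric with closed-form
determinant and inverse, and homogeneous vs group-specific residual
variances are both maximized numerically (Nelder–Mead on log-variances),
compared by LRT (df = #groups − 1) and AIC. The recommendation is
"heterogeneous" only when both agree (LRT p < .05 and lower AIC).

## Synthetic generator

`generate_dataset` emulates: the 3 × 7 × 5 prompt schedule with
four-week inter-burst gaps; Bernoulli regulation prompts (default
p = 0.27); instance-level tactic endorsements drawn as independent
Bernoullis from age-group-tilted propensities, redrawn until at least
one tactic is endorsed (so every generated instance satisfies the
instance definition); missingness thinning prompts at a configured rate
(default 0.13, matching a median of ~91 completed of 105 scheduled
prompts); and affect produced by rounding and clamping a latent Gaussian
two-level model to the 1–7 scale. The latent model is
`post* = γ₀₀ + u₀ + b_w(pre* − person mean) + b_b·(person pre deviation)
+ Σ_c β_c·used_c + ε`, with `used_c` the indicator that the instance
endorsed any tactic of category *c*, `u₀ ~ N(0, τ₀₀)`,
`ε ~ N(0, σ²)`, and optional per-person random slopes on the category
indicators. All randomness flows from one seed; identical configs give
bit-identical datasets.

Defaults in `preset_paper_like` are chosen to be realistic for this
study class: 82/77/77 participants across the 18–39/40–59/60–87 age
bands; τ₀₀ = 0.72 and σ² = 1.08 (total latent variance 1.8 with a 0.40
between-person share, typical for repeated affect ratings); post-affect
intercept 5.2 and within-person pre-affect slope 0.45; category effects
with a positive positivity-upregulation effect (+0.36) and a small
negative negativity-downregulation effect (−0.10); propensities that
make positivity-upregulating and acceptance tactics most endorsed, with
older adults tilted further toward positivity-upregulation and younger
adults toward negativity-downregulation, and negativity-upregulation
rare everywhere. `preset_parameter_recovery` (~200 participants, no
missingness, a single planted +0.4 within-person positivity-upregulation
effect, latent between-person variance share 0.40, all other affect
effects zero) is the configuration used by the recovery tests and the
acceptance script.

**What the generator does not emulate — and what passing tests
therefore do not show.** Tactic endorsements are independent within an
instance (a logistic-normal correlated option exists for stress-testing,
but real tactic co-occurrence structure is unknown); affect is generated
from category-*use* indicators, not from convoy-derived top-tactic
flags, so recovery tests validate the estimation machinery rather than
any claim that top-tactic effects in real data are unconfounded;
response-time behavior, notification mechanics, and compliance dynamics
are out of scope. Discretizing the latent affect to a 7-point scale adds
occasion-level rounding noise (~1/12 variance) and mild ceiling
compression, which biases the estimated ICC slightly below the latent
0.40 (typically ≈ 0.38) and attenuates slopes by a few percent — the
recovery tolerances (±0.05 on ICC, 2 SE on coefficients) cover this, and
it is a property of Likert measurement the analysis of real data would
face too.

## Problem sizes

Simulation-backed tests and the acceptance script run at deliberately
moderate scale — 100–200 participants, 3 bursts, ~5,000–21,000 prompts,
1,000 random profiles for the banding oracle, 100 datasets for the
Games–Howell identity — sizes at which the checked quantities are stable
(ICC standard error ≈ 0.025 at 200 participants) while the whole suite
stays fast.

## Known limitations

- Field datasets sometimes need manual burst repair after app failures;
  the deterministic gap rule cannot reproduce hand edits, only
  approximate them.
- The "Other / free-text" regulation category is supported via OTHER
  tactics in a user codebook but defaults to exclusion from the
  17-tactic convoys; free-text coding itself is out of scope.
- Mixed-model p values are Wald/normal; Kenward–Roger-style small-sample
  corrections are not implemented and would matter for studies with few
  participants.
- The heterogeneous-variance check covers group-specific residual
  variances in the unconditional model, not heterogeneity in covariate
  effects.
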