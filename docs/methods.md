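# Methods

## The model

A surface-active burrowing ectotherm is observed once: body temperature
*T*<sub>b</sub> (°C), surface temperature *S* at the capture point, and —
for a subset of records — the temperature *B* at the bottom of a nearby
30 cm reference burrow, all at 0.1 °C probe precision. Two derived
coordinates carry the analysis:

- cooling capacity *x* = *B* − *S* (negative when the burrow is cooler),
- thermoregulation capacity *y* = *T*<sub>b</sub> − *S*.

The working model is that observations fall on a line on these axes,

  *y* = *E*<sub>B</sub>·*x* + *b*,

where the slope *E*<sub>B</sub> ∈ [0, 1] is the burrow use efficiency
and the intercept *b* = *T̂*<sub>e</sub> − *S* is the passive (no-refuge)
offset of body over surface temperature, expected positive. A second
regression, of *y* on *S* (*y* = *m·S* + *c*, *m* < 0), describes how
thermoregulation capacity erodes as the surface warms; intersecting it
with the level *y* = *b* gives the onset surface temperature
*S\** = (*b* − *c*)/*m* and the onset body temperature
*T*<sub>reg</sub> = *S\** + *b*, with the x-intercept −*c*/*m* as an
upper bound. The same fit implies the marginal response
d*T*<sub>b</sub>/d*S* = 1 + *m*.

Animals are analysed in four sex-by-size classes defined on carapace
width (closed intervals, mm): small females 9–12.9, large females 13–17,
small males 10–14.9, large males 15–20. Widths inside the 0.1 mm
inter-class gap (unreachable at caliper precision) fall to the lower
class; widths outside a sex's range are excluded and reported. Records
without a burrow reading are kept for the *y*-vs-*S* analysis and
excluded from the axes analysis; both denominators are reported.

## Estimation and uncertainty

All regressions are ordinary least squares solved in closed form from
the normal equations; standard errors are the usual homoscedastic ones,
and each fit retains cov(slope, intercept). *T*<sub>reg</sub> inherits a
delta-method standard error from (*m*, *c*, *b*) treating the two
regressions as independent (an extension labelled as such in output — the
onset itself is a point construction). Group contrasts combine the two
groups' independent standard errors in quadrature. When *m* ≥ 0 the onset
does not exist; the estimate is reported as a reason-coded absence, never
a number.

Reported tables round to 2 decimals (estimates) and 3 decimals
(p-values); all internal computation is full precision. No
multiple-testing correction is applied across the four per-group
regressions; Dunn's post hoc uses Bonferroni over all pairs.

## Hypothesis tests

Size effects are tested per sex with the covariate entered first:
sequential (Type I) sums of squares over the nested designs
{1} ⊂ {1, covariate} ⊂ {1, covariate, size} ⊂ {1, covariate, size,
covariate×size}, each term's F using the residual mean square of the
largest model. The interaction term is the homogeneity-of-slopes test.
Size may enter as the dichotomous class or as continuous carapace width.
The sequential convention is a documented choice; it makes the
parametric table partition exactly the same total SS as the
permutational analogue. For the test of record (not for estimation) the
dependent variable may be variance-stabilised as
sqrt(y − min(y) + 0.01); capacities are routinely negative, so a bare
square root would be undefined.

The permutational analogue (PERMANOVA) Gower-centres the matrix of
−½·squared Euclidean interpoint distances and partitions its trace over
the same nested designs, SS(term) = tr((H<sub>i</sub> − H<sub>i−1</sub>)G).
For a univariate Euclidean response this is algebraically identical to
the raw-space partition (asserted to 1e−8 in tests). Significance comes
from free permutation of observations: p = (#{F<sub>perm</sub> ≥
F<sub>obs</sub>} + 1)/(n<sub>perm</sub> + 1), with n<sub>perm</sub> = 999
by default, hence a p-value floor of 0.001. One integer seed drives the
permutation stream; reports record it. Residual permutation and
non-Euclidean metrics are out of scope (the responses here are univariate
temperature differences).

Kruskal–Wallis uses average ranks with the tie correction
1 − Σ(t³ − t)/(N³ − N) and a χ² reference on k − 1 df; Dunn's z uses the
pooled-rank variance N(N+1)/12 − Σ(t³ − t)/(12(N − 1)).

## The synthetic field season

The generator emulates a four-month low-tide collection campaign
(March, May, August, October; "September" is accepted as an alias of
October on input). Defaults, all overridable:

| parameter | small ♀ | large ♀ | small ♂ | large ♂ |
|---|---|---|---|---|
| *E*<sub>B</sub> | 0.50 | 0.42 | 0.35 | 0.34 |
| *b* (°C) | 2.04 | 1.31 | 1.11 | 0.96 |
| *T*<sub>reg</sub> (°C) | 24.52 | 24.48 | 23.81 | 24.20 |
| n March/May/Aug/Oct | 22/19/24/5 | 19/51/22/27 | 38/48/32/9 | 38/29/35/23 |

totalling 441 crabs (189 female, 252 male); residual noise sd 0.8 °C
(chosen to put per-group R² in the observed 0.4–0.8 band); per-sex
missing-burrow fractions 32/189 and 32/252, leaving ≈157 female and
≈220 male burrow-paired records.

Environment: *S* ~ Normal per month with (mean, sd) = (21, 3) March,
(28, 3.5) May, (37, 4) August, (31, 2.5) October — surfaces span roughly
15–45 °C; burrows follow *B* = *S* − κ·max(0, *S* − *S*₀) + jitter with
κ = 0.9, *S*₀ = 23 °C, jitter sd 0.5 °C (the observed stability of the
deep-burrow microclimate), giving a cooling capacity near −20 °C at a
45 °C surface, the observed midday extreme. *S*₀ is placed at the
surface temperatures where the groups' onsets fall (22.5–23.2 °C): the
single-line onset estimator assumes the observed capacity line crosses
the level *b* at the onset, which requires the refuge to become
available roughly where thermoregulation begins.

Behavior is piecewise: each crab draws ε ~ Normal(0, sd) once and a
candidate passive temperature *T*₀ = *S* + *b* + ε; if
*T*₀ ≤ *T*<sub>reg</sub> the burrow is ignored (*T*<sub>b</sub> = *T*₀),
otherwise *T*<sub>b</sub> = *S* + *b* + *E*<sub>B</sub>·(*B* − *S*) + ε.
A JSON sidecar records every generating parameter, the seed, and each
record's branch, so any estimate can be joined to its truth; the same
seed reproduces the CSV byte-for-byte.

What the generator does not emulate: tidal timing, site geometry and
burrow maps, behavioral covariates (courtship, feeding), sex-specific
morphology such as the male claw's heat-sink effect, within-day
autocorrelation of surface temperature, and any nonlinearity of the true
capacity–surface relation beyond the single onset kink. Passing
recovery tests therefore demonstrate correctness of the estimator chain
under the stated model, not fidelity of that model to any particular
marsh.

## Known limitation: onset attenuation on piecewise data

Below onset the generated capacity is flat at *b*; above onset it
declines. A single line fitted across both regimes crosses the level *b*
near the centre of the non-thermoregulating cluster rather than at the
onset, so the full-sample *T*<sub>reg</sub> runs low — about 1.5–2.5 °C
under the default month structure (cool March records anchor the flat
segment). The full-sample estimate remains the headline analysis output,
since on real data the linearity of the observed relation is an explicit
model assumption; for synthetic runs the report's `recovery` section
additionally refits on the crabs the sidecar marks as thermoregulating,
on which subset the estimators are unbiased. Parameter-recovery checks
use that conditioned path. Fits on full-range synthetic data likewise
recover slightly attenuated *E*<sub>B</sub> (non-thermoregulating records
cluster at *x* ≈ 0, *y* ≈ *b* and mostly sit on the line, so this effect
is small).

## Numerical and design choices

- Degenerate designs fail loudly: constant covariate, < 3 points, an
  empty factor level, or an all-zero distance matrix raise errors; a
  constant cooling capacity raises an error advising that burrow
  temperatures did not vary. A single-level factor collapses the ANCOVA
  onto the covariate-only regression.
- With an exactly-fitting model (zero residual MS), term F statistics are
  reported as +∞ (p → 0) when the term explains variance and 0 otherwise.
- R² is clipped to [0, 1] against round-off and defined as 0 for a
  constant response.
- Validation never silently drops rows: accepted + flagged + rejected
  equals the input count, with reason codes per row; temperatures outside
  a configurable 0–60 °C plausibility window reject the row.
- Problem sizes in the test suite — 200 null simulations at n = 40 with
  199 permutations for calibration, 100 seasons of 441 records for
  recovery, 50 datasets for the classical-F equivalence — were chosen as
  the smallest sizes at which the binomial tolerance bands are
  meaningful.
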