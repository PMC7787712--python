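# burrowtherm

Behavioral thermoregulation analysis for burrowing intertidal ectotherms.

Surface-active animals such as fiddler crabs forage on exposed mud flats
where sediment temperatures can exceed their critical thermal limits, and
retreat into burrows to shed heat. `burrowtherm` estimates, from field
records of body temperature *T*<sub>b</sub>, capture-site surface
temperature *S*, and reference-burrow temperature *B*, three parameters
that characterise this strategy:

- **Burrow use efficiency *E*<sub>B</sub>** — the slope of the
  *thermoregulation axes*, the regression of the thermoregulation
  capacity *y* = *T*<sub>b</sub> − *S* on the burrow cooling capacity
  *x* = *B* − *S*:

  *y* = *E*<sub>B</sub>·*x* + *b*

  *E*<sub>B</sub> = 0 means the burrow is ignored; *E*<sub>B</sub> = 1
  means the body tracks the burrow completely.
- **No-refuge offset *b* = *T̂*<sub>e</sub> − *S*** — the intercept of
  that line: how much warmer than the surface the body runs when the
  burrow offers no refuge (*B* = *S*), set by passive thermal properties.
- **Onset temperature *T*<sub>reg</sub>** — the body temperature at which
  burrow thermoregulation begins. Writing the regression of
  *T*<sub>b</sub> − *S* on *S* as *y* = *m·S* + *c* (with *m* < 0), the
  onset surface temperature solves *m·S\** + *c* = *b*, so
  *S\** = (*b* − *c*)/*m* and *T*<sub>reg</sub> = *S\** + *b*; the
  x-intercept −*c*/*m* bounds *T*<sub>reg</sub> from above. The same fit
  yields the marginal body-temperature response
  d*T*<sub>b</sub>/d*S* = 1 + *m*.

Around these estimators the package provides the supporting statistics
implemented from first principles — OLS with exact normal-equation
solutions, sequential (Type I) ANCOVA with the homogeneity-of-slopes
interaction test, Kruskal–Wallis *H* with Dunn's Bonferroni post hoc, and
a distance-matrix PERMANOVA whose univariate-Euclidean pseudo-*F* is
algebraically identical to the classical *F* — plus a synthetic
field-season generator with a ground-truth sidecar, so the entire chain
is testable without field data.

## Worked example

```python
import burrowtherm as bt

model = bt.ThermoregModel.from_synthetic(seed=42)   # 441-crab season
results = model.fit(n_perm=999, seed=42)
print(results.summary())
```

The summary begins:

```
Thermoregulation estimates per group
----------------------------------------------------------------------
group             n     E_B    (se)  b=Te-S    (se)   T_reg   upper
small_female     61    0.49    0.01    2.07    0.13   22.95   26.32
large_female    101    0.41    0.02    1.06    0.13   23.06   25.23
small_male      112    0.35    0.01    1.10    0.11   22.03   25.23
large_male      108    0.33    0.01    0.94    0.10   21.39   24.37

Implied body-temperature sensitivity dTb/dS = 1 + m
  small_female    0.62 °C/°C
  large_female    0.67 °C/°C
  small_male      0.74 °C/°C
  large_male      0.76 °C/°C
```

Each row is one sex-by-size class: `n` burrow-paired records enter the
axes fit, `E_B` is the burrow use efficiency with its standard error,
`b=Te-S` the no-refuge offset, `T_reg` the estimated onset body
temperature and `upper` its x-intercept bound. Here females exploit the
burrow's cooling capacity more efficiently than males (0.49/0.41 versus
0.35/0.33 °C per °C), run warmer above the surface when the burrow is no
refuge, and consequently resist surface warming more strongly (their
bodies gain ~0.6–0.7 °C per 1 °C of surface warming, males ~0.75 °C).
This season was simulated, so the report's `recovery` section joins each
estimate to its generating value; the onset-conditioned small-female
estimates recover *E*<sub>B</sub> = 0.49 ± 0.02 and
*T*<sub>reg</sub> = 24.9 ± 0.53 °C against generating values 0.50 and
24.52 °C (the full-sample *T*<sub>reg</sub> of 22.95 °C illustrates the
attenuation discussed in `docs/methods.md`).

The same analysis runs from the shell on a CSV of field records
(`crab_id, site, sex, carapace_width_mm, body_temp_c, surface_temp_c,
burrow_temp_c, month`; burrow blank when not probed):

```sh
burrowtherm simulate --seed 42 --out season.csv
burrowtherm validate --input season.csv
burrowtherm report --input season.csv --seed 42 --out-dir run/
```

`run/` then contains `estimates.tsv`, `tests.json`, `report.json` and
diagnostic `figures/`.

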