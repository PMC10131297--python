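# densityfeedback

Simulation and inference toolkit for studying when census time series reveal —
or hide — the density feedbacks acting on vital rates.

Population ecologists routinely fit logistic-growth ("phenomenological")
models to abundance censuses to ask whether a population is regulated: does
the per-capita growth rate r_t = ln(N_{t+1}/N_t) decline with abundance?  But
the feedback detected that way (the *ensemble* feedback on r) can decouple
from the *component* feedback actually operating on a vital rate such as
survival.  This package builds a fully controlled testbed for that question:
age-structured (Leslie matrix) populations of 21 long-lived vertebrate life
histories carry a known compensatory feedback on survival,

    S_red(N) = a / (1 + (N / b)^c),

with a, b, c calibrated so each population is stationary at its carrying
capacity K = D·A (equilibrium density times a 250,000 km² closed region).
Populations are projected yearly with beta-resampled survival (5% SD),
Gaussian-resampled fertility, generation-scaled catastrophes
(p = 0.14/G per year, ~50% severity), and nine nonstationarity scenarios
(pulse mortality, harvest-driven decline, fluctuating or eroding carrying
capacity, and a feedback-free null).  Each simulated census is then analyzed
exactly as a field ecologist would analyze real data:

* four Gaussian models of r_t — random walk, exponential, Ricker
  (r = α + βN), Gompertz (r = α + β ln N) — compared by AICc weights;
* Pr(density feedback) = summed weights of the Ricker + Gompertz pair;
* ensemble strength = −β̂ of the Gompertz model;
* component strength = mean of (1 − S_red) along the series;
* a return-time stationarity index (mean/variance of times to re-cross the
  series mean);
* cross-species agreement via an interval bootstrap of Spearman's ρ and
  exponential-plateau fits y = ymax − (ymax − y0)e^(−kx).

## Worked example

Calibrate one fast and one slow life history, simulate the stable
catastrophe scenario, and summarize detection:

```python
from densityfeedback.pipeline import run_study
from densityfeedback.synthesis import scenario_report

results = run_study(["ii", "ix"], ["DM", "GN"], n_reps=100, seed=1)
table, _ = scenario_report(results, n_boot=2000, rng_seed=1)
print(table[["scenario", "median_pr_density_feedback",
             "share_pr_above_0.5"]].to_string(index=False))
```

prints

```
scenario  median_pr_density_feedback  share_pr_above_0.5
      ii                    0.932990               0.975
      ix                    0.441318               0.420
```

With the component feedback operating (scenario ii), the density-feedback
model pair wins in ~98% of the simulated censuses.  In the null
(scenario ix: survival reduction switched off, catastrophe intensity
recalibrated so the population is stable on average), median support drops
below 0.5 — though not to zero, because regressing r_t on the abundance of a
random-walking population is intrinsically biased toward spurious
mean-reversion.

The same analysis is available from a shell:

```bash
densityfeedback simulate --scenarios ii --species DM --n-reps 5 --seed 7 --out out/
densityfeedback fit --scenarios ii,ix --species DM,GN --n-reps 100 --seed 1 --out out/
densityfeedback report --results out/results.csv --out out/
densityfeedback fit-census my_census.csv   # your own year,N data
```

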