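# lbpcea

Cost-effectiveness analysis of adding acupuncture, delivered collaboratively
with conventional care, to usual care alone for chronic low back pain (LBP)
in South Korea — implemented as a tested, configurable decision-modelling
pipeline for health economists and HTA analysts.

## The model

A four-state Markov cohort model tracks 60-year-old women from a first
episode of acute LBP through states {acute LBP, chronic LBP, well, dead}
over 20 quarterly cycles (five years). Per cycle, with all-cause mortality
*m* and clinical transition probabilities applied to survivors:

- acute → chronic: (1−m)·0.24, acute → well: (1−m)·0.76 (acute lasts one cycle)
- chronic → well: (1−m)·p, with p = 0.35 under usual care and
  p = min(RR·0.35, 1) under collaboration, RR = 1.40 from a random-effects
  meta-analysis of recovery risk ratios
- well → chronic (recurrence): (1−m)·0.16; dead is absorbing

Costs (2009 KRW) accrue only in the chronic state — 507,776 per cycle under
usual care and 730,329 under collaboration (direct medical + direct
non-medical; an equal indirect productivity cost of 239,142 is toggled on
for univariate sensitivity analysis). Effectiveness is measured in QALYs
using state utilities 0.85 (acute), 0.62/0.65 (chronic, by strategy), 0.96
(well). The comparison reports the incremental cost-effectiveness ratio
ICER = ΔCost/ΔQALY; uncertainty is propagated by a 10,000-draw
probabilistic sensitivity analysis (Beta/Gamma/lognormal parameter
distributions) summarised as a cost-effectiveness acceptability curve
(CEAC, the probability that collaboration has the higher net monetary
benefit λ·QALY − Cost), and the expected value of perfect information
EVPI(λ) = E[maxₛ NMBₛ] − maxₛ E[NMBₛ], scaled to the 57,400 incident
cases per year over a five-year horizon.

The DerSimonian–Laird random-effects pooling that supplies RR, and
synthetic generators for the two externally sourced inputs (study-level
recovery counts; an age-specific life table), are part of the package.

## Worked example

```python
from lbpcea import default_config, base_case

result = base_case(default_config())
uc = result["outcomes"]["usual_care"]
ac = result["outcomes"]["collaborative"]
inc = result["incremental"]
print(f"usual care:     {uc.cost:,.0f} KRW, {uc.qaly:.2f} QALYs")
print(f"collaboration:  {ac.cost:,.0f} KRW, {ac.qaly:.2f} QALYs")
print(f"ICER: {inc.icer:,.0f} KRW per QALY")
```

prints

```
usual care:     2,923,397 KRW, 4.24 QALYs
collaboration:  3,374,836 KRW, 4.37 QALYs
ICER: 3,439,780 KRW per QALY
```

Per person over five years, collaboration buys ≈0.13 extra QALYs for
≈451,000 extra KRW, i.e. about 3.44 million KRW per QALY — far below the
20 million KRW per-capita-GDP willingness-to-pay benchmark. The same
pipeline from the shell:

```bash
lbp-cea run-base --out results        # deterministic + indirect-cost sensitivity
lbp-cea run-psa  --out results        # CE plane + acceptability curve
lbp-cea run-voi  --out results        # EVPI curve
lbp-cea run-all  --out results        # everything + manifest
lbp-cea simulate-data --out fixtures  # synthetic studies.csv / life_table.csv
lbp-cea meta-pool --studies fixtures/studies.csv
```

All behaviour is driven by one YAML configuration
(`src/lbpcea/data/default_config.yaml`); pass `--config your.yaml` to any
command to change states' parameters, distributions, cost schedules,
conventions, or the mortality schedule.

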