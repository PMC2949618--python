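# genequit

A Markov cohort cost-effectiveness model asking: **what impact would a
lung-cancer genetic test need to have, added to a usual smoking-cessation
program, to be worth paying for?**

Smoking-cessation programs (nicotine replacement therapy plus counselling)
are cheap but suffer low 12-month quit rates (~6%) and heavy long-term
relapse. Personalised genetic information about lung-cancer risk may
motivate smokers to quit and stay quit. A genetic test adds about AU$356
per person; the question is whether the downstream health gains — averted
lung cancers, quality-adjusted life-years (QALYs) — justify it.

The package is written for health economists and modellers: it implements
the full decision-analytic pipeline as a typed, tested library with a CLI,
driven entirely by parameter tables (no external data downloads).

## The model

Two strategies are compared for a cohort of heavy smokers (default: aged
50, followed 35 years in annual cycles, costs and effects discounted at 5%,
payer perspective, 2009 AU$):

* **USC** — usual smoking cessation (GP visit, NRT patches, telephone
  counselling, booklet): $802.10/person, 12-month quit rate 6%;
* **GT** — USC plus a genetic test (two clinic visits, assay, results
  booklet): $1,158.00/person, quit rate 11%.

Five health states: *no lung cancer (quit)*, *no lung cancer (smoking)*,
*early lung cancer* (stage I/II), *advanced lung cancer* (stage III/IV),
*dead*. Cancer states carry 5-year **tunnel states** so death risk and
treatment cost depend on time since diagnosis; quitters relapse at 10%/year
in years 2–6 and 4%/year thereafter (relapsers never re-quit, so time since
quit equals model time). Cancer onset is background incidence × relative
risk (6.609 for current heavy smokers; decaying with years since quit for
ex-smokers, never reaching 1). The headline statistic is the incremental
cost-effectiveness ratio

```
ICER = (C_GT − C_USC) / (E_GT − E_USC)
```

judged against a willingness-to-pay (WTP) of $20,000/QALY, plus net
monetary benefit (NMB = WTP·E − C), threshold/break-even searches and a
10,000-iteration probabilistic sensitivity analysis (beta distributions on
probabilities and utilities, gamma on costs) with a cost-effectiveness
acceptability curve.

The age-indexed epidemiology (all-cause mortality, lung-cancer incidence,
ex-smoker relative risks, cancer survival) is generated by
`genequit.synthetic_epi` from smooth parametric curves pinned exactly to
published anchor values (e.g. mortality 0.00936 and incidence 0.0018024 at
age 65, ex-smoker RR 4.75 at ages 50–55, cancer survival 36% at 1 year and
12% at 5 years). See `docs/methods.md` for the functional forms and every
modelling convention.

## Worked example

```python
import genequit as gq

cfg = gq.load_basecase()

# 12-month view, 1000 persons per arm
st = gq.short_term(1000, cfg.usc, cfg.gt)
print(st.as_dict())

# 35-year cohort model
res, usc_trace, gt_trace = gq.evaluate(cfg)
print(f"ICER ${res.as_dict()['icer']:,}/QALY")

print(gq.threshold_quit_rate(cfg))
```

prints (numbers produced by this code):

```
{'cohort_size': 1000, 'cost_usc': 802100.0, 'cost_gt': 1158000.0,
 'quitters_usc': 60, 'quitters_gt': 110, 'delta_cost': 355900.0,
 'delta_quitters': 50, 'cost_per_additional_quitter': 7118}
ICER $26,681/QALY
ThresholdResult(value=0.1229..., status='found', wtp=20000.0, parameter='quit_rate_gt')
```

Reading: the test buys 50 extra quitters per 1000 smokers at $7,118 each;
over 35 years it costs $26,681 per QALY gained — above the $20,000
threshold — and would need a 12-month quit rate of at least ~12.3% to break
even in net benefit. Older cohorts, men, and lower relapse all push the
ICER down (`analysis/05_scenarios.py`).

## The analysis pipeline

Numbered drivers under `analysis/` run the full study and write tables to
`results/`:

| script | what it does |
|---|---|
| `01_build_tables.py` | generate + export the anchored epidemiology tables |
| `02_short_term.py` | cost per additional quitter at 12 months |
| `03_base_case.py` | two-arm cohort run, ICER, cohort trace export |
| `04_sensitivity.py` | one-way sweeps, threshold quit/relapse rates, break-even |
| `05_scenarios.py` | cohort age 30/60, men/women, halved relapse |
| `06_psa.py` | 10,000-draw PSA, CE plane, CEAC |

The same operations are exposed as a CLI
(`genequit run|short-term|owsa|threshold|psa|scenario|synth-epi`); every
run directory includes a metadata file (config hash, seed, engine switches)
sufficient to reproduce it.

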