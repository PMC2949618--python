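# Methods

This note records the model's structure, conventions and design choices in
enough detail to re-derive every number the package produces.

## Cohort model

A closed cohort of heavy smokers enters at cycle 0, having just completed a
smoking-cessation program: a fraction `quit_rate_12m` (6% usual care, 11%
with the genetic test) starts in *no lung cancer (quit)*, the rest in *no
lung cancer (smoking)*; nobody has lung cancer at entry. Cycles are one
year; the default horizon is 35 cycles.

Compartments (per arm): the two no-cancer states; early-stage and
advanced-stage cancer tunnels of 5 annual steps each (year since diagnosis
drives the death probability and the first-year treatment cost); one
long-term "stable disease" survivor compartment per stage (ongoing cost,
background mortality only — the excess cancer hazard is set to zero after
the 5-year survival table runs out); and absorbing death. 15 compartments
in total.

**Event ordering within a cycle** (fixed; the source material does not
specify a competing-risk order): background death first, then cancer onset
among survivors, then relapse among the remainder. Cancer onset probability
is `incidence(age) × RR`, with the current-smoker RR for smokers and the
years-since-quit-dependent ex-smoker RR for quitters; incident cases split
20%/80% early/advanced. Transition rows are built to sum to exactly 1 and
are never renormalised; a row off by more than 1e−9 is treated as a
construction bug and raises.

**Relapse and the quit clock.** Relapse applies from the second year after
quitting (the first year is the abstinence window that defines a quitter):
10%/year in years 2–6, 4%/year thereafter. Relapsers never re-quit —
the intervention is one-off — so years-since-quit equals the cycle index
for every occupant of the quit state and no quit-time tunnel is needed.
Compounded over 35 years the schedule alone gives a lifetime relapse of
1 − 0.9⁵·0.96²⁹ ≈ 81.9%; read off the cohort trace (where some quitters die
first) it is ≈ 71.6%.

**Progression.** While in the early-cancer tunnel, survivors progress to
the advanced tunnel with annual probability 0.15 (a model choice — the
source material states progression exists but prints no rate; the value is
exposed in config and swept in sensitivity analysis). Progressors are
charged the progressive-disease cost in the cycle of progression.

**Rewards.** QALYs and state costs accrue on start-of-cycle occupancy,
discounted by 1/(1+r)^t with r = 5%/year. Utilities: 1 without cancer, 0.73
early, 0.66 advanced, 0 dead. Costs: first tunnel year charges the
first-year treatment cost by stage ($44,274 early / $27,057 advanced);
later tunnel years and stable survivors charge ongoing stable-disease cost
($7,115); cancer-attributed deaths (the share of deaths due to the cancer
hazard, `(1−q)·p_cancer`) charge terminal care ($9,961) in the death cycle.
The intervention cost is charged once at cycle 0, undiscounted (timing
unstated in the source; recorded in run metadata). No half-cycle correction
by default; a flag enables the standard occupancy-averaging variant, and
all shipped analyses pin it off.

## Synthetic epidemiology

The model needs age-indexed tables normally drawn from national statistics.
They are generated from parametric forms anchored *exactly* to the printed
values, so the pipeline is self-contained:

| quantity | form | anchor | default shape |
|---|---|---|---|
| all-cause mortality | Gompertz `q₀·e^{k(a−65)}` | q(65)=0.00936 | k=0.09 (≈ doubling per 8y) |
| LC incidence | exponential in age | i(65)=0.0018024 | k=0.08 |
| ex-smoker RR | floor + (6.609−floor)·e^{−k·ysq} | RR=4.75 at 5y since quit (ages 50–55) | floor 1.5 |
| LC survival | log-linear between S(1)=0.36, S(5)=0.12 | both anchors | constant hazard years 2–5 |

The ex-smoker curve starts at the current-smoker RR (6.609) at 0 years
since quit and asymptotes to a floor of 1.5 — the excess risk never fully
disappears, consistent with risk remaining elevated after 40+ years of
cessation. The same curve is used in every 5-year age group.

Stage-specific survival: advanced-stage survival is `S_all^1.25` (a
proportional log-survival penalty) and early-stage survival is solved so
the 20/80 case mix reproduces the printed all-stage curve exactly, giving
5-year survival of 31.7% (early) and 7.1% (advanced).

Sex: the "both" tables carry the anchors; male/female tables multiply
incidence by 1.30/0.70 and mortality by 1.15/0.85 (men are heavier smokers
with higher lung-cancer risk; male risk dominates female risk everywhere).
The smoker-specific excess in *all-cause* (non-cancer) mortality is off by
default — background mortality applies to all alive states — with a config
multiplier to switch it on.

What the synthetic tables do *not* emulate: real life-table curvature at
extreme ages (tables clamp at 100), cohort trends, and the actual
age-gradient of incidence beyond a single exponential. Consequently the
package's long-term dollar results are structurally faithful but only
approximately comparable to analyses built on the original national
tables; short-term cost arithmetic, anchors, and every qualitative ordering
are exact/robust, and the test suite treats the long-term ICERs as
corridors and orderings, not point targets.

## Economics

ICER = ΔC/ΔE with the usual quadrant handling: "dominant" (cheaper, more
effective), "dominated" (costlier, less effective), undefined at ΔE = 0;
reported dollars rounded half-up, raw doubles retained in JSON output.
NMB = WTP·E − C; for ΔE > 0, incremental NMB > 0 ⇔ ICER < WTP (the property
the threshold searches rely on, fuzz-tested). The short-term analysis is
exact decimal arithmetic on the cost line items: quitters are
`round(cohort × quit rate)` and the cost difference is the difference of
the per-arm totals ($355,900 per 1000 persons, i.e. $7,118 per additional
quitter).

## Searches

Threshold quit rate and threshold relapse reduction bisect the incremental
NMB (monotone in both controls) to |NMB| < 1e−6 dollars or an interval of
1e−7, max 200 iterations; break-even bisects the incremental cost. Brackets
default to (USC quit rate, 0.99) and [0, 1]. Each search is cross-validated
against an exhaustive 1e−3 grid scan in the tests. Scenario runs re-anchor
the horizon so a different start age still runs 35 years; the halved-relapse
scenario scales the shared schedule in both arms, unlike the per-arm
multiplier used for the relapse threshold.

## Probabilistic sensitivity analysis

Uncertain parameters: every scalar with a published one-way range (both
quit rates, stage split, both cancer utilities — beta) plus all five cancer
costs at ±30% (gamma). Ranges are read as central 95% intervals and
moment-matched: sd = (high − low)/(2·1.96); beta α,β from mean/variance;
gamma shape/scale likewise. Where a range is missing the packaged defaults
use cv = 0.3 for costs and ±20% for probabilities. Draws come from one
seeded NumPy generator, parameters in the configuration's declared order,
so runs are bit-reproducible per seed and appending a new parameter does
not disturb earlier draws within a version.

The summary ICER is the **ratio of means** (mean ΔC / mean ΔE) — the
expected-value estimator for a simulated ICER — which differs from both the
deterministic at-the-means ICER and the (badly behaved) mean of per-draw
ratios; the tests assert this divergence on the skewed base configuration.
The CEAC at each WTP is the fraction of draws with positive incremental
NMB, which handles all quadrants coherently. The 95% CI is the 2.5/97.5
percentile interval of per-draw ratios restricted to draws with ΔE > 0,
with the quadrant tally reported separately (a documented choice; CI
constructions for ratios are not unique).

## Validation strategy

An independent individual-level microsimulator (`genequit.microsim`)
re-implements the same transition logic by per-individual sampling, never
via matrices. Cohort occupancies must match its mean over 100,000
individuals per compartment and cycle within binomial Monte-Carlo error:
3 SE plus a 1/N continuity allowance, with at most 2% of cells between 3
and 5 SE and none beyond 5 SE. The 2% budget exists because one chance
excursion in incident cancers propagates down a tunnel chain, producing
clusters of correlated near-3 SE cells even under exact agreement; injected
model errors (e.g. a wrong progression rate, or a 10% relapse perturbation)
blow the band by an order of magnitude.

Other invariants under test: mass conservation to 1e−12 every cycle;
absorbing, non-decreasing death; QALY monotonicity in quit rate and
mortality; discounting identities; exact collapse of the PSA under
fixed-family distributions; and closed-form degenerate cases (no-risk
cohort accrues exactly `horizon` QALYs; constant mortality gives the
geometric life-expectancy sum).

## Problem sizes

Shipped analyses use the study's own scales: 35-year horizon, 1000-person
short-term arms, 10,000 PSA iterations, 100,000 microsimulated individuals
for validation. A full pipeline run completes in about two minutes on one
CPU.

## Known limitations

* Only lung cancer is modelled; other smoking-related diseases (COPD, CVD)
  are excluded, so QALY gains from quitting are conservative.
* The natural quit rate is assumed equal in both arms and folded into the
  12-month rates.
* Tunnel length is fixed at ≥5 years; survivors beyond it keep stable-
  disease costs for life, which may overstate very-long-term costs.
* Single-cohort, no heterogeneity beyond sex/age scenarios; the
  microsimulator exists for validation, not for subgroup inference.
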