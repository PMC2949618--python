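"""Probabilistic sensitivity analysis: 10,000 model re-runs under sampled
parameters (beta for probabilities and utilities, gamma for costs), with the
cost-effectiveness plane, the CEAC, and the probability the genetic test is
cost-effective at $20,000/QALY.
"""

import json
import sys
from pathlib import Path

import genequit as gq
from genequit.cli import _psa_plots
from genequit.economics import round_dollars
from genequit.psa import run_psa

OUT = Path(__file__).resolve().parent.parent / "results" / "psa"


def main(n: int = 10_000, seed: int = 20100916) -> None:
    cfg = gq.load_basecase()
    res = run_psa(cfg, n=n, seed=seed)
    OUT.mkdir(parents=True, exist_ok=True)
    res.draws_frame().to_csv(OUT / "psa_draws.csv", index=False)
    res.ceac_frame().to_csv(OUT / "ceac.csv", index=False)
    lo, hi, n_pos = res.icer_ci95()
    summary = {"n": n, "seed": seed,
               "mean_icer": round_dollars(res.mean_icer),
               "icer_ci95": [round_dollars(lo), round_dollars(hi)],
               "n_positive_effect_draws": n_pos,
               "quadrants": res.quadrant_counts(),
               "prob_cost_effective_at_wtp": res.prob_cost_effective(cfg.wtp)}
    (OUT / "psa_summary.json").write_text(json.dumps(summary, indent=2))
    _psa_plots(res, cfg, OUT)
    print(f"PSA, {n} iterations (seed {seed}):")
    print(f"  mean ICER (ratio of means)     ${summary['mean_icer']:,}/QALY")
    print(f"  95% percentile interval        ${summary['icer_ci95'][0]:,} - "
          f"${summary['icer_ci95'][1]:,}")
    print(f"  P(cost-effective at ${cfg.wtp:,.0f})  "
          f"{summary['prob_cost_effective_at_wtp']:.1%}")
    print(f"  quadrants: {summary['quadrants']}")


if __name__ == "__main__":
    n = int(sys.argv[1]) if len(sys.argv) > 1 else 10_000
    main(n=n)
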