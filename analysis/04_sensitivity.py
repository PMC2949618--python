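"""Deterministic sensitivity: one-way sweeps, thresholds, break-even.

Sweeps every parameter with a published range (plus +/-30% on cancer costs),
then asks three policy questions: what 12-month quit rate, or what relapse
reduction, would make the genetic test worth $20,000/QALY — and what quit
rate would make it outright cost-saving (dominant)?
"""

import json
from pathlib import Path

import pandas as pd

import genequit as gq
from genequit import sensitivity as sens
from genequit.cli import default_owsa_ranges

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = gq.load_basecase()
    OUT.mkdir(parents=True, exist_ok=True)

    frames = [sens.one_way(cfg, name, lo, hi, steps=3)
              for name, lo, hi in default_owsa_ranges(cfg)]
    owsa = pd.concat(frames, ignore_index=True)
    owsa.to_csv(OUT / "owsa.csv", index=False)
    # dominance labels ("dominant"/"dominated") are non-numeric; the spread
    # summary ranks parameters by the numeric ICERs only
    owsa["icer_num"] = pd.to_numeric(owsa["icer"], errors="coerce")
    spread = (owsa.groupby("parameter")["icer_num"]
              .agg(lambda s: s.max() - s.min()).sort_values(ascending=False))
    print("one-way ICER spread (high - low), most influential first:")
    for name, v in spread.items():
        print(f"  {name:28s} {v:12,.0f}")

    tq = sens.threshold_quit_rate(cfg)
    tr = sens.threshold_relapse_reduction(cfg)
    be = sens.breakeven_quit_rate(cfg)
    be0 = sens.breakeven_quit_rate(cfg.copy_with(relapse=cfg.relapse.scaled(0.0)))
    two = sens.two_way(cfg, "quit_rate_gt", [0.11, 0.22], "quit_rate_usc", [0.06, 0.12])
    two.to_csv(OUT / "two_way.csv", index=False)

    doc = {"threshold_quit_rate": tq.value,
           "threshold_relapse_reduction": tr.value,
           "breakeven_quit_rate": be.value,
           "breakeven_quit_rate_zero_relapse": be0.value,
           "wtp": cfg.wtp}
    (OUT / "thresholds.json").write_text(json.dumps(doc, indent=2))
    print(f"\nat WTP ${cfg.wtp:,.0f}/QALY the genetic-test arm needs:")
    print(f"  12-month quit rate      >= {tq.value:.1%}")
    print(f"  or relapse reduction    >= {tr.value:.1%}")
    print(f"to dominate usual care outright it needs quit rate >= {be.value:.1%}"
          f" ({be0.value:.1%} if nobody relapses)")


if __name__ == "__main__":
    main()
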