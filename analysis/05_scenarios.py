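"""Scenario analyses: cohort age 30/60, men vs women, halved relapse.

Each scenario re-runs the full two-arm model under a structural override.
The qualitative pattern to look for: older cohorts and men (higher lung
cancer risk) make the genetic test look better per QALY; young cohorts are
heavily eroded by relapse and discounting.
"""

from pathlib import Path

import pandas as pd

import genequit as gq
from genequit import sensitivity as sens

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = gq.load_basecase()
    base, _, _ = gq.evaluate(cfg, label="base case (age 50, both sexes)")
    runs = [base,
            sens.scenario(cfg, "cohort aged 30", start_age=30),
            sens.scenario(cfg, "cohort aged 60", start_age=60),
            sens.scenario(cfg, "men only (aged 50)", sex="male"),
            sens.scenario(cfg, "women only (aged 50)", sex="female"),
            sens.scenario(cfg, "relapse halved in both arms",
                          relapse_multiplier_both_arms=0.5)]
    df = pd.DataFrame([r.as_dict() for r in runs])
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "scenarios.csv", index=False)
    print(df[["label", "delta_cost", "delta_effect", "icer"]].to_string(index=False))


if __name__ == "__main__":
    main()
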