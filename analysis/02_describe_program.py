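#!/usr/bin/env python
"""Program-level descriptives of the simulated cohort.

Reads scratch/cohort.csv (from 01_simulate_cohort.py), classifies every
cancer case by detection mode per the EU service-screening guidelines, and
writes the participation/recall table (per invitation round) and the
age-group table (person-years, cases by mode, interval-cancer ratio,
incidence) under results/.
"""

from pathlib import Path

import pandas as pd

from screenmsm import age_group_summary, program_summary, read_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = read_cohort(ROOT / "scratch" / "cohort.csv")
    out = ROOT / "results"
    out.mkdir(exist_ok=True)

    prog = program_summary(cohort)
    prog.to_csv(out / "program_summary.csv", index=False)
    ages = age_group_summary(cohort)
    ages.to_csv(out / "age_group_summary.csv", index=False)

    total = prog[prog["round"] == "total"].iloc[0]
    print(f"invitations {int(total.invited)}, screens {int(total.screened)} "
          f"(participation {total.participation_pct:.1f}%), "
          f"recalls {int(total.recalled)} (recall rate {total.recall_pct:.2f}%)")
    with pd.option_context("display.width", 120):
        print(ages.round(1).to_string(index=False))
    print(f"wrote {out / 'program_summary.csv'} and {out / 'age_group_summary.csv'}")


if __name__ == "__main__":
    main()
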