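#!/usr/bin/env python
"""Goodness-of-fit: observed vs expected cumulative incidence curves.

Compares, among ever-attenders and separately for ages 50-59 and 60+, the
observed cumulative breast-cancer detection rate with the rates expected
under the fitted non-homogeneous and homogeneous models given each woman's
actual screening schedule.  Writes per-band CSVs and a comparison plot under
results/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from screenmsm import expected_cumulative_incidence, incidence_curves, read_cohort
from screenmsm.io import read_fit

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = read_cohort(ROOT / "scratch" / "cohort.csv")
    fit_nh = read_fit(ROOT / "results" / "fit_nonhomogeneous.json")
    fit_h = read_fit(ROOT / "results" / "fit_homogeneous.json")

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5), sharey=False)
    for ax, (band, tag) in zip(axes, (("50-59", "50_59"), ("60+", "60plus"))):
        curves = incidence_curves(cohort, fit_nh, band)
        hom = expected_cumulative_incidence(cohort, fit_h, band)
        curves["expected_cumulative_homogeneous"] = hom.cumulative
        curves.to_csv(ROOT / "results" / f"incidence_{tag}.csv", index=False)
        ax.step(curves.age, 1e5 * curves.observed_cumulative, where="post",
                color="k", label="observed")
        ax.plot(curves.age, 1e5 * curves.expected_cumulative, "--",
                label="non-homogeneous")
        ax.plot(curves.age, 1e5 * curves.expected_cumulative_homogeneous, ":",
                label="homogeneous")
        ax.set_title(f"ages {band}")
        ax.set_xlabel("age (years)")
        ax.set_ylabel("cumulative incidence per 100,000")
        ax.legend()
        gap = (curves.expected_cumulative.iloc[-1]
               - curves.observed_cumulative.iloc[-1])
        gap_h = (curves.expected_cumulative_homogeneous.iloc[-1]
                 - curves.observed_cumulative.iloc[-1])
        print(f"band {band}: final cumulative gap (expected - observed) "
              f"non-homogeneous {1e5 * gap:+.0f}, homogeneous {1e5 * gap_h:+.0f} per 1e5")
    fig.tight_layout()
    fig.savefig(ROOT / "results" / "incidence_curves.png", dpi=150)
    print(f"wrote results/incidence_50_59.csv, results/incidence_60plus.csv, "
          f"results/incidence_curves.png")


if __name__ == "__main__":
    main()
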