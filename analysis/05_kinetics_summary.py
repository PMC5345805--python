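#!/usr/bin/env python
"""Physiology of the simulated fermentations: rates, yields, RQ, switch
time, and the phase-truncated correlations.

Reads the CSVs written by 04_simulate_fermentations.py, estimates every
kinetic quantity with the package's estimators, and contrasts the
respiratory and Crabtree regimes.  Writes results/kinetics_summary.tsv and
results/phase_correlations.tsv.
"""

from pathlib import Path

import pandas as pd

from crabtree.io import read_gas_profile, read_timecourse
from crabtree.kinetics import kinetics_summary, phase_correlation

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM = ROOT / "sim_fermentation"


def main() -> None:
    frames = []
    for name in ("respiratory", "crabtree", "coculture"):
        tc = read_timecourse(SIM / f"{name}_timecourse.csv")
        gp = read_gas_profile(SIM / f"{name}_gas.csv")
        summary = kinetics_summary(tc, gp)
        summary.insert(0, "run", name)
        frames.append(summary)
    all_metrics = pd.concat(frames, ignore_index=True)
    out = ROOT / "kinetics_summary.tsv"
    all_metrics.to_csv(out, sep="\t", index=False)

    wide = all_metrics.pivot(index="metric", columns="run", values="value")
    print(wide.round(4).to_string())

    co = read_timecourse(SIM / "coculture_timecourse.csv")
    rows = []
    for a, b, rule in [("glucose", "ethanol", "until_decrease_of_b"),
                       ("glucose", "acetate", "until_decrease_of_b"),
                       ("ethanol", "bacterial_death", "until_ethanol_decline")]:
        r = phase_correlation(co, a, b, rule=rule)
        rows.append((a, b, rule, r.r_squared, r.sign, r.p_value, r.n_points))
        print(f"{a} ~ {b} ({rule}): R^2 = {r.r_squared:.3f}, "
              f"sign {'+' if r.sign > 0 else '-'}, n = {r.n_points}")
    pd.DataFrame(rows, columns=["var_a", "var_b", "rule", "r_squared",
                                "sign", "p_value", "n_points"]) \
        .to_csv(ROOT / "phase_correlations.tsv", sep="\t", index=False)
    print(f"wrote {out} and {ROOT / 'phase_correlations.tsv'}")


if __name__ == "__main__":
    main()
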