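"""Behavioral analysis of the simulated cohort.

Reads the response table written by 01_simulate_behavior.py and computes
the summary table of hit/CR rates and RTs, the per-subject signal-detection
measures (d', criterion c), the paired t tests comparing the incentive
conditions, the TOST equivalence test on sensitivity, and the 3 (Item) x 2
(Run) repeated-measures ANOVAs on accuracy and RT. Writes tables and a JSON
summary under results/analysis/behavior/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from plsmem.behavior import (accuracy_anova_table, paired_t, rm_anova_2way,
                             rt_anova_table, score_responses, sdt_summary,
                             tost_paired)

OUT = Path("results/analysis/behavior")


def main() -> None:
    responses = pd.read_csv(OUT / "responses.tsv", sep="\t")
    rates = score_responses(responses)
    rates.to_csv(OUT / "rates.tsv", sep="\t", index=False)

    table1 = rates.pivot_table(index="run_type", columns="item_type",
                               values=["rate", "mean_rt_correct_ms"],
                               aggfunc="mean").round(3)
    print("group-mean rates and correct RTs:")
    print(table1, "\n")

    sdt = sdt_summary(rates)
    sdt.to_csv(OUT / "sdt.tsv", sep="\t", index=False)
    wide = sdt.pivot(index="subject", columns="run_type")
    t_c, df_c, p_c, dz_c = paired_t(
        wide[("c", "incentivize-old")], wide[("c", "incentivize-new")])
    t_d, df_d, p_d, dz_d = paired_t(
        wide[("d_prime", "incentivize-old")],
        wide[("d_prime", "incentivize-new")])
    print(f"criterion shift: t({df_c}) = {t_c:.2f}, p = {p_c:.4g} "
          f"(mean c {wide[('c','incentivize-old')].mean():.2f} vs "
          f"{wide[('c','incentivize-new')].mean():.2f})")
    print(f"sensitivity:     t({df_d}) = {t_d:.2f}, p = {p_d:.4g}, "
          f"dz = {dz_d:.2f}")

    n = wide.shape[0]
    tost = {}
    for bound in (0.50, 0.80):
        res = tost_paired(dz_d, n, bound)
        tost[f"bound_{bound:.2f}"] = {
            "t_binding": res.t_binding, "p_binding": res.p_binding,
            "equivalent": res.equivalent}
        verdict = "equivalent" if res.equivalent else "not equivalent"
        print(f"TOST bound {bound:.2f}: binding t({res.df}) = "
              f"{res.t_binding:.2f}, p = {res.p_binding:.3f} -> {verdict}")

    anova_acc = rm_anova_2way(accuracy_anova_table(rates))
    anova_rt = rm_anova_2way(rt_anova_table(rates))
    for name, tab in (("accuracy", anova_acc), ("RT", anova_rt)):
        print(f"\n{name} ANOVA:")
        print(tab[["effect", "F", "df_num", "df_den", "p",
                   "partial_eta_sq"]].round(4).to_string(index=False))
        tab.to_csv(OUT / f"anova_{name.lower()}.tsv", sep="\t", index=False)

    summary = {
        "criterion_t": {"t": t_c, "df": df_c, "p": p_c, "dz": dz_c},
        "sensitivity_t": {"t": t_d, "df": df_d, "p": p_d, "dz": dz_d},
        "tost_sensitivity": tost,
    }
    (OUT / "behavior_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
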