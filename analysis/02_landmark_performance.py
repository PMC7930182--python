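"""Landmark diagnostic performance of the >= 20% rule on the printed-count fixture.

Rebuilds the 36-patient landmark fixture, runs score -> diagnostics at weeks
3/6/9/12 plus the baseline PD-L1 TPS >= 50% comparator, and writes
results/landmark_performance.csv (sensitivity/specificity/PPV/NPV/accuracy
with Jeffreys 95% intervals) and results/landmark_odds_ratios.csv (Woolf
intervals and Fisher p per landmark).
"""

from pathlib import Path

import pandas as pd

from cx3score import build_table1_fixture, confusion_table, evaluate_binary
from cx3score.score import score_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = build_table1_fixture()
    scores = score_table(cohort)
    labels = cohort.responder_labels()

    columns = {}
    for lw in (3, 6, 9, 12):
        sub = scores[(scores["landmark_week"] == lw) & scores["evaluable"]]
        lab = labels.reindex(sub["patient_id"]).to_numpy(bool)
        columns[f"week{lw}"] = confusion_table(sub["positive"].to_numpy(bool), lab)
    pdl1 = (cohort.metadata.set_index("patient_id")["pdl1_tps"] >= 50).reindex(labels.index)
    columns["pdl1_tps_ge50"] = confusion_table(pdl1.to_numpy(bool), labels.to_numpy(bool))

    perf_rows, or_rows = [], []
    for name, table in columns.items():
        decisions = [True] * (table.tp + table.fp) + [False] * (table.fn + table.tn)
        lab = ([True] * table.tp + [False] * table.fp
               + [True] * table.fn + [False] * table.tn)
        report = evaluate_binary(decisions, lab)
        for metric, value in report.rates.items():
            lo, hi = report.rate_intervals[metric]
            perf_rows.append({
                "column": name, "metric": metric,
                "value_pct": round(100 * value, 1),
                "ci_low_pct": round(100 * lo, 1), "ci_high_pct": round(100 * hi, 1),
                "n": table.n,
            })
        or_rows.append({
            "column": name,
            "odds_ratio": round(report.odds_ratio, 2),
            "or_ci_low": round(report.odds_ratio_interval[0], 2),
            "or_ci_high": round(report.odds_ratio_interval[1], 2),
            "fisher_p": float(f"{report.fisher_p:.4g}"),
        })

    OUT.mkdir(parents=True, exist_ok=True)
    perf = pd.DataFrame(perf_rows)
    perf.to_csv(OUT / "landmark_performance.csv", index=False)
    pd.DataFrame(or_rows).to_csv(OUT / "landmark_odds_ratios.csv", index=False)

    wide = perf.pivot(index="metric", columns="column", values="value_pct")
    print(wide.loc[["ppv", "npv", "sensitivity", "specificity", "accuracy"],
                   ["pdl1_tps_ge50", "week3", "week6", "week9", "week12"]])
    for row in or_rows:
        print(f"{row['column']}: OR {row['odds_ratio']} "
              f"({row['or_ci_low']}-{row['or_ci_high']}), Fisher p {row['fisher_p']}")


if __name__ == "__main__":
    main()
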