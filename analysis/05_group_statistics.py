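"""Group statistics over the metric tables produced by scripts 02-04.

For each metric column: normality/equal-variance gating routes to
one-way ANOVA (F) or ANOVA on ranks (Kruskal-Wallis H); Bonferroni
pooled-variance pairwise t tests follow a significant omnibus test.
Writes results/group_statistics.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))

import circabehave as cb  # noqa: E402

RESULTS = Path(__file__).resolve().parents[1] / "results"

TABLES = {
    "metrics_ld": ["nocturnality_pct", "power_pct", "activity_rev_per_hr",
                   "alpha_minutes", "fragmentation_bouts_per_day", "precision_minutes"],
    "metrics_dd": ["tau_hours", "power_pct", "activity_rev_per_hr",
                   "alpha_minutes", "fragmentation_bouts_per_day", "precision_minutes"],
    "photic_responses": ["recovered_delay_min", "subjective_night_pct"],
    "sleep_metrics": ["day_sleep_min", "night_sleep_min", "day_bouts",
                      "day_mean_bout_min"],
}


def main() -> None:
    rows = []
    for table, metrics in TABLES.items():
        path = RESULTS / f"{table}.csv"
        if not path.exists():
            print(f"skipping {table}: run the earlier scripts first")
            continue
        df = pd.read_csv(path)
        labels = sorted(df["group"].unique())
        for metric in metrics:
            groups = [
                df.loc[df["group"] == g, metric].dropna().to_numpy() for g in labels
            ]
            if any(len(g) < 2 for g in groups):
                continue
            res = cb.compare_groups(groups, labels=labels)
            rows.append(
                {
                    "table": table,
                    "metric": metric,
                    "test": res.test.value,
                    "statistic": round(res.statistic, 3),
                    "dof": "/".join(map(str, res.dof)),
                    "p_value": res.p_value,
                    "significant_pairs": ";".join(
                        f"{p.pair[0]}-{p.pair[1]}"
                        for p in res.pairwise
                        if p.p_adjusted < 0.05
                    ),
                }
            )
    out = pd.DataFrame(rows)
    out.to_csv(RESULTS / "group_statistics.csv", index=False)
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
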