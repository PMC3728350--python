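"""Record the cohort design and write one example actogram per group.

Writes results/cohort_parameters.csv (the generator settings that act
as ground truth for every later script) and, per group, a double-plot
actogram figure of one representative synthetic animal.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from cohorts import GROUPS, N_DAYS, N_PER_GROUP, animal_params  # noqa: E402

import circabehave as cb  # noqa: E402
from circabehave.plotting import plot_actogram  # noqa: E402

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "figures").mkdir(exist_ok=True)
    rows = [vars(g) | {"n_animals": N_PER_GROUP, "n_days": N_DAYS} for g in GROUPS]
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "cohort_parameters.csv", index=False)
    print(f"cohort design: {len(GROUPS)} groups x {N_PER_GROUP} animals x {N_DAYS} days")
    print(table.to_string(index=False))

    for g in GROUPS:
        rec = cb.simulate_activity(animal_params(g, 0, seed=1, ld=True),
                                   cb.LightSchedule.ld(), N_DAYS)
        ax = plot_actogram(cb.fold_days(rec))
        ax.set_title(f"{g.name}: synthetic LD actogram (animal 0)")
        fig_path = RESULTS / "figures" / f"actogram_{g.name}.png"
        ax.figure.savefig(fig_path, dpi=120)
        print(f"wrote {fig_path}")


if __name__ == "__main__":
    main()
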