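"""Two-group statistics for every design: the significance matrix.

Re-runs the chemogenetic and optogenetic designs, compares each
manipulation group with its control on every behavioral endpoint (Student's
t on per-mouse means, Mann-Whitney U alongside), applies the star
convention, and writes the results table under results/.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"

from volstop.engine import run_experiment  # noqa: E402
from volstop.experiments import ENDPOINTS, summarize_and_compare  # noqa: E402
from volstop.stats import InsufficientDataError  # noqa: E402

SEED = 20250932

DESIGN_LABEL = {
    "chemogenetic": {"hM3D": "hM3D", "hM4D": "hM4D"},
    "optogenetic_feedback": {"eNpHR": "eNpHR@feedback"},
    "optogenetic_cue": {"eNpHR": "eNpHR@cue"},
    "optogenetic_reward": {"eNpHR": "eNpHR@reward"},
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (design, labels) in enumerate(DESIGN_LABEL.items()):
        expt = run_experiment(design, SEED + i, synth_traces=False)
        for ep in ENDPOINTS:
            for test in ("student_t", "mann_whitney_u"):
                try:
                    comps = summarize_and_compare(expt, ep, test=test)
                except InsufficientDataError:
                    continue
                for group, label in labels.items():
                    c = comps[group]
                    rows.append({
                        "design": design, "group": label, "endpoint": ep,
                        "test": test, "statistic": round(c.statistic, 4),
                        "p_value": round(c.p_value, 5), "stars": c.stars,
                        "mean_group": round(c.mean_a, 4),
                        "mean_control": round(c.mean_b, 4),
                    })
    table = pd.DataFrame(rows)
    path = OUT / "group_stats.csv"
    table.to_csv(path, index=False)

    t_only = table[table["test"] == "student_t"]
    matrix = t_only.pivot_table(index="group", columns="endpoint",
                                values="stars", aggfunc="first")
    print("significance matrix (Student's t, per-mouse means vs control):")
    print(matrix.to_string())
    print(f"\nwrote {path}")


if __name__ == "__main__":
    sys.exit(main())
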