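"""Simulate the study's four behavioral designs and write per-mouse tables.

Runs the 6-day chemogenetic design (control/hM3D/hM4D, n=6 each, CNO on
alternate days) and the three 3-day optogenetic designs (control n=6 vs
eNpHR n=7; 1-s suppression locked to feedback, cue, or reward) at full
session size (50 successes), behavior-only.  Writes the per-mouse endpoint
summaries under results/experiments/.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "experiments"

from volstop.engine import run_experiment  # noqa: E402
from volstop.experiments import mouse_summary_table  # noqa: E402

SEED = 20250930


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    designs = ("chemogenetic", "optogenetic_feedback", "optogenetic_cue",
               "optogenetic_reward")
    for i, design in enumerate(designs):
        expt = run_experiment(design, SEED + i, synth_traces=False)
        table = mouse_summary_table(expt)
        path = OUT / f"{design}_mouse_summaries.csv"
        table.to_csv(path, index=False)
        wide = table.pivot_table(index="group", columns="endpoint",
                                 values="value")
        print(f"\n== {design} (per-mouse means averaged by group) ==")
        print(wide.round(3).to_string())
        print(f"wrote {path}")


if __name__ == "__main__":
    sys.exit(main())
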