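"""Validation suites at survey scale: type-I calibration, ablation power,
and significance-pattern recovery.

Smaller replicate counts than the test suite (which runs 100-1000
replicates); this driver is a quick narrative check that writes its numbers
to results/calibration.json.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"

from volstop.experiments import (ablation_detection,  # noqa: E402
                                 null_calibration, pattern_recovery)

SEED = 20250933


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cal = null_calibration(n_reps=300, seed=SEED)
    print("type-I error at alpha=0.05 (300 null experiments):")
    for test, rate in cal["rates"].items():
        print(f"  {test}: {rate:.3f}")

    abl = ablation_detection(n_reps=25, seed=SEED + 1)
    print("\nwithdrawal detection fraction (25 replicates, n=6 vs 6):")
    for variant, frac in abl["detect_fraction"].items():
        print(f"  {variant}: {frac:.2f}")

    pat = pattern_recovery(n_reps=25, seed=SEED + 2)
    print("\nsignificance-pattern recovery (25 replicates):")
    print(pat.round(2).to_string(index=False))

    payload = {
        "null_calibration": cal,
        "ablation_detection": abl,
        "pattern_recovery": pat.to_dict(orient="records"),
    }
    path = OUT / "calibration.json"
    path.write_text(json.dumps(payload, indent=1))
    print(f"\nwrote {path}")


if __name__ == "__main__":
    sys.exit(main())
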