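"""Simulate the synthetic study cohort.

Generates 15 control-like and 15 patient-like 91-channel resting-state
recordings (10 min at 250 Hz), the montage, the subject metadata table
and the planted ground truth, under results/cohort/.

    python analysis/01_simulate_cohort.py [--small] [--seed 1]
"""

import argparse
import sys
from dataclasses import replace
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from eegspan import CohortSpec, simulate_cohort  # noqa: E402


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--small", action="store_true",
                    help="3+3 subjects, 24 channels, 12 epochs (quick demo)")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "cohort")
    args = ap.parse_args()

    spec = CohortSpec(seed=args.seed)
    if args.small:
        spec = replace(spec, n_controls=3, n_patients=3, n_channels=24,
                       n_epochs=12)
    montage, subjects = simulate_cohort(spec, out_dir=args.out)
    groups = [r.group for _, r, _ in subjects]
    print(f"wrote {len(subjects)} subjects to {args.out}")
    print(f"  groups: {dict((g, groups.count(g)) for g in set(groups))}")
    print(f"  montage: {montage.n_channels} channels")


if __name__ == "__main__":
    main()
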