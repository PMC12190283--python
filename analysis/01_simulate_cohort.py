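#!/usr/bin/env python
"""Generate a synthetic two-group, two-site cohort and write it to disk.

Example::

    python analysis/01_simulate_cohort.py --workdir results/run1 \
        --seed 7 --subjects-per-group 20
"""

import argparse
from pathlib import Path

from eegmfe.cohort import SynthConfig, generate_cohort
from eegmfe.io import write_cohort


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--workdir", type=Path, required=True)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--subjects-per-group", type=int, default=52)
    parser.add_argument("--duration", type=float, default=51.0)
    parser.add_argument("--fs", type=float, default=200.0)
    parser.add_argument("--format", choices=["matrix", "edf"], default="matrix")
    args = parser.parse_args()

    config = SynthConfig(
        n_subjects_per_group=args.subjects_per_group,
        duration=args.duration,
        fs=args.fs,
        seed=args.seed,
    )
    cohort = generate_cohort(config)
    out = args.workdir / "cohort"
    write_cohort(cohort, out, format=args.format)
    print(f"wrote {len(cohort)} recordings to {out}")


if __name__ == "__main__":
    main()
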