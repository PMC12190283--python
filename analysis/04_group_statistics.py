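#!/usr/bin/env python
"""Group-level statistics on the full entropy grids of a stored cohort.

Recomputes the complete scale 1..20 entropy matrices (the feature
extraction step only needs the long scales), then reports:

* Welch t-tests per (channel, scale) cell with BH-FDR correction and
  Cohen's d (``ttest_grid.csv``);
* the two-between (group, dataset) one-within (scale) mixed ANOVA on
  channel-averaged entropy (``mixed_anova.csv``);
* elementwise agreement of the averaged inter-channel correlation
  matrices across amplitude conditions (``correlation_agreement.csv``).

Example::

    python analysis/04_group_statistics.py --workdir results/run1
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from eegmfe.entropy import MFEParams, mfe_matrix
from eegmfe.io import read_cohort
from eegmfe.preprocess import epoch, preprocess
from eegmfe.stats import (
    channel_mean_long,
    correlation_preservation,
    mixed_anova,
    subject_mean_mfe,
    ttest_grid_fdr,
)
from eegmfe.transforms import CONDITIONS


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--workdir", type=Path, required=True)
    args = parser.parse_args()

    cohort = read_cohort(args.workdir / "cohort")
    print(f"preprocessing {len(cohort)} recordings")
    pre = [preprocess(rec) for rec in cohort]
    params = MFEParams()
    print("computing full-scale entropy grids")
    mats = [mfe_matrix(epoch(rec, 3.0), params) for rec in pre]

    meta, values = subject_mean_mfe(mats)
    groups = sorted(meta["group"].unique())
    is_a = (meta["group"] == groups[0]).to_numpy()
    res = ttest_grid_fdr(values[is_a], values[~is_a])
    channels = mats[0].channel_names
    rows = []
    for c, ch in enumerate(channels):
        for s, tau in enumerate(params.scales):
            rows.append({
                "channel": ch, "scale": tau,
                "p_raw": res.p_raw[c, s], "p_fdr": res.p_adj[c, s],
                "significant": bool(res.significant[c, s]),
                "cohens_d": res.d[c, s],
            })
    grid = pd.DataFrame(rows)
    grid.to_csv(args.workdir / "ttest_grid.csv", index=False)
    print(f"t-test grid: {int(res.significant.sum())} of "
          f"{res.significant.size} cells significant after FDR")

    anova = mixed_anova(channel_mean_long(mats))
    anova.to_csv(args.workdir / "mixed_anova.csv")
    print(anova.round(4))

    corr = correlation_preservation(pre, list(CONDITIONS))
    ref = corr["reference"]
    rows = [
        {"condition": cond,
         "max_abs_difference_vs_reference": float(np.max(np.abs(mat - ref)))}
        for cond, mat in corr.items()
    ]
    pd.DataFrame(rows).to_csv(
        args.workdir / "correlation_agreement.csv", index=False
    )
    print(f"wrote statistics under {args.workdir}")


if __name__ == "__main__":
    main()
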