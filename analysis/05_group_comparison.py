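#!/usr/bin/env python
"""Permutation comparison of nodal measures between groups.

Runs the study's contrasts (each amyloid-positive group vs the
amyloid-negative controls, plus MCI vs AD) for overlapping strength and
degree overlap, with subject-reallocation permutation nulls, density
averaging for the binary measure, and BH-FDR control across the 72
regions.  Uses 1,000 replicates here to keep the driver quick; the
pipeline default is 10,000.
"""

from pathlib import Path

import pandas as pd

from mxad.atlas import default_atlas
from mxad.cohort import AMYLOID, GRAY_MATTER, load_cohort
from mxad.inference import permutation_test
from mxad.pipeline import DEFAULT_CONTRASTS, FLOAT_FMT

COHORT = Path("results/analysis/cohort")
OUT = Path("results/analysis/comparison")
SEED = 42
N_PERM = 1000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    atlas = default_atlas()
    gray = load_cohort(COHORT / "cohort_gray_matter.csv", atlas, GRAY_MATTER)
    amy = load_cohort(COHORT / "cohort_amyloid.csv", atlas, AMYLOID)
    gg, ag = gray.by_group(), amy.by_group()

    frames = []
    for measure, densities in (("overlapping_strength", None),
                               ("degree_overlap", None)):
        for ga, gb in DEFAULT_CONTRASTS:
            kwargs = {} if densities is None else {"densities": densities}
            res = permutation_test((gg[ga], ag[ga]), (gg[gb], ag[gb]), measure,
                                   n_perm=N_PERM, seed=SEED, group_a=ga,
                                   group_b=gb, **kwargs)
            frames.append(res.to_frame())
            print(f"{measure:22s} {ga} vs {gb}: "
                  f"{int(res.fdr_mask.sum())}/72 regions significant after FDR")
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(OUT / "group_differences.csv", index=False, float_format=FLOAT_FMT)
    print("\nWith the default synthetic conditions the amyloid-positive "
          "groups carry a planted amyloid-layer connectivity increase; "
          "contrasts against the CN A-beta- group also reflect their "
          "different planted module layouts and amyloid burden.")


if __name__ == "__main__":
    main()
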