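"""Published development-cohort margins of the screening test.

The screening models were developed on a cohort of 308 post-acute
rehabilitation inpatients (175 non-dysphagic, 133 with sarcopenic
dysphagia).  The individual-level data are not shared, but the published
group counts and group means are enough to rebuild a subject-level table
that reproduces every marginal quantity exactly: prevalence, sarcopenia
proportions, sex and primary-disease margins, and the group-size-weighted
mean age.  Variables not expressible from counts alone carry the group
mean as a constant, so group and overall means are exact while SDs are
not meaningful for those columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["DEVELOPMENT_COHORT_COUNTS", "development_cohort_records"]

#: Group sizes and within-group counts/means of the development cohort.
DEVELOPMENT_COHORT_COUNTS: dict = {
    "n_non_dysphagic": 175,
    "n_dysphagic": 133,
    "sarcopenia": {0: 104, 1: 133},
    "female": {0: 108, 1: 72},
    "orthopedic_primary": {0: 130, 1: 47},
    "mean_age": {0: 82.57, 1: 86.22},
}


def development_cohort_records() -> pd.DataFrame:
    """Subject-level reconstruction of the development-cohort margins.

    Returns a 308-row table with columns ``group`` (1 = sarcopenic
    dysphagia), ``sarcopenia``, ``sex``, ``orthopedic_primary`` and ``age``
    (the group mean, constant within group).
    """
    c = DEVELOPMENT_COHORT_COUNTS
    sizes = {0: c["n_non_dysphagic"], 1: c["n_dysphagic"]}
    frames = []
    for g, n in sizes.items():
        frames.append(
            pd.DataFrame(
                {
                    "group": g,
                    "sarcopenia": _indicator(n, c["sarcopenia"][g]),
                    "sex": np.where(
                        _indicator(n, c["female"][g]) == 1, "female", "male"
                    ),
                    "orthopedic_primary": _indicator(n, c["orthopedic_primary"][g]),
                    "age": float(c["mean_age"][g]),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _indicator(n: int, k: int) -> np.ndarray:
    out = np.zeros(n)
    out[:k] = 1.0
    return out
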