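import numpy as np
import pandas as pd
import pytest

from coordgait.cohort import CohortSpec, simulate_cohort
from coordgait.features import ALL_FEATURES


def dtw_bruteforce(a, b) -> float:
    """Independent DTW oracle: exhaustive recursion over all monotone
    warping paths with |.| local cost.  Only viable for short sequences."""
    a = list(map(float, a))
    b = list(map(float, b))

    def rec(i: int, j: int) -> float:
        c = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return c
        best = float("inf")
        if i > 0:
            best = min(best, rec(i - 1, j))
        if j > 0:
            best = min(best, rec(i, j - 1))
        if i > 0 and j > 0:
            best = min(best, rec(i - 1, j - 1))
        return c + best

    return rec(len(a) - 1, len(b) - 1)


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    return CohortSpec(group_sizes={"EOA": 2, "DCD": 2, "CTRL": 2}, seed=42)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return simulate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def degenerate_cohort():
    spec = CohortSpec.degenerate(group_sizes={"EOA": 1, "DCD": 1, "CTRL": 1},
                                 seed=7)
    return simulate_cohort(spec)


def random_feature_table(n_per_class=(5, 4, 6), rows=10, seed=0,
                         separation=0.0) -> pd.DataFrame:
    """Synthetic assembled-table stand-in: gaussian rows per participant,
    optional per-class mean shift for separable fixtures."""
    rng = np.random.default_rng(seed)
    rows_out = []
    for ci, (lab, n) in enumerate(zip(("EOA", "DCD", "CTRL"), n_per_class)):
        for p in range(n):
            pid = f"{lab}{p:02d}"
            center = rng.normal(scale=0.5, size=len(ALL_FEATURES)) \
                + separation * ci
            for _ in range(rows):
                vals = center + rng.normal(scale=0.2, size=len(ALL_FEATURES))
                row = {"participant_id": pid, "group": lab}
                row.update(dict(zip(ALL_FEATURES, vals)))
                rows_out.append(row)
    return pd.DataFrame(rows_out)
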