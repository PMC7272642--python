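"""Group comparisons per (value type, band, region) cell.

Each of the six value-type families spans 5 bands x 68 regions = 340
cells; every cell is compared between the AD and NC groups with a
two-tailed test (Welch's unequal-variance t by default) against the
Bonferroni threshold alpha / (n_regions x n_bands).  The printed divisor
counts regions and bands only, so the threshold is applied within each
value-type family.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import parse_feature_name

TESTS = ("welch", "student", "mannwhitney")


def bonferroni_threshold(
    alpha: float = 0.05, n_regions: int = 68, n_bands: int = 5
) -> float:
    """Per-cell significance threshold alpha / (n_regions * n_bands).

    The default 0.05 / 68 / 5 = 1.47e-4 (printed 0.000147).
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if n_regions < 1 or n_bands < 1:
        raise ValueError("region and band counts must be positive")
    return alpha / (n_regions * n_bands)


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    res = sps.ttest_ind(a, b, axis=0, equal_var=False)
    return np.asarray(res.statistic, float), np.asarray(res.pvalue, float)


def _student(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    res = sps.ttest_ind(a, b, axis=0, equal_var=True)
    return np.asarray(res.statistic, float), np.asarray(res.pvalue, float)


def _mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    res = sps.mannwhitneyu(a, b, axis=0, alternative="two-sided")
    return np.asarray(res.statistic, float), np.asarray(res.pvalue, float)


def compare_groups(
    values_ad: np.ndarray | pd.DataFrame,
    values_nc: np.ndarray | pd.DataFrame,
    threshold: float,
    test: str = "welch",
    cell_ids: pd.Index | None = None,
) -> pd.DataFrame:
    """Two-tailed AD-vs-NC comparison for every cell (column).

    Returns a DataFrame with one row per cell: statistic, two-tailed p,
    direction (which group mean is larger) and the significance flag
    ``p < threshold``.  Cells where both groups are constant and equal get
    statistic 0 and p = 1 by convention.
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; choose from {TESTS}")
    if isinstance(values_ad, pd.DataFrame):
        cell_ids = values_ad.columns if cell_ids is None else cell_ids
        values_ad = values_ad.to_numpy(float)
    if isinstance(values_nc, pd.DataFrame):
        values_nc = values_nc.to_numpy(float)
    a = np.atleast_2d(np.asarray(values_ad, float))
    b = np.atleast_2d(np.asarray(values_nc, float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups have different numbers of cells")

    import warnings

    with warnings.catch_warnings():
        # constant cells trip scipy's precision warning; handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        stat, p = {
            "welch": _welch,
            "student": _student,
            "mannwhitney": _mannwhitney,
        }[test](a, b)
    # Both groups constant: equal means -> no evidence (p = 1); unequal
    # means -> infinite separation (p = 0).
    mean_diff = a.mean(axis=0) - b.mean(axis=0)
    degenerate = np.isnan(p)
    stat = np.where(degenerate & (mean_diff == 0), 0.0, stat)
    p = np.where(degenerate, np.where(mean_diff == 0, 1.0, 0.0), p)

    if cell_ids is None:
        cell_ids = pd.RangeIndex(a.shape[1], name="cell")
    out = pd.DataFrame(
        {
            "statistic": stat,
            "p_two_tailed": p,
            "direction": np.where(mean_diff >= 0, "AD>NC", "NC>AD"),
            "significant": p < threshold,
        },
        index=pd.Index(cell_ids, name="cell"),
    )
    return out


def compare_feature_table(
    features: pd.DataFrame,
    alpha: float = 0.05,
    test: str = "welch",
) -> pd.DataFrame:
    """Run the full per-cell comparison on a cohort feature matrix.

    ``features`` is the assembled table (columns subject_id, group, then
    canonical feature names).  The Bonferroni threshold is derived from
    the band/region grid of the feature names and applied within each
    value-type family of cells.
    """
    meta = {"subject_id", "group"}
    cells = [c for c in features.columns if c not in meta]
    parsed = [parse_feature_name(c) for c in cells]
    n_bands = len({band for _, band, _ in parsed})
    n_regions = len({region for _, _, region in parsed})
    threshold = bonferroni_threshold(alpha, n_regions, n_bands)
    ad = features.loc[features["group"] == "AD", cells]
    nc = features.loc[features["group"] == "NC", cells]
    out = compare_groups(ad, nc, threshold, test=test, cell_ids=pd.Index(cells))
    out.insert(0, "value_type", [vt for vt, _, _ in parsed])
    out.insert(1, "band", [band for _, band, _ in parsed])
    out.insert(2, "region", [region for _, _, region in parsed])
    out.attrs["threshold"] = threshold
    return out
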