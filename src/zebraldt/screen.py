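"""Univariate two-group screening: Mann-Whitney U per feature, Bonferroni FWER.

Each of the 780 features is compared between the two groups with a
two-sided Mann-Whitney U test; raw p-values are Bonferroni-adjusted with
m fixed at the full feature count, and features with adjusted p < alpha
are called significant.  The headline output is the number of significant
univariate parameters (NSUP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import FeatureMatrix

#: Exact null enumeration is used up to this combined sample size (no ties);
#: beyond it the tie-corrected normal approximation with continuity correction.
EXACT_MAX_N = 12


@dataclass(frozen=True)
class ScreenResult:
    feature_name: str
    U_statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two independent samples.

    Returns ``(U, p)`` where U is the statistic for the first sample.
    Small tie-free samples (combined n <= 12) use exact enumeration of the
    rank distribution; otherwise the normal approximation with midrank tie
    correction and continuity correction.  Constant pooled data (all values
    equal) yields p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bonferroni_adjust(p_values, m: int) -> np.ndarray:
    """Bonferroni family-wise adjustment: ``min(1, p * m)``.

    ``m`` is the size of the tested family and may exceed the number of
    p-values passed (it is fixed at 780 for the LDT screen).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("p_values must be non-empty")
    if m < p.size:
        raise ValueError(f"m ({m}) must be >= number of p-values ({p.size})")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * m)


def screen_features(
    matrix: FeatureMatrix, alpha: float = 0.05
) -> tuple[list[ScreenResult], int]:
    """Per-feature Mann-Whitney screen of a two-group feature matrix.

    Every feature is tested (m = n_features for the Bonferroni adjustment,
    regardless of degenerate features, which get p = 1).  Returns the
    per-feature results and the count of significant features.
    """
    g0, g1 = matrix.require_two_groups()
    labels = matrix.labels.astype(str)
    x_rows = matrix.features[labels == g0]
    y_rows = matrix.features[labels == g1]
    if x_rows.shape[0] < 2 or y_rows.shape[0] < 2:
        raise ValueError("each group needs >= 2 samples")

    n_x, n_y = x_rows.shape[0], y_rows.shape[0]
    if n_x + n_y <= EXACT_MAX_N:
        stats_u = np.empty(matrix.n_features)
        p_raw = np.empty(matrix.n_features)
        for j in range(matrix.n_features):
            stats_u[j], p_raw[j] = mann_whitney_u(x_rows[:, j], y_rows[:, j])
    else:
        # one vectorized tie-corrected asymptotic pass over all features
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.mannwhitneyu(
                x_rows, y_rows, alternative="two-sided", method="asymptotic", axis=0
            )
        stats_u = np.asarray(res.statistic, dtype=float)
        p_raw = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
        pooled = np.vstack([x_rows, y_rows])
        constant = np.all(pooled == pooled[0], axis=0)
        stats_u[constant] = n_x * n_y / 2.0
        p_raw[constant] = 1.0
        p_raw = np.nan_to_num(p_raw, nan=1.0)
    p_adj = bonferroni_adjust(p_raw, m=matrix.n_features)
    sig = p_adj < alpha
    results = [
        ScreenResult(
            feature_name=matrix.feature_names[j],
            U_statistic=float(stats_u[j]),
            p_raw=float(p_raw[j]),
            p_adjusted=float(p_adj[j]),
            significant=bool(sig[j]),
        )
        for j in range(matrix.n_features)
    ]
    return results, int(sig.sum())


def results_to_frame(results: list[ScreenResult]):
    import pandas as pd

    return pd.DataFrame(
        {
            "feature_name": [r.feature_name for r in results],
            "U": [r.U_statistic for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "significant": [r.significant for r in results],
        }
    )
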