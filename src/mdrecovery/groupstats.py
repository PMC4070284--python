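"""Group-level statistics.

Population metrics are summarized as mean +/- SEM or median +/- SE (the
median's standard error estimated by bootstrap).  Cumulative frequency
distributions are compared between treatment groups with two-sample
Kolmogorov-Smirnov tests, Bonferroni-corrected over the group-pair family,
and bucketed into the significance levels used for tabular reporting.
Repeated-measures ANOVA / Kruskal-Wallis omnibus tests are delegated to
scipy as pass-throughs.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "bootstrap_median_se",
    "group_summary",
    "ks_compare",
    "bonferroni_adjust",
    "significance_bucket",
    "comparison_matrix",
    "kruskal_wallis",
    "one_way_anova",
    "SIGNIFICANCE_BUCKETS",
]

# bucket upper bounds, most stringent first; labels as printed in reports
SIGNIFICANCE_BUCKETS = (
    (1e-5, "<0.00001"),
    (1e-4, "<0.0001"),
    (1e-3, "<0.001"),
    (1e-2, "<0.01"),
    (5e-2, "<0.05"),
)


def bootstrap_median_se(values, n_boot: int = 1000, seed: int = 0) -> float:
    """Standard error of the median by bootstrap: the standard deviation
    of medians over ``n_boot`` with-replacement resamples."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    medians = np.median(values[idx], axis=1)
    return float(medians.std(ddof=1))


def group_summary(values, label: str = "", metric: str = "",
                  n_boot: int = 1000, seed: int = 0) -> dict:
    """Mean +/- SEM and median +/- bootstrap SE for one group's metric."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    return {
        "group": label,
        "metric": metric,
        "n": int(values.size),
        "mean": float(values.mean()),
        "sem": float(values.std(ddof=1) / np.sqrt(values.size))
               if values.size > 1 else np.nan,
        "median": float(np.median(values)),
        "median_se_bootstrap": bootstrap_median_se(values, n_boot, seed)
                               if values.size > 1 else np.nan,
    }


def ks_compare(a, b, exact_max_n: int = 25) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    Returns (D, p) with D the ECDF supremum distance.  The exact p-value
    is used when both samples have at most ``exact_max_n`` observations,
    the asymptotic formula otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    method = "exact" if max(a.size, b.size) <= exact_max_n else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: min(1, p * m) per entry, ``m`` defaulting to
    the number of tests."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than the "
                         f"{p.size} tests supplied")
    return np.minimum(1.0, p * m)


def significance_bucket(p_adjusted: float) -> str:
    """Map an adjusted p-value to its reporting bucket."""
    for bound, label in SIGNIFICANCE_BUCKETS:
        if p_adjusted < bound:
            return label
    return "n.s."


def comparison_matrix(groups: dict[str, pd.DataFrame], metrics,
                      pairs=None) -> pd.DataFrame:
    """Pairwise KS comparison table across treatment groups.

    ``groups`` maps labels to per-unit metric tables; ``metrics`` names the
    columns to compare.  Each metric row holds, per group pair, the
    Bonferroni-adjusted significance bucket (family = the number of pairs,
    per metric).  Columns ``D`` and raw/adjusted p are returned long-form
    alongside the bucket.
    """
    if pairs is None:
        pairs = list(combinations(sorted(groups), 2))
    m = len(pairs)
    rows = []
    for metric in metrics:
        for ga, gb in pairs:
            rec = {"metric": metric, "group_a": ga, "group_b": gb}
            if metric not in groups[ga] or metric not in groups[gb]:
                rec.update({"D": np.nan, "p_raw": np.nan,
                            "p_adjusted": np.nan, "bucket": "absent"})
                rows.append(rec)
                continue
            a = groups[ga][metric].dropna().to_numpy()
            b = groups[gb][metric].dropna().to_numpy()
            if a.size == 0 or b.size == 0:
                rec.update({"D": np.nan, "p_raw": np.nan,
                            "p_adjusted": np.nan, "bucket": "absent"})
                rows.append(rec)
                continue
            d, p = ks_compare(a, b)
            p_adj = float(bonferroni_adjust([p], m)[0])
            rec.update({"D": d, "p_raw": p, "p_adjusted": p_adj,
                        "bucket": significance_bucket(p_adj)})
            rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Omnibus tests (pass-throughs to scipy)

def kruskal_wallis(*samples) -> tuple[float, float]:
    res = stats.kruskal(*samples)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(*samples) -> tuple[float, float]:
    res = stats.f_oneway(*samples)
    return float(res.statistic), float(res.pvalue)
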