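"""Paired nonparametric inference: exact Wilcoxon signed-rank tests and
Hodges–Lehmann (Walsh-average) median differences with confidence
intervals, plus the cohort summary tables built on them.

The signed-rank p-value is exact — computed from the full null
distribution of the positive-rank sum — whenever that is feasible
(tie-free samples up to n = 20 via the rank-polynomial recursion; tied
samples up to n = 14 by direct enumeration of all 2^n sign patterns
with midranks), and falls back to the normal approximation with tie and
continuity corrections otherwise.  Zero differences are dropped before
ranking (the classical Wilcoxon convention).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "WilcoxonResult",
    "HodgesLehmannResult",
    "wilcoxon_signed_rank",
    "hodges_lehmann_ci",
    "compare_modalities",
    "stratified_summary",
    "holm_adjust",
]

_MAX_EXACT_N = 20
_MAX_ENUM_TIES_N = 14


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ : sum of ranks of positive differences
    pvalue: float
    n_used: int  # after dropping zero differences
    exact: bool
    degenerate: bool = False


@dataclass(frozen=True)
class HodgesLehmannResult:
    estimate: float
    ci_low: float
    ci_high: float
    level: float
    achieved_level: float  # guaranteed (conservative) coverage
    widest: bool = False  # n too small for the requested level


@lru_cache(maxsize=64)
def _signed_rank_counts(n: int) -> np.ndarray:
    """Frequencies of W+ = 0..n(n+1)/2 over all 2^n sign assignments."""
    counts = np.zeros(n * (n + 1) // 2 + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    return counts


def _exact_p_no_ties(w: float, n: int) -> float:
    counts = _signed_rank_counts(n)
    total = counts.sum()
    w = int(round(w))
    p_le = counts[: w + 1].sum() / total
    p_ge = counts[w:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _exact_p_enumerate(ranks: np.ndarray, w: float) -> float:
    """Exact two-sided p over all 2^n sign patterns (handles midranks)."""
    n = len(ranks)
    signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
    ws = signs @ ranks
    total = len(ws)
    p_le = np.count_nonzero(ws <= w + 1e-12) / total
    p_ge = np.count_nonzero(ws >= w - 1e-12) / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(diffs) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zeros are dropped; |differences| are ranked with midranks for ties.
    If every difference is zero, the test is degenerate and p = 1.
    """
    d = np.asarray(diffs, dtype=np.float64)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("diffs must be a non-empty 1D sequence")
    d = d[d != 0]
    if d.size == 0:
        return WilcoxonResult(statistic=0.0, pvalue=1.0, n_used=0,
                              exact=True, degenerate=True)
    n = d.size
    absd = np.abs(d)
    ranks = rankdata(absd)
    w = float(ranks[d > 0].sum())
    has_ties = len(np.unique(absd)) < n

    if not has_ties and n <= _MAX_EXACT_N:
        return WilcoxonResult(w, _exact_p_no_ties(w, n), n, exact=True)
    if has_ties and n <= _MAX_ENUM_TIES_N:
        return WilcoxonResult(w, _exact_p_enumerate(ranks, w), n, exact=True)

    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(absd, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return WilcoxonResult(w, 1.0, n, exact=False, degenerate=True)
    # Continuity correction pulls |W - mu| toward the mean by 0.5.
    z = (abs(w - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = float(min(1.0, 2.0 * norm.sf(z)))
    return WilcoxonResult(w, p, n, exact=False)


# ---------------------------------------------------------------------------
# Hodges–Lehmann estimate and confidence interval
# ---------------------------------------------------------------------------

def _walsh_averages(d: np.ndarray) -> np.ndarray:
    n = len(d)
    iu = np.triu_indices(n)
    return np.sort((d[iu[0]] + d[iu[1]]) / 2.0)


def hodges_lehmann_ci(diffs, level: float = 0.95) -> HodgesLehmannResult:
    """Hodges–Lehmann location estimate with a distribution-free CI.

    The estimate is the median of the n(n+1)/2 Walsh averages
    (d_i + d_j)/2, i ≤ j.  CI endpoints are the C+1-th smallest and
    largest Walsh averages, with C the largest integer such that
    P(W+ ≤ C) ≤ α/2 under the exact signed-rank null — giving coverage
    at least ``level``.  When n is too small for the requested level the
    widest attainable interval is returned, flagged.
    """
    d = np.asarray(diffs, dtype=np.float64)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("diffs must be a non-empty 1D sequence")
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    walsh = _walsh_averages(d)
    estimate = float(np.median(walsh))
    n = d.size
    alpha = 1.0 - level

    counts = _signed_rank_counts(n)
    cdf = np.cumsum(counts) / counts.sum()
    # Largest C with P(W+ <= C) <= alpha/2.
    ok = np.nonzero(cdf <= alpha / 2.0)[0]
    if ok.size == 0:
        warnings.warn(
            f"n = {n} is too small for a {level:.0%} interval; "
            "returning the widest attainable interval", stacklevel=2,
        )
        lo, hi = float(walsh[0]), float(walsh[-1])
        achieved = float(1.0 - 2.0 / counts.sum())
        return HodgesLehmannResult(estimate, lo, hi, level, achieved, widest=True)
    c = int(ok[-1])
    lo = float(walsh[c])
    hi = float(walsh[len(walsh) - 1 - c])
    achieved = float(1.0 - 2.0 * cdf[c])
    return HodgesLehmannResult(estimate, lo, hi, level, achieved)


# ---------------------------------------------------------------------------
# Cohort-level tables
# ---------------------------------------------------------------------------

def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvalues, dtype=np.float64)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def _median_iqr(x: np.ndarray) -> tuple[float, float, float]:
    # Quartiles by linear interpolation between order statistics.
    return (
        float(np.median(x)),
        float(np.percentile(x, 25)),
        float(np.percentile(x, 75)),
    )


def compare_modalities(
    db: pd.DataFrame,
    wb: pd.DataFrame,
    features: list[str] | None = None,
    *,
    case_col: str = "case_id",
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-feature paired comparison of two modality tables.

    Both tables must carry matching case identifiers; differences are
    taken db − wb per case.  Returns one row per feature with medians
    and IQRs per modality, the Hodges–Lehmann median difference with
    95% CI, the Wilcoxon p-value and a significance flag at ``alpha``
    (optionally Holm-adjusted).  No multiplicity adjustment is applied
    by default.
    """
    db_i = db.set_index(case_col) if case_col in db.columns else db
    wb_i = wb.set_index(case_col) if case_col in wb.columns else wb
    missing = sorted(set(db_i.index).symmetric_difference(wb_i.index))
    if missing:
        raise ValueError(f"unmatched case IDs between tables: {missing}")
    wb_i = wb_i.loc[db_i.index]
    if features is None:
        features = [
            c for c in db_i.columns
            if c in wb_i.columns and np.issubdtype(db_i[c].dtype, np.number)
        ]

    rows = []
    for feat in features:
        x = db_i[feat].to_numpy(dtype=np.float64)
        y = wb_i[feat].to_numpy(dtype=np.float64)
        keep = ~(np.isnan(x) | np.isnan(y))
        x, y = x[keep], y[keep]
        d = x - y
        test = wilcoxon_signed_rank(d)
        hl = hodges_lehmann_ci(d)
        m_db, q1_db, q3_db = _median_iqr(x)
        m_wb, q1_wb, q3_wb = _median_iqr(y)
        rows.append({
            "feature": feat,
            "db_median": m_db, "db_q1": q1_db, "db_q3": q3_db,
            "wb_median": m_wb, "wb_q1": q1_wb, "wb_q3": q3_wb,
            "median_difference": hl.estimate,
            "ci_low": hl.ci_low, "ci_high": hl.ci_high,
            "p_value": test.pvalue,
            "exact": test.exact,
            "degenerate": test.degenerate,
        })
    table = pd.DataFrame(rows)
    pcol = table["p_value"].to_numpy()
    if holm:
        table["p_adjusted"] = holm_adjust(pcol)
        table["significant"] = table["p_adjusted"] < alpha
    else:
        table["significant"] = pcol < alpha
    return table


def stratified_summary(
    metrics: pd.DataFrame,
    cutoff_cm: float = 2.5,
    value_cols: list[str] | None = None,
    *,
    case_col: str = "case_id",
    modality_col: str = "modality",
    diameter_col: str = "d_MRI_cm",
) -> pd.DataFrame:
    """Median (IQR) per size stratum and modality, with db/wb fold changes.

    The cohort is split at the MRI longest diameter ``cutoff_cm`` into
    ``<= cutoff`` and ``> cutoff`` strata; per stratum, metric and
    modality the median and quartiles (linear interpolation) are
    reported, and the fold change is the ratio of stratum medians,
    median_db / median_wb.  Empty strata are omitted with a warning.
    """
    required = {case_col, modality_col, diameter_col}
    if not required.issubset(metrics.columns):
        raise ValueError(f"metrics table must carry columns {sorted(required)}")
    if value_cols is None:
        value_cols = [
            c for c in metrics.columns
            if c not in required and np.issubdtype(metrics[c].dtype, np.number)
        ]

    labels = {
        True: f"d_MRI <= {cutoff_cm} cm",
        False: f"d_MRI > {cutoff_cm} cm",
    }
    rows = []
    for is_small in (True, False):
        sel = (metrics[diameter_col] <= cutoff_cm) == is_small
        sub = metrics[sel]
        if sub.empty:
            warnings.warn(f"stratum {labels[is_small]!r} is empty; omitted",
                          stacklevel=2)
            continue
        n_cases = sub[case_col].nunique()
        for metric in value_cols:
            stats = {}
            for mod in ("db", "wb"):
                vals = sub.loc[sub[modality_col] == mod, metric].dropna().to_numpy()
                stats[mod] = _median_iqr(vals) if vals.size else (np.nan,) * 3
            m_db, q1_db, q3_db = stats["db"]
            m_wb, q1_wb, q3_wb = stats["wb"]
            fold = m_db / m_wb if (np.isfinite(m_wb) and m_wb != 0) else np.nan
            rows.append({
                "stratum": labels[is_small],
                "n_cases": n_cases,
                "metric": metric,
                "db_median": m_db, "db_q1": q1_db, "db_q3": q3_db,
                "wb_median": m_wb, "wb_q1": q1_wb, "wb_q3": q3_wb,
                "fold_change": fold,
            })
    return pd.DataFrame(rows)
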