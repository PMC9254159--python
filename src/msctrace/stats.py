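"""Figure-legend statistics: paired and one-sample t tests, Holm–Šídák
family-wise correction, and the two-stage step-up (adaptive) FDR of
Benjamini, Krieger and Yekutieli (BKY) used for volcano analyses.

The t tests delegate to scipy; the multiple-testing procedures are
implemented explicitly so the exact stepwise rules are inspectable, and
are cross-checked against statsmodels in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "paired_t",
    "one_sample_t",
    "holm_sidak",
    "bky_two_stage_fdr",
    "bky_qvalues",
    "volcano_table",
]


@dataclass
class TTestResult:
    t: float
    p: float
    df: int
    degenerate: bool = False  # zero difference variance: p undefined


def paired_t(values_a, values_b) -> TTestResult:
    """Two-tailed Student's t for paired samples (complete pairs only)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be matched 1-D vectors")
    if len(a) < 2:
        raise ValueError("need >= 2 complete pairs")
    d = a - b
    if np.ptp(d) == 0:
        if np.all(d == 0):
            return TTestResult(t=0.0, p=1.0, df=len(d) - 1)
        return TTestResult(t=np.nan, p=np.nan, df=len(d) - 1, degenerate=True)
    res = sps.ttest_rel(a, b)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), df=len(a) - 1)


def one_sample_t(values, reference: float) -> TTestResult:
    """Two-tailed one-sample t against a reference value."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need >= 2 values")
    if np.ptp(v) == 0:
        if v[0] == reference:
            return TTestResult(t=0.0, p=1.0, df=len(v) - 1)
        return TTestResult(t=np.nan, p=np.nan, df=len(v) - 1, degenerate=True)
    res = sps.ttest_1samp(v, reference)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), df=len(v) - 1)


def holm_sidak(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm's step-down procedure with Šídák-type adjustment.

    Sorted ascending, the i-th smallest p gets 1 − (1 − p_(i))^(m−i+1),
    enforced monotone by a running maximum and capped at 1.  Returns
    (adjusted p in input order, rejection mask at ``alpha``).
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        step = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, min(step, 1.0))
        adj_sorted[rank] = running
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted < alpha


def _bh_n_rejections(p_sorted: np.ndarray, level: float) -> int:
    """Number of rejections of the linear (BH) step-up at ``level`` on an
    ascending-sorted p-vector."""
    m = len(p_sorted)
    thresh = level * np.arange(1, m + 1) / m
    below = np.nonzero(p_sorted <= thresh)[0]
    return 0 if len(below) == 0 else int(below[-1]) + 1


def bky_two_stage_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage step-up FDR control (Benjamini–Krieger–Yekutieli).

    Stage 1 runs a linear step-up at q' = q/(1+q) to estimate the number
    of true nulls m̂₀ = m − r₁; stage 2 reruns the linear step-up at
    q'·m/m̂₀.  No stage-1 rejections means no rejections; m̂₀ = 0 rejects
    everything.  Returns (q-values, rejection mask); the q-value of a
    feature is the smallest nominal q at which the two-stage rule rejects
    it, computed by bisection, which makes the pair self-consistent.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    reject = _bky_reject(p, q)
    qvals = bky_qvalues(p)
    return qvals, reject


def _bky_reject(p: np.ndarray, q: float) -> np.ndarray:
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    q1 = q / (1.0 + q)
    r1 = _bh_n_rejections(p_sorted, q1)
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    m0 = m - r1
    if m0 == 0:
        return np.ones(m, dtype=bool)
    r2 = _bh_n_rejections(p_sorted, q1 * m / m0)
    reject = np.zeros(m, dtype=bool)
    reject[order[:r2]] = True
    return reject


def bky_qvalues(pvalues, tol: float = 1e-10) -> np.ndarray:
    """Smallest nominal q at which each p is rejected by the two-stage
    rule, found by bisection (the rejection set grows with q)."""
    p = np.asarray(pvalues, dtype=float)
    qvals = np.ones(len(p))
    ever_rejected = _bky_reject(p, 1.0 - 1e-12)
    for i in range(len(p)):
        if not ever_rejected[i]:
            qvals[i] = 1.0
            continue
        lo, hi = 0.0, 1.0 - 1e-12
        while hi - lo > tol:
            mid = (lo + hi) / 2.0
            if _bky_reject(p, mid)[i]:
                hi = mid
            else:
                lo = mid
        qvals[i] = hi
    return qvals


def volcano_table(
    data: pd.DataFrame,
    group_a: str,
    group_b: str,
    q: float = 0.05,
    value_col: str = "value",
) -> tuple[pd.DataFrame, list[str]]:
    """Paired volcano analysis of a long-form table.

    ``data`` has columns feature, unit (the pairing id, e.g. donor),
    group, and ``value_col``.  Per feature: log2 fold change of group
    means (b over a), paired-t p-value, and BKY q across the retained
    family; rows sorted by q.  Features lacking >= 2 complete pairs are
    excluded and their ids returned separately.
    """
    required = {"feature", "unit", "group", value_col}
    if not required <= set(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    excluded: list[str] = []
    rows = []
    for feature, grp in data.groupby("feature", sort=True):
        wide = grp.pivot_table(index="unit", columns="group", values=value_col)
        if group_a not in wide.columns or group_b not in wide.columns:
            excluded.append(str(feature))
            continue
        complete = wide[[group_a, group_b]].dropna()
        if len(complete) < 2:
            excluded.append(str(feature))
            continue
        a = complete[group_a].to_numpy()
        b = complete[group_b].to_numpy()
        res = paired_t(b, a)
        mean_a, mean_b = a.mean(), b.mean()
        log2fc = (
            np.log2(mean_b / mean_a) if mean_a > 0 and mean_b > 0 else np.nan
        )
        rows.append(
            {
                "feature": feature,
                "log2_fold_change": log2fc,
                "p": res.p,
                "n_pairs": len(complete),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        table["q"] = []
        table["significant"] = []
        table["direction"] = []
        return table, excluded
    valid = table["p"].notna()
    qvals = np.full(len(table), np.nan)
    reject = np.zeros(len(table), dtype=bool)
    if valid.any():
        qv, rej = bky_two_stage_fdr(table.loc[valid, "p"].to_numpy(), q)
        qvals[valid.to_numpy()] = qv
        reject[valid.to_numpy()] = rej
    table["q"] = qvals
    table["significant"] = reject
    table["direction"] = np.where(table["log2_fold_change"] >= 0, "up", "down")
    table = table.sort_values(["q", "p", "feature"]).reset_index(drop=True)
    return table, excluded
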