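"""Statistical primitives used throughout the pipeline.

All routines share explicit conventions for degenerate inputs so that the
filter cascade can count "not testable" assays instead of silently dropping
them:

* two-sample t-test — pooled (Student) or Satterthwaite (Welch) flavors;
  zero variance in both groups yields t=0, p=1 when the means agree and
  p=0 (flagged) when they do not.
* Spearman correlation — average ranks for ties; two-sided p either from
  the t approximation or by exact enumeration of all n! orderings (used by
  default for n <= 8, matching the small group sizes of array-card screens).
* Kruskal-Wallis — tie-corrected H with a chi-square p-value.
* Benjamini-Hochberg — step-up FDR adjustment, missing p-values propagate.

Significance filters elsewhere in the package use the strict-inequality
rule: p < alpha passes, p == alpha fails.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.stats as sps

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "TestResult",
    "CorrelationRecord",
    "two_sample_t_test",
    "spearman",
    "kruskal_wallis",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    n: tuple
    note: str = ""


@dataclass(frozen=True)
class CorrelationRecord:
    x_name: str
    y_name: str
    r: float
    p_value: float
    n_pairs: int
    q_value: float = math.nan
    note: str = ""


def _as_clean_array(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return a


def two_sample_t_test(x, y, flavor: str = "student") -> TestResult:
    """Two-sided unpaired t-test.

    flavor "student" uses the pooled variance with df = nx + ny - 2;
    "welch" uses per-group variances with Satterthwaite df.
    """
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise DegenerateInputError(
            f"t-test needs >=2 values per group, got {nx} and {ny}"
        )
    if flavor not in ("student", "welch"):
        raise ValidationError(f"unknown t-test flavor {flavor!r}")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if mx == my:
            df = nx + ny - 2 if flavor == "student" else math.nan
            return TestResult(0.0, df, 1.0, (nx, ny))
        return TestResult(
            math.copysign(math.inf, mx - my),
            nx + ny - 2 if flavor == "student" else math.nan,
            0.0,
            (nx, ny),
            note="zero variance in both groups, unequal means",
        )
    if flavor == "student":
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se = math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
        df = float(nx + ny - 2)
    else:
        se = math.sqrt(vx / nx + vy / ny)
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
    t = (mx - my) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(min(p, 1.0)), (nx, ny))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0.0:
        return math.nan
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


@lru_cache(maxsize=8)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _exact_perm_p(rx: np.ndarray, ry: np.ndarray, r_obs: float) -> float:
    """Two-sided exact p: fraction of the n! orderings of y whose Spearman
    r has magnitude >= |r_obs| (tolerance 1e-12). Ties handled because the
    enumeration permutes the observed (possibly tied) ranks."""
    n = len(rx)
    perms = _perm_matrix(n)
    a = rx - rx.mean()
    b = ry - ry.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    r_all = (b[perms] @ a) / denom
    return float(np.mean(np.abs(r_all) >= abs(r_obs) - 1e-12))


def spearman(
    x,
    y,
    p_method: str = "auto",
    x_name: str = "x",
    y_name: str = "y",
) -> CorrelationRecord:
    """Spearman rank correlation with pairwise deletion of missing values.

    p_method: "t_approx" (t = r*sqrt((n-2)/(1-r^2)) on n-2 df),
    "exact_perm" (enumeration of all n! orderings, n <= 8), or "auto"
    (exact for n <= 8, t approximation otherwise).
    """
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    if len(x) != len(y):
        raise ValidationError("x and y must be paired (equal length)")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        return CorrelationRecord(
            x_name, y_name, math.nan, math.nan, n, note="fewer than 3 pairs"
        )
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    r = _pearson(rx, ry)
    if math.isnan(r):
        return CorrelationRecord(
            x_name, y_name, math.nan, math.nan, n, note="zero rank variance"
        )
    if p_method == "auto":
        p_method = "exact_perm" if n <= 8 else "t_approx"
    if p_method == "exact_perm":
        if n > 8:
            raise ValidationError("exact_perm enumeration limited to n <= 8")
        p = _exact_perm_p(rx, ry, r)
    elif p_method == "t_approx":
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * sps.t.sf(abs(t), n - 2)
    else:
        raise ValidationError(f"unknown p_method {p_method!r}")
    return CorrelationRecord(x_name, y_name, r, float(min(p, 1.0)), n)


def kruskal_wallis(groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p on k-1 df."""
    cleaned = [
        _as_clean_array(g, "group")[~np.isnan(_as_clean_array(g, "group"))]
        for g in groups
    ]
    cleaned = [g for g in cleaned if len(g) > 0]
    k = len(cleaned)
    total = sum(len(g) for g in cleaned)
    if k < 2 or total < 3:
        raise DegenerateInputError(
            "Kruskal-Wallis needs >=2 non-empty groups and total n >= 3"
        )
    pooled = np.concatenate(cleaned)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, float(k - 1), 1.0, tuple(len(g) for g in cleaned))
    h, p = sps.kruskal(*cleaned)
    return TestResult(float(h), float(k - 1), float(p), tuple(len(g) for g in cleaned))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min over j >= i of min(1, p_(j) * m / j) over the m non-missing
    p-values; NaN entries propagate to NaN q-values.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if pv.size and (np.any(pv < 0.0) or np.any(pv > 1.0)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    out[mask] = q
    return out
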