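"""qRT-PCR relative expression and group-comparison statistics.

Relative expression of a target transcript against a single housekeeping
reference uses the 2^-dCt rule (one PCR cycle = a factor of two in template
abundance; no calibrator sample).  Group comparisons cover the two-sample
tests typically reported for expression cohorts — Mann–Whitney U (with an
exact small-sample enumeration), Student's / Welch's t, and Spearman rank
correlation — and a cohort-level driver that compares a value column across
the levels of a categorical label, reporting medians and means alongside
the p-value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .survival import ValidationError

__all__ = [
    "TestResult",
    "GroupComparison",
    "relative_expression",
    "rescale_to_reference_median",
    "mann_whitney_u",
    "student_t",
    "spearman_corr",
    "compare_groups",
    "significance_stars",
]


class DegenerateStatisticError(ValidationError):
    """The requested statistic is undefined for this input (e.g. zero variance)."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample (or paired) hypothesis test."""

    test: str
    statistic: float
    p_value: float
    n_x: int
    n_y: int
    detail: dict = field(default_factory=dict)

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


@dataclass(frozen=True)
class GroupComparison:
    """Pairwise comparison of a value column between two label levels."""

    label: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    mean_a: float
    mean_b: float
    test: str
    statistic: float
    p_value: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)

    def to_dict(self) -> dict:
        import dataclasses

        d = dataclasses.asdict(self)
        d["stars"] = self.stars
        return d


def significance_stars(p: float) -> str:
    """Conventional significance annotation: ns / * / ** / *** / ****."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# relative quantification
# ---------------------------------------------------------------------------


def relative_expression(ct_target, ct_reference):
    """Relative expression ratio 2^-(ct_target - ct_reference).

    Both Ct values must be finite and positive.  Accepts scalars or arrays.
    """
    ct_t = np.asarray(ct_target, dtype=float)
    ct_r = np.asarray(ct_reference, dtype=float)
    if not (np.all(np.isfinite(ct_t)) and np.all(np.isfinite(ct_r))):
        raise ValidationError("Ct values must be finite")
    if np.any(ct_t <= 0) or np.any(ct_r <= 0):
        raise ValidationError("Ct values must be positive cycle counts")
    out = np.power(2.0, -(ct_t - ct_r))
    return float(out) if out.ndim == 0 else out


def rescale_to_reference_median(values, reference_values):
    """Rescale expression ratios so the reference cohort's median is 1.

    Useful when plotting patient ratios against a healthy-donor cohort.
    """
    ref = np.asarray(reference_values, dtype=float)
    if ref.size == 0 or np.any(ref <= 0):
        raise ValidationError("reference values must be positive and non-empty")
    med = float(np.median(ref))
    return np.asarray(values, dtype=float) / med


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _rank_sum_counts(n: int, total: int) -> tuple:
    """Number of ways to choose ``n`` of the ranks 1..total with each rank sum.

    Returns a tuple ``c`` where ``c[s]`` counts subsets with rank sum ``s``
    (index 0 unused below the minimum).  Classic Gaussian-binomial recursion.
    """
    max_sum = total * (total + 1) // 2
    # dp[k][s]
    dp = [[0] * (max_sum + 1) for _ in range(n + 1)]
    dp[0][0] = 1
    for r in range(1, total + 1):
        for k in range(min(r, n), 0, -1):
            row_k, row_km1 = dp[k], dp[k - 1]
            for s in range(max_sum, r - 1, -1):
                if row_km1[s - r]:
                    row_k[s] += row_km1[s - r]
    return tuple(dp[n])


def _exact_mw_p_noties(u_obs: float, n: int, m: int) -> float:
    """Two-sided exact p for U by symmetric tail counting (no ties)."""
    counts = _rank_sum_counts(n, n + m)
    offset = n * (n + 1) // 2
    mid = n * m / 2.0
    dev = abs(u_obs - mid)
    total = math.comb(n + m, n)
    hits = 0
    for s, c in enumerate(counts):
        if c and abs((s - offset) - mid) >= dev - 1e-9:
            hits += c
    return min(1.0, hits / total)


def _exact_mw_p_ties(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p via full enumeration over midrank assignments."""
    n, m = x.size, y.size
    if math.comb(n + m, n) > 500_000:
        raise ValidationError(
            "exact Mann–Whitney enumeration limited to C(n+m, n) <= 500000; use normal mode"
        )
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    mid = n * m / 2.0
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    dev = abs(u_obs - mid)
    hits = 0
    total = 0
    base = n * (n + 1) / 2.0
    for combo in itertools.combinations(range(n + m), n):
        u = ranks[list(combo)].sum() - base
        if abs(u - mid) >= dev - 1e-9:
            hits += 1
        total += 1
    return min(1.0, hits / total)


def mann_whitney_u(x, y, mode: str = "auto", continuity: bool = True) -> TestResult:
    """Two-sided Mann–Whitney U test.

    ``mode="exact"`` enumerates the permutation distribution (midranks, so
    ties are handled); ``mode="normal_approx"`` uses the normal
    approximation with tie and (by default) continuity correction;
    ``mode="auto"`` picks exact when both samples have n <= 10 and there
    are no ties, the approximation otherwise.

    The reported statistic is U for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_x = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    has_ties = np.unique(pooled).size < pooled.size

    if mode == "auto":
        mode = "exact" if (n <= 10 and m <= 10 and not has_ties) else "normal_approx"
    if mode == "exact":
        p = _exact_mw_p_noties(u_x, n, m) if not has_ties else _exact_mw_p_ties(x, y)
        method = "exact"
    elif mode == "normal_approx":
        mean = n * m / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        N = n + m
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (N * (N - 1)) if N > 1 else 0.0
        var = n * m / 12.0 * ((N + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            delta = u_x - mean
            if continuity:
                delta = np.sign(delta) * max(0.0, abs(delta) - 0.5)
            z = delta / math.sqrt(var)
            p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
        method = "normal_approx"
    else:
        raise ValidationError(f"unknown mode: {mode!r}")
    return TestResult(
        test="mann_whitney_u",
        statistic=u_x,
        p_value=float(p),
        n_x=n,
        n_y=m,
        detail={"method": method, "ties": bool(has_ties)},
    )


# ---------------------------------------------------------------------------
# t test and Spearman
# ---------------------------------------------------------------------------


def student_t(x, y, variant: str = "welch") -> TestResult:
    """Two-sided two-sample t test (Welch by default, ``variant="pooled"``)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("t test requires at least 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    n, m = x.size, y.size
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return TestResult("student_t", 0.0, 1.0, n, m, {"df": float(n + m - 2), "variant": variant})
        raise DegenerateStatisticError("zero variance in both groups with unequal means")
    if variant == "pooled":
        sp2 = ((n - 1) * vx + (m - 1) * vy) / (n + m - 2)
        se = math.sqrt(sp2 * (1 / n + 1 / m))
        df = n + m - 2
    elif variant == "welch":
        se = math.sqrt(vx / n + vy / m)
        df = (vx / n + vy / m) ** 2 / ((vx / n) ** 2 / (n - 1) + (vy / m) ** 2 / (m - 1))
    else:
        raise ValidationError(f"unknown variant: {variant!r}")
    t = (x.mean() - y.mean()) / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TestResult("student_t", float(t), p, n, m, {"df": float(df), "variant": variant})


def spearman_corr(x, y) -> TestResult:
    """Spearman rank correlation (midranks) with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired samples of equal length required")
    if x.size < 3:
        raise ValidationError("Spearman correlation requires n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise DegenerateStatisticError("constant input: rank correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if abs(rho) >= 1.0 - 1e-15:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return TestResult("spearman", rho, p, n, n, {"rho": rho})


# ---------------------------------------------------------------------------
# cohort-level comparisons
# ---------------------------------------------------------------------------

_TESTS = {
    "mannwhitney": lambda a, b: mann_whitney_u(a, b),
    "mann_whitney_u": lambda a, b: mann_whitney_u(a, b),
    "ttest": lambda a, b: student_t(a, b),
    "student_t": lambda a, b: student_t(a, b),
}


def compare_groups(
    cohort,
    label: str,
    value_field: str = "relative_expression",
    test: str = "mannwhitney",
    merge_levels: dict[str, list[str]] | None = None,
) -> list[GroupComparison]:
    """Compare a value column pairwise across the levels of a label column.

    ``cohort`` is a DataFrame or anything with a ``.table`` DataFrame
    attribute.  Rows with missing label or value are dropped (complete-case
    per comparison).  ``merge_levels`` optionally collapses levels, e.g.
    ``{"int_adv": ["intermediate", "adverse"]}`` to mirror a
    favorable-versus-rest analysis.
    """
    df = cohort.table if hasattr(cohort, "table") else cohort
    if label not in df.columns or value_field not in df.columns:
        raise ValidationError(f"cohort lacks required column {label!r} or {value_field!r}")
    sub = df[[label, value_field]].dropna()
    lab = sub[label].astype(str)
    if merge_levels:
        remap = {old: new for new, olds in merge_levels.items() for old in olds}
        lab = lab.map(lambda v: remap.get(v, v))
    levels = sorted(lab.unique())
    if len(levels) < 2:
        raise ValidationError(f"label {label!r} has fewer than 2 non-empty levels")
    if test not in _TESTS:
        raise ValidationError(f"unknown test {test!r}; choose from {sorted(_TESTS)}")
    runner = _TESTS[test]
    out = []
    values = sub[value_field].to_numpy(dtype=float)
    for a, b in itertools.combinations(levels, 2):
        va = values[(lab == a).to_numpy()]
        vb = values[(lab == b).to_numpy()]
        res = runner(va, vb)
        out.append(
            GroupComparison(
                label=label,
                group_a=a,
                group_b=b,
                n_a=va.size,
                n_b=vb.size,
                median_a=float(np.median(va)),
                median_b=float(np.median(vb)),
                mean_a=float(va.mean()),
                mean_b=float(vb.mean()),
                test=res.test,
                statistic=res.statistic,
                p_value=res.p_value,
            )
        )
    return out


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Tabulate GroupComparison records for TSV/JSON export."""
    return pd.DataFrame([c.to_dict() for c in comparisons])
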