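"""Right-censored survival machinery: Kaplan–Meier estimation, the two-group
log-rank test, single-covariate Cox proportional-hazards fitting, and
Benjamini–Hochberg FDR adjustment.

Everything here is implemented directly on top of numpy; external survival
packages are used only as cross-validation oracles in the test suite.

Conventions
-----------
* A record is a pair ``(time, event)`` with ``time > 0`` and ``event`` true
  for a death/event, false for right censoring.
* Censorings at an event time ``t`` are still at risk for the events at
  ``t`` (the standard product-limit convention).
* Median survival is the smallest event time at which the survival estimate
  is <= 0.5; ``None`` when the curve never reaches 0.5.  This matches the
  convention of mainstream survival software but is stated here explicitly
  because reports that quote a median depend on it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "KMCurve",
    "CoxFit",
    "km_estimate",
    "median_survival",
    "logrank_test",
    "cox_fit",
    "bh_fdr",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


def _as_survival_arrays(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if t.ndim != 1 or t.size == 0:
        raise ValidationError("survival input must be a non-empty 1-d sequence of times")
    if e.shape != t.shape:
        raise ValidationError("time and event must have identical length")
    if not np.all(np.isfinite(t)) or np.any(t <= 0):
        raise ValidationError("survival times must be finite and positive")
    return t, e


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate.

    Attributes
    ----------
    event_times : distinct times at which at least one event occurred, sorted.
    survival : estimated survival probability just after each event time.
    at_risk : number at risk immediately before each event time.
    n_events : number of events at each event time.
    censor_times : times of censored observations (with multiplicity).
    n_total : number of records the curve was estimated from.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray
    n_total: int

    @property
    def median(self) -> float | None:
        """Smallest event time with survival <= 0.5; None if never reached."""
        hit = np.nonzero(self.survival <= 0.5 + 1e-12)[0]
        if hit.size == 0:
            return None
        return float(self.event_times[hit[0]])

    def survival_at(self, t: float) -> float:
        """Step-function value of the estimate at time ``t``."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.n_events,
            }
        )

    def to_dict(self) -> dict:
        return {
            "event_times": self.event_times.tolist(),
            "survival": self.survival.tolist(),
            "at_risk": self.at_risk.tolist(),
            "n_events": self.n_events.tolist(),
            "censor_times": self.censor_times.tolist(),
            "n_total": int(self.n_total),
            "median": self.median,
        }


def km_estimate(time, event) -> KMCurve:
    """Kaplan–Meier product-limit estimate of the survival function.

    Parameters
    ----------
    time, event : per-record observation time and event indicator.

    Returns
    -------
    KMCurve with steps at the distinct event times.
    """
    t, e = _as_survival_arrays(time, event)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    ev_times, d = np.unique(t[e], return_counts=True)
    # at risk just before s: all records with time >= s
    at_risk = t.size - np.searchsorted(t, ev_times, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(
        event_times=ev_times,
        survival=surv,
        at_risk=at_risk.astype(int),
        n_events=d,
        censor_times=np.sort(t[~e]),
        n_total=int(t.size),
    )


def median_survival(curve: KMCurve) -> float | None:
    """Median survival time of a KM curve (<= 0.5 convention); None if undefined."""
    return curve.median


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test.

    ``group`` is a boolean (or 0/1) stratum label per record.  Returns the
    1-df chi-square statistic and its upper-tail p-value.  The variance at
    each distinct event time is hypergeometric.
    """
    t, e = _as_survival_arrays(time, event)
    g = np.asarray(group).astype(bool)
    if g.shape != t.shape:
        raise ValidationError("group must align with time/event")
    if g.all() or (~g).all():
        raise ValidationError("log-rank test requires two non-empty groups")

    order = np.argsort(t, kind="stable")
    t, e, g = t[order], e[order], g[order]
    ev_times, d = np.unique(t[e], return_counts=True)
    if ev_times.size == 0:
        return 0.0, 1.0

    starts = np.searchsorted(t, ev_times, side="left")
    r = t.size - starts
    # suffix counts of group-1 members give r1 at each event time
    suffix_g = np.concatenate([np.cumsum(g[::-1])[::-1], [0]])
    r1 = suffix_g[starts]
    group_idx = np.searchsorted(ev_times, t[e])
    d1 = np.bincount(group_idx, weights=g[e].astype(float), minlength=ev_times.size)

    frac = r1 / r
    o_minus_e = float(np.sum(d1 - d * frac))
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = np.where(
            r > 1, d * frac * (1 - frac) * (r - d) / np.maximum(r - 1, 1), 0.0
        )
    var = float(np.sum(var_terms))
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Cox proportional hazards, single covariate
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """Single-covariate proportional-hazards fit.

    ``hazard_ratio`` is ``exp(coef)``; ``p_value`` is the two-sided Wald
    p by default, with score and likelihood-ratio p-values alongside.
    ``converged`` is False for monotone-likelihood (perfect separation)
    data, in which case ``coef`` holds the last iterate and ``warning``
    explains the diagnostic.
    """

    coef: float
    se: float
    z: float
    p_value: float
    score_chi2: float
    score_p: float
    lr_chi2: float
    lr_p: float
    loglik: float
    loglik_null: float
    iterations: int
    converged: bool
    ties: str
    n: int
    n_events: int
    warning: str | None = None

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.coef))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hazard_ratio"] = self.hazard_ratio
        return d


def _cox_structure(t, e, x, ties: str):
    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    ev_times, d_per_group = np.unique(t[e], return_counts=True)
    if ev_times.size == 0:
        raise ValidationError("Cox fit requires at least one event")
    ev_group_start = np.searchsorted(t, ev_times, side="left")

    # events in time order are already grouped by event time
    tied_x = x[e]
    rep = np.repeat(np.arange(ev_times.size), d_per_group)
    tied_group = rep
    n_tied = int(d_per_group.sum())
    if ties == "efron":
        group_start = np.concatenate([[0], np.cumsum(d_per_group)[:-1]])
        within = np.arange(n_tied) - np.repeat(group_start, d_per_group)
        frac = within / np.repeat(d_per_group, d_per_group)
    elif ties == "breslow":
        frac = np.zeros(n_tied)
    else:
        raise ValidationError(f"unknown ties method: {ties!r}")
    sum_x_events = float(tied_x.sum())
    return (x, ev_group_start, tied_x, tied_group, d_per_group, frac, rep, sum_x_events)


def _cox_eval(beta, structure):
    """Log partial likelihood, gradient and Hessian at ``beta``.

    ``structure`` packs the pre-sorted risk-set layout from
    ``_cox_structure``; Breslow is the Efron formula with the tied-event
    fraction forced to zero.  Risk-set aggregates come from reverse
    cumulative sums over the time-sorted records.
    """
    (x_sorted, ev_group_start, tied_x, tied_group, d_per_group, frac, rep, sum_x_events) = structure
    w = np.exp(beta * x_sorted)
    xw = x_sorted * w
    S0 = np.cumsum(w[::-1])[::-1][ev_group_start]
    S1 = np.cumsum(xw[::-1])[::-1][ev_group_start]
    S2 = np.cumsum((x_sorted * xw)[::-1])[::-1][ev_group_start]

    tw = np.exp(beta * tied_x)
    n_groups = ev_group_start.size
    g0 = np.zeros(n_groups)
    g1 = np.zeros(n_groups)
    g2 = np.zeros(n_groups)
    np.add.at(g0, tied_group, tw)
    np.add.at(g1, tied_group, tied_x * tw)
    np.add.at(g2, tied_group, tied_x * tied_x * tw)

    D = S0[rep] - frac * g0[rep]
    N1 = S1[rep] - frac * g1[rep]
    N2 = S2[rep] - frac * g2[rep]

    loglik = beta * sum_x_events - float(np.sum(np.log(D)))
    grad = sum_x_events - float(np.sum(N1 / D))
    hess = -float(np.sum(N2 / D - (N1 / D) ** 2))
    return loglik, grad, hess


_SEPARATION_BETA = 30.0


def cox_fit(
    time,
    event,
    covariate,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Maximize the Cox partial likelihood for a single covariate.

    Newton–Raphson with step-halving on likelihood decrease; Efron tie
    correction by default (``ties="breslow"`` available, and required for
    exact agreement with the log-rank score test on tied data).

    Monotone likelihood (perfect separation of event order by the
    covariate) is reported as a non-converged fit with a diagnostic
    warning rather than raised, since scans over many cutoffs must be able
    to record and skip such candidates.
    """
    t, e = _as_survival_arrays(time, event)
    x = np.asarray(covariate, dtype=float)
    if x.shape != t.shape:
        raise ValidationError("covariate must align with time/event")
    if not np.all(np.isfinite(x)):
        raise ValidationError("covariate values must be finite")

    # centering improves conditioning and leaves beta unchanged
    x_centered = x - x.mean()
    structure = _cox_structure(t, e, x_centered, ties)

    # degenerate covariate: no variation among subjects at risk at event times
    if np.ptp(x_centered) == 0:
        raise ValidationError("covariate is constant; hazard ratio undefined")

    ll0, g0, h0 = _cox_eval(0.0, structure)
    if h0 >= 0:
        raise ValidationError("covariate carries no information at any event time")
    score_chi2 = g0 * g0 / (-h0)
    score_p = float(stats.chi2.sf(score_chi2, df=1))

    # Convergence is measured on the Newton step |g/I|, i.e. the gradient
    # scaled by the observed information: this keeps the criterion meaningful
    # in beta units across sample sizes (an absolute gradient threshold sits
    # below floating-point noise once the risk-set sums reach ~1e4).
    def _small(g_, h_):
        return abs(g_) <= tol * max(1.0, -h_)

    beta, ll, g, h = 0.0, ll0, g0, h0
    converged = False
    warning = None
    iterations = 0
    for iterations in range(1, max_iter + 1):
        if _small(g, h):
            converged = True
            break
        step = -g / h
        # step-halving: reject steps that decrease the likelihood beyond its
        # floating-point resolution (relative threshold, so near-optimum
        # noise-level fluctuations at large n do not block convergence)
        ll_noise = 1e-9 * max(1.0, abs(ll))
        new_beta = beta + step
        ll_new, g_new, h_new = _cox_eval(new_beta, structure)
        halvings = 0
        while ll_new < ll - ll_noise and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            ll_new, g_new, h_new = _cox_eval(new_beta, structure)
            halvings += 1
        if halvings == 30 and ll_new < ll - ll_noise:
            # stalled at numerical precision of the partial likelihood
            break
        beta, ll, g, h = new_beta, ll_new, g_new, h_new
        if abs(beta) > _SEPARATION_BETA:
            warning = (
                "monotone partial likelihood (perfect separation): "
                f"|beta| exceeded {_SEPARATION_BETA} without gradient convergence"
            )
            break
    else:
        iterations = max_iter
    if not converged and warning is None and _small(g, h):
        converged = True
    if not converged and warning is None:
        warning = "Newton–Raphson did not reach gradient tolerance"

    se = float(1.0 / np.sqrt(-h)) if h < 0 else float("inf")
    # monotone likelihood flattens both gradient and information, so the
    # scaled-gradient test can "converge" at an absurd beta; flag it instead
    if converged and (abs(beta) > 15.0 or se > 50.0):
        converged = False
        warning = (
            "monotone partial likelihood (perfect separation): "
            "estimate diverging, standard error unbounded"
        )
    z = beta / se if se > 0 and np.isfinite(se) else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    lr_chi2 = max(0.0, 2.0 * (ll - ll0))
    return CoxFit(
        coef=float(beta),
        se=se,
        z=float(z),
        p_value=p,
        score_chi2=float(score_chi2),
        score_p=score_p,
        lr_chi2=float(lr_chi2),
        lr_p=float(stats.chi2.sf(lr_chi2, df=1)),
        loglik=float(ll),
        loglik_null=float(ll0),
        iterations=iterations,
        converged=converged,
        ties=ties,
        n=int(t.size),
        n_events=int(e.sum()),
        warning=warning,
    )


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (q-values).

    For sorted p-values ``p_(1) <= ... <= p_(m)`` the adjusted value is
    ``q_(i) = min_{j >= i} p_(j) * m / j`` clipped to 1; results are
    returned in the original input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p_values must be a non-empty 1-d sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q
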