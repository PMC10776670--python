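"""In-vitro assay kinetics: exponential growth / doubling time, and
four-parameter-logistic (4PL) dose–response fitting with IC50.

Growth model
------------
Assuming exponential growth between two counts, the growth constant is

    lambda = (ln(Nt) - ln(N0)) / (t - t0)          [per hour]

and the doubling time is

    t_d = ln(2) / lambda                           [hours].

For a multi-timepoint series two estimators are provided: the mean of the
per-interval growth constants, and a log-linear least-squares regression of
ln(count) on time (the default for noisy data — it weights all points
jointly instead of only consecutive pairs).

Dose–response model
-------------------
Apoptotic fraction (or any response) against dose is fitted with the 4PL

    r(dose) = bottom + (top - bottom) / (1 + (ic50 / dose)^hill)

so the curve passes through (bottom+top)/2 exactly at dose = ic50, and
``hill > 0`` gives an increasing curve.  Fitting is least squares on
log-dose with multi-start initialization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .survival import ValidationError

__all__ = [
    "GrowthSeries",
    "FourPL",
    "DoseResponse",
    "growth_constant",
    "doubling_time",
    "fit_doubling_time",
    "four_pl",
    "fit_4pl",
    "compare_dose_response",
    "UndefinedDoublingError",
]


class UndefinedDoublingError(ValidationError):
    """The culture is not growing: lambda <= 0, doubling time undefined."""


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthSeries:
    """Timed cell counts for one replicate of a proliferation assay."""

    timepoints: np.ndarray  # hours
    counts: np.ndarray  # cells (per fixed volume)
    replicate: str = "r1"

    def __post_init__(self):
        t = np.asarray(self.timepoints, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        if t.ndim != 1 or t.size != c.size or t.size < 2:
            raise ValidationError("growth series needs >= 2 aligned timepoints and counts")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("timepoints must be strictly increasing")
        if np.any(c <= 0):
            raise ValidationError("cell counts must be positive")
        object.__setattr__(self, "timepoints", t)
        object.__setattr__(self, "counts", c)


def growth_constant(n0: float, nt: float, t0: float, t: float) -> float:
    """Exponential growth constant (ln(Nt) - ln(N0)) / (t - t0), per hour.

    Negative values are allowed (shrinking culture).
    """
    if n0 <= 0 or nt <= 0:
        raise ValidationError("cell counts must be positive")
    if t <= t0:
        raise ValidationError("observation time must exceed initial time")
    return (math.log(nt) - math.log(n0)) / (t - t0)


def doubling_time(lam: float) -> float:
    """Doubling time ln(2)/lambda in hours; requires lambda > 0."""
    if lam <= 0:
        raise UndefinedDoublingError("growth constant <= 0: culture is not growing")
    return math.log(2) / lam


@dataclass(frozen=True)
class DoublingEstimate:
    """Doubling-time estimate with its growth constant and a dispersion measure."""

    doubling_time: float  # hours
    growth_rate: float  # per hour
    method: str
    sd: float | None = None  # dispersion of per-interval/replicate estimates


def fit_doubling_time(
    series: GrowthSeries | list[GrowthSeries],
    method: str = "log_linear_regression",
) -> DoublingEstimate:
    """Estimate doubling time from one or more growth series.

    ``pairwise_mean`` averages the per-consecutive-interval growth
    constants; ``log_linear_regression`` fits ln(count) on time by least
    squares (pooled across replicates).  Both convert the growth constant
    with t_d = ln(2)/lambda and raise :class:`UndefinedDoublingError` when
    the estimated constant is not positive.
    """
    series_list = [series] if isinstance(series, GrowthSeries) else list(series)
    if not series_list:
        raise ValidationError("at least one growth series required")

    if method == "pairwise_mean":
        lams = []
        for s in series_list:
            for i in range(s.timepoints.size - 1):
                lams.append(
                    growth_constant(
                        s.counts[i], s.counts[i + 1], s.timepoints[i], s.timepoints[i + 1]
                    )
                )
        lam = float(np.mean(lams))
        sd = float(np.std(lams, ddof=1)) if len(lams) > 1 else None
    elif method == "log_linear_regression":
        t = np.concatenate([s.timepoints for s in series_list])
        logc = np.concatenate([np.log(s.counts) for s in series_list])
        slope, _ = np.polyfit(t, logc, 1)
        lam = float(slope)
        resid = logc - np.polyval(np.polyfit(t, logc, 1), t)
        sd = float(np.std(resid, ddof=min(2, resid.size - 1))) if resid.size > 2 else None
    else:
        raise ValidationError(f"unknown method: {method!r}")
    return DoublingEstimate(doubling_time=doubling_time(lam), growth_rate=lam, method=method, sd=sd)


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FourPL:
    """4PL parameters; ``bottom < top`` and ``ic50 > 0`` for a valid curve."""

    bottom: float
    top: float
    ic50: float
    hill: float

    def validate(self) -> "FourPL":
        if not self.bottom < self.top:
            raise ValidationError("4PL requires bottom < top")
        if self.ic50 <= 0:
            raise ValidationError("4PL requires ic50 > 0")
        return self


def four_pl(dose, params: FourPL):
    """Evaluate the 4PL curve at the given dose(s)."""
    d = np.asarray(dose, dtype=float)
    out = params.bottom + (params.top - params.bottom) / (1.0 + (params.ic50 / d) ** params.hill)
    return float(out) if out.ndim == 0 else out


@dataclass
class DoseResponse:
    """Dose–dilution responses, optionally carrying a fitted 4PL model."""

    doses: np.ndarray  # concentration, unit declared by caller
    responses: np.ndarray  # apoptotic fraction in [0,1] (or percent, declared)
    dose_unit: str = "nM"
    params: FourPL | None = None
    residual_ss: float | None = None
    converged: bool = False

    def __post_init__(self):
        d = np.asarray(self.doses, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if d.ndim != 1 or d.size != r.size:
            raise ValidationError("doses and responses must align")
        if np.any(d <= 0):
            raise ValidationError("doses must be positive")
        self.doses = d
        self.responses = r

    @property
    def ic50(self) -> float | None:
        return None if self.params is None else self.params.ic50


def _4pl_residuals(theta, log_dose, resp):
    bottom, top, log_ic50, hill = theta
    pred = bottom + (top - bottom) / (1.0 + np.exp(-hill * (log_dose - log_ic50)))
    return pred - resp


def fit_4pl(data: DoseResponse, normalize: bool = False) -> DoseResponse:
    """Least-squares 4PL fit with multi-start initialization.

    ``normalize=True`` rescales responses to percent-of-maximum before
    fitting (an option because raw apoptotic fractions are also fitted
    directly in practice).  Returns a copy of ``data`` carrying the fitted
    parameters; a fit that fails from every start is returned with
    ``converged=False`` and no parameters rather than raised, so batch
    pipelines can record the failure.
    """
    if np.unique(data.doses).size < 4:
        raise ValidationError("4PL fit requires >= 4 distinct doses")
    resp = data.responses.astype(float)
    if normalize:
        resp = resp / resp.max()
    log_dose = np.log(data.doses)

    lo, hi = float(resp.min()), float(resp.max())
    span = max(hi - lo, 1e-8)
    starts = []
    for hill0 in (0.5, 1.0, 2.0, 4.0):
        for q in (0.25, 0.5, 0.75):
            starts.append(
                np.array([lo, hi, float(np.quantile(log_dose, q)), hill0])
            )
    best = None
    for theta0 in starts:
        try:
            res = optimize.least_squares(
                _4pl_residuals, theta0, args=(log_dose, resp), method="lm", max_nfev=5000
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    out = replace_fields(data)
    if best is None:
        out.converged = False
        return out
    bottom, top, log_ic50, hill = best.x
    if hill < 0:  # flip to the canonical increasing-orientation parameterization
        bottom, top, hill = top, bottom, -hill
    if not bottom < top:
        out.converged = False
        return out
    out.params = FourPL(float(bottom), float(top), float(np.exp(log_ic50)), float(hill))
    out.residual_ss = float(2 * best.cost)
    out.converged = True
    return out


def replace_fields(data: DoseResponse) -> DoseResponse:
    return DoseResponse(
        doses=data.doses.copy(),
        responses=data.responses.copy(),
        dose_unit=data.dose_unit,
    )


@dataclass(frozen=True)
class DoseResponseShift:
    """IC50 ratio (a/b) and per-dose response differences between two fits."""

    ic50_ratio: float
    ic50_ratio_ci: tuple[float, float] | None
    dose_differences: dict  # dose -> (difference, ci or None)
    n_boot: int


def compare_dose_response(
    curve_a: DoseResponse,
    curve_b: DoseResponse,
    n_boot: int = 200,
    seed: int | None = None,
) -> DoseResponseShift:
    """Shift summary between two fitted dose–response curves.

    Reports the IC50 ratio a/b and, where the dose grids overlap, the
    per-dose fitted-response differences.  Confidence intervals come from
    residual-resampling bootstrap (percentile, 95%); ``n_boot=0`` gives
    point estimates only.
    """
    for name, c in (("curve_a", curve_a), ("curve_b", curve_b)):
        if not c.converged or c.params is None:
            raise ValidationError(f"{name} has no converged 4PL fit")
    ratio = curve_a.params.ic50 / curve_b.params.ic50
    common = np.intersect1d(curve_a.doses, curve_b.doses)
    diffs_point = {
        float(d): float(four_pl(d, curve_a.params) - four_pl(d, curve_b.params)) for d in common
    }

    if n_boot <= 0:
        return DoseResponseShift(
            ic50_ratio=float(ratio),
            ic50_ratio_ci=None,
            dose_differences={d: (v, None) for d, v in diffs_point.items()},
            n_boot=0,
        )

    rng = np.random.default_rng(seed)
    ratios = []
    diff_samples = {float(d): [] for d in common}
    resid_a = curve_a.responses - four_pl(curve_a.doses, curve_a.params)
    resid_b = curve_b.responses - four_pl(curve_b.doses, curve_b.params)
    for _ in range(n_boot):
        ra = four_pl(curve_a.doses, curve_a.params) + rng.choice(resid_a, resid_a.size)
        rb = four_pl(curve_b.doses, curve_b.params) + rng.choice(resid_b, resid_b.size)
        fa = fit_4pl(DoseResponse(curve_a.doses, ra, curve_a.dose_unit))
        fb = fit_4pl(DoseResponse(curve_b.doses, rb, curve_b.dose_unit))
        if not (fa.converged and fb.converged):
            continue
        ratios.append(fa.params.ic50 / fb.params.ic50)
        for d in common:
            diff_samples[float(d)].append(four_pl(d, fa.params) - four_pl(d, fb.params))
    ci = (
        tuple(np.quantile(ratios, [0.025, 0.975]).tolist()) if len(ratios) >= 20 else None
    )
    dose_diffs = {}
    for d, v in diffs_point.items():
        samples = diff_samples[d]
        dose_diffs[d] = (
            v,
            tuple(np.quantile(samples, [0.025, 0.975]).tolist()) if len(samples) >= 20 else None,
        )
    return DoseResponseShift(
        ic50_ratio=float(ratio),
        ic50_ratio_ci=ci,
        dose_differences=dose_diffs,
        n_boot=n_boot,
    )
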