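"""Quartile-restricted exhaustive cutoff scan for expression-biomarker
survival stratification.

The procedure: every distinct observed expression value falling within the
interquartile range [Q1, Q3] is a candidate cutoff; each candidate splits
the cohort into low (expression <= cutoff) and high strata; a
single-covariate Cox proportional-hazards model (or log-rank test) yields a
p-value per candidate; the whole candidate family is Benjamini–Hochberg
adjusted; the cutoff minimizing the FDR-adjusted value is selected, with
ties broken by the *highest* hazard ratio (then lowest raw p, then smallest
cutoff — fully deterministic).  Kaplan–Meier curves of the selected strata
are attached.

Scanning many cutoffs and taking the best is anti-conservative — the
minimum uncorrected p over a quartile-restricted scan rejects far more than
its nominal level under the null — which is exactly why the BH step is part
of the procedure; the test suite quantifies both rates.

Hazard-ratio orientation: the low-expression stratum is compared against
the high-expression reference, so HR > 1 means low expression is adverse.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import (
    KMCurve,
    ValidationError,
    bh_fdr,
    cox_fit,
    km_estimate,
    logrank_test,
)

__all__ = [
    "ScanConfig",
    "CutoffResult",
    "ScanOutcome",
    "EmptyScanError",
    "candidate_cutoffs",
    "scan",
    "subgroup_scan",
    "select_cutoff",
    "report",
    "write_report",
]

logger = logging.getLogger(__name__)


class EmptyScanError(ValidationError):
    """No candidate cutoff satisfies the quartile and group-size constraints."""


@dataclass(frozen=True)
class ScanConfig:
    """Configuration of one cutoff scan.

    ``lower_quantile``/``upper_quantile`` bound the candidate range
    (default: the interquartile range); quantiles use linear interpolation
    between order statistics — the convention matters because it shifts the
    candidate set, so it is echoed into every report.  ``min_group_size``
    drops candidates that would leave a degenerate tail stratum.
    ``p_source`` selects the per-cutoff test: Cox Wald (default) or
    log-rank.
    """

    lower_quantile: float = 0.25
    upper_quantile: float = 0.75
    min_group_size: int = 10
    p_source: str = "cox_wald"  # or "logrank"
    ties: str = "efron"
    fdr_alpha: float = 0.05
    quantile_convention: str = "linear"

    def validate(self) -> "ScanConfig":
        if not 0.0 <= self.lower_quantile < self.upper_quantile <= 1.0:
            raise ValidationError("require 0 <= lower_quantile < upper_quantile <= 1")
        if self.min_group_size < 1:
            raise ValidationError("min_group_size must be >= 1")
        if self.p_source not in ("cox_wald", "logrank"):
            raise ValidationError("p_source must be 'cox_wald' or 'logrank'")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class CutoffResult:
    """One row of the scan table."""

    cutoff: float
    n_low: int
    n_high: int
    hazard_ratio: float
    p_value: float
    fdr_q: float
    converged: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ScanOutcome:
    """Full scan table, the selected cutoff, and its stratified KM curves."""

    results: list  # CutoffResult, ordered by cutoff
    selected: CutoffResult
    selection_reason: str  # "unique_min_fdr" or "hr_tiebreak"
    km_low: KMCurve
    km_high: KMCurve
    subgroup: str = "all"
    endpoint: str = "os"
    config: ScanConfig = field(default_factory=ScanConfig)
    n: int = 0
    n_events: int = 0

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.results])


def candidate_cutoffs(expression, config: ScanConfig | None = None) -> np.ndarray:
    """Sorted unique observed values within [Q1, Q3] usable as cutoffs.

    A candidate ``v`` defines strata low = {expr <= v}, high = {expr > v};
    candidates leaving either stratum below ``min_group_size`` are removed.
    """
    config = (config or ScanConfig()).validate()
    expr = np.asarray(expression, dtype=float)
    if expr.size < 4:
        raise ValidationError("cutoff scan requires at least 4 samples")
    if np.any(~np.isfinite(expr)):
        raise ValidationError("expression values must be finite")
    q_lo, q_hi = np.quantile(
        expr, [config.lower_quantile, config.upper_quantile], method=config.quantile_convention
    )
    values = np.unique(expr)
    cands = values[(values >= q_lo) & (values <= q_hi)]
    n = expr.size
    keep = []
    for v in cands:
        n_low = int(np.count_nonzero(expr <= v))
        if n_low >= config.min_group_size and (n - n_low) >= config.min_group_size:
            keep.append(v)
    if not keep:
        raise EmptyScanError(
            "no candidate cutoff within the quantile range satisfies min_group_size"
        )
    return np.asarray(keep)


def select_cutoff(results: list) -> tuple[CutoffResult, str]:
    """Apply the selection rule to a scan table.

    Minimum FDR-adjusted value wins; among FDR ties the highest hazard
    ratio is prioritized; residual ties fall back to lowest raw p, then
    smallest cutoff.  Non-converged rows are excluded.
    """
    usable = [r for r in results if r.converged and np.isfinite(r.fdr_q)]
    if not usable:
        raise EmptyScanError("no converged cutoff available for selection")
    q_min = min(r.fdr_q for r in usable)
    tied = [r for r in usable if np.isclose(r.fdr_q, q_min, rtol=1e-12, atol=0.0)]
    if len(tied) == 1:
        return tied[0], "unique_min_fdr"
    best = max(tied, key=lambda r: (r.hazard_ratio, -r.p_value, -r.cutoff))
    return best, "hr_tiebreak"


def _split_p_and_hr(time, event, low_mask, config: ScanConfig):
    if config.p_source == "logrank":
        _, p = logrank_test(time, event, low_mask)
        fit = cox_fit(time, event, low_mask.astype(float), ties=config.ties)
        return p, fit.hazard_ratio, fit.converged
    fit = cox_fit(time, event, low_mask.astype(float), ties=config.ties)
    return fit.p_value, fit.hazard_ratio, fit.converged


def scan(
    cohort,
    config: ScanConfig | None = None,
    expr_field: str = "relative_expression",
    time_field: str = "os_months",
    event_field: str = "os_event",
    subgroup: str = "all",
) -> ScanOutcome:
    """Run the full cutoff scan on one cohort.

    ``cohort`` is a DataFrame or anything exposing a ``.table`` DataFrame.
    Returns the complete per-cutoff table (HR, p, BH-adjusted q), the
    selected cutoff with the reason for its selection, and KM curves of
    the selected low/high strata.
    """
    config = (config or ScanConfig()).validate()
    df = cohort.table if hasattr(cohort, "table") else cohort
    for col in (expr_field, time_field, event_field):
        if col not in df.columns:
            raise ValidationError(f"cohort lacks required column {col!r}")
    sub = df[[expr_field, time_field, event_field]].dropna()
    expr = sub[expr_field].to_numpy(dtype=float)
    time = sub[time_field].to_numpy(dtype=float)
    event = sub[event_field].to_numpy(dtype=bool)
    if int(event.sum()) < 2:
        raise ValidationError("cutoff scan requires at least 2 events")

    cands = candidate_cutoffs(expr, config)

    rows = []
    for v in cands:
        low = expr <= v
        try:
            p, hr, converged = _split_p_and_hr(time, event, low, config)
        except ValidationError:
            p, hr, converged = np.nan, np.nan, False
        if not converged:
            logger.warning("cutoff %.6g: non-converged fit excluded from selection", v)
        rows.append((float(v), int(low.sum()), int((~low).sum()), hr, p, converged))

    p_vec = np.array([r[4] for r in rows if r[5]])
    if p_vec.size == 0:
        raise EmptyScanError("every candidate cutoff failed to converge")
    q_vec = bh_fdr(p_vec)
    q_iter = iter(q_vec)
    results = [
        CutoffResult(
            cutoff=v,
            n_low=n_low,
            n_high=n_high,
            hazard_ratio=hr,
            p_value=p,
            fdr_q=float(next(q_iter)) if conv else float("nan"),
            converged=conv,
        )
        for (v, n_low, n_high, hr, p, conv) in rows
    ]
    selected, reason = select_cutoff(results)
    low = expr <= selected.cutoff
    return ScanOutcome(
        results=results,
        selected=selected,
        selection_reason=reason,
        km_low=km_estimate(time[low], event[low]),
        km_high=km_estimate(time[~low], event[~low]),
        subgroup=subgroup,
        endpoint=time_field.split("_")[0],
        config=config,
        n=int(expr.size),
        n_events=int(event.sum()),
    )


def subgroup_scan(
    cohort,
    subgroup_flags,
    config: ScanConfig | None = None,
    expr_field: str = "relative_expression",
    endpoint: str = "os",
    min_subgroup_size: int | None = None,
) -> list[ScanOutcome]:
    """Independent cutoff scans within each mutation-positive and -negative stratum.

    For each flag column (e.g. ``flt3_itd``, ``npm1``, ``cebpa``) the
    cohort is split by flag status and :func:`scan` runs separately in each
    stratum, on the requested endpoint (``"os"`` or ``"efs"``, mapped to
    ``<endpoint>_months`` / ``<endpoint>_event`` columns).  Undersized or
    unscannable strata are skipped with a logged warning, not raised.
    """
    config = (config or ScanConfig()).validate()
    df = cohort.table if hasattr(cohort, "table") else cohort
    time_field, event_field = f"{endpoint}_months", f"{endpoint}_event"
    min_n = min_subgroup_size if min_subgroup_size is not None else 4 * config.min_group_size
    outcomes = []
    for flag in subgroup_flags:
        if flag not in df.columns:
            raise ValidationError(f"subgroup flag {flag!r} not present in cohort")
        levels = sorted(pd.unique(df[flag].dropna()))
        for level in levels:
            stratum = df[df[flag] == level]
            label = f"{flag}{'+' if level in (1, True) else '-'}" if len(levels) > 1 else flag
            if len(stratum) < min_n:
                logger.warning(
                    "subgroup %s has %d samples (< %d); skipped", label, len(stratum), min_n
                )
                continue
            try:
                outcome = scan(
                    stratum,
                    config,
                    expr_field=expr_field,
                    time_field=time_field,
                    event_field=event_field,
                    subgroup=label,
                )
            except (EmptyScanError, ValidationError) as exc:
                logger.warning("subgroup %s not scannable: %s", label, exc)
                continue
            outcomes.append(outcome)
    return outcomes


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def report(outcomes, config: ScanConfig | None = None, seed: int | None = None) -> dict:
    """Machine-readable report over one or more scan outcomes.

    Contains the full scan tables, the selection and its reason, the KM
    curves and their median survivals per stratum, and the configuration
    (and seed, if the data were simulated) that produced everything.
    """
    outcomes = [outcomes] if isinstance(outcomes, ScanOutcome) else list(outcomes)
    if not outcomes:
        raise ValidationError("report requires at least one scan outcome")
    entries = []
    for o in outcomes:
        entries.append(
            {
                "subgroup": o.subgroup,
                "endpoint": o.endpoint,
                "n": o.n,
                "n_events": o.n_events,
                "scan_table": [r.to_dict() for r in o.results],
                "selected": o.selected.to_dict(),
                "selection_reason": o.selection_reason,
                "km_low": o.km_low.to_dict(),
                "km_high": o.km_high.to_dict(),
                "median_survival_low": o.km_low.median,
                "median_survival_high": o.km_high.median,
                "config": o.config.to_dict(),
            }
        )
    return {
        "outcomes": entries,
        "config": (config or outcomes[0].config).to_dict(),
        "seed": seed,
    }


def write_report(outcomes, outdir, config=None, seed=None, plots: bool = False) -> dict:
    """Write scan tables, selection JSON and KM exports into a directory.

    Produces ``scan_table.tsv``, ``selection.json``, ``km_low.tsv`` and
    ``km_high.tsv`` (per subgroup when several outcomes are given), plus
    optional SVG step plots.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rep = report(outcomes, config=config, seed=seed)
    outcomes = [outcomes] if isinstance(outcomes, ScanOutcome) else list(outcomes)
    for o in outcomes:
        prefix = "" if o.subgroup == "all" else f"{o.subgroup.replace('+', 'pos').replace('-', 'neg')}_"
        o.table().to_csv(outdir / f"{prefix}scan_table.tsv", sep="\t", index=False)
        o.km_low.to_frame().to_csv(outdir / f"{prefix}km_low.tsv", sep="\t", index=False)
        o.km_high.to_frame().to_csv(outdir / f"{prefix}km_high.tsv", sep="\t", index=False)
        if plots:
            _km_plot(o, outdir / f"{prefix}km.svg")
    (outdir / "selection.json").write_text(json.dumps(rep, indent=2, sort_keys=True) + "\n")
    return rep


def _km_plot(outcome: ScanOutcome, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for curve, label, color in (
        (outcome.km_low, f"low (n={curve_n(outcome.km_low)})", "tab:red"),
        (outcome.km_high, f"high (n={curve_n(outcome.km_high)})", "tab:blue"),
    ):
        t = np.concatenate([[0.0], curve.event_times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=label, color=color)
        if curve.censor_times.size:
            ax.plot(
                curve.censor_times,
                [curve.survival_at(ct) for ct in curve.censor_times],
                "|",
                color=color,
                markersize=6,
            )
    ax.set_xlabel(f"{outcome.endpoint.upper()} time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(
        title=f"cutoff {outcome.selected.cutoff:.3g}, HR {outcome.selected.hazard_ratio:.2f}"
    )
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def curve_n(curve: KMCurve) -> int:
    return curve.n_total
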