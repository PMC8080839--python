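"""Scoring indicator trends along a bifurcation sweep.

An indicator performs well when its oriented value rises monotonically as
the system approaches the transition.  Performance is the Kendall tau rank
correlation between the oriented indicator series and the sweep step index
(which increases toward the bifurcation), clipped at zero: an indicator
that trends the wrong way scores 0, a perfectly monotone rise scores 1.

For subset scenarios — where the analysis is repeated over every choice of
observed variables — the 5% and 95% quantiles of the raw taus are reported
as the worst and best case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EvaluationError, PreconditionError, UndefinedStatisticError
from .indicators import (
    INDICATOR_NAMES,
    IndicatorValue,
    compute_indicator,
    orientation,
)
from .simulate import SweepResult

__all__ = [
    "PerformanceEntry",
    "PerformanceTable",
    "kendall_tau",
    "oriented_values",
    "indicator_performance",
    "evaluate_sweep",
    "subset_performance",
    "build_performance_table",
    "specificity_null",
]


@dataclass(frozen=True)
class PerformanceEntry:
    """Clipped Kendall tau of one indicator in one scenario."""

    indicator: str
    tau: float
    raw_tau: float
    scenario: str = ""
    model_setting: str = ""
    quantile_tag: str = "point"  # point | worst_case_5pct | best_case_95pct
    n_replicates: int = 1
    tau_sd: float = 0.0
    undefined: bool = False


def kendall_tau(x, y) -> float:
    """Kendall tau-b (tie-corrected) rank correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PreconditionError("x and y must be equal-length vectors")
    if x.size < 2:
        raise PreconditionError("need at least 2 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("Kendall tau of an all-tied vector")
    return float(stats.kendalltau(x, y, variant="b").statistic)


def oriented_values(values: Sequence[IndicatorValue]) -> np.ndarray:
    """Indicator values with the declared orientation applied.

    Values of indicators that fall toward the transition are negated so
    that every well-performing indicator rises.
    """
    out = np.empty(len(values))
    for i, v in enumerate(values):
        sign = -1.0 if v.orientation == "decreases_toward_transition" else 1.0
        out[i] = sign * v.value
    return out


def indicator_performance(
    values: Sequence[IndicatorValue],
    max_failed_fraction: float = 0.1,
) -> PerformanceEntry:
    """Score one indicator's trend along a sweep.

    ``values`` holds the indicator at each sweep step, ordered toward the
    transition; entries may be ``None`` for steps where the indicator could
    not be computed (at most ``max_failed_fraction`` of them).  The raw tau
    is computed on the oriented values against the step index and clipped
    at zero for the reported performance.  A constant indicator has no
    trend: it scores 0 and is flagged ``undefined``.
    """
    if len(values) < 3:
        raise PreconditionError("need at least 3 sweep steps")
    ok = [i for i, v in enumerate(values) if v is not None and np.isfinite(v.value)]
    if len(ok) < len(values) * (1.0 - max_failed_fraction):
        raise EvaluationError(
            f"too many failed steps: {len(values) - len(ok)} of {len(values)}"
        )
    vals = [values[i] for i in ok]
    name = vals[0].name
    steps = np.asarray(ok, dtype=float)
    orient = oriented_values(vals)
    try:
        raw = kendall_tau(orient, steps)
    except UndefinedStatisticError:
        return PerformanceEntry(
            indicator=name, tau=0.0, raw_tau=0.0, undefined=True
        )
    return PerformanceEntry(indicator=name, tau=max(raw, 0.0), raw_tau=raw)


def evaluate_sweep(
    sweep: SweepResult,
    names: Iterable[str] | None = None,
    scenario: str = "",
    model_setting: str = "",
) -> tuple[pd.DataFrame, list[PerformanceEntry]]:
    """Compute indicators per step and score each one along the sweep.

    Returns ``(values, entries)``: a tidy DataFrame with one row per
    (step, indicator) and the per-indicator performance entries.
    """
    names = list(names or INDICATOR_NAMES)
    steps = sweep.valid_steps()
    if len(steps) < 3:
        raise EvaluationError("fewer than 3 valid sweep steps")
    rows = []
    per_indicator: dict[str, list] = {n: [] for n in names}
    for s in steps:
        for n in names:
            try:
                iv = compute_indicator(n, s.series)
            except Exception as exc:  # scored as a failed step
                warnings.warn(
                    f"{n} failed at step {s.step_index}: {exc}", stacklevel=2
                )
                iv = None
            per_indicator[n].append(iv)
            rows.append(
                {
                    "step": s.step_index,
                    "dominant_eigenvalue": s.stability.dominant_eigenvalue,
                    "indicator": n,
                    "value": np.nan if iv is None else iv.value,
                }
            )
    entries = [
        replace(
            indicator_performance(per_indicator[n]),
            scenario=scenario,
            model_setting=model_setting,
        )
        for n in names
    ]
    return pd.DataFrame(rows), entries


def subset_performance(
    entries: Sequence[PerformanceEntry],
    quantiles: tuple[float, float] = (0.05, 0.95),
) -> tuple[PerformanceEntry, PerformanceEntry]:
    """Worst-case and best-case performance over variable subsets.

    Takes the raw taus of one indicator across all observed subsets and
    returns their empirical ``quantiles`` (linear interpolation), clipped
    at zero, tagged ``worst_case_5pct`` / ``best_case_95pct``.
    """
    if not entries:
        raise PreconditionError("no subset entries")
    names = {e.indicator for e in entries}
    if len(names) != 1:
        raise PreconditionError("subset entries must belong to one indicator")
    raws = np.array([e.raw_tau for e in entries])
    if len(raws) < 20:
        warnings.warn(
            f"only {len(raws)} subset entries; 5%/95% quantiles are coarse",
            stacklevel=2,
        )
    lo, hi = np.quantile(raws, quantiles)
    base = entries[0]
    worst = replace(
        base,
        tau=max(float(lo), 0.0),
        raw_tau=float(lo),
        quantile_tag="worst_case_5pct",
        n_replicates=len(raws),
    )
    best = replace(
        base,
        tau=max(float(hi), 0.0),
        raw_tau=float(hi),
        quantile_tag="best_case_95pct",
        n_replicates=len(raws),
    )
    return worst, best


@dataclass(frozen=True)
class PerformanceTable:
    """Indicator x scenario grid of clipped Kendall taus."""

    data: pd.DataFrame  # tidy: model_setting, scenario, indicator, quantile_tag, ...

    def grid(self, model_setting: str | None = None) -> pd.DataFrame:
        """Pivot to an indicator x (scenario, quantile) matrix of taus."""
        df = self.data
        if model_setting is not None:
            df = df[df["model_setting"] == model_setting]
        return df.pivot_table(
            index="indicator",
            columns=["scenario", "quantile_tag"],
            values="tau",
            aggfunc="mean",
        ).reindex(list(INDICATOR_NAMES))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def build_performance_table(entries: Iterable[PerformanceEntry]) -> PerformanceTable:
    """Assemble entries into a tidy performance table.

    Replicate entries for the same (model setting, scenario, indicator,
    quantile tag) cell are aggregated by the mean, with the dispersion
    recorded; duplicate aggregation is intentional, but a cell must not mix
    quantile tags.
    """
    rows = [
        {
            "model_setting": e.model_setting,
            "scenario": e.scenario,
            "indicator": e.indicator,
            "quantile_tag": e.quantile_tag,
            "tau": e.tau,
            "raw_tau": e.raw_tau,
            "n_replicates": e.n_replicates,
        }
        for e in entries
    ]
    if not rows:
        return PerformanceTable(
            data=pd.DataFrame(
                columns=[
                    "model_setting",
                    "scenario",
                    "indicator",
                    "quantile_tag",
                    "tau",
                    "raw_tau",
                    "n_replicates",
                    "tau_sd",
                ]
            )
        )
    df = pd.DataFrame(rows)
    agg = (
        df.groupby(
            ["model_setting", "scenario", "indicator", "quantile_tag"],
            as_index=False,
        )
        .agg(
            tau=("tau", "mean"),
            raw_tau=("raw_tau", "mean"),
            tau_sd=("tau", "std"),
            n_replicates=("tau", "size"),
        )
        .fillna({"tau_sd": 0.0})
    )
    return PerformanceTable(data=agg)


def specificity_null(
    run_sweep,
    n_replicates: int = 10,
    names: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Raw-tau null distribution under a constant bifurcation parameter.

    ``run_sweep(replicate_index)`` must return a :class:`SweepResult` whose
    steps all share the same parameters (a "sweep" that goes nowhere); the
    steps are then exchangeable and any apparent trend is a false positive.
    Returns a tidy DataFrame (replicate, indicator, raw_tau).
    """
    names = list(names or INDICATOR_NAMES)
    rows = []
    for rep in range(n_replicates):
        sweep = run_sweep(rep)
        _, entries = evaluate_sweep(sweep, names=names)
        for e in entries:
            rows.append(
                {"replicate": rep, "indicator": e.indicator, "raw_tau": e.raw_tau}
            )
    return pd.DataFrame(rows)
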