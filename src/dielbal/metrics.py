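"""SAMPL-style evaluation statistics for log D predictions.

Error measures are computed on prediction-minus-experiment differences:
MSE (mean signed error, the systematic phase bias), AUE (mean absolute
error) and RMSE.  Trend quality is measured by the Pearson correlation and
the tie-corrected Kendall tau-b, plus the least-squares line of predicted
on experimental values.  Uncertainties on any metric come from case
bootstrap over solutes.

Zero-variance inputs (the null baseline is the canonical case) make the
correlations mathematically undefined; they raise UndefinedCorrelationError
rather than faking a value of 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PredictionEntry",
    "PredictionSet",
    "MetricReport",
    "UndefinedCorrelationError",
    "error_stats",
    "pearson_r",
    "kendall_tau",
    "bootstrap_metric",
    "error_profile",
    "dynamic_range",
    "evaluate",
    "METRIC_FUNCTIONS",
]

DEFAULT_N_BOOT = 10_000


class UndefinedCorrelationError(ValueError):
    """A correlation was requested on a zero-variance column."""


@dataclass(frozen=True)
class PredictionEntry:
    solute_id: str
    predicted: float
    experimental: float
    pred_uncertainty: float | None = None


@dataclass
class PredictionSet:
    """Paired predicted/experimental log D values for a set of solutes."""

    entries: list[PredictionEntry]

    def __post_init__(self) -> None:
        ids = [e.solute_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("solute_ids must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def predicted(self) -> np.ndarray:
        return np.array([e.predicted for e in self.entries])

    @property
    def experimental(self) -> np.ndarray:
        return np.array([e.experimental for e in self.entries])

    @property
    def solute_ids(self) -> list[str]:
        return [e.solute_id for e in self.entries]

    @classmethod
    def from_arrays(
        cls,
        solute_ids: Sequence[str],
        predicted: Sequence[float],
        experimental: Sequence[float],
        pred_uncertainty: Sequence[float] | None = None,
    ) -> "PredictionSet":
        unc = pred_uncertainty if pred_uncertainty is not None else [None] * len(solute_ids)
        return cls(
            [
                PredictionEntry(str(s), float(p), float(e), u if u is None else float(u))
                for s, p, e, u in zip(solute_ids, predicted, experimental, unc)
            ]
        )

    @classmethod
    def from_tsv(cls, source) -> "PredictionSet":
        df = pd.read_csv(source, sep="\t", comment="#")
        required = {"solute_id", "predicted", "experimental"}
        if not required <= set(df.columns):
            raise ValueError(f"prediction TSV needs columns {sorted(required)}")
        unc = df["uncertainty"].tolist() if "uncertainty" in df.columns else None
        return cls.from_arrays(
            df["solute_id"].astype(str), df["predicted"], df["experimental"], unc
        )

    def to_tsv(self, sink) -> None:
        pd.DataFrame(
            {
                "solute_id": self.solute_ids,
                "predicted": self.predicted,
                "experimental": self.experimental,
            }
        ).to_csv(sink, sep="\t", index=False)


@dataclass
class MetricReport:
    """The full evaluation of one PredictionSet.

    Correlation fields are ``None`` when undefined (zero variance).
    ``bootstrap`` maps metric name -> (mean, stddev) over resamples.
    """

    n: int
    mse: float
    aue: float
    rmse: float
    pearson_r: float | None
    kendall_tau: float | None
    ols_slope: float | None
    ols_intercept: float | None
    dynamic_range_pred: float
    dynamic_range_exp: float
    bootstrap: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "mse": self.mse,
            "aue": self.aue,
            "rmse": self.rmse,
            "pearson_r": self.pearson_r,
            "kendall_tau": self.kendall_tau,
            "ols_slope": self.ols_slope,
            "ols_intercept": self.ols_intercept,
            "dynamic_range_pred": self.dynamic_range_pred,
            "dynamic_range_exp": self.dynamic_range_exp,
            "bootstrap": {k: {"mean": m, "stddev": s} for k, (m, s) in self.bootstrap.items()},
        }
        return d


def _errors(pred: np.ndarray, exp: np.ndarray) -> np.ndarray:
    return np.asarray(pred, dtype=float) - np.asarray(exp, dtype=float)


def error_stats(ps: PredictionSet) -> tuple[float, float, float]:
    """(MSE, AUE, RMSE) of predicted minus experimental, in log D units."""
    if len(ps) < 1:
        raise ValueError("need at least one entry")
    e = _errors(ps.predicted, ps.experimental)
    return float(e.mean()), float(np.abs(e).mean()), float(np.sqrt((e**2).mean()))


def _check_variance(x: np.ndarray, label: str) -> None:
    if np.ptp(x) == 0:
        raise UndefinedCorrelationError(
            f"{label} values have zero variance; correlation is undefined"
        )


def pearson_r(ps: PredictionSet) -> float:
    """Sample Pearson correlation of predicted vs experimental."""
    if len(ps) < 2:
        raise ValueError("need at least two entries for a correlation")
    p, e = ps.predicted, ps.experimental
    _check_variance(p, "predicted")
    _check_variance(e, "experimental")
    return float(stats.pearsonr(p, e).statistic)


def kendall_tau(ps: PredictionSet) -> float:
    """Tie-corrected Kendall tau-b of predicted vs experimental ranks."""
    if len(ps) < 2:
        raise ValueError("need at least two entries for a correlation")
    p, e = ps.predicted, ps.experimental
    _check_variance(p, "predicted")
    _check_variance(e, "experimental")
    return float(stats.kendalltau(p, e, variant="b").statistic)


def _mse(p, e):
    return float(np.mean(p - e))


def _aue(p, e):
    return float(np.mean(np.abs(p - e)))


def _rmse(p, e):
    return float(np.sqrt(np.mean((p - e) ** 2)))


def _pearson(p, e):
    if np.ptp(p) == 0 or np.ptp(e) == 0:
        raise UndefinedCorrelationError("zero variance in resample")
    return float(stats.pearsonr(p, e).statistic)


def _kendall(p, e):
    if np.ptp(p) == 0 or np.ptp(e) == 0:
        raise UndefinedCorrelationError("zero variance in resample")
    return float(stats.kendalltau(p, e, variant="b").statistic)


METRIC_FUNCTIONS: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "mse": _mse,
    "aue": _aue,
    "rmse": _rmse,
    "pearson_r": _pearson,
    "kendall_tau": _kendall,
}


def bootstrap_metric(
    ps: PredictionSet,
    metric: str,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> tuple[float, float]:
    """Case-bootstrap (mean, stddev) of a metric over solute resamples.

    Solutes are resampled with replacement ``n_boot`` times; resamples on
    which the metric is undefined (a zero-variance draw for a correlation)
    are dropped.  Fully determined by ``seed``.
    """
    if metric not in METRIC_FUNCTIONS:
        raise ValueError(
            f"unknown metric '{metric}'; choose from {sorted(METRIC_FUNCTIONS)}"
        )
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    fn = METRIC_FUNCTIONS[metric]
    p, e = ps.predicted, ps.experimental
    n = len(ps)
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(fn(p[idx], e[idx]))
        except UndefinedCorrelationError:
            continue
    if len(values) < 2:
        raise UndefinedCorrelationError(
            f"metric '{metric}' undefined on essentially every resample"
        )
    arr = np.array(values)
    return float(arr.mean()), float(arr.std(ddof=1))


def error_profile(ps: PredictionSet) -> list[tuple[str, float, float]]:
    """(solute_id, experimental, signed error) sorted by experimental value.

    Ties in the experimental value are broken lexicographically by
    solute_id for reproducible ordering.
    """
    if len(ps) < 1:
        raise ValueError("need at least one entry")
    rows = [
        (e.solute_id, e.experimental, e.predicted - e.experimental)
        for e in ps.entries
    ]
    return sorted(rows, key=lambda r: (r[1], r[0]))


def dynamic_range(values: Sequence[float]) -> float:
    """max - min of a set of log D values."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    return float(v.max() - v.min())


def evaluate(
    ps: PredictionSet,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    bootstrap_metrics: Sequence[str] = ("mse", "aue", "rmse"),
) -> MetricReport:
    """Full metric report for a prediction set.

    The OLS line regresses predicted on experimental values; its slope is
    the trend-exaggeration diagnostic (slope > 1 means predictions span a
    wider range than experiment).
    """
    mse, aue, rmse = error_stats(ps)
    try:
        r = pearson_r(ps)
    except (UndefinedCorrelationError, ValueError):
        r = None
    try:
        tau = kendall_tau(ps)
    except (UndefinedCorrelationError, ValueError):
        tau = None
    exp = ps.experimental
    if len(ps) >= 2 and np.ptp(exp) > 0:
        slope, intercept = np.polyfit(exp, ps.predicted, 1)
        slope, intercept = float(slope), float(intercept)
    else:
        slope = intercept = None
    boot: dict[str, tuple[float, float]] = {}
    for name in bootstrap_metrics:
        try:
            boot[name] = bootstrap_metric(ps, name, n_boot=n_boot, seed=seed)
        except UndefinedCorrelationError:
            continue
    return MetricReport(
        n=len(ps),
        mse=mse,
        aue=aue,
        rmse=rmse,
        pearson_r=r,
        kendall_tau=tau,
        ols_slope=slope,
        ols_intercept=intercept,
        dynamic_range_pred=dynamic_range(ps.predicted),
        dynamic_range_exp=dynamic_range(exp),
        bootstrap=boot,
    )
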