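"""Thermodynamic-integration assembly of solvation free energies.

Solvation free energies are computed as the sum of two separated alchemical
legs: the uncharged solute is first grown in the solvent (nonpolar leg,
dG_np), then its charges are switched on (polar leg, dG_pol).  Each leg
supplies per-lambda-window samples of the Hamiltonian derivative dH/dlambda
(kJ/mol); the leg free energy is the composite-trapezoid integral of the
window means over lambda in [0, 1].

Window uncertainties come from block averaging (5 contiguous blocks by
default), which is robust to the serial correlation of MD time series, and
are propagated through the trapezoid weights in quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LambdaSchedule",
    "TIWindowData",
    "SolvationFreeEnergy",
    "NONPOLAR_LAMBDAS",
    "POLAR_LAMBDAS",
    "default_schedule",
    "window_mean",
    "trapezoid_weights",
    "integrate_ti",
    "solvation_free_energy",
    "read_ti_tsv",
    "write_ti_tsv",
]

# nonpolar (vdW growth) leg: dense near lambda = 0.5-1 where soft-core
# integrands curve most; polar (charging) leg: 6 even steps.
NONPOLAR_LAMBDAS: tuple[float, ...] = (
    0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.55, 0.6,
    0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 1.0,
)
POLAR_LAMBDAS: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

DEFAULT_N_BLOCKS = 5


@dataclass(frozen=True)
class LambdaSchedule:
    """A strictly increasing coupling-parameter grid spanning [0, 1]."""

    leg: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.leg not in ("nonpolar", "polar"):
            raise ValueError(f"unknown leg '{self.leg}'")
        v = self.values
        if len(v) < 2:
            raise ValueError("schedule needs at least 2 lambda points")
        if v[0] != 0.0 or v[-1] != 1.0:
            raise ValueError("schedule must start at 0.0 and end at 1.0")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("lambda values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)


def default_schedule(leg: str) -> LambdaSchedule:
    """The default lambda schedule for a leg.

    The nonpolar leg uses the 17-point grid, denser above lambda = 0.5;
    the polar leg uses 6 evenly spaced points (spacing 0.2).
    """
    if leg == "nonpolar":
        return LambdaSchedule("nonpolar", NONPOLAR_LAMBDAS)
    if leg == "polar":
        return LambdaSchedule("polar", POLAR_LAMBDAS)
    raise ValueError(f"unknown leg '{leg}' (expected 'nonpolar' or 'polar')")


@dataclass
class TIWindowData:
    """dH/dlambda data for one lambda window.

    Either raw ``samples`` (kJ/mol) or a precomputed ``(mean, stderr)``
    pair must be present.
    """

    lambda_value: float
    samples: np.ndarray | None = None
    mean: float | None = None
    stderr: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_value <= 1.0:
            raise ValueError("lambda_value must lie in [0, 1]")
        if self.samples is not None:
            self.samples = np.asarray(self.samples, dtype=float)
            if self.samples.size < 1:
                raise ValueError("samples must be non-empty")
        elif self.mean is None:
            raise ValueError("window needs samples or a (mean, stderr) pair")

    def summarize(
        self, n_blocks: int = DEFAULT_N_BLOCKS, equil_fraction: float = 0.0
    ) -> tuple[float, float]:
        """(mean, stderr) for this window, block-averaging raw samples."""
        if self.samples is None:
            return float(self.mean), float(self.stderr or 0.0)
        samples = self.samples
        if equil_fraction > 0.0:
            start = int(round(equil_fraction * samples.size))
            samples = samples[start:]
        if samples.size < n_blocks:
            return float(np.mean(samples)), 0.0
        return window_mean(samples, n_blocks)


@dataclass
class SolvationFreeEnergy:
    """Per-solute, per-solvent solvation free energy and its two legs."""

    solute_id: str
    solvent_id: str
    dG_np: float
    dG_pol: float
    uncertainty: float
    dG_solv: float = field(init=False)

    def __post_init__(self) -> None:
        self.dG_solv = self.dG_np + self.dG_pol


def window_mean(samples: Sequence[float], n_blocks: int = DEFAULT_N_BLOCKS) -> tuple[float, float]:
    """Mean and block-averaged standard error of a correlated sample series.

    The series is cut into ``n_blocks`` contiguous blocks; the stderr is the
    sample standard deviation of the block means over sqrt(n_blocks).
    """
    x = np.asarray(samples, dtype=float)
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if x.size < n_blocks:
        raise ValueError(f"need at least {n_blocks} samples, got {x.size}")
    block_means = np.array([b.mean() for b in np.array_split(x, n_blocks)])
    stderr = float(np.std(block_means, ddof=1) / np.sqrt(n_blocks))
    return float(x.mean()), stderr


def trapezoid_weights(lambdas: Sequence[float]) -> np.ndarray:
    """Composite-trapezoid quadrature weights for an uneven grid."""
    lam = np.asarray(lambdas, dtype=float)
    w = np.zeros_like(lam)
    d = np.diff(lam)
    w[:-1] += d / 2.0
    w[1:] += d / 2.0
    return w


def integrate_ti(
    schedule: LambdaSchedule,
    means: Sequence[float],
    stderrs: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Trapezoid-rule TI integral of mean dH/dlambda over the schedule.

    Returns (dG, uncertainty) in kJ/mol; the uncertainty propagates the
    per-window standard errors through the quadrature weights in quadrature.
    """
    m = np.asarray(means, dtype=float)
    if m.size != len(schedule):
        raise ValueError(
            f"{len(schedule)} schedule points but {m.size} window means"
        )
    w = trapezoid_weights(schedule.values)
    dG = float(w @ m)
    if stderrs is None:
        return dG, 0.0
    s = np.asarray(stderrs, dtype=float)
    if s.size != m.size:
        raise ValueError("stderrs length must match means")
    return dG, float(np.sqrt(np.sum((w * s) ** 2)))


def _leg_free_energy(
    windows: Iterable[TIWindowData],
    leg: str,
    n_blocks: int,
    equil_fraction: float,
) -> tuple[float, float]:
    wins = sorted(windows, key=lambda w: w.lambda_value)
    schedule = LambdaSchedule(leg, tuple(w.lambda_value for w in wins))
    stats = [w.summarize(n_blocks, equil_fraction) for w in wins]
    means = [m for m, _ in stats]
    errs = [e for _, e in stats]
    return integrate_ti(schedule, means, errs)


def solvation_free_energy(
    np_windows: Iterable[TIWindowData],
    pol_windows: Iterable[TIWindowData],
    solute_id: str,
    solvent_id: str,
    n_blocks: int = DEFAULT_N_BLOCKS,
    equil_fraction: float = 0.0,
) -> SolvationFreeEnergy:
    """Total solvation free energy from the two alchemical legs.

    dG_solv = dG_np + dG_pol; the leg uncertainties add in quadrature.
    ``equil_fraction`` discards a leading fraction of each window's samples
    (default 0: inputs are assumed post-equilibration).
    """
    dG_np, u_np = _leg_free_energy(np_windows, "nonpolar", n_blocks, equil_fraction)
    dG_pol, u_pol = _leg_free_energy(pol_windows, "polar", n_blocks, equil_fraction)
    return SolvationFreeEnergy(
        solute_id=solute_id,
        solvent_id=solvent_id,
        dG_np=dG_np,
        dG_pol=dG_pol,
        uncertainty=float(np.hypot(u_np, u_pol)),
    )


def read_ti_tsv(source) -> list[TIWindowData]:
    """Read per-window dH/dlambda data from TSV.

    Long form has columns ``lambda, sample`` (one row per sample); summary
    form has ``lambda, mean, stderr``.
    """
    df = pd.read_csv(source, sep="\t", comment="#")
    if "lambda" not in df.columns:
        raise ValueError("TI TSV needs a 'lambda' column")
    if "sample" in df.columns:
        return [
            TIWindowData(lambda_value=float(lam), samples=grp["sample"].to_numpy())
            for lam, grp in df.groupby("lambda", sort=True)
        ]
    if {"mean", "stderr"} <= set(df.columns):
        return [
            TIWindowData(
                lambda_value=float(r["lambda"]),
                mean=float(r["mean"]),
                stderr=float(r["stderr"]),
            )
            for _, r in df.sort_values("lambda").iterrows()
        ]
    raise ValueError("TI TSV needs 'sample' or 'mean'+'stderr' columns")


def write_ti_tsv(windows: Iterable[TIWindowData], sink) -> None:
    """Write windows in the long TSV form (``lambda, sample``)."""
    rows = []
    for w in windows:
        if w.samples is None:
            rows.append({"lambda": w.lambda_value, "mean": w.mean, "stderr": w.stderr or 0.0})
        else:
            rows.extend({"lambda": w.lambda_value, "sample": s} for s in w.samples)
    pd.DataFrame(rows).to_csv(sink, sep="\t", index=False)
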