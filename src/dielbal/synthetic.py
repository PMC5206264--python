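"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its seed and produces the same file
formats the consuming modules read, so the whole workflow is exercisable
without any simulation engine or external download:

* toy molecule topologies with controlled net charge;
* per-window dH/dlambda samples from a known polynomial integrand, whose
  exact integral is returned alongside;
* prediction sets with controlled slope, bias and noise against
  experimental values drawn uniformly from the log D range [-4, 3] the
  blind-challenge measurements spanned;
* Gaussian total-dipole series whose variance is inverted from the
  fluctuation formula so the dielectric estimator recovers a chosen eps(0)
  in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dielectric import FLUCTUATION_PREFACTOR, DipoleSeries
from .metrics import PredictionSet
from .ti import LambdaSchedule, TIWindowData
from .topology import AtomRecord, MoleculeTopology

__all__ = [
    "TIProfileSpec",
    "PredictionSetSpec",
    "gen_topology",
    "gen_ti_windows",
    "gen_prediction_set",
    "gen_dipole_series",
]


@dataclass(frozen=True)
class TIProfileSpec:
    """A polynomial ground-truth dH/dlambda profile for one alchemical leg.

    ``coefficients`` are (c0, c1, ...) of sum_i c_i * lambda^i in kJ/mol;
    the exact leg free energy is sum_i c_i / (i + 1).
    """

    coefficients: tuple[float, ...]
    noise_sigma: float = 0.0
    samples_per_window: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_window < 1:
            raise ValueError("samples_per_window must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def value(self, lam: float) -> float:
        return float(sum(c * lam**i for i, c in enumerate(self.coefficients)))

    @property
    def true_integral(self) -> float:
        return float(sum(c / (i + 1) for i, c in enumerate(self.coefficients)))


@dataclass(frozen=True)
class PredictionSetSpec:
    """Controlled error structure for a synthetic prediction set.

    Experimental values are uniform on [exp_low, exp_high]; predictions are
    ``bias + slope * experimental + N(0, noise_sigma)``.  slope > 1 mimics
    the exaggerated dynamic range of over-polarized transfer predictions,
    bias > 0 a systematic preference for the nonpolar phase.
    """

    n_solutes: int = 53
    exp_low: float = -4.0
    exp_high: float = 3.0
    slope: float = 1.0
    bias: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_solutes < 2:
            raise ValueError("n_solutes must be >= 2")
        if self.exp_high <= self.exp_low:
            raise ValueError("exp_high must exceed exp_low")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


_MASSES = (1.008, 12.011, 14.007, 15.999)


def gen_topology(n_atoms: int, net_charge: float = 0.0, seed: int = 0) -> MoleculeTopology:
    """A random toy molecule with an exactly prescribed net charge.

    Charges are drawn uniformly then shifted so their sum equals
    ``net_charge`` to machine precision; sigma in [0.05, 0.4] nm, epsilon
    in [0.1, 1.0] kJ/mol.  Each atom gets its own atom type so per-atom
    sigma modulation round-trips through file I/O.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    charges = rng.uniform(-0.8, 0.8, size=n_atoms)
    charges += (net_charge - charges.sum()) / n_atoms
    sigmas = rng.uniform(0.05, 0.4, size=n_atoms)
    epsilons = rng.uniform(0.1, 1.0, size=n_atoms)
    masses = rng.choice(_MASSES, size=n_atoms)
    atoms = [
        AtomRecord(
            index=i + 1,
            type_name=f"at{i + 1}",
            residue="MOL",
            atom_name=f"X{i + 1}",
            charge=round(float(charges[i]), 6),
            sigma=float(sigmas[i]),
            epsilon=float(epsilons[i]),
            mass=float(masses[i]),
            cgnr=i + 1,
        )
        for i in range(n_atoms)
    ]
    # rounding charges to write precision perturbs the sum; absorb on atom 1
    drift = net_charge - sum(a.charge for a in atoms)
    atoms[0].charge += drift
    return MoleculeTopology(name=f"SYN{seed}", atoms=atoms)


def gen_ti_windows(
    spec: TIProfileSpec, schedule: LambdaSchedule
) -> tuple[list[TIWindowData], float]:
    """Per-window noisy samples of the polynomial integrand plus exact dG."""
    rng = np.random.default_rng(spec.seed)
    windows = []
    for lam in schedule.values:
        true = spec.value(lam)
        samples = true + rng.normal(0.0, spec.noise_sigma, size=spec.samples_per_window)
        windows.append(TIWindowData(lambda_value=lam, samples=samples))
    return windows, spec.true_integral


def gen_prediction_set(spec: PredictionSetSpec) -> PredictionSet:
    """A prediction set with known slope/bias/noise error structure."""
    rng = np.random.default_rng(spec.seed)
    exp = rng.uniform(spec.exp_low, spec.exp_high, size=spec.n_solutes)
    pred = spec.bias + spec.slope * exp + rng.normal(0.0, spec.noise_sigma, size=spec.n_solutes)
    ids = [f"S{i:03d}" for i in range(spec.n_solutes)]
    return PredictionSet.from_arrays(ids, pred, exp)


def gen_dipole_series(
    target_epsilon: float,
    volume: float = 30.0,
    temperature: float = 298.15,
    n_frames: int = 10_000,
    seed: int = 0,
) -> DipoleSeries:
    """Isotropic Gaussian dipole series whose expected eps(0) is the target.

    The per-axis variance is the fluctuation formula inverted:
    (target - 1) * V * T / (3 * prefactor), in (e*nm)^2.  target = 1 gives
    a fluctuation-free (all-zero) series.
    """
    if target_epsilon < 1.0:
        raise ValueError("target_epsilon must be >= 1")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    axis_var = (target_epsilon - 1.0) * volume * temperature / (3.0 * FLUCTUATION_PREFACTOR)
    dipoles = rng.normal(0.0, np.sqrt(axis_var), size=(n_frames, 3))
    return DipoleSeries(dipoles=dipoles, volume=volume, temperature=temperature)
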