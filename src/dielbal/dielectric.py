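"""Static dielectric constants, vaporization enthalpies, solvent registry.

"Dielectric balance" means running the transfer calculation in solvent
models whose static dielectric constants eps(0) match experiment: 78.4 for
water and 2.0 for cyclohexane.  Plain TIP3P (eps(0) ~ 98) and a fully
nonpolar united-atom cyclohexane (eps(0) = 1) miss those targets on
opposite sides, which biases partitioning toward the nonpolar phase.  The
dielectric-corrected models H2O-DC and CYH-DC are tuned to the targets.

eps(0) is estimated from equilibrium total-dipole fluctuations with the
conducting-boundary (tin-foil) formula, the variant consistent with Ewald
electrostatics:

    eps = 1 + (<M.M> - <M>.<M>) / (3 eps0 V kB T)

Dipoles are handled in e*nm, volumes in nm^3 and temperatures in K; the
unit conversions are centralized below (1 e*nm = 48.0321 Debye).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import constants

__all__ = [
    "DipoleSeries",
    "SolventModel",
    "E_NM_TO_CM",
    "E_NM_TO_DEBYE",
    "FLUCTUATION_PREFACTOR",
    "AQUEOUS_TARGET_EPSILON",
    "NONPOLAR_TARGET_EPSILON",
    "epsilon_from_dipoles",
    "hvap_from_energies",
    "solvent_registry",
    "get_solvent",
    "balance_check",
    "read_dipole_tsv",
    "write_dipole_tsv",
]

# unit conversions, from CODATA constants
E_NM_TO_CM = constants.e * 1e-9                    # C*m per e*nm
E_NM_TO_DEBYE = E_NM_TO_CM / (1e-21 / constants.c)  # ~48.0321 D per e*nm

# (eps - 1) = FLUCTUATION_PREFACTOR * Var(M)[e^2 nm^2] / (V[nm^3] * T[K])
FLUCTUATION_PREFACTOR = E_NM_TO_CM**2 / (
    3.0 * constants.epsilon_0 * 1e-27 * constants.k
)

AQUEOUS_TARGET_EPSILON = 78.4   # experimental water eps(0)
NONPOLAR_TARGET_EPSILON = 2.0   # experimental cyclohexane eps(0)

GAS_CONSTANT_KJ = 1e-3 * constants.R  # kJ/(mol K)


@dataclass
class DipoleSeries:
    """Total-dipole time series of a simulation box.

    dipoles: (n_frames, 3) array in e*nm; volume in nm^3; temperature in K.
    """

    dipoles: np.ndarray
    volume: float
    temperature: float

    def __post_init__(self) -> None:
        self.dipoles = np.asarray(self.dipoles, dtype=float)
        if self.dipoles.ndim != 2 or self.dipoles.shape[1] != 3:
            raise ValueError("dipoles must be an (n_frames, 3) array")
        if self.dipoles.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if self.volume <= 0:
            raise ValueError("volume must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass(frozen=True)
class SolventModel:
    """A solvent force-field model and its dielectric bookkeeping.

    epsilon_model is the known eps(0) of the model as parametrized;
    epsilon_target is the experimental value a dielectric-corrected model
    aims for.  At least one must be present.
    """

    name: str
    kind: str  # "aqueous" or "nonpolar"
    epsilon_model: float | None = None
    epsilon_target: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("aqueous", "nonpolar"):
            raise ValueError(f"unknown solvent kind '{self.kind}'")
        if self.epsilon_model is None and self.epsilon_target is None:
            raise ValueError("need epsilon_model or epsilon_target")

    @property
    def effective_epsilon(self) -> float:
        """The eps(0) this model actually presents to a solute."""
        return self.epsilon_model if self.epsilon_model is not None else self.epsilon_target


def epsilon_from_dipoles(ds: DipoleSeries) -> float:
    """Static dielectric constant from total-dipole fluctuations.

    Conducting-boundary formula; returns exactly 1 for a fluctuation-free
    series, and is always >= 1 since the dipole variance is non-negative.
    """
    var_total = float(np.sum(ds.dipoles.var(axis=0)))  # <M.M> - <M>.<M>
    return 1.0 + FLUCTUATION_PREFACTOR * var_total / (ds.volume * ds.temperature)


def hvap_from_energies(u_liq_per_mol: float, u_gas: float, temperature: float) -> float:
    """Molar enthalpy of vaporization, kJ/mol.

    dHvap = U_gas - U_liq + R*T, treating the vapor as ideal (pV = RT per
    mole) and neglecting the liquid pV term.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    return u_gas - u_liq_per_mol + GAS_CONSTANT_KJ * temperature


_REGISTRY: dict[str, SolventModel] = {
    m.name: m
    for m in (
        SolventModel("TIP3P", "aqueous", epsilon_model=98.0),
        SolventModel("H2O-DC", "aqueous", epsilon_target=AQUEOUS_TARGET_EPSILON),
        SolventModel("CYH", "nonpolar", epsilon_model=1.0),
        SolventModel("CYH-DC", "nonpolar", epsilon_target=NONPOLAR_TARGET_EPSILON),
    )
}


def solvent_registry() -> list[SolventModel]:
    """The built-in solvent models and their eps(0) values."""
    return list(_REGISTRY.values())


def get_solvent(name: str) -> SolventModel:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown solvent '{name}'; known: {sorted(_REGISTRY)}"
        ) from None


def balance_check(
    water: SolventModel | str,
    organic: SolventModel | str,
    tolerance: float = 0.10,
) -> tuple[bool, dict]:
    """Is a solvent pair dielectrically balanced with experiment?

    Each model's effective eps(0) is compared to the experimental target of
    its kind (78.4 aqueous, 2.0 cyclohexane); the pair is balanced iff both
    fractional deviations are within ``tolerance``.  The report lists the
    per-solvent deviations.
    """
    if isinstance(water, str):
        water = get_solvent(water)
    if isinstance(organic, str):
        organic = get_solvent(organic)
    if water.kind != "aqueous":
        raise ValueError(f"'{water.name}' is not an aqueous model")
    if organic.kind != "nonpolar":
        raise ValueError(f"'{organic.name}' is not a nonpolar model")
    report: dict = {"tolerance": tolerance, "solvents": {}}
    balanced = True
    targets = {
        water.name: (water.effective_epsilon, AQUEOUS_TARGET_EPSILON),
        organic.name: (organic.effective_epsilon, NONPOLAR_TARGET_EPSILON),
    }
    for name, (eff, target) in targets.items():
        deviation = abs(eff - target) / target
        ok = deviation <= tolerance
        balanced &= ok
        report["solvents"][name] = {
            "effective_epsilon": eff,
            "target_epsilon": target,
            "fractional_deviation": deviation,
            "within_tolerance": ok,
        }
    report["balanced"] = balanced
    return balanced, report


def read_dipole_tsv(source) -> DipoleSeries:
    """Read a dipole series TSV: columns frame, Mx, My, Mz (e*nm), with
    header comment lines ``# volume_nm3=...`` and ``# temperature_K=...``."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    volume = temperature = None
    data_lines = []
    for line in text.splitlines():
        s = line.strip()
        if s.startswith("#"):
            body = s.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key = key.strip()
                if key == "volume_nm3":
                    volume = float(val)
                elif key == "temperature_K":
                    temperature = float(val)
        elif s:
            data_lines.append(line)
    if volume is None or temperature is None:
        raise ValueError(
            "dipole TSV needs '# volume_nm3=' and '# temperature_K=' headers"
        )
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(data_lines)), sep="\t")
    required = {"Mx", "My", "Mz"}
    if not required <= set(df.columns):
        raise ValueError("dipole TSV needs columns Mx, My, Mz")
    return DipoleSeries(
        dipoles=df[["Mx", "My", "Mz"]].to_numpy(),
        volume=volume,
        temperature=temperature,
    )


def write_dipole_tsv(ds: DipoleSeries, sink) -> None:
    close = False
    if not hasattr(sink, "write"):
        sink = open(sink, "w")
        close = True
    try:
        sink.write(f"# volume_nm3={ds.volume!r}\n")
        sink.write(f"# temperature_K={ds.temperature!r}\n")
        df = pd.DataFrame(ds.dipoles, columns=["Mx", "My", "Mz"])
        df.insert(0, "frame", np.arange(len(df)))
        df.to_csv(sink, sep="\t", index=False)
    finally:
        if close:
            sink.close()
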