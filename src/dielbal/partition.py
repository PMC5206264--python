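"""Water-to-cyclohexane partition coefficients from solvation free energies.

The transfer relation is

    log P = (dG_wat - dG_cyh) / (2.303 * R * T)

with the gas constant R = 8.31446e-3 kJ/(mol K) and T in kelvin.  The sign
convention is the SAMPL5 cyclohexane-over-water one: a solute whose
hydration is more favorable than its cyclohexane solvation (dG_wat more
negative) gets a negative log P, i.e. it prefers the aqueous phase.

log P of the single neutral species is used directly as the log D estimate;
no tautomer, protonation or aggregation corrections are applied.

The denominator constant is the conventional literal 2.303; pass
``exact_ln10=True`` to use ln 10 = 2.302585... instead (a 0.02 % change).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .ti import SolvationFreeEnergy

__all__ = [
    "GAS_CONSTANT_KJ",
    "LOG10_CONVENTIONAL",
    "TransferRecord",
    "log_partition",
    "transfer_record",
    "from_solvation",
    "scale_solvation",
    "null_baseline",
    "read_dg_tsv",
    "write_logp_tsv",
]

GAS_CONSTANT_KJ = 8.31446e-3  # kJ/(mol K)
LOG10_CONVENTIONAL = 2.303    # literal constant of the transfer relation
DEFAULT_TEMPERATURE = 298.15  # K


def _log10_factor(exact_ln10: bool) -> float:
    return math.log(10.0) if exact_ln10 else LOG10_CONVENTIONAL


@dataclass(frozen=True)
class TransferRecord:
    """One solute's water/cyclohexane free-energy pair and derived log P.

    ``uncertainty`` is 1 sigma in log units, from the quadrature-combined
    leg uncertainties of both solvents.
    """

    solute_id: str
    dG_wat: float
    dG_cyh: float
    logP: float
    uncertainty: float = 0.0
    temperature: float = DEFAULT_TEMPERATURE


def log_partition(
    dG_wat: float,
    dG_cyh: float,
    temperature: float = DEFAULT_TEMPERATURE,
    exact_ln10: bool = False,
) -> float:
    """log P from the two air-to-solvent transfer free energies (kJ/mol)."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    return (dG_wat - dG_cyh) / (_log10_factor(exact_ln10) * GAS_CONSTANT_KJ * temperature)


def transfer_record(
    solute_id: str,
    dG_wat: float,
    dG_cyh: float,
    dG_wat_uncertainty: float = 0.0,
    dG_cyh_uncertainty: float = 0.0,
    temperature: float = DEFAULT_TEMPERATURE,
    exact_ln10: bool = False,
) -> TransferRecord:
    """Build a TransferRecord, propagating both solvents' uncertainties."""
    logP = log_partition(dG_wat, dG_cyh, temperature, exact_ln10)
    denom = _log10_factor(exact_ln10) * GAS_CONSTANT_KJ * temperature
    unc = math.hypot(dG_wat_uncertainty, dG_cyh_uncertainty) / denom
    return TransferRecord(
        solute_id=solute_id,
        dG_wat=dG_wat,
        dG_cyh=dG_cyh,
        logP=logP,
        uncertainty=unc,
        temperature=temperature,
    )


def from_solvation(
    wat: SolvationFreeEnergy,
    cyh: SolvationFreeEnergy,
    temperature: float = DEFAULT_TEMPERATURE,
    exact_ln10: bool = False,
) -> TransferRecord:
    """TransferRecord from the two solvents' assembled solvation free energies."""
    if wat.solute_id != cyh.solute_id:
        raise ValueError(
            f"solute mismatch: '{wat.solute_id}' vs '{cyh.solute_id}'"
        )
    return transfer_record(
        wat.solute_id,
        wat.dG_solv,
        cyh.dG_solv,
        wat.uncertainty,
        cyh.uncertainty,
        temperature,
        exact_ln10,
    )


def scale_solvation(records: Sequence[TransferRecord], s: float) -> list[TransferRecord]:
    """Scale both solvents' free-energy magnitudes by ``s`` ("say less").

    Because log P is linear in the free energies, the scaled log P is
    exactly ``s`` times the original.  ``s = 0.5`` is the retrospective
    50 %-scaling transform; ``s = 0`` degenerates to the null baseline.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("scale factor must lie in [0, 1]")
    return [
        replace(
            r,
            dG_wat=s * r.dG_wat,
            dG_cyh=s * r.dG_cyh,
            logP=s * r.logP,
            uncertainty=s * r.uncertainty,
        )
        for r in records
    ]


def null_baseline(solute_ids: Iterable[str]) -> list[tuple[str, float]]:
    """The no-knowledge baseline: log D = 0 (equal phase preference) for all."""
    return [(sid, 0.0) for sid in solute_ids]


def read_dg_tsv(source) -> list[tuple[str, float, float, float, float]]:
    """Read a free-energy table: solute_id, dG_wat_kJmol, dG_cyh_kJmol
    and optional uncertainty columns dG_wat_unc, dG_cyh_unc."""
    df = pd.read_csv(source, sep="\t", comment="#")
    required = {"solute_id", "dG_wat_kJmol", "dG_cyh_kJmol"}
    if not required <= set(df.columns):
        raise ValueError(f"free-energy TSV needs columns {sorted(required)}")
    out = []
    for _, r in df.iterrows():
        out.append(
            (
                str(r["solute_id"]),
                float(r["dG_wat_kJmol"]),
                float(r["dG_cyh_kJmol"]),
                float(r.get("dG_wat_unc", 0.0) or 0.0),
                float(r.get("dG_cyh_unc", 0.0) or 0.0),
            )
        )
    return out


def write_logp_tsv(records: Sequence[TransferRecord], sink) -> None:
    pd.DataFrame(
        {
            "solute_id": [r.solute_id for r in records],
            "logP": [r.logP for r in records],
            "uncertainty": [r.uncertainty for r in records],
        }
    ).to_csv(sink, sep="\t", index=False)
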