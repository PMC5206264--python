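"""Reading and writing of the GROMACS-dialect topology subset used here.

Only the ``[atomtypes]``, ``[moleculetype]`` and ``[atoms]`` sections are
interpreted; every other section (bonds, angles, dihedrals, pairs, ...) is
carried through verbatim so that charge/sigma modulation can never disturb
the bonded part of a force field.  Units follow the GROMACS convention:
charges in elementary-charge units, Lennard-Jones sigma in nm and epsilon
in kJ/mol, masses in amu.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from typing import TextIO

__all__ = [
    "AtomRecord",
    "MoleculeTopology",
    "TopologyError",
    "TopologyFormatError",
    "TopologyParseError",
    "TopologyReferenceError",
    "read_topology",
    "write_topology",
    "net_charge",
]

CHARGE_DECIMALS = 6  # decimals written for charges; round-trip tolerance 1e-6
SIGMA_SIGFIGS = 7    # significant figures for sigma/epsilon on write


class TopologyError(Exception):
    """Base class for topology I/O errors."""


class TopologyFormatError(TopologyError):
    """The file is structurally not a usable topology (e.g. no [atoms])."""


class TopologyParseError(TopologyError):
    """A line could not be parsed; the message cites the line number."""


class TopologyReferenceError(TopologyError):
    """An atom references a type with no sigma/epsilon definition."""


@dataclass
class AtomRecord:
    """One line of the ``[atoms]`` section plus the resolved LJ parameters.

    ``charge_orig`` holds the pre-modulation charge once charges have been
    scaled; it is ``None`` for an unmodified topology.
    """

    index: int
    type_name: str
    residue: str
    atom_name: str
    charge: float
    sigma: float
    epsilon: float
    mass: float
    resnr: int = 1
    cgnr: int | None = None
    charge_orig: float | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"atom {self.index}: sigma must be >= 0")
        if self.epsilon < 0:
            raise ValueError(f"atom {self.index}: epsilon must be >= 0")
        if self.mass <= 0:
            raise ValueError(f"atom {self.index}: mass must be > 0")


@dataclass
class MoleculeTopology:
    """A single molecule's force-field description.

    ``passthrough_blocks`` are the verbatim texts (header line included) of
    every section this package does not interpret; they are emitted
    byte-identically on write.  ``provenance`` lines are written as comments
    at the top of the file and record any modulation applied.
    """

    name: str
    atoms: list[AtomRecord]
    passthrough_blocks: list[str] = field(default_factory=list)
    nrexcl: int = 3
    provenance: list[str] = field(default_factory=list)

    @property
    def net_charge(self) -> float:
        return sum(a.charge for a in self.atoms)

    def copy(self) -> "MoleculeTopology":
        return MoleculeTopology(
            name=self.name,
            atoms=[replace(a) for a in self.atoms],
            passthrough_blocks=list(self.passthrough_blocks),
            nrexcl=self.nrexcl,
            provenance=list(self.provenance),
        )

    def validate(self) -> None:
        indices = [a.index for a in self.atoms]
        if len(set(indices)) != len(indices):
            raise TopologyFormatError("duplicate atom indices")


_SECTION_RE = re.compile(r"^\s*\[\s*([A-Za-z0-9_-]+)\s*\]\s*$")


def _split_sections(text: str) -> list[tuple[str | None, str]]:
    """Split file text into (section_name, verbatim_text) chunks.

    Text before the first section header gets section name ``None``.
    """
    chunks: list[tuple[str | None, str]] = []
    current_name: str | None = None
    current_lines: list[str] = []
    for line in text.splitlines(keepends=True):
        m = _SECTION_RE.match(line)
        if m:
            if current_lines or current_name is not None:
                chunks.append((current_name, "".join(current_lines)))
            current_name = m.group(1).lower()
            current_lines = [line]
        else:
            current_lines.append(line)
    if current_lines or current_name is not None:
        chunks.append((current_name, "".join(current_lines)))
    return chunks


def _strip_comment(line: str) -> str:
    return line.split(";", 1)[0].strip()


def _parse_atomtypes(text: str, base_line: int) -> dict[str, tuple[float, float, float]]:
    """Parse an [atomtypes] body into name -> (mass, sigma, epsilon).

    Accepts the common 6- and 7-column layouts
    (``name [at.num] mass charge ptype sigma epsilon``); the last two
    columns are always sigma and epsilon.
    """
    table: dict[str, tuple[float, float, float]] = {}
    for offset, raw in enumerate(text.splitlines()):
        lineno = base_line + offset
        body = _strip_comment(raw)
        if not body or body.startswith("["):
            continue
        tok = body.split()
        if len(tok) < 6:
            raise TopologyParseError(
                f"line {lineno}: atomtype needs >= 6 fields, got {len(tok)}"
            )
        try:
            sigma = float(tok[-2])
            epsilon = float(tok[-1])
            mass = float(tok[-5])
        except ValueError as exc:
            raise TopologyParseError(f"line {lineno}: {exc}") from None
        table[tok[0]] = (mass, sigma, epsilon)
    return table


def _parse_atoms(
    text: str,
    base_line: int,
    types: dict[str, tuple[float, float, float]],
) -> list[AtomRecord]:
    atoms: list[AtomRecord] = []
    for offset, raw in enumerate(text.splitlines()):
        lineno = base_line + offset
        body = _strip_comment(raw)
        if not body or body.startswith("["):
            continue
        tok = body.split()
        if len(tok) < 7:
            raise TopologyParseError(
                f"line {lineno}: atom line needs >= 7 fields "
                "(nr type resnr residue atom cgnr charge [mass])"
            )
        try:
            index = int(tok[0])
            resnr = int(tok[2])
            cgnr = int(tok[5])
            charge = float(tok[6])
            mass = float(tok[7]) if len(tok) > 7 else None
        except ValueError as exc:
            raise TopologyParseError(f"line {lineno}: {exc}") from None
        type_name = tok[1]
        if type_name not in types:
            raise TopologyReferenceError(
                f"line {lineno}: atom type '{type_name}' has no "
                "[atomtypes] entry or parameter-table entry"
            )
        t_mass, sigma, epsilon = types[type_name]
        atoms.append(
            AtomRecord(
                index=index,
                type_name=type_name,
                residue=tok[3],
                atom_name=tok[4],
                charge=charge,
                sigma=sigma,
                epsilon=epsilon,
                mass=mass if mass is not None else t_mass,
                resnr=resnr,
                cgnr=cgnr,
            )
        )
    return atoms


def read_topology(
    source: TextIO | str,
    atomtypes: TextIO | str | dict[str, tuple[float, float, float]] | None = None,
) -> MoleculeTopology:
    """Read a GROMACS-dialect ``.itp``/``.top`` stream into a MoleculeTopology.

    Parameters
    ----------
    source
        Text stream or string with at least one ``[atoms]`` section.
    atomtypes
        Optional second source of LJ parameters: another stream/string
        containing an ``[atomtypes]`` section, or a ready-made mapping
        ``type_name -> (mass, sigma_nm, epsilon_kJmol)``.  GAFF-style
        topologies commonly keep atom types in a separate file.
    """
    text = source if isinstance(source, str) else source.read()

    types: dict[str, tuple[float, float, float]] = {}
    if atomtypes is not None:
        if isinstance(atomtypes, dict):
            types.update(atomtypes)
        else:
            at_text = atomtypes if isinstance(atomtypes, str) else atomtypes.read()
            for name, chunk in _split_sections(at_text):
                if name == "atomtypes":
                    types.update(_parse_atomtypes(chunk, 1))

    chunks = _split_sections(text)
    name = "MOL"
    nrexcl = 3
    atoms: list[AtomRecord] | None = None
    passthrough: list[str] = []
    provenance: list[str] = []

    # first pass: atomtypes may appear before or after [atoms]
    lineno = 1
    for sec, chunk in chunks:
        if sec == "atomtypes":
            types.update(_parse_atomtypes(chunk, lineno))
        lineno += chunk.count("\n")

    lineno = 1
    for sec, chunk in chunks:
        if sec is None:
            for raw in chunk.splitlines():
                stripped = raw.strip()
                if stripped.startswith("; dielbal:"):
                    provenance.append(stripped[len("; dielbal:"):].strip())
        elif sec == "atomtypes":
            pass  # already handled
        elif sec == "moleculetype":
            for raw in chunk.splitlines()[1:]:
                body = _strip_comment(raw)
                if body:
                    tok = body.split()
                    name = tok[0]
                    if len(tok) > 1:
                        nrexcl = int(tok[1])
                    break
        elif sec == "atoms":
            atoms = _parse_atoms(chunk, lineno, types)
        else:
            passthrough.append(chunk)
        lineno += chunk.count("\n")

    if atoms is None:
        raise TopologyFormatError("no [atoms] section found")
    top = MoleculeTopology(
        name=name,
        atoms=atoms,
        passthrough_blocks=passthrough,
        nrexcl=nrexcl,
        provenance=provenance,
    )
    top.validate()
    return top


def _fmt_sig(x: float) -> str:
    return f"{x:.{SIGMA_SIGFIGS}g}"


def write_topology(top: MoleculeTopology, sink: TextIO) -> None:
    """Write a MoleculeTopology as a self-contained GROMACS-dialect file.

    Charges are written with 6 decimal places and sigma/epsilon with 7
    significant figures, so ``read(write(T))`` reproduces ``T`` to those
    precisions.  Atoms whose sigma/epsilon no longer match the shared value
    of their type (e.g. after per-atom sigma inflation) are written under a
    uniquified type name ``<type>_<index>``.
    """
    if not top.atoms:
        raise TopologyFormatError("refusing to write a topology with no atoms")

    # resolve type -> LJ parameters, uniquifying on conflict
    type_params: dict[str, tuple[float, float, float]] = {}
    atom_types: list[str] = []
    for a in top.atoms:
        params = (a.mass, a.sigma, a.epsilon)
        tname = a.type_name
        if tname in type_params and type_params[tname] != params:
            tname = f"{a.type_name}_{a.index}"
        type_params.setdefault(tname, params)
        atom_types.append(tname)

    w = sink.write
    for line in top.provenance:
        w(f"; dielbal: {line}\n")
    w("[ atomtypes ]\n")
    w("; name      mass    charge  ptype  sigma        epsilon\n")
    for tname, (mass, sigma, epsilon) in type_params.items():
        w(f"{tname:<10s} {mass:8.4f}  0.0000  A  {_fmt_sig(sigma):>12s} {_fmt_sig(epsilon):>12s}\n")
    w("\n[ moleculetype ]\n")
    w("; name  nrexcl\n")
    w(f"{top.name}  {top.nrexcl}\n")
    w("\n[ atoms ]\n")
    w(";  nr  type  resnr residue atom cgnr     charge       mass\n")
    for a, tname in zip(top.atoms, atom_types):
        cgnr = a.cgnr if a.cgnr is not None else a.index
        w(
            f"{a.index:5d}  {tname:<8s} {a.resnr:4d}  {a.residue:<6s} "
            f"{a.atom_name:<6s} {cgnr:4d}  {a.charge:.{CHARGE_DECIMALS}f}  {a.mass:10.5f}\n"
        )
    for block in top.passthrough_blocks:
        w(block if block.endswith("\n") else block + "\n")


def topology_to_string(top: MoleculeTopology) -> str:
    buf = io.StringIO()
    write_topology(top, buf)
    return buf.getvalue()


def net_charge(top: MoleculeTopology) -> float:
    """Exact sum of the atomic partial charges, in elementary-charge units."""
    return top.net_charge
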