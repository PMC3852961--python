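"""PDB structure reading/writing and per-residue scoring centres.

Each residue is scored at its C-beta atom (C-alpha for glycine), so the
parser keeps full atom records but the rest of the package only ever sees
:class:`ScoringCentre` objects.  Only the first NMR model is read, the
first-listed alt-loc conformer is kept, and MSE/SEC are mapped onto their
standard parents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .geometry import IDENTITY, Transform, apply_transform

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Residue",
    "Structure",
    "ScoringCentre",
    "NoStructureError",
    "NoScoringCentresError",
    "read_structure",
    "scoring_centres",
    "write_structure",
    "transform_structure",
]


class NoStructureError(ValueError):
    """Raised when the input contains no parsable polymer ATOM records."""


class NoScoringCentresError(ValueError):
    """Raised when a structure yields no usable scoring centres."""


AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

# Common modified residues mapped to a standard parent.
NONSTANDARD_MAP = {"MSE": "MET", "SEC": "CYS", "PYL": "LYS", "MLY": "LYS", "SEP": "SER"}


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str
    x: float
    y: float
    z: float
    element: str = ""
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y) and np.isfinite(self.z)):
            raise ValueError("atom coordinates must be finite")
        if not self.res_name:
            raise ValueError("res_name must be non-empty")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Residue:
    chain_id: str
    res_seq: int
    i_code: str
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.i_code)


@dataclass
class Structure:
    id: str
    chains: list[list[Residue]] = field(default_factory=list)
    het_molecules: list[Residue] = field(default_factory=list)

    def residues(self) -> Iterable[Residue]:
        for chain in self.chains:
            yield from chain

    @property
    def chain_ids(self) -> list[str]:
        return [chain[0].chain_id for chain in self.chains if chain]

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())


@dataclass(frozen=True)
class ScoringCentre:
    aa: str
    position: np.ndarray
    chain_id: str
    res_seq: int

    def __post_init__(self) -> None:
        if self.aa not in AA_1TO3:
            raise ValueError(f"unknown amino acid code {self.aa!r}")


def _parse_float(text: str) -> float:
    return float(text.strip())


def read_structure(pdb_text: str, structure_id: str = "structure") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Only MODEL 1 is used; the first-listed alt-loc conformer of each atom
    is kept; ATOM records with standard (or mappable) residue names go
    into chains, everything else into ``het_molecules``.  Malformed
    records are skipped with a warning.
    """
    chains: dict[str, dict[tuple[int, str, str], Residue]] = {}
    chain_order: list[str] = []
    het: dict[tuple[str, int, str, str], Residue] = {}
    seen_atoms: set[tuple[str, int, str, str]] = set()
    in_model = 0

    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model += 1
            if in_model > 1:
                break
            continue
        if rec == "ENDMDL":
            break
        if rec not in ("ATOM", "HETATM"):
            continue
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            alt_loc = line[16]
            res_name = line[17:20].strip()
            chain_id = line[21]
            res_seq = int(line[22:26])
            i_code = line[26]
            x = _parse_float(line[30:38])
            y = _parse_float(line[38:46])
            z = _parse_float(line[46:54])
            element = line[76:78].strip() if len(line) >= 78 else ""
        except (ValueError, IndexError):
            logger.warning("skipping malformed record at line %d: %r", lineno, line)
            continue

        is_hetatm = rec == "HETATM"
        mapped = NONSTANDARD_MAP.get(res_name, res_name)
        is_polymer = (mapped in AA_3TO1 and not is_hetatm) or res_name in NONSTANDARD_MAP

        if is_polymer:
            akey = (chain_id, res_seq, i_code, name)
            if akey in seen_atoms:
                continue  # later alt-loc conformer
            seen_atoms.add(akey)
            try:
                atom = AtomRecord(serial, name, alt_loc, res_name, chain_id,
                                  res_seq, i_code, x, y, z, element, is_hetatm)
            except ValueError as exc:
                logger.warning("skipping record at line %d: %s", lineno, exc)
                continue
            if chain_id not in chains:
                chains[chain_id] = {}
                chain_order.append(chain_id)
            rkey = (res_seq, i_code, mapped)
            residue = chains[chain_id].get(rkey)
            if residue is None:
                residue = Residue(chain_id, res_seq, i_code, mapped)
                chains[chain_id][rkey] = residue
            residue.atoms.append(atom)
        else:
            if not is_hetatm and res_name not in AA_3TO1:
                logger.warning("skipping unmapped non-standard residue %s %s%d",
                               res_name, chain_id, res_seq)
                continue
            atom = AtomRecord(serial, name, alt_loc, res_name, chain_id,
                              res_seq, i_code, x, y, z, element, is_hetatm)
            hkey = (chain_id, res_seq, i_code, res_name)
            residue = het.get(hkey)
            if residue is None:
                residue = Residue(chain_id, res_seq, i_code, res_name)
                het[hkey] = residue
            residue.atoms.append(atom)

    chain_list = [list(chains[cid].values()) for cid in chain_order]
    chain_list = [c for c in chain_list if c]
    if not chain_list:
        raise NoStructureError("no structure: input contains no polymer ATOM records")
    return Structure(id=structure_id, chains=chain_list, het_molecules=list(het.values()))


def scoring_centres(s: Structure, chains: Sequence[str] | None = None) -> list[ScoringCentre]:
    """One centre per standard residue: C-beta, or C-alpha for glycine.

    Non-glycine residues missing a C-beta fall back to C-alpha (logged);
    residues with neither atom are skipped.
    """
    wanted = set(chains) if chains else None
    centres: list[ScoringCentre] = []
    for residue in s.residues():
        if wanted is not None and residue.chain_id not in wanted:
            continue
        aa = AA_3TO1.get(residue.res_name)
        if aa is None:
            continue
        if aa == "G":
            atom = residue.atom("CA")
        else:
            atom = residue.atom("CB")
            if atom is None:
                atom = residue.atom("CA")
                if atom is not None:
                    logger.info("residue %s %s%d lacks CB; using CA",
                                residue.res_name, residue.chain_id, residue.res_seq)
        if atom is None:
            continue
        centres.append(ScoringCentre(aa, atom.position, residue.chain_id, residue.res_seq))
    if not centres:
        raise NoScoringCentresError("no scoring centres in structure")
    return centres


def transform_structure(s: Structure, t: Transform) -> Structure:
    """Return a copy of ``s`` with every atom transformed by ``t``."""

    def _tx_res(residue: Residue) -> Residue:
        atoms = []
        for a in residue.atoms:
            x, y, z = apply_transform(np.array([a.x, a.y, a.z]), t)
            atoms.append(replace(a, x=float(x), y=float(y), z=float(z)))
        return Residue(residue.chain_id, residue.res_seq, residue.i_code,
                       residue.res_name, atoms)

    return Structure(
        id=s.id,
        chains=[[_tx_res(r) for r in chain] for chain in s.chains],
        het_molecules=[_tx_res(r) for r in s.het_molecules],
    )


def _format_atom(record_name: str, serial: int, a: AtomRecord,
                 res_name: str, pos: np.ndarray) -> str:
    name = a.name
    if len(name) < 4:
        name = f" {name:<3}"
    return (
        f"{record_name:<6}{serial:>5} {name:<4}{a.alt_loc if a.alt_loc.strip() else ' '}"
        f"{res_name:>3} {a.chain_id}{a.res_seq:>4}{a.i_code if a.i_code.strip() else ' '}"
        f"   {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {a.element:>2}"
    )


def write_structure(s: Structure, t: Transform = IDENTITY,
                    membrane_half_thickness: float = 15.0) -> str:
    """Serialise ``s`` with every coordinate transformed by ``t``.

    Two REMARK lines record the transform and the implied membrane
    boundaries (z = +/- ``membrane_half_thickness``, the hydrophobic
    half-width used for display).
    """
    lines = [
        f"REMARK MEMEMBED TRANSFORM {t.rot_x:.3f} {t.rot_y:.3f} {t.dz:.3f}",
        f"REMARK MEMEMBED MEMBRANE {-membrane_half_thickness:.3f} {membrane_half_thickness:.3f}",
    ]
    serial = 0
    for chain in s.chains:
        for residue in chain:
            for a in residue.atoms:
                serial += 1
                pos = apply_transform(np.array([a.x, a.y, a.z]), t)
                lines.append(_format_atom("ATOM", serial, a, residue.res_name, pos))
        lines.append(f"TER   {serial + 1:>5}")
        serial += 1
    for residue in s.het_molecules:
        for a in residue.atoms:
            serial += 1
            pos = apply_transform(np.array([a.x, a.y, a.z]), t)
            lines.append(_format_atom("HETATM", serial, a, residue.res_name, pos))
    lines.append("END")
    return "\n".join(lines) + "\n"
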