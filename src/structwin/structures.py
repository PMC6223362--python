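"""Protein structure model and PDB/mmCIF I/O.

Structures are read with gemmi into a small uniform hierarchy
(:class:`Structure` → chains → :class:`Residue` → :class:`Atom`) that keeps
exactly the information the sliding-window engine needs: author residue
numbering, one-letter codes for sequence alignment, 3D coordinates for
neighbor search, and B-factors/occupancies for round-trip output.

Alternate conformations are resolved at parse time: for each atom name the
conformer with the highest occupancy is kept (ties go to the first one in
the file), so downstream code always sees one coordinate per atom.

Output is PDB v3.3 fixed columns only, written by this module's own
serializer so that annotated output (scores in the B-factor column) differs
from a plain re-serialization of the parsed model in the B-factor field and
nowhere else.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .errors import (
    EmptyStructureError,
    FormattingError,
    InputError,
    ParseError,
)

logger = logging.getLogger(__name__)

# Standard 20 amino acids plus common modified residues that still occupy a
# polymer position (selenomethionine, selenocysteine, pyrrolysine, and the
# common phospho-residues mapped to their parent letter).
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # modified residues retained as polymer positions
    "MSE": "M", "SEC": "U", "PYL": "O", "SEP": "S", "TPO": "T", "PTR": "Y",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items() if len(k) == 3}
_MODIFIED_POLYMER = {"MSE", "SEC", "PYL", "SEP", "TPO", "PTR"}
_WATERS = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True, order=True)
class ResidueId:
    """Author-numbering address of a residue: (chain, number, insertion code).

    Ordered lexicographically by (chain, number, icode); this order defines
    the deterministic residue ordering used throughout the package.
    """

    chain: str
    number: int
    icode: str = ""

    def __str__(self) -> str:
        return f"{self.chain}/{self.number}{self.icode}"


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    bfactor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise InputError(f"atom {self.name}: coord must be 3 finite components")
        if not 0.0 <= self.occupancy <= 1.0:
            raise InputError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    id: ResidueId
    resname: str
    atoms: list[Atom]
    is_hetero: bool = False

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.resname, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self, include_hydrogens: bool = False) -> np.ndarray:
        pts = [a.coord for a in self.atoms if include_hydrogens or not a.is_hydrogen]
        if not pts:  # hydrogen-only residue: fall back to everything
            pts = [a.coord for a in self.atoms]
        return np.asarray(pts)


@dataclass
class Structure:
    """Chains of residues with 3D coordinates, in file order."""

    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    source_format: str = "pdb"

    def residues(self, include_hetero: bool = True) -> list[Residue]:
        out: list[Residue] = []
        for chain in self.chains.values():
            out.extend(r for r in chain if include_hetero or not r.is_hetero)
        return out

    def polymer_residues(self) -> list[Residue]:
        return self.residues(include_hetero=False)

    def __getitem__(self, rid: ResidueId) -> Residue:
        for r in self.chains.get(rid.chain, []):
            if r.id == rid:
                return r
        raise KeyError(rid)

    def residue_ids(self) -> set[ResidueId]:
        return {r.id for r in self.residues()}


# ---------------------------------------------------------------------------
# parsing

_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def _resolve_altlocs(res: gemmi.Residue) -> list[Atom]:
    """One atom per name: highest occupancy wins, ties keep the first in file."""
    best: dict[str, Atom] = {}
    for a in res:
        atom = Atom(
            name=a.name,
            element=a.element.name,
            coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
            occupancy=min(max(a.occ, 0.0), 1.0),
            bfactor=a.b_iso,
            altloc=a.altloc if a.altloc != "\0" else "",
        )
        prev = best.get(a.name)
        if prev is None or atom.occupancy > prev.occupancy:
            best[a.name] = atom
    return list(best.values())


def _classify_hetero(res: gemmi.Residue) -> bool:
    if res.name in _WATERS:
        return True
    flag = res.het_flag
    if flag == "H":
        return res.name not in _MODIFIED_POLYMER
    if flag == "A":
        return False
    return res.name not in THREE_TO_ONE  # no record flag: fall back to the table


def parse_structure(path: str | os.PathLike, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    ``format`` is ``pdb``, ``mmcif`` or ``auto`` (detect by extension, then
    content). Only the first model of multi-model (NMR) files is used.
    """
    path = os.fspath(path)
    if format not in _FORMATS:
        raise InputError(f"unknown structure format {format!r}; use pdb, mmcif or auto")
    if not os.path.exists(path):
        raise InputError(f"structure file not found: {path}")
    try:
        st = gemmi.read_structure(path, format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: file contains no models")
    if len(st) > 1:
        logger.info("%s: %d models present; using the first", path, len(st))

    model = st[0]
    source = "mmcif" if path.endswith((".cif", ".mmcif", ".cif.gz")) else "pdb"
    if format in ("pdb", "mmcif"):
        source = format
    out = Structure(id=st.name or os.path.basename(path), source_format=source)
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            atoms = _resolve_altlocs(res)
            if not atoms:
                continue
            rid = ResidueId(
                chain=chain.name,
                number=res.seqid.num,
                icode=res.seqid.icode.strip(),
            )
            residues.append(
                Residue(id=rid, resname=res.name, atoms=atoms, is_hetero=_classify_hetero(res))
            )
        if residues:
            polymer = sorted(
                (r for r in residues if not r.is_hetero), key=lambda r: r.id
            )
            hetero = [r for r in residues if r.is_hetero]
            out.chains[chain.name] = polymer + hetero
    if not out.polymer_residues():
        raise EmptyStructureError(f"{path}: no polymer residues found")
    seen: set[ResidueId] = set()
    for r in out.residues():
        if r.id in seen:
            raise ParseError(f"{path}: duplicate residue id {r.id}")
        seen.add(r.id)
    return out


# ---------------------------------------------------------------------------
# sequence extraction


def polymer_sequence(
    structure: Structure, chains: str | Sequence[str] = "all"
) -> tuple[str, list[ResidueId]]:
    """One-letter sequence of the selected chains plus the parallel residue index.

    Hetero residues and waters are skipped; unresolved residues are simply
    absent (no gap characters). ``chains`` is ``"all"``, a single chain id, or
    a sequence of chain ids; chains are concatenated in structure order for
    ``"all"``, otherwise in the order given.
    """
    if chains == "all":
        selected = list(structure.chains.keys())
    elif isinstance(chains, str):
        selected = [chains]
    else:
        selected = list(chains)
    unknown = [c for c in selected if c not in structure.chains]
    if unknown:
        raise InputError(
            f"unknown chain(s) {unknown}; available: {sorted(structure.chains)}"
        )
    seq_parts: list[str] = []
    index: list[ResidueId] = []
    for cid in selected:
        for res in structure.chains[cid]:
            if res.is_hetero:
                continue
            seq_parts.append(res.one_letter)
            index.append(res.id)
    return "".join(seq_parts), index


# ---------------------------------------------------------------------------
# PDB writing


def _format_atom_name(name: str) -> str:
    # columns 13-16: names of <4 chars start at column 14 (standard convention)
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def _pdb_line(serial: int, atom: Atom, res: Residue, bfactor: float) -> str:
    record = "HETATM" if res.is_hetero else "ATOM  "
    x, y, z = atom.coord
    return (
        f"{record}{serial:5d} {_format_atom_name(atom.name)}{atom.altloc or ' '}"
        f"{res.resname:>3s} {res.id.chain[:1]}{res.id.number:4d}{res.id.icode or ' '}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{bfactor:6.2f}"
        f"          {atom.element[:2]:>2s}  "
    )


def _check_representable(value: float) -> None:
    if value >= 1000 or value <= -100:
        raise FormattingError(
            f"score {value} does not fit the 6-column B-factor field "
            "(need -100 < v < 1000); rescale your scores"
        )


def structure_to_pdb(
    structure: Structure,
    bfactors: Mapping[ResidueId, float] | None = None,
    missing_value: float = 0.0,
) -> str:
    """Serialize to PDB v3.3 text.

    With ``bfactors`` given, every atom of a listed residue carries that
    residue's value; unlisted residues carry ``missing_value``. Without it,
    atoms keep their original B-factors.
    """
    lines: list[str] = []
    serial = 0
    for cid, residues in structure.chains.items():
        last_polymer: Residue | None = None
        for res in residues:
            for atom in res.atoms:
                serial += 1
                if bfactors is None:
                    b = atom.bfactor
                else:
                    v = bfactors.get(res.id)
                    b = missing_value if v is None else v
                    _check_representable(b)
                lines.append(_pdb_line(serial, atom, res, b))
            if not res.is_hetero:
                last_polymer = res
        if last_polymer is not None:
            serial += 1
            lines.append(
                f"TER   {serial:5d}      {last_polymer.resname:>3s} "
                f"{cid[:1]}{last_polymer.id.number:4d}{last_polymer.id.icode or ' '}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_bfactor_pdb(
    structure: Structure,
    result: Mapping[ResidueId, float | None],
    out_path: str | os.PathLike,
    missing_value: float = 0.0,
) -> None:
    """Write ``structure`` as PDB with per-residue scores in the B-factor column.

    ``result`` maps residue ids to scores (``None`` = missing); keys must be
    residues of ``structure``. Residues absent from ``result`` or mapped to
    ``None`` receive ``missing_value``. Everything except the B-factor column
    is identical to a plain re-serialization of the model.
    """
    scores = getattr(result, "scores", result)
    known = structure.residue_ids()
    unknown = [rid for rid in scores if rid not in known]
    if unknown:
        raise InputError(f"result contains residue ids not in the structure: {unknown[:5]}")
    _check_representable(missing_value)
    clean = {rid: v for rid, v in scores.items() if v is not None}
    for v in clean.values():
        _check_representable(v)
    text = structure_to_pdb(structure, bfactors=clean, missing_value=missing_value)
    try:
        with open(out_path, "w") as fh:
            fh.write(text)
    except OSError as exc:
        raise InputError(f"cannot write {out_path}: {exc}") from exc
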