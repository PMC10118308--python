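"""Minimal PDB reader/writer for biounit coordinate files.

Reads the fixed-column ATOM/HETATM/TER/MODEL/ENDMDL subset (first model
only), strips waters, groups hetero groups into ligands and assigns
element-derived van der Waals radii.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .radii import (
    AA_3TO1,
    METAL_ELEMENTS,
    WATER_RESNAMES,
    vdw_radius,
)


class PDBParseError(ValueError):
    """Raised on a malformed coordinate record; carries the line number."""


class ResidueKey(NamedTuple):
    """Residue identity: (chain id, author residue number, insertion code)."""

    chain: str
    resnum: int
    icode: str = ""


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue: ResidueKey
    resname: str
    coord: tuple[float, float, float]
    is_hetero: bool
    vdw_radius: float


@dataclass
class LigandRecord:
    ligand_id: str
    resname: str
    atoms: list[AtomRecord]
    is_metal: bool
    is_biologically_relevant: bool = True

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)


@dataclass
class StructureModel:
    """Protein atoms plus grouped ligands, first biounit model."""

    id: str
    atoms: list[AtomRecord]
    chains: list[str]
    ligands: list[LigandRecord]
    resnames: dict[ResidueKey, str] = field(default_factory=dict)

    def residues(self) -> dict[ResidueKey, list[AtomRecord]]:
        out: dict[ResidueKey, list[AtomRecord]] = {}
        for atom in self.atoms:
            out.setdefault(atom.residue, []).append(atom)
        return out

    def residue_keys(self) -> list[ResidueKey]:
        seen: dict[ResidueKey, None] = {}
        for atom in self.atoms:
            seen.setdefault(atom.residue)
        return list(seen)

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def sequence1(self, key: ResidueKey) -> str:
        """One-letter amino-acid code of a residue ('X' if non-standard)."""
        return AA_3TO1.get(self.resnames.get(key, ""), "X")

    def get_ligand(self, ligand_id: str) -> LigandRecord:
        for lig in self.ligands:
            if lig.ligand_id == ligand_id:
                return lig
        raise KeyError(f"no ligand {ligand_id!r} in structure {self.id!r}")


def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise PDBParseError(
            f"line {lineno}: malformed {what} field {text.strip()!r}"
        ) from exc


def _guess_element(name: str) -> str:
    stripped = name.strip()
    if not stripped:
        return ""
    # Columns 13-14 hold the element for standard PDB atom names.
    two = name[:2].strip()
    if two.upper() in METAL_ELEMENTS and len(stripped) <= 2:
        return two.upper()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


def parse_structure(pdb_text: str, structure_id: str = "structure") -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Only the first MODEL is read; waters are dropped; HETATM groups become
    :class:`LigandRecord` objects unless their residue name is a standard
    amino acid (covalently numbered hetero residues stay in-chain).
    """
    atoms: list[AtomRecord] = []
    chains: list[str] = []
    ligand_groups: dict[tuple[str, int, str, str], list[AtomRecord]] = {}
    resnames: dict[ResidueKey, str] = {}
    model_seen = 0

    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        record = line[:6].strip()
        if record == "MODEL":
            model_seen += 1
            if model_seen > 1:
                break
            continue
        if record == "ENDMDL":
            break
        if record not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: coordinate record too short")
        serial = int(_parse_float(line[6:11], "serial", lineno))
        name = line[12:16]
        altloc = line[16].strip()
        if altloc not in ("", "A"):
            continue
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resnum = int(_parse_float(line[22:26], "residue number", lineno))
        icode = line[26].strip()
        x = _parse_float(line[30:38], "x coordinate", lineno)
        y = _parse_float(line[38:46], "y coordinate", lineno)
        z = _parse_float(line[46:54], "z coordinate", lineno)
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
        if not element:
            element = _guess_element(name)
        if not element:
            raise PDBParseError(
                f"line {lineno}: cannot resolve element for atom "
                f"{name.strip()!r} (serial {serial})"
            )
        if resname in WATER_RESNAMES:
            continue

        is_hetero = record == "HETATM" and resname not in AA_3TO1
        atom = AtomRecord(
            serial=serial,
            name=name.strip(),
            element=element,
            residue=ResidueKey(chain, resnum, icode),
            resname=resname,
            coord=(x, y, z),
            is_hetero=is_hetero,
            vdw_radius=vdw_radius(element),
        )
        if is_hetero:
            ligand_groups.setdefault((chain, resnum, icode, resname), []).append(atom)
        else:
            atoms.append(atom)
            resnames[atom.residue] = resname
            if chain not in chains:
                chains.append(chain)

    if not atoms:
        raise PDBParseError("no protein atoms found")

    ligands = []
    for (chain, resnum, icode, resname), group in ligand_groups.items():
        is_metal = all(a.element in METAL_ELEMENTS for a in group)
        ligands.append(
            LigandRecord(
                ligand_id=f"{resname}_{chain}{resnum}{icode}",
                resname=resname,
                atoms=group,
                is_metal=is_metal,
                is_biologically_relevant=not is_metal,
            )
        )
    ligands.sort(key=lambda lig: lig.ligand_id)
    return StructureModel(
        id=structure_id, atoms=atoms, chains=chains, ligands=ligands,
        resnames=resnames,
    )


def write_pdb(
    chains: dict[str, list[tuple[int, str, list[tuple[str, str, np.ndarray]]]]],
    ligands: list[tuple[str, str, int, list[tuple[str, str, np.ndarray]]]] = (),
) -> str:
    """Serialize simple chain/ligand layouts to PDB text.

    ``chains`` maps chain id -> [(resnum, resname3, [(atom name, element,
    xyz)])]; ``ligands`` is [(resname3, chain, resnum, atoms)].
    """
    lines = []
    serial = 1
    for chain_id, residues in chains.items():
        for resnum, resname, atom_list in residues:
            for name, element, xyz in atom_list:
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {resname:>3s} {chain_id}"
                    f"{resnum:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {residues[-1][1]:>3s} {chain_id}")
        serial += 1
    for resname, chain, resnum, atom_list in ligands:
        for name, element, xyz in atom_list:
            lines.append(
                f"HETATM{serial:5d} {name:<4s} {resname:>3s} {chain}"
                f"{resnum:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
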