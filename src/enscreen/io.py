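"""Readers and writers for structure and pose formats.

Supported inputs: multi-MODEL PDB, PDBQT (AutoDock-4 dialect: partial
charge in columns 67–76, atom type in columns 78–79), AutoDock DLG
docking logs (``DOCKED:``-prefixed records), and SDF V2000 (via RDKit).
Unknown record types are skipped with a warning rather than rejected,
because real docking logs carry many record kinds.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import List, Optional

from .core import AtomRecord, Pose

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_structure",
    "write_structure",
    "read_poses",
]


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""


def _parse_atom_line(line: str, lineno: int, fmt: str) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain = line[21].strip()
        residue_number = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed fixed-width ATOM record at line {lineno}: {exc}") from exc
    charge = 0.0
    atom_type = ""
    if fmt == "PDBQT":
        charge_field = line[66:76].strip()
        if not charge_field:
            raise ParseError(f"PDBQT line {lineno}: missing partial-charge column (67-76)")
        try:
            charge = float(charge_field)
        except ValueError as exc:
            raise ParseError(f"PDBQT line {lineno}: bad charge field {charge_field!r}") from exc
        atom_type = line[77:79].strip()
    return AtomRecord(
        serial=serial,
        name=name,
        residue_name=residue_name,
        residue_number=residue_number,
        chain=chain,
        position=(x, y, z),
        charge=charge,
        atom_type=atom_type,
    )


def _parse_model_blocks(lines, fmt: str, start_lineno: int = 1):
    """Split ATOM/HETATM records into conformations, one per MODEL."""
    conformations: List[List[AtomRecord]] = []
    current: List[AtomRecord] = []
    in_model = False
    seen_model_record = False
    for offset, raw in enumerate(lines):
        lineno = start_lineno + offset
        rec = raw[:6].strip()
        if rec == "MODEL":
            if current:
                conformations.append(current)
                current = []
            in_model = True
            seen_model_record = True
        elif rec == "ENDMDL":
            conformations.append(current)
            current = []
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current.append(_parse_atom_line(raw, lineno, fmt))
        elif rec in ("TER", "END", "REMARK", "ROOT", "ENDROO", "BRANCH",
                     "ENDBRA", "TORSDO", "CONECT", "HEADER", "TITLE",
                     "CRYST1", "USER", "COMPND", "AUTHOR", "EXPDTA", "SEQRES",
                     ""):
            continue
        else:
            warnings.warn(f"skipping unknown record {rec!r} at line {lineno}")
    if current:
        conformations.append(current)
    if seen_model_record:
        conformations = [c for c in conformations if c]
    return conformations


def read_structure(path, format: Optional[str] = None) -> List[List[AtomRecord]]:
    """Read a (possibly multi-MODEL) PDB or PDBQT file.

    Returns a list of conformations, each a list of :class:`AtomRecord`.
    The format is inferred from the suffix when not given.
    """
    path = Path(path)
    if format is None:
        format = "PDBQT" if path.suffix.lower() == ".pdbqt" else "PDB"
    format = format.upper()
    if format not in ("PDB", "PDBQT"):
        raise ValueError(f"unsupported structure format {format!r}")
    lines = path.read_text().splitlines()
    conformations = _parse_model_blocks(lines, format)
    if not conformations:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    logger.info("read %d conformation(s), %d atoms each from %s",
                len(conformations), len(conformations[0]), path)
    return conformations


def _format_atom_line(atom: AtomRecord, fmt: str) -> str:
    line = (
        f"ATOM  {atom.serial:>5d} {atom.name:<4.4s}{atom.residue_name:>4.3s} "
        f"{atom.chain or 'A':1.1s}{atom.residue_number:>4d}    "
        f"{atom.position[0]:8.3f}{atom.position[1]:8.3f}{atom.position[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}"
    )
    if fmt == "PDBQT":
        line += f"    {atom.charge:6.3f} {atom.atom_type:<2.2s}"
    return line


def write_structure(conformations, path, format: Optional[str] = None) -> None:
    """Write conformations as (multi-MODEL) PDB or PDBQT.

    Round-trips with :func:`read_structure` to 3 decimals on coordinates
    and charges (the fixed-width contract).
    """
    path = Path(path)
    if format is None:
        format = "PDBQT" if path.suffix.lower() == ".pdbqt" else "PDB"
    format = format.upper()
    out = []
    multi = len(conformations) > 1
    for i, conf in enumerate(conformations, start=1):
        if multi:
            out.append(f"MODEL     {i:>4d}")
        for atom in conf:
            out.append(_format_atom_line(atom, format))
        if multi:
            out.append("ENDMDL")
    out.append("END")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# pose readers


_ENERGY_TAGS = (
    "Estimated Free Energy of Binding",
    "Final Docked Energy",
)


def _read_dlg(path: Path) -> List[Pose]:
    docked_lines = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if raw.startswith("DOCKED:"):
                docked_lines.append((lineno, raw[8:].rstrip("\n")))
    if not docked_lines:
        raise ParseError(f"{path}: no DOCKED records found")
    poses: List[Pose] = []
    atoms: List[AtomRecord] = []
    energy: Optional[float] = None
    ntor = 0
    run_id = 0

    def flush():
        nonlocal atoms, energy
        if atoms:
            run = len(poses) + 1
            poses.append(Pose(ligand_atoms=atoms, docking_energy=energy,
                              n_rotatable_bonds=ntor, run_id=run_id or run,
                              source_target=str(path.stem)))
        atoms = []
        energy = None

    for lineno, line in docked_lines:
        rec = line[:6].strip()
        if rec == "MODEL":
            flush()
            try:
                run_id = int(line.split()[1])
            except (IndexError, ValueError):
                run_id = 0
        elif rec == "ENDMDL":
            flush()
        elif rec in ("ATOM", "HETATM"):
            atoms.append(_parse_atom_line(line, lineno, "PDBQT"))
        elif rec == "USER":
            for tag in _ENERGY_TAGS:
                if tag in line:
                    try:
                        energy = float(line.split("=")[1].split()[0])
                    except (IndexError, ValueError) as exc:
                        raise ParseError(
                            f"{path} line {lineno}: unreadable energy field") from exc
        elif line.startswith("TORSDOF"):
            try:
                ntor = int(line.split()[1])
            except (IndexError, ValueError):
                pass
    flush()
    if not poses:
        raise ParseError(f"{path}: DOCKED records contain no poses")
    return poses


def _read_pdbqt_poses(path: Path) -> List[Pose]:
    lines = path.read_text().splitlines()
    ntor = 0
    for line in lines:
        if line.startswith("TORSDOF"):
            try:
                ntor = int(line.split()[1])
            except (IndexError, ValueError):
                pass
            break
    conformations = _parse_model_blocks(lines, "PDBQT")
    if not conformations:
        raise ParseError(f"{path}: no poses found")
    return [
        Pose(ligand_atoms=conf, n_rotatable_bonds=ntor, run_id=i + 1,
             source_target=str(path.stem))
        for i, conf in enumerate(conformations)
    ]


def _read_sdf(path: Path) -> List[Pose]:
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover - rdkit is an optional extra
        raise ImportError("SDF reading requires rdkit") from exc
    from rdkit.Chem import Descriptors

    try:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    except OSError as exc:
        raise ParseError(f"{path}: empty or unreadable SDF") from exc
    poses: List[Pose] = []
    for i, mol in enumerate(supplier):
        if mol is None:
            warnings.warn(f"{path}: skipping unreadable SDF record {i}")
            continue
        conf = mol.GetConformer()
        atoms = []
        for atom in mol.GetAtoms():
            pos = conf.GetAtomPosition(atom.GetIdx())
            charge = 0.0
            if atom.HasProp("_GasteigerCharge"):
                charge = float(atom.GetProp("_GasteigerCharge"))
            atoms.append(AtomRecord(
                serial=atom.GetIdx() + 1,
                name=atom.GetSymbol(),
                residue_name="LIG",
                residue_number=1,
                chain="L",
                position=(pos.x, pos.y, pos.z),
                charge=charge,
                atom_type=atom.GetSymbol(),
            ))
        ntor = int(Descriptors.NumRotatableBonds(mol))
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
        poses.append(Pose(ligand_atoms=atoms, n_rotatable_bonds=ntor,
                          run_id=i + 1, ligand_id=name,
                          source_target=str(path.stem)))
    if not poses:
        raise ParseError(f"{path}: empty SDF")
    return poses


def read_poses(path, format: Optional[str] = None) -> List[Pose]:
    """Read docked ligand poses from a DLG, multi-MODEL PDBQT, or SDF file.

    Pose order is preserved; docking energies (kcal/mol) are carried over
    from DLG ``USER`` records when present.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {"": "DLG", ".dlg": "DLG", ".pdbqt": "PDBQT", ".sdf": "SDF"}.get(
            suffix, "DLG")
    format = format.upper()
    if format == "DLG":
        return _read_dlg(path)
    if format in ("PDBQT", "PDBQT-MULTIMODEL"):
        return _read_pdbqt_poses(path)
    if format == "SDF":
        return _read_sdf(path)
    raise ValueError(f"unsupported pose format {format!r}")
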