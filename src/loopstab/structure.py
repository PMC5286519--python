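"""Annotated protein structure model and loop extraction.

Reads PDB files into a flat atom table, keeps the HELIX/SHEET records the
file carries as secondary-structure annotations, and defines loops as the
maximal runs of amino-acid residues *not* covered by any helix or strand
annotation.  Loops are numbered 1..K along the chain; terminal unannotated
runs count as loops.  Residue numbering is author numbering throughout
(1-based, possibly gapped, ranges inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "SecondaryStructureAnnotation",
    "StructureModel",
    "LoopDefinition",
    "PDBParseError",
    "read_structure",
    "write_structure",
    "extract_loops",
    "loops_to_table",
    "STANDARD_AMINO_ACIDS",
]

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_HYDROGEN_ELEMENTS = {"H", "D"}


class PDBParseError(ValueError):
    """Raised for malformed fixed-width PDB records; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the structure, author numbering, Å units."""

    serial: int
    name: str
    element: str
    alt_loc: str
    chain_id: str
    residue_number: int
    residue_name: str
    coordinates: tuple[float, float, float]
    b_factor: float
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self):
        xyz = np.asarray(self.coordinates, dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")
        if self.b_factor < 0:
            raise ValueError(f"negative B-factor for atom {self.serial}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)


@dataclass(frozen=True)
class SecondaryStructureAnnotation:
    """Inclusive helix/strand residue range from a HELIX or SHEET record."""

    kind: str  # "helix" | "strand"
    chain_id: str
    start_residue: int
    end_residue: int

    def __post_init__(self):
        if self.kind not in ("helix", "strand"):
            raise ValueError(f"unknown secondary-structure kind {self.kind!r}")
        if self.start_residue > self.end_residue:
            raise ValueError("annotation start must be <= end")

    def covers(self, residue_number: int) -> bool:
        return self.start_residue <= residue_number <= self.end_residue


@dataclass
class StructureModel:
    """Flat, ordered atom list plus secondary-structure annotations."""

    atoms: list[AtomRecord]
    annotations: list[SecondaryStructureAnnotation] = field(default_factory=list)

    @property
    def chains(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    def chain_atoms(self, chain_id: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.chain_id == chain_id]

    def residues(self, chain_id: str, amino_only: bool = True) -> list[int]:
        """Ordered unique residue numbers of a chain."""
        seen: dict[int, None] = {}
        for a in self.atoms:
            if a.chain_id != chain_id:
                continue
            if amino_only and a.residue_name not in STANDARD_AMINO_ACIDS:
                continue
            seen.setdefault(a.residue_number, None)
        return list(seen)

    def residue_name(self, chain_id: str, residue_number: int) -> str | None:
        for a in self.atoms:
            if a.chain_id == chain_id and a.residue_number == residue_number:
                return a.residue_name
        return None

    def coordinates(self, heavy_only: bool = False) -> np.ndarray:
        atoms = [a for a in self.atoms if not (heavy_only and a.is_hydrogen)]
        return np.array([a.coordinates for a in atoms], dtype=float)

    def validate(self) -> None:
        chains = self.chains
        for ann in self.annotations:
            if ann.chain_id not in chains:
                raise ValueError(
                    f"annotation chain {ann.chain_id!r} not present in structure"
                )


@dataclass(frozen=True)
class LoopDefinition:
    """Maximal unannotated run of amino-acid residues, inclusive range."""

    loop_id: int
    chain_id: str
    start_residue: int
    end_residue: int

    @property
    def n_residues(self) -> int:
        return self.end_residue - self.start_residue + 1

    def covers(self, residue_number: int) -> bool:
        return self.start_residue <= residue_number <= self.end_residue


# ---------------------------------------------------------------------------
# PDB I/O (fixed-width ATOM/HETATM/HELIX/SHEET/MODEL records)

def _parse_atom_line(line: str, lineno: int, hetero: bool) -> AtomRecord:
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError("ATOM/HETATM record shorter than coordinate fields", lineno)
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        alt_loc = line[16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or " "
        res_num = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        b_field = line[60:66].strip()
        b_factor = float(b_field) if b_field else 0.0
        element = line[76:78].strip()
    except ValueError as exc:
        raise PDBParseError(f"malformed fixed-width field ({exc})", lineno) from exc
    if not element:
        # fall back on the atom-name convention: first alphabetic character
        stripped = name.lstrip("0123456789")
        element = stripped[:1].upper() if stripped else "X"
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        alt_loc=alt_loc,
        chain_id=chain_id,
        residue_number=res_num,
        residue_name=res_name,
        coordinates=(x, y, z),
        b_factor=max(b_factor, 0.0),
        occupancy=occupancy,
        is_hetero=hetero,
    )


def _resolve_alt_locs(atoms: list[AtomRecord], policy: str) -> list[AtomRecord]:
    if policy == "all":
        return atoms
    if policy != "highest_occupancy":
        raise ValueError(f"unknown alt-loc policy {policy!r}")
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for atom in atoms:
        key = (atom.chain_id, atom.residue_number, atom.residue_name, atom.name)
        if key not in best:
            best[key] = atom
            order.append(key)
        elif atom.occupancy > best[key].occupancy:
            best[key] = atom  # ties keep the first conformer
    return [replace(best[k], alt_loc="") for k in order]


def read_structure(
    path: str | Path,
    model_index: int = 1,
    keep_alt_locs: str = "highest_occupancy",
) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Parameters
    ----------
    path:
        PDB file with ATOM/HETATM records; HELIX/SHEET records are mapped to
        annotations.  Waters and other heteroatoms are retained, flagged with
        ``is_hetero``.
    model_index:
        1-based MODEL number for multi-model files; files without MODEL
        records are treated as model 1.
    keep_alt_locs:
        ``"highest_occupancy"`` keeps one conformer per atom (ties: first);
        ``"all"`` keeps every alternate location.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    atoms: list[AtomRecord] = []
    annotations: list[SecondaryStructureAnnotation] = []
    current_model = None
    seen_models: set[int] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record == "MODEL":
                try:
                    current_model = int(line[6:].split()[0])
                except (ValueError, IndexError) as exc:
                    raise PDBParseError("malformed MODEL record", lineno) from exc
                seen_models.add(current_model)
            elif record == "ENDMDL":
                current_model = None
            elif record in ("ATOM", "HETATM"):
                model_no = current_model if current_model is not None else 1
                seen_models.add(model_no)
                if model_no != model_index:
                    continue
                atoms.append(_parse_atom_line(line, lineno, record == "HETATM"))
            elif record == "HELIX":
                try:
                    annotations.append(SecondaryStructureAnnotation(
                        "helix", line[19].strip() or " ",
                        int(line[21:25]), int(line[33:37])))
                except ValueError as exc:
                    raise PDBParseError(f"malformed HELIX record ({exc})", lineno) from exc
            elif record == "SHEET":
                try:
                    annotations.append(SecondaryStructureAnnotation(
                        "strand", line[21].strip() or " ",
                        int(line[22:26]), int(line[33:37])))
                except ValueError as exc:
                    raise PDBParseError(f"malformed SHEET record ({exc})", lineno) from exc
    if not atoms:
        if model_index not in seen_models and seen_models:
            raise ValueError(
                f"model {model_index} not present in {path} (models: {sorted(seen_models)})"
            )
        raise ValueError(f"no coordinates found in {path}")
    model = StructureModel(_resolve_alt_locs(atoms, keep_alt_locs), annotations)
    model.validate()
    return model


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write the model back to PDB text (round-trips with :func:`read_structure`)."""
    lines: list[str] = []
    for i, ann in enumerate(model.annotations, start=1):
        if ann.kind == "helix":
            lines.append(
                f"HELIX  {i:>3} {i:>3} XXX {ann.chain_id} {ann.start_residue:>4}"
                f"  XXX {ann.chain_id} {ann.end_residue:>4}  1"
                f"{'':30}{ann.end_residue - ann.start_residue + 1:>6}"
            )
        else:
            lines.append(
                f"SHEET  {i:>3} S{i:<2} 1 XXX {ann.chain_id}{ann.start_residue:>4} "
                f" XXX {ann.chain_id}{ann.end_residue:>4}  0"
            )
    for atom in model.atoms:
        record = "HETATM" if atom.is_hetero else "ATOM  "
        name = atom.name if len(atom.name) == 4 else f" {atom.name:<3}"
        x, y, z = atom.coordinates
        lines.append(
            f"{record}{atom.serial:>5} {name}{atom.alt_loc or ' ':1}"
            f"{atom.residue_name:>3} {atom.chain_id:1}{atom.residue_number:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
            f"{'':10}{atom.element:>2}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Loop extraction

def extract_loops(
    model: StructureModel,
    chain_id: str,
    external_ss: dict[int, str] | None = None,
) -> list[LoopDefinition]:
    """Loops of one chain: maximal runs of amino-acid residues outside every
    helix/strand annotation, numbered 1..K in sequence order.

    ``external_ss`` optionally maps residue number -> one-letter SS code
    ('H'/'E' annotated, anything else loop) for structures lacking
    HELIX/SHEET records.
    """
    if chain_id not in model.chains:
        raise ValueError(f"chain {chain_id!r} not present (chains: {sorted(model.chains)})")
    residues = model.residues(chain_id, amino_only=True)
    if not residues:
        raise ValueError(f"chain {chain_id!r} has no amino-acid residues")

    if external_ss is not None:
        annotated = {r for r in residues if external_ss.get(r, "-") in ("H", "E")}
    else:
        anns = [a for a in model.annotations if a.chain_id == chain_id]
        annotated = {r for r in residues if any(a.covers(r) for a in anns)}

    loops: list[LoopDefinition] = []
    run_start: int | None = None
    prev: int | None = None
    for r in residues:
        in_loop = r not in annotated
        if in_loop and run_start is None:
            run_start = r
        elif not in_loop and run_start is not None:
            loops.append(LoopDefinition(len(loops) + 1, chain_id, run_start, prev))
            run_start = None
        prev = r
    if run_start is not None:
        loops.append(LoopDefinition(len(loops) + 1, chain_id, run_start, prev))
    return loops


def loops_to_table(loops: Sequence[LoopDefinition]) -> pd.DataFrame:
    """Loop list as a tidy table (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "loop_id": lp.loop_id,
                "chain": lp.chain_id,
                "start": lp.start_residue,
                "end": lp.end_residue,
                "n_residues": lp.n_residues,
            }
            for lp in loops
        ],
        columns=["loop_id", "chain", "start", "end", "n_residues"],
    )
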