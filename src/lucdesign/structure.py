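"""Loop-proximity metrics on atomic coordinates.

Structural models of the variant family show the compensated peptide
blocks forming flexible loops near the substrate binding site, and the
enzymes' brightness tracks how closely a loop covers that site. The
metric used is the minimal inter-side-chain distance (Å) between a loop
residue and the methionine adjacent to the binding site, classified as
close / middle / far.

Only a small fixed-column PDB ATOM reader is provided — enough to compute
distances on externally produced models; no modeling is done here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .config import DEFAULT_PROXIMITY_THRESHOLDS
from .errors import ValidationError

log = logging.getLogger(__name__)

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class AtomRecord:
    chain: str
    residue_number: int
    residue_name: str
    atom_name: str
    x: float
    y: float
    z: float

    def __post_init__(self):
        for v in (self.x, self.y, self.z):
            if not math.isfinite(v):
                raise ValidationError("non-finite atom coordinate")


@dataclass(frozen=True)
class StructureModel:
    atoms: tuple

    def __post_init__(self):
        seen = set()
        index: dict = {}
        for a in self.atoms:
            key = (a.chain, a.residue_number, a.atom_name)
            if key in seen:
                raise ValidationError(f"duplicate atom {key}")
            seen.add(key)
            index.setdefault((a.chain, a.residue_number), []).append(a)
        object.__setattr__(self, "_index", index)

    def residue_atoms(self, chain: str, number: int) -> list:
        try:
            return self._index[(chain, number)]
        except KeyError:
            raise ValidationError(f"residue {chain}/{number} absent from model") from None


def _is_hydrogen(atom_name: str, element: str) -> bool:
    if element:
        return element == "H"
    stripped = atom_name.lstrip("0123456789")
    return stripped.startswith("H")


def read_structure(pdb_text: str, skip_hydrogens: bool = True) -> StructureModel:
    """Parse fixed-column PDB ATOM records.

    HETATM records and (by default) hydrogens are skipped; residues
    outside the 20 standard amino acids are skipped with a warning.
    Malformed coordinate fields raise, naming the offending line.
    """
    atoms = []
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith("ATOM"):
            continue
        if len(line) < 54:
            raise ValidationError(f"line {lineno}: ATOM record too short for coordinates")
        atom_name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain = line[21].strip() or "A"
        try:
            residue_number = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError:
            raise ValidationError(
                f"line {lineno}: malformed coordinate or residue-number field "
                f"(column drift?): {line.rstrip()!r}"
            ) from None
        element = line[76:78].strip() if len(line) >= 78 else ""
        if skip_hydrogens and _is_hydrogen(atom_name, element):
            continue
        if residue_name not in STANDARD_RESIDUES:
            log.warning("line %d: skipping non-standard residue %s", lineno, residue_name)
            continue
        atoms.append(AtomRecord(chain, residue_number, residue_name, atom_name, x, y, z))
    if not atoms:
        raise ValidationError("no ATOM records found")
    return StructureModel(tuple(atoms))


def _sidechain(atoms: Sequence) -> list:
    """Heavy side-chain atoms (Cβ and beyond); glycine falls back to Cα."""
    side = [a for a in atoms if a.atom_name not in BACKBONE_ATOMS]
    if side:
        return side
    ca = [a for a in atoms if a.atom_name == "CA"]
    if ca:
        log.info("glycine (or side-chain-less residue): falling back to CA")
        return ca
    raise ValidationError("residue has neither side-chain atoms nor CA")


def sidechain_min_distance(
    model: StructureModel, res_a: tuple, res_b: tuple
) -> float:
    """Minimal Euclidean distance (Å) between heavy side-chain atoms of
    two residues, given as (chain, residue_number) pairs."""
    a_atoms = _sidechain(model.residue_atoms(*res_a))
    b_atoms = _sidechain(model.residue_atoms(*res_b))
    best = math.inf
    for a in a_atoms:
        for b in b_atoms:
            d = math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))
            if d < best:
                best = d
    return best


def classify_loop_proximity(
    distance: float, thresholds: tuple = DEFAULT_PROXIMITY_THRESHOLDS
) -> str:
    """Partition a loop–binding-site distance into close / middle / far.

    Defaults: close ≤ 6.0 Å < middle ≤ 8.5 Å < far. The middle/far cut at
    8.5 Å places an 8.0 Å loop in the middle class and an 8.7 Å loop in
    the far class.
    """
    if distance < 0:
        raise ValidationError("distance must be non-negative")
    close_max, middle_max = thresholds
    if not (0 < close_max < middle_max):
        raise ValidationError("thresholds must satisfy 0 < close < middle")
    if distance <= close_max:
        return "close"
    if distance <= middle_max:
        return "middle"
    return "far"


def proximity_report(
    model: StructureModel, pairs: Sequence, thresholds: tuple = DEFAULT_PROXIMITY_THRESHOLDS
) -> str:
    """TSV report of distances and classes for (label, res_a, res_b) triples."""
    lines = ["label\tdistance_A\tclass"]
    for label, ra, rb in pairs:
        d = sidechain_min_distance(model, ra, rb)
        lines.append(f"{label}\t{d:.2f}\t{classify_loop_proximity(d, thresholds)}")
    return "\n".join(lines) + "\n"
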