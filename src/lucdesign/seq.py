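"""Sequence records, FASTA I/O and physicochemical properties.

The designed luciferase variants are ordinary amino-acid strings with
1-based region annotations (secretion peptide, N-terminal region, the two
catalytic domains, appended tags). This module keeps that bookkeeping and
computes the per-sequence statistics used to characterise a variant
family: residue length, average-mass molecular weight and theoretical
isoelectric point.

Ambiguity codes (B, Z, X, U, O) are rejected on ingest: the design
pipeline edits exact residue strings and mass/charge arithmetic is
undefined for ambiguous positions.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO

from .config import DNA_ALPHABET, PROTEIN_ALPHABET, PkaTable, default_pka_table
from .errors import ValidationError

WATER_MASS = 18.0153  # Da, average

#: Average (not monoisotopic) residue masses in Daltons.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

RegionLabel = Literal["SP", "N_REGION", "DOMAIN1", "DOMAIN2", "TAG", "other"]


@dataclass(frozen=True)
class RegionAnnotation:
    """A labelled residue span, 1-based inclusive coordinates."""

    label: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"invalid region {self.label}: start={self.start}, end={self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SequenceRecord:
    """An identified sequence with optional region annotations."""

    id: str
    seq: str
    alphabet: Literal["protein", "dna"] = "protein"
    annotations: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise ValidationError(f"record id must be non-empty, no whitespace: {self.id!r}")
        object.__setattr__(self, "seq", self.seq.upper())
        object.__setattr__(self, "annotations", tuple(self.annotations))
        if not self.seq:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_ALPHABET
        for i, c in enumerate(self.seq, start=1):
            if c not in allowed:
                raise ValidationError(
                    f"record {self.id!r}: invalid {self.alphabet} character "
                    f"{c!r} at position {i}"
                )
        spans = sorted((a.start, a.end) for a in self.annotations)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValidationError(f"record {self.id!r}: overlapping annotations")
        for a in self.annotations:
            if a.end > len(self.seq):
                raise ValidationError(
                    f"record {self.id!r}: annotation {a.label} ends at {a.end}, "
                    f"sequence has {len(self.seq)} residues"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def region(self, label: str) -> RegionAnnotation | None:
        for a in self.annotations:
            if a.label == label:
                return a
        return None


@dataclass(frozen=True)
class PropertyReport:
    """Length, molecular weight, theoretical pI and residue composition."""

    id: str
    length: int
    mw: float  # Daltons
    pi: float  # pH units
    composition: dict

    def __post_init__(self):
        if self.mw <= 0:
            raise ValidationError("mw must be positive")
        if not (0.0 < self.pi < 14.0):
            raise ValidationError("pI must lie in (0, 14)")
        if sum(self.composition.values()) != self.length:
            raise ValidationError("composition counts must sum to length")


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(source: str | Path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read FASTA from a path or directly from FASTA-formatted text.

    Sequences are uppercased and internal whitespace removed. Raises
    :class:`ValidationError` on empty input, duplicate ids, or characters
    outside the declared alphabet (the offending record and position are
    named).
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif source.lstrip().startswith(">"):
        text = source
    else:
        p = Path(source)
        if not p.exists():
            raise ValidationError(f"FASTA source not found and not FASTA text: {source!r}")
        text = p.read_text()
    records = []
    seen = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = "".join(str(rec.seq).split())
        records.append(SequenceRecord(id=rec.id, seq=seq, alphabet=alphabet))
    if not records:
        raise ValidationError("no FASTA records found in input")
    return records


def write_fasta(records: Sequence[SequenceRecord], width: int = 60) -> str:
    """Render records as FASTA text with lines wrapped at ``width``."""
    if not records:
        raise ValidationError("cannot write empty record list")
    if width < 1:
        raise ValidationError("line width must be >= 1")
    out = []
    for r in records:
        out.append(f">{r.id}")
        for i in range(0, len(r.seq), width):
            out.append(r.seq[i : i + width])
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Physicochemical properties


def molecular_weight(seq: str | SequenceRecord) -> float:
    """Average-mass molecular weight in Daltons.

    Sum of average residue masses plus one water (18.0153 Da), so the
    function is linear: mw(s1 + s2) = mw(s1) + mw(s2) - 18.0153.
    """
    s = seq.seq if isinstance(seq, SequenceRecord) else seq.upper()
    if not s:
        raise ValidationError("empty sequence")
    try:
        return sum(AVERAGE_RESIDUE_MASS[c] for c in s) + WATER_MASS
    except KeyError as exc:
        raise ValidationError(f"not a standard protein residue: {exc.args[0]!r}") from exc


def net_charge(seq: str, ph: float, table: PkaTable | None = None) -> float:
    """Henderson–Hasselbalch net charge at a given pH.

    Counts the free N- and C-terminus plus D/E/C/Y (acidic) and H/K/R
    (basic) side chains under the configured pKa table.
    """
    table = table or default_pka_table()
    s = seq.upper()
    charge = 1.0 / (1.0 + 10.0 ** (ph - table.n_terminus))
    charge -= 1.0 / (1.0 + 10.0 ** (table.c_terminus - ph))
    for res, pka in table.positive.items():
        n = s.count(res)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pka))
    for res, pka in table.negative.items():
        n = s.count(res)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka - ph))
    return charge


def isoelectric_point(
    seq: str | SequenceRecord,
    table: PkaTable | None = None,
    tol: float = 1e-4,
) -> float:
    """Theoretical pI: the pH where the net charge crosses zero.

    The net charge is strictly decreasing in pH, so plain bisection on
    [0, 14] converges; ``tol`` is the pH bracket width at termination.
    """
    s = seq.seq if isinstance(seq, SequenceRecord) else seq.upper()
    if not s:
        raise ValidationError("empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(s, mid, table) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def property_report(record: SequenceRecord, table: PkaTable | None = None) -> PropertyReport:
    comp: dict = {}
    for c in record.seq:
        comp[c] = comp.get(c, 0) + 1
    return PropertyReport(
        id=record.id,
        length=len(record.seq),
        mw=molecular_weight(record.seq),
        pi=isoelectric_point(record.seq, table),
        composition=comp,
    )


def summarise_properties(
    records: Iterable[SequenceRecord], table: PkaTable | None = None
) -> pd.DataFrame:
    """Per-record length/MW/pI table, one row per record (id as index)."""
    rows = []
    for r in records:
        rep = property_report(r, table)
        rows.append({"id": rep.id, "length": rep.length, "mw_Da": rep.mw, "pI": rep.pi})
    if not rows:
        raise ValidationError("no records to summarise")
    return pd.DataFrame(rows).set_index("id")


def properties_to_tsv(df: pd.DataFrame) -> str:
    return df.to_csv(sep="\t", float_format="%.4f")


def properties_to_json(df: pd.DataFrame) -> str:
    return json.dumps(df.reset_index().to_dict(orient="records"), indent=2)


# ---------------------------------------------------------------------------
# Editing helpers


def strip_signal_peptide(record: SequenceRecord, sp_len: int | None = None) -> SequenceRecord:
    """Remove the N-terminal secretion peptide.

    Uses the record's SP annotation (which must start at residue 1) or an
    explicit ``sp_len``. Remaining annotations are shifted left.
    """
    if sp_len is None:
        sp = record.region("SP")
        if sp is None:
            raise ValidationError(f"record {record.id!r}: no SP annotation and no sp_len given")
        if sp.start != 1:
            raise ValidationError(f"record {record.id!r}: SP annotation must start at residue 1")
        sp_len = sp.end
    if sp_len < 0:
        raise ValidationError("sp_len must be >= 0")
    if sp_len == 0:
        return record
    if sp_len >= len(record.seq):
        raise ValidationError(f"record {record.id!r}: SP covers the entire sequence")
    shifted = []
    for a in record.annotations:
        if a.label == "SP":
            continue
        if a.start <= sp_len:
            raise ValidationError(f"record {record.id!r}: annotation {a.label} overlaps SP")
        shifted.append(RegionAnnotation(a.label, a.start - sp_len, a.end - sp_len))
    return replace(record, seq=record.seq[sp_len:], annotations=tuple(shifted))


def append_retention_tag(
    record: SequenceRecord, tag: str = "KDEL", idempotent: bool = False
) -> SequenceRecord:
    """Append a C-terminal retention tag (default the ER signal KDEL).

    With ``idempotent=True`` a sequence already ending in the tag is
    returned unchanged. An empty tag is the identity.
    """
    tag = tag.upper()
    if not tag:
        return record
    bad = set(tag) - PROTEIN_ALPHABET
    if bad:
        raise ValidationError(f"tag contains non-protein characters: {sorted(bad)}")
    if idempotent and record.seq.endswith(tag):
        return record
    new_seq = record.seq + tag
    ann = record.annotations + (
        RegionAnnotation("TAG", len(record.seq) + 1, len(new_seq)),
    )
    return replace(record, seq=new_seq, annotations=ann)
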