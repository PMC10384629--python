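"""cDNA-level construct assembly for expression, strain and PCA probes.

Designed proteins are reverse-translated with murine codon usage (highest
usage codon per residue, with minimal synonymous swaps to eliminate
forbidden restriction recognition sequences), then wrapped into cloning
layouts:

* expression insert — HindIII / ORF / stop / XhoI
* strain probe — partnerN–reporter–partnerC in one frame, joined by
  in-frame KpnI (Gly-Thr) and BamHI (Gly-Ser) junctions; the reporter
  must have its secretion peptide removed first, since an SP between the
  partners breaks the probe
* PCA probe — reporter N-fragment / insert / reporter C-fragment with
  the same junction convention; dissection sites sit in coil hinges
  between α-helices

Whether junction sites are retained in-frame in the expressed protein is
a declared convention here (they are, encoding GT and GS), isolated so it
can be changed without touching the assembly logic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .config import default_codon_table_path, default_enzyme_registry_path
from .errors import ValidationError
from .seq import SequenceRecord

DNA = frozenset("ACGT")


# ---------------------------------------------------------------------------
# Codon tables and restriction sites


@dataclass(frozen=True)
class CodonTable:
    """Per-residue codon lists ordered by usage, plus stop codons."""

    codons: dict  # aa -> tuple of (codon, fraction), descending usage
    stops: tuple  # stop codons, descending usage
    organism: str = "mouse"

    def __post_init__(self):
        for aa, entries in self.codons.items():
            total = sum(f for _, f in entries)
            if abs(total - 1.0) > 0.01:
                raise ValidationError(f"usage fractions for {aa!r} sum to {total:.3f}, not 1")
            for codon, _ in entries:
                if len(codon) != 3 or set(codon) - DNA:
                    raise ValidationError(f"invalid codon {codon!r} for {aa!r}")
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.codons)
        if missing:
            raise ValidationError(f"codon table misses residues: {sorted(missing)}")
        if not self.stops:
            raise ValidationError("codon table needs at least one stop codon")

    @classmethod
    def from_tsv(cls, path: str | Path | None = None, organism: str = "mouse") -> "CodonTable":
        p = Path(path) if path is not None else default_codon_table_path()
        codons: dict = {}
        stops: list = []
        for line in p.read_text().splitlines()[1:]:
            if not line.strip():
                continue
            aa, codon, frac = line.split("\t")
            if aa == "*":
                stops.append((codon, float(frac)))
            else:
                codons.setdefault(aa, []).append((codon, float(frac)))
        return cls(
            codons={aa: tuple(sorted(v, key=lambda t: -t[1])) for aa, v in codons.items()},
            stops=tuple(c for c, _ in sorted(stops, key=lambda t: -t[1])),
            organism=organism,
        )

    def top_codon(self, aa: str) -> str:
        try:
            return self.codons[aa][0][0]
        except KeyError as exc:
            raise ValidationError(f"residue {aa!r} absent from codon table") from exc

    def alternatives(self, aa: str) -> tuple:
        """All codons for ``aa`` in descending usage order."""
        return tuple(c for c, _ in self.codons[aa])


@dataclass(frozen=True)
class RestrictionSite:
    name: str
    recognition: str

    def __post_init__(self):
        object.__setattr__(self, "recognition", self.recognition.upper())
        if len(self.recognition) < 4 or set(self.recognition) - DNA:
            raise ValidationError(f"invalid recognition sequence {self.recognition!r}")


def load_enzyme_registry(path: str | Path | None = None) -> dict:
    p = Path(path) if path is not None else default_enzyme_registry_path()
    out = {}
    for line in p.read_text().splitlines()[1:]:
        if not line.strip():
            continue
        name, rec = line.split("\t")
        out[name] = RestrictionSite(name, rec)
    return out


_REGISTRY: dict | None = None


def enzyme(name: str) -> RestrictionSite:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = load_enzyme_registry()
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValidationError(f"unknown enzyme {name!r}") from None


def find_restriction_sites(dna: str, sites: Sequence) -> list:
    """All (name, 1-based position) occurrences, overlapping included."""
    dna = dna.upper()
    if set(dna) - DNA:
        raise ValidationError("dna contains non-ACGT characters")
    hits = []
    for site in sites:
        rec = site.recognition
        start = dna.find(rec)
        while start != -1:
            hits.append((site.name, start + 1))
            start = dna.find(rec, start + 1)
    return sorted(hits, key=lambda t: (t[1], t[0]))


# ---------------------------------------------------------------------------
# Reverse translation with site avoidance


def translate(dna: str) -> str:
    """Standard-genetic-code translation of a full-codon DNA string."""
    if len(dna) % 3:
        raise ValidationError("DNA length not divisible by 3")
    return str(Seq(dna).translate())


def _occurrences(dna: str, patterns: Sequence) -> list:
    out = []
    for p in patterns:
        start = dna.find(p)
        while start != -1:
            out.append((start, p))
            start = dna.find(p, start + 1)
    return sorted(out)


def reverse_translate(
    protein: str,
    table: CodonTable | None = None,
    forbidden: Sequence = (),
    fixed_codons: dict | None = None,
    allowed_occurrences: set | None = None,
) -> str:
    """Codon-optimized reverse translation avoiding forbidden sites.

    Starts from the highest-usage codon per residue. Wherever a forbidden
    recognition sequence appears, the minimal number of codons (one at a
    time, next-ranked synonymous alternatives first) is swapped until the
    occurrence disappears. ``fixed_codons`` maps 0-based codon indices to
    codons that are used verbatim and never swapped (in-frame junction
    sites); ``allowed_occurrences`` is a set of (0-based dna start,
    pattern) pairs that are intentional and skipped by the avoidance
    (the junction sites themselves). Raises when an occurrence survives
    all synonymous choices.
    """
    table = table or CodonTable.from_tsv()
    protein = protein.upper()
    if not protein:
        raise ValidationError("empty protein")
    fixed_codons = fixed_codons or {}
    allowed = allowed_occurrences or set()
    codons = [fixed_codons.get(i) or table.top_codon(aa) for i, aa in enumerate(protein)]
    patterns = [s.recognition for s in forbidden]
    if not patterns:
        return "".join(codons)

    for _ in range(10 * len(protein) + 10):
        dna = "".join(codons)
        occ = [(s, p) for s, p in _occurrences(dna, patterns) if (s, p) not in allowed]
        if not occ:
            return dna
        start, pat = occ[0]
        first_codon = start // 3
        last_codon = (start + len(pat) - 1) // 3
        resolved = False
        for ci in range(first_codon, last_codon + 1):
            if ci in fixed_codons:
                continue
            for alt in table.alternatives(protein[ci])[1:]:
                trial = codons.copy()
                trial[ci] = alt
                tdna = "".join(trial)
                if tdna[start : start + len(pat)] != pat:
                    codons = trial
                    resolved = True
                    break
            if resolved:
                break
        if not resolved:
            raise ValidationError(
                f"unavoidable forbidden site {pat!r} at position {start + 1}: "
                "all synonymous choices exhausted"
            )
    raise ValidationError("site avoidance did not converge")


# ---------------------------------------------------------------------------
# Layouts and constructs


@dataclass(frozen=True)
class ProbeLayout:
    kind: str  # {"expression", "strain_probe", "pca_probe"}
    parts: tuple  # ordered (role, SequenceRecord)
    junction_sites: tuple  # RestrictionSite list: flanks plus junctions

    def __post_init__(self):
        if self.kind not in ("expression", "strain_probe", "pca_probe"):
            raise ValidationError(f"unknown layout kind {self.kind!r}")
        if not self.parts:
            raise ValidationError("layout needs at least one part")


@dataclass(frozen=True)
class DissectionSite:
    """Split point between after_residue and after_residue + 1."""

    after_residue: int
    protein_length: int
    context: str = "user"

    def __post_init__(self):
        if not (1 <= self.after_residue < self.protein_length):
            raise ValidationError(
                f"dissection after residue {self.after_residue} invalid for "
                f"{self.protein_length}-residue protein"
            )

    @property
    def n_frag_len(self) -> int:
        return self.after_residue

    @property
    def c_frag_len(self) -> int:
        return self.protein_length - self.after_residue


@dataclass(frozen=True)
class NucleotideConstruct:
    id: str
    dna: str
    orf_start: int  # 1-based
    orf_end: int  # 1-based inclusive
    features: tuple = field(default_factory=tuple)  # (label, start, end)

    def __post_init__(self):
        object.__setattr__(self, "dna", self.dna.upper())
        if set(self.dna) - DNA:
            raise ValidationError("construct dna has non-ACGT characters")
        if (self.orf_end - self.orf_start + 1) % 3:
            raise ValidationError("ORF length not divisible by 3")

    @property
    def orf(self) -> str:
        return self.dna[self.orf_start - 1 : self.orf_end]

    @property
    def protein(self) -> str:
        """Translation of the ORF with the stop codon removed."""
        p = translate(self.orf)
        return p[:-1] if p.endswith("*") else p


def _assert_flanks_unique(dna: str, flank5: RestrictionSite, flank3: RestrictionSite,
                          internal_once: Sequence = ()) -> None:
    for site, expected in ((flank5, 1), (flank3, 1)):
        n = len(find_restriction_sites(dna, [site]))
        if n != expected:
            raise ValidationError(f"{site.name} appears {n} times, expected {expected}")
    for site, expected in internal_once:
        n = len(find_restriction_sites(dna, [site]))
        if n != expected:
            raise ValidationError(f"{site.name} appears {n} times, expected {expected}")


def assemble_expression_insert(
    protein: SequenceRecord,
    table: CodonTable | None = None,
    flank5: RestrictionSite | None = None,
    flank3: RestrictionSite | None = None,
) -> NucleotideConstruct:
    """HindIII / ATG-initiated ORF / stop / XhoI expression insert."""
    table = table or CodonTable.from_tsv()
    flank5 = flank5 or enzyme("HindIII")
    flank3 = flank3 or enzyme("XhoI")
    aa = protein.seq if protein.seq.startswith("M") else "M" + protein.seq
    orf_body = reverse_translate(aa, table, forbidden=[flank5, flank3])
    stop = table.stops[0]
    dna = flank5.recognition + orf_body + stop + flank3.recognition
    # a flank/ORF junction could recreate a site; the avoidance above only
    # saw the ORF body, so re-check the final molecule
    _assert_flanks_unique(dna, flank5, flank3)
    orf_start = len(flank5.recognition) + 1
    orf_end = orf_start + len(orf_body) + 3 - 1
    features = (
        (flank5.name, 1, len(flank5.recognition)),
        ("ORF", orf_start, orf_end),
        (flank3.name, len(dna) - len(flank3.recognition) + 1, len(dna)),
    )
    return NucleotideConstruct(f"{protein.id}|expr", dna, orf_start, orf_end, features)


#: In-frame junction codon pairs: KpnI GGTACC = Gly-Thr, BamHI GGATCC = Gly-Ser.
JUNCTION_RESIDUES = {"KpnI": "GT", "BamHI": "GS"}


def _reverse_translate_with_junctions(
    segments: Sequence, table: CodonTable, forbidden: Sequence
) -> tuple:
    """Reverse-translate alternating peptide / junction-site segments.

    Junction segments contribute their recognition sequence verbatim (two
    in-frame codons, protected from swapping); the junction occurrences
    themselves are whitelisted for the site avoidance. Returns
    (dna, protein).
    """
    protein_parts = []
    pos = 0
    fixed: dict = {}
    allowed: set = set()
    for seg in segments:
        if isinstance(seg, RestrictionSite):
            res = JUNCTION_RESIDUES.get(seg.name)
            if res is None:
                raise ValidationError(f"no in-frame junction residues defined for {seg.name}")
            protein_parts.append(res)
            allowed.add((3 * pos, seg.recognition))
            for k in range(len(res)):
                fixed[pos + k] = seg.recognition[3 * k : 3 * k + 3]
            pos += len(res)
        else:
            protein_parts.append(seg)
            pos += len(seg)
    protein = "".join(protein_parts)
    dna = reverse_translate(
        protein, table, forbidden=forbidden, fixed_codons=fixed, allowed_occurrences=allowed
    )
    return dna, protein


def assemble_strain_probe(
    partner_n: SequenceRecord,
    reporter: SequenceRecord,
    partner_c: SequenceRecord,
    table: CodonTable | None = None,
) -> tuple:
    """Single-chain strain probe: partnerN–reporter–partnerC in one frame.

    The full-length reporter sits between the two interaction partners;
    intramolecular binding of the partners strains the sandwiched enzyme
    and modulates its activity. The reporter must carry no secretion
    peptide — an SP annotation raises, since secretion peptides hamper the
    probes and must be stripped first.
    """
    table = table or CodonTable.from_tsv()
    if reporter.region("SP") is not None:
        raise ValidationError(
            f"reporter {reporter.id!r} still carries an SP annotation; "
            "strip the secretion peptide before assembling a strain probe"
        )
    kpn, bam = enzyme("KpnI"), enzyme("BamHI")
    hind, xho = enzyme("HindIII"), enzyme("XhoI")

    # the initiator methionine is the caller's concern (FRB-type partners
    # already start with M); the assembled protein is exactly the parts
    # plus the in-frame junction residues
    segments = [partner_n.seq, kpn, reporter.seq, bam, partner_c.seq]
    body, protein = _reverse_translate_with_junctions(segments, table, forbidden=[hind, xho, kpn, bam])
    dna = hind.recognition + body + table.stops[0] + xho.recognition
    _assert_flanks_unique(dna, hind, xho, internal_once=[(kpn, 1), (bam, 1)])

    orf_start = len(hind.recognition) + 1
    orf_end = orf_start + len(body) + 3 - 1
    layout = ProbeLayout(
        kind="strain_probe",
        parts=(
            ("partner_n", partner_n),
            ("reporter", reporter),
            ("partner_c", partner_c),
        ),
        junction_sites=(hind, kpn, bam, xho),
    )
    construct = NucleotideConstruct(
        f"{partner_n.id}-{reporter.id}-{partner_c.id}",
        dna,
        orf_start,
        orf_end,
        features=(
            ("HindIII", 1, 6),
            ("ORF", orf_start, orf_end),
            ("XhoI", len(dna) - 5, len(dna)),
        ),
    )
    assert construct.protein == protein
    return layout, construct


def propose_dissection_sites(protein: SequenceRecord, ss: str) -> list:
    """Candidate split points in coil hinges flanked by α-helices.

    ``ss`` is a per-residue H/E/C string. One candidate per maximal coil
    run with helix runs on both sides; the split falls after the lower
    median residue of the coil run.
    """
    ss = ss.upper()
    if len(ss) != len(protein.seq):
        raise ValidationError(
            f"secondary structure length {len(ss)} != protein length {len(protein.seq)}"
        )
    if set(ss) - set("HEC"):
        raise ValidationError("secondary structure must be over {H, E, C}")
    sites = []
    i = 0
    n = len(ss)
    while i < n:
        if ss[i] != "C":
            i += 1
            continue
        start = i
        while i < n and ss[i] == "C":
            i += 1
        end = i - 1  # inclusive, 0-based
        if start > 0 and end < n - 1 and ss[start - 1] == "H" and ss[end + 1] == "H":
            after = (start + end) // 2 + 1  # lower median, 1-based
            sites.append(DissectionSite(after, len(protein.seq), context="coil_between_helices"))
    return sorted(sites, key=lambda s: s.after_residue)


def assemble_pca_probe(
    reporter: SequenceRecord,
    site: DissectionSite,
    insert: SequenceRecord | None,
    table: CodonTable | None = None,
) -> tuple:
    """Split-reporter PCA probe: N-fragment / insert / C-fragment.

    With ``insert=None`` the junctions are suppressed and the assembly is
    the intact reporter (the reconstitution identity used for checking).
    """
    table = table or CodonTable.from_tsv()
    if site.protein_length != len(reporter.seq):
        raise ValidationError("dissection site was defined for a different protein length")
    n_frag = reporter.seq[: site.after_residue]
    c_frag = reporter.seq[site.after_residue :]
    kpn, bam = enzyme("KpnI"), enzyme("BamHI")
    hind, xho = enzyme("HindIII"), enzyme("XhoI")

    if insert is None:
        segments: list = [n_frag + c_frag]
        junctions: tuple = (hind, xho)
        internal = []
        parts = (("n_frag", SequenceRecord(f"{reporter.id}|n{site.n_frag_len}", n_frag)),
                 ("c_frag", SequenceRecord(f"{reporter.id}|c{site.c_frag_len}", c_frag)))
        forbidden = [hind, xho]
    else:
        segments = [n_frag, kpn, insert.seq, bam, c_frag]
        junctions = (hind, kpn, bam, xho)
        internal = [(kpn, 1), (bam, 1)]
        parts = (("n_frag", SequenceRecord(f"{reporter.id}|n{site.n_frag_len}", n_frag)),
                 ("insert", insert),
                 ("c_frag", SequenceRecord(f"{reporter.id}|c{site.c_frag_len}", c_frag)))
        forbidden = [hind, xho, kpn, bam]

    body, protein = _reverse_translate_with_junctions(segments, table, forbidden=forbidden)
    dna = hind.recognition + body + table.stops[0] + xho.recognition
    _assert_flanks_unique(dna, hind, xho, internal_once=internal)
    orf_start = 7
    orf_end = orf_start + len(body) + 3 - 1
    layout = ProbeLayout(kind="pca_probe", parts=parts, junction_sites=junctions)
    construct = NucleotideConstruct(
        f"{reporter.id}|pca{site.after_residue}",
        dna,
        orf_start,
        orf_end,
        features=(
            ("HindIII", 1, 6),
            ("ORF", orf_start, orf_end),
            ("XhoI", len(dna) - 5, len(dna)),
        ),
    )
    assert construct.protein == protein
    return layout, construct


# ---------------------------------------------------------------------------
# Exports


def construct_to_fasta(c: NucleotideConstruct, width: int = 60) -> str:
    lines = [f">{c.id}"]
    for i in range(0, len(c.dna), width):
        lines.append(c.dna[i : i + width])
    return "\n".join(lines) + "\n"


def construct_manifest(c: NucleotideConstruct) -> str:
    return json.dumps(
        {
            "id": c.id,
            "length": len(c.dna),
            "orf": [c.orf_start, c.orf_end],
            "protein_length": len(c.protein),
            "features": [list(f) for f in c.features],
        },
        indent=2,
    )
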