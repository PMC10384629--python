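"""Global pairwise alignment and single-sequence self-alignment.

Copepod-type luciferases carry two homologous catalytic domains behind a
flexible N-terminal region. Stacking the three regions of ONE sequence on
top of each other (a "single-sequence alignment") exposes positions where
the N-terminal row lacks residues that both domain rows supply — the
vacant regions that consensus-block compensation fills.

The aligner is a deterministic Needleman–Wunsch/Gotoh global aligner with
affine gaps: a gap of length L costs ``gap_open + L * gap_extend`` and
end gaps are penalized (true global alignment). Traceback ties are broken
diagonal > up > left so alignments are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .errors import ValidationError
from .seq import RegionAnnotation, SequenceRecord

log = logging.getLogger(__name__)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {c: i for i, c in enumerate(AA_ORDER)}

NEG = -1e18


@lru_cache(maxsize=None)
def _blosum62_array() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20), dtype=float)
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            out[i, j] = m[a, b]
    return out


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (both ≥ 0)."""

    matrix: np.ndarray = field(default_factory=_blosum62_array)
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (20, 20):
            raise ValidationError("substitution matrix must be 20x20 over ACDEFGHIKLMNPQRSTVWY")
        if not np.allclose(m, m.T):
            raise ValidationError("substitution matrix must be symmetric")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValidationError("gap penalties must be non-negative")
        if self.gap_open < self.gap_extend:
            raise ValidationError("gap_open must be >= gap_extend")
        object.__setattr__(self, "matrix", m)

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[_AA_INDEX[a], _AA_INDEX[b]])


def default_scheme() -> ScoringScheme:
    return ScoringScheme()


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two gapped rows of equal length plus the global alignment score."""

    row_a: str
    row_b: str
    score: float

    def __post_init__(self):
        if len(self.row_a) != len(self.row_b):
            raise ValidationError("alignment rows differ in length")
        for i, (x, y) in enumerate(zip(self.row_a, self.row_b)):
            if x == "-" and y == "-":
                raise ValidationError(f"gap/gap column at {i + 1}")

    @property
    def columns(self) -> int:
        return len(self.row_a)

    @property
    def matches(self) -> int:
        return sum(
            1 for x, y in zip(self.row_a, self.row_b) if x == y and x != "-"
        )

    @property
    def identity(self) -> float:
        """Matching columns / total alignment columns (gap columns included)."""
        return self.matches / self.columns if self.columns else 1.0


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_AA_INDEX[c] for c in seq), dtype=np.intp, count=len(seq))
    except KeyError:
        bad = next(c for c in seq if c not in _AA_INDEX)
        raise ValidationError(f"invalid protein residue {bad!r}") from None


def global_align(a: str, b: str, scheme: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps (Gotoh, end gaps penalized).

    Deterministic: score ties during traceback resolve left > up > diagonal,
    which pushes gaps toward the end of the alignment and keeps co-optimal
    residue placements contiguous (e.g. a trailing overhang stays one
    terminal gap run instead of stranding a matching residue at the far
    end).
    """
    scheme = scheme or default_scheme()
    a, b = a.upper(), b.upper()
    if not a and not b:
        return PairwiseAlignment("", "", 0.0)
    o, e = scheme.gap_open, scheme.gap_extend
    if not a:
        return PairwiseAlignment("-" * len(b), b, -(o + len(b) * e))
    if not b:
        return PairwiseAlignment(a, "-" * len(a), -(o + len(a) * e))

    ai, bi = _encode(a), _encode(b)
    n, m = len(a), len(b)
    S = scheme.matrix

    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consume a; traceback "up")
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consume b; traceback "left")
    M[0, 0] = 0.0
    X[1:, 0] = -(o + np.arange(1, n + 1) * e)
    Y[0, 1:] = -(o + np.arange(1, m + 1) * e)

    je = np.arange(m) * e  # k-1 in 0..m-1 weights for the running-max trick
    jcols = np.arange(1, m + 1) * e
    for i in range(1, n + 1):
        srow = S[ai[i - 1], bi]
        prev_best = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1])
        M[i, 1:] = prev_best + srow
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) - o - e, X[i - 1, 1:] - e
        )
        # Y via prefix running max: a gap-in-a run ending at column j began
        # after some column k-1 in state M or X of this same row.
        C = np.maximum(M[i, :-1], X[i, :-1])
        Y[i, 1:] = np.maximum.accumulate(C + je) - o - jcols

    # traceback, state priority Y > X > M (left > up > diagonal): on ties,
    # prefer placing gaps here rather than matching, so gaps collect toward
    # the end of the alignment (canonical co-optimal path)
    def best_state(i: int, j: int) -> str:
        vals = (Y[i, j], X[i, j], M[i, j])
        k = int(np.argmax(vals))  # argmax returns first max -> Y > X > M
        return "YXM"[k]

    state = best_state(n, m)
    score = float(max(M[n, m], X[n, m], Y[n, m]))
    ra: list[str] = []
    rb: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == "M":
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            i, j = i - 1, j - 1
            state = best_state(i, j)
        elif state == "X":
            ra.append(a[i - 1])
            rb.append("-")
            target = X[i, j]
            i -= 1
            if M[i, j] - o - e == target:
                state = "M"
            elif X[i, j] - e == target:
                state = "X"
            else:
                state = "Y"
        else:  # Y
            ra.append("-")
            rb.append(b[j - 1])
            target = Y[i, j]
            j -= 1
            if M[i, j] - o - e == target:
                state = "M"
            elif X[i, j] - o - e == target:
                state = "X"
            else:
                state = "Y"
    return PairwiseAlignment("".join(reversed(ra)), "".join(reversed(rb)), score)


# ---------------------------------------------------------------------------
# Repeat partitioning


@dataclass(frozen=True)
class PartitionResult:
    """Three regions of one sequence plus the split points that produced them."""

    regions: tuple  # (N-region, domain1, domain2) SequenceRecords
    boundaries: tuple  # (b1, b2): region1 = 1..b1, domain1 = b1+1..b2
    domain_identity: float


def _split(record: SequenceRecord, b1: int, b2: int) -> tuple:
    s = record.seq
    return (
        SequenceRecord(f"{record.id}|n_region", s[:b1]),
        SequenceRecord(f"{record.id}|domain1", s[b1:b2]),
        SequenceRecord(f"{record.id}|domain2", s[b2:]),
    )


def partition_repeats(
    record: SequenceRecord,
    scheme: ScoringScheme | None = None,
    boundaries: tuple | None = None,
    min_n_region: int = 20,
    max_n_fraction: float = 0.45,
    domain_balance: float = 0.15,
    coarse_step: int = 5,
    refine_radius: int = 5,
) -> PartitionResult:
    """Split a sequence into (N-region, domain1, domain2).

    With explicit ``boundaries`` = (b1, b2) the split is taken verbatim.
    Otherwise the two split points are searched so that the
    domain1-vs-domain2 global alignment score is maximal, with the
    N-region length constrained to [min_n_region, max_n_fraction * L] and
    the two domain lengths differing by at most ``domain_balance`` of
    their mean. The search scans a coarse grid then refines ±``refine_radius``.
    """
    scheme = scheme or default_scheme()
    s = record.seq
    L = len(s)
    if L < 30:
        raise ValidationError(f"sequence too short to partition ({L} < 30 residues)")

    def domain_score(b1: int, b2: int) -> float:
        return global_align(s[b1:b2], s[b2:], scheme).score

    if boundaries is not None:
        b1, b2 = boundaries
        if not (1 <= b1 < b2 < L):
            raise ValidationError(f"boundaries out of range: {boundaries}")
        regions = _split(record, b1, b2)
        ident = global_align(regions[1].seq, regions[2].seq, scheme).identity
        return PartitionResult(regions, (b1, b2), ident)

    n_max = int(max_n_fraction * L)
    if n_max < min_n_region:
        raise ValidationError("sequence too short for the configured N-region bounds")

    def b2_window(b1: int) -> range:
        rest = L - b1
        half_slack = domain_balance * (rest / 2.0) / 2.0
        centre = (b1 + L) / 2.0
        lo = max(b1 + 1, int(np.ceil(centre - half_slack)))
        hi = min(L - 1, int(np.floor(centre + half_slack)))
        return range(lo, hi + 1)

    def search(b1s, b2_filter=None) -> tuple:
        best = None
        for b1 in b1s:
            if not (min_n_region <= b1 <= n_max):
                continue
            for b2 in b2_window(b1):
                if b2_filter and not b2_filter(b2):
                    continue
                sc = domain_score(b1, b2)
                key = (-sc, b1, b2)
                if best is None or key < best[0]:
                    best = (key, b1, b2, sc)
        if best is None:
            raise ValidationError("no admissible split points found")
        return best[1], best[2]

    cb1, cb2 = search(
        range(min_n_region, n_max + 1, coarse_step),
        b2_filter=lambda b2: b2 % coarse_step == 0 or coarse_step == 1,
    )
    b1, b2 = search(
        range(max(min_n_region, cb1 - refine_radius), min(n_max, cb1 + refine_radius) + 1),
        b2_filter=lambda b2: abs(b2 - cb2) <= refine_radius + coarse_step,
    )
    regions = _split(record, b1, b2)
    ident = global_align(regions[1].seq, regions[2].seq, scheme).identity
    return PartitionResult(regions, (b1, b2), ident)


# ---------------------------------------------------------------------------
# Three-row stacking


@dataclass(frozen=True)
class RepeatAlignment:
    """Three-row self-alignment: N-region row, domain-1 row, domain-2 row."""

    rows: tuple  # three gapped strings of equal length
    source_id: str = ""

    def __post_init__(self):
        if len(self.rows) != 3:
            raise ValidationError("repeat alignment needs exactly 3 rows")
        if len({len(r) for r in self.rows}) != 1:
            raise ValidationError("rows differ in column count")
        object.__setattr__(self, "rows", tuple(self.rows))

    @property
    def columns(self) -> int:
        return len(self.rows[0])

    def ungapped(self, row: int) -> str:
        return self.rows[row].replace("-", "")

    @property
    def region_map(self) -> list:
        """Per column, a 3-tuple of 1-based residue indices (None on gaps)."""
        counters = [0, 0, 0]
        out = []
        for col in range(self.columns):
            entry = []
            for r in range(3):
                if self.rows[r][col] == "-":
                    entry.append(None)
                else:
                    counters[r] += 1
                    entry.append(counters[r])
            out.append(tuple(entry))
        return out


def _pair_consensus(row_a: str, row_b: str) -> str:
    """Column-majority string of a 2-row alignment (first row wins ties)."""
    out = []
    for x, y in zip(row_a, row_b):
        out.append(x if x != "-" else y)
    return "".join(out)


def stack_regions(
    regions: Sequence, scheme: ScoringScheme | None = None, source_id: str = ""
) -> RepeatAlignment:
    """Stack (N-region, domain1, domain2) into a three-row alignment.

    Progressive construction: the two domains (the highest-homology pair)
    are aligned first; the N-region is then aligned against the column
    majority of that pair and the pair rows are expanded to match.
    """
    scheme = scheme or default_scheme()
    seqs = [r.seq if isinstance(r, SequenceRecord) else str(r).upper() for r in regions]
    if len(seqs) != 3 or any(not s for s in seqs):
        raise ValidationError("stack_regions needs three non-empty regions")
    n_region, d1, d2 = seqs

    pair = global_align(d1, d2, scheme)
    consensus = _pair_consensus(pair.row_a, pair.row_b)
    third = global_align(n_region, consensus, scheme)

    row0, row1, row2 = [], [], []
    k = 0  # cursor into pair columns
    for cn, cc in zip(third.row_a, third.row_b):
        row0.append(cn)
        if cc == "-":
            row1.append("-")
            row2.append("-")
        else:
            row1.append(pair.row_a[k])
            row2.append(pair.row_b[k])
            k += 1
    aln = RepeatAlignment(("".join(row0), "".join(row1), "".join(row2)), source_id)
    for i, src in enumerate(seqs):
        if aln.ungapped(i) != src:
            raise ValidationError("internal error: stacked row does not ungap to its region")
    return aln


# ---------------------------------------------------------------------------
# Vacancy detection & consensus


@dataclass(frozen=True)
class VacantRegion:
    """A maximal all-gap run in one row with residues in the other rows."""

    target_row: int
    col_start: int  # 1-based inclusive alignment columns
    col_end: int
    anchor_residue: int  # ungapped target-row residue just before the run (0 if none)
    donors: dict  # row index -> ungapped residue string across the run

    def __post_init__(self):
        if self.col_start > self.col_end:
            raise ValidationError("col_start must be <= col_end")

    @property
    def length(self) -> int:
        return self.col_end - self.col_start + 1


def detect_vacant_regions(
    aln: RepeatAlignment, target_row: int = 0, min_len: int = 5
) -> list:
    """Maximal *internal* runs of ≥ min_len columns where the target row is
    all-gap and at least one other row carries residues.

    Terminal gap runs are excluded: a shorter region necessarily ends in
    gaps against the full-length domains, and that overhang reflects the
    region boundary, not a missing internal block.
    """
    if not (0 <= target_row < 3):
        raise ValidationError(f"target_row out of range: {target_row}")
    row = aln.rows[target_row]
    out = []
    ncols = aln.columns
    col = 0
    residues_before = 0
    while col < ncols:
        if row[col] != "-":
            residues_before += 1
            col += 1
            continue
        start = col
        while col < ncols and row[col] == "-":
            col += 1
        end = col - 1
        if end - start + 1 < min_len:
            continue
        if start == 0 or end == ncols - 1:
            continue  # terminal overhang, not an internal vacancy
        donors = {
            r: aln.rows[r][start : col].replace("-", "")
            for r in range(3)
            if r != target_row
        }
        if not any(donors.values()):
            continue
        out.append(
            VacantRegion(
                target_row=target_row,
                col_start=start + 1,
                col_end=end + 1,
                anchor_residue=residues_before,
                donors=donors,
            )
        )
    return out


def consensus_score(aln: RepeatAlignment, target_row: int = 0) -> float:
    """Fraction of columns where the target row matches the column majority.

    The majority is taken over non-gap residues of all three rows (ties
    broken toward the lexicographically smallest residue); columns where
    the target row is gapped count against the score.
    """
    if not (0 <= target_row < 3):
        raise ValidationError(f"target_row out of range: {target_row}")
    matches = 0
    for col in range(aln.columns):
        chars = [aln.rows[r][col] for r in range(3)]
        residues = [c for c in chars if c != "-"]
        if not residues:
            continue
        counts: dict = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        majority = min(sorted(counts), key=lambda c: (-counts[c], c))
        if chars[target_row] == majority:
            matches += 1
    return matches / aln.columns if aln.columns else 0.0


# ---------------------------------------------------------------------------
# Rendering


def render_alignment(aln: RepeatAlignment, width: int = 60, labels: Sequence | None = None) -> str:
    """Fixed-width three-story text block of the stacked alignment."""
    labels = list(labels or ("n_region", "domain1", "domain2"))
    pad = max(len(l) for l in labels) + 2
    blocks = []
    for start in range(0, aln.columns, width):
        chunk = [f"{labels[r]:<{pad}}{aln.rows[r][start:start + width]}" for r in range(3)]
        blocks.append("\n".join(chunk))
    return "\n\n".join(blocks) + "\n"


def alignment_to_fasta(aln: RepeatAlignment, labels: Sequence | None = None) -> str:
    labels = list(labels or ("n_region", "domain1", "domain2"))
    out = []
    for r in range(3):
        out.append(f">{labels[r]}")
        out.append(aln.rows[r])
    return "\n".join(out) + "\n"


def vacancies_to_records(vacancies: Sequence) -> list:
    """JSON-ready dicts for a vacancy report."""
    return [
        {
            "target_row": v.target_row,
            "col_start": v.col_start,
            "col_end": v.col_end,
            "anchor_residue": v.anchor_residue,
            "donors": {str(k): s for k, s in v.donors.items()},
        }
        for v in vacancies
    ]
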