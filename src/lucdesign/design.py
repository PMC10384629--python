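"""Compensation-block derivation and sibling-variant generation.

A vacancy in the stacked self-alignment is compensated by inserting
peptide blocks copied from the homologous donor rows. Blocks are cut
into sub-blocks immediately after flexible residues (G, I, A, V) and the
cuts define a *nested* family: fragment 1, fragments 1+2, fragments
1+2+3, ... each inserted at the same anchor, so the variant series probes
how far the compensation should extend.

Insertion semantics: a block "occupying positions 51..58" is inserted
between template residues 50 and 51 — the anchor coordinate is the
1-based position its first residue takes in the new sequence. Each
generated variant finally receives the C-terminal retention tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .align import VacantRegion
from .config import DEFAULT_RETENTION_TAG, FLEXIBLE_RESIDUES, PROTEIN_ALPHABET
from .errors import ValidationError
from .seq import SequenceRecord, append_retention_tag


# ---------------------------------------------------------------------------
# Flexible-residue splitting


def flexible_positions(block: str, flexible_set: frozenset | set | None = None) -> list:
    """1-based positions of flexible residues (candidate cut points)."""
    flex = frozenset(flexible_set) if flexible_set else FLEXIBLE_RESIDUES
    return [i for i, c in enumerate(block.upper(), start=1) if c in flex]


def split_at_flexible(
    block: str,
    flexible_set: frozenset | set | None = None,
    target_fragment_len: int = 7,
    explicit_cuts: Iterable | None = None,
) -> list:
    """Cut a peptide block into fragments after flexible residues.

    Candidate cut points sit immediately after a flexible residue. With
    ``explicit_cuts`` those positions are used verbatim (each must be a
    candidate); otherwise cuts are chosen greedily so fragment lengths
    land closest to ``target_fragment_len``. Concatenating the returned
    fragments always restores the block.
    """
    block = block.upper()
    if not block:
        raise ValidationError("empty block")
    candidates = set(flexible_positions(block, flexible_set))
    n = len(block)

    if explicit_cuts is not None:
        cuts = sorted(set(int(c) for c in explicit_cuts))
        for c in cuts:
            if c not in candidates:
                raise ValidationError(
                    f"cut position {c} is not after a flexible residue in {block!r}"
                )
        cuts = [c for c in cuts if c < n]
    else:
        cuts = []
        start = 0
        while True:
            usable = [c for c in sorted(candidates) if start < c < n]
            if not usable:
                break
            best = min(usable, key=lambda c: (abs((c - start) - target_fragment_len), c))
            if abs((best - start) - target_fragment_len) >= abs((n - start) - target_fragment_len):
                break  # keeping the tail whole is at least as close to target
            cuts.append(best)
            start = best

    frags = []
    prev = 0
    for c in cuts:
        frags.append(block[prev:c])
        prev = c
    frags.append(block[prev:])
    return frags


# ---------------------------------------------------------------------------
# Blocks and edits


@dataclass(frozen=True)
class PeptideBlock:
    """A compensation peptide and the position its first residue will take."""

    seq: str
    anchor: int  # 1-based position in the edited sequence
    source: str = "user"

    def __post_init__(self):
        if not self.seq:
            raise ValidationError("empty peptide block")
        bad = set(self.seq.upper()) - PROTEIN_ALPHABET
        if bad:
            raise ValidationError(f"block has non-protein residues: {sorted(bad)}")
        object.__setattr__(self, "seq", self.seq.upper())
        if self.anchor < 2:
            raise ValidationError("anchor must be >= 2 (insertion after at least one residue)")


@dataclass(frozen=True)
class EditOperation:
    """An insertion (at_start = anchor) or a substitution of a residue span."""

    kind: str  # {"insertion", "substitution"}
    at_start: int
    at_end: int
    payload: str
    length_change_ok: bool = False

    def __post_init__(self):
        if self.kind not in ("insertion", "substitution"):
            raise ValidationError(f"unknown edit kind {self.kind!r}")
        if not self.payload:
            raise ValidationError("empty edit payload")
        object.__setattr__(self, "payload", self.payload.upper())
        if self.kind == "substitution":
            span = self.at_end - self.at_start + 1
            if span < 1:
                raise ValidationError("substitution span must be >= 1")
            if len(self.payload) != span and not self.length_change_ok:
                raise ValidationError(
                    "substitution payload length differs from span; "
                    "set length_change_ok to allow"
                )


def derive_blocks(
    vacancy: VacantRegion,
    donor_row: int,
    cuts: Iterable | None = None,
    flexible_set: frozenset | set | None = None,
    target_fragment_len: int = 7,
) -> list:
    """Nested cumulative compensation blocks from one donor row.

    The full donor string across the vacancy is split at flexible
    residues, and the cumulative prefixes (fragment 1, 1+2, 1+2+3, ...)
    are returned, all anchored at ``vacancy.anchor_residue + 1``.
    """
    donor = vacancy.donors.get(donor_row, "")
    if not donor:
        raise ValidationError(f"donor row {donor_row} is empty across the vacancy")
    frags = split_at_flexible(donor, flexible_set, target_fragment_len, cuts)
    anchor = vacancy.anchor_residue + 1
    blocks = []
    acc = ""
    for f in frags:
        acc += f
        blocks.append(PeptideBlock(seq=acc, anchor=anchor, source=f"donor_row_{donor_row}"))
    return blocks


# ---------------------------------------------------------------------------
# Variant generation


@dataclass(frozen=True)
class DesignedVariant:
    name: str
    seq: str
    edits: tuple
    inserted_span: tuple | None  # (start, end) 1-based, in new-sequence coordinates


@dataclass(frozen=True)
class VariantSeries:
    template_id: str
    variants: tuple
    naming: dict = field(default_factory=dict)

    def __post_init__(self):
        names = [v.name for v in self.variants]
        if len(set(names)) != len(names):
            raise ValidationError("variant names must be unique")

    def __iter__(self):
        return iter(self.variants)

    def __len__(self):
        return len(self.variants)

    def get(self, name: str) -> DesignedVariant:
        for v in self.variants:
            if v.name == name:
                return v
        raise KeyError(name)


def apply_edits(template: str, edits: Sequence) -> tuple:
    """Apply edits in order; returns (sequence, inserted_span or None)."""
    seq = template
    span = None
    offset = 0  # cumulative length shift from earlier edits
    for e in edits:
        if e.kind == "substitution":
            s, t = e.at_start + offset, e.at_end + offset
            if not (1 <= s <= t <= len(seq)):
                raise ValidationError(f"substitution span {e.at_start}-{e.at_end} out of range")
            seq = seq[: s - 1] + e.payload + seq[t:]
            offset += len(e.payload) - (t - s + 1)
        else:
            a = e.at_start + offset
            if not (2 <= a <= len(seq) + 1):
                raise ValidationError(f"insertion anchor {e.at_start} out of range")
            seq = seq[: a - 1] + e.payload + seq[a - 1 :]
            span = (a, a + len(e.payload) - 1)
            offset += len(e.payload)
    return seq, span


def _resolve_names(naming, count: int, prefix: str) -> list:
    if naming is None:
        return [f"{prefix}_{i + 1}" for i in range(count)]
    if isinstance(naming, Mapping):
        try:
            return [naming[i] for i in range(count)]
        except KeyError as exc:
            raise ValidationError(f"naming map misses index {exc.args[0]}") from exc
    names = list(naming)
    if len(names) < count:
        raise ValidationError(f"naming covers {len(names)} of {count} variants")
    return names[:count]


def generate_variant_series(
    template: SequenceRecord,
    blocks: Sequence = (),
    substitutions: Sequence = (),
    naming=None,
    tag: str = DEFAULT_RETENTION_TAG,
) -> VariantSeries:
    """Generate the sibling-variant series for one template.

    Produces, in order: one variant per block (insertion into the raw
    template), one variant per bare substitution, and — when both blocks
    and substitutions are given — one variant per block applied on top of
    the substituted template. With no edits at all, the series holds just
    the tagged template. Every variant receives the retention tag
    (idempotently) after its edits.
    """
    edit_lists: list = []
    for b in blocks:
        edit_lists.append((EditOperation("insertion", b.anchor, b.anchor, b.seq),))
    for s in substitutions:
        edit_lists.append((s,))
    if blocks and substitutions:
        for s in substitutions:
            for b in blocks:
                edit_lists.append((s, EditOperation("insertion", b.anchor, b.anchor, b.seq)))
    if not edit_lists:
        edit_lists.append(())

    names = _resolve_names(naming, len(edit_lists), template.id)
    variants = []
    for name, edits in zip(names, edit_lists):
        seq, span = apply_edits(template.seq, edits)
        if tag:
            tagged = append_retention_tag(SequenceRecord(name, seq), tag, idempotent=True)
            seq = tagged.seq
        variants.append(DesignedVariant(name=name, seq=seq, edits=tuple(edits), inserted_span=span))
    return VariantSeries(template.id, tuple(variants), dict(enumerate(names)))


def combine_series(*series: VariantSeries) -> VariantSeries:
    """Merge several series over the same template into one."""
    ids = {s.template_id for s in series}
    if len(ids) != 1:
        raise ValidationError("cannot combine series from different templates")
    variants = tuple(v for s in series for v in s.variants)
    return VariantSeries(ids.pop(), variants, dict(enumerate(v.name for v in variants)))


def nested_compensation_series(
    template: SequenceRecord,
    donor1_blocks: Sequence,
    donor2_blocks: Sequence,
    substitution: EditOperation,
    naming: Sequence,
    tag: str = DEFAULT_RETENTION_TAG,
) -> VariantSeries:
    """The full sibling scheme used for the ALuc55–68 family.

    Three nested insertions with the first donor, three with the second
    donor, the bare substitution, and the first-donor insertions repeated
    on the substituted template: 3 + 3 + 1 + 3 = 10 variants, named in
    that order via ``naming``.
    """
    n1, n2 = len(donor1_blocks), len(donor2_blocks)
    names = _resolve_names(naming, 2 * n1 + n2 + 1, "variant")
    s1 = generate_variant_series(template, donor1_blocks, naming=names[:n1], tag=tag)
    s2 = generate_variant_series(template, donor2_blocks, naming=names[n1 : n1 + n2], tag=tag)
    # s3 order is insertions-on-template first (duplicates of s1, dropped
    # below), then the bare substitution, then insertions on the
    # substituted template.
    s3 = generate_variant_series(
        template,
        donor1_blocks,
        substitutions=[substitution],
        naming=[f"__drop{i}" for i in range(n1)] + list(names[n1 + n2 :]),
        tag=tag,
    )
    keep = s3.variants[n1:]
    s3 = VariantSeries(template.id, keep, dict(enumerate(v.name for v in keep)))
    return combine_series(s1, s2, s3)


def revert_variant(variant: DesignedVariant, tag: str = DEFAULT_RETENTION_TAG) -> str:
    """Undo a variant's tag and edits, recovering the template string."""
    seq = variant.seq
    if tag and seq.endswith(tag):
        seq = seq[: -len(tag)]
    for e in reversed(variant.edits):
        if e.kind == "insertion":
            if variant.inserted_span is None:
                raise ValidationError("insertion edit without inserted_span")
            s, t = variant.inserted_span
            seq = seq[: s - 1] + seq[t:]
        else:
            raise ValidationError(
                "substitution reversal needs the template span; use apply_edits forward"
            )
    return seq


# ---------------------------------------------------------------------------
# Exports


def series_to_fasta(series: VariantSeries, width: int = 60) -> str:
    from .seq import write_fasta

    return write_fasta([SequenceRecord(v.name, v.seq) for v in series.variants], width)


def series_manifest(series: VariantSeries) -> str:
    rows = []
    for v in series.variants:
        rows.append(
            {
                "name": v.name,
                "length": len(v.seq),
                "inserted_span": list(v.inserted_span) if v.inserted_span else None,
                "edits": [
                    {
                        "kind": e.kind,
                        "at_start": e.at_start,
                        "at_end": e.at_end,
                        "payload": e.payload,
                    }
                    for e in v.edits
                ],
            }
        )
    return json.dumps({"template": series.template_id, "variants": rows}, indent=2)


def blocks_to_tsv(blocks: Sequence) -> str:
    lines = ["seq\tanchor\tsource"]
    for b in blocks:
        lines.append(f"{b.seq}\t{b.anchor}\t{b.source}")
    return "\n".join(lines) + "\n"
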