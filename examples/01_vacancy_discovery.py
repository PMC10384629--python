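"""Discover the vacant region in a copepod-luciferase-like template.

A copepod luciferase is a secretion peptide, a flexible N-terminal
region, and two homologous catalytic domains. Stacking the three regions
of ONE sequence on top of each other (a single-sequence alignment)
exposes where the N-terminal region is missing a block that the domains
still carry — the vacancy the design scheme compensates.

Run:  python examples/01_vacancy_discovery.py
"""

from lucdesign import (
    FamilyRecipe,
    ScoringScheme,
    detect_vacant_regions,
    generate_synthetic_family,
    partition_repeats,
    render_alignment,
    stack_regions,
    strip_signal_peptide,
)

# a synthetic template with a planted 21-residue vacancy (seeded, text-only)
record = generate_synthetic_family(FamilyRecipe(seed=0))
print(f"template: {record.id}, {len(record.seq)} aa")

# 1. remove the secretion peptide (annotated as SP)
mature = strip_signal_peptide(record)
print(f"mature protein: {len(mature.seq)} aa")

# 2. find the internal repeat structure: N-region | domain 1 | domain 2
scheme = ScoringScheme()  # BLOSUM62, gap open 10, extend 0.5
part = partition_repeats(mature, scheme)
print(f"split points: {part.boundaries}, domain identity {part.domain_identity:.2f}")

# 3. stack the three regions and look for all-gap runs in the N-region row
aln = stack_regions(part.regions, scheme, source_id=mature.id)
print()
print(render_alignment(aln))

vacancies = detect_vacant_regions(aln, target_row=0, min_len=5)
for v in vacancies:
    print(
        f"vacancy: columns {v.col_start}-{v.col_end} "
        f"(insert after residue {v.anchor_residue})"
    )
    print(f"  donor from domain 1: {v.donors[1]}")
    print(f"  donor from domain 2: {v.donors[2]}")
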