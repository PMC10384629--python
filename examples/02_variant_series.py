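"""Generate the nested compensation-variant series for one template.

The donor peptide across the vacancy is split after flexible residues
(G, I, A, V) into sub-blocks; the cumulative prefixes give a nested
family of insertions. Combined with a short substitution, the full
sibling scheme is: 3 nested insertions from donor 1, 3 from donor 2, the
bare substitution, and the 3 donor-1 insertions repeated on the
substituted template — 10 variants, each finished with the KDEL
retention tag.

Run:  python examples/02_variant_series.py
"""

import numpy as np

from lucdesign import (
    PeptideBlock,
    SequenceRecord,
    nested_compensation_series,
    split_at_flexible,
    summarise_properties,
)
from lucdesign.design import EditOperation

DONOR1 = "GRCHSYEGDKDTGQGGIGEPI"
DONOR2 = "DRCASFADKIQKEVDYIKGLAG"

# show the flexible-residue splitting on the first donor
fragments = split_at_flexible(DONOR1)
print("donor 1 fragments:", " / ".join(fragments))

def cumulative_blocks(donor, anchor=51, cuts=None):
    frags = split_at_flexible(donor, explicit_cuts=cuts)
    out, acc = [], ""
    for f in frags:
        acc += f
        out.append(PeptideBlock(acc, anchor))
    return out

rng = np.random.default_rng(7)
AA = "ACDEFGHIKLMNPQRSTVWY"
template = SequenceRecord("template", "".join(AA[i] for i in rng.integers(0, 20, 194)))

series = nested_compensation_series(
    template,
    cumulative_blocks(DONOR1),
    cumulative_blocks(DONOR2, cuts=(7, 14)),  # curated cuts for donor 2
    EditOperation("substitution", 47, 50, "KWLP"),
    naming=[f"variant_{i:02d}" for i in range(1, 11)],
)

print(f"\n{len(series)} variants from a {len(template.seq)}-aa template:")
for v in series:
    span = f"insert {v.inserted_span[0]}-{v.inserted_span[1]}" if v.inserted_span else "substitution only"
    print(f"  {v.name}: {len(v.seq)} aa ({span})")

records = [SequenceRecord(v.name, v.seq) for v in series]
df = summarise_properties(records)
print("\nproperty table:")
print(df.to_string())
print(
    f"\nfamily means: {df['length'].mean():.1f} aa, "
    f"{df['mw_Da'].mean() / 1000:.1f} kD, pI {df['pI'].mean():.1f}"
)
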