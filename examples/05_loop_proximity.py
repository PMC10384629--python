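"""Classify loop-to-binding-site distances from atomic coordinates.

The compensated peptide blocks fold into flexible loops near the
substrate binding site; brightness tracks how closely a loop covers the
site. The metric is the minimal heavy-atom side-chain distance between a
loop residue and the methionine adjacent to the binding site, binned as
close (≤ 6.0 Å), middle (≤ 8.5 Å), or far.

Run:  python examples/05_loop_proximity.py
"""

from lucdesign import classify_loop_proximity, read_structure, sidechain_min_distance
from lucdesign.structure import proximity_report

# a miniature model: a MET "binding-site" residue and three loop residues
# at increasing distances (fixed-column PDB ATOM records)
PDB = """\
ATOM      1  CA  MET A  10      10.000  10.000  10.000  1.00  0.00           C
ATOM      2  CB  MET A  10      11.000  10.000  10.000  1.00  0.00           C
ATOM      3  SD  MET A  10      12.000  10.000  10.000  1.00  0.00           S
ATOM      4  CA  SER A  55      16.000  10.000  10.000  1.00  0.00           C
ATOM      5  OG  SER A  55      16.500  10.000  10.000  1.00  0.00           O
ATOM      6  CA  LYS A  56      19.000  10.000  10.000  1.00  0.00           C
ATOM      7  NZ  LYS A  56      20.000  10.000  10.000  1.00  0.00           N
ATOM      8  CA  GLU A  57      24.000  10.000  10.000  1.00  0.00           C
ATOM      9  OE1 GLU A  57      24.000  11.000  10.000  1.00  0.00           O
"""

model = read_structure(PDB)
met = ("A", 10)
for resnum in (55, 56, 57):
    d = sidechain_min_distance(model, met, ("A", resnum))
    print(f"MET10 ↔ residue {resnum}: {d:.2f} Å -> {classify_loop_proximity(d)}")

print()
print(
    proximity_report(
        model,
        [(f"loop_res{n}", met, ("A", n)) for n in (55, 56, 57)],
    ),
    end="",
)
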