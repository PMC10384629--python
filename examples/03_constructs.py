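"""Assemble the three cDNA construct layouts.

* expression insert: HindIII / ATG-initiated ORF / stop / XhoI
* strain probe: partner–reporter–partner in one reading frame with
  in-frame KpnI (Gly-Thr) and BamHI (Gly-Ser) junctions
* PCA probe: the reporter split at a coil hinge, insert sandwiched
  between the N- and C-fragments

Reverse translation uses murine codon usage and swaps the minimum number
of codons to remove any internal restriction sites.

Run:  python examples/03_constructs.py
"""

import numpy as np

from lucdesign import (
    DissectionSite,
    SequenceRecord,
    assemble_expression_insert,
    assemble_pca_probe,
    assemble_strain_probe,
    find_restriction_sites,
    enzyme,
)
from lucdesign.constructs import CodonTable, propose_dissection_sites

rng = np.random.default_rng(3)
AA = "ACDEFGHIKLMNPQRSTVWY"
pep = lambda n: "".join(AA[i] for i in rng.integers(0, 20, n))

table = CodonTable.from_tsv()
reporter = SequenceRecord("reporter", pep(201))

# 1. plain expression insert
expr = assemble_expression_insert(reporter, table)
print(f"expression insert: {len(expr.dna)} bp, ORF {expr.orf_start}-{expr.orf_end}")
print(f"  5' ...{expr.dna[:24]}")
sites = find_restriction_sites(expr.dna, [enzyme("HindIII"), enzyme("XhoI")])
print(f"  flanking sites: {sites}")

# 2. strain probe (FRB/FKBP-style partners around the intact reporter)
partner_n = SequenceRecord("partnerN", "M" + pep(92))
partner_c = SequenceRecord("partnerC", pep(107))
layout, strain = assemble_strain_probe(partner_n, reporter, partner_c, table)
print(f"\nstrain probe {strain.id}: {len(strain.protein)} aa fusion")
print(f"  parts: {[role for role, _ in layout.parts]}")

# 3. PCA probe: pick a dissection site in a coil hinge between helices,
#    then sandwich an interaction peptide between the fragments
ss = "H" * 100 + "CCCCC" + "H" * 52 + "CCCC" + "H" * 40  # toy secondary structure
candidates = propose_dissection_sites(reporter, ss)
print(f"\ncandidate dissection sites: {[s.after_residue for s in candidates]}")
site = DissectionSite(157, len(reporter.seq))
insert = SequenceRecord("bait", pep(25))
layout, pca = assemble_pca_probe(reporter, site, insert, table)
print(
    f"PCA probe split {site.after_residue}/{site.after_residue + 1}: "
    f"N-fragment {site.n_frag_len} aa, C-fragment {site.c_frag_len} aa"
)

# sanity: the empty-insert assembly reconstitutes the intact reporter
_, empty = assemble_pca_probe(reporter, site, None, table)
print(f"empty-insert reconstitution identical to reporter: {empty.protein == reporter.seq}")
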