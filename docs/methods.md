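# Methods

This document states the models, algorithms, parameter defaults, and the
reasoning behind the numerical choices in `lucdesign`. Everything here is
computed by the package; no empirical claim is made that the code does not
verify.

## 1. Sequence model

A template is a `SequenceRecord`: an uppercase protein string over the 20
standard residues plus non-overlapping 1-based region annotations (SP,
N_REGION, DOMAIN1, DOMAIN2, TAG). The architecture assumed throughout is

```
SP (secretion peptide) | N-region | domain 1 | domain 2
```

with the two domains homologous to each other and the N-region homologous to
the domain prefix but missing an internal block (the *vacancy*).

Physicochemical properties:

- **Molecular weight** — sum of average residue masses plus one water
  (18.0153 Da). Cross-checked against Biopython in the tests.
- **Theoretical pI** — Henderson–Hasselbalch net charge with a
  Bjellqvist-style pKa set (shipped as `data/pka_bjellqvist.json`; N-terminus
  7.5, C-terminus 3.55, K 10.0, R 12.0, H 5.98, D 4.05, E 4.45, C 9.0,
  Y 10.0), solved by bisection on [0, 14] to 1e-4. The net-charge function is
  strictly decreasing in pH, so bisection is exact up to tolerance; the tests
  verify against a brute-force grid scan.

## 2. Alignment core

`global_align` is Gotoh's three-matrix affine-gap global alignment. Defaults:
BLOSUM62, gap open 10, gap extend 0.5 — the classic protein-alignment
settings; a gap of length L costs `open + L·extend`, and **end gaps are
penalized** (the repeat-partition objective needs absolute, comparable
scores, and free end gaps would let the optimizer shrink regions for free).

Numerics: the per-row recurrence is vectorized; the "gap in the first
sequence" matrix is computed with a running-max prefix scan
(`Y[i, j] = max_k (max(M, X)[i, k] + k·e) − o − j·e`), which is
algebraically identical to the scalar recurrence but lets NumPy do the inner
loop. Scores are exact floats (sums of matrix entries and multiples of 0.5),
so traceback can test equality exactly.

**Tie-breaking.** Co-optimal alignments are canonicalized by traceback
priority *left > up > diagonal*: at exact score ties gaps are preferred over
matches, which pushes gaps toward the end of the alignment and keeps residue
placements contiguous. The alternative (diagonal-first) can strand a single
residue at the far end of a terminal overhang whenever it coincidentally
matches there, splitting one terminal gap run into a spurious "internal"
vacancy. Scores are unaffected; the tests verify optimality against an
exhaustive enumeration oracle on all sequence pairs of length ≤ 3.

`partition_repeats` chooses split points (b1, b2) maximizing the global
alignment score of the two candidate domains. Search: a coarse grid (step 5)
over b1 ∈ [20, 0.45·L] with the domain-balance constraint
|len(d1) − len(d2)| ≤ 0.15 · mean, then a ±5 refinement; ties resolve to the
lowest (b1, b2). The balance constraint encodes the biological prior that
the two catalytic domains have similar lengths; 0.45·L caps the N-region at
roughly the domain scale.

`stack_regions` builds the three-row alignment progressively: the two domains
(the highest-homology pair) are aligned first, then the N-region is aligned
against their column majority and the pair rows are expanded. Each output row
must ungap exactly to its input region (checked).

**Vacancy detection** reports maximal all-gap runs of ≥ 5 columns
(`min_len=5`; shorter runs are ordinary indel noise, and the designable
blocks of interest are 7–22 residues) in the target row where at least one
other row carries residues. Runs touching either end of the alignment are
excluded: the N-region is shorter than the domains by construction, so a
terminal overhang reflects the region boundary, not a missing internal block.

**Consensus score** = fraction of all alignment columns where the target row
equals the column majority (ties toward the lexicographically smallest
residue; gap columns in the target count as mismatches). Keeping gap columns
in the denominator makes the score monotone in coverage: compensating a
21-column vacancy on an 80-column domain alignment raises the score by
exactly 21/80 when every covered column matches.

## 3. Variant design

Donor blocks are split **after flexible residues** (G, I, A, V — the set a
designer treats as hinge-tolerant). Cut selection is greedy toward a target
fragment length of 7 (the scale of the worked-example fragments), stopping
when keeping the whole tail is at least as close to the target; explicit cut
positions override the heuristic and must land after flexible residues. For
the worked donor `GRCHSYEGDKDTGQGGIGEPI` the heuristic happens to reproduce
the curated fragments (GRCHSYEG / DKDTGQG / GIGEPI); the second donor needs
its curated cuts (7, 14) passed explicitly.

Nested blocks are the cumulative fragment prefixes, all anchored at the same
position. *Insertion semantics:* a block anchored at position 51 is inserted
between template residues 50 and 51, so its k residues occupy positions
51..50+k of the new sequence. The full sibling scheme is: the nested donor-1
insertions, the nested donor-2 insertions, the bare substitution, and the
donor-1 insertions repeated on the substituted template
(n1 + n2 + 1 + n1 variants; 10 for the 3/3-block worked example). Every
variant receives the KDEL ER-retention tag idempotently.

## 4. Constructs

Reverse translation starts from the highest-usage murine codon per residue
(`data/codon_usage_mouse.tsv`) and removes each forbidden restriction
occurrence by swapping a single codon to its next-ranked synonymous
alternative — minimal edits keep the sequence as close to codon-optimal as
possible. Junction codons (KpnI `GGTACC` = Gly-Thr, BamHI `GGATCC` =
Gly-Ser) are fixed from the start and their own occurrences whitelisted, so
site avoidance sees the final molecule rather than a pre-splice draft.
Unavoidable sites (e.g. spanning a single-codon residue like Trp) raise.

Layouts:

- **expression insert** — `HindIII · ATG-initiated ORF · stop · XhoI`; a
  leading Met is added only if the protein lacks one.
- **strain probe** — `partnerN – KpnI – reporter – BamHI – partnerC` in one
  frame. The reporter must not carry an SP annotation (secretion peptides
  break intracellular single-chain probes); the caller strips it first.
- **PCA probe** — reporter split at a `DissectionSite` (after residue k),
  insert sandwiched between the fragments with the same junctions. With no
  insert the junctions are suppressed and the assembly is the intact
  reporter — the reconstitution identity used for verification.
  `propose_dissection_sites` nominates the lower-median residue of each
  maximal coil run flanked by helices on both sides (hinges between
  α-helices are where split reporters regain activity).

After assembly the full molecule is re-checked: flanks exactly once each,
internal junctions exactly once.

## 5. Phylogenetics

Distances are `1 − identity` from the in-package global aligner (identity =
matching columns / all columns by default; a flag restricts the denominator
to residue–residue columns). Trees are Saitou–Nei neighbor joining with a
deterministic tie-break (ties in the Q criterion resolve toward the
lexicographically smallest pair of cluster keys), negative branch estimates
clamped to zero with a warning, and a closed-form three-cluster finale. NJ is
exact on additive matrices; `random_additive_tree` synthesizes ground-truth
trees (uniform branch lengths 0.1–1.0) and the tests confirm leaf-to-leaf
distances are recovered to < 1e-9 (observed ≈ 4e-16). Newick output roots at
an internal node adjacent to the smallest leaf label and is round-tripped
through dendropy in the tests.

## 6. Spectra

λmax is the wavelength of the first intensity maximum (ties break blue).
FWHM spans the two outermost half-maximum crossings, linearly interpolated
between grid points — a single envelope width per spectrum, matching how one
FWHM is reported per enzyme–substrate pair. The fraction of emission above a
cutoff uses trapezoidal integration with the cutoff point interpolated in.
On a 1-nm grid the sampled-Gaussian FWHM error is ~1e-3 nm; triangle and
uniform cases are exact. Fold changes are ratios of replicate means with
first-order error propagation (relative SDs in quadrature).

## 7. Structure metrics

A minimal fixed-column PDB ATOM reader (HETATM and hydrogens skipped,
non-standard residues skipped with a warning, malformed coordinates raise
with the line number). Loop proximity = minimal Euclidean distance between
heavy side-chain atoms of two residues (glycine falls back to Cα), classified
close ≤ 6.0 Å < middle ≤ 8.5 Å < far. The 8.5 Å middle/far cut deliberately
places an 8.0 Å loop in the middle class and an 8.7 Å loop in the far class.

## 8. Synthetic generators: realism and limits

`generate_synthetic_family` plants exact ground truth: SP random; domain 1
random (optionally with a caller-supplied donor block written in verbatim);
the N-homolog is the domain prefix with the vacancy block deleted; domain 2
is a point-mutated copy (rate ≤ 0.5). Defaults (SP 17, N-region 36, domain
80, vacancy 21 residues anchored at position 45) sit at the scale of real
copepod luciferases (~200 aa). Two identifiability safeguards:

- the deletion's flanking residues are resampled until no shifted deletion
  produces the same N-region (otherwise "the planted donor" is ill-defined);
- generators are pure functions of their recipe — the seed lives in the
  recipe, so every fixture is reproducible text.

Limits: residues are i.i.d. uniform (no composition bias, no conserved
motifs), mutation is substitution-only (no indels), and domain homology is
all-or-nothing, so recovery statistics here are an upper bound on real-data
performance. These limits are intentional: the generators exist to give the
pipeline exact, checkable ground truth, not to imitate evolution.

## 9. Open design decisions

- Junction restriction sites are retained in-frame in expressed proteins
  (GT/GS linkers); the convention is isolated in `JUNCTION_RESIDUES`.
- Consensus uses all three rows (target included) for the column majority.
- Identity denominators include gap columns by default (see §5).
- One acceptance check (family property statistics: mean 195.7 aa, 21.2 kD,
  pI 5.7) requires a published sequence listing that is not redistributable
  as text here; the test fails honestly and documents the file
  (`tests/data/aluc55_68.fasta`) a user can supply to activate it.
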