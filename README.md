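# lucdesign

A design toolkit for **artificial copepod-type luciferases**: discover the
internal repeat structure of a small secreted luciferase, find the region its
flexible N-terminus is *missing* relative to its two homologous catalytic
domains, and generate the nested family of compensation variants that fills
that vacancy — then carry the designs through to clonable cDNA constructs and
the standard downstream analyses.

## The scientific problem

Copepod luciferases (GLuc, MLuc, and the artificial ALuc series) share one
architecture: a secretion peptide (SP), a flexible N-terminal region, and two
homologous catalytic domains. Aligning the three regions of a *single*
sequence against each other (a single-sequence alignment, SSA) exposes an
internal "vacancy" — a block of residues the domains carry but the N-region
lacks. Inserting consensus peptide blocks copied from the homologous domains
into that vacancy is a productive way to create brighter, spectrally shifted
sibling enzymes. This package implements that workflow end to end:

1. **Repeat partitioning & stacking** — split a mature sequence into
   N-region / domain 1 / domain 2 by maximizing domain self-homology, stack
   the regions into a three-row alignment (affine-gap Gotoh, BLOSUM62), and
   detect internal all-gap runs in the N-region row (`lucdesign.align`).
2. **Variant design** — split the donor peptide after flexible residues
   (G, I, A, V) into sub-blocks, build the nested cumulative insertions, a
   short substitution, and the combined scheme (3 + 3 + 1 + 3 = 10 sibling
   variants), each finished with a KDEL retention tag (`lucdesign.design`).
3. **Construct assembly** — reverse-translate with murine codon usage while
   avoiding internal restriction sites; emit expression inserts
   (HindIII/ORF/stop/XhoI), single-chain strain probes
   (partner–reporter–partner with in-frame KpnI/BamHI junctions), and
   split-reporter PCA probes with hinge-region dissection sites
   (`lucdesign.constructs`).
4. **Analyses** — length/MW/theoretical-pI tables (`lucdesign.seq`),
   neighbor-joining trees with a deterministic tie-break and Newick output
   (`lucdesign.phylo`), emission-spectrum summaries (λmax, FWHM, red-tail
   fraction) and signal-to-background fold changes (`lucdesign.spectra`),
   and loop-proximity classification on atomic coordinates
   (`lucdesign.structure`).
5. **Synthetic fixtures** — seeded generators for family records with a
   planted vacancy and for sum-of-Gaussian spectra, used as ground truth
   throughout the tests (`lucdesign.fixtures`).

## Worked example

```python
from lucdesign import (FamilyRecipe, ScoringScheme, generate_synthetic_family,
                       strip_signal_peptide, partition_repeats, stack_regions,
                       detect_vacant_regions, derive_blocks)

record = generate_synthetic_family(FamilyRecipe(seed=0))   # 213-aa template
mature = strip_signal_peptide(record)                      # drop the 17-aa SP
part = partition_repeats(mature, ScoringScheme())
aln = stack_regions(part.regions, ScoringScheme())
vacancy = detect_vacant_regions(aln)[0]
blocks = derive_blocks(vacancy, donor_row=1)               # nested insertions
```

Running `python examples/01_vacancy_discovery.py` prints the stacked
alignment and the detected vacancy:

```
n_region  MNWGTQAIVNASRTECVAMCGLKKAADA---------------------NRTMIHKL---
domain1   MNWGTQAIVNASRTECVAMCGLKKAADAQMPGPSILYTYIQYQTQRIVDNRTMIHKLRVC
domain2   MNWGTQAIVNASRTECVAMCGLKKAADAQMPGPSILYTYIQYQTQRIVDNRTMIHKLRVC
...
vacancy: columns 29-49 (insert after residue 28)
  donor from domain 1: QMPGPSILYTYIQYQTQRIVD
```

The other example scripts (`examples/02`–`05`) walk through variant-series
generation, construct assembly, phylogeny + spectra, and loop proximity.

## Command line

A thin CLI wraps the library (exit codes: 0 ok, 1 usage, 2 data error):

```bash
lucdesign fixtures --seed 0 --kind family        # synthetic template FASTA
lucdesign align synthetic_family_seed0.fasta     # partition + vacancy report
lucdesign design template.fasta plan.yaml        # variant series from a plan
lucdesign props variants.fasta                   # length / MW / pI table
lucdesign construct expression protein.fasta
lucdesign tree family.fasta
lucdesign spectra spectrum.csv --cutoff 600
```

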