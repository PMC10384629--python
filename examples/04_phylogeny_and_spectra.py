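"""Place a variant family on a tree and summarise emission spectra.

Run:  python examples/04_phylogeny_and_spectra.py
"""

import numpy as np

from lucdesign import (
    ScoringScheme,
    SequenceRecord,
    SpectrumRecipe,
    fold_intensity,
    generate_synthetic_spectrum,
    identity_distance_matrix,
    is_monophyletic,
    neighbor_joining,
    spectrum_summary,
    write_newick,
)
from lucdesign.design import EditOperation, apply_edits
from lucdesign.spectra import IntensityPanel, summaries_to_tsv

rng = np.random.default_rng(11)
AA = "ACDEFGHIKLMNPQRSTVWY"
pep = lambda n: "".join(AA[i] for i in rng.integers(0, 20, n))

# --- phylogeny: variants of one template vs unrelated sequences ---------
template = pep(120)
variants = []
for i, donor in enumerate(("GRCHSYEG", "GRCHSYEGDKDTGQG", "DRCASFA")):
    seq, _ = apply_edits(template, [EditOperation("insertion", 51, 51, donor)])
    variants.append(SequenceRecord(f"variant{i + 1}", seq))
others = [SequenceRecord(f"unrelated{i + 1}", pep(120)) for i in range(3)]

dm = identity_distance_matrix(variants + others, ScoringScheme())
tree = neighbor_joining(dm)
print(write_newick(tree, precision=3))
print("variant family is a clade:", is_monophyletic(tree, [v.id for v in variants]))

# --- spectra: blue-shifted vs red-shifted synthetic emitters ------------
blue = generate_synthetic_spectrum(SpectrumRecipe(peaks=((480.0, 35.0, 1.0),)), "blue")
red = generate_synthetic_spectrum(
    SpectrumRecipe(peaks=((530.0, 45.0, 0.8), (600.0, 35.0, 0.5))), "red_shoulder"
)
summaries = [spectrum_summary(s, cutoffs=(600.0,)) for s in (blue, red)]
print()
print(summaries_to_tsv(summaries), end="")

# --- intensity panel: signal-to-background fold change ------------------
panel = IntensityPanel(
    {"with_stimulus": [9800, 10400, 10100], "background": [410, 390, 405]},
    reference="background",
)
fc = fold_intensity(panel, "with_stimulus")
print(f"\nS/B ratio: {fc.fold:.1f} ± {fc.sd:.1f}")
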