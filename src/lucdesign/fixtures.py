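"""Synthetic data generators emulating copepod-luciferase architecture.

A synthetic family record mimics the template architecture the design
pipeline expects: a secretion peptide, a flexible N-terminal region that
is homologous to the catalytic domain but misses an internal block (the
planted vacancy), and two homologous catalytic domains (the second a
mutated copy of the first). Defaults are at the scale of real copepod
luciferases (~200 residues total, ~80-residue domains, a 17-residue SP,
and a 21-residue vacancy around the 50th residue) so that the planted
ground truth matches what the alignment pipeline must recover.

Synthetic emission spectra are sums of Gaussians on a nanometer grid with
optional multiplicative noise. All generators are pure functions of
their recipe; the seed lives in the recipe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .seq import RegionAnnotation, SequenceRecord
from .spectra import EmissionSpectrum

AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FamilyRecipe:
    """Blueprint of one synthetic template record.

    ``vacancy`` = (anchor, deleted_length): the homologous block deleted
    from the N-region, anchored in full-record coordinates (deletion sits
    between residue ``anchor`` and ``anchor + 1``); must fall inside the
    N-region. ``vacancy_donor`` optionally plants a given peptide as the
    deleted block (it is written into the homologous domain positions so
    the alignment donors equal it verbatim).
    """

    seed: int = 0
    sp_len: int = 17
    n_region_len: int = 36
    domain_len: int = 80
    domain_mut_rate: float = 0.0
    vacancy: tuple | None = (45, 21)
    vacancy_donor: str | None = None

    def __post_init__(self):
        if min(self.sp_len, self.n_region_len, self.domain_len) <= 0:
            raise ValidationError("lengths must be positive")
        if not (0.0 <= self.domain_mut_rate <= 0.5):
            raise ValidationError("domain_mut_rate must be in [0, 0.5]")
        if self.vacancy is not None:
            anchor, vlen = self.vacancy
            if vlen <= 0:
                raise ValidationError("vacancy length must be positive")
            local = anchor - self.sp_len
            if not (1 <= local <= self.n_region_len):
                raise ValidationError("vacancy anchor must lie inside the N-region")
            if self.vacancy_donor is not None and len(self.vacancy_donor) != vlen:
                raise ValidationError("vacancy_donor length must equal the vacancy length")


def _random_peptide(rng: np.random.Generator, n: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, len(AA), size=n))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = []
    for c in seq:
        if rate > 0 and rng.random() < rate:
            choices = AA.replace(c, "")
            out.append(choices[rng.integers(0, len(choices))])
        else:
            out.append(c)
    return "".join(out)


def generate_synthetic_family(recipe: FamilyRecipe) -> SequenceRecord:
    """Deterministic synthetic template: SP ∥ N-region ∥ domain1 ∥ domain2.

    The N-region is a copy of the start of domain1 with the vacancy block
    deleted, so stacking the partitioned record exposes an all-gap run in
    the top row whose donor strings equal the deleted block.
    """
    rng = np.random.default_rng(recipe.seed)
    sp = _random_peptide(rng, recipe.sp_len)
    domain1 = list(_random_peptide(rng, recipe.domain_len))

    if recipe.vacancy is not None:
        anchor, vlen = recipe.vacancy
        local = anchor - recipe.sp_len  # deletion offset inside the N homolog
        n_total = recipe.n_region_len + vlen
        if n_total > recipe.domain_len:
            raise ValidationError("N-region homolog longer than the domain")
        if recipe.vacancy_donor is not None:
            donor = recipe.vacancy_donor.upper()
            domain1[local : local + vlen] = list(donor)
        # keep the planted deletion identifiable: if the residue before the
        # block equals its last residue (or the residue after equals its
        # first), a shifted deletion would produce the same N-region and the
        # ground truth would be ill-defined. Resample the flanks (which lie
        # outside any planted donor) until the position is unique.
        while domain1[local - 1] == domain1[local + vlen - 1]:
            domain1[local - 1] = AA[rng.integers(0, len(AA))]
        if local + vlen < recipe.domain_len:
            while domain1[local + vlen] == domain1[local]:
                domain1[local + vlen] = AA[rng.integers(0, len(AA))]
        n_homolog = "".join(domain1[:n_total])
        n_region = n_homolog[:local] + n_homolog[local + vlen :]
    else:
        if recipe.n_region_len > recipe.domain_len:
            raise ValidationError("N-region homolog longer than the domain")
        n_region = "".join(domain1[: recipe.n_region_len])

    domain1 = "".join(domain1)
    domain2 = _mutate(rng, domain1, recipe.domain_mut_rate)
    seq = sp + n_region + domain1 + domain2
    b1 = recipe.sp_len + recipe.n_region_len
    b2 = b1 + recipe.domain_len
    annotations = (
        RegionAnnotation("SP", 1, recipe.sp_len),
        RegionAnnotation("N_REGION", recipe.sp_len + 1, b1),
        RegionAnnotation("DOMAIN1", b1 + 1, b2),
        RegionAnnotation("DOMAIN2", b2 + 1, len(seq)),
    )
    return SequenceRecord(
        id=f"synthetic_family_seed{recipe.seed}",
        seq=seq,
        annotations=annotations,
    )


def planted_boundaries(recipe: FamilyRecipe) -> tuple:
    """The true (b1, b2) split points of a generated record."""
    b1 = recipe.sp_len + recipe.n_region_len
    return b1, b1 + recipe.domain_len


def planted_donor(recipe: FamilyRecipe) -> str | None:
    """The block deleted from the N-region (ground truth for detection)."""
    if recipe.vacancy is None:
        return None
    rec = generate_synthetic_family(recipe)
    anchor, vlen = recipe.vacancy
    local = anchor - recipe.sp_len
    d1 = rec.region("DOMAIN1")
    return rec.seq[d1.start - 1 + local : d1.start - 1 + local + vlen]


@dataclass(frozen=True)
class SpectrumRecipe:
    """Sum-of-Gaussians emission spectrum on a wavelength grid."""

    seed: int = 0
    peaks: tuple = ((500.0, 40.0, 1.0),)  # (center nm, sigma nm, amplitude)
    grid: tuple = (350.0, 750.0, 1.0)  # start, stop, step nm
    noise_sd: float = 0.0  # relative multiplicative noise

    def __post_init__(self):
        start, stop, step = self.grid
        if step <= 0 or stop <= start:
            raise ValidationError("invalid wavelength grid")
        for c, s, a in self.peaks:
            if not (start <= c <= stop):
                raise ValidationError(f"peak center {c} outside grid")
            if s <= 0:
                raise ValidationError("peak sigma must be positive")
            if a <= 0:
                raise ValidationError("peak amplitude must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


def generate_synthetic_spectrum(recipe: SpectrumRecipe, label: str = "") -> EmissionSpectrum:
    """Deterministic synthetic spectrum for a recipe (seeded noise)."""
    rng = np.random.default_rng(recipe.seed)
    start, stop, step = recipe.grid
    w = np.arange(start, stop + step / 2, step)
    y = np.zeros_like(w)
    for c, s, a in recipe.peaks:
        y += a * np.exp(-0.5 * ((w - c) / s) ** 2)
    if recipe.noise_sd > 0:
        y = y * np.clip(1.0 + recipe.noise_sd * rng.standard_normal(w.size), 0.0, None)
    return EmissionSpectrum(w, y, label or f"synthetic_seed{recipe.seed}")
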