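"""Package configuration and shipped reference data.

Defaults live in ``lucdesign/data`` and can be overridden either by
passing explicit objects to the API or by pointing a YAML/JSON config
file at replacement tables (see :func:`load_config`).

Configurable knobs
------------------
scoring scheme      BLOSUM62, gap_open 10, gap_extend 0.5
flexible residues   {G, I, A, V} — cut-point candidates for peptide blocks
retention tag       KDEL
pKa table           Bjellqvist-style values (JSON)
codon usage         murine usage fractions (TSV)
enzyme registry     restriction-site recognition sequences (TSV)
loop thresholds     close ≤ 6.0 Å < middle ≤ 8.5 Å < far
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ValidationError

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
DNA_ALPHABET = frozenset("ACGT")

#: Residues after which compensation blocks may be cut into sub-blocks.
FLEXIBLE_RESIDUES = frozenset("GIAV")

#: C-terminal endoplasmic-reticulum retention tag appended to designed variants.
DEFAULT_RETENTION_TAG = "KDEL"

#: Loop-proximity class boundaries in Angstrom (close/middle and middle/far).
DEFAULT_PROXIMITY_THRESHOLDS = (6.0, 8.5)


def _data_path(name: str) -> Path:
    return Path(resources.files("lucdesign.data").joinpath(name))  # type: ignore[arg-type]


@dataclass(frozen=True)
class PkaTable:
    """Ionizable-group pKa values for the theoretical-pI solver."""

    n_terminus: float
    c_terminus: float
    positive: Mapping[str, float]  # residue -> pKa (protonated form is +)
    negative: Mapping[str, float]  # residue -> pKa (deprotonated form is -)

    @classmethod
    def from_json(cls, path: str | Path | None = None) -> "PkaTable":
        p = Path(path) if path is not None else _data_path("pka_bjellqvist.json")
        raw = json.loads(p.read_text())
        return cls(
            n_terminus=float(raw["n_terminus"]),
            c_terminus=float(raw["c_terminus"]),
            positive={k: float(v) for k, v in raw["positive"].items()},
            negative={k: float(v) for k, v in raw["negative"].items()},
        )


_DEFAULT_PKA: PkaTable | None = None


def default_pka_table() -> PkaTable:
    global _DEFAULT_PKA
    if _DEFAULT_PKA is None:
        _DEFAULT_PKA = PkaTable.from_json()
    return _DEFAULT_PKA


def default_codon_table_path() -> Path:
    return _data_path("codon_usage_mouse.tsv")


def default_enzyme_registry_path() -> Path:
    return _data_path("enzymes.tsv")


@dataclass
class Config:
    """Bundle of resolved configuration used by the CLI."""

    gap_open: float = 10.0
    gap_extend: float = 0.5
    matrix_name: str = "BLOSUM62"
    flexible_residues: frozenset = FLEXIBLE_RESIDUES
    retention_tag: str = DEFAULT_RETENTION_TAG
    codon_table_path: Path = field(default_factory=default_codon_table_path)
    enzyme_registry_path: Path = field(default_factory=default_enzyme_registry_path)
    pka_table_path: Path | None = None
    naming: dict = field(default_factory=dict)
    proximity_thresholds: tuple = DEFAULT_PROXIMITY_THRESHOLDS
    seed: int = 0


def load_config(path: str | Path | None = None) -> Config:
    """Load a YAML or JSON config file; missing keys fall back to defaults."""
    cfg = Config()
    if path is None:
        return cfg
    p = Path(path)
    if not p.exists():
        raise ValidationError(f"config file not found: {p}")
    raw = yaml.safe_load(p.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config file must contain a mapping")
    for key, value in raw.items():
        if not hasattr(cfg, key):
            raise ValidationError(f"unknown config key: {key!r}")
        if key == "flexible_residues":
            value = frozenset(str(value).upper())
        elif key in ("codon_table_path", "enzyme_registry_path", "pka_table_path"):
            value = Path(value)
        elif key == "proximity_thresholds":
            value = tuple(float(v) for v in value)
        setattr(cfg, key, value)
    return cfg
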