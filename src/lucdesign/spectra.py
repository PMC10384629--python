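"""Bioluminescence spectrum and intensity-panel summaries.

Spectra are wavelength/intensity series (nm, arbitrary units). The
summary statistics mirror how emission tables are reported for
luciferase–substrate pairs: the peak wavelength λmax, the full width at
half maximum (FWHM, from the two outermost half-maximum crossings by
linear interpolation), and the fraction of total emission beyond a
wavelength cutoff (e.g. above 600 nm, the tissue-permeable red tail),
computed by trapezoidal integration. Intensity panels hold replicate
measurements per condition and reduce to fold changes over a reference
(signal-to-background ratios).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class EmissionSpectrum:
    wavelengths: np.ndarray  # nm, strictly increasing
    intensities: np.ndarray  # arbitrary units, >= 0
    label: str = ""

    def __post_init__(self):
        w = np.asarray(self.wavelengths, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "intensities", y)
        if w.ndim != 1 or w.size < 3:
            raise ValidationError("spectrum needs at least 3 points")
        if y.shape != w.shape:
            raise ValidationError("wavelength and intensity lengths differ")
        if np.any(np.diff(w) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if np.any(y < 0):
            raise ValidationError("intensities must be non-negative")
        if y.max() <= 0:
            raise ValidationError("flat all-zero spectrum")

    @classmethod
    def from_csv(cls, text_or_path, label: str = "", sep: str | None = None) -> "EmissionSpectrum":
        if isinstance(text_or_path, str) and "\n" in text_or_path:
            buf = io.StringIO(text_or_path)
        else:
            buf = text_or_path
        df = pd.read_csv(buf, sep=sep, engine="python")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), label)


@dataclass(frozen=True)
class SpectrumSummary:
    label: str
    lambda_max: float  # nm
    fwhm: float  # nm
    fraction_above: dict  # cutoff nm -> fraction of total emission

    def __post_init__(self):
        if self.fwhm < 0:
            raise ValidationError("FWHM must be non-negative")
        for c, f in self.fraction_above.items():
            if not (0.0 <= f <= 1.0 + 1e-12):
                raise ValidationError(f"fraction above {c} nm out of [0, 1]: {f}")


def _half_max_crossings(w: np.ndarray, y: np.ndarray, half: float) -> tuple:
    """Outermost wavelengths where the spectrum crosses half-maximum."""
    above = y >= half
    idx = np.nonzero(above)[0]
    first, last = idx[0], idx[-1]
    if first == 0:
        left = w[0]
    else:
        x0, x1, y0, y1 = w[first - 1], w[first], y[first - 1], y[first]
        left = x0 + (half - y0) * (x1 - x0) / (y1 - y0)
    if last == len(w) - 1:
        right = w[-1]
    else:
        x0, x1, y0, y1 = w[last], w[last + 1], y[last], y[last + 1]
        right = x0 + (half - y0) * (x1 - x0) / (y1 - y0)
    return left, right


def spectrum_summary(
    s: EmissionSpectrum,
    cutoffs: Sequence = (600.0,),
    smooth_window: int = 0,
) -> SpectrumSummary:
    """λmax, FWHM and red-tail fractions of one spectrum.

    λmax ties break toward the blue (lowest wavelength). FWHM spans the
    two outermost half-maximum crossings of the global peak, linearly
    interpolated between grid points; for multi-modal spectra this is a
    single envelope width, matching how one FWHM is reported per
    spectrum. ``smooth_window`` > 1 applies a centered moving average
    before analysis (off by default).
    """
    w, y = s.wavelengths, s.intensities.astype(float)
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        y = np.convolve(y, kernel, mode="same")
    peak_idx = int(np.argmax(y))  # first max -> lowest wavelength on ties
    lam = float(w[peak_idx])
    left, right = _half_max_crossings(w, y, y[peak_idx] / 2.0)
    total = float(np.trapezoid(y, w))
    if total <= 0:
        raise ValidationError("spectrum has zero integrated intensity")
    fractions = {}
    for c in cutoffs:
        c = float(c)
        if c <= w[0]:
            fractions[c] = 1.0
        elif c >= w[-1]:
            fractions[c] = 0.0
        else:
            yc = float(np.interp(c, w, y))
            mask = w > c
            ww = np.concatenate([[c], w[mask]])
            yy = np.concatenate([[yc], y[mask]])
            fractions[c] = float(np.trapezoid(yy, ww)) / total
    return SpectrumSummary(s.label, lam, right - left, fractions)


def summaries_to_tsv(summaries: Sequence) -> str:
    """Table rows in the reporting layout: λmax with FWHM in parentheses."""
    cutoffs = sorted({c for s in summaries for c in s.fraction_above})
    header = ["label", "lambda_max_fwhm"] + [f"frac_above_{int(c)}nm" for c in cutoffs]
    lines = ["\t".join(header)]
    for s in summaries:
        row = [s.label, f"{s.lambda_max:.0f} ({s.fwhm:.0f})"]
        row += [f"{s.fraction_above.get(c, float('nan')):.3f}" for c in cutoffs]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Intensity panels


@dataclass(frozen=True)
class IntensityPanel:
    """Replicate intensities per condition plus a reference condition."""

    conditions: Mapping  # label -> sequence of replicate intensities
    reference: str

    def __post_init__(self):
        conds = {str(k): np.asarray(v, dtype=float) for k, v in self.conditions.items()}
        object.__setattr__(self, "conditions", conds)
        for label, vals in conds.items():
            if vals.size < 1:
                raise ValidationError(f"condition {label!r} has no replicates")
            if np.any(vals < 0):
                raise ValidationError(f"condition {label!r} has negative intensities")
        if self.reference not in conds:
            raise ValidationError(f"reference condition {self.reference!r} absent")

    @classmethod
    def from_csv(cls, text_or_path, reference: str, sep: str | None = None) -> "IntensityPanel":
        if isinstance(text_or_path, str) and "\n" in text_or_path:
            buf = io.StringIO(text_or_path)
        else:
            buf = text_or_path
        df = pd.read_csv(buf, sep=sep, engine="python")
        cond_col, val_col = df.columns[0], df.columns[-1]
        groups = {k: g[val_col].to_list() for k, g in df.groupby(cond_col)}
        return cls(groups, reference)


@dataclass(frozen=True)
class FoldChange:
    condition: str
    reference: str
    fold: float
    sd: float  # propagated replicate s.d. of the ratio


def fold_intensity(panel: IntensityPanel, condition: str) -> FoldChange:
    """mean(condition) / mean(reference) with propagated replicate s.d.

    The s.d. combines the relative sample standard deviations of the two
    means in quadrature (first-order propagation for a ratio).
    """
    if condition not in panel.conditions:
        raise ValidationError(f"unknown condition {condition!r}")
    num = panel.conditions[condition]
    den = panel.conditions[panel.reference]
    m_num, m_den = float(num.mean()), float(den.mean())
    if m_den <= 0:
        raise ValidationError("reference mean must be positive")
    fold = m_num / m_den
    sd_num = float(num.std(ddof=1)) if num.size > 1 else 0.0
    sd_den = float(den.std(ddof=1)) if den.size > 1 else 0.0
    rel = 0.0
    if m_num > 0:
        rel = np.hypot(sd_num / m_num, sd_den / m_den)
    return FoldChange(condition, panel.reference, fold, fold * rel)
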