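"""Outlier repair for absorbance spectra.

ATR-FTIR absorbance of these powders is physically confined to [0, 1];
sporadic detector spikes (typically near 1 THz and between 4.5 and 5 THz)
fall outside that interval.  Flagged values are replaced by modified-Akima
interpolation over the spectrum's remaining in-range points; replacements
that extrapolate beyond the valid support and still land outside [0, 1]
are clipped to the nearest bound.  In-range values are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Spectrum, SpectralDataset
from .makima import makima_interpolate


@dataclass
class CleaningReport:
    """Counts of replaced values, per spectrum and overall."""

    replaced_indices: list[list[int]]
    n_spectra: int
    n_points: int

    @property
    def n_spectra_corrected(self) -> int:
        return sum(1 for idx in self.replaced_indices if idx)

    @property
    def n_values_replaced(self) -> int:
        return sum(len(idx) for idx in self.replaced_indices)

    @property
    def fraction_replaced(self) -> float:
        """Replaced values as a percentage of all data points."""
        return 100.0 * self.n_values_replaced / (self.n_spectra * self.n_points)

    def to_dict(self) -> dict:
        return {
            "n_spectra": self.n_spectra,
            "n_points": self.n_points,
            "n_spectra_corrected": self.n_spectra_corrected,
            "n_values_replaced": self.n_values_replaced,
            "fraction_replaced_pct": self.fraction_replaced,
            "replaced_indices": self.replaced_indices,
        }


def flag_out_of_range(s: Spectrum, low: float = 0.0,
                      high: float = 1.0) -> np.ndarray:
    """Indices with absorbance strictly below ``low`` or above ``high``.

    The bounds themselves are valid values.
    """
    a = s.absorbance
    return np.flatnonzero((a < low) | (a > high))


def replace_outliers(s: Spectrum, low: float = 0.0,
                     high: float = 1.0) -> tuple[Spectrum, np.ndarray]:
    """Replace out-of-range values by makima interpolation, then clip.

    The interpolation support is the spectrum's in-range points (flagged
    points are excluded).  Returns the repaired spectrum and the flagged
    indices; a spectrum with fewer than two valid points cannot be repaired.
    """
    flagged = flag_out_of_range(s, low, high)
    if flagged.size == 0:
        return s, flagged
    valid = np.setdiff1d(np.arange(s.axis.n_points), flagged)
    if valid.size < 2:
        raise ValueError(
            f"spectrum {s.meta.compound}/{s.meta.supplier} r{s.meta.replicate}: "
            f"fewer than 2 in-range values; cannot interpolate")
    w = s.axis.wavenumbers
    filled = makima_interpolate(w[valid], s.absorbance[valid], w[flagged])
    out = s.absorbance.copy()
    out[flagged] = np.clip(filled, low, high)
    return s.with_absorbance(out), flagged


def clean_dataset(ds: SpectralDataset, low: float = 0.0,
                  high: float = 1.0) -> tuple[SpectralDataset, CleaningReport]:
    """Apply :func:`replace_outliers` to every spectrum and tally the counts."""
    cleaned = []
    replaced: list[list[int]] = []
    for s in ds:
        fixed, idx = replace_outliers(s, low, high)
        cleaned.append(fixed)
        replaced.append([int(i) for i in idx])
    report = CleaningReport(replaced_indices=replaced,
                            n_spectra=ds.n_spectra,
                            n_points=ds.axis.n_points)
    return SpectralDataset(cleaned, provenance="cleaned"), report
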