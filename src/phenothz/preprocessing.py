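"""Savitzky-Golay derivative pre-processing.

The measurement model for pressed powders carries additive baseline shifts
(optical-path variation) and multiplicative gain differences between
replicates.  A first derivative removes the additive component exactly and
sharpens band structure; Savitzky-Golay estimates it stably by fitting a
local least-squares polynomial before differentiating.  The study settings
are a second-order polynomial over a seven-point window.

Derivatives are taken with respect to frequency in THz, so loadings remain
comparable across spectral ranges.  Edge samples are handled by fitting the
polynomial to the first/last full window and evaluating its derivative at
the edge positions, which keeps polynomials of degree <= polyorder exact at
the edges as well.
"""

from __future__ import annotations

from scipy.signal import savgol_filter

from .core import Spectrum, SpectralDataset


def savgol_derivative(ds: SpectralDataset, window: int = 7,
                      polyorder: int = 2, deriv: int = 1) -> SpectralDataset:
    """Savitzky-Golay derivative of every spectrum, per THz.

    ``deriv=0`` is a smoothing-only passthrough used in tests.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if ds.axis.n_points < window:
        raise ValueError(
            f"spectra have {ds.axis.n_points} points, shorter than the "
            f"{window}-point window")
    delta = ds.axis.spacing_thz
    spectra = [
        s.with_absorbance(
            savgol_filter(s.absorbance, window_length=window,
                          polyorder=polyorder, deriv=deriv, delta=delta,
                          mode="interp"))
        for s in ds
    ]
    return SpectralDataset(spectra, provenance="preprocessed")


# study default alias
savgol_first_derivative = savgol_derivative
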