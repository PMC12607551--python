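"""Frequency-wise relative standard deviation (RSD) for measurement consistency.

For a class k of n_k spectra (repeated measurements that should agree), the
statistic at frequency v is

    RSD_k(v) = sigma_k_inter(v) / mean_i sigma_i_intra

where sigma_k_inter(v) is the sample SD over the class's spectra at v, and
sigma_i_intra is the sample SD of spectrum i across all frequencies.  RSD = 1
means between-measurement variability equals the average variability within a
single spectrum; good repeatability implies RSD << 1.  The mean curve over
all classes summarizes instrument consistency per frequency.

Class definitions:

* repeatability  — successive measurements of the same sample (same standard
  within one session);
* reproducibility — measurements of the same standard across sessions, with
  duplicate measurements within a session averaged first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import Spectrum, SpectralDataset, FrequencyAxis, _group_mean

logger = logging.getLogger(__name__)


@dataclass
class RSDResult:
    axis: FrequencyAxis
    per_class: dict[tuple, np.ndarray]
    class_sizes: dict[tuple, int]

    @property
    def n_classes(self) -> int:
        return len(self.per_class)

    @property
    def mean_rsd(self) -> np.ndarray:
        """Arithmetic mean of the per-class RSD curves at each frequency."""
        return np.mean(list(self.per_class.values()), axis=0)


def intra_spectrum_sd(s: Spectrum) -> float:
    """Sample SD (n-1 denominator) of a spectrum across all frequencies."""
    return float(np.std(s.absorbance, ddof=1))


def inter_class_sd(spectra: list[Spectrum]) -> np.ndarray:
    """Per-frequency sample SD over a class's spectra (vector over v)."""
    if len(spectra) < 2:
        raise ValueError("inter-class SD needs at least 2 spectra")
    return np.std(np.vstack([s.absorbance for s in spectra]), axis=0, ddof=1)


def rsd_curve(spectra: list[Spectrum]) -> np.ndarray:
    """RSD_k(v) for one class: inter-spectrum SD over mean intra-spectrum SD."""
    inter = inter_class_sd(spectra)
    denom = float(np.mean([intra_spectrum_sd(s) for s in spectra]))
    if denom <= 0.0:
        raise ValueError("class has zero mean intra-spectrum SD "
                         "(all spectra constant); RSD undefined")
    return inter / denom


def mean_rsd(ds: SpectralDataset, class_by: str = "repeatability") -> RSDResult:
    """Per-class and mean RSD curves for a dataset.

    Classes with fewer than 2 members (e.g. a standard measured once) are
    skipped with a warning rather than failing the whole analysis.
    """
    if class_by == "repeatability":
        groups: dict[tuple, list[Spectrum]] = {}
        for s in ds:
            key = (s.meta.compound, s.meta.supplier, s.meta.session)
            groups.setdefault(key, []).append(s)
    elif class_by == "reproducibility":
        # average duplicate measurements within each session first
        per_session = _group_mean(
            ds,
            key=lambda m: (m.compound, m.supplier, m.session),
            meta_of=lambda ms: ms[0].meta,
            provenance=ds.provenance)
        groups = {}
        for s in per_session:
            groups.setdefault((s.meta.compound, s.meta.supplier), []).append(s)
    else:
        raise ValueError("class_by must be 'repeatability' or 'reproducibility'")

    per_class: dict[tuple, np.ndarray] = {}
    sizes: dict[tuple, int] = {}
    for key, members in groups.items():
        if len(members) < 2:
            logger.warning("skipping class %s with a single measurement", key)
            continue
        per_class[key] = rsd_curve(members)
        sizes[key] = len(members)
    if not per_class:
        raise ValueError("no class has 2 or more measurements")
    return RSDResult(axis=ds.axis, per_class=per_class, class_sizes=sizes)
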