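"""Data model for ATR-FTIR absorbance spectra on a shared wavenumber axis.

The instrument records absorbance on a uniform wavenumber grid
(29.98-678.92 cm^-1, 674 points, i.e. 0.90-20.35 THz).  This module holds the
axis/spectrum/dataset containers, CSV round-tripping, frequency-range
selection, and the replicate -> supplier averaging chain that reduces the
measured standards to one representative spectrum per compound.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

#: Speed of light in cm * THz (exact SI definition, 2.99792458e10 cm/s).
CM_THZ = 0.0299792458

#: Nominal instrument axis: 674 equally spaced points over 29.98-678.92 cm^-1.
INSTRUMENT_START_CM = 29.98
INSTRUMENT_END_CM = 678.92
INSTRUMENT_N_POINTS = 674

FAMILIES = ("phenolic_acid", "flavonoid")
CLASSES = (
    "hydroxybenzoic_acid",
    "hydroxycinnamic_acid",
    "flavanol",
    "flavonol",
    "anthocyanin",
    "dihydrochalcone",
    "flavone",
    "flavanone",
    "isoflavone",
)

METADATA_COLUMNS = ("compound", "family", "compound_class", "supplier",
                    "replicate", "session")


def wavenumber_to_thz(wavenumber):
    """Convert wavenumber (cm^-1) to frequency (THz): nu = c * wavenumber.

    Accepts scalars or arrays; negative wavenumbers are rejected.
    """
    w = np.asarray(wavenumber, dtype=float)
    if np.any(w < 0):
        raise ValueError("wavenumber must be non-negative")
    out = w * CM_THZ
    return float(out) if np.isscalar(wavenumber) else out


def thz_to_wavenumber(thz):
    """Inverse of :func:`wavenumber_to_thz`."""
    t = np.asarray(thz, dtype=float)
    if np.any(t < 0):
        raise ValueError("frequency must be non-negative")
    out = t / CM_THZ
    return float(out) if np.isscalar(thz) else out


@dataclass(frozen=True)
class FrequencyAxis:
    """Uniformly spaced, strictly increasing wavenumber grid (cm^-1)."""

    wavenumbers: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavenumbers, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("axis needs at least 2 points")
        d = np.diff(w)
        if np.any(d <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if np.max(np.abs(d - d[0])) > 1e-9 * max(abs(w[-1]), 1.0):
            raise ValueError("axis spacing is not uniform")

    @property
    def n_points(self) -> int:
        return self.wavenumbers.size

    @property
    def spacing(self) -> float:
        """Grid spacing in cm^-1."""
        return (self.wavenumbers[-1] - self.wavenumbers[0]) / (self.n_points - 1)

    @property
    def thz(self) -> np.ndarray:
        """The same grid expressed in THz."""
        return self.wavenumbers * CM_THZ

    @property
    def spacing_thz(self) -> float:
        return self.spacing * CM_THZ

    def __len__(self) -> int:
        return self.n_points

    def __eq__(self, other) -> bool:
        return (isinstance(other, FrequencyAxis)
                and self.wavenumbers.shape == other.wavenumbers.shape
                and bool(np.array_equal(self.wavenumbers, other.wavenumbers)))

    def __hash__(self):
        return hash((self.n_points, float(self.wavenumbers[0]),
                     float(self.wavenumbers[-1])))


def make_axis(start_wavenumber: float, end_wavenumber: float,
              n_points: int) -> FrequencyAxis:
    """Build a uniform axis from ``start`` to ``end`` (inclusive) in cm^-1."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if end_wavenumber <= start_wavenumber:
        raise ValueError("end_wavenumber must exceed start_wavenumber")
    return FrequencyAxis(np.linspace(start_wavenumber, end_wavenumber, n_points))


def instrument_axis() -> FrequencyAxis:
    """The spectrometer's native 674-point axis."""
    return make_axis(INSTRUMENT_START_CM, INSTRUMENT_END_CM, INSTRUMENT_N_POINTS)


@dataclass(frozen=True)
class SpectrumMeta:
    """Sample annotation: which standard a measurement belongs to.

    ``session`` is an opaque grouping label (acquisition date), never parsed.
    """

    compound: str
    family: str
    compound_class: str
    supplier: str
    replicate: int = 1
    session: str = "s1"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.compound_class not in CLASSES:
            raise ValueError(f"unknown class {self.compound_class!r}")


@dataclass(frozen=True)
class Spectrum:
    """One absorbance vector (dimensionless AU) on a :class:`FrequencyAxis`."""

    axis: FrequencyAxis
    absorbance: np.ndarray
    meta: SpectrumMeta

    def __post_init__(self):
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "absorbance", a)
        if a.shape != (self.axis.n_points,):
            raise ValueError("absorbance length must equal axis length")

    def with_absorbance(self, values: np.ndarray) -> "Spectrum":
        return Spectrum(self.axis, values, self.meta)


@dataclass
class SpectralDataset:
    """Ordered collection of spectra sharing one axis."""

    spectra: list[Spectrum]
    provenance: str = "raw"

    def __post_init__(self):
        if self.spectra:
            ax = self.spectra[0].axis
            for s in self.spectra:
                if s.axis != ax:
                    raise ValueError("all spectra must share the same axis")

    @property
    def axis(self) -> FrequencyAxis:
        if not self.spectra:
            raise ValueError("dataset is empty")
        return self.spectra[0].axis

    @property
    def n_spectra(self) -> int:
        return len(self.spectra)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def matrix(self) -> np.ndarray:
        """Stack absorbances into an (n_spectra, n_points) array."""
        return np.vstack([s.absorbance for s in self.spectra])

    def labels(self, attr: str) -> list:
        return [getattr(s.meta, attr) for s in self.spectra]


@dataclass(frozen=True)
class RangeSpec:
    """A closed frequency interval in THz used for range selection."""

    name: str
    fmin_thz: float
    fmax_thz: float

    def __post_init__(self):
        if not self.fmin_thz < self.fmax_thz:
            raise ValueError("fmin_thz must be below fmax_thz")


#: The study's nominal ranges: full, low-end trimmed, and both ends trimmed.
RANGES = {
    "R0": RangeSpec("R0", 0.9, 20.3),
    "R1": RangeSpec("R1", 1.5, 20.3),
    "R2": RangeSpec("R2", 5.0, 17.0),
}


def select_range(ds: SpectralDataset, r: RangeSpec) -> SpectralDataset:
    """Keep exactly the axis points whose THz value lies in [fmin, fmax].

    The interval is closed at both ends; no pre-processing happens here.
    Note the nominal full range R0 (0.9 THz) excludes the instrument's first
    point at 0.8988 THz — the nominal bound is a rounded value.
    """
    thz = ds.axis.thz
    mask = (thz >= r.fmin_thz) & (thz <= r.fmax_thz)
    if not mask.any():
        raise ValueError(f"range {r.name} selects no axis points")
    new_axis = FrequencyAxis(ds.axis.wavenumbers[mask])
    spectra = [Spectrum(new_axis, s.absorbance[mask], s.meta) for s in ds]
    return SpectralDataset(spectra, provenance=ds.provenance)


def _group_mean(ds: SpectralDataset, key: Callable[[SpectrumMeta], tuple],
                meta_of: Callable[[list[Spectrum]], SpectrumMeta],
                provenance: str) -> SpectralDataset:
    groups: dict[tuple, list[Spectrum]] = {}
    for s in ds:
        groups.setdefault(key(s.meta), []).append(s)
    out = []
    for members in groups.values():
        mean = np.mean([m.absorbance for m in members], axis=0)
        out.append(Spectrum(ds.axis, mean, meta_of(members)))
    return SpectralDataset(out, provenance=provenance)


def average_replicates(ds: SpectralDataset) -> SpectralDataset:
    """Pointwise mean over replicates: one spectrum per (compound, supplier).

    Singletons pass through unchanged.  Group order follows first occurrence.
    """
    return _group_mean(
        ds,
        key=lambda m: (m.compound, m.supplier),
        meta_of=lambda ms: replace(ms[0].meta, replicate=1, session="averaged"),
        provenance="averaged",
    )


def average_suppliers(ds: SpectralDataset) -> SpectralDataset:
    """Mean over supplier-level spectra: one representative per compound."""
    return _group_mean(
        ds,
        key=lambda m: (m.compound,),
        meta_of=lambda ms: replace(ms[0].meta, supplier="pooled",
                                   replicate=1, session="averaged"),
        provenance="averaged",
    )


# ---------------------------------------------------------------------------
# CSV exchange format: one row per spectrum; leading metadata columns, then
# one column per wavenumber named ``wn_<value>``.

def write_spectra_csv(ds: SpectralDataset, path) -> None:
    wn_cols = [f"wn_{w:.10g}" for w in ds.axis.wavenumbers]
    df = pd.DataFrame(ds.matrix(), columns=wn_cols)
    for col in reversed(METADATA_COLUMNS):
        df.insert(0, col, [getattr(s.meta, col) for s in ds])
    df.insert(0, "provenance", ds.provenance)
    df.to_csv(path, index=False, float_format="%.12g")


def read_spectra_csv(path) -> SpectralDataset:
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: empty or unparsable CSV ({exc})") from exc
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    wn_cols = [c for c in df.columns if c.startswith("wn_")]
    if not wn_cols:
        raise ValueError(f"{path}: no wavenumber columns (wn_*)")
    axis = FrequencyAxis(np.array([float(c[3:]) for c in wn_cols]))
    values = df[wn_cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        row = int(np.argwhere(np.isnan(values))[0, 0])
        raise ValueError(f"{path}: row {row} has missing absorbance values")
    spectra = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            meta = SpectrumMeta(
                compound=row.compound, family=row.family,
                compound_class=row.compound_class, supplier=row.supplier,
                replicate=int(row.replicate), session=str(row.session))
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
        spectra.append(Spectrum(axis, values[i], meta))
    provenance = str(df["provenance"].iloc[0]) if "provenance" in df.columns else "raw"
    return SpectralDataset(spectra, provenance=provenance)
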