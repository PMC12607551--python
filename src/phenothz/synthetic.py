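"""Synthetic FIR/THz spectra with the measurement structure of the study.

The generator emulates what the analysis assumes about the real data, not
the physics of any particular compound:

* the instrument's 674-point axis (29.98-678.92 cm^-1);
* the measured roster — 39 distinct phenolic compounds from up to three
  suppliers, 55 standards in all (28 phenolic acids, 27 flavonoids), with
  2-4 replicates per standard and one compound measured only once;
* compound-specific absorption bands (Lorentzian by default, Gaussian by
  config) plus a class-shared band motif with per-compound jitter, so class
  membership is spectrally detectable;
* replicate-level additive baseline offsets and multiplicative gain
  (optical-path and compaction variation in pressed powders);
* heteroscedastic noise inflated at low frequency (below 4 THz), where the
  instrument loses signal-to-noise;
* sporadic out-of-[0,1] spikes confined to the zones where the study saw
  them (around 1 THz and between 4.5 and 5 THz), with ground truth returned
  so cleaning recall is measurable.

All randomness flows from one master seed through named substreams, so the
band library, replicate effects, noise, and spikes are each independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (FrequencyAxis, Spectrum, SpectrumMeta, SpectralDataset,
                   instrument_axis)

_SUPPLIERS = {"1": "VWR", "2": "Sigma-Aldrich", "3": "Extrasynthese"}


@dataclass(frozen=True)
class RosterEntry:
    compound: str
    family: str
    compound_class: str
    suppliers: tuple[str, ...]


# The measured roster: (compound, class, supplier codes).  Codes: 1 = VWR,
# 2 = Sigma-Aldrich, 3 = Extrasynthese.  One standard = (compound, supplier).
_ROSTER_TABLE = [
    # phenolic acids / hydroxybenzoic
    ("gentisic acid", "phenolic_acid", "hydroxybenzoic_acid", "123"),
    ("ellagic acid", "phenolic_acid", "hydroxybenzoic_acid", "123"),
    ("syringic acid", "phenolic_acid", "hydroxybenzoic_acid", "123"),
    ("vanillic acid", "phenolic_acid", "hydroxybenzoic_acid", "123"),
    ("gallic acid", "phenolic_acid", "hydroxybenzoic_acid", "12"),
    ("salicylic acid", "phenolic_acid", "hydroxybenzoic_acid", "2"),
    ("4-hydroxybenzoic acid", "phenolic_acid", "hydroxybenzoic_acid", "23"),
    ("protocatechuic acid", "phenolic_acid", "hydroxybenzoic_acid", "23"),
    # phenolic acids / hydroxycinnamic
    ("caffeic acid", "phenolic_acid", "hydroxycinnamic_acid", "123"),
    ("chlorogenic acid", "phenolic_acid", "hydroxycinnamic_acid", "12"),
    ("sinapic acid", "phenolic_acid", "hydroxycinnamic_acid", "2"),
    ("ferulic acid", "phenolic_acid", "hydroxycinnamic_acid", "2"),
    ("2-coumaric acid", "phenolic_acid", "hydroxycinnamic_acid", "23"),
    # flavonoids / flavanol
    ("catechin", "flavonoid", "flavanol", "3"),
    ("catechin hydrate", "flavonoid", "flavanol", "1"),
    ("epicatechin", "flavonoid", "flavanol", "3"),
    ("epigallocatechin", "flavonoid", "flavanol", "3"),
    ("epicatechin gallate", "flavonoid", "flavanol", "3"),
    ("epigallocatechin gallate", "flavonoid", "flavanol", "3"),
    # flavonoids / flavonol
    ("quercetin anhydrous", "flavonoid", "flavonol", "2"),
    ("quercetin dihydrate", "flavonoid", "flavonol", "1"),
    ("quercetin-3-b-D-glucoside", "flavonoid", "flavonol", "2"),
    ("quercetin", "flavonoid", "flavonol", "1"),
    ("rutin hydrate", "flavonoid", "flavonol", "2"),
    ("rutin", "flavonoid", "flavonol", "3"),
    ("kaempferol", "flavonoid", "flavonol", "2"),
    ("myricetin", "flavonoid", "flavonol", "2"),
    ("isorhamnetin", "flavonoid", "flavonol", "3"),
    # flavonoids / anthocyanin
    ("cyanidin chloride", "flavonoid", "anthocyanin", "3"),
    ("keracyanin chloride", "flavonoid", "anthocyanin", "3"),
    ("kuromanin chloride", "flavonoid", "anthocyanin", "3"),
    ("myrtillin chloride", "flavonoid", "anthocyanin", "3"),
    # flavonoids / dihydrochalcone
    ("phloretin", "flavonoid", "dihydrochalcone", "2"),
    ("phlorizin", "flavonoid", "dihydrochalcone", "2"),
    # flavonoids / flavone
    ("luteolin", "flavonoid", "flavone", "13"),
    # flavonoids / flavanone
    ("eriodictyol", "flavonoid", "flavanone", "2"),
    ("bavachinin", "flavonoid", "flavanone", "3"),
    # flavonoids / isoflavone
    ("genistein", "flavonoid", "isoflavone", "3"),
    ("daidzein", "flavonoid", "isoflavone", "3"),
]


def default_roster() -> list[RosterEntry]:
    """The study roster: 39 compounds, 55 (compound, supplier) standards."""
    return [
        RosterEntry(name, family, cls,
                    tuple(_SUPPLIERS[c] for c in codes))
        for name, family, cls, codes in _ROSTER_TABLE
    ]


@dataclass(frozen=True)
class BandSpec:
    """One absorption band: center/width in THz, amplitude in AU."""

    center_thz: float
    width_thz: float   # full width at half maximum
    amplitude: float
    shape: str = "lorentzian"

    def __post_init__(self):
        if self.width_thz <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be non-negative")

    def profile(self, thz: np.ndarray) -> np.ndarray:
        if self.shape == "lorentzian":
            hw = self.width_thz / 2.0
            return self.amplitude * hw ** 2 / ((thz - self.center_thz) ** 2 + hw ** 2)
        if self.shape == "gaussian":
            return self.amplitude * np.exp(
                -4.0 * np.log(2.0) * (thz - self.center_thz) ** 2
                / self.width_thz ** 2)
        raise ValueError(f"unknown band shape {self.shape!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults mirror the study's measurement structure."""

    seed: int = 0
    band_shape: str = "lorentzian"
    # replicates per standard (uniform draw), with one singleton compound
    replicates_min: int = 2
    replicates_max: int = 4
    singleton_compound: str = "cyanidin chloride"
    # compound-specific bands
    n_compound_bands: tuple[int, int] = (3, 8)
    band_center_span_thz: tuple[float, float] = (1.0, 19.5)
    band_width_span_thz: tuple[float, float] = (0.2, 1.0)
    band_amplitude_span: tuple[float, float] = (0.05, 0.25)
    # class- and family-shared motif bands (make group membership spectrally
    # real: discrimination at both taxonomy levels is what the analysis tests)
    n_motif_bands: int = 3
    n_family_motif_bands: int = 2
    motif_amplitude: float = 0.15
    motif_width_span_thz: tuple[float, float] = (0.2, 0.4)
    motif_jitter_thz: float = 0.05
    motif_min_separation_thz: float = 0.5
    # replicate-level measurement effects
    baseline_offset_sd: float = 0.02
    gain_sd: float = 0.05
    session_offset_sd: float = 0.03
    # heteroscedastic noise: sd = noise_sd, inflated below the knee
    noise_sd: float = 0.005
    noise_inflation: float = 5.0
    noise_knee_thz: float = 4.0
    baseline_level: float = 0.2
    # spike contamination
    spike_probability: float = 0.3
    spikes_max_per_spectrum: int = 7
    spike_zones_thz: tuple[tuple[float, float], ...] = ((0.9, 1.1), (4.5, 5.0))
    spike_low_span: tuple[float, float] = (-0.4, -0.02)
    spike_high_span: tuple[float, float] = (1.02, 1.4)


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("library", "replicates", "noise", "spikes")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def make_compound_library(config: SyntheticConfig,
                          seed: int | None = None,
                          roster: list[RosterEntry] | None = None
                          ) -> dict[str, list[BandSpec]]:
    """Draw each compound's band set: own bands + its class's jittered motif.

    Motif centers are placed on a randomly permuted uniform grid over the
    band-center span, so centers belonging to different classes are always
    separated by at least one grid slot (minus the within-slot jitter) and
    classes never share a motif band.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    roster = default_roster() if roster is None else roster
    lo, hi = config.band_center_span_thz

    classes: list[str] = []
    families: list[str] = []
    for e in roster:
        if e.compound_class not in classes:
            classes.append(e.compound_class)
        if e.family not in families:
            families.append(e.family)
    # one grid slot per motif band: classes first, then families
    counts = ([config.n_motif_bands] * len(classes)
              + [config.n_family_motif_bands] * len(families))
    n_slots = sum(counts)
    slot_width = (hi - lo) / n_slots
    slot_jitter = min(0.15 * slot_width,
                      max(0.0, (slot_width - config.motif_min_separation_thz) / 2))
    grid = lo + (np.arange(n_slots) + 0.5) * slot_width
    grid = grid + rng.uniform(-slot_jitter, slot_jitter, n_slots)
    order = rng.permutation(n_slots)
    motif_bands: dict[str, list[BandSpec]] = {}
    start = 0
    for group, cnt in zip(classes + families, counts):
        # a motif band's width is a property of the motif, shared by every
        # compound of the group; only its center is jittered per compound
        motif_bands[group] = [
            BandSpec(center_thz=float(c),
                     width_thz=float(rng.uniform(*config.motif_width_span_thz)),
                     amplitude=config.motif_amplitude,
                     shape=config.band_shape)
            for c in grid[np.sort(order[start:start + cnt])]
        ]
        start += cnt

    library: dict[str, list[BandSpec]] = {}
    for e in roster:
        bands = []
        shared = motif_bands[e.compound_class] + motif_bands[e.family]
        for b in shared:
            bands.append(BandSpec(
                center_thz=float(b.center_thz
                                 + rng.normal(0, config.motif_jitter_thz)),
                width_thz=b.width_thz,
                amplitude=b.amplitude,
                shape=b.shape))
        n_own = int(rng.integers(config.n_compound_bands[0],
                                 config.n_compound_bands[1] + 1))
        for _ in range(n_own):
            bands.append(BandSpec(
                center_thz=float(rng.uniform(lo, hi)),
                width_thz=float(rng.uniform(*config.band_width_span_thz)),
                amplitude=float(rng.uniform(*config.band_amplitude_span)),
                shape=config.band_shape))
        library[e.compound] = bands
    return library


def band_sum(bands: list[BandSpec], axis: FrequencyAxis) -> np.ndarray:
    thz = axis.thz
    total = np.zeros(axis.n_points)
    for b in bands:
        total += b.profile(thz)
    return total


def noise_sigma(config: SyntheticConfig, axis: FrequencyAxis) -> np.ndarray:
    """Per-frequency noise SD: inflated below the low-frequency knee."""
    sigma = np.full(axis.n_points, config.noise_sd)
    sigma[axis.thz < config.noise_knee_thz] *= config.noise_inflation
    return sigma


def simulate_spectrum(bands: list[BandSpec], axis: FrequencyAxis,
                      meta: SpectrumMeta, config: SyntheticConfig,
                      rng: np.random.Generator,
                      session_offset: float = 0.0) -> Spectrum:
    """One replicate measurement: baseline + gain * bands + noise.

    A(v) = baseline_level + b + g * sum_bands(v) + eps(v) with b ~
    N(0, offset SD) and g ~ N(1, gain SD) drawn per replicate and eps(v)
    heteroscedastic.  Values are NOT clipped; out-of-range contamination is
    injected only by :func:`inject_spikes`.
    """
    b = float(rng.normal(0.0, config.baseline_offset_sd))
    g = float(rng.normal(1.0, config.gain_sd))
    eps = rng.normal(0.0, 1.0, axis.n_points) * noise_sigma(config, axis)
    values = config.baseline_level + b + session_offset + g * band_sum(bands, axis) + eps
    return Spectrum(axis, values, meta)


def simulate_dataset(config: SyntheticConfig,
                     roster: list[RosterEntry] | None = None,
                     axis: FrequencyAxis | None = None) -> SpectralDataset:
    """Full roster x replicates on the instrument axis; spike-free."""
    axis = instrument_axis() if axis is None else axis
    roster = default_roster() if roster is None else roster
    streams = _substreams(config.seed)
    library = make_compound_library(config, roster=roster)
    rep_rng, noise_rng = streams["replicates"], streams["noise"]

    spectra = []
    for e in roster:
        for supplier in e.suppliers:
            if e.compound == config.singleton_compound:
                n_rep = 1
            else:
                n_rep = int(rep_rng.integers(config.replicates_min,
                                             config.replicates_max + 1))
            for r in range(1, n_rep + 1):
                meta = SpectrumMeta(compound=e.compound, family=e.family,
                                    compound_class=e.compound_class,
                                    supplier=supplier, replicate=r)
                spectra.append(simulate_spectrum(
                    library[e.compound], axis, meta, config, noise_rng))
    return SpectralDataset(spectra, provenance="raw")


def simulate_reproducibility_dataset(
        config: SyntheticConfig,
        compounds: tuple[str, ...] = ("ferulic acid", "4-hydroxybenzoic acid",
                                      "catechin hydrate", "quercetin"),
        n_sessions: int = 5, duplicates: int = 2) -> SpectralDataset:
    """Time-reproducibility fixture: selected standards measured in duplicate
    over several weekly sessions, each session with its own baseline offset."""
    axis = instrument_axis()
    roster = {e.compound: e for e in default_roster()}
    streams = _substreams(config.seed)
    library = make_compound_library(config)
    rep_rng, noise_rng = streams["replicates"], streams["noise"]

    spectra = []
    for name in compounds:
        e = roster[name]
        supplier = e.suppliers[0]
        for s in range(1, n_sessions + 1):
            session_offset = float(rep_rng.normal(0.0, config.session_offset_sd))
            for r in range(1, duplicates + 1):
                meta = SpectrumMeta(compound=e.compound, family=e.family,
                                    compound_class=e.compound_class,
                                    supplier=supplier, replicate=r,
                                    session=f"week{s}")
                spectra.append(simulate_spectrum(
                    library[e.compound], axis, meta, config, noise_rng,
                    session_offset=session_offset))
    return SpectralDataset(spectra, provenance="raw")


def spike_zone_indices(config: SyntheticConfig,
                       axis: FrequencyAxis) -> np.ndarray:
    thz = axis.thz
    mask = np.zeros(axis.n_points, dtype=bool)
    for lo, hi in config.spike_zones_thz:
        mask |= (thz >= lo) & (thz <= hi)
    return np.flatnonzero(mask)


def inject_spikes(ds: SpectralDataset, config: SyntheticConfig,
                  seed: int | None = None, n_total: int | None = None
                  ) -> tuple[SpectralDataset, list[tuple[int, int]]]:
    """Contaminate spectra with out-of-[0,1] values inside the spike zones.

    By default each spectrum is hit with ``spike_probability``; with
    ``n_total`` exactly that many (spectrum, index) cells are spiked,
    useful for calibrated contamination experiments.  Returns the
    contaminated dataset and the ground-truth spike map.
    """
    if seed is None:
        seed = config.seed
    rng = _substreams(seed)["spikes"]
    zone = spike_zone_indices(config, ds.axis)
    if zone.size == 0:
        raise ValueError("spike zones select no axis points")

    matrix = ds.matrix()
    truth: list[tuple[int, int]] = []
    if n_total is not None:
        cells = [(i, j) for i in range(ds.n_spectra) for j in zone]
        pick = rng.choice(len(cells), size=n_total, replace=False)
        targets = [cells[c] for c in pick]
    else:
        targets = []
        for i in range(ds.n_spectra):
            if rng.random() < config.spike_probability:
                count = int(rng.integers(1, config.spikes_max_per_spectrum + 1))
                count = min(count, zone.size)
                for j in rng.choice(zone, size=count, replace=False):
                    targets.append((i, int(j)))
    for i, j in targets:
        if rng.random() < 0.5:
            matrix[i, j] = rng.uniform(*config.spike_low_span)
        else:
            matrix[i, j] = rng.uniform(*config.spike_high_span)
        truth.append((int(i), int(j)))

    spectra = [s.with_absorbance(matrix[i]) for i, s in enumerate(ds.spectra)]
    return SpectralDataset(spectra, provenance=ds.provenance), truth
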