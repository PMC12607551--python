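import numpy as np
import pytest

from phenothz.core import (FrequencyAxis, Spectrum, SpectrumMeta,
                           SpectralDataset, make_axis)
from phenothz.synthetic import SyntheticConfig, simulate_dataset, inject_spikes
from phenothz import clean_dataset, average_replicates, average_suppliers


def meta(compound="gallic acid", family="phenolic_acid",
         compound_class="hydroxybenzoic_acid", supplier="VWR",
         replicate=1, session="s1") -> SpectrumMeta:
    return SpectrumMeta(compound, family, compound_class, supplier,
                        replicate, session)


def spectrum(values, axis=None, **meta_kwargs) -> Spectrum:
    values = np.asarray(values, dtype=float)
    if axis is None:
        axis = make_axis(1.0, float(len(values)), len(values))
    return Spectrum(axis, values, meta(**meta_kwargs))


@pytest.fixture(scope="session")
def sim_config():
    return SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def raw_dataset(sim_config):
    """Default synthetic roster dataset with spike contamination."""
    ds = simulate_dataset(sim_config)
    ds, truth = inject_spikes(ds, sim_config)
    ds.spike_truth = truth
    return ds


@pytest.fixture(scope="session")
def cleaned_dataset(raw_dataset):
    ds, _ = clean_dataset(raw_dataset)
    return ds


@pytest.fixture(scope="session")
def compound_dataset(cleaned_dataset):
    """One representative spectrum per compound (39 spectra)."""
    return average_suppliers(average_replicates(cleaned_dataset))
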