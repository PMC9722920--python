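"""Shared fixtures: small synthetic studies generated at test time."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from milkguard.data_model_io import CompositionalProfile, SampleRecord, SampleSet
from milkguard.synthetic_data import default_generator_config, generate_study


@pytest.fixture(scope="session")
def default_study():
    """The full default two-batch study (training 657, crossval 155)."""
    return generate_study(default_generator_config(seed=7))


@pytest.fixture(scope="session")
def small_config():
    """A reduced study: fewer normals/spikes, compositional-only."""
    return default_generator_config(
        seed=3, n_normal_training=80, n_normal_crossval=30,
        n_spikes_per_adulterant=5, with_spectra=False)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


def make_record(values, sample_id="S1", label="normal",
                date=dt.date(2020, 6, 1), **kw) -> SampleRecord:
    return SampleRecord(sample_id=sample_id, date=date, label=label,
                        profile=CompositionalProfile.from_array(values), **kw)


@pytest.fixture
def plain_samples():
    """Three hand-built records (two normal, one spiked)."""
    base = np.array([3.8, 3.2, 8.7, 12.5, 4.8, 1.030, 0.525, 16.0])
    return SampleSet([
        make_record(base, "A", "normal"),
        make_record(base + 0.1, "B", "normal"),
        make_record(base + 0.3, "C", "spiked", adulterant="melamine",
                    concentration=0.1),
    ])
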