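"""Shared fixtures: synthetic recordings and prepared pulse series."""

import numpy as np
import pytest

from ppginv import (
    PulseSeries,
    SimulationPlan,
    generate_recording,
    prepare,
)


@pytest.fixture
def make_plan():
    """Factory for simulation plans with study-protocol defaults."""

    def _make(seed=0, **overrides):
        return SimulationPlan(seed=seed, **overrides)

    return _make


@pytest.fixture
def make_prepared(make_plan):
    """Generate a recording and return (prepared IR series, ground truth)."""

    def _make(seed=0, **overrides):
        rec, truth = generate_recording(make_plan(seed=seed, **overrides))
        return prepare(rec, "ir"), truth

    return _make


@pytest.fixture
def make_series():
    """Wrap a bare array as a PulseSeries (padded if below the minimum)."""

    def _make(values, sampling_rate=800.0):
        return PulseSeries(
            values=np.asarray(values, dtype=float),
            sampling_rate=sampling_rate,
            channel="ir",
            source_id="test",
        )

    return _make
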