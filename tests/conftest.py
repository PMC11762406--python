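import numpy as np
import pytest

from rhythmpower import simulate


@pytest.fixture
def null_config():
    """One arrhythmic protein, one participant, defaults otherwise."""
    return simulate.CohortConfig(
        rhythm_specs=(simulate.RhythmSpec("NULL1"),),
        n_participants=1,
        noise_sd=1.0,
        seed=42,
    )


@pytest.fixture
def make_rhythmic_config():
    """Factory for a cohort with one planted 24 h rhythm plus optional nulls."""

    def _make(amplitude=0.3, period=24.0, acrophase=5.0, n_nulls=0, seed=0, **kwargs):
        specs = [
            simulate.RhythmSpec(
                "RHY1",
                (simulate.RhythmComponent(period, amplitude, acrophase),),
            )
        ]
        specs += [simulate.RhythmSpec(f"NULL{i}") for i in range(n_nulls)]
        return simulate.CohortConfig(rhythm_specs=tuple(specs), seed=seed, **kwargs)

    return _make


@pytest.fixture
def times_2h_30h():
    """The default sampling design: 16 two-hourly DLMO-hour points over 30 h."""
    return np.arange(0.0, 31.0, 2.0)
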