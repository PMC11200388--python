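import pytest

from stepbench import NoiseSpec, SensorSettings, generate_impulse_train, generate_optical_trace


@pytest.fixture
def clean():
    return NoiseSpec()


@pytest.fixture
def permissive_settings():
    """Settings that count every impulse of a clean regular train."""
    return SensorSettings(threshold_mg=480.0, debounce_steps=2, debounce_time_ms=2480.0)


@pytest.fixture
def regular_train_60():
    """Clean 60 steps/min train, 60 s: 60 impulses at 1.1 g, 1 s apart."""
    return generate_impulse_train(60, 60.0)


@pytest.fixture
def clean_trace_30():
    """Clean 30 steps/min optical trace, 60 s: 30 steps, 2 s apart."""
    return generate_optical_trace(30, 60.0)
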