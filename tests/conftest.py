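import pytest

import preictal as p


@pytest.fixture(scope="session")
def default_spec():
    return p.SyntheticSpec(seed=7)


@pytest.fixture(scope="session")
def seizure_record(default_spec):
    """Default synthetic seizure record (precursor 50 s, onset 80 s)."""
    return p.gen_seizure_record(default_spec)


@pytest.fixture(scope="session")
def seizure_decimated(seizure_record):
    rec, ann = seizure_record
    return p.lowpass_decimate(rec), ann


@pytest.fixture(scope="session")
def stationary_decimated():
    """Precursor-free record: baseline statistics throughout."""
    rec, ann = p.gen_seizure_record(p.stationary_spec(seed=11))
    return p.lowpass_decimate(rec), ann
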