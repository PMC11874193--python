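import warnings

import numpy as np
import pytest

from isochron import ParadigmSpec, SubjectParams, synth_subject
from isochron.preprocess import segment_sequences

# the ITPC zero-coefficient warning and pandas future warnings are noise
# in bulk simulation tests
warnings.filterwarnings("ignore", message="zero coefficients")


def noiseless_params(**kw) -> SubjectParams:
    """Evoked-only subject with every stochastic component switched off."""
    defaults = dict(evoked_amp=-5.0, latency_jitter_sd=0.0, entrain_amp=0.0,
                    entrain_amp_theta=0.0, alpha_amp=0.0,
                    aperiodic_offset=-np.inf)
    defaults.update(kw)
    return SubjectParams(**defaults)


@pytest.fixture(scope="session")
def quiet_recording():
    """Small noiseless evoked-only recording + events (6 sequences, 500 Hz)."""
    spec = ParadigmSpec(n_sequences=6)
    rec, events = synth_subject(spec, noiseless_params(), fs=500.0, seed=11)
    return spec, rec, events


@pytest.fixture(scope="session")
def quiet_epochs(quiet_recording):
    """Raw (unfiltered) sequence epochs of the noiseless recording."""
    spec, rec, events = quiet_recording
    return segment_sequences(rec, events)
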