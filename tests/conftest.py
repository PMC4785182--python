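import numpy as np
import pytest

from stepnet import connectivity as conn
from stepnet import preprocess as pp
from stepnet import synthetic as syn
from stepnet.params import LIMBS, PipelineParams
from stepnet.recording import Recording


@pytest.fixture(scope="session")
def params():
    return PipelineParams()


@pytest.fixture(scope="session")
def small_dataset(params):
    """120 s of the default stride-modulated 7-source network (sources only)."""
    spec = syn.default_network_spec()
    events = syn.generate_events(spec.cadence_per_min, 120.0, LIMBS,
                                 phase_jitter_sd=0.01, seed=101)
    src = syn.simulate_source_network(spec, events, params.fs_raw, 120.0,
                                      seed=102)
    return src


@pytest.fixture(scope="session")
def conn_epochs(params, small_dataset):
    """Connectivity-branch epochs (trials, 7, L) at 128 Hz from the fixture."""
    src = small_dataset
    rec = Recording(data=src.sources, fs=src.fs,
                    channel_labels=list(src.spec.source_names))
    ds = pp.downsample(rec, params.fs_mvar)
    ds = pp.piecewise_detrend(ds, params.detrend_window, params.detrend_step)
    return conn.epoch_for_connectivity(ds.data, ds.fs, src.events, params)


@pytest.fixture(scope="session")
def dtf_tensor(params, conn_epochs):
    """Sliding-window DTF (no bootstrap) on the session fixture."""
    return conn.sliding_window_dtf(conn_epochs, params.fs_mvar, order=3,
                                   params=params, n_boot=0)
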