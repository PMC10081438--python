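import numpy as np
import pytest

from metastate import SynthConfig, generate_feature_stream, generate_raw_signals
from metastate.components import ActivationSeries


@pytest.fixture(scope="session")
def feature_rec():
    """Default-condition feature stream (4 days) shared across tests."""
    cfg = SynthConfig(duration=4 * 86400.0, seed=5)
    return generate_feature_stream(cfg)


@pytest.fixture(scope="session")
def feature_acts(feature_rec):
    return ActivationSeries(feature_rec.truth.activations, feature_rec.grid)


@pytest.fixture(scope="session")
def day_index(feature_rec):
    n = feature_rec.grid.n_windows
    wpd = int(round(86400.0 / feature_rec.grid.window_len))
    return np.minimum(np.arange(n) // wpd, 3)


@pytest.fixture(scope="session")
def raw_rec():
    """Raw tier with 8 planted parcels over 40 channels, unit noise."""
    cfg = SynthConfig(n_channels=40, n_parcels=8, fs=200.0, duration=300.0,
                      noise_sd=1.0, seed=7)
    return generate_raw_signals(cfg)


def boundary_f1(pred, truth, tol=2):
    """Boundary-level F1 between two interval lists at +-tol windows."""
    pb = [b for s, e in pred for b in (s, e)]
    tb = [b for s, e in truth for b in (s, e)]
    if not pb or not tb:
        return 0.0
    tp = sum(any(abs(b - t) <= tol for t in tb) for b in pb)
    tp2 = sum(any(abs(b - t) <= tol for t in pb) for b in tb)
    prec, rec = tp / len(pb), tp2 / len(tb)
    return 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
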