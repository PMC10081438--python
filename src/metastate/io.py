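"""Standard-format I/O: HDF5 for arrays/models, CSV for events and labels.

Raw multichannel signals are stored as HDF5 (``signal`` channels x samples,
with ``fs`` attribute) or read from EDF through :mod:`mne` when available.
The coherence tensor, parcel series, component set and Koopman model have
dedicated HDF5 layouts; events, labels and heart rate are plain CSV.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .bands import WindowGrid
from .coherence import CoherenceTensor
from .components import NetworkComponentSet
from .koopman import KoopmanEmbedding

__all__ = [
    "write_signals_h5", "read_signals", "read_events_csv", "read_label_intervals_csv",
    "read_heart_rate_csv", "write_coherence_h5", "read_coherence_h5",
    "write_components_h5", "read_components_h5", "write_koopman_h5", "read_koopman_h5",
    "labels_per_window",
]


def write_signals_h5(path, signal, fs: float):
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=np.asarray(signal))
        f.attrs["fs"] = float(fs)


def read_signals(path):
    """Read (signal, fs) from HDF5 (.h5/.hdf5) or EDF (.edf, needs mne)."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            return f["signal"][:], float(f.attrs["fs"])
    if path.endswith(".edf"):
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return raw.get_data() * 1e6, float(raw.info["sfreq"])  # volts -> uV
    raise ValueError(f"unsupported signal format: {path}")


def read_events_csv(path):
    """Events CSV with columns start_s, end_s[, label] -> list of (start, end)."""
    df = pd.read_csv(path)
    return list(zip(df["start_s"].astype(float), df["end_s"].astype(float)))


def read_label_intervals_csv(path):
    """Label intervals CSV with columns start_s, end_s, category."""
    df = pd.read_csv(path)
    return [(float(r.start_s), float(r.end_s), str(r.category)) for r in df.itertuples()]


def labels_per_window(intervals, grid: WindowGrid, fill: str = "unlabeled"):
    """Snap labeled intervals onto the window grid (floor convention)."""
    out = np.full(grid.n_windows, fill, dtype=object)
    centers = grid.start_times
    for start, end, cat in intervals:
        out[(centers >= start) & (centers < end)] = cat
    return out.astype(str)


def read_heart_rate_csv(path, grid: WindowGrid):
    """Heart-rate CSV (window_start_s, bpm) aligned onto the grid (NaN gaps)."""
    df = pd.read_csv(path)
    out = np.full(grid.n_windows, np.nan)
    idx = np.searchsorted(grid.start_times, df["window_start_s"].to_numpy())
    idx = np.clip(idx, 0, grid.n_windows - 1)
    out[idx] = df["bpm"].to_numpy(dtype=float)
    return out


def write_coherence_h5(path, coh: CoherenceTensor):
    with h5py.File(path, "w") as f:
        f.create_dataset("coherence", data=coh.values)
        f.create_dataset("pair_index", data=np.asarray(coh.pair_index, dtype=np.int64))
        f.create_dataset("window_start_s", data=coh.grid.start_times)
        f.create_dataset("keep_mask", data=coh.grid.keep_mask)
        f.attrs["window_len"] = coh.grid.window_len
        f.attrs["band_names"] = json.dumps(coh.bands.names)


def read_coherence_h5(path) -> CoherenceTensor:
    with h5py.File(path, "r") as f:
        grid = WindowGrid(float(f.attrs["window_len"]), f["window_start_s"][:], f["keep_mask"][:])
        pairs = [tuple(map(int, p)) for p in f["pair_index"][:]]
        return CoherenceTensor(f["coherence"][:], pairs, grid)


def write_components_h5(path, comps: NetworkComponentSet):
    with h5py.File(path, "w") as f:
        f.create_dataset("loadings", data=comps.loadings)
        f.create_dataset("singular_values", data=comps.singular_values)
        f.create_dataset("centering", data=comps.centering)
        if comps.feature_index is not None:
            f.attrs["feature_index"] = json.dumps([list(t) for t in comps.feature_index])
        f.attrs["converged"] = bool(comps.converged)


def read_components_h5(path) -> NetworkComponentSet:
    with h5py.File(path, "r") as f:
        fi = None
        if "feature_index" in f.attrs:
            fi = [tuple(t) for t in json.loads(f.attrs["feature_index"])]
        return NetworkComponentSet(f["loadings"][:], f["singular_values"][:],
                                   f["centering"][:], fi, bool(f.attrs["converged"]))


def write_koopman_h5(path, model: KoopmanEmbedding):
    with h5py.File(path, "w") as f:
        for name in ("operator_", "bias_", "decoder_", "decoder_bias_", "mean_", "scale_"):
            f.create_dataset(name.rstrip("_"), data=getattr(model, name))
        f.attrs["params"] = json.dumps(model.get_params())
        f.attrs["training_log"] = json.dumps(model.training_log_)


def read_koopman_h5(path) -> KoopmanEmbedding:
    with h5py.File(path, "r") as f:
        params = json.loads(f.attrs["params"])
        if params.get("heldout_days") is not None:
            params["heldout_days"] = tuple(params["heldout_days"])
        model = KoopmanEmbedding(**params)
        for name in ("operator_", "bias_", "decoder_", "decoder_bias_", "mean_", "scale_"):
            setattr(model, name, f[name.rstrip("_")][:])
        model.training_log_ = json.loads(f.attrs["training_log"])
        lam, modes = np.linalg.eig(model.operator_)
        order = np.argsort(-np.abs(lam))
        model.eigenvalues_, model.modes_ = lam[order], modes[:, order]
        model.latent_dim_ = model.operator_.shape[0]
        model.n_features_in_ = model.mean_.shape[0]
    return model
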