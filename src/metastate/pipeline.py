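"""End-to-end orchestration of the synthetic analysis pipeline.

A declarative JSON config (strictly validated: unknown keys are rejected)
drives the stages in dependency order:

``simulate -> connectome -> parcellate -> components -> physiology ->
dynamics -> koopman -> behavior -> report``

Each stage writes standard-format outputs under the run directory and the
manifest records per-stage status, wall time and a SHA-256 hash of every
output file, so a re-run with the same config and seed is verifiable.
Deterministic stages reproduce identical hashes; stochastic stages reproduce
identical statistics at a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import behavior as bh
from . import dynamics as dyn
from . import io as mio
from . import koopman as kp
from .bands import DEFAULT_BANDS
from .coherence import build_exclusion_mask, mean_coherence_matrix, pairwise_coherence
from .components import ActivationSeries, RobustPCA, interaction_test
from .parcellation import cluster_channels, estimate_timescale, parcel_series
from .physiology import CircadianTarget, link_circadian, link_heart_rate
from .synth import SynthConfig, generate_feature_stream, generate_raw_signals

__all__ = ["PipelineConfig", "run_pipeline", "ConfigError"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "connectome", "parcellate", "components", "physiology",
          "dynamics", "koopman", "behavior", "report")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated pipeline settings; round-trips losslessly through JSON."""

    out_dir: str = "metastate_run"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    version: str = "0.1.0"
    # raw tier used by connectome/parcellation (short span at full rate)
    raw: dict = field(default_factory=lambda: {"n_channels": 24, "n_parcels": 6,
                                               "fs": 200.0, "duration": 300.0})
    # feature tier used by everything downstream (multi-day)
    features: dict = field(default_factory=lambda: {"duration": 4 * 86400.0})
    events: list = field(default_factory=list)     # (start_s, end_s) exclusions
    n_perm: int = 200
    heldout_days: list = field(default_factory=lambda: [2, 3])

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**d)
        bad = set(cfg.stages) - set(STAGES)
        if bad:
            raise ConfigError(f"unknown stage(s): {sorted(bad)}")
        synth_fields = {f.name for f in dataclasses.fields(SynthConfig)}
        for blk_name in ("raw", "features"):
            blk = getattr(cfg, blk_name)
            extra = set(blk) - synth_fields
            if extra:
                raise ConfigError(f"unknown {blk_name} key(s): {sorted(extra)}")
        return cfg

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path):
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": config.version, "seed": config.seed, "stages": {}}
    state: dict = {}

    def record(name, t0, outputs, status="ok", error=None):
        manifest["stages"][name] = {
            "status": status,
            "wall_s": round(time.time() - t0, 3),
            "outputs": {str(p): _sha256(Path(p)) for p in outputs if Path(p).exists()},
            **({"error": error} if error else {}),
        }

    failed = False
    for name in STAGES:
        if name not in config.stages:
            continue
        if failed:
            manifest["stages"][name] = {"status": "skipped (upstream failure)"}
            continue
        t0 = time.time()
        try:
            outputs = _STAGE_FUNCS[name](config, out, state)
            record(name, t0, outputs)
        except Exception as e:  # noqa: BLE001 - manifest must record the failure
            logger.exception("stage %s failed", name)
            record(name, t0, [], status="failed", error=f"{type(e).__name__}: {e}")
            failed = True
    manifest["completed"] = not failed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _stage_simulate(cfg: PipelineConfig, out: Path, st: dict):
    raw_cfg = SynthConfig(**{**cfg.raw, "seed": cfg.seed})
    feat_cfg = SynthConfig(**{**cfg.features, "seed": cfg.seed})
    st["raw"] = generate_raw_signals(raw_cfg)
    st["feat"] = generate_feature_stream(feat_cfg)
    p_sig = out / "raw_signals.h5"
    mio.write_signals_h5(p_sig, st["raw"].raw_signal, raw_cfg.fs)
    import h5py

    p_feat = out / "features.h5"
    with h5py.File(p_feat, "w") as f:
        f.create_dataset("features", data=st["feat"].feature_stream)
        f.create_dataset("window_start_s", data=st["feat"].grid.start_times)
    truth = st["feat"].truth
    p_truth = out / "ground_truth.json"
    p_truth.write_text(json.dumps({
        "attractor_point": truth.attractor_point.tolist(),
        "n_transitions": len(truth.transition_intervals),
        "hr_components": list(truth.hr_components),
        "v_pair": list(truth.v_pair),
    }, indent=2))
    import pandas as pd

    p_lab = out / "labels.csv"
    pd.DataFrame({"window_start_s": st["feat"].grid.start_times,
                  "behavior": truth.behavior_labels,
                  "sleep_stage": truth.sleep_stage}).to_csv(p_lab, index=False)
    return [p_sig, p_feat, p_truth, p_lab]


def _stage_connectome(cfg: PipelineConfig, out: Path, st: dict):
    rec = st["raw"]
    grid = build_exclusion_mask(cfg.events, rec.grid)
    coh = pairwise_coherence(rec.raw_signal, rec.fs, grid, DEFAULT_BANDS)
    st["coh"] = coh
    p = out / "coherence.h5"
    mio.write_coherence_h5(p, coh)
    return [p]


def _stage_parcellate(cfg: PipelineConfig, out: Path, st: dict):
    import pandas as pd

    coh = st["coh"]
    n_ch = st["raw"].raw_signal.shape[0]
    C = mean_coherence_matrix(coh, n_ch)
    parc = cluster_channels(C)
    st["parc"] = parc
    ps = parcel_series(coh, parc)
    st["parcel_series"] = ps
    taus = []
    for p_id in range(parc.n_parcels):
        for b in range(ps.values.shape[2]):
            series = ps.values[:, p_id, b]
            if np.isfinite(series).sum() >= 10 * 10:
                est = estimate_timescale(series, max_lag=min(10, max(2, ps.values.shape[0] // 12)))
                taus.append({"parcel": p_id, "band": b, "A": est.magnitude,
                             "tau": est.tau, "rmse": est.fit_rmse,
                             "identifiable": est.identifiable})
    p1 = out / "parcellation.csv"
    pd.DataFrame({"channel": np.arange(n_ch), "parcel_id": parc.assignment}).to_csv(p1, index=False)
    p2 = out / "timescales.csv"
    pd.DataFrame(taus).to_csv(p2, index=False)
    return [p1, p2]


def _stage_components(cfg: PipelineConfig, out: Path, st: dict):
    rec = st["feat"]
    rpca = RobustPCA(n_components=rec.config.n_components, max_iter=200, tol=1e-6)
    rpca.fit(rec.feature_stream)
    st["rpca"] = rpca
    acts = ActivationSeries(rpca.transform(rec.feature_stream), rec.grid)
    st["acts"] = acts
    # the planted component coordinates, for analyses that need axis identity
    st["truth_acts"] = ActivationSeries(rec.truth.activations, rec.grid)
    p = out / "components.h5"
    mio.write_components_h5(p, rpca.to_component_set(rec.truth.feature_index))
    # per-day boundaries on the window grid
    wpd = int(round(86400.0 / rec.grid.window_len))
    n = rec.grid.n_windows
    st["days"] = [(s, min(s + wpd, n)) for s in range(0, n, wpd)]
    st["day_index"] = np.minimum(np.arange(n) // wpd, len(st["days"]) - 1)
    import pandas as pd

    rows = []
    truth_pair = tuple(rec.truth.v_pair)
    test_pairs = {truth_pair, (0, 1)}
    for pair in sorted(test_pairs):
        r = interaction_test(st["truth_acts"], pair, st["days"],
                             n_perm=cfg.n_perm, seed=cfg.seed)
        rows.append({"c1": pair[0], "c2": pair[1],
                     "cross_day_distance": r.cross_day_distance,
                     "null_distance": r.null_distance,
                     "effect_size": r.effect_size, "perm_p": r.perm_p})
    p2 = out / "interactions.csv"
    pd.DataFrame(rows).to_csv(p2, index=False)
    return [p, p2]


def _stage_physiology(cfg: PipelineConfig, out: Path, st: dict):
    rec = st["feat"]
    acts = st["truth_acts"]
    target = CircadianTarget.from_times(rec.grid.start_times)
    circ = link_circadian(acts, target, n_perm=cfg.n_perm, seed=cfg.seed)
    hr = link_heart_rate(acts, rec.truth.heart_rate, n_perm=cfg.n_perm, seed=cfg.seed)
    st["circ"], st["hr"] = circ, hr
    p = out / "physiology.json"
    p.write_text(json.dumps({
        "circadian": {"train_r": circ.train_r, "test_r": circ.test_r, "perm_p": circ.perm_p},
        "heart_rate": {"train_r": hr.train_r, "test_r": hr.test_r, "perm_p": hr.perm_p,
                       "support": np.flatnonzero(hr.support).tolist()},
    }, indent=2))
    return [p]


def _stage_dynamics(cfg: PipelineConfig, out: Path, st: dict):
    import pandas as pd

    rec = st["feat"]
    acts = st["truth_acts"]
    speed = dyn.compute_speed(acts)
    obs, exp, p_burst = dyn.burst_gap_test(speed, seed=cfg.seed)
    seg = dyn.segment_states(speed, acts, seed=cfg.seed)
    st["speed"], st["seg"] = speed, seg
    tm_trans = dyn.trajectory_metrics(seg.transitions(), acts)
    matched = dyn.duration_matched_state_ratios(seg.transitions(), seg.states(), acts,
                                                seed=cfg.seed)
    gaps = np.diff([s for s, _ in seg.transitions()]) if len(seg.transitions()) > 1 else np.array([])
    results = {
        "burst": {"observed_gap": obs, "expected_gap": exp, "p": p_burst},
        "ratio_transitions": float(np.nanmean(tm_trans.ratios)) if len(tm_trans.ratios) else np.nan,
        "ratio_states_matched": float(np.nanmean(matched)) if len(matched) else np.nan,
        "n_transitions": len(seg.transitions()),
    }
    # chaos by regime: transition windows concatenated (short bursts) vs the
    # longest contiguous state run, on the non-slow activation components
    from ._utils import contiguous_runs

    trans_w = np.zeros(rec.grid.n_windows, bool)
    for s0, e0 in seg.transitions():
        trans_w[s0:e0] = True
    comps = [c for c in range(acts.values.shape[1])
             if c not in (rec.truth.slow_axis_component, rec.truth.v_pair[1])]
    state_runs = contiguous_runs(~trans_w)
    if trans_w.sum() > 600 and state_runs:
        s0, e0 = max(state_runs, key=lambda r: r[1] - r[0])
        if e0 - s0 > 600:
            results["chaos_transition_K"] = dyn.chaos01(
                acts.values[trans_w][:5000][:, comps], seed=cfg.seed).K
            results["chaos_state_K"] = dyn.chaos01(
                acts.values[s0:e0][:, comps], seed=cfg.seed).K
    if len(gaps) >= 120:
        fit = dyn.fit_powerlaw(gaps.astype(int), discrete=True, xmin=1,
                               n_bootstrap=20, seed=cfg.seed)
        results["gap_powerlaw"] = {"alpha": fit.alpha,
                                   "lr_vs_exponential": fit.lr_vs_exponential}
    p = out / "dynamics.json"
    p.write_text(json.dumps(results, indent=2, default=float))
    rows = [{"kind": k, "start_window": s0, "end_window": e0,
             "state_id": seg.state_ids.get(i, -1)}
            for i, (k, s0, e0) in enumerate(seg.segments)]
    p2 = out / "segmentation.csv"
    pd.DataFrame(rows).to_csv(p2, index=False)
    return [p, p2]


def _stage_koopman(cfg: PipelineConfig, out: Path, st: dict):
    acts = st["truth_acts"]
    model = kp.KoopmanEmbedding(heldout_days=tuple(cfg.heldout_days), seed=cfg.seed)
    model.fit(acts, day_index=st["day_index"])
    st["koop"] = model
    spec = kp.spectrum(model)
    att = kp.find_attractor(model,
                            feature_groups=st["feat"].truth.feature_index,
                            component_loadings=st["feat"].truth.component_loadings)
    man = kp.center_manifold(model, spec)
    st["spec"], st["att"], st["man"] = spec, att, man
    p = out / "koopman.h5"
    mio.write_koopman_h5(p, model)
    p2 = out / "koopman_summary.json"
    p2.write_text(json.dumps({
        "max_eig_modulus": spec.max_modulus,
        "attractor_residual": att.residual,
        "center_eigenvalue": [float(np.real(man.eigenvalues[0])),
                              float(np.imag(man.eigenvalues[0]))],
        "training_log": model.training_log_,
    }, indent=2))
    return [p, p2]


def _stage_behavior(cfg: PipelineConfig, out: Path, st: dict):
    rec = st["feat"]
    model, man, att = st["koop"], st["man"], st["att"]
    t, Z = model.encode(st["truth_acts"])
    along = kp.along_coordinate(man, Z)
    labels = rec.truth.behavior_labels[t]
    wake = np.isin(labels, ["digital", "social", "physical", "wakeful_rest"])
    sleep = np.isin(labels, ["N1", "N2/N3", "REM"])
    kp.orient_axis(man, along, wake, sleep)
    along = kp.along_coordinate(man, Z)
    day_index = st["day_index"][t]
    dec = bh.decode_behavior(Z, st["truth_acts"].values[t], labels, day_index,
                             tuple(cfg.heldout_days))
    bursts = np.array([rec.grid.start_times[s0] for s0, _ in st["seg"].transitions()])
    lab_all = rec.truth.behavior_labels
    chg = np.flatnonzero(lab_all[1:] != lab_all[:-1]) + 1
    changes = rec.grid.start_times[chg]
    coin = bh.transition_coincidence(bursts, changes, span=rec.config.duration,
                                     n_surrogates=cfg.n_perm, seed=cfg.seed)
    dist = bh.attractor_distance_by_state(Z, labels, att.z_star)
    p = out / "behavior.json"
    p.write_text(json.dumps({
        "decode_auc": dec.auc,
        "mean_auc": dec.mean_auc,
        "coincidence": {"statistic_s": coin.statistic, "null_mean_s": coin.null_mean,
                        "p": coin.p},
        "attractor_distance": {"active": dist["active_mean"], "rest": dist["rest_mean"]},
        "along_slow_axis_corr": float(np.corrcoef(along, rec.truth.slow_axis_value[t])[0, 1]),
    }, indent=2))
    return [p]


def _stage_report(cfg: PipelineConfig, out: Path, st: dict):
    report = {"stages_run": [s for s in STAGES if s in cfg.stages]}
    p = out / "report.json"
    p.write_text(json.dumps(report, indent=2))
    return [p]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "connectome": _stage_connectome,
    "parcellate": _stage_parcellate,
    "components": _stage_components,
    "physiology": _stage_physiology,
    "dynamics": _stage_dynamics,
    "koopman": _stage_koopman,
    "behavior": _stage_behavior,
    "report": _stage_report,
}
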