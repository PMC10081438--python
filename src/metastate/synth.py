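"""Synthetic week-long recordings with known planted structure.

Two tiers are generated:

* **raw tier** — multichannel signals in which channels belonging to the same
  planted parcel share a band-limited oscillator plus independent white noise,
  so within-parcel coherence exceeds across-parcel coherence in the driven
  band. Used to validate the connectome and parcellation stages.

* **feature tier** — a windows x features stream built from a low-rank mixture
  of latent network-component activations whose dynamics emulate the
  statistical structure the analysis assumes: metastable states with
  power-law dwell times, chaotic transition bursts (logistic-map driven),
  mean reversion toward a central attractor, a 24-h circadian drive, a slow
  sleep-wake axis carrying behavior and sleep-stage labels, a V-shaped
  (non-independent) component pair, and heart-rate-coupled components.

Every planted parameter is recorded in :class:`GroundTruth` so downstream
estimators can be scored on parameter recovery. Generation is bit-identical
given the same :class:`SynthConfig` (including seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import butter, filtfilt

from .bands import BandSpec, DEFAULT_BANDS, WindowGrid

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SyntheticRecording",
    "generate_raw_signals",
    "generate_state_sequence",
    "generate_feature_stream",
    "CANONICAL_NETWORKS",
]

CANONICAL_NETWORKS = ("default", "dorsal-attention", "salience", "somatomotor", "control", "visual")

#: logistic-map parameter used for chaotic transition paths
LOGISTIC_R = 3.99

#: amplitude of within-state fluctuation of state offsets, activation units
STATE_SCALE = 1.2


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults are the package's reference study conditions.

    ``duration`` defaults to one week of 5-s windows (the feature tier); raw
    signal generation at full sampling rate is typically run at shorter
    durations passed explicitly.
    """

    n_channels: int = 40
    n_parcels: int = 8
    fs: float = 200.0
    duration: float = 7 * 86400.0
    window_len: float = 5.0
    n_components: int = 10
    n_features: int = 30
    n_states: int = 4
    dwell_exponent: float = 1.8
    dwell_xmin: int = 12
    transition_len_range: tuple = (8, 24)
    circadian_amplitude: float = 1.0
    hr_coupling: float = 1.0
    attractor_strength: float = 0.1
    slow_axis_period: float = 24.0  # hours
    slow_axis_amplitude: float = 2.0
    state_osc_amplitude: float = 0.5
    state_osc_period: float = 40.0  # windows
    noise_sd: float = 0.1
    seed: int = 0

    def validate(self, raw: bool = False, bands: BandSpec = DEFAULT_BANDS):
        for name in ("n_channels", "n_parcels", "n_components", "n_features", "n_states"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if raw and self.fs < 2 * bands.max_edge:
            raise ValueError(
                f"fs={self.fs} cannot cover band '{bands.bands[-1].name}' "
                f"({bands.bands[-1].low}-{bands.bands[-1].high} Hz): need fs >= {2 * bands.max_edge}"
            )
        if not 0 < self.attractor_strength < 1:
            raise ValueError("attractor_strength must lie in (0, 1)")
        if self.dwell_exponent <= 1:
            raise ValueError("dwell_exponent must exceed 1 (zeta normalization)")
        if self.dwell_xmin < 1:
            raise ValueError("dwell_xmin must be >= 1 window")
        if self.n_components > self.n_features:
            raise ValueError("n_components may not exceed n_features")
        lo, hi = self.transition_len_range
        if not (1 <= lo <= hi):
            raise ValueError("transition_len_range must satisfy 1 <= lo <= hi")

    @property
    def n_windows(self) -> int:
        return int(np.floor(self.duration / self.window_len))


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic recording."""

    parcel_labels: Optional[np.ndarray] = None
    component_loadings: Optional[np.ndarray] = None
    state_sequence: Optional[np.ndarray] = None
    transition_intervals: list = field(default_factory=list)
    transitions: list = field(default_factory=list)  # (start, end, old_state, new_state)
    circadian_phase: Optional[np.ndarray] = None
    heart_rate: Optional[np.ndarray] = None
    behavior_labels: Optional[np.ndarray] = None
    sleep_stage: Optional[np.ndarray] = None
    slow_axis_value: Optional[np.ndarray] = None
    attractor_point: Optional[np.ndarray] = None
    activations: Optional[np.ndarray] = None
    state_means: Optional[np.ndarray] = None
    feature_index: Optional[list] = None
    # designated component roles
    slow_axis_component: int = 0
    circadian_components: tuple = (0, 1)
    v_pair: tuple = (2, 3)
    hr_components: tuple = (4, 5, 6)


@dataclass
class SyntheticRecording:
    tier: str  # "raw" | "features"
    truth: GroundTruth
    grid: WindowGrid
    fs: Optional[float] = None
    raw_signal: Optional[np.ndarray] = None
    feature_stream: Optional[np.ndarray] = None
    config: Optional[SynthConfig] = None


def _bandpass_noise(rng, n, fs, low, high):
    """Unit-variance band-limited Gaussian noise."""
    b, a = butter(4, [low / (fs / 2), high / (fs / 2)], btype="band")
    x = filtfilt(b, a, rng.standard_normal(n + int(4 * fs)))[int(2 * fs):int(2 * fs) + n]
    return x / x.std()


def generate_raw_signals(config: SynthConfig, bands: BandSpec = DEFAULT_BANDS) -> SyntheticRecording:
    """Raw tier: parcels of channels sharing a band-limited oscillator.

    Parcel ``p`` is driven in band ``p mod len(bands)``; each channel adds
    independent white noise of standard deviation ``config.noise_sd``. With
    ``noise_sd=0`` channels within a parcel are identical.
    """
    config.validate(raw=True, bands=bands)
    ss = np.random.SeedSequence(config.seed)
    rng_assign, rng_osc, rng_noise = [np.random.default_rng(s) for s in ss.spawn(3)]

    n_samp = int(round(config.fs * config.duration))
    # balanced random parcel assignment (each parcel >= 2 channels when possible)
    labels = np.repeat(np.arange(config.n_parcels), -(-config.n_channels // config.n_parcels))
    labels = labels[:config.n_channels]
    rng_assign.shuffle(labels)

    oscillators = np.empty((config.n_parcels, n_samp))
    for p in range(config.n_parcels):
        band = bands.bands[p % len(bands)]
        oscillators[p] = _bandpass_noise(rng_osc, n_samp, config.fs, band.low, band.high)

    signal = oscillators[labels] + config.noise_sd * rng_noise.standard_normal((config.n_channels, n_samp))
    grid = WindowGrid.regular(config.duration, config.window_len)
    truth = GroundTruth(parcel_labels=labels)
    return SyntheticRecording("raw", truth, grid, fs=config.fs, raw_signal=signal, config=config)


def _sample_discrete_powerlaw(rng, exponent, size, cap, xmin=1):
    """Dwell times from a zeta-normalized discrete power law on {xmin, ...}.

    The support is truncated at ``cap`` (the recording length): tail mass
    beyond the recording cannot be realized anyway.
    """
    k = np.arange(xmin, max(cap, xmin + 1) + 1, dtype=float)
    pmf = k ** (-exponent)
    cdf = np.cumsum(pmf / pmf.sum())
    return xmin + np.searchsorted(cdf, rng.random(size))


def generate_state_sequence(config: SynthConfig, rng=None) -> GroundTruth:
    """Metastable state sequence with power-law dwell times and burst transitions.

    Dwell times (in windows) are drawn from a discrete power law with
    exponent ``dwell_exponent`` on {dwell_xmin, ...}; each state change is realized as
    a transition burst of length uniform in ``transition_len_range`` windows.
    The state sequence takes the destination state's id from the first window
    of its transition interval, so the sequence only changes value inside
    transition intervals.
    """
    config.validate()
    if config.n_states < 2:
        raise ValueError("need n_states >= 2 for a state sequence")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    n = config.n_windows
    lo, hi = config.transition_len_range

    # oversample dwells, then lay out dwell / transition / dwell ...
    seq = np.empty(n, dtype=int)
    intervals, transitions = [], []
    state = int(rng.integers(config.n_states))
    t = 0
    while t < n:
        dwell = int(_sample_discrete_powerlaw(rng, config.dwell_exponent, 1,
                                              max(n, 1000), config.dwell_xmin)[0])
        stop = min(n, t + dwell)
        seq[t:stop] = state
        t = stop
        if t >= n:
            break
        new = int((state + 1 + rng.integers(config.n_states - 1)) % config.n_states)
        tlen = int(rng.integers(lo, hi + 1))
        stop = min(n, t + tlen)
        seq[t:stop] = new
        intervals.append((t, stop))
        transitions.append((t, stop, state, new))
        state = new
        t = stop
    return GroundTruth(state_sequence=seq, transition_intervals=intervals, transitions=transitions)


def _logistic_path(rng, length, n_dims):
    """Chaotic perturbation series in [-1, 1] from independent logistic maps."""
    x = rng.uniform(0.05, 0.95, size=n_dims)
    out = np.empty((length, n_dims))
    for t in range(length):
        x = LOGISTIC_R * x * (1 - x)
        out[t] = 2.0 * (x - 0.5)
    return out


def _planted_loadings(rng, n_components, n_features):
    """Orthonormal component loadings with a default-mode/theta-concentrated row.

    Feature ``f`` is labeled (network ``f mod 6``, band ``f mod-cycle``); the
    last component (the "attractor component") loads predominantly on the
    default-network theta/alpha features.
    """
    bands = DEFAULT_BANDS.names
    feature_index = [(CANONICAL_NETWORKS[f % len(CANONICAL_NETWORKS)],
                      bands[(f // len(CANONICAL_NETWORKS)) % len(bands)])
                     for f in range(n_features)]
    dm_row = np.full(n_features, 0.0)
    for f, (net, band) in enumerate(feature_index):
        if net == "default" and band == "theta":
            dm_row[f] = 1.0
        elif net == "default" and band == "alpha":
            dm_row[f] = 0.5
    if not dm_row.any():  # tiny feature counts: fall back to first feature
        dm_row[0] = 1.0
    dm_row = dm_row / np.linalg.norm(dm_row)
    basis = np.concatenate([dm_row[None, :], rng.standard_normal((n_components - 1, n_features))])
    q, _ = np.linalg.qr(basis.T)
    q = q.T  # rows orthonormal; row 0 spans dm_row direction
    if np.dot(q[0], dm_row) < 0:
        q[0] = -q[0]
    loadings = np.empty_like(q)
    loadings[-1] = q[0]        # attractor component last
    loadings[:-1] = q[1:]
    return loadings, feature_index


def generate_feature_stream(config: SynthConfig) -> SyntheticRecording:
    """Feature tier: low-rank mixture of planted latent component dynamics.

    Latent activations follow, inside states,
    ``z[t+1] = z[t] + a * (target[t+1] - z[t]) + sigma * eps`` with
    ``a = attractor_strength`` and ``target = attractor_point + state offset +
    drives``; inside transition bursts the trajectory interpolates between
    state targets with a logistic-map chaotic perturbation (sin-shaped
    envelope) so paths converge only near their destination. State offsets
    are occupancy-centered so the planted attractor is the true long-run
    mean. The V-pair, circadian, slow-axis and heart-rate structures are
    planted on designated components recorded in the ground truth.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(8)
    rng_states = np.random.default_rng(seeds[3])
    rng_comp = np.random.default_rng(seeds[4])
    rng_dyn = np.random.default_rng(seeds[5])
    rng_obs = np.random.default_rng(seeds[6])
    rng_lab = np.random.default_rng(seeds[7])

    n = config.n_windows
    d = config.n_components
    truth = generate_state_sequence(config, rng=rng_states) if config.n_states >= 2 else GroundTruth(
        state_sequence=np.zeros(n, dtype=int))
    seq = truth.state_sequence

    loadings, feature_index = _planted_loadings(rng_comp, d, config.n_features)
    truth.component_loadings = loadings
    truth.feature_index = feature_index

    slow_c = truth.slow_axis_component
    circ = [c for c in truth.circadian_components if c < d]
    v1, v2 = truth.v_pair
    hr_comps = [c for c in truth.hr_components if c < d]

    # attractor: large on the default-mode-like (last) component
    attractor = np.zeros(d)
    attractor[-1] = 1.5
    free = [c for c in range(d - 1) if c not in (slow_c, v1, v2) and c not in circ]
    attractor[free] = 0.3 * rng_comp.standard_normal(len(free))
    truth.attractor_point = attractor

    # drives
    t_sec = config.window_len * np.arange(n)
    phase = 2 * np.pi * ((t_sec % 86400.0) / 86400.0)
    truth.circadian_phase = phase
    slow = config.slow_axis_amplitude * np.sin(2 * np.pi * t_sec / (config.slow_axis_period * 3600.0))
    truth.slow_axis_value = slow
    drive = np.zeros((n, d))
    for c in circ:
        drive[:, c] += config.circadian_amplitude * np.sin(phase + 0.7 * c)
    drive[:, slow_c] += slow

    # arousal gate: state offsets are fully expressed during outwardly active
    # behavior (high slow-axis values) and shrink toward the attractor during
    # wakeful rest and sleep, giving the hourglass its narrow waist
    vn_gate = slow / (config.slow_axis_amplitude if config.slow_axis_amplitude > 0 else 1.0)
    gate = (0.5 + 0.5 * np.clip((vn_gate - 0.35) / 0.2, 0.0, 1.0))[:, None]

    # state offsets: zero on slow/v-pair components, centered under the
    # gate-weighted occupancy so the planted attractor is the long-run mean
    M = STATE_SCALE * rng_comp.standard_normal((config.n_states, d))
    M[:, slow_c] = 0.0
    M[:, v2] = 0.0
    w = np.zeros(config.n_states)
    np.add.at(w, seq, gate[:, 0])
    w /= w.sum()
    M -= w @ M
    truth.state_means = M

    # chaotic amplitude scaled to the typical inter-state separation
    if config.n_states >= 2:
        seps = [np.linalg.norm(M[i] - M[j]) for i in range(config.n_states) for j in range(i)]
        chaos_amp = 0.5 * float(np.mean(seps))
    else:
        chaos_amp = 1.0

    in_transition = np.zeros(n, dtype=bool)
    for s, e in truth.transition_intervals:
        in_transition[s:e] = True

    a = config.attractor_strength
    sigma = config.noise_sd * np.sqrt(max(2 * a - a * a, 1e-12))
    target = attractor[None, :] + gate * M[seq] + drive
    z = np.empty((n, d))
    z[0] = target[0]
    eps = rng_dyn.standard_normal((n, d))
    chaos_dims = [c for c in range(d) if c != slow_c]

    # precompute chaotic paths per transition; amplitude follows the local
    # arousal gate so burst geometry (circuitousness, divergence profile) is
    # the same during wake and sleep transitions
    chaos = np.zeros((n, len(chaos_dims)))
    for (s, e, old, new) in truth.transitions:
        L = e - s
        u = (np.arange(L) + 1) / L
        env = np.sin(np.pi * np.minimum(u, 1.0))
        chaos[s:e] = chaos_amp * gate[s:e] * env[:, None] * _logistic_path(rng_dyn, L, len(chaos_dims))

    trans_target = target.copy()
    for (s, e, old, new) in truth.transitions:
        L = e - s
        u = ((np.arange(L) + 1) / L)[:, None]
        interp = attractor[None, :] + gate[s:e] * ((1 - u) * M[old] + u * M[new]) + drive[s:e]
        trans_target[s:e] = interp

    for t in range(1, n):
        if in_transition[t]:
            z[t] = trans_target[t]
            z[t, chaos_dims] += chaos[t]
        else:
            z[t] = z[t - 1] + a * (target[t] - z[t - 1]) + sigma * eps[t]

    # quasi-periodic within-state rhythm: regular (non-chaotic) deterministic
    # structure added outside the mean-reverting recursion so it is not
    # low-pass filtered away
    if config.state_osc_amplitude > 0:
        osc_phase = 2 * np.pi * np.arange(n)[:, None] / config.state_osc_period
        comp_phase = rng_comp.uniform(0, 2 * np.pi, d)[None, :]
        osc = config.state_osc_amplitude * np.sin(osc_phase + comp_phase)
        osc[:, slow_c] = 0.0
        z = z + osc

    # V-shaped dependent pair: |z[v2]| determined by z[v1]; the branch sign
    # is persistent (geometric dwells with a 10-window floor) so isolated
    # sign jumps read as single-step spikes, not bursts
    flip_gaps = 10 + rng_dyn.geometric(0.02, size=max(8, n // 20))
    flip_at = np.cumsum(flip_gaps)
    flips = np.zeros(n, dtype=bool)
    flips[flip_at[flip_at < n]] = True
    signs = np.where(np.cumsum(flips) % 2 == 0, 1.0, -1.0) * rng_dyn.choice([-1.0, 1.0])
    z[:, v2] = signs * np.abs(z[:, v1]) + 0.15 * rng_dyn.standard_normal(n)

    truth.activations = z

    # heart rate coupled to designated components
    w = np.zeros(d)
    for k, c in enumerate(hr_comps):
        w[c] = (3.0, -2.5, 2.0)[k % 3]
    truth.heart_rate = 70.0 + config.hr_coupling * (z @ w) + 1.0 * rng_obs.standard_normal(n)

    # behavior & sleep labels from slow-axis thresholds
    amp = config.slow_axis_amplitude if config.slow_axis_amplitude > 0 else 1.0
    vn = slow / amp
    behavior = np.full(n, "unlabeled", dtype=object)
    stage = np.full(n, "wake", dtype=object)
    active_names = np.array(["digital", "social", "physical"], dtype=object)
    active = vn > 0.55
    rest = (vn > 0.15) & ~active
    n1 = (vn > -0.15) & (vn <= 0.15)
    rem = (vn > -0.6) & (vn <= -0.15)
    deep = vn <= -0.6
    behavior[active] = active_names[seq[active] % 3]
    behavior[rest] = "wakeful_rest"
    behavior[n1] = "N1"
    behavior[rem] = "REM"
    behavior[deep] = "N2/N3"
    stage[n1] = "N1"
    stage[rem] = "REM"
    stage[deep] = "N2/N3"
    truth.behavior_labels = behavior.astype(str)
    truth.sleep_stage = stage.astype(str)

    X = z @ loadings + config.noise_sd * rng_obs.standard_normal((n, config.n_features))
    grid = WindowGrid.regular(config.duration, config.window_len)
    return SyntheticRecording("features", truth, grid, feature_stream=X, config=config)
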