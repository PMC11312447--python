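"""Synthetic coupled fMRI / physiology / EEG data with known ground truth.

Everything downstream of raw recordings can be validated against the
quantities stored in :class:`GroundTruth`: the latent arousal series, the
per-voxel lag/sign map, the true systolic beat times and amplitudes, the
per-sample breathing rate/depth, the injected evoked waveform, and the
per-frame T2*/S0 series.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .filters import LOW_FREQ_BAND, bandpass, check_band_duration, shift_series

#: default per-modality coupling of physiological signals to the latent
#: arousal process: gain (unitless), lag (seconds), and sign.
DEFAULT_COUPLINGS = {
    "heart_rate": {"gain": 0.30, "lag_s": 1.0, "sign": +1},
    "ppg_amplitude": {"gain": 0.40, "lag_s": 2.0, "sign": -1},
    "respiratory_volume": {"gain": 0.35, "lag_s": 0.5, "sign": +1},
    "skin_conductance": {"gain": 0.30, "lag_s": 2.0, "sign": +1},
    "pupil": {"gain": 0.30, "lag_s": 0.5, "sign": +1},
    "eeg_alpha": {"gain": 0.30, "lag_s": 0.0, "sign": +1},
}


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic recording session."""

    duration_s: float = 600.0
    tr_s: float = 1.0
    physio_fs_hz: float = 100.0
    n_voxels: int = 500
    tissue_fractions: tuple = (0.7, 0.2, 0.1)  # gray, white, csf
    voxel_lag_range_s: tuple = (0.0, 6.0)
    physio_couplings: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COUPLINGS.items()})
    noise_sd: float = 0.5
    echo_times_ms: tuple = (13.7, 30.0, 47.0)
    event_rate: float = 0.5  # events per minute
    event_min_gap_s: float = 60.0
    seed: int = 0
    # carrier parameters (not exposed in the spec-level knobs but configurable)
    base_heart_rate_bpm: float = 60.0
    base_breath_rate_hz: float = 0.25
    eeg_carrier_hz: float = 10.0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        fr = np.asarray(self.tissue_fractions, dtype=float)
        if np.any(fr < 0) or np.any(fr > 1) or not np.isclose(fr.sum(), 1.0):
            raise ValueError("tissue_fractions must lie in [0,1] and sum to 1")
        carrier = max(self.eeg_carrier_hz, 8.0)  # PPG harmonics reach ~8 Hz
        if self.physio_fs_hz < 2.5 * carrier:
            raise ValueError(
                f"physio_fs_hz={self.physio_fs_hz} too low for carrier {carrier} Hz"
            )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.tr_s))

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr_s

    def tissue_labels(self) -> np.ndarray:
        """Synthetic block tissue assignment over the voxel index."""
        n = self.n_voxels
        n_gray = int(round(self.tissue_fractions[0] * n))
        n_white = int(round(self.tissue_fractions[1] * n))
        labels = np.array(
            ["gray"] * n_gray + ["white"] * n_white + ["csf"] * (n - n_gray - n_white)
        )
        return labels


@dataclass
class GroundTruth:
    """Latent quantities sufficient to verify every downstream stage."""

    arousal: np.ndarray | None = None
    voxel_lag_s: np.ndarray | None = None
    voxel_sign: np.ndarray | None = None
    beat_times_s: np.ndarray | None = None
    beat_amplitudes: np.ndarray | None = None
    breath_rate_hz: np.ndarray | None = None
    breath_depth: np.ndarray | None = None
    true_series: dict = field(default_factory=dict)  # modality -> frame-grid series
    true_irf: dict = field(default_factory=dict)
    t2s_series_ms: np.ndarray | None = None
    s0_series: np.ndarray | None = None
    event_waveform: np.ndarray | None = None
    event_waveform_t_s: np.ndarray | None = None

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray):
                out[f.name] = v.tolist()
            elif isinstance(v, dict):
                out[f.name] = {k: np.asarray(a).tolist() for k, a in v.items()}
            else:
                out[f.name] = v
        return out


def generate_arousal(cfg: SyntheticConfig, rng: np.random.Generator | None = None):
    """Latent low-frequency arousal process on the fMRI frame grid.

    White noise is passed through the same fifth-order 0.01-0.1 Hz
    zero-phase bandpass used in preprocessing and then standardized to
    zero mean, unit variance.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    fs = 1.0 / cfg.tr_s
    check_band_duration(cfg.n_frames, fs, LOW_FREQ_BAND[0])
    white = rng.standard_normal(cfg.n_frames)
    arousal = bandpass(white, fs)
    arousal = arousal - arousal.mean()
    arousal = arousal / arousal.std()
    return arousal


#: PPG beat morphology in seconds after beat onset: (center_s, width_s,
#: relative amplitude) of the systolic peak and the dicrotic bump. The
#: dicrotic delay is fixed in absolute time (tied to ejection), not
#: scaled with the inter-beat interval.
PULSE_SHAPE = {"systole": (0.15, 0.05, 1.0), "dicrotic": (0.45, 0.12, 0.35)}


def _pulse_template(n: int, fs_hz: float, shape=PULSE_SHAPE) -> np.ndarray:
    """One-beat PPG waveform: systolic peak plus dicrotic bump."""
    t = np.arange(n) / fs_hz
    out = np.zeros(n)
    for center, width, amp in shape.values():
        out += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return out


def _coupled(arousal_fine, t_fine, coupling):
    lagged = shift_series(arousal_fine, t_fine, coupling["lag_s"])
    return coupling["sign"] * coupling["gain"] * lagged


def generate_physio(cfg: SyntheticConfig, arousal: np.ndarray,
                    rng: np.random.Generator | None = None):
    """Raw physiological/EEG recordings coupled to the latent arousal.

    Returns ``(signals, truth)`` where ``signals`` maps modality name to a
    dict with ``samples`` and ``fs_hz`` and ``truth`` is a partially
    filled :class:`GroundTruth` (beat times/amplitudes, breathing
    rate/depth, and the frame-grid true feature series per modality).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    arousal = np.asarray(arousal, dtype=float)
    if arousal.std() == 0:
        raise ValueError("arousal series is degenerate (zero variance)")
    fs = cfg.physio_fs_hz
    n_fine = int(round(cfg.duration_s * fs))
    t_fine = np.arange(n_fine) / fs
    t_frames = cfg.frame_times_s
    arousal_fine = np.interp(t_fine, t_frames, arousal)
    cp = cfg.physio_couplings
    truth = GroundTruth()
    signals = {}
    noise = cfg.noise_sd

    # --- PPG: pulse train; rate follows arousal, beat amplitude anti-follows.
    hr_mod = _coupled(arousal_fine, t_fine, cp["heart_rate"])
    rate_hz = cfg.base_heart_rate_bpm / 60.0 * np.clip(1.0 + hr_mod, 0.3, 3.0)
    phase = np.cumsum(rate_hz) / fs
    onset_idx = np.searchsorted(phase, np.arange(0, int(np.floor(phase[-1])) + 1))
    onsets = t_fine[np.minimum(onset_idx, n_fine - 1)]
    amp_mod = np.clip(_coupled(arousal_fine, t_fine, cp["ppg_amplitude"]), -0.6, 0.6)
    amp_fine = 1.0 + amp_mod
    ppg = np.zeros(n_fine)
    bounds = np.concatenate([onsets, [cfg.duration_s]])
    systole_delay = PULSE_SHAPE["systole"][0]
    beat_times, beat_amps = [], []
    # each inter-beat interval carries one pulse (fixed absolute-time shape)
    for k in range(len(bounds) - 1):
        i0 = int(round(bounds[k] * fs))
        i1 = int(round(bounds[k + 1] * fs))
        if i1 <= i0:
            continue
        systole = bounds[k] + systole_delay
        if systole >= cfg.duration_s:
            continue
        amp = float(np.interp(systole, t_fine, amp_fine))
        ppg[i0:i1] = amp * _pulse_template(i1 - i0, fs)
        beat_times.append(systole)
        beat_amps.append(amp)
    ppg += 0.01 * noise * rng.standard_normal(n_fine)
    signals["ppg"] = {"samples": ppg, "fs_hz": fs, "modality": "ppg"}
    truth.beat_times_s = np.asarray(beat_times)
    truth.beat_amplitudes = np.asarray(beat_amps)

    # --- respiration: oscillation with arousal-coupled rate and depth.
    rv_mod = _coupled(arousal_fine, t_fine, cp["respiratory_volume"])
    breath_rate = cfg.base_breath_rate_hz * np.clip(1.0 + rv_mod, 0.3, 2.5)
    breath_depth = np.clip(1.0 + rv_mod, 0.1, None)
    breath_phase = 2 * np.pi * np.cumsum(breath_rate) / fs
    resp = breath_depth * np.sin(breath_phase)
    resp += 0.02 * noise * rng.standard_normal(n_fine)
    signals["respiration"] = {"samples": resp, "fs_hz": fs, "modality": "respiration"}
    truth.breath_rate_hz = breath_rate
    truth.breath_depth = breath_depth

    # --- skin conductance / pupil: lagged smoothed copies plus noise.
    for name, modality in (("skin_conductance", "skin_conductance"), ("pupil", "pupil")):
        series = 5.0 + _coupled(arousal_fine, t_fine, cp[name])
        series = series + 0.05 * noise * rng.standard_normal(n_fine)
        signals[modality] = {"samples": series, "fs_hz": fs, "modality": modality}

    # --- EEG: alpha-band carrier whose envelope tracks lagged arousal.
    env = np.clip(1.0 + _coupled(arousal_fine, t_fine, cp["eeg_alpha"]), 0.05, None)
    carrier = np.sin(2 * np.pi * cfg.eeg_carrier_hz * t_fine + rng.uniform(0, 2 * np.pi))
    eeg = env * carrier + 0.05 * noise * rng.standard_normal(n_fine)
    signals["eeg_channel"] = {"samples": eeg, "fs_hz": fs, "modality": "eeg_channel"}

    # frame-grid true feature series (for oracle cross-correlations)
    for name in cp:
        truth.true_series[name] = shift_series(
            arousal, t_frames, cp[name]["lag_s"]
        ) * cp[name]["sign"] * cp[name]["gain"]
    return signals, truth


def generate_fmri(cfg: SyntheticConfig, arousal: np.ndarray,
                  rng: np.random.Generator | None = None):
    """Voxel time series = signed, lag-shifted arousal + iid noise.

    Gray/white voxels carry sign +1, CSF voxels sign -1 (anti-phase).
    Returns ``(data, lag_s, sign, labels)`` with ``data`` frames x voxels.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    labels = cfg.tissue_labels()
    lo, hi = cfg.voxel_lag_range_s
    lag_s = rng.uniform(lo, hi, size=cfg.n_voxels)
    sign = np.where(labels == "csf", -1.0, 1.0)
    t = cfg.frame_times_s
    data = np.empty((cfg.n_frames, cfg.n_voxels))
    for v in range(cfg.n_voxels):
        data[:, v] = sign[v] * shift_series(arousal, t, lag_s[v])
    if cfg.noise_sd > 0:
        data += cfg.noise_sd * rng.standard_normal(data.shape)
    return data, lag_s, sign, labels


def generate_multiecho(cfg: SyntheticConfig, arousal: np.ndarray,
                       rng: np.random.Generator | None = None,
                       t2s_gain: float = 0.05, s0_gain: float = 0.02,
                       t2s_lag_s: float = 1.0,
                       base_t2s_ms: float = 30.0, base_s0: float = 1000.0,
                       noise_sd: float = 0.0):
    """Echo-resolved signal S(TE,t) = S0(t) * exp(-TE / T2*(t)).

    T2* and S0 are modulated by the (lagged) arousal series, with CSF
    voxels modulated with opposite sign. Returns
    ``(data, t2s_ms, s0, labels)`` with ``data`` frames x echoes x voxels.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 3)
    tes = np.asarray(cfg.echo_times_ms, dtype=float)
    if tes.size < 2:
        raise ValueError("at least two echo times are required")
    if np.any(tes <= 0):
        raise ValueError("echo times must be positive")
    labels = cfg.tissue_labels()
    sign = np.where(labels == "csf", -1.0, 1.0)
    t = cfg.frame_times_s
    mod = shift_series(arousal, t, t2s_lag_s)
    t2s = base_t2s_ms * (1.0 + t2s_gain * np.outer(mod, sign))  # frames x voxels
    s0 = base_s0 * (1.0 + s0_gain * np.outer(mod, sign))
    data = s0[:, None, :] * np.exp(-tes[None, :, None] / t2s[:, None, :])
    if noise_sd > 0:
        data *= np.exp(noise_sd * rng.standard_normal(data.shape))
    return data, t2s, s0, labels


def default_event_waveform(tr_s: float, length_s: float = 25.0,
                           peak_amp: float = 1.0, undershoot_amp: float = 1.5):
    """Bimodal evoked response: early positive peak, deeper later undershoot."""
    t = np.arange(0.0, length_s + tr_s / 2, tr_s)
    peak = peak_amp * np.exp(-0.5 * ((t - 4.0) / 1.8) ** 2)
    undershoot = undershoot_amp * np.exp(-0.5 * ((t - 12.0) / 3.5) ** 2)
    return t, peak - undershoot


def generate_events(cfg: SyntheticConfig, rng: np.random.Generator | None = None):
    """Jittered event onsets with a guaranteed minimum gap.

    Returns ``(onsets_s, (waveform_t_s, waveform))``. Onsets are drawn
    sequentially with inter-onset interval ``min_gap + Exp(mean_extra)``
    where the mean interval matches ``event_rate`` events/minute.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 4)
    wav_t, wav = default_event_waveform(cfg.tr_s)
    if cfg.event_rate <= 0:
        return np.array([]), (wav_t, wav)
    mean_interval = 60.0 / cfg.event_rate
    extra = max(mean_interval - cfg.event_min_gap_s, 1e-6)
    onsets = []
    t = cfg.event_min_gap_s / 2 + rng.exponential(extra)
    while t < cfg.duration_s - wav_t[-1]:
        onsets.append(t)
        t += cfg.event_min_gap_s + rng.exponential(extra)
    return np.asarray(onsets), (wav_t, wav)


def add_evoked(series: np.ndarray, tr_s: float, onsets_s: np.ndarray,
               waveform_t_s: np.ndarray, waveform: np.ndarray) -> np.ndarray:
    """Superimpose the evoked waveform at each onset (linear interp to grid)."""
    out = np.asarray(series, dtype=float).copy()
    n = out.size
    t = np.arange(n) * tr_s
    for onset in np.atleast_1d(onsets_s):
        rel = t - onset
        sel = (rel >= waveform_t_s[0]) & (rel <= waveform_t_s[-1])
        out[sel] += np.interp(rel[sel], waveform_t_s, waveform)
    return out


def generate_session(cfg: SyntheticConfig, with_events: bool = False):
    """Full coupled session: arousal, physio, fMRI, multi-echo, events.

    Returns ``(bundle, truth)``; ``bundle`` holds all generated arrays.
    """
    rng = np.random.default_rng(cfg.seed)
    child = rng.spawn(6)
    arousal = generate_arousal(cfg, child[0])
    if with_events:
        onsets, (wav_t, wav) = generate_events(cfg, child[4])
    else:
        onsets, (wav_t, wav) = np.array([]), default_event_waveform(cfg.tr_s)
    if with_events and onsets.size:
        arousal = add_evoked(arousal, cfg.tr_s, onsets, wav_t, wav)
        arousal = (arousal - arousal.mean()) / arousal.std()
    signals, truth = generate_physio(cfg, arousal, child[1])
    fmri, lag_s, sign, labels = generate_fmri(cfg, arousal, child[2])
    me_data, t2s, s0, _ = generate_multiecho(cfg, arousal, child[3])
    truth.arousal = arousal
    truth.voxel_lag_s = lag_s
    truth.voxel_sign = sign
    truth.t2s_series_ms = t2s
    truth.s0_series = s0
    truth.event_waveform = wav
    truth.event_waveform_t_s = wav_t
    bundle = {
        "arousal": arousal,
        "physio": signals,
        "fmri": fmri,
        "tissue_labels": labels,
        "multiecho": me_data,
        "echo_times_ms": np.asarray(cfg.echo_times_ms, dtype=float),
        "event_onsets_s": onsets,
    }
    return bundle, truth
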