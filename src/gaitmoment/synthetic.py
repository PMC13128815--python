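"""Synthetic gait-like biosignals with a known signal-to-moment mapping.

The generator builds everything from a single gait-phase trajectory phi(t):
four nonnegative EMG envelopes (Gaussian bumps in phase), two smooth angle
trajectories (two harmonics of phi each), and two moments computed by a
known delayed, mildly nonlinear map of the angles and envelopes:

    m1 = a1*angle1(t) + b1*(env1 - env2)(t - d) + q1*angle1(t)^2
    m2 = a2*angle2(t) + b2*(env3 - env4)(t - d) + q2*angle2(t)^2

The delay d is in milliseconds (electromechanical delay), evaluated in
continuous time, so the deterministic components are identical on any
sampling grid — generating at 1000 Hz and sample-dropping to 200 Hz lands on
the same values as generating at 200 Hz directly.

Observed EMG is envelope x rectified broadband carrier (per-sample noise),
optionally with a floor so the envelope stays recoverable from short
windows.  `corrupt` injects band-limited high-frequency noise and sparse
spike artifacts into the predictors only.

All randomness flows from the config seed through fixed substream keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .signal_io import ChannelSpec, RecordingBundle, SignalRecording

# substream keys (seed, key) -> independent generators
_KEY_PHASE = 1
_KEY_CARRIER = 2
_KEY_OBS = 3
_KEY_NOISE = 4
_KEY_SPIKES = 5

EMG_NAMES = ("emg_gmed", "emg_semi", "emg_bf", "emg_rf")
ANGLE_NAMES = ("hip_adduction", "hip_flexion")
MOMENT_NAMES = ("hip_fe", "hip_aa")


@dataclass
class SyntheticConfig:
    duration_s: float = 20.0
    rate: float = 200.0
    gait_freq: float = 1.0
    freq_jitter: float = 0.03  # relative per-cycle period jitter (std)
    activation_centers: Sequence[float] = (0.05, 0.30, 0.55, 0.80)
    activation_widths: Sequence[float] = (0.10, 0.10, 0.10, 0.10)
    # per angle: ((amp1, phase1), (amp2, phase2)) for harmonics k = 1, 2 of phi;
    # the two angles are in quadrature so together they pin down gait phase
    angle_harmonics: Sequence = (
        ((10.0, 0.0), (4.0, 1.2)),
        ((10.0, 1.5708), (4.0, 2.8)),
    )
    moment_lin_angle: Sequence[float] = (0.9, 0.9)
    moment_env_gain: Sequence[float] = (30.0, 30.0)
    moment_quad: Sequence[float] = (0.012, 0.012)
    delay_ms: float = 50.0
    carrier_floor: float = 0.7  # 0 = pure rectified carrier, 1 = pure envelope
    obs_noise: float = 0.0  # moment observation noise, relative to moment std
    noise_sigma: float = 0.0
    spike_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.rate <= 0 or self.gait_freq <= 0:
            raise ParameterError("duration_s, rate and gait_freq must be positive")
        if self.noise_sigma < 0 or self.spike_rate < 0:
            raise ParameterError("noise_sigma and spike_rate must be >= 0")
        if not 0.0 <= self.carrier_floor <= 1.0:
            raise ParameterError("carrier_floor must be in [0, 1]")
        if len(self.activation_centers) != 4 or len(self.activation_widths) != 4:
            raise ParameterError("exactly 4 EMG activation centers/widths required")
        if len(self.angle_harmonics) != 2:
            raise ParameterError("exactly 2 angle channels are modelled")


def _rng(cfg: SyntheticConfig, key: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, key])


def _phase_boundaries(cfg: SyntheticConfig) -> np.ndarray:
    """Cycle boundary times; depends on seed and duration only, not rate."""
    n_cycles = int(np.ceil(cfg.duration_s * cfg.gait_freq)) + 3
    rng = _rng(cfg, _KEY_PHASE)
    jitter = np.clip(rng.normal(0.0, cfg.freq_jitter, n_cycles), -0.3, 0.3)
    periods = (1.0 / cfg.gait_freq) * (1.0 + jitter)
    return np.concatenate([[0.0], np.cumsum(periods)])


def _phase_at(cfg: SyntheticConfig, t: np.ndarray) -> np.ndarray:
    bounds = _phase_boundaries(cfg)
    return np.interp(t, bounds, np.arange(len(bounds), dtype=np.float64))


def _envelopes(cfg: SyntheticConfig, phi: np.ndarray) -> np.ndarray:
    """(n, 4) nonnegative activation envelopes, wrapped Gaussian bumps."""
    frac = np.mod(phi, 1.0)
    envs = []
    for center, width in zip(cfg.activation_centers, cfg.activation_widths):
        d = np.abs(frac - center)
        d = np.minimum(d, 1.0 - d)  # wrapped phase distance
        envs.append(np.exp(-0.5 * (d / width) ** 2))
    return np.stack(envs, axis=1)


def _angles(cfg: SyntheticConfig, phi: np.ndarray) -> np.ndarray:
    """(n, 2) smooth angle trajectories from the configured harmonics."""
    cols = []
    for harmonics in cfg.angle_harmonics:
        total = np.zeros_like(phi)
        for k, (amp, phase) in enumerate(harmonics, start=1):
            total += amp * np.cos(2.0 * np.pi * k * phi + phase)
        cols.append(total)
    return np.stack(cols, axis=1)


def deterministic_components(
    cfg: SyntheticConfig, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Envelopes (n,4), angles (n,2) and clean moments (n,2) at times `t`.

    Pure functions of absolute time, so values agree across sampling grids.
    """
    t = np.asarray(t, dtype=np.float64)
    phi = _phase_at(cfg, t)
    envs = _envelopes(cfg, phi)
    angles = _angles(cfg, phi)
    phi_delayed = _phase_at(cfg, np.maximum(t - cfg.delay_ms / 1000.0, 0.0))
    envs_d = _envelopes(cfg, phi_delayed)
    moments = np.empty((len(t), 2))
    pairs = ((0, 1), (2, 3))
    for j in range(2):
        a, b, q = cfg.moment_lin_angle[j], cfg.moment_env_gain[j], cfg.moment_quad[j]
        i1, i2 = pairs[j]
        ang = angles[:, j]
        moments[:, j] = a * ang + b * (envs_d[:, i1] - envs_d[:, i2]) + q * ang**2
    return envs, angles, moments


def generate(cfg: SyntheticConfig) -> tuple[RecordingBundle, RecordingBundle]:
    """Generate (noisy, clean) aligned recording bundles.

    The clean bundle has no injected noise or spikes; with noise_sigma = 0,
    spike_rate = 0 and obs_noise = 0 the two are identical.
    """
    n = int(round(cfg.duration_s * cfg.rate))
    if n < 1:
        raise ParameterError("duration too short for a single sample")
    t = np.arange(n) / cfg.rate
    envs, angles, moments = deterministic_components(cfg, t)

    carrier = np.abs(_rng(cfg, _KEY_CARRIER).standard_normal((n, 4)))
    mix = cfg.carrier_floor + (1.0 - cfg.carrier_floor) * carrier
    emg = envs * mix

    pred_channels = [ChannelSpec(name, "emg", "mV") for name in EMG_NAMES] + [
        ChannelSpec(name, "angle", "deg") for name in ANGLE_NAMES
    ]
    tgt_channels = [ChannelSpec(name, "moment", "N·m") for name in MOMENT_NAMES]

    predictors = SignalRecording(
        channels=pred_channels,
        samples=np.hstack([emg, angles]),
        rate=cfg.rate,
        subject_id="synthetic",
        trial_id=f"seed{cfg.seed}",
    )
    targets_clean = moments
    targets = targets_clean
    if cfg.obs_noise > 0:
        obs = _rng(cfg, _KEY_OBS)
        scale = cfg.obs_noise * targets_clean.std(axis=0)
        targets = targets_clean + obs.standard_normal(targets_clean.shape) * scale

    clean = RecordingBundle(
        predictors=predictors,
        targets=SignalRecording(
            channels=tgt_channels, samples=targets_clean, rate=cfg.rate,
            subject_id="synthetic", trial_id=f"seed{cfg.seed}",
        ),
        aligned=True,
    )
    noisy_pred = predictors
    if cfg.noise_sigma > 0 or cfg.spike_rate > 0:
        noisy_pred = corrupt(
            predictors, cfg.noise_sigma, cfg.spike_rate, cfg.seed,
            gait_freq=cfg.gait_freq,
        )
    noisy = RecordingBundle(
        predictors=noisy_pred,
        targets=SignalRecording(
            channels=tgt_channels, samples=targets, rate=cfg.rate,
            subject_id="synthetic", trial_id=f"seed{cfg.seed}",
        ),
        aligned=True,
    )
    return noisy, clean


def corrupt(
    rec: SignalRecording,
    noise_sigma: float,
    spike_rate: float,
    seed: int,
    gait_freq: float = 1.0,
) -> SignalRecording:
    """Inject high-frequency noise and transient spikes ("local features").

    Noise is Gaussian, high-passed above 10x the gait frequency (half of
    20x) via FFT masking, scaled to noise_sigma times each channel's std.
    Spikes are Poisson-placed single samples of amplitude 5x the channel
    std with random sign.  Targets are never passed through this function.
    """
    if noise_sigma < 0 or spike_rate < 0:
        raise ParameterError("noise_sigma and spike_rate must be >= 0")
    if noise_sigma == 0 and spike_rate == 0:
        return replace(rec, samples=rec.samples.copy())
    n, c = rec.samples.shape
    out = rec.samples.copy()
    if noise_sigma > 0:
        rng = np.random.default_rng([seed, _KEY_NOISE])
        white = rng.standard_normal((n, c))
        spec = np.fft.rfft(white, axis=0)
        freqs = np.fft.rfftfreq(n, d=1.0 / rec.rate)
        cutoff = 10.0 * gait_freq  # half of 20x the gait frequency
        spec[freqs < cutoff] = 0.0
        hf = np.fft.irfft(spec, n=n, axis=0)
        hf_std = hf.std(axis=0)
        hf_std[hf_std == 0] = 1.0
        scale = noise_sigma * rec.samples.std(axis=0) / hf_std
        out = out + hf * scale
    if spike_rate > 0:
        rng = np.random.default_rng([seed, _KEY_SPIKES])
        duration = n / rec.rate
        for ch in range(c):
            count = rng.poisson(spike_rate * duration)
            if count == 0:
                continue
            pos = rng.integers(0, n, size=count)
            sign = rng.choice([-1.0, 1.0], size=count)
            out[pos, ch] += sign * 5.0 * rec.samples[:, ch].std()
    return replace(rec, samples=out)
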