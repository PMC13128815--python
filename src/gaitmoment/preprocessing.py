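"""Windowing, per-channel normalization and spectral transformation.

Windows are 0-based and half-open: window i covers samples
[i*stride, i*stride + window_len).  The target of a window is the moment
vector at its last sample (causal labelling) unless `target_alignment`
selects the window center.  The spectral transform is the full two-sided
DFT magnitude, so the feature length equals the window length.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import (
    DegenerateChannelError,
    InsufficientDataError,
    ParameterError,
)
from .signal_io import RecordingBundle


@dataclass
class NormStats:
    """Per-channel z-score statistics fitted on training windows."""

    mean: np.ndarray  # (n_channels,)
    std: np.ndarray  # (n_channels,)
    channel_names: list[str]


@dataclass
class WindowSet:
    """Overlapping windows with aligned targets.

    windows: (n_windows, window_len, n_pred_channels)
    targets: (n_windows, n_targets)
    """

    windows: np.ndarray
    targets: np.ndarray
    window_len: int
    stride: int
    rate: float
    channel_names: list[str]
    target_names: list[str]
    norm_stats: Optional[NormStats] = None

    def __post_init__(self):
        if self.window_len < 1 or self.stride < 1:
            raise ParameterError("window_len and stride must be >= 1")
        if self.windows.shape[0] != self.targets.shape[0]:
            raise ParameterError("windows/targets count mismatch")
        if self.windows.shape[1] != self.window_len:
            raise ParameterError("window axis does not match window_len")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[2]

    @property
    def n_targets(self) -> int:
        return self.targets.shape[1]

    def slice(self, idx) -> "WindowSet":
        return replace(self, windows=self.windows[idx], targets=self.targets[idx])


@dataclass
class SpectralWindow:
    """Two-sided DFT magnitudes (and optionally phases) per window/channel."""

    magnitudes: np.ndarray  # (n_windows, window_len, n_pred_channels), >= 0
    fft_mode: str = "magnitude"
    phase: Optional[np.ndarray] = None


def expected_window_count(n_time: int, window_len: int, stride: int) -> int:
    """floor((n_time - window_len)/stride) + 1, the sliding-window count."""
    return (n_time - window_len) // stride + 1


def segment(
    bundle: RecordingBundle,
    window_len: int,
    stride: int = 1,
    target_alignment: str = "last",
) -> WindowSet:
    """Cut an aligned bundle into overlapping windows with causal targets."""
    if stride < 1:
        raise ParameterError(f"stride must be >= 1, got {stride}")
    if window_len < 1:
        raise ParameterError(f"window_len must be >= 1, got {window_len}")
    if not bundle.aligned:
        raise ParameterError("bundle must be aligned before segmentation")
    if target_alignment not in ("last", "center"):
        raise ParameterError(f"unknown target_alignment {target_alignment!r}")
    x = bundle.predictors.samples
    y = bundle.targets.samples
    n_time = x.shape[0]
    if n_time < window_len:
        raise InsufficientDataError(
            f"trace of {n_time} samples is shorter than one window ({window_len})"
        )
    n_windows = expected_window_count(n_time, window_len, stride)
    starts = np.arange(n_windows) * stride
    windows = np.stack([x[s : s + window_len] for s in starts])
    offset = window_len - 1 if target_alignment == "last" else window_len // 2
    targets = y[starts + offset]
    return WindowSet(
        windows=windows,
        targets=targets,
        window_len=window_len,
        stride=stride,
        rate=bundle.predictors.rate,
        channel_names=bundle.predictors.channel_names(),
        target_names=bundle.targets.channel_names(),
    )


def fit_normalizer(train: WindowSet) -> NormStats:
    """Per-channel mean/std over all training samples (population std)."""
    if train.n_windows == 0:
        raise ParameterError("cannot fit normalizer on an empty window set")
    flat = train.windows.reshape(-1, train.n_channels)
    mean = flat.mean(axis=0)
    std = flat.std(axis=0)
    bad = np.flatnonzero(std <= 0)
    if bad.size:
        names = ", ".join(train.channel_names[i] for i in bad)
        raise DegenerateChannelError(f"zero-variance channel(s): {names}")
    return NormStats(mean=mean, std=std, channel_names=list(train.channel_names))


def apply_normalizer(ws: WindowSet, stats: NormStats) -> WindowSet:
    """z-score predictor channels; targets are never normalized."""
    normalized = (ws.windows - stats.mean) / stats.std
    return replace(ws, windows=normalized, norm_stats=stats)


def spectral_transform(
    windows: WindowSet | np.ndarray, fft_mode: str = "magnitude"
) -> SpectralWindow:
    """Full two-sided DFT magnitude of each window, per channel.

    The feature length equals window_len: |X_k| for k = 0..window_len-1.
    Phases are kept only in ``magnitude_and_phase`` mode.
    """
    if fft_mode not in ("magnitude", "magnitude_and_phase"):
        raise ParameterError(f"unknown fft_mode {fft_mode!r}")
    data = windows.windows if isinstance(windows, WindowSet) else np.asarray(windows)
    spectra = np.fft.fft(data, axis=1)
    magnitudes = np.abs(spectra)
    phase = np.angle(spectra) if fft_mode == "magnitude_and_phase" else None
    return SpectralWindow(magnitudes=magnitudes, fft_mode=fft_mode, phase=phase)
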