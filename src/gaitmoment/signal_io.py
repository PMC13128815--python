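"""Reading, resampling and aligning multichannel biosignal recordings.

Recordings are delimited text tables (CSV with a header row, one column per
channel, optional time column).  Rows containing NaN in any mapped column are
dropped and counted; nothing is ever interpolated.  Decimation is pure
sample-dropping with phase fixed at sample 0 — an optional low-pass flag
exists for callers who want anti-aliasing, but it defaults off.
"""

from __future__ import annotations

import glob as _glob
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, EmptyDataError, ParameterError, SchemaError

logger = logging.getLogger(__name__)

CHANNEL_KINDS = ("emg", "angle", "moment")

# CSV float format chosen so that write -> read is exact for float64
_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class ChannelSpec:
    """Name, role and units of one recorded channel."""

    name: str
    kind: str
    units: str = ""

    def __post_init__(self):
        if not self.name:
            raise ParameterError("channel name must be nonempty")
        if self.kind not in CHANNEL_KINDS:
            raise ParameterError(
                f"channel kind must be one of {CHANNEL_KINDS}, got {self.kind!r}"
            )


@dataclass
class SignalRecording:
    """A uniformly sampled multichannel trace.

    samples has shape (n_time, n_channels); `rate` is in Hz.  Construction
    validates finiteness — NaN rows must be dropped upstream (see
    :func:`read_table_recording`).
    """

    channels: list[ChannelSpec]
    samples: np.ndarray
    rate: float
    subject_id: str = ""
    trial_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ParameterError("samples must be a 2-D (n_time, n_channels) array")
        if self.rate <= 0:
            raise ParameterError(f"rate must be positive, got {self.rate}")
        if self.samples.shape[1] != len(self.channels):
            raise ParameterError(
                f"samples has {self.samples.shape[1]} columns for "
                f"{len(self.channels)} channels"
            )
        if self.samples.shape[0] < 1:
            raise EmptyDataError("recording has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("samples contain NaN/Inf after validation")

    @property
    def n_time(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def duration_s(self) -> float:
        return self.n_time / self.rate

    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def select(self, kinds: Iterable[str]) -> "SignalRecording":
        """Return a copy keeping only channels of the given kinds (order kept)."""
        kinds = set(kinds)
        idx = [i for i, c in enumerate(self.channels) if c.kind in kinds]
        if not idx:
            raise EmptyDataError(f"no channels of kind {sorted(kinds)}")
        return replace(
            self,
            channels=[self.channels[i] for i in idx],
            samples=self.samples[:, idx],
        )


@dataclass
class RecordingBundle:
    """Predictor (emg+angle) and target (moment) recordings, possibly aligned."""

    predictors: SignalRecording
    targets: SignalRecording
    aligned: bool = False

    def __post_init__(self):
        if self.aligned:
            if self.predictors.rate != self.targets.rate:
                raise AlignmentError("aligned bundle with mismatched rates")
            if self.predictors.n_time != self.targets.n_time:
                raise AlignmentError("aligned bundle with mismatched lengths")


def read_table_recording(
    path: str | os.PathLike,
    channel_map: Sequence[tuple[str, ChannelSpec]] | Mapping[str, ChannelSpec],
    rate: float,
    subject_id: str = "",
    trial_id: str = "",
    sep: str = ",",
) -> SignalRecording:
    """Read a delimited table into a :class:`SignalRecording`.

    `channel_map` is an ordered mapping from column name to
    :class:`ChannelSpec`; output columns follow its order.  Rows with NaN in
    any mapped column are dropped and the count is logged.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    items = list(channel_map.items()) if isinstance(channel_map, Mapping) else list(channel_map)
    frame = pd.read_csv(path, sep=sep)
    missing = [col for col, _ in items if col not in frame.columns]
    if missing:
        raise SchemaError(f"missing mapped column(s): {', '.join(missing)}")
    sub = frame[[col for col, _ in items]].astype(np.float64)
    mask = sub.notna().all(axis=1)
    dropped = int((~mask).sum())
    if dropped:
        logger.info("dropped %d row(s) with NaN from %s", dropped, path)
    sub = sub[mask]
    if len(sub) == 0:
        raise EmptyDataError(f"no usable rows in {path}")
    return SignalRecording(
        channels=[spec for _, spec in items],
        samples=sub.to_numpy(),
        rate=rate,
        subject_id=subject_id,
        trial_id=trial_id,
    )


def write_fixture(
    rec: SignalRecording, path: str | os.PathLike, time_column: bool = True
) -> None:
    """Write a recording as CSV, bit-stably (comma, '.' decimal, LF ends).

    The float format round-trips float64 exactly, so a written fixture read
    back with :func:`read_table_recording` reproduces the samples.
    """
    cols = {}
    if time_column:
        cols["t"] = np.arange(rec.n_time) / rec.rate
    for i, ch in enumerate(rec.channels):
        cols[ch.name] = rec.samples[:, i]
    frame = pd.DataFrame(cols)
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def decimate(
    rec: SignalRecording, step_ms: float, lowpass: bool = False
) -> SignalRecording:
    """Keep every k-th sample, where k = step_ms * rate / 1000.

    The step must correspond to an integer decimation factor; no resampling
    interpolation is attempted.  The first retained sample is sample 0 and
    the new rate is 1000/step_ms Hz.  With ``lowpass=True`` an order-8
    Chebyshev anti-alias filter is applied first (scipy); default is pure
    sample dropping.
    """
    if step_ms <= 0:
        raise ParameterError(f"step_ms must be positive, got {step_ms}")
    factor = step_ms * rec.rate / 1000.0
    k = int(round(factor))
    if k < 1 or abs(factor - k) > 1e-9:
        raise ParameterError(
            f"step {step_ms} ms is not an integer multiple of the sample "
            f"period {1000.0 / rec.rate} ms (factor {factor})"
        )
    if k == 1:
        return replace(rec, samples=rec.samples.copy())
    samples = rec.samples
    if lowpass:
        from scipy.signal import decimate as _sp_decimate

        samples = _sp_decimate(samples, k, axis=0, zero_phase=True)
        new = samples
    else:
        new = samples[::k]
    return replace(rec, samples=np.ascontiguousarray(new), rate=rec.rate / k)


def align_bundle(
    predictors: SignalRecording, targets: SignalRecording
) -> RecordingBundle:
    """Bring predictors and targets onto a common grid.

    If the rates differ by an integer factor the faster recording is
    decimated (sample dropping) to the slower; both are then truncated to
    the common length.
    """
    fast, slow = predictors, targets
    if fast.rate != slow.rate:
        hi, lo = (predictors, targets) if predictors.rate > targets.rate else (targets, predictors)
        ratio = hi.rate / lo.rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise AlignmentError(
                f"rates {predictors.rate} and {targets.rate} Hz differ by a "
                f"non-integer factor {ratio}"
            )
        step_ms = 1000.0 / lo.rate
        if predictors.rate > targets.rate:
            predictors = decimate(predictors, step_ms)
        else:
            targets = decimate(targets, step_ms)
    n = min(predictors.n_time, targets.n_time)
    if predictors.n_time != n:
        predictors = replace(predictors, samples=predictors.samples[:n].copy())
    if targets.n_time != n:
        targets = replace(targets, samples=targets.samples[:n].copy())
    return RecordingBundle(predictors=predictors, targets=targets, aligned=True)


def read_nested_directory(
    root: str | os.PathLike,
    pattern: str,
    channel_map: Sequence[tuple[str, ChannelSpec]] | Mapping[str, ChannelSpec],
    rate: float,
) -> list[SignalRecording]:
    """Load per-trial tables from a subject/date/mode/sensor directory tree.

    `pattern` is a glob relative to `root` (e.g. ``"*/*/treadmill/emg/*.csv"``).
    One recording is returned per matched file, with subject and trial ids
    derived from the path (first component and file stem respectively),
    sorted by path for determinism.
    """
    paths = sorted(_glob.glob(os.path.join(str(root), pattern)))
    if not paths:
        raise EmptyDataError(f"no files match {pattern!r} under {root}")
    recordings = []
    for p in paths:
        rel = os.path.relpath(p, root)
        parts = rel.split(os.sep)
        subject = parts[0] if len(parts) > 1 else ""
        trial = os.path.splitext(os.path.basename(p))[0]
        recordings.append(
            read_table_recording(p, channel_map, rate, subject_id=subject, trial_id=trial)
        )
    return recordings
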