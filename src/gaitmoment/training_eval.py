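"""Training loop, split protocols, and the three regression metrics.

Conventions fixed here for reproducibility:

* VAF uses the population variance (divisor N) of the residual and of the
  actual values; the +- aggregation across test trials uses the sample
  standard deviation (divisor n-1), reported as 0 for a single trial.
* BMI is rounded half-away-from-zero to one decimal.
* The "first trial" of the train-on-first protocol is the lexicographically
  smallest trial id; the 80/20 protocol splits chronologically, no shuffle
  (gait data are autocorrelated).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .autodiff import Adam, Tensor
from .errors import (
    ConfigurationError,
    DimensionError,
    DivergenceError,
    DomainError,
    EmptyDataError,
    ParameterError,
)
from .model import ModelConfig, MomentModel
from .preprocessing import WindowSet

# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _as_pair(p, p_hat) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64).ravel()
    p_hat = np.asarray(p_hat, dtype=np.float64).ravel()
    if p.shape != p_hat.shape:
        raise DimensionError(f"length mismatch: {p.shape} vs {p_hat.shape}")
    if p.size == 0:
        raise ParameterError("metrics need at least one sample")
    return p, p_hat


def rmse(p, p_hat) -> float:
    """Root mean squared error, sqrt(mean((p - p_hat)^2))."""
    p, p_hat = _as_pair(p, p_hat)
    return float(np.sqrt(np.mean((p - p_hat) ** 2)))


def r_squared(p, p_hat) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot."""
    p, p_hat = _as_pair(p, p_hat)
    if p.size < 2:
        raise ParameterError("r_squared needs at least two samples")
    ss_tot = np.sum((p - p.mean()) ** 2)
    if ss_tot == 0:
        raise DomainError("r_squared undefined for constant actual values")
    return float(1.0 - np.sum((p - p_hat) ** 2) / ss_tot)


def vaf(p, p_hat) -> float:
    """Variance accounted for, 1 - var(p_hat - p)/var(p), population variance.

    Unlike R^2, a constant prediction offset does not lower VAF.
    """
    p, p_hat = _as_pair(p, p_hat)
    if p.size < 2:
        raise ParameterError("vaf needs at least two samples")
    denom = np.var(p)
    if denom == 0:
        raise DomainError("vaf undefined for constant actual values")
    return float(1.0 - np.var(p_hat - p) / denom)


_BMI_BANDS = (
    (18.5, "Underweight"),
    (25.0, "Normal weight"),
    (30.0, "Overweight"),
    (math.inf, "Obese"),
)


def bmi(mass_kg: float, height_cm: float) -> tuple[float, str]:
    """Body-mass index mass/(height in m)^2, rounded to 1 decimal.

    Rounding is half-away-from-zero so printed values like 18.5 or 27.4 are
    reproduced exactly; the classification uses the rounded value.
    """
    if mass_kg <= 0 or height_cm <= 0:
        raise DomainError("mass and height must be positive")
    raw = mass_kg / (height_cm / 100.0) ** 2
    value = math.floor(raw * 10 + 0.5) / 10.0
    for upper, label in _BMI_BANDS:
        if value < upper:
            return value, label
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# split protocols
# ---------------------------------------------------------------------------


@dataclass
class SplitProtocol:
    """Trial-level train/test assignment.

    ``first_trial_train_rest_test``: lexicographically first trial trains,
    the rest test (needs >= 2 trials).  ``fraction_80_20``: each trial is
    split chronologically, first 80% train.
    """

    scheme: str
    trial_ids: list[str] = field(default_factory=list)

    SCHEMES = ("first_trial_train_rest_test", "fraction_80_20")

    def __post_init__(self):
        if self.scheme not in self.SCHEMES:
            raise ConfigurationError(f"unknown split scheme {self.scheme!r}")
        if self.scheme == "first_trial_train_rest_test" and len(self.trial_ids) < 2:
            raise ConfigurationError("first-trial protocol needs at least two trials")

    def split_ids(self) -> tuple[list[str], list[str]]:
        ordered = sorted(self.trial_ids)
        if self.scheme == "first_trial_train_rest_test":
            return ordered[:1], ordered[1:]
        return ordered, ordered


def split_fraction(ws: WindowSet, train_frac: float = 0.8) -> tuple[WindowSet, WindowSet]:
    """Chronological split of one window set (first `train_frac` trains)."""
    if not 0 < train_frac < 1:
        raise ParameterError("train_frac must be in (0, 1)")
    n_train = int(ws.n_windows * train_frac)
    if n_train == 0 or n_train == ws.n_windows:
        raise EmptyDataError("fraction split leaves an empty train or test set")
    return ws.slice(slice(0, n_train)), ws.slice(slice(n_train, None))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train(
    model: MomentModel,
    train_windows: WindowSet,
    cfg: Optional[ModelConfig] = None,
) -> list[float]:
    """Minibatch Adam on MSE (+ optional reconstruction term), no early stop.

    Runs exactly cfg.epochs epochs with batches of cfg.batch windows in a
    seeded shuffled order; returns the per-epoch mean loss (cfg.epochs
    entries).  Raises :class:`DivergenceError` on a non-finite loss.
    """
    cfg = cfg or model.cfg
    n = train_windows.n_windows
    if n == 0:
        raise EmptyDataError("empty training window set")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    use_recon = model.flags["autoencoder"] and cfg.aux_recon_weight > 0
    history: list[float] = []
    x = train_windows.windows
    y = train_windows.targets
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch):
            idx = order[start : start + cfg.batch]
            pred, recon = model.forward_batch(x[idx], training=True, rng=rng)
            diff = pred - Tensor(y[idx])
            loss = (diff * diff).mean()
            if use_recon and recon is not None:
                loss = loss + cfg.aux_recon_weight * recon
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        epoch_loss = float(np.mean(losses))
        if not np.isfinite(epoch_loss):
            raise DivergenceError(epoch)
        history.append(epoch_loss)
    return history


# ---------------------------------------------------------------------------
# evaluation reports
# ---------------------------------------------------------------------------


@dataclass
class MetricRow:
    target: str
    trial_id: str
    rmse: float
    r2: float
    vaf: float


@dataclass
class EvaluationReport:
    """Per-(target, trial) metrics plus mean +- std aggregates per target."""

    rows: list[MetricRow]
    aggregates: dict[str, dict[str, tuple[float, float]]]
    seed: int = 0
    config_hash: str = ""

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["target", "trial_id", "rmse", "r2", "vaf"])
            for r in self.rows:
                w.writerow([r.target, r.trial_id, repr(r.rmse), repr(r.r2), repr(r.vaf)])

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "aggregates": {
                tgt: {m: {"mean": mu, "std": sd} for m, (mu, sd) in metrics.items()}
                for tgt, metrics in self.aggregates.items()
            },
            "rows": [vars(r) for r in self.rows],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    def summary(self) -> str:
        lines = [f"{'target':<10}{'metric':<8}{'mean':>10}{'std':>10}"]
        for tgt, metrics in self.aggregates.items():
            for m, (mu, sd) in metrics.items():
                lines.append(f"{tgt:<10}{m:<8}{mu:>10.3f}{sd:>10.3f}")
        return "\n".join(lines)


def _aggregate(rows: Sequence[MetricRow]) -> dict[str, dict[str, tuple[float, float]]]:
    out: dict[str, dict[str, tuple[float, float]]] = {}
    targets = sorted({r.target for r in rows})
    for tgt in targets:
        sub = [r for r in rows if r.target == tgt]
        out[tgt] = {}
        for metric in ("rmse", "r2", "vaf"):
            vals = np.array([getattr(r, metric) for r in sub])
            std = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            out[tgt][metric] = (float(vals.mean()), std)
    return out


def evaluate(
    model: MomentModel,
    protocol: SplitProtocol,
    trials: Mapping[str, WindowSet],
) -> EvaluationReport:
    """Compute per-test-trial metrics for a trained model.

    For the first-trial protocol the test trials are all but the first; for
    the 80/20 protocol the chronological tail of each trial is scored.
    """
    missing = [t for t in protocol.trial_ids if t not in trials]
    if missing:
        raise ConfigurationError(f"protocol names unknown trials: {missing}")
    _, test_ids = protocol.split_ids()
    rows: list[MetricRow] = []
    for tid in test_ids:
        ws = trials[tid]
        if protocol.scheme == "fraction_80_20":
            _, ws = split_fraction(ws)
        pred = model.predict(ws)
        for j, name in enumerate(ws.target_names):
            rows.append(
                MetricRow(
                    target=name,
                    trial_id=tid,
                    rmse=rmse(ws.targets[:, j], pred[:, j]),
                    r2=r_squared(ws.targets[:, j], pred[:, j]),
                    vaf=vaf(ws.targets[:, j], pred[:, j]),
                )
            )
    return EvaluationReport(
        rows=rows,
        aggregates=_aggregate(rows),
        seed=model.cfg.seed,
        config_hash=model.cfg.hash(),
    )
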