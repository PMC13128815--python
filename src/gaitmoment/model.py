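"""Sequence regression core: LSTM cell, attention head, variant factory.

The ablation ladder has five variants:

  I    plain LSTM over the raw time-domain window (last hidden state -> head)
  II   LSTM + attention over the raw window
  III  spectral magnitudes -> shared encoder -> LSTM (last hidden -> head)
  IV   as III plus attention over the hidden states
  V    as IV plus the conv refiner on the latent codes (the full model)

For variants III-V the LSTM iterates over the latent-feature axis (length
window_len/4) with the predictor channels as per-step features; this keeps
one prediction per window and lets attention weight frequency-derived steps.
Variants I-II iterate over the raw time axis.  This wiring is an
interpretation choice and is documented in the README.

`lstm_step` and `attention` below are the plain-numpy reference forms of the
recurrence and the softmax pooling; :class:`MomentModel` re-expresses them on
the autodiff tape for training, and the test suite checks the two routes
against each other.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autoencoder import (
    AutoencoderParams,
    ConvRefinerParams,
    LatentFeatures,
    conv_refine,
    decode,
    encode,
)
from .errors import ConfigurationError, DimensionError, ParameterError
from .preprocessing import WindowSet, spectral_transform

VARIANTS = ("I", "II", "III", "IV", "V")


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ez = np.exp(x[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# reference (numpy) forms
# ---------------------------------------------------------------------------


@dataclass
class LSTMParams:
    """Gate matrices W_* (hidden x feature), U_* (hidden x hidden), biases.

    Biases default to zero vectors; the printed recurrence has no bias terms,
    and equation-conformance tests run with biases zeroed.
    """

    W_i: np.ndarray
    W_f: np.ndarray
    W_o: np.ndarray
    W_c: np.ndarray
    U_i: np.ndarray
    U_f: np.ndarray
    U_o: np.ndarray
    U_c: np.ndarray
    b_i: Optional[np.ndarray] = None
    b_f: Optional[np.ndarray] = None
    b_o: Optional[np.ndarray] = None
    b_c: Optional[np.ndarray] = None

    def __post_init__(self):
        w_shape = self.W_i.shape
        u_shape = self.U_i.shape
        hidden = w_shape[0]
        for name in ("W_f", "W_o", "W_c"):
            if getattr(self, name).shape != w_shape:
                raise DimensionError(f"{name} shape differs from W_i {w_shape}")
        for name in ("U_f", "U_o", "U_c"):
            if getattr(self, name).shape != u_shape:
                raise DimensionError(f"{name} shape differs from U_i {u_shape}")
        if u_shape != (hidden, hidden):
            raise DimensionError(f"U matrices must be square (hidden x hidden)")
        for name in ("b_i", "b_f", "b_o", "b_c"):
            b = getattr(self, name)
            if b is None:
                setattr(self, name, np.zeros(hidden))
            elif b.shape != (hidden,):
                raise DimensionError(f"{name} must have length {hidden}")

    @property
    def hidden(self) -> int:
        return self.W_i.shape[0]

    @property
    def feature(self) -> int:
        return self.W_i.shape[1]


@dataclass
class LSTMState:
    """Cell memory C and hidden state H, both length `hidden`."""

    C: np.ndarray
    H: np.ndarray

    def __post_init__(self):
        if self.C.shape != self.H.shape:
            raise DimensionError("C and H must share shape")
        if not (np.all(np.isfinite(self.C)) and np.all(np.isfinite(self.H))):
            raise ParameterError("LSTM state must be finite")


@dataclass
class AttentionParams:
    """Score vector W (length hidden) mapping each hidden state to a scalar."""

    W: np.ndarray

    def __post_init__(self):
        if self.W.ndim != 1:
            raise DimensionError("attention W must be a vector")


def lstm_step(t: np.ndarray, prev: LSTMState, params: LSTMParams) -> LSTMState:
    """One recurrence step.

    I = sigma(W_i t + U_i H);  F = sigma(W_f t + U_f H);
    O = sigma(W_o t + U_o H);  Ccand = tanh(W_c t + U_c H);
    C' = F*C + I*Ccand;        H' = O * tanh(C').
    """
    t = np.asarray(t, dtype=np.float64)
    if t.shape != (params.feature,):
        raise DimensionError(f"input must have length {params.feature}, got {t.shape}")
    if prev.H.shape != (params.hidden,):
        raise DimensionError("previous state does not match hidden size")
    if not np.all(np.isfinite(t)):
        raise ParameterError("non-finite input to lstm_step")
    h_prev = prev.H
    gate_i = _sigmoid(params.W_i @ t + params.U_i @ h_prev + params.b_i)
    gate_f = _sigmoid(params.W_f @ t + params.U_f @ h_prev + params.b_f)
    gate_o = _sigmoid(params.W_o @ t + params.U_o @ h_prev + params.b_o)
    cand = np.tanh(params.W_c @ t + params.U_c @ h_prev + params.b_c)
    c_new = gate_f * prev.C + gate_i * cand
    h_new = gate_o * np.tanh(c_new)
    return LSTMState(C=c_new, H=h_new)


def attention(x: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Softmax-weighted pooling of a (T, hidden) sequence of hidden states.

    scores_t = x_t . W; weights = softmax(scores); context = sum_t w_t x_t.
    Softmax uses max-subtraction (mathematically identical, numerically safe).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise DimensionError("x must be (T, hidden)")
    if x.shape[0] == 0:
        raise ParameterError("attention over an empty sequence")
    if x.shape[1] != params.W.shape[0]:
        raise DimensionError("hidden size mismatch between x and attention W")
    scores = x @ params.W
    e = np.exp(scores - scores.max())
    weights = e / e.sum()
    return weights @ x


# ---------------------------------------------------------------------------
# configuration and trainable model
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """Hyperparameters of one run; defaults follow the training protocol
    (Adam lr 0.001, MSE, dropout 0.2, 30 epochs, batch 60, window 60)."""

    variant: str = "V"
    window_len: int = 60
    stride: int = 1
    hidden: int = 64
    n_channels: int = 6
    conv_kernel: int = 3
    fft_mode: str = "magnitude"
    dropout: float = 0.2
    lr: float = 0.001
    epochs: int = 30
    batch: int = 60
    n_targets: int = 2
    aux_recon_weight: float = 0.1
    target_alignment: str = "last"
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        if self.window_len % 4 != 0:
            raise ConfigurationError("window_len must be divisible by 4")
        if self.conv_kernel % 2 == 0:
            raise ConfigurationError("conv_kernel must be odd")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")

    @property
    def latent_dim(self) -> int:
        return self.window_len // 4

    def component_flags(self) -> dict[str, bool]:
        v = self.variant
        return {
            "spectral": v in ("III", "IV", "V"),
            "autoencoder": v in ("III", "IV", "V"),
            "conv": v == "V",
            "attention": v in ("II", "IV", "V"),
        }

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class MomentModel:
    """Trainable joint-moment regressor for one ablation variant.

    Parameters live in `self.params` (name -> autodiff Tensor).  Evaluation
    forward passes are pure functions of the input and parameters; dropout
    is applied only when `training=True` and an rng is supplied.
    """

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.flags = cfg.component_flags()
        rng = np.random.default_rng(cfg.seed)
        p: dict[str, ad.Tensor] = {}
        d = cfg.window_len
        h, q = d // 2, d // 4
        c = cfg.n_channels
        hid = cfg.hidden
        if self.flags["autoencoder"]:
            p["enc.W1"] = self._param(rng, (h, d), d)
            p["enc.b1"] = self._param(rng, (h,), d)
            p["enc.W2"] = self._param(rng, (q, h), h)
            p["enc.b2"] = self._param(rng, (q,), h)
            p["dec.W3"] = self._param(rng, (h, q), q)
            p["dec.b3"] = self._param(rng, (h,), q)
            p["dec.W4"] = self._param(rng, (d, h), h)
            p["dec.b4"] = self._param(rng, (d,), h)
        if self.flags["conv"]:
            fan = c * cfg.conv_kernel
            p["conv.kernels"] = self._param(rng, (c, c, cfg.conv_kernel), fan)
            p["conv.biases"] = self._param(rng, (c,), fan)
        feat = c  # per-step feature count is the channel count in all variants
        for gate in ("i", "f", "o", "c"):
            p[f"lstm.W_{gate}"] = self._param(rng, (hid, feat), feat)
            p[f"lstm.U_{gate}"] = self._param(rng, (hid, hid), hid)
            p[f"lstm.b_{gate}"] = self._param(rng, (hid,), hid)
        if self.flags["attention"]:
            p["att.W"] = self._param(rng, (hid,), hid)
        p["head.W"] = self._param(rng, (cfg.n_targets, hid), hid)
        p["head.b"] = self._param(rng, (cfg.n_targets,), hid)
        self.params = p

    @staticmethod
    def _param(rng, shape, fan_in) -> ad.Tensor:
        return ad.Tensor(_uniform(rng, shape, fan_in), requires_grad=True)

    # -- introspection ----------------------------------------------------

    def parameters(self) -> list[ad.Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- forward ----------------------------------------------------------

    def forward_batch(
        self,
        windows: np.ndarray,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> tuple[ad.Tensor, Optional[ad.Tensor]]:
        """Predict moments for a batch of normalized windows.

        Returns (predictions (B, n_targets), reconstruction_mse or None).
        The reconstruction term exists only for variants with the
        autoencoder stage and is the MSE between decoded and input spectra.
        """
        windows = np.asarray(windows, dtype=np.float64)
        if windows.ndim != 3 or windows.shape[1] != self.cfg.window_len:
            raise ConfigurationError(
                f"expected (B, {self.cfg.window_len}, {self.cfg.n_channels}) "
                f"windows, got {windows.shape}"
            )
        if windows.shape[2] != self.cfg.n_channels:
            raise ConfigurationError(
                f"model built for {self.cfg.n_channels} channels, "
                f"got {windows.shape[2]}"
            )
        p = self.params
        batch, d, c = windows.shape
        recon: Optional[ad.Tensor] = None

        if self.flags["spectral"]:
            spec = spectral_transform(windows, self.cfg.fft_mode).magnitudes
            # (B, d, c) -> (B*c, d): one spectral vector per window/channel
            flat = ad.Tensor(spec.transpose(0, 2, 1).reshape(batch * c, d))
            h1 = (flat @ p["enc.W1"].transpose(1, 0) + p["enc.b1"]).relu()
            lat = (h1 @ p["enc.W2"].transpose(1, 0) + p["enc.b2"]).relu()
            if self.cfg.aux_recon_weight > 0:
                h3 = (lat @ p["dec.W3"].transpose(1, 0) + p["dec.b3"]).relu()
                rec = (h3 @ p["dec.W4"].transpose(1, 0) + p["dec.b4"]).relu()
                diff = rec - flat
                recon = (diff * diff).mean()
            seq = lat.reshape(batch, c, self.cfg.latent_dim).transpose(0, 2, 1)
            if self.flags["conv"]:
                seq = ad.conv1d_same(seq, p["conv.kernels"], p["conv.biases"]).relu()
            steps = self.cfg.latent_dim
        else:
            seq = ad.Tensor(windows)
            steps = d

        hid = self.cfg.hidden
        h_t = ad.Tensor(np.zeros((batch, hid)))
        c_t = ad.Tensor(np.zeros((batch, hid)))
        hiddens = []
        wi, wf, wo, wc = (p[f"lstm.W_{g}"].transpose(1, 0) for g in "ifoc")
        ui, uf, uo, uc = (p[f"lstm.U_{g}"].transpose(1, 0) for g in "ifoc")
        for t in range(steps):
            x_t = seq[:, t, :]
            gi = (x_t @ wi + h_t @ ui + p["lstm.b_i"]).sigmoid()
            gf = (x_t @ wf + h_t @ uf + p["lstm.b_f"]).sigmoid()
            go = (x_t @ wo + h_t @ uo + p["lstm.b_o"]).sigmoid()
            cand = (x_t @ wc + h_t @ uc + p["lstm.b_c"]).tanh()
            c_t = gf * c_t + gi * cand
            h_t = go * c_t.tanh()
            hiddens.append(h_t)

        if self.flags["attention"]:
            hs = ad.stack(hiddens, axis=1)  # (B, T, hid)
            scores = (hs * p["att.W"].reshape(1, 1, hid)).sum(axis=2)
            weights = ad.softmax(scores, axis=1)
            context = (hs * weights.reshape(batch, steps, 1)).sum(axis=1)
        else:
            context = hiddens[-1]

        if training and self.cfg.dropout > 0:
            if rng is None:
                raise ConfigurationError("training forward pass needs an rng for dropout")
            keep = 1.0 - self.cfg.dropout
            mask = (rng.random(context.shape) < keep) / keep
            context = context * ad.Tensor(mask)

        return context @ p["head.W"].transpose(1, 0) + p["head.b"], recon

    def predict(self, ws: WindowSet | np.ndarray) -> np.ndarray:
        """Eval-mode predictions as a plain (n, n_targets) array."""
        windows = ws.windows if isinstance(ws, WindowSet) else ws
        out, _ = self.forward_batch(windows, training=False)
        return out.data

    # -- interop with the reference forms ---------------------------------

    def lstm_params(self) -> LSTMParams:
        p = self.params
        return LSTMParams(
            W_i=p["lstm.W_i"].data, W_f=p["lstm.W_f"].data,
            W_o=p["lstm.W_o"].data, W_c=p["lstm.W_c"].data,
            U_i=p["lstm.U_i"].data, U_f=p["lstm.U_f"].data,
            U_o=p["lstm.U_o"].data, U_c=p["lstm.U_c"].data,
            b_i=p["lstm.b_i"].data, b_f=p["lstm.b_f"].data,
            b_o=p["lstm.b_o"].data, b_c=p["lstm.b_c"].data,
        )

    def autoencoder_params(self) -> AutoencoderParams:
        if not self.flags["autoencoder"]:
            raise ConfigurationError(f"variant {self.cfg.variant} has no autoencoder")
        p = self.params
        return AutoencoderParams(
            W1=p["enc.W1"].data, b1=p["enc.b1"].data,
            W2=p["enc.W2"].data, b2=p["enc.b2"].data,
            W3=p["dec.W3"].data, b3=p["dec.b3"].data,
            W4=p["dec.W4"].data, b4=p["dec.b4"].data,
        )

    def conv_params(self) -> ConvRefinerParams:
        if not self.flags["conv"]:
            raise ConfigurationError(f"variant {self.cfg.variant} has no conv refiner")
        return ConvRefinerParams(
            kernels=self.params["conv.kernels"].data,
            biases=self.params["conv.biases"].data,
        )

    def attention_params(self) -> AttentionParams:
        if not self.flags["attention"]:
            raise ConfigurationError(f"variant {self.cfg.variant} has no attention")
        return AttentionParams(W=self.params["att.W"].data)

    # -- persistence ------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        missing = set(self.params) - set(state)
        if missing:
            raise ConfigurationError(f"checkpoint missing parameters: {sorted(missing)}")
        for k, v in self.params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != v.data.shape:
                raise ConfigurationError(
                    f"checkpoint {k} has shape {arr.shape}, expected {v.data.shape}"
                )
            v.data = arr.copy()


def build_variant(cfg: ModelConfig) -> MomentModel:
    """Construct a model for the configured ablation variant.

    Component flags per variant: I raw LSTM only; II adds attention; III
    spectral+autoencoder+LSTM; IV adds attention; V adds the conv refiner.
    """
    return MomentModel(cfg)


def forward_reference(model: MomentModel, windows: np.ndarray) -> np.ndarray:
    """Eval-mode forward pass rebuilt from the numpy reference primitives.

    Used as the independent second route when testing
    :meth:`MomentModel.forward_batch`; intentionally loops per window.
    """
    cfg = model.cfg
    flags = model.flags
    lstm_p = model.lstm_params()
    head_w = model.params["head.W"].data
    head_b = model.params["head.b"].data
    outputs = []
    for w in np.asarray(windows, dtype=np.float64):
        if flags["spectral"]:
            mag = spectral_transform(w[None], cfg.fft_mode).magnitudes[0]  # (d, c)
            ae = model.autoencoder_params()
            lat = np.stack([encode(mag[:, ch], ae) for ch in range(w.shape[1])], axis=1)
            if flags["conv"]:
                lat = conv_refine(lat[None], model.conv_params()).codes[0]
            seq = lat
        else:
            seq = w
        state = LSTMState(C=np.zeros(cfg.hidden), H=np.zeros(cfg.hidden))
        hs = []
        for t in range(seq.shape[0]):
            state = lstm_step(seq[t], state, lstm_p)
            hs.append(state.H)
        if flags["attention"]:
            context = attention(np.stack(hs), model.attention_params())
        else:
            context = hs[-1]
        outputs.append(head_w @ context + head_b)
    return np.stack(outputs)
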