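"""MLP encoder/decoder over spectral vectors and the 1-D conv refiner.

The encoder halves the feature dimension twice (input_dim -> input_dim/2 ->
input_dim/4) and the decoder mirrors it; all four layers are affine+ReLU
with the bias inside the activation.  The conv refiner is a single
same-length 1-D convolution (+bias, ReLU) along the latent-feature axis that
mixes predictor channels, used to blur short transients in the latent code.

The functions here are the plain-numpy reference forms; the trainable model
re-expresses the same maps on the autodiff tape and is tested against these.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, ParameterError


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


@dataclass
class AutoencoderParams:
    """Weights/biases of the 4-layer autoencoder; input_dim divisible by 4."""

    W1: np.ndarray  # (input_dim/2, input_dim)
    b1: np.ndarray
    W2: np.ndarray  # (input_dim/4, input_dim/2)
    b2: np.ndarray
    W3: np.ndarray  # (input_dim/2, input_dim/4)
    b3: np.ndarray
    W4: np.ndarray  # (input_dim, input_dim/2)
    b4: np.ndarray

    def __post_init__(self):
        d = self.W1.shape[1]
        if d % 4 != 0:
            raise ParameterError(f"input_dim must be divisible by 4, got {d}")
        expected = {
            "W1": (d // 2, d),
            "b1": (d // 2,),
            "W2": (d // 4, d // 2),
            "b2": (d // 4,),
            "W3": (d // 2, d // 4),
            "b3": (d // 2,),
            "W4": (d, d // 2),
            "b4": (d,),
        }
        for name, shape in expected.items():
            actual = getattr(self, name).shape
            if actual != shape:
                raise DimensionError(f"{name} has shape {actual}, expected {shape}")

    @property
    def input_dim(self) -> int:
        return self.W1.shape[1]

    @property
    def latent_dim(self) -> int:
        return self.W2.shape[0]

    @classmethod
    def init(cls, input_dim: int, rng: np.random.Generator) -> "AutoencoderParams":
        if input_dim % 4 != 0:
            raise ParameterError(f"input_dim must be divisible by 4, got {input_dim}")
        h, q = input_dim // 2, input_dim // 4
        return cls(
            W1=_uniform(rng, (h, input_dim), input_dim),
            b1=_uniform(rng, (h,), input_dim),
            W2=_uniform(rng, (q, h), h),
            b2=_uniform(rng, (q,), h),
            W3=_uniform(rng, (h, q), q),
            b3=_uniform(rng, (h,), q),
            W4=_uniform(rng, (input_dim, h), h),
            b4=_uniform(rng, (input_dim,), h),
        )


@dataclass
class LatentFeatures:
    """Nonnegative latent codes, shape (n_windows, latent_dim, n_pred_channels)."""

    codes: np.ndarray

    def __post_init__(self):
        if np.any(self.codes < 0):
            raise ParameterError("latent codes must be nonnegative (ReLU output)")


@dataclass
class ConvRefinerParams:
    """One same-length 1-D conv layer: kernels (c_out, c_in, k), k odd."""

    kernels: np.ndarray
    biases: np.ndarray

    def __post_init__(self):
        if self.kernels.ndim != 3:
            raise DimensionError("kernels must be (c_out, c_in, kernel_len)")
        if self.kernels.shape[2] % 2 == 0:
            raise ParameterError("kernel_len must be odd")
        if self.biases.shape != (self.kernels.shape[0],):
            raise DimensionError("biases must have one entry per output channel")

    @property
    def kernel_len(self) -> int:
        return self.kernels.shape[2]

    @classmethod
    def init(
        cls, n_channels: int, kernel_len: int, rng: np.random.Generator
    ) -> "ConvRefinerParams":
        if kernel_len % 2 == 0:
            raise ParameterError("kernel_len must be odd")
        fan_in = n_channels * kernel_len
        return cls(
            kernels=_uniform(rng, (n_channels, n_channels, kernel_len), fan_in),
            biases=_uniform(rng, (n_channels,), fan_in),
        )


def encode(E: np.ndarray, params: AutoencoderParams) -> np.ndarray:
    """ReLU(W2 @ ReLU(W1 @ E + b1) + b2).

    Accepts a single vector of length input_dim or a batch (n, input_dim).
    """
    E = np.asarray(E, dtype=np.float64)
    single = E.ndim == 1
    batch = E[None, :] if single else E
    if batch.shape[1] != params.input_dim:
        raise DimensionError(
            f"expected vectors of length {params.input_dim}, got {batch.shape[1]}"
        )
    h = np.maximum(batch @ params.W1.T + params.b1, 0.0)
    d = np.maximum(h @ params.W2.T + params.b2, 0.0)
    return d[0] if single else d


def decode(D: np.ndarray, params: AutoencoderParams) -> np.ndarray:
    """ReLU(W4 @ ReLU(W3 @ D + b3) + b4)."""
    D = np.asarray(D, dtype=np.float64)
    single = D.ndim == 1
    batch = D[None, :] if single else D
    if batch.shape[1] != params.latent_dim:
        raise DimensionError(
            f"expected latent vectors of length {params.latent_dim}, got {batch.shape[1]}"
        )
    h = np.maximum(batch @ params.W3.T + params.b3, 0.0)
    e = np.maximum(h @ params.W4.T + params.b4, 0.0)
    return e[0] if single else e


def conv_refine(
    latent: LatentFeatures | np.ndarray, params: ConvRefinerParams
) -> LatentFeatures:
    """Same-length 1-D convolution along the latent axis, then ReLU.

    Input/output shape (n_windows, latent_dim, n_channels); output channel
    count follows the kernels.
    """
    codes = latent.codes if isinstance(latent, LatentFeatures) else np.asarray(latent)
    if codes.ndim != 3:
        raise DimensionError("latent codes must be (n_windows, latent_dim, n_channels)")
    n, length, c_in = codes.shape
    c_out, c_in_k, k = params.kernels.shape
    if c_in_k != c_in:
        raise DimensionError(f"kernels expect {c_in_k} channels, got {c_in}")
    pad = k // 2
    padded = np.zeros((n, length + 2 * pad, c_in))
    padded[:, pad : pad + length, :] = codes
    out = np.broadcast_to(params.biases, (n, length, c_out)).copy()
    for j in range(k):
        out += padded[:, j : j + length, :] @ params.kernels[:, :, j].T
    return LatentFeatures(codes=np.maximum(out, 0.0))
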