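"""Stacked denoising autoencoder for multichannel EEG feature extraction.

Two sigmoid autoencoders are trained greedily: the first compresses the c
input channels to n hidden units, the second compresses those n units to m.
Inputs are corrupted by masking noise (each entry independently zeroed with
a fixed probability) before encoding, while the reconstruction target stays
clean, so the bottleneck learns noise-robust structure. The m deep hidden
series, averaged, form the extracted per-area feature.

The model/results split follows the usual estimator convention:
:class:`StackedDenoisingAutoencoder` holds the architecture and training
configuration, :meth:`~StackedDenoisingAutoencoder.fit` returns an
:class:`SDAEResults` carrying the trained weights, the scaler and the
reconstruction errors, with ``transform``/``extract_feature`` methods.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "sigmoid", "corrupt", "TrainConfig", "DenoisingAutoencoder",
    "train_autoencoder", "StackedDenoisingAutoencoder", "SDAEResults",
    "stack_train",
]


def sigmoid(a):
    """Logistic function s(a) = 1 / (1 + exp(-a)), elementwise.

    Saturates smoothly for large |a|; output is always in (0, 1).
    """
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out if out.ndim else float(out)


def corrupt(x: np.ndarray, fraction: float,
            rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Masking corruption: zero each entry independently with ``fraction``.

    Deterministic under a fixed seed / generator state.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    x = np.asarray(x, dtype=float)
    if fraction == 0.0:
        return x.copy()
    rng = np.random.default_rng(rng)
    mask = rng.random(x.shape) >= fraction
    return x * mask


@dataclass(frozen=True)
class TrainConfig:
    """SGD hyperparameters for one greedy training stage.

    Defaults are the reference configuration for 1-minute EEG segments:
    masking probability 0.5, learning rate 1, minibatch 200, 8 epochs.
    """

    corruption_fraction: float = 0.5
    learning_rate: float = 1.0
    minibatch: int = 200
    epochs: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.corruption_fraction <= 1.0:
            raise ValueError("corruption_fraction must be in [0, 1]")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.minibatch < 1 or self.epochs < 0:
            raise ValueError("minibatch >= 1 and epochs >= 0 required")


@dataclass
class DenoisingAutoencoder:
    """One trained autoencoder: sigmoid encoder and (untied) sigmoid decoder.

    ``W`` is hidden x input, ``W_dec`` input x hidden; biases match the
    output side of each map.
    """

    W: np.ndarray
    b: np.ndarray
    W_dec: np.ndarray
    b_dec: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float).reshape(-1)
        self.W_dec = np.asarray(self.W_dec, dtype=float)
        self.b_dec = np.asarray(self.b_dec, dtype=float).reshape(-1)
        if self.W.shape != self.W_dec.shape[::-1]:
            raise ValueError("W and W_dec must have transposed shapes")
        for arr in (self.W, self.b, self.W_dec, self.b_dec):
            if not np.all(np.isfinite(arr)):
                raise ValueError("autoencoder parameters must be finite")

    @property
    def n_input(self) -> int:
        return self.W.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Hidden activations s(W x + b); ``x`` is input_dim x samples."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[0] != self.n_input:
            raise ValueError(
                f"input has {x.shape[0]} rows, encoder expects {self.n_input}")
        return sigmoid(self.W @ x + self.b[:, None])

    def decode(self, y: np.ndarray) -> np.ndarray:
        """Reconstruction s(W' y + b'); ``y`` is hidden_dim x samples."""
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if y.shape[0] != self.n_hidden:
            raise ValueError(
                f"input has {y.shape[0]} rows, decoder expects {self.n_hidden}")
        return sigmoid(self.W_dec @ y + self.b_dec[:, None])

    def reconstruction_error(self, x: np.ndarray) -> float:
        """Per-channel time-averaged squared error, summed over channels."""
        z = self.decode(self.encode(x))
        return float(np.sum(np.mean((np.atleast_2d(x) - z) ** 2, axis=1)))


try:  # pragma: no cover - exercised implicitly by every training call
    from numba import njit
except ImportError:  # fallback keeps the package importable without numba
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def _sgd_epochs(x, W, b, W_dec, b_dec, epochs, minibatch, lr, fraction, seed):
    """Minibatch SGD on denoising squared error (in-place parameter updates).

    Uses the legacy numpy RNG (seeded here) for shuffling and masking so the
    whole loop stays inside compiled code; deterministic under ``seed``.
    """
    np.random.seed(seed)
    dim, n_samp = x.shape
    hid = W.shape[0]
    for _ in range(epochs):
        order = np.random.permutation(n_samp)
        for start in range(0, n_samp, minibatch):
            stop = min(start + minibatch, n_samp)
            B = stop - start
            xb = np.empty((dim, B))
            for j in range(B):
                xb[:, j] = x[:, order[start + j]]
            if fraction > 0.0:
                x1 = xb * (np.random.random((dim, B)) >= fraction)
            else:
                x1 = xb.copy()
            y = 1.0 / (1.0 + np.exp(-(W @ x1 + b.reshape(-1, 1))))
            z = 1.0 / (1.0 + np.exp(-(W_dec @ y + b_dec.reshape(-1, 1))))
            d_out = 2.0 * (z - xb) * z * (1.0 - z)
            d_hid = (W_dec.T @ d_out) * y * (1.0 - y)
            W_dec -= lr * (d_out @ y.T) / B
            b_dec -= lr * d_out.sum(axis=1) / B
            W -= lr * (d_hid @ x1.T) / B
            b -= lr * d_hid.sum(axis=1) / B


def _init_autoencoder(n_input: int, n_hidden: int,
                      rng: np.random.Generator) -> DenoisingAutoencoder:
    # classic sigmoid-net uniform range +-4*sqrt(6/(fan_in+fan_out))
    lim = 4.0 * np.sqrt(6.0 / (n_input + n_hidden))
    return DenoisingAutoencoder(
        W=rng.uniform(-lim, lim, size=(n_hidden, n_input)),
        b=np.zeros(n_hidden),
        W_dec=rng.uniform(-lim, lim, size=(n_input, n_hidden)),
        b_dec=np.zeros(n_input),
    )


def train_autoencoder(x: np.ndarray, hidden: int, cfg: TrainConfig,
                      rng: np.random.Generator | None = None,
                      ) -> tuple[DenoisingAutoencoder, float]:
    """Train one denoising autoencoder by minibatch SGD on squared error.

    Parameters
    ----------
    x : ndarray, shape (dim, samples)
        Training data scaled to [0, 1]; each time sample is one example.
    hidden : int
        Bottleneck width. Values >= the input dimension are accepted with a
        warning (no longer a compression).
    cfg : TrainConfig
    rng : Generator, optional
        Shared generator for a multi-stage run; defaults to one seeded from
        ``cfg.seed``.

    Returns
    -------
    (autoencoder, final_error)
        ``final_error`` is the clean-input reconstruction error (squared
        error averaged over time, summed over input dimensions).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    dim, n_samp = x.shape
    if hidden < 1:
        raise ValueError("hidden must be >= 1")
    if hidden >= dim:
        warnings.warn(f"hidden={hidden} >= input dim={dim}: the layer is no "
                      "longer a bottleneck", stacklevel=2)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ae = _init_autoencoder(dim, hidden, rng)
    sgd_seed = int(rng.integers(0, 2 ** 31 - 1))
    if cfg.epochs > 0 and cfg.learning_rate > 0:
        _sgd_epochs(np.ascontiguousarray(x), ae.W, ae.b, ae.W_dec, ae.b_dec,
                    cfg.epochs, cfg.minibatch, float(cfg.learning_rate),
                    float(cfg.corruption_fraction), sgd_seed)
    return ae, ae.reconstruction_error(x)


@dataclass
class SDAEResults:
    """Fitted two-stage SDAE: weights, scaler and reconstruction errors."""

    stage1: DenoisingAutoencoder
    stage2: DenoisingAutoencoder
    n: int
    m: int
    scale_min: np.ndarray
    scale_range: np.ndarray
    recon_err_1: float
    recon_err_2: float
    config: TrainConfig = field(default_factory=TrainConfig)

    def scale(self, x: np.ndarray) -> np.ndarray:
        """Map raw channels to [0, 1] with the training min/max."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[0] != self.scale_min.size:
            raise ValueError(f"expected {self.scale_min.size} channels, got "
                             f"{x.shape[0]}")
        return (x - self.scale_min[:, None]) / self.scale_range[:, None]

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Deep hidden activations Y2 (m x samples) for raw-channel input."""
        return self.stage2.encode(self.stage1.encode(self.scale(x)))

    def extract_feature(self, x: np.ndarray) -> np.ndarray:
        """Per-area feature: the m deep hidden series averaged to one."""
        return self.transform(x).mean(axis=0)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        """Stage-1 reconstruction of the scaled input (diagnostic)."""
        return self.stage1.decode(self.stage1.encode(self.scale(x)))

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        meta = {"n": self.n, "m": self.m,
                "config": {"corruption_fraction": self.config.corruption_fraction,
                           "learning_rate": self.config.learning_rate,
                           "minibatch": self.config.minibatch,
                           "epochs": self.config.epochs,
                           "seed": self.config.seed},
                "recon_err_1": self.recon_err_1,
                "recon_err_2": self.recon_err_2}
        np.savez(path, W1=self.stage1.W, b1=self.stage1.b,
                 W1d=self.stage1.W_dec, b1d=self.stage1.b_dec,
                 W2=self.stage2.W, b2=self.stage2.b,
                 W2d=self.stage2.W_dec, b2d=self.stage2.b_dec,
                 scale_min=self.scale_min, scale_range=self.scale_range,
                 meta=np.array(json.dumps(meta)))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SDAEResults":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["meta"]))
            return cls(
                stage1=DenoisingAutoencoder(npz["W1"], npz["b1"],
                                            npz["W1d"], npz["b1d"]),
                stage2=DenoisingAutoencoder(npz["W2"], npz["b2"],
                                            npz["W2d"], npz["b2d"]),
                n=meta["n"], m=meta["m"],
                scale_min=npz["scale_min"], scale_range=npz["scale_range"],
                recon_err_1=meta["recon_err_1"],
                recon_err_2=meta["recon_err_2"],
                config=TrainConfig(**meta["config"]),
            )

    def summary(self) -> str:
        lines = [
            "Stacked denoising autoencoder (2 stages)",
            f"  input channels : {self.stage1.n_input}",
            f"  hidden widths  : n={self.n}, m={self.m}",
            f"  corruption     : {self.config.corruption_fraction}",
            f"  recon error 1  : {self.recon_err_1:.6f}",
            f"  recon error 2  : {self.recon_err_2:.6f}",
        ]
        return "\n".join(lines)


class StackedDenoisingAutoencoder:
    """Two-stage SDAE model: configure widths, then ``fit`` raw channels.

    Parameters
    ----------
    n, m : int
        Hidden widths of stage 1 and stage 2; require m <= n.
    config : TrainConfig, optional
    """

    def __init__(self, n: int, m: int, config: TrainConfig | None = None):
        if m > n:
            raise ValueError(f"require m <= n, got n={n}, m={m}")
        if m < 1:
            raise ValueError("m must be >= 1")
        self.n = n
        self.m = m
        self.config = config or TrainConfig()

    def fit(self, x: np.ndarray) -> SDAEResults:
        """Greedy layer-wise training on a channels x samples matrix.

        Stage 1 learns to reconstruct the min-max-scaled channels from a
        masked copy; stage 2 is then trained the same way on stage 1's clean
        hidden output. Fully deterministic under ``config.seed``.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if self.n >= x.shape[0]:
            warnings.warn(
                f"n={self.n} >= channel count {x.shape[0]}: stage 1 is not a "
                "bottleneck", stacklevel=2)
        smin = x.min(axis=1)
        srange = x.max(axis=1) - smin
        srange = np.where(srange < 1e-12, 1.0, srange)
        xs = (x - smin[:, None]) / srange[:, None]

        rng = np.random.default_rng(self.config.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # bottleneck warning re-raised above
            ae1, err1 = train_autoencoder(xs, self.n, self.config, rng)
            y1 = ae1.encode(xs)
            ae2, err2 = train_autoencoder(y1, self.m, self.config, rng)
        return SDAEResults(stage1=ae1, stage2=ae2, n=self.n, m=self.m,
                           scale_min=smin, scale_range=srange,
                           recon_err_1=err1, recon_err_2=err2,
                           config=self.config)


def stack_train(x: np.ndarray, n: int, m: int,
                cfg: TrainConfig | None = None) -> SDAEResults:
    """Functional wrapper: build and fit a two-stage SDAE in one call."""
    return StackedDenoisingAutoencoder(n, m, cfg).fit(x)
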