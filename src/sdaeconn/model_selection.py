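"""Hidden-width selection for the SDAE by the c_f spectral criterion.

For each admissible width pair (n, m) an SDAE is trained and scored by

    c_f = lambda * exp(-(e1 + e2) / (2 c)) + (1 - lambda) * sum_j cbar_j^3

where e1 and e2 are the two stages' reconstruction errors (squared error
time-averaged per channel/unit, summed), c is the input channel count, and
cbar_j are the min-max-normalized time-summed STFT magnitudes of the
extracted feature over the frequency bins below a ceiling (20 Hz by
default). The first term rewards faithful reconstruction; the cubed second
term rewards a feature whose low-frequency spectrum has strong dominant
components. The admissible pair maximizing c_f is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from .sdae import SDAEResults, TrainConfig

__all__ = ["STFTGram", "SelectionConfig", "SelectionResult", "stft",
           "normalize_cstft", "compute_cf", "admissible_pairs", "grid_search"]


@dataclass
class STFTGram:
    """Magnitude spectrogram: |STFT| coefficients, bin frequencies, framing."""

    coeffs: np.ndarray          # (freq bins, time frames), nonnegative
    freqs: np.ndarray           # Hz per bin
    window_len: int
    hop: int

    @property
    def q(self) -> int:
        """Number of time frames."""
        return self.coeffs.shape[1]


@dataclass(frozen=True)
class SelectionConfig:
    """Constraint constants and weighting for the width search.

    Defaults: U_def=30 (product bound on n*m), C_def=15 (upper bound on n,
    must stay below the channel count), C_com=5 (upper bound on m),
    lambda=0.2, frequency ceiling 20 Hz.
    """

    u_def: int = 30
    c_def: int = 15
    c_com: int = 5
    lam: float = 0.2
    freq_ceiling: float = 20.0

    def __post_init__(self) -> None:
        if min(self.u_def, self.c_def, self.c_com) < 1:
            raise ValueError("u_def, c_def, c_com must be positive integers")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")


@dataclass
class SelectionResult:
    """Full c_f grid with per-pair diagnostics and the selected pair."""

    grid: dict[tuple[int, int], float]
    chosen: tuple[int, int]
    diagnostics: dict[tuple[int, int], dict] = field(default_factory=dict)
    models: dict[tuple[int, int], SDAEResults] = field(default_factory=dict)

    @property
    def best_model(self) -> SDAEResults:
        return self.models[self.chosen]

    def to_frame(self) -> pd.DataFrame:
        """Grid as a tidy table (n, m, c_f, reconstruction and STFT terms)."""
        rows = []
        for (n, m), cf in sorted(self.grid.items()):
            d = self.diagnostics.get((n, m), {})
            rows.append({"n": n, "m": m, "c_f": cf,
                         "recon_err_1": d.get("recon_err_1", np.nan),
                         "recon_err_2": d.get("recon_err_2", np.nan),
                         "stft_term": d.get("stft_term", np.nan)})
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        """Heat map of c_f over the (n, m) grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ns = sorted({n for n, _ in self.grid})
        ms = sorted({m for _, m in self.grid})
        img = np.full((len(ms), len(ns)), np.nan)
        for (n, m), cf in self.grid.items():
            img[ms.index(m), ns.index(n)] = cf
        pcm = ax.pcolormesh(ns, ms, img, shading="nearest")
        ax.set_xlabel("n (stage-1 hidden units)")
        ax.set_ylabel("m (stage-2 hidden units)")
        ax.figure.colorbar(pcm, ax=ax, label="$c_f$")
        return ax


def stft(x: np.ndarray, fs: float, window_len: int, hop: int) -> STFTGram:
    """Magnitude short-time Fourier transform with a Hann window.

    Frames cover the signal without zero-padded edge frames, so the frame
    count is floor((len - window_len)/hop) + 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    if window_len > x.size:
        raise ValueError(f"window_len={window_len} exceeds signal length "
                         f"{x.size}")
    if hop < 1:
        raise ValueError("hop must be >= 1")
    # explicit framing: only windows fully inside the signal, no padding,
    # so q = floor((len - window_len)/hop) + 1
    frames = np.lib.stride_tricks.sliding_window_view(x, window_len)[::hop]
    win = hann(window_len, sym=False)
    coeffs = np.abs(np.fft.rfft(frames * win, axis=1)).T
    freqs = np.fft.rfftfreq(window_len, d=1.0 / fs)
    return STFTGram(coeffs=coeffs, freqs=freqs,
                    window_len=window_len, hop=hop)


def normalize_cstft(gram: STFTGram, freq_ceiling: float = 20.0) -> np.ndarray:
    """Min-max normalize the time-summed STFT magnitudes below a ceiling.

    Each retained frequency bin i gets

        cbar_i = (S_i - min_k S_k) / (max_k S_k - min_k S_k),

    with S_i the sum of |STFT| over time frames. If all bins tie (flat
    spectrum) every score is defined as 0. Requires >= 2 bins at or below
    the ceiling.
    """
    keep = gram.freqs <= freq_ceiling
    if keep.sum() < 2:
        raise ValueError(f"need >= 2 frequency bins <= {freq_ceiling} Hz")
    sums = gram.coeffs[keep].sum(axis=1)
    lo, hi = sums.min(), sums.max()
    if hi - lo < 1e-300:
        return np.zeros(sums.size)
    return (sums - lo) / (hi - lo)


def compute_cf(recon_err_1: float, recon_err_2: float, cscores: np.ndarray,
               lam: float, c: int) -> float:
    """The c_f model-selection score.

    Parameters
    ----------
    recon_err_1, recon_err_2 : float
        Stage-1 (input vs reconstruction, summed over the c channels) and
        stage-2 (hidden vs reconstruction, summed over n units) mean squared
        errors.
    cscores : array
        Normalized time-summed STFT magnitudes cbar_1..cbar_d in [0, 1].
    lam : float
        Trade-off weight in [0, 1].
    c : int
        Input channel count (normalizes the error exponent).
    """
    cscores = np.asarray(cscores, dtype=float)
    recon_term = np.exp(-(recon_err_1 + recon_err_2) / (2.0 * c))
    return float(lam * recon_term + (1.0 - lam) * np.sum(cscores ** 3))


def admissible_pairs(cfg: SelectionConfig) -> list[tuple[int, int]]:
    """All (n, m) with m*n <= U_def, m <= n < C_def and 1 <= m < C_com.

    The product constraint is read as an upper bound so that bounded-budget
    pairs (for the default constants, the reference pair (8, 3)) are
    admissible.
    """
    pairs = [(n, m)
             for m in range(1, cfg.c_com)
             for n in range(m, cfg.c_def)
             if m * n <= cfg.u_def]
    if not pairs:
        raise ValueError("admissible (n, m) set is empty; relax the "
                         "selection constraints")
    return sorted(pairs)


def _train_grid(x: np.ndarray, pairs: list[tuple[int, int]],
                tcfg: TrainConfig):
    """Train an SDAE per (n, m) pair, sharing stage-1 models across m.

    Stage 1 depends only on n (and the shared seed), so it is trained once
    per distinct n; the generator state entering stage-2 training is
    replayed so every pair's result is bit-identical to an independent
    :func:`~sdaeconn.sdae.stack_train` call with the same configuration.
    """
    import warnings as _warnings

    from .sdae import train_autoencoder

    x = np.atleast_2d(np.asarray(x, dtype=float))
    smin = x.min(axis=1)
    srange = x.max(axis=1) - smin
    srange = np.where(srange < 1e-12, 1.0, srange)
    xs = (x - smin[:, None]) / srange[:, None]
    by_n: dict[int, list[int]] = {}
    for n, m in pairs:
        by_n.setdefault(n, []).append(m)
    for n in sorted(by_n):
        rng = np.random.default_rng(tcfg.seed)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            ae1, err1 = train_autoencoder(xs, n, tcfg, rng)
            y1 = ae1.encode(xs)
            state = rng.bit_generator.state
            for m in sorted(by_n[n]):
                rng.bit_generator.state = state
                try:
                    ae2, err2 = train_autoencoder(y1, m, tcfg, rng)
                except Exception as exc:
                    raise RuntimeError(
                        f"SDAE training failed for (n={n}, m={m}): {exc}"
                    ) from exc
                yield (n, m), SDAEResults(
                    stage1=ae1, stage2=ae2, n=n, m=m, scale_min=smin,
                    scale_range=srange, recon_err_1=err1, recon_err_2=err2,
                    config=tcfg)


def grid_search(rec_area: np.ndarray, cfg: SelectionConfig | None = None,
                tcfg: TrainConfig | None = None, fs: float = 120.0,
                window_len: int | None = None, hop: int | None = None,
                keep_models: bool = True) -> SelectionResult:
    """Train an SDAE per admissible (n, m) and select the c_f maximizer.

    Every pair is trained with the same seed so the comparison isolates the
    architecture. STFT framing defaults to a 1 s Hann window with 50% hop at
    the working rate. Ties are broken toward smaller m, then smaller n.

    Parameters
    ----------
    rec_area : ndarray, shape (channels, samples)
        One area's channels.
    cfg : SelectionConfig
    tcfg : TrainConfig
    fs : float
        Sampling rate of ``rec_area`` in Hz.
    """
    cfg = cfg or SelectionConfig()
    tcfg = tcfg or TrainConfig()
    rec_area = np.atleast_2d(np.asarray(rec_area, dtype=float))
    c = rec_area.shape[0]
    if c <= cfg.c_def:
        raise ValueError(f"channel count {c} must exceed C_def={cfg.c_def}")
    if window_len is None:
        window_len = int(round(fs))
    if hop is None:
        hop = max(1, window_len // 2)

    grid: dict[tuple[int, int], float] = {}
    diagnostics: dict[tuple[int, int], dict] = {}
    models: dict[tuple[int, int], SDAEResults] = {}
    for (n, m), res in _train_grid(rec_area, admissible_pairs(cfg), tcfg):
        feature = res.extract_feature(rec_area)
        gram = stft(feature, fs=fs, window_len=window_len, hop=hop)
        cscores = normalize_cstft(gram, cfg.freq_ceiling)
        stft_term = float(np.sum(cscores ** 3))
        cf = compute_cf(res.recon_err_1, res.recon_err_2, cscores, cfg.lam, c)
        grid[(n, m)] = cf
        diagnostics[(n, m)] = {"recon_err_1": res.recon_err_1,
                               "recon_err_2": res.recon_err_2,
                               "stft_term": stft_term}
        if keep_models:
            models[(n, m)] = res

    best = max(grid.items(), key=lambda kv: (kv[1], -kv[0][1], -kv[0][0]))
    return SelectionResult(grid=grid, chosen=best[0], diagnostics=diagnostics,
                           models=models)
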