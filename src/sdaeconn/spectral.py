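"""Power spectra, the RPFA peakiness statistic, PCA baseline, t-tests.

RPFA ("ratio of the power on the first primary frequency to the average
power") measures how strongly the dominant in-band frequency stands out
above the mean in-band power — a proxy for the SNR of the rhythm of
interest. The awake condition is scored on the alpha+beta bands, fatigue
and sleep deprivation on delta+theta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as spsignal
from scipy import stats
from sklearn.decomposition import PCA

from .recording import EEG_BANDS, BandSpec

__all__ = ["PowerSpectrum", "power_spectrum", "rpfa", "pca_extract",
           "paired_ttest", "condition_bands"]


@dataclass
class PowerSpectrum:
    """Welch power spectral density: frequencies (Hz) and power per bin."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have equal shapes")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")

    def band_mask(self, bands: BandSpec | Iterable[BandSpec]) -> np.ndarray:
        if isinstance(bands, BandSpec):
            bands = [bands]
        mask = np.zeros(self.freqs.shape, dtype=bool)
        for band in bands:
            mask |= band.contains(self.freqs)
        return mask


def power_spectrum(x: np.ndarray, fs: float,
                   segment_seconds: float = 2.0) -> PowerSpectrum:
    """Welch-averaged periodogram (Hann window, 50% overlap).

    Default segment length 2 s gives 0.5 Hz resolution, enough to separate
    the EEG bands.
    """
    x = np.asarray(x, dtype=float).ravel()
    nperseg = int(round(segment_seconds * fs))
    if x.size < nperseg:
        raise ValueError(f"signal of {x.size} samples shorter than one "
                         f"{nperseg}-sample segment")
    freqs, power = spsignal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                                  noverlap=nperseg // 2)
    return PowerSpectrum(freqs=freqs, power=power)


def condition_bands(condition: str) -> list[BandSpec]:
    """Bands scored per mental-state condition.

    awake -> alpha+beta; fatigue / sleep_deprivation -> delta+theta.
    """
    key = condition.lower()
    if key == "awake":
        return [EEG_BANDS["alpha"], EEG_BANDS["beta"]]
    if key in ("fatigue", "sleep_deprivation"):
        return [EEG_BANDS["delta"], EEG_BANDS["theta"]]
    raise ValueError(f"unknown condition {condition!r}; expected awake, "
                     "fatigue or sleep_deprivation")


def rpfa(ps: PowerSpectrum, bands: BandSpec | Iterable[BandSpec]) -> float:
    """Peak-to-mean in-band power ratio; always >= 1.

    The "first primary frequency" is the in-band bin with maximal power;
    RPFA = max(in-band power) / mean(in-band power). Gain-invariant.
    """
    mask = ps.band_mask(bands)
    if not mask.any():
        raise ValueError("band contains no frequency bins")
    p = ps.power[mask]
    mean = p.mean()
    if mean <= 0:
        raise ValueError("in-band power is zero; RPFA undefined")
    return float(p.max() / mean)


def pca_extract(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """PCA baseline extractor: project channels onto the top-k axes.

    Returns the k projection series (k x samples, variance-ordered) and the
    explained variances. The comparison feature used elsewhere is the mean
    of the k series, mirroring the SDAE's feature averaging.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds channel count {x.shape[0]}")
    pca = PCA(n_components=k)
    scores = pca.fit_transform(x.T).T
    return scores, pca.explained_variance_


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Classical paired t-test on matched observations; two-sided p.

    Raises on zero-variance differences (degenerate t) rather than
    returning NaN silently.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length samples with >= 2 pairs")
    d = a - b
    if np.allclose(d, d[0]):
        if d[0] == 0:
            return 0.0, 1.0
        raise ValueError("differences have zero variance; t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
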