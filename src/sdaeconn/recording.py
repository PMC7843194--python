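"""Multichannel recording container with montage and area grouping.

A :class:`Recording` holds a channels x samples matrix together with the
sampling rate, channel labels, an optional 4-neighbor montage map (used by
the surface Laplacian spatial filter) and an optional grouping of channels
into brain areas (frontal / motor / parietal / visual in the intended use).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Recording", "BandSpec", "INCOMPLETE", "EEG_BANDS"]

#: Marker placed in a montage map for channels without a full 4-neighbor set.
INCOMPLETE = "incomplete"


@dataclass(frozen=True)
class BandSpec:
    """A frequency band [lo, hi) in Hz.

    The canonical EEG rhythm bands are available in :data:`EEG_BANDS`.
    """

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError(f"require 0 <= lo < hi, got lo={self.lo}, hi={self.hi}")

    def contains(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask of frequency bins falling inside the band."""
        f = np.asarray(freqs, dtype=float)
        return (f >= self.lo) & (f <= self.hi)


#: Standard EEG bands: delta 0.5-4, theta 4-7, alpha 8-13, beta 13-30 Hz.
EEG_BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 0.5, 4.0),
    "theta": BandSpec("theta", 4.0, 7.0),
    "alpha": BandSpec("alpha", 8.0, 13.0),
    "beta": BandSpec("beta", 13.0, 30.0),
}


@dataclass
class Recording:
    """Channels x samples EEG-style recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal amplitudes (microvolt scale in typical use).
    fs : float
        Sampling rate in Hz, > 0.
    labels : list of str
        One identifier per channel, unique.
    montage : dict, optional
        Maps a channel label to its list of exactly 4 neighbor labels, or to
        the string :data:`INCOMPLETE` for border channels that lack a full
        symmetric neighbor set.
    areas : dict, optional
        Maps an area id (int) to the list of channel labels in that area.
        Area lists must be disjoint.
    meta : dict
        Free-form provenance metadata (filters applied, flags, ...).
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    montage: dict[str, object] | None = None
    areas: dict[int, list[str]] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.data.shape[1] < 1:
            raise ValueError("every channel needs at least one sample")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.montage is not None:
            self._check_montage(self.montage)
        if self.areas is not None:
            self._check_areas(self.areas)

    # -- validation helpers -------------------------------------------------
    def _check_montage(self, montage: dict) -> None:
        known = set(self.labels)
        for ch, neigh in montage.items():
            if ch not in known:
                raise ValueError(f"montage channel {ch!r} not in labels")
            if isinstance(neigh, str):
                if neigh != INCOMPLETE:
                    raise ValueError(f"montage value for {ch!r} must be a "
                                     f"4-list or {INCOMPLETE!r}")
                continue
            if len(neigh) != 4:
                raise ValueError(f"channel {ch!r} needs exactly 4 neighbors")
            for nb in neigh:
                if nb not in known:
                    raise ValueError(f"neighbor {nb!r} of {ch!r} not in labels")

    def _check_areas(self, areas: dict) -> None:
        known = set(self.labels)
        seen: set[str] = set()
        for aid, chans in areas.items():
            for ch in chans:
                if ch not in known:
                    raise ValueError(f"area {aid} channel {ch!r} not in labels")
                if ch in seen:
                    raise ValueError(f"channel {ch!r} assigned to two areas")
                seen.add(ch)

    # -- accessors ----------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def area_data(self, area_id: int) -> np.ndarray:
        """Channels x samples submatrix for one area."""
        if not self.areas or area_id not in self.areas:
            raise KeyError(f"no area {area_id} attached to this recording")
        idx = [self.index(ch) for ch in self.areas[area_id]]
        return self.data[idx]

    def with_data(self, data: np.ndarray, fs: float | None = None,
                  **meta_updates) -> "Recording":
        """Copy carrying new samples (and optionally a new rate)."""
        new = replace(self, data=np.asarray(data, dtype=float),
                      fs=self.fs if fs is None else fs)
        new.meta = {**self.meta, **meta_updates}
        return new

    def attach(self, montage: dict | None = None,
               areas: dict[int, list[str]] | None = None) -> "Recording":
        """Return a copy with montage and/or area grouping attached."""
        new = replace(self,
                      montage=montage if montage is not None else self.montage,
                      areas=areas if areas is not None else self.areas)
        new.meta = dict(self.meta)
        return new
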