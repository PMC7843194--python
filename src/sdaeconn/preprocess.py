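"""Temporal filtering, surface Laplacian spatial filtering, decimation.

The preprocessing chain mirrors common EEG practice: a zero-phase band-pass
(0.5-100 Hz by default) plus a power-line notch (48-52 Hz), the 4-neighbor
surface Laplacian to sharpen spatial resolution, and an optional anti-aliased
decimation since all content analyzed downstream lies below 30 Hz.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .recording import INCOMPLETE, BandSpec, Recording

__all__ = ["bandpass_notch", "surface_laplacian", "decimate"]


def bandpass_notch(rec: Recording, band: BandSpec | None = None,
                   notch_lo: float = 48.0, notch_hi: float = 52.0) -> Recording:
    """Zero-phase band-pass + band-stop (notch) filtering.

    A 4th-order Butterworth band-pass and a 2nd-order Butterworth band-stop
    are each applied forward-backward (``filtfilt``), so the output has no
    group delay. Defaults follow standard EEG acquisition settings:
    band 0.5-100 Hz, notch 48-52 Hz.

    Parameters
    ----------
    rec : Recording
    band : BandSpec, optional
        Pass band; defaults to 0.5-100 Hz. ``band.hi`` must be below the
        Nyquist frequency.
    notch_lo, notch_hi : float
        Stop-band edges in Hz; must lie inside the pass band. Pass
        ``notch_lo=None`` to skip the notch.
    """
    if band is None:
        band = BandSpec("broadband", 0.5, 100.0)
    nyq = rec.fs / 2.0
    if band.hi >= nyq:
        raise ValueError(f"band.hi={band.hi} Hz must be below Nyquist {nyq} Hz")
    if notch_lo is not None and not (band.lo <= notch_lo < notch_hi <= band.hi):
        raise ValueError("notch interval must lie inside the pass band")

    # generous reflective padding keeps the start-up transient of the
    # 0.5 Hz high-pass edge out of the measured response
    padlen = int(min(rec.n_samples - 2, 3 * rec.fs))
    sos_bp = signal.butter(4, [band.lo, band.hi], btype="bandpass",
                           fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos_bp, rec.data, axis=1, padlen=padlen)
    if notch_lo is not None:
        sos_bs = signal.butter(2, [notch_lo, notch_hi], btype="bandstop",
                               fs=rec.fs, output="sos")
        out = signal.sosfiltfilt(sos_bs, out, axis=1, padlen=padlen)
    return rec.with_data(out, filters={
        "band": (band.lo, band.hi),
        "notch": None if notch_lo is None else (notch_lo, notch_hi),
    })


def surface_laplacian(rec: Recording) -> Recording:
    """4-neighbor surface Laplacian spatial filter.

    Every channel with a complete set of 4 symmetric neighbors is replaced,
    per sample, by

        V_C = V_CO - (1/4) * (V_1 + V_2 + V_3 + V_4)

    where V_CO is the channel itself and V_1..V_4 its montage neighbors.
    Channels marked ``incomplete`` in the montage (border electrodes) are
    passed through unchanged and listed in ``meta['laplacian_passthrough']``.

    Raises
    ------
    RuntimeError
        If no montage is attached to the recording.
    """
    if rec.montage is None:
        raise RuntimeError("surface_laplacian requires an attached montage")
    out = rec.data.copy()
    passthrough: list[str] = []
    for ch in rec.labels:
        neigh = rec.montage.get(ch, INCOMPLETE)
        if isinstance(neigh, str):
            passthrough.append(ch)
            continue
        i = rec.index(ch)
        nb = [rec.index(n) for n in neigh]
        out[i] = rec.data[i] - 0.25 * rec.data[nb].sum(axis=0)
    return rec.with_data(out, laplacian=True, laplacian_passthrough=passthrough)


def decimate(rec: Recording, target_fs: float) -> Recording:
    """Anti-alias filter and downsample to ``target_fs``.

    The decimation factor must be an integer and the new Nyquist frequency
    must stay above 20 Hz so the analyzed EEG bands survive.
    """
    factor = rec.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"target_fs={target_fs} is not an integer divisor of fs={rec.fs}")
    if target_fs / 2.0 <= 20.0:
        raise ValueError(
            f"target_fs={target_fs} leaves Nyquist <= 20 Hz; analyzed bands "
            "would alias")
    factor = int(round(factor))
    if factor == 1:
        return rec.with_data(rec.data.copy())
    out = signal.decimate(rec.data, factor, axis=1, ftype="iir",
                          zero_phase=True)
    return rec.with_data(out, fs=target_fs, decimated_from=rec.fs)
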