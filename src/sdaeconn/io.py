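"""Reading and writing recordings: EDF, NPZ containers, YAML montage config.

EDF/EDF+ files are read through MNE's native reader. Because no EDF *writer*
is available in the dependency set, a minimal fixed-layout EDF writer
(16-bit, single physical dimension) is provided so synthetic fixtures can be
exported and round-tripped; it covers plain EDF only, not annotations.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .recording import Recording

__all__ = ["read_edf", "write_edf", "save_npz", "load_npz", "load_montage_config"]


def read_edf(path: str | Path) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording`.

    Montage and areas are left unattached; attach them from a config file
    with :func:`load_montage_config` and :meth:`Recording.attach`.

    Raises
    ------
    IOError
        If the file does not exist or cannot be parsed as EDF.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"EDF file not found: {path}")
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed files
        raise IOError(f"cannot read EDF file {path}: {exc}") from exc
    # MNE rescales recognized physical dimensions (uV) to SI volts; undo so
    # the in-memory values match the file's physical values.
    data = raw.get_data() * 1e6
    return Recording(data=data, fs=float(raw.info["sfreq"]),
                     labels=list(raw.ch_names),
                     meta={"source": str(path), "format": "edf"})


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a recording as a plain EDF file (16-bit, microvolt dimension).

    Samples are quantized to the 16-bit digital range per channel, so the
    round-trip error is bounded by half a quantization step.
    """
    path = Path(path)
    data = rec.data
    n_ch, n_samp = data.shape
    # one record per second when the rate divides evenly, else one big record
    if float(rec.fs).is_integer() and n_samp % int(rec.fs) == 0:
        spr = int(rec.fs)  # samples per record per channel
        n_rec = n_samp // spr
        rec_dur = 1.0
    else:
        spr = n_samp
        n_rec = 1
        rec_dur = n_samp / rec.fs

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    gain = (pmax - pmin) / (dmax - dmin)
    digital = np.rint((data - pmin[:, None]) / gain[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate X X X X", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (n_ch + 1)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad(f"{rec_dur:.6g}", 8),
        _pad(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(_pad(lbl, 16) for lbl in rec.labels),
        b"".join(_pad("", 80) for _ in rec.labels),
        b"".join(_pad("uV", 8) for _ in rec.labels),
        b"".join(_pad(f"{v:.6g}", 8) for v in pmin),
        b"".join(_pad(f"{v:.6g}", 8) for v in pmax),
        b"".join(_pad(str(dmin), 8) for _ in rec.labels),
        b"".join(_pad(str(dmax), 8) for _ in rec.labels),
        b"".join(_pad("", 80) for _ in rec.labels),
        b"".join(_pad(str(spr), 8) for _ in rec.labels),
        b"".join(_pad("", 32) for _ in rec.labels),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_rec):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())
    return path


def save_npz(rec: Recording, path: str | Path) -> Path:
    """Export a recording to a portable NPZ container with metadata."""
    path = Path(path)
    np.savez(
        path,
        data=rec.data,
        fs=np.float64(rec.fs),
        labels=np.array(rec.labels),
        meta=np.array(json.dumps({
            "montage": rec.montage,
            "areas": {str(k): v for k, v in (rec.areas or {}).items()},
            **rec.meta,
        })),
    )
    return path


def load_npz(path: str | Path) -> Recording:
    """Load a recording previously written by :func:`save_npz`."""
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta"]))
        montage = meta.pop("montage", None)
        areas = meta.pop("areas", None) or None
        if areas:
            areas = {int(k): list(v) for k, v in areas.items()}
        return Recording(data=npz["data"], fs=float(npz["fs"]),
                         labels=[str(l) for l in npz["labels"]],
                         montage=montage, areas=areas, meta=meta)


def load_montage_config(path: str | Path) -> tuple[dict, dict[int, list[str]]]:
    """Load a YAML montage/area config.

    Expected layout::

        montage:
          C3: [C1, C5, FC3, CP3]
          Fp1: incomplete
        areas:
          1: [Fp1, Fpz, ...]

    Returns ``(montage, areas)``; either may be empty if absent.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    montage = cfg.get("montage") or {}
    areas = {int(k): list(v) for k, v in (cfg.get("areas") or {}).items()}
    return montage, areas
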