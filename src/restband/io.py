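"""EDF/BDF file I/O for EEG signals.

Reading goes through :mod:`mne` (its EDF/BDF readers need no external
dependencies). Writing is done by a minimal standards-conforming writer for
16-bit EDF and 24-bit BDF (BioSemi) files, since no EDF-writing library is
available: fixed 1 s data records, one physical-dimension (uV) scaling per
channel, little-endian integer samples. Values round-trip through mne's
reader within the quantization step of the integer encoding.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

__all__ = ["write_edf", "write_bdf", "read_eeg"]

TARGET_SFREQ = 512.0  # Hz; offline analysis rate


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def _write_header(
    fh, version_bytes: bytes, reserved: str, n_records: int, n_channels: int,
    ch_names: list[str], sfreq: int, phys_min: np.ndarray, phys_max: np.ndarray,
    dig_min: int, dig_max: int,
):
    fh.write(version_bytes)
    fh.write(_pad("synthetic subject", 80))
    fh.write(_pad("restband synthetic recording", 80))
    fh.write(_pad("01.01.20", 8))
    fh.write(_pad("00.00.00", 8))
    fh.write(_pad(str(256 * (1 + n_channels)), 8))
    fh.write(_pad(reserved, 44))
    fh.write(_pad(str(n_records), 8))
    fh.write(_pad("1", 8))  # record duration in seconds
    fh.write(_pad(str(n_channels), 4))
    for name in ch_names:
        fh.write(_pad(name, 16))
    for _ in ch_names:
        fh.write(_pad("AgAgCl electrode", 80))
    for _ in ch_names:
        fh.write(_pad("uV", 8))
    for v in phys_min:
        fh.write(_pad(f"{v:.6g}"[:8], 8))
    for v in phys_max:
        fh.write(_pad(f"{v:.6g}"[:8], 8))
    for _ in ch_names:
        fh.write(_pad(str(dig_min), 8))
    for _ in ch_names:
        fh.write(_pad(str(dig_max), 8))
    for _ in ch_names:
        fh.write(_pad("HP:DC LP:None", 80))
    for _ in ch_names:
        fh.write(_pad(str(sfreq), 8))
    for _ in ch_names:
        fh.write(_pad("", 32))


def _digitize(data: np.ndarray, dig_min: int, dig_max: int):
    """Per-channel symmetric physical range and integer codes."""
    span = np.abs(data).max(axis=1)
    span = np.where(span <= 0, 1.0, span * 1.001)
    phys_min, phys_max = -span, span
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    codes = np.rint((data - phys_min[:, None]) / gain[:, None]) + dig_min
    return phys_min, phys_max, np.clip(codes, dig_min, dig_max)


def _prepare(data: np.ndarray, sfreq: float):
    arr = np.atleast_2d(np.asarray(data, dtype=float))
    sf = int(round(sfreq))
    if not np.isclose(sf, sfreq):
        raise ValueError("sampling rate must be an integer number of Hz")
    n_records = arr.shape[1] // sf
    if n_records < 1:
        raise ValueError("signal shorter than one 1 s data record")
    return arr[:, : n_records * sf], sf, n_records


def write_edf(path: str | os.PathLike, data: np.ndarray, sfreq: float, ch_names=None) -> Path:
    """Write a (channels x samples) uV signal as a 16-bit EDF file.

    The signal is truncated to whole seconds (1 s data records).
    """
    arr, sf, n_records = _prepare(data, sfreq)
    nch = arr.shape[0]
    if ch_names is None:
        ch_names = [f"EEG{i:03d}" for i in range(nch)]
    dig_min, dig_max = -32768, 32767
    phys_min, phys_max, codes = _digitize(arr, dig_min, dig_max)
    path = Path(path)
    with open(path, "wb") as fh:
        _write_header(fh, _pad("0", 8), "", n_records, nch, list(ch_names), sf,
                      phys_min, phys_max, dig_min, dig_max)
        recs = codes.astype("<i2").reshape(nch, n_records, sf)
        fh.write(np.ascontiguousarray(recs.transpose(1, 0, 2)).tobytes())
    return path


def write_bdf(path: str | os.PathLike, data: np.ndarray, sfreq: float, ch_names=None) -> Path:
    """Write a (channels x samples) uV signal as a 24-bit BioSemi BDF file."""
    arr, sf, n_records = _prepare(data, sfreq)
    nch = arr.shape[0]
    if ch_names is None:
        ch_names = [f"A{i + 1}" for i in range(nch)]
    dig_min, dig_max = -8388608, 8388607
    phys_min, phys_max, codes = _digitize(arr, dig_min, dig_max)
    path = Path(path)
    with open(path, "wb") as fh:
        _write_header(fh, b"\xffBIOSEMI", "24BIT", n_records, nch, list(ch_names), sf,
                      phys_min, phys_max, dig_min, dig_max)
        ints = codes.astype("<i4").reshape(nch, n_records, sf).transpose(1, 0, 2)
        raw = np.ascontiguousarray(ints).view(np.uint8).reshape(n_records, nch, sf, 4)
        fh.write(np.ascontiguousarray(raw[..., :3]).tobytes())  # 24-bit little-endian
    return path


def read_eeg(path: str | os.PathLike, target_sfreq: float = TARGET_SFREQ):
    """Read an EDF or BDF recording; return (data uV, sfreq, channel names).

    Resamples to 512 Hz when the file's rate differs (the offline analysis
    rate for these recordings). The format is chosen by file extension.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EEG file not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif suffix == ".bdf":
        raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported EEG format {suffix!r}: expected .edf or .bdf")
    if not np.isclose(raw.info["sfreq"], target_sfreq):
        raw = raw.resample(target_sfreq, verbose="error")
    data = raw.get_data() * 1e6  # mne holds volts; analysis units are uV
    return data, float(raw.info["sfreq"]), list(raw.ch_names)
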