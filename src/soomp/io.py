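"""Plain-text record I/O.

Records are stored as one sample per line (optionally with a ``# key: value``
comment header carrying the sampling rate and bit depth), which keeps
fixtures human-readable and diffable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["read_record", "write_record", "read_wav"]


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a WAV file into an (N, Q) float array plus its sample rate.

    Integer PCM is scaled to [-1, 1]; mono files come back with Q = 1.
    """
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    x = np.asarray(data, dtype=np.float64)
    if np.issubdtype(data.dtype, np.integer):
        x /= float(np.iinfo(data.dtype).max)
    if x.ndim == 1:
        x = x[:, None]
    return x, float(rate)


def write_record(path, samples, sampling_rate: float = 360.0, bit_depth: int = 11) -> None:
    path = Path(path)
    header = f"sampling_rate: {sampling_rate}\nbit_depth: {bit_depth}"
    np.savetxt(path, np.asarray(samples, dtype=np.float64), header=header)


def read_record(path) -> tuple[np.ndarray, float, int]:
    """Returns (samples, sampling_rate, bit_depth); defaults 360 Hz / 11 bit
    when the header is absent."""
    path = Path(path)
    fs, bits = 360.0, 11
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").partition(":")
            if key.strip() == "sampling_rate":
                fs = float(value)
            elif key.strip() == "bit_depth":
                bits = int(float(value))
    samples = np.loadtxt(path)
    return np.atleast_1d(samples), fs, bits
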