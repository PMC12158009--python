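"""Quality and sparsity metrics: SNR, SR, PRDN, CR.

PRDN (percentage root-mean-square difference, normalized) divides the
reconstruction error norm by the norm of the mean-subtracted original, so
it does not depend on the signal baseline:

    PRDN = ||f - f_a|| / ||f - mean(f)|| * 100 %.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "UndefinedMetricError",
    "snr",
    "sparsity_ratio",
    "prdn",
    "prdn_per_beat",
    "compression_ratio",
]


class UndefinedMetricError(ValueError):
    """The metric is undefined for this input (e.g. zero denominator)."""


def snr(originals, approximations) -> float:
    """Signal-to-noise ratio in dB over a set of channels.

    10 log10( sum_q ||f{q}||^2 / sum_q ||f{q} - f_a{q}||^2 ).  Accepts
    1-D signals or (N, Q) arrays.  Exact approximation returns +inf.
    """
    f = np.asarray(originals, dtype=np.float64)
    fa = np.asarray(approximations, dtype=np.float64)
    if f.shape != fa.shape:
        raise ValueError("originals and approximations must have equal shape")
    signal_energy = float(np.sum(f**2))
    if signal_energy == 0.0:
        raise UndefinedMetricError("SNR undefined for zero signal energy")
    error_energy = float(np.sum((f - fa) ** 2))
    if error_energy == 0.0:
        return math.inf
    return 10.0 * math.log10(signal_energy / error_energy)


def sparsity_ratio(samples_per_channel: int, total_atoms: int) -> float:
    """SR = 2N / K for a two-channel signal of N samples approximated with
    K atoms in total; higher means sparser."""
    if total_atoms <= 0:
        raise UndefinedMetricError("sparsity ratio undefined for K <= 0")
    return 2.0 * samples_per_channel / total_atoms


def prdn(record, reconstruction) -> float:
    """PRDN of a whole record, in percent."""
    f = np.asarray(record, dtype=np.float64).ravel()
    fa = np.asarray(reconstruction, dtype=np.float64).ravel()
    if f.shape != fa.shape:
        raise ValueError("record and reconstruction must have equal length")
    denom = np.linalg.norm(f - f.mean())
    if denom == 0.0:
        raise UndefinedMetricError("PRDN undefined for a constant record")
    return float(np.linalg.norm(f - fa) / denom * 100.0)


def prdn_per_beat(beat, approximation) -> float:
    """Per-beat PRDN: same formula with the beat's own mean."""
    return prdn(beat, approximation)


def compression_ratio(uncompressed_bits: float, compressed_bits: float) -> float:
    """CR = uncompressed size / compressed size (any consistent unit)."""
    if compressed_bits <= 0:
        raise UndefinedMetricError("compression ratio undefined for empty stream")
    if uncompressed_bits < 0:
        raise ValueError("uncompressed size must be nonnegative")
    return float(uncompressed_bits) / float(compressed_bits)
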