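"""Seeded synthetic-data generators.

Every generator is a pure function of its arguments (including the seed),
and returns enough ground truth for exact assertions: the generating atom
support and coefficients for joint-sparse sets, and the true R-peak
positions for ECG-like records.

The ECG model is deliberately transparent: each beat is a sum of five
Gaussian deflections (P, Q, R, S, T waves) with per-beat amplitude jitter
and jittered RR intervals, plus optional white noise.  It reproduces the
features the codec relies on — a dominant R deflection, quasi-periodicity,
beat-to-beat similarity — not the full physiology of real ECGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dictionaries import AtomLabel, Dictionary
from .pursuit import SignalSet

__all__ = [
    "JointSparseTruth",
    "EcgTruth",
    "gaussian_dictionary",
    "make_joint_sparse",
    "make_synthetic_ecg",
    "make_correlated_multichannel",
    "DEFAULT_MORPHOLOGY",
]


@dataclass
class JointSparseTruth:
    atom_indices: np.ndarray     # common support, sorted
    coefficients: np.ndarray     # (Q, k)
    noise_sd: float
    seed: int


@dataclass
class EcgTruth:
    rpeaks: np.ndarray           # sample indices
    sampling_rate: float
    noise_sd: float
    seed: int


def gaussian_dictionary(n_samples: int, n_atoms: int, seed: int) -> Dictionary:
    """Random unit-norm dictionary (i.i.d. Gaussian columns): incoherent
    with high probability, useful for exact-recovery experiments."""
    rng = np.random.default_rng(seed)
    atoms = rng.standard_normal((n_samples, n_atoms))
    atoms /= np.linalg.norm(atoms, axis=0, keepdims=True)
    labels = tuple(AtomLabel("random", None, float(m)) for m in range(n_atoms))
    return Dictionary(atoms=atoms, labels=labels)


def make_joint_sparse(
    n_signals: int,
    n_samples: int,
    dictionary: Dictionary,
    support_size: int,
    coefficient_scale: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[SignalSet, JointSparseTruth]:
    """Q signals sharing a k-sparse common support in the dictionary.

    Coefficients are i.i.d. N(0, coefficient_scale^2) per signal; white
    Gaussian noise of standard deviation ``noise_sd`` is added.
    """
    if dictionary.signal_length != n_samples:
        raise ValueError("dictionary row dimension must equal n_samples")
    rank = min(dictionary.atoms.shape)
    if support_size > rank:
        raise ValueError(f"support_size {support_size} exceeds dictionary rank bound {rank}")
    rng = np.random.default_rng(seed)
    support = np.sort(rng.choice(dictionary.n_atoms, size=support_size, replace=False))
    coeffs = coefficient_scale * rng.standard_normal((n_signals, support_size))
    signals = dictionary.atoms[:, support] @ coeffs.T  # (N, Q)
    if noise_sd > 0:
        signals = signals + noise_sd * rng.standard_normal(signals.shape)
    truth = JointSparseTruth(support, coeffs, noise_sd, seed)
    return SignalSet(signals), truth


#: (center offset s, width s, amplitude) of the P, Q, R, S, T deflections
DEFAULT_MORPHOLOGY: tuple[tuple[float, float, float], ...] = (
    (-0.20, 0.025, 0.15),   # P
    (-0.03, 0.010, -0.12),  # Q
    (0.00, 0.012, 1.20),    # R
    (0.035, 0.012, -0.25),  # S
    (0.25, 0.060, 0.35),    # T
)


def make_synthetic_ecg(
    n_beats: int,
    sampling_rate: float = 360.0,
    rr_mean: float = 0.8,
    rr_jitter: float = 0.04,
    morphology: tuple[tuple[float, float, float], ...] = DEFAULT_MORPHOLOGY,
    noise_sd: float = 0.0,
    amplitude_jitter: float = 0.05,
    aberrant_beats: dict[int, float] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, EcgTruth]:
    """Quasi-periodic ECG-like record with known R-peak positions.

    Each beat is a sum of Gaussian deflections centred on its R-peak; RR
    intervals are N(rr_mean, rr_jitter^2) seconds (clipped to stay above
    the beat template extent), each beat's amplitude is scaled by
    N(1, amplitude_jitter^2), and ``aberrant_beats`` maps beat indices to
    extra amplitude factors (e.g. {7: 3.0} makes beat 7 three times
    taller).  White noise of sd ``noise_sd`` is added on top.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    fs = float(sampling_rate)
    # 3-sigma extents either side of the R-peak; adjacent beats may overlap
    # mildly in their Gaussian tails, as real P/T waves do
    left = max(0.0, -min(c - 3 * w for c, w, _ in morphology))
    right = max(0.0, max(c + 3 * w for c, w, _ in morphology))
    span = left + right
    if rr_mean <= span:
        raise ValueError(
            f"rr_mean={rr_mean}s shorter than the beat template extent ({span:.2f}s)"
        )
    rng = np.random.default_rng(seed)
    rr = rng.normal(rr_mean, rr_jitter, size=n_beats)
    rr = np.clip(rr, span + 2.0 / fs, None)
    peak_times = left + 1.0 / fs + np.concatenate([[0.0], np.cumsum(rr[:-1])])
    duration = peak_times[-1] + right + 1.0 / fs
    n = int(np.ceil(duration * fs)) + 1
    t = np.arange(n) / fs

    scales = rng.normal(1.0, amplitude_jitter, size=n_beats)
    if aberrant_beats:
        for q, factor in aberrant_beats.items():
            scales[q] *= factor

    x = np.zeros(n)
    for q, tp in enumerate(peak_times):
        for c, w, a in morphology:
            # evaluate each deflection only on its 6-sigma window
            i0 = max(0, int((tp + c - 6 * w) * fs))
            i1 = min(n, int((tp + c + 6 * w) * fs) + 1)
            tt = t[i0:i1]
            x[i0:i1] += scales[q] * a * np.exp(-0.5 * ((tt - tp - c) / w) ** 2)
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(n)

    rpeaks = np.round(peak_times * fs).astype(int)
    return x, EcgTruth(rpeaks, fs, noise_sd, seed)


def make_correlated_multichannel(
    n_samples: int,
    n_components: int = 12,
    n_channels: int = 2,
    noise_sd: float = 1e-3,
    seed: int = 0,
) -> SignalSet:
    """Channels sharing sinusoidal components with channel-specific gains.

    Frequencies are drawn off any dictionary grid, amplitudes decay
    slowly, and a small amount of white noise keeps every frame nonzero —
    a stand-in for correlated stereo audio in pursuit comparisons.
    """
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.005, 0.45, size=n_components)  # cycles/sample
    phases = rng.uniform(0, 2 * np.pi, size=n_components)
    amps = rng.uniform(0.5, 1.0, size=n_components) / np.sqrt(1 + np.arange(n_components))
    gains = rng.uniform(0.5, 1.5, size=(n_channels, n_components))

    i = np.arange(n_samples)
    comps = amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * i + phases[:, None])
    signals = (gains @ comps).T  # (N, Q)
    if noise_sd > 0:
        signals = signals + noise_sd * rng.standard_normal(signals.shape)
    return SignalSet(signals)
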