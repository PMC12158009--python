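"""Redundant dictionaries for greedy pursuit.

Two constructions are provided:

* a redundant trigonometric dictionary (union of an overcomplete discrete
  cosine family and an overcomplete discrete sine family), the classic
  choice for frame-based audio approximation;
* a CDF 9/7 (Cohen-Daubechies-Feauveau) wavelet dictionary of redundancy
  approximately two, used for joint approximation of aligned heartbeats.

All atoms are columns of unit 2-norm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pywt

__all__ = [
    "AtomLabel",
    "Dictionary",
    "build_trig_dictionary",
    "cdf97_prototypes",
    "build_cdf97_dictionary",
]


class AtomLabel(NamedTuple):
    """Descriptor of one atom.

    family: "cosine" | "sine" | "scaling" | "wavelet" (or a custom tag for
        user-supplied dictionaries such as random test dictionaries).
    scale: dyadic level j for wavelet atoms, None otherwise.
    index: frequency index n for trigonometric atoms, half-integer
        translation k/2 for wavelet/scaling atoms.
    """

    family: str
    scale: int | None
    index: float


@dataclass
class Dictionary:
    """A redundant dictionary: unit-norm atoms as columns of a matrix."""

    atoms: np.ndarray  # shape (N, M), float64
    labels: tuple[AtomLabel, ...]
    norm_tolerance: float = 1e-10

    def __post_init__(self) -> None:
        self.atoms = np.ascontiguousarray(np.asarray(self.atoms, dtype=np.float64))
        if self.atoms.ndim != 2:
            raise ValueError("atoms must be a 2-D matrix (one atom per column)")
        if len(self.labels) != self.atoms.shape[1]:
            raise ValueError("one label per atom required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("atom labels must be unique")

    @property
    def signal_length(self) -> int:
        return self.atoms.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]

    @property
    def redundancy(self) -> float:
        return self.n_atoms / self.signal_length

    def validate_norms(self) -> None:
        norms = np.linalg.norm(self.atoms, axis=0)
        if not np.allclose(norms, 1.0, atol=self.norm_tolerance, rtol=0.0):
            worst = float(np.max(np.abs(norms - 1.0)))
            raise ValueError(f"atom norms deviate from 1 by up to {worst:g}")

    def to_text(self, path) -> None:
        """Export the atom matrix to a plain text file (one atom per column)."""
        np.savetxt(path, self.atoms)


def _check_positive_int(value, name: str) -> int:
    if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
        raise ValueError(f"{name} must be a positive integer, got {value!r}")
    if value <= 0:
        raise ValueError(f"{name} must be positive, got {value}")
    return int(value)


def build_trig_dictionary(frame_length: int, atoms_per_family: int | None = None) -> Dictionary:
    """Redundant discrete cosine + sine dictionary for frames of length L.

    Cosine atoms are cos(pi (2i-1)(n-1) / (2M)), i = 1..L, n = 1..M and sine
    atoms sin(pi (2i-1) n / (2M)), each column divided by its own 2-norm
    (the normalization factors w_c(n), w_s(n)).  With M atoms per family the
    dictionary holds 2M atoms; M = 2L (the default) gives redundancy four.
    With M = L each family is an orthogonal transform basis.
    """
    L = _check_positive_int(frame_length, "frame_length")
    if L < 2:
        raise ValueError("frame_length must be at least 2")
    M = 2 * L if atoms_per_family is None else _check_positive_int(atoms_per_family, "atoms_per_family")
    if M < L:
        raise ValueError("atoms_per_family must be >= frame_length (redundant construction)")

    i = np.arange(1, L + 1)[:, None]  # (L, 1)
    n = np.arange(1, M + 1)[None, :]  # (1, M)
    cos_atoms = np.cos(np.pi * (2 * i - 1) * (n - 1) / (2 * M))
    sin_atoms = np.sin(np.pi * (2 * i - 1) * n / (2 * M))
    atoms = np.hstack([cos_atoms, sin_atoms])
    atoms /= np.linalg.norm(atoms, axis=0, keepdims=True)

    labels = tuple(
        [AtomLabel("cosine", None, float(nn)) for nn in range(1, M + 1)]
        + [AtomLabel("sine", None, float(nn)) for nn in range(1, M + 1)]
    )
    return Dictionary(atoms=atoms, labels=labels)


class Cdf97Prototypes(NamedTuple):
    scaling: np.ndarray
    wavelet: np.ndarray
    grid: np.ndarray  # common abscissae, spacing 2**-cascade_iterations


def cdf97_prototypes(cascade_iterations: int = 8) -> Cdf97Prototypes:
    """Sampled CDF 9/7 scaling function phi and wavelet psi.

    The prototypes are produced by the cascade algorithm applied to the
    CDF 9/7 analysis filter pair, on a dyadic grid of spacing
    2**(-cascade_iterations).  phi integrates to 1 (partition of unity),
    psi to 0 (zero mean).
    """
    it = _check_positive_int(cascade_iterations, "cascade_iterations")
    if it < 4:
        raise ValueError("cascade_iterations must be >= 4 for a converged prototype")
    phi, psi, _phi_r, _psi_r, x = pywt.Wavelet("bior4.4").wavefun(level=it)
    return Cdf97Prototypes(np.asarray(phi), np.asarray(psi), np.asarray(x))


def _support(samples: np.ndarray, grid: np.ndarray, tol: float = 1e-12) -> tuple[float, float]:
    nz = np.flatnonzero(np.abs(samples) > tol)
    return float(grid[nz[0]]), float(grid[nz[-1]])


def build_cdf97_dictionary(
    signal_length: int,
    wavelet_levels: int = 5,
    cascade_iterations: int = 8,
    drop_norm: float = 1e-8,
    dedup_tol: float = 1e-12,
) -> Dictionary:
    """CDF 9/7 wavelet dictionary of redundancy approximately two.

    The dictionary is the union V0 ∪ W0 ∪ ... ∪ W_{levels-1} where V0 holds
    translated scaling functions phi(x_i - k/2) and W_j holds dilated
    wavelets 2^{j/2} psi(2^j x_i - k/2), every function restricted to the
    sample interval and renormalized to unit norm.  Translations step by
    half-integers.  The sample grid is x_i = (i-1) / 2^levels, so the
    finest wavelet level contributes one atom per sample and the total atom
    count is close to twice the signal length.  Restricted atoms whose raw
    norm falls below ``drop_norm`` are dropped, and exact duplicates arising
    from boundary restrictions are removed.
    """
    N = _check_positive_int(signal_length, "signal_length")
    if wavelet_levels < 0 or not isinstance(wavelet_levels, (int, np.integer)):
        raise ValueError("wavelet_levels must be a nonnegative integer")
    J = int(wavelet_levels)
    if N < 8:
        raise ValueError("signal_length must be >= 8")
    if N < 2**J:
        raise ValueError(
            f"signal_length={N} too small for wavelet_levels={J} (need >= {2**J})"
        )

    phi, psi, grid = cdf97_prototypes(cascade_iterations)
    phi_lo, phi_hi = _support(phi, grid)
    psi_lo, psi_hi = _support(psi, grid)

    x = (np.arange(1, N + 1) - 1) / 2.0**J  # grid on [0, (N-1)/2^J]
    c, d = float(x[0]), float(x[-1])

    def family(proto, p_lo, p_hi, p_grid, scale_j: int | None, fam: str):
        """All half-integer translations whose restriction meets the interval."""
        s = 1.0 if scale_j is None else 2.0**scale_j
        amp = 1.0 if scale_j is None else 2.0 ** (scale_j / 2.0)
        # need s*x - k/2 in [p_lo, p_hi] for some x in [c, d]
        k_min = int(np.ceil(2 * (s * c - p_hi)))
        k_max = int(np.floor(2 * (s * d - p_lo)))
        cols, labs = [], []
        for k in range(k_min, k_max + 1):
            arg = s * x - k / 2.0
            col = amp * np.interp(arg, p_grid, proto, left=0.0, right=0.0)
            nrm = np.linalg.norm(col)
            if nrm < drop_norm:
                continue
            cols.append(col / nrm)
            labs.append(AtomLabel(fam, scale_j, k / 2.0))
        return cols, labs

    all_cols: list[np.ndarray] = []
    all_labels: list[AtomLabel] = []
    cols, labs = family(phi, phi_lo, phi_hi, grid, None, "scaling")
    all_cols += cols
    all_labels += labs
    for j in range(J):
        cols, labs = family(psi, psi_lo, psi_hi, grid, j, "wavelet")
        all_cols += cols
        all_labels += labs

    if not all_cols:
        raise ValueError("no atoms survive restriction; signal_length too small")

    # drop exact duplicates from boundary restrictions
    A = np.column_stack(all_cols)
    keep: list[int] = []
    for m in range(A.shape[1]):
        if keep:
            overlaps = np.abs(A[:, keep].T @ A[:, m])
            if overlaps.max() > 1.0 - dedup_tol:
                continue
        keep.append(m)
    atoms = A[:, keep]
    labels = tuple(all_labels[m] for m in keep)
    return Dictionary(atoms=atoms, labels=labels)
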