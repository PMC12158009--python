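"""Simultaneous greedy pursuit over a common atom subspace.

Given Q similar signals f{q} and a redundant dictionary, the goal is a
common set of atoms d_l1..d_lk so that every signal is approximated as
f{q} ~= sum_n c{q}(n) d_ln.  Quality is judged in weighted mean square:

    E_k = sum_q p(q) ||f{q} - f{q}_k||^2,   p(q) >= 0, sum p(q) = 1.

Two selection rules are implemented:

* SOOMP (simultaneous optimized orthogonal matching pursuit): at each step
  pick the atom maximizing

      sum_q p(q) |<d_n, r{q}>|^2  /  (1 - sum_i |<d_n, w~_i>|^2),

  where the w~_i are an orthonormal basis of the span of the selected
  atoms.  This is stepwise optimal: it minimizes E_{k+1} over all
  candidate atoms, given the atoms already chosen.

* SOMP (simultaneous OMP): the same numerator without the span-correction
  denominator, i.e. plain weighted residual correlation.

Both are implemented with adaptive biorthogonalization: alongside the
Gram-Schmidt vectors w_n the algorithm maintains dual vectors beta_n with
<beta_n, d_lm> = delta_nm, so the expansion coefficients of every signal
are plain inner products c{q}(n) = <beta_n, f{q}>.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SignalSet",
    "PursuitResult",
    "NoSelectableAtomError",
    "DegenerateAtomError",
    "soomp",
    "somp",
    "oomp",
    "select_atom_soomp",
    "select_atom_somp",
    "extend_orthogonal_basis",
    "update_duals",
    "update_residuals",
]

#: atoms whose squared distance to span(selected) falls below this are
#: treated as numerically dependent and never selected
SPAN_TOLERANCE = 1e-10


class NoSelectableAtomError(RuntimeError):
    """Every remaining atom is numerically in the span of the selection."""


class DegenerateAtomError(RuntimeError):
    """The candidate atom is numerically in the span of the current basis."""


@dataclass
class SignalSet:
    """Q equal-length signals with normalized nonnegative weights.

    ``signals`` is stored as an (N, Q) array, one signal per column.
    Weights default to uniform p(q) = 1/Q.
    """

    signals: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        sig = np.asarray(self.signals, dtype=np.float64)
        if sig.ndim == 1:
            sig = sig[:, None]
        if sig.ndim != 2:
            raise ValueError("signals must be 1-D or 2-D (one signal per column)")
        self.signals = np.ascontiguousarray(sig)
        Q = sig.shape[1]
        if self.weights is None:
            self.weights = np.full(Q, 1.0 / Q)
        else:
            w = np.asarray(self.weights, dtype=np.float64)
            if w.shape != (Q,):
                raise ValueError(f"weights must have shape ({Q},)")
            if np.any(w < 0):
                raise ValueError("weights must be nonnegative")
            if abs(w.sum() - 1.0) > 1e-12:
                raise ValueError("weights must sum to 1")
            self.weights = w

    @classmethod
    def from_rows(cls, rows: np.ndarray, weights=None) -> "SignalSet":
        """Build from a (Q, N) array, one signal per row."""
        return cls(np.asarray(rows, dtype=np.float64).T, weights)

    @property
    def n_samples(self) -> int:
        return self.signals.shape[0]

    @property
    def n_signals(self) -> int:
        return self.signals.shape[1]


@dataclass
class PursuitResult:
    """State of a finished pursuit.

    coefficients has shape (Q, k) with C[q, n] = c{q}(n); residuals has one
    column per signal; error_trace[k] is the weighted error after k atoms
    (squared or unsquared according to the stopping mode used).
    """

    selected_indices: list[int]
    ortho_vectors: np.ndarray          # (N, k) the w_n
    ortho_normalized: np.ndarray       # (N, k) the w~_n
    duals: np.ndarray                  # (N, k) the beta_n
    coefficients: np.ndarray           # (Q, k)
    residuals: np.ndarray              # (N, Q)
    error_trace: np.ndarray            # (k + 1,)
    tolerance_reached: bool
    stop_reason: str

    @property
    def n_atoms(self) -> int:
        return len(self.selected_indices)

    def approximations(self, signal_set: SignalSet) -> np.ndarray:
        """Final approximations f{q}_k = f{q} - r{q}_k, shape (N, Q)."""
        return signal_set.signals - self.residuals


def _atoms_matrix(dictionary) -> np.ndarray:
    return dictionary.atoms if hasattr(dictionary, "atoms") else np.asarray(dictionary)


def _selection_scores(residuals, atoms, ortho_normalized, excluded, weights):
    """Numerator and denominator of the SOOMP criterion for every atom."""
    R = np.asarray(residuals, dtype=np.float64)
    if R.ndim == 1:
        R = R[:, None]
    corr = atoms.T @ R  # (M, Q)
    numerator = (corr**2) @ np.asarray(weights, dtype=np.float64)
    if ortho_normalized is not None and np.size(ortho_normalized):
        Wt = np.asarray(ortho_normalized, dtype=np.float64)
        if Wt.ndim == 1:
            Wt = Wt[:, None]
        denominator = 1.0 - np.sum((atoms.T @ Wt) ** 2, axis=1)
    else:
        denominator = np.ones(atoms.shape[1])
    mask = np.ones(atoms.shape[1], dtype=bool)
    mask[list(excluded)] = False
    return numerator, denominator, mask


def select_atom_soomp(residuals, dictionary, ortho_normalized, excluded, weights) -> int:
    """Stepwise-optimal joint selection.

    Returns the index maximizing
    sum_q p(q) |<d_n, r{q}>|^2 / (1 - sum_i |<d_n, w~_i>|^2) over atoms not
    yet selected.  Atoms with denominator below SPAN_TOLERANCE are skipped
    (they lie in the span of the selection, so they cannot reduce the
    error).  Ties break to the lowest index.
    """
    atoms = _atoms_matrix(dictionary)
    numerator, denominator, mask = _selection_scores(
        residuals, atoms, ortho_normalized, excluded, weights
    )
    mask &= denominator >= SPAN_TOLERANCE
    if not mask.any():
        raise NoSelectableAtomError("all candidate atoms lie in the selected span")
    scores = np.where(mask, numerator / np.where(mask, denominator, 1.0), -np.inf)
    return int(np.argmax(scores))


def select_atom_somp(residuals, dictionary, excluded, weights, ortho_normalized=None) -> int:
    """SOMP selection: weighted residual correlation, no span correction.

    ``ortho_normalized`` is only used to skip atoms already numerically in
    the selected span (which would stall the pursuit); it does not enter
    the score.
    """
    atoms = _atoms_matrix(dictionary)
    numerator, denominator, mask = _selection_scores(
        residuals, atoms, ortho_normalized, excluded, weights
    )
    mask &= denominator >= SPAN_TOLERANCE
    if not mask.any():
        raise NoSelectableAtomError("all candidate atoms lie in the selected span")
    scores = np.where(mask, numerator, -np.inf)
    return int(np.argmax(scores))


#: basis extension rejects atoms whose orthogonalized norm falls below this;
#: looser than SPAN_TOLERANCE because selection already filters near-dependent
#: atoms — this guard only catches outright degeneracy
DEGENERATE_NORM = 1e-7


def extend_orthogonal_basis(ortho_vectors, new_atom, span_tolerance: float | None = None) -> np.ndarray:
    """One Gram-Schmidt step with re-orthogonalization.

    w_{k+1} = d - sum_i w_i <w_i, d> / ||w_i||^2, followed by one full
    re-orthogonalization pass; a second pass runs only if the orthogonality
    check still exceeds 1e-10 (twice is enough).
    """
    min_norm = DEGENERATE_NORM if span_tolerance is None else np.sqrt(span_tolerance)
    d = np.asarray(new_atom, dtype=np.float64)
    W = np.asarray(ortho_vectors, dtype=np.float64)
    if W.ndim == 1:
        W = W[:, None]
    if W.size == 0:
        return d.copy()
    inv_norms2 = 1.0 / np.sum(W**2, axis=0)
    w = d - W @ ((W.T @ d) * inv_norms2)
    w = w - W @ ((W.T @ w) * inv_norms2)  # re-orthogonalization (always one pass)
    wn = np.linalg.norm(w)
    if wn < min_norm:
        raise DegenerateAtomError("new atom is numerically in span(ortho_vectors)")
    overlap = np.max(np.abs(W.T @ w) * np.sqrt(inv_norms2)) / wn
    if overlap > 1e-10:
        w = w - W @ ((W.T @ w) * inv_norms2)
        if np.linalg.norm(w) < min_norm:
            raise DegenerateAtomError("new atom is numerically in span(ortho_vectors)")
    return w


def update_duals(duals, w_new, atom) -> np.ndarray:
    """Append beta_{k+1} = w/||w||^2 and correct the previous duals.

    beta_n <- beta_n - beta_{k+1} <d_{l_{k+1}}, beta_n> restores the
    biorthogonality <beta_n, d_{l_m}> = delta_nm.
    """
    w = np.asarray(w_new, dtype=np.float64)
    wn2 = float(w @ w)
    if wn2 < SPAN_TOLERANCE:
        raise DegenerateAtomError("zero-norm orthogonal vector")
    beta_new = w / wn2
    B = np.asarray(duals, dtype=np.float64)
    if B.ndim == 1:
        B = B[:, None]
    if B.size == 0:
        return beta_new[:, None]
    B = B - np.outer(beta_new, np.asarray(atom, dtype=np.float64) @ B)
    return np.column_stack([B, beta_new])


def update_residuals(signal_set: SignalSet, residuals, w_new) -> np.ndarray:
    """r{q} <- r{q} - w <w, f{q}> / ||w||^2 (projection step)."""
    w = np.asarray(w_new, dtype=np.float64)
    wn2 = float(w @ w)
    R = np.asarray(residuals, dtype=np.float64)
    return R - np.outer(w, (w @ signal_set.signals) / wn2)


def _weighted_error(residuals, weights, squared: bool) -> float:
    norms = np.linalg.norm(residuals, axis=0)
    if squared:
        return float(weights @ norms**2)
    return float(weights @ norms)


def _run_pursuit(signal_set, dictionary, tolerance, stop_mode, max_atoms, select):
    if stop_mode not in ("squared", "unsquared"):
        raise ValueError("stop_mode must be 'squared' or 'unsquared'")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    atoms = _atoms_matrix(dictionary)
    N, M = atoms.shape
    if N != signal_set.n_samples:
        raise ValueError(
            f"dictionary atoms have length {N}, signals have length {signal_set.n_samples}"
        )
    if max_atoms is None:
        max_atoms = N
    if max_atoms < 1:
        raise ValueError("max_atoms must be positive")
    max_atoms = min(int(max_atoms), M)

    F = signal_set.signals
    p = signal_set.weights
    squared = stop_mode == "squared"

    R = F.copy()
    W = np.empty((N, 0))
    Wt = np.empty((N, 0))
    B = np.empty((N, 0))
    selected: list[int] = []
    trace = [_weighted_error(R, p, squared)]
    reached = trace[0] < tolerance
    reason = "tolerance" if reached else ""

    while not reached and len(selected) < max_atoms:
        try:
            idx = select(R, atoms, Wt, selected, p)
        except NoSelectableAtomError:
            reason = "no_selectable_atom"
            break
        w = extend_orthogonal_basis(W, atoms[:, idx])
        B = update_duals(B, w, atoms[:, idx])
        R = update_residuals(signal_set, R, w)
        selected.append(idx)
        W = np.column_stack([W, w])
        Wt = np.column_stack([Wt, w / np.linalg.norm(w)])
        trace.append(_weighted_error(R, p, squared))
        if trace[-1] < tolerance:
            reached = True
            reason = "tolerance"
    if not reason:
        reason = "max_atoms"

    C = (B.T @ F).T if B.size else np.empty((signal_set.n_signals, 0))
    return PursuitResult(
        selected_indices=selected,
        ortho_vectors=W,
        ortho_normalized=Wt,
        duals=B,
        coefficients=C,
        residuals=R,
        error_trace=np.asarray(trace),
        tolerance_reached=reached,
        stop_reason=reason,
    )


def soomp(
    signal_set: SignalSet,
    dictionary,
    tolerance: float = 0.0,
    stop_mode: str = "squared",
    max_atoms: int | None = None,
) -> PursuitResult:
    """Simultaneous optimized orthogonal matching pursuit.

    Iterates stepwise-optimal atom selection until the weighted error
    (sum_q p(q) ||r{q}||^2 in 'squared' mode, sum_q p(q) ||r{q}|| in
    'unsquared' mode) drops below ``tolerance``, ``max_atoms`` atoms have
    been selected, or no selectable atom remains.  If the tolerance could
    not be reached the result carries ``tolerance_reached=False`` (no
    error is raised).
    """

    def select(R, atoms, Wt, selected, p):
        return select_atom_soomp(R, atoms, Wt, selected, p)

    return _run_pursuit(signal_set, dictionary, tolerance, stop_mode, max_atoms, select)


def somp(
    signal_set: SignalSet,
    dictionary,
    tolerance: float = 0.0,
    stop_mode: str = "squared",
    max_atoms: int | None = None,
) -> PursuitResult:
    """Simultaneous OMP baseline: correlation-only selection."""

    def select(R, atoms, Wt, selected, p):
        return select_atom_somp(R, atoms, selected, p, ortho_normalized=Wt)

    return _run_pursuit(signal_set, dictionary, tolerance, stop_mode, max_atoms, select)


def oomp(signal, dictionary, tolerance: float = 0.0, stop_mode: str = "squared",
         max_atoms: int | None = None) -> PursuitResult:
    """Single-signal optimized orthogonal matching pursuit (Q = 1 case)."""
    return soomp(SignalSet(np.asarray(signal, dtype=np.float64)), dictionary,
                 tolerance, stop_mode, max_atoms)
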