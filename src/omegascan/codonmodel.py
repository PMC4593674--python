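"""Goldman–Yang codon substitution process.

The instantaneous rate from sense codon *i* to *j* is nonzero only for
single-nucleotide changes and equals

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous],

with the diagonal set so rows sum to zero.  ``kappa`` is the
transition/transversion rate ratio and ``omega`` the nonsynonymous/synonymous
rate ratio (dN/dS).  Equilibrium codon frequencies ``pi`` follow the F3x4
convention: position-specific nucleotide frequencies, pooled over taxa,
multiplied per codon and renormalised over the sense codons.

The chain is time-reversible, so transition probabilities are computed by
eigendecomposition of the pi-symmetrised rate matrix; :func:`transition_probabilities`
is the public entry point and a dense ``expm`` fallback exists for matrices
supplied without frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.linalg

from .alignments import MISSING, CodonAlignment, GeneticCode, STANDARD_CODE

__all__ = [
    "f3x4_frequencies",
    "dump_tsv",
    "build_rate_matrix",
    "substitution_rate",
    "transition_probabilities",
    "SpectralRates",
]

_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}


@lru_cache(maxsize=4)
def _code_structure(code: GeneticCode):
    """Precompute the single-nucleotide-change structure of a genetic code.

    Returns boolean/index arrays over ordered sense-codon pairs (i, j) that
    differ at exactly one position: whether the change is a transition and
    whether it is nonsynonymous.
    """
    n = code.n_states
    ii, jj, ts, nonsyn = [], [], [], []
    for i in range(n):
        ci = code.sense_codons[i]
        for j in range(n):
            if i == j:
                continue
            cj = code.sense_codons[j]
            diff = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diff) != 1:
                continue
            ii.append(i)
            jj.append(j)
            ts.append(frozenset(diff[0]) in _TRANSITION_PAIRS)
            nonsyn.append(code.codon_to_aa[ci] != code.codon_to_aa[cj])
    return (
        np.array(ii),
        np.array(jj),
        np.array(ts, dtype=bool),
        np.array(nonsyn, dtype=bool),
    )


def f3x4_frequencies(alignment: CodonAlignment) -> np.ndarray:
    """F3x4 equilibrium codon frequencies from an alignment.

    Nucleotide frequencies are tabulated separately for the three codon
    positions, pooled over all taxa and excluding missing codons, then
    multiplied per sense codon and renormalised.
    """
    code = alignment.code
    states = alignment.codons[alignment.codons != MISSING]
    if states.size == 0:
        raise ValueError("alignment has no non-missing codons")
    nuc_idx = code.codon_nucleotide_indices()  # (61, 3)
    table = np.zeros((3, 4))
    for pos in range(3):
        counts = np.bincount(nuc_idx[states, pos], minlength=4)
        table[pos] = counts / counts.sum()
    pi = table[0, nuc_idx[:, 0]] * table[1, nuc_idx[:, 1]] * table[2, nuc_idx[:, 2]]
    total = pi.sum()
    if total <= 0:
        raise ValueError("all sense codons have zero F3x4 weight")
    return pi / total


def substitution_rate(kappa: float, omega: float, pi: np.ndarray,
                      code: GeneticCode = STANDARD_CODE) -> float:
    """Expected substitutions per codon per unit time of the *unscaled* matrix."""
    ii, jj, ts, nonsyn = _code_structure(code)
    rates = pi[jj] * np.where(ts, kappa, 1.0) * np.where(nonsyn, omega, 1.0)
    return float(np.sum(pi[ii] * rates))


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray,
                      code: GeneticCode = STANDARD_CODE, *,
                      scale: bool = True) -> np.ndarray:
    """Goldman–Yang rate matrix Q.

    With ``scale=True`` (default) Q is rescaled so that the expected number of
    substitutions per codon per unit time at equilibrium, ``-sum_i pi_i q_ii``,
    equals one; branch lengths are then in expected substitutions per codon.
    """
    if not (np.isfinite(kappa) and kappa > 0):
        raise ValueError(f"kappa must be positive and finite, got {kappa}")
    if not (np.isfinite(omega) and omega >= 0):
        raise ValueError(f"omega must be non-negative and finite, got {omega}")
    pi = np.asarray(pi, dtype=float)
    n = code.n_states
    ii, jj, ts, nonsyn = _code_structure(code)
    Q = np.zeros((n, n))
    Q[ii, jj] = pi[jj] * np.where(ts, kappa, 1.0) * np.where(nonsyn, omega, 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        mu = -np.sum(pi * np.diag(Q))
        if mu > 0:
            Q = Q / mu
    return Q


class SpectralRates:
    """Eigendecomposition of a reversible codon rate matrix for fast P(t).

    The matrix ``B = D^{1/2} Q D^{-1/2}`` (D = diag(pi)) is symmetric, so
    ``Q = D^{-1/2} U Lambda U' D^{1/2}`` with orthogonal U, and
    ``P(t) = D^{-1/2} U exp(Lambda t) U' D^{1/2}``.

    Frequencies are floored at a tiny value before symmetrisation so that
    codons assigned zero F3x4 weight (e.g. when a base never occurs at some
    position) do not break the decomposition.
    """

    _PI_FLOOR = 1e-8

    def __init__(self, kappa: float, omega: float, pi: np.ndarray,
                 code: GeneticCode = STANDARD_CODE):
        pi = np.asarray(pi, dtype=float)
        pi = np.maximum(pi, self._PI_FLOOR)
        pi = pi / pi.sum()
        Q = build_rate_matrix(kappa, omega, pi, code, scale=False)
        d = np.sqrt(pi)
        B = (d[:, None] * Q) / d[None, :]
        B = 0.5 * (B + B.T)  # symmetrise away rounding noise
        lam, U = np.linalg.eigh(B)
        self.eigenvalues = lam
        self._left = U / d[:, None]      # D^{-1/2} U
        self._right = (U * d[:, None]).T  # U' D^{1/2}
        self.rate = float(-np.sum(pi * np.diag(Q)))
        self.pi = pi

    def probabilities(self, t: float) -> np.ndarray:
        """P(t) for one branch length (unscaled-rate time units)."""
        return self.probabilities_batch(np.array([t]))[0]

    def probabilities_batch(self, ts: np.ndarray) -> np.ndarray:
        """Stack of P(t) matrices for several branch lengths at once."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValueError("branch lengths must be non-negative")
        E = np.exp(self.eigenvalues[None, :] * ts[:, None])  # (k, n)
        # P_k = left @ diag(E_k) @ right
        tmp = self._left[None, :, :] * E[:, None, :]
        P = tmp @ self._right
        np.clip(P, 0.0, None, out=P)
        P[ts == 0.0] = np.eye(len(self.eigenvalues))  # exact identity at t=0
        return P


def dump_tsv(array: np.ndarray, path, code: GeneticCode = STANDARD_CODE) -> None:
    """Write pi (vector) or Q/P (matrix) to TSV with codon labels, for debugging."""
    import pandas as pd

    labels = list(code.sense_codons)
    arr = np.asarray(array)
    if arr.ndim == 1:
        pd.Series(arr, index=labels, name="value").to_csv(path, sep="\t")
    else:
        pd.DataFrame(arr, index=labels, columns=labels).to_csv(path, sep="\t")


def transition_probabilities(Q: np.ndarray, t: float,
                             pi: np.ndarray | None = None) -> np.ndarray:
    """Transition probability matrix ``P(t) = expm(Q t)``.

    When ``pi`` is supplied the reversible eigendecomposition path is used;
    otherwise a dense matrix exponential.  Tiny negative entries from
    round-off are clamped to zero.
    """
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if pi is not None:
        d = np.sqrt(np.maximum(np.asarray(pi, float), 1e-300))
        B = (d[:, None] * Q) / d[None, :]
        B = 0.5 * (B + B.T)
        lam, U = np.linalg.eigh(B)
        P = (U / d[:, None] * np.exp(lam * t)[None, :]) @ (U * d[:, None]).T
    else:
        P = scipy.linalg.expm(Q * t)
    neg = P < 0
    if np.any(P[neg] < -1e-12):
        raise FloatingPointError("transition matrix has non-trivial negative entries")
    P[neg] = 0.0
    return P
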