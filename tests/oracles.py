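"""Independent brute-force oracles used by the test suite.

Everything here is written against first principles (direct enumeration,
explicit formulas) and deliberately avoids the code paths it is used to
check.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.linalg

from omegascan.alignments import MISSING
from omegascan.codonmodel import build_rate_matrix, substitution_rate


def gc3_by_string_scan(nucleotide_string: str) -> float:
    """GC3 computed by scanning the raw nucleotide string."""
    n_used = 0
    n_gc = 0
    for j in range(0, len(nucleotide_string), 3):
        codon = nucleotide_string[j : j + 3]
        if all(b in "ACGT" for b in codon):
            n_used += 1
            if codon[2] in "GC":
                n_gc += 1
    return n_gc / n_used if n_used else math.nan


def bh_step_up(pvalues) -> np.ndarray:
    """Reference BH q-values via the textbook double loop."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return np.array(q)


def median_interval(positions) -> float | None:
    """Reference median PSS interval: sort, diff, median by hand."""
    pos = sorted(positions)
    if len(pos) < 2:
        return None
    gaps = [b - a for a, b in zip(pos, pos[1:])]
    gaps.sort()
    k = len(gaps)
    if k % 2 == 1:
        return float(gaps[k // 2])
    return (gaps[k // 2 - 1] + gaps[k // 2]) / 2.0


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), via explicit binomial sums."""
    total = 0.0
    denom = math.comb(N, n)
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / denom
    return total


def brute_force_mixture_loglik(aln, tree, params, pi) -> float:
    """Branch-site log-likelihood by exhaustive internal-state enumeration.

    For every codon column and site class, sums the joint probability over
    all assignments of sense codons to internal nodes, with transition
    matrices from scipy's dense ``expm``.  Only feasible for a handful of
    tips (61^n_internal terms).
    """
    code = aln.code
    n = code.n_states
    scale = _background_mixture_rate(params, pi, code)

    nodes = list(tree.postorder())
    internals = [nd for nd in nodes if not nd.is_tip]
    tips = [nd for nd in nodes if nd.is_tip]
    k = len(internals)
    grids = np.meshgrid(*([np.arange(n)] * k), indexing="ij")
    istate = {id(nd): g.ravel() for nd, g in zip(internals, grids)}

    fg = tree.foreground_nodes()
    assert len(fg) == 1
    fg_id = id(fg[0])

    # per-class, per-node transition matrices from the independent expm path
    specs = params.class_omegas
    P_cache: dict[tuple[float, float], np.ndarray] = {}

    def P_for(omega: float, t: float) -> np.ndarray:
        key = (omega, t)
        if key not in P_cache:
            Q = build_rate_matrix(params.kappa, omega, pi, code, scale=False)
            P_cache[key] = scipy.linalg.expm(Q * (t / scale))
        return P_cache[key]

    props = params.proportions
    total = 0.0
    for col in range(aln.length):
        col_lik = 0.0
        for c, (w_bg, w_fg) in enumerate(specs):
            if props[c] == 0:
                continue
            joint = pi[istate[id(tree.root)]].astype(float).copy()
            for nd in nodes:
                if nd.parent is None:
                    continue
                w = w_fg if id(nd) == fg_id else w_bg
                P = P_for(w, nd.length)
                parent_states = istate[id(nd.parent)]
                if nd.is_tip:
                    s = aln.row(nd.name)[col]
                    if s == MISSING:
                        continue  # marginalising the tip gives a factor of 1
                    joint *= P[parent_states, s]
                else:
                    joint *= P[parent_states, istate[id(nd)]]
            col_lik += props[c] * joint.sum()
        total += math.log(col_lik)
    return total


def _background_mixture_rate(params, pi, code) -> float:
    props = params.proportions
    r0 = substitution_rate(params.kappa, params.omega0, pi, code)
    r1 = substitution_rate(params.kappa, 1.0, pi, code)
    return (props[0] + props[2]) * r0 + (props[1] + props[3]) * r1
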