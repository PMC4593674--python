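"""Branch-site model A: likelihood, ML fitting, LRT and BEB site posteriors.

The model mixes four site classes over codon columns.  With background ratio
``omega0`` in (0,1), neutral ratio 1, and foreground ratio ``omega2 >= 1``:

    class    proportion                       background   foreground
    0        p0                               omega0       omega0
    1        p1                               1            1
    2a       (1-p0-p1) * p0/(p0+p1)           omega0       omega2
    2b       (1-p0-p1) * p1/(p0+p1)           1            omega2

"Foreground" is the single flagged branch of the tree; positive selection is
allowed only there (classes 2a/2b).  The null model fixes ``omega2 = 1``; the
alternative estimates it.  Twice the log-likelihood difference is referred to
the chi-square distribution with one degree of freedom.

Site posteriors for the positively-selected classes are computed by Bayes
Empirical Bayes: a uniform discrete grid prior over (p0, p1), omega0 and
omega2, with kappa and branch lengths fixed at their ML estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.optimize
from scipy.special import expit, logit, logsumexp
from scipy.stats import chi2

from .alignments import MISSING, CodonAlignment, GeneticCode, STANDARD_CODE
from .codonmodel import SpectralRates
from .trees import PhyloTree, TreeNode

__all__ = [
    "BranchSiteParams",
    "FitResult",
    "PSSRecord",
    "FitConfig",
    "LikelihoodEngine",
    "gene_log_likelihood",
    "fit_m0",
    "fit_alternative",
    "fit_null",
    "fit_gene",
    "lrt",
    "beb_site_posteriors",
    "beb_class_posteriors",
]


@dataclass(frozen=True)
class BranchSiteParams:
    """Free parameters of branch-site model A."""

    kappa: float
    omega0: float
    omega2: float
    p0: float
    p1: float

    def __post_init__(self) -> None:
        if not (self.kappa > 0 and np.isfinite(self.kappa)):
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        if not (0.0 < self.omega0 < 1.0):
            raise ValueError(f"omega0 must lie in (0, 1), got {self.omega0}")
        if self.omega2 < 1.0:
            raise ValueError(f"omega2 must be >= 1, got {self.omega2}")
        if self.p0 < 0 or self.p1 < 0 or self.p0 + self.p1 > 1.0 + 1e-12:
            raise ValueError(f"invalid proportions p0={self.p0}, p1={self.p1}")
        if self.p0 + self.p1 <= 0:
            raise ValueError("p0 + p1 must be positive")

    @property
    def proportions(self) -> np.ndarray:
        """Class proportions (p0, p1, p2a, p2b); they sum to one."""
        p0, p1 = self.p0, self.p1
        rest = max(0.0, 1.0 - p0 - p1)
        p2a = rest * p0 / (p0 + p1)
        p2b = rest * p1 / (p0 + p1)
        return np.array([p0, p1, p2a, p2b])

    @property
    def class_omegas(self) -> list[tuple[float, float]]:
        """(background, foreground) omega per site class."""
        return [
            (self.omega0, self.omega0),
            (1.0, 1.0),
            (self.omega0, self.omega2),
            (1.0, self.omega2),
        ]


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    params: BranchSiteParams
    lnl: float
    converged: bool
    n_starts: int
    branch_length_mode: str  # "fixed" (given tree) or "m0" (estimated upstream)
    tree: PhyloTree | None = None
    model: str = "alternative"  # "alternative" or "null"


@dataclass(frozen=True)
class PSSRecord:
    """Per-column BEB posterior of the positively-selected classes (2a+2b)."""

    position: int  # 1-based codon column in alignment coordinates
    posterior: float
    best_class: int  # argmax over the four class posteriors (0,1,2=2a,3=2b)


@dataclass(frozen=True)
class FitConfig:
    """Optimiser settings; the seed makes restart points reproducible."""

    n_starts: int = 3
    seed: int = 0
    maxiter: int = 200
    ftol: float = 1e-10
    gtol: float = 1e-5
    beb_grid: int = 10


# ---------------------------------------------------------------------------
# likelihood engine
# ---------------------------------------------------------------------------


class LikelihoodEngine:
    """Pruning likelihood for one gene on one (rooted) tree.

    Site patterns are collapsed once at construction; all evaluations work on
    the pattern matrix and expand with multiplicities.  Partial likelihoods
    are rescaled per pattern at every internal node, so the machinery is safe
    for trees of arbitrary depth.
    """

    def __init__(self, aln: CodonAlignment, tree: PhyloTree,
                 code: GeneticCode | None = None):
        self.code = code or aln.code
        self.n_states = self.code.n_states
        self.tree = tree
        tip_names = tree.tip_names
        missing_taxa = set(tip_names) - set(aln.taxa)
        if missing_taxa:
            raise ValueError(f"tree tips absent from alignment: {sorted(missing_taxa)}")

        rows = np.array([aln.row(t) for t in tip_names])
        patterns, inverse, counts = np.unique(
            rows, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns            # (n_tips, n_pat)
        self.pattern_of_column = inverse    # (L,)
        self.counts = counts.astype(float)  # (n_pat,)
        self.n_patterns = patterns.shape[1]
        self.n_columns = rows.shape[1]

        # flatten the tree: postorder node list; per node its parent edge
        self.nodes: list[TreeNode] = list(tree.postorder())
        self.node_index = {id(n): i for i, n in enumerate(self.nodes)}
        self.root_index = self.node_index[id(tree.root)]
        self.edge_nodes = [i for i, n in enumerate(self.nodes) if n.parent is not None]
        self.default_lengths = np.array(
            [self.nodes[i].length for i in self.edge_nodes]
        )
        self.edge_slot = {i: k for k, i in enumerate(self.edge_nodes)}
        fg = [i for i, n in enumerate(self.nodes) if n.foreground and n.parent is not None]
        if len(fg) > 1:
            raise ValueError("more than one foreground branch flagged")
        self.fg_node_index = fg[0] if fg else None

        tip_row = {name: r for r, name in enumerate(tip_names)}
        self.tip_slot = {
            i: tip_row[n.name] for i, n in enumerate(self.nodes) if n.is_tip
        }
        # safe state indices + missing masks per tip for fancy indexing
        self._tip_states = np.where(patterns == MISSING, 0, patterns)
        self._tip_missing = patterns == MISSING
        # caches reused across optimiser evaluations (keyed on exact floats)
        self._spectral_cache: dict[tuple[float, float], SpectralRates] = {}
        self._siteloglik_cache: dict[tuple, np.ndarray] = {}
        # rescale partial likelihoods every third level plus at the root
        depth: dict[int, int] = {}
        for i in reversed(range(len(self.nodes))):  # preorder-ish over indices
            node = self.nodes[i]
            parent = node.parent
            depth[i] = 0 if parent is None else depth[self.node_index[id(parent)]] + 1
        self._rescale_nodes = {
            i for i, n in enumerate(self.nodes)
            if not n.is_tip and (depth[i] % 3 == 0 or i == self.root_index)
        }

    # -- core pruning -------------------------------------------------------

    def _site_loglik_batch(self, P_by_edge: dict[int, np.ndarray],
                           pi: np.ndarray) -> np.ndarray:
        """Log-likelihood per (class, pattern) for stacked per-edge P matrices.

        ``P_by_edge[i]`` has shape (C, n, n): one transition matrix per class
        for the edge above node *i*.  One pruning pass serves all classes via
        batched matrix products.
        """
        n_pat, n = self.n_patterns, self.n_states
        C = next(iter(P_by_edge.values())).shape[0]
        partials: dict[int, np.ndarray] = {}
        logscale = np.zeros((C, n_pat))
        for i, node in enumerate(self.nodes):
            if node.is_tip:
                continue
            F: np.ndarray | None = None
            for child in node.children:
                ci = self.node_index[id(child)]
                P = P_by_edge[ci]
                if child.is_tip:
                    r = self.tip_slot[ci]
                    M = P[:, :, self._tip_states[r]].transpose(0, 2, 1).copy()
                    M[:, self._tip_missing[r], :] = 1.0
                else:
                    M = np.matmul(partials.pop(ci), P.transpose(0, 2, 1))
                if F is None:
                    F = M
                else:
                    F *= M
            # rescaling guards against underflow; P entries are <= 1 so
            # partials only shrink, and rescaling every few levels suffices
            if i in self._rescale_nodes:
                scale = F.max(axis=2)
                nz = scale > 0
                np.divide(F, np.where(nz, scale, 1.0)[:, :, None], out=F)
                with np.errstate(divide="ignore"):
                    logscale += np.where(
                        nz, np.log(np.where(nz, scale, 1.0)), -np.inf
                    )
            partials[i] = F
        lik = partials[self.root_index] @ pi
        with np.errstate(divide="ignore"):
            return np.log(lik) + logscale

    def _spectral(self, kappa: float, omega: float) -> SpectralRates:
        key = (kappa, omega)
        cached = self._spectral_cache.get(key)
        if cached is None:
            if len(self._spectral_cache) > 128:
                self._spectral_cache.clear()
            cached = self._spectral_cache[key] = SpectralRates(
                kappa, omega, self._pi_current, self.code
            )
        return cached

    def class_site_logliks(
        self,
        kappa: float,
        class_specs: Sequence[tuple[float, float]],
        pi: np.ndarray,
        scale: float,
        edge_lengths: np.ndarray | None = None,
    ) -> np.ndarray:
        """Per-class, per-pattern log site likelihoods.

        ``class_specs`` gives (background, foreground) omega for each class;
        ``scale`` converts branch lengths (expected substitutions per codon)
        to the time units of the unscaled rate matrices.  Results are cached
        per (kappa, omegas, scale) while the default branch lengths are in
        use, which saves most of the finite-difference overhead during
        optimisation.
        """
        # the caches are only valid for one set of frequencies
        pi_key = hash(pi.tobytes())
        if getattr(self, "_pi_key", None) != pi_key:
            self._pi_key = pi_key
            self._pi_current = pi
            self._spectral_cache.clear()
            self._siteloglik_cache.clear()
        cacheable = edge_lengths is None
        out = np.empty((len(class_specs), self.n_patterns))
        todo: list[tuple[int, tuple[float, float]]] = []
        for c, spec in enumerate(class_specs):
            key = (kappa, spec[0], spec[1], scale)
            if cacheable and key in self._siteloglik_cache:
                out[c] = self._siteloglik_cache[key]
            else:
                todo.append((c, spec))
        if not todo:
            return out

        t = self.default_lengths if edge_lengths is None else np.asarray(edge_lengths)
        t_eff = t / scale
        distinct = {w for _, spec in todo for w in spec}
        spectral = {w: self._spectral(kappa, w) for w in distinct}
        P_all = {w: s.probabilities_batch(t_eff) for w, s in spectral.items()}
        P_by_edge: dict[int, np.ndarray] = {}
        for i in self.edge_nodes:
            k = self.edge_slot[i]
            stack = [
                P_all[spec[1] if i == self.fg_node_index else spec[0]][k]
                for _, spec in todo
            ]
            P_by_edge[i] = np.stack(stack)
        pi_eff = spectral[next(iter(distinct))].pi
        block = self._site_loglik_batch(P_by_edge, pi_eff)
        for row, (c, spec) in enumerate(todo):
            out[c] = block[row]
            if cacheable:
                if len(self._siteloglik_cache) > 512:
                    self._siteloglik_cache.clear()
                self._siteloglik_cache[(kappa, spec[0], spec[1], scale)] = block[row]
        return out

    # -- model-level likelihoods -------------------------------------------

    @staticmethod
    def mixture_scale(params: BranchSiteParams, pi: np.ndarray,
                      code: GeneticCode) -> float:
        """One scaling constant for the whole gene.

        The class-weighted average substitution rate of the background
        classes, so that branch lengths mean expected substitutions per codon
        averaged over site classes on a background branch.
        """
        from .codonmodel import substitution_rate

        props = params.proportions
        r0 = substitution_rate(params.kappa, params.omega0, pi, code)
        r1 = substitution_rate(params.kappa, 1.0, pi, code)
        return float((props[0] + props[2]) * r0 + (props[1] + props[3]) * r1)

    def branch_site_loglik(self, params: BranchSiteParams, pi: np.ndarray,
                           edge_lengths: np.ndarray | None = None) -> float:
        if self.fg_node_index is None:
            raise ValueError("no foreground branch flagged on the tree")
        scale = self.mixture_scale(params, pi, self.code)
        site_ll = self.class_site_logliks(
            params.kappa, params.class_omegas, pi, scale, edge_lengths
        )
        with np.errstate(divide="ignore"):
            logprops = np.log(params.proportions)
        per_pattern = logsumexp(site_ll + logprops[:, None], axis=0)
        return float(per_pattern @ self.counts)

    def single_omega_loglik(self, kappa: float, omega: float, pi: np.ndarray,
                            edge_lengths: np.ndarray | None = None) -> float:
        """M0-style likelihood: one omega on every branch."""
        from .codonmodel import substitution_rate

        scale = substitution_rate(kappa, omega, pi, self.code)
        site_ll = self.class_site_logliks(kappa, [(omega, omega)], pi, scale,
                                          edge_lengths)
        return float(site_ll[0] @ self.counts)


def gene_log_likelihood(aln: CodonAlignment, tree: PhyloTree,
                        params: BranchSiteParams, pi: np.ndarray) -> float:
    """Branch-site model A log-likelihood of one gene (convenience wrapper)."""
    return LikelihoodEngine(aln, tree).branch_site_loglik(params, pi)


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

_LOG_KAPPA_BOUNDS = (np.log(0.05), np.log(50.0))
_LOGIT_W0_BOUNDS = (-12.0, 12.0)
_SIMPLEX_BOUNDS = (-12.0, 12.0)
_LOG_W2M1_BOUNDS = (-12.0, 6.0)


def _simplex_from(z1: float, z2: float) -> tuple[float, float]:
    e = np.exp([z1, z2, 0.0])
    e /= e.sum()
    return float(e[0]), float(e[1])


def _simplex_to(p0: float, p1: float) -> tuple[float, float]:
    rest = max(1.0 - p0 - p1, 1e-8)
    return float(np.log(max(p0, 1e-8) / rest)), float(np.log(max(p1, 1e-8) / rest))


def _unpack_alt(x: np.ndarray) -> BranchSiteParams:
    p0, p1 = _simplex_from(x[2], x[3])
    return BranchSiteParams(
        kappa=float(np.exp(x[0])),
        omega0=float(expit(x[1])),
        omega2=1.0 + float(np.exp(x[4])),
        p0=p0,
        p1=p1,
    )


def _pack_alt(p: BranchSiteParams) -> np.ndarray:
    z1, z2 = _simplex_to(p.p0, p.p1)
    return np.array([
        np.log(p.kappa),
        logit(np.clip(p.omega0, 1e-5, 1 - 1e-5)),
        z1,
        z2,
        np.log(max(p.omega2 - 1.0, 1e-5)),
    ])


def _random_start(rng: np.random.Generator, null: bool) -> np.ndarray:
    kappa = np.exp(rng.uniform(np.log(0.8), np.log(8.0)))
    omega0 = rng.uniform(0.03, 0.8)
    p = rng.dirichlet([4.0, 2.0, 1.0])
    omega2 = 1.0 + np.exp(rng.uniform(np.log(0.2), np.log(15.0)))
    x = _pack_alt(BranchSiteParams(kappa, omega0, omega2, p[0], p[1]))
    return x[:4] if null else x


_DEFAULT_START = BranchSiteParams(kappa=2.0, omega0=0.3, omega2=2.5, p0=0.65, p1=0.25)


def _maximise(objective, starts, bounds, config: FitConfig):
    best = None
    for x0 in starts:
        res = scipy.optimize.minimize(
            objective,
            np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds]),
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": config.maxiter,
                "ftol": config.ftol,
                "gtol": config.gtol,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit_alternative(
    aln: CodonAlignment,
    tree: PhyloTree,
    pi: np.ndarray,
    config: FitConfig = FitConfig(),
    *,
    engine: LikelihoodEngine | None = None,
    extra_starts: Sequence[BranchSiteParams] = (),
    branch_length_mode: str = "fixed",
) -> FitResult:
    """Maximum-likelihood fit of the alternative model (omega2 free, >= 1)."""
    eng = engine or LikelihoodEngine(aln, tree)
    rng = np.random.default_rng(config.seed)

    def objective(x: np.ndarray) -> float:
        ll = eng.branch_site_loglik(_unpack_alt(x), pi)
        return -ll if np.isfinite(ll) else 1e12

    starts = [_pack_alt(_DEFAULT_START)]
    starts += [_pack_alt(p) for p in extra_starts]
    while len(starts) < config.n_starts + len(extra_starts):
        starts.append(_random_start(rng, null=False))
    bounds = [_LOG_KAPPA_BOUNDS, _LOGIT_W0_BOUNDS, _SIMPLEX_BOUNDS,
              _SIMPLEX_BOUNDS, _LOG_W2M1_BOUNDS]
    best = _maximise(objective, starts, bounds, config)
    return FitResult(
        params=_unpack_alt(best.x),
        lnl=-float(best.fun),
        converged=bool(best.success),
        n_starts=len(starts),
        branch_length_mode=branch_length_mode,
        tree=tree,
    )


def fit_null(
    aln: CodonAlignment,
    tree: PhyloTree,
    pi: np.ndarray,
    config: FitConfig = FitConfig(),
    *,
    engine: LikelihoodEngine | None = None,
    extra_starts: Sequence[BranchSiteParams] = (),
    branch_length_mode: str = "fixed",
) -> FitResult:
    """Fit of the null model: omega2 fixed at 1 (no foreground selection)."""
    eng = engine or LikelihoodEngine(aln, tree)
    rng = np.random.default_rng(config.seed + 1)

    def objective(x: np.ndarray) -> float:
        x5 = np.append(x, _LOG_W2M1_BOUNDS[0])
        params = _unpack_alt(x5)
        params = replace(params, omega2=1.0)
        ll = eng.branch_site_loglik(params, pi)
        return -ll if np.isfinite(ll) else 1e12

    starts = [_pack_alt(_DEFAULT_START)[:4]]
    starts += [_pack_alt(p)[:4] for p in extra_starts]
    while len(starts) < max(config.n_starts, len(starts)):
        starts.append(_random_start(rng, null=True))
    bounds = [_LOG_KAPPA_BOUNDS, _LOGIT_W0_BOUNDS, _SIMPLEX_BOUNDS, _SIMPLEX_BOUNDS]
    best = _maximise(objective, starts, bounds, config)
    params = replace(_unpack_alt(np.append(best.x, _LOG_W2M1_BOUNDS[0])), omega2=1.0)
    return FitResult(
        params=params,
        lnl=-float(best.fun),
        converged=bool(best.success),
        n_starts=len(starts),
        branch_length_mode=branch_length_mode,
        tree=tree,
        model="null",
    )


def fit_m0(
    aln: CodonAlignment,
    tree: PhyloTree,
    pi: np.ndarray,
    config: FitConfig = FitConfig(),
    *,
    optimise_branch_lengths: bool = True,
) -> tuple[PhyloTree, float, float, float]:
    """Single-omega (M0) fit used to estimate per-gene branch lengths.

    Returns ``(tree_with_fitted_lengths, kappa, omega, lnl)``.  The fitted
    lengths are then held fixed in both branch-site fits, the standard
    practice for genome-scale screens.
    """
    eng = LikelihoodEngine(aln, tree)
    n_edges = len(eng.edge_nodes)
    t0 = np.clip(eng.default_lengths, 1e-3, 20.0)

    if optimise_branch_lengths:
        def objective(x: np.ndarray) -> float:
            ll = eng.single_omega_loglik(
                float(np.exp(x[n_edges])), float(np.exp(x[n_edges + 1])), pi,
                edge_lengths=np.exp(x[:n_edges]),
            )
            return -ll if np.isfinite(ll) else 1e12

        x0 = np.concatenate([np.log(t0), [np.log(2.0), np.log(0.3)]])
        bounds = [(np.log(1e-4), np.log(20.0))] * n_edges + [
            _LOG_KAPPA_BOUNDS, (np.log(1e-4), np.log(5.0)),
        ]
        res = scipy.optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": config.maxiter, "ftol": config.ftol,
                     "gtol": config.gtol},
        )
        t_hat = np.exp(res.x[:n_edges])
        kappa, omega = float(np.exp(res.x[n_edges])), float(np.exp(res.x[n_edges + 1]))
        lnl = -float(res.fun)
    else:
        def objective(x: np.ndarray) -> float:
            ll = eng.single_omega_loglik(float(np.exp(x[0])), float(np.exp(x[1])), pi)
            return -ll if np.isfinite(ll) else 1e12

        res = scipy.optimize.minimize(
            objective, np.log([2.0, 0.3]), method="L-BFGS-B",
            bounds=[_LOG_KAPPA_BOUNDS, (np.log(1e-4), np.log(5.0))],
            options={"maxiter": config.maxiter, "ftol": config.ftol,
                     "gtol": config.gtol},
        )
        t_hat = eng.default_lengths
        kappa, omega = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
        lnl = -float(res.fun)

    fitted = tree.copy()
    fitted_nodes = list(fitted.postorder())
    for k, i in enumerate(eng.edge_nodes):
        fitted_nodes[i].length = float(t_hat[k])
    return fitted, kappa, omega, lnl


def fit_gene(
    aln: CodonAlignment,
    tree: PhyloTree,
    pi: np.ndarray,
    config: FitConfig = FitConfig(),
    *,
    branch_length_mode: str = "m0",
) -> tuple[FitResult, FitResult]:
    """Null and alternative fits for one gene, with the standard repair step.

    With ``branch_length_mode="m0"`` branch lengths are first estimated under
    a single-omega model and then fixed for both branch-site fits; with
    ``"fixed"`` the lengths on the input tree are used as-is.  If optimiser
    noise leaves the alternative below the null, the alternative is refitted
    from the null's parameters before the pair is returned.
    """
    if branch_length_mode == "m0":
        work_tree, _, _, _ = fit_m0(aln, tree, pi, config)
    elif branch_length_mode == "fixed":
        work_tree = tree
    else:
        raise ValueError(f"unknown branch_length_mode {branch_length_mode!r}")

    engine = LikelihoodEngine(aln, work_tree)
    alt = fit_alternative(aln, work_tree, pi, config, engine=engine,
                          branch_length_mode=branch_length_mode)
    null_seed = replace(alt.params, omega2=1.0)
    null = fit_null(aln, work_tree, pi, config, engine=engine,
                    extra_starts=[null_seed],
                    branch_length_mode=branch_length_mode)
    if alt.lnl < null.lnl - 1e-6:
        # repair: restart the alternative from the null's optimum
        repaired = fit_alternative(
            aln, work_tree, pi, replace(config, n_starts=1), engine=engine,
            extra_starts=[replace(null.params, omega2=1.0 + 1e-4)],
            branch_length_mode=branch_length_mode,
        )
        if repaired.lnl > alt.lnl:
            alt = repaired
    if alt.lnl < null.lnl:
        # the null optimum is itself a feasible alternative point (omega2=1),
        # so the models nest exactly; adopt it rather than report noise
        alt = replace(
            alt, params=replace(null.params, omega2=1.0), lnl=null.lnl
        )
    return null, alt


def lrt(lnl_null: float, lnl_alt: float) -> tuple[float, float]:
    """Likelihood ratio test with one degree of freedom.

    The statistic ``2 * (lnL_alt - lnL_null)`` is clamped at zero (residual
    optimiser noise) and referred to the upper tail of chi-square(1).
    """
    if not (np.isfinite(lnl_null) and np.isfinite(lnl_alt)):
        raise ValueError("log-likelihoods must be finite")
    stat = max(0.0, 2.0 * (lnl_alt - lnl_null))
    return stat, float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Bayes Empirical Bayes
# ---------------------------------------------------------------------------


def beb_class_posteriors(
    aln: CodonAlignment,
    tree: PhyloTree,
    fit: FitResult,
    pi: np.ndarray,
    *,
    engine: LikelihoodEngine | None = None,
    n_grid: int = 10,
) -> np.ndarray:
    """(4, L) matrix of per-column posterior probabilities of the site classes.

    The prior is a uniform discrete grid: ``n_grid`` midpoints per dimension
    for omega0 in (0,1), omega2 in (1,11) and a two-parameter coverage of the
    (p0, p1) simplex.  kappa, branch lengths and the rate scaling constant
    are fixed at their ML estimates; grid points are weighted by their data
    likelihoods and class posteriors averaged accordingly.  Each column's
    four posteriors sum to one.
    """
    if fit.model != "alternative":
        raise ValueError("BEB site posteriors require the alternative-model fit")
    eng = engine or LikelihoodEngine(aln, tree)
    if eng.fg_node_index is None:
        raise ValueError("no foreground branch flagged on the tree")
    kappa = fit.params.kappa
    scale = eng.mixture_scale(fit.params, pi, eng.code)

    mid = (np.arange(n_grid) + 0.5) / n_grid
    w0_grid = mid                       # omega0 in (0, 1)
    w2_grid = 1.0 + 10.0 * mid          # omega2 in (1, 11)
    # (p0, p1) grid: p0 = u, p1 = v * (1 - u) over the unit-square midpoints
    u, v = np.meshgrid(mid, mid, indexing="ij")
    p0g = u.ravel()
    p1g = (v * (1.0 - u)).ravel()
    rest = 1.0 - p0g - p1g
    props = np.stack([
        p0g,
        p1g,
        rest * p0g / (p0g + p1g),
        rest * p1g / (p0g + p1g),
    ], axis=1)  # (n_grid^2, 4)

    # site log-likelihood tables per class variant
    specs_w0 = [(w, w) for w in w0_grid]
    L0 = eng.class_site_logliks(kappa, specs_w0, pi, scale)           # (G, n_pat)
    L1 = eng.class_site_logliks(kappa, [(1.0, 1.0)], pi, scale)[0]    # (n_pat,)
    L2b = eng.class_site_logliks(kappa, [(1.0, w2) for w2 in w2_grid], pi, scale)
    L2a = np.empty((n_grid, n_grid, eng.n_patterns))
    for a, w0 in enumerate(w0_grid):
        L2a[a] = eng.class_site_logliks(
            kappa, [(w0, w2) for w2 in w2_grid], pi, scale
        )

    counts = eng.counts
    n_pat = eng.n_patterns
    n_p = props.shape[0]

    # pass 1: marginal data log-likelihood at every grid point
    log_px = np.empty((n_grid, n_grid, n_p))
    cache_S = {}
    for a in range(n_grid):
        for b in range(n_grid):
            logL = np.stack([L0[a], L1, L2a[a, b], L2b[b]])  # (4, n_pat)
            m = logL.max(axis=0)
            S = np.exp(logL - m)
            cache_S[(a, b)] = (S, m)
            F = props @ S  # (n_p, n_pat)
            log_px[a, b] = (np.log(F) + m) @ counts
    log_weights = log_px - logsumexp(log_px)
    weights = np.exp(log_weights)

    # pass 2: posterior-weighted class probabilities per pattern
    post = np.zeros((4, n_pat))
    for a in range(n_grid):
        for b in range(n_grid):
            S, _ = cache_S[(a, b)]
            F = props @ S
            w = weights[a, b]  # (n_p,)
            inv = np.where(F > 0, 1.0 / F, 0.0)
            for k in range(4):
                post[k] += (w * props[:, k]) @ (S[k][None, :] * inv)

    return post[:, eng.pattern_of_column]  # (4, L)


def beb_site_posteriors(
    aln: CodonAlignment,
    tree: PhyloTree,
    fit: FitResult,
    pi: np.ndarray,
    *,
    engine: LikelihoodEngine | None = None,
    n_grid: int = 10,
) -> list[PSSRecord]:
    """Per-column BEB records: posterior of the selected classes (2a + 2b)."""
    post_cols = beb_class_posteriors(aln, tree, fit, pi, engine=engine,
                                     n_grid=n_grid)
    p_selected = post_cols[2] + post_cols[3]
    best = post_cols.argmax(axis=0)
    return [
        PSSRecord(position=j + 1, posterior=float(p_selected[j]),
                  best_class=int(best[j]))
        for j in range(post_cols.shape[1])
    ]
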