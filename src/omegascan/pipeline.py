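"""Genome-wide scan orchestration: fits, LRTs, PSS filter, FDR, diagnostics.

The scan walks every gene over every requested focal branch and applies, in
order: a single-omega branch-length fit, the branch-site null/alternative
fits, the one-degree-of-freedom LRT, BEB site posteriors, the
positively-selected-site (PSS) aggregation filter, and Benjamini–Hochberg
FDR control.  The aggregation filter excludes genes whose PSSs (posterior
strictly above the threshold) have a median inter-site distance of at most
``agg_cutoff`` codons — tightly clustered signal is the classic footprint of
alignment error rather than selection.  FDR correction is applied per focal
branch, across the genes tested on that branch that survive the filter, i.e.
filtering precedes correction.

Summary counts follow a monotone cascade per branch:

    tested >= raw-significant >= kept raw-significant >= FDR-significant.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignments import CodonAlignment, delta_gc3
from .branchsite import (
    FitConfig,
    FitResult,
    PSSRecord,
    LikelihoodEngine,
    beb_site_posteriors,
    fit_gene,
    lrt,
)
from .codonmodel import f3x4_frequencies
from .trees import PhyloTree, prune_to_taxa, tag_foreground

__all__ = [
    "ScanConfig",
    "SelectionTestResult",
    "ScanSummary",
    "median_pss_interval",
    "aggregation_filter",
    "select_pss",
    "bh_fdr",
    "run_scan",
    "gc3_lrt_correlation",
]


@dataclass(frozen=True)
class ScanConfig:
    """Tunable thresholds of the scan (defaults follow the screen design)."""

    seed: int = 0
    alpha: float = 0.05           # raw LRT significance gate
    fdr_q: float = 0.10           # q-value threshold
    agg_cutoff: float = 10.0      # median PSS interval (codons), inclusive
    pss_threshold: float = 0.50   # posterior must be strictly greater
    min_taxa: int = 3
    branch_length_mode: str = "m0"
    compute_beb: bool = True
    fit: FitConfig = field(default_factory=FitConfig)


@dataclass
class SelectionTestResult:
    """Outcome of one gene x focal-branch branch-site test."""

    gene: str
    branch: str
    n_taxa: int
    length: int
    lnl_null: float
    lnl_alt: float
    lrt_stat: float
    p_value: float
    params: Mapping[str, float]
    pss: list[PSSRecord]
    d_med: float | None
    q_value: float | None = None
    raw_significant: bool = False
    aggregation_excluded: bool = False
    fdr_significant: bool = False
    delta_gc3: float | None = None

    @property
    def n_pss(self) -> int:
        return len(self.pss)


@dataclass
class ScanSummary:
    """Per-branch cascade counts (tested -> p<alpha -> filtered -> q<fdr)."""

    branch: str
    n_tested: int
    n_raw_significant: int
    n_kept_raw_significant: int
    n_fdr_significant: int

    def is_monotone(self) -> bool:
        return (
            self.n_tested
            >= self.n_raw_significant
            >= self.n_kept_raw_significant
            >= self.n_fdr_significant
        )


def select_pss(records: Sequence[PSSRecord], threshold: float = 0.50) -> list[PSSRecord]:
    """Positively selected sites: columns with posterior strictly above the threshold.

    "More than 0.50" is strict: a posterior of exactly 0.50 is not a PSS.
    """
    return [r for r in records if r.posterior > threshold]


def median_pss_interval(positions: Sequence[int]) -> float | None:
    """Median distance (codons) between consecutive PSS positions.

    Adjacent codons are one codon apart.  Fewer than two positions leave the
    statistic undefined (``None``).  Positions must be distinct.
    """
    pos = sorted(int(p) for p in positions)
    if len(pos) != len(set(pos)):
        raise ValueError("duplicate PSS positions")
    if len(pos) < 2:
        return None
    intervals = np.diff(pos)
    return float(np.median(intervals))


def aggregation_filter(
    results: Iterable[SelectionTestResult], cutoff: float = 10.0
) -> tuple[list[SelectionTestResult], list[SelectionTestResult]]:
    """Partition results into (kept, excluded) by the PSS clustering rule.

    A gene is excluded iff its median PSS interval is defined and <= cutoff
    (the boundary itself is excluded); genes with fewer than two PSSs cannot
    show clustering and are always kept.
    """
    kept, excluded = [], []
    for r in results:
        if r.d_med is not None and r.d_med <= cutoff:
            r.aggregation_excluded = True
            excluded.append(r)
        else:
            r.aggregation_excluded = False
            kept.append(r)
    return kept, excluded


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the ascending-sorted
    p-values, capped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def gc3_lrt_correlation(
    p_values: Sequence[float], delta_gc3_values: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between LRT p-values and per-gene deltaGC3.

    A strong correlation would indicate that apparent selection signal
    tracks third-position base-composition differences (a compositional
    artifact) rather than protein-level adaptation.
    """
    x = np.asarray(list(p_values), float)
    y = np.asarray(list(delta_gc3_values), float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# scan driver
# ---------------------------------------------------------------------------


def _test_gene_on_branch(
    aln: CodonAlignment,
    tagged_tree: PhyloTree,
    branch: str,
    clade_tips: Sequence[str],
    config: ScanConfig,
    log: list[dict],
) -> SelectionTestResult | None:
    shared = set(tagged_tree.tip_names) & set(aln.taxa)
    if len(shared) < config.min_taxa:
        log.append({"gene": aln.gene_id, "branch": branch, "event": "skip",
                    "reason": f"only {len(shared)} shared taxa"})
        return None
    try:
        pruned = prune_to_taxa(tagged_tree, shared)
    except ValueError as err:
        log.append({"gene": aln.gene_id, "branch": branch, "event": "skip",
                    "reason": str(err)})
        return None
    if not pruned.has_foreground:
        log.append({"gene": aln.gene_id, "branch": branch, "event": "skip",
                    "reason": "foreground branch lost in pruning"})
        return None

    sub = aln.subset_taxa(pruned.tip_names)
    pi = f3x4_frequencies(sub)
    null, alt = fit_gene(sub, pruned, pi, config.fit,
                         branch_length_mode=config.branch_length_mode)
    if not (alt.converged or null.converged):
        log.append({"gene": aln.gene_id, "branch": branch, "event": "skip",
                    "reason": "fit did not converge"})
        return None
    stat, p = lrt(null.lnl, alt.lnl)

    pss: list[PSSRecord] = []
    if config.compute_beb:
        engine = LikelihoodEngine(sub, alt.tree)
        records = beb_site_posteriors(sub, alt.tree, alt, pi, engine=engine,
                                      n_grid=config.fit.beb_grid)
        pss = select_pss(records, config.pss_threshold)
    d_med = median_pss_interval([r.position for r in pss])

    fg_tips = set(clade_tips) & set(pruned.tip_names)
    dgc3 = None
    if fg_tips and fg_tips < set(pruned.tip_names):
        dgc3 = delta_gc3(sub, sorted(fg_tips))

    log.append({"gene": aln.gene_id, "branch": branch, "event": "tested",
                "lnl0": null.lnl, "lnl1": alt.lnl, "p": p,
                "n_pss": len(pss)})
    return SelectionTestResult(
        gene=aln.gene_id,
        branch=branch,
        n_taxa=len(pruned.tip_names),
        length=sub.length,
        lnl_null=null.lnl,
        lnl_alt=alt.lnl,
        lrt_stat=stat,
        p_value=p,
        params={
            "kappa": alt.params.kappa,
            "omega0": alt.params.omega0,
            "omega2": alt.params.omega2,
            "p0": alt.params.p0,
            "p1": alt.params.p1,
        },
        pss=pss,
        d_med=d_med,
        delta_gc3=dgc3,
    )


def run_scan(
    genes: Sequence[CodonAlignment],
    tree: PhyloTree,
    clades: Mapping[str, Sequence[str]],
    config: ScanConfig = ScanConfig(),
) -> tuple[list[SelectionTestResult], list[ScanSummary], list[dict]]:
    """Run the branch-site scan over all genes and focal branches.

    ``clades`` maps branch names to tip lists; a single tip denotes a
    terminal branch.  Genes lacking the taxa that define a focal clade are
    skipped for that branch and logged, so different branches may have
    different tested-gene denominators.  Returns the per-gene results, the
    per-branch cascade summaries, and a structured log.
    """
    if not genes:
        raise ValueError("no genes supplied")
    if not clades:
        raise ValueError("no focal branches supplied")
    results: list[SelectionTestResult] = []
    summaries: list[ScanSummary] = []
    log: list[dict] = []

    for branch, clade_tips in clades.items():
        try:
            tagged = tag_foreground(tree, clade_tips)
        except (KeyError, ValueError) as err:
            raise ValueError(f"clade {branch!r} does not resolve on the tree: {err}")
        branch_results: list[SelectionTestResult] = []
        for aln in genes:
            res = _test_gene_on_branch(aln, tagged, branch, clade_tips, config, log)
            if res is not None:
                branch_results.append(res)

        for r in branch_results:
            r.raw_significant = r.p_value < config.alpha
        kept, _excluded = aggregation_filter(branch_results, config.agg_cutoff)
        if kept:
            qvals = bh_fdr([r.p_value for r in kept])
            for r, q in zip(kept, qvals):
                r.q_value = float(q)
                r.fdr_significant = (
                    r.raw_significant and q < config.fdr_q
                )
        summaries.append(ScanSummary(
            branch=branch,
            n_tested=len(branch_results),
            n_raw_significant=sum(r.raw_significant for r in branch_results),
            n_kept_raw_significant=sum(r.raw_significant for r in kept),
            n_fdr_significant=sum(r.fdr_significant for r in kept),
        ))
        results.extend(branch_results)

    for s in summaries:
        assert s.is_monotone(), f"cascade violated for branch {s.branch}"
    return results, summaries, log


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------


def results_table(results: Sequence[SelectionTestResult]) -> pd.DataFrame:
    """Flatten scan results to the per-gene TSV layout."""
    rows = []
    for r in results:
        rows.append({
            "gene": r.gene,
            "branch": r.branch,
            "n_taxa": r.n_taxa,
            "L": r.length,
            "lnL0": r.lnl_null,
            "lnL1": r.lnl_alt,
            "LRT": r.lrt_stat,
            "p": r.p_value,
            "q": r.q_value if r.q_value is not None else np.nan,
            "kappa": r.params["kappa"],
            "omega0": r.params["omega0"],
            "omega2": r.params["omega2"],
            "p0": r.params["p0"],
            "p1": r.params["p1"],
            "n_PSS": r.n_pss,
            "D_med": r.d_med if r.d_med is not None else np.nan,
            "raw_significant": r.raw_significant,
            "aggregation_excluded": r.aggregation_excluded,
            "fdr_significant": r.fdr_significant,
            "delta_GC3": r.delta_gc3 if r.delta_gc3 is not None else np.nan,
            "PSS": ";".join(f"{p.position}:{p.posterior:.3f}" for p in r.pss),
        })
    return pd.DataFrame(rows)


def summary_table(summaries: Sequence[ScanSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


def write_outputs(results, summaries, log, config: ScanConfig, out_dir) -> None:
    """Write results/summary TSVs, the run log and a config echo."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    results_table(results).to_csv(
        os.path.join(out_dir, "results.tsv"), sep="\t", index=False
    )
    summary_table(summaries).to_csv(
        os.path.join(out_dir, "summary.tsv"), sep="\t", index=False
    )
    with open(os.path.join(out_dir, "run_log.jsonl"), "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry) + "\n")
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(asdict(config), fh, indent=2)
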