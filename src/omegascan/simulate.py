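"""Synthetic data with known truth for every stage of the scan.

Codon alignments are evolved forward along a tree under the branch-site
generative model: each column draws a site class i.i.d. from
(p0, p1, p2a, p2b), the root codon is drawn from the equilibrium
frequencies, and states are propagated along each branch with the class- and
branch-appropriate omega.  Missing data is injected as whole-taxon dropout
or contiguous codon blocks, mimicking fragmentary transcriptome assemblies
rather than i.i.d. missingness.

A planted-partition generator produces protein-interaction edge lists with
STRING-style combined scores and per-cluster GO labels for the network and
enrichment stages.

All randomness flows from a single integer seed via
``numpy.random.default_rng``; identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .alignments import MISSING, CodonAlignment, GeneticCode, STANDARD_CODE
from .branchsite import BranchSiteParams
from .codonmodel import SpectralRates, substitution_rate
from .trees import PhyloTree, parse_newick

__all__ = [
    "DropoutSpec",
    "SimulationTruth",
    "default_study_tree",
    "default_pi",
    "default_params",
    "simulate_gene",
    "simulate_study",
    "make_network_fixture",
]

#: Six-taxon study tree with the branch above the (T1, T2) cherry flagged
#: foreground; lengths are expected substitutions per codon, in the range
#: typical of mammalian orthologue alignments.  The foreground branch is a
#: long internal branch (0.30), the regime in which an episodic burst of
#: selection leaves a detectable substitution excess.
DEFAULT_STUDY_NEWICK = (
    "((((T1:0.10,T2:0.10)#1:0.30,T3:0.18):0.06,T4:0.25):0.06,"
    "(T5:0.16,T6:0.16):0.12);"
)


def default_study_tree() -> PhyloTree:
    """The default 6-taxon simulation tree (foreground branch pre-flagged)."""
    return parse_newick(DEFAULT_STUDY_NEWICK)


def default_pi(code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    """Mildly non-uniform F3x4-style codon frequencies.

    Base composition differs by codon position, with a GC-richer third
    position, as commonly seen in mammalian coding sequence.
    """
    table = np.array([
        [0.22, 0.26, 0.28, 0.24],  # T C A G at position 1
        [0.26, 0.24, 0.28, 0.22],  # position 2
        [0.20, 0.30, 0.20, 0.30],  # position 3 (GC3 = 0.6)
    ])
    idx = code.codon_nucleotide_indices()
    pi = table[0, idx[:, 0]] * table[1, idx[:, 1]] * table[2, idx[:, 2]]
    return pi / pi.sum()


def default_params(omega2: float = 8.0) -> BranchSiteParams:
    """Default generating parameters: 20% of sites in the selected classes."""
    return BranchSiteParams(kappa=2.0, omega0=0.2, omega2=omega2, p0=0.5, p1=0.3)


@dataclass(frozen=True)
class DropoutSpec:
    """Missing-data injection rates.

    whole_taxon_rate:
        Per gene, per taxon probability that the taxon is entirely missing.
    block_rate:
        Per gene, per taxon probability of masking one contiguous codon block.
    block_fraction:
        Length of the masked block as a fraction of the alignment.
    """

    whole_taxon_rate: float = 0.0
    block_rate: float = 0.0
    block_fraction: float = 0.3


@dataclass
class SimulationTruth:
    """Ground truth of a simulated study."""

    seed: int
    tree_newick: str
    genes: pd.DataFrame  # gene, selected, kappa, omega0, omega2, p0, p1, L
    site_classes: dict[str, np.ndarray] = field(default_factory=dict)

    def classes_for(self, gene: str) -> np.ndarray:
        return self.site_classes[gene]


def _sample_markov_step(P: np.ndarray, parent_states: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw child states given parent states and a transition matrix."""
    probs = P[parent_states]                      # (n, 61)
    cdf = np.cumsum(probs, axis=1)
    cdf /= cdf[:, -1:]
    r = rng.random((len(parent_states), 1))
    return (cdf > r).argmax(axis=1)


def simulate_gene(
    tree: PhyloTree,
    params: BranchSiteParams,
    pi: np.ndarray,
    L: int,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    gene_id: str = "sim",
    site_classes: np.ndarray | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve one codon alignment under branch-site model A.

    Returns the alignment and the per-column true site class (0, 1, 2=2a,
    3=2b).  ``site_classes`` may be supplied explicitly, e.g. to plant a
    contiguous run of selected sites that exercises the aggregation filter.
    Branch lengths are interpreted with the same class-averaged scaling
    constant the likelihood uses, so fitted and generating parameters live
    on the same scale.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    fg_nodes = tree.foreground_nodes()
    if len(fg_nodes) != 1:
        raise ValueError("exactly one foreground branch must be flagged")
    if rng is None:
        rng = np.random.default_rng(seed)

    if site_classes is None:
        site_classes = rng.choice(4, size=L, p=params.proportions)
    else:
        site_classes = np.asarray(site_classes)
        if site_classes.shape != (L,):
            raise ValueError("site_classes must have length L")

    from .branchsite import LikelihoodEngine

    scale = LikelihoodEngine.mixture_scale(params, pi, code)
    omegas = params.class_omegas
    distinct = sorted({w for pair in omegas for w in pair})
    spectral = {w: SpectralRates(params.kappa, w, pi, code) for w in distinct}
    pi_eff = spectral[distinct[0]].pi

    cdf_root = np.cumsum(pi_eff)
    root_states = np.searchsorted(cdf_root, rng.random(L) * cdf_root[-1])

    states: dict[int, np.ndarray] = {}
    nodes = list(tree.preorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    states[index[id(tree.root)]] = root_states
    fg_id = id(fg_nodes[0])

    for node in nodes:
        if node.parent is None:
            continue
        parent_states = states[index[id(node.parent)]]
        child = np.empty(L, dtype=np.int64)
        t_eff = node.length / scale
        for c in range(4):
            cols = np.where(site_classes == c)[0]
            if cols.size == 0:
                continue
            w = omegas[c][1] if id(node) == fg_id else omegas[c][0]
            P = spectral[w].probabilities(t_eff)
            child[cols] = _sample_markov_step(P, parent_states[cols], rng)
        states[index[id(node)]] = child

    tip_names = tree.tip_names
    matrix = np.stack([
        states[index[id(tree.find_tip(name))]] for name in tip_names
    ])
    aln = CodonAlignment(gene_id, tip_names, matrix, code)
    return aln, site_classes


def _apply_dropout(aln: CodonAlignment, dropout: DropoutSpec,
                   rng: np.random.Generator) -> CodonAlignment:
    codons = aln.codons.copy()
    L = aln.length
    block = max(1, int(round(dropout.block_fraction * L)))
    for i in range(aln.n_taxa):
        if dropout.whole_taxon_rate and rng.random() < dropout.whole_taxon_rate:
            codons[i, :] = MISSING
            continue
        if dropout.block_rate and rng.random() < dropout.block_rate:
            start = int(rng.integers(0, max(1, L - block + 1)))
            codons[i, start:start + block] = MISSING
    return CodonAlignment(aln.gene_id, aln.taxa, codons, aln.code)


def simulate_study(
    n_genes: int,
    fraction_selected: float,
    tree: PhyloTree | None = None,
    *,
    L: int = 200,
    params: BranchSiteParams | None = None,
    selected_omega2: float = 8.0,
    dropout: DropoutSpec | None = None,
    pi: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[list[CodonAlignment], SimulationTruth]:
    """Simulate a gene set with a known fraction of selected genes.

    Selected genes are generated with ``omega2 = selected_omega2``; null
    genes with ``omega2 = 1`` (foreground behaves like the background).  The
    number of selected genes is exactly ``round(n_genes * fraction_selected)``,
    assigned to a seed-determined random subset.
    """
    if not 0.0 <= fraction_selected <= 1.0:
        raise ValueError("fraction_selected must lie in [0, 1]")
    tree = tree or default_study_tree()
    base = params or default_params()
    pi = default_pi() if pi is None else pi
    rng = np.random.default_rng(seed)

    n_selected = int(round(n_genes * fraction_selected))
    selected_flags = np.zeros(n_genes, dtype=bool)
    selected_flags[rng.permutation(n_genes)[:n_selected]] = True

    genes: list[CodonAlignment] = []
    rows = []
    truth = SimulationTruth(seed=seed, tree_newick=tree.newick(),
                            genes=pd.DataFrame())
    for g in range(n_genes):
        gene_id = f"gene{g + 1:04d}"
        p = replace(base, omega2=selected_omega2 if selected_flags[g] else 1.0)
        aln, classes = simulate_gene(tree, p, pi, L, rng=rng, gene_id=gene_id)
        if dropout is not None:
            aln = _apply_dropout(aln, dropout, rng)
        genes.append(aln)
        truth.site_classes[gene_id] = classes
        rows.append({
            "gene": gene_id, "selected": bool(selected_flags[g]),
            "kappa": p.kappa, "omega0": p.omega0, "omega2": p.omega2,
            "p0": p.p0, "p1": p.p1, "L": L,
        })
    truth.genes = pd.DataFrame(rows)
    return genes, truth


def make_network_fixture(
    n_proteins: int,
    n_clusters: int,
    within_edge_prob: float,
    between_edge_prob: float,
    go_terms_per_cluster: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, set[str]], dict]:
    """Planted-partition interaction network with per-cluster GO labels.

    Returns ``(edges, annotations, truth)``: an edge table in the STRING
    protein-links dialect (protein1, protein2, combined_score), a gene ->
    GO-term-set annotation map, and the planted truth (cluster membership
    and the GO term(s) planted in each cluster).  Within-cluster edges carry
    higher combined scores than between-cluster edges.
    """
    if not within_edge_prob > between_edge_prob:
        raise ValueError("within_edge_prob must exceed between_edge_prob")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    cluster_of = {p: i % n_clusters for i, p in enumerate(proteins)}

    rows = []
    for i in range(n_proteins):
        for j in range(i + 1, n_proteins):
            same = cluster_of[proteins[i]] == cluster_of[proteins[j]]
            prob = within_edge_prob if same else between_edge_prob
            if rng.random() < prob:
                score = int(rng.integers(700, 1000) if same
                            else rng.integers(150, 500))
                rows.append((proteins[i], proteins[j], score))
    edges = pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])

    annotations: dict[str, set[str]] = {p: set() for p in proteins}
    cluster_terms: dict[int, list[str]] = {}
    for c in range(n_clusters):
        terms = [f"GO:C{c:02d}T{t:02d}" for t in range(go_terms_per_cluster)]
        cluster_terms[c] = terms
        for p in proteins:
            if cluster_of[p] == c:
                annotations[p].update(terms)
    # a couple of diffuse background terms so enrichment has competition
    for t in range(2):
        term = f"GO:BG{t:02d}"
        for p in proteins:
            if rng.random() < 0.3:
                annotations[p].add(term)

    truth = {"cluster_of": cluster_of, "cluster_terms": cluster_terms}
    return edges, annotations, truth
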