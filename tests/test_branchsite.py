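import numpy as np
import pytest

from omegascan.alignments import MISSING, STANDARD_CODE, CodonAlignment
from omegascan.branchsite import (
    BranchSiteParams,
    FitConfig,
    LikelihoodEngine,
    beb_class_posteriors,
    beb_site_posteriors,
    fit_alternative,
    fit_gene,
    fit_null,
    gene_log_likelihood,
    lrt,
)
from omegascan.codonmodel import SpectralRates, f3x4_frequencies
from omegascan.simulate import default_params, default_pi, default_study_tree, simulate_gene
from omegascan.trees import parse_newick, prune_to_taxa

from .oracles import brute_force_mixture_loglik

PARAMS = BranchSiteParams(kappa=2.0, omega0=0.3, omega2=4.0, p0=0.5, p1=0.3)


def random_instance(rng, n_taxa, L=4, missing=0.15):
    """Random tree (with #1 on a random edge), params, pi, alignment."""
    if n_taxa == 3:
        nwk = "((A:{:.3f},B:{:.3f})#1:{:.3f},C:{:.3f});"
    else:
        nwk = "((A:{:.3f},B:{:.3f})#1:{:.3f},(C:{:.3f},D:{:.3f}):{:.3f});"
    n_lens = nwk.count("{")
    tree = parse_newick(nwk.format(*rng.uniform(0.05, 0.6, size=n_lens)))
    params = BranchSiteParams(
        kappa=rng.uniform(1.0, 5.0),
        omega0=rng.uniform(0.05, 0.8),
        omega2=rng.uniform(1.0, 9.0),
        p0=0.45, p1=0.35,
    )
    pi = rng.dirichlet(np.full(61, 5.0))
    pi = np.maximum(pi, 1e-4)
    pi /= pi.sum()
    m = rng.integers(0, 61, size=(n_taxa, L))
    m[rng.random(m.shape) < missing] = MISSING
    taxa = tuple("ABCD"[:n_taxa])
    return tree, params, pi, CodonAlignment("g", taxa, m)


class TestParams:
    def test_proportions_sum_to_one(self):
        assert PARAMS.proportions.sum() == pytest.approx(1.0, abs=1e-12)
        assert (PARAMS.proportions >= 0).all()

    def test_class_omega_assignments(self):
        assert PARAMS.class_omegas == [(0.3, 0.3), (1.0, 1.0), (0.3, 4.0), (1.0, 4.0)]

    @pytest.mark.parametrize(
        "kw",
        [
            dict(kappa=-1),
            dict(omega0=0.0),
            dict(omega0=1.0),
            dict(omega2=0.9),
            dict(p0=0.8, p1=0.3),
        ],
    )
    def test_invalid_parameters_raise(self, kw):
        base = dict(kappa=2.0, omega0=0.3, omega2=2.0, p0=0.5, p1=0.3)
        base.update(kw)
        with pytest.raises(ValueError):
            BranchSiteParams(**base)


class TestLikelihood:
    def test_zero_lengths_identical_sequences_give_log_pi(self):
        tree = parse_newick("((A:0,B:0)#1:0,C:0);")
        states = [5, 17, 42]
        m = np.tile(states, (3, 1))
        aln = CodonAlignment("g", ("A", "B", "C"), m)
        pi = np.full(61, 1 / 61)
        lnl = gene_log_likelihood(aln, tree, PARAMS, pi)
        assert lnl == pytest.approx(3 * np.log(1 / 61), rel=1e-10)

    def test_zero_lengths_conflicting_column_is_impossible(self):
        tree = parse_newick("((A:0,B:0)#1:0,C:0);")
        m = np.array([[5], [6], [5]])
        aln = CodonAlignment("g", ("A", "B", "C"), m)
        pi = np.full(61, 1 / 61)
        assert gene_log_likelihood(aln, tree, PARAMS, pi) == -np.inf

    @pytest.mark.parametrize("n_taxa", [3, 4])
    def test_pruning_matches_exhaustive_enumeration(self, rng, n_taxa):
        for _ in range(4):
            tree, params, pi, aln = random_instance(rng, n_taxa)
            got = gene_log_likelihood(aln, tree, params, pi)
            want = brute_force_mixture_loglik(aln, tree, params, pi)
            assert got == pytest.approx(want, rel=1e-10)

    def test_invariant_to_column_order(self, rng):
        tree, params, pi, aln = random_instance(rng, 4, L=30)
        perm = rng.permutation(30)
        shuffled = CodonAlignment("g", aln.taxa, aln.codons[:, perm])
        assert gene_log_likelihood(aln, tree, params, pi) == pytest.approx(
            gene_log_likelihood(shuffled, tree, params, pi), rel=1e-12
        )

    def test_invariant_to_taxon_storage_order(self, rng):
        tree, params, pi, aln = random_instance(rng, 4, L=20)
        order = [3, 0, 2, 1]
        reordered = CodonAlignment(
            "g", tuple(aln.taxa[i] for i in order), aln.codons[order]
        )
        assert gene_log_likelihood(aln, tree, params, pi) == pytest.approx(
            gene_log_likelihood(reordered, tree, params, pi), rel=1e-12
        )

    def test_fully_missing_taxon_equals_pruned_tree(self, rng):
        nwk = "(((A:0.1,B:0.2)#1:0.1,C:0.3):0.1,(D:0.2,E:0.25):0.15);"
        tree = parse_newick(nwk)
        m = rng.integers(0, 61, size=(5, 25))
        taxa = ("A", "B", "C", "D", "E")
        aln_full = CodonAlignment("g", taxa, m.copy())
        m_missing = m.copy()
        m_missing[4, :] = MISSING  # E entirely missing
        aln_missing = CodonAlignment("g", taxa, m_missing)
        pi = np.full(61, 1 / 61)
        pruned = prune_to_taxa(tree, {"A", "B", "C", "D"})
        lnl_missing = gene_log_likelihood(aln_missing, tree, PARAMS, pi)
        lnl_pruned = gene_log_likelihood(aln_full, pruned, PARAMS, pi)
        assert lnl_missing == pytest.approx(lnl_pruned, rel=1e-10)

    def test_no_foreground_flag_raises(self, rng):
        tree = parse_newick("((A:0.1,B:0.1):0.1,C:0.2);")
        m = rng.integers(0, 61, size=(3, 10))
        aln = CodonAlignment("g", ("A", "B", "C"), m)
        with pytest.raises(ValueError, match="foreground"):
            gene_log_likelihood(aln, tree, PARAMS, np.full(61, 1 / 61))


class TestLRT:
    def test_equal_likelihoods_give_zero_and_p_one(self):
        assert lrt(-100.0, -100.0) == (0.0, 1.0)

    def test_chi2_quantile(self):
        stat, p = lrt(-100.0, -100.0 + 3.841459 / 2)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_optimizer_noise_clamped_to_zero(self):
        stat, p = lrt(-100.0, -100.0 - 1e-8)
        assert stat == 0.0 and p == 1.0

    def test_non_finite_input_raises(self):
        with pytest.raises(ValueError):
            lrt(-np.inf, -100.0)


class TestFitting:
    def test_nesting_alt_at_least_null(self):
        tree = default_study_tree()
        pi0 = default_pi()
        cfg = FitConfig(n_starts=2, maxiter=80)
        for seed, w2 in [(11, 1.0), (12, 6.0), (13, 1.0)]:
            aln, _ = simulate_gene(tree, default_params(omega2=w2), pi0, 80,
                                   seed=seed)
            pi = f3x4_frequencies(aln)
            null, alt = fit_gene(aln, tree, pi, cfg)
            assert alt.lnl >= null.lnl - 1e-6
            assert null.params.omega2 == 1.0

    def test_fits_are_deterministic_given_seed(self):
        tree = default_study_tree()
        pi0 = default_pi()
        aln, _ = simulate_gene(tree, default_params(omega2=1.0), pi0, 60, seed=5)
        pi = f3x4_frequencies(aln)
        cfg = FitConfig(n_starts=2, maxiter=60, seed=7)
        a1 = fit_alternative(aln, tree, pi, cfg)
        a2 = fit_alternative(aln, tree, pi, cfg)
        assert a1.lnl == a2.lnl and a1.params == a2.params


@pytest.fixture(scope="module")
def fitted_gene():
    tree = default_study_tree()
    pi0 = default_pi()
    aln, classes = simulate_gene(tree, default_params(omega2=8.0), pi0, 150,
                                 seed=42)
    pi = f3x4_frequencies(aln)
    null, alt = fit_gene(aln, tree, pi, FitConfig(n_starts=2, maxiter=100))
    return aln, classes, alt, pi


class TestBEB:

    def test_class_posteriors_normalised_per_column(self, fitted_gene):
        aln, _, alt, pi = fitted_gene
        post = beb_class_posteriors(aln, alt.tree, alt, pi)
        assert post.shape == (4, aln.length)
        np.testing.assert_allclose(post.sum(axis=0), 1.0, atol=1e-9)

    def test_true_selected_sites_score_higher_than_background(self, fitted_gene):
        aln, classes, alt, pi = fitted_gene
        records = beb_site_posteriors(aln, alt.tree, alt, pi)
        post = np.array([r.posterior for r in records])
        assert post[classes >= 2].mean() > post[classes == 0].mean()

    def test_positions_are_one_based(self, fitted_gene):
        aln, _, alt, pi = fitted_gene
        records = beb_site_posteriors(aln, alt.tree, alt, pi)
        assert records[0].position == 1
        assert records[-1].position == aln.length

    def test_null_fit_rejected(self, fitted_gene):
        aln, _, alt, pi = fitted_gene
        null = fit_null(aln, alt.tree, pi, FitConfig(n_starts=1, maxiter=40))
        with pytest.raises(ValueError, match="alternative"):
            beb_site_posteriors(aln, alt.tree, null, pi)
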