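"""GY94 engine: rate matrices, likelihoods, fits, LRTs, posteriors, NG86.

The likelihood oracles here are deliberately independent of the pruning
path: explicit sums over the 61 root states with scipy's expm, grid searches,
and hand evaluations of the GY94 rate rule.
"""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.linalg import expm

from yeastevol import codonmodel as cm
from yeastevol.codonmodel import (
    CodonAlignment,
    GY94Params,
    build_rate_matrix,
    empirical_codon_frequencies,
    fit_branch_models,
    fit_model,
    log_likelihood,
    lrt,
    lrt_threshold,
    pairwise_dnds_ng86,
    rate_matrix_unscaled,
    site_posteriors,
    transition_probabilities,
)
from yeastevol.genetic_code import CODON_INDEX, SENSE_CODONS
from yeastevol.simulate import SimulationConfig, simulate_codon_alignment
from yeastevol.trees import BranchClassTree

UNIFORM = np.full(61, 1.0 / 61)


def random_pi(seed):
    rng = np.random.default_rng(seed)
    pi = rng.dirichlet(np.ones(61))
    return pi / pi.sum()


class TestRateMatrix:
    @given(st.integers(0, 10_000))
    def test_rows_sum_to_zero_and_detailed_balance(self, seed):
        rng = np.random.default_rng(seed)
        pi = random_pi(seed)
        kappa = float(rng.uniform(0.5, 10))
        omega = float(rng.uniform(0.0, 3))
        Q = build_rate_matrix(pi, kappa, omega)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12
        # reversibility: pi_i q_ij = pi_j q_ji
        flux = pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-12
        # normalisation: expected rate 1
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0, abs=1e-10)

    def test_hand_evaluated_entries(self):
        """TTT→CTT is a nonsynonymous transition (F→L), TTT→TTC a synonymous
        transition (F→F); both single-position changes under the GY94 rule."""
        pi = random_pi(7)
        kappa, omega = 3.0, 0.5
        Q = rate_matrix_unscaled(pi, kappa, omega)
        i = CODON_INDEX["TTT"]
        assert Q[i, CODON_INDEX["CTT"]] == pytest.approx(
            pi[CODON_INDEX["CTT"]] * kappa * omega
        )
        assert Q[i, CODON_INDEX["TTC"]] == pytest.approx(
            pi[CODON_INDEX["TTC"]] * kappa
        )
        # multi-position change and change-to-stop are forbidden
        assert Q[i, CODON_INDEX["CCT"]] == 0.0
        assert "TGA" not in CODON_INDEX  # stop codons outside state space

    @pytest.mark.parametrize("kappa,omega", [(0.0, 0.5), (2.0, -0.1)])
    def test_invalid_params_rejected(self, kappa, omega):
        with pytest.raises(ValueError):
            build_rate_matrix(UNIFORM, kappa, omega)


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self):
        Q = build_rate_matrix(UNIFORM, 2.0, 0.5)
        assert np.allclose(transition_probabilities(Q, 0.0), np.eye(61))

    def test_long_time_reaches_stationarity(self):
        pi = random_pi(3)
        Q = build_rate_matrix(pi, 2.0, 0.5)
        P = transition_probabilities(Q, 500.0)
        assert np.abs(P - pi[None, :]).max() < 1e-6

    def test_short_time_series_expansion(self):
        Q = build_rate_matrix(UNIFORM, 2.0, 0.5)
        t = 1e-4
        P = transition_probabilities(Q, t)
        assert np.abs(P - (np.eye(61) + Q * t)).max() < 5 * t**2

    def test_stationarity_preserved(self):
        pi = random_pi(11)
        Q = build_rate_matrix(pi, 1.5, 0.8)
        P = transition_probabilities(Q, 0.7)
        assert np.abs(pi @ P - pi).max() < 1e-8

    def test_negative_time_rejected(self):
        Q = build_rate_matrix(UNIFORM, 2.0, 0.5)
        with pytest.raises(ValueError):
            transition_probabilities(Q, -0.1)


def two_taxon_oracle(codon_a, codon_b, pi, kappa, omega, t1, t2):
    """Brute-force likelihood of one site on a two-leaf tree: sum over the
    61 root states with expm transition matrices."""
    Q = build_rate_matrix(pi, kappa, omega)
    P1, P2 = expm(Q * t1), expm(Q * t2)
    a, b = CODON_INDEX[codon_a], CODON_INDEX[codon_b]
    return float(np.log((pi * P1[:, a] * P2[:, b]).sum()))


class TestLogLikelihood:
    def test_two_taxon_single_site_matches_enumeration(self):
        tree = BranchClassTree.from_newick("(A:0.13,B:0.27);")
        pi = random_pi(5)
        params = GY94Params(2.5, pi, omega_by_class={0: 0.6})
        for ca, cb in [("TTT", "TTT"), ("TTT", "TTC"), ("ATG", "CAA")]:
            aln = CodonAlignment(["A", "B"], [ca, cb])
            got = log_likelihood(aln, tree, params, "M0")
            assert got == pytest.approx(
                two_taxon_oracle(ca, cb, pi, 2.5, 0.6, 0.13, 0.27), abs=1e-8
            )

    def test_duplicating_sites_doubles_loglik(self, seven_taxon_tree):
        cfg = SimulationConfig(codon_length=30, seed=2)
        aln, _ = simulate_codon_alignment(seven_taxon_tree, cfg)
        params = GY94Params(2.0, UNIFORM, omega_by_class={0: 0.3, 1: 0.3})
        base = log_likelihood(aln, seven_taxon_tree, params, "branch")
        doubled = CodonAlignment(aln.taxa, [s + s for s in aln.seqs])
        assert log_likelihood(doubled, seven_taxon_tree, params, "branch") == (
            pytest.approx(2 * base, abs=1e-6)
        )

    def test_reroot_invariance(self):
        """Pulley principle: the reversible likelihood does not depend on the
        root position."""
        tree = BranchClassTree.from_newick(
            "((A:0.1,B:0.2)ab:0.15,(C:0.3,D:0.05)cd:0.08);"
        )
        cfg = SimulationConfig(codon_length=40, seed=9, omega_by_class={0: 0.4})
        aln, _ = simulate_codon_alignment(tree, cfg)
        pi = random_pi(1)
        params = GY94Params(1.8, pi, omega_by_class={0: 0.4})
        ref = log_likelihood(aln, tree, params, "M0")
        for target in ("ab", "cd", "A", "D"):
            re = tree.rerooted_at(target)
            assert log_likelihood(aln, re, params, "M0") == pytest.approx(ref, abs=1e-6)

    def test_taxon_order_invariance(self, seven_taxon_tree):
        cfg = SimulationConfig(codon_length=25, seed=4)
        aln, _ = simulate_codon_alignment(seven_taxon_tree, cfg)
        params = GY94Params(2.0, UNIFORM, omega_by_class={0: 0.3, 1: 0.3})
        shuffled = CodonAlignment(aln.taxa[::-1], aln.seqs[::-1])
        assert log_likelihood(shuffled, seven_taxon_tree, params, "branch") == (
            pytest.approx(log_likelihood(aln, seven_taxon_tree, params, "branch"))
        )

    def test_leaf_mismatch_reported(self, seven_taxon_tree):
        aln = CodonAlignment(["X", "Y"], ["TTT", "TTC"])
        with pytest.raises(ValueError, match="offenders"):
            log_likelihood(
                aln, seven_taxon_tree,
                GY94Params(2.0, UNIFORM, omega_by_class={0: 0.3}), "M0",
            )

    def test_gaps_treated_as_missing(self):
        tree = BranchClassTree.from_newick("(A:0.1,B:0.2);")
        pi = random_pi(5)
        params = GY94Params(2.5, pi, omega_by_class={0: 0.6})
        aln = CodonAlignment(["A", "B"], ["TTT", "---"])
        # with B missing, the site likelihood is sum_r pi_r P(r->TTT, t1+?)...
        Q = build_rate_matrix(pi, 2.5, 0.6)
        P1 = expm(Q * 0.1)
        expect = math.log((pi * P1[:, CODON_INDEX["TTT"]]).sum())
        assert log_likelihood(aln, tree, params, "M0") == pytest.approx(expect, abs=1e-8)


class TestFitModel:
    def test_two_taxon_ml_matches_grid_search(self):
        """Tiny instance: the optimiser's (κ, ω, t) maximum agrees with an
        exhaustive grid over the likelihood surface."""
        tree = BranchClassTree.from_newick("(A:0.2,B:0.2);")
        cfg = SimulationConfig(codon_length=30, seed=12, kappa=2.0,
                               omega_by_class={0: 0.5})
        aln, _ = simulate_codon_alignment(tree, cfg)
        pi = empirical_codon_frequencies(aln)
        fit = fit_model(aln, tree, "M0", pi=pi, n_starts=2, seed=0,
                        optimize_branch_lengths=True)
        best = (-np.inf, None)
        for kappa in np.linspace(0.5, 6, 12):
            for omega in np.linspace(0.05, 2.0, 14):
                for t in np.linspace(0.02, 1.2, 14):
                    g = tree.copy()
                    g.set_branch_lengths([t / 2, t / 2])
                    lnl = log_likelihood(
                        aln, g, GY94Params(kappa, pi, omega_by_class={0: omega}), "M0"
                    )
                    if lnl > best[0]:
                        best = (lnl, omega)
        assert fit.lnL >= best[0] - 1e-6
        # ML omega within one grid step of the grid argmax
        assert abs(fit.params.omega_by_class[0] - best[1]) <= 0.15 + 1e-9

    def test_m0_recovery(self, seven_taxon_tree):
        omegas = []
        for seed in range(3):
            cfg = SimulationConfig(codon_length=300, omega_by_class={0: 0.3, 1: 0.3},
                                   seed=seed)
            aln, _ = simulate_codon_alignment(seven_taxon_tree, cfg)
            fit = fit_model(aln, seven_taxon_tree, "M0", n_starts=1, seed=seed)
            omegas.append(fit.params.omega_by_class[0])
        assert 0.2 <= float(np.median(omegas)) <= 0.4

    def test_nesting_chain(self, seven_taxon_tree):
        """lnL(free) >= lnL(two-ratio) >= lnL(M0) with shared branch lengths."""
        cfg = SimulationConfig(codon_length=120, omega_by_class={0: 0.2, 1: 1.0},
                               seed=6)
        aln, _ = simulate_codon_alignment(seven_taxon_tree, cfg)
        fits = fit_branch_models(
            aln, seven_taxon_tree, models=("branch", "free"), n_starts=1, seed=0
        )
        assert fits["branch"].lnL >= fits["M0"].lnL - 1e-6
        assert fits["free"].lnL >= fits["branch"].lnL - 1e-6

    def test_branch_site_alt_nests_null(self, seven_taxon_tree):
        cfg = SimulationConfig(codon_length=80, omega_by_class={0: 0.3, 1: 0.3},
                               seed=8)
        aln, _ = simulate_codon_alignment(seven_taxon_tree, cfg)
        fits = fit_branch_models(
            aln, seven_taxon_tree,
            models=("branch-site-null", "branch-site-alt"), n_starts=1, seed=0,
        )
        assert fits["branch-site-alt"].lnL >= fits["branch-site-null"].lnL - 1e-6

    def test_too_few_taxa_rejected(self):
        aln = CodonAlignment(["A", "B"], ["TTT", "TTC"])
        tree = BranchClassTree.from_newick("(A:0.1,B:0.1);")
        with pytest.raises(ValueError, match="taxa"):
            fit_model(aln, tree, "branch")


class TestLRT:
    def test_equal_likelihoods(self, seven_taxon_tree):
        f = cm.ModelFit("M0", -100.0, GY94Params(2.0, UNIFORM), seven_taxon_tree)
        g = cm.ModelFit("branch", -100.0, GY94Params(2.0, UNIFORM), seven_taxon_tree)
        res = lrt(g, f, df=1)
        assert res.stat == 0.0
        assert res.p == pytest.approx(1.0)
        assert not res.significant

    def test_chi2_threshold_two_decimals(self):
        assert round(lrt_threshold(1), 2) == 3.84

    def test_significance_boundary(self, seven_taxon_tree):
        null = cm.ModelFit("M0", -100.0, GY94Params(2.0, UNIFORM), seven_taxon_tree)
        alt = cm.ModelFit(
            "branch", -100.0 + 3.85 / 2, GY94Params(2.0, UNIFORM), seven_taxon_tree
        )
        assert lrt(alt, null, df=1).significant

    def test_swapped_arguments_detected(self, seven_taxon_tree):
        null = cm.ModelFit("M0", -100.0, GY94Params(2.0, UNIFORM), seven_taxon_tree)
        alt = cm.ModelFit("branch", -90.0, GY94Params(2.0, UNIFORM), seven_taxon_tree)
        with pytest.raises(ValueError, match="swapped"):
            lrt(null, alt, df=1)


class TestSitePosteriors:
    @staticmethod
    def _star_tree():
        return BranchClassTree.from_newick("(A:0.2,B:0.2,C:0.2 #1);")

    def _fit(self, params, tree):
        return cm.ModelFit("branch-site-alt", 0.0, params, tree)

    def test_zero_prior_mass_gives_zero_posterior(self):
        tree = self._star_tree()
        aln = CodonAlignment(["A", "B", "C"], ["TTT", "TTC", "CTT"])
        params = GY94Params(2.0, UNIFORM, omega0=0.2, omega2=4.0, p0=0.6, p1=0.4)
        assert params.p2a == pytest.approx(0.0)
        post = site_posteriors(self._fit(params, tree), aln, tree)
        assert all(p.posterior == pytest.approx(0.0, abs=1e-12) for p in post)

    def test_single_site_matches_four_term_oracle(self):
        """Posterior equals the explicit normalisation of the four class
        likelihoods computed with expm on a star tree, including the
        mixture-rate branch scaling."""
        tree = self._star_tree()
        aln = CodonAlignment(["A", "B", "C"], ["TTT", "TTC", "CTT"])
        pi = UNIFORM
        params = GY94Params(2.0, pi, omega0=0.2, omega2=4.0, p0=0.5, p1=0.3)
        props = [params.p0, params.p1, params.p2a, params.p2b]
        class_w = {  # site class -> omega on (background, foreground)
            0: (0.2, 0.2), 1: (1.0, 1.0), 2: (0.2, 4.0), 3: (1.0, 4.0),
        }
        rate = {
            w: cm.expected_rate(pi, rate_matrix_unscaled(pi, 2.0, w))
            for w in (0.2, 1.0, 4.0)
        }
        mix = {
            bc: sum(p * rate[class_w[c][bc]] for c, p in enumerate(props))
            for bc in (0, 1)
        }
        obs = {b.name: CODON_INDEX[c] for b, c in
               zip(tree.branches(), ["TTT", "TTC", "CTT"])}
        liks = []
        for c, p in enumerate(props):
            site_l = np.ones(61) * pi
            for b in tree.branches():
                w = class_w[c][b.branch_class]
                Q = rate_matrix_unscaled(pi, 2.0, w)
                P = expm(Q * b.length / mix[b.branch_class])
                site_l = site_l * P[:, obs[b.name]]
            liks.append(p * site_l.sum())
        expected = (liks[2] + liks[3]) / sum(liks)
        post = site_posteriors(self._fit(params, tree), aln, tree)
        assert post[0].posterior == pytest.approx(expected, abs=1e-10)

    def test_requires_branch_site_fit(self, seven_taxon_tree):
        fit = cm.ModelFit(
            "branch", -1.0, GY94Params(2.0, UNIFORM, omega_by_class={0: 0.2, 1: 1.0}),
            seven_taxon_tree,
        )
        aln = CodonAlignment(["A"], ["TTT"])
        with pytest.raises(ValueError, match="branch-site"):
            site_posteriors(fit, aln)

    def test_flags_enriched_for_true_selected_sites(self, seven_taxon_tree):
        """~10%% of sites carry foreground ω2 = 5 (classes 2a/2b); sites
        flagged at posterior > 0.95 should be mostly true positives."""
        from yeastevol.simulate import simulate_branch_site_alignment

        n_true_flags = n_flags = 0
        for seed in range(5):
            aln, classes, _ = simulate_branch_site_alignment(
                seven_taxon_tree, 200, omega2=5.0, p0=0.63, p1=0.27, seed=seed
            )
            fits = fit_branch_models(
                aln, seven_taxon_tree,
                models=("branch-site-null", "branch-site-alt"), n_starts=1, seed=seed,
            )
            post = site_posteriors(fits["branch-site-alt"], aln,
                                   fits["branch-site-alt"].tree)
            true = set(np.where(classes >= 2)[0])
            for p in post:
                if p.flagged:
                    n_flags += 1
                    n_true_flags += p.site in true
        assert n_flags > 0, "no sites flagged in any replicate"
        assert n_true_flags / n_flags > 0.5


class TestNG86:
    def test_identical_sequences(self):
        res = pairwise_dnds_ng86("TTTGGA", "TTTGGA")
        assert res.dN == 0.0 and res.dS == 0.0
        assert res.ratio is None

    def test_single_synonymous_change(self):
        res = pairwise_dnds_ng86("TTT", "TTC")
        assert res.dN == 0.0
        assert res.dS > 0.0

    def test_single_nonsynonymous_change(self):
        # GGA (Gly) vs AGA (Arg): one nonsynonymous difference
        res = pairwise_dnds_ng86("GGA", "AGA")
        assert res.dS == 0.0
        assert res.dN > 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            pairwise_dnds_ng86("TTT", "TTTTTT")

    def test_agrees_with_biopython_on_moderate_divergence(self, seven_taxon_tree):
        from Bio.Align import MultipleSeqAlignment, SeqRecord
        from Bio.Seq import Seq
        from Bio.codonalign.codonalignment import CodonAlignment as BioCodonAln
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        cfg = SimulationConfig(codon_length=200, omega_by_class={0: 0.5, 1: 0.5},
                               seed=17)
        aln, _ = simulate_codon_alignment(seven_taxon_tree, cfg)
        a = aln.seqs[0]
        b = aln.seqs[1]
        mine = pairwise_dnds_ng86(a, b)
        dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
        assert mine.dN == pytest.approx(dn, abs=0.02)
        assert mine.dS == pytest.approx(ds, abs=0.05)
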