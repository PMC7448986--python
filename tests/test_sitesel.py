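"""Codon alignment, M7/M8 fits, LRT, and NEB/BEB site posteriors."""

import numpy as np
import pytest
from scipy.stats import chi2

from chemoscan.codonmodel import (
    CodonSimSpec,
    N_CODONS,
    rate_matrix,
    simulate_codon_pair,
    transition_matrix,
)
from chemoscan.sitesel import (
    alignment_from_pair,
    analyze_pair,
    beb_sites,
    call_selection,
    codon_align,
    fit_pair,
    fit_site_model,
    lrt,
    neb_sites,
    SiteModelFit,
)

from _oracles import codon_loglik_bruteforce


class TestMatrixValidity:
    @pytest.mark.parametrize("kappa,omega", [(1.0, 1.0), (2.0, 0.3), (5.0, 3.0)])
    def test_rows_sum_to_zero_and_pt_stochastic(self, kappa, omega):
        Q = rate_matrix(kappa, omega)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12
        P = transition_matrix(Q, 0.7)
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-10
        assert P.min() >= 0

    def test_detailed_balance_under_uniform_frequencies(self):
        Q = rate_matrix(2.0, 0.5)
        pi = np.full(N_CODONS, 1 / N_CODONS)
        flux = pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-14


class TestCodonAlign:
    def test_gapless_identical_pair_verbatim(self):
        cds = "ATGAAAGTTCTG"
        aln = codon_align(("MKVL", "MKVL"), cds, cds)
        assert "".join(aln.codons_a) == cds == "".join(aln.codons_b)

    def test_protein_gap_expands_to_codon_gap(self):
        cds_a = "ATGAAAGTTCTGGGG"
        cds_b = "ATGAAACTGGGG"
        aln = codon_align(("MKVLG", "MK-LG"), cds_a, cds_b)
        assert aln.codons_b[2] == "---"
        assert "".join(c for c in aln.codons_b if c != "---") == cds_b

    def test_mismatched_cds_reports_position(self):
        with pytest.raises(ValueError, match="residue 2"):
            codon_align(("MKVL", "MKVL"), "ATGCGTGTTCTG", "ATGAAAGTTCTG")

    def test_stop_columns_removed_with_warning(self):
        cds_a = "ATGTAAGTT"  # internal stop
        with pytest.warns(UserWarning, match="stop"):
            aln = codon_align(("MXV", "MKV"), cds_a, "ATGAAAGTT")
        assert aln.n_codons == 2


class TestFitting:
    def test_identical_sequences_hit_lower_bound(self):
        (a, _), _ = simulate_codon_pair(CodonSimSpec(n_codons=80, t=0.0, rng_seed=1))
        aln = alignment_from_pair(a, a)
        fit = fit_site_model(aln, "M7", n_restarts=1)
        assert fit.t <= 1.01e-4
        assert fit.lnL == pytest.approx(80 * np.log(1 / 61), abs=0.05)

    def test_m8_never_below_m7(self):
        for seed in (1, 2, 3):
            (a, b), _ = simulate_codon_pair(
                CodonSimSpec(model="M7", n_codons=150, t=0.4, rng_seed=seed)
            )
            aln = alignment_from_pair(a, b)
            m7, m8 = fit_pair(aln, n_restarts=1, seed=seed)
            assert m8.lnL >= m7.lnL - 1e-4

    def test_loglik_matches_bruteforce_oracle_on_two_codons(self):
        """Direct category-and-state summation agrees to high precision."""
        from chemoscan.sitesel import _loglik

        aln = alignment_from_pair("ATGAAA", "ATGACG")
        counts = aln.pair_count_matrix()
        for model, theta in (
            ("M7", np.array([0.6, 2.0, 0.7, 1.3])),
            ("M8", np.array([0.6, 2.0, 0.7, 1.3, 0.8, 2.5])),
        ):
            mine = _loglik(counts, model, theta)
            oracle = codon_loglik_bruteforce(aln, model, *theta)
            assert mine == pytest.approx(oracle, abs=1e-8)

    def test_parameter_recovery_under_m8(self):
        (a, b), _ = simulate_codon_pair(
            CodonSimSpec(model="M8", n_codons=500, t=0.5, kappa=2.0, p0=0.5,
                         omega_s=2.0, rng_seed=3)
        )
        aln = alignment_from_pair(a, b)
        _, m8 = fit_pair(aln, n_restarts=2, seed=0)
        assert 1.2 <= m8.omega_s <= 4.0
        assert 0.2 <= m8.p0 <= 0.9


class TestLrt:
    def _fit(self, lnL, key=1):
        return SiteModelFit(model="M7", lnL=lnL, t=0.5, kappa=2, beta_p=1, beta_q=1,
                            aln_key=key)

    def test_equal_likelihoods_give_p_one(self):
        d, p = lrt(self._fit(-100.0), self._fit(-100.0))
        assert d == 0.0 and p == 1.0

    def test_chi2_quantile_oracle(self):
        q = chi2.ppf(0.99, 1)
        d, p = lrt(self._fit(-100.0), self._fit(-100.0 + q / 2))
        assert p == pytest.approx(0.01, rel=1e-9)

    def test_negative_delta_floored(self):
        d, p = lrt(self._fit(-100.0), self._fit(-100.001))
        assert d == 0.0 and p == 1.0

    def test_different_alignments_rejected(self):
        with pytest.raises(ValueError):
            lrt(self._fit(-100.0, key=1), self._fit(-99.0, key=2))

    def test_df_two_option_is_more_conservative(self):
        d1, p1 = lrt(self._fit(-100.0), self._fit(-97.0), df=1)
        d2, p2 = lrt(self._fit(-100.0), self._fit(-97.0), df=2)
        assert p2 > p1


class TestSitePosteriors:
    @pytest.fixture(scope="class")
    def m8_case(self):
        (a, b), cats = simulate_codon_pair(
            CodonSimSpec(model="M8", n_codons=400, t=0.8, kappa=2.0, p0=0.5,
                         omega_s=3.0, rng_seed=17)
        )
        aln = alignment_from_pair(a, b)
        _, m8 = fit_pair(aln, n_restarts=1, seed=5)
        return aln, m8, cats

    def test_neb_single_site_matches_hand_bayes(self):
        """One-site alignment: posterior equals brute-force Bayes over
        the K+1 categories."""
        from chemoscan.codonmodel import class_transition_matrices, site_classes
        from chemoscan.codonmodel import CODON_INDEX

        aln = alignment_from_pair("ATG", "CGG")
        fit = SiteModelFit(model="M8", lnL=0, t=0.7, kappa=2.0, beta_p=0.8,
                           beta_q=1.4, p0=0.8, omega_s=3.0, aln_key=id(aln))
        neb = neb_sites(fit, aln)
        w, om = site_classes("M8", 0.8, 1.4, 0.8, 3.0)
        Ps = class_transition_matrices(0.7, 2.0, w, om)
        x, y = CODON_INDEX["ATG"], CODON_INDEX["CGG"]
        li = np.array([P[x, y] for P in Ps])
        post = w * li / (w * li).sum()
        assert neb[0] == pytest.approx(post[om > 1].sum(), abs=1e-12)

    def test_all_beta_classes_give_zero_selection_probability(self):
        aln = alignment_from_pair("ATGAAAGTTCTGGGGCATAAAGTTCTGGGG",
                                  "ATGAAAGTGCTGGGGCATAAAGTTCTTGGG")
        fit = SiteModelFit(model="M8", lnL=0, t=0.3, kappa=2.0, beta_p=0.8,
                           beta_q=1.4, p0=1.0, omega_s=2.0, aln_key=id(aln))
        neb = neb_sites(fit, aln)
        assert np.all(neb == 0.0)  # p0=1: only beta classes, all means < 1

    def test_selected_sites_rank_higher_under_neb(self, m8_case):
        aln, m8, cats = m8_case
        neb = neb_sites(m8, aln)
        assert neb[cats == 10].mean() > neb[cats < 10].mean()

    def test_beb_with_single_point_grid_equals_neb(self, m8_case):
        aln, m8, _ = m8_case
        neb = neb_sites(m8, aln)
        grid = {k: np.array([v]) for k, v in
                (("p0", m8.p0), ("p", m8.beta_p), ("q", m8.beta_q), ("omega_s", m8.omega_s))}
        beb = beb_sites(m8, aln, grid=grid)
        assert np.allclose(beb, neb, atol=1e-10)

    def test_beb_bounded_and_shrunk_toward_prior_on_short_alignments(self):
        diffs = []
        for rep in range(6):
            (a, b), _ = simulate_codon_pair(
                CodonSimSpec(model="M8", n_codons=60, t=0.6, p0=0.6, omega_s=3.0,
                             rng_seed=300 + rep)
            )
            aln = alignment_from_pair(a, b)
            _, m8 = fit_pair(aln, n_restarts=1, seed=rep)
            neb = neb_sites(m8, aln)
            beb = beb_sites(m8, aln)
            assert np.all((beb >= 0) & (beb <= 1))
            diffs.append(np.abs(beb - 0.5).mean() - np.abs(neb - 0.5).mean())
        assert np.mean(diffs) <= 0.02  # BEB no more extreme than NEB on average


class TestCallSelection:
    def _res(self, p_value, neb, beb):
        f7 = SiteModelFit(model="M7", lnL=-100.0, t=0.5, kappa=2, beta_p=1, beta_q=1,
                          aln_key=1)
        delta = chi2.ppf(1 - p_value, 1)
        f8 = SiteModelFit(model="M8", lnL=-100.0 + delta / 2, t=0.5, kappa=2,
                          beta_p=1, beta_q=1, p0=0.8, omega_s=2.0, aln_key=1)
        return call_selection("pair", f7, f8, np.array(neb), np.array(beb))

    def test_pvalue_above_cutoff_not_selected(self):
        r = self._res(0.02, [0.99], [0.99])
        assert not r.positively_selected

    def test_site_failing_beb_not_selected(self):
        r = self._res(0.005, [0.97], [0.93])
        assert not r.positively_selected and r.selected_sites == []

    def test_site_passing_both_selected(self):
        r = self._res(0.005, [0.97], [0.96])
        assert r.positively_selected and r.selected_sites == [0]
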