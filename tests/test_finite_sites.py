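import numpy as np
import pytest
import tskit

from pyjaatha import (DemographyParams, FiniteSitesConfig, LocusConfig,
                      draw_site_rates, evolve_alignment, expected_titv,
                      hky_rate_matrix, simulate_genealogies, titv_to_kappa)
from pyjaatha.finite_sites import hky_mutation_model
from scipy.linalg import expm

EQUAL = (0.25, 0.25, 0.25, 0.25)
SKEWED = (0.35, 0.15, 0.20, 0.30)


def _three_tip_ts(t_pair: float, t_out: float, L: int) -> tskit.TreeSequence:
    """((P1, P2):t_pair/2, outgroup):t_out — a fixed genealogy fixture."""
    tables = tskit.TableCollection(sequence_length=L)
    for _ in range(4):
        tables.populations.add_row()
    flags = tskit.NODE_IS_SAMPLE
    tables.nodes.add_row(flags=flags, population=0, time=0)       # 0: P1 tip
    tables.nodes.add_row(flags=flags, population=1, time=0)       # 1: P2 tip
    tables.nodes.add_row(flags=flags, population=3, time=0)       # 2: outgroup
    tables.nodes.add_row(flags=0, population=2, time=t_pair / 2)  # 3: pair mrca
    tables.nodes.add_row(flags=0, population=2, time=t_out)       # 4: root
    tables.edges.add_row(0, L, parent=3, child=0)
    tables.edges.add_row(0, L, parent=3, child=1)
    tables.edges.add_row(0, L, parent=4, child=3)
    tables.edges.add_row(0, L, parent=4, child=2)
    tables.sort()
    return tables.tree_sequence()


class TestTiTvKappa:
    def test_jukes_cantor_point(self):
        assert titv_to_kappa(0.5, EQUAL) == pytest.approx(1.0)

    def test_equal_frequencies_titv_two(self):
        assert titv_to_kappa(2.0, EQUAL) == pytest.approx(4.0)

    def test_round_trip_with_skewed_frequencies(self):
        for titv in (0.4, 1.0, 2.0, 6.0):
            kappa = titv_to_kappa(titv, SKEWED)
            assert expected_titv(kappa, SKEWED) == pytest.approx(titv)

    def test_degenerate_frequencies_rejected(self):
        with pytest.raises(ValueError):
            titv_to_kappa(2.0, (0.5, 0.0, 0.5, 0.0))


class TestHkyRateMatrix:
    def test_rows_sum_to_zero_and_unit_rate(self):
        Q = hky_rate_matrix(SKEWED, 3.0)
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        pi = np.asarray(SKEWED)
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_detailed_balance(self):
        Q = hky_rate_matrix(SKEWED, 2.5)
        pi = np.asarray(SKEWED)
        np.testing.assert_allclose(pi[:, None] * Q, (pi[:, None] * Q).T, atol=1e-12)

    def test_kappa_one_equal_freqs_is_jukes_cantor(self):
        Q = hky_rate_matrix(EQUAL, 1.0)
        off = Q[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, off[0])

    def test_stationary_distribution_reached(self):
        Q = hky_rate_matrix(SKEWED, 2.0)
        P = expm(Q * 50.0)
        for row in P:
            np.testing.assert_allclose(row, SKEWED, atol=1e-8)

    def test_short_time_transition_fraction(self):
        # at small t the fraction of changes that are transitions is
        # titv / (1 + titv)
        titv = 2.0
        Q = hky_rate_matrix(SKEWED, titv_to_kappa(titv, SKEWED))
        pi = np.asarray(SKEWED)
        t = 1e-4
        P = expm(Q * t)
        flux = pi[:, None] * P
        ts_flux = flux[0, 2] + flux[2, 0] + flux[1, 3] + flux[3, 1]
        tv_flux = sum(flux[i, j] for i in range(4) for j in range(4)
                      if i != j) - ts_flux
        assert ts_flux / (ts_flux + tv_flux) == pytest.approx(titv / (1 + titv),
                                                              rel=1e-3)

    def test_uniformized_jump_matrix_is_stochastic(self):
        model, q_max = hky_mutation_model(SKEWED, 3.0)
        P = model.transition_matrix
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(P >= 0)
        Q = hky_rate_matrix(SKEWED, 3.0)
        np.testing.assert_allclose(q_max * (P - np.eye(4)), Q, atol=1e-12)


class TestSiteRates:
    def test_moments(self):
        rates = draw_site_rates(0.7, 100_000, seed=1)
        se_mean = rates.std(ddof=1) / np.sqrt(len(rates))
        assert abs(rates.mean() - 1.0) < 3 * se_mean
        assert rates.var(ddof=1) == pytest.approx(1 / 0.7, rel=0.05)

    def test_homogeneous_limit(self):
        rates = draw_site_rates(1e6, 1000, seed=2)
        np.testing.assert_allclose(rates, 1.0, atol=0.02)

    def test_rejects_nonpositive_alpha(self):
        with pytest.raises(ValueError):
            draw_site_rates(0.0, 10, seed=1)


class TestEvolveAlignment:
    def test_zero_theta_gives_monomorphic_stationary_draw(self):
        ts = _three_tip_ts(0.5, 2.0, 2000)
        cfg = FiniteSitesConfig(base_freqs=SKEWED, titv=2.0, alpha=1e6)
        aln = evolve_alignment(ts, cfg, theta=0.0, seed=3)
        assert (aln.seqs == aln.seqs[0]).all()
        freq_a = (aln.seqs[0] == "A").mean()
        assert abs(freq_a - SKEWED[0]) < 4 * np.sqrt(0.35 * 0.65 / 2000)

    @pytest.mark.parametrize("t", [0.1, 1.0])
    def test_jc_branch_mismatch_probability(self, t):
        # P(site differs between two tips at distance t) = 3/4 (1 - e^{-4t/3})
        L = 30_000
        ts = _three_tip_ts(t, max(2.0, 2 * t), L)
        cfg = FiniteSitesConfig(base_freqs=EQUAL, titv=0.5, alpha=1e9)
        aln = evolve_alignment(ts, cfg, theta=float(L), seed=5)  # theta/site = 1
        p_hat = (aln.seqs[0] != aln.seqs[1]).mean()
        p = 0.75 * (1 - np.exp(-4 * t / 3))
        assert abs(p_hat - p) < 3 * np.sqrt(p * (1 - p) / L)

    def test_long_branch_base_composition_reaches_stationarity(self):
        L = 20_000
        ts = _three_tip_ts(0.1, 30.0, L)
        cfg = FiniteSitesConfig(base_freqs=SKEWED, titv=2.0, alpha=1e9)
        aln = evolve_alignment(ts, cfg, theta=float(L), seed=7)
        out = aln.outgroup_row
        for base, pi in zip("ACGT", SKEWED):
            assert abs((out == base).mean() - pi) < 4 * np.sqrt(pi * (1 - pi) / L)

    def test_requires_outgroup(self):
        params = DemographyParams(theta=5, tau=0.5, q=1, m=0, s1=1, s2=1)
        lc = LocusConfig(n_loc=1, y1=4, y2=4, seq_length_bp=100)  # no outgroup
        ts = next(simulate_genealogies(params, lc, seed=1))
        with pytest.raises(ValueError, match="outgroup"):
            evolve_alignment(ts, FiniteSitesConfig(), 5.0, seed=1)

    def test_deterministic_given_seed(self):
        ts = _three_tip_ts(0.5, 2.0, 500)
        cfg = FiniteSitesConfig()
        a1 = evolve_alignment(ts, cfg, 25.0, seed=11)
        a2 = evolve_alignment(ts, cfg, 25.0, seed=11)
        np.testing.assert_array_equal(a1.seqs, a2.seqs)

    def test_multiple_hit_fraction_grows_with_theta_and_heterogeneity(self):
        params = DemographyParams(theta=1, tau=0.5, q=1, m=0.1, s1=1, s2=1)
        lc = LocusConfig(n_loc=1, y1=4, y2=4, seq_length_bp=400,
                         outgroup_factor=2.0)
        rng = np.random.default_rng(13)
        loci = [next(simulate_genealogies(params, lc, seed=100 + i))
                for i in range(15)]

        def multi_allelic_fraction(theta_site, alpha):
            cfg = FiniteSitesConfig(titv=2.0, alpha=alpha)
            multi = poly = 0
            for i, ts in enumerate(loci):
                aln = evolve_alignment(ts, cfg, theta_site * 400, rng)
                n_alleles = np.array([len(set(col)) for col in aln.seqs.T])
                poly += (n_alleles >= 2).sum()
                multi += (n_alleles >= 3).sum()
            return multi / max(poly, 1)

        low = multi_allelic_fraction(0.005, 5.0)
        high_theta = multi_allelic_fraction(0.08, 5.0)
        high_het = multi_allelic_fraction(0.005, 0.2)
        assert high_theta > low
        assert high_het > low


def test_config_validation():
    with pytest.raises(ValueError):
        FiniteSitesConfig(base_freqs=(0.5, 0.5, 0.2, -0.2))
    with pytest.raises(ValueError):
        FiniteSitesConfig(titv=0.0)
    with pytest.raises(ValueError):
        FiniteSitesConfig(outgroup_factor=0.5)
    assert FiniteSitesConfig(titv=2.0).kappa == pytest.approx(4.0)
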