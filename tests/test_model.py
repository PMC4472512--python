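"""Link functions, linear predictors, likelihood and priors."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from commocc.model import (CommunityParams, PriorSpec, inv_logit,
                           log_prior, logit, site_marginal_loglik,
                           total_loglik, z_full_conditional,
                           occupancy_linpred, detection_linpred)
from commocc.pipeline import enumerate_loglik


class TestLinks:
    def test_inv_logit_at_zero(self):
        assert inv_logit(0.0) == pytest.approx(0.5)

    def test_logit_closed_form(self):
        assert logit(0.8) == pytest.approx(np.log(4), abs=1e-12)

    @pytest.mark.parametrize("p", np.round(np.arange(0.01, 1.0, 0.07), 3).tolist())
    def test_mutual_inverses(self, p):
        assert inv_logit(logit(p)) == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_logit_rejects_boundary(self, bad):
        with pytest.raises(ValueError):
            logit(bad)

    @given(st.floats(-700, 700))
    def test_inv_logit_bounded_monotone(self, x):
        v = inv_logit(x)
        assert 0.0 <= v <= 1.0
        assert inv_logit(x + 1.0) >= v


def _params(N=2, Y=2, C=6, fill=0.0):
    return CommunityParams(
        u=np.full((N, Y), fill), v=np.full((N, Y), fill),
        a=np.zeros((N, C)), b=np.zeros(N),
        mu_u=np.zeros(N), sig_u=np.ones(N),
        mu_v=np.zeros(N), sig_v=np.ones(N),
    )


class TestLinearPredictors:
    def test_occupancy_reduces_to_intercept(self, small_bundle):
        p = _params()
        p.u[0, 0] = 1.7
        val = occupancy_linpred(p, small_bundle.site_cov, 0, 0, 0)
        # covariates are nonzero, slopes are zero
        assert val == pytest.approx(1.7)

    def test_occupancy_hand_value(self, small_bundle):
        p = _params()
        p.a[0, 2] = 2.0  # soy slope
        cov = small_bundle.site_cov
        cov.soy[0, 0] = 0.5
        cov.lat[0, 0] = cov.long[0, 0] = cov.corn[0, 0] = 0.0
        cov.per_past[0, 0] = cov.forest[0, 0] = 0.0
        val = occupancy_linpred(p, cov, 0, 0, 0)
        assert val == pytest.approx(1.0)
        assert inv_logit(val) == pytest.approx(0.7311, abs=1e-4)

    def test_detection_hand_value(self, small_bundle):
        p = _params()
        p.v[0, 0] = -1.0
        p.b[0] = 2.0
        pc = small_bundle.point_cov
        pc.p_fors[0, 0, 0] = 0.5
        val = detection_linpred(p, pc, 0, 0, 0, 0)
        assert val == pytest.approx(0.0)

    def test_missing_covariate_identified(self, small_bundle):
        p = _params()
        cov = small_bundle.site_cov
        cov.soy[1, 0] = np.nan
        with pytest.raises(ValueError, match="site 1"):
            occupancy_linpred(p, cov, 0, 1, 0)


class TestSiteMarginal:
    def test_all_zero_history(self):
        # enumeration over z: 0.5 * 0.5^5 + 0.5
        val = site_marginal_loglik(np.zeros(5), 0.5, np.full(5, 0.5))
        assert val == pytest.approx(np.log(0.515625), abs=1e-10)
        assert val == pytest.approx(-0.66237, abs=1e-5)

    def test_single_detection_forces_occupancy(self):
        val = site_marginal_loglik(np.array([1, 0, 0, 0, 0.0]), 0.5, np.full(5, 0.5))
        assert val == pytest.approx(np.log(0.5 * 0.5 ** 5), abs=1e-10)
        assert val == pytest.approx(-4.15888, abs=1e-5)

    def test_certain_detection(self):
        assert site_marginal_loglik(np.ones(5), 1.0, np.ones(5)) == pytest.approx(0.0)

    def test_all_points_missing_contributes_zero(self):
        # a surveyed site with no usable replicates carries no information
        assert site_marginal_loglik(np.full(5, np.nan), 0.4, np.full(5, 0.3)) \
            == pytest.approx(0.0, abs=1e-12)

    def test_missing_points_dropped(self):
        y = np.array([0.0, np.nan, 0.0])
        val = site_marginal_loglik(y, 0.5, np.full(3, 0.5))
        assert val == pytest.approx(np.log(0.5 * 0.25 + 0.5), abs=1e-12)

    def test_psi_one_reduces_to_bernoulli_product(self, rng):
        y = (rng.random(5) < 0.4).astype(float)
        p = rng.uniform(0.1, 0.9, 5)
        expect = np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))
        assert site_marginal_loglik(y, 1.0, p) == pytest.approx(expect, abs=1e-12)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            site_marginal_loglik(np.array([0.5]), 0.5, np.array([0.5]))


class TestZFullConditional:
    def test_detection_forces_presence(self):
        assert z_full_conditional(np.array([0, 1, 0.0]), 0.3, np.full(3, 0.2)) == 1.0

    def test_hand_value(self):
        val = z_full_conditional(np.zeros(5), 0.5, np.full(5, 0.5))
        assert val == pytest.approx(0.015625 / 0.515625, abs=1e-10)
        assert val == pytest.approx(0.030303, abs=1e-6)

    def test_uninformative_when_p_zero(self):
        assert z_full_conditional(np.zeros(4), 0.37, np.zeros(4)) == pytest.approx(0.37)

    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.95))
    def test_monotone_in_psi_and_p(self, psi, p):
        y = np.zeros(4)
        base = z_full_conditional(y, psi, np.full(4, p))
        assert z_full_conditional(y, min(psi + 0.02, 0.99), np.full(4, p)) >= base
        assert z_full_conditional(y, psi, np.full(4, min(p + 0.02, 0.99))) <= base


class TestTotalLoglik:
    def test_single_cell_reduces_to_site_marginal(self, rng):
        y = (rng.random((1, 4, 1, 1)) < 0.3).astype(float)
        psi = np.array([[[0.6]]])
        p = rng.uniform(0.2, 0.8, size=(1, 4, 1, 1))
        expect = site_marginal_loglik(y[0, :, 0, 0], 0.6, p[0, :, 0, 0])
        assert total_loglik(psi, p, y) == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        """Marginal likelihood equals brute-force sum over all latent states
        on toys with S*N*Y <= 12."""
        r = np.random.default_rng(seed)
        S, K, N, Y = [(2, 3, 2, 1), (3, 2, 2, 2), (2, 2, 3, 2),
                      (1, 5, 2, 2), (4, 3, 1, 3)][seed]
        y = (r.random((S, K, N, Y)) < 0.35).astype(float)
        if seed % 2:  # make one site-year unsurveyed
            y[0, :, :, 0] = np.nan
        psi = r.uniform(0.05, 0.95, (S, N, Y))
        p = r.uniform(0.05, 0.95, (S, K, N, Y))
        assert total_loglik(psi, p, y) == pytest.approx(
            enumerate_loglik(psi, p, y), abs=1e-10)

    def test_invariant_to_species_relabeling(self, rng):
        y = (rng.random((3, 4, 3, 2)) < 0.3).astype(float)
        psi = rng.uniform(0.1, 0.9, (3, 3, 2))
        p = rng.uniform(0.1, 0.9, (3, 4, 3, 2))
        perm = [2, 0, 1]
        assert total_loglik(psi, p, y) == pytest.approx(
            total_loglik(psi[:, perm], p[:, :, perm], y[:, :, perm]), abs=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            total_loglik(np.zeros((2, 2, 2)), np.zeros((2, 3, 2, 2)),
                         np.zeros((3, 3, 2, 2)))


class TestLogPrior:
    def _random_params(self, rng, N=3, Y=2, C=6):
        return CommunityParams(
            u=rng.standard_normal((N, Y)), v=rng.standard_normal((N, Y)),
            a=rng.standard_normal((N, C)), b=rng.standard_normal(N),
            mu_u=rng.standard_normal(N), sig_u=rng.uniform(0.5, 2, N),
            mu_v=rng.standard_normal(N), sig_v=rng.uniform(0.5, 2, N),
            mu2_u=0.3, sig2_u=1.2, mu2_v=-0.2, sig2_v=0.8,
            mu_a=rng.standard_normal(C), sig_a=rng.uniform(0.5, 2, C),
            mu_b=0.1, sig_b=1.5,
        )

    def test_matches_scipy_density_sum(self, rng):
        """Hierarchical prior equals an independent scipy-based summation."""
        pa = self._random_params(rng)
        prior = PriorSpec()
        expect = 0.0
        expect += stats.norm.logpdf(pa.u, pa.mu_u[:, None], pa.sig_u[:, None]).sum()
        expect += stats.norm.logpdf(pa.v, pa.mu_v[:, None], pa.sig_v[:, None]).sum()
        expect += stats.norm.logpdf(pa.mu_u, pa.mu2_u, pa.sig2_u).sum()
        expect += stats.norm.logpdf(pa.mu_v, pa.mu2_v, pa.sig2_v).sum()
        expect += stats.norm.logpdf(pa.a, pa.mu_a, pa.sig_a).sum()
        expect += stats.norm.logpdf(pa.b, pa.mu_b, pa.sig_b).sum()
        expect += stats.norm.logpdf([pa.mu2_u, pa.mu2_v, pa.mu_b], 0, 10).sum()
        expect += stats.norm.logpdf(pa.mu_a, 0, 10).sum()
        n_sds = 2 * 3 + 6 + 3
        expect += n_sds * stats.uniform.logpdf(0.5, 0, 10)
        assert log_prior(pa, prior) == pytest.approx(expect, abs=1e-8)

    def test_neutral_point_normal_terms(self):
        pa = _params(N=1, Y=1)
        pa.a = np.zeros((1, 0))
        pa.b = np.zeros(0)
        pa.mu_a = np.zeros(0)
        pa.sig_a = np.ones(0)
        val = log_prior(pa, PriorSpec(pooling="independent"))
        # u and v both at the prior mode of N(0, 10)
        assert val == pytest.approx(2 * stats.norm.logpdf(0, 0, 10), abs=1e-10)

    def test_sd_outside_support_is_minus_inf(self, rng):
        pa = self._random_params(rng)
        pa.sig2_u = 11.0
        assert log_prior(pa, PriorSpec()) == -np.inf
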