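import warnings

import numpy as np
import pandas as pd
import pytest
from _oracles import direct_reml_loglik, random_pd_components

from longrr.basis import BasisSpec, build_basis, legendre_basis
from longrr.genotypes import GenomicRelationship
from longrr.mtm import mtm_fit
from longrr.phenotypes import BlueTable, compute_blues
from longrr.rrm import (
    RRMData,
    VarianceComponents,
    assemble,
    count_parameters,
    genetic_covariance_over_time,
    genetic_trajectory,
    information_criteria,
    reml_fit,
    reml_loglik,
)
from conftest import model_exact_config, simulate_dataset


def toy_grm(n, rng=None, ridge=0.3):
    rng = rng or np.random.default_rng(0)
    A = rng.standard_normal((n, n))
    G = A @ A.T / n + ridge * np.eye(n)
    return GenomicRelationship(G, np.array([f"a{i}" for i in range(n)]))


def toy_data(n=5, t=3, K=2, seed=0, missing=()):
    rng = np.random.default_rng(seed)
    G = toy_grm(n, rng)
    days = np.arange(1.0, t + 1)
    phi = legendre_basis(days, K - 1, t_min=1, t_max=t)
    vals = pd.DataFrame(
        rng.normal(10, 3, (n, t)), index=G.accession_ids, columns=days
    )
    for acc, day in missing:
        vals.loc[acc, day] = np.nan
    blues = BlueTable.__new__(BlueTable)  # bypass the no-missing check
    object.__setattr__(blues, "values", vals)
    object.__setattr__(blues, "treatment", "control")
    return assemble(blues, phi, G), phi, G


class TestAssemble:
    def test_small_instance_layout(self):
        data, phi, G = toy_data(n=2, t=3, K=2)
        assert data.y.size == 6
        np.testing.assert_array_equal(data.acc_idx, [0, 0, 0, 1, 1, 1])
        np.testing.assert_array_equal(data.day_idx, [0, 1, 2, 0, 1, 2])
        assert data.phi.Phi.shape == (3, 2)

    def test_missing_day_drops_row(self):
        data, *_ = toy_data(n=3, t=3, missing=[("a1", 2.0)])
        assert data.y.size == 8
        assert np.sum(data.acc_idx == 1) == 2

    def test_accession_mismatch_is_an_error(self):
        data, phi, G = toy_data(n=3)
        vals = pd.DataFrame(
            np.ones((3, 3)), index=["a0", "a1", "zz"], columns=[1.0, 2.0, 3.0]
        )
        blues = BlueTable(vals, "control")
        with pytest.raises(ValueError, match="zz"):
            assemble(blues, phi, G)

    def test_g_reordered_to_blue_order(self):
        data, phi, G = toy_data(n=4, seed=3)
        perm = [2, 0, 3, 1]
        vals = pd.DataFrame(
            np.zeros((4, 3)),
            index=G.accession_ids[perm],
            columns=[1.0, 2.0, 3.0],
        )
        shuffled = assemble(BlueTable(vals, "c"), phi, G)
        np.testing.assert_allclose(shuffled.G.G, G.G[np.ix_(perm, perm)])


class TestBookkeeping:
    @pytest.mark.parametrize(
        "spec,t,p",
        [
            (BasisSpec("legendre", 1), 20, 26),
            (BasisSpec("legendre", 2), 20, 32),
            (BasisSpec("bspline", 1, 3), 20, 32),
            (BasisSpec("bspline", 1, 4), 20, 40),
            (BasisSpec("legendre", 0), 1, 3),
        ],
    )
    def test_parameter_count(self, spec, t, p):
        assert count_parameters(spec, t) == p

    def test_information_criteria_identities(self):
        half_aic, half_bic = information_criteria(-100.0, 10, 500, 2)
        assert half_aic == pytest.approx(-110.0)
        assert half_bic == pytest.approx(-100.0 - 5 * np.log(498))
        assert information_criteria(-50.0, 0, 10, 1)[0] == pytest.approx(-50.0)


class TestREMLObjective:
    @pytest.mark.parametrize("include_pe", [True, False])
    def test_matches_direct_covariance_oracle(self, include_pe):
        data, *_ = toy_data(n=5, t=3, K=2, seed=1)
        rng = np.random.default_rng(5)
        for _ in range(5):
            vc = random_pd_components(rng, 2, 3)
            ours = reml_loglik(data, vc, include_pe=include_pe)
            ref = direct_reml_loglik(data, vc, include_pe=include_pe)
            assert ours == pytest.approx(ref, abs=1e-6)

    def test_unbalanced_data_supported(self):
        data, *_ = toy_data(n=5, t=3, K=2, seed=2, missing=[("a0", 1.0), ("a3", 3.0)])
        rng = np.random.default_rng(6)
        vc = random_pd_components(rng, 2, 3)
        assert reml_loglik(data, vc) == pytest.approx(
            direct_reml_loglik(data, vc), abs=1e-6
        )


class TestEMFit:
    def test_loglik_non_decreasing(self):
        data, *_ = toy_data(n=8, t=4, K=2, seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reml_fit(data, max_iter=60, tol=1e-10)
        assert np.all(np.diff(fit.logL_path) > -1e-7)

    def test_noise_only_data_shrinks_genetic_variance(self):
        cfg = model_exact_config(
            n_accessions=100,
            n_markers=400,
            Cu=np.zeros((2, 2)),
            Cpe=np.zeros((2, 2)),
            seed=21,
        )
        _, records, _, grm = simulate_dataset(cfg)
        blues = compute_blues(records, "control")
        phi = build_basis(cfg.basis, blues.days)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reml_fit(assemble(blues, phi, grm), max_iter=400, tol=1e-6)
        genetic_day_var = np.diag(genetic_covariance_over_time(fit.vc, phi))
        assert genetic_day_var.max() < 0.05 * fit.vc.sigma2_eps.mean()

    def test_scale_equivariance(self):
        data, phi, G = toy_data(n=6, t=4, K=2, seed=8)
        c = 10.0
        scaled = RRMData(
            data.y * c, data.acc_idx, data.day_idx, data.phi, data.G,
            data.accession_ids,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = reml_fit(data, max_iter=80, tol=1e-9)
            f2 = reml_fit(scaled, max_iter=80, tol=1e-9)
        np.testing.assert_allclose(f2.vc.Cu, c ** 2 * f1.vc.Cu, rtol=1e-6)
        np.testing.assert_allclose(
            f2.vc.sigma2_eps, c ** 2 * f1.vc.sigma2_eps, rtol=1e-6
        )
        np.testing.assert_allclose(f2.u, c * f1.u, rtol=1e-6, atol=1e-9)

    def test_saturated_basis_matches_multi_trait_model(self):
        # with K = t and a permanent-environment term the random regression
        # model spans the multi-trait model, so the implied genetic
        # covariance Phi Cu Phi' should agree with Sigma_u
        cfg = model_exact_config(
            n_accessions=80,
            n_markers=400,
            days=(1, 2, 3),
            basis=BasisSpec("legendre", 2, t_min=1, t_max=3),
            Cu=np.array([[900.0, 300.0, 0.0], [300.0, 400.0, 100.0], [0.0, 100.0, 200.0]]),
            Cpe=np.diag([200.0, 100.0, 50.0]),
            sigma2_eps=np.array([60.0, 80.0, 100.0]),
            seed=31,
        )
        _, records, _, grm = simulate_dataset(cfg)
        blues = compute_blues(records, "control")
        phi = build_basis(cfg.basis, blues.days)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rfit = reml_fit(assemble(blues, phi, grm), max_iter=2000, tol=1e-8)
            mfit = mtm_fit(blues, grm, max_iter=2000, tol=1e-8)
        rrm_cov = genetic_covariance_over_time(rfit.vc, phi)
        rel = np.linalg.norm(rrm_cov - mfit.Sigma_u) / np.linalg.norm(mfit.Sigma_u)
        assert rel < 0.05
        # the MTM's unrestricted Sigma_eps nests the RRM's
        # Phi Cpe Phi' + diag(sigma2) form, so its maximum can only be higher
        assert mfit.logL >= rfit.logL - 1e-3
        assert abs(mfit.logL - rfit.logL) < 5.0


class TestTrajectories:
    def test_zero_coefficients_give_flat_zero(self):
        data, phi, G = toy_data(n=4, t=4, K=2, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reml_fit(data, max_iter=5)
        zeroed = fit.__class__(**{**fit.__dict__, "u": np.zeros_like(fit.u)})
        traj = genetic_trajectory(zeroed, "a0")
        np.testing.assert_array_equal(traj, 0.0)

    def test_interpolates_between_phenotyped_days(self):
        data, phi, G = toy_data(n=4, t=4, K=2, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reml_fit(data, max_iter=30)
        mid = genetic_trajectory(fit, "a1", days=[2.5])
        lo, hi = genetic_trajectory(fit, "a1", days=[2.0, 3.0])
        # linear basis: interpolated value is the midpoint
        assert mid[0] == pytest.approx((lo + hi) / 2)

    def test_no_extrapolation_outside_window(self):
        data, phi, G = toy_data(n=4, t=4, K=2, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reml_fit(data, max_iter=5)
        with pytest.raises(ValueError):
            genetic_trajectory(fit, "a0", days=[5.0])

    def test_blup_trajectory_beats_raw_blues(self):
        cfg = model_exact_config(n_accessions=150, n_markers=600, seed=41)
        _, records, truth, grm = simulate_dataset(cfg)
        blues = compute_blues(records, "control")
        phi = build_basis(cfg.basis, blues.days)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = reml_fit(assemble(blues, phi, grm), max_iter=200, tol=1e-5)
        g_true = truth.g["control"]
        g_hat = (phi.Phi @ fit.u).T
        b = blues.to_array()
        r_hat = np.mean(
            [np.corrcoef(g_hat[:, t], g_true[:, t])[0, 1] for t in range(20)]
        )
        r_blue = np.mean(
            [np.corrcoef(b[:, t], g_true[:, t])[0, 1] for t in range(20)]
        )
        assert r_hat > r_blue


class TestGeneticCovariance:
    def test_orthonormal_basis_identity_covariance_has_trace_K(self):
        spec = BasisSpec("legendre", 1, t_min=1, t_max=4)
        phi = build_basis(spec, np.arange(1.0, 5.0))
        Q, _ = np.linalg.qr(phi.Phi)
        phi_ortho = phi.__class__(Q, phi.days, spec)
        vc = VarianceComponents(np.eye(2), np.eye(2), np.ones(4))
        cov = genetic_covariance_over_time(vc, phi_ortho)
        assert np.trace(cov) == pytest.approx(2.0)

    def test_zero_covariance_function_gives_zero(self):
        phi = legendre_basis(np.arange(1.0, 21.0), 1)
        vc = VarianceComponents(np.zeros((2, 2)), np.eye(2), np.ones(20))
        assert not genetic_covariance_over_time(vc, phi).any()

    def test_result_symmetric_psd(self, rng):
        phi = legendre_basis(np.arange(1.0, 21.0), 2)
        vc = random_pd_components(rng, 3, 20)
        cov = genetic_covariance_over_time(vc, phi)
        np.testing.assert_allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() > -1e-10
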