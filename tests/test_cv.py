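import warnings

import numpy as np
import pytest

from longrr.basis import BasisSpec, build_basis
from longrr.cv import CV3_DAY_SETS, CVPlan, accuracy, cv1_run, cv2_run, cv3_run
from longrr.genotypes import GenomicRelationship, compute_grm, impute_mean, qc_filter
from longrr.phenotypes import compute_blues
from longrr.rrm import assemble, reml_fit
from longrr.simulate import simulate_markers, simulate_trajectories
from conftest import model_exact_config, simulate_dataset

FAST = dict(max_iter=150, tol=1e-5)


def quiet(fn, *args, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fn(*args, **kw)


class TestAccuracy:
    def test_perfect_and_inverted_agreement(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert accuracy(x, x) == pytest.approx(1.0)
        assert accuracy(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # {(1,2),(2,4),(3,9)}: cov=7/3, sx^2=2/3, sy^2=26/3 (population
        # moments cancel in r) -> r = 0.9707253...
        r = accuracy([1.0, 2.0, 3.0], [2.0, 4.0, 9.0])
        assert r == pytest.approx(0.970725343394151, abs=1e-12)

    def test_constant_vector_is_missing_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(accuracy([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_too_few_pairs(self):
        with pytest.warns(UserWarning, match="3 pairs"):
            assert np.isnan(accuracy([1.0, 2.0], [1.0, 2.0]))


class TestScenarioDefinitions:
    def test_day_sets_match_design(self):
        assert CV3_DAY_SETS["A"] == (1, 3, 5, 7, 9, 11, 13, 15)
        assert CV3_DAY_SETS["B"] == (2, 4, 6, 8, 10, 12, 14)
        assert CV3_DAY_SETS["C"] == (1, 4, 7, 10, 13)

    def test_plan_rejects_overlapping_day_sets(self):
        with pytest.raises(ValueError):
            CVPlan("CV2", train_days=(1, 2, 3), forecast_days=(3, 4))


@pytest.fixture(scope="module")
def cv_dataset():
    cfg = model_exact_config(n_accessions=80, n_markers=400, seed=5)
    _, records, truth, grm = simulate_dataset(cfg)
    blues = quiet(compute_blues, records, "control")
    return cfg, blues, grm, truth


class TestCV1:
    def test_diagnostic_mode_projection_identity(self, cv_dataset):
        # test set == training set makes the G-projection the identity, so
        # predictions must equal the training-line genetic values
        cfg, blues, grm, _ = cv_dataset
        res_diag = quiet(
            cv1_run, blues, grm, cfg.basis, n_repeats=1, seed=3,
            fit_kwargs=FAST, diagnostic_training_set=True,
        )
        phi = build_basis(cfg.basis, blues.days)
        rng = np.random.default_rng(3 * 1009)  # the run's split for repeat 0
        n = blues.accession_ids.size
        trn = np.sort(rng.permutation(n)[: int(np.ceil(n / 2))])
        fit = quiet(
            reml_fit, assemble(
                blues.__class__(blues.values.iloc[trn], blues.treatment),
                phi, grm.subset(trn)),
            **FAST,
        )
        g_trn = phi.Phi @ fit.u
        Y = blues.to_array()[trn]
        for j, day in enumerate(blues.days):
            expect = accuracy(g_trn[j], Y[:, j])
            got = res_diag[res_diag.day == day].accuracy.iloc[0]
            assert got == pytest.approx(expect, abs=1e-8)

    def test_clones_of_training_lines_predicted_perfectly(self):
        # heritability-one limit: no pe, vanishing residual; the test set
        # duplicates the training genotypes, so the G-projection recovers
        # each clone's genetic value exactly
        cfg = model_exact_config(
            n_accessions=30, n_markers=200,
            Cpe=np.zeros((2, 2)),
            sigma2_eps=np.full(20, 1e-4),
            seed=9,
        )
        markers = simulate_markers(cfg)
        records, truth = simulate_trajectories(markers, cfg)
        grm = compute_grm(impute_mean(qc_filter(markers, 0.0, 0.0)))
        blues = quiet(compute_blues, records, "control")
        phi = build_basis(cfg.basis, blues.days)
        fit = quiet(reml_fit, assemble(blues, phi, grm), max_iter=300, tol=1e-8,
                    include_pe=False)
        g_trn = phi.Phi @ fit.u  # day x n
        # clones: identical genotypes => G rows equal; project onto the
        # training block itself through the relationship matrix
        proj = grm.G @ np.linalg.solve(grm.G, g_trn.T)
        Y = blues.to_array()
        for j in range(20):
            assert accuracy(proj[:, j], Y[:, j]) > 0.999

    def test_mismatched_relationships_give_null_accuracy(self, cv_dataset):
        # phenotypes carry real genetic signal, but the relationship matrix
        # of an independent panel carries no information about it
        cfg, blues, _, _ = cv_dataset
        alt_cfg = model_exact_config(n_accessions=80, n_markers=400, seed=99)
        _, _, _, alt_grm = simulate_dataset(alt_cfg)
        alt = GenomicRelationship(alt_grm.G, blues.accession_ids)
        res = quiet(
            cv1_run, blues, alt, cfg.basis, n_repeats=3, seed=7, fit_kwargs=FAST
        )
        n_test = blues.accession_ids.size // 2
        assert abs(res.accuracy.mean()) < 2 / np.sqrt(n_test)

    def test_shared_splits_between_models(self, cv_dataset):
        cfg, blues, grm, _ = cv_dataset
        days3 = blues.__class__(blues.values[[1.0, 2.0, 3.0]], blues.treatment)
        spec3 = BasisSpec("legendre", 1, t_min=1, t_max=3)
        r1 = quiet(cv1_run, days3, grm, spec3, n_repeats=2, seed=11, fit_kwargs=FAST)
        r2 = quiet(cv1_run, days3, grm, spec3, n_repeats=2, seed=11, model="mtm",
                   fit_kwargs=dict(max_iter=200, tol=1e-5))
        assert (r1["repeat"].values == r2["repeat"].values).all()
        assert not r1.accuracy.equals(r2.accuracy)


class TestForecasting:
    def test_noiseless_linear_growth_forecast_is_exact(self):
        cfg = model_exact_config(
            n_accessions=40, n_markers=200,
            Cpe=np.zeros((2, 2)),
            sigma2_eps=np.full(20, 1e-6),
            seed=13,
        )
        _, records, _, grm = simulate_dataset(cfg)
        blues = quiet(compute_blues, records, "control")
        res = quiet(
            cv2_run, blues, grm, cfg.basis, train_through=15, n_repeats=2,
            seed=1, fit_kwargs=dict(max_iter=300, tol=1e-8, include_pe=False),
        )
        assert (res.accuracy > 0.999).all()

    def test_cv3a_matches_full_window_when_noiseless(self):
        cfg = model_exact_config(
            n_accessions=40, n_markers=200,
            Cpe=np.zeros((2, 2)),
            sigma2_eps=np.full(20, 1e-6),
            seed=13,
        )
        _, records, _, grm = simulate_dataset(cfg)
        blues = quiet(compute_blues, records, "control")
        kw = dict(n_repeats=2, seed=1,
                  fit_kwargs=dict(max_iter=300, tol=1e-8, include_pe=False))
        full = quiet(cv2_run, blues, grm, cfg.basis, train_through=15, **kw)
        thinned = quiet(cv3_run, blues, grm, cfg.basis, "A", **kw)
        np.testing.assert_allclose(
            thinned.accuracy.values, full.accuracy.values, atol=1e-6
        )

    def test_longer_training_window_forecasts_better(self, cv_dataset):
        # walk-forward information monotonicity: training on days 1..15
        # predicts days 16..20 better than training on days 1..5 only
        cfg, blues, grm, _ = cv_dataset
        kw = dict(n_repeats=6, seed=2, fit_kwargs=FAST)
        short = quiet(cv2_run, blues, grm, cfg.basis, train_through=5, **kw)
        long = quiet(cv2_run, blues, grm, cfg.basis, train_through=15, **kw)
        far = lambda df: df[df.day >= 16].accuracy.median()
        assert far(long) > far(short)

    def test_too_few_training_days_rejected(self, cv_dataset):
        cfg, blues, grm, _ = cv_dataset
        spec = BasisSpec("bspline", 1, 6)  # K = 6 coefficients
        with pytest.raises(ValueError, match="identify"):
            quiet(cv3_run, blues, grm, spec, "C", n_repeats=1, seed=0)

    def test_scenario_labels(self, cv_dataset):
        cfg, blues, grm, _ = cv_dataset
        res = quiet(cv2_run, blues, grm, cfg.basis, train_through=5,
                    n_repeats=1, seed=0, fit_kwargs=FAST)
        assert set(res.scenario) == {"CV2-5/15"}
        assert sorted(res.day.unique()) == list(np.arange(6.0, 21.0))


class TestReproducibility:
    def test_identical_seed_identical_results(self, cv_dataset):
        cfg, blues, grm, _ = cv_dataset
        a = quiet(cv1_run, blues, grm, cfg.basis, n_repeats=2, seed=5, fit_kwargs=FAST)
        b = quiet(cv1_run, blues, grm, cfg.basis, n_repeats=2, seed=5, fit_kwargs=FAST)
        assert a.equals(b)

    def test_different_seeds_differ(self, cv_dataset):
        cfg, blues, grm, _ = cv_dataset
        a = quiet(cv1_run, blues, grm, cfg.basis, n_repeats=1, seed=5, fit_kwargs=FAST)
        b = quiet(cv1_run, blues, grm, cfg.basis, n_repeats=1, seed=6, fit_kwargs=FAST)
        assert not a.accuracy.equals(b.accuracy)
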