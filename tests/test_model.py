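"""Hierarchical and flat model: likelihood correctness and limit behavior."""

import numpy as np
import pytest

from shade import FlatSICModel, PriorConfig, SHADEModel, log_intensity
from shade.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="module")
def single_image_setup():
    cfg = SimulationConfig(n_patients=1, images_per_patient=1,
                           expected_source=120, expected_target=60, seed=17)
    patterns, hier, truth = simulate_study(cfg)
    model = SHADEModel.from_patterns(patterns, hier, "T", ("tumor",),
                                     basis=cfg.basis, seed=5)
    return cfg, model, hier


@pytest.fixture(scope="module")
def single_image_fit(single_image_setup):
    _, model, _ = single_image_setup
    return model.fit(draws=400, warmup=500, chains=2, seed=3)


def reference_log_posterior(model, theta):
    """Independent dense re-implementation of the unnormalized posterior."""
    pr = model.priors
    psi_t, gam_t, del_t, beta0, beta, sig = model._unpack(theta)
    psi = sig[0] * psi_t
    gam = psi[model.coh_of_pat] + sig[1] * gam_t
    dlt = gam[model.pat_of_img] + sig[2] * del_t
    total = 0.0
    for i, ds in enumerate(model.datasets):
        X = np.hstack([ds.features[k] for k in ds.source_labels])
        Z = model._stack.Z[model._stack.img == i]
        for row in range(ds.n):
            eta = beta0[i] + ds.offset + float(X[row] @ dlt[i])
            if model.J:
                eta += float(Z[row] @ beta)
            # log sigmoid(+/-eta), written in stable closed form
            if ds.y[row] == 1:
                total += -np.logaddexp(0.0, -eta)
            else:
                total += -np.logaddexp(0.0, eta)
    for block in (psi_t, gam_t, del_t):
        total += float(np.sum(-0.5 * block**2))
    total += float(np.sum(-0.5 * beta0**2 / pr.intercept_scale**2))
    scales = [pr.sigma_cohort_scale, pr.sigma_patient_scale, pr.sigma_image_scale]
    for s_val, s_scale in zip(sig, scales):
        total += -0.5 * (s_val / s_scale) ** 2 + np.log(s_val)
    return total


class TestLogIntensity:
    def _tiny_dataset(self, basis):
        from shade.quadrature import LogisticDataset
        rng = np.random.default_rng(0)
        n = 4
        return LogisticDataset(
            y=np.array([1, 0, 0, 1]), locations=rng.uniform(0, 100, (n, 2)),
            offset=-np.log(4e-4), Z=rng.standard_normal((n, 2)),
            features={"tumor": rng.uniform(0, 2, (n, basis.P))},
            image_id="m", lambda_dummy=4e-4, source_labels=("tumor",))

    def test_zero_coefficients_give_zero(self, basis):
        ds = self._tiny_dataset(basis)
        val = log_intensity(0.0, np.zeros(2), {"tumor": np.zeros(basis.P)}, ds, 0)
        assert val == 0.0

    def test_intercept_only(self, basis):
        ds = self._tiny_dataset(basis)
        ds.Z = np.zeros_like(ds.Z)
        ds.features["tumor"][:] = 0.0
        assert log_intensity(-7.0, np.zeros(2), {"tumor": np.zeros(basis.P)},
                             ds, 2) == -7.0

    def test_matches_explicit_dot_product(self, basis):
        rng = np.random.default_rng(1)
        ds = self._tiny_dataset(basis)
        beta = rng.standard_normal(2)
        delta = rng.standard_normal(basis.P)
        got = log_intensity(0.3, beta, {"tumor": delta}, ds, 1)
        expected = 0.3 + ds.Z[1] @ beta + ds.features["tumor"][1] @ delta
        assert got == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_rejected(self, basis):
        ds = self._tiny_dataset(basis)
        with pytest.raises(ValueError):
            log_intensity(0.0, np.zeros(3), {"tumor": np.zeros(basis.P)}, ds, 0)


class TestPosteriorCorrectness:
    def test_log_posterior_matches_independent_implementation(self):
        cfg = SimulationConfig(n_patients=2, images_per_patient=2,
                               window_size=500.0, expected_source=10,
                               expected_target=6, seed=2)
        patterns, hier, _ = simulate_study(cfg)
        model = SHADEModel.from_patterns(patterns, hier, "T", ("tumor",),
                                         basis=cfg.basis, seed=1)
        assert model._stack.y.size <= 250
        rng = np.random.default_rng(7)
        for _ in range(10):
            theta = 0.5 * rng.standard_normal(model.n_params)
            ref = reference_log_posterior(model, theta)
            assert model.log_posterior(theta) == pytest.approx(ref, abs=1e-8)

    def test_gradient_matches_finite_differences(self):
        cfg = SimulationConfig(n_patients=2, images_per_patient=1,
                               window_size=500.0, expected_source=15,
                               expected_target=8, seed=4)
        patterns, hier, _ = simulate_study(cfg)
        model = SHADEModel.from_patterns(patterns, hier, "T", ("tumor",),
                                         basis=cfg.basis, seed=1)
        rng = np.random.default_rng(8)
        theta = 0.4 * rng.standard_normal(model.n_params)
        _, grad = model.log_posterior_grad(theta)
        eps = 1e-6
        idx = rng.choice(model.n_params, 15, replace=False)
        for i in idx:
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            num = (model.log_posterior(tp) - model.log_posterior(tm)) / (2 * eps)
            assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-5)

    def test_unmapped_image_rejected(self):
        from shade import HierarchyMap
        cfg = SimulationConfig(n_patients=1, images_per_patient=1,
                               window_size=500.0, expected_source=10,
                               expected_target=5, seed=5)
        patterns, hier, _ = simulate_study(cfg)
        with pytest.raises(Exception):
            SHADEModel.from_patterns(patterns, HierarchyMap({}, {}), "T",
                                     ("tumor",), basis=cfg.basis)


class TestDegenerateHierarchy:
    def test_levels_agree_for_single_image_study(self, single_image_fit):
        """With one cohort = one patient = one image the variance components
        are unidentified, so the posterior splits the image-level signal
        across levels: adjacent levels agree within one posterior SD and the
        level means are monotonically ordered between the prior zero and the
        image-level estimate."""
        res = single_image_fit
        grid = np.arange(0.0, 151.0, 5.0)
        curves = {lev: res.sic_draws(lev, grid=grid)
                  for lev in ("cohort", "patient", "image")}
        for hi, lo in (("cohort", "patient"), ("patient", "image")):
            gap = np.abs(curves[hi].mean(axis=0) - curves[lo].mean(axis=0))
            assert np.all(gap <= curves[hi].std(axis=0) + 0.05)
        # shrinkage ordering at the peak of the image-level curve
        img_mean = curves["image"].mean(axis=0)
        peak = int(np.argmax(np.abs(img_mean)))
        s = np.sign(img_mean[peak])
        assert 0.0 <= s * curves["cohort"].mean(axis=0)[peak] \
            <= s * curves["patient"].mean(axis=0)[peak] \
            <= s * img_mean[peak]

    def test_flat_fit_agrees_with_degenerate_hierarchical(
            self, single_image_setup, single_image_fit):
        _, model, _ = single_image_setup
        flat = FlatSICModel(model.datasets[0], model.basis).fit(
            draws=400, warmup=500, chains=2, seed=11)
        hier_mean = single_image_fit.coefficient_draws("image").mean(axis=0)
        flat_mean = flat.coefficient_draws().mean(axis=0)
        assert np.abs(hier_mean - flat_mean).max() < 0.35

    def test_prior_domination_shrinks_sics_to_zero(self, single_image_setup):
        cfg, model, hier = single_image_setup
        tight = PriorConfig(sigma_cohort_scale=1e-3, sigma_patient_scale=1e-3,
                            sigma_image_scale=1e-3)
        m2 = SHADEModel(model.datasets, hier, model.basis, priors=tight)
        res = m2.fit(draws=300, warmup=400, chains=2, seed=13)
        post_mean = res.coefficient_draws("image").mean(axis=0)
        assert np.abs(post_mean).max() < 0.05


class TestNoLikelihoodLimit:
    def test_empty_image_posterior_close_to_prior(self):
        """An image with zero target cells keeps the prior's width on the
        interaction coefficients; the zero counts exert only a weak
        (negative, sub-prior-SD) pull through the dummy rows."""
        from conftest import random_pattern
        from shade import ObservationWindow, build_logistic_dataset
        from shade.basis import BasisSystem

        basis = BasisSystem()
        window = ObservationWindow(0, 800, 0, 800)
        rng = np.random.default_rng(21)
        pat = random_pattern(rng, window, {"T": 0, "tumor": 60})
        ds = build_logistic_dataset(pat, "T", ("tumor",), basis, seed=2)
        flat = FlatSICModel(ds, basis).fit(draws=600, warmup=500, chains=2,
                                           seed=3)
        draws = flat.coefficient_draws()
        prior_sd = flat.model.priors.flat_scale
        # prior is N(0, flat_scale^2)
        assert np.abs(draws.mean(axis=0)).max() < prior_sd
        assert np.all(draws.std(axis=0) > 0.5 * prior_sd)
        assert np.all(draws.std(axis=0) < 1.5 * prior_sd)


class TestShrinkage:
    def test_hierarchical_image_estimates_less_dispersed_than_flat(self):
        cfg = SimulationConfig(n_patients=2, images_per_patient=3,
                               expected_source=100, expected_target=20,
                               sigma_patient=0.2, sigma_image=0.2, seed=31)
        patterns, hier, _ = simulate_study(cfg)
        model = SHADEModel.from_patterns(patterns, hier, "T", ("tumor",),
                                         basis=cfg.basis, seed=2)
        res = model.fit(draws=300, warmup=400, chains=2, seed=5)
        grid = np.arange(25.0, 150.0, 5.0)
        hier_curves = np.array([res.sic_draws("image", m, grid=grid).mean(axis=0)
                                for m in model.image_ids])
        flat_curves = []
        for i, ds in enumerate(model.datasets):
            f = FlatSICModel(ds, model.basis).fit(draws=300, warmup=400,
                                                  chains=2, seed=100 + i)
            flat_curves.append(f.sic_draws(grid=grid).mean(axis=0))
        flat_curves = np.array(flat_curves)
        assert hier_curves.var(axis=0).mean() <= flat_curves.var(axis=0).mean()


class TestResultsInterface:
    def test_summary_table_and_save(self, single_image_fit, tmp_path):
        df = single_image_fit.summary()
        assert {"peak_distance_um", "persistence", "detected"} <= set(df.columns)
        single_image_fit.save(tmp_path / "draws.csv", tmp_path / "diag.json")
        import json
        diag = json.loads((tmp_path / "diag.json").read_text())
        assert "max_rhat_sic" in diag
        import pandas as pd
        draws = pd.read_csv(tmp_path / "draws.csv")
        assert {"chain", "draw", "parameter", "value"} <= set(draws.columns)

    def test_unknown_unit_rejected(self, single_image_fit):
        with pytest.raises(KeyError):
            single_image_fit.sic_draws("patient", "nope")


class TestCovariatePath:
    def test_binary_covariate_effect_recovered(self):
        """A known binary covariate doubling-plus the target intensity on
        half the window is recovered by the shared covariate coefficient."""
        from shade import HierarchyMap, MultitypePattern, ObservationWindow
        from shade.basis import BasisSystem

        basis = BasisSystem()
        win = ObservationWindow(0, 1000, 0, 1000)
        rng = np.random.default_rng(61)
        # piecewise-homogeneous targets: lam_right = e * lam_left
        lam_left = 150 / 500000.0
        n_l = rng.poisson(lam_left * 500000)
        n_r = rng.poisson(np.e * lam_left * 500000)
        pts = np.vstack([
            np.column_stack([rng.uniform(0, 500, n_l), rng.uniform(0, 1000, n_l)]),
            np.column_stack([rng.uniform(500, 1000, n_r), rng.uniform(0, 1000, n_r)]),
            np.column_stack([rng.uniform(0, 1000, 30), rng.uniform(0, 1000, 30)]),
        ])
        types = np.array(["T"] * (n_l + n_r) + ["tumor"] * 30, dtype=object)
        pat = MultitypePattern(pts, types, win, image_id="m0",
                               labels=("T", "tumor"))
        hier = HierarchyMap({"m0": "p0"}, {"p0": "c0"})
        model = SHADEModel.from_patterns(
            [pat], hier, "T", ("tumor",), basis=basis, seed=3,
            extra_covariates=lambda locs: (locs[:, :1] > 500).astype(float),
            covariate_names=("right_half",))
        res = model.fit(draws=400, warmup=500, chains=2, seed=9)
        beta = res.posterior["beta"].reshape(-1)
        assert abs(beta.mean() - 1.0) < max(3 * beta.std(), 0.3)


class TestQuadratureConvergence:
    def test_logistic_mle_approaches_grid_poisson_mle(self):
        """On one fixed image, the logistic-approximation MLE converges to
        the Berman-Turner grid-quadrature Poisson MLE as the dummy
        intensity grows (2x, 4x, 8x the target density)."""
        from scipy.optimize import minimize

        from shade import ObservationWindow, build_logistic_dataset, sample_dummy_points
        from shade.basis import BasisSystem
        from shade.quadrature import interaction_features
        from shade.simulate import bump_coefficients, simulate_source, simulate_target

        basis = BasisSystem(P=4)
        win = ObservationWindow(0, 1000, 0, 1000)
        src = {"tumor": simulate_source(win, 100, seed=71, image_id="m")}
        delta = {"tumor": bump_coefficients(basis, height=0.8)}
        beta0 = np.log(200 / win.area)
        tgt = simulate_target(src, delta, basis, beta0, win, seed=72,
                              grid_res=96, image_id="m")
        pts = np.vstack([src["tumor"].points, tgt.points])
        types = np.concatenate([src["tumor"].types, tgt.types])
        from shade import MultitypePattern
        pat = MultitypePattern(pts, types, win, image_id="m",
                               labels=("T", "tumor"))

        # Berman-Turner oracle: Poisson MLE on a quadrature grid
        res_g = 50
        gx = np.linspace(0, 1000, res_g + 1)[:-1] + 10.0
        mesh = np.column_stack([np.repeat(gx, res_g), np.tile(gx, res_g)])
        w = win.area / mesh.shape[0]
        Q_data = interaction_features(tgt.points, src["tumor"], basis)
        Q_grid = interaction_features(mesh, src["tumor"], basis)

        def poisson_nll(par):
            eta_d = par[0] + Q_data @ par[1:]
            eta_g = par[0] + Q_grid @ par[1:]
            return -(np.sum(eta_d) - w * np.sum(np.exp(eta_g)))

        x0 = np.zeros(basis.P + 1)
        x0[0] = beta0
        ref = minimize(poisson_nll, x0, method="BFGS").x

        dens = len(tgt) / win.area
        gaps = []
        for mult in (2.0, 4.0, 8.0):
            ests = []
            for s in range(16):  # average out dummy-placement noise
                quad = sample_dummy_points(win, mult * dens, seed=900 + 10 * s + int(mult))
                ds = build_logistic_dataset(pat, "T", ("tumor",), basis, quad)
                X = ds.features["tumor"]
                y = ds.y.astype(float)

                def logistic_nll(par):
                    eta = par[0] + ds.offset + X @ par[1:]
                    return -(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))

                ests.append(minimize(logistic_nll, x0, method="BFGS").x)
            # expected coefficient-norm gap to the grid-quadrature MLE
            gaps.append(np.mean([np.linalg.norm(e - ref) for e in ests]))
        assert gaps[0] > gaps[1] > gaps[2]
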