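"""The multilevel REML fit and its post-fit summaries."""

import math

import numpy as np
import pytest
from scipy import stats

from matemeta import meta_model as mm
from matemeta.meta_model import (ModelSpec, RandomLevel, build_model,
                                 fit_reml, marginal_r2, pairwise_posthoc,
                                 prediction_interval, qm_test, reml_loglik)
from matemeta.synthetic_data import SimulationTruth, simulate_dataset
from matemeta.validation import brute_force_reml_loglik, random_fixture


def spec_without_random(y, v, X=None):
    y = np.asarray(y, float)
    X = np.ones((len(y), 1)) if X is None else X
    return ModelSpec(y=y, v=np.asarray(v, float), X=X,
                     colnames=[f"b{i}" for i in range(X.shape[1])],
                     random_levels=[], include_intercept=True)


class TestFitClosedForms:
    def test_inverse_variance_mean(self):
        """No random effects: fit is the inverse-variance weighted mean."""
        spec = spec_without_random([0.1, 0.3], [0.01, 0.01])
        fit = fit_reml(spec)
        assert fit.beta[0] == pytest.approx(0.2, abs=1e-12)
        assert fit.se[0] == pytest.approx(math.sqrt(1 / 200), abs=1e-12)

    def test_single_component_matches_grid_search(self, rng):
        """REML sigma2 for one random level agrees with a 1-D grid search."""
        k = 10
        v = rng.uniform(0.02, 0.08, k)
        y = 0.2 + rng.standard_normal(k) * np.sqrt(v + 0.05)
        spec = ModelSpec(y=y, v=v, X=np.ones((k, 1)), colnames=["intercept"],
                         random_levels=[RandomLevel("observation", np.eye(k))],
                         include_intercept=True)
        fit = fit_reml(spec)
        grid = np.linspace(0, 0.5, 50_001)
        lls = [reml_loglik(spec, [s2]) for s2 in grid]
        s2_grid = grid[int(np.argmax(lls))]
        assert fit.sigma2["observation"] == pytest.approx(s2_grid, abs=1e-3)

    def test_loglik_matches_brute_force_dense(self, rng):
        """Cholesky-based loglik equals the explicit inv/slogdet formula."""
        for i in range(5):
            spec = random_fixture(rng, k=12, with_phylo=bool(i % 2))
            structures = [lv.matrix for lv in spec.random_levels]
            for s2 in ([0.0, 0.0], [0.05, 0.02], [0.3, 0.001]):
                ll = reml_loglik(spec, s2)
                bf = brute_force_reml_loglik(spec.y, spec.v, spec.X,
                                             structures, s2)
                assert ll == pytest.approx(bf, abs=1e-8)

    def test_observation_component_confounded_with_v_shift(self, rng):
        """Moving mass c between diag(v) and sigma2_obs leaves V unchanged."""
        spec = random_fixture(rng, k=10)
        c = 0.005
        shifted = ModelSpec(y=spec.y, v=spec.v + c, X=spec.X,
                            colnames=spec.colnames,
                            random_levels=spec.random_levels,
                            include_intercept=True)
        ll1 = reml_loglik(spec, [0.03, 0.04])
        ll2 = reml_loglik(shifted, [0.03, 0.04 - c])
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_zero_variance_gradient_at_wls_solution(self):
        """At sigma2 = 0 the GLS estimate solves weighted least squares."""
        y = np.array([0.1, 0.25, 0.4, 0.05])
        v = np.array([0.01, 0.02, 0.05, 0.04])
        spec = spec_without_random(y, v)
        fit = fit_reml(spec)
        w = 1 / v
        assert fit.beta[0] == pytest.approx(np.sum(w * y) / np.sum(w), abs=1e-12)

    def test_row_permutation_invariance(self):
        truth = SimulationTruth(seed=21, n_species=10, n_studies=20)
        ds, _ = simulate_dataset(truth)
        fit1 = fit_reml(build_model(ds))
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.k)
        ds_shuffled = type(ds)([ds.effects[i] for i in perm], ds.tree,
                               ds.variant, ds.correlation)
        spec2 = build_model(ds_shuffled)
        fit2 = fit_reml(spec2)
        # the likelihood itself is permutation-invariant to float precision
        s2 = [0.02, 0.01, 0.03, 0.04]
        assert reml_loglik(build_model(ds), s2) == pytest.approx(
            reml_loglik(spec2, s2), abs=1e-10)
        # estimates agree to optimizer precision
        assert fit1.beta[0] == pytest.approx(fit2.beta[0], abs=1e-8)
        for name in ("phylogeny", "species", "study", "observation"):
            assert fit1.sigma2[name] == pytest.approx(fit2.sigma2[name],
                                                      abs=1e-6)

    def test_two_level_closed_form_iteration(self, rng):
        """One random level: agrees with the classic REML fixed-point update

        tau2 = sum(w^2 ((y-mu)^2 - v)) / sum(w^2) iterated to convergence,
        with w = 1/(v + tau2).
        """
        k = 40
        v = rng.uniform(0.01, 0.05, k)
        y = 0.15 + rng.standard_normal(k) * np.sqrt(v + 0.03)
        spec = ModelSpec(y=y, v=v, X=np.ones((k, 1)), colnames=["intercept"],
                         random_levels=[RandomLevel("observation", np.eye(k))],
                         include_intercept=True)
        fit = fit_reml(spec)
        tau2 = 0.01
        for _ in range(2000):
            w = 1 / (v + tau2)
            mu = np.sum(w * y) / np.sum(w)
            # REML fixed point (Paule-Mandel flavoured with REML correction)
            num = np.sum(w**2 * ((y - mu) ** 2 - v)) + np.sum(w**2) / np.sum(w)
            tau2_new = max(num / np.sum(w**2), 0.0) - 0.0
            tau2_new = num / np.sum(w**2)
            if abs(tau2_new - tau2) < 1e-14:
                tau2 = tau2_new
                break
            tau2 = tau2_new
        assert fit.sigma2["observation"] == pytest.approx(tau2, abs=5e-4)


class TestBuildModel:
    def test_intercept_only_design(self, default_dataset):
        _, ds, _ = default_dataset
        spec = build_model(ds)
        assert spec.X.shape == (ds.k, 1)
        assert np.all(spec.X == 1.0)

    def test_small_levels_dropped_with_intercept(self, default_dataset):
        _, ds, _ = default_dataset
        # craft counts: rename a handful of effects to a rare level
        effects = list(ds.effects)
        rare = [e for e in effects[:9]]
        for i, e in enumerate(rare):
            effects[i] = type(e)(**{**e.__dict__, "taxonomic_group": "rare_taxon"})
        for i, e in enumerate(effects[9:], start=9):
            effects[i] = type(e)(**{**e.__dict__, "taxonomic_group":
                                    "common_a" if i % 2 else "common_b"})
        ds2 = type(ds)(effects, ds.tree, ds.variant, ds.correlation)
        spec = build_model(ds2, moderator="taxonomic_group")
        assert spec.n_dropped == 9
        assert spec.X.shape[1] == 2  # intercept + 1 dummy
        spec_no = build_model(ds2, moderator="taxonomic_group",
                              include_intercept=False)
        assert spec_no.n_dropped == 0
        assert spec_no.X.shape[1] == 3  # one indicator per level, all kept

    def test_single_level_moderator_degenerate(self, default_dataset):
        _, ds, _ = default_dataset
        with pytest.raises(ValueError, match="fewer than 2 levels"):
            build_model(ds, moderator="sex")  # all female in the simulation


class TestPredictionInterval:
    def test_equals_ci_when_no_heterogeneity(self):
        spec = spec_without_random([0.1, 0.3, 0.2], [0.01, 0.02, 0.01])
        fit = fit_reml(spec)
        assert prediction_interval(fit) == pytest.approx(fit.ci_r, abs=1e-12)

    def test_formula_oracle(self, default_fit):
        fit = default_fit
        half = 1.959963984540054 * math.sqrt(fit.se[0] ** 2 + fit.sigma2.total)
        lo, hi = prediction_interval(fit)
        assert lo == pytest.approx(math.tanh(fit.beta[0] - half), abs=1e-12)
        assert hi == pytest.approx(math.tanh(fit.beta[0] + half), abs=1e-12)

    def test_contains_ci_and_widens_with_variance(self, default_fit):
        lo_pi, hi_pi = default_fit.pi_r
        lo_ci, hi_ci = default_fit.ci_r
        assert lo_pi < lo_ci and hi_pi > hi_ci


@pytest.fixture(scope="module")
def moderated_fit():
    truth = SimulationTruth(
        seed=5, n_species=10, n_studies=40, effects_per_study=3,
        moderator_effects={"age": 0.0, "body_size": 0.3, "condition": -0.1},
        sigma2_phylo=0.0, sigma2_species=0.0,
    )
    ds, _ = simulate_dataset(truth)
    spec = build_model(ds, moderator="state_factor",
                       random_levels=("study", "observation"))
    return fit_reml(spec)


class TestQmAndR2:
    def test_qm_z_identity_single_coefficient(self, moderated_fit):
        qm, df, p = qm_test(moderated_fit, tested=[1])
        z = moderated_fit.zval[1]
        assert qm == pytest.approx(z * z, abs=1e-12)
        assert df == 1

    def test_qm_detects_real_moderator(self, moderated_fit):
        qm, df, p = qm_test(moderated_fit)
        assert df == 2
        assert p < 0.01

    def test_qm_near_zero_for_identical_levels(self):
        # noiseless-ish: equal level means, tiny variances
        k = 30
        y = np.full(k, 0.2)
        v = np.full(k, 0.01)
        X = np.column_stack([np.ones(k),
                             (np.arange(k) % 3 == 1).astype(float),
                             (np.arange(k) % 3 == 2).astype(float)])
        spec = ModelSpec(y=y, v=v, X=X, colnames=["intercept", "m[b]", "m[c]"],
                         random_levels=[], include_intercept=True)
        fit = fit_reml(spec)
        qm, df, p = qm_test(fit)
        assert qm == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_marginal_r2_zero_when_level_means_equal(self):
        k = 30
        rngl = np.random.default_rng(4)
        v = np.full(k, 0.01)
        y = 0.2 + rngl.standard_normal(k) * 0.15
        X = np.column_stack([np.ones(k),
                             (np.arange(k) % 2).astype(float)])
        spec = ModelSpec(y=y, v=v, X=X, colnames=["intercept", "m[b]"],
                         random_levels=[RandomLevel("observation", np.eye(k))],
                         include_intercept=True)
        fit = fit_reml(spec)
        fit_zero_spread = mm.MetaFit(
            beta=np.array([0.2, 0.0]), beta_cov=fit.beta_cov,
            colnames=fit.colnames, sigma2=fit.sigma2,
            reml_loglik=fit.reml_loglik, k=fit.k, spec=spec)
        assert marginal_r2(fit_zero_spread) == pytest.approx(0.0, abs=1e-15)

    def test_marginal_r2_formula_oracle(self, moderated_fit):
        fit = moderated_fit
        fitted = fit.spec.X @ fit.beta
        expect = np.var(fitted, ddof=1) / (np.var(fitted, ddof=1)
                                           + fit.sigma2.total)
        assert marginal_r2(fit) == pytest.approx(expect, abs=1e-12)
        assert 0.0 <= marginal_r2(fit) <= 1.0

    def test_marginal_r2_near_one_when_no_heterogeneity(self):
        k = 40
        grp = (np.arange(k) % 2).astype(float)
        y = 0.1 + 0.5 * grp
        v = np.full(k, 0.005)
        X = np.column_stack([np.ones(k), grp])
        spec = ModelSpec(y=y, v=v, X=X, colnames=["intercept", "m[b]"],
                         random_levels=[RandomLevel("observation", np.eye(k))],
                         include_intercept=True)
        fit = fit_reml(spec)
        assert marginal_r2(fit) > 0.99


class TestPosthoc:
    def test_identical_levels_give_z_zero_p_one(self):
        k = 40
        grp = np.arange(k) % 2
        y = np.where(grp == 0, 0.2, 0.2)
        v = np.full(k, 0.01)
        X = np.column_stack([(grp == 0).astype(float), (grp == 1).astype(float)])
        spec = ModelSpec(y=y, v=v, X=X, colnames=["m[a]", "m[b]"],
                         random_levels=[], include_intercept=False,
                         level_counts={"a": 20, "b": 20})
        fit = fit_reml(spec)
        contrasts = pairwise_posthoc(fit)
        assert len(contrasts) == 1
        _, _, z, p = contrasts[0]
        assert z == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_number_of_contrasts(self):
        k = 100
        grp = np.arange(k) % 5
        rngl = np.random.default_rng(8)
        y = 0.1 * grp + rngl.standard_normal(k) * 0.1
        v = np.full(k, 0.01)
        X = np.column_stack([(grp == g).astype(float) for g in range(5)])
        spec = ModelSpec(y=y, v=v, X=X,
                         colnames=[f"m[{g}]" for g in range(5)],
                         random_levels=[RandomLevel("observation", np.eye(k))],
                         include_intercept=False,
                         level_counts={str(g): 20 for g in range(5)})
        fit = fit_reml(spec)
        assert len(pairwise_posthoc(fit)) == 10

    def test_holm_adjustment_matches_stepdown_oracle(self, rng):
        """Holm p-values equal the brute-force sorted step-down computation."""
        pvals = rng.uniform(0, 1, 10)
        from statsmodels.stats.multitest import multipletests
        adj = multipletests(pvals, method="holm")[1]
        # brute force: sort, multiply by (m - rank), running max, cap at 1
        order = np.argsort(pvals)
        m = len(pvals)
        expect = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            expect[idx] = min(running, 1.0)
        assert np.allclose(adj, expect, atol=1e-12)


class TestMetaforCrossCheck:
    def test_fit_matches_rma_mv(self, tmp_path, default_dataset):
        """Independent oracle: metafor's rma.mv on the same data and tree."""
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        import pandas as pd
        _, ds, _ = default_dataset
        df = pd.DataFrame({
            "zr": [e.zr for e in ds.effects],
            "v": [e.v for e in ds.effects],
            "species": [e.species for e in ds.effects],
            "study": [e.study_id for e in ds.effects],
            "obs": [e.record_id for e in ds.effects]})
        df["phylo"] = df["species"]
        df.to_csv(tmp_path / "d.csv", index=False)
        c = ds.correlation
        pd.DataFrame(c.matrix, index=c.labels, columns=c.labels) \
            .to_csv(tmp_path / "A.csv")
        script = tmp_path / "fit.R"
        script.write_text(
            'suppressMessages(library(metafor))\n'
            f'df <- read.csv("{tmp_path}/d.csv")\n'
            f'A <- as.matrix(read.csv("{tmp_path}/A.csv", row.names=1,'
            ' check.names=FALSE))\n'
            'res <- rma.mv(zr, v, random = list(~1|phylo, ~1|species,'
            ' ~1|study, ~1|obs), R = list(phylo = A), data = df,'
            ' method = "REML")\n'
            'cat(res$b, res$se, res$sigma2, sep="\\n")\n')
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        vals = [float(x) for x in out.stdout.strip().splitlines()]
        fit = fit_reml(build_model(ds))
        assert fit.beta[0] == pytest.approx(vals[0], abs=2e-4)
        assert fit.se[0] == pytest.approx(vals[1], rel=2e-3)
        for got, want in zip(
                [fit.sigma2[n] for n in ("phylogeny", "species", "study",
                                         "observation")], vals[2:6]):
            assert got == pytest.approx(want, abs=2e-4)
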