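"""Self-contained validation studies for the multilevel REML machinery.

Three studies back the package's correctness claims:

* :func:`run_oracle_check` — on small random fixtures, an independent dense
  brute-force REML implementation (explicit inverses and determinants,
  simplex optimization on the standard-deviation scale) must agree with
  :func:`matemeta.meta_model.fit_reml`;
* :func:`run_recovery_study` — repeated simulation at the generator's default
  design scores bias of the grand mean, CI coverage, and variance-component
  recovery;
* :func:`run_qm_calibration` — the omnibus moderator test is simulated under
  the null and its rejection rate compared with the nominal level.

The brute-force oracle deliberately shares no code with the production fit:
different linear algebra (``inv``/``slogdet`` instead of Cholesky solves),
a different parametrization (sigma, not log sigma^2), and a different
optimizer path (Nelder-Mead only, no gradients).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats

from .meta_model import (ModelSpec, RandomLevel, build_model, fit_reml,
                         qm_test)
from .synthetic_data import SimulationTruth, simulate_dataset, simulate_tree
from .phylogeny import brownian_correlation

__all__ = [
    "brute_force_reml_loglik",
    "brute_force_fit",
    "random_fixture",
    "run_oracle_check",
    "run_recovery_study",
    "run_qm_calibration",
]


# ---------------------------------------------------------------------------
# Brute-force oracle

def brute_force_reml_loglik(y, v, X, structures, sigma2) -> float:
    """REML log-likelihood from the textbook formula, dense and explicit."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    V = np.diag(np.asarray(v, float))
    for s2, M in zip(sigma2, structures):
        V = V + s2 * M
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    resid = y - X @ beta
    _, logdet_V = np.linalg.slogdet(V)
    _, logdet_XtViX = np.linalg.slogdet(XtViX)
    return -0.5 * (logdet_V + logdet_XtViX + float(resid @ Vi @ resid))


def brute_force_fit(y, v, X, structures):
    """Simplex REML fit on the sigma (SD) scale; returns (beta, sigma2, ll).

    Multi-start Nelder-Mead over sigma with sigma^2 = x^2 (so the boundary
    at zero is reachable), followed by GLS for the fixed effects.
    """
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    X = np.asarray(X, float)
    L = len(structures)

    def neg_ll(x):
        return -brute_force_reml_loglik(y, v, X, structures, x * x)

    tau = max(float(np.var(y, ddof=1) - np.mean(v)), 1e-4)
    starts = [np.full(L, np.sqrt(tau / L)), np.full(L, 1e-4),
              np.full(L, np.sqrt(tau)), np.full(L, 0.3)]
    best = None
    for x0 in starts:
        res = optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                                options=dict(xatol=1e-10, fatol=1e-12,
                                             maxiter=6000, maxfev=12000))
        if best is None or res.fun < best.fun:
            best = res
    sigma2 = best.x**2
    sigma2[sigma2 < 1e-12] = 0.0
    V = np.diag(v)
    for s2, M in zip(sigma2, structures):
        V = V + s2 * M
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    return beta, sigma2, -best.fun


# ---------------------------------------------------------------------------
# Random small fixtures

def random_fixture(rng: np.random.Generator, k: int | None = None,
                   with_phylo: bool = False) -> ModelSpec:
    """A small random two-component fixture (study+obs, or phylo+obs)."""
    if k is None:
        k = int(rng.integers(8, 16))
    v = rng.uniform(0.01, 0.1, k)
    if with_phylo:
        n_sp = max(3, k // 3)
        tree = simulate_tree(n_sp, rng.integers(2**31))
        A = brownian_correlation(tree).matrix
        sp = rng.integers(0, n_sp, k)
        M1 = A[np.ix_(sp, sp)]
        name1 = "phylogeny"
        u = np.linalg.cholesky(A + 1e-12 * np.eye(n_sp)) @ rng.standard_normal(n_sp)
        group_effect = 0.15 * u[sp]
    else:
        n_st = max(3, k // 3)
        st = rng.integers(0, n_st, k)
        M1 = (st[:, None] == st[None, :]).astype(float)
        name1 = "study"
        group_effect = 0.15 * rng.standard_normal(n_st)[st]
    y = (0.2 + group_effect + 0.2 * rng.standard_normal(k)
         + rng.standard_normal(k) * np.sqrt(v))
    X = np.ones((k, 1))
    levels = [RandomLevel(name1, M1), RandomLevel("observation", np.eye(k))]
    return ModelSpec(y=y, v=v, X=X, colnames=["intercept"],
                     random_levels=levels, include_intercept=True)


def run_oracle_check(seed: int, n_fixtures: int = 20) -> dict:
    """Max |Δbeta| and |Δsigma2| between fit_reml and the brute-force oracle."""
    rng = np.random.default_rng(seed)
    max_dbeta = 0.0
    max_dsigma2 = 0.0
    for i in range(n_fixtures):
        spec = random_fixture(rng, with_phylo=bool(i % 2))
        fit = fit_reml(spec)
        structures = [lv.matrix for lv in spec.random_levels]
        b_beta, b_sigma2, _ = brute_force_fit(spec.y, spec.v, spec.X, structures)
        s2 = np.array([fit.sigma2[lv.name] for lv in spec.random_levels])
        max_dbeta = max(max_dbeta, float(np.max(np.abs(fit.beta - b_beta))))
        max_dsigma2 = max(max_dsigma2, float(np.max(np.abs(s2 - b_sigma2))))
    return {"n_fixtures": n_fixtures, "max_abs_dbeta": max_dbeta,
            "max_abs_dsigma2": max_dsigma2}


# ---------------------------------------------------------------------------
# Parameter recovery

def run_recovery_study(seed: int, n_reps: int = 200,
                       truth: SimulationTruth | None = None) -> dict:
    """Repeated-simulation recovery of the grand mean and variance components.

    Each replicate draws a fresh tree and dataset at ``truth`` (default: the
    generator's standard recovery design, true grand mean 0.1 Zr), fits the
    intercept-only four-level model, and scores the estimate against truth.
    """
    base = truth or SimulationTruth()
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31, n_reps)
    betas, covered = [], []
    s2_names = ("phylogeny", "species", "study", "observation")
    s2_rows = []
    for rs in rep_seeds:
        t = SimulationTruth(**{**_truth_kwargs(base), "seed": int(rs)})
        ds, _ = simulate_dataset(t)
        fit = fit_reml(build_model(ds))
        betas.append(float(fit.beta[0]))
        lo, hi = fit.ci_zr()[0]
        covered.append(lo <= base.beta0 <= hi)
        s2_rows.append([fit.sigma2[nm] for nm in s2_names])
    betas = np.asarray(betas)
    s2 = np.asarray(s2_rows)
    truth_s2 = [base.sigma2[nm] for nm in s2_names]
    return {
        "n_reps": n_reps,
        "beta0_true": base.beta0,
        "beta0_mean": float(betas.mean()),
        "beta0_bias": float(betas.mean() - base.beta0),
        "beta0_mc_sem": float(betas.std(ddof=1) / np.sqrt(n_reps)),
        "ci_coverage": float(np.mean(covered)),
        "sigma2_true": dict(zip(s2_names, truth_s2)),
        "sigma2_mean": dict(zip(s2_names, s2.mean(axis=0))),
        "sigma2_mc_sem": dict(zip(s2_names, s2.std(axis=0, ddof=1) / np.sqrt(n_reps))),
    }


def _truth_kwargs(t: SimulationTruth) -> dict:
    from dataclasses import asdict
    return asdict(t)


# ---------------------------------------------------------------------------
# QM null calibration

#: Null-moderator calibration design: three moderator levels with no effect,
#: 60 studies x 2 effects, study + observation heterogeneity only, n in
#: 40..200.  Large enough per level (expected 40) for the chi-square
#: approximation to be the thing under test rather than small-sample noise.
QM_NULL_TRUTH = dict(
    n_species=10, n_studies=60, effects_per_study=2,
    moderator_effects={"age": 0.0, "body_size": 0.0, "condition": 0.0},
    sigma2_phylo=0.0, sigma2_species=0.0, sigma2_study=0.03, sigma2_obs=0.04,
    n_range=(40, 200),
)


def run_qm_calibration(seed: int, n_reps: int = 2000, alpha: float = 0.05) -> dict:
    """Type-I error of the omnibus moderator (QM) test under the null."""
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31, n_reps)
    pvals = []
    for rs in rep_seeds:
        truth = SimulationTruth(seed=int(rs), **QM_NULL_TRUTH)
        ds, _ = simulate_dataset(truth)
        spec = build_model(ds, moderator="state_factor",
                           random_levels=("study", "observation"))
        _, _, p = qm_test(fit_reml(spec))
        pvals.append(p)
    pvals = np.asarray(pvals)
    return {
        "n_reps": n_reps,
        "alpha": alpha,
        "rejection_rate": float(np.mean(pvals < alpha)),
        "ks_uniform_p": float(stats.kstest(pvals, "uniform").pvalue),
    }
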