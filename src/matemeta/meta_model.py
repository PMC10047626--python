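"""Multilevel random-effects meta-analysis fitted by REML.

The observed Fisher-Z effects y_i are modelled as

    y = X beta + u_phylo + u_species + u_study + e_obs + m,

with m_i ~ N(0, v_i) the known sampling errors, and the marginal covariance

    V = s2_phylo * A  +  s2_species * S  +  s2_study * T  +  s2_obs * I  + diag(v),

where A expands the Brownian phylogenetic correlation matrix to effects,
S and T are same-species / same-study indicator blocks, and I the identity
(the observation-level component required to estimate residual
heterogeneity).  Variance components maximize the restricted likelihood

    l_R = -1/2 [ log|V| + log|X' V^-1 X| + (y - Xb)' V^-1 (y - Xb) ],

optimized on the log-variance scale with multiple starts; estimates pinned
below 1e-12 are reported as exactly 0.  Fixed effects are the GLS solution
at the REML variances, with Wald-z confidence intervals by default.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_solve
from statsmodels.stats.multitest import multipletests

from .data_io import Dataset
from .phylogeny import normalize_label

logger = logging.getLogger("matemeta.meta_model")

__all__ = [
    "DEFAULT_RANDOM_LEVELS",
    "RandomLevel",
    "ModelSpec",
    "VarianceComponents",
    "MetaFit",
    "ModeratorResult",
    "ConvergenceError",
    "build_model",
    "build_custom_model",
    "random_structures",
    "reml_loglik",
    "fit_reml",
    "prediction_interval",
    "qm_test",
    "marginal_r2",
    "pairwise_posthoc",
    "moderator_analysis",
]

DEFAULT_RANDOM_LEVELS = ("phylogeny", "species", "study", "observation")
MIN_LEVEL_K = 10          # categorical levels below this are excluded from QM fits
BOUNDARY_PIN = 1e-12      # variance estimates below this are reported as 0
CONVERGENCE_FTOL = 1e-10


class ConvergenceError(RuntimeError):
    """REML optimization failed to converge; carries the best candidate."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class RandomLevel:
    """One random factor: a name and its k×k unit-variance structure matrix."""

    name: str
    matrix: np.ndarray


@dataclass
class ModelSpec:
    """A fully materialized design: response, weights, X, random structures."""

    y: np.ndarray
    v: np.ndarray
    X: np.ndarray
    colnames: list[str]
    random_levels: list[RandomLevel]
    include_intercept: bool
    moderator: str | None = None
    level_counts: dict[str, int] = field(default_factory=dict)
    n_dropped: int = 0
    effects: list = field(default_factory=list)

    def __post_init__(self) -> None:
        k, p = self.X.shape
        if np.linalg.matrix_rank(self.X) < p:
            raise ValueError("fixed design is rank deficient")
        if np.any(self.v <= 0):
            raise ValueError("all sampling variances must be positive")
        for lv in self.random_levels:
            if lv.matrix.shape != (k, k):
                raise ValueError(f"random structure {lv.name} has wrong shape")

    @property
    def k(self) -> int:
        return self.X.shape[0]


@dataclass
class VarianceComponents:
    """REML variance components on the Zr scale, keyed by level name."""

    components: dict[str, float]

    def __post_init__(self) -> None:
        for name, val in self.components.items():
            if val < 0:
                raise ValueError(f"sigma2[{name}] must be >= 0")

    def __getitem__(self, name: str) -> float:
        return self.components.get(name, 0.0)

    @property
    def sigma2_phylo(self) -> float:
        return self["phylogeny"]

    @property
    def sigma2_species(self) -> float:
        return self["species"]

    @property
    def sigma2_study(self) -> float:
        return self["study"]

    @property
    def sigma2_obs(self) -> float:
        return self["observation"]

    @property
    def total(self) -> float:
        return float(sum(self.components.values()))


@dataclass
class MetaFit:
    """Fixed-effect estimates, their covariance, and the REML components."""

    beta: np.ndarray
    beta_cov: np.ndarray
    colnames: list[str]
    sigma2: VarianceComponents
    reml_loglik: float
    k: int
    spec: ModelSpec
    ci_level: float = 0.95
    crit: str = "z"

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.beta_cov))

    @property
    def zval(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def pval(self) -> np.ndarray:
        if self.crit == "t":
            df = self.k - len(self.beta)
            return 2 * stats.t.sf(np.abs(self.zval), df)
        return 2 * stats.norm.sf(np.abs(self.zval))

    @property
    def _crit_value(self) -> float:
        alpha = 1 - self.ci_level
        if self.crit == "t":
            return float(stats.t.ppf(1 - alpha / 2, self.k - len(self.beta)))
        return float(stats.norm.ppf(1 - alpha / 2))

    def ci_zr(self) -> np.ndarray:
        c = self._crit_value
        return np.column_stack([self.beta - c * self.se, self.beta + c * self.se])

    # Intercept-only summaries on the correlation scale
    @property
    def mean_zr(self) -> float:
        return float(self.beta[0])

    @property
    def mean_r(self) -> float:
        return math.tanh(self.mean_zr)

    @property
    def ci_r(self) -> tuple[float, float]:
        lo, hi = self.ci_zr()[0]
        return (math.tanh(lo), math.tanh(hi))

    @property
    def pi_r(self) -> tuple[float, float]:
        return prediction_interval(self)

    def significant(self, index: int = 0) -> bool:
        lo, hi = self.ci_zr()[index]
        return not (lo <= 0.0 <= hi)


# ---------------------------------------------------------------------------
# Design construction

def random_structures(effects, correlation, levels=DEFAULT_RANDOM_LEVELS):
    """Build the k×k unit-variance structure matrix for each random level."""
    k = len(effects)
    out = []
    species = np.array([normalize_label(e.species) for e in effects])
    studies = np.array([e.study_id for e in effects])
    for name in levels:
        if name == "phylogeny":
            if correlation is None:
                raise ValueError("phylogeny level requested but no correlation "
                                 "matrix is attached to the dataset")
            m = correlation.submatrix(list(species))
        elif name == "species":
            m = (species[:, None] == species[None, :]).astype(float)
        elif name == "study":
            m = (studies[:, None] == studies[None, :]).astype(float)
        elif name == "observation":
            m = np.eye(k)
        else:
            raise ValueError(f"unknown random level {name!r}")
        out.append(RandomLevel(name, m))
    return out


def build_model(data: Dataset, moderator: str | None = None,
                include_intercept: bool = True,
                random_levels=DEFAULT_RANDOM_LEVELS) -> ModelSpec:
    """Materialize the design for an intercept-only or meta-regression fit.

    With a categorical moderator and an intercept, levels having fewer than
    10 effects are excluded (their records dropped, reference-level dummy
    coding for the rest).  Without the intercept every level gets its own
    indicator column and no records are dropped, which yields per-level mean
    estimates directly.
    """
    effects = list(data.effects)
    dropped = 0
    level_counts: dict[str, int] = {}

    if moderator is None:
        X = np.ones((len(effects), 1))
        names = ["intercept"]
    else:
        if not effects or not hasattr(effects[0], moderator):
            raise ValueError(f"unknown moderator field {moderator!r}")
        values = [getattr(e, moderator) for e in effects]
        if all(isinstance(x, (int, float)) and not isinstance(x, bool) for x in values):
            col = np.asarray(values, float)
            if include_intercept:
                X = np.column_stack([np.ones(len(effects)), col])
                names = ["intercept", moderator]
            else:
                X = col[:, None]
                names = [moderator]
        else:
            levels = sorted({str(x) for x in values})
            level_counts = {lv: sum(str(x) == lv for x in values) for lv in levels}
            if include_intercept:
                keep_levels = [lv for lv in levels if level_counts[lv] >= MIN_LEVEL_K]
                if len(keep_levels) < 2:
                    raise ValueError(
                        f"moderator {moderator!r} has fewer than 2 levels with "
                        f">= {MIN_LEVEL_K} effects")
                mask = [str(x) in keep_levels for x in values]
                dropped = len(effects) - sum(mask)
                if dropped:
                    logger.info("moderator %s: dropped %d effects in levels "
                                "with k < %d", moderator, dropped, MIN_LEVEL_K)
                effects = [e for e, m in zip(effects, mask) if m]
                values = [str(getattr(e, moderator)) for e in effects]
                ref, rest = keep_levels[0], keep_levels[1:]
                cols = [np.ones(len(effects))]
                names = ["intercept"]
                for lv in rest:
                    cols.append(np.array([x == lv for x in values], float))
                    names.append(f"{moderator}[{lv}]")
                X = np.column_stack(cols)
            else:
                cols = [np.array([str(x) == lv for x in values], float)
                        for lv in levels]
                names = [f"{moderator}[{lv}]" for lv in levels]
                X = np.column_stack(cols)

    structures = random_structures(effects, data.correlation, random_levels)
    y = np.array([e.zr for e in effects])
    v = np.array([e.v for e in effects])
    return ModelSpec(y=y, v=v, X=X, colnames=names, random_levels=structures,
                     include_intercept=include_intercept, moderator=moderator,
                     level_counts=level_counts, n_dropped=dropped,
                     effects=effects)


def build_custom_model(data: Dataset, columns: dict[str, np.ndarray],
                       include_intercept: bool = True,
                       random_levels=DEFAULT_RANDOM_LEVELS,
                       drop_constant: bool = True) -> ModelSpec:
    """Design with arbitrary continuous covariates (publication-bias models).

    Constant (zero-variance) covariate columns are dropped with a warning by
    default rather than producing a singular design.
    """
    effects = list(data.effects)
    k = len(effects)
    names, cols = [], []
    if include_intercept:
        names.append("intercept")
        cols.append(np.ones(k))
    for name, col in columns.items():
        col = np.asarray(col, float)
        if col.shape != (k,):
            raise ValueError(f"covariate {name!r} has wrong length")
        if drop_constant and np.ptp(col) == 0:
            logger.warning("covariate %s is constant; dropped from the design",
                           name)
            continue
        names.append(name)
        cols.append(col)
    if not cols:
        raise ValueError("no usable covariates in the design")
    X = np.column_stack(cols)
    structures = random_structures(effects, data.correlation, random_levels)
    y = np.array([e.zr for e in effects])
    v = np.array([e.v for e in effects])
    return ModelSpec(y=y, v=v, X=X, colnames=names, random_levels=structures,
                     include_intercept=include_intercept, effects=effects)


# ---------------------------------------------------------------------------
# REML objective and fitting

def _marginal_cov(spec: ModelSpec, sigma2: np.ndarray) -> np.ndarray:
    V = np.diag(spec.v.copy())
    for s2, lv in zip(sigma2, spec.random_levels):
        if s2 != 0.0:
            V = V + s2 * lv.matrix
    return V


def _chol(V: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        logger.warning("V not positive definite; applying 1e-10 ridge jitter")
        try:
            return np.linalg.cholesky(V + 1e-10 * np.eye(V.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "marginal covariance is singular even after jitter; check for "
                "duplicated effects or zero sampling variances") from exc


def _reml_pieces(spec: ModelSpec, sigma2: np.ndarray):
    V = _marginal_cov(spec, sigma2)
    L = _chol(V)
    X, y = spec.X, spec.y
    Vi_X = cho_solve((L, True), X)
    Vi_y = cho_solve((L, True), y)
    XtViX = X.T @ Vi_X
    XtViy = X.T @ Vi_y
    beta = np.linalg.solve(XtViX, XtViy)
    resid = y - X @ beta
    quad = float(resid @ cho_solve((L, True), resid))
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(L))))
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X' V^-1 X is not positive definite")
    ll = -0.5 * (logdet_V + logdet_XtViX + quad)
    beta_cov = np.linalg.inv(XtViX)
    return ll, beta, beta_cov


def _reml_value_and_score(spec: ModelSpec, sigma2: np.ndarray):
    """REML log-likelihood and its score vector d l / d sigma2.

    Uses the standard identities with P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1:
        d l / d s2_l = 1/2 [ (Py)' M_l (Py) - tr(P M_l) ].
    """
    V = _marginal_cov(spec, sigma2)
    L = _chol(V)
    X, y = spec.X, spec.y
    k = len(y)
    Vi = cho_solve((L, True), np.eye(k))
    Vi_X = Vi @ X
    XtViX = X.T @ Vi_X
    XtViX_inv = np.linalg.inv(XtViX)
    P = Vi - Vi_X @ XtViX_inv @ Vi_X.T
    Py = P @ y
    quad = float(y @ Py)
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(L))))
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X' V^-1 X is not positive definite")
    ll = -0.5 * (logdet_V + logdet_XtViX + quad)
    score = np.array([
        0.5 * (float(Py @ (lv.matrix @ Py)) - float(np.sum(P * lv.matrix)))
        for lv in spec.random_levels
    ])
    return ll, score


def reml_loglik(spec: ModelSpec, sigma2, data: Dataset | None = None) -> float:
    """Restricted log-likelihood (up to an additive constant).

    ``sigma2`` is a sequence of variance components, one per random level in
    the spec (a :class:`VarianceComponents` is also accepted).
    """
    if isinstance(sigma2, VarianceComponents):
        sigma2 = [sigma2[lv.name] for lv in spec.random_levels]
    sigma2 = np.asarray(sigma2, float)
    if np.any(sigma2 < 0):
        raise ValueError("variance components must be >= 0")
    ll, _, _ = _reml_pieces(spec, sigma2)
    return ll


def _start_points(spec: ModelSpec, n_levels: int) -> list[np.ndarray]:
    """Five starts on the variance scale, including the zero boundary."""
    tau2 = max(float(np.var(spec.y, ddof=1) - np.mean(spec.v)), 1e-4)
    starts = [
        np.full(n_levels, tau2 / max(n_levels, 1)),
        np.full(n_levels, 1e-8),
        np.full(n_levels, tau2),
        np.full(n_levels, 0.1),
    ]
    obs_heavy = np.full(n_levels, 1e-6)
    obs_heavy[-1] = tau2
    starts.append(obs_heavy)
    return starts


def fit_reml(spec: ModelSpec, data: Dataset | None = None,
             fixed_sigma2: dict[str, float] | None = None,
             ci_level: float = 0.95, crit: str = "z") -> MetaFit:
    """Fit the multilevel model by REML.

    ``fixed_sigma2`` pins named components at given values (e.g. all at 0 to
    recover weighted least squares); the rest are estimated.  Optimization is
    Nelder-Mead on log-variances from five starts; components driven below
    1e-12 are reported as exactly 0.
    """
    level_names = [lv.name for lv in spec.random_levels]
    fixed_sigma2 = dict(fixed_sigma2 or {})
    unknown = set(fixed_sigma2) - set(level_names)
    if unknown:
        raise ValueError(f"fixed_sigma2 names not in the model: {sorted(unknown)}")
    free_idx = [i for i, nm in enumerate(level_names) if nm not in fixed_sigma2]
    base = np.array([fixed_sigma2.get(nm, 0.0) for nm in level_names])

    if spec.k <= spec.X.shape[1]:
        raise ValueError("need more effects than fixed-effect columns")

    if free_idx:
        def objective(theta: np.ndarray) -> float:
            s2 = base.copy()
            s2[free_idx] = np.exp(np.clip(theta, -60.0, 8.0))
            try:
                ll, _, _ = _reml_pieces(spec, s2)
            except np.linalg.LinAlgError:
                return 1e12
            return -ll

        def objective_grad(theta: np.ndarray):
            theta = np.clip(theta, -60.0, 8.0)
            s2 = base.copy()
            s2[free_idx] = np.exp(theta)
            try:
                ll, score = _reml_value_and_score(spec, s2)
            except np.linalg.LinAlgError:
                return 1e12, np.zeros_like(theta)
            # chain rule for the log-variance parametrization
            return -ll, -score[free_idx] * s2[free_idx]

        best = None
        for start in _start_points(spec, len(free_idx)):
            theta0 = np.log(np.maximum(start, 1e-30))
            res = optimize.minimize(
                objective_grad, theta0, method="L-BFGS-B", jac=True,
                bounds=[(-60.0, 8.0)] * len(free_idx),
                options=dict(ftol=1e-14, gtol=1e-10, maxiter=500),
            )
            if best is None or res.fun < best.fun:
                best = res
        # Nelder-Mead polish from the best candidate guards against early
        # line-search termination near the zero-variance boundary.
        gradient_fun = best.fun
        polish = optimize.minimize(
            objective, best.x, method="Nelder-Mead",
            options=dict(xatol=1e-10, fatol=CONVERGENCE_FTOL,
                         maxiter=2000, maxfev=4000),
        )
        if polish.fun <= best.fun:
            best = polish
        if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
            raise ConvergenceError("REML optimization failed from all starts",
                                   best=best)
        if not best.success and gradient_fun - best.fun > 1e-6:
            # a flat boundary region that merely exhausts the simplex budget
            # after a negligible improvement is effectively converged
            logger.warning("REML optimizer reported non-convergence "
                           "(best objective %.6g); using best candidate",
                           best.fun)
        s2_hat = base.copy()
        s2_hat[free_idx] = np.exp(np.clip(best.x, -60.0, 8.0))
        s2_hat[s2_hat < BOUNDARY_PIN] = 0.0
    else:
        s2_hat = base

    ll, beta, beta_cov = _reml_pieces(spec, s2_hat)
    sigma2 = VarianceComponents(
        {nm: float(s2_hat[i]) for i, nm in enumerate(level_names)})
    return MetaFit(beta=beta, beta_cov=beta_cov, colnames=list(spec.colnames),
                   sigma2=sigma2, reml_loglik=float(ll), k=spec.k, spec=spec,
                   ci_level=ci_level, crit=crit)


# ---------------------------------------------------------------------------
# Post-fit summaries

def prediction_interval(fit: MetaFit, index: int = 0) -> tuple[float, float]:
    """95% prediction interval on the correlation scale.

    On the Zr scale: beta ± crit * sqrt(SE² + total sigma²), back-transformed
    endpoint-wise.  Equals the CI when all variance components are zero.
    """
    c = fit._crit_value
    half = c * math.sqrt(fit.se[index] ** 2 + fit.sigma2.total)
    b = float(fit.beta[index])
    return (math.tanh(b - half), math.tanh(b + half))


def qm_test(fit: MetaFit, tested=None) -> tuple[float, int, float]:
    """Omnibus Wald chi-square that the tested coefficients are jointly zero.

    By default all non-intercept coefficients are tested.
    """
    if tested is None:
        tested = [i for i, nm in enumerate(fit.colnames) if nm != "intercept"]
    tested = list(tested)
    if not tested:
        raise ValueError("no coefficients to test")
    b = fit.beta[tested]
    C = fit.beta_cov[np.ix_(tested, tested)]
    try:
        qm = float(b @ np.linalg.solve(C, b))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular covariance of tested "
                                    "coefficients") from exc
    df = len(tested)
    return qm, df, float(stats.chi2.sf(qm, df))


def marginal_r2(fit: MetaFit, spec: ModelSpec | None = None) -> float:
    """Share of total variance explained by the fixed moderators.

    R² = Var(X beta) / (Var(X beta) + total sigma²), the variance taken over
    the k fitted values (sample variance).
    """
    spec = spec or fit.spec
    fitted = spec.X @ fit.beta
    var_fixed = float(np.var(fitted, ddof=1))
    denom = var_fixed + fit.sigma2.total
    if denom == 0:
        return 0.0
    return min(max(var_fixed / denom, 0.0), 1.0)


def pairwise_posthoc(fit: MetaFit, min_k: int = MIN_LEVEL_K):
    """All pairwise contrasts among well-populated moderator levels.

    Operates on a no-intercept (per-level means) fit; levels with fewer than
    ``min_k`` effects are skipped.  Returns (level_i, level_j, z, p_holm).
    """
    counts = fit.spec.level_counts
    idx = [i for i, nm in enumerate(fit.colnames)
           if not counts or counts.get(_level_of(nm), 0) >= min_k]
    if len(idx) < 2:
        raise ValueError("need at least 2 levels with enough effects")
    pairs = list(itertools.combinations(idx, 2))
    zs, raw_p = [], []
    for i, j in pairs:
        var = fit.beta_cov[i, i] + fit.beta_cov[j, j] - 2 * fit.beta_cov[i, j]
        z = (fit.beta[i] - fit.beta[j]) / math.sqrt(var)
        zs.append(z)
        raw_p.append(2 * stats.norm.sf(abs(z)))
    adj = multipletests(raw_p, method="holm")[1] if raw_p else []
    return [(fit.colnames[i], fit.colnames[j], float(z), float(p))
            for (i, j), z, p in zip(pairs, zs, adj)]


def _level_of(colname: str) -> str:
    if "[" in colname and colname.endswith("]"):
        return colname[colname.index("[") + 1:-1]
    return colname


@dataclass
class ModeratorResult:
    """Meta-regression summary for one moderator."""

    moderator: str
    k: int
    qm: float
    qm_df: int
    qm_p: float
    r2_marginal: float
    levels: list          # (name, k, mean_r, (lo, hi)) from the no-intercept fit
    pairwise: list        # (level_i, level_j, z, p_holm)


def moderator_analysis(data: Dataset, moderator: str) -> ModeratorResult:
    """Run the full moderator workflow for one categorical moderator.

    The omnibus fit (intercept + dummies, levels with k < 10 excluded)
    supplies QM and marginal R²; the no-intercept refit on all records
    supplies per-level means and the post hoc contrasts.
    """
    spec_qm = build_model(data, moderator=moderator, include_intercept=True)
    fit_qm = fit_reml(spec_qm)
    qm, df, p = qm_test(fit_qm)
    r2 = marginal_r2(fit_qm)

    spec_nointc = build_model(data, moderator=moderator, include_intercept=False)
    fit_nointc = fit_reml(spec_nointc)
    ci = fit_nointc.ci_zr()
    levels = []
    for i, nm in enumerate(fit_nointc.colnames):
        lv = _level_of(nm)
        levels.append((lv, fit_nointc.spec.level_counts.get(lv, 0),
                       math.tanh(float(fit_nointc.beta[i])),
                       (math.tanh(float(ci[i, 0])), math.tanh(float(ci[i, 1])))))
    try:
        pairwise = pairwise_posthoc(fit_nointc)
    except ValueError:
        pairwise = []
    return ModeratorResult(moderator=moderator, k=spec_qm.k, qm=qm, qm_df=df,
                           qm_p=p, r2_marginal=r2, levels=levels,
                           pairwise=pairwise)
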