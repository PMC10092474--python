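"""Binary-item normal-ogive IRT: tetrachorics, 1PL/2PL MML estimation,
nested-model testing, information curves and approximate fit indices.

The measurement model is the two-parameter normal ogive: with a standard
normal latent trait theta, item j is endorsed with probability

    P_j(theta) = Phi(a_j * (theta - b_j)),

where ``a_j`` is the discrimination (probit slope) and ``b_j`` the difficulty
(the trait level at which endorsement probability is 0.5).  The 1PL model
constrains all discriminations to a common value.  Estimation is marginal
maximum likelihood: for the 2PL, Bock-Aitkin EM over Gauss-Hermite quadrature
followed by a quasi-Newton polish of the marginal likelihood; the 1PL is
optimized directly on the same objective under the equality constraint.
Standard errors come from the observed information at the optimum.

The normal-ogive factor-analytic duality links these parameters to a
one-factor model on the tetrachoric correlation matrix:
loading  lambda = a / sqrt(1 + a^2),  threshold  tau = a*b / sqrt(1 + a^2),
and the population endorsement rate is Phi(-tau).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp, ndtr

__all__ = [
    "ItemParams2PL",
    "TetrachoricMatrix",
    "FitIndices",
    "FitResult",
    "tetrachoric_correlation",
    "tetrachoric_matrix",
    "fit_2pl",
    "fit_1pl",
    "lr_test",
    "marginal_endorsement",
    "information_curves",
    "loading_from_discrimination",
    "discrimination_from_loading",
    "threshold_from_params",
    "difficulty_from_threshold",
    "fit_indices",
]

A_BOUND = 10.0  # |a| cap during optimization; hitting it flags a Heywood-type item


@dataclass(frozen=True)
class ItemParams2PL:
    """Discrimination/difficulty for one item in the probit metric."""

    a: float
    b: float
    se_a: Optional[float] = None
    se_b: Optional[float] = None


@dataclass(frozen=True)
class TetrachoricMatrix:
    """Pairwise tetrachoric correlations plus per-item non-endorsement
    thresholds (normal quantiles of the proportion scoring 0)."""

    r: np.ndarray
    thresholds: np.ndarray


@dataclass(frozen=True)
class FitIndices:
    chi2: float
    df: int
    srmr: float
    rmsea: Optional[float]
    cfi: float
    tli: Optional[float]


@dataclass
class FitResult:
    """Fitted 1PL or 2PL model."""

    model: str                      # "1PL" or "2PL"
    params: list[ItemParams2PL]
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    n_iter: int
    loglik_path: np.ndarray         # EM / optimizer trajectory (non-decreasing for EM)
    fit: Optional[FitIndices] = None
    flagged_items: list[int] = field(default_factory=list)  # 1-based, at |a| bound

    @property
    def a(self) -> np.ndarray:
        return np.array([p.a for p in self.params])

    @property
    def b(self) -> np.ndarray:
        return np.array([p.b for p in self.params])

    @property
    def loadings(self) -> np.ndarray:
        return loading_from_discrimination(self.a)


# ---------------------------------------------------------------------------
# parameter conversions (normal-ogive factor duality)

def loading_from_discrimination(a):
    a = np.asarray(a, dtype=float)
    return a / np.sqrt(1.0 + a**2)


def discrimination_from_loading(lam):
    lam = np.asarray(lam, dtype=float)
    if np.any(np.abs(lam) >= 1):
        raise ValueError("loadings must satisfy |lambda| < 1")
    return lam / np.sqrt(1.0 - lam**2)


def threshold_from_params(a, b):
    """Threshold tau on the standardized latent response: tau = ab/sqrt(1+a^2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return a * b / np.sqrt(1.0 + a**2)


def difficulty_from_threshold(a, tau):
    a = np.asarray(a, dtype=float)
    tau = np.asarray(tau, dtype=float)
    return tau * np.sqrt(1.0 + a**2) / a


def marginal_endorsement(a: float, b: float) -> float:
    """Population endorsement rate under theta ~ N(0,1).

    Integrating the item response function over the trait distribution has
    the closed form Phi(-a*b / sqrt(1 + a^2)).
    """
    return float(ndtr(-threshold_from_params(a, b)))


# ---------------------------------------------------------------------------
# tetrachoric correlation

def _bvn_cdf(x: float, y: float, r: float) -> float:
    return float(
        stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]]).cdf([x, y])
    )


def tetrachoric_correlation(counts) -> float:
    """ML tetrachoric correlation from a 2x2 table.

    ``counts[i][j]`` is the number of respondents scoring i on the first item
    and j on the second (i, j in {0, 1}).  Thresholds are fixed at the normal
    quantiles of the margins; the correlation of the underlying bivariate
    normal is then solved to reproduce the observed cell probabilities, which
    is the maximum-likelihood solution for a 2x2 table.  A table containing a
    zero cell gets a 0.5 continuity correction on every cell (with a warning);
    a zero margin leaves the correlation undefined.
    """
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("counts must be a nonnegative 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("tetrachoric correlation undefined: a margin is zero")
    if np.any(t == 0):
        warnings.warn("zero cell in 2x2 table: applying 0.5 continuity correction")
        t = t + 0.5
    n = t.sum()
    p_row0 = t[0].sum() / n        # P(first item = 0)
    p_col0 = t[:, 0].sum() / n
    tx = stats.norm.ppf(p_row0)
    ty = stats.norm.ppf(p_col0)
    p00 = t[0, 0] / n

    def gap(r: float) -> float:
        return _bvn_cdf(tx, ty, r) - p00

    lo, hi = -0.9999, 0.9999
    glo, ghi = gap(lo), gap(hi)
    if glo > 0:
        return -1.0 + 1e-4
    if ghi < 0:
        return 1.0 - 1e-4
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))


def tetrachoric_matrix(binary_data) -> TetrachoricMatrix:
    """Pairwise tetrachoric correlation matrix of a respondents x items 0/1 array."""
    x = np.asarray(binary_data, dtype=float)
    n, p = x.shape
    r = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            tab = np.zeros((2, 2))
            for a_ in (0, 1):
                for b_ in (0, 1):
                    tab[a_, b_] = np.sum((x[:, i] == a_) & (x[:, j] == b_))
            r[i, j] = r[j, i] = tetrachoric_correlation(tab)
    thresholds = stats.norm.ppf(1.0 - x.mean(axis=0))
    return TetrachoricMatrix(r=r, thresholds=thresholds)


# ---------------------------------------------------------------------------
# marginal likelihood machinery

def _gh_nodes(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes/weights transformed to integrate against N(0,1)."""
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


def _collapse_patterns(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, counts = np.unique(data, axis=0, return_counts=True)
    return patterns.astype(float), counts.astype(float)


_LOG_EPS = 1e-300


def _pattern_loglik(
    patterns: np.ndarray, a: np.ndarray, b: np.ndarray,
    nodes: np.ndarray, logw: np.ndarray,
) -> np.ndarray:
    """Log marginal likelihood per response pattern (npat,) and the joint
    (npat, nquad) log density used for posterior weights."""
    p = ndtr(a[:, None] * (nodes[None, :] - b[:, None]))      # items x Q
    logp = np.log(np.clip(p, _LOG_EPS, 1.0))
    log1mp = np.log(np.clip(1.0 - p, _LOG_EPS, 1.0))
    joint = patterns @ logp + (1.0 - patterns) @ log1mp + logw[None, :]
    return logsumexp(joint, axis=1), joint


def _marginal_loglik(patterns, counts, a, b, nodes, logw) -> float:
    lp, _ = _pattern_loglik(patterns, a, b, nodes, logw)
    return float(counts @ lp)


def _nll_and_grad(theta, patterns, counts, nodes, logw, p, common_a=False):
    """Negative marginal loglik and its analytic gradient in the slope/
    intercept parameterization z = a*theta + c (so b = -c/a).

    With posterior pattern weights W, the expected per-node endorsement
    counts r_jq and totals n_q give
    d ll / d z_jq = (r_jq - n_q P_jq) * phi(z_jq) / [P(1-P)].
    """
    if common_a:
        a = np.full(p, theta[0])
        c = theta[1:]
    else:
        a = theta[:p]
        c = theta[p:]
    z = a[:, None] * nodes[None, :] + c[:, None]
    prob = np.clip(ndtr(z), _LOG_EPS, 1 - 1e-16)
    logp = np.log(prob)
    log1mp = np.log1p(-prob)
    joint = patterns @ logp + (1.0 - patterns) @ log1mp + logw[None, :]
    lp = logsumexp(joint, axis=1)
    ll = float(counts @ lp)
    w_post = np.exp(joint - lp[:, None]) * counts[:, None]
    nq = w_post.sum(axis=0)
    rjq = patterns.T @ w_post
    pdf = np.exp(-0.5 * z**2) / np.sqrt(2 * np.pi)
    coef = (rjq - nq[None, :] * prob) * pdf / np.clip(prob * (1 - prob), 1e-12, None)
    g_a = (coef * nodes[None, :]).sum(axis=1)
    g_c = coef.sum(axis=1)
    if common_a:
        grad = np.concatenate([[g_a.sum()], g_c])
    else:
        grad = np.concatenate([g_a, g_c])
    return -ll, -grad


def _validate_binary(data) -> np.ndarray:
    x = np.asarray(data)
    if x.ndim != 2:
        raise ValueError("binary_data must be a 2-D respondents x items array")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("binary_data must contain only 0/1 values")
    return x.astype(float)


def _start_values(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic starts: one-factor principal loadings of the tetrachoric
    matrix converted to (a, b) via the normal-ogive identities."""
    tet = tetrachoric_matrix(data)
    evals, evecs = np.linalg.eigh(tet.r)
    lam = evecs[:, -1] * np.sqrt(max(evals[-1], 1e-6))
    if lam.sum() < 0:
        lam = -lam
    lam = np.clip(lam, 0.05, 0.95)
    a0 = discrimination_from_loading(lam)
    tau = stats.norm.ppf(1.0 - data.mean(axis=0))
    b0 = difficulty_from_threshold(a0, tau)
    return a0, b0


def fit_2pl(
    binary_data,
    quadrature: int = 61,
    seed: Optional[int] = None,
    max_em_iter: int = 200,
    tol: float = 1e-7,
    compute_se: bool = True,
) -> FitResult:
    """Fit the two-parameter normal-ogive model by MML.

    Bock-Aitkin EM: the E-step distributes each response pattern over the
    quadrature grid by its posterior trait density; the M-step refits each
    item's probit regression on the grid against the expected endorsement
    counts.  A final L-BFGS-B polish maximizes the marginal likelihood
    directly with |a| bounded at ``A_BOUND``.  ``seed`` is accepted for
    interface symmetry with the simulation routines; estimation itself is
    deterministic.
    """
    x = _validate_binary(binary_data)
    n, p_all = x.shape
    if p_all < 2:
        raise ValueError("at least 2 items are required to identify the model")
    means = x.mean(axis=0)
    keep = (means > 0) & (means < 1)
    dropped = np.where(~keep)[0]
    if dropped.size:
        warnings.warn(
            f"items {[int(i)+1 for i in dropped]} have zero variance and were excluded"
        )
    x = x[:, keep]
    p = x.shape[1]
    if p < 2:
        raise ValueError("fewer than 2 items with response variance; model unidentified")

    nodes, w = _gh_nodes(quadrature)
    logw = np.log(w)
    patterns, counts = _collapse_patterns(x)
    a, b = _start_values(x)

    # --- EM
    from statsmodels.api import GLM, families

    path = []
    ll_old = -np.inf
    converged = False
    it = 0
    design = np.column_stack([nodes, np.ones_like(nodes)])
    for it in range(1, max_em_iter + 1):
        lp, joint = _pattern_loglik(patterns, a, b, nodes, logw)
        ll = float(counts @ lp)
        path.append(ll)
        post = np.exp(joint - lp[:, None])                       # npat x Q
        nq = post.T @ counts                                     # expected n per node
        rjq = patterns.T @ (post * counts[:, None])              # items x Q
        for j in range(p):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                prop = np.clip(rjq[j] / np.clip(nq, 1e-12, None), 1e-9, 1 - 1e-9)
                res = GLM(
                    prop, design, family=families.Binomial(families.links.Probit()),
                    var_weights=nq,
                ).fit(start_params=[a[j], -a[j] * b[j]], maxiter=25)
            slope, intercept = res.params
            slope = float(np.clip(slope, 1e-3, A_BOUND))
            a[j], b[j] = slope, -intercept / slope
        if ll - ll_old < tol * max(1.0, abs(ll)) and it > 1:
            converged = True
            break
        ll_old = ll

    # --- quasi-Newton polish on (a, c) with c = -a*b, analytic gradient
    def unpack(theta):
        return theta[:p], -theta[p:] / theta[:p]

    theta0 = np.concatenate([a, -a * b])
    bounds = [(1e-3, A_BOUND)] * p + [(None, None)] * p
    opt = optimize.minimize(
        _nll_and_grad, theta0, args=(patterns, counts, nodes, logw, p),
        jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-8})
    a, b = unpack(opt.x)
    a, b = np.asarray(a, float), np.asarray(b, float)
    path.append(-opt.fun)
    flagged = [int(j) + 1 for j in range(p) if a[j] >= A_BOUND - 1e-6]
    if flagged:
        warnings.warn(f"discrimination at bound for items {flagged} (Heywood-type)")

    se_a = se_b = [None] * p
    if compute_se:
        se_a, se_b = _observed_info_se(patterns, counts, a, b, nodes, logw)

    params = [ItemParams2PL(float(a[j]), float(b[j]),
                            se_a[j], se_b[j]) for j in range(p)]
    return FitResult(
        model="2PL", params=params, loglik=float(-opt.fun), n_params=2 * p,
        n_obs=n, converged=bool(converged or opt.success), n_iter=it,
        loglik_path=np.asarray(path), flagged_items=flagged,
    )


def _observed_info_se(patterns, counts, a, b, nodes, logw):
    """SEs from the observed information (numerical Hessian of the marginal
    log-likelihood in the (a, b) parameterization)."""
    from statsmodels.tools.numdiff import approx_hess

    p = a.size

    def nll_ab(theta):
        return -_marginal_loglik(patterns, counts, theta[:p], theta[p:], nodes, logw)

    theta = np.concatenate([a, b])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hess = approx_hess(theta, nll_ab)
        try:
            cov = np.linalg.inv(hess)
            d = np.diag(cov).copy()
            d[d < 0] = np.nan
            se = np.sqrt(d)
        except np.linalg.LinAlgError:
            se = np.full(2 * p, np.nan)
    return [float(s) if np.isfinite(s) else None for s in se[:p]], \
           [float(s) if np.isfinite(s) else None for s in se[p:]]


def fit_1pl(
    binary_data,
    quadrature: int = 61,
    seed: Optional[int] = None,
    tol: float = 1e-7,
    compute_se: bool = True,
) -> FitResult:
    """Fit the equal-discrimination (1PL) normal-ogive model by MML.

    The common slope couples the items, so the constrained marginal
    likelihood is maximized directly by L-BFGS-B from the tetrachoric-based
    start rather than by per-item EM steps.
    """
    x = _validate_binary(binary_data)
    n, p_all = x.shape
    if p_all < 2:
        raise ValueError("at least 2 items are required to identify the model")
    means = x.mean(axis=0)
    keep = (means > 0) & (means < 1)
    if (~keep).any():
        warnings.warn(
            f"items {[int(i)+1 for i in np.where(~keep)[0]]} have zero variance and were excluded"
        )
    x = x[:, keep]
    p = x.shape[1]
    if p < 2:
        raise ValueError("fewer than 2 items with response variance; model unidentified")

    nodes, w = _gh_nodes(quadrature)
    logw = np.log(w)
    patterns, counts = _collapse_patterns(x)
    a0, b0 = _start_values(x)
    common_a0 = float(np.clip(np.mean(a0), 1e-2, A_BOUND))

    def unpack(theta):
        aa = np.full(p, theta[0])
        return aa, -theta[1:] / aa

    theta0 = np.concatenate([[common_a0], -common_a0 * b0])
    bounds = [(1e-3, A_BOUND)] + [(None, None)] * p
    opt = optimize.minimize(
        _nll_and_grad, theta0, args=(patterns, counts, nodes, logw, p, True),
        jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 800, "ftol": 1e-13, "gtol": 1e-8})
    a, b = unpack(opt.x)
    flagged = [0] if a[0] >= A_BOUND - 1e-6 else []

    se_common = None
    se_b = [None] * p
    if compute_se:
        from statsmodels.tools.numdiff import approx_hess

        def nll_ab(theta):
            return -_marginal_loglik(patterns, counts, np.full(p, theta[0]),
                                     theta[1:], nodes, logw)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hess = approx_hess(np.concatenate([[a[0]], b]), nll_ab)
            try:
                d = np.diag(np.linalg.inv(hess)).copy()
                d[d < 0] = np.nan
                se = np.sqrt(d)
                se_common = float(se[0]) if np.isfinite(se[0]) else None
                se_b = [float(s) if np.isfinite(s) else None for s in se[1:]]
            except np.linalg.LinAlgError:
                pass

    params = [ItemParams2PL(float(a[j]), float(b[j]), se_common, se_b[j])
              for j in range(p)]
    return FitResult(
        model="1PL", params=params, loglik=float(-opt.fun), n_params=p + 1,
        n_obs=n, converged=bool(opt.success), n_iter=int(opt.nit),
        loglik_path=np.asarray([-opt.fun]), flagged_items=flagged,
    )


def lr_test(fit_restricted: FitResult, fit_full: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested MML fits (e.g., 1PL vs 2PL).

    Returns (chi2, df, p).  The models must be fitted to the same data
    (checked via n_obs and item count) with the restricted model having
    fewer parameters.
    """
    if fit_restricted.n_obs != fit_full.n_obs or \
            len(fit_restricted.params) != len(fit_full.params):
        raise ValueError("models must be fitted to the same data")
    df = fit_full.n_params - fit_restricted.n_params
    if df <= 0:
        raise ValueError("first argument must be the restricted (smaller) model")
    chi2 = max(0.0, 2.0 * (fit_full.loglik - fit_restricted.loglik))
    return chi2, df, float(stats.chi2.sf(chi2, df))


def information_curves(
    params: Sequence[ItemParams2PL], theta_grid
) -> dict[str, np.ndarray]:
    """Item characteristic curves and Fisher information over a trait grid.

    Item information for the normal ogive is
    I_j(theta) = a^2 phi(a(theta-b))^2 / [P(1-P)].
    Returns ``{"theta", "icc", "item_info", "total_info"}`` with item arrays
    of shape (n_items, len(grid)).
    """
    theta = np.asarray(theta_grid, dtype=float)
    if theta.size == 0:
        raise ValueError("theta_grid must be nonempty")
    a = np.array([p.a for p in params])[:, None]
    b = np.array([p.b for p in params])[:, None]
    z = a * (theta[None, :] - b)
    icc = ndtr(z)
    dens = stats.norm.pdf(z)
    pq = np.clip(icc * (1.0 - icc), 1e-12, None)
    info = (a**2) * dens**2 / pq
    return {"theta": theta, "icc": icc, "item_info": info,
            "total_info": info.sum(axis=0)}


def fit_indices(
    observed: TetrachoricMatrix | np.ndarray,
    model_implied: np.ndarray,
    n: int,
    df: int,
) -> FitIndices:
    """Approximate limited-information fit indices from correlation residuals.

    SRMR is the root mean square of the below-diagonal residuals.  A chi-square
    analogue is formed from the unweighted least-squares discrepancy
    F = sum of squared below-diagonal residuals, scaled by (n - 1); RMSEA,
    CFI and TLI follow from that statistic with the zero-correlation
    independence model as baseline.  These are documented approximations, not
    the weighted-least-squares indices a full categorical-data fit would give.
    """
    robs = observed.r if isinstance(observed, TetrachoricMatrix) else np.asarray(observed)
    rimp = np.asarray(model_implied)
    if robs.shape != rimp.shape:
        raise ValueError("observed and implied matrices must be conformable")
    p = robs.shape[0]
    iu = np.triu_indices(p, k=1)
    resid = robs[iu] - rimp[iu]
    srmr = float(np.sqrt(np.mean(resid**2)))
    f_model = float(np.sum(resid**2))
    chi2 = (n - 1) * f_model
    rmsea = None
    if df > 0:
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    # independence baseline: implied correlations all zero
    f_base = float(np.sum(robs[iu] ** 2))
    chi2_b = (n - 1) * f_base
    df_b = p * (p - 1) // 2
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    tli = None
    if df > 0 and df_b > 0 and chi2_b / df_b != 1.0:
        tli = float((chi2_b / df_b - chi2 / df) / (chi2_b / df_b - 1.0))
    return FitIndices(chi2=float(chi2), df=int(df), srmr=srmr,
                      rmsea=rmsea, cfi=float(cfi), tli=tli)


def model_df(n_items: int, model: str) -> int:
    """Degrees of freedom for the limited-information chi-square: distinct
    correlations minus free loading-type parameters (thresholds are saturated
    by the margins)."""
    pairs = n_items * (n_items - 1) // 2
    if model == "2PL":
        return pairs - n_items
    if model == "1PL":
        return pairs - 1
    raise ValueError("model must be '1PL' or '2PL'")
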