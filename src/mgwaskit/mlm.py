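"""Multi-locus mixed-model association engine.

Per metabolite feature y the model is

    y_i = mu + sum_l x_i^l theta_a^l + w_i^l theta_d^l + A_i + D_i + e_i

with A ~ N(0, sigma2_a K_a), D ~ N(0, sigma2_d K_d), e ~ N(0, sigma2_e I),
where K_a / K_d are the additive / dominance alike-in-state kinships, x is
the centered genotype code and w the centered heterozygote indicator.

Variance components are estimated by REML over V = sigma2_a K_a +
sigma2_d K_d + sigma2_e I via direct Cholesky factorization and multi-start
Nelder-Mead on log variance ratios (two kinships preclude a single spectral
rotation).  Markers are scanned with a joint 2-df Wald test of
(theta_a, theta_d) at the current step's variance components; forward
selection admits the smallest-p marker per step (at most 20 steps) and the
extended BIC chooses the model size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from scipy.special import gammaln

from .genostruct import DesignMatrices, KinshipPair

logger = logging.getLogger(__name__)

_LOG_RATIO_BOUND = 25.0


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

@dataclass
class MixedModelFit:
    sigma2_a: float
    sigma2_d: float
    sigma2_e: float
    beta: np.ndarray
    reml_loglik: float
    ml_loglik: float
    n: int
    p_eff: int  # number of candidate markers in the surrounding scan (0 if n/a)
    chol_V: np.ndarray  # lower Cholesky factor of fitted V (absolute scale)
    X0: np.ndarray

    @property
    def h2_a(self) -> float:
        tot = self.sigma2_a + self.sigma2_d + self.sigma2_e
        return self.sigma2_a / tot if tot > 0 else np.nan


def _reml_profile(params: np.ndarray, Ka: np.ndarray, Kd: np.ndarray,
                  X: np.ndarray, y: np.ndarray):
    """Profiled negative REML criterion at log variance ratios (la, ld).

    V = sigma2_e * V0 with V0 = e^la Ka + e^ld Kd + I; sigma2_e is profiled
    out analytically.  Returns (criterion, extras) where extras carry the
    pieces needed to reconstruct the full fit.
    """
    la, ld = np.clip(params, -_LOG_RATIO_BOUND, _LOG_RATIO_BOUND)
    n, p = X.shape
    V0 = np.exp(la) * Ka + np.exp(ld) * Kd
    idx = np.arange(n)
    V0[idx, idx] += 1.0
    try:
        L0 = linalg.cholesky(V0, lower=True, check_finite=False, overwrite_a=True)
    except linalg.LinAlgError:
        V0 = np.exp(la) * Ka + np.exp(ld) * Kd + (1.0 + 1e-8) * np.eye(n)
        L0 = linalg.cholesky(V0, lower=True, check_finite=False, overwrite_a=True)
    logdet_V0 = 2.0 * np.log(np.diag(L0)).sum()
    Z = linalg.solve_triangular(L0, np.column_stack([X, y]), lower=True,
                                check_finite=False)
    Xi, yi = Z[:, :p], Z[:, p]
    XtVX = Xi.T @ Xi
    sign, logdet_XtVX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return 1e30, None
    Xty = Xi.T @ yi
    beta = np.linalg.solve(XtVX, Xty)
    quad = float(yi @ yi - Xty @ beta)  # y' P0 y (V0 scale)
    if quad <= 0:
        return 1e30, None
    crit = 0.5 * ((n - p) * np.log(quad) + logdet_V0 + logdet_XtVX)
    return crit, (la, ld, L0, logdet_V0, logdet_XtVX, beta, quad)


def _ml_profile(params: np.ndarray, Ka: np.ndarray, Kd: np.ndarray,
                X: np.ndarray, y: np.ndarray):
    """Profiled negative ML criterion (beta and sigma2_e profiled out).

    The eBIC needs the *maximized* ML log-likelihood: evaluating the ML
    likelihood at REML variance estimates inflates likelihood differences
    between nested cofactor models.
    """
    la, ld = np.clip(params, -_LOG_RATIO_BOUND, _LOG_RATIO_BOUND)
    n, p = X.shape
    V0 = np.exp(la) * Ka + np.exp(ld) * Kd
    idx = np.arange(n)
    V0[idx, idx] += 1.0
    try:
        L0 = linalg.cholesky(V0, lower=True, check_finite=False, overwrite_a=True)
    except linalg.LinAlgError:
        return 1e30, None
    logdet_V0 = 2.0 * np.log(np.diag(L0)).sum()
    Z = linalg.solve_triangular(L0, np.column_stack([X, y]), lower=True,
                                check_finite=False)
    Xi, yi = Z[:, :p], Z[:, p]
    XtVX = Xi.T @ Xi
    Xty = Xi.T @ yi
    try:
        beta = np.linalg.solve(XtVX, Xty)
    except np.linalg.LinAlgError:
        return 1e30, None
    quad = float(yi @ yi - Xty @ beta)
    if quad <= 0:
        return 1e30, None
    crit = 0.5 * (n * np.log(quad) + logdet_V0)
    return crit, (logdet_V0, quad)


def fit_reml(
    y: np.ndarray,
    X0: np.ndarray,
    kin: KinshipPair,
    n_starts: int = 3,
    p_eff: int = 0,
    tol: float = 1e-8,
    starts: list[tuple[float, float]] | None = None,
) -> MixedModelFit:
    """REML variance components for the two-kinship mixed model.

    ``X0`` holds the fixed covariates (intercept plus any marker cofactors)
    and must have full column rank after dropping numerically dependent
    columns.  The returned fit carries both the restricted log-likelihood
    and the ML log-likelihood at the GLS fixed effects (the quantity the
    eBIC compares across models with different cofactor sets).
    """
    y = np.asarray(y, dtype=float).ravel()
    if not np.isfinite(y).all():
        raise ValueError("non-finite phenotype values")
    X0 = np.atleast_2d(np.asarray(X0, dtype=float))
    if X0.shape[0] != y.size:
        X0 = X0.T
    Ka = kin.K_a.to_numpy() if isinstance(kin.K_a, pd.DataFrame) else np.asarray(kin.K_a)
    Kd = kin.K_d.to_numpy() if isinstance(kin.K_d, pd.DataFrame) else np.asarray(kin.K_d)
    n, p = X0.shape
    if n - p <= 0:
        raise ValueError("more fixed effects than samples")

    if starts is None:
        starts = [(0.0, 0.0), (1.5, -2.0), (-2.0, 1.5)][:n_starts]
    obj = lambda th: _reml_profile(th, Ka, Kd, X0, y)[0]  # noqa: E731
    # coarse Nelder-Mead from every start, then polish the best to `tol`
    best = None
    for s in starts:
        res = optimize.minimize(obj, x0=np.array(s), method="Nelder-Mead",
                                options={"xatol": 1e-2, "fatol": 1e-4,
                                         "maxiter": 120})
        if best is None or res.fun < best.fun:
            best = res
    best = optimize.minimize(obj, x0=best.x, method="Nelder-Mead",
                             options={"xatol": 1e-5, "fatol": tol,
                                      "maxiter": 400})
    crit, extras = _reml_profile(best.x, Ka, Kd, X0, y)
    if extras is None:
        raise np.linalg.LinAlgError("singular V in REML fit")
    la, ld, L0, logdet_V0, logdet_XtVX, beta, quad = extras

    sigma2_e = quad / (n - p)
    sigma2_a = sigma2_e * np.exp(la)
    sigma2_d = sigma2_e * np.exp(ld)
    reml_ll = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma2_e) + 1.0)
                      + logdet_V0 + logdet_XtVX)

    # maximized ML log-likelihood (short polish from the REML optimum)
    ml_obj = lambda th: _ml_profile(th, Ka, Kd, X0, y)[0]  # noqa: E731
    ml_res = optimize.minimize(ml_obj, x0=np.array([la, ld]), method="Nelder-Mead",
                               options={"xatol": 1e-4, "fatol": 1e-7,
                                        "maxiter": 200})
    _, ml_extras = _ml_profile(ml_res.x, Ka, Kd, X0, y)
    if ml_extras is None:
        raise np.linalg.LinAlgError("singular V in ML fit")
    ml_logdet_V0, ml_quad = ml_extras
    ml_sigma2_e = ml_quad / n
    ml_ll = -0.5 * (n * (np.log(2 * np.pi * ml_sigma2_e) + 1.0) + ml_logdet_V0)

    return MixedModelFit(
        sigma2_a=float(sigma2_a), sigma2_d=float(sigma2_d), sigma2_e=float(sigma2_e),
        beta=beta, reml_loglik=float(reml_ll), ml_loglik=float(ml_ll),
        n=n, p_eff=p_eff, chol_V=np.sqrt(sigma2_e) * L0, X0=X0,
    )


# ---------------------------------------------------------------------------
# per-marker GLS tests
# ---------------------------------------------------------------------------

@dataclass
class MarkerTest:
    pvalue: float
    theta_a: float
    theta_d: float
    wald: float
    df: int
    flagged: bool = False  # collinear with existing cofactors


class MarkerTester:
    """Joint 2-df Wald scan of (theta_a, theta_d) at fixed V.

    Working in the whitened space z = L^-1 v (L the Cholesky factor of the
    fitted V), candidate columns are residualized against the current fixed
    effects; the Wald statistic is then the GLS quadratic form with
    Var(beta) read off the residual Gram matrix (no extra variance is
    estimated -- V is held at the current step's REML fit).
    """

    _COLLINEAR_TOL = 1e-10

    def __init__(self, fit: MixedModelFit, y: np.ndarray):
        L = fit.chol_V
        self._yt = linalg.solve_triangular(L, np.asarray(y, float).ravel(), lower=True)
        T0 = linalg.solve_triangular(L, fit.X0, lower=True)
        Q, _ = np.linalg.qr(T0)
        self._Q = Q
        self._L = L
        self._yres = self._yt - Q @ (Q.T @ self._yt)
        self._n = len(self._yt)

    def _whiten_residual(self, M: np.ndarray) -> np.ndarray:
        Mt = linalg.solve_triangular(self._L, M, lower=True)
        return Mt - self._Q @ (self._Q.T @ Mt)

    def test_all(self, X_add: np.ndarray, W_dom: np.ndarray) -> list[MarkerTest]:
        """Vectorized scan over all candidate columns."""
        A = self._whiten_residual(X_add)
        W = self._whiten_residual(W_dom)
        y = self._yres
        aa = np.einsum("ij,ij->j", A, A)
        ww = np.einsum("ij,ij->j", W, W)
        aw = np.einsum("ij,ij->j", A, W)
        ay = A.T @ y
        wy = W.T @ y
        scale = max(float(np.max(aa, initial=0.0)), 1.0)
        out: list[MarkerTest] = []
        for j in range(X_add.shape[1]):
            out.append(self._one(aa[j], ww[j], aw[j], ay[j], wy[j], scale))
        return out

    def test(self, x: np.ndarray, w: np.ndarray | None = None) -> MarkerTest:
        x = np.asarray(x, float).reshape(-1, 1)
        a = self._whiten_residual(x)[:, 0]
        if w is None:
            wv = np.zeros(self._n)
        else:
            wv = self._whiten_residual(np.asarray(w, float).reshape(-1, 1))[:, 0]
        y = self._yres
        return self._one(float(a @ a), float(wv @ wv), float(a @ wv),
                         float(a @ y), float(wv @ y), max(float(a @ a), 1.0))

    def _one(self, aa, ww, aw, ay, wy, scale) -> MarkerTest:
        tol = self._COLLINEAR_TOL * scale
        if aa <= tol and ww <= tol:
            return MarkerTest(1.0, 0.0, 0.0, 0.0, 0, flagged=True)
        if aa <= tol:  # additive column collinear; dominance-only 1-df
            beta = wy / ww
            wald = wy * beta
            return MarkerTest(float(stats.chi2.sf(wald, 1)), 0.0, float(beta),
                              float(wald), 1, flagged=True)
        det = aa * ww - aw * aw
        if ww <= tol or det <= self._COLLINEAR_TOL * aa * max(ww, 1e-300):
            # monomorphic-dominance (or collinear pair): 1-df additive test
            beta = ay / aa
            wald = ay * beta
            return MarkerTest(float(stats.chi2.sf(wald, 1)), float(beta), 0.0,
                              float(wald), 1)
        ba = (ww * ay - aw * wy) / det
        bd = (aa * wy - aw * ay) / det
        wald = ay * ba + wy * bd
        wald = max(float(wald), 0.0)
        return MarkerTest(float(stats.chi2.sf(wald, 2)), float(ba), float(bd),
                          float(wald), 2)


def test_marker(fit: MixedModelFit, y: np.ndarray, x: np.ndarray,
                w: np.ndarray | None = None) -> MarkerTest:
    """Single-marker joint test against the fitted model (see MarkerTester)."""
    return MarkerTester(fit, y).test(x, w)


# ---------------------------------------------------------------------------
# eBIC
# ---------------------------------------------------------------------------

def default_gamma(n: int, p: int) -> float:
    """Model-space penalty weight from the eBIC consistency bound."""
    if p <= 1:
        return 0.0
    return max(0.0, 1.0 - np.log(n) / (2.0 * np.log(p)))


def compute_ebic(fit: MixedModelFit, k: int, p: int, gamma: float,
                 df: int | None = None, loglik: float | None = None) -> float:
    """Extended BIC: -2 logLik + df log n + 2 gamma log C(p, k).

    ``df`` counts fixed effects (defaults to the fitted beta length);
    ``loglik`` defaults to the model's maximized ML log-likelihood.  During
    forward selection the caller passes a profile log-likelihood evaluated
    at a common covariance (see :func:`forward_select`) so that nested
    models are compared on one scale.  gamma = 0 recovers BIC.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    if k > p:
        raise ValueError(f"cofactor count {k} exceeds candidate count {p}")
    if df is None:
        df = len(fit.beta)
    if loglik is None:
        loglik = fit.ml_loglik
    log_binom = gammaln(p + 1) - gammaln(k + 1) - gammaln(p - k + 1)
    return float(-2.0 * loglik + df * np.log(fit.n) + 2.0 * gamma * log_binom)


# ---------------------------------------------------------------------------
# forward selection
# ---------------------------------------------------------------------------

@dataclass
class ForwardSelectionResult:
    path: list[str]
    admit_pvalues: list[float]
    ebic: list[float]
    gamma: float
    selected_step: int
    scan_pvalues: pd.Series      # step-0 p-value per candidate
    effects: pd.DataFrame        # theta_a / theta_d of selected cofactors
    variance_components: list[tuple[float, float, float]]

    @property
    def selected_snps(self) -> list[str]:
        return self.path[: self.selected_step]


def _drop_dependent(X: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Remove numerically dependent columns (keeps the earliest)."""
    keep: list[int] = []
    Q: list[np.ndarray] = []
    for j in range(X.shape[1]):
        v = X[:, j].astype(float)
        for q in Q:
            v = v - (q @ X[:, j]) * q
        nrm = np.linalg.norm(v)
        if nrm > tol * max(np.linalg.norm(X[:, j]), 1.0):
            Q.append(v / nrm)
            keep.append(j)
    return X[:, keep]


def forward_select(
    y: np.ndarray,
    kin: KinshipPair,
    candidates: DesignMatrices,
    max_steps: int = 20,
    gamma: float | None = None,
    snp_map: pd.DataFrame | None = None,
) -> ForwardSelectionResult:
    """Multi-locus forward selection with eBIC model choice.

    At step k the mixed model is re-fit by REML with the k admitted
    cofactors as fixed effects, every remaining candidate gets a joint
    additive+dominance Wald test at those variance components, and the
    smallest-p candidate is admitted (ties broken by larger Wald statistic,
    then genomic position, then id).  The eBIC of every step's model is
    recorded; the reported associations are the cofactors of the
    eBIC-minimizing step.

    The eBIC compares each step's Gaussian profile log-likelihood (GLS
    fixed effects) with the covariance held at the cofactor-free REML fit
    — the "population parameters previously determined" convention of
    fast mixed-model GWAS.  Re-maximizing the variance components inside
    every step's likelihood makes successive differences exceed the
    marker's own test statistic (boundary effects at sigma ~ 0), which
    inflates null model growth; holding V makes the eBIC difference equal
    the admitted marker's Wald statistic.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    snps = candidates.snps
    if not snps:
        raise ValueError("no candidate markers")
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    p = len(snps)
    if gamma is None:
        gamma = default_gamma(n, p)

    Xa = candidates.X_add.to_numpy(dtype=float)
    Wd = candidates.W_dom.to_numpy(dtype=float)
    col = {s: j for j, s in enumerate(snps)}

    def order_key(s: str, t: MarkerTest):
        pos = (snp_map.at[s, "chrom"], snp_map.at[s, "pos"]) if snp_map is not None else ("", 0)
        return (t.pvalue, -t.wald, pos, s)

    path: list[str] = []
    admit_p: list[float] = []
    ebics: list[float] = []
    vcs: list[tuple[float, float, float]] = []
    effects_rows = []
    scan_pvalues: pd.Series | None = None
    remaining = list(snps)

    prev_opt: tuple[float, float] | None = None
    L_null = None  # Cholesky of the cofactor-free fitted V (common scale)
    yt_null = None
    logdet_null = None
    for step in range(max_steps + 1):
        fixed = [np.ones((n, 1))]
        for s in path:
            fixed.append(Xa[:, [col[s]]])
            fixed.append(Wd[:, [col[s]]])
        X0 = _drop_dependent(np.hstack(fixed))
        # warm-start later steps from the previous optimum (variance
        # components move little when one cofactor is added)
        starts = None if prev_opt is None else [prev_opt, (0.0, 0.0)]
        fit = fit_reml(y, X0, kin, p_eff=p, starts=starts)
        prev_opt = (
            float(np.log(max(fit.sigma2_a, 1e-10) / fit.sigma2_e)),
            float(np.log(max(fit.sigma2_d, 1e-10) / fit.sigma2_e)),
        )
        if L_null is None:
            L_null = fit.chol_V
            yt_null = linalg.solve_triangular(L_null, y, lower=True,
                                              check_finite=False)
            logdet_null = 2.0 * np.log(np.diag(L_null)).sum()
        # profile log-likelihood of this model at the common (null) V
        Xt = linalg.solve_triangular(L_null, X0, lower=True, check_finite=False)
        Q, _ = np.linalg.qr(Xt)
        rss = float(yt_null @ yt_null - (Q.T @ yt_null) @ (Q.T @ yt_null))
        ll_fixedV = -0.5 * (n * np.log(2 * np.pi) + logdet_null + rss)
        ebics.append(compute_ebic(fit, k=len(path), p=p, gamma=gamma,
                                  df=X0.shape[1], loglik=ll_fixedV))
        vcs.append((fit.sigma2_a, fit.sigma2_d, fit.sigma2_e))
        if step == max_steps or not remaining:
            break
        tester = MarkerTester(fit, y)
        idx = [col[s] for s in remaining]
        tests = tester.test_all(Xa[:, idx], Wd[:, idx])
        if scan_pvalues is None:
            scan_pvalues = pd.Series({s: t.pvalue for s, t in zip(remaining, tests)},
                                     name="pvalue")
        best_s, best_t = min(zip(remaining, tests), key=lambda st: order_key(*st))
        if best_t.pvalue >= 1.0:
            break
        path.append(best_s)
        admit_p.append(best_t.pvalue)
        effects_rows.append({"snp": best_s, "theta_a": best_t.theta_a,
                             "theta_d": best_t.theta_d})
        remaining.remove(best_s)

    selected_step = int(np.argmin(ebics))
    effects = pd.DataFrame(effects_rows).set_index("snp") if effects_rows else \
        pd.DataFrame(columns=["theta_a", "theta_d"])
    return ForwardSelectionResult(
        path=path, admit_pvalues=admit_p, ebic=ebics, gamma=float(gamma),
        selected_step=selected_step, scan_pvalues=scan_pvalues,
        effects=effects, variance_components=vcs,
    )


# ---------------------------------------------------------------------------
# genomic heritability (single additive kinship)
# ---------------------------------------------------------------------------

def h2g_eigendecomposition(K_a) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the baseline-normalized additive kinship,
    reusable across features in :func:`estimate_h2g`."""
    from .genostruct import normalize_kinship

    return np.linalg.eigh(normalize_kinship(K_a))


def estimate_h2g(
    y: np.ndarray,
    K_a: pd.DataFrame | np.ndarray,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """h2_g = sigma2_a / (sigma2_a + sigma2_e) from an additive-only REML fit.

    The AIS kinship is baseline-normalized first (see
    :func:`mgwaskit.genostruct.normalize_kinship`) so the ratio reads as the
    fraction of phenotypic variance captured by the additive relationship.
    A single kinship admits the spectral shortcut: rotate by the
    eigenvectors once, then the REML criterion is a cheap 1-d function of
    the variance ratio lambda = sigma2_a / sigma2_e.  Pass
    ``eig=h2g_eigendecomposition(K_a)`` to reuse a decomposition across
    features.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if np.var(y) == 0:
        raise ValueError("phenotype has zero variance; h2g undefined")
    if eig is None:
        eig = h2g_eigendecomposition(K_a)
    s, U = eig
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def crit(log_lam: float) -> float:
        lam = np.exp(np.clip(log_lam, -_LOG_RATIO_BOUND, _LOG_RATIO_BOUND))
        d = lam * s + 1.0
        xx = float((xt * xt / d).sum())
        xy = float((xt * yt / d).sum())
        yy = float((yt * yt / d).sum())
        quad = yy - xy * xy / xx
        if quad <= 0 or xx <= 0:
            return 1e30
        return 0.5 * ((n - 1) * np.log(quad) + np.log(d).sum() + np.log(xx))

    grid = np.linspace(-12.0, 12.0, 49)
    vals = [crit(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(crit, bounds=(g0 - 1.0, g0 + 1.0),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    lam = float(np.exp(np.clip(res.x, -_LOG_RATIO_BOUND, _LOG_RATIO_BOUND)))
    h2 = lam / (1.0 + lam)
    return float(min(max(h2, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Tukey genotypic classes
# ---------------------------------------------------------------------------

GENOTYPE_CLASS_LABELS = {0.0: "00", 1.0: "01|10", 2.0: "11"}


def tukey_classes(y: np.ndarray, codes: np.ndarray, alpha: float = 0.05) -> dict[str, str]:
    """Compact-letter display of genotype-group means (Tukey HSD, alpha=0.05).

    Groups sharing a letter are not significantly different.  Groups with a
    single observation cannot be tested and receive the union of all letters
    (merged-letter fallback); letters are assigned by maximal cliques of the
    "not significantly different" graph ordered by group mean.
    """
    y = np.asarray(y, dtype=float).ravel()
    codes = np.asarray(codes, dtype=float).ravel()
    labels = np.array([GENOTYPE_CLASS_LABELS.get(c, str(c)) for c in codes])
    groups = [g for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty genotype groups")
    sizes = {g: int((labels == g).sum()) for g in groups}
    testable = [g for g in groups if sizes[g] >= 2]
    small = [g for g in groups if sizes[g] < 2]
    if small:
        logger.warning("genotype groups with <2 observations: %s", small)
    if len(testable) < 2:
        return {g: "a" for g in groups}

    mask = np.isin(labels, testable)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(y[mask], labels[mask], alpha=alpha)
    uniq = list(res.groupsunique)
    reject = {}
    pairs = [(i, j) for i in range(len(uniq)) for j in range(i + 1, len(uniq))]
    for (i, j), rej in zip(pairs, res.reject):
        reject[(uniq[i], uniq[j])] = bool(rej)
        reject[(uniq[j], uniq[i])] = bool(rej)

    means = {g: float(y[labels == g].mean()) for g in testable}
    order = sorted(testable, key=lambda g: means[g])

    def not_diff(a: str, b: str) -> bool:
        return not reject.get((a, b), False)

    # maximal cliques of the non-significance graph (groups are few)
    cliques: list[set[str]] = []
    m = len(order)
    for size in range(m, 0, -1):
        from itertools import combinations

        for comb in combinations(order, size):
            if all(not_diff(a, b) for a, b in zip(comb, comb[1:])) and \
               all(not_diff(a, b) for i, a in enumerate(comb) for b in comb[i + 1:]):
                cs = set(comb)
                if not any(cs <= c for c in cliques):
                    cliques.append(cs)
    cliques.sort(key=lambda c: min(means[g] for g in c))
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in testable}
    for li, c in enumerate(cliques):
        for g in order:
            if g in c:
                out[g] += letters[li]
    all_letters = "".join(letters[i] for i in range(len(cliques)))
    for g in small:
        out[g] = all_letters  # untestable: merged letters
    return out


# ---------------------------------------------------------------------------
# per-feature GWAS driver and plot table
# ---------------------------------------------------------------------------

@dataclass
class GwasResult:
    per_feature: dict[str, ForwardSelectionResult]
    associations: pd.DataFrame  # feature, reference_snp, pvalue, theta_a, theta_d, step
    h2g: pd.Series

    @property
    def n_features(self) -> int:
        return len(self.per_feature)


def run_gwas(
    phenotypes: pd.DataFrame,
    kin: KinshipPair,
    candidates: DesignMatrices,
    snp_map: pd.DataFrame | None = None,
    max_steps: int = 20,
    gamma: float | None = None,
    log_transform: bool = True,
    compute_h2: bool = True,
) -> GwasResult:
    """Forward-selection GWAS of every feature column plus h2_g per feature.

    ``phenotypes`` is samples x features (intensities; log-transformed here
    by default).  Samples are aligned with the kinship/design indices.
    """
    samples = kin.K_a.index
    missing = samples.difference(phenotypes.index)
    if len(missing):
        raise ValueError(f"phenotypes missing for hybrids: {list(missing[:5])}")
    Y = phenotypes.loc[samples]
    if log_transform:
        if (Y.to_numpy() <= 0).any():
            raise ValueError("log transform requires positive intensities")
        Y = np.log(Y)

    eig = h2g_eigendecomposition(kin.K_a) if compute_h2 else None

    per_feature: dict[str, ForwardSelectionResult] = {}
    assoc_rows = []
    h2 = {}
    for feat in Y.columns:
        yv = Y[feat].to_numpy(dtype=float)
        res = forward_select(yv, kin, candidates, max_steps=max_steps,
                             gamma=gamma, snp_map=snp_map)
        per_feature[feat] = res
        for step, snp in enumerate(res.selected_snps, start=1):
            eff = res.effects.loc[snp]
            assoc_rows.append({
                "feature": feat, "reference_snp": snp,
                "pvalue": res.admit_pvalues[step - 1],
                "theta_a": float(eff["theta_a"]), "theta_d": float(eff["theta_d"]),
                "step": step,
            })
        if compute_h2:
            h2[feat] = estimate_h2g(yv, kin.K_a, eig=eig)

    associations = pd.DataFrame(
        assoc_rows, columns=["feature", "reference_snp", "pvalue",
                             "theta_a", "theta_d", "step"])
    return GwasResult(per_feature=per_feature, associations=associations,
                      h2g=pd.Series(h2, name="h2g", dtype=float))


def manhattan_table(result: ForwardSelectionResult, snp_map: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table: chrom, pos, -log10 p per tested reference SNP, with
    the eBIC-selected cofactors flagged."""
    if result.scan_pvalues is None:
        raise ValueError("no scan p-values recorded")
    pv = result.scan_pvalues
    selected = set(result.selected_snps)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(np.clip(pv.to_numpy(), 1e-300, None))
    return pd.DataFrame({
        "snp": pv.index,
        "chrom": snp_map.loc[pv.index, "chrom"].to_numpy(),
        "pos": snp_map.loc[pv.index, "pos"].to_numpy(),
        "pvalue": pv.to_numpy(),
        "neglog10_p": neglog,
        "ebic_selected": [s in selected for s in pv.index],
    }).reset_index(drop=True)
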