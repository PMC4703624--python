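"""Variance components by AI-REML and the pool-level heritability estimators.

The mixed model is

    y = X t + sum_u Z_u u_u + e,     u_u ~ N(0, A_u sigma2_u),  e ~ N(0, I sigma2_e)

with A_u an identity or a supplied genomic relationship matrix.  Variance
components are estimated by restricted maximum likelihood using the
average-information (AI) algorithm: a quasi-Newton update whose curvature
matrix is the average of the observed and expected information,

    AI_ij = 0.5 * y' P V_i P V_j P y,      score_i = -0.5 (tr(P V_i) - y' P V_i P y),

where V_i = Z_i A_i Z_i' (V for the residual is I) and
P = Vinv - Vinv X (X' Vinv X)^-1 X' Vinv.  The first iterations use EM
updates for stability, and any AI step that would decrease the REML
log-likelihood falls back to an EM step, so the objective is non-decreasing
across accepted iterations.  Negative proposals are truncated at a small
positive floor.

Two computational kernels share this algorithm: a generic dense kernel, and
a diagonal kernel used after rotating balanced family-replicate GBLUP models
into the eigenbasis of the relationship matrix (an orthogonal data
transformation, under which the REML likelihood is invariant), which makes
each iteration O(n) instead of O(n^3).

From a fit, total phenotypic variance is evaluated as

    var(y) = meandiag(G) sigma2_g + sigma2_f + wwdiag sigma2_p + sigma2_e

and the three heritability estimators are

    h2_G     = sigma2_g / var(y)
    h2_G+PP  = (sigma2_g + wwdiag sigma2_p) / var(y)
    H2       = (meandiag(G) sigma2_g + wwdiag sigma2_p + sigma2_f) / var(y)

with delta-method standard errors from the inverse-AI covariance of the
variance-component estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg as sla

from .errors import ConvergenceError, ValidationError
from .grm import GenomicRelationshipMatrix

log = logging.getLogger(__name__)

RESIDUAL = "residual"

# canonical coefficient of each component in the var(y) decomposition:
# genomic -> mean GRM diagonal, parent_population -> WW' diagonal, others -> 1
GENOMIC = "genomic"
FAMILY = "family"
PARENT_POP = "parent_population"


# ---------------------------------------------------------------------------
# model specification


def incidence_matrix(labels: Sequence) -> tuple[np.ndarray, list]:
    """0/1 observation-by-level design matrix from a label vector."""
    labels = list(labels)
    levels = sorted(set(labels))
    idx = {lv: k for k, lv in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    for i, lab in enumerate(labels):
        Z[i, idx[lab]] = 1.0
    return Z, levels


@dataclass
class RandomTerm:
    """One random term: incidence design Z and covariance structure A (None=I)."""

    name: str
    design: np.ndarray
    cov: Optional[np.ndarray] = None

    def __post_init__(self):
        self.design = np.asarray(self.design, dtype=float)
        if self.design.ndim != 2:
            raise ValidationError(f"term {self.name}: design must be 2-D")
        if self.cov is not None:
            self.cov = np.asarray(self.cov, dtype=float)
            q = self.design.shape[1]
            if self.cov.shape != (q, q):
                raise ValidationError(
                    f"term {self.name}: covariance shape {self.cov.shape} does not "
                    f"match {q} levels"
                )
            if not np.allclose(self.cov, self.cov.T, atol=1e-8):
                raise ValidationError(f"term {self.name}: covariance not symmetric")

    @property
    def n_levels(self) -> int:
        return self.design.shape[1]

    def vmat(self) -> np.ndarray:
        if self.cov is None:
            return self.design @ self.design.T
        return self.design @ self.cov @ self.design.T


@dataclass
class MixedModelSpec:
    """Response, fixed design and random terms, plus iteration controls."""

    y: np.ndarray
    X: np.ndarray
    random_terms: list
    start: Optional[np.ndarray] = None
    max_iter: int = 200
    tol_param: float = 1e-8
    tol_loglik: float = 1e-9
    n_em: int = 2

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.size:
            raise ValidationError("X row count does not match length of y")
        for t in self.random_terms:
            if t.design.shape[0] != self.y.size:
                raise ValidationError(f"term {t.name}: design rows do not match y")


@dataclass
class VarianceComponentFit:
    """REML estimates with their asymptotic (inverse-AI) covariance."""

    names: list                      # component order; last entry is residual
    estimates: dict                  # name -> sigma2
    cov: np.ndarray                  # asymptotic covariance, same order as names
    loglik: float
    n_iter: int
    converged: bool
    history: list = field(default_factory=list)   # (theta, loglik) per iteration

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.estimates[n] for n in self.names])


@dataclass
class HeritabilityEstimates:
    h2_G: float
    h2_G_PP: float
    H2: float
    var_y: float
    components: dict                 # var(y) decomposition, name -> contribution
    se: dict                         # estimator name -> delta-method SE


# ---------------------------------------------------------------------------
# REML kernels


class _DenseKernel:
    """Generic kernel: covariance parts are dense n x n matrices."""

    def __init__(self, y, X, parts):
        self.y, self.X, self.parts = y, X, parts   # parts excl. residual
        self.n, self.p = X.shape

    def _part(self, i):
        return self.parts[i] if i < len(self.parts) else None  # None = identity

    def quantities(self, theta):
        n, p = self.n, self.p
        V = theta[-1] * np.eye(n)
        for t, Vi in zip(theta[:-1], self.parts):
            V += t * Vi
        c = sla.cho_factor(V, lower=True)
        logdetV = 2.0 * np.sum(np.log(np.diag(c[0])))
        Vinv = sla.cho_solve(c, np.eye(n))
        VinvX = sla.cho_solve(c, self.X)
        Vinvy = sla.cho_solve(c, self.y)
        C = self.X.T @ VinvX
        cC = sla.cho_factor(C, lower=True)
        logdetC = 2.0 * np.sum(np.log(np.diag(cC[0])))
        Py = Vinvy - VinvX @ sla.cho_solve(cC, self.X.T @ Vinvy)
        ll = -0.5 * (logdetV + logdetC + float(self.y @ Py))

        m = len(theta)
        trPV = np.empty(m)
        yPVPy = np.empty(m)
        W = np.empty((m, n))
        for i in range(m):
            Vi = self._part(i)
            if Vi is None:
                trVinvVi = float(np.trace(Vinv))
                T = VinvX.T @ VinvX
                w = Py.copy()
            else:
                trVinvVi = float(np.sum(Vinv * Vi))
                T = VinvX.T @ (Vi @ VinvX)
                w = Vi @ Py
            trPV[i] = trVinvVi - float(np.trace(sla.cho_solve(cC, T)))
            yPVPy[i] = float(Py @ w)
            W[i] = w
        # AI_ij = 0.5 w_i' P w_j
        U = sla.cho_solve(c, W.T)                     # Vinv w_j
        PW = U - VinvX @ sla.cho_solve(cC, self.X.T @ U)
        AI = 0.5 * (W @ PW)
        AI = 0.5 * (AI + AI.T)
        score = -0.5 * (trPV - yPVPy)
        return ll, score, AI, trPV, yPVPy


class _DiagKernel:
    """Kernel for models whose covariance parts are all diagonal."""

    def __init__(self, y, X, parts):
        self.y, self.X = y, X
        self.parts = parts                            # list of (n,) vectors
        self.n, self.p = X.shape

    def _part(self, i):
        return self.parts[i] if i < len(self.parts) else None

    def quantities(self, theta):
        v = np.full(self.n, theta[-1])
        for t, d in zip(theta[:-1], self.parts):
            v = v + t * d
        vinv = 1.0 / v
        VinvX = self.X * vinv[:, None]
        C = self.X.T @ VinvX
        cC = sla.cho_factor(C, lower=True)
        logdetC = 2.0 * np.sum(np.log(np.diag(cC[0])))
        Vinvy = self.y * vinv
        Py = Vinvy - VinvX @ sla.cho_solve(cC, self.X.T @ Vinvy)
        ll = -0.5 * (float(np.sum(np.log(v))) + logdetC + float(self.y @ Py))

        m = len(theta)
        trPV = np.empty(m)
        yPVPy = np.empty(m)
        W = np.empty((m, self.n))
        for i in range(m):
            d = self._part(i)
            dv = np.ones(self.n) if d is None else d
            T = VinvX.T @ (dv[:, None] * VinvX)
            trPV[i] = float(np.sum(dv * vinv)) - float(np.trace(sla.cho_solve(cC, T)))
            w = dv * Py
            yPVPy[i] = float(Py @ w)
            W[i] = w
        U = W.T * vinv[:, None]
        PW = U - VinvX @ sla.cho_solve(cC, self.X.T @ U)
        AI = 0.5 * (W @ PW)
        AI = 0.5 * (AI + AI.T)
        score = -0.5 * (trPV - yPVPy)
        return ll, score, AI, trPV, yPVPy


def _reduce_design(X: np.ndarray) -> np.ndarray:
    """Full-column-rank basis of X (REML is invariant to reparameterization)."""
    X = np.atleast_2d(X)
    if X.shape[1] == 0:
        raise ValidationError("fixed-effect design has no columns")
    _, R, piv = sla.qr(X, pivoting=True, mode="economic")
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > max(X.shape) * np.finfo(float).eps * diag.max()))
    if rank == 0:
        raise ValidationError("fixed-effect design is singular (rank 0)")
    return X[:, np.sort(piv[:rank])]


def _ai_reml(kernel, q_levels, start, max_iter, tol_param, tol_loglik, n_em):
    y, X = kernel.y, kernel.X
    n, p = kernel.n, kernel.p
    m = len(q_levels)
    if n - p < 1:
        raise ValidationError("no residual degrees of freedom")
    # starting values: equal partition of the OLS residual variance
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = float(resid @ resid) / max(n - p, 1)
    theta = np.asarray(start, dtype=float).copy() if start is not None else np.full(m, s2 / m)
    if theta.shape != (m,) or (theta <= 0).any():
        raise ValidationError("starting values must be positive, one per component")
    floor = 1e-8 * s2
    q_levels = np.asarray(q_levels, dtype=float)

    def em_step(th, score_aux):
        trPV, yPVPy = score_aux
        return np.maximum(th + th ** 2 * (yPVPy - trPV) / q_levels, floor)

    ll, score, AI, trPV, yPVPy = kernel.quantities(theta)
    history = [(theta.copy(), ll)]
    converged = False
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        if it < n_em:
            theta_new = em_step(theta, (trPV, yPVPy))
            new_q = None
        else:
            free = (theta > floor * (1 + 1e-6)) | (score > 0)
            delta = np.zeros(m)
            if free.any():
                Af = AI[np.ix_(free, free)]
                try:
                    delta[free] = np.linalg.solve(Af, score[free])
                except np.linalg.LinAlgError:
                    delta[free] = np.linalg.lstsq(Af, score[free], rcond=None)[0]
            theta_new = np.maximum(theta + delta, floor)
            new_q = kernel.quantities(theta_new)
            if new_q[0] < ll - 1e-10:   # AI step decreased the objective -> EM
                theta_new = em_step(theta, (trPV, yPVPy))
                new_q = None
        if new_q is None:
            new_q = kernel.quantities(theta_new)
        dll = new_q[0] - ll
        dpar = float(np.max(np.abs(theta_new - theta) / np.maximum(np.abs(theta), floor)))
        theta = theta_new
        ll, score, AI, trPV, yPVPy = new_q
        history.append((theta.copy(), ll))
        if it >= n_em and (abs(dll) < tol_loglik or dpar < tol_param):
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"AI-REML did not converge in {max_iter} iterations", history=history
        )
    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(AI)
    return theta, cov, ll, n_iter, history


# ---------------------------------------------------------------------------
# public fitting interfaces


def reml_loglik(theta, y, X, parts, diag: bool = False) -> float:
    """REML log-likelihood (constants dropped) at variance components theta.

    ``parts`` are the covariance contributions of the random terms (dense
    matrices, or diagonal vectors with ``diag=True``); the residual identity
    is implicit and ``theta[-1]`` is the residual variance.
    """
    X = _reduce_design(np.atleast_2d(np.asarray(X, dtype=float)))
    kernel = (_DiagKernel if diag else _DenseKernel)(np.asarray(y, float).ravel(), X, list(parts))
    return kernel.quantities(np.asarray(theta, dtype=float))[0]


def reml_fit(spec: MixedModelSpec) -> VarianceComponentFit:
    """Fit the mixed model by dense AI-REML."""
    X = _reduce_design(spec.X)
    parts = [t.vmat() for t in spec.random_terms]
    q_levels = [t.n_levels for t in spec.random_terms] + [spec.y.size]
    kernel = _DenseKernel(spec.y, X, parts)
    theta, cov, ll, n_iter, history = _ai_reml(
        kernel, q_levels, spec.start, spec.max_iter, spec.tol_param,
        spec.tol_loglik, spec.n_em,
    )
    names = [t.name for t in spec.random_terms] + [RESIDUAL]
    return VarianceComponentFit(
        names=names,
        estimates=dict(zip(names, theta)),
        cov=cov,
        loglik=ll,
        n_iter=n_iter,
        converged=True,
        history=history,
    )


def fit_family_gblup(
    y: np.ndarray,
    family: np.ndarray,
    G: np.ndarray,
    include_family: str | bool = "auto",
    **controls,
) -> VarianceComponentFit:
    """GBLUP fit for family-replicated phenotypes with a fast exact path.

    ``family`` maps each observation to a family index 0..q-1 matching the
    rows of ``G``.  With one observation per family an iid family term is
    confounded with the residual and is always omitted; with a balanced two
    observations per family it is included by default (``include_family=
    "auto"``).  Balanced designs are rotated into the eigenbasis of G (sums
    and differences of the two replicates, then the eigenvector rotation), an
    orthogonal transformation under which the REML likelihood is unchanged,
    and fitted with the O(n)-per-iteration diagonal kernel.  Unbalanced data
    fall back to the dense kernel.
    """
    y = np.asarray(y, dtype=float).ravel()
    family = np.asarray(family)
    if isinstance(G, GenomicRelationshipMatrix):
        G = G.G
    G = np.asarray(G, dtype=float)
    q = G.shape[0]
    counts = np.bincount(family, minlength=q)
    opts = dict(start=None, max_iter=200, tol_param=1e-8, tol_loglik=1e-9, n_em=2)
    opts.update(controls)

    if (counts == 1).all():
        if include_family is True:
            raise ValidationError(
                "iid family term is not identifiable with one replicate per family"
            )
        order = np.argsort(family)
        lam, U = np.linalg.eigh(G)
        ystar = U.T @ y[order]
        Xstar = (U.T @ np.ones(q))[:, None]
        kernel = _DiagKernel(ystar, Xstar, [lam])
        theta, cov, ll, n_iter, history = _ai_reml(kernel, [q, q], **opts)
        names = [GENOMIC, RESIDUAL]
    elif (counts == 2).all():
        use_family = include_family in ("auto", True)
        if include_family == "auto":
            log.debug("two replicates per family: iid family term included")
        idx = np.argsort(family, kind="stable")
        y2 = y[idx].reshape(q, 2)
        sums = (y2[:, 0] + y2[:, 1]) / np.sqrt(2.0)
        diffs = (y2[:, 0] - y2[:, 1]) / np.sqrt(2.0)
        lam, U = np.linalg.eigh(G)
        ystar = np.concatenate([U.T @ sums, diffs])
        Xstar = np.concatenate([np.sqrt(2.0) * (U.T @ np.ones(q)), np.zeros(q)])[:, None]
        zeros = np.zeros(q)
        d_g = np.concatenate([2.0 * lam, zeros])
        parts = [d_g]
        names = [GENOMIC]
        q_levels = [q]
        if use_family:
            parts.append(np.concatenate([2.0 * np.ones(q), zeros]))
            names.append(FAMILY)
            q_levels.append(q)
        kernel = _DiagKernel(ystar, Xstar, parts)
        theta, cov, ll, n_iter, history = _ai_reml(kernel, q_levels + [2 * q], **opts)
        names.append(RESIDUAL)
    else:
        # unbalanced: generic dense fit
        Z = np.zeros((y.size, q))
        Z[np.arange(y.size), family] = 1.0
        terms = [RandomTerm(GENOMIC, Z, G)]
        if include_family is True or (include_family == "auto" and (counts >= 2).any()):
            terms.append(RandomTerm(FAMILY, Z))
        spec = MixedModelSpec(y=y, X=np.ones((y.size, 1)), random_terms=terms, **opts)
        return reml_fit(spec)
    return VarianceComponentFit(
        names=names,
        estimates=dict(zip(names, theta)),
        cov=cov,
        loglik=ll,
        n_iter=n_iter,
        converged=True,
        history=history,
    )


# ---------------------------------------------------------------------------
# heritability estimators


def _vary_coefficients(names, mean_diag, ww_diag) -> np.ndarray:
    coef = []
    for n in names:
        if n == GENOMIC:
            coef.append(mean_diag)
        elif n == PARENT_POP:
            coef.append(ww_diag)
        else:                      # family, residual, any other iid term
            coef.append(1.0)
    return np.array(coef)


def total_variance(fit: VarianceComponentFit, mean_diag: float, ww_diag: float = 2.0) -> float:
    """var(y) = meandiag*sigma2_g + sigma2_f + wwdiag*sigma2_p + sigma2_e."""
    if mean_diag < 0:
        raise ValidationError("mean_diag must be non-negative")
    coef = _vary_coefficients(fit.names, mean_diag, ww_diag)
    return float(coef @ fit.theta)


def heritability_se(fit: VarianceComponentFit, mean_diag: float, ww_diag: float = 2.0) -> dict:
    """Delta-method standard errors of the three heritability ratios."""
    theta = fit.theta
    coef = _vary_coefficients(fit.names, mean_diag, ww_diag)
    vary = float(coef @ theta)
    numerators = _heritability_numerators(fit.names, mean_diag, ww_diag)
    cov = fit.cov
    eigmin = float(np.linalg.eigvalsh(0.5 * (cov + cov.T)).min())
    psd_ok = eigmin >= -1e-10 * max(1.0, float(np.abs(cov).max()))
    if not psd_ok:
        log.warning("asymptotic covariance is not PSD; heritability SEs undefined")
    se = {}
    for est, a in numerators.items():
        num = float(a @ theta)
        grad = (a * vary - num * coef) / vary ** 2
        if psd_ok:
            se[est] = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        else:
            se[est] = float("nan")
    return se


def _heritability_numerators(names, mean_diag, ww_diag):
    def a_for(weights):
        return np.array([weights.get(n, 0.0) for n in names])

    return {
        "h2_G": a_for({GENOMIC: 1.0}),
        "h2_G_PP": a_for({GENOMIC: 1.0, PARENT_POP: ww_diag}),
        "H2": a_for({GENOMIC: mean_diag, PARENT_POP: ww_diag, FAMILY: 1.0}),
    }


def heritabilities(
    fit: VarianceComponentFit, mean_diag: float, ww_diag: float = 2.0
) -> HeritabilityEstimates:
    """The three heritability estimators with delta-method standard errors.

    The genomic variance enters H2 and var(y) multiplied by the mean diagonal
    of the GRM used in the fit; the parent-population variance enters
    multiplied by the diagonal of WW' (2 when every family has two parents
    from two parent populations).  Terms absent from the fit contribute 0.
    """
    vary = total_variance(fit, mean_diag, ww_diag)
    if vary <= 0:
        raise ValidationError("total variance must be positive")
    theta = fit.theta
    nums = _heritability_numerators(fit.names, mean_diag, ww_diag)
    h2_G = float(nums["h2_G"] @ theta) / vary
    h2_G_PP = float(nums["h2_G_PP"] @ theta) / vary
    H2 = float(nums["H2"] @ theta) / vary
    coef = _vary_coefficients(fit.names, mean_diag, ww_diag)
    components = {n: float(c * t) for n, c, t in zip(fit.names, coef, theta)}
    return HeritabilityEstimates(
        h2_G=h2_G,
        h2_G_PP=h2_G_PP,
        H2=H2,
        var_y=vary,
        components=components,
        se=heritability_se(fit, mean_diag, ww_diag),
    )
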