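"""Univariate mixed-linear-model fitting by REML.

Model: y = X beta + g + e with cov(g) = G sigma2_g, cov(e) = I sigma2_e and
G = Z Z' / M the genomic relationship matrix, so V = G sigma2_g + I sigma2_e.
Two maximizers of the restricted likelihood are provided:

``airml_fit``
    Average-information REML: Newton-type updates using the AI matrix
    (the average of observed and expected information), with step-halving
    and boundary clamping.  The AI matrix at the optimum furnishes standard
    errors.

``reml_fit_eigen``
    The eigen-rotation fast path: in the eigenbasis of G the covariance is
    sigma2_e * diag(delta * d_k + 1) with delta = sigma2_g / sigma2_e, so
    sigma2_e and the fixed effects can be profiled out and the restricted
    likelihood maximized over log10(delta) by Brent's method.

Both paths evaluate the identical restricted likelihood (the constant
-(N-c)/2*log(2*pi) is omitted in both) and agree to high precision; this
equivalence is a core correctness check of the package.

All trace and quadratic forms are evaluated in a diagonalized
representation of the problem: the spectral basis of G, or the left singular
basis of Z when the GRM is given implicitly as Z Z' / M.  When Z has fewer
columns than samples, the components of y and X lying in the null space of
G are carried exactly as synthetic zero-eigenvalue coordinates, so the
representation is algebraically exact (no approximation) at any rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy.optimize import minimize_scalar

from .genotype_io import StandardizedGenotypes
from .grm import GRM, GRMEigen, eigendecompose_grm


class SingularModelError(ValueError):
    """V or X'V^-1X is numerically singular."""


@dataclass
class MLMData:
    """Aligned phenotype, fixed-effect design and genomic covariance.

    Exactly one of ``grm`` / ``z`` may be omitted; when ``z`` is given the
    GRM is implied as Z Z' / M.  ``x`` defaults to an intercept-only design.
    Rows of ``y``, ``x`` and the GRM/Z must refer to the same samples in the
    same order.
    """

    y: np.ndarray
    x: np.ndarray | None = None
    grm: GRM | None = None
    z: StandardizedGenotypes | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        n = self.y.size
        if self.x is None:
            self.x = np.ones((n, 1))
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.x.ndim == 1:
            self.x = self.x[:, None]
        if self.x.shape[0] != n:
            raise ValueError("X row count does not match y")
        c = self.x.shape[1]
        if n <= c:
            raise ValueError("need more samples than fixed effects")
        if np.linalg.matrix_rank(self.x) < c:
            raise ValueError("fixed-effect design X is rank deficient")
        if self.grm is None and self.z is None:
            raise ValueError("one of grm or z is required")
        if self.grm is not None and self.grm.n_samples != n:
            raise ValueError("GRM dimension does not match y")
        if self.z is not None and self.z.n_samples != n:
            raise ValueError("Z row count does not match y")
        self._rep: _DiagonalizedMLM | None = None

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def c(self) -> int:
        return self.x.shape[1]

    def rep(self, grm_eigen: GRMEigen | None = None) -> "_DiagonalizedMLM":
        if self._rep is None:
            self._rep = _DiagonalizedMLM.build(self, grm_eigen)
        return self._rep


@dataclass
class VarianceComponents:
    """REML estimates of (sigma2_g, sigma2_e) with uncertainty and diagnostics.

    ``h2 = sigma2_g / (sigma2_g + sigma2_e)``.  ``boundary`` is set when a
    component sits at its lower constraint (1e-6 * var(y)).  ``loglik`` is
    the restricted log-likelihood without the constant -(N-c)/2*log(2*pi).
    ``loglik_path`` records the value after each accepted iteration.
    """

    sigma2_g: float
    sigma2_e: float
    h2: float
    se_sigma2_g: float
    se_sigma2_e: float
    se_h2: float
    loglik: float
    n_iter: int
    converged: bool
    boundary: bool
    loglik_path: list = field(default_factory=list)


@dataclass
class _DiagonalizedMLM:
    """Exact diagonal-covariance form of an MLM problem.

    Coordinates k = 1..K carry eigenvalue ``d[k]``, rotated phenotype
    ``yt[k]`` and design row ``xt[k]``; a further ``n_extra`` coordinates
    have d = 0 and no phenotype/design content (they contribute only
    degrees of freedom and log|V| terms).
    """

    d: np.ndarray
    yt: np.ndarray
    xt: np.ndarray
    n_extra: int
    n: int
    c: int

    @classmethod
    def build(cls, data: MLMData, grm_eigen: GRMEigen | None = None
              ) -> "_DiagonalizedMLM":
        n, c = data.n, data.c
        if grm_eigen is not None or data.grm is not None:
            eig = grm_eigen if grm_eigen is not None else eigendecompose_grm(data.grm)
            if eig.vectors.shape[0] != n:
                raise ValueError("eigendecomposition does not match data")
            d = np.maximum(eig.values, 0.0)
            u = eig.vectors
            return cls(d, u.T @ data.y, u.T @ data.x, 0, n, c)

        zmat = data.z.values
        m = data.z.n_snps
        u, s, _ = np.linalg.svd(zmat, full_matrices=False)
        d = s**2 / m
        yt = u.T @ data.y
        xt = u.T @ data.x
        r = d.size
        if r >= n:
            return cls(d, yt, xt, 0, n, c)
        # exact null-space content of [X y] as synthetic zero-eigenvalue rows
        a = np.column_stack([data.x, data.y])
        at = np.column_stack([xt, yt])
        s0 = a.T @ a - at.T @ at
        s0 = (s0 + s0.T) / 2.0
        w, q = np.linalg.eigh(s0)
        tol = max(np.trace(s0), 1.0) * 1e-12
        keep = w > tol
        k = min(int(keep.sum()), n - r)
        order = np.argsort(w)[::-1][:k]
        f = q[:, order] * np.sqrt(w[order])       # (c+1, k)
        d_full = np.concatenate([d, np.zeros(k)])
        yt_full = np.concatenate([yt, f[c, :]])
        xt_full = np.vstack([xt, f[:c, :].T])
        return cls(d_full, yt_full, xt_full, n - r - k, n, c)

    # -- likelihood machinery ------------------------------------------------

    def _solve(self, sg: float, se: float):
        lam = sg * self.d + se
        if se <= 0 or (lam <= 0).any():
            raise ValueError("variance components give non-PD V")
        a = 1.0 / lam
        xtvx = self.xt.T @ (self.xt * a[:, None])
        xtvy = self.xt.T @ (a * self.yt)
        try:
            cho = sla.cho_factor(xtvx)
        except np.linalg.LinAlgError as err:
            raise SingularModelError("X'V^-1X is singular") from err
        beta = sla.cho_solve(cho, xtvy)
        p = a * (self.yt - self.xt @ beta)  # rotated Py
        ypy = float(self.yt @ p)
        logdet_v = float(np.log(lam).sum()) + self.n_extra * np.log(se)
        logdet_xvx = 2.0 * float(np.log(np.diag(cho[0])).sum())
        ll = -0.5 * (logdet_v + logdet_xvx + ypy)
        return lam, a, cho, beta, p, ll

    def loglik(self, sg: float, se: float) -> float:
        return self._solve(sg, se)[5]

    def beta_cov(self, sg: float, se: float):
        """GLS fixed effects and their covariance (X'V^-1X)^-1."""
        _, _, cho, beta, _, _ = self._solve(sg, se)
        cov = sla.cho_solve(cho, np.eye(self.c))
        return beta, cov

    def score_ai(self, sg: float, se: float):
        """REML score vector and average-information matrix at (sg, se)."""
        lam, a, cho, beta, p, ll = self._solve(sg, se)
        b = sla.cho_solve(cho, np.eye(self.c))
        ad = a * self.d
        tr_vg = float(ad.sum())
        tr_v = float(a.sum()) + self.n_extra / se
        wg = self.xt.T @ (self.xt * (a * ad)[:, None])
        wi = self.xt.T @ (self.xt * (a * a)[:, None])
        tr_pg = tr_vg - float(np.trace(b @ wg))
        tr_p = tr_v - float(np.trace(b @ wi))
        pgp = float(self.d @ (p * p))
        ppp = float(p @ p)
        score = np.array([-0.5 * (tr_pg - pgp), -0.5 * (tr_p - ppp)])

        tg = self.d * p

        def quad(u: np.ndarray, v: np.ndarray) -> float:
            xu = self.xt.T @ (a * u)
            xv = self.xt.T @ (a * v)
            return float(u @ (a * v) - xu @ (b @ xv))

        ai = 0.5 * np.array(
            [[quad(tg, tg), quad(tg, p)], [quad(tg, p), quad(p, p)]]
        )
        return score, ai, ll


def restricted_loglik(theta, data: MLMData) -> float:
    """Restricted log-likelihood at theta = (sigma2_g, sigma2_e).

    Returns -0.5 * [log|V| + log|X'V^-1X| + y'Py]; the additive constant
    -(N-c)/2*log(2*pi) is omitted, consistently across all fit paths.
    """
    sg, se = float(theta[0]), float(theta[1])
    if se <= 0:
        raise ValueError("sigma2_e must be positive")
    if sg < 0:
        raise ValueError("sigma2_g must be non-negative")
    return data.rep().loglik(sg, se)


def _se_from_ai(rep: _DiagonalizedMLM, sg: float, se: float):
    """Standard errors from the inverse AI matrix; h2 s.e. by delta method."""
    try:
        _, ai, _ = rep.score_ai(sg, se)
        cov = np.linalg.inv(ai)
    except (np.linalg.LinAlgError, SingularModelError):
        return np.nan, np.nan, np.nan
    if (np.diag(cov) < 0).any():
        return np.nan, np.nan, np.nan
    se_sg = float(np.sqrt(cov[0, 0]))
    se_se = float(np.sqrt(cov[1, 1]))
    tot = sg + se
    grad = np.array([se / tot**2, -sg / tot**2])
    var_h2 = float(grad @ cov @ grad)
    return se_sg, se_se, float(np.sqrt(max(var_h2, 0.0)))


def airml_fit(
    data: MLMData,
    max_iter: int = 100,
    tol: float = 1e-6,
    max_halvings: int = 10,
) -> VarianceComponents:
    """AI-REML: maximize the restricted likelihood over (sigma2_g, sigma2_e).

    Starting values are var(y)/2 for both components.  Each iteration takes
    a Newton step with the average-information matrix, halving the step (up
    to ``max_halvings`` times) whenever the restricted likelihood would
    decrease, and clamping components at eps = 1e-6 * var(y).  Convergence:
    |delta loglik| < tol and max relative parameter change < tol.
    Non-convergence is reported through the ``converged`` flag, not raised.
    """
    rep = data.rep()
    vary = float(np.var(data.y))
    if vary <= 0:
        raise ValueError("phenotype has zero variance")
    eps = 1e-6 * vary
    theta = np.array([vary / 2.0, vary / 2.0])
    ll = rep.loglik(*theta)
    path = [ll]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        score, ai, _ = rep.score_ai(*theta)
        try:
            delta = np.linalg.solve(ai, score)
        except np.linalg.LinAlgError:
            # singular AI: fall back to a (step-halved) gradient step
            delta = score
        step = 1.0
        accepted = None
        for _ in range(max_halvings + 1):
            cand = np.maximum(theta + step * delta, eps)
            try:
                ll_cand = rep.loglik(*cand)
            except (SingularModelError, ValueError):
                step /= 2.0
                continue
            if ll_cand >= ll - 1e-12:
                accepted = (cand, ll_cand)
                break
            step /= 2.0
        if accepted is None:
            break  # cannot improve at numerical precision
        cand, ll_cand = accepted
        rel_change = float(np.max(np.abs(cand - theta) / np.maximum(theta, eps)))
        dll = ll_cand - ll
        theta, ll = cand, ll_cand
        path.append(ll)
        if abs(dll) < tol and rel_change < tol:
            converged = True
            break
    sg, se = float(theta[0]), float(theta[1])
    boundary = bool(sg <= eps * (1 + 1e-9) or se <= eps * (1 + 1e-9))
    se_sg, se_se, se_h2 = _se_from_ai(rep, sg, se)
    return VarianceComponents(
        sigma2_g=sg, sigma2_e=se, h2=sg / (sg + se),
        se_sigma2_g=se_sg, se_sigma2_e=se_se, se_h2=se_h2,
        loglik=ll, n_iter=n_iter, converged=converged, boundary=boundary,
        loglik_path=path,
    )


def reml_fit_eigen(
    data: MLMData,
    grm_eigen: GRMEigen | None = None,
    log10_delta_bounds: tuple = (-5.0, 5.0),
    xatol: float = 1e-8,
) -> VarianceComponents:
    """Eigen-rotation REML: Brent's method on the profiled likelihood.

    For delta = sigma2_g/sigma2_e the rotated covariance is
    sigma2_e * diag(delta*d_k + 1); sigma2_e and beta are profiled out and
    the restricted likelihood is maximized over log10(delta) within
    ``log10_delta_bounds``.  A maximum at a bracket edge is reported with
    the boundary flag, with sigma2_g clamped to the same eps = 1e-6*var(y)
    convention airml_fit uses at its lower constraint.
    """
    rep = data.rep(grm_eigen)
    n, c = rep.n, rep.c
    vary = float(np.var(data.y))
    if vary <= 0:
        raise ValueError("phenotype has zero variance")

    def profile(l10d: float):
        delta = 10.0**l10d
        lam0 = delta * rep.d + 1.0
        a0 = 1.0 / lam0
        xtwx = rep.xt.T @ (rep.xt * a0[:, None])
        xtwy = rep.xt.T @ (a0 * rep.yt)
        ywy = float(rep.yt @ (a0 * rep.yt))
        cho = sla.cho_factor(xtwx)
        beta = sla.cho_solve(cho, xtwy)
        rss = ywy - float(xtwy @ beta)
        se_hat = rss / (n - c)
        logdet_xwx = 2.0 * float(np.log(np.diag(cho[0])).sum())
        ll = -0.5 * (
            (n - c) * np.log(se_hat)
            + float(np.log(lam0).sum())
            + logdet_xwx
            + (n - c)
        )
        return ll, se_hat

    res = minimize_scalar(
        lambda t: -profile(t)[0],
        bounds=log10_delta_bounds,
        method="bounded",
        options={"xatol": xatol},
    )
    l10d = float(res.x)
    ll, se_hat = profile(l10d)
    lo, hi = log10_delta_bounds
    at_lower = l10d <= lo + 1e-3
    at_upper = l10d >= hi - 1e-3
    boundary = bool(at_lower or at_upper)
    eps = 1e-6 * vary
    if at_lower:
        sg = eps
        se = se_hat
        ll = rep.loglik(sg, se)
    else:
        delta = 10.0**l10d
        se = se_hat
        sg = delta * se
    se_sg, se_se, se_h2 = _se_from_ai(rep, sg, se)
    return VarianceComponents(
        sigma2_g=float(sg), sigma2_e=float(se), h2=float(sg / (sg + se)),
        se_sigma2_g=se_sg, se_sigma2_e=se_se, se_h2=se_h2,
        loglik=float(ll), n_iter=int(res.nfev), converged=bool(res.success),
        boundary=boundary, loglik_path=[float(ll)],
    )


def gls_fixed_effects(data: MLMData, vc: VarianceComponents):
    """GLS fixed effects at the fitted variances.

    beta = (X'V^-1X)^-1 X'V^-1 y; standard errors from the diagonal of
    (X'V^-1X)^-1.
    """
    beta, cov = data.rep().beta_cov(vc.sigma2_g, vc.sigma2_e)
    return beta, np.sqrt(np.diag(cov))
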