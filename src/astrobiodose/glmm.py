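"""Poisson regression with subject-level normal random effects.

The marginal likelihood integrates the Poisson likelihood over a random
intercept, or a random intercept plus one random slope with unstructured
2x2 covariance:

    k_ij ~ Poisson(n_ij * lambda_ij),
    log lambda_ij = x_ij' beta + z_ij' u_i,      u_i ~ N(0, Sigma),

with offset log n_ij folded into the linear predictor.  The per-subject
integral is evaluated by adaptive Gauss-Hermite quadrature centered at the
subject's posterior mode with the posterior curvature as the scale; plain
(prior-centered) Gauss-Hermite is available as a fallback.  Standard errors
come from the inverse of the numerically differentiated observed information
at the optimum.  Empirical-Bayes posterior means/SDs of the random effects
are computed from the same quadrature machinery.

The covariance is parameterized unconstrained as (log sd_0[, log sd_1,
atanh rho]) for optimization; estimates are reported on the natural scale
with delta-method standard errors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

logger = logging.getLogger(__name__)

_ETA_MAX = 50.0        # clip on the linear predictor inside exp()
_SIGMA_FLOOR = 1e-10   # numerical floor when a fitted SD collapses
_SIGMA_ZERO = 1e-8     # below this both SDs count as exactly zero
_BOUNDARY_LOGSD = -5.0  # log-SD below this is flagged as a boundary fit

LOG_SD_BOUNDS = (-8.0, 4.0)
ATANH_RHO_BOUNDS = (-4.0, 4.0)


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Design for one mixed Poisson model.

    X : (n, p) fixed-effect design, columns named by ``x_names``.
    Z : (n, d) random-effect design with d in {0, 1, 2}; by convention the
        first column is the intercept.
    groups : (n,) integer codes 0..m-1 mapping rows to subjects.
    offset : (n,) log exposure (log cells scored).
    """

    X: np.ndarray
    x_names: list[str]
    Z: np.ndarray
    z_names: list[str]
    groups: np.ndarray
    group_labels: list
    offset: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.Z = np.asarray(self.Z, float).reshape(len(self.X), -1)
        self.groups = np.asarray(self.groups, int)
        self.offset = np.asarray(self.offset, float)
        n = len(self.X)
        if not (len(self.Z) == len(self.groups) == len(self.offset) == n):
            raise ValueError("design arrays must share the row dimension")
        if self.Z.shape[1] > 2:
            raise ValueError("at most two random-effect columns supported")
        if not np.all(np.isfinite(self.offset)):
            raise ValueError("offset must be finite (zero cells scored?)")
        if self.groups.min(initial=0) < 0 or (
            len(self.group_labels) and self.groups.max(initial=0) >= len(self.group_labels)
        ):
            raise ValueError("group codes out of range")

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def n_random(self) -> int:
        return self.Z.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        fixed: Sequence[str],
        random: Sequence[str],
        group: str = "subject_id",
        counts: str = "aberrations",
        exposure: str = "cells_scored",
    ) -> tuple["ModelSpec", np.ndarray]:
        """Build a spec (plus the count vector) from a long-format frame.

        ``fixed``/``random`` name columns of ``df``; the name ``"const"``
        denotes an intercept column of ones.
        """

        def col(name: str) -> np.ndarray:
            if name == "const":
                return np.ones(len(df))
            return df[name].to_numpy(float)

        # degenerate (constant) covariates are dropped: a cohort of, e.g.,
        # all-male subjects cannot identify a gender effect
        kept = []
        for c in fixed:
            if c != "const" and np.ptp(col(c)) == 0.0:
                logger.info("dropping constant design column %r", c)
                continue
            kept.append(c)
        fixed = kept
        X = np.column_stack([col(c) for c in fixed]) if fixed else np.empty((len(df), 0))
        Z = (
            np.column_stack([col(c) for c in random])
            if random
            else np.empty((len(df), 0))
        )
        codes, labels = pd.factorize(df[group])
        spec = cls(
            X=X,
            x_names=list(fixed),
            Z=Z,
            z_names=list(random),
            groups=codes,
            group_labels=list(labels),
            offset=np.log(df[exposure].to_numpy(float)),
        )
        return spec, df[counts].to_numpy(float)


# ---------------------------------------------------------------------------
# grouped (padded) data layout for vectorized per-subject integrals
# ---------------------------------------------------------------------------


class _Grouped:
    def __init__(self, spec: ModelSpec, counts: np.ndarray):
        counts = np.asarray(counts, float)
        if np.any(counts < 0):
            raise ValueError("negative counts")
        m = spec.n_groups
        sizes = np.bincount(spec.groups, minlength=m)
        jmax = max(int(sizes.max()), 1)
        n, p, d = len(counts), spec.n_fixed, spec.n_random
        self.m, self.jmax, self.p, self.d = m, jmax, p, d
        self.K = np.zeros((m, jmax))
        self.X = np.zeros((m, jmax, p))
        self.Z = np.zeros((m, jmax, d))
        self.off = np.zeros((m, jmax))
        self.mask = np.zeros((m, jmax))
        pos = np.zeros(m, int)
        for r in range(n):
            i = spec.groups[r]
            j = pos[i]
            self.K[i, j] = counts[r]
            self.X[i, j] = spec.X[r]
            self.Z[i, j] = spec.Z[r]
            self.off[i, j] = spec.offset[r]
            self.mask[i, j] = 1.0
            pos[i] += 1
        self.const = -(self.mask * gammaln(self.K + 1.0)).sum()

    def eta0(self, beta: np.ndarray) -> np.ndarray:
        return self.X @ beta + self.off


# ---------------------------------------------------------------------------
# covariance packing
# ---------------------------------------------------------------------------


def pack_params(beta: np.ndarray, sigmas: Sequence[float], rho: float = 0.0) -> np.ndarray:
    """Pack (beta, SDs, correlation) into the unconstrained vector."""
    theta = list(np.log(np.maximum(np.asarray(sigmas, float), _SIGMA_FLOOR)))
    if len(sigmas) == 2:
        theta.append(np.arctanh(np.clip(rho, -0.999, 0.999)))
    return np.concatenate([np.asarray(beta, float), theta])


def unpack_params(params: np.ndarray, p: int, d: int):
    """Inverse of :func:`pack_params`: returns (beta, sigmas, rho, Sigma)."""
    params = np.asarray(params, float)
    beta = params[:p]
    if d == 0:
        return beta, np.empty(0), 0.0, np.empty((0, 0))
    if d == 1:
        s0 = np.exp(params[p])
        return beta, np.array([s0]), 0.0, np.array([[s0**2]])
    s0, s1 = np.exp(params[p]), np.exp(params[p + 1])
    rho = np.tanh(params[p + 2])
    Sigma = np.array(
        [[s0**2, rho * s0 * s1], [rho * s0 * s1, s1**2]]
    )
    return beta, np.array([s0, s1]), float(rho), Sigma


def _sigma_inv_logdet(sigmas: np.ndarray, rho: float):
    s = np.maximum(sigmas, _SIGMA_FLOOR)
    if len(s) == 1:
        return np.array([[1.0 / s[0] ** 2]]), 2.0 * np.log(s[0])
    det = (s[0] * s[1]) ** 2 * (1.0 - rho**2)
    inv = (
        np.array(
            [[s[1] ** 2, -rho * s[0] * s[1]], [-rho * s[0] * s[1], s[0] ** 2]]
        )
        / det
    )
    return inv, float(np.log(det))


# ---------------------------------------------------------------------------
# posterior modes (vectorized Newton) and quadrature
# ---------------------------------------------------------------------------


def _solve_sym(H: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Solve H u = g for stacks of 1x1 or 2x2 symmetric H."""
    d = H.shape[-1]
    if d == 1:
        return g / H[..., 0, 0][..., None]
    a, b, c = H[..., 0, 0], H[..., 0, 1], H[..., 1, 1]
    det = a * c - b * b
    u0 = (c * g[..., 0] - b * g[..., 1]) / det
    u1 = (a * g[..., 1] - b * g[..., 0]) / det
    return np.stack([u0, u1], axis=-1)


def _modes(grp: _Grouped, eta0, Sinv, start=None, tol=1e-9, max_iter=100):
    """Per-subject posterior modes of u and the curvature H at the mode."""
    m, d = grp.m, grp.d
    u = np.zeros((m, d)) if start is None else np.array(start, float)

    def h_of(u):
        eta = np.clip(eta0 + np.einsum("ijd,id->ij", grp.Z, u), None, _ETA_MAX)
        mu = np.exp(eta) * grp.mask
        ll = (grp.mask * (grp.K * eta) - mu).sum(axis=1)
        return ll - 0.5 * np.einsum("id,de,ie->i", u, Sinv, u), mu

    h, mu = h_of(u)
    for _ in range(max_iter):
        g = np.einsum("ijd,ij->id", grp.Z, (grp.K - mu) * grp.mask) - u @ Sinv
        H = np.einsum("ijd,ij,ije->ide", grp.Z, mu, grp.Z) + Sinv
        step = _solve_sym(H, g)
        if np.max(np.abs(g)) < tol * (1.0 + np.max(np.abs(h))):
            break
        alpha = np.ones(m)
        for _ in range(40):
            u_new = u + alpha[:, None] * step
            h_new, mu_new = h_of(u_new)
            bad = h_new < h - 1e-12
            if not bad.any():
                break
            alpha[bad] *= 0.5
        u, h, mu = u_new, h_new, mu_new
    H = np.einsum("ijd,ij,ije->ide", grp.Z, mu, grp.Z) + Sinv
    return u, H


def _chol_of_inverse(H: np.ndarray):
    """Lower Cholesky L of H^{-1} plus log|L| for stacks of 1x1/2x2 H."""
    d = H.shape[-1]
    if d == 1:
        L = 1.0 / np.sqrt(H)
        return L, np.log(L[..., 0, 0])
    a, b, c = H[..., 0, 0], H[..., 0, 1], H[..., 1, 1]
    det = a * c - b * b
    C00, C01, C11 = c / det, -b / det, a / det
    L00 = np.sqrt(C00)
    L10 = C01 / L00
    L11 = np.sqrt(np.maximum(C11 - L10**2, 1e-300))
    L = np.zeros(H.shape)
    L[..., 0, 0], L[..., 1, 0], L[..., 1, 1] = L00, L10, L11
    return L, np.log(L00) + np.log(L11)


def _gh_grid(order: int, d: int):
    z, w = hermgauss(order)
    if d == 1:
        nodes = z[:, None]
        logw = np.log(w) + z**2
    else:
        Z0, Z1 = np.meshgrid(z, z, indexing="ij")
        nodes = np.column_stack([Z0.ravel(), Z1.ravel()])
        W0, W1 = np.meshgrid(w, w, indexing="ij")
        logw = np.log(W0.ravel()) + np.log(W1.ravel()) + (nodes**2).sum(axis=1)
    return nodes, logw


def _group_logliks(
    grp, eta0, sigmas, rho, quad_order, adaptive=True, start_modes=None,
    want_posterior=False,
):
    """Per-subject log marginal likelihoods (and optionally EB summaries)."""
    d = grp.d
    Sinv, logdetS = _sigma_inv_logdet(sigmas, rho)
    if adaptive:
        mode, H = _modes(grp, eta0, Sinv, start=start_modes)
        L, logdetL = _chol_of_inverse(H)
    else:
        mode = np.zeros((grp.m, d))
        Sig = np.linalg.inv(Sinv)
        Lp = np.linalg.cholesky(Sig)
        L = np.broadcast_to(Lp, (grp.m, d, d))
        logdetL = np.full(grp.m, 0.5 * np.linalg.slogdet(Sig)[1])

    z, logw = _gh_grid(quad_order, d)
    U = mode[:, None, :] + np.sqrt(2.0) * np.einsum("ide,qe->iqd", L, z)
    eta = np.clip(eta0[:, None, :] + np.einsum("iqd,ijd->iqj", U, grp.Z), None, _ETA_MAX)
    ll = (grp.mask[:, None, :] * (grp.K[:, None, :] * eta - np.exp(eta))).sum(axis=2)
    quad = np.einsum("iqd,de,iqe->iq", U, Sinv, U)
    logphi = -0.5 * (d * np.log(2 * np.pi) + logdetS + quad)
    g = ll + logphi + logw[None, :]
    logI = logsumexp(g, axis=1) + 0.5 * d * np.log(2.0) + logdetL

    if not want_posterior:
        return logI, mode
    wq = np.exp(g - logI[:, None] - 0.5 * d * np.log(2.0) - logdetL[:, None])
    # normalized posterior weights at the nodes (sum_q wq ~ 1)
    wq /= wq.sum(axis=1, keepdims=True)
    pm = np.einsum("iq,iqd->id", wq, U)
    pm2 = np.einsum("iq,iqd,iqe->ide", wq, U, U)
    var = pm2 - np.einsum("id,ie->ide", pm, pm)
    psd = np.sqrt(np.maximum(np.diagonal(var, axis1=1, axis2=2), 0.0))
    return logI, mode, pm, psd


def _exact_loglik(grp, eta0) -> float:
    eta = np.clip(eta0, None, _ETA_MAX)
    return float((grp.mask * (grp.K * eta - np.exp(eta))).sum() + grp.const)


def marginal_loglik(
    params: np.ndarray,
    spec: ModelSpec,
    counts: np.ndarray,
    quad_order: int = 7,
    adaptive: bool = True,
    _grouped: Optional[_Grouped] = None,
    _mode_cache: Optional[dict] = None,
) -> float:
    """Marginal log-likelihood of the mixed Poisson model.

    Sum over subjects of log ∫ Π_j Poisson(k_ij | n_ij λ_ij(β, u)) φ(u; 0, Σ) du,
    with the integral by (adaptive) Gauss-Hermite quadrature.  When every
    random-effect SD is (numerically) zero this reduces to the exact sum of
    Poisson log-pmfs.
    """
    if quad_order < 1:
        raise ValueError("quad_order must be >= 1")
    grp = _grouped if _grouped is not None else _Grouped(spec, counts)
    beta, sigmas, rho, _ = unpack_params(params, spec.n_fixed, spec.n_random)
    eta0 = grp.eta0(beta)
    if grp.d == 0 or np.all(sigmas < _SIGMA_ZERO):
        return _exact_loglik(grp, eta0)
    start = _mode_cache.get("modes") if _mode_cache else None
    logI, mode = _group_logliks(
        grp, eta0, sigmas, rho, quad_order, adaptive=adaptive, start_modes=start
    )
    if _mode_cache is not None:
        _mode_cache["modes"] = mode
    total = float(logI.sum() + grp.const)
    if not np.isfinite(total):
        bad = int(np.argmax(~np.isfinite(logI)))
        raise FitError(
            f"non-finite marginal likelihood for subject "
            f"{spec.group_labels[bad]!r}"
        )
    return total


# ---------------------------------------------------------------------------
# plain Poisson GLM (IRLS) used for starting values
# ---------------------------------------------------------------------------


def poisson_glm_irls(X, k, offset, tol=1e-10, max_iter=100):
    """Newton/IRLS fit of log-link Poisson regression with offset.

    Returns (beta, vcov, loglik).  Small and self-contained so that starting
    values do not depend on an external GLM implementation.
    """
    X = np.asarray(X, float)
    k = np.asarray(k, float)
    beta = np.zeros(X.shape[1])
    # initialize the intercept-like direction from the overall rate
    mean_rate = max(k.sum(), 0.5) / np.exp(offset).sum()
    eta = np.full(len(k), np.log(mean_rate)) + offset
    beta = np.linalg.lstsq(X, eta - offset, rcond=None)[0]
    ll_old = -np.inf
    for it in range(max_iter):
        eta = np.clip(X @ beta + offset, None, _ETA_MAX)
        mu = np.exp(eta)
        W = mu
        XtWX = X.T @ (X * W[:, None])
        score = X.T @ (k - mu)
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError as e:
            raise FitError("singular design in Poisson GLM (collinear columns?)") from e
        alpha = 1.0
        for _ in range(40):
            b_new = beta + alpha * step
            eta_n = np.clip(X @ b_new + offset, None, _ETA_MAX)
            ll_new = float((k * eta_n - np.exp(eta_n)).sum())
            if ll_new >= ll_old - 1e-12:
                break
            alpha *= 0.5
        beta = b_new
        if abs(ll_new - ll_old) < tol * (1.0 + abs(ll_new)):
            ll_old = ll_new
            break
        ll_old = ll_new
    mu = np.exp(np.clip(X @ beta + offset, None, _ETA_MAX))
    vcov = np.linalg.inv(X.T @ (X * mu[:, None]))
    ll = float((k * np.clip(X @ beta + offset, None, _ETA_MAX) - mu - gammaln(k + 1)).sum())
    return beta, vcov, ll


# ---------------------------------------------------------------------------
# fit result containers
# ---------------------------------------------------------------------------


@dataclass
class RandomEffectPrediction:
    """Empirical-Bayes posterior means and SDs of the random effects."""

    group_labels: list
    names: list[str]
    mean: np.ndarray  # (m, d)
    sd: np.ndarray    # (m, d)

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.mean, columns=[f"w_{n}" for n in self.names])
        for j, n in enumerate(self.names):
            df[f"sd_{n}"] = self.sd[:, j]
        df.insert(0, "group", self.group_labels)
        return df

    def by_group(self) -> dict:
        return {g: self.mean[i] for i, g in enumerate(self.group_labels)}


@dataclass
class MixedPoissonFit:
    """Maximum-likelihood fit of the mixed Poisson model."""

    spec: ModelSpec
    counts: np.ndarray
    params: np.ndarray          # packed (beta, log-SDs, atanh-rho)
    beta: np.ndarray
    se_beta: np.ndarray
    vcov_beta: np.ndarray
    sigmas: np.ndarray          # random-effect SDs, natural scale
    se_sigmas: np.ndarray
    rho: float
    se_rho: float
    loglik: float
    quad_order: int
    converged: bool
    n_iter: int
    message: str = ""
    boundary: list = field(default_factory=list)
    vcov_packed: Optional[np.ndarray] = None

    # -- accessors ---------------------------------------------------------

    @property
    def x_names(self) -> list[str]:
        return self.spec.x_names

    def coef(self, name: str, default: Optional[float] = None) -> float:
        if name not in self.x_names:
            if default is not None:
                return default
            raise KeyError(f"no coefficient {name!r} in this fit")
        return float(self.beta[self.x_names.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se_beta[self.x_names.index(name)])

    @property
    def n_obs(self) -> int:
        return len(self.counts)

    @property
    def n_groups(self) -> int:
        return self.spec.n_groups

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.params)

    def coef_table(self) -> pd.DataFrame:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se_beta > 0, self.beta / self.se_beta, np.nan)
        p = 2.0 * norm.sf(np.abs(z))
        return pd.DataFrame(
            {"est": self.beta, "se": self.se_beta, "z": z, "p": p},
            index=self.x_names,
        )

    def to_dict(self) -> dict:
        tab = self.coef_table()
        return {
            "coefficients": [
                {"name": n, "est": float(r.est), "se": float(r.se),
                 "z": float(r.z), "p": float(r.p)}
                for n, r in tab.iterrows()
            ],
            "vcov_beta": np.asarray(self.vcov_beta).tolist(),
            "random_effects": {
                "names": self.spec.z_names,
                "sd": [float(s) for s in self.sigmas],
                "sd_se": [None if not np.isfinite(s) else float(s) for s in self.se_sigmas],
                "rho": float(self.rho) if len(self.sigmas) == 2 else None,
                "rho_se": float(self.se_rho) if np.isfinite(self.se_rho) else None,
            },
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "quad_order": int(self.quad_order),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "n_obs": int(self.n_obs),
            "n_groups": int(self.n_groups),
            "boundary": list(self.boundary),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_coefficients(
        cls,
        names: Sequence[str],
        estimates: Sequence[float],
        vcov: Optional[np.ndarray] = None,
        sigmas: Sequence[float] = (),
        rho: float = 0.0,
        z_names: Sequence[str] = (),
    ) -> "MixedPoissonFit":
        """Build a fit object from externally supplied (published) coefficients.

        Used to inject printed coefficient tables into prediction and
        effect-translation operations.
        """
        names = list(names)
        est = np.asarray(estimates, float)
        p = len(names)
        V = np.asarray(vcov, float) if vcov is not None else np.full((p, p), np.nan)
        spec = ModelSpec(
            X=np.zeros((1, p)), x_names=names,
            Z=np.zeros((1, len(z_names))), z_names=list(z_names),
            groups=np.zeros(1, int), group_labels=["_"], offset=np.zeros(1),
        )
        return cls(
            spec=spec, counts=np.zeros(1), params=est.copy(), beta=est,
            se_beta=np.sqrt(np.maximum(np.diag(V), 0.0)), vcov_beta=V,
            sigmas=np.asarray(sigmas, float), se_sigmas=np.full(len(sigmas), np.nan),
            rho=rho, se_rho=np.nan, loglik=np.nan, quad_order=0,
            converged=True, n_iter=0, message="injected coefficients",
        )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _numerical_hessian(f, x, rel_step=1e-4):
    """Central-difference Hessian with step rel_step*(1+|x_j|) per axis."""
    x = np.asarray(x, float)
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit(
    spec: ModelSpec,
    counts: np.ndarray,
    quad_order: int = 7,
    start: Optional[np.ndarray] = None,
    adaptive: bool = True,
    start_sigma: float = 0.3,
    max_iter: int = 300,
    compute_se: bool = True,
) -> MixedPoissonFit:
    """Maximum-likelihood fit by quasi-Newton maximization of the marginal
    likelihood; default start is the plain Poisson GLM with small positive
    random-effect SDs."""
    counts = np.asarray(counts, float)
    p, d = spec.n_fixed, spec.n_random
    if spec.n_groups < 2 and d > 0:
        raise FitError("at least 2 subjects required for a random-effects fit")
    grp = _Grouped(spec, counts)

    # ---- pure fixed-effects model: IRLS directly -------------------------
    if d == 0:
        beta, vcov, ll = poisson_glm_irls(spec.X, counts, spec.offset)
        return MixedPoissonFit(
            spec=spec, counts=counts, params=beta.copy(), beta=beta,
            se_beta=np.sqrt(np.diag(vcov)), vcov_beta=vcov,
            sigmas=np.empty(0), se_sigmas=np.empty(0), rho=0.0, se_rho=np.nan,
            loglik=ll, quad_order=quad_order, converged=True, n_iter=0,
            vcov_packed=vcov,
        )

    if start is None:
        beta0, _, _ = poisson_glm_irls(spec.X, counts, spec.offset)
        start = pack_params(beta0, [start_sigma] * d, 0.0)
    start = np.asarray(start, float)

    cache: dict = {}
    n_eval = [0]

    def nll(th):
        n_eval[0] += 1
        return -marginal_loglik(
            th, spec, counts, quad_order=quad_order, adaptive=adaptive,
            _grouped=grp, _mode_cache=cache,
        )

    bounds = [(None, None)] * p + [LOG_SD_BOUNDS] * d
    if d == 2:
        bounds.append(ATANH_RHO_BOUNDS)
    res = optimize.minimize(
        nll, start, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-11, "gtol": 1e-7},
    )
    params = res.x
    converged = bool(res.success)
    if not converged:
        logger.warning("mixed Poisson fit did not converge: %s", res.message)

    beta, sigmas, rho, _ = unpack_params(params, p, d)
    boundary = [
        spec.z_names[j] for j in range(d) if params[p + j] <= _BOUNDARY_LOGSD
    ]

    se_beta = np.full(p, np.nan)
    vcov_beta = np.full((p, p), np.nan)
    se_sig = np.full(d, np.nan)
    se_rho = np.nan
    Vp = None
    if compute_se:
        H = _numerical_hessian(nll, params)
        try:
            Vp = np.linalg.inv(H)
        except np.linalg.LinAlgError as e:
            raise FitError(
                "singular information matrix; consider a simpler random-effect "
                "structure"
            ) from e
        dg = np.diag(Vp)
        if np.any(dg[:p] < 0):
            logger.warning("information matrix not positive definite at optimum")
        vcov_beta = Vp[:p, :p]
        se_beta = np.sqrt(np.maximum(np.diag(vcov_beta), 0.0))
        for j in range(d):
            if spec.z_names[j] in boundary:
                continue  # SE suppressed at a boundary fit
            if dg[p + j] > 0:
                se_sig[j] = sigmas[j] * np.sqrt(dg[p + j])
        if d == 2 and dg[p + 2] > 0:
            se_rho = (1.0 - rho**2) * np.sqrt(dg[p + 2])

    return MixedPoissonFit(
        spec=spec, counts=counts, params=params, beta=beta, se_beta=se_beta,
        vcov_beta=vcov_beta, sigmas=sigmas, se_sigmas=se_sig, rho=rho,
        se_rho=se_rho, loglik=float(-res.fun), quad_order=quad_order,
        converged=converged, n_iter=int(res.nit), message=str(res.message),
        boundary=boundary, vcov_packed=Vp,
    )


def empirical_bayes(
    fit_result: MixedPoissonFit,
    spec: Optional[ModelSpec] = None,
    counts: Optional[np.ndarray] = None,
    quad_order: Optional[int] = None,
) -> RandomEffectPrediction:
    """Per-subject posterior means and SDs of the random effects under the
    fitted prior (prior x Poisson likelihood, normalized by quadrature)."""
    spec = spec if spec is not None else fit_result.spec
    counts = counts if counts is not None else fit_result.counts
    d = spec.n_random
    if d == 0:
        raise ValueError("model has no random effects")
    q = quad_order or max(fit_result.quad_order, 7)
    grp = _Grouped(spec, counts)
    beta, sigmas, rho, _ = unpack_params(fit_result.params, spec.n_fixed, d)
    if np.all(sigmas < _SIGMA_ZERO):
        zero = np.zeros((grp.m, d))
        return RandomEffectPrediction(spec.group_labels, spec.z_names, zero, zero)
    _, _, pm, psd = _group_logliks(
        grp, grp.eta0(beta), sigmas, rho, q, adaptive=True, want_posterior=True
    )
    return RandomEffectPrediction(list(spec.group_labels), list(spec.z_names), pm, psd)


def predict_rate(
    fit_result: MixedPoissonFit,
    covariates: dict,
    re_values: Sequence[float] = (),
    level: float = 0.95,
):
    """Predicted rate exp(eta) with a CI from the fixed-effect covariance.

    ``covariates`` maps fixed-design column names to values ("const" is
    implicit 1).  ``re_values`` are plugged-in random effects treated as known
    constants: each pairs with the corresponding random design column
    evaluated at the same covariates.
    """
    c = np.empty(len(fit_result.x_names))
    for j, name in enumerate(fit_result.x_names):
        if name == "const":
            c[j] = 1.0
        elif name in covariates:
            c[j] = covariates[name]
        else:
            raise ValueError(f"missing covariate {name!r}")
    eta = float(c @ fit_result.beta)
    for w, name in zip(re_values, fit_result.spec.z_names):
        zval = 1.0 if name == "const" else covariates.get(name)
        if zval is None:
            raise ValueError(f"missing covariate {name!r} for random term")
        eta += float(w) * zval
    V = np.asarray(fit_result.vcov_beta, float)
    if np.all(np.isfinite(V)):
        se = float(np.sqrt(max(c @ V @ c, 0.0)))
        zc = norm.ppf(0.5 + level / 2.0)
        lo, hi = np.exp(eta - zc * se), np.exp(eta + zc * se)
    else:
        lo = hi = np.nan
    return float(np.exp(eta)), float(lo), float(hi)
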