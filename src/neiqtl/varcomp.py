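"""Variance partitioning with self and neighbor genome-wide covariances.

The mixed model is

    y = X beta + u1 + u2 + e,   Var(u1) = sigma1^2 K1,  Var(u2) = sigma2^2 K2,
                                Var(e)  = sigma_e^2 I,

where K1 = P1' P1 / (q - 1) is the kinship built from expected additive
self-genotype values (codes AA, AB, BB = -1, 0, 1) over all q grid
positions, and K2 is the analogous matrix of conditional neighbor genotypic
identities under the additive-polygenic coding at a spatial scale s.
Columns of P1 / P2 are mean-centered before the cross-product.

Gaussian traits are fitted by average-information REML (Fisher-scoring and
EM fallbacks, non-negativity by projection); binary traits by penalized
quasi-likelihood on the logistic scale, which yields sigma1^2 and sigma2^2
but no residual variance, so the neighbor contribution is summarized as the
ratio RVE_nei = sigma2^2 / sigma1^2 instead of a proportion.

The effective scale of neighbor effects is chosen by the delta-PVE rule:
fit the model over a percentile grid of scales, difference consecutive
PVE_nei values (the first scale differenced against zero), and take the
scale where the increment is largest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .exceptions import (
    ConvergenceWarning,
    IsolatedIndividualsError,
    ParameterError,
    ProfileError,
)
from .genotypes import GenoProbs
from .neighbors import DistanceScales, SpatialMap, neighbor_identity
from .scan import Phenotype, _sigmoid


@dataclass
class GenomeCovariance:
    """Self (K1) and neighbor (K2) individual-similarity matrices."""

    K1: np.ndarray
    K2: np.ndarray
    q: int
    s: float | None
    source: str = "genotype"


@dataclass
class VarComps:
    """REML / PQL variance-component estimates."""

    sigma1: float
    sigma2: float
    sigma_e: float | None
    beta: np.ndarray
    loglik: float
    converged: bool
    family: str = "gaussian"
    n_iter: int = 0

    @property
    def pve_self(self) -> float:
        tot = self.sigma1 + self.sigma2 + (self.sigma_e or 0.0)
        return self.sigma1 / tot if tot > 0 else 0.0

    @property
    def pve_nei(self) -> float:
        tot = self.sigma1 + self.sigma2 + (self.sigma_e or 0.0)
        return self.sigma2 / tot if tot > 0 else 0.0

    @property
    def rve_nei(self) -> float:
        return self.sigma2 / self.sigma1 if self.sigma1 > 0 else np.inf


@dataclass
class VarCompProfile:
    """Per-scale variance partition and the delta-PVE-selected scale."""

    table: pd.DataFrame  # s, percentile, pve_self, pve_nei_or_rve, delta_pve, converged
    s_hat: float
    s_hat_percentile: float
    h2: float
    family: str = "gaussian"
    fits: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# covariance construction
# ---------------------------------------------------------------------------

def _prepare_columns(P: np.ndarray, center: bool, standardize: bool) -> np.ndarray:
    if center or standardize:
        P = P - P.mean(axis=0, keepdims=True)
    if standardize:
        sd = P.std(axis=0, keepdims=True)
        P = np.divide(P, sd, out=np.zeros_like(P), where=sd > 1e-12)
    return P


def build_covariance(
    gp: GenoProbs,
    smap: SpatialMap,
    s: float,
    source: str = "genotype",
    ph: Phenotype | None = None,
    center: bool = True,
    standardize: bool = True,
    **identity_kwargs,
) -> GenomeCovariance:
    """Build K1 (self kinship) and K2 (neighbor identity similarity) at scale s.

    By default the columns of P1 and P2 are standardized to mean 0 /
    variance 1 before the cross-product, so both kernels have unit-scale
    diagonals and the variance components are comparable across spatial
    scales.  (Identity columns shrink roughly as 1/L with the neighbor
    count; without standardization the neighbor kernel's scale collapses at
    large s and PVE_nei is no longer comparable across scales.)

    With ``source="phenotype"`` the neighbor matrix is built from the mean
    neighbor phenotype within s (standardized) instead of genotypic identity,
    which is the contrast used to check that phenotype spillover is not
    mistaken for genotype-identity effects.
    """
    q = gp.n_positions
    if q < 2:
        raise ParameterError("need at least 2 grid positions to build covariances")
    P1 = _prepare_columns(gp.additive_score(), center, standardize)
    K1 = (P1 @ P1.T) / (q - 1)

    if source == "genotype":
        # additive polygenic codes (-1, 0, 1); a backcross needs the symmetric
        # two-class product instead, since its second genotype is the heterozygote
        kernel_coding = (
            "backcross-linear" if gp.cross_type == "backcross" else "additive-polygenic"
        )
        ni = neighbor_identity(gp, smap, s, coding=kernel_coding, **identity_kwargs)
        if ni.values.shape[0] != gp.n_individuals:
            raise IsolatedIndividualsError(s, [])
        P2 = _prepare_columns(ni.values, center, standardize)
        K2 = (P2 @ P2.T) / (q - 1)
    elif source == "phenotype":
        if ph is None:
            raise ParameterError("phenotype source requires ph")
        from .neighbors import neighborhood_matrix

        A = neighborhood_matrix(smap, s)
        L = A.sum(axis=1)
        if np.any(L == 0):
            raise IsolatedIndividualsError(s, [smap.ids[i] for i in np.flatnonzero(L == 0)])
        w = (A @ ph.values) / L
        w = w - w.mean()
        sd = w.std()
        if sd > 0:
            w = w / sd
        K2 = np.outer(w, w)
    else:
        raise ParameterError(f"unknown covariance source {source!r}")
    return GenomeCovariance(K1=K1, K2=K2, q=q, s=float(s), source=source)


# ---------------------------------------------------------------------------
# AI-REML
# ---------------------------------------------------------------------------

def _reml_parts(y, X, V):
    n, p = X.shape
    c, low = cho_factor(V, lower=True)
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    Vi = cho_solve((c, low), np.eye(n))
    XtVi = X.T @ Vi
    M = XtVi @ X
    sign, logdet_m = np.linalg.slogdet(M)
    Minv = np.linalg.inv(M)
    P = Vi - XtVi.T @ Minv @ XtVi
    Py = P @ y
    ll = -0.5 * (logdet_v + logdet_m + float(y @ Py))
    beta = Minv @ (XtVi @ y)
    return P, Py, ll, beta


def aireml(
    y: np.ndarray,
    X: np.ndarray,
    components: list[np.ndarray],
    R: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    """Average-information REML for V = sum_k sigma_k^2 G_k (+ fixed R).

    Variances are kept non-negative by projection; an EM step backs up any
    AI step that fails to improve the restricted likelihood.  Returns
    ``(sigma, beta, loglik, converged, n_iter)``.
    """
    y = np.asarray(y, float)
    n = len(y)
    K = len(components)
    scale = y.var(ddof=1)
    if scale <= 0:
        raise ParameterError("response is constant")
    ys = y / np.sqrt(scale)
    if init is None:
        sig = np.full(K, 1.0 / (K + (0 if R is not None else 0)))
        if R is None:
            sig = np.full(K, 1.0 / K)
    else:
        sig = np.clip(np.asarray(init, float) / scale, 0.0, None)
        if not np.any(sig > 0):
            sig = np.full(K, 1.0 / K)

    jitter = 1e-8 * np.eye(n)

    def make_v(s):
        V = sum(sk * Gk for sk, Gk in zip(s, components))
        if R is not None:
            V = V + R
        return V + jitter

    # for PQL the caller passes R on the working-response scale, so the fit
    # runs on the raw response there instead of the unit-variance rescaling
    if R is not None:
        ys = y
        if init is None:
            sig = np.full(K, max(scale, 1e-3) / K)

    P, Py, ll, beta = _reml_parts(ys, X, make_v(sig))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        tr_pg = np.array([np.sum(P * G) for G in components])
        u = [G @ Py for G in components]
        grad = np.array([-0.5 * (tr_pg[k] - float(Py @ u[k])) for k in range(K)])

        free = [k for k in range(K) if sig[k] > 1e-10 or grad[k] > 0]
        if free:
            grad_free = np.max(np.abs(grad[free]))
        else:
            grad_free = 0.0
        if grad_free < tol:
            converged = True
            break

        AI = np.empty((K, K))
        Pu = [P @ uk for uk in u]
        for a in range(K):
            for b in range(a, K):
                AI[a, b] = AI[b, a] = 0.5 * float(u[a] @ Pu[b])
        ok_step = False
        if free:
            f = np.array(free)
            try:
                delta = np.linalg.solve(
                    AI[np.ix_(f, f)] + 1e-10 * np.eye(len(f)), grad[f]
                )
            except np.linalg.LinAlgError:
                delta = None
            if delta is not None:
                step = 1.0
                for _ in range(25):
                    trial = sig.copy()
                    trial[f] = np.clip(sig[f] + step * delta, 0.0, None)
                    try:
                        P_t, Py_t, ll_t, beta_t = _reml_parts(ys, X, make_v(trial))
                    except np.linalg.LinAlgError:
                        step *= 0.5
                        continue
                    if ll_t >= ll - 1e-10:
                        sig, P, Py, ll, beta = trial, P_t, Py_t, ll_t, beta_t
                        ok_step = True
                        break
                    step *= 0.5
        if not ok_step:
            # EM fallback: guaranteed non-negative update
            trial = np.array(
                [
                    sig[k] + (sig[k] ** 2) * (float(Py @ u[k]) - tr_pg[k]) / n
                    for k in range(K)
                ]
            )
            trial = np.clip(trial, 0.0, None)
            if np.allclose(trial, sig, rtol=0, atol=1e-14):
                break
            try:
                P, Py, ll, beta = _reml_parts(ys, X, make_v(trial))
                sig = trial
            except np.linalg.LinAlgError:
                break
    out_scale = 1.0 if R is not None else scale
    return sig * out_scale, beta * (1.0 if R is not None else np.sqrt(scale)), ll, converged, it


def fit_varcomp(
    ph: Phenotype,
    K: GenomeCovariance,
    max_iter: int = 200,
    tol: float = 1e-6,
    init: np.ndarray | None = None,
) -> VarComps:
    """Fit the two-kernel mixed model for a gaussian or binary trait."""
    n = ph.n
    if n < 10:
        raise ParameterError("need at least 10 individuals for variance components")
    X = ph.design_null()
    if ph.family == "gaussian":
        comps = [K.K1, K.K2, np.eye(n)]
        sig, beta, ll, converged, it = aireml(
            ph.values, X, comps, max_iter=max_iter, tol=tol, init=init
        )
        if not converged:
            warnings.warn("AI-REML did not reach tolerance", ConvergenceWarning)
        return VarComps(
            sigma1=float(sig[0]),
            sigma2=float(sig[1]),
            sigma_e=float(sig[2]),
            beta=beta,
            loglik=ll,
            converged=converged,
            family="gaussian",
            n_iter=it,
        )
    return _pql_binomial(ph, K, max_iter=max_iter, tol=tol)


def _pql_binomial(
    ph: Phenotype, K: GenomeCovariance, max_iter: int = 200, tol: float = 1e-6,
    max_outer: int = 30,
) -> VarComps:
    """Penalized quasi-likelihood logistic mixed model (no residual variance)."""
    y = ph.values
    n = ph.n
    X = ph.design_null()
    comps = [K.K1, K.K2]
    eta = np.full(n, np.log((y.mean() + 0.05) / (1 - y.mean() + 0.05)))
    sig = None
    beta = np.zeros(X.shape[1])
    ll = np.nan
    converged = False
    for outer in range(max_outer):
        mu = _sigmoid(eta)
        w = np.clip(mu * (1 - mu), 1e-6, None)
        z = eta + (y - mu) / w
        R = np.diag(1.0 / w)
        sig, beta, ll, conv, _ = aireml(
            z, X, comps, R=R, max_iter=max_iter, tol=tol, init=sig
        )
        V = sig[0] * K.K1 + sig[1] * K.K2 + R + 1e-8 * np.eye(n)
        resid = z - X @ beta
        u = (sig[0] * K.K1 + sig[1] * K.K2) @ np.linalg.solve(V, resid)
        eta_new = X @ beta + u
        delta = np.max(np.abs(eta_new - eta))
        eta = eta_new
        if delta < 1e-4:
            converged = conv
            break
    if not converged:
        warnings.warn("PQL did not reach tolerance", ConvergenceWarning)
    return VarComps(
        sigma1=float(sig[0]),
        sigma2=float(sig[1]),
        sigma_e=None,
        beta=beta,
        loglik=ll,
        converged=converged,
        family="binomial",
    )


def heritability(ph: Phenotype, gp: GenoProbs) -> float:
    """Marker heritability h2 = sigma1^2 / (sigma1^2 + sigma_e^2).

    Equivalent to the two-kernel model with sigma2^2 and s fixed at zero.
    """
    q = gp.n_positions
    P1 = _prepare_columns(gp.additive_score(), center=True, standardize=True)
    K1 = (P1 @ P1.T) / (q - 1)
    X = ph.design_null()
    n = ph.n
    if ph.family == "gaussian":
        sig, *_ = aireml(ph.values, X, [K1, np.eye(n)])
        tot = sig[0] + sig[1]
        return float(sig[0] / tot) if tot > 0 else 0.0
    cov = GenomeCovariance(K1=K1, K2=np.zeros((n, n)), q=q, s=None)
    vc = _pql_binomial(ph, cov)
    tot = vc.sigma1 + vc.sigma2
    return float(vc.sigma1 / tot) if tot > 0 else 0.0


# ---------------------------------------------------------------------------
# delta-PVE scale selection
# ---------------------------------------------------------------------------

def delta_pve(
    ph: Phenotype,
    gp: GenoProbs,
    smap: SpatialMap,
    scales: DistanceScales,
    center: bool = True,
    standardize: bool = True,
) -> VarCompProfile:
    """Estimate the effective neighbor distance by the delta-PVE rule.

    Scales that carry no spatial contrast are skipped with a warning: at the
    small end those leaving any individual without neighbors, and at the
    large end those whose neighborhood graph is complete (every individual
    neighbors every other, so the identity degenerates into a pure
    self-genotype function and the two kernels are no longer separable).
    ``delta_pve`` at the first usable scale is its PVE_nei (a difference
    against zero); ties in the argmax resolve to the smaller scale.  For
    binary traits the profile tracks RVE_nei = s2^2 / s1^2.
    """
    from .neighbors import neighborhood_matrix

    rows = []
    fits: dict[float, VarComps] = {}
    init = None
    diagnostics = []
    n = smap.n_individuals
    for s, pct in zip(scales.values, scales.percentiles):
        if neighborhood_matrix(smap, s).sum(axis=1).min() >= n - 1:
            diagnostics.append(f"s={s:g}: complete neighborhood graph")
            warnings.warn(
                f"scale s={s:g} skipped: every individual neighbors every other "
                "(no spatial contrast)",
                UserWarning,
            )
            continue
        try:
            cov = build_covariance(gp, smap, s, center=center, standardize=standardize)
        except IsolatedIndividualsError as exc:
            diagnostics.append(str(exc))
            warnings.warn(f"scale s={s:g} skipped: {exc}", UserWarning)
            continue
        try:
            vc = fit_varcomp(ph, cov, init=init)
        except Exception as exc:  # keep scanning other scales
            diagnostics.append(f"s={s:g}: {exc}")
            warnings.warn(f"variance fit failed at s={s:g}: {exc}", UserWarning)
            continue
        if vc.family == "gaussian":
            init = np.array([vc.sigma1, vc.sigma2, vc.sigma_e])
        fits[float(s)] = vc
        metric = vc.pve_nei if ph.family == "gaussian" else vc.rve_nei
        rows.append(
            {
                "s": float(s),
                "percentile": float(pct),
                "pve_self": vc.pve_self if ph.family == "gaussian" else np.nan,
                "pve_nei": metric,
                "converged": vc.converged,
            }
        )
    if not rows:
        raise ProfileError(
            "all spatial scales failed:\n" + "\n".join(diagnostics or ["(no scales)"])
        )
    table = pd.DataFrame(rows)
    if len(rows) == 1:
        warnings.warn("only one usable spatial scale; returning it", UserWarning)
    pv = table["pve_nei"].to_numpy()
    dpve = np.diff(np.concatenate([[0.0], pv]))
    table["delta_pve"] = dpve
    k_hat = int(np.argmax(dpve))  # argmax takes the first (smallest scale) on ties
    h2 = heritability(ph, gp)
    return VarCompProfile(
        table=table,
        s_hat=float(table["s"].iloc[k_hat]),
        s_hat_percentile=float(table["percentile"].iloc[k_hat]),
        h2=h2,
        family=ph.family,
        fits=fits,
    )
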