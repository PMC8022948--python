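"""Genome scans for self and neighbor QTL effects.

The scan follows a stepwise Haley-Knott scheme.  At every evaluation
position:

1. regress the trait on the expected additive genotype score (codes
   AA, AB, BB = -1, 0, 1) and, for three-genotype crosses, the expected
   dominance score (codes 0, 1, 0), plus any covariates;
2. construct the fitted self-QTL effect from the step-1 coefficients;
3. LOD_self = (LL_self - LL_null) / ln 10, the null being covariates only;
4. with the fitted self effect held as a covariate, regress the trait on
   the conditional neighbor genotypic identity z (and z^2 for
   three-genotype crosses);
5. LOD_nei = (LL_nei - LL_self) / ln 10.

Fitting the self effect before testing the neighbor term guards the
neighbor test against the built-in correlation between self and neighbor
components, which strengthens as the neighborhood radius grows.

Gaussian traits use least squares (LL differences reduce to
(n/2) * log10(RSS_0 / RSS_1)); binary traits use logistic regression with
deviance-based LODs and a ridge fallback under separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateTraitError, ParameterError, RankWarning
from .genotypes import GenoProbs
from .neighbors import NeighborIdentity

LOG10 = np.log(10.0)


@dataclass
class Phenotype:
    """A trait vector with optional covariates.

    ``family`` is ``"gaussian"`` for continuous traits or ``"binomial"`` for
    binary traits coded {0, 1}.
    """

    values: np.ndarray
    name: str = "trait"
    covariates: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)
    family: str = "gaussian"
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ParameterError("trait must be a 1-D vector")
        if self.family not in ("gaussian", "binomial"):
            raise ParameterError(f"unknown family {self.family!r}")
        if self.family == "binomial" and not np.isin(self.values, (0.0, 1.0)).all():
            raise ParameterError("binomial trait must contain only {0, 1}")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != len(self.values):
                self.covariates = self.covariates.T
            if self.covariates.shape[0] != len(self.values):
                raise ParameterError("covariate rows do not match trait length")

    @property
    def n(self) -> int:
        return len(self.values)

    def design_null(self) -> np.ndarray:
        cols = [np.ones(self.n)]
        if self.covariates is not None:
            cols.append(self.covariates)
        return np.column_stack(cols)

    def permuted(self, order: np.ndarray) -> "Phenotype":
        """Rows of the trait and covariates shuffled jointly."""
        return Phenotype(
            values=self.values[order],
            name=self.name,
            covariates=None if self.covariates is None else self.covariates[order],
            covariate_names=list(self.covariate_names),
            family=self.family,
            ids=list(self.ids),
        )


@dataclass
class ScanResult:
    """Per-position effect estimates and LOD scores."""

    table: pd.DataFrame
    cross_type: str
    family: str
    self_effect: np.ndarray | None = None  # (n, positions) fitted self-QTL effect
    scale: float | None = None
    covariate_names: list[str] = field(default_factory=list)

    def max_lod(self, which: str = "lod_nei") -> float:
        return float(np.nanmax(self.table[which].to_numpy()))


@dataclass
class PermutationThresholds:
    """Empirical genome-wide max-LOD null distributions and thresholds."""

    n_perm: int
    max_lod_self: np.ndarray
    max_lod_nei: np.ndarray
    thresholds_self: dict[float, float]
    thresholds_nei: dict[float, float]
    seed: int

    def to_dict(self) -> dict:
        return {
            "n_perm": self.n_perm,
            "seed": self.seed,
            "thresholds_self": {str(a): v for a, v in self.thresholds_self.items()},
            "thresholds_nei": {str(a): v for a, v in self.thresholds_nei.items()},
        }


# ---------------------------------------------------------------------------
# model fitting primitives
# ---------------------------------------------------------------------------

def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    beta, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1] or rss.size == 0:
        resid = y - X @ beta
        rss_val = float(resid @ resid)
    else:
        rss_val = float(rss[0])
    return beta, rss_val, rank


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))


def _logistic_fit(
    X: np.ndarray, y: np.ndarray, ridge: float = 0.0, max_iter: int = 100, tol: float = 1e-10
) -> tuple[np.ndarray, float, bool]:
    """IRLS logistic regression returning (beta, log-likelihood, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log((y.mean() + 1e-6) / (1 - y.mean() + 1e-6))
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = _sigmoid(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        H = XtW @ X + ridge * np.eye(p)
        try:
            beta = np.linalg.solve(H, XtW @ z)
        except np.linalg.LinAlgError:
            return _logistic_fit(X, y, ridge=max(ridge, 1e-4) * 10, max_iter=max_iter)
        mu = _sigmoid(X @ beta)
        ll = float(np.sum(y * np.log(np.clip(mu, 1e-12, None)))
                   + np.sum((1 - y) * np.log(np.clip(1 - mu, 1e-12, None))))
        if abs(ll - ll_old) < tol:
            return beta, ll, True
        ll_old = ll
    if np.max(np.abs(beta)) > 30 and ridge == 0.0:
        warnings.warn("separation in logistic fit; refitting with ridge penalty", UserWarning)
        return _logistic_fit(X, y, ridge=1e-4, max_iter=max_iter)
    return beta, ll_old, False


def _fit(X: np.ndarray, y: np.ndarray, family: str):
    """Return (beta, pseudo log-likelihood, rank_ok). Gaussian LL omits constants."""
    n = len(y)
    if family == "gaussian":
        beta, rss, rank = _ols_rss(X, y)
        ll = -0.5 * n * np.log(max(rss, 1e-300) / n)
        return beta, ll, rank == X.shape[1]
    beta, ll, _ = _logistic_fit(X, y)
    rank = np.linalg.matrix_rank(X)
    return beta, ll, rank == X.shape[1]


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

def scan_self(gp: GenoProbs, ph: Phenotype) -> ScanResult:
    """Genome scan for self-QTL effects (Haley-Knott regression on scores).

    Reported ``eff_2a1`` is the fitted difference between the two extreme
    genotype-class means (AA minus BB for three-genotype and inbred crosses;
    AA minus AB for backcrosses); ``eff_d1`` is the heterozygote deviation
    from the homozygote midpoint.
    """
    n = gp.n_individuals
    if ph.n != n:
        raise ParameterError("phenotype and genotype probabilities are not aligned")
    y = ph.values
    if np.ptp(y) == 0:
        raise DegenerateTraitError("trait is constant")
    X0 = ph.design_null()
    if np.linalg.matrix_rank(X0) < X0.shape[1]:
        raise ParameterError("covariate matrix is rank-deficient")
    if n <= X0.shape[1] + 3:
        raise ParameterError("too few individuals for the scan design")
    _, ll0, _ = _fit(X0, y, ph.family)

    xa = gp.additive_score()
    xd = gp.dominance_score()
    use_dom = gp.cross_type == "f2"

    P = gp.n_positions
    lod = np.full(P, np.nan)
    eff_2a1 = np.full(P, np.nan)
    eff_d1 = np.full(P, np.nan)
    ghat = np.zeros((n, P))
    for p in range(P):
        cols = [xa[:, p]] + ([xd[:, p]] if use_dom else [])
        X1 = np.column_stack([X0] + cols)
        beta, ll1, ok = _fit(X1, y, ph.family)
        if not ok:
            warnings.warn(f"rank-deficient design at position {p}; LOD set to NaN", RankWarning)
            continue
        k = X0.shape[1]
        b_a = beta[k]
        lod[p] = max((ll1 - ll0) / LOG10, 0.0) if ph.family == "gaussian" else (ll1 - ll0) / LOG10
        if gp.cross_type == "backcross":
            eff_2a1[p] = -b_a  # AA minus AB class difference
        else:
            eff_2a1[p] = -2.0 * b_a  # AA minus BB homozygote difference
        geno_part = b_a * xa[:, p]
        if use_dom:
            eff_d1[p] = beta[k + 1]
            geno_part = geno_part + beta[k + 1] * xd[:, p]
        ghat[:, p] = geno_part

    table = gp.grid.to_frame().reset_index()
    table["eff_2a1"] = eff_2a1
    table["eff_d1"] = eff_d1
    table["lod_self"] = lod
    return ScanResult(
        table=table,
        cross_type=gp.cross_type,
        family=ph.family,
        self_effect=ghat,
        covariate_names=list(ph.covariate_names),
    )


def scan_neighbor(
    gp: GenoProbs, ni: NeighborIdentity, ph: Phenotype, self_fit: ScanResult
) -> ScanResult:
    """Genome scan for neighbor QTL effects conditional on the self effects.

    The fitted self effect from ``self_fit`` enters the design as a single
    constructed covariate; the neighbor identity enters linearly for
    two-genotype crosses and with a quadratic term for F2.  ``eff_2a2sq`` is
    the signed effect of identical homozygote neighbors over opposite ones
    (twice the linear coefficient); a positive sign means the trait increases
    when neighbors share alleles.  ``eff_d2sq`` is the quadratic coefficient,
    floored at zero with a flag since it estimates a squared deviation.
    """
    n = gp.n_individuals
    if ni.values.shape[0] != n:
        raise ParameterError(
            "neighbor identity does not cover all individuals; "
            "recompute without dropping or subset the cross first"
        )
    if self_fit.self_effect is None or self_fit.self_effect.shape != (n, gp.n_positions):
        raise ParameterError("self_fit does not match the genotype probabilities")
    y = ph.values
    X0 = ph.design_null()
    quadratic = gp.cross_type == "f2"

    P = gp.n_positions
    lod = np.full(P, np.nan)
    eff_a2 = np.full(P, np.nan)
    eff_d2 = np.full(P, np.nan)
    clipped = np.zeros(P, dtype=bool)
    for p in range(P):
        Xs = np.column_stack([X0, self_fit.self_effect[:, p]])
        _, ll_s, _ = _fit(Xs, y, ph.family)
        z = ni.values[:, p]
        cols = [z] + ([z * z] if quadratic else [])
        Xn = np.column_stack([Xs] + cols)
        beta, ll_n, ok = _fit(Xn, y, ph.family)
        if not ok:
            warnings.warn(f"rank-deficient design at position {p}; LOD set to NaN", RankWarning)
            continue
        k = Xs.shape[1]
        lod[p] = max((ll_n - ll_s) / LOG10, 0.0) if ph.family == "gaussian" else (ll_n - ll_s) / LOG10
        eff_a2[p] = 2.0 * beta[k]
        if quadratic:
            q = beta[k + 1]
            clipped[p] = q < 0
            eff_d2[p] = max(q, 0.0)

    table = self_fit.table.copy()
    table["eff_2a2sq"] = eff_a2
    table["eff_d2sq"] = eff_d2
    table["d2sq_clipped"] = clipped
    table["lod_nei"] = lod
    return ScanResult(
        table=table,
        cross_type=gp.cross_type,
        family=ph.family,
        self_effect=self_fit.self_effect,
        scale=ni.s,
        covariate_names=list(ph.covariate_names),
    )


def perm_threshold(
    gp: GenoProbs,
    ni: NeighborIdentity,
    ph: Phenotype,
    n_perm: int = 999,
    alphas: tuple[float, ...] = (0.05, 0.10),
    seed: int = 0,
) -> PermutationThresholds:
    """Genome-wide LOD thresholds from trait permutations.

    The trait and covariate rows are shuffled jointly against the fixed
    genotype/spatial structure; the genome-wide maximum LOD of each permuted
    scan forms the null distribution, thresholded at empirical nearest-rank
    (1 - alpha) percentiles, separately for the self and neighbor scans.
    """
    if any(a <= 0.1 for a in alphas) and n_perm < 100:
        raise ParameterError("n_perm must be >= 100 for alpha <= 0.1")
    rng = np.random.default_rng(seed)
    max_self = np.empty(n_perm)
    max_nei = np.empty(n_perm)
    for b in range(n_perm):
        order = rng.permutation(ph.n)
        php = ph.permuted(order)
        sf = scan_self(gp, php)
        nf = scan_neighbor(gp, ni, php, sf)
        max_self[b] = np.nanmax(sf.table["lod_self"].to_numpy())
        max_nei[b] = np.nanmax(nf.table["lod_nei"].to_numpy())
    thr_self = {a: float(np.percentile(max_self, 100 * (1 - a), method="higher")) for a in alphas}
    thr_nei = {a: float(np.percentile(max_nei, 100 * (1 - a), method="higher")) for a in alphas}
    return PermutationThresholds(
        n_perm=n_perm,
        max_lod_self=max_self,
        max_lod_nei=max_nei,
        thresholds_self=thr_self,
        thresholds_nei=thr_nei,
        seed=seed,
    )


def scan_epistasis(
    gp: GenoProbs,
    ni: NeighborIdentity,
    ph: Phenotype,
    focal: int,
    linked_cm: float = 1.0,
) -> pd.DataFrame:
    """Two-way interaction scan for neighbor effects against a focal position.

    For every other position the additive-joint model (focal + other
    identities, plus covariates) is compared against the model adding their
    product; the interaction LOD comes from the deviance difference.
    Positions on the focal chromosome within ``linked_cm`` of the focal
    position are reported but flagged ``linked``.
    """
    grid = gp.grid.to_frame().reset_index()
    P = gp.n_positions
    if not (0 <= focal < P):
        raise ParameterError(f"focal position {focal} outside grid of size {P}")
    y = ph.values
    X0 = ph.design_null()
    zf = ni.values[:, focal]
    lod = np.full(P, np.nan)
    for p in range(P):
        if p == focal:
            continue
        zm = ni.values[:, p]
        Xa = np.column_stack([X0, zf, zm])
        _, ll_a, _ = _fit(Xa, y, ph.family)
        Xi = np.column_stack([Xa, zf * zm])
        _, ll_i, ok = _fit(Xi, y, ph.family)
        if not ok:
            continue
        d = (ll_i - ll_a) / LOG10
        lod[p] = max(d, 0.0) if ph.family == "gaussian" else d

    out = grid.copy()
    out["lod_int"] = lod
    fchrom = grid.loc[focal, "chromosome"]
    fpos = grid.loc[focal, "position"]
    out["linked"] = (out["chromosome"] == fchrom) & (
        (out["position"] - fpos).abs() <= linked_cm
    )
    return out[out.index != focal].reset_index(drop=True)
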