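"""Spatial neighborhoods and conditional neighbor genotypic identity.

The neighbor effect carried by a locus is the expected product of genotype
codings between a focal individual i and each neighbor j within spatial
distance s:

    z_i = (1 / L_i) * sum_{j : d_ij <= s} sum_v sum_w p_{i,v} p_{j,w} C[v, w]

where p are conditional genotype probabilities and C is a 3x3 coding table
over the states (AA, AB, BB).  Four codings are provided:

``quadratic``
    the nine-combination table used in the genome scan for three-genotype
    crosses: AA/AA=BB/BB=1, AA/AB=AB/AA=0.25, AB/AB=0, AB/BB=BB/AB=-0.25,
    AA/BB=BB/AA=-1;
``additive-polygenic``
    the product of additive codes (AA, AB, BB) = (-1, 0, 1), used for the
    genome-wide neighbor covariance matrix;
``inbred-linear`` / ``backcross-linear``
    products of symmetric two-genotype self codes: {AA, BB} = {1, -1} for
    selfed RILs and {AA, AB} = {-1, 1} for backcrosses (the heterozygote
    plays the second-genotype role).  Identical genotype pairs score +1 and
    opposite pairs -1 in both designs, so the two tables induce identical
    identity values on relabeled two-genotype data; an asymmetric 0/-1
    coding would instead zero out every pair involving the second genotype
    and discard the identity contrast for half the individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .exceptions import DegenerateGeometryError, IsolatedIndividualsError, ParameterError
from .genotypes import GenoProbs

_ADD_CODES = np.array([-1.0, 0.0, 1.0])

CODING_MATRICES: dict[str, np.ndarray] = {
    "quadratic": np.array(
        [
            [1.0, 0.25, -1.0],
            [0.25, 0.0, -0.25],
            [-1.0, -0.25, 1.0],
        ]
    ),
    "additive-polygenic": np.outer(_ADD_CODES, _ADD_CODES),
    "inbred-linear": np.outer([1.0, 0.0, -1.0], [1.0, 0.0, -1.0]),
    "backcross-linear": np.outer([-1.0, 1.0, 0.0], [-1.0, 1.0, 0.0]),
}

#: scan coding appropriate for each cross design
SCAN_CODING = {"f2": "quadratic", "riself": "inbred-linear", "backcross": "backcross-linear"}


@dataclass
class SpatialMap:
    """x/y positions of phenotyped individuals (arbitrary spatial units)."""

    ids: list[str]
    coords: np.ndarray  # (n, 2)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ParameterError("coords must have shape (n, 2)")
        if np.isnan(self.coords).any():
            raise ParameterError("spatial coordinates contain NaN")
        self.ids = [str(i) for i in self.ids]
        if len(self.ids) != self.coords.shape[0]:
            raise ParameterError("number of ids does not match coordinate rows")

    @property
    def n_individuals(self) -> int:
        return self.coords.shape[0]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpatialMap":
        return cls(df["id"].tolist(), df[["x", "y"]].to_numpy(float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "x": self.coords[:, 0], "y": self.coords[:, 1]})

    def distance_matrix(self) -> np.ndarray:
        return squareform(pdist(self.coords))


@dataclass
class DistanceScales:
    """Candidate neighborhood radii tagged with pairwise-distance percentiles."""

    values: np.ndarray
    percentiles: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.percentiles = np.asarray(self.percentiles, dtype=float)
        if np.any(self.values <= 0) or np.any(np.diff(self.values) <= 0):
            raise ParameterError("scales must be positive and strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"percentile": self.percentiles, "s": self.values})


def distance_scales(smap: SpatialMap, percentile_step: float = 10.0) -> DistanceScales:
    """Percentile grid of the pairwise Euclidean distance distribution.

    Returns the ``percentile_step, 2*percentile_step, ..., 100`` linear-
    interpolation percentiles, deduplicated keeping the smallest scale for a
    tied value.
    """
    if smap.n_individuals < 2:
        raise ParameterError("need at least 2 individuals to derive distance scales")
    if not (0 < percentile_step <= 50):
        raise ParameterError(f"percentile_step must be in (0, 50], got {percentile_step}")
    d = pdist(smap.coords)
    if np.all(d == 0):
        raise DegenerateGeometryError("all individuals are coincident; no distance scales")
    pcts = np.arange(percentile_step, 100 + 1e-9, percentile_step)
    vals = np.percentile(d, pcts, method="linear")
    keep_vals, keep_pcts = [], []
    for p, v in zip(pcts, vals):
        if v <= 0:
            continue
        if keep_vals and v <= keep_vals[-1]:
            continue  # tie: keep the smallest percentile's scale
        keep_vals.append(float(v))
        keep_pcts.append(float(p))
    return DistanceScales(np.asarray(keep_vals), np.asarray(keep_pcts))


@dataclass
class NeighborIdentity:
    """Conditional neighbor genotypic identity per individual and grid position."""

    values: np.ndarray  # (n, grid positions)
    s: float
    neighbor_counts: np.ndarray  # L_i
    coding: str
    ids: list[str]

    def to_frame(self, grid_frame: pd.DataFrame | None = None) -> pd.DataFrame:
        n, p = self.values.shape
        out = {
            "individual": np.repeat(self.ids, p),
            "position": np.tile(np.arange(p), n),
            "s": self.s,
            "value": self.values.reshape(-1),
        }
        df = pd.DataFrame(out)
        if grid_frame is not None:
            df["chromosome"] = np.tile(grid_frame["chromosome"].to_numpy(), n)
            df["position_cM"] = np.tile(grid_frame["position"].to_numpy(), n)
        return df


def neighborhood_matrix(
    smap: SpatialMap, s: float, include_boundary: bool = True
) -> np.ndarray:
    """Binary adjacency: j is a neighbor of i iff 0 < d_ij <= s (or < s)."""
    if s <= 0:
        raise ParameterError(f"spatial scale must be positive, got {s}")
    D = smap.distance_matrix()
    A = (D <= s) if include_boundary else (D < s)
    np.fill_diagonal(A, False)
    return A.astype(float)


def neighbor_identity(
    gp: GenoProbs,
    smap: SpatialMap,
    s: float,
    coding: str | None = None,
    include_boundary: bool = True,
    scale_counts: str = "per-individual",
    on_isolated: str = "error",
) -> NeighborIdentity:
    """Conditional neighbor genotypic identity at spatial scale s.

    Parameters
    ----------
    coding
        Name of the coding table; ``None`` selects the scan coding for the
        cross type (quadratic for F2, linear for two-genotype crosses).
    scale_counts
        ``"per-individual"`` divides each focal sum by that individual's own
        neighbor count L_i; ``"global"`` divides by the mean count.
    on_isolated
        ``"error"`` rejects the scale listing isolated individuals;
        ``"drop"`` removes them from the result.
    """
    if gp.n_individuals != smap.n_individuals:
        raise ParameterError("genotype probabilities and spatial map are not aligned")
    if coding is None:
        coding = SCAN_CODING[gp.cross_type]
    W = CODING_MATRICES[coding]
    A = neighborhood_matrix(smap, s, include_boundary)
    L = A.sum(axis=1)
    keep = np.ones(len(L), dtype=bool)
    if np.any(L == 0):
        isolated = [smap.ids[i] for i in np.flatnonzero(L == 0)]
        if on_isolated == "drop":
            keep = L > 0
        else:
            raise IsolatedIndividualsError(s, isolated)

    n, P, _ = gp.probs.shape
    # z_i = p_i' W (sum_j p_j) / L_i, vectorized over grid positions
    neigh_sum = (A @ gp.probs.reshape(n, P * 3)).reshape(n, P, 3)
    pw = np.einsum("npv,vw->npw", gp.probs, W)
    raw = np.einsum("npw,npw->np", pw, neigh_sum)
    if scale_counts == "per-individual":
        denom = np.where(L > 0, L, 1.0)[:, None]
    elif scale_counts == "global":
        denom = float(L[keep].mean())
    else:
        raise ParameterError(f"unknown scale_counts {scale_counts!r}")
    values = raw / denom
    ids = [smap.ids[i] for i in np.flatnonzero(keep)]
    return NeighborIdentity(
        values=values[keep],
        s=float(s),
        neighbor_counts=L[keep],
        coding=coding,
        ids=ids,
    )
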