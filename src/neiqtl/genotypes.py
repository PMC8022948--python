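"""Genetic maps and conditional genotype probabilities for experimental crosses.

Genotypes are stored as integer codes ``0 = AA``, ``1 = AB``, ``2 = BB`` and
``-1 = missing``.  Three cross designs are supported:

``f2``
    intercross; three genotype states with a 1:2:1 prior,
``backcross``
    F1 x AA; two states (AA, AB) with a 1:1 prior,
``riself``
    recombinant inbred lines by selfing; two homozygous states (AA, BB)
    whose transition probability uses the RIL-expanded recombination
    fraction R = 2r / (1 + 2r).

Conditional genotype probabilities ``Pr(g | M)`` at markers and inserted
pseudomarkers are computed by the forward-backward algorithm on a hidden
Markov chain along each chromosome, with transition probabilities derived
from inter-position map distances (Haldane by default, Kosambi selectable)
and an emission model allowing a small genotyping-error rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .exceptions import CrossTypeError, ParameterError

AA, AB, BB, MISSING = 0, 1, 2, -1
GENO_LABELS = ("AA", "AB", "BB")

CROSS_TYPES = ("f2", "backcross", "riself")
_CROSS_ALIASES = {
    "f2": "f2",
    "intercross": "f2",
    "backcross": "backcross",
    "bc": "backcross",
    "riself": "riself",
    "selfed-ril": "riself",
    "ril": "riself",
}

#: genotype states observable in each cross design
CROSS_STATES = {"f2": (AA, AB, BB), "backcross": (AA, AB), "riself": (AA, BB)}


def canonical_cross_type(cross_type: str) -> str:
    try:
        return _CROSS_ALIASES[cross_type.strip().lower()]
    except KeyError:
        raise CrossTypeError(
            f"unknown cross type {cross_type!r}; expected one of {CROSS_TYPES}"
        ) from None


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

def haldane_cm_to_rf(d_cm):
    """Map distance (cM) -> recombination fraction, no interference."""
    return 0.5 * (1.0 - np.exp(-np.asarray(d_cm, float) / 50.0))


def haldane_rf_to_cm(r):
    return -50.0 * np.log(1.0 - 2.0 * np.asarray(r, float))


def kosambi_cm_to_rf(d_cm):
    return 0.5 * np.tanh(np.asarray(d_cm, float) / 50.0)


def kosambi_rf_to_cm(r):
    return 25.0 * np.log((1.0 + 2.0 * np.asarray(r, float)) / (1.0 - 2.0 * np.asarray(r, float)))


MAP_FUNCTIONS = {
    "haldane": (haldane_cm_to_rf, haldane_rf_to_cm),
    "kosambi": (kosambi_cm_to_rf, kosambi_rf_to_cm),
}


def _get_map_function(name: str):
    try:
        return MAP_FUNCTIONS[name.lower()]
    except KeyError:
        raise ParameterError(
            f"unknown map function {name!r}; expected one of {tuple(MAP_FUNCTIONS)}"
        ) from None


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Ordered marker positions (cM) on each chromosome.

    Positions within a chromosome must be sorted and non-negative; marker
    names must be unique genome-wide.
    """

    chromosomes: list[str]
    marker_names: dict[str, list[str]]
    positions: dict[str, np.ndarray]

    def __post_init__(self):
        self.chromosomes = [str(c) for c in self.chromosomes]
        seen: set[str] = set()
        for chrom in self.chromosomes:
            pos = np.asarray(self.positions[chrom], dtype=float)
            names = [str(m) for m in self.marker_names[chrom]]
            if len(names) != len(pos):
                raise ParameterError(f"chromosome {chrom}: names/positions length mismatch")
            if len(pos) and (np.any(np.diff(pos) < 0) or pos[0] < 0):
                raise ParameterError(f"chromosome {chrom}: positions must be sorted, non-negative")
            dup = seen.intersection(names)
            if dup or len(set(names)) != len(names):
                raise ParameterError(f"duplicated marker name(s): {dup or 'within chromosome'}")
            seen.update(names)
            self.positions[chrom] = pos
            self.marker_names[chrom] = names

    @property
    def n_markers(self) -> int:
        return sum(len(v) for v in self.marker_names.values())

    def all_marker_names(self) -> list[str]:
        return [m for c in self.chromosomes for m in self.marker_names[c]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (m, c, p)
            for c in self.chromosomes
            for m, p in zip(self.marker_names[c], self.positions[c])
        ]
        return pd.DataFrame(rows, columns=["marker", "chromosome", "position"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        chroms = list(dict.fromkeys(df["chromosome"].astype(str)))
        names = {c: df.loc[df["chromosome"].astype(str) == c, "marker"].tolist() for c in chroms}
        pos = {
            c: df.loc[df["chromosome"].astype(str) == c, "position"].to_numpy(float)
            for c in chroms
        }
        return cls(chroms, names, pos)


@dataclass
class CrossPopulation:
    """Observed marker matrix M for a mapped experimental cross."""

    cross_type: str
    genotypes: np.ndarray  # (n individuals, n markers) int8 codes
    ids: list[str]
    map: GeneticMap

    def __post_init__(self):
        self.cross_type = canonical_cross_type(self.cross_type)
        g = np.asarray(self.genotypes)
        if g.ndim != 2:
            raise ParameterError("genotype matrix must be 2-D (individuals x markers)")
        if g.shape[1] != self.map.n_markers:
            raise ParameterError(
                f"genotype matrix has {g.shape[1]} columns but map has "
                f"{self.map.n_markers} markers"
            )
        g = g.astype(np.int8, copy=True)
        if not np.isin(g, (AA, AB, BB, MISSING)).all():
            raise ParameterError("genotype codes must be in {0:AA, 1:AB, 2:BB, -1:missing}")
        if self.cross_type == "backcross" and np.any(g == BB):
            raise ParameterError("backcross genotypes cannot contain BB")
        if self.cross_type == "riself" and np.any(g == AB):
            n_het = int(np.sum(g == AB))
            warnings.warn(
                f"selfed-RIL cross contains {n_het} heterozygous call(s); treated as missing",
                UserWarning,
                stacklevel=2,
            )
            g[g == AB] = MISSING
        self.genotypes = g
        self.ids = [str(i) for i in self.ids]
        if len(self.ids) != g.shape[0]:
            raise ParameterError("number of ids does not match genotype rows")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def states(self) -> tuple[int, ...]:
        return CROSS_STATES[self.cross_type]


@dataclass
class PositionGrid:
    """Evaluation positions (markers + pseudomarkers) for interval mapping."""

    chromosomes: list[str]
    positions: dict[str, np.ndarray]
    labels: dict[str, list[str]]
    is_marker: dict[str, np.ndarray]
    step: float | None = None
    offsets: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        off = 0
        self.offsets = {}
        for chrom in self.chromosomes:
            self.offsets[chrom] = off
            off += len(self.positions[chrom])
        self._n_positions = off

    @property
    def n_positions(self) -> int:
        return self._n_positions

    def chrom_slice(self, chrom: str) -> slice:
        start = self.offsets[chrom]
        return slice(start, start + len(self.positions[chrom]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chromosomes:
            for lab, pos, obs in zip(
                self.labels[chrom], self.positions[chrom], self.is_marker[chrom]
            ):
                rows.append((chrom, float(pos), lab, bool(obs)))
        df = pd.DataFrame(rows, columns=["chromosome", "position", "label", "is_marker"])
        df.index.name = "grid_index"
        return df

    def marker_grid_indices(self, gmap: GeneticMap) -> np.ndarray:
        """Global grid index of each observed marker, in map column order."""
        out = []
        for chrom in gmap.chromosomes:
            labs = self.labels[chrom]
            base = self.offsets[chrom]
            lookup = {lab: base + k for k, lab in enumerate(labs)}
            out.extend(lookup[m] for m in gmap.marker_names[chrom])
        return np.asarray(out, dtype=int)


@dataclass
class GenoProbs:
    """Conditional self-genotype probabilities Pr(g_i | M) on a grid.

    ``probs`` has shape (n individuals, n grid positions, 3 states) with the
    state axis ordered AA, AB, BB; slices for states absent from the cross
    design are identically zero.
    """

    probs: np.ndarray
    cross_type: str
    grid: PositionGrid
    error_prob: float
    map_function: str = "haldane"
    ids: list[str] = field(default_factory=list)

    @property
    def n_individuals(self) -> int:
        return self.probs.shape[0]

    @property
    def n_positions(self) -> int:
        return self.probs.shape[1]

    def additive_score(self) -> np.ndarray:
        """Expected genotype value with codes AA=-1, AB=0, BB=+1."""
        return self.probs[:, :, BB] - self.probs[:, :, AA]

    def dominance_score(self) -> np.ndarray:
        """Expected heterozygosity (codes AA=0, AB=1, BB=0)."""
        return self.probs[:, :, AB].copy()

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (individual, chromosome, position, state, probability)."""
        grid = self.grid.to_frame()
        n, p, _ = self.probs.shape
        recs = {
            "individual": np.repeat(self.ids if self.ids else np.arange(n), p * 3),
            "chromosome": np.tile(np.repeat(grid["chromosome"].to_numpy(), 3), n),
            "position": np.tile(np.repeat(grid["position"].to_numpy(), 3), n),
            "state": np.tile(list(GENO_LABELS), n * p),
            "probability": self.probs.reshape(-1),
        }
        return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# grid construction
# ---------------------------------------------------------------------------

def insert_pseudomarkers(gmap: GeneticMap, step: float | None = 1.0) -> PositionGrid:
    """Insert evenly spaced pseudomarkers so adjacent grid gaps are <= step (cM).

    ``step=None`` (or infinity) evaluates at observed markers only.
    """
    if step is not None and not math.isinf(step):
        if step <= 0:
            raise ParameterError(f"pseudomarker step must be positive, got {step}")
    positions, labels, is_marker = {}, {}, {}
    for chrom in gmap.chromosomes:
        mpos = gmap.positions[chrom]
        mnames = gmap.marker_names[chrom]
        pos_list: list[float] = []
        lab_list: list[str] = []
        obs_list: list[bool] = []
        for k, (p, name) in enumerate(zip(mpos, mnames)):
            if k > 0 and step is not None and not math.isinf(step):
                gap = p - mpos[k - 1]
                if gap > step:
                    n_pseudo = math.ceil(gap / step) - 1
                    inner = np.linspace(mpos[k - 1], p, n_pseudo + 2)[1:-1]
                    for q in inner:
                        pos_list.append(float(q))
                        lab_list.append(f"c{chrom}.loc{q:g}")
                        obs_list.append(False)
            pos_list.append(float(p))
            lab_list.append(name)
            obs_list.append(True)
        positions[chrom] = np.asarray(pos_list)
        labels[chrom] = lab_list
        is_marker[chrom] = np.asarray(obs_list, dtype=bool)
    return PositionGrid(list(gmap.chromosomes), positions, labels, is_marker, step=step)


# ---------------------------------------------------------------------------
# hidden-Markov machinery
# ---------------------------------------------------------------------------

def _init_prob(cross_type: str) -> np.ndarray:
    if cross_type == "f2":
        return np.array([0.25, 0.5, 0.25])
    return np.array([0.5, 0.5])  # backcross, riself


def transition_matrix(cross_type: str, r: float) -> np.ndarray:
    """One-step transition between hidden genotype states given meiotic r."""
    cross_type = canonical_cross_type(cross_type)
    if cross_type == "f2":
        s = 1.0 - r
        return np.array(
            [
                [s * s, 2 * r * s, r * r],
                [r * s, s * s + r * r, r * s],
                [r * r, 2 * r * s, s * s],
            ]
        )
    if cross_type == "backcross":
        return np.array([[1 - r, r], [r, 1 - r]])
    # selfed RIL: expanded recombination fraction
    R = 2.0 * r / (1.0 + 2.0 * r)
    return np.array([[1 - R, R], [R, 1 - R]])


def _emission_probs(
    cross: CrossPopulation, grid: PositionGrid, error_prob: float
) -> dict[str, np.ndarray]:
    """Per-chromosome emission arrays of shape (n, grid positions, states)."""
    states = cross.states
    K = len(states)
    out = {}
    col = 0
    for chrom in cross.map.chromosomes:
        n_mark = len(cross.map.marker_names[chrom])
        obs = cross.genotypes[:, col : col + n_mark]
        col += n_mark
        n_grid = len(grid.positions[chrom])
        emis = np.ones((cross.n_individuals, n_grid, K))
        marker_cols = np.flatnonzero(grid.is_marker[chrom])
        for m, gcol in enumerate(marker_cols):
            o = obs[:, m]
            for k, state in enumerate(states):
                match = o == state
                miss = o == MISSING
                emis[match, gcol, k] = 1.0 - error_prob
                emis[~match & ~miss, gcol, k] = (
                    error_prob / (K - 1) if K > 1 else error_prob
                )
        out[chrom] = emis
    return out


def calc_genoprob(
    cross: CrossPopulation,
    grid: PositionGrid | None = None,
    error_prob: float = 1e-4,
    map_function: str = "haldane",
) -> GenoProbs:
    """Conditional genotype probabilities by forward-backward along each chromosome.

    Missing genotypes emit uniformly; observed ones emit the true state with
    probability ``1 - error_prob``.
    """
    if not (0.0 <= error_prob < 0.5):
        raise ParameterError(f"error_prob must be in [0, 0.5), got {error_prob}")
    if grid is None:
        grid = insert_pseudomarkers(cross.map, step=None)
    cm_to_rf, _ = _get_map_function(map_function)
    states = cross.states
    K = len(states)
    n = cross.n_individuals
    init = _init_prob(cross.cross_type)
    emissions = _emission_probs(cross, grid, error_prob)

    probs = np.zeros((n, grid.n_positions, 3))
    for chrom in grid.chromosomes:
        gpos = grid.positions[chrom]
        P = len(gpos)
        emis = emissions[chrom]
        if P == 0:
            continue
        gaps = np.diff(gpos)
        trans = [transition_matrix(cross.cross_type, float(cm_to_rf(d))) for d in gaps]

        alpha = np.empty((n, P, K))
        alpha[:, 0] = init * emis[:, 0]
        alpha[:, 0] /= alpha[:, 0].sum(axis=1, keepdims=True)
        for t in range(1, P):
            a = alpha[:, t - 1] @ trans[t - 1]
            a *= emis[:, t]
            alpha[:, t] = a / a.sum(axis=1, keepdims=True)

        beta = np.empty((n, P, K))
        beta[:, -1] = 1.0
        for t in range(P - 2, -1, -1):
            b = (beta[:, t + 1] * emis[:, t + 1]) @ trans[t].T
            beta[:, t] = b / b.sum(axis=1, keepdims=True)

        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)
        probs[:, grid.chrom_slice(chrom), list(states)] = post

    return GenoProbs(
        probs=probs,
        cross_type=cross.cross_type,
        grid=grid,
        error_prob=error_prob,
        map_function=map_function,
        ids=list(cross.ids),
    )


# ---------------------------------------------------------------------------
# two-point map estimation
# ---------------------------------------------------------------------------

RF_CAP = 0.49  # recombination-fraction ceiling before cM conversion


def _pair_loglik(r: float, counts: np.ndarray, cross_type: str) -> float:
    init = _init_prob(cross_type)
    T = transition_matrix(cross_type, r)
    joint = init[:, None] * T
    with np.errstate(divide="ignore"):
        ll = np.where(counts > 0, counts * np.log(np.maximum(joint, 1e-300)), 0.0)
    return float(ll.sum())


def estimate_map(
    cross: CrossPopulation,
    map_function: str = "haldane",
    rf_cap: float = RF_CAP,
) -> GeneticMap:
    """Re-estimate inter-marker distances from two-point recombination fractions.

    Adjacent-marker recombination fractions are estimated by maximum likelihood
    from the observed two-marker genotype counts under the cross-specific
    chain (for selfed RILs the likelihood is parameterized by the meiotic r
    through the RIL expansion R = 2r/(1+2r), so the returned distances are on
    the meiotic scale).  Estimates are capped at ``rf_cap`` before conversion
    to cM; a capped pair or an uninformative pair triggers a warning and, for
    the latter, retains the input distance.
    """
    _, rf_to_cm = _get_map_function(map_function)
    states = cross.states
    state_index = {s: k for k, s in enumerate(states)}
    new_positions = {}
    col = 0
    for chrom in cross.map.chromosomes:
        n_mark = len(cross.map.marker_names[chrom])
        obs = cross.genotypes[:, col : col + n_mark]
        col += n_mark
        pos = np.zeros(n_mark)
        for m in range(1, n_mark):
            g1, g2 = obs[:, m - 1], obs[:, m]
            ok = (g1 != MISSING) & (g2 != MISSING)
            if not ok.any():
                d = cross.map.positions[chrom][m] - cross.map.positions[chrom][m - 1]
                warnings.warn(
                    f"no informative pair for {cross.map.marker_names[chrom][m-1]}-"
                    f"{cross.map.marker_names[chrom][m]}; input distance retained",
                    UserWarning,
                    stacklevel=2,
                )
                pos[m] = pos[m - 1] + d
                continue
            counts = np.zeros((len(states), len(states)))
            for a, b in zip(g1[ok], g2[ok]):
                counts[state_index[int(a)], state_index[int(b)]] += 1
            res = minimize_scalar(
                lambda r: -_pair_loglik(r, counts, cross.cross_type),
                bounds=(1e-8, 0.5 - 1e-8),
                method="bounded",
                options={"xatol": 1e-10},
            )
            rhat = float(res.x)
            if rhat > rf_cap:
                warnings.warn(
                    f"recombination fraction for pair ending at "
                    f"{cross.map.marker_names[chrom][m]} capped at {rf_cap}",
                    UserWarning,
                    stacklevel=2,
                )
                rhat = rf_cap
            pos[m] = pos[m - 1] + float(rf_to_cm(rhat))
        new_positions[chrom] = pos
    return GeneticMap(
        list(cross.map.chromosomes),
        {c: list(cross.map.marker_names[c]) for c in cross.map.chromosomes},
        new_positions,
    )
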