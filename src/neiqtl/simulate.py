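"""Synthetic crosses, spatial maps, and neighbor-effect traits.

The generator reproduces the benchmark design used to validate the method:

- genotypes arise chromosome-wise from the cross-appropriate Markov chain
  with Haldane transition probabilities derived from the map gaps;
- individuals sit at independent Unif(1, 100) x/y positions in a
  continuous two-dimensional arena;
- the self phenotype carries one major-effect marker (additive deviation
  ``max_a1``, 0.56 for F2 and 0.56/2 = 0.28 for backcross by default) plus
  ``1e-3 * max_a1`` polygenic effects at every other marker and unit
  normal noise, standardized to mean 0 / variance 1;
- the neighbor component follows the nine-combination genotype-identity
  table with scenario-specific (a2, d2) and is rescaled per replicate so
  that a stated share (default 50%) of the total trait variance is
  attributable to neighbor effects;
- the ``neighbor-phenotype`` scenario instead adds the scaled mean of
  neighbor self-phenotypes, the contrast used to check that phenotype
  spillover is not reported as a genotype-identity QTL.

Scenario coefficients (in units of ``max_a1``):

================== ===== =====
scenario            a2    d2
================== ===== =====
additive            1     0.25
dominant            1     1
overdominant        1     1.25
backcross-additive  1     -1
================== ===== =====
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError, SimulationError
from .genotypes import (
    AA,
    AB,
    BB,
    CROSS_STATES,
    CrossPopulation,
    GeneticMap,
    calc_genoprob,
    canonical_cross_type,
    haldane_cm_to_rf,
    insert_pseudomarkers,
    transition_matrix,
)
from .neighbors import SpatialMap, distance_scales, neighbor_identity, neighborhood_matrix
from .scan import Phenotype, scan_neighbor, scan_self
from .varcomp import delta_pve

SCENARIOS = {
    "null": (0.0, 0.0),
    "additive": (1.0, 0.25),
    "dominant": (1.0, 1.0),
    "overdominant": (1.0, 1.25),
    "backcross-additive": (1.0, -1.0),
    "neighbor-phenotype": (None, None),
}

#: largest self additive deviation assigned to the major marker
DEFAULT_MAX_A1 = {"f2": 0.56, "backcross": 0.28, "riself": 0.56}


@dataclass
class SimScenario:
    """One benchmark condition."""

    cross_type: str = "f2"
    scenario: str = "additive"
    true_percentile: float = 10.0
    pve_nei: float = 0.5
    major_marker: int | None = None  # marker column; None draws one at random
    polygenic_ratio: float = 1e-3
    n: int = 200
    seed: int = 0
    max_a1: float | None = None

    def __post_init__(self):
        self.cross_type = canonical_cross_type(self.cross_type)
        if self.scenario not in SCENARIOS:
            raise ParameterError(f"unknown scenario {self.scenario!r}")
        if not (0 < self.pve_nei < 1):
            raise ParameterError("pve_nei share must be in (0, 1)")
        if self.scenario in ("dominant", "overdominant") and self.cross_type != "f2":
            raise ParameterError(f"{self.scenario} scenario requires an F2 cross")
        if self.scenario == "backcross-additive" and self.cross_type != "backcross":
            raise ParameterError("backcross-additive scenario requires a backcross")
        if self.max_a1 is None:
            self.max_a1 = DEFAULT_MAX_A1[self.cross_type]


@dataclass
class SimResult:
    """A simulated data set with its generating parameters."""

    cross: CrossPopulation
    smap: SpatialMap
    trait: np.ndarray
    self_component: np.ndarray
    a2: float | None
    d2: float | None
    s_true: float
    true_percentile: float
    realized_share: float
    major_marker: int
    scenario: SimScenario


def default_map(n_chromosomes: int = 5, markers_per_chromosome: int = 5,
                spacing_cm: float = 15.0) -> GeneticMap:
    """A compact multi-chromosome map with regular marker spacing."""
    chroms = [str(c + 1) for c in range(n_chromosomes)]
    names = {
        c: [f"m{c}_{k + 1}" for k in range(markers_per_chromosome)] for c in chroms
    }
    pos = {c: np.arange(markers_per_chromosome) * spacing_cm for c in chroms}
    return GeneticMap(chroms, names, pos)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def sim_cross(
    cross_type: str, gmap: GeneticMap, n: int, seed: int | np.random.Generator = 0
) -> CrossPopulation:
    """Simulate genotypes chromosome-wise by the cross Markov chain (Haldane)."""
    cross_type = canonical_cross_type(cross_type)
    if gmap.n_markers == 0:
        raise ParameterError("empty genetic map")
    if n < 2:
        raise ParameterError("need at least 2 individuals")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = np.array(CROSS_STATES[cross_type])
    K = len(states)
    init = np.full(K, 0.5) if K == 2 else np.array([0.25, 0.5, 0.25])
    cols = []
    for chrom in gmap.chromosomes:
        pos = gmap.positions[chrom]
        m = len(pos)
        idx = np.empty((n, m), dtype=int)
        idx[:, 0] = rng.choice(K, size=n, p=init)
        for k in range(1, m):
            r = float(haldane_cm_to_rf(pos[k] - pos[k - 1]))
            T = transition_matrix(cross_type, r)
            u = rng.random(n)
            cum = np.cumsum(T[idx[:, k - 1]], axis=1)
            idx[:, k] = (u[:, None] > cum).sum(axis=1)
        cols.append(states[idx])
    geno = np.concatenate(cols, axis=1).astype(np.int8)
    ids = [f"ind{i + 1}" for i in range(n)]
    return CrossPopulation(cross_type, geno, ids, gmap)


def sim_spatial(n: int, seed: int | np.random.Generator = 0,
                low: float = 1.0, high: float = 100.0) -> SpatialMap:
    """Individuals at independent Unif(low, high) x/y positions."""
    if n < 2:
        raise ParameterError("need at least 2 individuals")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coords = rng.uniform(low, high, size=(n, 2))
    return SpatialMap([f"ind{i + 1}" for i in range(n)], coords)


def _self_genotype_values(cross_type: str, a1: float) -> np.ndarray:
    """Genotype effect values (AA, AB, BB) = (a1, d1, -a1) with additive self
    effects for three-genotype crosses and d1 = -a1 for backcrosses (two
    classes with opposite values)."""
    if cross_type == "backcross":
        return np.array([a1, -a1, 0.0])
    return np.array([a1, 0.0, -a1])


def _identity_table(cross_type: str, a2: float, d2: float) -> np.ndarray:
    """Nine-combination neighbor effect table with deviations (a2, d2).

    Rows/columns are ordered AA, AB, BB; the BB entries are unused for a
    backcross, where the AB class plays the second-genotype role.
    """
    return np.array(
        [
            [a2 * a2, a2 * d2, -a2 * a2],
            [a2 * d2, d2 * d2, -a2 * d2],
            [-a2 * a2, -a2 * d2, a2 * a2],
        ]
    )


def sim_phenotype(
    cross: CrossPopulation,
    smap: SpatialMap,
    scenario: SimScenario,
    rng: np.random.Generator | None = None,
) -> SimResult:
    """Simulate a trait with self, polygenic, and neighbor components.

    The self component is standardized to mean 0 / variance 1 before the
    neighbor component is added; the neighbor component is rescaled so its
    variance share of the final trait equals ``scenario.pve_nei`` exactly in
    sample (solving the quadratic that accounts for the covariance between
    the two components).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    n, m = cross.genotypes.shape
    if scenario.major_marker is not None and not (0 <= scenario.major_marker < m):
        raise ParameterError(f"major marker index {scenario.major_marker} out of range")
    major = (
        scenario.major_marker
        if scenario.major_marker is not None
        else int(rng.integers(m))
    )
    a1 = scenario.max_a1
    geno = np.where(cross.genotypes == -1, AB, cross.genotypes)  # impute rare missing

    gvals_major = _self_genotype_values(cross.cross_type, a1)
    gvals_minor = _self_genotype_values(cross.cross_type, scenario.polygenic_ratio * a1)
    self_geno = gvals_minor[geno].sum(axis=1) - gvals_minor[geno[:, major]] + gvals_major[
        geno[:, major]
    ]
    genetic_var = float(np.var(self_geno))
    noise_var = max(1.0 - genetic_var, 0.05)
    y_self = self_geno + rng.normal(0.0, np.sqrt(noise_var), size=n)
    y_self = (y_self - y_self.mean()) / y_self.std()

    s_true = float(np.percentile(
        smap.distance_matrix()[np.triu_indices(n, 1)], scenario.true_percentile
    ))
    A = neighborhood_matrix(smap, s_true)
    L = A.sum(axis=1)
    if np.any(L == 0):
        raise SimulationError(
            f"true scale at the {scenario.true_percentile:g}th percentile leaves "
            "isolated individuals; increase the percentile or n"
        )

    if scenario.scenario == "neighbor-phenotype":
        a2 = d2 = None
        w = (A @ y_self) / L
    else:
        ratio_a2, ratio_d2 = SCENARIOS[scenario.scenario]
        a2, d2 = ratio_a2 * a1, ratio_d2 * a1
        T = _identity_table(cross.cross_type, a2, d2)
        w = T[geno[:, major][:, None], geno[:, major][None, :]]
        w = (A * w).sum(axis=1) / L
        # polygenic neighbor effects at the remaining markers
        Tp = _identity_table(
            cross.cross_type, scenario.polygenic_ratio * a2, scenario.polygenic_ratio * d2
        )
        for k in range(m):
            if k == major:
                continue
            wk = Tp[geno[:, k][:, None], geno[:, k][None, :]]
            w = w + (A * wk).sum(axis=1) / L

    if a2 == 0 and d2 == 0:
        trait = y_self
        c = 0.0
    else:
        sw2 = float(np.var(w))
        if sw2 <= 1e-12:
            raise SimulationError("neighbor identity has no variance; share unattainable")
        rho = scenario.pve_nei
        sy2 = float(np.var(y_self))
        cov = float(np.mean((y_self - y_self.mean()) * (w - w.mean())))
        disc = rho * rho * cov * cov + rho * (1 - rho) * sw2 * sy2
        c = (rho * cov + np.sqrt(disc)) / ((1 - rho) * sw2)
        trait = y_self + c * (w - w.mean())
    realized = float(np.var(c * w) / np.var(trait)) if c else 0.0
    return SimResult(
        cross=cross,
        smap=smap,
        trait=trait,
        self_component=y_self,
        a2=a2,
        d2=d2,
        s_true=s_true,
        true_percentile=scenario.true_percentile,
        realized_share=realized,
        major_marker=major,
        scenario=scenario,
    )


def simulate_dataset(scenario: SimScenario, gmap: GeneticMap | None = None) -> SimResult:
    """Convenience wrapper: cross + spatial map + trait from one seed."""
    if gmap is None:
        gmap = default_map()
    rng = np.random.default_rng(scenario.seed)
    cross = sim_cross(scenario.cross_type, gmap, scenario.n, rng)
    smap = sim_spatial(scenario.n, rng)
    return sim_phenotype(cross, smap, scenario, rng)


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------

def load_scenarios(path) -> list[SimScenario]:
    """Read benchmark scenarios from a YAML file.

    The file holds a list (or a ``scenarios:`` list) of mappings whose keys
    are ``SimScenario`` fields, e.g.::

        scenarios:
          - {cross_type: f2, scenario: additive, n: 200}
          - {cross_type: backcross, scenario: backcross-additive}
    """
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if isinstance(payload, dict):
        payload = payload.get("scenarios", [])
    return [SimScenario(**entry) for entry in payload]


def analyze_simulation(
    sim: SimResult,
    percentile_step: float = 10.0,
    error_prob: float = 1e-4,
    pseudomarker_step: float | None = None,
) -> dict:
    """Full pipeline on one simulated data set.

    Runs genotype probabilities, the delta-PVE scale selection, and the
    self/neighbor scans at the selected scale; returns the major-marker LODs
    and the variance-partition summaries.
    """
    grid = insert_pseudomarkers(sim.cross.map, step=pseudomarker_step)
    gp = calc_genoprob(sim.cross, grid, error_prob=error_prob)
    ph = Phenotype(sim.trait, name="sim")
    scales = distance_scales(sim.smap, percentile_step)
    prof = delta_pve(ph, gp, sim.smap, scales)
    ni = neighbor_identity(gp, sim.smap, prof.s_hat)
    sf = scan_self(gp, ph)
    nf = scan_neighbor(gp, ni, ph, sf)
    marker_idx = grid.marker_grid_indices(sim.cross.map)
    row = int(marker_idx[sim.major_marker])
    fits = prof.fits.get(prof.s_hat)
    pve_self = fits.pve_self if fits is not None else np.nan
    pve_nei = fits.pve_nei if fits is not None else np.nan
    return {
        "s_hat": prof.s_hat,
        "s_hat_percentile": prof.s_hat_percentile,
        "s_true": sim.s_true,
        "true_percentile": sim.true_percentile,
        "lod_self_major": float(sf.table["lod_self"].iloc[row]),
        "lod_nei_major": float(nf.table["lod_nei"].iloc[row]),
        "pve_self": pve_self,
        "pve_nei": pve_nei,
        "h2": prof.h2,
        "net_nei_pve": (pve_self + pve_nei) - prof.h2,
        "realized_share": sim.realized_share,
    }


def run_benchmark(
    scenarios: Sequence[str | SimScenario] = ("additive",),
    percentiles: Sequence[float] = (10, 20, 30, 40, 50),
    reps: int = 10,
    n: int = 200,
    seed: int = 0,
    cross_type: str = "f2",
    gmap: GeneticMap | None = None,
) -> pd.DataFrame:
    """Replicate-level benchmark table over scenarios and true distances.

    Per-replicate failures are recorded with NaN results rather than
    propagated.
    """
    if reps < 5:
        raise ParameterError("reps must be >= 5")
    ss = np.random.SeedSequence(seed)
    rows = []
    for scen in scenarios:
        for pct in percentiles:
            for rep in range(reps):
                child = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                if isinstance(scen, SimScenario):
                    sc = SimScenario(
                        cross_type=scen.cross_type,
                        scenario=scen.scenario,
                        true_percentile=pct,
                        pve_nei=scen.pve_nei,
                        n=scen.n,
                        seed=child,
                        max_a1=scen.max_a1,
                    )
                else:
                    ct = "backcross" if scen == "backcross-additive" else cross_type
                    sc = SimScenario(
                        cross_type=ct, scenario=scen, true_percentile=pct, n=n, seed=child
                    )
                base = {"scenario": sc.scenario, "percentile": pct, "rep": rep, "seed": child}
                try:
                    sim = simulate_dataset(sc, gmap)
                    base.update(analyze_simulation(sim))
                except Exception as exc:  # recorded, not fatal
                    base["error"] = str(exc)
                rows.append(base)
    return pd.DataFrame(rows)
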