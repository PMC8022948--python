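# neiqtl

Interval mapping of QTLs underlying **spatial neighbor effects** in
experimental crosses (F2 intercross, backcross, selfed recombinant inbred
lines).

Phenotypes of sessile organisms — plants above all — depend not only on an
individual's own genotype but on the genotypes of its spatial neighbors:
herbivores move between adjacent plants, volatiles and shading act over
short distances, pollinators integrate over patches.  `neiqtl` detects loci
where the *genotypic identity* between a focal individual and its neighbors
within a distance *s* affects the focal trait, and estimates the effective
distance *s* at which those effects act.

## Model

For focal individual *i* with neighbors *j* within distance *s*, the trait
is decomposed as

    y_i = ȳ + g_i + Σ_{<i,j>} g_i g_j(s) / L_i + e_i

where `g_i ∈ {a1, d1, -a1}` for genotypes AA, AB, BB are the additive and
dominance deviations of the ordinary (self) QTL effect, `g_i g_j` is the
neighbor effect of each of the nine ordered genotype combinations
(`a2²`, `±a2 d2`, `d2²`, with sign flipping when the pair carries opposite
alleles — an Ising-type interaction between genotype "spins"), and `L_i` is
the number of neighbors.  A positive fitted neighbor effect means the trait
increases when neighbors share alleles.

The pipeline mirrors interval mapping throughout:

1. **Conditional genotype probabilities** `p_i = Pr(g_i | M)` at markers and
   pseudomarkers from a hidden Markov chain along each chromosome
   (Haldane or Kosambi map functions, genotyping-error emission).
2. **Conditional neighbor genotypic identity**
   `z_i = Σ_{<i,j>} Σ_v Σ_w p_{i,v} p_{j,w} C[v,w] / L_i` for a coding
   table C (quadratic for F2; symmetric ±1 products for two-genotype
   crosses).
3. **Effective distance by ΔPVE**: a two-kernel mixed model
   `y = Xβ + u1 + u2 + e`, with `Var(u1) = σ1² K1` (self kinship) and
   `Var(u2) = σ2² K2` (neighbor-identity similarity at scale s), is fitted
   by AI-REML across a percentile grid of scales; the selected scale `ŝ`
   maximizes the increment of PVE_nei.  Binary traits use a logistic PQL
   fit and report `RVE_nei = σ2²/σ1²`.
4. **Stepwise genome scans** (Haley-Knott regression): `LOD_self` tests the
   self effect against the covariate-only model; the fitted self effect then
   enters as a covariate and `LOD_nei` tests the identity `z` (plus `z²` for
   F2) against it, guarding the neighbor test against the built-in
   self/neighbor correlation.  Genome-wide significance by trait
   permutation (999 by default), plus two-way epistasis scans against a
   focal position.

## Worked example

```python
import neiqtl as nq

# F2 arena: 200 individuals at Unif(1,100)^2 positions, one major-effect
# marker, neighbor effects at the 10th distance percentile carrying 50%
# of trait variance
sc = nq.SimScenario(cross_type="f2", scenario="additive",
                    true_percentile=10, pve_nei=0.5, n=200, seed=42)
sim = nq.simulate_dataset(sc)

gp = nq.calc_genoprob(sim.cross, error_prob=1e-4)
ph = nq.Phenotype(sim.trait, name="trait")
scales = nq.distance_scales(sim.smap, percentile_step=10)
prof = nq.delta_pve(ph, gp, sim.smap, scales)

ni = nq.neighbor_identity(gp, sim.smap, prof.s_hat)
sf = nq.scan_self(gp, ph)
res = nq.scan_neighbor(gp, ni, ph, sf)
thr = nq.perm_threshold(gp, ni, ph, n_perm=199, seed=42)
```

prints (via the assembled report in the docstrings):

```
simulated 200 F2 individuals, 25 markers, true neighbor scale s* = 18.97 (10th pct), realized neighbor share = 0.50
delta-PVE selected s_hat = 18.97 (10th pct); PVE_nei at s_hat = 0.33, h2 = 0.25
major marker m3_3 (chr 3, 30 cM): LOD_self = 17.13, LOD_nei = 37.53, 2a1 = 2.57, 2a2^2 = 12.26
permutation thresholds (199 perms): LOD_nei 5% = 2.44, 10% = 2.22
```

Reading the numbers: the ΔPVE profile recovers the true interaction
distance exactly (the 10th-percentile scale); a third of trait variance is
attributed to polygenic neighbor effects; at the causal marker the neighbor
LOD of 37.5 towers over the 5% genome-wide permutation threshold of 2.4;
the positive `2a2²` says sharing alleles with neighbors raises the trait.

The same pipeline runs from the shell:

```sh
neiqtl simulate --n 200 --seed 42 --out sim
neiqtl pve  --cross sim_cross.csv --smap sim_smap.csv --cross-type f2 --trait trait
neiqtl scan --cross sim_cross.csv --smap sim_smap.csv --cross-type f2 \
            --trait trait --scale auto --n-perm 999 --seed 42
```

File formats: a cross CSV (row 1 marker/phenotype names, row 2 chromosome
ids — blank for phenotype columns, row 3 cM positions, one row per
individual; genotype codes AA/AB/BB or A/H/B, `-` or blank for missing) and
a spatial map CSV with columns `id,x,y`.

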