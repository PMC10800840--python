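# ecoassembly

Community-assembly inference for microbial survey data — estuarine fungal
communities being the motivating case.  Given a sample × taxon abundance
table, a rooted phylogeny and sample metadata (habitat group, coordinates,
environmental variables), the package quantifies how much of community
structure is shaped by deterministic processes (environmental selection)
versus stochastic ones (dispersal and ecological drift), and characterises
the community's diversity and co-occurrence structure along the way.

## What it computes

**Assembly processes** (the core):

- **βMNTD / βNTI** — the abundance-weighted beta mean nearest taxon
  distance between two communities,
  βMNTD(k,l) = ½·[Σᵢ f\_ik·min\_{j∈l} d\_ij + Σⱼ f\_jl·min\_{i∈k} d\_ij],
  standardised against a tip-label-shuffle null:
  βNTI = (βMNTD\_obs − μ\_null)/σ\_null.  βNTI < −2 signals homogeneous
  selection, βNTI > +2 variable selection.
- **RC(Bray)** — a Raup–Crick metric on Bray–Curtis dissimilarity under a
  probabilistic assembly null that preserves each sample's richness and
  read depth (taxa drawn by occurrence frequency, reads by pooled
  abundance), scaled to [−1, 1].  Among |βNTI| < 2 pairs, RC < −0.95 is
  read as homogenizing dispersal, RC > +0.95 as dispersal limitation, and
  the rest as drift — the standard five-process classification.
- **Sloan neutral community model** — a taxon of mean relative abundance p
  is predicted to occur in a local community with frequency
  F(p) = 1 − I\_d(N·m·p, N·m·(1−p)), where I is the regularized incomplete
  beta function, N the community (read-depth) size, m the migration rate
  and d the detection limit (1/N by default).  m is fitted by least
  squares; R² measures how much of the occupancy–abundance relationship
  neutrality explains.
- **pNST** — the phylogenetic normalized stochasticity ratio: each
  within-group pair's observed βMNTD is compared to its taxa-shuffle null
  expectation and normalized to [0, 1]; values above 0.5 indicate
  stochasticity-dominated assembly.

**Around it**: alpha diversity (richness, Chao1, ACE, Shannon, Simpson,
Pielou), four beta-diversity metrics with UPGMA dendrograms, beta-diversity
partitioning into replacement vs richness-difference components (Baselga
and Podani families), VIF screening, db-RDA/CPCoA constrained ordination
with permutation tests, Spearman correlation tables with BH-FDR, LMG
relative-importance decomposition, great-circle distance–decay regression,
and FDR-filtered co-occurrence networks with Louvain modules and Zi–Pi
keystone classification (keystone iff Zi ≥ 2.5 or Pi ≥ 0.62).

A synthetic-community generator produces surveys under known regimes —
neutral Sloan sampling, conserved-niche selection, distance-dependent
turnover, and a full 21-station × 4-habitat estuarine survey — so every
inference stage is validated by ground-truth recovery rather than by
fixtures alone.

## Worked example

```python
import ecoassembly as ea

scen = ea.SyntheticScenario(n_taxa=300, reads_per_sample=1000,
                            migration_rate=0.1, seed=42)
table = ea.simulate_neutral(scen, n_samples=50)
tree = ea.simulate_tree(300, seed=42)
groups = {s: ("north" if i < 25 else "south")
          for i, s in enumerate(table.sample_ids)}

fit = ea.fit_ncm(table)
print(f"NCM: m = {fit.m:.3f}, Nm = {fit.Nm:.0f}, R^2 = {fit.r_squared:.3f}")

z = ea.bnti(table, tree, n_null=199, seed=1)
rc = ea.raup_crick_bray(table, n_null=199, seed=2)
cls = ea.classify_processes(z, rc, groups=groups)
print(cls.fractions.round(1))

nst = ea.pnst(table, tree, groups, n_null=199, seed=3)
print(nst.group_means.round(3))
```

prints

```
NCM: m = 0.131, Nm = 131, R^2 = 0.936
        homogeneous_selection  variable_selection  ...  dispersal_limitation  drift
pooled                    0.2                 0.5  ...                   3.8   95.6
north                     0.0                 0.0  ...                   4.7   95.3
south                     0.3                 0.0  ...                   1.7   98.0

north    0.869
south    0.863
```

The data were generated neutrally (m = 0.1), and the inference agrees:
the neutral model explains 94% of the occupancy–abundance relationship
(the fitted m runs slightly high because the sharp detection threshold
d = 1/N under-counts detections of taxa just below the limit — see
`docs/methods.md`), 95–98% of sample pairs classify as drift, and pNST is
well above 0.5 in both groups.

## Command line

```bash
ecoassembly simulate --scenario survey --seed 1 --out demo/
ecoassembly all --table demo/table.tsv --tree demo/tree.nwk \
    --metadata demo/metadata.tsv --out-dir demo/results --n-null 199
```

writes per-stage TSVs (alpha.tsv, bnti.tsv, rcbray.tsv, fractions.tsv,
ncm_fit.tsv, pnst.tsv, decay.tsv, network tables) plus a `manifest.json`
recording seeds and output checksums; a rerun with the same config is
byte-identical.

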