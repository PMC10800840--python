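# Methods

This note records the models behind each stage, the defaults that matter,
the numerical conventions, and the known limits of what the synthetic
validation shows.

## Data model and normalization

All stages consume a validated sample × taxon count matrix (samples as
rows), a rooted tree whose leaves cover the taxa used in phylogenetic
operations, and per-sample metadata.  The only abundance normalization
anywhere is total-sum scaling to relative abundance, applied where a method
requires it (βMNTD weights, the neutral model's p, network correlations);
there is no rarefaction.  `align_inputs` restricts analyses to the
intersection of table/metadata samples and tree taxa, sorts ids
canonically, and reports what was dropped.  Missing values are allowed
only in environmental variables; operations needing a variable drop the
samples lacking it and log the count.

## Alpha and beta diversity

Shannon entropy is in nats and Simpson is 1 − Σp², matching the R
ecosystem's defaults.  Chao1 uses the bias-corrected form
S + F₁(F₁−1)/(2(F₂+1)), which is defined even without doubletons; the
classic form is available via `bias_corrected_chao1=False`.  ACE uses the
conventional rare-taxon cutoff of 10.  Jaccard dissimilarity is computed
on presence/absence; Bray–Curtis, Euclidean and Manhattan on abundances as
given.  UPGMA places each internal node at half its merge distance and
sorts labels first so ties resolve deterministically.

Beta-diversity partitioning implements both decompositions in use:
Baselga's (total = Sørensen, replacement = Simpson turnover
min(b,c)/(a+min(b,c))) and Podani's (total = Jaccard, replacement =
2·min(b,c)/(a+b+c), richness difference = |b−c|/(a+b+c)).  They are
numerically different, so the family is a mandatory argument with no
default.  Group summaries aggregate within-group pairs only, as mean
component over mean total × 100.

## Constrained ordination and factor statistics

db-RDA embeds the dissimilarity matrix by principal coordinates, discards
negative eigenvalues (logging the discarded fraction of absolute inertia;
Lingoes/Cailliez corrections are not implemented), and regresses the
coordinates on the centered constraint matrix.  The constrained proportion
is fitted over total inertia; conditioning variables are partialled out of
both sides first.  Permutation p-values use the (b+1)/(m+1) estimator;
term tests are marginal, permuting residuals under the reduced model.
Envfit-style vector fitting reports each variable's R² against the first
two constrained axes with its own permutation p.  VIF screening removes
variables iteratively, largest VIF ≥ 10 first; perfectly collinear
variables are removed with a warning rather than an error.  LMG
relative importance is computed by exact subset enumeration (Shapley
decomposition of R²), limited to 12 predictors — the environmental sets
this package targets have about five.

Correlation tables default to Spearman with Benjamini–Hochberg adjustment;
significance stars follow the convention \*: 0.01 ≤ p < 0.05,
\*\*: 0.005 ≤ p < 0.01, \*\*\*: 0.001 ≤ p < 0.005, \*\*\*\*: p < 0.001,
applied to adjusted p-values when FDR is on.

## βMNTD, βNTI and RC(Bray)

βMNTD weights each taxon's distance to its nearest relative in the other
community by relative abundance; a taxon present in both communities
contributes its own zero distance (the standard nearest-taxon convention).
The βNTI null shuffles taxon labels across all tree tips — implemented as
a joint row/column permutation of the cophenetic matrix — with 999
replicates by default.  Pairs with zero null variance (e.g., star
phylogenies) are reported as NaN with a warning, never ±∞, and are
excluded from (and counted alongside) the process fractions.

The RC(Bray) null rebuilds each sample at its observed richness and read
depth: taxa are drawn without replacement with probability proportional to
occurrence frequency, seeded with one read each, and remaining reads are
distributed multinomially by pooled relative abundance.  RC = 2·[P(null <
obs) + ½·P(null = obs)] − 1; the half-weight tie rule makes RC exactly 0
under a null-identical process.  RC is a rank statistic: its sign reflects
whether the data are over- or under-dispersed *relative to this null*, so
even fully neutral data can sit far from 0 — Sloan sampling at Nm = 100 is
overdispersed (RC mean ≈ +0.8, read as dispersal limitation), at Nm = 1000
underdispersed (≈ −0.5), and pure multinomial sampling strongly so
(≈ −0.96).  The classification's drift fraction is therefore meaningful
only jointly with βNTI, which is how the five-process rule uses it.

The five-process rule, in order: βNTI < −2 → homogeneous selection;
βNTI > +2 → variable selection; otherwise RC < −0.95 → homogenizing
dispersal; RC > +0.95 → dispersal limitation; else drift.  (The
dispersal conditions are one-sided; an absolute-value reading of the lower
cutoff would be unsatisfiable.)  Fractions are reported both pooled over
all pairs and per within-group pairs, since the two summaries differ
whenever group sizes differ.

## Sloan neutral community model

N is the mean read depth, p the mean relative abundance, and the observed
frequency the fraction of samples with nonzero counts.  The single
parameter m is fitted by bounded scalar least squares of observed on
predicted frequency; the 95% band is a Wilson binomial interval around the
predicted frequency at the number of samples, and taxa are flagged
above/within/below it.

The detection limit defaults to the conventional d = 1/N.  For data whose
detection process truly is N-read multinomial sampling this sharp
threshold is biased: the probability of *not* detecting a taxon with local
relative abundance q is (1−q)^N ≈ e^(−Nq), not a step at q = 1/N, so taxa
just below the limit are still detected appreciably often and the fitted m
runs ≈ 30% high at N = 1000 (an exact beta-binomial computation, not
sampling noise).  Setting `detection_limit = ln(2)/N` — the abundance at
which the N-read detection probability is one half — removes almost all of
the bias; the default stays at 1/N for comparability with the standard
fitting convention.

## pNST

For every within-group pair, observed βMNTD is compared with the mean of
its taxa-shuffle null distribution (1000 replicates by default).  Within
each group, dissimilarities are scaled by the group's maximum over
observed and null values; a pair more similar than expected contributes
D/E, one more dissimilar contributes (Dmax−D)/(Dmax−E), both clamped to
[0, 1].  The normalization is per group because stochasticity is a
within-group question — a global maximum dominated by between-habitat
distances would crush the dissimilar branch towards 1.  The implementation
was checked against an independent R route (picante's nearest-taxon
dissimilarity plus the same normalization coded separately in R): βMNTD
agrees to 10 decimal places and group-mean pNST within 0.02 on shared
fixtures; the frozen R values live in the test suite.

pNST detects phylogenetically structured departures from the null.  When
strong selection makes within-group communities nearly identical, most
abundance is shared between pair members and contributes zero to both
observed and null βMNTD — the signal then rides on the minor non-shared
taxa, and pNST stays high even though assembly is deterministic.  The
signature it does catch is communities assembled from *different members
of the same small clade*: observed nearest-taxon distances are
within-clade, null ones tree-wide.

## Synthetic generators (and what they do not show)

All generators are pure functions of (parameters, seed).

- **Trees** are random ultrametric binary trees (coalescent-style merges,
  depth rescaled to 1, leaves t1..tn).
- **Metacommunity** abundances default to a lognormal rank-abundance
  (σ = 1.5, 300 taxa), which yields realistic occupancy–abundance curves.
- **Neutral** samples draw relative abundances taxon-wise from
  Beta(Nm·p, Nm·(1−p)) — the Sloan stationary distribution — renormalise,
  and draw N-read multinomial counts (defaults N = 1000, m = 0.1).  This
  targets the stationary distribution directly rather than running forward
  birth–death–immigration dynamics.
- **Selection** evolves niche optima by Brownian motion on the tree and
  weights taxa by p·exp(−w(env−opt)²).  The ground-truth fixture for
  selection recovery (`selection_fixture`) anchors the optima on two small
  disjoint clades (≈ n/8 leaves each, Brownian rate 0.3 around anchors at
  ±1, remaining taxa pushed off-axis; w = 6, 500 reads, environment
  clusters at ±1).  Anchoring guarantees the conserved-niche premise on
  every tree realization; with free Brownian traits, many realizations put
  no clade structure at the trait extremes, and no phylogenetic method
  could — or should — call selection there.
- **Distance decay** gives every location a lognormally perturbed copy of
  the metacommunity and blends them with an exp(−rate·distance) kernel;
  rate 0 is exactly exchangeable, and the positive-control rate of
  3 × 10⁻⁵ per metre (≈ 30 km length scale) yields slopes of order 10⁻⁷
  per metre over a one-degree box.
- **The full survey fixture** places 21 stations on a grid in 125–126°E,
  30–31°N with four habitats per station: water-column groups are
  drift-dominated (m = 0.08), the sediment group leans homogenizing
  (m = 0.8), and five environmental variables share one latent estuarine
  gradient with NH4-N co-varying positively with PO4-P and NO2-N and
  negatively with NO3-N and pH.

What passing these recoveries does **not** show: the generators produce no
compositional closure effects beyond multinomial sampling, no sequencing
error or chimeras, no spatial autocorrelation in the selection scenario,
and equal read depths across samples — real amplicon data violate all
four.  The network stage in particular inherits the usual caveat that
correlation networks on relative abundances are not compositionally aware
(SparCC/SPIEC-EASI-style estimators would be the upgrade path).

## Network conventions

The edge filter reads the common "R² > 0.7" reporting convention as
|ρ| ≥ 0.7 on the correlation coefficient itself; BH adjustment runs over
all tested pairs and the significance cutoff applies to adjusted p.  A 20%
prevalence pre-filter avoids spurious zero-driven correlations (set it to
0 to test every taxon).  Topology metrics are unweighted; the average path
length is computed on the largest connected component with its coverage
reported, and node counts are given both with and without isolated nodes.
Louvain modules use absolute edge weights at resolution 1.0 with a fixed
seed.  Zi uses the within-module degree z-score with Zi = 0 by convention
in zero-variance modules (flagged); Pi = 1 − Σ(k_s/k)²; roles follow the
2.5 / 0.62 cutoffs and keystone status is Zi ≥ 2.5 or Pi ≥ 0.62.

## Problem sizes and replicate counts

Defaults are 999 null replicates for βNTI and RC(Bray) and 1000 for pNST.
The validation suite and the acceptance script run the same algorithms at
199 replicates with 50 samples × 300 taxa (neutral), 20 samples × 300 taxa
(selection), 25 samples × 100 taxa × 20 replicate surveys (distance
decay), and 50 replicate 10-taxon noise panels (network calibration) —
sizes at which every stage's behaviour is already stable, as the
between-seed spreads in the tests show.
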