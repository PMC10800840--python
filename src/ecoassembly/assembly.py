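"""Community-assembly inference: phylogenetic and taxonomic null models.

This is the package's core engine.  It quantifies the balance of
deterministic and stochastic assembly processes from three complementary
angles:

* **betaNTI** — the standardized effect size of the abundance-weighted beta
  mean nearest taxon distance (betaMNTD) against a tip-label-shuffle null.
  |betaNTI| >= 2 signals selection (negative: homogeneous selection across
  samples; positive: variable selection along environmental gradients).
* **RC(Bray)** — a Raup-Crick metric on Bray-Curtis under a probabilistic
  community-assembly null that preserves each sample's richness and read
  depth while drawing taxa by occurrence frequency and abundance.  Extreme
  values (|RC| > 0.95) signal dispersal processes, the centre signals drift.
* **Sloan neutral community model** — predicts a taxon's occurrence
  frequency across local communities from its mean relative abundance via
  the beta distribution governed by N*m; the fit's R^2 measures how much of
  the community a purely neutral birth-death-immigration balance explains.
* **pNST** — the phylogenetic normalized stochasticity ratio; per sample
  pair, the observed betaMNTD is compared with its taxa-shuffle null
  expectation and normalized to [0, 1], with > 0.5 read as
  stochasticity-dominated.

Pairs are classified by the standard two-stage rule: selection first by
betaNTI, then dispersal vs drift by RC(Bray) among the |betaNTI| < 2 pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.proportion import proportion_confint

from .io import CommunityTable, PairwiseMatrix, PhyloTree, to_relative_abundance

logger = logging.getLogger("ecoassembly")

__all__ = [
    "ProcessThresholds",
    "ProcessClassification",
    "NCMFit",
    "NSTResult",
    "PROCESS_LABELS",
    "beta_mntd",
    "bnti",
    "raup_crick_bray",
    "classify_processes",
    "fit_ncm",
    "pnst",
]

PROCESS_LABELS = (
    "homogeneous_selection",
    "variable_selection",
    "homogenizing_dispersal",
    "dispersal_limitation",
    "drift",
)


@dataclass
class ProcessThresholds:
    """Classification cutoffs: |betaNTI| >= bnti_cut -> selection;
    |RC| > rc_cut -> dispersal; pNST > pnst_cut -> stochasticity-dominated."""

    bnti_cut: float = 2.0
    rc_cut: float = 0.95
    pnst_cut: float = 0.5

    def __post_init__(self) -> None:
        if self.bnti_cut <= 0 or self.rc_cut <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.pnst_cut < 1.0:
            raise ValueError("pnst_cut must lie in (0, 1)")


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI

def _min_dist_to_sample(d: np.ndarray, presence: np.ndarray) -> np.ndarray:
    """M[s, i] = min over taxa j present in sample s of d[i, j]."""
    n, S = presence.shape
    m = np.empty((n, S))
    for s in range(n):
        cols = np.flatnonzero(presence[s])
        m[s] = d[:, cols].min(axis=1)
    return m


def _beta_mntd_values(weights: np.ndarray, presence: np.ndarray,
                      d: np.ndarray) -> np.ndarray:
    m = _min_dist_to_sample(d, presence)
    b = weights @ m.T       # b[k, l] = sum_i f_ik * min_{j in l} d_ij
    return 0.5 * (b + b.T)


def beta_mntd(table: CommunityTable, phylo_dist: PairwiseMatrix,
              weighted: bool = True) -> PairwiseMatrix:
    """Beta mean nearest taxon distance between all sample pairs.

    For samples k and l:
    0.5 * [sum_i f_ik * min_{j in l} d_ij + sum_j f_jl * min_{i in k} d_ij],
    the minimum running over taxa present in the other sample (a taxon
    shared by both contributes its own zero distance).  Weights f are
    relative abundances when ``weighted``, else uniform over present taxa.
    """
    missing = set(table.taxon_ids) - set(phylo_dist.labels)
    if missing:
        raise KeyError(f"taxa missing from phylogenetic distances: "
                       f"{sorted(missing)[:5]}...")
    d = phylo_dist.subset(table.taxon_ids).values
    presence = table.counts > 0
    if not presence.any(axis=1).all():
        empty = [s for s, ok in zip(table.sample_ids, presence.any(axis=1)) if not ok]
        raise ValueError(f"samples with no taxa present: {empty}")
    if weighted:
        weights = to_relative_abundance(table).counts
    else:
        weights = presence / presence.sum(axis=1, keepdims=True)
    vals = _beta_mntd_values(weights, presence, d)
    np.fill_diagonal(vals, 0.0)
    return PairwiseMatrix(vals, list(table.sample_ids), "beta_mntd")


def _bnti_from_dist(table: CommunityTable, phylo_dist: PairwiseMatrix,
                    n_null: int, seed: int, weighted: bool = True
                    ) -> tuple[PairwiseMatrix, np.ndarray]:
    """betaNTI matrix plus the raw null betaMNTD draws (n_null, n, n)."""
    d = phylo_dist.subset(table.taxon_ids).values
    presence = table.counts > 0
    if weighted:
        weights = to_relative_abundance(table).counts
    else:
        weights = presence / presence.sum(axis=1, keepdims=True)
    obs = _beta_mntd_values(weights, presence, d)
    rng = np.random.default_rng(seed)
    S = d.shape[0]
    nulls = np.empty((n_null, *obs.shape))
    for r in range(n_null):
        perm = rng.permutation(S)
        nulls[r] = _beta_mntd_values(weights, presence, d[np.ix_(perm, perm)])
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    degenerate = (sd <= 0) & ~np.eye(obs.shape[0], dtype=bool)
    if degenerate.any():
        logger.warning("bnti: %d pair(s) have zero null variance; "
                       "betaNTI undefined for them", int(degenerate.sum() // 2))
        z[degenerate] = np.nan
    np.fill_diagonal(z, 0.0)
    return PairwiseMatrix(z, list(table.sample_ids), "bnti"), nulls


def bnti(table: CommunityTable, tree: PhyloTree, n_null: int = 999,
         seed: int = 0, weighted: bool = True) -> PairwiseMatrix:
    """Beta nearest taxon index under the taxa-shuffle null.

    The null shuffles taxon labels across the tree tips (equivalently,
    jointly permutes rows and columns of the cophenetic matrix) and
    recomputes betaMNTD each replicate; betaNTI is (obs - null mean) / null
    sd per pair.  Pairs whose null distribution is degenerate (for example
    on a star phylogeny) are reported as NaN with a warning rather than
    +/-inf.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    phylo_dist = tree.cophenetic(table.taxon_ids)
    z, _ = _bnti_from_dist(table, phylo_dist, n_null, seed, weighted)
    return z


# ---------------------------------------------------------------------------
# Raup-Crick (Bray-Curtis)

def raup_crick_bray(table: CommunityTable, n_null: int = 999,
                    seed: int = 0) -> PairwiseMatrix:
    """Bray-Curtis-based Raup-Crick under the probabilistic-assembly null.

    Each null sample keeps its observed richness and read depth: taxa are
    drawn without replacement with probability proportional to occurrence
    frequency across all samples, seeded with one read each, and the
    remaining reads are distributed multinomially with probability
    proportional to pooled relative abundance.  RC scales the null rank of
    the observed Bray-Curtis to [-1, 1] with ties given half weight, so a
    perfectly exchangeable community yields RC ~ 0.
    """
    if not table.is_integer():
        raise ValueError("Raup-Crick null requires integer counts")
    counts = np.round(table.counts).astype(int)
    n, S = counts.shape
    presence = counts > 0
    richness = presence.sum(axis=1)
    if (richness > S).any():
        raise ValueError("sample richness exceeds taxon pool")
    totals = counts.sum(axis=1)
    occ = presence.sum(axis=0).astype(float)
    occ_p = occ / occ.sum()
    pool = counts.sum(axis=0).astype(float)
    pool_p = pool / pool.sum()

    obs_bc = squareform(pdist(counts, metric="braycurtis"))
    rng = np.random.default_rng(seed)
    lt = np.zeros((n, n))
    eq = np.zeros((n, n))
    null = np.zeros((n, S))
    for _ in range(n_null):
        null[:] = 0
        for k in range(n):
            chosen = rng.choice(S, size=richness[k], replace=False, p=occ_p)
            null[k, chosen] = 1
            extra = totals[k] - richness[k]
            if extra > 0:
                w = pool_p[chosen]
                null[k, chosen] += rng.multinomial(extra, w / w.sum())
        nb = squareform(pdist(null, metric="braycurtis"))
        lt += nb < obs_bc - 1e-12
        eq += np.abs(nb - obs_bc) <= 1e-12
    rc = 2.0 * (lt + 0.5 * eq) / n_null - 1.0
    np.fill_diagonal(rc, 0.0)
    return PairwiseMatrix(rc, list(table.sample_ids), "rc_bray")


# ---------------------------------------------------------------------------
# process classification

@dataclass
class ProcessClassification:
    bnti: PairwiseMatrix
    rc_bray: PairwiseMatrix
    pair_labels: dict[tuple[str, str], str]
    fractions: pd.DataFrame          # rows: pooled + per group; columns: labels
    n_undefined: int
    thresholds: ProcessThresholds


def classify_pair(b: float, rc: float, thr: ProcessThresholds) -> str:
    """Two-stage rule: selection by betaNTI first, then dispersal/drift by RC."""
    if b < -thr.bnti_cut:
        return "homogeneous_selection"
    if b > thr.bnti_cut:
        return "variable_selection"
    if rc < -thr.rc_cut:
        return "homogenizing_dispersal"
    if rc > thr.rc_cut:
        return "dispersal_limitation"
    return "drift"


def classify_processes(bnti_mat: PairwiseMatrix, rc: PairwiseMatrix,
                       thresholds: ProcessThresholds | None = None,
                       groups: dict[str, str] | None = None
                       ) -> ProcessClassification:
    """Assign each sample pair to one of the five assembly processes.

    ``fractions`` holds the percentage of pairs per process, pooled over all
    pairs and (when ``groups`` is given) separately over within-group pairs.
    Pairs with undefined betaNTI are excluded and counted.
    """
    thr = thresholds or ProcessThresholds()
    if bnti_mat.labels != rc.labels:
        raise ValueError("betaNTI and RC matrices must share sample labels")
    labels = bnti_mat.labels
    n = len(labels)
    pair_labels: dict[tuple[str, str], str] = {}
    n_undef = 0
    rows: list[dict] = []
    for i in range(n):
        for j in range(i + 1, n):
            b = bnti_mat.values[i, j]
            r = rc.values[i, j]
            if np.isnan(b):
                n_undef += 1
                continue
            lab = classify_pair(b, r, thr)
            pair_labels[(labels[i], labels[j])] = lab
            rows.append({"i": labels[i], "j": labels[j], "label": lab})
    df = pd.DataFrame(rows)

    def frac(sub: pd.DataFrame) -> dict[str, float]:
        out = {lab: 0.0 for lab in PROCESS_LABELS}
        if len(sub):
            counts = sub["label"].value_counts()
            for lab in PROCESS_LABELS:
                out[lab] = 100.0 * counts.get(lab, 0) / len(sub)
        return out

    frac_rows = {"pooled": frac(df)}
    if groups is not None and len(df):
        gi = df["i"].map(groups)
        gj = df["j"].map(groups)
        within = df[gi == gj]
        for g in sorted(set(groups.values())):
            sub = within[gi[within.index] == g]
            if len(sub):
                frac_rows[g] = frac(sub)
    fractions = pd.DataFrame(frac_rows).T
    fractions.index.name = "scope"
    return ProcessClassification(bnti_mat, rc, pair_labels, fractions,
                                 n_undef, thr)


# ---------------------------------------------------------------------------
# Sloan neutral community model

@dataclass
class NCMFit:
    m: float
    Nm: float
    r_squared: float
    N: float
    detection_limit: float
    taxa: pd.DataFrame        # p, observed_freq, predicted_freq, lower, upper, band
    ci_level: float = 0.95


def ncm_predicted_frequency(p: np.ndarray, N: float, m: float,
                            detection_limit: float) -> np.ndarray:
    """Sloan expected occurrence frequency: 1 - BetaCDF(d; Nm*p, Nm*(1-p))."""
    nm = N * m
    return 1.0 - stats.beta.cdf(detection_limit, nm * p, nm * (1.0 - p))


def fit_ncm(table: CommunityTable, ci_level: float = 0.95,
            detection_limit: float | None = None) -> NCMFit:
    """Fit the Sloan neutral community model to occurrence frequencies.

    N is the mean read depth, p_i the mean relative abundance of taxon i
    and the observed frequency its fraction of samples with nonzero counts.
    The single free parameter m is fit by least squares of observed on
    predicted frequency; the confidence band around the prediction is a
    Wilson binomial interval at the number of samples, and taxa are flagged
    above/within/below it.

    ``detection_limit`` defaults to the conventional d = 1/N.  Note that
    for data whose detection process truly is N-read multinomial sampling,
    the sharp-threshold approximation with d = 1/N overestimates m (rare
    taxa just below the limit are still detected with appreciable
    probability); d = ln(2)/N, the abundance at which the N-read detection
    probability is one half, removes most of that bias.
    """
    rel = to_relative_abundance(table)
    p = rel.counts.mean(axis=0)
    freq = (table.counts > 0).mean(axis=0)
    keep = p > 0
    if keep.sum() < 10:
        raise ValueError("need at least 10 taxa with nonzero abundance")
    p, freq = p[keep], freq[keep]
    taxa_ids = [t for t, k in zip(table.taxon_ids, keep) if k]
    N = float(table.counts.sum(axis=1).mean())
    d = 1.0 / N if detection_limit is None else float(detection_limit)

    def sse(m: float) -> float:
        pred = ncm_predicted_frequency(p, N, m, d)
        return float(((freq - pred) ** 2).sum())

    res = optimize.minimize_scalar(sse, bounds=(1e-6, 1.0), method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError(f"NCM fit failed to converge: {res.message}")
    m = float(np.clip(res.x, 1e-6, 1.0))
    pred = ncm_predicted_frequency(p, N, m, d)
    sst = float(((freq - freq.mean()) ** 2).sum())
    r2 = 1.0 - sse(m) / sst if sst > 0 else np.nan

    n_samples = table.n_samples
    lower, upper = proportion_confint(
        np.round(pred * n_samples).astype(int), n_samples,
        alpha=1 - ci_level, method="wilson")
    band = np.where(freq > upper, "above", np.where(freq < lower, "below",
                                                    "within"))
    taxa = pd.DataFrame({
        "taxon_id": taxa_ids, "p": p, "observed_freq": freq,
        "predicted_freq": pred, "lower": lower, "upper": upper, "band": band,
    }).set_index("taxon_id")
    return NCMFit(m=m, Nm=N * m, r_squared=float(r2), N=N,
                  detection_limit=d, taxa=taxa, ci_level=ci_level)


# ---------------------------------------------------------------------------
# phylogenetic normalized stochasticity ratio

@dataclass
class NSTResult:
    pairwise: pd.DataFrame    # sample_i, sample_j, group, pnst
    group_means: pd.Series
    n_null: int
    seed: int


def pnst(table: CommunityTable, tree: PhyloTree, groups: dict[str, str],
         n_null: int = 1000, seed: int = 0) -> NSTResult:
    """Phylogenetic normalized stochasticity ratio per within-group pair.

    Observed betaMNTD is compared with its taxa-shuffle null expectation
    E; within each group, dissimilarities are scaled to [0, 1] by the
    group's maximum over observed and null values (stochasticity is a
    within-group notion, so the normalization is per group).  A pair more
    dissimilar than expected gets stochasticity (Dmax - D)/(Dmax - E), one
    more similar than expected gets D/E, so a community indistinguishable
    from its null scores 1 and a strongly selected one approaches 0.
    Group values are means over within-group pairs, clamped to [0, 1].
    """
    group_sizes: dict[str, int] = {}
    for s in table.sample_ids:
        g = groups.get(s)
        if g is None:
            raise KeyError(f"sample {s!r} has no group assignment")
        group_sizes[g] = group_sizes.get(g, 0) + 1
    small = [g for g, k in group_sizes.items() if k < 3]
    if small:
        raise ValueError(f"groups with fewer than 3 samples: {small}")

    phylo_dist = tree.cophenetic(table.taxon_ids)
    d = phylo_dist.subset(table.taxon_ids).values
    presence = table.counts > 0
    weights = to_relative_abundance(table).counts
    obs = _beta_mntd_values(weights, presence, d)
    rng = np.random.default_rng(seed)
    S = d.shape[0]
    nulls = np.empty((n_null, *obs.shape))
    for r in range(n_null):
        perm = rng.permutation(S)
        nulls[r] = _beta_mntd_values(weights, presence, d[np.ix_(perm, perm)])

    e_mat = nulls.mean(axis=0)
    labels = table.sample_ids
    rows = []
    for g in sorted(group_sizes):
        idx = [i for i, s in enumerate(labels) if groups[s] == g]
        dmax = max(float(obs[np.ix_(idx, idx)].max()),
                   float(nulls[:, idx][:, :, idx].max()))
        if dmax <= 0:
            raise ValueError(f"degenerate dissimilarities in group {g!r}")
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                D, E = obs[i, j] / dmax, e_mat[i, j] / dmax
                if D >= E:
                    st = (1.0 - D) / (1.0 - E) if E < 1.0 else 1.0
                else:
                    st = D / E if E > 0 else 1.0
                rows.append({"sample_i": labels[i], "sample_j": labels[j],
                             "group": g, "pnst": float(np.clip(st, 0.0, 1.0))})
    pairwise = pd.DataFrame(rows)
    group_means = pairwise.groupby("group")["pnst"].mean()
    return NSTResult(pairwise, group_means, n_null, seed)
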