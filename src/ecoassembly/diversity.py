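"""Alpha diversity, pairwise dissimilarity, UPGMA, beta partitioning.

Alpha indices follow the conventions of the R ecology stack: Shannon in
natural log, Simpson as 1 - sum(p^2), bias-corrected Chao1, ACE with the
rare-taxon cutoff at 10.  Beta diversity can be partitioned into species
replacement (turnover) and richness-difference components in either the
Baselga (Sorensen) or the Podani (Jaccard) family; the two families are
numerically different decompositions, so the family is always an explicit
argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import alpha as skb_alpha

from .io import CommunityTable, PairwiseMatrix

__all__ = [
    "AlphaDiversityRecord",
    "BetaPartition",
    "alpha_diversity",
    "beta_distance",
    "upgma",
    "partition_beta",
]

BETA_METRICS = ("bray_curtis", "jaccard", "euclidean", "manhattan")


@dataclass
class AlphaDiversityRecord:
    sample_id: str
    richness: int
    chao1: float
    ace: float
    shannon: float   # nats
    simpson: float   # 1 - sum p^2
    pielou: float


def alpha_diversity(table: CommunityTable, bias_corrected_chao1: bool = True
                    ) -> pd.DataFrame:
    """Per-sample alpha-diversity indices.

    Chao1 and ACE are abundance-based richness estimators and require
    integer counts; the bias-corrected Chao1 form
    S + F1*(F1-1)/(2*(F2+1)) is the default (defined even when no
    doubletons exist).
    """
    if not table.is_integer():
        raise ValueError("chao1/ACE require integer counts")
    rows = []
    for sid, x in zip(table.sample_ids, table.counts):
        x = np.round(x).astype(int)
        if x.sum() == 0:
            raise ValueError(f"empty sample: {sid}")
        nz = x[x > 0].astype(float)
        p = nz / nz.sum()
        s = int(nz.size)
        shannon = float(-(p * np.log(p)).sum())
        simpson = float(1.0 - (p ** 2).sum())
        pielou = shannon / np.log(s) if s > 1 else np.nan
        rows.append(AlphaDiversityRecord(
            sample_id=sid,
            richness=s,
            chao1=float(skb_alpha.chao1(x, bias_corrected=bias_corrected_chao1)),
            ace=float(skb_alpha.ace(x, rare_threshold=10)),
            shannon=shannon,
            simpson=simpson,
            pielou=float(pielou),
        ))
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("sample_id")


def beta_distance(table: CommunityTable, metric: str) -> PairwiseMatrix:
    """Pairwise sample dissimilarity (bray_curtis, jaccard, euclidean, manhattan).

    Jaccard is computed on presence/absence; the other metrics use
    abundances as given.
    """
    if metric not in BETA_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {BETA_METRICS}")
    x = table.counts
    if metric in ("bray_curtis", "jaccard"):
        zero_rows = x.sum(axis=1) == 0
        if zero_rows.any():
            bad = [s for s, z in zip(table.sample_ids, zero_rows) if z]
            raise ValueError(f"all-zero samples for {metric}: {bad}")
    if metric == "bray_curtis":
        cond = pdist(x, metric="braycurtis")
    elif metric == "jaccard":
        cond = pdist(x > 0, metric="jaccard")
    elif metric == "euclidean":
        cond = pdist(x, metric="euclidean")
    else:
        cond = pdist(x, metric="cityblock")
    return PairwiseMatrix(squareform(cond), list(table.sample_ids), metric)


# ---------------------------------------------------------------------------
# UPGMA

def upgma(dist: PairwiseMatrix) -> str:
    """Average-linkage dendrogram as a Newick string with node heights.

    Leaves sit at height 0 and each internal node at half its merge
    distance, so leaf-to-leaf path length through the dendrogram equals the
    cophenetic (average-linkage) distance.  Labels are sorted first so tie
    handling is deterministic.
    """
    if not np.isfinite(dist.values).all():
        raise ValueError("distance matrix contains NaN/inf")
    order = sorted(range(len(dist.labels)), key=lambda i: dist.labels[i])
    labels = [dist.labels[i] for i in order]
    d = dist.values[np.ix_(order, order)]
    if len(labels) == 1:
        return f"{labels[0]}:0;"
    cond = squareform(d, checks=False)
    z = hierarchy.linkage(cond, method="average")
    n = len(labels)
    newick = {i: (labels[i], 0.0) for i in range(n)}
    for k, (a, b, h, _) in enumerate(z):
        (sa, ha), (sb, hb) = newick[int(a)], newick[int(b)]
        height = h / 2.0
        newick[n + k] = (f"({sa}:{height - ha:.10g},{sb}:{height - hb:.10g})",
                         height)
    return newick[n + len(z) - 1][0] + ";"


# ---------------------------------------------------------------------------
# beta partitioning

@dataclass
class BetaPartition:
    family: str
    total: PairwiseMatrix
    replacement: PairwiseMatrix
    richness_difference: PairwiseMatrix
    group_summary: pd.DataFrame | None = None


def _abc(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared/unique presence counts a, b, c for every sample pair."""
    pa = (x > 0).astype(float)
    a = pa @ pa.T
    rich = pa.sum(axis=1)
    b = rich[:, None] - a
    c = rich[None, :] - a
    return a, b, c


def partition_beta(table: CommunityTable, family: str,
                   groups: dict[str, str] | None = None) -> BetaPartition:
    """Decompose presence/absence beta diversity into replacement and
    richness-difference components.

    baselga_sorensen: total = Sorensen; replacement = Simpson turnover
    min(b,c)/(a+min(b,c)); richness difference = the nestedness remainder.
    podani_jaccard: total = Jaccard; replacement = 2*min(b,c)/(a+b+c);
    richness difference = |b-c|/(a+b+c).

    With ``groups`` given, a per-group summary reports each component as a
    percentage of total beta diversity over within-group pairs
    (mean component / mean total * 100).
    """
    if family not in ("baselga_sorensen", "podani_jaccard"):
        raise ValueError(f"unknown family {family!r}")
    a, b, c = _abc(table.counts)
    mn = np.minimum(b, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        if family == "baselga_sorensen":
            total = (b + c) / (2 * a + b + c)
            repl = mn / (a + mn)
        else:
            total = (b + c) / (a + b + c)
            repl = 2 * mn / (a + b + c)
    total = np.nan_to_num(total)
    repl = np.nan_to_num(repl)
    np.fill_diagonal(total, 0.0)
    np.fill_diagonal(repl, 0.0)
    rich = total - repl
    labels = list(table.sample_ids)
    part = BetaPartition(
        family=family,
        total=PairwiseMatrix(total, labels, f"{family}_total"),
        replacement=PairwiseMatrix(repl, labels, f"{family}_replacement"),
        richness_difference=PairwiseMatrix(rich, labels,
                                           f"{family}_richness_difference"),
    )
    if groups is not None:
        recs = []
        glabels = sorted(set(groups.values()))
        iu = np.triu_indices(len(labels), k=1)
        gvec = np.array([groups[s] for s in labels])
        same = gvec[iu[0]] == gvec[iu[1]]
        for g in glabels:
            mask = same & (gvec[iu[0]] == g)
            if not mask.any():
                continue
            t = total[iu][mask].mean()
            r = repl[iu][mask].mean()
            n = rich[iu][mask].mean()
            recs.append({"group": g, "n_pairs": int(mask.sum()),
                         "replacement_pct": 100.0 * r / t if t > 0 else 0.0,
                         "richness_difference_pct": 100.0 * n / t if t > 0 else 0.0})
        part.group_summary = pd.DataFrame(recs).set_index("group")
    return part
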