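"""Pairwise nucleotide distances and within-site diversity comparison.

Distances are raw mismatch counts under pairwise deletion: positions where
either sequence is unresolved (N/gap) are excluded. Site-level diversity is
compared against a reference group (e.g. all sequences on the main Late
Neanderthal branch) with a two-sided Wilcoxon rank-sum test and
multiple-testing adjustment across sites.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    n_compared: np.ndarray


@dataclass
class DiversityComparison:
    group: str
    reference: str
    group_distances: np.ndarray
    reference_distances: np.ndarray
    statistic: float  # rank-sum W of the group vector
    p_raw: float
    p_adjusted: float = float("nan")
    adjustment: str = "none"


def pairwise_distance(a: str, b: str) -> tuple[int, int]:
    """Mismatch count and number of mutually resolved positions."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    aa = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    bb = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    res = np.isin(aa, _ACGT) & np.isin(bb, _ACGT)
    return int((aa[res] != bb[res]).sum()), int(res.sum())


def distance_matrix(sequences: dict[str, str]) -> DistanceMatrix:
    ids = list(sequences)
    n = len(ids)
    d = np.zeros((n, n), dtype=np.int64)
    nc = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        nc[i, i] = len(sequences[ids[i]])
        for j in range(i + 1, n):
            dij, nij = pairwise_distance(sequences[ids[i]], sequences[ids[j]])
            d[i, j] = d[j, i] = dij
            nc[i, j] = nc[j, i] = nij
    return DistanceMatrix(ids=ids, d=d, n_compared=nc)


def within_group_distances(sequences: dict[str, str]) -> np.ndarray:
    """Distances over all unordered pairs within a group (no self-pairs)."""
    ids = sorted(sequences)
    out = [
        pairwise_distance(sequences[a], sequences[b])[0]
        for a, b in itertools.combinations(ids, 2)
    ]
    return np.asarray(out, dtype=float)


def _exact_ranksum_p(ranks: np.ndarray, n: int, w_obs: float) -> float:
    """Exact two-sided p by enumerating all n-subsets of the pooled ranks:
    P(|W - mu| >= |w_obs - mu|)."""
    mu = n * ranks.mean()
    thr = abs(w_obs - mu) - 1e-9
    total = hits = 0
    for comb in itertools.combinations(range(len(ranks)), n):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mu) >= thr:
            hits += 1
    return hits / total


def rank_sum_test(x, y, exact_limit: int = 200_000) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank-sum of ``x`` in the pooled midranks.
    p is exact (full enumeration, or the exact Mann-Whitney distribution
    when there are no ties and n+m <= 25) whenever C(n+m, n) fits under
    ``exact_limit``; otherwise a tie-corrected normal approximation with
    continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    w = float(ranks[:n].sum())
    nm = n + m
    has_ties = len(np.unique(pooled)) < nm

    if not has_ties and nm <= 25:
        res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return w, float(res.pvalue)
    if math.comb(nm, n) <= exact_limit:
        return w, _exact_ranksum_p(ranks, n, w)

    mu = n * (nm + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (nm * (nm - 1))
    var = n * m / 12.0 * ((nm + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    return w, float(2.0 * scipy.stats.norm.sf(max(z, 0.0)))


def compare_site_diversity(
    site_groups: dict[str, dict[str, str]],
    branch_group: dict[str, str],
    region_label: str = "coding",
    adjust: str = "fdr_bh",
) -> list[DiversityComparison]:
    """Compare each site's within-site distance vector to the branch-wide one.

    Sites with fewer than two sequences are skipped with a warning. P-values
    are adjusted across the retained sites (Benjamini-Hochberg by default;
    any statsmodels ``multipletests`` method label is accepted).
    """
    branch_d = within_group_distances(branch_group)
    comparisons = []
    for site, seqs in site_groups.items():
        if len(seqs) < 2:
            warnings.warn(f"site {site!r} has < 2 sequences; skipped")
            continue
        site_d = within_group_distances(seqs)
        w, p = rank_sum_test(site_d, branch_d)
        comparisons.append(
            DiversityComparison(
                group=site,
                reference="branch",
                group_distances=site_d,
                reference_distances=branch_d,
                statistic=w,
                p_raw=p,
            )
        )
    if comparisons:
        adj = multipletests([c.p_raw for c in comparisons], method=adjust)[1]
        for c, pa in zip(comparisons, adj):
            c.p_adjusted = float(pa)
            c.adjustment = adjust
    return comparisons


def distances_long_table(dm: DistanceMatrix) -> pd.DataFrame:
    rows = []
    for i, a in enumerate(dm.ids):
        for j in range(i + 1, len(dm.ids)):
            rows.append(
                {
                    "id_a": a,
                    "id_b": dm.ids[j],
                    "distance": int(dm.d[i, j]),
                    "n_compared": int(dm.n_compared[i, j]),
                }
            )
    return pd.DataFrame(rows, columns=["id_a", "id_b", "distance", "n_compared"])
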