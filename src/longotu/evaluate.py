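"""Clustering-quality evaluation against ground truth.

The primary score is the adjusted Rand index (ARI), the
corrected-for-chance agreement between an inferred OTU partition and the
genome-of-origin truth.  ARI = 1 means perfect agreement; values near 0
are what random assignment achieves.  It penalizes both chimeric OTUs
(reads of several genomes merged) and split genomes (reads of one genome
scattered), which precision and recall report separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .cluster import Partition, count_singletons, cut, linkage
from .records import DataError

__all__ = [
    "contingency",
    "adjusted_rand_index",
    "precision_recall",
    "threshold_sweep",
    "median_otus",
    "ari_read_length_regression",
    "directional_benchmark",
]


def contingency(p: Partition | dict, q: Partition | dict) -> np.ndarray:
    """Contingency table n_ij between two partitions of the same ids."""
    pl = p.labels if isinstance(p, Partition) else p
    ql = q.labels if isinstance(q, Partition) else q
    if set(pl) != set(ql):
        raise DataError("partitions cover different id sets")
    pu = {lab: i for i, lab in enumerate(sorted(set(pl.values()), key=str))}
    qu = {lab: j for j, lab in enumerate(sorted(set(ql.values()), key=str))}
    tab = np.zeros((len(pu), len(qu)), dtype=np.int64)
    for sid, lab in pl.items():
        tab[pu[lab], qu[ql[sid]]] += 1
    return tab


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) / 2.0


def adjusted_rand_index(p: Partition | dict, q: Partition | dict) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    ARI = (sum_ij C(n_ij,2) - E) / (M - E) with
    E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2) and
    M = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2.

    Degenerate conventions: when both partitions are a single cluster
    (1x1 contingency table, complete trivial agreement) the score is 1;
    any other case with M == E (e.g. both partitions all singletons)
    returns 0.
    """
    tab = contingency(p, q)
    n = tab.sum()
    if n < 2:
        return 0.0
    if tab.shape == (1, 1):
        return 1.0
    sum_ij = _comb2(tab.astype(float)).sum()
    a = _comb2(tab.sum(axis=1).astype(float)).sum()
    b = _comb2(tab.sum(axis=0).astype(float)).sum()
    expected = a * b / _comb2(np.array(float(n)))
    max_index = (a + b) / 2.0
    if max_index == expected:
        return 0.0
    return float((sum_ij - expected) / (max_index - expected))


def precision_recall(
    p: Partition | dict, truth: Partition | dict
) -> tuple[float, float]:
    """Cluster purity and class integrity, both weighted by size.

    Precision: for each inferred cluster, the fraction of its reads
    belonging to its best-represented truth class, averaged over
    clusters weighted by cluster size.  Recall: for each truth class,
    the largest fraction of the class captured by a single cluster,
    weighted by class size.  Both are 1 on perfect clustering.
    """
    tab = contingency(p, truth)
    n = tab.sum()
    if n == 0:
        raise DataError("empty partitions")
    precision = float(tab.max(axis=1).sum() / n)
    recall = float(tab.max(axis=0).sum() / n)
    return precision, recall


def threshold_sweep(
    dm: DistanceMatrix,
    truth: dict[str, str],
    h_list: Sequence[float] = (0.01, 0.02, 0.03, 0.04, 0.05, 0.06),
    method: str = "complete",
) -> pd.DataFrame:
    """Cluster at every threshold and score against the truth.

    Returns one row per threshold with n_otus, n_singletons, ARI,
    precision and recall, plus a boolean ``best`` column marking the
    argmax-ARI row (ties: the smallest threshold).  The OTU count is
    non-increasing in the threshold.
    """
    tree = linkage(dm, method=method)
    truth_part = Partition(labels={i: truth[i] for i in dm.ids})
    rows = []
    for h in h_list:
        part = cut(tree, h)
        prec, rec = precision_recall(part, truth_part)
        rows.append(
            {
                "h": h,
                "n_otus": part.n_clusters(),
                "n_singletons": count_singletons(part),
                "ari": adjusted_rand_index(part, truth_part),
                "precision": prec,
                "recall": rec,
            }
        )
    df = pd.DataFrame(rows)
    best_idx = df["ari"].idxmax()
    df["best"] = df.index == best_idx
    return df


def median_otus(
    report: pd.DataFrame,
    value: str = "n_otus",
    by: Sequence[str] = ("technology", "h"),
) -> pd.Series:
    """Median of ``value`` across replicates per group (mean-of-middle for
    even replicate counts)."""
    return report.groupby(list(by))[value].median()


def directional_benchmark(
    technologies: Sequence[str] = ("miseq_2x150", "ccs_1450"),
    n_replicates: int = 3,
    n_genomes: int = 25,
    reads_per_genome: int = 5,
    h_list: Sequence[float] = (0.01, 0.02, 0.03, 0.04, 0.05, 0.06),
    seed: int = 0,
    band: int = 60,
) -> pd.DataFrame:
    """Scaled-down simulation benchmark comparing read technologies.

    Builds mock communities from a synthetic reference database (genus
    divergence 0.10, within-genus 0.03), simulates each technology on
    every community, clusters the pairwise distances with complete
    linkage and scores every threshold against the genome-of-origin
    truth.  Returns one row per (technology, replicate, h) with OTU
    counts and ARI; the ``best`` column marks each replicate's best
    threshold.  The headline expectation is that the full-length CCS
    median best-ARI is at least that of the merged 2x150 short reads.
    """
    from .mocksim import build_mocks, filter_reference_db, simulate_community_reads
    from .mocksim import synth_reference_db

    ss = np.random.SeedSequence(seed)
    db_seed, mock_seed, read_seed = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3)
    ]
    n_genera = max(10, n_genomes // 2)
    db = filter_reference_db(
        synth_reference_db(n_genera, 10, seed=db_seed)
    )
    mocks = build_mocks(db, n_genomes, n_replicates, seed=mock_seed)
    rng = np.random.default_rng(read_seed)
    rows = []
    for rep, mock in enumerate(mocks):
        for tech in technologies:
            reads = simulate_community_reads(
                mock, tech, reads_per_genome,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            from .align import distance_matrix

            dm = distance_matrix(reads, band=band)
            truth = {r.id: mock.truth[r.id] for r in reads}
            sweep = threshold_sweep(dm, truth, h_list)
            sweep["technology"] = tech
            sweep["replicate"] = rep
            rows.append(sweep)
    return pd.concat(rows, ignore_index=True)


def ari_read_length_regression(report: pd.DataFrame) -> dict:
    """Least-squares fit of ARI on read length with an F-test.

    A reporting helper for the benchmark: is clustering quality linearly
    related to read length?  Expects columns ``read_length`` and ``ari``.
    """
    x = report["read_length"].to_numpy(dtype=float)
    y = report["ari"].to_numpy(dtype=float)
    from scipy import stats as _stats

    res = _stats.linregress(x, y)
    n = len(x)
    f_stat = res.rvalue**2 / (1 - res.rvalue**2) * (n - 2) if res.rvalue**2 < 1 else np.inf
    return {
        "slope": res.slope,
        "intercept": res.intercept,
        "r_squared": res.rvalue**2,
        "f_statistic": float(f_stat),
        "p_value": res.pvalue,
        "n": n,
    }
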