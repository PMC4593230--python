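"""Agglomerative clustering of amplicon distance matrices into OTUs.

Hierarchical clustering is attractive for OTU inference because it is
input-order independent and, once the merge tree is built, arbitrary
similarity thresholds can be applied by cutting the tree at different
heights.  Complete linkage is the default: it guarantees that no OTU cut
at height h contains a pair of sequences more distant than h (an upper
bound on intra-OTU diameter), which maps directly onto "x % sequence
similarity".  Average and single linkage are available for comparison.

The agglomeration is implemented here (rather than delegated) so that
equal-height merge candidates are resolved deterministically: among tied
pairs the one whose clusters carry the lexicographically smallest member
ids is merged first, making results independent of input order even in
the presence of ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from skbio import DistanceMatrix

from .align import Scoring, DEFAULT_SCORING, distance_matrix
from .records import DataError, SeqRecord

__all__ = [
    "Dendrogram",
    "Partition",
    "OTUTable",
    "linkage",
    "cut",
    "name_otus",
    "otu_table",
    "filter_min_size",
    "count_singletons",
    "representative",
    "hybrid_analysis",
    "HybridResult",
    "otu_quality_diagnostics",
]

_METHODS = ("complete", "average", "single")


@dataclass
class Dendrogram:
    """Agglomerative merge history.

    Leaves are numbered 0..n-1 in the order of ``ids``; the k-th merge
    creates internal node n+k.  ``merges`` holds (left, right, height)
    triples with non-decreasing heights.
    """

    ids: list[str]
    merges: list[tuple[int, int, float]]

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def to_scipy(self) -> np.ndarray:
        """SciPy linkage-matrix form (left, right, height, size)."""
        n = len(self.ids)
        sizes = {i: 1 for i in range(n)}
        z = np.zeros((len(self.merges), 4))
        for k, (a, b, h) in enumerate(self.merges):
            sizes[n + k] = sizes[a] + sizes[b]
            z[k] = [a, b, h, sizes[n + k]]
        return z


@dataclass
class Partition:
    """Assignment of every sequence id to a cluster label."""

    labels: dict[str, object]
    cut_height: float = float("nan")

    def clusters(self) -> dict[object, list[str]]:
        out: dict[object, list[str]] = {}
        for sid, lab in self.labels.items():
            out.setdefault(lab, []).append(sid)
        return out

    def sizes(self) -> dict[object, int]:
        return {lab: len(m) for lab, m in self.clusters().items()}

    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def __len__(self) -> int:
        return len(self.labels)


def linkage(dm: DistanceMatrix, method: str = "complete") -> Dendrogram:
    """Build the agglomerative merge tree for a dissimilarity matrix.

    Ties in merge height are broken by the lexicographically smallest
    member ids of the candidate clusters, so the result does not depend
    on input order (up to leaf numbering).
    """
    if method not in _METHODS:
        raise DataError(f"unknown linkage method {method!r}")
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise DataError("need at least two observations to cluster")
    if np.any(d < 0) or np.any(d > 1):
        raise DataError("distances must lie in [0, 1]")
    ids = list(dm.ids)
    w = d.copy()
    np.fill_diagonal(w, np.inf)
    active = list(range(n))  # slot -> active?
    alive = np.ones(n, dtype=bool)
    node_of = {i: i for i in range(n)}          # slot -> dendrogram node
    size = {i: 1 for i in range(n)}             # slot -> cluster size
    min_id = {i: ids[i] for i in range(n)}      # slot -> smallest member id
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        sub = w[np.ix_(alive, alive)]
        hmin = sub.min()
        # candidate slot pairs at the minimum height
        alive_idx = np.flatnonzero(alive)
        rows, cols = np.where(sub == hmin)
        best_key = None
        best_pair = None
        for r, c in zip(rows, cols):
            if r >= c:
                continue
            i, j = alive_idx[r], alive_idx[c]
            key = tuple(sorted((min_id[i], min_id[j])))
            if best_key is None or key < best_key:
                best_key = key
                best_pair = (i, j)
        i, j = best_pair  # type: ignore[misc]
        merges.append((node_of[i], node_of[j], float(hmin)))
        # Lance-Williams update into slot i
        ni, nj = size[i], size[j]
        others = alive_idx[(alive_idx != i) & (alive_idx != j)]
        if method == "complete":
            w[i, others] = np.maximum(w[i, others], w[j, others])
        elif method == "single":
            w[i, others] = np.minimum(w[i, others], w[j, others])
        else:  # average
            w[i, others] = (ni * w[i, others] + nj * w[j, others]) / (ni + nj)
        w[others, i] = w[i, others]
        alive[j] = False
        node_of[i] = n + step
        size[i] = ni + nj
        min_id[i] = min(min_id[i], min_id[j])
    return Dendrogram(ids=ids, merges=merges)


def cut(dendrogram: Dendrogram, h: float) -> Partition:
    """Cut the tree at height ``h`` (inclusive: merges at height <= h kept).

    "3 % similarity" therefore means sequences merged at dissimilarity
    up to and including 0.03 share an OTU.
    """
    if h < 0 or h > 1:
        raise DataError("cut height must lie in [0, 1]")
    n = len(dendrogram.ids)
    parent = list(range(n + len(dendrogram.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (a, b, height) in enumerate(dendrogram.merges):
        node = n + k
        if height <= h:
            parent[find(a)] = node
            parent[find(b)] = node
        else:
            # still link children to the internal node id so later merges
            # reference a consistent forest; mark node as its own root
            pass
    # roots of leaves define clusters; unmerged internal references are
    # handled by only uniting when height <= h and always pointing the
    # internal node at itself otherwise
    labels: dict[str, object] = {}
    root_label: dict[int, int] = {}
    for leaf, sid in enumerate(dendrogram.ids):
        r = find(leaf)
        if r not in root_label:
            root_label[r] = len(root_label)
        labels[sid] = root_label[r]
    return Partition(labels=labels, cut_height=h)


def name_otus(partition: Partition) -> Partition:
    """Relabel clusters as OTU_1, OTU_2, ... by decreasing size.

    Size ties are ordered by the lexicographically smallest member id.
    """
    clusters = partition.clusters()
    order = sorted(
        clusters.items(), key=lambda kv: (-len(kv[1]), min(kv[1]))
    )
    mapping = {lab: f"OTU_{k + 1}" for k, (lab, _) in enumerate(order)}
    return Partition(
        labels={sid: mapping[lab] for sid, lab in partition.labels.items()},
        cut_height=partition.cut_height,
    )


@dataclass
class OTUTable:
    """OTU x sample read-count matrix."""

    counts: pd.DataFrame  # index: OTU label; columns: sample ids

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def singletons(self) -> pd.Series:
        """Boolean flag per OTU: supported by exactly one read."""
        return self.totals == 1

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def normalized(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        colsum = self.counts.sum(axis=0)
        return self.counts / colsum.replace(0, np.nan)

    def zscored(self) -> pd.DataFrame:
        """Normalized abundances centered/scaled per sample (heat-map display)."""
        norm = self.normalized()
        return (norm - norm.mean(axis=0)) / norm.std(axis=0, ddof=0).replace(0, np.nan)


def otu_table(partition: Partition, records: Sequence[SeqRecord]) -> OTUTable:
    """Tabulate reads per OTU per sample.

    Cluster labels are renamed OTU_1, OTU_2, ... by decreasing size.
    Every clustered read must carry a sample id.
    """
    by_id = {r.id: r for r in records}
    named = name_otus(partition)
    rows: dict[str, dict[str, int]] = {}
    for sid, lab in named.labels.items():
        rec = by_id.get(sid)
        if rec is None or not rec.sample_id:
            raise DataError(f"read {sid!r} has no sample assignment")
        rows.setdefault(lab, {}).setdefault(rec.sample_id, 0)
        rows[lab][rec.sample_id] += 1
    df = pd.DataFrame(rows).T.fillna(0).astype(int)
    df = df.reindex(sorted(df.index, key=lambda s: int(s.split("_")[1])))
    df = df[sorted(df.columns)]
    return OTUTable(counts=df)


def filter_min_size(table: OTUTable, min_reads: int = 10) -> OTUTable:
    """Keep OTUs supported by at least ``min_reads`` reads (inclusive)."""
    if min_reads < 1:
        raise DataError("min_reads must be >= 1")
    keep = table.totals >= min_reads
    return OTUTable(counts=table.counts.loc[keep])


def count_singletons(partition: Partition) -> int:
    """Number of clusters containing exactly one sequence."""
    return sum(1 for m in partition.clusters().values() if len(m) == 1)


def representative(otu_members: Sequence[str], dm: DistanceMatrix) -> str:
    """Member with the minimum mean distance to the other members.

    Singletons represent themselves; exact ties go to the
    lexicographically smallest id.
    """
    members = list(otu_members)
    if not members:
        raise DataError("empty OTU")
    if len(members) == 1:
        return members[0]
    try:
        sub = dm.filter(members)
    except Exception as exc:
        raise DataError(f"missing distance entries for OTU members: {exc}") from exc
    means = sub.data.sum(axis=1) / (len(members) - 1)
    best = min(zip(means, sub.ids))
    return best[1]


@dataclass
class HybridResult:
    """Mixed-technology OTU classification at one threshold."""

    h: float
    partition: Partition
    shared: list[str]
    ccs_only: list[str]
    short_only: list[str]
    sub_otu_counts: dict[str, int]
    n_dropped: int


def _trim_to_region(rec: SeqRecord, region) -> Optional[SeqRecord]:
    """Extract the short-read region from a (long) read; None if absent."""
    from .mocksim import find_primer_product  # local import to avoid cycle

    seq = rec.without_spacer().seq
    if isinstance(region[0], int):
        start, end = region  # 1-based inclusive
        if end > len(seq):
            return None
        sub = seq[start - 1 : end]
    else:
        fwd, rev = region
        prod = find_primer_product(seq, fwd, rev)
        if prod is None:
            return None
        sub = prod
    if not sub:
        return None
    quals = None
    return SeqRecord(id=rec.id, seq=sub, sample_id=rec.sample_id,
                     technology=rec.technology, quals=quals, passes=rec.passes)


def hybrid_analysis(
    ccs_records: Sequence[SeqRecord],
    short_records: Sequence[SeqRecord],
    region,
    h_list: Sequence[float],
    min_reads: int = 10,
    seed: int = 0,
    scoring: Scoring = DEFAULT_SCORING,
    band: int = -1,
    top_k: int = 10,
) -> dict[float, HybridResult]:
    """Joint OTU inference across technologies plus sub-OTU refinement.

    Long CCS reads are trimmed to the short-read region (``region`` is a
    1-based inclusive (start, end) on the read, or a (forward, reverse)
    primer pair), short reads are sub-sampled (seeded) to the trimmed CCS
    count, and the pool is clustered at every threshold in ``h_list``.
    OTUs with >= ``min_reads`` reads are classified shared (at least one
    read from each technology) or technology-specific.  For the
    ``top_k`` shared OTUs with the most CCS reads, the full-length CCS
    members are re-clustered at the same threshold; the resulting
    cluster count is the sub-OTU count.
    """
    trimmed = []
    n_dropped = 0
    for rec in ccs_records:
        t = _trim_to_region(rec, region)
        if t is None:
            n_dropped += 1
        else:
            trimmed.append(t)
    if len(trimmed) < 2:
        raise DataError("fewer than two CCS reads contain the target region")
    rng = np.random.default_rng(seed)
    shorts = list(short_records)
    if len(shorts) > len(trimmed):
        pick = rng.choice(len(shorts), size=len(trimmed), replace=False)
        shorts = [shorts[i] for i in sorted(pick)]
    pool = trimmed + shorts
    dm = distance_matrix(pool, scoring=scoring, band=band)
    tree = linkage(dm, method="complete")
    ccs_ids = {r.id for r in trimmed}
    full_by_id = {r.id: r.without_spacer() for r in ccs_records}
    results: dict[float, HybridResult] = {}
    for h in h_list:
        part = name_otus(cut(tree, h))
        clusters = part.clusters()
        shared, ccs_only, short_only = [], [], []
        for lab, members in clusters.items():
            if len(members) < min_reads:
                continue
            n_ccs = sum(1 for m in members if m in ccs_ids)
            if n_ccs == 0:
                short_only.append(lab)
            elif n_ccs == len(members):
                ccs_only.append(lab)
            else:
                shared.append(lab)
        # sub-OTU refinement on full-length CCS members of top shared OTUs
        by_ccs_count = sorted(
            shared,
            key=lambda lab: (-sum(1 for m in clusters[lab] if m in ccs_ids), lab),
        )
        sub_counts: dict[str, int] = {}
        for lab in by_ccs_count[:top_k]:
            full = [full_by_id[m] for m in clusters[lab] if m in ccs_ids]
            if len(full) < 2:
                sub_counts[lab] = len(full)
                continue
            sub_dm = distance_matrix(full, scoring=scoring, band=band)
            sub_part = cut(linkage(sub_dm, method="complete"), h)
            sub_counts[lab] = sub_part.n_clusters()
        results[h] = HybridResult(
            h=h, partition=part, shared=sorted(shared),
            ccs_only=sorted(ccs_only), short_only=sorted(short_only),
            sub_otu_counts=sub_counts, n_dropped=n_dropped,
        )
    return results


def otu_quality_diagnostics(
    partition: Partition,
    records: Sequence[SeqRecord],
    size_cutoff: int = 10,
) -> dict:
    """Compare mean per-read quality between small and large OTUs.

    Small = OTU with fewer than ``size_cutoff`` reads; large = at least
    ``size_cutoff``.  Reports group means/SDs and two-sample KS and t
    statistics (descriptive; small OTUs driven by sequencing error tend
    to show lower read quality).
    """
    by_id = {r.id: r for r in records}
    sizes = partition.sizes()
    small, large = [], []
    for sid, lab in partition.labels.items():
        rec = by_id.get(sid)
        if rec is None or rec.quals is None:
            raise DataError(f"read {sid!r} lacks qualities for diagnostics")
        mq = float(np.mean(rec.quals))
        (small if sizes[lab] < size_cutoff else large).append(mq)
    report: dict = {
        "n_small_reads": len(small),
        "n_large_reads": len(large),
        "small_mean_quality": float(np.mean(small)) if small else None,
        "large_mean_quality": float(np.mean(large)) if large else None,
        "small_sd_quality": float(np.std(small, ddof=1)) if len(small) > 1 else None,
        "large_sd_quality": float(np.std(large, ddof=1)) if len(large) > 1 else None,
        "comparison_available": bool(small and large),
    }
    if small and large:
        ks = _stats.ks_2samp(small, large)
        tt = _stats.ttest_ind(small, large, equal_var=False)
        report.update(
            ks_statistic=float(ks.statistic), ks_pvalue=float(ks.pvalue),
            t_statistic=float(tt.statistic), t_pvalue=float(tt.pvalue),
        )
    return report
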