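"""Agglomerative clustering, OTU tables and the hybrid-OTU analysis."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from longotu.cluster import (
    count_singletons,
    cut,
    filter_min_size,
    hybrid_analysis,
    linkage,
    name_otus,
    otu_quality_diagnostics,
    otu_table,
    representative,
)
from longotu.mocksim import ErrorModel, sim_ccs_reads, sim_short_reads
from longotu.records import DataError, SeqRecord
from tests.conftest import random_dna
from tests.oracles import naive_linkage


def random_dm(n, rng, ids=None):
    d = rng.random((n, n)) * 0.5
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    return DistanceMatrix(d, ids or [f"s{i:02d}" for i in range(n)])


class TestLinkage:
    def test_two_leaves_any_method(self):
        dm = DistanceMatrix(np.array([[0, 0.04], [0.04, 0]]), ["a", "b"])
        for method in ("complete", "average", "single"):
            tree = linkage(dm, method)
            assert tree.merges == [(0, 1, pytest.approx(0.04))]

    @pytest.mark.parametrize("method", ["complete", "average", "single"])
    def test_matches_naive_oracle(self, method, rng):
        """Merge heights agree with from-scratch recomputation of
        cluster distances at every agglomeration step."""
        for _ in range(12):
            n = int(rng.integers(4, 13))
            dm = random_dm(n, rng)
            d = {
                frozenset([dm.ids[i], dm.ids[j]]): dm.data[i, j]
                for i in range(n)
                for j in range(i + 1, n)
            }
            expected = naive_linkage(list(dm.ids), d, method)
            tree = linkage(dm, method)
            assert [h for _, _, h in tree.merges] == pytest.approx(
                [h for _, _, h in expected]
            )

    @pytest.mark.parametrize("method", ["complete", "average", "single"])
    def test_matches_scipy_on_tie_free_matrices(self, method, rng):
        from scipy.cluster.hierarchy import linkage as scipy_linkage
        from scipy.spatial.distance import squareform

        for _ in range(10):
            n = int(rng.integers(4, 13))
            dm = random_dm(n, rng)
            ours = sorted(h for _, _, h in linkage(dm, method).merges)
            theirs = sorted(scipy_linkage(squareform(dm.data), method)[:, 2])
            assert ours == pytest.approx(theirs)

    def test_all_equal_distances_same_final_height(self):
        d = np.full((5, 5), 0.2)
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d, list("abcde"))
        for method in ("complete", "average", "single"):
            tree = linkage(dm, method)
            assert tree.merges[-1][2] == pytest.approx(0.2)

    def test_input_order_independence_with_ties(self, rng):
        d = rng.integers(1, 6, size=(8, 8)) / 20.0  # many exact ties
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"s{i}" for i in range(8)]
        dm = DistanceMatrix(d, ids)
        perm = rng.permutation(8)
        dm2 = DistanceMatrix(d[np.ix_(perm, perm)], [ids[i] for i in perm])
        for h in (0.05, 0.1, 0.15, 0.2):
            p1 = cut(linkage(dm, "complete"), h).clusters()
            p2 = cut(linkage(dm2, "complete"), h).clusters()
            assert {frozenset(m) for m in p1.values()} == {
                frozenset(m) for m in p2.values()
            }

    def test_heights_non_decreasing(self, rng):
        for method in ("complete", "average", "single"):
            tree = linkage(random_dm(10, rng), method)
            h = tree.heights
            assert all(x <= y + 1e-12 for x, y in zip(h, h[1:]))

    def test_invalid_matrix_rejected(self):
        with pytest.raises(DataError):
            linkage(DistanceMatrix(np.array([[0, 2.0], [2.0, 0]]), ["a", "b"]))


class TestCut:
    def test_extreme_heights(self, rng):
        dm = random_dm(6, rng)
        tree = linkage(dm)
        assert cut(tree, 0.0).n_clusters() == 6
        assert cut(tree, 1.0).n_clusters() == 1

    def test_cluster_count_non_increasing(self, rng):
        tree = linkage(random_dm(12, rng))
        counts = [cut(tree, h).n_clusters() for h in np.linspace(0, 0.5, 26)]
        assert counts == sorted(counts, reverse=True)

    def test_complete_linkage_diameter_guarantee(self, rng):
        """No OTU cut at height h contains a pair more distant than h."""
        for _ in range(5):
            dm = random_dm(12, rng)
            tree = linkage(dm, "complete")
            for h in (0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.2, 0.4):
                for members in cut(tree, h).clusters().values():
                    for a in members:
                        for b in members:
                            assert dm[a, b] <= h + 1e-12

    def test_inclusive_at_exact_height(self):
        dm = DistanceMatrix(np.array([[0, 0.03], [0.03, 0]]), ["a", "b"])
        tree = linkage(dm)
        assert cut(tree, 0.03).n_clusters() == 1
        assert cut(tree, 0.0299).n_clusters() == 2


class TestOTUTable:
    def _records(self):
        return [
            SeqRecord(id=f"r{i}", seq="ACGT", sample_id=f"s{i % 2}")
            for i in range(4)
        ]

    def test_balanced_counts_and_normalization(self):
        from longotu.cluster import Partition

        part = Partition(labels={"r0": 0, "r1": 0, "r2": 1, "r3": 1})
        tab = otu_table(part, self._records())
        assert tab.grand_total == 4
        assert (tab.counts.to_numpy() == 1).all()
        assert np.allclose(tab.normalized().to_numpy(), 0.5)

    def test_single_otu_normalizes_to_one(self):
        from longotu.cluster import Partition

        part = Partition(labels={"r0": 0, "r1": 0, "r2": 0, "r3": 0})
        tab = otu_table(part, self._records())
        assert np.allclose(tab.normalized().to_numpy(), 1.0)

    def test_missing_sample_errors(self):
        from longotu.cluster import Partition

        recs = [SeqRecord(id="r0", seq="ACGT")]
        with pytest.raises(DataError):
            otu_table(Partition(labels={"r0": 0}), recs)

    def test_filter_min_size_rules(self):
        counts = pd.DataFrame(
            {"sA": [9, 10, 1], "sB": [0, 0, 0]},
            index=["OTU_1", "OTU_2", "OTU_3"],
        )
        from longotu.cluster import OTUTable

        tab = OTUTable(counts=counts)
        kept = filter_min_size(tab, 10)
        assert list(kept.counts.index) == ["OTU_2"]
        assert kept.counts.loc["OTU_2", "sA"] == 10
        # idempotent, and min_reads=1 is the identity
        assert filter_min_size(kept, 10).counts.equals(kept.counts)
        assert filter_min_size(tab, 1).counts.equals(tab.counts)

    def test_otu_labels_by_decreasing_size(self):
        from longotu.cluster import Partition

        recs = [SeqRecord(id=f"r{i}", seq="ACGT", sample_id="s") for i in range(5)]
        part = Partition(labels={"r0": 9, "r1": 9, "r2": 9, "r3": 4, "r4": 7})
        tab = otu_table(part, recs)
        assert tab.totals["OTU_1"] == 3
        assert set(tab.counts.index) == {"OTU_1", "OTU_2", "OTU_3"}


class TestSingletonsAndRepresentative:
    def test_count_singletons(self):
        from longotu.cluster import Partition

        assert count_singletons(Partition(labels={"a": 1, "b": 2, "c": 2, "d": 3})) == 2
        assert count_singletons(Partition(labels={"a": 1, "b": 1})) == 0
        assert count_singletons(Partition(labels={c: c for c in "abcd"})) == 4

    def test_representative_min_mean_distance(self):
        d = np.array([[0, 0.01, 0.01], [0.01, 0, 0.05], [0.01, 0.05, 0]])
        dm = DistanceMatrix(d, ["a", "b", "c"])
        assert representative(["a", "b", "c"], dm) == "a"
        assert representative(["b"], dm) == "b"

    def test_representative_tie_lexicographic(self):
        d = np.full((3, 3), 0.02)
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d, ["c", "a", "b"])
        assert representative(["c", "a", "b"], dm) == "a"

    def test_missing_member_errors(self):
        dm = DistanceMatrix(np.zeros((2, 2)), ["a", "b"])
        with pytest.raises(DataError):
            representative(["a", "z"], dm)


def _two_genome_fixture(rng):
    """Two genomes identical inside positions 389..801, ~10 % diverged
    outside, so full-length distance clearly exceeds a 3 % cut."""
    g1 = random_dna(1550, rng)
    g2 = list(g1)
    for p in range(1550):
        if 388 <= p < 801:
            continue
        if rng.random() < 0.10:
            g2[p] = "ACGT"[("ACGT".index(g2[p]) + 1) % 4]
    return g1, "".join(g2)


class TestHybridAnalysis:
    def test_substructure_outside_short_region(self):
        rng = np.random.default_rng(424_242)
        g1, g2 = _two_genome_fixture(rng)
        perfect_ccs = ErrorModel(kind="ccs", accuracy_mean=1.0, accuracy_sd=1e-12)
        clean_short = ErrorModel(kind="short_paired",
                                 sub_rate_start=1e-9, sub_rate_end=1e-9)
        ccs, short = [], []
        for gi, g in enumerate((g1, g2)):
            full_amp = SeqRecord(id=f"g{gi}", seq=g[3:1506], technology="amplicon")
            v4_amp = SeqRecord(id=f"g{gi}", seq=g[388:801], technology="amplicon")
            ccs += sim_ccs_reads(full_amp, 8, perfect_ccs, seed=gi,
                                 genome_id=f"g{gi}", id_prefix=f"c{gi}_")
            short += sim_short_reads(v4_amp, 150, 8, clean_short, seed=gi,
                                     genome_id=f"g{gi}", id_prefix=f"p{gi}_")
        # V4 region on the full-length read: genome pos 389..801 -> read 386..798
        results = hybrid_analysis(ccs, short, (386, 798), [0.03],
                                  min_reads=10, seed=1, band=60)
        res = results[0.03]
        assert len(res.shared) == 1
        assert res.ccs_only == [] and res.short_only == []
        assert list(res.sub_otu_counts.values()) == [2]

    def test_identical_input_shared_single_otu(self, rng):
        s = random_dna(400, rng)
        ccs = [SeqRecord(id=f"c{i}", seq=s, technology="ccs") for i in range(6)]
        short = [SeqRecord(id=f"p{i}", seq=s[:310], technology="short_merged")
                 for i in range(6)]
        res = hybrid_analysis(ccs, short, (1, 310), [0.03], min_reads=3, seed=0)
        assert len(res[0.03].shared) == 1
        assert res[0.03].short_only == []

    def test_seed_determinism(self, rng):
        s = random_dna(400, rng)
        ccs = [SeqRecord(id=f"c{i}", seq=s, technology="ccs") for i in range(4)]
        short = [SeqRecord(id=f"p{i}", seq=s[:300], technology="short_merged")
                 for i in range(10)]
        r1 = hybrid_analysis(ccs, short, (1, 300), [0.03], min_reads=2, seed=5)
        r2 = hybrid_analysis(ccs, short, (1, 300), [0.03], min_reads=2, seed=5)
        assert r1[0.03].partition.labels == r2[0.03].partition.labels


class TestQualityDiagnostics:
    def _fixture(self):
        from longotu.cluster import Partition

        recs, labels = [], {}
        # large OTU: 12 high-quality reads; small OTUs: 4 low-quality reads
        for i in range(12):
            recs.append(SeqRecord(id=f"hi{i}", seq="ACGT", quals=[80] * 4))
            labels[f"hi{i}"] = "big"
        for i in range(4):
            recs.append(SeqRecord(id=f"lo{i}", seq="ACGT",
                                  quals=[60 + i] * 4))
            labels[f"lo{i}"] = f"small{i}"
        return Partition(labels=labels), recs

    def test_low_quality_reads_in_small_otus(self):
        part, recs = self._fixture()
        rep = otu_quality_diagnostics(part, recs, size_cutoff=10)
        assert rep["comparison_available"]
        assert rep["small_mean_quality"] < rep["large_mean_quality"]
        assert rep["ks_pvalue"] < 0.05

    def test_equal_quality_equal_means(self):
        from longotu.cluster import Partition

        recs = [SeqRecord(id=f"r{i}", seq="ACGT", quals=[40] * 4) for i in range(6)]
        part = Partition(labels={"r0": 1, "r1": 1, "r2": 1, "r3": 1,
                                 "r4": 2, "r5": 3})
        rep = otu_quality_diagnostics(part, recs, size_cutoff=3)
        assert rep["small_mean_quality"] == rep["large_mean_quality"]

    def test_empty_group_marked_unavailable(self):
        from longotu.cluster import Partition

        recs = [SeqRecord(id="r0", seq="ACGT", quals=[40] * 4)]
        rep = otu_quality_diagnostics(Partition(labels={"r0": 1}),
                                      recs, size_cutoff=100)
        assert not rep["comparison_available"]
        assert rep["large_mean_quality"] is None
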