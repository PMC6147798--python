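"""Bin matrices, coverage filtering, embedding, clustering and annotation."""
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from snmcpipe.genome import Genome, make_intervals
from snmcpipe.mcall import context_class
from snmcpipe.mcluster import (
    BinMatrix,
    ClusterAssignment,
    MarkerRule,
    aggregate_and_correlate,
    annotate_clusters,
    bin_mch,
    cluster_cells,
    filter_bins,
    gene_body_mch,
    make_bins,
    normalize_and_embed,
    normalize_ratios,
)


def _allc(rows):
    return pd.DataFrame(
        rows, columns=["contig", "pos", "strand", "context", "mc", "cov"]
    ).assign(methylated=False)


@pytest.fixture(scope="module")
def flat_genome():
    rng = np.random.default_rng(3)
    return Genome({"b": "".join(rng.choice(list("ACGT"), size=30_000))})


class TestBinMch:
    def test_single_record_ratio(self, flat_genome):
        allc = _allc([("b", 250, "+", "CTA", 3, 10)])
        bm = bin_mch({"c0": allc}, flat_genome, bin_size=1_000)
        r = bm.ratio()
        assert r[0, 0] == pytest.approx(0.3)
        assert np.isnan(r[0, 1:]).all()

    def test_boundary_assignment_conserves_totals(self, flat_genome):
        # pos 1000 (1-based) is the last base of bin 0; 1001 the first of bin 1
        allc = _allc(
            [("b", 1000, "+", "CAA", 1, 4), ("b", 1001, "+", "CAA", 2, 6)]
        )
        bm = bin_mch({"c0": allc}, flat_genome, bin_size=1_000)
        assert bm.cov[0, 0] == 4 and bm.cov[0, 1] == 6
        assert bm.mc.sum() == 3 and bm.cov.sum() == 10

    def test_totals_match_allc_ch_sums(self, demo_run):
        bm = bin_mch(demo_run.allc, demo_run.syn.genome, bin_size=5_000)
        for i, cell in enumerate(bm.cells):
            allc = demo_run.allc[cell]
            ch = allc[
                (context_class(allc["context"]) == "CH")
                & (allc["contig"] != "chrL")
            ]
            assert bm.cov[i].sum() == ch["cov"].sum()
            assert bm.mc[i].sum() == ch["mc"].sum()

    def test_cg_records_excluded(self, flat_genome):
        allc = _allc([("b", 10, "+", "CGA", 5, 5)])
        bm = bin_mch({"c0": allc}, flat_genome, bin_size=1_000)
        assert bm.cov.sum() == 0


class TestFilterBins:
    def _bm(self, cov):
        cov = np.asarray(cov)
        bins = pd.DataFrame(
            {"contig": "b", "start": np.arange(cov.shape[1]) * 1000,
             "end": (np.arange(cov.shape[1]) + 1) * 1000}
        )
        cells = [f"c{i}" for i in range(cov.shape[0])]
        return BinMatrix(cells, bins, np.zeros_like(cov), cov)

    def test_all_above_threshold_kept(self):
        bm = self._bm(np.full((10, 4), 101))
        assert filter_bins(bm).n_bins == 4

    def test_97_percent_of_cells_is_not_enough(self):
        # 97 of 100 cells above threshold: fails the strict > 97.5% rule
        cov = np.full((100, 1), 101)
        cov[:3, 0] = 50
        with pytest.raises(ValueError, match="no bins survive"):
            filter_bins(self._bm(cov))

    def test_exactly_100_basecalls_is_not_enough(self):
        # strict > min_basecalls: cov == 100 in every cell drops the bin
        cov = np.hstack([np.full((10, 1), 100), np.full((10, 1), 101)])
        kept = filter_bins(self._bm(cov))
        assert kept.n_bins == 1
        assert kept.bins.iloc[0]["start"] == 1000

    def test_idempotent(self):
        cov = np.hstack([np.full((10, 1), 300), np.full((10, 1), 5)])
        once = filter_bins(self._bm(cov))
        twice = filter_bins(once)
        assert np.array_equal(once.cov, twice.cov)
        assert once.bins.equals(twice.bins)


class TestNormalizeEmbed:
    def test_row_of_global_level_normalises_to_one(self, flat_genome):
        bins = make_bins(flat_genome, 10_000)
        cov = np.full((3, 3), 200)
        mc = (cov * np.array([[0.02], [0.04], [0.08]])).astype(int)
        bm = BinMatrix(["a", "b", "c"], bins, mc, cov)
        g = {"a": 0.02, "b": 0.04, "c": 0.08}
        cells, norm, _ = normalize_ratios(bm, g)
        assert np.allclose(norm, 1.0)

    def test_scale_invariance_of_structure(self, flat_genome):
        """Multiplying a cell's methylome ratios (and hence its global mCH)
        by a constant leaves the normalised row unchanged."""
        bins = make_bins(flat_genome, 10_000)
        cov = np.full((2, 3), 1000)
        mc = np.array([[10, 40, 20], [30, 120, 60]])  # row 2 = 3 x row 1
        bm = BinMatrix(["a", "b"], bins, mc, cov)
        _, norm, _ = normalize_ratios(bm, {"a": 0.02, "b": 0.06})
        assert np.allclose(norm[0], norm[1])

    def test_zero_global_mch_cell_excluded_with_warning(self, flat_genome):
        bins = make_bins(flat_genome, 10_000)
        cov = np.full((3, 3), 200)
        bm = BinMatrix(["a", "b", "c"], bins, cov // 10, cov)
        with pytest.warns(UserWarning, match="non-positive"):
            emb = normalize_and_embed(bm, {"a": 0.0, "b": 0.05, "c": 0.05})
        assert emb.excluded_cells == ["a"]
        assert emb.cells == ["b", "c"]

    def test_n_pcs_clipped_to_rank(self, demo_run):
        bm = filter_bins(bin_mch(demo_run.allc, demo_run.syn.genome, bin_size=5_000))
        g = {c: demo_run.levels[c].mch for c in bm.cells}
        emb = normalize_and_embed(bm, g, n_pcs=150)
        assert emb.components.shape[1] == min(150, len(bm.cells) - 1, bm.n_bins)

    def test_pc1_separates_two_types(self, demo_run):
        bm = filter_bins(bin_mch(demo_run.allc, demo_run.syn.genome, bin_size=5_000))
        two = [c for c in bm.cells if c.startswith(("L23", "Inh"))]
        idx = [bm.cells.index(c) for c in two]
        sub = BinMatrix(two, bm.bins, bm.mc[idx], bm.cov[idx])
        g = {c: demo_run.levels[c].mch for c in two}
        emb = normalize_and_embed(sub, g)
        labels = [c.split("_")[0] for c in emb.cells]
        s = silhouette_score(emb.components[:, :1], labels)
        assert s > 0


class TestClusterCells:
    def test_identical_rows_collapse_to_one_cluster(self):
        from snmcpipe.mcluster import Embedding

        emb = Embedding([f"c{i}" for i in range(6)], np.ones((6, 3)), np.ones(3))
        assert cluster_cells(emb).k == 1

    def test_k_larger_than_n_rejected(self):
        from snmcpipe.mcluster import Embedding

        emb = Embedding(["a", "b"], np.eye(2), np.ones(2))
        with pytest.raises(ValueError, match="outside"):
            cluster_cells(emb, k=5)

    def test_three_types_recovered(self, demo_run):
        a = demo_run.assignment
        types = [demo_run.truth.cell_types[c] for c in a.cells]
        assert adjusted_rand_score(types, a.labels) >= 0.9

    def test_stable_across_pc_count(self, demo_run):
        bm = filter_bins(bin_mch(demo_run.allc, demo_run.syn.genome, bin_size=5_000))
        g = {c: demo_run.levels[c].mch for c in bm.cells}
        a = cluster_cells(normalize_and_embed(bm, g, n_pcs=100), k=3)
        b = cluster_cells(normalize_and_embed(bm, g, n_pcs=150), k=3)
        assert adjusted_rand_score(a.labels, b.labels) >= 0.9

    def test_deterministic(self, demo_run):
        bm = filter_bins(bin_mch(demo_run.allc, demo_run.syn.genome, bin_size=5_000))
        g = {c: demo_run.levels[c].mch for c in bm.cells}
        emb = normalize_and_embed(bm, g)
        a = cluster_cells(emb, k=3)
        b = cluster_cells(emb, k=3)
        assert np.array_equal(a.labels, b.labels)


class TestAnnotate:
    def test_l23_cluster_labelled(self, demo_run):
        a = demo_run.assignment
        labelled = [cl for cl, lab in a.annotations.items() if lab == "L2/3 excitatory"]
        assert len(labelled) == 1 and not a.ambiguous
        cells = [c for c, l in zip(a.cells, a.labels) if l == labelled[0]]
        assert all(demo_run.truth.cell_types[c] == "L23" for c in cells)

    def test_flat_marker_profile_gets_no_label(self, flat_genome):
        genes = make_intervals(
            [("b", 0, 10_000, "Cux1"), ("b", 10_000, 20_000, "Satb2"),
             ("b", 20_000, 30_000, "Rorb")]
        )
        allc = {
            c: _allc(
                [("b", 5, "+", "CAA", 1, 20), ("b", 10_005, "+", "CAA", 1, 20),
                 ("b", 20_005, "+", "CAA", 1, 20)]
            )
            for c in ("x", "y", "z", "w")
        }
        assignment = ClusterAssignment(
            ["x", "y", "z", "w"], np.array([1, 1, 2, 2]), 2
        )
        out = annotate_clusters(assignment, allc, genes)
        assert out.annotations == {}

    def test_two_qualifying_clusters_marked_ambiguous(self, flat_genome):
        genes = make_intervals([("b", 0, 10_000, "M")])
        lo = _allc([("b", 5, "+", "CAA", 0, 50)])
        hi = _allc([("b", 5, "+", "CAA", 30, 50)])
        allc = {"a": lo, "b": lo, "c": hi, "d": hi}
        assignment = ClusterAssignment(
            ["a", "b", "c", "d"], np.array([1, 2, 3, 4]), 4
        )
        out = annotate_clusters(
            assignment, allc, genes, rules=[MarkerRule("low-M", low=("M",), high=())]
        )
        assert out.ambiguous
        assert sorted(out.annotations) == [1, 2]

    def test_missing_marker_gene_rejected(self, flat_genome):
        genes = make_intervals([("b", 0, 100, "NotAMarker")])
        assignment = ClusterAssignment(["a", "b"], np.array([1, 2]), 2)
        allc = {"a": _allc([]), "b": _allc([])}
        with pytest.raises(ValueError, match="absent"):
            annotate_clusters(assignment, allc, genes)


class TestCorrelate:
    def test_self_correlation_is_one(self, demo_run):
        allc = [demo_run.allc["L23_000"], demo_run.allc["L23_001"]]
        bins = make_bins(demo_run.syn.genome, 2_000, exclude_contigs=("chrL",))
        res = aggregate_and_correlate(allc, allc, bins)
        assert res.r == pytest.approx(1.0)

    def test_anti_correlation_with_complement(self, flat_genome):
        rng = np.random.default_rng(12)
        rows_a, rows_b = [], []
        for i in range(15):
            pos = 1_000 * i + 7
            m = int(rng.integers(0, 51))
            rows_a.append(("b", pos, "+", "CAA", m, 50))
            rows_b.append(("b", pos, "+", "CAA", 50 - m, 50))
        bins = make_bins(flat_genome, 1_000)
        res = aggregate_and_correlate([_allc(rows_a)], [_allc(rows_b)], bins[:15])
        assert res.r == pytest.approx(-1.0)

    def test_replicate_simulations_correlate(self, syn, truth):
        """Two independent deeply-sequenced replicates of one cell type:
        small-bin mCH correlation exceeds 0.9 (replicate consistency; 2 kb
        bins are the desk-scale analogue — the handful of CH sites per
        smaller bin would bound the attainable correlation below that)."""
        from snmcpipe.bsalign import ConvertedIndex, align_pairs, filter_alignments
        from snmcpipe.genome import ReadPair
        from snmcpipe.mcall import call_methylation
        from snmcpipe.preprocess import TrimPolicy, trim_pairs
        from snmcpipe.synthio import LibraryParams, simulate_library

        params = LibraryParams(
            seq_error_rate=0.0, dimer_fraction=0.0, duplicate_rate=0.0,
            lambda_spike_fraction=0.0,
        )
        index = ConvertedIndex(syn.genome)
        tables = []
        for cell, seed in (("Inh_000", 55), ("Inh_001", 56)):
            reads, _ = simulate_library(syn, truth, cell, params, 2500, seed=seed)
            stripped = [ReadPair(p.read_id, p.r1[8:], p.r2) for p in reads]
            kept, _ = trim_pairs(stripped, TrimPolicy())
            hits, _ = align_pairs(kept, index, cell=cell)
            tables.append(
                call_methylation(filter_alignments(hits), syn.genome, syn.catalog)[cell]
            )
        bins = make_bins(syn.genome, 2_000, exclude_contigs=("chrL",))
        res = aggregate_and_correlate([tables[0]], [tables[1]], bins)
        assert res.n_intervals > 50
        assert res.r > 0.9

    def test_too_few_shared_intervals_refused(self, flat_genome):
        bins = make_bins(flat_genome, 1_000)
        a = [_allc([("b", 5, "+", "CAA", 1, 10)])]
        with pytest.raises(ValueError, match="need >= 3"):
            aggregate_and_correlate(a, a, bins)
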