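"""Simulator contracts: genome composition, methylome truth, read artifacts."""
import numpy as np
import pandas as pd
import pytest

from snmcpipe.genome import make_intervals
from snmcpipe.synthio import (
    CellTypeMethylome,
    GenomeSpec,
    LibraryParams,
    MethylomeModel,
    cg_density_contrast,
    default_genome_spec,
    default_methylome_model,
    simulate_genome,
    simulate_library,
    simulate_methylome,
)


def _one_contig_spec(seed=0, gc=0.42, cgis=True):
    cgi = make_intervals(
        [("c1", 10_000, 11_000, "cgi1"), ("c1", 30_000, 31_000, "cgi2")]
    ) if cgis else None
    return GenomeSpec(contigs=[("c1", 50_000)], gc_fraction=gc,
                      cgi_intervals=cgi, seed=seed)


class TestSimulateGenome:
    def test_contig_lengths_and_cgi_density(self):
        syn = simulate_genome(_one_contig_spec(seed=5))
        assert len(syn.genome.contigs["c1"]) == 50_000
        inside, outside = cg_density_contrast(syn)
        assert inside > outside

    def test_zero_gc_gives_at_only(self):
        syn = simulate_genome(_one_contig_spec(seed=5, gc=0.0, cgis=False))
        assert set(syn.genome.contigs["c1"]) == {"A", "T"}

    def test_deterministic_for_fixed_seed(self):
        a = simulate_genome(_one_contig_spec(seed=9)).genome.contigs["c1"]
        b = simulate_genome(_one_contig_spec(seed=9)).genome.contigs["c1"]
        assert a == b

    def test_interval_outside_contig_rejected_by_name(self):
        spec = GenomeSpec(
            contigs=[("c1", 50_000)],
            cgi_intervals=make_intervals([("c1", 49_500, 50_500, "badCGI")]),
        )
        with pytest.raises(ValueError, match="badCGI"):
            simulate_genome(spec)

    def test_short_contig_rejected(self):
        with pytest.raises(ValueError, match="length"):
            simulate_genome(GenomeSpec(contigs=[("c1", 500)]))


class TestSimulateMethylome:
    def test_zero_mch_means_no_ch_methylation(self, syn):
        model = MethylomeModel({"t": CellTypeMethylome(mch_level=0.0)})
        truth = simulate_methylome(syn, model, 1, seed=1)
        for contig in syn.genome.genomic_names():
            ch = ~syn.catalog[contig].cg
            assert not truth.meth[contig][0][ch].any()

    def test_mcg_level_recovered_within_3_se(self, syn):
        model = MethylomeModel(
            {"t": CellTypeMethylome(mch_level=0.0, mcg_default=0.8, mcg_cgi=0.8)}
        )
        truth = simulate_methylome(syn, model, 1, seed=2)
        m = n = 0
        for contig in syn.genome.genomic_names():
            cg = syn.catalog[contig].cg
            m += truth.meth[contig][0][cg].sum()
            n += cg.sum()
        assert n > 10_000
        se = np.sqrt(0.8 * 0.2 / n)
        assert abs(m / n - 0.8) < 3 * se

    def test_marker_multiplier_shapes_gene_body_truth(self, syn, truth):
        """Cux1 multiplier 0.2 for L23: gene-body truth mCH tracks the
        per-site level array and sits well below the cell's global mCH."""
        gene = truth.syn.gene_models.set_index("name").loc["Cux1"]
        cat = syn.catalog[gene.contig]
        in_gene = (cat.pos >= gene.start) & (cat.pos < gene.end) & ~cat.cg
        lvl = truth.mean_level("L23_000", gene.contig, in_gene)
        expect = truth.levels["L23"][gene.contig][in_gene].mean()
        se = np.sqrt(max(expect, 1e-4) * (1 - expect) / in_gene.sum())
        assert abs(lvl - expect) < 4 * se
        # the 0.2 multiplier suppresses the gene body far below global
        assert lvl < 0.5 * truth.global_truth_mch("L23_000")

    def test_global_mch_matches_model_within_3_se(self, truth):
        for cell, tname in truth.cell_types.items():
            level = truth.model.cell_types[tname].mch_level
            n = sum(
                (~truth.syn.catalog[c].cg).sum()
                for c in truth.syn.genome.genomic_names()
            )
            se = np.sqrt(level * (1 - level) / n)
            # gene-body multipliers shift the genome average slightly
            assert abs(truth.global_truth_mch(cell) - level) < 3 * se + 0.01

    def test_lambda_contig_fully_unmethylated(self, syn, truth):
        assert not truth.meth[syn.genome.lambda_contig].any()

    def test_indistinct_markers_rejected(self):
        flat = {g: 1.0 for g in ("Cux1", "Satb2", "Rorb")}
        model = MethylomeModel(
            {
                "a": CellTypeMethylome(mch_level=0.03, gene_body_mch=dict(flat)),
                "b": CellTypeMethylome(mch_level=0.05, gene_body_mch=dict(flat)),
            }
        )
        with pytest.raises(ValueError, match="distinct"):
            model.validate()


class TestSimulateLibrary:
    def test_dimer_fraction_one_marks_all_dimers(self, syn, truth):
        params = LibraryParams(dimer_fraction=1.0, duplicate_rate=0.0)
        _, tdf = simulate_library(syn, truth, "L23_000", params, 50, seed=3)
        assert tdf["is_dimer"].all()

    def test_truth_tail_mean_and_cap(self, syn, truth):
        params = LibraryParams(seq_error_rate=0.0)
        _, tdf = simulate_library(syn, truth, "L23_000", params, 10_000, seed=4)
        assert abs(tdf["tail_len"].mean() - 8.0) < 0.5
        assert tdf["tail_len"].max() <= 50

    def test_fixed_seed_is_byte_identical(self, syn, truth):
        p = LibraryParams()
        a, _ = simulate_library(syn, truth, "L23_000", p, 60, seed=5)
        b, _ = simulate_library(syn, truth, "L23_000", p, 60, seed=5)
        assert [(x.read_id, x.r1, x.r2) for x in a] == [
            (x.read_id, x.r1, x.r2) for x in b
        ]

    def test_each_read_has_exactly_one_truth_row(self, clean_library):
        _, reads, tdf = clean_library
        assert sorted(tdf["read_id"]) == sorted(p.read_id for p in reads)
        assert tdf["read_id"].is_unique

    def test_r1_starts_with_barcode(self, clean_library):
        params, reads, _ = clean_library
        assert all(p.r1.startswith(params.barcode) for p in reads)

    def test_conversion_conservation_exact_at_full_conversion(self, syn, truth):
        """With conversion 1.0 and no errors, a C survives on the R2 genomic
        segment iff its site is truth-methylated; unmethylated survival at
        c<1 matches 1-c within binomial error."""
        params = LibraryParams(
            conversion_rate=1.0, seq_error_rate=0.0, dimer_fraction=0.0,
            duplicate_rate=0.0, tail_mean=0.0, lambda_spike_fraction=0.0,
        )
        reads, tdf = simulate_library(syn, truth, "L23_000", params, 300, seed=6)
        row_i = truth.cell_row("L23_000")
        checked = 0
        for p, t in zip(reads, tdf.itertuples(index=False)):
            if t.strand != "+":
                continue
            cat = syn.catalog[t.contig]
            # R2 = converted fragment 5' prefix (no tail here); stop at the
            # insert end so read-through adapter bases are not compared
            gen = p.r2[: t.end - t.start]
            for j, base in enumerate(gen):
                pos = t.start + j
                row = cat.plus_map[pos]
                if row < 0:
                    continue
                want = truth.meth[t.contig][row_i][row]
                if base == "C":
                    assert want, f"unmethylated C survived at {t.contig}:{pos}"
                    checked += 1
                elif base == "T" and syn.genome.contigs[t.contig][pos] == "C":
                    assert not want, f"methylated C converted at {t.contig}:{pos}"
        assert checked > 50

    def test_unmethylated_survival_rate_near_1_minus_c(self, syn):
        model = MethylomeModel(
            {"t": CellTypeMethylome(mch_level=0.0, mcg_default=0.0, mcg_cgi=0.0)}
        )
        tr = simulate_methylome(syn, model, 1, seed=7)
        params = LibraryParams(
            conversion_rate=0.97, seq_error_rate=0.0, dimer_fraction=0.0,
            duplicate_rate=0.0, tail_mean=0.0, lambda_spike_fraction=0.0,
        )
        reads, tdf = simulate_library(syn, tr, "t_000", params, 400, seed=8)
        n_c = n_tot = 0
        for p, t in zip(reads, tdf.itertuples(index=False)):
            if t.strand != "+":
                continue
            ref = syn.genome.contigs[t.contig][t.start : t.end]
            for rb, gb in zip(p.r2[: t.end - t.start], ref):
                if gb == "C":
                    n_tot += 1
                    n_c += rb == "C"
        rate = n_c / n_tot
        se = np.sqrt(0.03 * 0.97 / n_tot)
        assert abs(rate - 0.03) < 4 * se

    def test_contaminated_tail_elevates_c_at_r2_start(
        self, syn, truth, clean_library, contaminated_library
    ):
        from snmcpipe.preprocess import (
            composition_profile,
            expected_composition_from_truth,
        )

        _, _, _ = clean_library
        _, creads, _ = contaminated_library
        prof = composition_profile([p.r2 for p in creads], 1)
        e_c, _ = expected_composition_from_truth(syn.genome, truth, 0.995)
        assert prof.loc[0, "C"] > e_c + 0.05

    def test_duplicates_copy_coordinates(self, syn, truth):
        params = LibraryParams(duplicate_rate=0.5, dimer_fraction=0.0)
        _, tdf = simulate_library(syn, truth, "L23_000", params, 400, seed=9)
        dups = tdf[tdf["is_duplicate"]]
        assert len(dups) > 50
        originals = tdf[~tdf["is_duplicate"]].set_index(["contig", "start", "end"])
        for t in dups.itertuples(index=False):
            assert (t.contig, t.start, t.end) in originals.index

    def test_invalid_params_rejected(self, syn, truth):
        with pytest.raises(ValueError, match="tail_max"):
            LibraryParams(tail_mean=60.0, tail_max=50).validate()
        with pytest.raises(ValueError, match="not in configured set"):
            LibraryParams(barcode="AAAATTTT").validate(barcode_set=("GCTAAAGA",))
        with pytest.raises(ValueError, match="n_pairs"):
            simulate_library(syn, truth, "L23_000", LibraryParams(), 0, seed=1)
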