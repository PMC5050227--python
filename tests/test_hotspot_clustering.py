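"""Window tiling, HNA accumulation, expression calls, specificity, ratios."""

import itertools

import numpy as np
import pandas as pd
import pytest

from srna_gxe import hotspot_clustering as hc
from srna_gxe.sequence_io import Genome


def hna_frame(rows):
    return pd.DataFrame(
        rows, columns=["tag", "chrom", "start", "end", "strand", "length", "hits", "tp4m", "hna"]
    )


class TestTileGenome:
    def test_short_final_window(self):
        windows = hc.tile_genome(Genome({"c": "A" * 1250}), 500)
        assert windows.windows.values.tolist() == [
            ["c", 0, 500], ["c", 500, 1000], ["c", 1000, 1250]
        ]

    def test_exact_multiple(self):
        assert len(hc.tile_genome(Genome({"c": "A" * 1000}), 500)) == 2

    def test_multiple_chromosomes(self):
        genome = Genome({"c1": "A" * 600, "c2": "C" * 400})
        assert len(hc.tile_genome(genome, 500)) == 2 + 1

    def test_organellar_excluded(self):
        genome = Genome({"c1": "A" * 600, "org": "C" * 5000}, {"org": "organellar"})
        assert len(hc.tile_genome(genome, 500)) == 2

    def test_window_count_formula(self):
        lengths = {"c1": 1234, "c2": 500, "c3": 4999}
        genome = Genome({k: "A" * v for k, v in lengths.items()})
        expected = sum(-(-v // 500) for v in lengths.values())
        assert len(hc.tile_genome(genome, 500)) == expected


class TestAccumulate:
    def setup_method(self):
        self.windows = hc.tile_genome(Genome({"c": "A" * 1000}), 500)

    def test_sums_hna_within_window(self):
        table = hna_frame([
            ("t1", "c", 10, 31, "+", 21, 1, 5.0, 5.0),
            ("t2", "c", 100, 121, "-", 21, 1, 10.0, 10.0),
            ("t3", "c", 499, 520, "+", 21, 1, 15.0, 15.0),
        ])
        out = hc.accumulate(self.windows, {"lib": table})
        assert out.loc[("c", 0), "lib"] == pytest.approx(30.0)
        assert out.loc[("c", 500), "lib"] == pytest.approx(0.0)

    def test_out_of_size_range_ignored(self):
        table = hna_frame([("t1", "c", 10, 30, "+", 20, 1, 1e6, 1e6)])
        out = hc.accumulate(self.windows, {"lib": table})
        assert out["lib"].sum() == 0.0

    def test_assignment_by_start_coordinate(self):
        # a 24-nt alignment starting at 498 spans the boundary: one window only
        table = hna_frame([("t1", "c", 498, 522, "+", 24, 1, 7.0, 7.0)])
        out = hc.accumulate(self.windows, {"lib": table})
        assert out.loc[("c", 0), "lib"] == pytest.approx(7.0)
        assert out.loc[("c", 500), "lib"] == 0.0

    def test_alignment_beyond_chromosome_end_raises(self):
        table = hna_frame([("t1", "c", 1005, 1026, "+", 21, 1, 1.0, 1.0)])
        with pytest.raises(ValueError, match="beyond chromosome end"):
            hc.accumulate(self.windows, {"lib": table})

    def test_partition_of_qualifying_mass(self, small_ws):
        windows = hc.tile_genome(small_ws.genome, 500)
        profiles = hc.accumulate(windows, small_ws.hna_tables)
        for code, table in small_ws.hna_tables.items():
            nuclear = table[table.chrom.isin(windows.chrom_lengths)]
            qualifying = nuclear[(nuclear.length >= 21) & (nuclear.length <= 24)]
            assert profiles[code].sum() == pytest.approx(qualifying.hna.sum(), rel=1e-9)


class TestExpressedCalls:
    def test_threshold_is_inclusive(self):
        prof = pd.DataFrame({"s": [30.0, 29.999, 0.0]})
        flags, counts, _ = hc.call_expressed(prof, 30.0)
        assert flags["s"].tolist() == [True, False, False]
        assert counts["s"] == 1

    def test_replicate_averaging_precedes_threshold(self):
        prof = pd.DataFrame({"Bol_CS_bc_1": [50.0], "Bol_CS_bc_2": [8.0]})
        averaged = hc.average_replicates(prof)
        flags, _, _ = hc.call_expressed(averaged, 30.0)
        assert averaged.loc[0, "Bol_CS_bc"] == pytest.approx(29.0)
        assert not flags.loc[0, "Bol_CS_bc"]

    def test_monotone_in_threshold(self, small_ws):
        windows = hc.tile_genome(small_ws.genome, 500)
        averaged = hc.average_replicates(hc.accumulate(windows, small_ws.hna_tables))
        lo, _, _ = hc.call_expressed(averaged, 30.0)
        hi, _, _ = hc.call_expressed(averaged, 50.0)
        assert not (hi & ~lo).any().any()


class TestAnnotation:
    def make_annotation(self):
        return pd.DataFrame(
            [
                ("c", 100, 900, "+", "gene", "gene", "g1"),
                ("c", 800, 1400, "+", "transposable_element", "LTR/gypsy", "te1"),
            ],
            columns=["chrom", "start", "end", "strand", "type", "feature_class", "feature_id"],
        )

    def test_genic_and_te_flags_are_orthogonal(self):
        from srna_gxe.sequence_io import FeatureTable

        annot = FeatureTable(self.make_annotation())
        out = hc.annotate_clusters([("c", 0), ("c", 500), ("c", 1000), ("c", 1500)], annot)
        assert out.loc[("c", 0)].genic and not out.loc[("c", 0)].te
        assert out.loc[("c", 500)].genic and out.loc[("c", 500)].te  # both flags
        assert not out.loc[("c", 1000)].genic and out.loc[("c", 1000)].te
        assert out.loc[("c", 500)].te_class == "LTR/gypsy"
        assert not out.loc[("c", 1500)].genic and not out.loc[("c", 1500)].te

    def test_te_classes_match_manifest(self, small_ws):
        annot = hc.annotate_clusters(
            [(e.chrom, e.start // 500 * 500) for e in small_ws.manifest.by_kind("te_locus")],
            small_ws.annotation,
        )
        assert annot.te.all()


def venn_oracle(flags: pd.DataFrame, level_of: dict) -> dict:
    """Exhaustive set-algebra recomputation of the Venn cells."""
    cells = {}
    for _, row in flags.iterrows():
        present = tuple(sorted({level_of[c] for c in flags.columns if row[c]}))
        if present:
            cells[present] = cells.get(present, 0) + 1
    return cells


class TestSpecificity:
    def test_specific_and_shared_cells(self):
        flags = pd.DataFrame(
            {
                "Bol_CS_bc": [True, True, False],
                "Ric_CS_bc": [False, True, False],
                "Ric_SG_19": [False, True, True],
            }
        )
        cells, specific = hc.specificity_sets(flags, "vineyard")
        assert specific == {"Bol": 1, "Ric": 1}
        assert cells[("Bol", "Ric")] == 1

    def test_single_level_grouping_rejected(self):
        flags = pd.DataFrame({"Bol_CS_bc": [True], "Bol_SG_19": [True]})
        with pytest.raises(ValueError, match="single level"):
            hc.specificity_sets(flags, "vineyard")

    def test_random_fixture_matches_brute_force(self):
        rng = np.random.default_rng(12)
        samples = [
            f"{v}_{c}_{s}"
            for v in ("Bol", "Mont", "Ric")
            for c in ("CS", "SG")
            for s in ("bc", "19")
        ]
        flags = pd.DataFrame(
            rng.random((200, len(samples))) < 0.3, columns=samples
        )
        for factor, idx in (("vineyard", 0), ("cultivar", 1), ("stage", 2)):
            level_of = {c: c.split("_")[idx] for c in samples}
            cells, _ = hc.specificity_sets(flags, factor)
            assert cells == venn_oracle(flags, level_of)
            assert sum(cells.values()) == int(flags.any(axis=1).sum())


class TestRatioAnalysis:
    def make_profiles(self, a, b):
        return pd.DataFrame(
            {"Ric_CS_bc": [a], "Ric_SG_bc": [b]},
            index=pd.MultiIndex.from_tuples([("c", 0)], names=["chrom", "start"]),
        )

    def test_eligible_record(self):
        out = hc.ratio_analysis(self.make_profiles(5.0, 26.0))
        assert len(out) == 1
        rec = out.iloc[0]
        assert rec.fold == pytest.approx(5.2)
        assert rec.direction == "up-in-B" and rec.bin == 2.0

    def test_min_each_gate(self):
        assert hc.ratio_analysis(self.make_profiles(4.9, 1000.0)).empty

    def test_min_sum_gate(self):
        assert hc.ratio_analysis(self.make_profiles(10.0, 20.0)).empty  # sum == 30 not > 30

    def test_symmetric_under_cultivar_swap(self):
        profiles = pd.DataFrame(
            {"Ric_CS_bc": [5.0, 100.0], "Ric_SG_bc": [26.0, 6.0]},
            index=pd.MultiIndex.from_tuples([("c", 0), ("c", 500)], names=["chrom", "start"]),
        )
        fwd = hc.ratio_analysis(profiles)
        swapped = profiles.rename(columns={"Ric_CS_bc": "Ric_SG_bc", "Ric_SG_bc": "Ric_CS_bc"})
        rev = hc.ratio_analysis(swapped)
        flip = {"up-in-A": "up-in-B", "up-in-B": "up-in-A"}
        assert fwd.fold.tolist() == rev.fold.tolist()
        assert [flip[d] for d in fwd.direction] == rev.direction.tolist()


class TestComposition:
    def test_uniform_sense_21mers(self):
        table = hna_frame([
            ("t1", "c", 10, 31, "+", 21, 1, 5.0, 5.0),
            ("t2", "c", 31, 52, "+", 21, 1, 5.0, 5.0),
        ])
        comp = hc.cluster_composition(table, "c", 0, 500)
        assert comp["sense_fraction"] == 1.0
        assert comp["size_histogram"] == {21: 1.0}

    def test_empty_window(self):
        comp = hc.cluster_composition(hna_frame([]), "c", 0, 500)
        assert comp["total_hna"] == 0.0

    def test_planted_phased_locus_register(self, small_ws):
        locus = small_ws.manifest.by_kind("phas_like")[0]
        table = pd.concat(small_ws.hna_tables.values(), ignore_index=True)
        comp = hc.cluster_composition(table, locus.chrom, locus.start, locus.end)
        assert comp["register_fraction"] >= 0.8
        assert comp["size_histogram"].get(21, 0) >= 0.9

    def test_hotspot_register_near_uniform(self, small_ws):
        locus = small_ws.manifest.by_kind("sirna_hotspot")[0]
        table = pd.concat(small_ws.hna_tables.values(), ignore_index=True)
        comp = hc.cluster_composition(table, locus.chrom, locus.start, locus.end)
        # random phases: modal class well below a phased locus's share
        assert comp["register_fraction"] <= 0.5


class TestDendrogram:
    def test_identical_samples_merge_at_zero(self):
        rng = np.random.default_rng(0)
        base = rng.random(50) * 100
        prof = pd.DataFrame({"a": base, "b": base, "c": rng.random(50) * 100})
        newick, corr, z = hc.cluster_dendrogram(prof)
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_correlation_matrix_properties(self, small_ws):
        windows = hc.tile_genome(small_ws.genome, 500)
        averaged = hc.average_replicates(hc.accumulate(windows, small_ws.hna_tables))
        _, _, expressed = hc.call_expressed(averaged, 30.0)
        newick, corr, _ = hc.cluster_dendrogram(averaged, expressed)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)
        assert newick.endswith(";")
        for code in averaged.columns:
            assert code in newick

    def test_constant_sample_raises(self):
        prof = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 3.0], "c": [2.0, 5.0]})
        with pytest.raises(ValueError, match="b"):
            hc.cluster_dendrogram(prof)

    def test_needs_three_samples(self):
        prof = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        with pytest.raises(ValueError, match="3 samples"):
            hc.cluster_dendrogram(prof)
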