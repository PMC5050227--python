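"""The five-filter miRNA cascade: prefilter, excision, structure, bias,
mature assignment and catalog classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srna_gxe import mirna_discovery as md
from srna_gxe.sequence_io import Alignment, Genome, revcomp
from srna_gxe.structure import evaluate_hairpin
from srna_gxe.synthetic_data import _design_hairpin


def tag_record(seq, hits=1, tp4m=100.0, blacklisted=False):
    return md.TagRecord(seq, hits, {"lib1": tp4m}, blacklisted)


class TestPrefilter:
    def test_threshold_in_at_least_one_library(self):
        rec = md.TagRecord("A" * 21, 1, {f"l{i}": 0.0 for i in range(47)} | {"l47": 30.0})
        kept, trace = md.prefilter_tags({rec.seq: rec})
        assert trace[rec.seq] == "kept"

    @pytest.mark.parametrize(
        "rec,expected",
        [
            (tag_record("A" * 21, hits=21), "max_hits"),
            (tag_record("A" * 27), "length"),
            (tag_record("A" * 17), "length"),
            (tag_record("A" * 21, tp4m=29.999), "abundance"),
            (tag_record("A" * 21, blacklisted=True), "blacklist"),
        ],
    )
    def test_first_failing_filter_recorded(self, rec, expected):
        kept, trace = md.prefilter_tags({rec.seq: rec})
        assert trace[rec.seq] == expected and rec.seq not in kept

    def test_trace_is_a_partition(self, small_ws):
        records = md.build_tag_records(
            {c: n.tp4m for c, n in small_ws.normalized.items()},
            small_ws.alignments,
            blacklisted={t for p in small_ws.partitions.values() for t in p.excluded},
        )
        kept, trace = md.prefilter_tags(records)
        assert set(trace) == set(records)
        assert {t for t, s in trace.items() if s == "kept"} == set(kept)

    def test_disabled_thresholds_keep_everything(self):
        params = md.DiscoveryParams(min_tp4m=0.0, min_len=0, max_len=10**9, max_hits=10**9)
        records = {s: tag_record(s, hits=h, tp4m=v)
                   for s, h, v in [("A" * 17, 1, 0.0), ("C" * 30, 500, 1.0)]}
        kept, trace = md.prefilter_tags(records, params)
        assert set(kept) == set(records)


class TestExcision:
    def test_window_arithmetic(self):
        genome = Genome({"c": "A" * 5000})
        aln = Alignment("G" * 21, "c", 1000, "+", 1)
        spans = {(w.start, w.end) for w in md.excise_candidates(aln, genome)}
        assert spans == {(750, 1051), (970, 1271)}

    def test_clipping_at_chromosome_start(self):
        genome = Genome({"c": "A" * 500})
        aln = Alignment("G" * 21, "c", 5, "+", 1)
        spans = sorted((w.start, w.end) for w in md.excise_candidates(aln, genome))
        assert spans[0][0] == 0

    def test_planted_hairpin_contained_in_one_window(self, small_ws):
        for e in small_ws.manifest.by_kind("mirna_hairpin"):
            mature = next(
                a for a in small_ws.alignments[e.tags[0].seq]
                if a.chrom == e.chrom and e.start <= a.start < e.end and a.strand == "+"
            )
            windows = md.excise_candidates(mature, small_ws.genome)
            assert any(w.start <= e.start and w.end >= e.end for w in windows), e.locus_id


class TestFoldAndEvaluate:
    def make_window(self, seed=2, arm="5p"):
        rng = np.random.default_rng(seed)
        hairpin, mature, offset, _ = _design_hairpin(rng, 21, arm)
        left = "".join(rng.choice(list("ACGT"), 200))
        right = "".join(rng.choice(list("ACGT"), 200))
        genome = Genome({"c": left + hairpin + right})
        m_start = 200 + offset
        return genome, Alignment(mature, "c", m_start, "+", 1)

    def test_planted_hairpin_accepted(self):
        genome, aln = self.make_window()
        cands = [
            md.fold_and_evaluate(w, genome)
            for w in md.excise_candidates(aln, genome)
        ]
        passing = [c for c in cands if c is not None]
        assert passing
        cand = passing[0]
        assert cand.start <= aln.start and cand.end >= aln.end
        assert cand.evaluation.mature_arm == "5p"

    def test_minus_strand_candidate(self):
        genome, aln = self.make_window(seed=4)
        # the same hairpin read from the - strand of the reverse-complemented genome
        rc_genome = Genome({"c": revcomp(genome.sequences["c"])})
        n = len(genome.sequences["c"])
        rc_aln = Alignment(aln.tag, "c", n - aln.end, "-", 1)
        passing = [
            c for w in md.excise_candidates(rc_aln, rc_genome)
            if (c := md.fold_and_evaluate(w, rc_genome)) is not None
        ]
        assert passing and passing[0].strand == "-"

    def test_random_window_mostly_rejected(self):
        rng = np.random.default_rng(8)
        genome = Genome({"c": "".join(rng.choice(list("ACGT"), 2000))})
        rejected = 0
        for start in range(300, 1300, 100):
            tag = genome.sequences["c"][start : start + 21]
            windows = md.excise_candidates(Alignment(tag, "c", start, "+", 1), genome)
            if all(md.fold_and_evaluate(w, genome) is None for w in windows):
                rejected += 1
        assert rejected >= 8

    def test_prescreen_accepts_planted_and_is_optional(self):
        genome, aln = self.make_window(seed=6)
        w = md.excise_candidates(aln, genome)[1]
        seq = genome.sequences["c"][w.start : w.end]
        m0 = w.mature_start - w.start
        assert md.has_star_candidate(seq, m0, m0 + 21, 6)
        assert md.has_star_candidate("A" * 300, 10, 31, 0)  # disabled screen


class TestBias:
    def make_precursor(self):
        from srna_gxe.structure import HairpinEvaluation

        window = md.CandidateWindow("c", 0, 200, "+", 50, 71)
        ev = HairpinEvaluation(passed=True, structure="." * 200, mature_arm="5p",
                              star_span=(120, 141))
        return md.PrecursorCandidate("c", 40, 160, "+", window, "A" * 200, ev, "A" * 21)

    def test_strand_and_abundance_bias(self):
        prec = self.make_precursor()
        tags = {
            "S1": md.TagRecord("S1", 1, {"l": 50.0}),
            "S2": md.TagRecord("S2", 1, {"l": 25.0}),
            "S3": md.TagRecord("S3", 1, {"l": 25.0}),
        }
        alns = {
            "S1": [Alignment("S1", "c", 50, "+", 1)],
            "S2": [Alignment("S2", "c", 80, "+", 1)],
            "S3": [Alignment("S3", "c", 120, "-", 1)],
        }
        index = md.LocusTagIndex(alns)
        bias, _within = md.compute_bias(prec, index, tags)
        assert bias.strand_bias == pytest.approx(0.75)
        assert bias.abundance_bias == pytest.approx(0.75)
        assert not bias.passes(md.DiscoveryParams())  # strand bias below 0.9

    def test_zero_abundance_raises(self):
        prec = self.make_precursor()
        with pytest.raises(ValueError, match="no abundance"):
            md.compute_bias(prec, md.LocusTagIndex({}), {})

    def test_reported_bias_matches_brute_force(self, small_ws):
        """Bias statistics of every reported precursor agree with a direct
        recomputation from the raw alignment and abundance tables."""
        totals = {}
        for code, nl in small_ws.normalized.items():
            for tag, v in nl.tp4m.items():
                totals[tag] = totals.get(tag, 0.0) + v
        params = md.DiscoveryParams()
        for r in small_ws.discovery.reported:
            prec = r.loci[0]
            start, end = prec.start, prec.end
            if end - start < params.bias_region_min:
                pad = (params.bias_region_min - (end - start) + 1) // 2
                start, end = max(0, start - pad), end + pad
            per_tag, sense, total = {}, 0.0, 0.0
            for tag, alns in small_ws.alignments.items():
                if tag not in totals:
                    continue
                for a in alns:
                    if a.chrom == prec.chrom and a.start >= start and a.end <= end:
                        ab = totals[tag]
                        total += ab
                        per_tag[tag] = ab
                        if a.strand == prec.strand:
                            sense += ab
            top = sorted(per_tag.values(), reverse=True)
            assert sense / total == pytest.approx(r.bias.strand_bias)
            assert sum(top[:2]) / sum(top) == pytest.approx(r.bias.abundance_bias)

    def test_planted_hotspots_fail_a_bias_filter(self, small_ws):
        """siRNA hotspots must never satisfy both bias thresholds."""
        totals = {}
        for code, nl in small_ws.normalized.items():
            for tag, v in nl.tp4m.items():
                totals[tag] = totals.get(tag, 0.0) + v
        params = md.DiscoveryParams()
        for e in small_ws.manifest.by_kind("sirna_hotspot"):
            per_tag, sense, total = {}, 0.0, 0.0
            for t in e.tags:
                ab = totals.get(t.seq, 0.0)
                per_tag[t.seq] = ab
                total += ab
                if t.strand == "+":
                    sense += ab
            top = sorted(per_tag.values(), reverse=True)
            strand_bias = max(sense, total - sense) / total
            abundance_bias = sum(top[:2]) / total
            assert strand_bias < params.strand_bias_min or abundance_bias < params.abundance_bias_min


class TestAssignMature:
    def build(self, mature_ab, star_ab, extra=None, seed=5):
        rng = np.random.default_rng(seed)
        hairpin, mature, offset, _ = _design_hairpin(rng, 21, "5p")
        pad = "".join(rng.choice(list("ACGT"), 100))
        genome = Genome({"c": pad + hairpin + pad})
        m_start = 100 + offset
        aln = Alignment(mature, "c", m_start, "+", 1)
        cand = next(
            c for w in md.excise_candidates(aln, genome)
            if (c := md.fold_and_evaluate(w, genome)) is not None
        )
        s0, s1 = cand.evaluation.star_span
        g_star = cand.window.start + s0
        star = genome.sequences["c"][g_star : g_star + 21]
        tags = {
            mature: md.TagRecord(mature, 1, {"l": mature_ab}),
            star: md.TagRecord(star, 1, {"l": star_ab}),
        }
        alns = [aln, Alignment(star, "c", g_star, "+", 1)]
        if extra:
            for seq, ab, pos in extra:
                tags[seq] = md.TagRecord(seq, 1, {"l": ab})
                alns.append(Alignment(seq, "c", pos, "+", 1))
        return cand, alns, tags, mature, star

    def test_both_arms_kept_above_star_threshold(self):
        cand, alns, tags, mature, star = self.build(66306.0, 2074.0)
        out = md.assign_mature(cand, alns, tags)
        assert out.mature_seq == mature and out.reason == "both-arms"
        assert out.star_seq == star and out.star_abundance == pytest.approx(2074.0)

    def test_star_at_exactly_200_not_kept(self):
        cand, alns, tags, mature, star = self.build(3136.0, 200.0)
        out = md.assign_mature(cand, alns, tags)
        assert out.mature_seq == mature
        assert out.star_seq is None and out.reason == "single"

    def test_tie_breaks_lexicographically(self):
        cand, alns, tags, mature, star = self.build(500.0, 500.0)
        out = md.assign_mature(cand, alns, tags)
        assert out.mature_seq == min(mature, star)


class TestCatalogs:
    HAIRPIN = (
        "GGGG" + "TGACAGAAGAGAGTGAGCACA" + "TTTTTTTTTTTTTTTT"
        + revcomp("TGACAGAAGAGAGTGAGCACA") + "CCCC"
    )

    def catalog(self):
        return md.MirnaCatalog(
            {"vvi-miR156a": "TGACAGAAGAGAGTGAGCACA"},
            {"vvi-MIR156a": self.HAIRPIN},
        )

    def test_exact_match(self):
        out = md.match_known("TGACAGAAGAGAGTGAGCACA", self.catalog())
        assert out.identity_class == "known-exact" and out.catalog_ref == "vvi-miR156a"

    def test_small_offset_is_isomir(self):
        iso = self.HAIRPIN[5:26]  # annotated position 4, offset 1
        out = md.match_known(iso, self.catalog())
        assert out.identity_class == "known-isomiR" and out.offset == 1

    def test_large_offset_is_shifted(self):
        shifted = self.HAIRPIN[20:41]  # offset 16 from the annotated mature
        out = md.match_known(shifted, self.catalog())
        assert out.identity_class == "known-shifted" and out.offset == 16

    def test_unrelated_sequence_goes_to_novel_path(self):
        assert md.match_known("ACGTACGTACGTACGTACGTA", self.catalog()) is None

    def test_novel_length_rule(self):
        out = md.classify_novel("A" * 23, md.MirnaCatalog({}))
        assert out.identity_class == "rejected"

    def test_homolog_detection(self):
        cross = md.MirnaCatalog({"ath-miR156a": "TGACAGAAGAGAGTGAGCACA"})
        out = md.classify_novel("TGACAGAAGAGAGAGAGCACC", cross)  # 2 mismatches
        assert out.identity_class == "homolog-novel" and out.mismatches == 2

    def test_bona_fide_when_no_homolog(self):
        cross = md.MirnaCatalog({"ath-miR156a": "TGACAGAAGAGAGTGAGCACA"})
        out = md.classify_novel("CCCCCCCCCCGGGGGGGGGGG", cross)
        assert out.identity_class == "bona-fide-novel"


def mismatch_oracle(a: str, b: str) -> int:
    """Exhaustive ungapped comparison via explicit padding."""
    if len(a) > len(b):
        a, b = b, a
    best = None
    for off in range(len(b) - len(a) + 1):
        padded = "#" * off + a + "#" * (len(b) - len(a) - off)
        mm = sum(1 for x, y in zip(padded, b) if x != y)
        best = mm if best is None else min(best, mm)
    return best


@settings(max_examples=80, deadline=None)
@given(
    st.text(alphabet="ACGT", min_size=18, max_size=24),
    st.text(alphabet="ACGT", min_size=18, max_size=24),
)
def test_ungapped_mismatches_matches_oracle(a, b):
    assert md.ungapped_mismatches(a, b) == mismatch_oracle(a, b)


def test_empty_catalog_warns_and_routes_to_novel(small_ws):
    records = {
        s: md.TagRecord(s, 1, {"l": 1000.0})
        for s in list(small_ws.alignments)[:1]
    }
    with pytest.warns(UserWarning, match="empty known-miRNA catalog"):
        md.run_discovery(records, small_ws.alignments, small_ws.genome)
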