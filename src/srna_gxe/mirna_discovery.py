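"""miRNA identification cascade.

Five successive filters mirror the canonical conservative plant-miRNA
pipelines: (1) a tag prefilter on blacklist status, abundance (>= 30 TP4M in
at least one library), length (18-26 nt) and genomic hits (1-20, more being
too repetitive for a miRNA); (2) precursor excision around every alignment
of a surviving tag and thermodynamic stem-loop evaluation; (3) strand bias
(sense/total >= 0.9) and abundance bias ((top1+top2)/total >= 0.7) at the
precursor; (4) mature selection (most abundant tag; the opposite-arm top tag
is co-reported when its summed abundance exceeds 200 TP4M); (5) catalog
comparison splitting matures into known/isomiR/shifted and, for the rest,
20-22-nt novel candidates that are homologs of other species' matures or
bona fide novel.

Abundances throughout are TP4M summed over all libraries of the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import edlib
import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .sequence_io import Alignment, Genome, revcomp
from .structure import HairpinCriteria, HairpinEvaluation, evaluate_hairpin


@dataclass
class DiscoveryParams:
    min_tp4m: float = 30.0
    min_len: int = 18
    max_len: int = 26
    max_hits: int = 20
    long_flank: int = 250
    short_flank: int = 30
    strand_bias_min: float = 0.9
    abundance_bias_min: float = 0.7
    star_min_tp4m: float = 200.0
    novel_lengths: tuple[int, ...] = (20, 21, 22)
    homolog_max_mismatches: int = 2
    shifted_offset: int = 3
    prescreen_max_edits: int = 6  # 0 disables the star-complementarity screen
    bias_region_min: int = 150  # minimum extent (nt) over which bias is evaluated
    criteria: HairpinCriteria = field(default_factory=HairpinCriteria)
    engine: str = "auto"


@dataclass
class TagRecord:
    """A candidate tag with its per-library normalized abundances."""

    seq: str
    hits: int
    tp4m: dict[str, float]  # library code -> TP4M
    blacklisted: bool = False

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def max_tp4m(self) -> float:
        return max(self.tp4m.values(), default=0.0)

    @property
    def total_tp4m(self) -> float:
        return float(sum(self.tp4m.values()))


def build_tag_records(
    normalized: Mapping[str, Mapping[str, float]],
    alignments: Mapping[str, list[Alignment]],
    blacklisted: Iterable[str] = (),
) -> dict[str, TagRecord]:
    """Assemble TagRecords from per-library TP4M maps and the alignment table."""
    blacklisted = set(blacklisted)
    tp4m: dict[str, dict[str, float]] = {}
    for code, values in normalized.items():
        for tag, v in values.items():
            tp4m.setdefault(tag, {})[code] = v
    out = {}
    for tag, vec in tp4m.items():
        alns = alignments.get(tag)
        if not alns:
            continue
        out[tag] = TagRecord(tag, alns[0].hits, vec, tag in blacklisted)
    for tag in blacklisted:
        if tag in alignments and tag not in out:
            out[tag] = TagRecord(tag, alignments[tag][0].hits, {}, True)
    return out


# ---------------------------------------------------------------------------
# filter 1: tag prefilter


def prefilter_tags(
    tags: Mapping[str, TagRecord], params: DiscoveryParams | None = None
) -> tuple[dict[str, TagRecord], dict[str, str]]:
    """Keep tags passing the abundance/length/hits prefilter.

    The trace maps every input tag to ``"kept"`` or the first failing filter
    (``blacklist`` | ``abundance`` | ``length`` | ``max_hits``), forming a
    partition of the input.
    """
    params = params or DiscoveryParams()
    kept: dict[str, TagRecord] = {}
    trace: dict[str, str] = {}
    for seq, rec in tags.items():
        if rec.blacklisted:
            trace[seq] = "blacklist"
        elif rec.max_tp4m < params.min_tp4m:
            trace[seq] = "abundance"
        elif not (params.min_len <= rec.length <= params.max_len):
            trace[seq] = "length"
        elif not (1 <= rec.hits <= params.max_hits):
            trace[seq] = "max_hits"
        else:
            trace[seq] = "kept"
            kept[seq] = rec
    return kept, trace


# ---------------------------------------------------------------------------
# filter 2: precursor excision + structure


@dataclass(frozen=True)
class CandidateWindow:
    """An excised genomic region, sense-oriented along ``strand``."""

    chrom: str
    start: int
    end: int
    strand: str
    mature_start: int  # genomic
    mature_end: int


def excise_candidates(
    alignment: Alignment, genome: Genome, long_flank: int = 250, short_flank: int = 30
) -> list[CandidateWindow]:
    """Two asymmetric windows around an alignment (the precursor may extend
    mostly 5' or mostly 3' of the mature), clipped to chromosome bounds;
    duplicates after clipping are merged."""
    n = len(genome.sequences[alignment.chrom])
    spans = {
        (max(0, alignment.start - long_flank), min(n, alignment.end + short_flank)),
        (max(0, alignment.start - short_flank), min(n, alignment.end + long_flank)),
    }
    return [
        CandidateWindow(alignment.chrom, s, e, alignment.strand, alignment.start, alignment.end)
        for s, e in sorted(spans)
    ]


def has_star_candidate(seq: str, m0: int, m1: int, max_edits: int) -> bool:
    """Cheap complementarity screen run before thermodynamic folding: the
    window must contain, outside the mature span, an approximate reverse
    complement of the mature (the star arm) within ``max_edits`` edits.

    The bound is in plain Watson-Crick edits; precursors pairing the mature
    largely through G:U wobble need a higher bound (or ``max_edits=0`` to
    disable the screen and fold every window).
    """
    if max_edits <= 0:
        return True
    rc = revcomp(seq[m0:m1])
    masked = seq[:m0] + "N" * (m1 - m0) + seq[m1:]
    hit = edlib.align(rc, masked, mode="HW", task="distance", k=max_edits)
    return hit["editDistance"] != -1


@dataclass
class PrecursorCandidate:
    chrom: str
    start: int  # genomic span of the evaluated stem-loop (mature..star extent)
    end: int
    strand: str
    window: CandidateWindow
    seq: str  # excised window, sense-oriented
    evaluation: HairpinEvaluation
    mature_seq: str

    @property
    def structure(self) -> str:
        return self.evaluation.structure

    @property
    def energy(self) -> float:
        return self.evaluation.energy

    def to_candidate_coords(self, g_start: int, g_end: int) -> tuple[int, int]:
        """Genomic interval -> 0-based half-open span in the sense-oriented seq."""
        if self.strand == "+":
            return g_start - self.window.start, g_end - self.window.start
        return self.window.end - g_end, self.window.end - g_start


def fold_and_evaluate(
    window: CandidateWindow, genome: Genome, params: DiscoveryParams | None = None
) -> PrecursorCandidate | None:
    """Fold an excised window and evaluate the mature placement; returns a
    PrecursorCandidate on pass, None on fail."""
    params = params or DiscoveryParams()
    seq = genome.sequences[window.chrom][window.start : window.end]
    if window.strand == "-":
        seq = revcomp(seq)
        m0 = window.end - window.mature_end
    else:
        m0 = window.mature_start - window.start
    m1 = m0 + (window.mature_end - window.mature_start)
    ev = evaluate_hairpin(seq, m0, m1, params.criteria, engine=params.engine)
    if not ev.passed:
        return None
    lo, hi = ev.star_span
    c_lo, c_hi = min(lo, m0), max(hi, m1)
    if window.strand == "+":
        g_lo, g_hi = window.start + c_lo, window.start + c_hi
    else:
        g_lo, g_hi = window.end - c_hi, window.end - c_lo
    mature = seq[m0:m1]
    return PrecursorCandidate(window.chrom, g_lo, g_hi, window.strand, window, seq, ev, mature)


# ---------------------------------------------------------------------------
# filter 3: bias statistics


@dataclass
class BiasStatistics:
    strand_bias: float  # sense abundance / total at the locus
    abundance_bias: float  # (top1 + top2) / total over precursor tags

    def passes(self, params: DiscoveryParams) -> bool:
        return (
            self.strand_bias >= params.strand_bias_min
            and self.abundance_bias >= params.abundance_bias_min
        )


class LocusTagIndex:
    """Range queries for alignments fully contained in a genomic interval."""

    def __init__(self, alignments: Mapping[str, list[Alignment]]):
        per_chrom: dict[str, list[Alignment]] = {}
        for alns in alignments.values():
            for a in alns:
                per_chrom.setdefault(a.chrom, []).append(a)
        self._chrom: dict[str, tuple[np.ndarray, list[Alignment]]] = {}
        for chrom, alns in per_chrom.items():
            alns.sort(key=lambda a: a.start)
            self._chrom[chrom] = (np.array([a.start for a in alns]), alns)

    def within(self, chrom: str, start: int, end: int) -> list[Alignment]:
        if chrom not in self._chrom:
            return []
        starts, alns = self._chrom[chrom]
        i = int(np.searchsorted(starts, start, side="left"))
        out = []
        while i < len(alns) and alns[i].start < end:
            if alns[i].end <= end:
                out.append(alns[i])
            i += 1
        return out


def compute_bias(
    precursor: PrecursorCandidate,
    index: LocusTagIndex,
    tags: Mapping[str, TagRecord],
    min_region: int = 150,
) -> tuple[BiasStatistics, list[Alignment]]:
    """Strand and abundance bias over all tags mapping within the precursor,
    with abundances summed over libraries.

    Short duplex spans are widened symmetrically to ``min_region`` nt (a
    typical plant pri-miRNA core) so that a siRNA locus cannot pass the bias
    filters through a fortuitous tight local hairpin whose span excludes its
    sibling reads.
    """
    start, end = precursor.start, precursor.end
    if end - start < min_region:
        pad = (min_region - (end - start) + 1) // 2
        start, end = max(0, start - pad), end + pad
    alns = index.within(precursor.chrom, start, end)
    alns = [a for a in alns if a.tag in tags]
    total = sense = 0.0
    per_tag: dict[str, float] = {}
    for a in alns:
        ab = tags[a.tag].total_tp4m
        total += ab
        if a.strand == precursor.strand:
            sense += ab
        per_tag[a.tag] = ab
    if total == 0:
        raise ValueError("no abundance mapped to precursor")
    top = sorted(per_tag.values(), reverse=True)
    bias = BiasStatistics(sense / total, sum(top[:2]) / sum(top))
    return bias, alns


# ---------------------------------------------------------------------------
# filter 4: mature / star assignment


@dataclass
class MatureAssignment:
    mature_seq: str
    mature_arm: str
    mature_abundance: float
    star_seq: str | None = None
    star_arm: str | None = None
    star_abundance: float = 0.0
    reason: str = "single"  # single | both-arms


def _arm_of(precursor: PrecursorCandidate, a: Alignment) -> str:
    """5p / 3p / loop label of an alignment relative to the folded stem-loop."""
    ev = precursor.evaluation
    m0, m1 = precursor.to_candidate_coords(
        precursor.window.mature_start, precursor.window.mature_end
    )
    s0, s1 = ev.star_span
    if ev.mature_arm == "5p":
        arm5, arm3 = (m0, m1), (s0, s1)
    else:
        arm5, arm3 = (s0, s1), (m0, m1)
    loop_lo, loop_hi = arm5[1], arm3[0]
    c0, c1 = precursor.to_candidate_coords(a.start, a.end)
    mid = (c0 + c1) / 2
    if mid < loop_lo:
        return "5p"
    if mid >= loop_hi:
        return "3p"
    return "loop"


def assign_mature(
    precursor: PrecursorCandidate,
    locus_alignments: list[Alignment],
    tags: Mapping[str, TagRecord],
    params: DiscoveryParams | None = None,
) -> MatureAssignment | None:
    """Most abundant precursor tag becomes the mature; the opposite-arm top
    tag is co-retained only when its summed abundance strictly exceeds the
    star threshold.  Ties break toward the lexicographically smallest
    sequence.  Returns None when the top tag falls in the loop."""
    params = params or DiscoveryParams()
    sense = [a for a in locus_alignments if a.strand == precursor.strand]
    by_tag: dict[str, Alignment] = {}
    for a in sense:
        by_tag.setdefault(a.tag, a)
    if not by_tag:
        return None
    ranked = sorted(by_tag, key=lambda t: (-tags[t].total_tp4m, t))
    top = ranked[0]
    top_arm = _arm_of(precursor, by_tag[top])
    if top_arm == "loop":
        return None
    out = MatureAssignment(top, top_arm, tags[top].total_tp4m)
    other = "3p" if top_arm == "5p" else "5p"
    for t in ranked[1:]:
        if _arm_of(precursor, by_tag[t]) == other:
            if tags[t].total_tp4m > params.star_min_tp4m:
                out.star_seq = t
                out.star_arm = other
                out.star_abundance = tags[t].total_tp4m
                out.reason = "both-arms"
            break
    return out


# ---------------------------------------------------------------------------
# filter 5: catalog comparison


@dataclass
class MirnaCatalog:
    matures: dict[str, str]  # name -> sequence (DNA alphabet)
    hairpins: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_fasta(cls, mature_path: str | Path, hairpin_path: str | Path | None = None
                   ) -> "MirnaCatalog":
        def load(path):
            out = {}
            with open(path) as fh:
                for header, seq in SimpleFastaParser(fh):
                    out[header.split()[0]] = seq.upper().replace("U", "T")
            return out

        return cls(load(mature_path), load(hairpin_path) if hairpin_path else {})

    def __len__(self) -> int:
        return len(self.matures)


@dataclass
class ClassifiedMiRNA:
    mature_seq: str
    identity_class: str  # known-exact | known-isomiR | known-shifted | homolog-novel | bona-fide-novel | rejected
    catalog_ref: str | None = None
    offset: int = 0
    length_delta: int = 0
    mismatches: int | None = None


def _family(name: str) -> str:
    return name.lower().replace("mir", "")


def match_known(mature_seq: str, catalog: MirnaCatalog) -> ClassifiedMiRNA | None:
    """Exact / isomiR / shifted classification against the same-species
    catalog; None when the mature touches no catalog precursor."""
    seq = mature_seq.upper().replace("U", "T")
    for name, cat_seq in catalog.matures.items():
        if seq == cat_seq:
            return ClassifiedMiRNA(mature_seq, "known-exact", name)
    for hp_name, hp_seq in catalog.hairpins.items():
        pos = hp_seq.find(seq)
        if pos < 0:
            continue
        annotated = None
        for m_name, m_seq in catalog.matures.items():
            if _family(m_name) == _family(hp_name) and m_seq in hp_seq:
                annotated = (m_name, hp_seq.find(m_seq))
                break
        if annotated is None:
            return ClassifiedMiRNA(mature_seq, "known-isomiR", hp_name)
        m_name, m_pos = annotated
        offset = abs(pos - m_pos)
        delta = len(seq) - len(catalog.matures[m_name])
        cls = "known-shifted" if offset >= 3 else "known-isomiR"
        return ClassifiedMiRNA(mature_seq, cls, m_name, offset=offset, length_delta=delta)
    return None


def ungapped_mismatches(a: str, b: str) -> int:
    """Minimum mismatch count over all ungapped offsets; overhanging bases
    count as mismatches."""
    if len(a) > len(b):
        a, b = b, a
    best = len(a) + len(b)
    for off in range(len(b) - len(a) + 1):
        mm = sum(1 for x, y in zip(a, b[off : off + len(a)]) if x != y)
        best = min(best, mm + (len(b) - len(a)))
    return best


def classify_novel(
    mature_seq: str,
    cross_catalog: MirnaCatalog,
    params: DiscoveryParams | None = None,
) -> ClassifiedMiRNA:
    params = params or DiscoveryParams()
    seq = mature_seq.upper().replace("U", "T")
    if len(seq) not in params.novel_lengths:
        return ClassifiedMiRNA(mature_seq, "rejected")
    best_name, best_mm = None, None
    for name, cat_seq in cross_catalog.matures.items():
        mm = ungapped_mismatches(seq, cat_seq)
        if best_mm is None or mm < best_mm:
            best_name, best_mm = name, mm
    if best_mm is not None and best_mm <= params.homolog_max_mismatches:
        return ClassifiedMiRNA(mature_seq, "homolog-novel", best_name, mismatches=best_mm)
    return ClassifiedMiRNA(mature_seq, "bona-fide-novel")


# ---------------------------------------------------------------------------
# cascade driver


@dataclass
class ReportedMiRNA:
    """One reported miRNA family: a unique mature with all its precursor loci."""

    mature_seq: str
    classification: ClassifiedMiRNA
    assignment: MatureAssignment
    loci: list[PrecursorCandidate]
    bias: BiasStatistics


@dataclass
class DiscoveryResult:
    reported: list[ReportedMiRNA]
    trace: dict[str, str]
    n_candidates_folded: int = 0
    n_precursors: int = 0

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.trace.items()), columns=["tag", "status"]
        )

    def table(self) -> pd.DataFrame:
        """Per-family summary table (one row per reported mature)."""
        rows = []
        for r in self.reported:
            loci = ";".join(f"{p.chrom}:{p.start}-{p.end}({p.strand})" for p in r.loci)
            a = r.assignment
            five = (a.mature_seq, a.mature_abundance) if a.mature_arm == "5p" else (a.star_seq, a.star_abundance)
            three = (a.mature_seq, a.mature_abundance) if a.mature_arm == "3p" else (a.star_seq, a.star_abundance)
            rows.append(dict(
                mature=r.mature_seq,
                classification=r.classification.identity_class,
                catalog_ref=r.classification.catalog_ref,
                loci=loci,
                seq_5p=five[0], abundance_5p=round(five[1], 2) if five[0] else None,
                seq_3p=three[0], abundance_3p=round(three[1], 2) if three[0] else None,
                strand_bias=round(r.bias.strand_bias, 4),
                abundance_bias=round(r.bias.abundance_bias, 4),
            ))
        return pd.DataFrame(rows)


def run_discovery(
    tags: Mapping[str, TagRecord],
    alignments: Mapping[str, list[Alignment]],
    genome: Genome,
    catalog: MirnaCatalog | None = None,
    cross_catalog: MirnaCatalog | None = None,
    params: DiscoveryParams | None = None,
) -> DiscoveryResult:
    """Run the full cascade and merge overlapping precursors that produce the
    same mature into one family record."""
    import warnings

    params = params or DiscoveryParams()
    catalog = catalog or MirnaCatalog({})
    cross_catalog = cross_catalog or MirnaCatalog({})
    if not catalog.matures:
        warnings.warn("empty known-miRNA catalog: all matures take the novel path",
                      stacklevel=2)
    kept, trace = prefilter_tags(tags, params)
    index = LocusTagIndex({t: alignments[t] for t in tags if t in alignments})
    result = DiscoveryResult([], trace)

    evaluated: dict[CandidateWindow, PrecursorCandidate | None] = {}
    accepted: dict[tuple, tuple[PrecursorCandidate, MatureAssignment, BiasStatistics]] = {}
    for seq in sorted(kept):
        for aln in alignments[seq]:
            for window in excise_candidates(aln, genome, params.long_flank, params.short_flank):
                if window in evaluated:
                    continue
                wseq = genome.sequences[window.chrom][window.start : window.end]
                if window.strand == "-":
                    wseq = revcomp(wseq)
                    m0 = window.end - window.mature_end
                else:
                    m0 = window.mature_start - window.start
                m1 = m0 + (window.mature_end - window.mature_start)
                if not has_star_candidate(wseq, m0, m1, params.prescreen_max_edits):
                    evaluated[window] = None
                    continue
                result.n_candidates_folded += 1
                cand = fold_and_evaluate(window, genome, params)
                evaluated[window] = cand
                if cand is None:
                    continue
                try:
                    bias, locus_alns = compute_bias(cand, index, tags, params.bias_region_min)
                except ValueError:
                    continue
                if not bias.passes(params):
                    continue
                assignment = assign_mature(cand, locus_alns, tags, params)
                if assignment is None:
                    continue
                key = (cand.chrom, cand.start, cand.end, cand.strand)
                if key not in accepted:
                    accepted[key] = (cand, assignment, bias)

    # one mature (or mature + star) per genomic locus: merge overlapping
    # accepted precursors, keeping the most abundant assignment
    merged: list[tuple[PrecursorCandidate, MatureAssignment, BiasStatistics]] = []
    by_strand: dict[tuple[str, str], list] = {}
    for entry in accepted.values():
        cand = entry[0]
        by_strand.setdefault((cand.chrom, cand.strand), []).append(entry)
    for group in by_strand.values():
        group.sort(key=lambda g: g[0].start)
        cluster: list = []
        cluster_end = -1
        for entry in group:
            if cluster and entry[0].start >= cluster_end:
                merged.append(min(cluster, key=lambda g: (-g[1].mature_abundance, g[1].mature_seq)))
                cluster = []
                cluster_end = -1
            cluster.append(entry)
            cluster_end = max(cluster_end, entry[0].end)
        if cluster:
            merged.append(min(cluster, key=lambda g: (-g[1].mature_abundance, g[1].mature_seq)))
    result.n_precursors = len(merged)

    families: dict[str, list[tuple[PrecursorCandidate, MatureAssignment, BiasStatistics]]] = {}
    for cand, assignment, bias in merged:
        families.setdefault(assignment.mature_seq, []).append((cand, assignment, bias))
    for mature_seq in sorted(families):
        group = families[mature_seq]
        group.sort(key=lambda g: (g[0].chrom, g[0].start))
        cand, assignment, bias = max(group, key=lambda g: g[2].abundance_bias)
        group.sort(key=lambda g: g[0] is not cand)  # representative locus first
        classification = match_known(mature_seq, catalog)
        if classification is None:
            classification = classify_novel(mature_seq, cross_catalog, params)
            if classification.identity_class == "rejected":
                continue
        result.reported.append(ReportedMiRNA(
            mature_seq, classification, assignment, [g[0] for g in group], bias
        ))
    return result
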