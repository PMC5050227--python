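"""Reading and collapsing small-RNA reads, exact genome mapping, and blacklist partitioning.

Coordinates are 0-based half-open everywhere inside the package; GFF3 is
translated to/from its native 1-based inclusive convention at the file
boundary only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
import pysam
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from intervaltree import IntervalTree

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Annotation classes whose reads are removed before normalization.
BLACKLIST_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA")
ORGANELLAR = "organellar"


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Genome:
    """Ordered nuclear + organellar reference sequences.

    ``compartments`` maps each sequence name to ``"nuclear"`` or
    ``"organellar"``; unlisted names default to nuclear.
    """

    sequences: dict[str, str]
    compartments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sequences) != len(set(self.sequences)):
            raise ValueError("duplicate sequence names")
        self.sequences = {n: s.upper() for n, s in self.sequences.items()}
        for name, seq in self.sequences.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"{name}: alphabet outside ACGTN: {sorted(bad)}")

    def compartment(self, name: str) -> str:
        return self.compartments.get(name, "nuclear")

    @property
    def nuclear_names(self) -> list[str]:
        return [n for n in self.sequences if self.compartment(n) == "nuclear"]

    def __len__(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @classmethod
    def from_fasta(cls, path: str | Path, organellar: Iterable[str] = ()) -> "Genome":
        """Load a genome FASTA.  Sequences whose name (or a ``compartment=organellar``
        tag in the description) marks them as organellar are labelled so."""
        organellar = set(organellar)
        seqs: dict[str, str] = {}
        comps: dict[str, str] = {}
        with open(path) as fh:
            for header, seq in SimpleFastaParser(fh):
                name = header.split()[0]
                seqs[name] = seq.upper()
                if name in organellar or "compartment=organellar" in header:
                    comps[name] = ORGANELLAR
        return cls(seqs, comps)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                tag = " compartment=organellar" if self.compartment(name) == ORGANELLAR else ""
                fh.write(f">{name}{tag}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass
class SampleInfo:
    """Factor levels of one sequencing library (e.g. ``Ric_SG_bc_1``)."""

    vineyard: str
    cultivar: str
    stage: str
    replicate: int

    @property
    def code(self) -> str:
        return f"{self.vineyard}_{self.cultivar}_{self.stage}_{self.replicate}"

    @property
    def condition(self) -> tuple[str, str, str]:
        return (self.vineyard, self.cultivar, self.stage)

    @classmethod
    def from_code(cls, code: str) -> "SampleInfo":
        vineyard, cultivar, stage, rep = code.rsplit("_", 3)
        return cls(vineyard, cultivar, stage, int(rep))


@dataclass
class ReadLibrary:
    """Collapsed unique tags (sequence -> raw count) of one library."""

    sample: SampleInfo | None
    tags: dict[str, int]

    @property
    def code(self) -> str:
        return self.sample.code if self.sample else "library"

    @property
    def total(self) -> int:
        return sum(self.tags.values())


@dataclass(frozen=True)
class Alignment:
    """One perfect full-length genomic match of a tag.

    ``hits`` is the total number of such matches of the tag anywhere in the
    genome (both strands, all compartments) and is identical across all
    alignments of one tag.
    """

    tag: str
    chrom: str
    start: int
    strand: str
    hits: int

    @property
    def end(self) -> int:
        return self.start + len(self.tag)

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the read's 5' end."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class BlacklistPartition:
    """Tags split into retained vs excluded (structural RNA / organellar)."""

    retained: set[str]
    excluded: dict[str, str]  # tag -> class
    class_counts: dict[str, int]  # class -> summed raw counts


# ---------------------------------------------------------------------------
# Read collapsing


def _trim_adapter(seq: str, adapter: str, min_match: int = 6) -> str:
    """Cut at the first occurrence of >= min_match nt of the adapter prefix."""
    idx = seq.find(adapter)
    if idx >= 0:
        return seq[:idx]
    # partial adapter at the very 3' end
    for k in range(len(adapter) - 1, min_match - 1, -1):
        if seq.endswith(adapter[:k]):
            return seq[: len(seq) - k]
    return seq


def collapse_reads(
    path: str | Path,
    adapter: str | None = None,
    min_len: int = 18,
    max_len: int = 34,
    sample: SampleInfo | None = None,
) -> ReadLibrary:
    """Collapse a FASTQ or (collapsed-tag) FASTA file into unique tags.

    Reads are adapter-trimmed when ``adapter`` is given (>=6-nt prefix match
    at the 3' end) and dropped when the trimmed length falls outside
    ``[min_len, max_len]``.  FASTA headers in the ``>name_x<count>`` dialect
    carry pre-collapsed counts.
    """
    if adapter is not None and len(adapter) < 6:
        raise ValueError("adapter must be at least 6 nt")
    path = Path(path)
    tags: dict[str, int] = {}
    with open(path) as fh:
        first = fh.read(1)
        fh.seek(0)
        if first == ">":
            records: Iterable[tuple[str, str, int]] = (
                (h, s, _fasta_count(h)) for h, s in SimpleFastaParser(fh)
            )
        elif first == "@":
            records = ((h, s, 1) for h, s, _q in FastqGeneralIterator(fh))
        elif first == "":
            records = iter(())
        else:
            raise ValueError(f"{path}: not FASTA or FASTQ (starts with {first!r})")
        for i, (_header, seq, count) in enumerate(records):
            seq = seq.upper()
            if adapter:
                seq = _trim_adapter(seq, adapter)
            if min_len <= len(seq) <= max_len:
                tags[seq] = tags.get(seq, 0) + count
    if not tags:
        warnings.warn(f"{path}: no reads retained", stacklevel=2)
    return ReadLibrary(sample, tags)


def _fasta_count(header: str) -> int:
    name = header.split()[0]
    if "_x" in name:
        suffix = name.rsplit("_x", 1)[1]
        if suffix.isdigit():
            return int(suffix)
    return 1


def write_collapsed_fasta(library: ReadLibrary, path: str | Path) -> None:
    """Write tags in the ``>tag_<n>_x<count>`` dialect, descending by count."""
    items = sorted(library.tags.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w") as fh:
        for n, (seq, count) in enumerate(items, start=1):
            fh.write(f">tag_{n}_x{count}\n{seq}\n")


# ---------------------------------------------------------------------------
# Exact mapping


class GenomeIndex:
    """Seed-and-verify exact matcher over both strands.

    A k-mer seed table of the forward genome is probed with the tag (for +
    strand matches) and its reverse complement (for - strand matches); each
    seed hit is verified by full string comparison, so every perfect
    full-length occurrence is reported, overlapping ones included.
    """

    def __init__(self, genome: Genome, k: int = 18):
        self.genome = genome
        self.k = k
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for name, seq in genome.sequences.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._seeds.setdefault(kmer, []).append((name, i))

    def _occurrences(self, query: str) -> list[tuple[str, int]]:
        if len(query) < self.k:
            out = []
            for name, seq in self.genome.sequences.items():
                i = seq.find(query)
                while i >= 0:
                    out.append((name, i))
                    i = seq.find(query, i + 1)
            return out
        hits = []
        for name, i in self._seeds.get(query[: self.k], ()):
            if self.genome.sequences[name].startswith(query, i):
                hits.append((name, i))
        return hits

    def map_tag(self, tag: str) -> list[Alignment]:
        """All perfect full-length occurrences of ``tag`` on either strand."""
        if "N" in tag:
            return []
        fwd = self._occurrences(tag)
        rc = revcomp(tag)
        rev = self._occurrences(rc)
        hits = len(fwd) + len(rev)
        if hits == 0:
            return []
        out = [Alignment(tag, c, i, "+", hits) for c, i in fwd]
        out += [Alignment(tag, c, i, "-", hits) for c, i in rev]
        return out


def map_tags(
    library: ReadLibrary | Iterable[str],
    genome: Genome,
    index: GenomeIndex | None = None,
) -> tuple[dict[str, list[Alignment]], set[str]]:
    """Map every tag of a library; returns (alignments per tag, unmapped tags)."""
    index = index or GenomeIndex(genome)
    tags = library.tags if isinstance(library, ReadLibrary) else library
    aligned: dict[str, list[Alignment]] = {}
    unmapped: set[str] = set()
    for tag in tags:
        hits = index.map_tag(tag)
        if hits:
            aligned[tag] = hits
        else:
            unmapped.add(tag)
    return aligned, unmapped


# ---------------------------------------------------------------------------
# SAM interoperability


def write_sam(alignments: Mapping[str, list[Alignment]], genome: Genome, path: str | Path) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": len(s)} for n, s in genome.sequences.items()],
    }
    names = list(genome.sequences)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for n, (tag, alns) in enumerate(sorted(alignments.items())):
            for a in alns:
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = f"tag_{n}"
                rec.query_sequence = tag if a.strand == "+" else revcomp(tag)
                rec.flag = 0 if a.strand == "+" else 16
                rec.reference_id = names.index(a.chrom)
                rec.reference_start = a.start
                rec.mapping_quality = 255
                rec.cigartuples = [(0, len(tag))]
                rec.set_tag("NM", 0)
                out.write(rec)


def ingest_sam(
    sam_path: str | Path, library: ReadLibrary | None = None
) -> tuple[dict[str, list[Alignment]], int]:
    """Read perfect full-length alignments from a SAM file.

    Records that are unmapped are ignored; records with mismatches (NM>0) or
    clipped/gapped CIGARs are rejected.  ``hits`` is recomputed as the number
    of accepted records per tag.  Returns (alignments per tag, n rejected).
    """
    rejected = 0
    raw: dict[str, list[tuple[str, int, str]]] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            full_match = rec.cigartuples is not None and all(
                op == 0 for op, _n in rec.cigartuples
            )
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            if not full_match or nm != 0:
                rejected += 1
                continue
            seq = rec.query_sequence
            tag = revcomp(seq) if rec.is_reverse else seq
            strand = "-" if rec.is_reverse else "+"
            raw.setdefault(tag, []).append((rec.reference_name, rec.reference_start, strand))
    if library is not None:
        raw = {t: v for t, v in raw.items() if t in library.tags}
    out = {
        tag: [Alignment(tag, c, s, st, len(recs)) for c, s, st in recs]
        for tag, recs in raw.items()
    }
    if rejected:
        warnings.warn(f"{sam_path}: rejected {rejected} imperfect records", stacklevel=2)
    return out, rejected


# ---------------------------------------------------------------------------
# Annotation (GFF3) and blacklist partitioning


class FeatureTable:
    """Genomic features with a ``feature_class`` label, indexed for overlap."""

    def __init__(self, features: pd.DataFrame):
        required = {"chrom", "start", "end", "strand", "type", "feature_class", "feature_id"}
        missing = required - set(features.columns)
        if missing:
            raise ValueError(f"feature table missing columns {sorted(missing)}")
        self.df = features.reset_index(drop=True)
        self._trees: dict[tuple[str, str], IntervalTree] = {}

    def _tree(self, chrom: str, feature_class: str | None) -> IntervalTree:
        key = (chrom, feature_class or "*")
        if key not in self._trees:
            sub = self.df[self.df.chrom == chrom]
            if feature_class is not None:
                sub = sub[sub.feature_class == feature_class]
            tree = IntervalTree()
            for row in sub.itertuples():
                if row.end > row.start:
                    tree.addi(row.start, row.end, row.Index)
            self._trees[key] = tree
        return self._trees[key]

    def overlapping(self, chrom: str, start: int, end: int, feature_class: str | None = None) -> pd.DataFrame:
        """Features overlapping [start, end) by >= 1 bp."""
        idx = [iv.data for iv in self._tree(chrom, feature_class).overlap(start, end)]
        return self.df.loc[sorted(idx)]

    @classmethod
    def from_gff3(cls, path: str | Path) -> "FeatureTable":
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        rows = []
        for feat in db.all_features():
            if feat.featuretype in ("chromosome", "contig", "region"):
                continue
            fclass = feat.attributes.get("feature_class", [feat.featuretype])[0]
            fid = feat.attributes.get("ID", [feat.id])[0]
            rows.append(
                dict(
                    chrom=feat.seqid,
                    start=feat.start - 1,  # GFF3 is 1-based inclusive
                    end=feat.end,
                    strand=feat.strand or ".",
                    type=feat.featuretype,
                    feature_class=fclass,
                    feature_id=fid,
                )
            )
        cols = ["chrom", "start", "end", "strand", "type", "feature_class", "feature_id"]
        return cls(pd.DataFrame(rows, columns=cols))

    def to_gff3(self, path: str | Path, genome: Genome | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            if genome is not None:
                for name, seq in genome.sequences.items():
                    fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            for row in self.df.itertuples():
                attrs = f"ID={row.feature_id};feature_class={row.feature_class}"
                fh.write(
                    f"{row.chrom}\tsrna_gxe\t{row.type}\t{row.start + 1}\t{row.end}\t.\t"
                    f"{row.strand}\t.\t{attrs}\n"
                )


def apply_blacklist(
    alignments: Mapping[str, list[Alignment]],
    annotation: FeatureTable,
    genome: Genome,
    library: ReadLibrary | None = None,
) -> BlacklistPartition:
    """Exclude any tag with >= 1 bp overlap of a structural-RNA feature or an
    organellar alignment; the whole tag is excluded even when other loci are
    clean.  Classes are assigned with priority rRNA > tRNA > snRNA > snoRNA >
    organellar for multiply-offending tags."""
    retained: set[str] = set()
    excluded: dict[str, str] = {}
    class_counts: dict[str, int] = {c: 0 for c in (*BLACKLIST_CLASSES, ORGANELLAR)}
    for tag, alns in alignments.items():
        classes = set()
        for a in alns:
            if genome.compartment(a.chrom) == ORGANELLAR:
                classes.add(ORGANELLAR)
                continue
            for c in BLACKLIST_CLASSES:
                if not annotation.overlapping(a.chrom, a.start, a.end, c).empty:
                    classes.add(c)
        if classes:
            for c in (*BLACKLIST_CLASSES, ORGANELLAR):
                if c in classes:
                    excluded[tag] = c
                    if library is not None:
                        class_counts[c] += library.tags.get(tag, 0)
                    break
        else:
            retained.add(tag)
    return BlacklistPartition(retained, excluded, class_counts)
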