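"""Self-contained synthetic fixture: genome, annotation, catalogs, libraries.

The generator emulates the statistical structure the analysis assumes: a
multi-chromosome nuclear genome plus one organellar contig; planted miRNA
hairpins that satisfy the precursor structure criteria (verified by refolding
at generation time); 21-nt-biased double-stranded siRNA hotspots confined to
single 500-bp windows; a 21-nt-registered phased locus carrying an extreme
cultivar-by-environment fold change; transposable-element families whose
copies share sequence (multi-mapping reads); structural-RNA blacklist loci;
and a factorial library design (vineyard x cultivar x stage x replicate) with
multiplicative planted fold changes and negative-binomial count noise.

Background reads model degradation fragments: a fixed genome-wide pool of
uniformly placed positions whose size distribution is concentrated outside
the 21-24-nt siRNA classes, so random windows only occasionally reach the
cluster expression threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np

from .sequence_io import Genome, ReadLibrary, SampleInfo, revcomp, FeatureTable
from .structure import available_engines, evaluate_hairpin
import pandas as pd

VINEYARDS = ("Bol", "Mont", "Ric")
CULTIVARS = ("CS", "SG")
STAGES = ("ps", "bc", "19", "hv")
GREEN_STAGES = ("ps", "bc")
RIPE_STAGES = ("19", "hv")

#: degradation-fragment length weights (21-24 nt kept near zero; see module doc)
_BACKGROUND_LEN_WEIGHTS = {
    18: 0.14, 19: 0.18, 20: 0.20, 21: 0.0003, 22: 0.0002, 23: 0.0002, 24: 0.0003,
    25: 0.14, 26: 0.10, 27: 0.08, 28: 0.07, 29: 0.05, 30: 0.039,
}


class PlacementError(ValueError):
    pass


def default_factor_design() -> list[SampleInfo]:
    """The full 3 vineyards x 2 cultivars x 4 stages x 2 replicates design."""
    return [
        SampleInfo(v, c, s, r)
        for v in VINEYARDS
        for c in CULTIVARS
        for s in STAGES
        for r in (1, 2)
    ]


@dataclass
class Effect:
    """A planted multiplicative fold change; None factor levels are wildcards."""

    locus_id: str
    fold: float
    vineyard: str | None = None
    cultivar: str | None = None
    stage: str | None = None

    def applies(self, sample: SampleInfo) -> bool:
        return (
            (self.vineyard is None or self.vineyard == sample.vineyard)
            and (self.cultivar is None or self.cultivar == sample.cultivar)
            and (self.stage is None or self.stage == sample.stage)
        )


@dataclass
class GenerationConfig:
    seed: int = 0
    n_chromosomes: int = 4
    chrom_length: int = 250_000
    organellar_length: int = 20_000
    n_hairpins: int = 16
    n_hotspots: int = 20
    n_phas_loci: int = 2
    n_te_loci: int = 15
    n_blacklist_loci: int = 8
    n_genes: int = 40
    n_background_tags: int = 4000
    factor_design: list[SampleInfo] = field(default_factory=default_factor_design)
    effect_table: list[Effect] | None = None  # None -> default_effects(manifest)
    library_depth: int = 50_000
    noise: float = 0.05  # NB overdispersion: var = mu + noise * mu^2
    adapter: str | None = None  # appended to FASTQ reads when set

    def validate(self) -> None:
        for name in (
            "n_chromosomes", "chrom_length", "n_hairpins", "n_hotspots", "n_phas_loci",
            "n_te_loci", "n_blacklist_loci", "n_genes", "library_depth",
        ):
            if getattr(self, name) < 0 or (name in ("n_chromosomes", "chrom_length") and getattr(self, name) <= 0):
                raise ValueError(f"invalid config field {name}")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.adapter is not None and len(self.adapter) < 6:
            raise ValueError("adapter must be >= 6 nt")


@dataclass
class TagSpec:
    """One emittable read species of a locus."""

    seq: str
    chrom: str
    start: int
    strand: str
    prob: float


@dataclass
class ManifestEntry:
    locus_id: str
    kind: str  # mirna_hairpin | sirna_hotspot | phas_like | te_locus | blacklist_locus | gene | organellar_background
    chrom: str
    start: int
    end: int
    strand: str
    baseline_mean: float = 0.0
    mature_seq: str | None = None
    star_seq: str | None = None
    mature_start: int | None = None  # genomic, 0-based
    mature_end: int | None = None
    feature_class: str | None = None  # TE class or blacklist class
    catalog_status: str | None = None  # known | known_shifted | homolog | novel (hairpins)
    annotated_mature: str | None = None  # catalog mature when != dominant tag
    tags: list[TagSpec] = field(default_factory=list)
    condition_means: dict[str, float] = field(default_factory=dict)  # "Vy_Cv_St" -> mean reads


@dataclass
class GroundTruthManifest:
    config_seed: int
    entries: list[ManifestEntry]
    background: list[TagSpec] = field(default_factory=list)
    background_weights: list[float] = field(default_factory=list)

    def by_kind(self, kind: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.kind == kind]

    def get(self, locus_id: str) -> ManifestEntry:
        for e in self.entries:
            if e.locus_id == locus_id:
                return e
        raise KeyError(locus_id)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        with open(path) as fh:
            raw = json.load(fh)
        entries = []
        for e in raw["entries"]:
            tags = [TagSpec(**t) for t in e.pop("tags")]
            entries.append(ManifestEntry(**e, tags=tags))
        return cls(
            config_seed=raw["config_seed"],
            entries=entries,
            background=[TagSpec(**t) for t in raw["background"]],
            background_weights=raw["background_weights"],
        )


# ---------------------------------------------------------------------------
# genome construction helpers

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _mutate(
    rng: np.random.Generator, seq: str, n_sub: int, n_del: int,
    force_sub_at: int | None = None,
) -> str:
    s = list(seq)
    interior = [i for i in range(2, len(s) - 2) if i != force_sub_at]
    pos = list(rng.choice(interior, size=n_sub + n_del, replace=False))
    subs = pos[:n_sub]
    if force_sub_at is not None:
        subs = [force_sub_at] + subs[1:] if n_sub else [force_sub_at]
    for p in subs:
        alternatives = [b for b in "ACGT" if b != s[p]]
        s[p] = alternatives[rng.integers(0, 3)]
    for p in sorted(pos[n_sub:], reverse=True):
        del s[p]
    return "".join(s)


def _design_hairpin(
    rng: np.random.Generator, mature_len: int, arm: str, mature_seq: str | None = None
) -> tuple[str, str, int, str]:
    """Returns (hairpin, mature, mature offset in hairpin, star seq).

    Stem arm = 5-nt pad + mature + 12-nt extension; loop 15 nt; star arm =
    reverse complement of the stem arm carrying 2 substitutions and one 1-nt
    deletion (an asymmetric bulge well inside the structure-filter limits).
    The designed fold is verified with every available structure engine;
    failing designs are redrawn.
    """
    engines = available_engines()
    for _attempt in range(60):
        mature = mature_seq or _random_seq(rng, mature_len)
        pad5 = _random_seq(rng, 5)
        ext = _random_seq(rng, 12)
        stem = pad5 + mature + ext
        # one substitution is forced into the center of the mature-complement
        # so no exact reverse complement of the mature survives in the star
        center = len(ext) + len(mature) // 2
        star_arm = _mutate(rng, revcomp(stem), n_sub=2, n_del=1, force_sub_at=center)
        loop = _random_seq(rng, 15)
        tail = _random_seq(rng, 3)
        if arm == "5p":
            hairpin = stem + loop + star_arm + tail
            offset = len(pad5)
        else:
            hairpin = tail + star_arm + loop + stem
            offset = len(tail) + len(star_arm) + len(loop) + len(pad5)
        ok = all(
            evaluate_hairpin(hairpin, offset, offset + len(mature), engine=e).passed
            for e in engines
        )
        if ok:
            return hairpin, mature, offset, star_arm
        if mature_seq is not None and _attempt > 20:
            # fixed mature: vary only the flanks
            continue
    raise RuntimeError("could not design a hairpin satisfying the structure criteria")


class _Placer:
    """Rejection-samples non-overlapping intervals on the nuclear chromosomes."""

    def __init__(self, rng: np.random.Generator, chrom_names: list[str], length: int):
        self.rng = rng
        self.names = chrom_names
        self.length = length
        self.occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in chrom_names}

    def _free(self, chrom: str, start: int, end: int) -> bool:
        return all(e <= start or s >= end for s, e in self.occupied[chrom])

    def place(self, size: int, locus_id: str, window: int | None = None,
              within: tuple[str, int, int] | None = None) -> tuple[str, int]:
        """Place an interval of ``size`` bp; when ``window`` is given the
        interval is confined to a single window of that width; ``within``
        restricts placement to a given (chrom, start, end) region."""
        for _ in range(300):
            if within is not None:
                chrom, lo, hi = within
            else:
                chrom = self.names[self.rng.integers(0, len(self.names))]
                lo, hi = 0, self.length
            if window is not None:
                w0 = lo // window + (1 if lo % window else 0)
                w1 = (hi - size) // window
                if w1 < w0:
                    continue
                w = int(self.rng.integers(w0, w1 + 1))
                off = int(self.rng.integers(0, window - size + 1))
                start = w * window + off
                if start < lo or start + size > hi:
                    continue
            else:
                if hi - lo < size:
                    continue
                start = int(self.rng.integers(lo, hi - size + 1))
            if self._free(chrom, start - 10, start + size + 10):
                self.occupied[chrom].append((start, start + size))
                return chrom, start
        raise PlacementError(f"cannot place locus {locus_id} without overlap")


# ---------------------------------------------------------------------------
# generate_genome


def generate_genome(config: GenerationConfig) -> tuple[Genome, FeatureTable, GroundTruthManifest]:
    """Build the genome, its annotation and the ground-truth manifest.

    Read-emitting loci never overlap one another; gene features are placed
    first and may deliberately contain siRNA hotspots (to exercise the
    genic/intergenic annotation), so genes are excluded from the mutual
    overlap guarantee of read-emitting loci.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chroms = {n: bytearray(_random_seq(rng, config.chrom_length), "ascii") for n in chrom_names}
    org_name = "orgContig"
    org_seq = _random_seq(rng, config.organellar_length)

    # rough footprint check (genes included; they dominate the footprint)
    footprint = (
        config.n_hairpins * 100 + config.n_hotspots * 400 + config.n_phas_loci * 450
        + config.n_te_loci * 800 + config.n_blacklist_loci * 250 + config.n_genes * 1600
    )
    if config.n_chromosomes * config.chrom_length < 10 * footprint:
        raise PlacementError("chromosomes too short for the requested locus density")

    placer = _Placer(rng, chrom_names, config.chrom_length)
    entries: list[ManifestEntry] = []
    features: list[dict] = []

    genes: list[ManifestEntry] = []
    for i in range(config.n_genes):
        size = int(rng.integers(1200, 1900))
        lid = f"gene_{i:03d}"
        chrom, start = placer.place(size, lid)
        strand = "+-"[rng.integers(0, 2)]
        e = ManifestEntry(lid, "gene", chrom, start, start + size, strand, feature_class="gene")
        genes.append(e)
        entries.append(e)
        features.append(dict(chrom=chrom, start=start, end=start + size, strand=strand,
                             type="gene", feature_class="gene", feature_id=lid))
    # genes are annotation strata: read-emitting loci may sit inside them
    placer.occupied = {n: [] for n in chrom_names}

    # --- miRNA hairpins -------------------------------------------------
    shared_mature: str | None = None
    for i in range(config.n_hairpins):
        lid = f"mir_{i:03d}"
        arm = "5p" if i % 2 == 0 else "3p"
        mature_len = (20, 21, 22)[i % 3]
        fixed = None
        if config.n_hairpins >= 4 and i == 3:
            fixed = shared_mature  # second locus of a two-locus family
        hairpin, mature, offset, star = _design_hairpin(rng, mature_len, arm, fixed)
        if config.n_hairpins >= 4 and i == 2:
            shared_mature = mature
        chrom, start = placer.place(len(hairpin), lid)
        chroms[chrom][start : start + len(hairpin)] = hairpin.encode()
        m_start = start + offset
        e = ManifestEntry(
            lid, "mirna_hairpin", chrom, start, start + len(hairpin), "+",
            mature_seq=mature, star_seq=star, mature_start=m_start,
            mature_end=m_start + len(mature),
        )
        entries.append(e)
        features.append(dict(chrom=chrom, start=start, end=start + len(hairpin), strand="+",
                             type="miRNA_primary_transcript", feature_class="miRNA", feature_id=lid))

    # --- siRNA hotspots (single-window, double-stranded, 21-nt biased) --
    for i in range(config.n_hotspots):
        lid = f"hot_{i:03d}"
        within = None
        if genes and i % 2 == 0:  # half of the hotspots genic
            g = genes[i % len(genes)]
            within = (g.chrom, g.start, g.end)
        chrom, start = placer.place(400, lid, window=500, within=within)
        entries.append(ManifestEntry(lid, "sirna_hotspot", chrom, start, start + 400, "+"))

    # --- phased loci ----------------------------------------------------
    for i in range(config.n_phas_loci):
        lid = f"phas_{i:03d}"
        chrom, start = placer.place(441, lid, window=500)
        entries.append(ManifestEntry(lid, "phas_like", chrom, start, start + 441, "+"))

    # --- TE families (copies share sequence -> multi-mapping reads) -----
    te_classes = ("LTR/gypsy", "LTR/copia", "DNA/hAT")
    if config.n_te_loci:
        n_fam = min(len(te_classes), config.n_te_loci)
        consensus = [_random_seq(rng, 800) for _ in range(n_fam)]
        for i in range(config.n_te_loci):
            fam = i % n_fam
            lid = f"te_{i:03d}"
            seq = consensus[fam]
            n_mut = max(1, int(0.01 * len(seq)))
            seq = _mutate(rng, seq, n_sub=n_mut, n_del=0)
            chrom, start = placer.place(len(seq), lid)
            chroms[chrom][start : start + len(seq)] = seq.encode()
            strand = "+-"[rng.integers(0, 2)]
            e = ManifestEntry(lid, "te_locus", chrom, start, start + len(seq), strand,
                              feature_class=te_classes[fam])
            entries.append(e)
            features.append(dict(chrom=chrom, start=start, end=start + len(seq), strand=strand,
                                 type="transposable_element", feature_class=te_classes[fam],
                                 feature_id=lid))

    # --- blacklist structural-RNA loci ----------------------------------
    bl_classes = ("rRNA", "tRNA", "snRNA", "snoRNA")
    for i in range(config.n_blacklist_loci):
        lid = f"bl_{i:03d}"
        size = int(rng.integers(120, 300))
        chrom, start = placer.place(size, lid)
        cls = bl_classes[i % 4]
        e = ManifestEntry(lid, "blacklist_locus", chrom, start, start + size, "+",
                          feature_class=cls)
        entries.append(e)
        features.append(dict(chrom=chrom, start=start, end=start + size, strand="+",
                             type=cls, feature_class=cls, feature_id=lid))

    genome = Genome(
        {**{n: bytes(b).decode() for n, b in chroms.items()}, org_name: org_seq},
        {org_name: "organellar"},
    )
    if config.organellar_length >= 600:
        entries.append(ManifestEntry("org_000", "organellar_background", org_name,
                                     0, config.organellar_length, "+"))

    _attach_tag_tables(rng, genome, entries)
    background, weights = _background_pool(rng, genome, entries, config)
    manifest = GroundTruthManifest(config.seed, entries, background, weights)
    cols = ["chrom", "start", "end", "strand", "type", "feature_class", "feature_id"]
    annotation = FeatureTable(pd.DataFrame(features, columns=cols))
    return genome, annotation, manifest


def _locus_seq(genome: Genome, chrom: str, start: int, length: int, strand: str) -> str:
    s = genome.sequences[chrom][start : start + length]
    return s if strand == "+" else revcomp(s)


def _dirichlet(rng: np.random.Generator, n: int, alpha: float, cap: float) -> np.ndarray:
    for _ in range(100):
        p = rng.dirichlet(np.full(n, alpha))
        if p.max() <= cap:
            return p
    return np.full(n, 1.0 / n)


def _attach_tag_tables(rng: np.random.Generator, genome: Genome,
                       entries: list[ManifestEntry]) -> None:
    """Build the per-locus read-species tables (sequence, position, probability)."""
    mir_index = 0
    for e in entries:
        if e.kind == "mirna_hairpin":
            shifted = mir_index == 1  # one known hairpin dominated by a shifted isomiR
            star_rich = mir_index % 2 == 0
            e.tags = _mirna_tags(genome, e, shifted=shifted, star_rich=star_rich)
            mir_index += 1
        elif e.kind == "sirna_hotspot":
            e.tags = _hotspot_tags(rng, genome, e)
        elif e.kind == "phas_like":
            e.tags = _phas_tags(rng, genome, e)
        elif e.kind == "te_locus":
            e.tags = _te_tags(rng, genome, e)
        elif e.kind in ("blacklist_locus", "organellar_background"):
            e.tags = _fragment_tags(rng, genome, e)


def _mirna_tags(genome: Genome, e: ManifestEntry, shifted: bool, star_rich: bool) -> list[TagSpec]:
    ml = e.mature_end - e.mature_start
    seq = lambda s, ln, strand="+": _locus_seq(genome, e.chrom, s, ln, strand)
    star_start = e.end - 3 - (e.mature_start - e.start) - ml  # approximate mirror position
    star_start = max(e.start, min(star_start, e.end - ml))
    tags = []
    if shifted:
        # dominant tag shifted 4 nt from the annotated mature (isomiR case)
        tags.append(TagSpec(seq(e.mature_start + 4, ml), e.chrom, e.mature_start + 4, "+", 0.78))
        tags.append(TagSpec(seq(e.mature_start, ml), e.chrom, e.mature_start, "+", 0.02))
        e.annotated_mature = seq(e.mature_start, ml)
    else:
        tags.append(TagSpec(seq(e.mature_start, ml), e.chrom, e.mature_start, "+", 0.80))
    star_p = 0.06 if star_rich else 0.0004
    tags.append(TagSpec(seq(star_start, ml), e.chrom, star_start, "+", star_p))
    tags.append(TagSpec(seq(e.mature_start + 1, ml), e.chrom, e.mature_start + 1, "+", 0.03))
    tags.append(TagSpec(seq(e.mature_start, ml - 1), e.chrom, e.mature_start, "+", 0.03))
    loop_pos = min(e.start + (e.end - e.start) // 2, e.end - 22)
    tags.append(TagSpec(seq(loop_pos, 22), e.chrom, loop_pos, "+", 0.04))
    anti = revcomp(seq(e.mature_start, ml))
    tags.append(TagSpec(anti, e.chrom, e.mature_start, "-", 0.03))
    total = sum(t.prob for t in tags)
    for t in tags:
        t.prob /= total
    return tags


def _hotspot_tags(rng: np.random.Generator, genome: Genome, e: ManifestEntry) -> list[TagSpec]:
    n = 24
    sizes = rng.choice([21, 22, 23, 24], size=n, p=[0.50, 0.15, 0.10, 0.25])
    probs = _dirichlet(rng, n, alpha=5.0, cap=0.25)
    tags = []
    for i in range(n):
        ln = int(sizes[i])
        start = int(rng.integers(e.start, e.end - ln + 1))
        strand = "+" if i % 2 == 0 else "-"  # both strands, ~balanced
        tags.append(TagSpec(_locus_seq(genome, e.chrom, start, ln, strand),
                            e.chrom, start, strand, float(probs[i])))
    return tags


def _phas_tags(rng: np.random.Generator, genome: Genome, e: ManifestEntry) -> list[TagSpec]:
    """21-nt reads whose 5' coordinates share a 21-nt register on both strands."""
    tags = []
    registers = [(k, "+") for k in range(0, 21, 2)] + [(k, "-") for k in range(1, 21, 2)]
    probs = _dirichlet(rng, len(registers), alpha=5.0, cap=0.25)
    for (k, strand), p in zip(registers, probs):
        if strand == "+":
            start = e.start + 21 * k
        else:
            start = e.start + 21 * k - 20  # 5' end (end-1) on the register
            if start < e.start:
                start += 21
        tags.append(TagSpec(_locus_seq(genome, e.chrom, start, 21, strand),
                            e.chrom, start, strand, float(p) * 0.92))
    for _ in range(3):  # off-register minority
        off = int(rng.integers(e.start + 3, e.end - 24))
        if (off - e.start) % 21 == 0:
            off += 1
        tags.append(TagSpec(_locus_seq(genome, e.chrom, off, 21, "+"),
                            e.chrom, off, "+", 0.08 / 3))
    total = sum(t.prob for t in tags)
    for t in tags:
        t.prob /= total
    return tags


def _te_tags(rng: np.random.Generator, genome: Genome, e: ManifestEntry) -> list[TagSpec]:
    n = 12
    sizes = rng.choice([21, 22, 23, 24], size=n, p=[0.10, 0.10, 0.10, 0.70])
    probs = _dirichlet(rng, n, alpha=5.0, cap=0.3)
    tags = []
    for i in range(n):
        ln = int(sizes[i])
        start = int(rng.integers(e.start, e.end - ln + 1))
        strand = "+" if i % 2 == 0 else "-"
        tags.append(TagSpec(_locus_seq(genome, e.chrom, start, ln, strand),
                            e.chrom, start, strand, float(probs[i])))
    return tags


def _fragment_tags(rng: np.random.Generator, genome: Genome, e: ManifestEntry) -> list[TagSpec]:
    n = 12
    probs = _dirichlet(rng, n, alpha=3.0, cap=0.4)
    tags = []
    for i in range(n):
        ln = int(rng.integers(18, 31))
        start = int(rng.integers(e.start, e.end - ln + 1))
        tags.append(TagSpec(_locus_seq(genome, e.chrom, start, ln, "+"),
                            e.chrom, start, "+", float(probs[i])))
    return tags


def _background_pool(rng: np.random.Generator, genome: Genome,
                     entries: list[ManifestEntry], config: GenerationConfig
                     ) -> tuple[list[TagSpec], list[float]]:
    lens = np.array(sorted(_BACKGROUND_LEN_WEIGHTS))
    lp = np.array([_BACKGROUND_LEN_WEIGHTS[int(l)] for l in lens])
    lp = lp / lp.sum()
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in genome.nuclear_names}
    for e in entries:
        if e.kind not in ("gene",) and e.chrom in occupied:
            occupied[e.chrom].append((e.start, e.end))
    pool: list[TagSpec] = []
    names = genome.nuclear_names
    while len(pool) < config.n_background_tags:
        chrom = names[rng.integers(0, len(names))]
        ln = int(rng.choice(lens, p=lp))
        start = int(rng.integers(0, len(genome.sequences[chrom]) - ln))
        if any(s < start + ln and start < t for s, t in occupied[chrom]):
            continue
        strand = "+-"[rng.integers(0, 2)]
        pool.append(TagSpec(_locus_seq(genome, chrom, start, ln, strand), chrom, start, strand, 0.0))
    weights = _dirichlet(rng, len(pool), alpha=2.0, cap=0.01)
    for t, w in zip(pool, weights):
        t.prob = float(w)
    return pool, [float(w) for w in weights]


# ---------------------------------------------------------------------------
# default effect table


def default_effects(manifest: GroundTruthManifest, rng: np.random.Generator | None = None
                    ) -> list[Effect]:
    """Planted fold changes emulating the study's structure: a dominant
    developmental-stage effect on miRNAs and hotspots, cultivar-by-vineyard
    effects on hotspots spanning the >=2/>=10/>=50 fold bins, an extreme
    ~390-fold single-cultivar single-vineyard phased locus, and mild
    Riccione activation of gypsy-family TEs."""
    effects: list[Effect] = []
    hairpins = manifest.by_kind("mirna_hairpin")
    for i, e in enumerate(hairpins):
        stages = RIPE_STAGES if i % 2 == 0 else GREEN_STAGES
        for s in stages:
            effects.append(Effect(e.locus_id, 10.0, stage=s))
        if i % 5 == 4:
            effects.append(Effect(e.locus_id, 1.8, cultivar="CS"))
    hotspots = manifest.by_kind("sirna_hotspot")
    folds = (3.0, 12.0, 60.0)
    for i, e in enumerate(hotspots):
        stages = RIPE_STAGES if i % 2 == 0 else GREEN_STAGES
        for s in stages:
            effects.append(Effect(e.locus_id, 4.0, stage=s))
        effects.append(Effect(
            e.locus_id, folds[i % 3],
            vineyard=VINEYARDS[i % len(VINEYARDS)],
            cultivar=CULTIVARS[(i // 3) % 2],
        ))
    phas = manifest.by_kind("phas_like")
    if phas:
        effects.append(Effect(phas[0].locus_id, 390.0, vineyard="Ric", cultivar="SG", stage="bc"))
    for e in manifest.by_kind("te_locus"):
        if e.feature_class == "LTR/gypsy":
            effects.append(Effect(e.locus_id, 2.0, vineyard="Ric"))
    return effects


_BASELINES = {
    "mirna_hairpin": (60.0, 200.0),
    "sirna_hotspot": (30.0, 60.0),
    "phas_like": (40.0, 80.0),
    "te_locus": (30.0, 70.0),
    "blacklist_locus": (60.0, 140.0),
    "organellar_background": (400.0, 600.0),
}


def _assign_baselines(manifest: GroundTruthManifest, rng: np.random.Generator) -> None:
    for e in manifest.entries:
        lo, hi = _BASELINES.get(e.kind, (0.0, 0.0))
        e.baseline_mean = float(rng.uniform(lo, hi)) if hi else 0.0
    phas = manifest.by_kind("phas_like")
    if phas:
        phas[0].baseline_mean = 3.0  # extreme-ratio locus: near-silent baseline


def expected_mean(entry: ManifestEntry, effects: Iterable[Effect], sample: SampleInfo) -> float:
    mean = entry.baseline_mean
    for eff in effects:
        if eff.locus_id == entry.locus_id and eff.applies(sample):
            mean *= eff.fold
    return mean


# ---------------------------------------------------------------------------
# simulate_libraries


def simulate_libraries(
    genome: Genome, manifest: GroundTruthManifest, config: GenerationConfig
) -> dict[str, ReadLibrary]:
    """Draw every library of the factorial design.

    Per-locus totals are negative-binomial around the planted mean (gamma-
    Poisson with overdispersion ``config.noise``); reads within a locus follow
    its tag table; the degradation background absorbs the remaining depth so
    each library holds exactly ``library_depth`` reads.  Replicates share all
    planted means and differ only by sampling noise.
    """
    rng_master = np.random.default_rng(np.random.SeedSequence(config.seed))
    _assign_baselines(manifest, rng_master)
    effects = config.effect_table
    if effects is None:
        effects = default_effects(manifest)
    emitting = [e for e in manifest.entries if e.tags]
    conditions = [SampleInfo(v, c, s, 1) for v in VINEYARDS for c in CULTIVARS for s in STAGES]
    # keep every locus within a small share of the depth, and the summed
    # planted means within the depth, so background absorbs the remainder
    # and planted fold changes survive unthinned
    cap = 0.025 * config.library_depth
    for e in emitting:
        peak = max(expected_mean(e, effects, s) for s in conditions)
        if peak > cap:
            e.baseline_mean *= cap / peak
    worst = max(
        sum(expected_mean(e, effects, s) for e in emitting) for s in conditions
    )
    budget = 0.7 * config.library_depth
    if worst > budget:
        for e in emitting:
            e.baseline_mean *= budget / worst
    for e in emitting:
        e.condition_means = {
            f"{v}_{c}_{s}": expected_mean(e, effects, SampleInfo(v, c, s, 1))
            for v in VINEYARDS for c in CULTIVARS for s in STAGES
        }
    bg_probs = np.array(manifest.background_weights)
    libraries: dict[str, ReadLibrary] = {}
    for lib_idx, sample in enumerate(config.factor_design):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(lib_idx,)))
        counts = []
        for e in emitting:
            mu = expected_mean(e, effects, sample)
            counts.append(_nb_draw(rng, mu, config.noise))
        counts = np.array(counts, dtype=int)
        total = int(counts.sum())
        if total > config.library_depth:  # thin proportionally; background gets nothing
            keep = rng.multivariate_hypergeometric(counts, config.library_depth)
            counts = np.asarray(keep, dtype=int)
            n_background = 0
        else:
            n_background = config.library_depth - total
        tags: dict[str, int] = {}
        for e, n in zip(emitting, counts):
            if n == 0:
                continue
            probs = np.array([t.prob for t in e.tags])
            draw = rng.multinomial(int(n), probs / probs.sum())
            for t, k in zip(e.tags, draw):
                if k:
                    tags[t.seq] = tags.get(t.seq, 0) + int(k)
        if n_background and len(bg_probs):
            draw = rng.multinomial(n_background, bg_probs)
            for t, k in zip(manifest.background, draw):
                if k:
                    tags[t.seq] = tags.get(t.seq, 0) + int(k)
        libraries[sample.code] = ReadLibrary(sample, tags)
    return libraries


def _nb_draw(rng: np.random.Generator, mu: float, noise: float) -> int:
    if mu <= 0:
        return 0
    if noise <= 0:
        return int(rng.poisson(mu))
    lam = rng.gamma(shape=1.0 / noise, scale=mu * noise)
    return int(rng.poisson(lam))


# ---------------------------------------------------------------------------
# file output


def write_fastq(library: ReadLibrary, path: str | Path, adapter: str | None = None) -> None:
    """Expand collapsed tags to per-read FASTQ records (constant quality)."""
    with open(path, "w") as fh:
        r = 0
        for seq in sorted(library.tags):
            full = seq + (adapter or "")
            qual = "I" * len(full)
            for _ in range(library.tags[seq]):
                fh.write(f"@{library.code}_r{r}\n{full}\n+\n{qual}\n")
                r += 1


def write_catalogs(manifest: GroundTruthManifest, genome: Genome, outdir: str | Path,
                   n_known: int | None = None) -> dict[str, Path]:
    """Write known-miRNA catalogs in the miRBase header dialect.

    The first half of the planted hairpins (or ``n_known``) form the
    same-species catalog (mature + hairpin); of the remainder, every other
    one gets a 1-mismatch homolog in the cross-species catalog and the rest
    stay absent everywhere (bona fide novel).  The shifted-isomiR hairpin is
    always in the same-species catalog with its annotated (planted) mature.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hairpins = manifest.by_kind("mirna_hairpin")
    if n_known is None:
        n_known = len(hairpins) // 2
    mature_fa = outdir / "known_mature.fa"
    hairpin_fa = outdir / "known_hairpin.fa"
    cross_fa = outdir / "cross_species_mature.fa"
    with open(mature_fa, "w") as mf, open(hairpin_fa, "w") as hf, open(cross_fa, "w") as xf:
        for i, e in enumerate(hairpins):
            name = f"vvi-miR90{i:02d}"
            hp_seq = genome.sequences[e.chrom][e.start : e.end]
            mature = e.annotated_mature or e.mature_seq
            if i < n_known:
                e.catalog_status = "known_shifted" if e.annotated_mature else "known"
                mf.write(f">{name} Vitis vinifera synthetic\n{mature}\n")
                hf.write(f">{name.replace('miR', 'MIR')} Vitis vinifera synthetic\n{hp_seq}\n")
            elif (i - n_known) % 2 == 0:
                e.catalog_status = "homolog"
                hom = list(mature)
                hom[3] = {"A": "C", "C": "A", "G": "T", "T": "G"}[hom[3]]
                xf.write(f">ath-miR91{i:02d} Arabidopsis thaliana synthetic\n{''.join(hom)}\n")
            else:
                e.catalog_status = "novel"
        # decoy entries absent from the genome
        rng = np.random.default_rng(np.random.SeedSequence(manifest.config_seed, spawn_key=(991,)))
        for d in range(3):
            xf.write(f">osa-miR92{d:02d} Oryza sativa synthetic\n{_random_seq(rng, 21)}\n")
    return {"mature": mature_fa, "hairpin": hairpin_fa, "cross_species": cross_fa}
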