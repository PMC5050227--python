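"""Stage orchestration: declarative config, reproducible runs, run manifest.

A run executes a subset of the stages ``simulate -> map -> normalize ->
clusters -> mirna -> expression`` inside one workspace directory; every
stage reads its inputs from, and writes its outputs to, canonical file names
so any stage can also be re-run standalone on an existing workspace.  The
run manifest records parameter snapshots, input/output digests and
wall-clock per stage; defaults reproduce the published thresholds (500-bp
windows, 30-HNA cluster call, 5/30/2 ratio rules, 30-TP4M prefilter, 20
hits, 200-TP4M star rule, 10-TP4M expressed call).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import expression_profiles as ep
from . import hotspot_clustering as hc
from . import mirna_discovery as md
from . import normalization as norm
from . import sequence_io as sio
from . import synthetic_data as syn

STAGES = ("simulate", "map", "normalize", "clusters", "mirna", "expression")
_STAGE_DEPS = {
    "simulate": (),
    "map": ("simulate",),
    "normalize": ("map",),
    "clusters": ("normalize",),
    "mirna": ("normalize",),
    "expression": ("mirna",),
}


@dataclass
class RunConfig:
    outdir: str = "srna_gxe_run"
    seed: int = 0
    # synthetic fixture
    library_depth: int = 50_000
    n_chromosomes: int = 4
    chrom_length: int = 250_000
    n_hairpins: int = 16
    n_hotspots: int = 20
    n_phas_loci: int = 2
    n_te_loci: int = 15
    n_blacklist_loci: int = 8
    n_genes: int = 40
    n_background_tags: int = 4000
    noise: float = 0.05
    write_fastq: bool = False
    # mapping / normalization
    min_len: int = 18
    max_len: int = 34
    denominator_mode: str = "reads"
    # clustering
    window: int = 500
    cluster_min_hna: float = 30.0
    ratio_min_each: float = 5.0
    ratio_min_sum: float = 30.0
    fc: float = 2.0
    linkage_samples: str = "complete"
    linkage_rows: str = "average"
    # discovery
    prefilter_tp4m: float = 30.0
    max_hits: int = 20
    star_min: float = 200.0
    novel_lengths: tuple[int, ...] = (20, 21, 22)
    long_flank: int = 250
    short_flank: int = 30
    structure_engine: str = "auto"
    # expression
    expressed_min: float = 10.0

    def validate(self) -> list[str]:
        errors = []
        positive = ("library_depth", "n_chromosomes", "chrom_length", "window", "fc",
                    "max_hits", "max_len", "min_len")
        for name in positive:
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be positive")
        non_negative = ("cluster_min_hna", "ratio_min_each", "ratio_min_sum",
                        "prefilter_tp4m", "star_min", "expressed_min", "noise",
                        "long_flank", "short_flank", "n_hairpins", "n_hotspots")
        for name in non_negative:
            if getattr(self, name) < 0:
                errors.append(f"{name} must be non-negative")
        if self.denominator_mode not in ("reads", "alignments"):
            errors.append("denominator_mode must be 'reads' or 'alignments'")
        if self.structure_engine not in ("auto", "vienna", "builtin"):
            errors.append("structure_engine must be auto|vienna|builtin")
        return errors

    def discovery_params(self) -> md.DiscoveryParams:
        return md.DiscoveryParams(
            min_tp4m=self.prefilter_tp4m,
            max_hits=self.max_hits,
            star_min_tp4m=self.star_min,
            novel_lengths=tuple(self.novel_lengths),
            long_flank=self.long_flank,
            short_flank=self.short_flank,
            engine=self.structure_engine,
        )


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a flat key-value (YAML mapping) config document."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key-value mapping")
    known = {f.name: f for f in dataclasses.fields(RunConfig)}
    errors = [f"unknown key: {k}" for k in raw if k not in known]
    coerced = {}
    for k, v in raw.items():
        if k not in known:
            continue
        ftype = known[k].type
        try:
            if ftype == "int":
                coerced[k] = int(v)
            elif ftype == "float":
                coerced[k] = float(v)
            elif ftype == "bool":
                coerced[k] = bool(v)
            elif "tuple" in str(ftype):
                coerced[k] = tuple(int(x) for x in (v.split(",") if isinstance(v, str) else v))
            else:
                coerced[k] = str(v)
        except (TypeError, ValueError):
            errors.append(f"bad value for {k}: {v!r}")
    config = RunConfig(**coerced)
    errors.extend(config.validate())
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    return config


@dataclass
class StageResult:
    stage: str
    seconds: float
    outputs: dict[str, str]  # path -> sha256
    params: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _log(msg: str) -> None:
    print(f"[{time.strftime('%H:%M:%S')}] srna-gxe {msg}", flush=True)


class Workspace:
    """In-memory state of a run, lazily (re)loaded from the workspace dir."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.root = Path(config.outdir)
        self.genome: sio.Genome | None = None
        self.annotation: sio.FeatureTable | None = None
        self.manifest: syn.GroundTruthManifest | None = None
        self.libraries: dict[str, sio.ReadLibrary] | None = None
        self.alignments: dict[str, list[sio.Alignment]] | None = None
        self.unmapped: set[str] | None = None
        self.partitions: dict[str, sio.BlacklistPartition] | None = None
        self.normalized: dict[str, norm.NormalizedLibrary] | None = None
        self.hna_tables: dict[str, pd.DataFrame] | None = None
        self.discovery: md.DiscoveryResult | None = None
        self.catalog_paths: dict[str, Path] | None = None

    # -- loading from disk ------------------------------------------------
    def require(self, stage: str) -> None:
        loader = getattr(self, f"_load_{stage}", None)
        attr = {"simulate": "genome", "map": "alignments",
                "normalize": "normalized", "mirna": "discovery"}.get(stage)
        if attr and getattr(self, attr) is None:
            if loader is None or not loader():
                raise RuntimeError(
                    f"missing inputs: run the '{stage}' stage first (or point outdir "
                    f"at a workspace containing its outputs)"
                )

    def _load_simulate(self) -> bool:
        fa = self.root / "genome.fa"
        if not fa.exists():
            return False
        self.genome = sio.Genome.from_fasta(fa)
        self.annotation = sio.FeatureTable.from_gff3(self.root / "annotation.gff3")
        self.manifest = syn.GroundTruthManifest.from_json(self.root / "manifest.json")
        libdir = self.root / "libraries"
        self.libraries = {}
        for fa in sorted(libdir.glob("*.fa")):
            code = fa.stem
            self.libraries[code] = sio.collapse_reads(
                fa, min_len=self.config.min_len, max_len=self.config.max_len,
                sample=sio.SampleInfo.from_code(code),
            )
        cat = self.root / "catalogs"
        if cat.exists():
            self.catalog_paths = {
                "mature": cat / "known_mature.fa",
                "hairpin": cat / "known_hairpin.fa",
                "cross_species": cat / "cross_species_mature.fa",
            }
        return True

    def _load_map(self) -> bool:
        path = self.root / "alignments.tsv"
        if not path.exists() or self.genome is None and not self._load_simulate():
            return False
        df = pd.read_csv(path, sep="\t")
        alns: dict[str, list[sio.Alignment]] = {}
        for row in df.itertuples():
            alns.setdefault(row.tag, []).append(
                sio.Alignment(row.tag, row.chrom, int(row.start), row.strand, int(row.hits))
            )
        self.alignments = alns
        return True

    def _load_normalize(self) -> bool:
        return False  # normalized state is cheap: recompute via run()

    def _load_mirna(self) -> bool:
        return False

    # -- stages ------------------------------------------------------------
    def stage_simulate(self) -> list[Path]:
        c = self.config
        gen = syn.GenerationConfig(
            seed=c.seed, n_chromosomes=c.n_chromosomes, chrom_length=c.chrom_length,
            n_hairpins=c.n_hairpins, n_hotspots=c.n_hotspots, n_phas_loci=c.n_phas_loci,
            n_te_loci=c.n_te_loci, n_blacklist_loci=c.n_blacklist_loci, n_genes=c.n_genes,
            n_background_tags=c.n_background_tags,
            library_depth=c.library_depth, noise=c.noise,
        )
        self.genome, self.annotation, self.manifest = syn.generate_genome(gen)
        self.libraries = syn.simulate_libraries(self.genome, self.manifest, gen)
        self.root.mkdir(parents=True, exist_ok=True)
        outputs = []
        self.genome.to_fasta(self.root / "genome.fa")
        self.annotation.to_gff3(self.root / "annotation.gff3", self.genome)
        self.catalog_paths = syn.write_catalogs(self.manifest, self.genome, self.root / "catalogs")
        self.manifest.to_json(self.root / "manifest.json")
        libdir = self.root / "libraries"
        libdir.mkdir(exist_ok=True)
        for code, lib in self.libraries.items():
            sio.write_collapsed_fasta(lib, libdir / f"{code}.fa")
            outputs.append(libdir / f"{code}.fa")
            if c.write_fastq:
                syn.write_fastq(lib, libdir / f"{code}.fastq")
                outputs.append(libdir / f"{code}.fastq")
        outputs += [self.root / "genome.fa", self.root / "annotation.gff3",
                    self.root / "manifest.json", *self.catalog_paths.values()]
        return outputs

    def stage_map(self) -> list[Path]:
        self.require("simulate")
        union: set[str] = set()
        for lib in self.libraries.values():
            union.update(lib.tags)
        index = sio.GenomeIndex(self.genome)
        self.alignments, self.unmapped = sio.map_tags(union, self.genome, index)
        rows = [
            (a.tag, a.chrom, a.start, a.end, a.strand, a.hits)
            for alns in self.alignments.values()
            for a in alns
        ]
        df = pd.DataFrame(rows, columns=["tag", "chrom", "start", "end", "strand", "hits"])
        out = self.root / "alignments.tsv"
        df.sort_values(["chrom", "start", "tag"]).to_csv(out, sep="\t", index=False)
        (self.root / "unmapped.txt").write_text("\n".join(sorted(self.unmapped)) + "\n")
        return [out, self.root / "unmapped.txt"]

    def stage_normalize(self) -> list[Path]:
        if self.alignments is None:
            self.require("map")
        self.require("simulate")
        self.partitions, self.normalized, self.hna_tables = {}, {}, {}
        rows = []
        # blacklist status is a property of the tag: classify once globally
        global_part = sio.apply_blacklist(self.alignments, self.annotation, self.genome)
        for code, lib in self.libraries.items():
            retained = {t for t in lib.tags if t in global_part.retained}
            excluded = {t: global_part.excluded[t] for t in lib.tags if t in global_part.excluded}
            counts = {c: 0 for c in (*sio.BLACKLIST_CLASSES, sio.ORGANELLAR)}
            for t, c in excluded.items():
                counts[c] += lib.tags[t]
            part = sio.BlacklistPartition(retained, excluded, counts)
            self.partitions[code] = part
            hits = None
            if self.config.denominator_mode == "alignments":
                hits = {t: alns[0].hits for t, alns in self.alignments.items()}
            denom = norm.compute_denominator(lib, part, self.config.denominator_mode, hits)
            nl = norm.normalize_library(lib, part, denom)
            self.normalized[code] = nl
            self.hna_tables[code] = norm.locus_abundances(nl, self.alignments)
            rows.append((code, denom.value, lib.total, nl.total))
        df = pd.DataFrame(rows, columns=["library", "denominator", "raw_total", "tp4m_total"])
        out = self.root / "denominators.tsv"
        df.to_csv(out, sep="\t", index=False)
        long = pd.concat(
            [t.assign(library=code) for code, t in self.hna_tables.items()],
            ignore_index=True,
        )
        hna_out = self.root / "hna.tsv"
        long.to_csv(hna_out, sep="\t", index=False)
        return [out, hna_out]

    def stage_clusters(self) -> list[Path]:
        if self.hna_tables is None:
            self.stage_normalize()
        c = self.config
        windows = hc.tile_genome(self.genome, c.window)
        profiles = hc.accumulate(windows, self.hna_tables)
        averaged = hc.average_replicates(profiles)
        flags, counts, expressed = hc.call_expressed(averaged, c.cluster_min_hna)
        annot = hc.annotate_clusters(expressed, self.annotation, c.window)
        summary = hc.annotation_summary(flags.loc[expressed], annot)
        ratios = hc.ratio_analysis(
            averaged, min_each=c.ratio_min_each, min_sum=c.ratio_min_sum, fc=c.fc
        )
        outputs = []
        for name, obj in [
            ("cluster_profiles.tsv", averaged.loc[expressed]),
            ("cluster_annotation_summary.tsv", summary),
            ("cluster_ratios.tsv", ratios),
            ("cluster_fold_bins.tsv", hc.fold_bin_counts(ratios)),
        ]:
            path = self.root / name
            obj.to_csv(path, sep="\t")
            outputs.append(path)
        bed = self.root / "expressed_clusters.bed"
        hc.expressed_to_bed(flags, c.window, bed)
        outputs.append(bed)
        venn = {}
        for factor in ("vineyard", "cultivar", "stage"):
            cells, specific = hc.specificity_sets(flags, factor)
            venn[factor] = {
                "cells": {"+".join(k): v for k, v in cells.items()},
                "specific": specific,
            }
        venn_path = self.root / "cluster_specificity.json"
        venn_path.write_text(json.dumps(venn, indent=1))
        outputs.append(venn_path)
        if averaged.shape[1] >= 3 and len(expressed) >= 2:
            newick, _corr, _z = hc.cluster_dendrogram(
                averaged, expressed, method=c.linkage_samples
            )
            tree = self.root / "cluster_dendrogram.nwk"
            tree.write_text(newick + "\n")
            outputs.append(tree)
        return outputs

    def stage_mirna(self) -> list[Path]:
        if self.normalized is None:
            self.stage_normalize()
        records = md.build_tag_records(
            {c: n.tp4m for c, n in self.normalized.items()},
            self.alignments,
            blacklisted={t for p in self.partitions.values() for t in p.excluded},
        )
        catalog = cross = None
        if self.catalog_paths:
            catalog = md.MirnaCatalog.from_fasta(
                self.catalog_paths["mature"], self.catalog_paths["hairpin"]
            )
            cross = md.MirnaCatalog.from_fasta(self.catalog_paths["cross_species"])
        self.discovery = md.run_discovery(
            records, self.alignments, self.genome, catalog, cross,
            self.config.discovery_params(),
        )
        table = self.root / "mirna_table.tsv"
        self.discovery.table().to_csv(table, sep="\t", index=False)
        trace = self.root / "filter_trace.tsv"
        self.discovery.trace_frame().to_csv(trace, sep="\t", index=False)
        structures = self.root / "mirna_structures.txt"
        with open(structures, "w") as fh:
            for r in self.discovery.reported:
                p = r.loci[0]
                fh.write(f">{p.chrom}:{p.start}-{p.end}({p.strand}) {r.mature_seq}\n")
                fh.write(f"{p.seq}\n{p.structure} ({p.energy:.1f})\n")
        return [table, trace, structures]

    def stage_expression(self) -> list[Path]:
        if self.discovery is None:
            self.require("mirna")
        c = self.config
        matures = [r.mature_seq for r in self.discovery.reported]
        matrix = ep.build_matrix(matures, {c_: n.tp4m for c_, n in self.normalized.items()})
        flags, per_library = ep.call_expressed(matrix, c.expressed_min)
        labels, venn = ep.specificity(flags)
        raw = ep.precursor_raw_counts(self.discovery.reported, self.libraries, self.alignments)
        outputs = []
        for name, obj in [
            ("mirna_tp4m_matrix.tsv", matrix),
            ("mirna_expressed_calls.tsv", flags),
            ("mirna_expressed_per_library.tsv", per_library.rename("n_expressed")),
            ("mirna_specificity.tsv", labels.rename("label")),
            ("precursor_raw_counts.tsv", raw),
        ]:
            path = self.root / name
            obj.to_csv(path, sep="\t")
            outputs.append(path)
        venn_path = self.root / "mirna_venn.json"
        venn_path.write_text(json.dumps(
            {f: {"+".join(k): v for k, v in cells.items()} for f, cells in venn.items()},
            indent=1,
        ))
        outputs.append(venn_path)
        expressed = flags.index[flags.any(axis=1)] if not flags.empty else matrix.index
        if matrix.shape[1] >= 3 and len(expressed) >= 2:
            newick, _corr, order = ep.correlate_and_cluster(
                matrix.loc[expressed], c.linkage_samples, c.linkage_rows
            )
            (self.root / "mirna_dendrogram.nwk").write_text(newick + "\n")
            ordered = matrix.loc[order]
            ordered.to_csv(self.root / "mirna_heatmap_matrix.tsv", sep="\t")
            outputs += [self.root / "mirna_dendrogram.nwk", self.root / "mirna_heatmap_matrix.tsv"]
        return outputs


def run(config: RunConfig, stages: tuple[str, ...] = STAGES) -> list[StageResult]:
    """Execute stages in dependency order; returns per-stage results and
    writes ``run_manifest.json`` in the workspace."""
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    errors = config.validate()
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    ordered = [s for s in STAGES if s in stages]
    ws = Workspace(config)
    results = []
    for stage in ordered:
        for dep in _STAGE_DEPS[stage]:
            if dep not in ordered[: ordered.index(stage)]:
                ws.require(dep)
        _log(f"stage {stage} started")
        t0 = time.perf_counter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            outputs = getattr(ws, f"stage_{stage}")()
        seconds = time.perf_counter() - t0
        results.append(StageResult(
            stage=stage,
            seconds=round(seconds, 3),
            outputs={str(p.relative_to(ws.root)): _digest(p) for p in outputs},
            params=dataclasses.asdict(config),
            warnings=[str(w.message) for w in caught],
        ))
        _log(f"stage {stage} finished in {seconds:.1f}s")
    manifest_path = ws.root / "run_manifest.json"
    manifest_path.write_text(json.dumps(
        [dataclasses.asdict(r) for r in results], indent=1, default=str
    ))
    return results
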