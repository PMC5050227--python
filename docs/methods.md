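# Methods

`srna-gxe` implements a proximity-based small-RNA analysis of the kind used
to profile grapevine berry libraries across genotypes (cultivars) and
environments (vineyards): linear normalization of collapsed sequencing tags,
genome-wide detection of small-RNA hotspots in fixed windows, a conservative
five-filter miRNA identification cascade, and expression / specificity /
correlation profiling of the identified matures.  A synthetic-data generator
produces the full study design with a ground-truth manifest, so every stage
can be validated against planted structures.

## Normalization model

Reads are adapter-trimmed, length-filtered to 18–34 nt, collapsed to unique
tags, and mapped to the genome requiring perfect full-length matches on
either strand.  Tags touching annotated rRNA/tRNA/snRNA/snoRNA features (≥1
bp overlap at *any* of their loci) or mapping to an organellar contig are
excluded.  Two statistics drive everything downstream:

- **TP4M** (transcripts per 4 million): `raw / D × 4·10⁶`, where the library
  denominator `D` is the summed raw count of retained tags.  By default each
  tag's raw count enters `D` once regardless of its number of genomic hits
  (`denominator_mode: reads`), which makes per-library TP4M totals exactly
  4,000,000; the alternative `alignments` mode weights each tag by its hit
  count, for comparison with pipelines that count alignments.
- **HNA** (hits-normalized abundance): `TP4M / hits`, assigned to each of a
  tag's perfect genomic matches.  A *hit* is one perfect full-length match;
  summed over a tag's loci, HNA restores its TP4M, so multi-mapping
  distributes abundance without creating or destroying mass.  Both
  conservation laws are asserted in the test suite.

For correlation analyses abundances are transformed as `log10(1 + x)` (zero
stays zero) and Pearson correlations are converted to dendrogram distances.
The correlation-to-distance formula is not uniquely determined by common
usage; `1 − r` is used (0 at perfect agreement, monotone), with `(1 − r)/2`
available by passing a transformed matrix.

## Hotspot (static cluster) analysis

The nuclear genome is tiled into adjacent, non-overlapping 500-bp windows.
Each 21–24-nt alignment contributes its HNA to exactly one window — the one
containing its 5′-most genomic coordinate (alignment start) — so
boundary-spanning reads are counted once and the window totals partition the
qualifying HNA mass.  Replicates are averaged per condition (vineyard ×
cultivar × stage) *before* thresholds; a window is **expressed** at ≥30 HNA.
Per-replicate calling is available by passing the unaveraged profile matrix
to the same caller.

Windows are annotated genic when they overlap ≥1 bp of a gene feature
(genes take precedence in the binary genic/intergenic split); TE association
is an independent flag carrying the repeat class (e.g. LTR/gypsy).
Cultivar ratio records within an environment × stage pair require both
sides ≥5 HNA, a sum >30 HNA, and a fold change ≥2, binned cumulatively at
≥2 / ≥10 / ≥50.  Composition diagnostics per window report the size-class
histogram, sense-strand fraction, and a 21-nt register fraction (share of
21-nt HNA whose 5′ positions fall in the modal phase class, ties broken
toward the smallest offset).  The register fraction is descriptive — it is
not a phasing *p*-value and the package does not call PHAS loci.

Sample trees use complete linkage on `1 − r` over log-transformed expressed
windows (matching the default of R's `hclust`); heatmap row ordering uses
average linkage.  Both are configurable.

## miRNA discovery cascade

1. **Tag prefilter** — keep tags that are not blacklisted, reach ≥30 TP4M in
   at least one library (the threshold applies to the per-library maximum),
   are 18–26 nt, and have 1–20 genomic hits (more is considered too
   repetitive for a miRNA).  A filter trace records the first failing filter
   per removed tag and partitions the input.
2. **Precursor excision** — around every alignment of a surviving tag, two
   asymmetric windows are cut (250 nt up / 30 nt down, and the mirror),
   clipped to chromosome bounds, since the hairpin may extend mostly 5′ or
   mostly 3′ of the mature.  Before thermodynamic folding, a cheap
   complementarity screen requires an approximate reverse complement of the
   mature elsewhere in the window (≤6 edits, computed with `edlib`); windows
   without a star candidate cannot fold into a qualifying duplex and are
   skipped.  The screen is conservative for precursors that pair the mature
   largely through G:U wobble; raising the bound or setting it to 0 disables
   it at proportional folding cost.
3. **Structure evaluation** — candidates are folded (ViennaRNA MFE; a
   built-in base-pair-maximization engine with pseudo-energies serves as
   fallback) and accepted when the mature lies entirely on one arm of a
   stem-loop, ≤5 mature positions are unpaired, no asymmetric bulge in the
   mature/star duplex exceeds 3 nt, the mature does not overlap the loop,
   and the folding energy is ≤ −18 kcal/mol.  The thresholds follow accepted
   plant-miRNA precursor criteria and are configurable.
4. **Bias filters** — over all tags mapping within the precursor, with
   abundances summed over all libraries: strand bias (sense/total) ≥0.9 and
   abundance bias ((top1+top2)/total) ≥0.7.  Spans shorter than 150 nt are
   widened symmetrically to that extent before tallying, the scale of a
   compact plant pri-miRNA: without this, a siRNA hotspot read can pass both
   biases through a fortuitous tight local hairpin whose tiny span excludes
   the locus's other reads.
5. **Mature selection and classification** — the most abundant precursor tag
   is the mature (ties break to the lexicographically smallest sequence);
   the top tag of the opposite arm is co-reported only when its summed
   abundance strictly exceeds 200 TP4M.  Overlapping accepted precursors are
   merged (one mature per locus) and precursors sharing a mature form one
   family record listing all loci.  Matures identical to a same-species
   catalog entry are *known-exact*; matures inside a catalog hairpin are
   *known-isomiR* (offset <3 nt) or *known-shifted* (≥3 nt, reported with
   the offset); the rest are retained only at 20–22 nt and become
   *homolog-novel* (≤2 ungapped mismatches to any cross-species mature,
   overhangs counting as mismatches) or *bona-fide-novel*.

## Expression profiling

Matures are quantified by exact sequence (multi-locus families share one
mature), in TP4M per library.  A miRNA is expressed in a condition when
both replicates are ≥10 TP4M; per-library counts (single library ≥10) are
also reported because the two views differ and both are useful.  A miRNA is
vineyard-/cultivar-/stage-specific when every condition where it is
expressed shares that factor level.  A raw-count matrix per precursor locus
(summed counts of tags aligning fully within the precursor) is exported for
external count-based differential-expression tools; the package does not
perform differential testing itself.

## Synthetic data: what it emulates, and what it does not

The generator plants, on a multi-chromosome random genome plus one
organellar contig:

- **miRNA hairpins** (default 16): stem arm = 5-nt pad + 20–22-nt mature +
  12-nt extension; 15-nt loop; star arm = reverse complement with 2
  substitutions and one 1-nt deletion, one substitution forced into the
  center of the mature complement so no exact reverse complement of the
  mature survives (otherwise the locus acquires a spurious antisense
  self-match that wrecks its strand bias).  Designs are refolded with every
  available engine at generation time and redrawn until they satisfy the
  structure criteria, so discovery failures indicate pipeline bugs, not
  fixture defects.  One hairpin pair shares a mature (a two-locus family);
  one catalog hairpin is dominated by a 4-nt-shifted isomiR.
- **siRNA hotspots** (default 20): 400-bp loci confined to single 500-bp
  windows, emitting 21–24-nt (21-biased) reads from both strands through
  ~24 read species with near-uniform probabilities capped so no tag exceeds
  30% of the locus — they must fail the abundance-bias filter.
- **phased loci**: 21-nt reads whose 5′ coordinates share a 21-nt register
  on both strands (92% on-register).  The first one models an extreme
  single-cultivar, single-vineyard locus: near-silent baseline (3
  reads/library) with a planted 390-fold activation in Sangiovese, Riccione,
  green berries.
- **TE families** whose copies share a consensus (1% divergence), producing
  genuinely multi-mapping 24-nt-biased reads; classes LTR/gypsy, LTR/copia,
  DNA/hAT.
- **blacklist loci** (rRNA/tRNA/snRNA/snoRNA) and organellar reads, which
  exercise the denominator exclusion.
- **genes** are annotation strata placed first; half of the hotspots are
  deliberately placed inside genes to exercise the genic/intergenic split.
  Read-emitting loci never overlap one another; genes may contain them.

Libraries follow the full 3 vineyards × 2 cultivars × 4 stages × 2
replicates design at 50,000 reads each.  Per-locus totals are
gamma-Poisson (negative binomial) around baseline × planted fold effects
(variance = μ + 0.05 μ²); replicates share all means.  Planted means are
capped at 2.5% of depth per locus and 70% of depth in aggregate so extreme
folds survive without thinning.  The default effect table gives every
hairpin and hotspot a dominant ripening effect (fold 10 and 4 respectively,
half up in green, half in ripened stages) plus smaller cultivar-by-vineyard
effects spanning the ≥2/≥10/≥50 ratio bins — reflecting the empirical
finding that developmental stage, not environment, dominates sample
clustering.

**Background** models degradation fragments as a fixed genome-wide pool of
uniformly placed positions (outside planted loci) reused across libraries,
with a size distribution concentrated outside 21–24 nt.  This is a
deliberate compromise: at desk scale (50,000 reads/library) a single read is
worth ≈80 TP4M, so the 30-HNA window threshold sits *below one read* and any
21–24-nt background read alone would light up its window; at the study's
real depths the same threshold corresponds to many reads and uniform
background is harmless.  Keeping 21–24-nt background rare preserves the
intended false-positive behavior (<1% of windows per sample) while still
exercising the thresholds.  For the same reason most planted loci are
expressed nearly everywhere at desk scale, so the specificity/Venn machinery
is validated against exhaustive set-algebra oracles on randomized calls
rather than by reproducing the published Venn proportions.  The simulator
makes no attempt at sequencing-error substitutions or quality-score realism,
and its genome is random sequence, not a real assembly.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; GFF3 is converted at the
  file boundary (1-based inclusive).  BED output is 0-based.
- Threshold comparisons use `≥` with no epsilon; TP4M is IEEE double.
- Tags containing ambiguous bases are unmappable by definition.
- A library whose retained set is empty is flagged unusable and refused by
  normalization.
- Dendrograms refuse constant or all-zero profiles, naming the sample.
- Constant rows in the heatmap-ordering step are treated as uncorrelated
  rather than raising, since a constant expressed mature is legitimate.
- Empty windows yield all-zero composition; ties in the modal phase class
  break toward the smallest offset.
- All randomness descends from one integer seed through
  `numpy.random.SeedSequence` spawning, so every artifact is byte-identical
  under a fixed seed.

## Problem sizes

The default fixture is a 1 Mb nuclear genome (4 × 250 kb) plus a 20 kb
organellar contig, 48 libraries × 50,000 reads, and a 4,000-species
background pool.  The full pipeline (simulation through expression
profiling) completes in roughly two minutes on one CPU; the folding stage
dominates and scales with the number of distinct tags passing the prefilter
and complementarity screen.

## Known limitations

- The exact mapper is a seed-and-verify k-mer index (k = 18), adequate for
  desk-scale genomes; production-scale data would use an FM-index aligner
  and the SAM ingestion path.
- The complementarity pre-screen can, in principle, skip a genuine precursor
  whose duplex is dominated by G:U pairs; disable it (`prescreen_max_edits:
  0`) when that matters.
- Bias-region widening (150 nt) can absorb reads from a closely adjacent
  independent locus; planted loci are spaced to avoid this, and real
  genomes rarely place independent sRNA loci within 75 nt of a hairpin.
- Specificity labels consider factor levels independently; interaction
  specificity (e.g. "only in cultivar × vineyard cell") is visible in the
  Venn cells but not labeled.
- Differential expression is exported, not computed.
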