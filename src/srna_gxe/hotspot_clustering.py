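"""Static clustering: genome-wide 500-bp sRNA hotspot detection and G x E ratios.

The nuclear genome is tiled into adjacent, non-overlapping fixed-width
windows ("clusters").  Per library, the hits-normalized abundance (HNA) of
every 21-24-nt alignment is summed into the window containing the
alignment's start (5'-most genomic coordinate), giving the cluster
abundance.  Replicates are averaged per condition before any threshold: a
cluster is expressed when its averaged abundance reaches ``threshold`` HNA
(default 30), and cultivar ratios within an environment/stage pair require
both sides >= ``min_each`` (5), their sum > ``min_sum`` (30) and a fold
change >= ``fc`` (2), binned at >=2 / >=10 / >=50.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .normalization import log_transform, pearson_distance
from .sequence_io import FeatureTable, Genome, SampleInfo
from .treeio import linkage_to_newick

FOLD_BINS = (2.0, 10.0, 50.0)


@dataclass
class WindowIndex:
    """Adjacent fixed-width windows covering every nuclear chromosome."""

    windows: pd.DataFrame  # chrom, start, end
    width: int
    chrom_lengths: dict[str, int]

    def __len__(self) -> int:
        return len(self.windows)


def tile_genome(genome: Genome, width: int = 500) -> WindowIndex:
    if width < 1:
        raise ValueError("width must be >= 1")
    rows = []
    lengths = {}
    for name in genome.nuclear_names:
        n = len(genome.sequences[name])
        lengths[name] = n
        for s in range(0, n, width):
            rows.append((name, s, min(s + width, n)))
    return WindowIndex(pd.DataFrame(rows, columns=["chrom", "start", "end"]), width, lengths)


def accumulate(
    windows: WindowIndex,
    hna_tables: Mapping[str, pd.DataFrame],
    size_min: int = 21,
    size_max: int = 24,
) -> pd.DataFrame:
    """Per-replicate cluster abundances.

    ``hna_tables`` maps library code -> alignment-level HNA table (as from
    :func:`srna_gxe.normalization.locus_abundances`).  Each qualifying
    alignment contributes its HNA to exactly one window, the one containing
    its start coordinate.  Returns a dense DataFrame indexed by
    (chrom, start) with one column per library.
    """
    width = windows.width
    index = pd.MultiIndex.from_frame(windows.windows[["chrom", "start"]])
    out = pd.DataFrame(0.0, index=index, columns=list(hna_tables))
    for code, table in hna_tables.items():
        if table.empty:
            continue
        sub = table[(table.length >= size_min) & (table.length <= size_max)]
        sub = sub[sub.chrom.isin(windows.chrom_lengths)]
        if sub.empty:
            continue
        limits = sub.chrom.map(windows.chrom_lengths)
        if (sub.start >= limits).any() or (sub.start < 0).any():
            bad = sub[sub.start >= limits].iloc[0]
            raise ValueError(f"alignment beyond chromosome end: {bad.chrom}:{bad.start}")
        wstart = (sub.start // width) * width
        summed = sub.hna.groupby([sub.chrom, wstart]).sum()
        summed.index.names = ["chrom", "start"]
        out[code] = summed.reindex(index, fill_value=0.0)
        out[code] = out[code].fillna(0.0)
    return out


def average_replicates(profiles: pd.DataFrame) -> pd.DataFrame:
    """Average replicate columns; output columns are condition codes
    ``vineyard_cultivar_stage``."""
    groups: dict[str, list[str]] = {}
    for code in profiles.columns:
        info = SampleInfo.from_code(code)
        groups.setdefault("_".join(info.condition), []).append(code)
    return pd.DataFrame(
        {cond: profiles[codes].mean(axis=1) for cond, codes in groups.items()}
    )


def call_expressed(
    sample_profiles: pd.DataFrame, threshold: float = 30.0
) -> tuple[pd.DataFrame, pd.Series, pd.Index]:
    """Expressed flags per sample; a cluster enters the global expressed set
    when it is expressed in at least one sample."""
    flags = sample_profiles >= threshold
    counts = flags.sum(axis=0)
    global_set = flags.index[flags.any(axis=1)]
    return flags, counts, global_set


def annotate_clusters(
    windows: pd.Index | Sequence[tuple[str, int]],
    annotation: FeatureTable,
    width: int = 500,
) -> pd.DataFrame:
    """Genic / TE annotation of windows (>= 1 bp overlap).

    Genic and TE-associated are orthogonal flags; the binary
    genic/intergenic split gives genes precedence.
    """
    rows = []
    for chrom, start in windows:
        end = start + width
        genic = not annotation.overlapping(chrom, start, end, "gene").empty
        te = annotation.overlapping(chrom, start, end)
        te = te[te.type == "transposable_element"]
        te_class = te.feature_class.iloc[0] if not te.empty else None
        rows.append((chrom, start, genic, not te.empty, te_class))
    df = pd.DataFrame(rows, columns=["chrom", "start", "genic", "te", "te_class"])
    return df.set_index(["chrom", "start"])


def annotation_summary(flags: pd.DataFrame, annot: pd.DataFrame) -> pd.DataFrame:
    """Per-sample counts of expressed clusters by genic/intergenic and TE."""
    rows = []
    for sample in flags.columns:
        idx = flags.index[flags[sample]]
        sub = annot.loc[idx]
        n = len(sub)
        rows.append(
            dict(
                sample=sample,
                expressed=n,
                genic=int(sub.genic.sum()),
                intergenic=int((~sub.genic).sum()),
                te_associated=int(sub.te.sum()),
                te_fraction=float(sub.te.mean()) if n else 0.0,
            )
        )
    return pd.DataFrame(rows).set_index("sample")


def specificity_sets(
    flags: pd.DataFrame, grouping: str
) -> tuple[dict[tuple[str, ...], int], dict[str, int]]:
    """Venn cells over one factor (``vineyard`` | ``cultivar`` | ``stage``).

    A cluster is group-specific iff expressed in >= 1 sample of the group and
    in no sample outside it.  Returns (cell -> count, level -> specific count);
    cells are sorted tuples of factor levels.
    """
    field_idx = {"vineyard": 0, "cultivar": 1, "stage": 2}[grouping]
    level_of = {c: c.split("_")[field_idx] for c in flags.columns}
    levels = sorted(set(level_of.values()))
    if len(levels) < 2:
        raise ValueError(f"grouping {grouping!r} has a single level")
    cells: dict[tuple[str, ...], int] = {}
    for _, row in flags.iterrows():
        present = tuple(sorted({level_of[c] for c in flags.columns if row[c]}))
        if present:
            cells[present] = cells.get(present, 0) + 1
    specific = {lv: cells.get((lv,), 0) for lv in levels}
    return cells, specific


def ratio_analysis(
    sample_profiles: pd.DataFrame,
    numerator: str = "CS",
    denominator: str = "SG",
    min_each: float = 5.0,
    min_sum: float = 30.0,
    fc: float = 2.0,
) -> pd.DataFrame:
    """Cultivar ratio records per environment x stage.

    For each window and each (vineyard, stage) with both cultivars present,
    emits a record when A >= min_each, B >= min_each, A + B > min_sum and
    max/min >= fc.  Columns: chrom, start, vineyard, stage, a, b, fold,
    direction (``up-in-A``/``up-in-B``), bin (largest of 2/10/50 reached).
    """
    pairs: dict[tuple[str, str], dict[str, str]] = {}
    for cond in sample_profiles.columns:
        v, c, s = cond.split("_")
        pairs.setdefault((v, s), {})[c] = cond
    records = []
    for (v, s), sides in sorted(pairs.items()):
        if numerator not in sides or denominator not in sides:
            continue
        a = sample_profiles[sides[numerator]]
        b = sample_profiles[sides[denominator]]
        eligible = (a >= min_each) & (b >= min_each) & (a + b > min_sum)
        hi = np.maximum(a, b)
        lo = np.minimum(a, b)
        fold = hi / lo.where(lo > 0)
        keep = eligible & (fold >= fc)
        for (chrom, start), av, bv, fv in zip(
            sample_profiles.index[keep], a[keep], b[keep], fold[keep]
        ):
            top = max(t for t in FOLD_BINS if fv >= t)
            records.append(
                (chrom, start, v, s, av, bv, fv,
                 "up-in-A" if av > bv else "up-in-B", top)
            )
    return pd.DataFrame(
        records,
        columns=["chrom", "start", "vineyard", "stage", "a", "b", "fold", "direction", "bin"],
    )


def fold_bin_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Cumulative fold-bin counts per vineyard/stage/direction (>=2, >=10, >=50)."""
    rows = []
    for (v, s, d), sub in records.groupby(["vineyard", "stage", "direction"]):
        row = dict(vineyard=v, stage=s, direction=d)
        for t in FOLD_BINS:
            row[f"ge{int(t)}"] = int((sub.fold >= t).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def cluster_composition(
    hna_table: pd.DataFrame, chrom: str, start: int, end: int, phase: int = 21
) -> dict:
    """Descriptive size/strand/register composition of one window.

    Register fraction: share of 21-nt HNA whose 5' positions fall in the
    modal ``phase``-class (ties broken toward the smallest offset).  A
    diagnostic, not a phasing statistic.
    """
    sub = hna_table[(hna_table.chrom == chrom) & (hna_table.start >= start) & (hna_table.start < end)]
    if sub.empty:
        return dict(size_histogram={}, sense_fraction=0.0, register_fraction=0.0, total_hna=0.0)
    total = float(sub.hna.sum())
    hist = (sub.groupby("length").hna.sum() / total).to_dict()
    sense = float(sub.loc[sub.strand == "+", "hna"].sum() / total)
    p21 = sub[sub.length == phase]
    if p21.empty:
        register = 0.0
    else:
        five = np.where(p21.strand == "+", p21.start, p21.end - 1)
        classes = pd.Series(p21.hna.values, index=five % phase).groupby(level=0).sum()
        modal = classes[classes == classes.max()].index.min()
        register = float(classes[modal] / classes.sum())
    return dict(
        size_histogram={int(k): float(v) for k, v in hist.items()},
        sense_fraction=sense,
        register_fraction=register,
        total_hna=total,
    )


def cluster_dendrogram(
    sample_profiles: pd.DataFrame,
    expressed: pd.Index | None = None,
    method: str = "complete",
) -> tuple[str, pd.DataFrame, np.ndarray]:
    """Hierarchical tree of samples from log10(1+HNA) profile correlations.

    Returns (newick, correlation matrix, scipy linkage matrix).
    """
    data = sample_profiles if expressed is None else sample_profiles.loc[expressed]
    if data.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    mat = log_transform(data.to_numpy(dtype=float))
    stds = mat.std(axis=0)
    for j, s in enumerate(stds):
        if s == 0:
            raise ValueError(f"constant profile for sample {data.columns[j]}")
    corr = np.corrcoef(mat, rowvar=False)
    dist = pearson_distance(corr)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    z = linkage(squareform(dist, checks=False), method=method)
    newick = linkage_to_newick(z, list(data.columns))
    corr_df = pd.DataFrame(corr, index=data.columns, columns=data.columns)
    return newick, corr_df, z


def expressed_to_bed(flags: pd.DataFrame, width: int, path) -> None:
    """Write the global expressed set as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for (chrom, start), row in flags.iterrows():
            if row.any():
                fh.write(f"{chrom}\t{start}\t{start + width}\tcluster\n")
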