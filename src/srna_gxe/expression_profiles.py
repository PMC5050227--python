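"""Mature-miRNA expression matrices, expressed/specific calls and dendrograms.

Quantification is by exact mature sequence (multi-locus families share one
mature), in TP4M.  A miRNA is expressed in a condition (vineyard x cultivar
x stage) when both biological replicates reach the threshold (default 10
TP4M); it is vineyard-/cultivar-/stage-specific when every condition where
it is expressed shares that factor level.  A companion raw-count matrix per
precursor locus is exported for external differential-expression tools.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .mirna_discovery import ReportedMiRNA
from .normalization import log_transform, pearson_distance
from .sequence_io import Alignment, ReadLibrary, SampleInfo
from .treeio import linkage_to_newick

FACTORS = ("vineyard", "cultivar", "stage")


def build_matrix(
    matures: Iterable[str],
    normalized: Mapping[str, Mapping[str, float]],
) -> pd.DataFrame:
    """TP4M per mature sequence per library (exact-sequence accounting;
    absent tags are 0)."""
    codes = list(normalized)
    rows = {m: [normalized[c].get(m, 0.0) for c in codes] for m in matures}
    return pd.DataFrame.from_dict(rows, orient="index", columns=codes)


def precursor_raw_counts(
    reported: Iterable[ReportedMiRNA],
    libraries: Mapping[str, ReadLibrary],
    alignments: Mapping[str, list[Alignment]],
) -> pd.DataFrame:
    """Raw read counts per precursor locus per library: the sum of raw counts
    of every tag aligning fully within the precursor coordinates.  This is
    the export contract for external count-based DGE tools."""
    loci = {}
    for r in reported:
        for p in r.loci:
            loci[f"{p.chrom}:{p.start}-{p.end}({p.strand})"] = p
    tag_loci: dict[str, list[str]] = {}
    for tag, alns in alignments.items():
        for name, p in loci.items():
            for a in alns:
                if a.chrom == p.chrom and a.start >= p.start and a.end <= p.end:
                    tag_loci.setdefault(tag, []).append(name)
                    break
    codes = list(libraries)
    out = pd.DataFrame(0, index=sorted(loci), columns=codes, dtype=int)
    for tag, names in tag_loci.items():
        for code in codes:
            raw = libraries[code].tags.get(tag, 0)
            if raw:
                for name in names:
                    out.loc[name, code] += raw
    return out


def replicate_pairs(columns: Iterable[str]) -> dict[str, list[str]]:
    """Condition code -> its replicate library codes."""
    pairs: dict[str, list[str]] = {}
    for code in columns:
        info = SampleInfo.from_code(code)
        pairs.setdefault("_".join(info.condition), []).append(code)
    return pairs


def call_expressed(
    matrix: pd.DataFrame, threshold: float = 10.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Expressed calls per condition (both replicates >= threshold) and
    per-library expressed counts (single-library >= threshold, the
    figure-style per-library report)."""
    pairs = replicate_pairs(matrix.columns)
    calls = {}
    for cond, codes in pairs.items():
        if len(codes) < 2:
            warnings.warn(f"condition {cond} lacks a replicate; skipped", stacklevel=2)
            continue
        calls[cond] = (matrix[codes] >= threshold).all(axis=1)
    flags = pd.DataFrame(calls)
    per_library = (matrix >= threshold).sum(axis=0)
    return flags, per_library


def specificity(
    flags: pd.DataFrame,
) -> tuple[pd.Series, dict[str, dict[tuple[str, ...], int]]]:
    """Specificity labels and per-factor Venn cells over the expressed set.

    Labels: ``vineyard:Ric``-style when all expressed conditions share the
    level, ``ubiquitous`` when expressed in every condition, else ``none``.
    """
    cond_levels = {c: dict(zip(FACTORS, c.split("_"))) for c in flags.columns}
    labels = {}
    venn: dict[str, dict[tuple[str, ...], int]] = {f: {} for f in FACTORS}
    expressed_any = flags.index[flags.any(axis=1)]
    for mature in expressed_any:
        conds = [c for c in flags.columns if flags.at[mature, c]]
        label = "none"
        if len(conds) == len(flags.columns):
            label = "ubiquitous"
        else:
            for f in FACTORS:
                levels = {cond_levels[c][f] for c in conds}
                if len(levels) == 1:
                    label = f"{f}:{levels.pop()}"
                    break
        labels[mature] = label
        for f in FACTORS:
            cell = tuple(sorted({cond_levels[c][f] for c in conds}))
            venn[f][cell] = venn[f].get(cell, 0) + 1
    return pd.Series(labels, dtype=object), venn


def correlate_and_cluster(
    matrix: pd.DataFrame,
    sample_method: str = "complete",
    row_method: str = "average",
) -> tuple[str, pd.DataFrame, list]:
    """Sample dendrogram and heatmap row order from log10(1+TP4M) profiles.

    Samples are clustered on Pearson distances between library columns
    (default complete linkage); heatmap row order comes from average-linkage
    clustering of the matures.  Returns (newick, correlation matrix,
    row order as a list of mature sequences).
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    mat = log_transform(matrix.to_numpy(dtype=float))
    for j, code in enumerate(matrix.columns):
        if not np.any(mat[:, j]):
            raise ValueError(f"all-zero library {code}")
        if mat[:, j].std() == 0:
            raise ValueError(f"constant profile for library {code}")
    corr = np.corrcoef(mat, rowvar=False)
    dist = np.clip(pearson_distance(corr), 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method=sample_method)
    newick = linkage_to_newick(z, list(matrix.columns))
    corr_df = pd.DataFrame(corr, index=matrix.columns, columns=matrix.columns)

    if matrix.shape[0] >= 3:
        with np.errstate(invalid="ignore"):
            rcorr = np.corrcoef(mat, rowvar=True)
        rcorr = np.nan_to_num(rcorr, nan=0.0)  # constant rows: uncorrelated
        rdist = np.clip(1.0 - rcorr, 0.0, None)
        np.fill_diagonal(rdist, 0.0)
        rz = linkage(squareform(rdist, checks=False), method=row_method)
        order = [matrix.index[i] for i in leaves_list(rz)]
    else:
        order = list(matrix.index)
    return newick, corr_df, order
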