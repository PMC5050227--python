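"""TP4M / HNA normalization.

TP4M (transcripts per 4 million) linearly scales a tag's raw count by the
library's retained mappable total::

    TP4M = raw / (total genome matches - structural-RNA/organellar matches) * 4e6

HNA (hits-normalized abundance) divides a tag's TP4M evenly over its perfect
genomic matches::

    HNA = TP4M / hits

so that a tag mapping to h loci contributes TP4M/h at each locus and the
total normalized mass is conserved under multi-mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .sequence_io import Alignment, BlacklistPartition, ReadLibrary

N_BASE = 4_000_000


@dataclass
class LibraryDenominator:
    library_code: str
    value: int

    @property
    def usable(self) -> bool:
        return self.value > 0


@dataclass
class NormalizedLibrary:
    library_code: str
    tp4m: dict[str, float]  # retained tag -> TP4M

    @property
    def total(self) -> float:
        return float(sum(self.tp4m.values()))


def compute_denominator(
    library: ReadLibrary,
    partition: BlacklistPartition,
    mode: str = "reads",
    hits: Mapping[str, int] | None = None,
) -> LibraryDenominator:
    """Total retained (mapped, non-blacklist, nuclear) raw counts.

    In the default ``reads`` mode each tag's raw count enters once regardless
    of its number of genomic hits, which makes per-library TP4M totals equal
    4,000,000 exactly.  In ``alignments`` mode the count is weighted by the
    tag's hit count (every alignment counts), which inflates the denominator
    for repetitive libraries; ``hits`` must then map tag -> hit count.
    """
    if mode == "reads":
        value = sum(library.tags.get(t, 0) for t in partition.retained)
    elif mode == "alignments":
        if hits is None:
            raise ValueError("alignments mode needs per-tag hit counts")
        value = sum(library.tags.get(t, 0) * hits.get(t, 1) for t in partition.retained)
    else:
        raise ValueError(f"unknown denominator_mode {mode!r}")
    return LibraryDenominator(library.code, value)


def tp4m(raw: float, denominator: LibraryDenominator | int) -> float:
    denom = denominator.value if isinstance(denominator, LibraryDenominator) else denominator
    if denom <= 0:
        raise ValueError("library denominator must be positive")
    return raw / denom * N_BASE


def normalize_library(
    library: ReadLibrary,
    partition: BlacklistPartition,
    denominator: LibraryDenominator | None = None,
) -> NormalizedLibrary:
    """TP4M values for every retained tag of a library."""
    denominator = denominator or compute_denominator(library, partition)
    if not denominator.usable:
        raise ValueError(f"{library.code}: empty retained set, library unusable")
    values = {t: tp4m(library.tags[t], denominator) for t in partition.retained}
    return NormalizedLibrary(library.code, values)


def hna(tp4m_value: float, hits: int) -> float:
    if hits < 1:
        raise ValueError("hits must be >= 1")
    return tp4m_value / hits


def locus_abundances(
    normalized: NormalizedLibrary, alignments: Mapping[str, list[Alignment]]
) -> pd.DataFrame:
    """Per-alignment HNA table for one library.

    Columns: tag, chrom, start, end, strand, length, hits, tp4m, hna.
    Only tags present in the normalized (retained) set are emitted.
    """
    rows = []
    for tag, value in normalized.tp4m.items():
        for a in alignments.get(tag, ()):
            rows.append(
                (tag, a.chrom, a.start, a.end, a.strand, len(tag), a.hits, value, value / a.hits)
            )
    return pd.DataFrame(
        rows,
        columns=["tag", "chrom", "start", "end", "strand", "length", "hits", "tp4m", "hna"],
    )


def log_transform(x):
    """log10(1 + x); zero maps to zero, keeping profiles comparable."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    out = np.log10(1.0 + x)
    return float(out) if out.ndim == 0 else out


def pearson_distance(r):
    """Convert a Pearson correlation into a dendrogram distance, 1 - r."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlation outside [-1, 1]")
    out = 1.0 - r
    return float(out) if out.ndim == 0 else out
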