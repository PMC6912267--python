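"""Hierarchical small-RNA annotation and expression quantification.

Reads are collapsed to unique sequences, then annotated by sequential
matching against an ordered database cascade (miRNA, rRNA, tRNA, ensembl,
rfam, piRNA): the first database with a hit assigns the category. Sequences
matching the genome but no database are ``unannotated_genomic`` (the pool
that may harbour unlisted piRNAs); sequences matching nothing are
``unmatched``. Matching is sense-strand substring/equality with an optional
Hamming mismatch tolerance.

Expression is quantified as counts per million retained reads (CPM);
"expressed" molecules are those strictly above a CPM floor.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import read_fastq_sequences
from .types import ReferenceBundle

ANNOTATION_CATEGORIES = (
    "miRNA", "rRNA", "tRNA", "ensembl", "rfam", "piRNA",
    "unannotated_genomic", "unmatched",
)

DEFAULT_LENGTH_WINDOW = (18, 45)


# ---------------------------------------------------------------------------
# Collapsing and CPM
# ---------------------------------------------------------------------------

def collapse_sequences(
    sequences: Iterable[str],
    length_window: tuple[int, int] = DEFAULT_LENGTH_WINDOW,
    sample: str = "sample",
) -> pd.DataFrame:
    """Collapse raw read sequences to a unique-sequence count table.

    Reads outside the closed length window are dropped and tallied in
    ``table.attrs["dropped"]``.
    """
    lo, hi = length_window
    if lo > hi:
        raise ValueError("length window min must not exceed max")
    counts: dict[str, int] = {}
    dropped = 0
    for seq in sequences:
        if lo <= len(seq) <= hi:
            counts[seq] = counts.get(seq, 0) + 1
        else:
            dropped += 1
    table = pd.DataFrame(
        {f"count_{sample}": pd.Series(counts, dtype=int)}
    )
    table.index.name = "sequence"
    table.attrs["dropped"] = dropped
    table.attrs["total_retained"] = int(table[f"count_{sample}"].sum()) if len(table) else 0
    return table


def collapse_reads(
    fastq: str | Path,
    length_window: tuple[int, int] = DEFAULT_LENGTH_WINDOW,
    sample: str | None = None,
) -> pd.DataFrame:
    """Collapse a FASTQ library (parse errors carry the line number)."""
    sample = sample or Path(fastq).stem
    return collapse_sequences(read_fastq_sequences(fastq), length_window, sample)


def counts_to_table(counts: pd.Series, sample: str = "sample",
                    length_window: tuple[int, int] | None = None) -> pd.DataFrame:
    """Wrap a per-sequence count Series as a collapsed-read table."""
    counts = counts[counts > 0]
    if length_window is not None:
        lo, hi = length_window
        lengths = counts.index.str.len()
        keep = (lengths >= lo) & (lengths <= hi)
        dropped = int(counts[~keep].sum())
        counts = counts[keep]
    else:
        dropped = 0
    table = pd.DataFrame({f"count_{sample}": counts.astype(int)})
    table.index.name = "sequence"
    table.attrs["dropped"] = dropped
    table.attrs["total_retained"] = int(counts.sum())
    return table


def merge_tables(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Outer-join collapsed tables from several samples (missing -> 0)."""
    pieces = []
    for _, t in tables.items():
        pieces.append(t[[c for c in t.columns if c.startswith("count_")]])
    merged = pd.concat(pieces, axis=1).fillna(0).astype(int)
    merged.index.name = "sequence"
    return merged


def compute_cpm(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``cpm_<sample>`` column per ``count_<sample>`` column.

    CPM = count * 1e6 / total retained reads of the sample; raises on a
    zero-total sample.
    """
    out = table.copy()
    out.attrs.update(table.attrs)
    for col in table.columns:
        if not col.startswith("count_"):
            continue
        total = table[col].sum()
        if total <= 0:
            raise ValueError(f"sample {col[6:]!r} has zero retained reads")
        out[f"cpm_{col[6:]}"] = table[col] * 1e6 / total
    return out


def filter_expressed(table: pd.DataFrame, cpm_min: float = 0.1) -> pd.DataFrame:
    """Keep sequences whose CPM is strictly above ``cpm_min`` in at least one
    sample. The number removed is reported in ``attrs["filtered_out"]``."""
    cpm_cols = [c for c in table.columns if c.startswith("cpm_")]
    if not cpm_cols:
        raise ValueError("compute_cpm must run before filter_expressed")
    keep = (table[cpm_cols] > cpm_min).any(axis=1)
    out = table[keep].copy()
    out.attrs.update(table.attrs)
    out.attrs["filtered_out"] = int((~keep).sum())
    return out


# ---------------------------------------------------------------------------
# Cascade annotation
# ---------------------------------------------------------------------------

def _hamming_contains(haystack: str, needle: str, k: int) -> bool:
    n, m = len(haystack), len(needle)
    if m > n:
        return False
    hay = np.frombuffer(haystack.encode(), dtype="S1")
    ned = np.frombuffer(needle.encode(), dtype="S1")
    for off in range(n - m + 1):
        if int((hay[off:off + m] != ned).sum()) <= k:
            return True
    return False


def _match_db(seq: str, db: Mapping[str, str], k: int) -> str | None:
    """Lowest-lexicographic entry id containing ``seq`` (sense strand) at
    <= k mismatches, or None."""
    hits = []
    for entry_id in db:
        entry = db[entry_id]
        if (seq in entry) if k == 0 else _hamming_contains(entry, seq, k):
            hits.append(entry_id)
    return min(hits) if hits else None


def _match_genome(seq: str, genome: Mapping[str, str], k: int) -> bool:
    if k == 0:
        return any(seq in chrom for chrom in genome.values())
    return any(_hamming_contains(chrom, seq, k) for chrom in genome.values())


def cascade_annotate(
    reads: pd.DataFrame | Sequence[str],
    bundle: ReferenceBundle,
    mismatches: int = 0,
) -> pd.DataFrame:
    """Assign each sequence the first cascade level with a database hit.

    Returns a DataFrame indexed by sequence with ``category``, ``db_hit_id``
    and ``genome_matched`` columns; raises on an empty bundle.
    """
    if not bundle.db_list or not bundle.genome:
        raise ValueError("reference bundle has no databases or genome")
    if isinstance(reads, pd.DataFrame):
        sequences = list(reads.index)
    else:
        sequences = list(reads)

    categories, hit_ids, genome_flags = [], [], []
    for seq in sequences:
        category, hit = None, ""
        for db_name, db in bundle.db_list:
            found = _match_db(seq, db, mismatches)
            if found is not None:
                category, hit = db_name, found
                break
        in_genome = _match_genome(seq, bundle.genome, mismatches)
        if category is None:
            category = "unannotated_genomic" if in_genome else "unmatched"
        categories.append(category)
        hit_ids.append(hit)
        genome_flags.append(in_genome)

    ann = pd.DataFrame(
        {"category": categories, "db_hit_id": hit_ids, "genome_matched": genome_flags},
        index=pd.Index(sequences, name="sequence"),
    )
    if isinstance(reads, pd.DataFrame):
        ann = pd.concat([ann, reads], axis=1)
        ann.attrs.update(reads.attrs)
    return ann


def category_composition(annotated: pd.DataFrame) -> pd.DataFrame:
    """Fraction of retained reads per annotation category and sample
    (columns sum to 1)."""
    count_cols = [c for c in annotated.columns if c.startswith("count_")]
    if "category" not in annotated.columns or not count_cols:
        raise ValueError("needs an annotated table with count columns")
    sums = annotated.groupby("category")[count_cols].sum()
    frac = sums / sums.sum(axis=0)
    frac.columns = [c[6:] for c in count_cols]
    return frac.reindex(ANNOTATION_CATEGORIES).dropna(how="all").fillna(0.0)
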