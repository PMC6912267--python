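"""piRISC mRNA co-capture: long-read extraction, transcript mapping,
enrichment testing, and piRNA-target complementarity pairing.

Because the RIP protocol purifies intact PIWIL1-piRNA-target complexes
without crosslinking, mRNA fragments of the engaged targets (46-75 nt, the
longest reads in a small-RNA library) co-sequence with the piRNAs. Mapping
those reads to transcripts and re-running the enrichment analysis at the
transcript level yields physically captured targets; pairing then requires
antisense complementarity between a bound piRNA and the captured transcript:
perfect Watson-Crick pairing across the piRNA seed (positions 2-11 by
default) and at least 80% complementarity overall, with G:U wobble pairs
tolerated outside the seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotate import collapse_sequences
from .io import read_fastq_sequences
from .types import TargetSite, TranscriptRecord
from . import rip

LONG_READ_WINDOW = (46, 75)

_COMPLEMENT = {("A", "T"), ("C", "G"), ("G", "C"), ("T", "A")}
_WOBBLE = {("G", "T"), ("T", "G")}  # rG:U and rU:G pairs in DNA alphabet


# ---------------------------------------------------------------------------
# Long-read extraction and transcript mapping
# ---------------------------------------------------------------------------

def extract_long_reads(
    fastq: str | Path, window: tuple[int, int] = LONG_READ_WINDOW,
    sample: str | None = None,
) -> pd.DataFrame:
    """Collapsed table of reads whose length lies in the closed window."""
    sample = sample or Path(fastq).stem
    return collapse_sequences(read_fastq_sequences(fastq), window, sample)


def extract_long_reads_table(
    counts: pd.DataFrame, window: tuple[int, int] = LONG_READ_WINDOW
) -> pd.DataFrame:
    """Length-window filter on an existing collapsed count matrix."""
    lo, hi = window
    lengths = counts.index.str.len()
    return counts[(lengths >= lo) & (lengths <= hi)]


def map_to_transcripts(
    reads: pd.DataFrame,
    transcripts: Sequence[TranscriptRecord],
    mismatches: int = 0,
    fractional: bool = True,
) -> pd.DataFrame:
    """Per-transcript count matrix from a collapsed long-read table.

    Each read is assigned to every transcript containing it as a sense-strand
    substring (optionally at <= ``mismatches`` Hamming distance); reads
    hitting n transcripts contribute 1/n to each (``fractional=False`` counts
    1 everywhere).
    """
    if not transcripts:
        raise ValueError("transcript set is empty")
    from .annotate import _hamming_contains  # shared matcher

    count_cols = [c for c in reads.columns if c.startswith("count_")]
    values = reads[count_cols].to_numpy(dtype=float)
    acc = np.zeros((len(transcripts), len(count_cols)))
    row_of = {t.transcript_id: i for i, t in enumerate(transcripts)}
    for j, seq in enumerate(reads.index):
        hits = []
        for t in transcripts:
            if (seq in t.sequence) if mismatches == 0 else _hamming_contains(
                t.sequence, seq, mismatches
            ):
                hits.append(t.transcript_id)
        if not hits:
            continue
        weight = 1.0 / len(hits) if fractional else 1.0
        for tid in hits:
            acc[row_of[tid]] += values[j] * weight
    return pd.DataFrame(
        acc,
        index=pd.Index([t.transcript_id for t in transcripts], name="transcript_id"),
        columns=count_cols,
    )


def test_transcript_enrichment(
    matrix: pd.DataFrame,
    classes: dict[str, str],
    lfc_min: float = rip.DEFAULT_LFC_MIN,
    fdr_max: float = rip.DEFAULT_FDR_MAX,
    exclude_igg: bool = False,
    normalization: str = "total",
) -> pd.DataFrame:
    """Transcript-level bound-set determination, delegating to the same
    enrichment/exclusion/intersection machinery used for small RNAs.

    ``matrix`` columns must be ``count_<sample>`` with samples matching the
    RIP design; values may be fractional (rounded for the exact test).
    Normalization defaults to plain totals because the co-captured fragment
    pool is small and sparse.
    """
    counts = matrix.copy()
    counts.columns = [c[6:] if c.startswith("count_") else c for c in counts.columns]
    counts = counts.round().astype(int)
    counts = counts.loc[:, [c for c in counts.columns if c in classes]]
    return rip.identify_bound(
        counts, {c: classes[c] for c in counts.columns},
        lfc_min=lfc_min, fdr_max=fdr_max, exclude_igg=exclude_igg,
        normalization=normalization,
    )


# ---------------------------------------------------------------------------
# Complementarity scanning
# ---------------------------------------------------------------------------

def scan_target_sites(
    pirna: str,
    transcript: TranscriptRecord,
    seed_start: int = 2,
    seed_end: int = 11,
    min_complementarity: float = 0.8,
    wobble: bool = True,
) -> list[TargetSite]:
    """All antisense complementarity sites of one piRNA on one transcript.

    The piRNA pairs the transcript antiparallel: piRNA position ``i``
    (1-based from its 5' end) faces transcript position
    ``start + len - i``. Seed positions (``seed_start``..``seed_end``,
    1-based, inclusive) must pair Watson-Crick; outside the seed G:U wobble
    counts as paired when ``wobble`` is set; overall paired fraction must
    reach ``min_complementarity``. The site's region label comes from its
    5'-most transcript position.
    """
    if not 20 <= len(pirna) <= 35:
        raise ValueError("piRNA length must be within 20-35 nt")
    L = len(pirna)
    tseq = transcript.sequence
    sites: list[TargetSite] = []
    seed_idx = set(range(seed_start - 1, seed_end))  # 0-based piRNA indices
    for start in range(len(tseq) - L + 1):
        mism = 0
        seed_ok = True
        for i in range(L):
            pair = (pirna[i], tseq[start + L - 1 - i])
            if pair in _COMPLEMENT:
                continue
            if i in seed_idx:
                seed_ok = False
                break
            if wobble and pair in _WOBBLE:
                continue
            mism += 1
        if not seed_ok:
            continue
        if (L - mism) / L >= min_complementarity:
            sites.append(
                TargetSite(
                    pirna_sequence=pirna,
                    transcript_id=transcript.transcript_id,
                    start=start,
                    region=transcript.region_of(start),
                    mismatches=mism,
                    seed_perfect=True,
                )
            )
    return sites


def pair_pirna_targets(
    bound_pirnas: Iterable[str],
    enriched_transcripts: Iterable[str],
    transcripts: Sequence[TranscriptRecord],
    fold_enrichment: pd.DataFrame | None = None,
    **scan_params,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Pair bound piRNAs with enriched transcripts via complementarity.

    Returns ``(pairs, sites, region_summary)``: one pair row per
    (piRNA, transcript) with at least one site, every site found, and total
    site counts per region. Output is restricted to the Cartesian product of
    the two input sets by construction.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    enriched = [tid for tid in enriched_transcripts if tid in by_id]
    pair_rows, site_rows = [], []
    summary = {"utr5": 0, "cds": 0, "utr3": 0}
    for pirna in bound_pirnas:
        for tid in enriched:
            found = scan_target_sites(pirna, by_id[tid], **scan_params)
            if not found:
                continue
            for s in found:
                summary[s.region] += 1
                site_rows.append(
                    {"pirna_sequence": pirna, "transcript_id": tid,
                     "start": s.start, "region": s.region,
                     "mismatches": s.mismatches, "seed_perfect": s.seed_perfect}
                )
            row = {
                "pirna_sequence": pirna,
                "transcript_id": tid,
                "n_sites": len(found),
                "regions": ",".join(sorted({s.region for s in found})),
            }
            if fold_enrichment is not None and tid in fold_enrichment.index:
                for ab in ("IP1", "IP2"):
                    col = f"factor_{ab}"
                    if col in fold_enrichment.columns:
                        row[f"fold_enrichment_{ab}"] = float(
                            fold_enrichment.loc[tid, col]
                        )
            pair_rows.append(row)
    if pair_rows:
        pairs = pd.DataFrame(pair_rows)
    else:
        pairs = pd.DataFrame(
            columns=["pirna_sequence", "transcript_id", "n_sites", "regions"]
        )
    sites = pd.DataFrame(
        site_rows,
        columns=["pirna_sequence", "transcript_id", "start", "region",
                 "mismatches", "seed_perfect"],
    )
    return pairs, sites, summary
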