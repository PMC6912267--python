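"""File-format helpers: FASTQ (4-line records), FASTA via Biopython, TSV via
pandas.

The FASTQ reader is deliberately local: the collapse step must report the
offending line number on a malformed record, which generic parsers do not
surface.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FastqParseError(ValueError):
    """Malformed FASTQ record; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def read_fastq_sequences(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a 4-line-record FASTQ file."""
    path = Path(path)
    with path.open() as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise FastqParseError("header must start with '@'", lineno)
            seq = fh.readline()
            if not seq:
                raise FastqParseError("truncated record: missing sequence", lineno + 1)
            lineno += 1
            seq = seq.strip()
            if not seq or any(c not in "ACGTUN" for c in seq.upper()):
                raise FastqParseError("invalid sequence characters", lineno)
            plus = fh.readline()
            if not plus:
                raise FastqParseError("truncated record: missing '+' line", lineno + 1)
            lineno += 1
            if not plus.startswith("+"):
                raise FastqParseError("separator must start with '+'", lineno)
            qual = fh.readline()
            if not qual:
                raise FastqParseError("truncated record: missing qualities", lineno + 1)
            lineno += 1
            if len(qual.strip()) != len(seq):
                raise FastqParseError("quality length differs from sequence", lineno)
            yield seq.upper().replace("U", "T")


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]]) -> None:
    """Write (read_id, sequence) pairs with constant 'I' qualities."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_fasta(path: str | Path, entries: Iterable[tuple[str, str]]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in entries
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
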