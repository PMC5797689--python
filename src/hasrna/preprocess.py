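"""Raw sRNA-seq reads -> per-library unique-sequence raw count tables.

Three steps, applied per read: 3' adapter removal (exact match of a read
suffix against an adapter prefix), quality truncation at the first low-quality
base, and collapsing of identical sequences into counts, keeping only reads of
15-40 nt without ambiguous bases.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .core import CountMatrix, counts_to_matrix

DEFAULT_MIN_PHRED = 30  # error probability 1e-3, i.e. 99.9% base accuracy
DEFAULT_MIN_LEN = 15
DEFAULT_MAX_LEN = 40


@dataclass
class ReadLibrary:
    library_id: str
    records: list[tuple[str, list[int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for seq, qual in self.records:
            if len(seq) != len(qual):
                raise ValueError("sequence and quality lengths must match")


@dataclass
class RawCounts:
    library_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.counts.values())

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sequence\tcount\n")
            for seq in sorted(self.counts):
                fh.write(f"{seq}\t{self.counts[seq]}\n")


def strip_adapter(read: str, adapter: str, min_overlap: int = 5) -> str:
    """Remove the longest read suffix that exactly matches a prefix of the adapter.

    The earliest position at which the remainder of the read equals a prefix of
    the adapter (of at least ``min_overlap`` bases) is taken as the adapter
    start; a full internal adapter occurrence removes everything downstream of
    it.  Without a match the read is returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    n, la = len(read), len(adapter)
    for i in range(0, n - min_overlap + 1):
        m = min(n - i, la)
        if read[i : i + m] == adapter[:m]:
            return read[:i]
    return read


def quality_trim(read: str, quals: Iterable[int], min_phred: int = DEFAULT_MIN_PHRED) -> str:
    """Truncate the read at the first base (5'->3') with Phred < ``min_phred``."""
    if min_phred < 0:
        raise ValueError("min_phred must be >= 0")
    for i, q in enumerate(quals):
        if q < min_phred:
            return read[:i]
    return read


def collapse(
    reads: Iterable[str],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> dict[str, int]:
    """Merge identical sequences into counts; drop reads outside the length
    window or containing N."""
    counter: Counter[str] = Counter()
    for seq in reads:
        if min_len <= len(seq) <= max_len and "N" not in seq:
            counter[seq] += 1
    return dict(counter)


def preprocess_library(
    library: ReadLibrary,
    adapter: str,
    min_overlap: int = 5,
    min_phred: int = DEFAULT_MIN_PHRED,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> RawCounts:
    """Adapter-strip, quality-trim and collapse one read library."""
    trimmed = (
        quality_trim(strip_adapter(seq, adapter, min_overlap), qual, min_phred)
        for seq, qual in library.records
    )
    return RawCounts(library.library_id, collapse(trimmed, min_len, max_len))


def read_fastq(path: str | Path, library_id: str | None = None) -> ReadLibrary:
    """Read a (plain or gzipped) Sanger Phred+33 FASTQ file into a ReadLibrary."""
    path = Path(path)
    if library_id is None:
        library_id = path.name.split(".")[0]
    opener = gzip.open if path.suffix == ".gz" else open
    records = []
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            records.append((str(rec.seq).upper(), rec.letter_annotations["phred_quality"]))
    return ReadLibrary(library_id, records)


def preprocess_fastqs(
    paths: Iterable[str | Path],
    adapter: str,
    **kwargs,
) -> CountMatrix:
    """Preprocess several FASTQ files and combine them into a raw CountMatrix."""
    per_lib = {}
    for path in paths:
        lib = read_fastq(path)
        per_lib[lib.library_id] = preprocess_library(lib, adapter, **kwargs).counts
    return counts_to_matrix(per_lib)
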