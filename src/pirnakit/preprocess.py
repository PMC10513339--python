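"""Raw-read processing: 3'-adapter removal, 4N trimming, length filtering.

Raw reads are sequenced as ``[4 random nt][insert][4 random nt][3' adapter]``
capped at the read length of the run. Processing locates the adapter core
(allowing a configurable number of substitutions, default <2 i.e. at most 1),
strips the adapter and the two 4-nt randomized blocks, rejects inserts outside
the configured length window, and collapses identical inserts into a count
table. Every input read receives exactly one fate: ``no_adapter``,
``length_rejected`` or ``kept``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator

from ._sequtil import normalize_rna

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
MIN_CORE_OVERLAP = 10  # shortest adapter prefix accepted when the read ends first
_RANDOM_BLOCK = 4      # randomized bases ligated on each side of the insert


@dataclass(frozen=True)
class RawRead:
    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for read {self.id!r}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"quality length mismatch for read {self.id!r}")


@dataclass
class ProcessedLibrary:
    """Collapsed unique-insert count table plus exact read-fate bookkeeping."""

    library_id: str = "library"
    metadata: dict = field(default_factory=dict)
    counts: Counter = field(default_factory=Counter)
    stats: dict = field(default_factory=lambda: {
        "input": 0, "no_adapter": 0, "length_rejected": 0, "kept": 0})

    def check_conservation(self) -> None:
        s = self.stats
        if s["input"] != s["no_adapter"] + s["length_rejected"] + s["kept"]:
            raise AssertionError(f"fate partition violated: {s}")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("insert\tcount\n")
            for insert in sorted(self.counts):
                fh.write(f"{insert}\t{self.counts[insert]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, library_id: str = "library",
                 metadata: dict | None = None) -> "ProcessedLibrary":
        counts: Counter = Counter()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("insert"):
                raise ValueError("count table must have an 'insert' column header")
            for line in fh:
                insert, n = line.rstrip("\n").split("\t")
                counts[insert] = int(n)
        kept = sum(counts.values())
        return cls(library_id, metadata or {}, counts,
                   {"input": kept, "no_adapter": 0, "length_rejected": 0,
                    "kept": kept})


def trim_adapter(sequence: str, adapter_core: str = DEFAULT_ADAPTER,
                 max_mismatches: int = 1) -> str | None:
    """Strip the 3' adapter and both 4N blocks from one read.

    Scans left to right for the leftmost position where the adapter core (or a
    core prefix of at least ``MIN_CORE_OVERLAP`` nt when the read ends first)
    aligns with at most ``max_mismatches`` substitutions. Returns the insert
    5' of the adapter with the terminal 4 nt removed on each side, or ``None``
    when no adapter is found. A degenerate hit too close to the read start
    yields an empty insert (rejected later by the length filter).
    """
    if not adapter_core:
        raise ValueError("adapter core must be non-empty")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    seq = normalize_rna(sequence)
    n, c = len(seq), len(adapter_core)
    min_overlap = min(c, MIN_CORE_OVERLAP)
    hit = -1
    for j in range(0, n - min_overlap + 1):
        overlap = min(c, n - j)
        mm = 0
        ok = True
        for k in range(overlap):
            if seq[j + k] != adapter_core[k]:
                mm += 1
                if mm > max_mismatches:
                    ok = False
                    break
        if ok:
            hit = j
            break
    if hit == -1:
        return None
    if hit < 2 * _RANDOM_BLOCK:
        return ""
    return seq[_RANDOM_BLOCK: hit - _RANDOM_BLOCK]


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Stream 4-line FASTQ records (gzip transparently supported).

    Malformed records raise ``ValueError`` naming the record index.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lines = [header] + [fh.readline() for _ in range(3)]
            if (not lines[0].startswith("@") or not lines[2].startswith("+")
                    or not lines[3].strip() or not lines[1].strip()):
                raise ValueError(f"malformed FASTQ record at index {idx}")
            seq = lines[1].strip().upper()
            qual = lines[3].strip()
            if len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record at index {idx}")
            yield RawRead(lines[0][1:].split()[0], seq, qual)
            idx += 1


def process_library(reads: Iterable[RawRead | tuple],
                    adapter_core: str = DEFAULT_ADAPTER,
                    max_mismatches: int = 1,
                    min_len: int = 20, max_len: int = 40,
                    library_id: str = "library",
                    metadata: dict | None = None) -> ProcessedLibrary:
    """Trim every read and collapse identical inserts with summed counts."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    lib = ProcessedLibrary(library_id, metadata or {})
    stats = lib.stats
    for read in reads:
        if isinstance(read, tuple):
            read = RawRead(*read)
        stats["input"] += 1
        insert = trim_adapter(read.sequence, adapter_core, max_mismatches)
        if insert is None:
            stats["no_adapter"] += 1
        elif not min_len <= len(insert) <= max_len:
            stats["length_rejected"] += 1
        else:
            stats["kept"] += 1
            lib.counts[insert] += 1
    lib.check_conservation()
    return lib
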