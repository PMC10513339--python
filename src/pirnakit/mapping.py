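"""Placement of collapsed inserts on the reference catalog, and RPM tables.

The aligner enumerates every placement of each unique insert on both strands
of every reference with at most ``max_mismatches`` substitutions (0 or 1),
keeps the placements in the best (minimum-mismatch) stratum and, when several
remain, chooses one uniformly with a seeded generator. Reads are therefore
counted once, never fractionally apportioned.

Normalization follows the small-RNA convention of the field: the denominator
is either the copy-weighted read count on transposon references (rRNA-derived
repeats excluded) or the count on the 10 most abundant miRNA references of
the library. RPM(ref, strand) = 1e6 * reads(ref, strand) / denominator, so in
transposon mode the RPM summed over the non-rRNA transposon references closes
to 1e6.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from ._sequtil import hamming, revcomp, find_all
from .catalog import ReferenceCatalog
from .preprocess import ProcessedLibrary

_SEP = "#"


@dataclass(frozen=True)
class AlignmentRecord:
    """Strand-aware placement of one collapsed insert on a reference.

    ``start``/``end`` are 0-based half-open on the reference. The 5' end is
    ``start`` on the plus strand and ``end - 1`` on the minus strand. The
    stored ``insert`` is the read as sequenced (reverse complement of the
    covered reference interval for minus-strand placements).
    """

    insert: str
    ref_id: str
    strand: str
    start: int
    end: int
    copies: int
    mismatches: int

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class NormalizationFactor:
    library_id: str
    mode: str  # "transposon" | "mirna_top10"
    denominator: float

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError("normalization denominator must be > 0")

    def rpm(self, copy_count: float) -> float:
        return 1e6 * copy_count / self.denominator


class _StrandIndex:
    """Concatenated-sequence index for exact substring lookup on one strand."""

    def __init__(self, seqs: list[tuple[str, str]]):
        starts, ids, lens, parts = [], [], [], []
        pos = 0
        for ref_id, seq in seqs:
            starts.append(pos)
            ids.append(ref_id)
            lens.append(len(seq))
            parts.append(seq)
            pos += len(seq) + 1
        self.concat = _SEP.join(parts)
        self.starts = starts
        self.ids = ids
        self.lens = lens

    def locate(self, concat_pos: int, length: int) -> tuple[str, int] | None:
        """Map a concatenated offset to (ref_id, offset) if fully in-bounds."""
        i = bisect.bisect_right(self.starts, concat_pos) - 1
        off = concat_pos - self.starts[i]
        if off + length > self.lens[i]:
            return None
        return self.ids[i], off


class CatalogIndex:
    """Substring index over both strands of a reference catalog."""

    def __init__(self, catalog: ReferenceCatalog):
        self.catalog = catalog
        self.plus = _StrandIndex([(e.id, e.sequence) for e in catalog.entries])
        self.minus = _StrandIndex([(e.id, revcomp(e.sequence))
                                   for e in catalog.entries])

    def _strand_hits(self, idx: _StrandIndex, insert: str,
                     max_mm: int) -> list[tuple[str, int, int]]:
        """(ref_id, offset-on-indexed-strand, mismatches) placements."""
        n = len(insert)
        hits: dict[tuple[str, int], int] = {}
        for pos in find_all(idx.concat, insert):
            loc = idx.locate(pos, n)
            if loc:
                hits[loc] = 0
        if max_mm >= 1:
            half = n // 2
            for part, shift in ((insert[:half], 0), (insert[half:], half)):
                for pos in find_all(idx.concat, part):
                    start = pos - shift
                    if start < 0 or start + n > len(idx.concat):
                        continue
                    loc = idx.locate(start, n)
                    if loc is None or loc in hits:
                        continue
                    window = idx.concat[start:start + n]
                    mm = hamming(insert, window, limit=max_mm)
                    if mm <= max_mm:
                        hits[loc] = mm
        return [(ref_id, off, mm) for (ref_id, off), mm in hits.items()]

    def placements(self, insert: str, max_mm: int) -> list[AlignmentRecord]:
        """All minimum-mismatch-stratum placements of one insert (copies=1)."""
        n = len(insert)
        found: list[AlignmentRecord] = []
        for ref_id, off, mm in self._strand_hits(self.plus, insert, max_mm):
            found.append(AlignmentRecord(insert, ref_id, "+", off, off + n, 1, mm))
        for ref_id, off, mm in self._strand_hits(self.minus, insert, max_mm):
            ref_len = self.catalog[ref_id].length
            start = ref_len - off - n
            found.append(AlignmentRecord(insert, ref_id, "-", start, start + n,
                                         1, mm))
        if not found:
            return []
        best = min(a.mismatches for a in found)
        return [a for a in found if a.mismatches == best]


def align_reads(library: ProcessedLibrary, catalog: ReferenceCatalog,
                max_mismatches: int = 1, seed: int = 0,
                index: CatalogIndex | None = None
                ) -> tuple[list[AlignmentRecord], int]:
    """Place every unique insert of a processed library on the catalog.

    Returns the chosen alignment records (one per mapped unique insert, with
    its collapsed copy number) and the copy-weighted unmapped count. Inserts
    containing N count as unmapped.
    """
    if max_mismatches not in (0, 1):
        raise ValueError("max_mismatches must be 0 or 1")
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    idx = index or CatalogIndex(catalog)
    rng = np.random.default_rng(seed)
    records: list[AlignmentRecord] = []
    unmapped = 0
    for insert in sorted(library.counts):
        copies = library.counts[insert]
        if "N" in insert:
            unmapped += copies
            continue
        best = idx.placements(insert, max_mismatches)
        if not best:
            unmapped += copies
            continue
        chosen = best[rng.integers(len(best))] if len(best) > 1 else best[0]
        records.append(AlignmentRecord(insert, chosen.ref_id, chosen.strand,
                                       chosen.start, chosen.end, copies,
                                       chosen.mismatches))
    return records, unmapped


def mapping_rate(alignments: list[AlignmentRecord], library: ProcessedLibrary,
                 catalog: ReferenceCatalog, target_class: str = "transposon"
                 ) -> float:
    """Percentage of copy-weighted kept reads placed on ``target_class``."""
    kept = library.stats["kept"]
    if kept == 0:
        raise ValueError("empty library")
    on_target = sum(a.copies for a in alignments
                    if catalog.class_of(a.ref_id) == target_class)
    return 100.0 * on_target / kept


def normalization_factor(alignments: list[AlignmentRecord],
                         catalog: ReferenceCatalog, mode: str = "transposon",
                         library_id: str = "library") -> NormalizationFactor:
    """Library-size denominator for RPM scaling.

    ``transposon``: copy-weighted reads on transposon references (the
    rRNA-derived repeat class never contributes). ``mirna_top10``:
    copy-weighted reads on the 10 most abundant miRNA references of this
    library (all of them when fewer than 10 are hit).
    """
    if mode == "transposon":
        denom = sum(a.copies for a in alignments
                    if catalog.class_of(a.ref_id) == "transposon")
    elif mode == "mirna_top10":
        per_mirna: dict[str, int] = {}
        for a in alignments:
            if catalog.class_of(a.ref_id) == "miRNA":
                per_mirna[a.ref_id] = per_mirna.get(a.ref_id, 0) + a.copies
        denom = sum(sorted(per_mirna.values(), reverse=True)[:10])
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if denom == 0:
        raise ValueError("no mapped reads for normalization")
    return NormalizationFactor(library_id, mode, float(denom))


def rpm_table(alignments: list[AlignmentRecord], factor: NormalizationFactor,
              catalog: ReferenceCatalog) -> pd.DataFrame:
    """Per-(reference, strand) RPM table.

    Rows cover every catalog reference on both strands (zero where no read
    maps); columns ``ref_id, strand, ref_class, count, rpm``.
    """
    counts: dict[tuple[str, str], int] = {}
    for a in alignments:
        key = (a.ref_id, a.strand)
        counts[key] = counts.get(key, 0) + a.copies
    rows = []
    for entry in catalog.entries:
        for strand in "+-":
            c = counts.get((entry.id, strand), 0)
            rows.append((entry.id, strand, entry.ref_class, c, factor.rpm(c)))
    df = pd.DataFrame(rows, columns=["ref_id", "strand", "ref_class", "count",
                                     "rpm"])
    df.attrs["factor"] = factor
    return df


# --------------------------------------------------------------------------
# SAM interchange


def write_sam(alignments: list[AlignmentRecord], catalog: ReferenceCatalog,
              path: str | Path) -> None:
    """Minimal SAM export: one line per collapsed insert, NM tag, full-match
    CIGAR; the collapsed copy number is carried in the read-count tag XC."""
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": e.id, "LN": e.length} for e in catalog.entries]}
    tid = {e.id: i for i, e in enumerate(catalog.entries)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, a in enumerate(alignments):
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = f"insert{i:07d}"
            seg.flag = 16 if a.strand == "-" else 0
            seg.reference_id = tid[a.ref_id]
            seg.reference_start = a.start
            seg.mapping_quality = 255
            seg.cigarstring = f"{len(a.insert)}M"
            seg.query_sequence = (a.insert if a.strand == "+"
                                  else revcomp(a.insert))
            seg.set_tag("NM", a.mismatches)
            seg.set_tag("XC", a.copies)
            out.write(seg)


def read_sam(path: str | Path, copies_tag: str = "XC") -> list[AlignmentRecord]:
    """Import alignments produced externally (or by :func:`write_sam`).

    The stored sequence is flipped back to sequencing orientation for
    minus-strand records; copy numbers default to 1 when the tag is absent.
    """
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            seq = seg.query_sequence or ""
            strand = "-" if seg.is_reverse else "+"
            insert = revcomp(seq) if strand == "-" else seq
            copies = seg.get_tag(copies_tag) if seg.has_tag(copies_tag) else 1
            nm = seg.get_tag("NM") if seg.has_tag("NM") else 0
            records.append(AlignmentRecord(
                insert, seg.reference_name, strand, seg.reference_start,
                seg.reference_start + len(seq), int(copies), int(nm)))
    return records
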