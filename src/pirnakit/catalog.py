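"""Reference catalog: the classed set of sequences every statistic is defined against.

A catalog bundles transposon consensus sequences, gene models, mature miRNAs
and rRNA-derived repeats. Small-RNA mapping, RPM normalization (which excludes
the rRNA-derived repeats from the denominator) and producer classification all
consult the class labels stored here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

REFERENCE_CLASSES = ("transposon", "gene", "miRNA", "rRNA_repeat")


@dataclass(frozen=True)
class ReferenceEntry:
    """One reference sequence with its class annotation."""

    id: str
    ref_class: str
    sequence: str

    def __post_init__(self) -> None:
        if self.ref_class not in REFERENCE_CLASSES:
            raise ValueError(f"unknown reference class: {self.ref_class!r}")
        if not self.sequence:
            raise ValueError(f"empty sequence for reference {self.id!r}")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"non-ACGT characters in reference {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceCatalog:
    """Ordered collection of :class:`ReferenceEntry` with unique ids."""

    entries: list[ReferenceEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reference ids in catalog")
        self._by_id = {e.id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self._by_id

    def __getitem__(self, ref_id: str) -> ReferenceEntry:
        return self._by_id[ref_id]

    def ids(self, ref_class: str | None = None) -> list[str]:
        if ref_class is None:
            return [e.id for e in self.entries]
        return [e.id for e in self.entries if e.ref_class == ref_class]

    def class_entries(self, ref_class: str) -> list[ReferenceEntry]:
        return [e for e in self.entries if e.ref_class == ref_class]

    def class_of(self, ref_id: str) -> str:
        return self._by_id[ref_id].ref_class

    def sequence(self, ref_id: str) -> str:
        return self._by_id[ref_id].sequence

    # ---------------------------------------------------------------- I/O

    def to_fasta(self, path: str | Path | io.TextIOBase) -> None:
        records = [
            SeqRecord(Seq(e.sequence), id=e.id, description=e.ref_class)
            for e in self.entries
        ]
        SeqIO.write(records, path, "fasta")

    def to_class_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"id": [e.id for e in self.entries],
             "class": [e.ref_class for e in self.entries]}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_fasta(cls, fasta: str | Path, class_tsv: str | Path) -> "ReferenceCatalog":
        classes = pd.read_csv(class_tsv, sep="\t").set_index("id")["class"]
        entries = []
        for rec in SeqIO.parse(str(fasta), "fasta"):
            if rec.id not in classes.index:
                raise ValueError(f"reference {rec.id!r} missing from class annotation")
            entries.append(
                ReferenceEntry(rec.id, str(classes.loc[rec.id]), str(rec.seq).upper())
            )
        return cls(entries)
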