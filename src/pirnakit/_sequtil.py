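"""Small sequence helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_rna(seq: str) -> str:
    """Uppercase and convert U to T so RNA and DNA inputs compare directly."""
    return seq.upper().replace("U", "T")


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Substitution count between equal-length strings.

    With ``limit`` the scan aborts early once ``limit + 1`` mismatches are
    seen, returning that count; useful for mismatch-thresholded scans.
    """
    if len(a) != len(b):
        raise ValueError("hamming requires equal-length strings")
    mm = 0
    if limit is None:
        for x, y in zip(a, b):
            if x != y:
                mm += 1
        return mm
    stop = limit + 1
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm >= stop:
                return mm
    return mm


def find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) exact occurrence offsets of needle."""
    hits = []
    j = haystack.find(needle)
    while j != -1:
        hits.append(j)
        j = haystack.find(needle, j + 1)
    return hits
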