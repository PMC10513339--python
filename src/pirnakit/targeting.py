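"""Slicer and ping-pong sequence rules.

A PIWI-loaded guide piRNA recognizes a target RNA through antiparallel
Watson-Crick pairing of its 5'-proximal bases; pairing of guide positions
2-18 suffices for cleavage, which falls between the target bases paired to
guide positions 10 and 11. The 3' cleavage fragment becomes the precursor of
the responder piRNA, whose 5' end therefore overlaps the guide's 5' end by
exactly 10 nt - the ping-pong geometry. Guide position 1 is a loading bias
(1U), not a pairing requirement, and is never constrained here.

Coordinates are 0-based half-open on the target; the cleavage bond is the
ordered index pair (i, i + 1). Pairing is strict Watson-Crick (no G:U
wobble); a mismatch-tolerance parameter exists but defaults to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._sequtil import hamming, normalize_rna, revcomp

PAIRING_SPAN = (2, 18)  # 1-based guide positions that must pair


@dataclass(frozen=True)
class CleavageSite:
    """One predicted slicer site of a guide on a target."""

    target_id: str
    pair_start: int        # 0-based start of the paired target interval
    pair_end: int          # half-open end of the paired target interval
    cleavage_bond: tuple[int, int]
    mismatches: int

    def __post_init__(self) -> None:
        i, j = self.cleavage_bond
        if j != i + 1:
            raise ValueError("cleavage bond must be an adjacent index pair")
        if not (self.pair_start <= i and j < self.pair_end):
            raise ValueError("cleavage bond must lie inside the pairing interval")


def _check_guide(seq: str, min_len: int) -> str:
    s = normalize_rna(seq)
    if len(s) < min_len:
        raise ValueError(f"guide must be at least {min_len} nt, got {len(s)}")
    if set(s) - set("ACGT"):
        raise ValueError("guide contains non-ACGU characters")
    return s


def pairs_by_pingpong(seq_a: str, seq_b: str) -> bool:
    """True iff the first 10 nt of the two RNAs are reverse complements.

    This is the sequence footprint of a ping-pong pair: the responder's
    5'-proximal 10 nt pair the guide's, putting an A at responder position 10
    opposite a guide 1U. Watson-Crick only, symmetric in its arguments.
    """
    a = _check_guide(seq_a, 10)
    b = _check_guide(seq_b, 10)
    return revcomp(a[:10]) == b[:10]


def find_cleavage_sites(guide: str, target: str,
                        required_span: tuple[int, int] = PAIRING_SPAN,
                        max_mismatches: int = 0,
                        target_id: str = "target") -> list[CleavageSite]:
    """Scan a target for slicer sites of one guide.

    A site is any target window whose bases pair antiparallel Watson-Crick
    with guide positions ``required_span`` (1-based, default 2-18) with at
    most ``max_mismatches`` defects. Guide position 1 and positions beyond
    the span are unconstrained. Returns sites 5'->3' along the target.
    """
    lo, hi = required_span
    if not 1 <= lo < hi:
        raise ValueError(f"invalid pairing span {required_span}")
    g = _check_guide(guide, hi)
    t = normalize_rna(target)
    # target bases pairing guide positions lo..hi, read 5'->3' on the target
    probe = revcomp(g[lo - 1: hi])
    span = len(probe)
    sites = []
    for s in range(0, len(t) - span + 1):
        mm = hamming(t[s: s + span], probe, limit=max_mismatches)
        if mm > max_mismatches:
            continue
        # guide position k pairs target index s + (hi - k)
        bond_lo = s + (hi - 11)   # paired to guide position 11
        sites.append(CleavageSite(target_id, s, s + span,
                                  (bond_lo, bond_lo + 1), mm))
    return sites


def responder_five_prime(site: CleavageSite) -> int:
    """Target index of the 5' end of the responder piRNA implied by a site.

    The responder is the 3' cleavage fragment, so its 5' end is the target
    base paired to guide position 10 - the downstream partner of the
    cleavage bond - which realizes the exact 10-nt 5'-5' overlap with the
    guide."""
    return site.cleavage_bond[1]


def responder_sequence(site: CleavageSite, target: str,
                       length: int | None = None) -> str:
    """Sequence of the implied responder (the target's 3' cleavage fragment),
    optionally truncated to a mature piRNA length."""
    t = normalize_rna(target)
    frag = t[responder_five_prime(site):]
    return frag if length is None else frag[:length]
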