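"""piRNA statistics: length/first-base profiles, ping-pong signature, 1U/10A
strand bias, 5'-end profiles, producer classification and Venn decomposition,
named-piRNA quantification, and the genic-silencing candidate search.

The ping-pong signature is quantified as the 5'-5' overlap histogram

    z(o) = sum over references and positions p of  n+(p) * n-(p + o - 1)

where n+ and n- are copy-weighted counts of sense and antisense 5' ends, and
o is the overlap length in nt. The signal is the o = 10 bin; the summary
statistic is z(10) / sum(z) over o in [1, o_max].

Biases are evaluated on the read sequence as sequenced (an antisense read is
the reverse complement of the reference interval it covers), so 1U means a
5'-terminal T on the read itself and 10A an A at read position 10.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

import numpy as np
import pandas as pd

from ._sequtil import normalize_rna
from .catalog import ReferenceCatalog
from .mapping import AlignmentRecord, NormalizationFactor
from .preprocess import ProcessedLibrary

PIRNA_LENGTH_WINDOW = (26, 30)  # operationalizes "around 27 nt" / "26-30 nt"


# --------------------------------------------------------------------------
# library-level profiles


def length_distribution(library: ProcessedLibrary,
                        factor: NormalizationFactor) -> pd.Series:
    """Copy-weighted insert-length histogram scaled to RPM."""
    per_len: dict[int, int] = defaultdict(int)
    for insert, copies in library.counts.items():
        per_len[len(insert)] += copies
    return pd.Series({l: factor.rpm(c) for l, c in sorted(per_len.items())},
                     dtype=float, name="rpm")


def first_base_composition(library: ProcessedLibrary,
                           length_window: tuple[int, int] = PIRNA_LENGTH_WINDOW
                           ) -> pd.Series:
    """Percentage of A/C/G/U at read position 1 within the length window.

    T is reported as U. An all-NaN series is returned when no read falls in
    the window (the empty flag lives in ``.attrs['empty']``).
    """
    lo, hi = length_window
    tallies = {b: 0 for b in "ACGU"}
    total = 0
    for insert, copies in library.counts.items():
        if lo <= len(insert) <= hi:
            base = "U" if insert[0] == "T" else insert[0]
            if base in tallies:
                tallies[base] += copies
                total += copies
    if total == 0:
        out = pd.Series({b: np.nan for b in "ACGU"}, name="percent")
        out.attrs["empty"] = True
        return out
    out = pd.Series({b: 100.0 * c / total for b, c in tallies.items()},
                    name="percent")
    out.attrs["empty"] = False
    return out


# --------------------------------------------------------------------------
# ping-pong signature


@dataclass
class OverlapHistogram:
    """5'-5' overlap weights z(o) for o in [1, o_max]."""

    z: pd.Series  # index: overlap o, values: weight

    @property
    def pingpong_fraction(self) -> float:
        total = float(self.z.sum())
        return float(self.z.loc[10] / total) if total > 0 else 0.0


def overlap_signature(alignments: list[AlignmentRecord], o_max: int = 25,
                      ref_ids: set[str] | None = None,
                      weighting: str = "copies") -> OverlapHistogram:
    """Copy-weighted (default) or species-weighted 5'-5' overlap histogram.

    ``weighting='species'`` counts each unique insert once, for the reading
    of the signature in which sense/antisense *species* pairs are tallied.
    """
    if o_max < 10:
        raise ValueError("o_max must be >= 10")
    if weighting not in ("copies", "species"):
        raise ValueError("weighting must be 'copies' or 'species'")
    plus: dict[str, dict[int, float]] = defaultdict(lambda: defaultdict(float))
    minus: dict[str, dict[int, float]] = defaultdict(lambda: defaultdict(float))
    for a in alignments:
        if ref_ids is not None and a.ref_id not in ref_ids:
            continue
        w = a.copies if weighting == "copies" else 1
        (plus if a.strand == "+" else minus)[a.ref_id][a.five_prime] += w
    z = np.zeros(o_max + 1)
    for ref_id, nplus in plus.items():
        nminus = minus.get(ref_id)
        if not nminus:
            continue
        for p, wp in nplus.items():
            for o in range(1, o_max + 1):
                wm = nminus.get(p + o - 1)
                if wm:
                    z[o] += wp * wm
    return OverlapHistogram(pd.Series(z[1:], index=np.arange(1, o_max + 1),
                                      name="z"))


# --------------------------------------------------------------------------
# 1U/10A strand bias


def strand_bias_table(alignments: list[AlignmentRecord],
                      catalog: ReferenceCatalog,
                      length_window: tuple[int, int] = PIRNA_LENGTH_WINDOW,
                      sort_keys: pd.Series | None = None) -> pd.DataFrame:
    """Per-transposon 1U/10A percentages per strand, read as sequenced.

    Returns one row per transposon with at least one in-window read, columns
    ``pct_1U_sense, pct_1U_antisense, pct_10A_sense, pct_10A_antisense,
    n_sense, n_antisense, sort_key``; rows sorted descending by
    ``sort_key = pct_1U_sense - pct_1U_antisense``. Percentages on a strand
    with no reads are NaN. Pass ``sort_keys`` (ref_id -> key, e.g. taken from
    a designated reference library's table) to impose that library's order.
    """
    lo, hi = length_window
    acc: dict[str, dict[str, float]] = {}
    for a in alignments:
        if catalog.class_of(a.ref_id) != "transposon":
            continue
        if not lo <= len(a.insert) <= hi:
            continue
        d = acc.setdefault(a.ref_id, {"n+": 0, "n-": 0, "1U+": 0, "1U-": 0,
                                      "10A+": 0, "10A-": 0})
        s = a.strand
        d[f"n{s}"] += a.copies
        if a.insert[0] == "T":
            d[f"1U{s}"] += a.copies
        if len(a.insert) >= 10 and a.insert[9] == "A":
            d[f"10A{s}"] += a.copies
    rows = []
    for ref_id, d in acc.items():
        def pct(num, den):
            return 100.0 * num / den if den > 0 else np.nan
        rows.append({
            "ref_id": ref_id,
            "pct_1U_sense": pct(d["1U+"], d["n+"]),
            "pct_1U_antisense": pct(d["1U-"], d["n-"]),
            "pct_10A_sense": pct(d["10A+"], d["n+"]),
            "pct_10A_antisense": pct(d["10A-"], d["n-"]),
            "n_sense": d["n+"],
            "n_antisense": d["n-"],
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["sort_key"] = df["pct_1U_sense"] - df["pct_1U_antisense"]
    if sort_keys is not None:
        df["sort_key"] = df["ref_id"].map(sort_keys)
    return (df.sort_values("sort_key", ascending=False, na_position="last")
              .reset_index(drop=True))


def five_prime_profile(alignments: list[AlignmentRecord], ref_id: str
                       ) -> dict[str, dict[int, float]]:
    """Copy-weighted 5'-end counts per position and strand on one reference."""
    profile: dict[str, dict[int, float]] = {"+": defaultdict(float),
                                            "-": defaultdict(float)}
    for a in alignments:
        if a.ref_id == ref_id:
            profile[a.strand][a.five_prime] += a.copies
    return {s: dict(d) for s, d in profile.items()}


def five_prime_profile_bed(profile: dict[str, dict[int, float]], ref_id: str,
                           path) -> None:
    """BED-like export: ref, 0-based position, strand, count; antisense counts
    exported as negative values for plotting on a mirrored axis."""
    with open(path, "w") as fh:
        for strand in "+-":
            sign = 1 if strand == "+" else -1
            for pos in sorted(profile[strand]):
                fh.write(f"{ref_id}\t{pos}\t{strand}\t"
                         f"{sign * profile[strand][pos]:g}\n")


# --------------------------------------------------------------------------
# producer classification and Venn decomposition


def classify_producers(rpm: pd.DataFrame, threshold: float = 4.0) -> set[str]:
    """Transposons whose sense + antisense RPM strictly exceeds ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    te = rpm[rpm["ref_class"] == "transposon"]
    totals = te.groupby("ref_id")["rpm"].sum()
    return set(totals.index[totals > threshold])


@dataclass(frozen=True)
class VennRegions:
    """Exclusive-region decomposition of three labeled sets."""

    only_a: int
    only_b: int
    only_c: int
    ab: int   # in a and b, not c
    ac: int
    bc: int
    abc: int
    union: int

    def __post_init__(self) -> None:
        total = (self.only_a + self.only_b + self.only_c
                 + self.ab + self.ac + self.bc + self.abc)
        if total != self.union:
            raise AssertionError("exclusive regions do not sum to the union")


def venn_regions(set_a: set, set_b: set, set_c: set) -> VennRegions:
    """Seven exclusive region sizes plus the union of three sets.

    The inclusion-exclusion identity |A u B u C| = |A|+|B|+|C|-|AB|-|AC|-|BC|
    +|ABC| is verified internally.
    """
    a, b, c = set(set_a), set(set_b), set(set_c)
    abc = a & b & c
    regions = VennRegions(
        only_a=len(a - b - c), only_b=len(b - a - c), only_c=len(c - a - b),
        ab=len((a & b) - c), ac=len((a & c) - b), bc=len((b & c) - a),
        abc=len(abc), union=len(a | b | c))
    ie = (len(a) + len(b) + len(c) - len(a & b) - len(a & c) - len(b & c)
          + len(abc))
    if ie != regions.union:
        raise AssertionError("inclusion-exclusion identity violated")
    return regions


# --------------------------------------------------------------------------
# named piRNAs and genic silencing candidates


def quantify_named_pirna(library: ProcessedLibrary, query: str,
                         factor: NormalizationFactor,
                         length_tolerance: int = 3) -> float:
    """Normalized RPM of a named piRNA in a processed library.

    Counts collapsed inserts identical to the query over the first
    min(insert, query) bases (5'-anchored, zero mismatches) whose length is
    within ``length_tolerance`` nt of the query, accommodating 3'-end length
    heterogeneity of mature piRNAs.
    """
    q = normalize_rna(query)
    if len(q) < 20:
        raise ValueError("query must be at least 20 nt")
    total = 0
    for insert, copies in library.counts.items():
        if abs(len(insert) - len(q)) > length_tolerance:
            continue
        m = min(len(insert), len(q))
        if insert[:m] == q[:m]:
            total += copies
    return factor.rpm(total)


def genic_silencing_candidates(sense_rpm: pd.DataFrame,
                               antisense_rpm: pd.DataFrame,
                               tpm_wt: pd.DataFrame, tpm_ko: pd.DataFrame,
                               rpm_threshold: float = 10.0,
                               fc_threshold: float = 2.0,
                               pseudocount: float = 0.01) -> list[str]:
    """Genes with both-strand piRNA coverage and KO up-regulation.

    All four inputs are gene x tissue tables over the same genes and tissues.
    A gene qualifies when, in at least one tissue, sense RPM and antisense
    RPM both strictly exceed ``rpm_threshold`` and
    (TPM_ko + c) / (TPM_wt + c) strictly exceeds ``fc_threshold``.
    """
    if rpm_threshold <= 0 or fc_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    frames = {"sense_rpm": sense_rpm, "antisense_rpm": antisense_rpm,
              "tpm_wt": tpm_wt, "tpm_ko": tpm_ko}
    ref = sense_rpm
    offenders = [name for name, df in frames.items()
                 if not (df.index.equals(ref.index)
                         and df.columns.equals(ref.columns))]
    if offenders:
        raise ValueError(f"mismatched gene/tissue universes in: {offenders}")
    fc = (tpm_ko + pseudocount) / (tpm_wt + pseudocount)
    hit = ((sense_rpm > rpm_threshold) & (antisense_rpm > rpm_threshold)
           & (fc > fc_threshold)).any(axis=1)
    return sorted(ref.index[hit])
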