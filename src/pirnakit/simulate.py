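"""Synthetic small-RNA libraries and RNA-seq experiments with known ground truth.

The small-RNA generator emulates the structure of piRNA sequencing libraries
from a piRNA-rich insect tissue:

* ~26-30 nt piRNA populations on transposon references, with antisense
  "primary" piRNAs carrying a 5' uridine bias (1U) and sense "responder"
  piRNAs carrying an adenine-at-position-10 bias (10A);
* a configurable fraction of sense/antisense 5'-end pairs overlapping by
  exactly 10 nt (the ping-pong signature), the remainder of the sense piRNA
  mass scattered over the other 5'-5' overlap offsets;
* background small RNAs (mature miRNA reads of exactly 22 nt and broad-length
  degradation fragments of the other reference classes);
* knockout libraries in which the piRNA read mass (primary + responder +
  scattered sense piRNAs) is multiplied by ``ko_depletion`` while the
  background mass is untouched;
* raw reads in sequencing orientation, ``4N + insert + 4N + 3'-adapter core``
  capped at 50 nt, mirroring 50 nt single-end sequencing of 4N-adapter
  libraries.

Ping-pong geometry is planted at a small set of initiator loci per transposon
(spaced further apart than the largest overlap offset considered), so the
realized overlap histogram is governed by the per-locus offset draws and the
realized z(10)/sum(z) matches ``pingpong_fraction`` up to sampling noise.

Every emitted read has exactly one row in the truth table, which is the
independent oracle for the downstream estimators.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._sequtil import revcomp
from .catalog import REFERENCE_CLASSES, ReferenceCatalog, ReferenceEntry

# 3'-adapter core printed after the four randomized bases of the 3' adapter.
ADAPTER_CORE = "TGGAATTCTCGGGTGCCAAGG"

READ_CAP = 50  # single-end read length of the emulated sequencer
MIRNA_LENGTH = 22

_CATEGORIES = ("primary", "responder", "background")


def default_length_law(center: float = 27.0, sd: float = 1.5,
                       lengths: tuple[int, int] = (20, 35)) -> dict[int, float]:
    """Discretized normal over the insert-length support, centered near 27 nt."""
    lo, hi = lengths
    ls = np.arange(lo, hi + 1)
    w = np.exp(-0.5 * ((ls - center) / sd) ** 2)
    w /= w.sum()
    return dict(zip(ls.tolist(), w.tolist()))


@dataclass
class SmallRnaSimParams:
    """Study conditions for one simulated small-RNA library."""

    depth: int
    pingpong_fraction: float = 0.7
    bias_1U: float = 0.9
    bias_10A: float = 0.8
    background_fraction: float = 0.2
    ko_depletion: float = 1.0
    length_law: dict[int, float] = field(default_factory=default_length_law)
    loci_per_reference: int = 3
    o_max: int = 25
    background_class_weights: dict[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("pingpong_fraction", "bias_1U", "bias_10A",
                     "background_fraction", "ko_depletion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not math.isclose(sum(self.length_law.values()), 1.0, rel_tol=1e-9):
            raise ValueError("length_law must sum to 1")
        if any(not 20 <= l <= 35 for l in self.length_law):
            raise ValueError("length_law support must lie in [20, 35]")
        if self.loci_per_reference < 1:
            raise ValueError("loci_per_reference must be >= 1")
        if self.o_max < 10:
            raise ValueError("o_max must be >= 10")


@dataclass
class SimTruth:
    """Per-read ground truth plus library-level summaries."""

    reads: pd.DataFrame  # read_id, origin_ref, strand, five_prime, category, insert
    true_pingpong_fraction: float
    true_1U_rate: float


@dataclass
class ExprSimParams:
    """Study conditions for one simulated RNA-seq comparison (WT vs KO)."""

    n_reps: int = 3
    baseline_mean: float | dict[str, float] | pd.Series = 200.0
    dispersion: float = 0.1
    log2fc_map: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


# --------------------------------------------------------------------------
# reference catalog generation


def make_reference_catalog(n_transposons: int, n_genes: int, n_mirnas: int,
                           n_rrna: int, length_range: tuple[int, int] = (500, 1000),
                           seed: int = 0) -> ReferenceCatalog:
    """Random reference catalog with the requested class composition.

    Transposon, gene and rRNA-repeat references draw their lengths uniformly
    from ``length_range``; miRNA references are mature-miRNA-sized (22 nt) so
    miRNA-derived background reads cover them exactly.
    """
    counts = {"transposon": n_transposons, "gene": n_genes,
              "miRNA": n_mirnas, "rRNA_repeat": n_rrna}
    if any(c < 0 for c in counts.values()):
        raise ValueError("entry counts must be >= 0")
    if sum(counts.values()) == 0:
        raise ValueError("empty catalog")
    lo, hi = length_range
    if not 0 < lo <= hi:
        raise ValueError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    prefixes = {"transposon": "TE", "gene": "GENE",
                "miRNA": "MIR", "rRNA_repeat": "RRNA"}
    bases = np.frombuffer(b"ACGT", dtype="S1")
    entries = []
    for ref_class in REFERENCE_CLASSES:
        for i in range(counts[ref_class]):
            length = MIRNA_LENGTH if ref_class == "miRNA" else int(rng.integers(lo, hi + 1))
            seq = rng.choice(bases, size=length).tobytes().decode()
            entries.append(ReferenceEntry(f"{prefixes[ref_class]}{i + 1:04d}",
                                          ref_class, seq))
    return ReferenceCatalog(entries)


# --------------------------------------------------------------------------
# small RNA library generation

_LOCUS_MARGIN = 40
_LOCUS_SPACING = 60


def _initiator_loci(catalog: ReferenceCatalog, per_ref: int,
                    rng: np.random.Generator) -> list[tuple[str, int]]:
    """Antisense 5'-end positions for ping-pong initiation, per transposon.

    Loci sit on a grid spaced wider than o_max + max read length so overlap
    mass never leaks between loci.
    """
    loci: list[tuple[str, int]] = []
    for entry in catalog.class_entries("transposon"):
        grid = np.arange(_LOCUS_MARGIN, entry.length - _LOCUS_MARGIN, _LOCUS_SPACING)
        if grid.size == 0:
            continue
        take = min(per_ref, grid.size)
        chosen = rng.choice(grid, size=take, replace=False)
        loci.extend((entry.id, int(q)) for q in sorted(chosen))
    return loci


def _mutate(seq: str, pos: int, want: str, rng: np.random.Generator,
            prob: float) -> str:
    """Force base ``want`` at ``pos`` with probability ``prob``; otherwise a
    uniform draw from the other three bases."""
    if rng.random() < prob:
        base = want
    else:
        others = [b for b in "ACGT" if b != want]
        base = others[rng.integers(3)]
    if seq[pos] == base:
        return seq
    return seq[:pos] + base + seq[pos + 1:]


def _truth_pingpong_fraction(truth: pd.DataFrame, catalog: ReferenceCatalog,
                             o_max: int) -> float:
    """Overlap fraction z(10)/sum(z) computed directly from true 5' ends."""
    te = {e.id for e in catalog.class_entries("transposon")}
    rows = truth[truth["origin_ref"].isin(te)]
    z = np.zeros(o_max + 1)
    for ref_id, grp in rows.groupby("origin_ref"):
        plus = grp[grp["strand"] == "+"]["five_prime"].value_counts()
        minus = grp[grp["strand"] == "-"]["five_prime"].value_counts()
        for p, n_plus in plus.items():
            for o in range(1, o_max + 1):
                q = p + o - 1
                if q in minus.index:
                    z[o] += n_plus * minus[q]
    total = z.sum()
    return float(z[10] / total) if total > 0 else 0.0


def simulate_small_rna_library(
    catalog: ReferenceCatalog, params: SmallRnaSimParams
) -> tuple[list[tuple[str, str, str]], SimTruth]:
    """Emit raw reads ``(read_id, sequence, quality)`` plus their truth table.

    Each ping-pong event draws an initiator locus (an antisense 5' position q
    on a transposon), emits a 1U-biased antisense primary with 5' end at q and
    a 10A-biased sense partner whose 5' end realizes a 5'-5' overlap of
    exactly 10 (a responder) with probability ``pingpong_fraction``, or a
    scattered off-signature overlap drawn uniformly from the other offsets in
    [1, o_max] otherwise. ``ko_depletion`` scales the number of piRNA events;
    background reads (miRNA + degradation) are unscaled.
    """
    params.validate()
    if not catalog.class_entries("transposon"):
        raise ValueError("catalog contains no transposons")
    rng = np.random.default_rng(params.seed)

    loci = _initiator_loci(catalog, params.loci_per_reference, rng)
    if not loci:
        raise ValueError("no transposon long enough to host an initiator locus")

    n_background = int(round(params.depth * params.background_fraction))
    n_pirna = int(round(params.depth * (1.0 - params.background_fraction)
                        * params.ko_depletion))

    lengths = np.array(sorted(params.length_law), dtype=int)
    length_p = np.array([params.length_law[l] for l in lengths])
    off_offsets = np.array([o for o in range(1, params.o_max + 1) if o != 10])

    inserts: list[str] = []
    truth_rows: list[tuple[str, str, int, str]] = []  # ref, strand, 5', category

    # --- piRNA events -----------------------------------------------------
    n_events, odd = divmod(n_pirna, 2)
    ev_loci = rng.integers(len(loci), size=n_events + odd)
    ev_is_pp = rng.random(n_events) < params.pingpong_fraction
    ev_off = rng.choice(off_offsets, size=n_events)
    ev_len = rng.choice(lengths, size=(n_events + odd, 2), p=length_p)

    for i in range(n_events + odd):
        ref_id, q = loci[ev_loci[i]]
        ref_seq = catalog.sequence(ref_id)
        lp = int(ev_len[i, 0])
        primary = revcomp(ref_seq[q - lp + 1: q + 1])
        primary = _mutate(primary, 0, "T", rng, params.bias_1U)
        inserts.append(primary)
        truth_rows.append((ref_id, "-", q, "primary"))
        if i >= n_events:  # odd leftover: primary only
            continue
        o = 10 if ev_is_pp[i] else int(ev_off[i])
        p = q - o + 1
        ls = int(ev_len[i, 1])
        partner = ref_seq[p: p + ls]
        partner = _mutate(partner, 9, "A", rng, params.bias_10A)
        inserts.append(partner)
        truth_rows.append((ref_id, "+", p, "responder" if o == 10 else "background"))

    # --- background reads -------------------------------------------------
    if n_background > 0:
        weights = params.background_class_weights
        if weights is None:
            weights = {c: 1.0 for c in REFERENCE_CLASSES if catalog.class_entries(c)}
        classes = [c for c, w in weights.items() if w > 0 and catalog.class_entries(c)]
        if not classes:
            raise ValueError("background weights select no catalog class")
        w = np.array([weights[c] for c in classes], dtype=float)
        w /= w.sum()
        bg_class = rng.choice(len(classes), size=n_background, p=w)
        for ci in bg_class:
            ref_class = classes[ci]
            pool = catalog.class_entries(ref_class)
            entry = pool[rng.integers(len(pool))]
            if ref_class == "miRNA":
                insert, strand, fp = entry.sequence, "+", 0
            else:
                # degradation fragment: broad length, either strand
                l = int(rng.integers(20, min(35, entry.length) + 1))
                start = int(rng.integers(0, entry.length - l + 1))
                if rng.random() < 0.5:
                    insert, strand, fp = entry.sequence[start:start + l], "+", start
                else:
                    insert = revcomp(entry.sequence[start:start + l])
                    strand, fp = "-", start + l - 1
            inserts.append(insert)
            truth_rows.append((entry.id, strand, fp, "background"))

    # --- assemble raw reads in sequencing orientation ---------------------
    order = rng.permutation(len(inserts))
    bases = np.frombuffer(b"ACGT", dtype="S1")
    reads: list[tuple[str, str, str]] = []
    out_rows = []
    for rank, idx in enumerate(order):
        insert = inserts[idx]
        ref_id, strand, fp, category = truth_rows[idx]
        n8 = rng.choice(bases, size=8).tobytes().decode()
        raw = n8[:4] + insert + n8[4:] + ADAPTER_CORE
        raw = raw[:READ_CAP]
        read_id = f"read{rank:07d}"
        reads.append((read_id, raw, "I" * len(raw)))
        out_rows.append((read_id, ref_id, strand, fp, category, insert))

    truth = pd.DataFrame(
        out_rows,
        columns=["read_id", "origin_ref", "strand", "five_prime", "category",
                 "insert"],
    )
    primaries = truth[truth["category"] == "primary"]
    true_1u = (float((primaries["insert"].str[0] == "T").mean())
               if len(primaries) else 0.0)
    true_pp = _truth_pingpong_fraction(truth, catalog, params.o_max)
    return reads, SimTruth(truth, true_pp, true_1u)


def write_fastq(reads: list[tuple[str, str, str]], path: str | Path) -> None:
    """Write 4-line FASTQ records (gzip if the path ends in .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


# --------------------------------------------------------------------------
# RNA-seq experiment generation


@dataclass
class CountMatrix:
    """Integer count table with the feature metadata TPM computation needs."""

    counts: pd.DataFrame               # features x samples
    feature_meta: pd.DataFrame         # columns: class, length
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if (self.feature_meta["length"] <= 0).any():
            raise ValueError("feature lengths must be > 0")

    @property
    def lengths(self) -> pd.Series:
        return self.feature_meta["length"]


def simulate_expression_experiment(
    catalog: ReferenceCatalog, params: ExprSimParams
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame]:
    """Negative-binomial WT/KO count matrices with planted log2 fold changes.

    Features are the transposon and gene entries of the catalog. Counts are
    drawn NB(mean, dispersion) with Var = mu + dispersion * mu^2; KO means are
    the WT means scaled by 2**log2fc. Returns (wt, ko, truth) where truth has
    columns feature, log2fc.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    feats = [e for e in catalog.entries if e.ref_class in ("transposon", "gene")]
    if not feats:
        raise ValueError("catalog has no transposon or gene features")
    ids = [e.id for e in feats]

    if isinstance(params.baseline_mean, (int, float)):
        base = pd.Series(float(params.baseline_mean), index=ids)
    else:
        base = pd.Series(params.baseline_mean, dtype=float).reindex(ids)
        if base.isna().any():
            raise ValueError("baseline_mean missing for some features")
    if (base <= 0).any():
        raise ValueError("baseline means must be > 0")
    unknown = set(params.log2fc_map) - set(ids)
    if unknown:
        raise ValueError(f"log2fc_map names unknown features: {sorted(unknown)}")

    lfc = pd.Series(0.0, index=ids)
    for k, v in params.log2fc_map.items():
        lfc.loc[k] = float(v)

    size = 1.0 / params.dispersion  # NB shape parameter

    def draw(mu: pd.Series, label: str) -> pd.DataFrame:
        cols = {}
        for r in range(params.n_reps):
            p = size / (size + mu.to_numpy())
            cols[f"{label}_{r + 1}"] = rng.negative_binomial(size, p)
        return pd.DataFrame(cols, index=ids)

    wt_counts = draw(base, "WT")
    ko_counts = draw(base * np.exp2(lfc), "KO")
    meta = pd.DataFrame(
        {"class": [e.ref_class for e in feats],
         "length": [e.length for e in feats]}, index=ids)
    truth = pd.DataFrame({"feature": ids, "log2fc": lfc.to_numpy()})
    wt = CountMatrix(wt_counts, meta,
                     pd.DataFrame({"genotype": ["WT"] * params.n_reps}))
    ko = CountMatrix(ko_counts, meta,
                     pd.DataFrame({"genotype": ["KO"] * params.n_reps}))
    return wt, ko, truth
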