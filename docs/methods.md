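# Methods

This note records the models, conventions and parameter choices behind
pirnakit, and what the synthetic-data generator does and does not emulate.

## Preprocessing model

Raw reads are assumed to be single-end sequences of layout
`[4 random nt][insert][4 random nt][3′ adapter]`, capped at the machine read
length (50 nt): the library structure produced by 4N-randomized adapter
cloning protocols. The 3′-adapter core defaults to
`TGGAATTCTCGGGTGCCAAGG` (the universal small-RNA 3′ adapter minus its 4N
block) and is configurable.

Adapter search scans left to right for the leftmost position where the core
— or a core prefix of at least 10 nt when the read ends first — matches with
at most 1 substitution ("fewer than 2 mismatches"). Indels are not modeled:
a substitution-only scan is the conventional reading and is independently
checkable by exhaustive enumeration. Reads without a detectable adapter are
discarded rather than kept untrimmed, because an untrimmed 50-nt read cannot
be a genuine ≤ 40-nt insert. The 20–40 nt length filter is applied to the
final insert, after both 4N blocks are removed; the filter stage is a
convention of this package (the alternative — filtering before 4N removal —
shifts the window by 8 nt). No quality filtering and no 4N-based
deduplication are performed. One structural consequence: inserts longer than
32 nt leave fewer than 10 visible adapter bases within a 50-nt read and are
therefore unrecoverable (counted `no_adapter`); with the default length law
this affects ≈ 0.2 % of piRNA-length reads.

## Alignment and normalization

The built-in aligner enumerates every placement of each unique insert on
both strands of every reference with ≤ 1 substitution (exact matching plus a
half-split pigeonhole for the 1-mismatch stratum), keeps the
minimum-mismatch stratum, and resolves ties uniformly with a seeded
generator — so multi-mappers are counted once, never fractionally. This is
deliberately a fully specified, deterministic re-statement of "map with a
short-read aligner"; SAM import/export (via pysam) lets an external aligner
be substituted at the same interface. The aligner is validated against an
all-substrings brute force on small catalogs.

RPM denominators: `transposon` mode counts copy-weighted reads on
transposon-class references, never the rRNA-derived repeat class (rRNA
repeats inflate library-size estimates without reflecting piRNA pathway
activity); `mirna_top10` mode counts reads on the 10 most abundant miRNA
references of the library. The transposon mode makes RPM sum to 10⁶ over
non-rRNA transposon references (a closure used as an invariant); the miRNA
mode is the right yardstick when the transposon-mapped total itself is the
quantity being destroyed, as in PIWI-knockout libraries. The two modes are
alternatives, not sequential rescalings.

## Ping-pong and strand statistics

The overlap histogram z(o) multiplies copy-weighted sense and antisense
5′-end counts at each offset o ∈ [1, O_max]; O_max defaults to 25 so the
denominator Σz spans all overlaps shorter than a typical read. The summary
z(10)/Σz is 0 when no opposite-strand co-occurrence exists. Because "pairs"
can mean read pairs or sequence-species pairs, both weightings are
implemented (`copies`, the default, and `species`). The estimator is
validated against an O(n²) all-read-pairs tally.

1U/10A percentages are evaluated on the read as sequenced (an antisense read
is the reverse complement of its reference interval), inside a 26–30 nt
window that operationalizes "around 27 nt" piRNA length. Sorting of the
strand-bias table follows the sense-minus-antisense 1U difference, by
default from the table itself, optionally from a designated reference
library's keys so several tissues can share one ordering.

Producer classification uses strict RPM > threshold (default 4) on
sense + antisense RPM; the three-set Venn decomposition verifies the
inclusion–exclusion identity internally. Named-piRNA quantification counts
collapsed inserts identical to the query over the first min(insert, query)
bases with zero mismatches and |Δlength| ≤ 3 nt, accommodating 3′
heterogeneity of mature piRNAs without admitting distinct species; the
counting rule is a convention of this package. Genic-silencing candidates
require sense and antisense RPM > 10 and a KO/WT TPM ratio > 2 (pseudocount
0.01) in at least one tissue, genes only.

## Expression analysis

TPM is computed per sample as 10⁶·(c/L)/Σ(c/L). The MA transform uses
pseudocount 0.01 on TPM before log₂ so zero-expression features remain
finite; derepression is M > 1 and A > 0 on condition-averaged TPM
(arithmetic mean over replicates).

The differential test is a self-contained replacement for count-model DEG
engines. Per feature, the statistic is d = (mean_KO − mean_WT)/(se + s₀) on
log₂(TPM + 0.01), where se is the Welch standard error and s₀ the median se
across features — the SAM-style regularizer, without which the df ≈ 4 tails
of a raw t statistic at 3-vs-3 dominate the pooled null and destroy power at
stringent FDR. Before the log transform, samples are rescaled by
median-of-ratios size factors (geometric-mean reference over features
expressed everywhere): TPM is closed-sum, so a block of strongly derepressed
features would otherwise depress every other feature's apparent expression
in the affected condition — the composition effect that the robust
normalizations of count-based DEG packages exist to remove. P-values come
from a gene-pooled permutation null over group-label reassignments,
excluding the observed labeling and its mirror (20 splits exist at 3-vs-3;
18 enter the null), with p = (1 + #{|d_null| ≥ |d|})/(1 + N). The pooled
null gives p-value resolution ≈ 1/(features × 18), which is what makes
FDR < 0.001 reachable at triplicate designs; Benjamini–Hochberg converts p
to FDR. Constant features get d = 0, p = 1.

Z-score clustering standardizes each feature row (sample SD; constant rows
dropped with a warning) and applies Ward/Euclidean agglomerative clustering
cut at k clusters (default 6) — chosen as the deterministic standard since
any linkage choice is a convention. Tissue specificity requires strictly
more than twice the TPM of both other tissues; fold-change classes use
strict |log₂FC| > 1.

## Targeting rules

Target recognition requires perfect antiparallel Watson–Crick pairing of
guide positions 2–18 (1-based); position 1 is a loading bias, not a pairing
requirement, and positions beyond 18 are unconstrained. A mismatch-tolerance
parameter exists but defaults to 0, and G:U wobble never counts as a pair.
The cleavage bond is the ordered target index pair between the bases paired
to guide positions 10 and 11 (0-based half-open coordinates on the target);
the responder 5′ end is the downstream bond partner, which by construction
realizes the exact 10-nt 5′–5′ overlap with the guide.

## Synthetic-data generator

The generator emulates piRNA-rich small-RNA libraries of an insect tissue:

* **piRNA geometry.** Each transposon hosts a few initiator loci (default 3,
  drawn from a grid spaced 60 nt — wider than O_max plus the longest read,
  so overlap mass cannot leak between loci). A ping-pong event picks a
  locus, emits a 1U-biased antisense primary with its 5′ end at the locus,
  and a 10A-biased sense partner whose 5′–5′ overlap is exactly 10 with
  probability `pingpong_fraction`, or uniform over the other offsets in
  [1, O_max] otherwise. Within a locus the overlap histogram factorizes as
  n₋ × (offset draws), so the realized z(10)/Σz equals the requested
  fraction up to sampling noise plus a small downward leakage (≈ 0.01 at
  20 % background) from background reads landing near loci. The truth table
  labels exact-10 sense partners `responder`; the scattered sense piRNA
  mass is labeled `background` (it is not part of a true ping-pong pair)
  but carries the 10A bias and is depleted in knockouts together with the
  rest of the piRNA mass.
* **Biases.** Primary first bases are forced to U with probability
  `bias_1U` (else uniform over the other three); sense-read tenth bases to A
  with `bias_10A`. A forced base may differ from the reference — at most
  one substitution per read, within the aligner's default tolerance.
* **Lengths.** Insert lengths follow a discretized normal centered at 27 nt
  (SD 1.5) on [20, 35] — the canonical 26–30 nt piRNA population; responders
  draw from the same law (no separate responder length model is claimed).
* **Background.** `background_fraction` of reads are non-ping-pong: mature
  miRNA reads of exactly 22 nt (so the top-10-miRNA normalization is
  meaningfully exercised) and degradation fragments of the other classes
  with uniform 20–35 nt lengths and random positions/strands. Class weights
  default to uniform over the classes present and are configurable; the
  knockout-emulation studies use miRNA-only background, because in a real
  piRNA-pathway knockout the surviving small-RNA population is dominated by
  miRNAs, and planting non-depleting 26–30 nt degradation reads would
  misrepresent the near-total collapse of the piRNA-length band those
  libraries show.
* **Knockouts.** `ko_depletion` multiplies the piRNA event count (primary,
  responder and scattered sense mass alike) and leaves the background mass
  untouched; the pair statistic z(10) therefore scales with its square.
* **Raw reads.** Emitted as `4N + insert + 4N + adapter core` truncated at
  50 nt, constant high quality (no quality model), shuffled, seeded.

RNA-seq experiments draw counts from a negative binomial with
Var = μ + φμ² (φ = `dispersion`, default 0.1 — a typical replicate
dispersion for inbred laboratory animals), means per feature from
`baseline_mean`, and knockout means scaled by 2^log2fc for planted features.

**What the generator does not emulate** — sequencing errors and quality
variation, ligation bias beyond the 4N design, genomic multi-mapping between
near-identical transposon copies, phased (trailing) piRNA production,
transcript-level effects (isoforms, 3′ bias), and batch structure. Passing
tests therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to these real-data complications.

## Problem sizes and numerical conventions

Recovery studies use 10⁵-read libraries over a 25-transposon catalog (the
scale at which the ±0.02 ping-pong and ±2-point bias recoveries are
statistically meaningful), 5 × 10⁴-read pairs for knockout emulation, and
2000-feature, 3-vs-3 expression designs with 20 derepressed transposons
(log₂FC 3) or 100 DEGs (log₂FC 4) planted. RPM closure is asserted to
relative 10⁻⁶; TPM column sums to absolute 10⁻³. Ties in alignment are
broken with `numpy.random.default_rng` seeded per run; all simulations are
bit-reproducible given their seed.

## Known limitations

* The aligner is exhaustive and substitution-only (≤ 1 mismatch); it is
  meant for transposon/gene-model catalogs of a few Mb, not whole genomes.
* The permutation DEG test's p-value floor is 1/(18 × features + 1); very
  small feature sets cannot reach stringent FDR levels, and at 2-vs-2
  designs only 4 usable splits exist.
* Ping-pong significance testing (z-score against a positional null) is out
  of scope; the package reports signal fractions, not p-values, for the
  overlap statistic.
* The named-piRNA counting rule and the 26–30 nt window are conventions;
  both are parameters.
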