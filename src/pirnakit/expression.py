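"""RNA-seq side of the pipeline: TPM, MA/derepression calls, differential
expression with permutation FDR, Z-score clustering, tissue specificity and
fold-change classes.

TPM is the standard length-normalized measure, TPM_i = 1e6 * (c_i / L_i) /
sum_j (c_j / L_j) per sample. The MA transform compares condition-averaged
TPM on the log2 scale with a pseudocount c: A = (log2(ko + c) +
log2(wt + c)) / 2 and M = log2(ko + c) - log2(wt + c); a transposon is called
derepressed at M > 1 and A > 0.

The differential test is self-contained: a moderated two-sample statistic
d = (mean_ko - mean_wt) / (se + s0) on log2(TPM + c), where s0 is the median
standard error across features (a SAM-style regularizer that tames the
heavy finite-sample tails a raw t statistic has at 3-vs-3), with p-values
from a gene-pooled permutation null over group-label reassignments
(identity and mirror labelings excluded) and Benjamini-Hochberg adjustment.
Before the log transform, samples are rescaled by median-of-ratios size
factors: TPM is composition-sensitive, so a block of strongly derepressed
features would otherwise deflate every other feature's apparent expression
in the affected condition (the problem the robust normalizations of the
count-based DEG packages address).
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .simulate import CountMatrix

DEFAULT_PSEUDOCOUNT = 0.01


def tpm_table(counts: pd.DataFrame | CountMatrix,
              lengths: pd.Series | None = None) -> pd.DataFrame:
    """Transcripts-per-million table; every column sums to 1e6."""
    if isinstance(counts, CountMatrix):
        lengths = counts.lengths
        counts = counts.counts
    if lengths is None:
        raise ValueError("feature lengths required for TPM")
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("missing lengths for some features")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    empty = denom[denom == 0]
    if len(empty):
        raise ValueError(f"empty sample: {list(empty.index)}")
    return rate.div(denom, axis=1) * 1e6


def ma_transform(tpm_wt: pd.Series, tpm_ko: pd.Series,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Per-feature (A, M) with the derepression flag at M > 1 and A > 0.

    Inputs are replicate-averaged TPM per feature for the reference (WT) and
    alternative (KO) condition.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    x = np.log2(tpm_ko + pseudocount)
    y = np.log2(tpm_wt + pseudocount)
    df = pd.DataFrame({"A": (x + y) / 2.0, "M": x - y})
    df["derepressed"] = (df["M"] > 1.0) & (df["A"] > 0.0)
    return df


def _group_stats(x: np.ndarray, idx1: np.ndarray, idx2: np.ndarray,
                 s0: float | None) -> tuple[np.ndarray, float]:
    """Moderated difference statistic for one labeling of the columns."""
    g1, g2 = x[:, idx1], x[:, idx2]
    diff = g2.mean(axis=1) - g1.mean(axis=1)
    v1 = g1.var(axis=1, ddof=1)
    v2 = g2.var(axis=1, ddof=1)
    se = np.sqrt(v1 / g1.shape[1] + v2 / g2.shape[1])
    if s0 is None:
        s0 = float(np.median(se))
        if s0 == 0.0:
            s0 = 1e-8
    return diff / (se + s0), s0


def _median_ratio_factors(tpm: np.ndarray) -> np.ndarray:
    """Per-sample size factors: median ratio to the geometric-mean reference,
    computed over features expressed in every sample."""
    keep = tpm.min(axis=1) > 0
    if keep.sum() < 10:  # too few ubiquitous features to estimate a factor
        return np.ones(tpm.shape[1])
    logx = np.log(tpm[keep])
    ref = logx.mean(axis=1)
    return np.exp(np.median(logx - ref[:, None], axis=0))


def differential_test(counts_wt: CountMatrix, counts_ko: CountMatrix,
                      n_null_perms: int | None = None, seed: int = 0,
                      pseudocount: float = DEFAULT_PSEUDOCOUNT,
                      median_ratio: bool = True) -> pd.DataFrame:
    """Per-feature differential test between two replicated conditions.

    Returns a DataFrame with ``statistic`` (moderated log2-TPM difference,
    KO minus WT), pooled-permutation ``p`` and BH-adjusted ``fdr``. Features
    constant across all samples get statistic 0 and p = 1. With
    ``n_null_perms=None`` every distinct label reassignment (except the
    observed one and its mirror) is enumerated; otherwise that many distinct
    reassignments are sampled with the seeded generator.
    ``median_ratio`` applies the composition-robust per-sample rescaling
    described in the module docstring.
    """
    n1 = counts_wt.counts.shape[1]
    n2 = counts_ko.counts.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 replicates per group")
    if not counts_wt.counts.index.equals(counts_ko.counts.index):
        raise ValueError("feature universes differ between groups")
    tpm = tpm_table(
        CountMatrix(pd.concat([counts_wt.counts, counts_ko.counts], axis=1),
                    counts_wt.feature_meta))
    values = tpm.to_numpy(dtype=float)
    if median_ratio:
        values = values / _median_ratio_factors(values)
    x = np.log2(values + pseudocount)
    n = n1 + n2
    obs1 = np.arange(n1)
    obs2 = np.arange(n1, n)
    stat, s0 = _group_stats(x, obs1, obs2, None)

    all_splits = [frozenset(c) for c in combinations(range(n), n1)]
    observed = frozenset(obs1.tolist())
    mirror = frozenset(obs2.tolist()) if n1 == n2 else None
    null_splits = [s for s in all_splits if s != observed and s != mirror]
    rng = np.random.default_rng(seed)
    if n_null_perms is not None and n_null_perms < len(null_splits):
        pick = rng.choice(len(null_splits), size=n_null_perms, replace=False)
        null_splits = [null_splits[i] for i in pick]

    null_stats = []
    for split in null_splits:
        i1 = np.fromiter(sorted(split), dtype=int)
        i2 = np.fromiter(sorted(set(range(n)) - split), dtype=int)
        null_stats.append(_group_stats(x, i1, i2, s0)[0])
    pool = np.sort(np.abs(np.concatenate(null_stats)))

    abs_stat = np.abs(stat)
    # p = (1 + #null >= |d|) / (1 + N), two-sided on the pooled null
    exceed = len(pool) - np.searchsorted(pool, abs_stat, side="left")
    p = (1.0 + exceed) / (1.0 + len(pool))

    constant = x.std(axis=1) == 0
    stat[constant] = 0.0
    p[constant] = 1.0
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"statistic": stat, "p": p, "fdr": fdr},
                        index=tpm.index)


def zscore_cluster(tpm: pd.DataFrame, k: int = 6) -> pd.DataFrame:
    """Row-wise Z-scoring followed by Ward/Euclidean agglomerative clustering
    cut into ``k`` clusters; deterministic for a fixed input.

    Constant rows are dropped with a warning. Returns the Z-score matrix with
    an extra ``cluster`` column of labels in 1..k.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    sd = tpm.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant feature(s) "
                      "before Z-scoring")
        tpm = tpm.loc[~constant]
        sd = sd.loc[~constant]
    if len(tpm) < k:
        raise ValueError(f"need at least k={k} non-constant features, "
                         f"got {len(tpm)}")
    z = tpm.sub(tpm.mean(axis=1), axis=0).div(sd, axis=0)
    linkage = hierarchy.linkage(z.to_numpy(), method="ward",
                                metric="euclidean")
    labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    out = z.copy()
    out["cluster"] = labels
    return out


def tissue_specific_genes(tpm: pd.DataFrame) -> dict[str, set[str]]:
    """Genes more than twice as expressed in one tissue as in both others.

    ``tpm`` has exactly three tissue columns; a gene is specific to tissue t
    iff TPM_t > 2 * TPM_u strictly for both other tissues u.
    """
    if tpm.shape[1] != 3:
        raise ValueError("exactly three tissue columns required")
    out: dict[str, set[str]] = {}
    for t in tpm.columns:
        others = [u for u in tpm.columns if u != t]
        mask = ((tpm[t] > 2 * tpm[others[0]]) & (tpm[t] > 2 * tpm[others[1]]))
        out[t] = set(tpm.index[mask])
    return out


def fold_change_classes(tpm_wt: pd.Series, tpm_ko: pd.Series,
                        pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.Series:
    """Classify features as up / down / unchanged at |log2FC| > 1 (strict)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    lfc = np.log2(tpm_ko + pseudocount) - np.log2(tpm_wt + pseudocount)
    out = pd.Series("unchanged", index=lfc.index, name="class")
    out[lfc > 1.0] = "up"
    out[lfc < -1.0] = "down"
    return out
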