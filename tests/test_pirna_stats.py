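"""Ping-pong signature, strand bias, profiles, producer sets and Venn."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import pirnakit as pk
from pirnakit.catalog import ReferenceCatalog, ReferenceEntry


def rec(ref, strand, five_prime, length=26, copies=1, insert=None):
    if insert is None:
        insert = "T" + "A" * (length - 1)
    if strand == "+":
        start, end = five_prime, five_prime + length
    else:
        start, end = five_prime - length + 1, five_prime + 1
    return pk.AlignmentRecord(insert, ref, strand, start, end, copies, 0)


def brute_force_overlaps(alignments, o_max=25, weighting="copies"):
    """All read-pairs oracle for the 5'-5' overlap histogram."""
    z = Counter()
    for a in alignments:
        for b in alignments:
            if a.ref_id != b.ref_id or a.strand != "+" or b.strand != "-":
                continue
            o = b.five_prime - a.five_prime + 1
            if 1 <= o <= o_max:
                w = a.copies * b.copies if weighting == "copies" else 1
                z[o] += w
    return z


class TestOverlapSignature:
    def test_exact_ten_overlap_is_full_signal(self):
        aln = [rec("TE1", "+", 0), rec("TE1", "-", 9)]
        hist = pk.overlap_signature(aln)
        assert hist.z.loc[10] == 1
        assert hist.pingpong_fraction == 1.0

    def test_fifteen_overlap_contributes_no_signal(self):
        aln = [rec("TE1", "+", 0), rec("TE1", "-", 14)]
        hist = pk.overlap_signature(aln)
        assert hist.z.loc[15] == 1
        assert hist.pingpong_fraction == 0.0

    def test_copy_weighted_mixture(self):
        aln = [rec("TE1", "+", 0, copies=3), rec("TE1", "-", 9, copies=2),
               rec("TE1", "-", 14, copies=1)]
        hist = pk.overlap_signature(aln)
        assert hist.z.loc[10] == 6 and hist.z.loc[15] == 3
        assert hist.pingpong_fraction == pytest.approx(6 / 9)
        assert dict(brute_force_overlaps(aln)) == {10: 6, 15: 3}

    def test_no_opposite_strand_cooccurrence(self):
        aln = [rec("TE1", "+", 0), rec("TE2", "-", 9)]
        assert pk.overlap_signature(aln).pingpong_fraction == 0.0

    @pytest.mark.parametrize("weighting", ["copies", "species"])
    def test_equals_all_pairs_brute_force(self, weighting):
        rng = np.random.default_rng(7)
        for _ in range(20):
            aln = []
            for _ in range(rng.integers(5, 120)):
                aln.append(rec(f"TE{rng.integers(3)}",
                               "+-"[rng.integers(2)],
                               int(rng.integers(30, 130)),
                               copies=int(rng.integers(1, 5))))
            hist = pk.overlap_signature(aln, weighting=weighting)
            oracle = brute_force_overlaps(aln, weighting=weighting)
            assert dict(hist.z[hist.z > 0].items()) == dict(oracle)

    def test_estimator_recovers_generated_fraction_midscale(self,
                                                            small_catalog):
        params = pk.SmallRnaSimParams(depth=10_000, pingpong_fraction=0.5,
                                      seed=3)
        reads, truth = pk.simulate_small_rna_library(small_catalog, params)
        lib = pk.process_library(reads)
        aln, _ = pk.align_reads(lib, small_catalog, 1, seed=0)
        hist = pk.overlap_signature(
            aln, ref_ids=set(small_catalog.ids("transposon")))
        assert hist.pingpong_fraction == pytest.approx(0.5, abs=0.05)
        assert hist.pingpong_fraction == pytest.approx(
            truth.true_pingpong_fraction, abs=0.03)


class TestLibraryProfiles:
    def _factor(self, denom):
        return pk.NormalizationFactor("lib", "transposon", denom)

    def test_length_distribution_arithmetic(self):
        lib = pk.ProcessedLibrary(counts=Counter({"A" * 26: 2, "C" * 28: 2}))
        hist = pk.length_distribution(lib, self._factor(4))
        assert hist.loc[26] == pytest.approx(5e5)
        assert hist.loc[28] == pytest.approx(5e5)

    def test_empty_library_gives_empty_histogram(self):
        hist = pk.length_distribution(pk.ProcessedLibrary(), self._factor(1))
        assert hist.empty

    def test_first_base_percentages_report_u(self):
        lib = pk.ProcessedLibrary(counts=Counter(
            {"T" + "G" * 26: 3, "A" + "G" * 26: 1}))
        comp = pk.first_base_composition(lib, (26, 30))
        assert comp["U"] == pytest.approx(75.0)
        assert comp["A"] == pytest.approx(25.0)
        assert comp.sum() == pytest.approx(100.0)

    def test_window_excluding_all_reads_flags_empty(self):
        lib = pk.ProcessedLibrary(counts=Counter({"T" * 22: 5}))
        comp = pk.first_base_composition(lib, (26, 30))
        assert comp.attrs["empty"] and comp.isna().all()

    def test_ko_depletes_pirna_length_band(self, small_catalog):
        shared = dict(depth=30_000, background_fraction=0.2,
                      background_class_weights={"miRNA": 1.0}, seed=41)
        runs = {}
        for label, ko in (("wt", 1.0), ("ko", 0.01)):
            reads, _ = pk.simulate_small_rna_library(
                small_catalog,
                pk.SmallRnaSimParams(ko_depletion=ko, **shared))
            lib = pk.process_library(reads)
            aln, _ = pk.align_reads(lib, small_catalog, 1, seed=0)
            factor = pk.normalization_factor(aln, small_catalog,
                                             "mirna_top10")
            hist = pk.length_distribution(lib, factor)
            runs[label] = hist.reindex(range(26, 31)).fillna(0).sum()
        assert runs["ko"] / runs["wt"] <= 0.02


class TestStrandBias:
    def _pipeline_table(self, catalog, **overrides):
        params = pk.SmallRnaSimParams(depth=20_000, seed=29, **overrides)
        reads, _ = pk.simulate_small_rna_library(catalog, params)
        lib = pk.process_library(reads)
        aln, _ = pk.align_reads(lib, catalog, 1, seed=0)
        return aln

    def test_percentage_arithmetic(self):
        aln = [rec("TE1", "+", 0, insert="T" + "C" * 25),
               rec("TE1", "+", 50, insert="T" + "C" * 25, copies=2),
               rec("TE1", "+", 100, insert="A" + "C" * 25),
               rec("TE1", "-", 200, insert="C" * 9 + "A" + "C" * 16),
               rec("TE1", "-", 260, insert="C" * 26)]
        cat = ReferenceCatalog([ReferenceEntry("TE1", "transposon",
                                               "A" * 400)])
        (row,) = pk.strand_bias_table(aln, cat).to_dict("records")
        assert row["pct_1U_sense"] == pytest.approx(75.0)
        assert row["pct_10A_antisense"] == pytest.approx(50.0)
        assert row["n_sense"] == 4 and row["n_antisense"] == 2

    def test_invariant_under_read_duplication(self):
        rng = np.random.default_rng(11)
        cat = ReferenceCatalog([ReferenceEntry("TE1", "transposon",
                                               "A" * 500)])
        aln = [rec("TE1", "+-"[rng.integers(2)], int(rng.integers(40, 400)),
                   insert="".join(rng.choice(list("ACGT"), size=27)),
                   copies=int(rng.integers(1, 4)))
               for _ in range(60)]
        doubled = [pk.AlignmentRecord(a.insert, a.ref_id, a.strand, a.start,
                                      a.end, 2 * a.copies, a.mismatches)
                   for a in aln]
        cols = ["pct_1U_sense", "pct_1U_antisense", "pct_10A_sense",
                "pct_10A_antisense"]
        pd.testing.assert_frame_equal(
            pk.strand_bias_table(aln, cat)[cols],
            pk.strand_bias_table(doubled, cat)[cols])

    def test_biases_land_on_opposite_strands(self, small_catalog):
        aln = self._pipeline_table(small_catalog)
        table = pk.strand_bias_table(aln, small_catalog)
        deep = table[(table.n_sense >= 20) & (table.n_antisense >= 20)]
        assert len(deep) >= 3
        opposite = ((deep.pct_1U_antisense > deep.pct_1U_sense)
                    & (deep.pct_10A_sense > deep.pct_10A_antisense))
        assert opposite.mean() >= 0.95

    def test_sorted_by_designated_keys(self):
        cat = ReferenceCatalog(
            [ReferenceEntry("TE1", "transposon", "A" * 200),
             ReferenceEntry("TE2", "transposon", "A" * 200)])
        aln = [rec("TE1", "+", 0, insert="T" * 26),
               rec("TE2", "+", 0, insert="A" + "T" * 25)]
        keys = pd.Series({"TE1": -5.0, "TE2": 3.0})
        table = pk.strand_bias_table(aln, cat, sort_keys=keys)
        assert list(table.ref_id) == ["TE2", "TE1"]


class TestFivePrimeProfile:
    def test_plus_and_minus_conventions(self):
        aln = [rec("TE1", "+", 5, copies=2),
               pk.AlignmentRecord("A" * 26, "TE1", "-", 10, 36, 4, 0)]
        profile = pk.five_prime_profile(aln, "TE1")
        assert profile["+"] == {5: 2}
        assert profile["-"] == {35: 4}

    def test_profile_mass_equals_copy_total(self, small_catalog):
        params = pk.SmallRnaSimParams(depth=3000, seed=37)
        reads, _ = pk.simulate_small_rna_library(small_catalog, params)
        lib = pk.process_library(reads)
        aln, _ = pk.align_reads(lib, small_catalog, 1, seed=0)
        ref = small_catalog.ids("transposon")[0]
        profile = pk.five_prime_profile(aln, ref)
        mass = sum(profile["+"].values()) + sum(profile["-"].values())
        assert mass == sum(a.copies for a in aln if a.ref_id == ref)


class TestProducersAndVenn:
    def test_threshold_is_strict(self):
        rpm = pd.DataFrame({
            "ref_id": ["TE1", "TE1", "TE2", "TE2", "G1", "G1"],
            "strand": ["+", "-"] * 3,
            "ref_class": ["transposon"] * 4 + ["gene"] * 2,
            "count": [0] * 6,
            "rpm": [2.0, 2.0, 2.1, 2.0, 50.0, 50.0]})
        assert pk.classify_producers(rpm, 4.0) == {"TE2"}

    def test_classification_equals_brute_force(self):
        rng = np.random.default_rng(23)
        ids = [f"TE{i}" for i in range(40)]
        rows = [(i, s, "transposon", 0, float(rng.exponential(4)))
                for i in ids for s in "+-"]
        rpm = pd.DataFrame(rows, columns=["ref_id", "strand", "ref_class",
                                          "count", "rpm"])
        expected = {i for i in ids
                    if rpm[rpm.ref_id == i]["rpm"].sum() > 4.0}
        assert pk.classify_producers(rpm, 4.0) == expected

    def test_published_inclusion_exclusion_worked_example(self):
        # three producer sets with |OV|=1008, |WD|=412, |FB|=208,
        # |OV&WD|=412 (WD subset of OV), |OV&FB|=205, |OV&WD&FB|=200
        ov = set(range(1008))
        wd = set(range(412))                        # wholly inside OV
        fb = (set(range(200))                       # triple region
              | set(range(600, 605))                # OV&FB only
              | {2000, 2001, 2002})                 # FB-exclusive
        assert len(ov & wd) == 412 and len(ov & fb) == 205
        assert len(ov & wd & fb) == 200 and len(fb) == 208
        regions = pk.venn_regions(ov, wd, fb)
        assert regions.union == 1011
        assert regions.only_a == 591
        assert regions.only_c == 3

    def test_disjoint_singletons(self):
        regions = pk.venn_regions({1}, {2}, {3})
        assert (regions.only_a, regions.only_b, regions.only_c) == (1, 1, 1)
        assert regions.union == 3 and regions.abc == 0

    @given(st.sets(st.integers(0, 99)), st.sets(st.integers(0, 99)),
           st.sets(st.integers(0, 99)))
    def test_regions_match_membership_enumeration(self, a, b, c):
        r = pk.venn_regions(a, b, c)
        regions = {(True, False, False): r.only_a,
                   (False, True, False): r.only_b,
                   (False, False, True): r.only_c,
                   (True, True, False): r.ab,
                   (True, False, True): r.ac,
                   (False, True, True): r.bc,
                   (True, True, True): r.abc}
        for key, size in regions.items():
            members = [x for x in a | b | c
                       if (x in a, x in b, x in c) == key]
            assert len(members) == size
        assert sum(regions.values()) == r.union == len(a | b | c)


class TestNamedPirna:
    def _factor(self, denom):
        return pk.NormalizationFactor("lib", "transposon", denom)

    def test_exact_copies_scaled_to_rpm(self):
        query = "TGACGGTCAAGCTATTTCGGAAGCTT"
        lib = pk.ProcessedLibrary(counts=Counter({query: 10}))
        assert pk.quantify_named_pirna(lib, query, self._factor(200_000)) \
            == pytest.approx(50.0)

    def test_length_heterogeneity_within_three_nt(self):
        query = "TGACGGTCAAGCTATTTCGGAAGCTTAC"
        lib = pk.ProcessedLibrary(counts=Counter({
            query[:-2]: 4,            # 2 nt shorter, same 5' end
            query + "GA": 1,          # 2 nt longer
            query[:-4]: 7,            # 4 nt shorter: outside tolerance
            "A" + query[1:]: 9,       # 5' mismatch
        }))
        rpm = pk.quantify_named_pirna(lib, query, self._factor(1e6))
        assert rpm == pytest.approx(5.0)

    def test_absent_query_is_zero(self):
        lib = pk.ProcessedLibrary(counts=Counter({"T" * 27: 3}))
        assert pk.quantify_named_pirna(lib, "A" * 27, self._factor(100)) == 0.0

    def test_spiked_copy_number_recovered_from_simulation(self, small_catalog):
        params = pk.SmallRnaSimParams(depth=5000, seed=43)
        reads, truth = pk.simulate_small_rna_library(small_catalog, params)
        lib = pk.process_library(reads)
        primaries = truth.reads[truth.reads.category == "primary"]
        query = primaries["insert"].value_counts().index[0]
        expected = sum(c for ins, c in lib.counts.items()
                       if abs(len(ins) - len(query)) <= 3
                       and ins[:min(len(ins), len(query))]
                       == query[:min(len(ins), len(query))])
        rpm = pk.quantify_named_pirna(lib, query, self._factor(1e6))
        assert rpm == pytest.approx(expected)


class TestGenicSilencing:
    def _tables(self):
        tissues = ["OV", "FB", "WD"]
        genes = ["g1", "g2", "g3"]
        z = pd.DataFrame(0.0, index=genes, columns=tissues)
        return z.copy(), z.copy(), z.copy(), z.copy()

    def test_candidate_requires_all_three_conditions(self):
        sense, anti, wt, ko = self._tables()
        sense.loc["g1", "OV"] = 12; anti.loc["g1", "OV"] = 15
        wt.loc["g1", "OV"] = 5; ko.loc["g1", "OV"] = 21
        # g2: antisense below threshold
        sense.loc["g2", "FB"] = 30; anti.loc["g2", "FB"] = 8
        wt.loc["g2", "FB"] = 5; ko.loc["g2", "FB"] = 21
        # g3: fold change 1.9 only
        sense.loc["g3", "WD"] = 30; anti.loc["g3", "WD"] = 30
        wt.loc["g3", "WD"] = 10; ko.loc["g3", "WD"] = 19
        assert pk.genic_silencing_candidates(sense, anti, wt, ko) == ["g1"]

    def test_mismatched_universes_error(self):
        sense, anti, wt, ko = self._tables()
        with pytest.raises(ValueError, match="tpm_ko"):
            pk.genic_silencing_candidates(sense, anti, wt,
                                          ko.drop(index="g3"))
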