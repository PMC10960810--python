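import numpy as np
import pytest

from icp import (
    Edit,
    apply_edit,
    build_observed_dictionary,
    build_peppr_dictionary,
    classify_reads,
    curate_primer_errors,
    derive_seed,
    make_allele_record,
    wt_seed,
)
from icp.dictionaries import ShortSeedError

from conftest import random_locus
from oracles import oracle_classify


class TestDeriveSeed:
    def test_wt_seed_spans_cut(self, locus):
        assert wt_seed(locus) == locus.ref_seq[locus.cut - 12 : locus.cut + 12]

    def test_peppr_seed_splice_arithmetic(self, locus):
        cut, ref = locus.cut, locus.ref_seq
        rec = make_allele_record(locus, Edit(cut - 10, cut))
        expected = ref[cut - 22 : cut - 10] + ref[cut : cut + 12]
        # canonical placement may shift the junction; either way the seed is
        # the 24-mer around the splice point of the same mutant sequence
        j = rec.edit.del_start
        assert rec.seed24 == rec.mutant_seq[j - 12 : j + 12]
        if rec.edit == Edit(cut - 10, cut):
            assert rec.seed24 == expected

    def test_short_flank_flagged(self):
        with pytest.raises(ShortSeedError):
            derive_seed("ACGT" * 3, 2, 24)

    def test_odd_k_rejected(self):
        with pytest.raises(ValueError, match="even"):
            derive_seed("ACGT" * 20, 40, 23)

    def test_seed_occurs_once_at_recorded_offset(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            loc = random_locus(rng, 100)
            d = build_peppr_dictionary(loc, 30)
            for rec in d.entries:
                assert rec.seed24 is not None
                assert rec.mutant_seq.count(rec.seed24) == 1
                assert (
                    rec.mutant_seq[rec.seed_offset : rec.seed_offset + 24]
                    == rec.seed24
                )


class TestPepprDictionary:
    def test_empty_when_max_zero(self, locus):
        assert len(build_peppr_dictionary(locus, 0)) == 0

    def test_count_identity_against_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            loc = random_locus(rng, 100)
            d = build_peppr_dictionary(loc, 30)
            assert len(d.entries) + len(d.mmej_excluded) == 30
            for rec in d.mmej_excluded:
                # exclusion confirmed by the brute-force oracle on the
                # original (pre-canonicalization) candidate interval
                assert rec.class_label == "MMEJ"
                assert (
                    oracle_classify(
                        loc.ref_seq, loc.cut, rec.edit.del_start, rec.edit.del_end
                    )
                    == "MMEJ"
                )
            for rec in d.entries:
                assert rec.class_label == "PEPPR"

    def test_no_repeat_reference_yields_full_dictionary(self):
        # search (fixed seed) for a reference whose 30 candidates are all
        # repeat-free at the junction, verified by the oracle
        rng = np.random.default_rng(23)
        for _ in range(500):
            loc = random_locus(rng, 100)
            labels = [
                oracle_classify(loc.ref_seq, loc.cut, loc.cut - L, loc.cut)
                for L in range(1, 31)
            ]
            if all(l == "PEPPR" for l in labels):
                d = build_peppr_dictionary(loc, 30)
                assert len(d.entries) == 30 and not d.mmej_excluded
                return
        pytest.fail("no repeat-free reference found")

    def test_single_mmej_candidate_excluded(self):
        # find a locus where exactly one candidate length is MMEJ
        rng = np.random.default_rng(29)
        for _ in range(1000):
            loc = random_locus(rng, 100)
            labels = [
                oracle_classify(loc.ref_seq, loc.cut, loc.cut - L, loc.cut)
                for L in range(1, 31)
            ]
            if labels.count("MMEJ") == 1:
                d = build_peppr_dictionary(loc, 30)
                assert len(d.entries) == 29
                assert len(d.mmej_excluded) == 1
                L = labels.index("MMEJ") + 1
                assert d.mmej_excluded[0].edit.del_len == L
                return
        pytest.fail("no single-MMEJ locus found")

    def test_invalid_max_del_len(self, locus):
        with pytest.raises(ValueError):
            build_peppr_dictionary(locus, locus.cut + 1)
        with pytest.raises(ValueError):
            build_peppr_dictionary(locus, locus.cut - 5)  # <12 nt flank


class TestObservedDictionary:
    def test_empty_pool(self, locus):
        d = build_observed_dictionary([], "MMEJ", locus)
        assert len(d) == 0

    def test_dedupe_and_support_across_samples(self, locus):
        # one fabricated MMEJ-class read in two samples
        rng = np.random.default_rng(31)
        mmej_edit = None
        for _ in range(500):
            loc = random_locus(rng, 100)
            for L in range(3, 31):
                e = Edit(loc.cut - L, loc.cut)
                if oracle_classify(loc.ref_seq, loc.cut, e.del_start, e.del_end) == "MMEJ":
                    mmej_edit, locus = e, loc
                    break
            if mmej_edit:
                break
        assert mmej_edit is not None
        read = apply_edit(locus, mmej_edit)
        pools = {}
        for sample in ("s1", "s2"):
            classified, _ = classify_reads([(f"{sample}_r", read)] * 1, locus)
            pools[sample] = classified
        d = build_observed_dictionary(pools, "MMEJ", locus, min_reads=2)
        assert len(d) == 1
        rec = d.entries[0]
        assert d.support[rec.allele_id] == {"s1": 1, "s2": 1}

    def test_min_reads_filters_singletons(self, locus):
        # 5 planted DELET alleles at >=3 reads, plus singleton artifacts
        rng = np.random.default_rng(37)
        cut = locus.cut
        truth_edits = [Edit(cut - 20 - i, cut - 3 - i) for i in range(5)]
        reads = []
        for i, e in enumerate(truth_edits):
            reads += [(f"t{i}_{j}", apply_edit(locus, e)) for j in range(3)]
        singles = [Edit(cut - 30, cut - 9), Edit(cut - 28, cut - 11)]
        reads += [(f"s{i}", apply_edit(locus, e)) for i, e in enumerate(singles)]
        classified, _ = classify_reads(reads, locus)
        d = build_observed_dictionary(classified, "DELET", locus, min_reads=3)
        truth_kept = {
            make_allele_record(locus, e).allele_id
            for e in truth_edits
            if make_allele_record(locus, e).class_label == "DELET"
        }
        assert {r.allele_id for r in d.entries} == truth_kept
        assert len(truth_kept) >= 3  # fixed locus: most planted alleles are DELET

    def test_wrong_category_rejected(self, locus):
        with pytest.raises(ValueError):
            build_observed_dictionary([], "PEPPR", locus)


class TestPrimerCuration:
    def test_primer_overlapping_deletion_rejected(self, locus):
        rec = make_allele_record(locus, Edit(5, 30))  # overlaps primer [0,12)
        kept, rejects = curate_primer_errors([rec], locus)
        assert not kept and rejects[0][1].startswith("deletion overlaps")

    def test_internal_edit_kept(self, locus):
        rec = make_allele_record(locus, Edit(40, 50))
        kept, rejects = curate_primer_errors([rec], locus)
        assert kept == [rec] and not rejects

    def test_wt_kept(self, locus):
        rec = make_allele_record(locus, Edit(0, 0))
        kept, _ = curate_primer_errors([rec], locus)
        assert kept == [rec]


class TestDeterminism:
    def test_rebuild_is_identical(self, locus):
        reads = [("a", apply_edit(locus, Edit(locus.cut - 20, locus.cut - 4)))] * 4
        classified, _ = classify_reads(reads, locus)
        d1 = build_observed_dictionary(classified, "DELET", locus)
        d2 = build_observed_dictionary(classified, "DELET", locus)
        assert [r.allele_id for r in d1.entries] == [r.allele_id for r in d2.entries]
        assert d1.seed_index == d2.seed_index
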