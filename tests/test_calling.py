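"""Pair dedup, reference-anchored alignment, codon calling and the
confidence filters."""

import numpy as np
import pandas as pd
import pytest

from nf2scan.calling import (ReferenceAligner, SampleCounts,
                             call_codon_mutations, call_sample, dedup_pairs,
                             filter_low_confidence, filter_secondary,
                             read_fastq_pairs, read_sam_pairs)
from nf2scan.simulate import SimulationConfig, simulate_screen

_COMP = str.maketrans("ACGT", "TGCA")


def rc(s):
    return s.translate(_COMP)[::-1]


def write_fastq(path, reads):
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def make_pair(cds, start, length, rl=60, patches=()):
    frag = cds[start:start + length]
    for pos0, codon in patches:
        rel = pos0 - start
        frag = frag[:rel] + codon + frag[rel + 3:]
    return frag[:rl], rc(frag[-rl:]) if length > rl else rc(frag)


class TestDedup:
    def test_identical_pairs_collapse_with_multiplicity(self):
        pairs = [("r1", "AAAA", "TTTT")] * 3 + [("r4", "CCCC", "GGGG")]
        unique = dedup_pairs(pairs)
        assert sorted(u.multiplicity for u in unique) == [1, 3]
        assert len(unique) == 2

    def test_empty_input(self):
        assert dedup_pairs([]) == []

    def test_mate_count_mismatch_raises(self, tmp_path):
        write_fastq(tmp_path / "r1.fastq", [("a/1", "ACGT"), ("b/1", "ACGT")])
        write_fastq(tmp_path / "r2.fastq", [("a/2", "ACGT")])
        with pytest.raises(ValueError, match="mate"):
            list(read_fastq_pairs(tmp_path / "r1.fastq", tmp_path / "r2.fastq"))

    def test_simulated_duplicates_match_molecule_replication(self, tmp_path,
                                                             toy_catalog,
                                                             toy_cds):
        cfg = SimulationConfig(seed=2, n_pairs_control=500, n_pairs_selected=10,
                               error_rate=0, secondary_rate=0, indel_rate=0,
                               wt_fraction=0, abundance_sigma=0,
                               enrichment_factor=1.0, n_perturbing=1,
                               fragment_length_mean=90, fragment_length_sd=5)
        files = simulate_screen(cfg, toy_catalog, toy_cds, tmp_path)
        pairs = list(read_fastq_pairs(files.control_r1, files.control_r2))
        unique = dedup_pairs(pairs)
        assert sum(u.multiplicity for u in unique) == 500
        # reconstruct expected multiplicities from the molecule-encoding names
        seen = {}
        for name, s1, s2 in pairs:
            seen[(s1, s2)] = seen.get((s1, s2), 0) + 1
        assert sorted(seen.values()) == sorted(u.multiplicity for u in unique)


class TestAligner:
    def test_exact_substring_placement(self, toy_cds):
        al = ReferenceAligner(toy_cds)
        a = al.align(toy_cds[30:90])
        assert a.offset == 30 and a.identity == 1.0 and not a.indel_removed

    def test_reverse_complement_placement(self, toy_cds):
        al = ReferenceAligner(toy_cds)
        a = al.align(rc(toy_cds[30:90]))
        assert a.offset == 30 and a.identity == 1.0

    def test_single_substitution_recovered(self, toy_cds):
        al = ReferenceAligner(toy_cds)
        read = list(toy_cds[30:90])
        read[20] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[20]]
        a = al.align("".join(read))
        assert a.offset == 30
        mism = np.nonzero(a.obs != al.ref_arr[30:90])[0]
        assert list(mism) == [20]

    def test_insertion_locally_removed(self, toy_cds):
        al = ReferenceAligner(toy_cds)
        read = toy_cds[30:60] + "GG" + toy_cds[60:90]
        a = al.align(read)
        assert a.indel_removed
        assert a.offset == 30
        # after removal the observation matches the reference again
        assert np.array_equal(a.obs[a.mask],
                              al.ref_arr[a.offset:a.offset + a.span][a.mask])

    def test_deletion_masks_reference_positions(self, toy_cds):
        al = ReferenceAligner(toy_cds)
        read = toy_cds[30:60] + toy_cds[63:93]
        a = al.align(read)
        assert a.indel_removed
        assert a.mask.sum() == len(read)

    def test_unalignable_read_returns_none(self, toy_cds):
        al = ReferenceAligner(toy_cds)
        assert al.align("ACGT" * 20) is None


class TestCodonCalls:
    def test_single_codon_call_from_planted_substitution(self, toy_cds):
        al = ReferenceAligner(toy_cds, k=15)
        wt = toy_cds[57:60]
        mut = "GCT" if wt != "GCT" else "AAA"
        r1, r2 = make_pair(toy_cds, 30, 90, patches=[(57, mut)])
        sc = call_codon_mutations(dedup_pairs([("p", r1, r2)]), al)
        assert sc.counts == {(20, mut): 1}
        # codons 11..40 fully covered by the pair
        assert sc.coverage[10:40].sum() == 30

    def test_multi_nt_change_within_codon_is_one_call(self, toy_cds):
        al = ReferenceAligner(toy_cds, k=15)
        wt = toy_cds[57:60]
        mut = "".join({"A": "C", "C": "A", "G": "T", "T": "G"}[b] for b in wt)
        r1, r2 = make_pair(toy_cds, 30, 90, patches=[(57, mut)])
        sc = call_codon_mutations(dedup_pairs([("p", r1, r2)]), al)
        assert sc.counts == {(20, mut): 1}

    def test_programmed_plus_secondary_records_cooccurrence(self, toy_cds):
        al = ReferenceAligner(toy_cds, k=15)
        w1, w2 = toy_cds[36:39], toy_cds[72:75]
        m1 = "GCT" if w1 != "GCT" else "AAA"
        m2 = "CAT" if w2 != "CAT" else "CAC"
        r1, r2 = make_pair(toy_cds, 30, 90, patches=[(36, m1), (72, m2)])
        sc = call_codon_mutations(dedup_pairs([("p", r1, r2)] * 4), al)
        assert sc.count((13, m1)) == 4 and sc.count((25, m2)) == 4
        assert sc.cooc[(13, m1)][(25, m2)] == 4

    def test_mate_disagreement_voids_the_position(self, toy_cds):
        al = ReferenceAligner(toy_cds, k=15)
        # fully overlapping mates; mate1 carries a substitution, mate2 is WT
        frag = toy_cds[30:90]
        read1 = list(frag)
        read1[27] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read1[27]]
        sc = call_codon_mutations(
            dedup_pairs([("p", "".join(read1), rc(frag))]), al)
        assert sc.counts == {}
        assert sc.coverage[19] == 0              # voided codon not covered
        assert sc.coverage[12] == 1

    def test_partial_codon_evidence_is_discarded(self, toy_cds):
        al = ReferenceAligner(toy_cds, k=15)
        # read covers only 2 of 3 bases of codon 11 (nt 30..32): start at 31
        r = toy_cds[31:76]
        sc = call_codon_mutations(dedup_pairs([("p", r, rc(r))]), al)
        assert sc.coverage[10] == 0 and sc.coverage[11] == 1

    def test_zero_noise_calling_equals_ground_truth(self, tmp_path,
                                                    toy_catalog, toy_cds):
        for seed in (0, 1, 2):
            cfg = SimulationConfig(
                seed=seed, n_pairs_control=1500, n_pairs_selected=1500,
                error_rate=0, secondary_rate=0, indel_rate=0, wt_fraction=0,
                abundance_sigma=0.3, enrichment_factor=5.0, n_perturbing=3,
                fragment_length_mean=90, fragment_length_sd=10)
            files = simulate_screen(cfg, toy_catalog, toy_cds,
                                    tmp_path / str(seed))
            gt = pd.read_csv(files.ground_truth, sep="\t", comment="#")
            for sample, r1, r2 in (("covered_control", files.control_r1,
                                    files.control_r2),
                                   ("covered_selected", files.selected_r1,
                                    files.selected_r2)):
                sc = call_sample(r1, r2, reference=toy_cds)
                called = dict(sc.counts)
                for _, row in gt.iterrows():
                    assert called.pop((row.codon_index, row.mut_codon), 0) \
                        == row[sample]
                assert called == {}


class TestSamInput:
    def test_sam_and_fastq_paths_agree(self, tmp_path, toy_catalog, toy_cds):
        import pysam

        cfg = SimulationConfig(seed=4, n_pairs_control=300, n_pairs_selected=10,
                               error_rate=0, secondary_rate=0, indel_rate=0,
                               wt_fraction=0, abundance_sigma=0,
                               enrichment_factor=1.0, n_perturbing=1,
                               fragment_length_mean=90, fragment_length_sd=5)
        files = simulate_screen(cfg, toy_catalog, toy_cds, tmp_path)
        sam_path = tmp_path / "reads.sam"
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"},
             "SQ": [{"SN": "orf", "LN": len(toy_cds)}]})
        with pysam.AlignmentFile(sam_path, "w", header=header) as out:
            for name, s1, s2 in read_fastq_pairs(files.control_r1,
                                                 files.control_r2):
                for seq, flag in ((s1, 77), (s2, 141)):
                    rec = pysam.AlignedSegment(header)
                    rec.query_name = name
                    rec.query_sequence = seq
                    rec.flag = flag
                    rec.query_qualities = pysam.qualitystring_to_array(
                        "I" * len(seq))
                    out.write(rec)
        sc_fastq = call_sample(files.control_r1, files.control_r2,
                               reference=toy_cds)
        sc_sam = call_sample(sam_path=sam_path, reference=toy_cds)
        assert sc_fastq.counts == sc_sam.counts
        assert np.array_equal(sc_fastq.coverage, sc_sam.coverage)


def _counts_with_cooc():
    sc = SampleCounts("s", 50)
    sc.counts = {(10, "GCT"): 100, (20, "CAT"): 90, (30, "AAA"): 100,
                 (40, "TTG"): 7}
    sc.cooc = {(10, "GCT"): {(20, "CAT"): 90},
               (20, "CAT"): {(10, "GCT"): 90},
               (30, "AAA"): {(40, "TTG"): 7},
               (40, "TTG"): {(30, "AAA"): 7}}
    sc.coverage[:] = 120
    return sc


class TestSecondaryFilter:
    def test_dominant_secondary_excludes_joint_reads(self):
        out = filter_secondary(_counts_with_cooc(), threshold=0.8)
        assert out.count((10, "GCT")) == 10      # 90 of 100 joint -> removed
        assert out.count((30, "AAA")) == 100     # 7 of 100 -> below threshold

    def test_no_secondaries_is_identity(self, toy_cds):
        sc = SampleCounts("s", 50)
        sc.counts = {(5, "GAA"): 42}
        out = filter_secondary(sc)
        assert out.counts == sc.counts

    def test_filter_is_logged(self):
        out = filter_secondary(_counts_with_cooc())
        assert any(entry[0] == "secondary" for entry in out.filter_log)


class TestLowConfidenceFilter:
    def _fixture(self):
        # 10 supporting reads at position 7: GCT x7 clean, AAA x3 from
        # indel-corrected pairs -> AAA is below 0.7 x max signal (7)
        sc = SampleCounts("s", 50)
        sc.counts = {(7, "GCT"): 7, (7, "AAA"): 3, (9, "TTG"): 2}
        sc.ambiguous = {(7, "AAA"): 3, (9, "TTG"): 2}
        sc.coverage[:] = 10
        return sc

    def test_ambiguous_minority_call_dropped(self):
        out = filter_low_confidence(self._fixture(), threshold=0.7)
        assert (7, "AAA") not in out.counts
        assert out.count((7, "GCT")) == 7        # clean call untouched
        assert out.count((9, "TTG")) == 2        # it *is* the max at its locus

    def test_clean_calls_unchanged(self):
        sc = self._fixture()
        sc.ambiguous = {}
        out = filter_low_confidence(sc)
        assert out.counts == sc.counts

    def test_zero_threshold_drops_nothing(self):
        out = filter_low_confidence(self._fixture(), threshold=0.0)
        assert out.counts == self._fixture().counts


class TestFilterProperties:
    def test_stricter_thresholds_never_increase_counts(self):
        base = _counts_with_cooc()
        base.ambiguous = {(40, "TTG"): 3}
        prev = None
        for thr in (1.0, 0.8, 0.5, 0.2, 0.05):   # lower = stricter
            cur = filter_secondary(base, threshold=thr)
            if prev is not None:
                for call in base.counts:
                    assert cur.count(call) <= prev.count(call)
            prev = cur
        prev = None
        for thr in (0.0, 0.3, 0.7, 0.9, 1.0):    # higher = stricter
            cur = filter_low_confidence(base, threshold=thr)
            if prev is not None:
                for call in base.counts:
                    assert cur.count(call) <= prev.count(call)
            prev = cur

    def test_filters_conserve_totals_and_coverage(self):
        base = _counts_with_cooc()
        base.ambiguous = {(40, "TTG"): 3}
        for f in (filter_secondary, filter_low_confidence):
            out = f(base)
            assert out.total_mutant_reads() <= base.total_mutant_reads()
            assert np.array_equal(out.coverage, base.coverage)


def test_counts_tsv_round_trip(tmp_path):
    sc = _counts_with_cooc()
    sc.to_tsv(tmp_path / "c.tsv", ["unit-test"])
    back = SampleCounts.from_tsv(tmp_path / "c.tsv")
    assert back.counts == sc.counts
    assert back.n_codons == sc.n_codons
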