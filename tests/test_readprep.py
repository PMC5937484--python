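"""Read preparation: trimming, merging, demultiplexing, dereplication."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motupipe import (PipelineConfig, SampleSheet, SampleSheetEntry,
                      demultiplex, dereplicate, get_marker, length_filter,
                      merge_pair, merge_pairs_batch, remove_singletons,
                      run_readprep, trim_by_median_quality)
from motupipe.readprep import ReadPair, UniqueSeq
from motupipe._seq import revcomp
from tests.conftest import reads_to_pairs


def brute_force_longest_prefix(qual, thr):
    """Independent oracle: scan every prefix length, true median."""
    best = 0
    for k in range(1, len(qual) + 1):
        if float(np.median(qual[:k])) > thr:
            best = k
    return best


class TestTrim:
    def test_high_quality_unchanged(self):
        seq, qual = "A" * 100, [40] * 100
        s, q = trim_by_median_quality(seq, qual, 30)
        assert s == seq and list(q) == qual

    def test_decaying_tail_matches_brute_force(self):
        qual = [40] * 50 + [2] * 50
        seq = "A" * 100
        s, _ = trim_by_median_quality(seq, qual, 30)
        assert len(s) == brute_force_longest_prefix(qual, 30)

    def test_all_low_quality_empty(self):
        s, q = trim_by_median_quality("ACGT" * 10, [2] * 40, 30)
        assert s == "" and len(q) == 0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            trim_by_median_quality("ACGT", [40, 40], 30)

    @given(st.lists(st.integers(min_value=0, max_value=41), min_size=0,
                    max_size=60),
           st.integers(min_value=0, max_value=40))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_brute_force_everywhere(self, qual, thr):
        """Property: output is exactly the longest prefix with median above
        the threshold, for arbitrary quality profiles (not just 3' decay)."""
        seq = "A" * len(qual)
        s, _ = trim_by_median_quality(seq, qual, thr)
        assert len(s) == brute_force_longest_prefix(qual, thr)


def make_pair(template, overlap, read_q=40, rng=None, mismatch_pos=()):
    """Construct mates reading a template from both ends with a given exact
    overlap; optionally plant mismatches into mate 2 inside the overlap."""
    L = len(template)
    rlen = (L + overlap) // 2
    r1 = template[:rlen]
    r2_region = template[L - rlen:]
    r2 = list(r2_region)
    # the overlap is the first `overlap` bases of mate 2's region
    for p in mismatch_pos:
        r2[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[r2[p]]
    r2 = revcomp("".join(r2))
    return ReadPair("p", r1, np.full(rlen, read_q), r2, np.full(rlen, read_q))


TEMPLATE_313 = "".join("ACGT"[i % 4] for i in range(313))


class TestMerge:
    def test_exact_overlap_reconstructs_template(self, rng):
        template = "".join("ACGT"[i] for i in rng.integers(0, 4, 313))
        pair = make_pair(template, overlap=101)
        res = merge_pair(pair, min_overlap=10)
        assert res.accepted
        assert res.merged == template
        assert res.overlap == 101
        # all-Q40 columns: score equals overlap length
        assert res.score == pytest.approx(101)

    def test_no_true_overlap_rejected(self, rng):
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        pair = ReadPair("p", a, np.full(120, 40), b, np.full(120, 40))
        res = merge_pair(pair, min_overlap=10, min_score=40)
        assert not res.accepted

    def test_three_mismatches_score_94(self, rng):
        """Independent column tally: 97 matches - 3 mismatches at Q40 -> 94."""
        template = "".join("ACGT"[i] for i in rng.integers(0, 4, 301))
        pair = make_pair(template, overlap=101, mismatch_pos=(10, 50, 90))
        res = merge_pair(pair, min_overlap=95)
        assert res.overlap == 101
        # hand tally confirmed: (101-3-3)*1.0 per spec scoring at Q40
        assert res.score == pytest.approx(101 - 2 * 3)

    def test_consensus_takes_higher_quality_base(self):
        template = "ACGTACGTACGTACGTACGTACGTACGTACGT"  # 32 nt
        pair = make_pair(template, overlap=32)
        # full overlap; plant a conflict with asymmetric quality
        r1 = list(pair.seq_fwd)
        r1[5] = "T" if r1[5] != "T" else "A"
        q1 = np.full(len(r1), 20)
        res = merge_pair(ReadPair("p", "".join(r1), q1, pair.seq_rev,
                                  np.full(len(pair.seq_rev), 40)),
                         min_overlap=10, min_score=5)
        assert res.accepted
        assert res.merged == template  # mate 2 (Q40) wins the conflict

    def test_batch_equals_scalar(self, rng):
        pairs = []
        for _ in range(30):
            template = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
            ov = int(rng.integers(20, 90))
            nmm = int(rng.integers(0, 4))
            pos = tuple(rng.choice(ov, size=nmm, replace=False)) if nmm else ()
            pairs.append(make_pair(template, ov, mismatch_pos=pos))
        batch = merge_pairs_batch(pairs, 10, 0.25, 40.0)
        for p, b in zip(pairs, batch):
            s = merge_pair(p, 10, 0.25, 40.0)
            assert b.accepted == s.accepted
            assert b.overlap == s.overlap
            assert b.score == pytest.approx(s.score)
            assert b.merged == s.merged


def sheet_for(tag_samples, marker="COI"):
    mk = get_marker(marker)
    return SampleSheet([
        SampleSheetEntry(sample_id=sid, marker=marker, tag=tag,
                         fwd_primer=mk.fwd_primer, rev_primer=mk.rev_primer,
                         fraction="A")
        for tag, sid in tag_samples.items()])


def build_read(tag5, tag3, insert, marker="COI", spacer="NN"):
    """spacer+tag+fwdprimer+insert+rc(revprimer)+rc(tag)+rc(spacer)."""
    from motupipe.simulate import concretize_primer
    mk = get_marker(marker)
    rng = np.random.default_rng(0)
    fwd = concretize_primer(mk.fwd_primer, rng)
    rev = concretize_primer(mk.rev_primer, rng)
    sp = spacer.replace("N", "A")
    return (sp + tag5 + fwd + insert + revcomp(rev) + revcomp(tag3)
            + revcomp(sp))


class TestDemultiplex:
    INSERT = TEMPLATE_313

    def test_constructed_read_assigned(self):
        sheet = sheet_for({"AACCGGTT": "s1", "TTGGCCAA": "s2"})
        read = build_read("AACCGGTT", "AACCGGTT", self.INSERT)
        res = demultiplex(read, sheet, "COI")
        assert res.sample_id == "s1"
        assert res.insert == self.INSERT

    def test_reverse_orientation_assigned(self):
        """A reverse-complemented read is recognized and its insert is
        reported in canonical (forward-primer) orientation."""
        sheet = sheet_for({"AACCGGTT": "s1"})
        read = revcomp(build_read("AACCGGTT", "AACCGGTT", self.INSERT))
        res = demultiplex(read, sheet, "COI")
        assert res.sample_id == "s1"
        assert res.insert == self.INSERT
        assert res.orientation == "-"

    def test_mismatched_tag_pair_is_intersample_chimera(self):
        sheet = sheet_for({"AACCGGTT": "s1", "TTGGCCAA": "s2"})
        read = build_read("AACCGGTT", "TTGGCCAA", self.INSERT)
        res = demultiplex(read, sheet, "COI")
        assert res.sample_id is None
        assert res.reason == "tag_pair_mismatch"

    def test_unknown_tag_rejected(self):
        sheet = sheet_for({"AACCGGTT": "s1"})
        read = build_read("GGGGTTTT", "GGGGTTTT", self.INSERT)
        res = demultiplex(read, sheet, "COI")
        assert res.reason == "unknown_tag"

    def test_primer_mismatch_rejected(self):
        sheet = sheet_for({"AACCGGTT": "s1"})
        read = build_read("AACCGGTT", "AACCGGTT", self.INSERT)
        # force >2 genuine mismatches: GG + W can never match CCC
        pos = 2 + 8
        bad = read[:pos] + "CCC" + read[pos + 3:]
        res = demultiplex(bad, sheet, "COI")
        assert res.sample_id is None
        assert res.reason == "primer_mismatch"

    def test_noise_free_simulation_fully_recovered(self, clean_sim):
        """With no errors/switching, every read lands in its true sample."""
        pairs = reads_to_pairs(clean_sim.reads)
        uniques, report, assigned = run_readprep(
            pairs, clean_sim.samplesheet, clean_sim.cfg.marker)
        assert report.conserves_reads()
        assert report.n_assigned == report.n_input
        truth = clean_sim.truth.reads.set_index("read_id")
        ok = sum(assigned[r] == truth.loc[r, "true_sample_id"] for r in assigned)
        assert ok == len(assigned) == len(pairs)


class TestLengthFilter:
    @pytest.mark.parametrize("marker,length,kept", [
        ("COI", 313, True),   # the ~313-bp Leray fragment
        ("COI", 300, True),   # closed lower bound
        ("COI", 299, False),
        ("COI", 320, True),   # closed upper bound
        ("COI", 321, False),
        ("18S", 110, True),   # the ~110-bp V7 fragment
        ("18S", 75, True),
        ("18S", 74, False),
        ("18S", 180, True),
        ("18S", 181, False),
    ])
    def test_boundaries(self, marker, length, kept):
        out, removed = length_filter([("s", "A" * length)], marker)
        assert (len(out) == 1) is kept

    def test_unknown_marker_raises(self):
        with pytest.raises(ValueError):
            length_filter([("s", "A" * 100)], "16S")


class TestDereplicate:
    def test_basic_grouping(self):
        out = dereplicate([("s1", "ACGT"), ("s1", "ACGT"), ("s1", "ACGA")])
        assert sorted((u.seq, u.total) for u in out) == [("ACGA", 1), ("ACGT", 2)]

    def test_cross_sample_counts(self):
        out = dereplicate([("s1", "ACGT")] * 3 + [("s2", "ACGT")] * 5)
        assert len(out) == 1
        assert out[0].counts == {"s1": 3, "s2": 5}
        assert out[0].total == 8

    def test_conservation_vs_counting_oracle(self, rng):
        n = 10_000
        seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 8))
                for _ in range(n)]
        samples = [f"s{rng.integers(3)}" for _ in range(n)]
        out = dereplicate(list(zip(samples, seqs)))
        # independent oracle: plain dict counting
        oracle = {}
        for sid, s in zip(samples, seqs):
            oracle[s] = oracle.get(s, 0) + 1
        assert sum(u.total for u in out) == n
        assert {u.seq: u.total for u in out} == oracle

    @given(st.lists(st.tuples(st.sampled_from(["s1", "s2"]),
                              st.text(alphabet="ACGT", min_size=1, max_size=6)),
                    max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_order_independence(self, items):
        a = dereplicate(items)
        b = dereplicate(list(reversed(items)))
        assert [(u.seq, u.counts) for u in a] == [(u.seq, u.counts) for u in b]


class TestSingletons:
    def test_18s_policy_removes_singletons(self):
        uniqs = [UniqueSeq("AA", {"s": 1}), UniqueSeq("CC", {"s": 1}),
                 UniqueSeq("GG", {"s": 2}), UniqueSeq("TT", {"s": 5})]
        out = remove_singletons(uniqs, "18S")
        assert sorted(u.total for u in out) == [2, 5]

    def test_coi_policy_keeps_everything(self):
        uniqs = [UniqueSeq("AA", {"s": 1}), UniqueSeq("TT", {"s": 5})]
        assert remove_singletons(uniqs, "COI") == uniqs

    def test_empty_input(self):
        assert remove_singletons([], "18S") == []
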