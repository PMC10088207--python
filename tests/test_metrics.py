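import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import porebench as pb
from conftest import make_alignment
from helpers import jsd_direct, regex_homopolymers
from porebench.metrics import jensen_shannon_discrete


def make_read(seq, quals=None, read_id="r"):
    return pb.Read(read_id, seq, quals if quals is not None else [20] * len(seq))


class TestClassifyOutcome:
    def test_empty_sequence_is_not_basecalled(self):
        out = pb.classify_outcome(make_read(""), None, reference_length=100)
        assert out.category == "not_basecalled"

    def test_missing_alignment_is_not_aligned(self):
        out = pb.classify_outcome(make_read("ACGT"), None, reference_length=100)
        assert out.category == "not_aligned"

    @pytest.mark.parametrize("span,expected", [(40, "short_alignment"), (60, "pass"), (50, "pass")])
    def test_half_reference_rule(self, span, expected):
        aln = make_alignment("M" * span, "A" * span, "A" * span)
        out = pb.classify_outcome(make_read("A" * span), aln, reference_length=100)
        assert out.category == expected

    def test_error_absorbed_as_other(self):
        out = pb.classify_outcome(make_read("ACGT"), None, 100, error="boom")
        assert out.category == "other"
        assert "boom" in out.detail


class TestEventRates:
    def test_all_match(self):
        aln = make_alignment("M" * 100, "A" * 100, "A" * 100)
        r = pb.event_rates(aln)
        assert (r.match_rate, r.mismatch_rate, r.insertion_rate, r.deletion_rate) == (1.0, 0, 0, 0)

    def test_constructed_counts(self):
        # 90 M, 5 X, 5 D, 3 I over reference span 100
        ops = "M" * 90 + "X" * 5 + "D" * 5 + "I" * 3
        q = "A" * 90 + "C" * 5 + "-" * 5 + "G" * 3
        r = "A" * 95 + "G" * 5 + "-" * 3
        rates = pb.event_rates(make_alignment(ops, q, r))
        assert rates.match_rate == pytest.approx(0.90)
        assert rates.mismatch_rate == pytest.approx(0.05)
        assert rates.deletion_rate == pytest.approx(0.05)
        assert rates.insertion_rate == pytest.approx(0.03)

    def test_reference_normalized_rates_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(5, 60))
            ops, q, r = [], [], []
            for _ in range(n):
                op = rng.choice(list("MXID"), p=[0.7, 0.1, 0.1, 0.1])
                ops.append(op)
                if op == "M":
                    q.append("A"); r.append("A")
                elif op == "X":
                    q.append("A"); r.append("C")
                elif op == "I":
                    q.append("G"); r.append("-")
                else:
                    q.append("-"); r.append("T")
            if "".join(ops).count("I") == n:
                continue
            rates = pb.event_rates(make_alignment("".join(ops), "".join(q), "".join(r)))
            assert rates.match_rate + rates.mismatch_rate + rates.deletion_rate == pytest.approx(1, abs=1e-12)

    def test_empty_path_rejected(self):
        with pytest.raises(ValueError):
            pb.event_rates(make_alignment("", "", ""))


class TestFindHomopolymers:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAAA", [(0, 5, "A")]),
            ("AAAA", []),
            ("CCCCCGTTTTTT", [(0, 5, "C"), (6, 12, "T")]),
            ("NNNNNN", []),
        ],
    )
    def test_examples(self, seq, expected):
        got = [(h.start, h.end, h.base) for h in pb.find_homopolymers(seq)]
        assert got == expected

    @given(st.text(alphabet="AC", max_size=10))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_regex_oracle_binary_alphabet(self, seq):
        got = [(h.start, h.end, h.base) for h in pb.find_homopolymers(seq)]
        assert got == regex_homopolymers(seq)

    def test_regex_oracle_random_strings(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        for _ in range(300):
            seq = "".join(rng.choice(bases, size=50))
            got = [(h.start, h.end, h.base) for h in pb.find_homopolymers(seq)]
            assert got == regex_homopolymers(seq)

    def test_min_length_guard(self):
        with pytest.raises(ValueError):
            pb.find_homopolymers("AAAA", min_length=1)


def _expand(query, reference, ref_start=0, cigar=None, read_id="r", ref_id="ref"):
    aln = pb.global_align(query, reference)
    return pb.Alignment(
        read_id=read_id,
        ref_id=ref_id,
        ops=aln.ops,
        query_aligned=aln.query_aligned,
        ref_aligned=aln.ref_aligned,
        ref_start=ref_start,
    )


class TestHomopolymerErrorRates:
    REF = pb.ReferenceSequence("ref", "GCGCAAAAATGCA")  # one A-homopolymer at [4, 9)

    def test_perfect_alignment_rate_zero(self):
        aln = _expand(self.REF.sequence, self.REF.sequence)
        rates = pb.homopolymer_error_rates([aln], [self.REF])
        assert rates["A"] == 0.0
        assert rates["C"] is None  # no C-homopolymer covered: undefined, not 0

    def test_deletion_inside_region_counts(self):
        query = "GCGCAAAATGCA"  # one A deleted
        aln = _expand(query, self.REF.sequence)
        rates = pb.homopolymer_error_rates([aln], [self.REF])
        assert rates["A"] == 1.0

    def test_partially_covered_region_excluded(self):
        # alignment covering only [0, 7) cuts the homopolymer: excluded
        aln = make_alignment("M" * 7, self.REF.sequence[:7], self.REF.sequence[:7])
        rates = pb.homopolymer_error_rates([aln], [self.REF])
        assert rates["A"] is None

    def test_insertion_strictly_inside_counts_but_boundary_does_not(self):
        # insertion anchored between positions 5 and 6 (inside [4, 9))
        inside = make_alignment(
            "M" * 6 + "I" + "M" * 7,
            self.REF.sequence[:6] + "A" + self.REF.sequence[6:],
            self.REF.sequence[:6] + "-" + self.REF.sequence[6:],
        )
        assert pb.homopolymer_error_rates([inside], [self.REF])["A"] == 1.0
        # insertion at the region's left edge (gap before position 4): no error
        edge = make_alignment(
            "M" * 4 + "I" + "M" * 9,
            self.REF.sequence[:4] + "T" + self.REF.sequence[4:],
            self.REF.sequence[:4] + "-" + self.REF.sequence[4:],
        )
        assert pb.homopolymer_error_rates([edge], [self.REF])["A"] == 0.0

    def test_per_base_denominator_switch(self):
        query = "GCGCAAAATGCA"
        aln = _expand(query, self.REF.sequence)
        rates = pb.homopolymer_error_rates([aln], [self.REF], per_base_denominator=True)
        assert rates["A"] == 1.0  # 5 erroneous bases / 5 homopolymer bases

    def test_no_homopolymer_all_undefined(self):
        ref = pb.ReferenceSequence("ref", "ACGTACGTACGT")
        aln = _expand(ref.sequence, ref.sequence)
        assert all(v is None for v in pb.homopolymer_error_rates([aln], [ref]).values())


class TestBaseCorrectness:
    @pytest.mark.parametrize(
        "ops,q,r,expected",
        [
            ("MMMM", "ACGT", "ACGT", [True] * 4),
            ("MXIM", "ACGT", "AT-T", [True, False, False, True]),
            ("MDDM", "A--T", "ACGT", [True, True]),
        ],
    )
    def test_labels(self, ops, q, r, expected):
        assert pb.label_base_correctness(make_alignment(ops, q, r)) == expected


class TestPhredOverlap:
    def test_identical_distributions(self):
        assert pb.phredq_overlap([10, 20, 30], [30, 10, 20]) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert pb.phredq_overlap([1, 2, 3], [10, 11]) == 0.0

    def test_worked_example(self):
        assert pb.phredq_overlap([10, 10, 20], [20, 20, 30]) == pytest.approx(1 / 3)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.integers(0, 40, size=rng.integers(1, 30)).tolist()
            b = rng.integers(0, 40, size=rng.integers(1, 30)).tolist()
            o1, o2 = pb.phredq_overlap(a, b), pb.phredq_overlap(b, a)
            assert o1 == pytest.approx(o2)
            assert 0 <= o1 <= 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pb.phredq_overlap([], [1])


class TestMeanReadQuality:
    @pytest.mark.parametrize("quals,mean", [([20, 20, 20], 20.0), ([10, 30], 20.0), ([0, 0, 30], 10.0)])
    def test_mean(self, quals, mean):
        assert pb.mean_read_quality(make_read("A" * len(quals), quals)) == mean

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pb.mean_read_quality(make_read(""))


class TestQualityAuc:
    def test_constant_match_rate(self):
        recs = [(float(q), 0.9) for q in range(37)]
        assert pb.quality_auc(recs, step=5) == pytest.approx(0.9, abs=1e-9)

    def test_two_read_worked_example(self):
        # points (0.5, 1.0), (1.0, 0.5): anchor 0.5*1.0 + trapezoid 0.375
        assert pb.quality_auc([(30, 1.0), (10, 0.0)], step=1) == pytest.approx(0.875)

    def test_reversed_quality_order_lowers_auc(self):
        # anti-sorted curve: points (0.5, 0.0), (1.0, 0.5) -> 0.125 < 0.875
        assert pb.quality_auc([(10, 1.0), (30, 0.0)], step=1) == pytest.approx(0.125)

    def test_shuffled_never_beats_sorted(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(3, 40))
            rates = rng.random(n)
            quals = np.sort(rng.random(n) * 40)[::-1]
            sorted_recs = list(zip(quals, np.sort(rates)[::-1]))
            best = pb.quality_auc(sorted_recs, step=3)
            perm = rng.permutation(n)
            shuffled = list(zip(quals, np.sort(rates)[::-1][perm]))
            assert pb.quality_auc(shuffled, step=3) <= best + 1e-12

    def test_fewer_reads_than_step(self):
        recs = [(30.0, 0.8), (20.0, 0.4)]
        assert pb.quality_auc(recs, step=50) == pytest.approx(0.6)


class TestErrorProfile:
    def test_perfect_read_counts_occurrences_only(self):
        aln = make_alignment("MMMMM", "ACGTA", "ACGTA")
        prof = pb.error_profile([aln])
        assert prof.total("mismatch") == 0
        assert {c: n for c, n in prof.context_occurrences.items() if n} == {
            "ACG": 1, "CGT": 1, "GTA": 1,
        }

    def test_mismatch_centered_on_basecall_context(self):
        # basecall ACGT with a mismatch at position 1 -> context ACG
        aln = make_alignment("MXMM", "ACGT", "ATGT")
        prof = pb.error_profile([aln])
        assert prof.context_counts["ACG"]["mismatch"] == 1
        assert prof.base_counts["C"]["mismatch"] == 1

    def test_deletion_anchored_to_preceding_base(self):
        # basecall ACGT, deletion after basecall position 1 (C)
        aln = make_alignment("MMDMM", "AC-GT", "ACAGT")
        prof = pb.error_profile([aln])
        assert prof.context_counts["ACG"]["deletion"] == 1
        assert prof.base_counts["C"]["deletion"] == 1

    def test_boundary_event_in_base_counts_only(self):
        # mismatch at basecall position 0: no 3-mer context
        aln = make_alignment("XMMM", "ACGT", "TCGT")
        prof = pb.error_profile([aln])
        assert prof.base_counts["A"]["mismatch"] == 1
        assert sum(c["mismatch"] for c in prof.context_counts.values()) == 0

    def test_empty_alignment_list_all_zero(self):
        prof = pb.error_profile([])
        assert prof.total("mismatch") == prof.total("insertion") == prof.total("deletion") == 0

    def test_context_totals_plus_boundary_equal_class_counts(self):
        rng = np.random.default_rng(2)
        ref = pb.generate_reference(3000, seed=4)
        model = pb.ErrorModel()
        alns = [
            pb.simulate_read(ref, (0, 3000), model, seed=rng, read_id=f"r{i}").truth
            for i in range(5)
        ]
        prof = pb.error_profile(alns)
        for cls, op in (("mismatch", "X"), ("insertion", "I"), ("deletion", "D")):
            path_count = sum(a.count(op) for a in alns)
            base_total = prof.total(cls)
            ctx_total = sum(c[cls] for c in prof.context_counts.values())
            assert base_total == path_count  # anchorable events all counted per base
            assert ctx_total <= base_total  # boundary events excluded per context


class TestJsdAndSignatures:
    def test_randomness_zero_when_context_matches_base(self):
        prof = pb.ErrorProfile()
        for ctx in ("ACA", "ACG"):
            prof.context_counts[ctx]["mismatch"] = 10
            prof.context_counts[ctx]["deletion"] = 10
        prof.base_counts["C"]["mismatch"] = 20
        prof.base_counts["C"]["deletion"] = 20
        rnd = pb.profile_randomness(prof)
        assert rnd["ACA"] == pytest.approx(0.0, abs=1e-12)

    def test_randomness_disjoint_is_one_bit(self):
        prof = pb.ErrorProfile()
        prof.context_counts["ACA"]["deletion"] = 5
        prof.base_counts["C"]["mismatch"] = 100  # base profile all mismatches
        assert pb.profile_randomness(prof)["ACA"] == pytest.approx(1.0)

    def test_randomness_half_vs_point_mass(self):
        prof = pb.ErrorProfile()
        prof.context_counts["ACA"]["mismatch"] = 5
        prof.context_counts["ACA"]["insertion"] = 5
        prof.base_counts["C"]["mismatch"] = 100
        assert pb.profile_randomness(prof)["ACA"] == pytest.approx(0.3113, abs=1e-4)

    def test_signature_divergence_identity_and_symmetry(self):
        a, b = pb.ErrorProfile(), pb.ErrorProfile()
        a.context_counts["ACA"]["mismatch"] = 3
        a.context_counts["TGT"]["deletion"] = 1
        b.context_counts["ACA"]["mismatch"] = 1
        b.context_counts["GGG"]["insertion"] = 2
        assert pb.signature_divergence(a, a) == pytest.approx(0.0, abs=1e-12)
        assert pb.signature_divergence(a, b) == pytest.approx(pb.signature_divergence(b, a))

    def test_signature_divergence_matches_direct_formula(self):
        a, b = pb.ErrorProfile(), pb.ErrorProfile()
        a.context_counts["AAA"]["mismatch"] = 1
        a.context_counts["CCC"]["deletion"] = 1
        b.context_counts["AAA"]["mismatch"] = 1
        b.context_counts["CCC"]["insertion"] = 1
        # flattened distributions: overlap only on AAA-mismatch (0.5 each)
        expected = jsd_direct([0.5, 0.5, 0.0], [0.5, 0.0, 0.5])
        assert pb.signature_divergence(a, b) == pytest.approx(expected)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            pb.signature_divergence(pb.ErrorProfile(), pb.ErrorProfile())


class TestClusterSignatures:
    def _profile(self, ctx, cls, n):
        p = pb.ErrorProfile()
        p.context_counts[ctx][cls] = n
        return p

    def test_identical_pair_merges_first(self):
        a = self._profile("AAA", "mismatch", 5)
        b = self._profile("AAA", "mismatch", 7)  # same normalized signature as a
        c = self._profile("TTT", "deletion", 5)
        z, labels = pb.cluster_signatures([a, c, b], ["a", "c", "b"])
        assert labels == ["a", "c", "b"]
        first = sorted([int(z[0, 0]), int(z[0, 1])])
        assert first == [0, 2]  # leaves a and b
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_heights_zero(self):
        profs = [self._profile("AAA", "mismatch", n) for n in (1, 2, 3)]
        z, _ = pb.cluster_signatures(profs, list("abc"))
        assert np.allclose(z[:, 2], 0.0)

    def test_permutation_preserves_heights(self):
        a = self._profile("AAA", "mismatch", 5)
        b = self._profile("CCC", "insertion", 5)
        c = self._profile("TTT", "deletion", 5)
        z1, _ = pb.cluster_signatures([a, b, c], list("abc"))
        z2, _ = pb.cluster_signatures([c, a, b], list("cab"))
        assert np.allclose(np.sort(z1[:, 2]), np.sort(z2[:, 2]))

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            pb.cluster_signatures([pb.ErrorProfile()], ["a"])


@given(
    p=st.lists(st.floats(0.01, 1), min_size=2, max_size=6),
    q=st.lists(st.floats(0.01, 1), min_size=2, max_size=6),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_jsd_discrete_matches_direct_formula(p, q):
    k = max(len(p), len(q))
    p = np.pad(np.asarray(p), (0, k - len(p)))
    q = np.pad(np.asarray(q), (0, k - len(q)))
    p, q = p / p.sum(), q / q.sum()
    got = jensen_shannon_discrete(p, q)
    assert got == pytest.approx(jsd_direct(p, q), abs=1e-10)
    assert 0 <= got <= 1 + 1e-12
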