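"""Consensus alignment and HR/NHE mechanism classifier tests."""

import numpy as np
import pytest

from temrkit._seq import random_dna, revcomp
from temrkit.classify import TEAnnotationIndex
from temrkit.junction import compute_microhomology
from temrkit.mechanism import (AlignScoring, classify_cohort, extract_flanks,
                               infer_mechanism, local_align, map_mh_to_consensus,
                               percent_similarity)
from temrkit.stats import binom_two_tailed


def gotoh_local_score(query: str, target: str, scoring: AlignScoring) -> float:
    """Independent full-matrix affine local-alignment oracle (score only).

    Same gap convention as the implementation: a gap of length L costs
    open + extend*(L-1).
    """
    m, n = len(query), len(target)
    NEG = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]   # gap in target
    F = [[NEG] * (n + 1) for _ in range(m + 1)]   # gap in query
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i - 1][j] - scoring.gap_open,
                          E[i - 1][j] - scoring.gap_extend)
            F[i][j] = max(H[i][j - 1] - scoring.gap_open,
                          F[i][j - 1] - scoring.gap_extend)
            s = scoring.match if query[i - 1] == target[j - 1] else scoring.mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestLocalAlign:
    def test_self_alignment(self, alu):
        a = local_align(alu.sequence, alu)
        assert a.consensus_span == (0, len(alu.sequence))
        assert a.identity_percent == 100.0

    def test_monomer_slice_maps_into_right_monomer(self, alu):
        s, e = alu.monomer_bounds[1]
        a = local_align(alu.sequence[s:s + 120], alu)
        assert s <= a.consensus_span[0] and a.consensus_span[1] <= e

    def test_internal_mismatch_twelve_mer(self):
        scoring = AlignScoring()
        q = "ACGTAAGTCCGT"
        t = "ACGTACGTCCGT"
        a = local_align(q, t, scoring=scoring)
        assert a.score == gotoh_local_score(q, t, scoring) == 11 * 5 - 4
        assert a.identity_percent == pytest.approx(100 * 11 / 12)

    def test_matches_brute_force_dp_on_random_pairs(self):
        scoring = AlignScoring()
        rng = np.random.default_rng(17)
        for _ in range(200):
            q = random_dna(rng, int(rng.integers(5, 31)), gc=0.5)
            t = random_dna(rng, int(rng.integers(5, 31)), gc=0.5)
            assert local_align(q, t, scoring=scoring).score == \
                pytest.approx(gotoh_local_score(q, t, scoring))

    def test_empty_query_rejected(self, alu):
        with pytest.raises(ValueError):
            local_align("", alu)


class TestPercentSimilarity:
    def test_identical(self):
        assert percent_similarity("ACGTACGTAC", "ACGTACGTAC") == 100.0

    def test_single_mismatch_eight_mer(self):
        assert percent_similarity("ACGTACGT", "ACGAACGT") == 87.5

    def test_symmetric(self, rng):
        for _ in range(25):
            a = random_dna(rng, 60, gc=0.5)
            b = random_dna(rng, 60, gc=0.5)
            assert percent_similarity(a, b) == pytest.approx(percent_similarity(b, a))

    def test_diverged_copies_near_expectation(self, alu):
        from temrkit.synth import mutate_from_consensus
        s1, _ = mutate_from_consensus(alu, 0.05, seed=3)
        s2, _ = mutate_from_consensus(alu, 0.05, seed=4)
        sim = percent_similarity(s1, s2)
        # two independent 5% substitution processes: ~90.25% expected identity
        assert 84.0 < sim < 96.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percent_similarity("", "ACGT")


class TestExtractFlanks:
    def test_plus_strand_flank_length(self, small_study):
        idx = TEAnnotationIndex(small_study.reference.annotation)
        ref = small_study.reference.sequence
        for t in small_study.truth:
            if not t.is_temr or t.te_orientation != "direct":
                continue
            te5 = idx.query(t.chrom, t.start)
            if te5.strand != "+":
                continue
            fl = extract_flanks(ref, t.sv_type, t.start, t.end, te5,
                                idx.query(t.chrom, t.end))
            assert fl.mh_cons == t.mh_length
            break

    def test_minus_strand_flank_is_reverse_complement_slice(self, small_study):
        idx = TEAnnotationIndex(small_study.reference.annotation)
        ref = small_study.reference.sequence
        found = False
        for t in small_study.truth:
            if not t.is_temr:
                continue
            te5 = idx.query(t.chrom, t.start)
            te3 = idx.query(t.chrom, t.end)
            if te5.strand == "-" and te3.strand == "-" and t.sv_type == "DEL":
                fl = extract_flanks(ref, t.sv_type, t.start, t.end, te5, te3)
                # the head element on minus pairs is the 3' genomic copy
                assert not fl.head_is_te5
                genomic = ref[te3.te_start:te3.te_end]
                assert fl.flank3 in revcomp(genomic) or fl.flank5 in revcomp(genomic)
                found = True
                break
        assert found

    def test_chimera_reconstruction_covers_consensus(self, small_study):
        """For a planted direct HR event, flank5 ++ flank3[mh:] aligns to the
        consensus as one contiguous local alignment covering >= 95% of the
        chimera."""
        idx = TEAnnotationIndex(small_study.reference.annotation)
        ref = small_study.reference.sequence
        checked = 0
        for t in small_study.truth:
            if not (t.is_temr and t.mechanism == "HR" and t.te_family == "Alu"
                    and t.monomer_cross is None):
                continue
            fl = extract_flanks(ref, t.sv_type, t.start, t.end,
                                idx.query(t.chrom, t.start), idx.query(t.chrom, t.end))
            chimera = fl.flank5 + fl.flank3[t.mh_length:]
            a = local_align(chimera, small_study.consensus_set["Alu"])
            assert a.query_coverage >= 0.95
            checked += 1
            if checked == 5:
                break
        assert checked >= 3


class TestInferMechanism:
    def _call(self, study, truth, idx=None):
        idx = idx or TEAnnotationIndex(study.reference.annotation)
        ref = study.reference.sequence
        te5 = idx.query(truth.chrom, truth.start)
        te3 = idx.query(truth.chrom, truth.end)
        mh = compute_microhomology(ref, truth.start, truth.end,
                                   "DUP" if truth.sv_type == "mCNV" else truth.sv_type)
        fl = extract_flanks(ref, truth.sv_type, truth.start, truth.end, te5, te3)
        return infer_mechanism(fl, mh.mh_sequence,
                               study.consensus_set[truth.te_family])

    def test_recovers_planted_labels(self, small_study):
        idx = TEAnnotationIndex(small_study.reference.annotation)
        results = []
        for t in small_study.truth:
            if not t.is_temr:
                continue
            call = self._call(small_study, t, idx)
            results.append((t.mechanism, call))
            if call.label == "HR":
                # hard invariant: HR overlap equals the junction microhomology
                assert call.overlap_bp == t.mh_length
                if t.mechanism == "HR" and t.consensus_junction_position is not None:
                    assert call.consensus_junction_position == t.consensus_junction_position
        agree = sum(truth_label == c.label for truth_label, c in results)
        assert agree == len(results)

    def test_monomer_cross_direction(self, small_study):
        idx = TEAnnotationIndex(small_study.reference.annotation)
        seen = {"single": 0, "triple": 0}
        for t in small_study.truth:
            if not t.is_temr or t.monomer_cross is None:
                continue
            call = self._call(small_study, t, idx)
            assert call.label == "HR"
            expected = "left-to-right" if t.monomer_cross == "single" else "right-to-left"
            assert call.monomer_cross == expected
            seen[t.monomer_cross] += 1
        assert seen["single"] >= 1 and seen["triple"] >= 1

    def test_polya_microhomology_flagged(self, alu):
        from temrkit.mechanism import FlankPair
        fl = FlankPair(flank5=alu.sequence[:100], flank3=alu.sequence[100:],
                       mh_cons=10, head_is_te5=True, c_head=100, c_tail=100)
        call = infer_mechanism(fl, "AAAAAAAAAA", alu)
        assert call.label == "MANUAL_REVIEW" and call.review_reason == "polyA"

    def test_discordant_overlap_flagged(self, alu):
        from temrkit.mechanism import FlankPair
        # flanks overlap by 40 consensus bases but mh is only 6
        fl = FlankPair(flank5=alu.sequence[:140], flank3=alu.sequence[100:],
                       mh_cons=6, head_is_te5=True, c_head=140, c_tail=100)
        call = infer_mechanism(fl, "GCGCGC", alu)
        assert call.label == "MANUAL_REVIEW" and call.review_reason == "discordant"


class TestMapMhToConsensus:
    def test_interval_arithmetic(self, alu):
        from temrkit.mechanism import MechanismCall
        call = MechanismCall("HR", 10, 50, None, "none")
        mapped = map_mh_to_consensus(call, 10, alu)
        assert mapped["interval"] == (50, 60)

    def test_box_annotation(self, alu):
        from temrkit.mechanism import MechanismCall
        bs, be = alu.boxes["A-Box"]
        call = MechanismCall("HR", 5, bs + 1, None, "none")
        assert "A-Box" in map_mh_to_consensus(call, 5, alu)["boxes"]

    def test_non_hr_rejected(self):
        from temrkit.mechanism import MechanismCall
        with pytest.raises(ValueError):
            map_mh_to_consensus(MechanismCall("NHE", 0, None, None, "none"), 3)

    def test_planted_junction_positions_match_truth(self, small_study):
        idx = TEAnnotationIndex(small_study.reference.annotation)
        ref = small_study.reference.sequence
        for t in small_study.truth:
            if not (t.is_temr and t.mechanism == "HR"):
                continue
            te5 = idx.query(t.chrom, t.start)
            te3 = idx.query(t.chrom, t.end)
            mh = compute_microhomology(ref, t.start, t.end,
                                       "DUP" if t.sv_type == "mCNV" else t.sv_type)
            fl = extract_flanks(ref, t.sv_type, t.start, t.end, te5, te3)
            call = infer_mechanism(fl, mh.mh_sequence, small_study.consensus_set[t.te_family])
            mapped = map_mh_to_consensus(call, mh.mh_length,
                                         small_study.consensus_set[t.te_family])
            assert mapped["interval"][0] == t.consensus_junction_position


class TestClassifyCohort:
    def test_label_counts(self):
        calls = ([("Alu", _mk("HR"))] * 80 + [("Alu", _mk("NHE"))] * 20)
        summary = classify_cohort(calls)
        assert summary["n_hr"] == 80 and summary["n_nhe"] == 20
        assert summary["hr_fraction_percent"] == 80.0

    def test_all_review(self):
        calls = [("Alu", _mk("MANUAL_REVIEW", reason="polyA"))] * 4
        summary = classify_cohort(calls)
        assert summary["percent_categorized"] == 0.0

    def test_monomer_tally_feeds_binomial(self):
        calls = ([("Alu", _mk("HR", cross="left-to-right"))] * 1
                 + [("Alu", _mk("HR", cross="right-to-left"))] * 9)
        summary = classify_cohort(calls)
        assert summary["monomer_chimeras"] == {"single": 1, "three": 9}
        p = binom_two_tailed(summary["monomer_chimeras"]["single"],
                             sum(summary["monomer_chimeras"].values()))
        assert f"{p:.3f}" == "0.021"


def _mk(label, cross=None, reason="none"):
    from temrkit.mechanism import MechanismCall
    return MechanismCall(label, 1 if label == "HR" else 0,
                         5 if label == "HR" else None, cross, reason)


class TestMechanismRecoveryBenchmark:
    def test_recovery_at_scale_per_class(self):
        """With >= 100 planted events per mechanism class (fixed seed, copy
        divergence <= 0.15), HR/NHE labels are recovered with >= 95%
        agreement in each class."""
        from temrkit.synth import simulate_study

        study = simulate_study(
            seed=71, genome_length=8_000_000, n_temr=240, n_background_svs=0,
            params={"hr_prob": {"Alu": 0.5, "LINE-1": 0.5}, "hr_prob_inv": 0.5,
                    "alu_fraction": 0.85})
        idx = TEAnnotationIndex(study.reference.annotation)
        ref = study.reference.sequence
        per_class = {"HR": [0, 0], "NHE": [0, 0]}
        for t in study.truth:
            te5 = idx.query(t.chrom, t.start)
            te3 = idx.query(t.chrom, t.end)
            mh = compute_microhomology(ref, t.start, t.end,
                                       "DUP" if t.sv_type == "mCNV" else t.sv_type)
            fl = extract_flanks(ref, t.sv_type, t.start, t.end, te5, te3)
            call = infer_mechanism(fl, mh.mh_sequence,
                                   study.consensus_set[t.te_family])
            per_class[t.mechanism][0] += call.label == t.mechanism
            per_class[t.mechanism][1] += 1
        for label, (ok, n) in per_class.items():
            assert n >= 100, f"{label}: only {n} planted events"
            assert ok / n >= 0.95, f"{label}: {ok}/{n} recovered"
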