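from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import indelprof as ip
from indelprof.calling import RawIndel, call_read, to_cut_relative
from indelprof.simulate import realized_truth_counts


def rec(cigar, seq, ref_start=0, mapq=60, dup=False, read_id="r1", ref_name="amp"):
    return ip.AlignedReadRecord(
        read_id=read_id, ref_name=ref_name, ref_start=ref_start,
        cigar=cigar, query_seq=seq, mapq=mapq, is_duplicate=dup,
    )


class TestRecordFilters:
    def test_mapq_boundary_38(self):
        records = [rec("4M", "ACGT", mapq=q) for q in (37, 38, 39)]
        kept = ip.record_filters(records)
        assert [r.mapq for r in kept] == [38, 39]

    def test_duplicates_removed(self):
        records = [rec("4M", "ACGT", dup=True), rec("4M", "ACGT")]
        assert ip.record_filters(records) == [records[1]]

    def test_empty_and_order_preserved(self):
        assert ip.record_filters([]) == []
        records = [rec("4M", "ACGT", read_id=f"r{i}") for i in range(5)]
        assert ip.record_filters(records) == records


class TestParseAlignmentRecord:
    @pytest.mark.parametrize(
        "cigar,seq,start,expected",
        [
            ("100M", "A" * 100, 0, []),
            ("50M2D50M", "A" * 100, 0, [("deletion", 50, 2, "")]),
            ("30M1I70M", "C" * 30 + "A" + "C" * 70, 0, [("insertion", 30, 1, "A")]),
            ("10M3I5M2D10M", "G" * 10 + "TTT" + "G" * 15, 100,
             [("insertion", 110, 3, "TTT"), ("deletion", 115, 2, "")]),
        ],
    )
    def test_cigar_semantics(self, cigar, seq, start, expected):
        raws = ip.parse_alignment_record(rec(cigar, seq, ref_start=start))
        assert [(r.kind, r.pos, r.size, r.inserted_seq) for r in raws] == expected

    def test_soft_clips_consume_query_only(self):
        raws = ip.parse_alignment_record(rec("5S10M5S", "A" * 20, ref_start=7))
        assert raws == []

    def test_cigar_query_mismatch_rejected(self):
        with pytest.raises(ip.RecordRejected, match="consumes"):
            ip.parse_alignment_record(rec("100M", "ACGT"))

    def test_malformed_cigar_rejected(self):
        with pytest.raises(ip.RecordRejected, match="malformed"):
            ip.parse_alignment_record(rec("10Q", "A" * 10))


def _apply(ref, indel):
    """Edited sequence produced by a raw indel — oracle helper."""
    if indel.kind == "deletion":
        return ref[: indel.pos] + ref[indel.pos + indel.size :]
    return ref[: indel.pos] + indel.inserted_seq + ref[indel.pos :]


class TestLeftAlign:
    def test_deletion_in_homopolymer_goes_leftmost(self):
        ref = "CAAAT"
        for pos in (1, 2, 3):
            out = ip.left_align_indel(RawIndel("deletion", pos, 1), ref)
            assert out.pos == 1

    def test_insertion_adjacent_to_repeat(self):
        ref = "CTTA"
        out = ip.left_align_indel(RawIndel("insertion", 3, 1, "T"), ref)
        assert out.pos == 1 and out.inserted_seq == "T"

    def test_non_repetitive_context_unchanged(self):
        ref = "ACGTACGT"
        raw = RawIndel("deletion", 3, 2)
        assert ip.left_align_indel(raw, ref) == raw

    @settings(max_examples=200, derandomize=True)
    @given(st.data())
    def test_matches_enumeration_oracle(self, data):
        """Left alignment lands on the leftmost placement among all
        reference-equivalent placements (same edited sequence)."""
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        ref = "".join(rng.choice(list("AACT"), size=30))
        kind = data.draw(st.sampled_from(["deletion", "insertion"]))
        size = data.draw(st.integers(1, 3))
        if kind == "deletion":
            pos = data.draw(st.integers(0, 30 - size))
            raw = RawIndel("deletion", pos, size)
            candidates = [
                RawIndel("deletion", p, size) for p in range(0, 30 - size + 1)
            ]
        else:
            pos = data.draw(st.integers(0, 30))
            seq = "".join(rng.choice(list("ACT"), size=size))
            raw = RawIndel("insertion", pos, size, seq)
            candidates = [
                RawIndel("insertion", p, size, s)
                for p in range(0, 31)
                for s in {"".join(x) for x in __import__("itertools").product("ACGT", repeat=size)}
            ]
        edited = _apply(ref, raw)
        leftmost = min(
            (c for c in candidates if _apply(ref, c) == edited), key=lambda c: c.pos
        )
        out = ip.left_align_indel(raw, ref)
        assert out.pos == leftmost.pos
        assert _apply(ref, out) == edited
        assert ip.left_align_indel(out, ref) == out  # idempotent


class TestWindowFilter:
    def test_start_boundary_at_5(self, site):
        cut = site.guide_strand_cut
        inside = RawIndel("deletion", cut - 5, 1)  # start_rel -5
        outside = RawIndel("deletion", cut - 6, 1)  # start_rel -6
        events = ip.window_filter([inside, outside], site)
        assert [e.start_rel for e in events] == [-5]

    def test_plus_side_boundary(self, site):
        cut = site.guide_strand_cut
        inside = RawIndel("deletion", cut + 4, 1)  # start_rel +5
        outside = RawIndel("deletion", cut + 5, 1)  # start_rel +6
        events = ip.window_filter([inside, outside], site)
        assert [e.start_rel for e in events] == [5]

    def test_insertion_boundary_zero_is_cut(self, site):
        raw = RawIndel("insertion", site.guide_strand_cut, 1, "A")
        (event,) = ip.window_filter([raw], site)
        assert event.start_rel == 0 and event.kind == "insertion"

    def test_empty_input(self, site):
        assert ip.window_filter([], site) == []

    def test_overlap_mode_keeps_long_spanning_deletion(self, site):
        cut = site.guide_strand_cut
        spanning = RawIndel("deletion", cut - 8, 12)  # starts at -8, crosses cut
        assert ip.window_filter([spanning], site) == []
        (event,) = ip.window_filter([spanning], site, membership="overlap")
        assert event.start_rel == -8

    def test_never_emits_outside_window_in_start_mode(self, site):
        rng = np.random.default_rng(0)
        cut = site.guide_strand_cut
        raws = [
            RawIndel("deletion", int(rng.integers(cut - 20, cut + 20)), int(rng.integers(1, 6)))
            for _ in range(200)
        ]
        events = ip.window_filter(raws, site)
        assert all(abs(e.start_rel) <= 5 for e in events)


class TestNaming:
    @pytest.mark.parametrize(
        "kind,start,size,ins,expected",
        [
            ("deletion", -4, 2, "", "-4:2D"),
            ("insertion", 0, 1, "A", "0:1I"),
            ("deletion", 5, 11, "", "5:11D"),
        ],
    )
    def test_grammar(self, kind, start, size, ins, expected):
        event = ip.IndelEvent("s", kind, start, size, ins)
        assert ip.name_indel(event) == expected

    def test_round_trip(self):
        for event in (
            ip.IndelEvent("s", "deletion", -3, 7),
            ip.IndelEvent("s", "insertion", -1, 2, "AT"),
        ):
            back = ip.parse_indel_name(event.name, site_id="s",
                                       inserted_seq=event.inserted_seq)
            assert back == event

    def test_unparseable_rejected(self):
        with pytest.raises(ValueError, match="unparseable"):
            ip.parse_indel_name("4D:2")


def _profile(site_id, events_counts, **kw):
    counts = Counter()
    for e, c in events_counts:
        counts[e] = c
    return ip.SiteIndelProfile(site_id=site_id, counts=counts, **kw)


class TestSubtractControl:
    def test_control_events_removed(self):
        e1 = ip.IndelEvent("s", "deletion", -1, 1)
        e2 = ip.IndelEvent("s", "insertion", 0, 1, "A")
        prof = _profile("s", [(e1, 5), (e2, 3)])
        control = _profile("s", [(e1, 1)])
        out = ip.subtract_control(prof, control)
        assert set(out.counts) == {e2}

    def test_empty_control_identity(self):
        e1 = ip.IndelEvent("s", "deletion", -1, 1)
        prof = _profile("s", [(e1, 5)])
        out = ip.subtract_control(prof, _profile("s", []))
        assert out.counts == prof.counts

    def test_superset_control_empties_profile(self):
        e1 = ip.IndelEvent("s", "deletion", -1, 1)
        prof = _profile("s", [(e1, 5)])
        out = ip.subtract_control(prof, _profile("s", [(e1, 2)]))
        assert out.total_indel_reads == 0

    def test_site_mismatch_rejected(self):
        with pytest.raises(ValueError, match="site mismatch"):
            ip.subtract_control(_profile("a", []), _profile("b", []))


class TestLowCountSiteFilter:
    def test_threshold_10_across_replicates(self):
        e = lambda sid: ip.IndelEvent(sid, "deletion", -1, 1)
        profs = [
            _profile("keep", [(e("keep"), 6)], replicate_id="r1"),
            _profile("keep", [(e("keep"), 4)], replicate_id="r2"),
            _profile("drop", [(e("drop"), 9)], replicate_id="r1"),
        ]
        kept = ip.filter_low_count_sites(profs)
        assert {p.site_id for p in kept} == {"keep"}

    def test_single_replicate_exactly_10(self):
        e = ip.IndelEvent("s", "deletion", -1, 1)
        assert ip.filter_low_count_sites([_profile("s", [(e, 10)])])

    def test_empty(self):
        assert ip.filter_low_count_sites([]) == []


class TestBackgroundEstimate:
    def test_mean_of_off_pool_counts(self):
        e = lambda sid: ip.IndelEvent(sid, "deletion", -1, 1)
        on = _profile("s", [(e("s"), 7)])
        off = [_profile("s", [(e("s"), 2)]), _profile("s", [(e("s"), 4)])]
        result = ip.background_estimate(on, off)
        assert result["background_indels"] == 3.0
        assert result["on_pool_indels"] == 7

    def test_zero_off_pool(self):
        on = _profile("s", [])
        assert ip.background_estimate(on, [_profile("s", [])])["background_indels"] == 0

    def test_noise_free_off_pool_simulation_gives_zero(self, clean_params):
        # unedited off-pool reads with zero noise carry no indels anywhere
        site = ip.make_target_sites(1, seed=21)[0]
        params = ip.RepairTruthParams(
            edited_fraction=0.0, noise_indel_rate=0.0, substitution_error_rate=0.0
        )
        truth = ip.build_truth_model(site, params)
        bundle = ip.simulate_reads(site, truth, 500, seed=5)
        prof = ip.call_site_profile(bundle.records, site)
        result = ip.background_estimate(prof, [prof])
        assert result["background_indels"] == 0.0


class TestEndToEnd:
    def test_zero_noise_profile_equals_truth_exactly(self, clean_params):
        for i, site in enumerate(ip.make_target_sites(4, seed=13)):
            truth = ip.build_truth_model(site, clean_params)
            bundle = ip.simulate_reads(site, truth, 3000, seed=50 + i)
            prof = ip.call_site_profile(bundle.records, site)
            assert dict(prof.counts) == realized_truth_counts(bundle)

    def test_event_call_precision_recall_with_default_noise(self):
        """At 5,000 reads with default error rates, per-read indel calls
        agree with truth labels at precision/recall >= 0.99."""
        site = ip.make_target_sites(1, seed=17)[0]
        truth = ip.build_truth_model(site)
        bundle = ip.simulate_reads(site, truth, 5000, seed=99)
        tp = fp = fn = 0
        for record, label in zip(bundle.records, bundle.truth_labels):
            called = call_read(record, site)
            if label in ("unedited", "noise"):
                # noise indels are real indels in the read; only unedited
                # reads with calls are false positives
                if label == "unedited" and called:
                    fp += 1
                continue
            expected = truth.outcomes[int(label)][0]
            if len(called) == 1 and called[0] == expected:
                tp += 1
            elif called:
                fp += 1
            else:
                fn += 1
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        assert precision >= 0.99 and recall >= 0.99
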