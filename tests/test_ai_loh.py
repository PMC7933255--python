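import math

import numpy as np
import pandas as pd
import pytest

from wgdevolve.ai_loh import (AI_LOH, AI_NO_LOH, BALANCED, UNDETERMINED,
                              acquired_loh, classify_state, detect_mirrored_ai,
                              genome_summary, lost_mutation_loh_fraction,
                              merge_loh_events)
from wgdevolve.errors import InsufficientDataError, ValidationError
from wgdevolve.io_formats import BafTable, segment_table_from_records


class TestClassifyState:
    @pytest.mark.parametrize("major,minor,expected", [
        (1, 1, BALANCED), (2, 2, BALANCED),
        (2, 1, AI_NO_LOH), (3, 1, AI_NO_LOH),
        (2, 0, AI_LOH), (1, 0, AI_LOH), (0, 0, AI_LOH),
        (None, None, UNDETERMINED),
    ])
    def test_state_rules(self, major, minor, expected):
        assert classify_state(major, minor) == expected

    def test_inverted_alleles_rejected(self):
        with pytest.raises(ValidationError):
            classify_state(1, 2)


class TestGenomeSummary:
    def test_whole_genome_heterozygous_diploid(self):
        table = segment_table_from_records("s", [("1", 0, 1000, 1, 1)])
        summary = genome_summary(table, 1000)
        assert summary.fractions[BALANCED] == pytest.approx(1.0)
        assert summary.mean_ploidy == pytest.approx(2.0)

    def test_half_loh_half_balanced(self):
        table = segment_table_from_records(
            "s", [("1", 0, 500, 1, 0), ("1", 500, 1000, 1, 1)])
        summary = genome_summary(table, 1000)
        assert summary.fractions[AI_LOH] == pytest.approx(0.5)
        assert summary.fractions[BALANCED] == pytest.approx(0.5)
        assert summary.mean_ploidy == pytest.approx(1.5)

    def test_doubled_genome(self):
        table = segment_table_from_records("s", [("1", 0, 1000, 2, 2)])
        summary = genome_summary(table, 1000)
        assert summary.mean_ploidy == pytest.approx(4.0)
        assert summary.fractions[BALANCED] == pytest.approx(1.0)

    def test_uncovered_genome_is_undetermined(self):
        table = segment_table_from_records("s", [("1", 0, 400, 1, 1)])
        summary = genome_summary(table, 1000)
        assert summary.fractions[UNDETERMINED] == pytest.approx(0.6)

    def test_no_determined_segments_rejected(self):
        table = segment_table_from_records("s", [("1", 0, 400, None, None)])
        with pytest.raises(InsufficientDataError):
            genome_summary(table, 1000)

    @pytest.mark.parametrize("seed", range(5))
    def test_fractions_sum_to_one_property(self, seed):
        rng = np.random.default_rng(seed)
        records = []
        pos = 0
        for _ in range(rng.integers(1, 20)):
            start = pos + int(rng.integers(0, 50))
            end = start + int(rng.integers(1, 100))
            pos = end
            if rng.random() < 0.2:
                records.append(("1", start, end, None, None))
            else:
                minor = int(rng.integers(0, 3))
                major = minor + int(rng.integers(0, 3))
                records.append(("1", start, end, major, minor))
        table = segment_table_from_records("s", records)
        try:
            summary = genome_summary(table, pos + 100)
        except InsufficientDataError:
            return
        assert sum(summary.fractions.values()) == pytest.approx(1.0, abs=1e-9)


class TestAcquiredLoh:
    def test_new_loh_over_heterozygous_background(self):
        early = segment_table_from_records("e", [("9", 0, 1000, 1, 1)])
        late = segment_table_from_records("l", [("9", 0, 1000, 1, 0)])
        acq = acquired_loh(early, late)
        assert len(acq) == 1
        assert (acq.iloc[0]["start"], acq.iloc[0]["end"]) == (0, 1000)

    def test_preexisting_loh_not_acquired(self):
        early = segment_table_from_records("e", [("9", 0, 1000, 1, 0)])
        late = segment_table_from_records("l", [("9", 0, 1000, 2, 0)])
        assert len(acquired_loh(early, late)) == 0

    def test_early_undetermined_excluded(self):
        early = segment_table_from_records(
            "e", [("9", 0, 500, 1, 1), ("9", 500, 1000, None, None)])
        late = segment_table_from_records("l", [("9", 0, 1000, 1, 0)])
        acq = acquired_loh(early, late)
        assert len(acq) == 1
        assert (acq.iloc[0]["start"], acq.iloc[0]["end"]) == (0, 500)

    def test_output_contained_in_late_loh(self):
        rng = np.random.default_rng(3)
        def random_table(sid):
            records, pos = [], 0
            for _ in range(10):
                start = pos + int(rng.integers(0, 20))
                end = start + int(rng.integers(1, 200))
                pos = end
                minor = int(rng.integers(0, 2))
                records.append(("5", start, end, minor + int(rng.integers(0, 2)), minor))
            return segment_table_from_records(sid, records)
        early, late = random_table("e"), random_table("l")
        acq = acquired_loh(early, late)
        late_loh = [(int(r["start"]), int(r["end"]))
                    for _, r in late.df.iterrows() if r["minor_cn"] == 0]
        for _, row in acq.iterrows():
            assert any(s <= row["start"] and row["end"] <= e for s, e in late_loh)


class TestLostMutationAttribution:
    def _mutations(self, positions, present_sets):
        return pd.DataFrame({
            "mutation_id": [f"m{i}" for i in range(len(positions))],
            "chromosome": ["9"] * len(positions),
            "position": positions,
            "gene": [""] * len(positions),
            "consequence": ["nonsynonymous"] * len(positions),
            "present_in": [frozenset(s) for s in present_sets],
            "ccf": [0.5] * len(positions),
        })

    def _acquired(self):
        return pd.DataFrame({"chromosome": ["9"], "start": [0], "end": [500],
                             "early_sample": ["e"], "late_sample": ["l"],
                             "early_state": [BALANCED], "length": [500]})

    def test_counts_fraction_inside_loh(self):
        positions = [10 * i for i in range(1, 11)]  # 7 below 500, 3 above
        positions = [50, 100, 150, 200, 250, 300, 350, 600, 700, 800]
        muts = self._mutations(positions, [{"e"}] * 10)
        res = lost_mutation_loh_fraction(muts, "e", "l", self._acquired())
        assert res.fraction == pytest.approx(0.7)

    def test_no_acquired_loh_gives_zero(self):
        muts = self._mutations([100, 200], [{"e"}, {"e"}])
        empty = self._acquired().iloc[0:0]
        res = lost_mutation_loh_fraction(muts, "e", "l", empty)
        assert res.fraction == 0.0

    def test_no_lost_mutations_flagged_undefined(self):
        muts = self._mutations([100], [{"e", "l"}])
        res = lost_mutation_loh_fraction(muts, "e", "l", self._acquired())
        assert not res.defined
        assert math.isnan(res.fraction)


class TestMergeLohEvents:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["chromosome", "start", "end"])

    def test_overlapping_segments_from_two_samples_merge(self):
        acq = {"s1": self._frame([("9", 0, 10_000_000)]),
               "s2": self._frame([("9", 0, 10_000_000)])}
        events = merge_loh_events(acq)
        assert len(events) == 1
        assert events[0].samples == frozenset({"s1", "s2"})

    def test_disjoint_segments_stay_separate(self):
        acq = {"s1": self._frame([("9", 0, 5_000_000),
                                  ("9", 6_000_000, 10_000_000)])}
        assert len(merge_loh_events(acq)) == 2

    def test_single_linkage_chain_closure(self):
        acq = {"s1": self._frame([("9", 0, 100)]),
               "s2": self._frame([("9", 90, 200)]),
               "s3": self._frame([("9", 190, 300)])}
        events = merge_loh_events(acq)
        assert len(events) == 1
        assert events[0].samples == frozenset({"s1", "s2", "s3"})
        assert (events[0].start, events[0].end) == (0, 300)

    def test_events_disjoint_and_cover_union(self):
        rng = np.random.default_rng(11)
        acq = {}
        for s in range(3):
            rows = []
            for _ in range(15):
                start = int(rng.integers(0, 1000))
                rows.append(("3", start, start + int(rng.integers(1, 120))))
            acq[f"s{s}"] = self._frame(rows)
        events = sorted(merge_loh_events(acq), key=lambda e: e.start)
        for a, b in zip(events, events[1:]):
            assert a.end <= b.start
        union = sum(e.end - e.start for e in events)
        marks = np.zeros(2000, dtype=bool)
        for df in acq.values():
            for _, r in df.iterrows():
                marks[r["start"]:r["end"]] = True
        assert union == int(marks.sum())


class TestMirroredAi:
    def _baf(self, sid, values, positions=None):
        positions = positions or list(range(len(values)))
        return BafTable(sample_id=sid, df=pd.DataFrame(
            {"chromosome": "10", "position": positions, "baf": values}))

    def test_perfect_mirror_detected(self):
        rng = np.random.default_rng(0)
        a = 0.8 + rng.normal(0, 0.02, 50)
        t_a = self._baf("a", np.clip(a, 0, 1))
        t_b = self._baf("b", np.clip(1 - a, 0, 1))
        res = detect_mirrored_ai(t_a, t_b, "10")
        assert res.mirror_score > 0.9
        assert res.is_mirrored

    def test_same_allele_lost_not_mirrored(self):
        rng = np.random.default_rng(1)
        a = np.clip(0.8 + rng.normal(0, 0.02, 50), 0, 1)
        res = detect_mirrored_ai(self._baf("a", a), self._baf("b", a), "10")
        assert res.mirror_score < -0.9
        assert not res.is_mirrored

    def test_balanced_samples_never_mirrored(self):
        rng = np.random.default_rng(2)
        a = np.clip(0.5 + rng.normal(0, 0.03, 100), 0, 1)
        b = np.clip(0.5 - (a - 0.5) + rng.normal(0, 0.001, 100), 0, 1)
        res = detect_mirrored_ai(self._baf("a", a), self._baf("b", b), "10")
        assert not res.is_mirrored  # imbalance gate, despite high score

    def test_antisymmetric_under_baf_reflection(self):
        rng = np.random.default_rng(3)
        a = np.clip(0.7 + rng.normal(0, 0.05, 40), 0, 1)
        b = np.clip(0.3 + rng.normal(0, 0.05, 40), 0, 1)
        s1 = detect_mirrored_ai(self._baf("a", a), self._baf("b", b), "10")
        s2 = detect_mirrored_ai(self._baf("a", a), self._baf("b", 1 - b), "10")
        assert s1.mirror_score == pytest.approx(-s2.mirror_score, abs=1e-9)

    def test_too_few_shared_snps_rejected(self):
        with pytest.raises(InsufficientDataError):
            detect_mirrored_ai(self._baf("a", [0.8] * 5),
                               self._baf("b", [0.2] * 5), "10")
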