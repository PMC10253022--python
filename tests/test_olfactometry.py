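"""Event assignment, FQ/AI spectrograms, characteristic calls, consensus."""

import numpy as np
import pandas as pd
import pytest

from riceflavor.core import FlavorTypeMap, GCOPanel, ValidationError, round_half_up
from riceflavor.olfactometry import (
    assign_events,
    build_spectrograms,
    characteristic_compounds,
    consensus_table,
    spectrogram,
)
from tests.conftest import make_random_panel


def _panel(rows, n_evaluators=4) -> GCOPanel:
    return GCOPanel(
        pd.DataFrame(rows, columns=["sample", "evaluator", "time_min", "descriptor",
                                    "intensity"]),
        n_evaluators=n_evaluators,
    )


def _peaks(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["sample", "compound", "retention_time"])


class TestAssignEvents:
    def test_exact_match(self):
        panel = _panel([("SY1", "E1", 17.6, "popcorn fragrance", 5)])
        peaks = _peaks([("SY1", "2-acetyl-1-pyrroline", 17.6)])
        out = assign_events(panel, peaks)
        assert out["compound"].tolist() == ["2-acetyl-1-pyrroline"]

    def test_outside_tolerance_unassigned(self):
        panel = _panel([("SY1", "E1", 17.6, "x", 3)])
        peaks = _peaks([("SY1", "nonanal", 18.0)])
        out = assign_events(panel, peaks, tolerance=0.2)
        assert out["compound"].isna().all()

    def test_no_peaks_for_sample_leaves_unassigned(self):
        panel = _panel([("SY2", "E1", 10.0, "x", 3)])
        peaks = _peaks([("SY1", "nonanal", 10.0)])
        assert assign_events(panel, peaks)["compound"].isna().all()

    def test_tie_broken_lexically(self):
        panel = _panel([("S", "E1", 10.0, "x", 3)])
        peaks = _peaks([("S", "bbb", 10.1), ("S", "aaa", 9.9)])
        assert assign_events(panel, peaks)["compound"].tolist() == ["aaa"]

    def test_matches_exhaustive_nearest_oracle(self):
        rng = np.random.default_rng(13)
        peaks = _peaks([("S", f"c{i:02d}", float(rng.uniform(5, 35))) for i in range(30)])
        panel = _panel([("S", f"E{rng.integers(4)+1}", float(rng.uniform(5, 35)), "x",
                         int(rng.integers(1, 6))) for _ in range(100)])
        out = assign_events(panel, peaks, tolerance=0.2)
        for row in out.itertuples(index=False):
            cands = [
                (abs(p.retention_time - row.time_min), p.compound)
                for p in peaks.itertuples(index=False)
                if abs(p.retention_time - row.time_min) <= 0.2
            ]
            expect = min(cands)[1] if cands else None
            got = None if pd.isna(row.compound) else row.compound
            assert got == expect

    def test_shrinking_tolerance_never_adds_assignments(self):
        rng = np.random.default_rng(4)
        peaks = _peaks([("S", f"c{i}", float(rng.uniform(5, 35))) for i in range(15)])
        panel = _panel([("S", "E1", float(rng.uniform(5, 35)), "x", 3) for _ in range(60)])
        counts = [
            assign_events(panel, peaks, tolerance=t)["compound"].notna().sum()
            for t in (0.4, 0.2, 0.1, 0.05)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_nonpositive_tolerance_rejected(self):
        panel = _panel([("S", "E1", 10.0, "x", 3)])
        with pytest.raises(ValidationError):
            assign_events(panel, _peaks([]), tolerance=0.0)


class TestSpectrogram:
    def test_four_evaluators_ai_rounds_half_up(self):
        # scores 4,5,5,5 -> mean 4.75 -> AI 4.8 under half-up rounding
        assigned = pd.DataFrame({
            "sample": ["S"] * 4,
            "evaluator": ["E1", "E2", "E3", "E4"],
            "time_min": [10.0] * 4,
            "descriptor": ["x"] * 4,
            "intensity": [4, 5, 5, 5],
            "compound": ["a"] * 4,
        })
        spec = spectrogram(assigned, "S", n_evaluators=4)
        e = spec.entry("a")
        assert e["FQ"] == 4 and e["AI"] == 4.8

    def test_single_evaluator(self):
        assigned = make_random_panel(np.random.default_rng(0), n_events=0)
        assigned.loc[0] = ["S1", "E1", 12.0, "x", 3, "a"]
        e = spectrogram(assigned, "S1", 4).entry("a")
        assert e["FQ"] == 1 and e["AI"] == 3.0

    def test_repeat_events_count_once_with_max_score(self):
        assigned = pd.DataFrame({
            "sample": ["S"] * 3,
            "evaluator": ["E1", "E1", "E2"],
            "time_min": [10.0] * 3,
            "descriptor": ["x"] * 3,
            "intensity": [2, 5, 3],
            "compound": ["a"] * 3,
        })
        e = spectrogram(assigned, "S", 4).entry("a")
        assert e["FQ"] == 2 and e["AI"] == 4.0  # mean(max(2,5), 3)

    def test_peak_without_events_is_zero_entry(self):
        assigned = make_random_panel(np.random.default_rng(0), n_events=0)
        peaks = _peaks([("S1", "quiet", 20.0)])
        e = spectrogram(assigned, "S1", 4, peaks=peaks).entry("quiet")
        assert e["FQ"] == 0 and e["AI"] == 0.0

    def test_matches_count_mean_oracle_prerounding(self):
        rng = np.random.default_rng(8)
        assigned = make_random_panel(rng, n_events=60, compounds=tuple("abcdef"))
        spec = spectrogram(assigned, "S1", 4)
        mine = assigned[assigned["sample"] == "S1"]
        for c, grp in mine.groupby("compound"):
            per_eval = grp.groupby("evaluator")["intensity"].max()
            e = spec.entry(c)
            assert e["FQ"] == len(per_eval)
            assert e["AI"] == round_half_up(float(per_eval.mean()), 1)

    def test_roster_enforced(self):
        assigned = make_random_panel(np.random.default_rng(1), n_events=5)
        with pytest.raises(ValidationError, match="roster"):
            spectrogram(assigned, "S1", 4, roster=["X1"])

    @pytest.mark.parametrize("seed", range(10))
    def test_bounds_hold_on_random_panels(self, seed):
        rng = np.random.default_rng(seed)
        assigned = make_random_panel(rng, n_events=int(rng.integers(0, 30)))
        spec = spectrogram(assigned, "S1", 4)
        for row in spec.entries.itertuples(index=False):
            assert 0 <= row.FQ <= 4
            assert 0.0 <= row.AI <= 5.0
            if row.FQ == 0:
                assert row.AI == 0.0


class TestCharacteristicCompounds:
    def _spec_for(self, sample, fq_ai: dict[str, tuple[int, float]]):
        entries = pd.DataFrame(
            [
                {"compound": c, "retention_time": 10.0, "FQ": fq, "AI": ai,
                 "descriptors": ""}
                for c, (fq, ai) in fq_ai.items()
            ]
        )
        from riceflavor.olfactometry import Spectrogram

        return Spectrogram(sample_id=sample, n_evaluators=4, entries=entries)

    def test_fq_rule_in_two_of_four_samples(self):
        types = FlavorTypeMap({f"P{i}": "popcorn" for i in range(1, 5)})
        specs = {
            "P1": self._spec_for("P1", {"a": (3, 2.0)}),
            "P2": self._spec_for("P2", {"a": (3, 2.0)}),
            "P3": self._spec_for("P3", {"a": (0, 0.0)}),
            "P4": self._spec_for("P4", {"a": (0, 0.0)}),
        }
        call = characteristic_compounds(specs, types)
        assert call.compounds_of("popcorn") == {"a"}

    def test_below_both_thresholds_never_called(self):
        types = FlavorTypeMap({"P1": "popcorn", "P2": "popcorn"})
        specs = {s: self._spec_for(s, {"a": (2, 2.9)}) for s in types.assignments}
        assert characteristic_compounds(specs, types).compounds_of("popcorn") == frozenset()

    def test_single_sample_type_uses_effective_minimum(self):
        types = FlavorTypeMap({"L1": "lotus_root"})
        specs = {"L1": self._spec_for("L1", {"a": (4, 4.5)})}
        call = characteristic_compounds(specs, types, min_samples=2)
        assert call.compounds_of("lotus_root") == {"a"}

    def test_ai_rule_triggers_independently(self):
        types = FlavorTypeMap({"P1": "popcorn", "P2": "popcorn"})
        specs = {s: self._spec_for(s, {"a": (1, 3.0)}) for s in types.assignments}
        call = characteristic_compounds(specs, types)
        assert call.compounds_of("popcorn") == {"a"}
        assert all(ev["criterion"] == "AI" for ev in call.calls["popcorn"]["a"])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_rule_oracle(self, seed):
        rng = np.random.default_rng(seed)
        assignments = {f"S{i}": ["t1", "t2", "t3"][i % 3] for i in range(6)}
        types = FlavorTypeMap(assignments)
        compounds = list("abcde")
        specs = {
            s: self._spec_for(
                s,
                {c: (int(rng.integers(0, 5)), float(rng.integers(0, 11)) / 2)
                 for c in compounds},
            )
            for s in assignments
        }
        call = characteristic_compounds(specs, types, fq_min=3, ai_min=3.0, min_samples=2)
        for t in types.types:
            samples = types.samples_of(t)
            need = min(2, len(samples))
            expect = set()
            for c in compounds:
                n = sum(
                    1
                    for s in samples
                    if specs[s].entry(c)["FQ"] >= 3 or specs[s].entry(c)["AI"] >= 3.0
                )
                if n >= need:
                    expect.add(c)
            assert call.compounds_of(t) == expect

    def test_monotone_in_added_detection(self):
        types = FlavorTypeMap({"P1": "popcorn", "P2": "popcorn"})
        base = {s: self._spec_for(s, {"a": (3, 3.5)}) for s in types.assignments}
        called = characteristic_compounds(base, types).compounds_of("popcorn")
        boosted = {s: self._spec_for(s, {"a": (4, 4.5)}) for s in types.assignments}
        assert called <= characteristic_compounds(boosted, types).compounds_of("popcorn")


class TestConsensusTable:
    def test_two_type_filter_and_ordering(self):
        types = FlavorTypeMap({"A": "t1", "B": "t2"})
        from riceflavor.olfactometry import Spectrogram

        def spec(sample, entries):
            return Spectrogram(sample, 4, pd.DataFrame(entries))

        specs = {
            "A": spec("A", [{"compound": "x", "retention_time": 20.0, "FQ": 2,
                             "AI": 3.0, "descriptors": "sweet"},
                            {"compound": "solo", "retention_time": 8.0, "FQ": 1,
                             "AI": 1.0, "descriptors": "faint"}]),
            "B": spec("B", [{"compound": "x", "retention_time": 20.1, "FQ": 1,
                             "AI": 2.0, "descriptors": "sweet; floral"}]),
        }
        out = consensus_table(specs, types)
        assert out["compound"].tolist() == ["x"]  # 'solo' seen in one type only
        assert out.iloc[0]["n_types"] == 2

    def test_single_type_dataset_is_empty(self):
        rng = np.random.default_rng(2)
        assigned = make_random_panel(rng, n_events=20)
        spec = spectrogram(assigned, "S1", 4)
        out = consensus_table({"S1": spec}, FlavorTypeMap({"S1": "popcorn"}))
        assert out.empty

    def test_matches_brute_force_type_count(self):
        rng = np.random.default_rng(6)
        types = FlavorTypeMap({f"S{i}": ["t1", "t2", "t3"][i % 3] for i in range(6)})
        specs = {}
        for s in types.assignments:
            assigned = make_random_panel(rng, samples=(s,), n_events=10,
                                         compounds=tuple("abcd"))
            specs[s] = spectrogram(assigned, s, 4)
        out = consensus_table(specs, types)
        counts = {}
        for s, spec in specs.items():
            for row in spec.entries.itertuples(index=False):
                if row.FQ >= 1:
                    counts.setdefault(row.compound, set()).add(types.type_of(s))
        expect = {c for c, ts in counts.items() if len(ts) >= 2}
        assert set(out["compound"]) == expect
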