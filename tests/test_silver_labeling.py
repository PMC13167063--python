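import datetime as dt
import math
from collections import Counter

import numpy as np
import pytest

from notesieve.errors import (ConsistencyError, ReferentialIntegrityError,
                              SamplingError)
from notesieve.silver_labeling import (Pool, SubsetConfig, assign_pool,
                                       build_pools, sample_training_subset,
                                       shift_months, split_gold,
                                       read_pools, write_pools)

from conftest import make_corpus


class TestShiftMonths:
    def test_simple(self):
        assert shift_months(dt.date(2015, 6, 15), -24) == dt.date(2013, 6, 15)

    def test_day_clamped(self):
        assert shift_months(dt.date(2015, 3, 31), -1) == dt.date(2015, 2, 28)

    def test_leap_year(self):
        assert shift_months(dt.date(2016, 2, 29), 12) == dt.date(2017, 2, 28)

    def test_year_wrap(self):
        assert shift_months(dt.date(2015, 1, 10), -2) == dt.date(2014, 11, 10)


def _timeline_corpus():
    """One patient, first target code on 2016-01-01; one never-coded patient.

    Hand-traced truth table (lookback 24 months, patient scope):
        n_pos   coded encounter              -> COPD_ENCOUNTER
        n_pre   2013-06-01 (31 mo before)    -> PRE_COPD
        n_edge  2014-01-01 (exactly -24 mo)  -> PRE_COPD (boundary inclusive)
        n_gray  2015-01-01 (12 mo before)    -> EXCLUDED
        n_post  2017-01-01 uncoded, post-dx  -> EXCLUDED
        n_non   never-coded patient          -> NON_COPD
    """
    rows = [
        ("n_pos", "p1", "e1", "2016-01-01", "progress", "copd flare",
         [("J44.9", "ICD10CM")]),
        ("n_pre", "p1", "e2", "2013-06-01", "progress", "ankle sprain", []),
        ("n_edge", "p1", "e3", "2014-01-01", "progress", "checkup", []),
        ("n_gray", "p1", "e4", "2015-01-01", "progress", "mild cough", []),
        ("n_post", "p1", "e5", "2017-01-01", "progress", "follow up", []),
        ("n_non", "p2", "e6", "2015-05-05", "progress", "headache", []),
    ]
    return make_corpus(rows)


EXPECTED_POOLS = {
    "n_pos": Pool.COPD_ENCOUNTER,
    "n_pre": Pool.PRE_COPD,
    "n_edge": Pool.PRE_COPD,
    "n_gray": Pool.EXCLUDED,
    "n_post": Pool.EXCLUDED,
    "n_non": Pool.NON_COPD,
}


class TestAssignPool:
    def test_hand_traced_truth_table(self, copd_codeset):
        corpus = _timeline_corpus()
        for note_id, expected in EXPECTED_POOLS.items():
            note = corpus.notes[note_id]
            patient = corpus.patients[note.patient_id]
            assert assign_pool(note, patient, copd_codeset) is expected, \
                note_id

    def test_encounter_scope_reclassifies_gray_zone(self, copd_codeset):
        corpus = _timeline_corpus()
        note = corpus.notes["n_gray"]
        patient = corpus.patients["p1"]
        assert assign_pool(note, patient, copd_codeset,
                           negatives_scope="encounter") is Pool.NON_COPD

    def test_wrong_patient_raises(self, copd_codeset):
        corpus = _timeline_corpus()
        with pytest.raises(ConsistencyError):
            assign_pool(corpus.notes["n_pos"], corpus.patients["p2"],
                        copd_codeset)

    def test_custom_lookback(self, copd_codeset):
        corpus = _timeline_corpus()
        note = corpus.notes["n_gray"]  # 12 months before diagnosis
        patient = corpus.patients["p1"]
        assert assign_pool(note, patient, copd_codeset,
                           lookback_months=12) is Pool.PRE_COPD


class TestBuildPools:
    def test_partition_is_exhaustive(self, copd_codeset):
        corpus = _timeline_corpus()
        pools, report = build_pools(corpus, copd_codeset)
        assert pools == EXPECTED_POOLS
        assert sum(report.values()) == len(corpus)

    def test_no_target_codes_all_non(self, copd_codeset):
        rows = [(f"n{i}", "p1", f"e{i}", "2015-01-01", "progress", "x",
                 [("I10", "ICD10CM")]) for i in range(4)]
        pools, report = build_pools(make_corpus(rows), copd_codeset)
        assert report["NON_COPD"] == 4
        assert report["COPD_ENCOUNTER"] == report["PRE_COPD"] == 0

    def test_all_coded_no_negatives(self, copd_codeset):
        rows = [(f"n{i}", "p1", f"e{i}", "2015-01-01", "progress", "x",
                 [("496", "ICD9CM")]) for i in range(4)]
        pools, report = build_pools(make_corpus(rows), copd_codeset)
        assert report["COPD_ENCOUNTER"] == 4
        assert report["NON_COPD"] == report["PRE_COPD"] == 0

    def test_pools_round_trip(self, copd_codeset, tmp_path):
        pools, _ = build_pools(_timeline_corpus(), copd_codeset)
        path = tmp_path / "pools.jsonl"
        write_pools(pools, path)
        assert read_pools(path) == pools


class TestSubsetConfig:
    def test_mixed_invariant(self):
        cfg = SubsetConfig.mixed(50, seed=1)
        assert (cfg.n_pos, cfg.n_neg_non, cfg.n_neg_pre) == (50, 25, 25)

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError):
            SubsetConfig("MIXED", 50, 30, 25, seed=1)

    def test_non_only_shape(self):
        cfg = SubsetConfig.non_only(40, seed=1)
        assert cfg.n_neg_pre == 0 and cfg.n_neg_non == 40


def _sampling_corpus(n_per_pool=60):
    rows = []
    k = 0
    # positives: coded encounters, spread over years/types/patients
    for i in range(n_per_pool):
        pid = f"cp{i % 25}"
        rows.append((f"pos{i}", pid, f"pe{k}",
                     f"{2016 + i % 3}-0{1 + i % 9}-10",
                     ["progress", "nursing"][i % 2], f"copd note {i}",
                     [("J44.9", "ICD10CM")]))
        k += 1
    # negatives: never-coded patients
    for i in range(n_per_pool):
        pid = f"np{i % 25}"
        rows.append((f"non{i}", pid, f"ne{k}",
                     f"{2016 + i % 3}-0{1 + i % 9}-12",
                     ["progress", "nursing"][i % 2], f"other note {i}", []))
        k += 1
    # pre-window: uncoded notes long before the coded patients' diagnoses
    for i in range(n_per_pool):
        pid = f"cp{i % 25}"
        rows.append((f"pre{i}", pid, f"re{k}",
                     f"{2012 + i % 2}-0{1 + i % 9}-15",
                     ["progress", "nursing"][i % 2], f"early note {i}", []))
        k += 1
    return make_corpus(rows)


class TestSampleTrainingSubset:
    def test_mixed_counts(self, copd_codeset):
        corpus = _sampling_corpus()
        pools, _ = build_pools(corpus, copd_codeset)
        docs = sample_training_subset(corpus, pools,
                                      SubsetConfig.mixed(50, seed=3))
        prov = Counter(d.provenance for d in docs)
        assert prov["silver:COPD_ENCOUNTER"] == 50
        assert prov["silver:NON_COPD"] == 25
        assert prov["silver:PRE_COPD"] == 25
        labels = Counter(d.label for d in docs)
        assert labels[1] == labels[0] == 50

    def test_deterministic_under_seed(self, copd_codeset):
        corpus = _sampling_corpus()
        pools, _ = build_pools(corpus, copd_codeset)
        cfg = SubsetConfig.mixed(50, seed=3)
        a = [d.note_id for d in sample_training_subset(corpus, pools, cfg)]
        b = [d.note_id for d in sample_training_subset(corpus, pools, cfg)]
        assert a == b

    def test_different_seed_differs(self, copd_codeset):
        corpus = _sampling_corpus()
        pools, _ = build_pools(corpus, copd_codeset)
        a = [d.note_id for d in sample_training_subset(
            corpus, pools, SubsetConfig.mixed(50, seed=3))]
        b = [d.note_id for d in sample_training_subset(
            corpus, pools, SubsetConfig.mixed(50, seed=4))]
        assert a != b

    def test_empty_pool_raises_naming_pool(self, copd_codeset):
        rows = [(f"n{i}", "p1", f"e{i}", "2015-01-01", "progress", "x",
                 [("496", "ICD9CM")]) for i in range(60)]
        corpus = make_corpus(rows)
        pools, _ = build_pools(corpus, copd_codeset)
        with pytest.raises(SamplingError, match="PRE_COPD"):
            sample_training_subset(corpus, pools,
                                   SubsetConfig.pre_only(50, seed=1))

    def test_per_patient_cap(self, copd_codeset):
        corpus = _sampling_corpus()
        pools, _ = build_pools(corpus, copd_codeset)
        docs = sample_training_subset(corpus, pools,
                                      SubsetConfig.mixed(50, seed=3))
        cap = math.ceil(len(docs) / 20)
        per_patient = Counter()
        for d in docs:
            per_patient[corpus.notes[d.note_id].patient_id] += 1
        # 50 distinct patients across pools make the cap feasible here
        assert max(per_patient.values()) <= cap

    def test_no_replacement(self, copd_codeset):
        corpus = _sampling_corpus()
        pools, _ = build_pools(corpus, copd_codeset)
        docs = sample_training_subset(corpus, pools,
                                      SubsetConfig.mixed(50, seed=3))
        ids = [d.note_id for d in docs]
        assert len(ids) == len(set(ids))


class TestSplitGold:
    def _annotations(self, n=307):
        return [(f"g{i}", i % 2) for i in range(n)]

    def test_sizes_84_223(self):
        val, test = split_gold(self._annotations(), 84, seed=1)
        assert (len(val), len(test)) == (84, 223)
        assert set(i for i, _ in val).isdisjoint(i for i, _ in test)

    def test_validation_zero(self):
        val, test = split_gold(self._annotations(), 0, seed=1)
        assert val == [] and len(test) == 307

    def test_duplicate_raises(self):
        anns = self._annotations(10) + [("g0", 1)]
        with pytest.raises(ReferentialIntegrityError):
            split_gold(anns, 2, seed=1)

    def test_unknown_note_id_raises(self):
        pools = {"g0": Pool.COPD_ENCOUNTER}
        with pytest.raises(ReferentialIntegrityError):
            split_gold([("g0", 1), ("ghost", 0)], 1, seed=1,
                       pool_by_note=pools)

    def test_stratified_by_pool(self):
        anns = self._annotations(300)
        pools = {f"g{i}": [Pool.COPD_ENCOUNTER, Pool.NON_COPD,
                           Pool.PRE_COPD][i % 3] for i in range(300)}
        val, _ = split_gold(anns, 90, seed=1, pool_by_note=pools)
        counts = Counter(pools[i].value for i, _ in val)
        assert all(c == 30 for c in counts.values())

    def test_deterministic(self):
        anns = self._annotations()
        assert split_gold(anns, 84, seed=9) == split_gold(anns, 84, seed=9)
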