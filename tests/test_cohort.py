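"""Clinical feature engineering, cohort filters and trajectory tokenization."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mbehrt as mb
from mbehrt.cohort import (
    DEFAULT_MARKERS, EXCL_INSUFFICIENT_FOLLOWUP, EXCL_PRE_INDEX_RELAPSE,
    EXCL_TOO_FEW_VISITS, MAX_TOKENS, PROGNOSTIC_GROUPS, SPECIAL_TOKENS,
    TokenizedTrajectory, TokenizerContext, Vocabulary, apply_cohort_filters,
    build_trajectory, filter_bio_features, impute_for_dnpi, normalize_label,
    select_history_window, token_modality_stream, tokenize_visit,
)
from conftest import make_record, make_visit

LEUK = mb.BioMarkerSpec("LEUK", 4.0, 10.0)


class TestNodeStage:
    @pytest.mark.parametrize("n_nodes,stage", [(0, 1), (1, 2), (2, 2), (3, 2), (4, 3), (12, 3)])
    def test_mapping(self, n_nodes, stage):
        assert mb.compute_node_stage(n_nodes) == stage

    @pytest.mark.parametrize("bad", [-1, 1.5, "2", True])
    def test_rejects_invalid(self, bad):
        with pytest.raises(ValueError):
            mb.compute_node_stage(bad)


class TestNPI:
    def test_zero_size_best_case(self):
        assert mb.compute_npi(0.0, 1, 0).npi == pytest.approx(2.0)

    def test_formula(self):
        res = mb.compute_npi(2.0, 2, 2)
        assert res.npi == pytest.approx(4.4)
        assert res.node_stage == 2
        assert res.prognostic_group == "MPG I"

    def test_one_cm_adds_a_fifth(self):
        a = mb.compute_npi(2.0, 2, 1).npi
        b = mb.compute_npi(3.0, 2, 1).npi
        assert b - a == pytest.approx(0.2)

    def test_missing_inputs_demand_imputation(self):
        with pytest.raises(ValueError, match="impute"):
            mb.compute_npi(None, 2, 1)

    @settings(derandomize=True, max_examples=60)
    @given(size=st.floats(0, 12), grade=st.integers(1, 3), nodes=st.integers(0, 20))
    def test_nondecreasing_in_each_argument(self, size, grade, nodes):
        base = mb.compute_npi(size, grade, nodes).npi
        assert mb.compute_npi(size + 0.5, grade, nodes).npi >= base
        if grade < 3:
            assert mb.compute_npi(size, grade + 1, nodes).npi >= base
        assert mb.compute_npi(size, grade, nodes + 1).npi >= base


class TestPrognosticGroups:
    @pytest.mark.parametrize("npi,group", [
        (0.0, "EPG"), (2.4, "EPG"), (2.5, "GPG"), (3.4, "GPG"), (4.4, "MPG I"),
        (5.4, "MPG II"), (6.4, "PPG"), (6.5, "VPPG"), (7.0, "VPPG"), (50.0, "VPPG"),
    ])
    def test_blamey_bands(self, npi, group):
        assert mb.assign_prognostic_group(npi) == group

    @settings(derandomize=True, max_examples=100)
    @given(npi=st.floats(0, 20, allow_nan=False))
    def test_partitions_nonnegative_reals(self, npi):
        assert mb.assign_prognostic_group(npi) in PROGNOSTIC_GROUPS

    def test_adjacent_thresholds_one_apart(self):
        from mbehrt.cohort import _PG_UPPER
        finite = [u for u in _PG_UPPER if np.isfinite(u)]
        assert np.allclose(np.diff(finite), 1.0)


class TestDnpiImputation:
    def test_defaults_for_grade_and_nodes(self):
        rec = make_record(tumor_grade=None, n_nodes=None,
                          visits=[make_visit(dt.date(2016, 3, 1), tumor_size_cm=1.5)])
        assert impute_for_dnpi(rec, []) == (1.5, 2, 0)

    def test_size_from_tnm_peer_mode(self):
        peers = [make_record(patient_id=f"Q{i}", tnm_stage="T2",
                             visits=[make_visit(dt.date(2016, 3, 1), tumor_size_cm=s)])
                 for i, s in enumerate([2.0, 2.0, 3.0])]
        rec = make_record(tnm_stage="T2",
                          visits=[make_visit(dt.date(2016, 3, 1))])
        assert impute_for_dnpi(rec, peers + [rec]) == (2.0, 2, 1)

    def test_fully_observed_unchanged(self):
        rec = make_record(visits=[make_visit(dt.date(2016, 3, 1), tumor_size_cm=2.5)])
        assert impute_for_dnpi(rec, []) == (2.5, 2, 1)

    def test_unavailable_when_everything_missing(self):
        rec = make_record(tumor_grade=None, n_nodes=None,
                          visits=[make_visit(dt.date(2016, 3, 1))])
        assert impute_for_dnpi(rec, []) is None

    def test_unavailable_without_tnm_peers(self):
        rec = make_record(tnm_stage="T9", visits=[make_visit(dt.date(2016, 3, 1))])
        assert impute_for_dnpi(rec, [rec]) is None


class TestBioDiscretization:
    @pytest.mark.parametrize("value,token", [
        (12.0, 1), (3.9, 1), (7.0, 2), (4.0, 2), (10.0, 2),
    ])
    def test_binarization_with_closed_normal_range(self, value, token):
        assert mb.binarize_bio(value, LEUK) == token

    def test_missing_value_is_skipped_not_tokenized(self):
        with pytest.raises(ValueError):
            mb.binarize_bio(None, LEUK)

    @pytest.mark.parametrize("v_t,v_prev,expected", [
        (47.0, 0.0, 5),      # round(4.7)
        (10.0, 10.0, None),  # zero deltas are not emitted
        (0.0, 12.0, -1),     # round(-1.2)
        (15.0, 0.0, 2),      # half away from zero
        (0.0, 15.0, -2),
    ])
    def test_delta_discretization(self, v_t, v_prev, expected):
        assert mb.delta_token(v_t, v_prev, LEUK) == expected

    def test_first_observation_has_no_delta(self):
        assert mb.delta_token(5.0, None, LEUK) is None

    def test_marker_spec_validation(self):
        with pytest.raises(ValueError):
            mb.BioMarkerSpec("X", 5.0, 5.0)
        with pytest.raises(ValueError):
            mb.BioMarkerSpec("X", 1.0, 2.0, delta_unit_divisor=0)


class TestAgeAndDelay:
    def test_age_rounding(self):
        birth = dt.date(1960, 1, 1)
        assert mb.discretize_age(birth, dt.date(2010, 1, 1)) == 50
        assert mb.discretize_age(birth, dt.date(2009, 8, 1)) == 50   # 49.6 yr
        assert mb.discretize_age(birth, dt.date(2009, 5, 25)) == 49  # 49.4 yr

    def test_age_missing_birth(self):
        assert mb.discretize_age(None, dt.date(2010, 1, 1)) is None

    @pytest.mark.parametrize("days,bucket", [
        (0, "W0"), (5, "W0"), (7, "W1"), (27, "W3"), (28, "M1"), (59, "M2"),
        (100, "M4"), (355, "M12"), (364, "M12"), (365, "LT"), (400, "LT"),
    ])
    def test_delay_buckets(self, days, bucket):
        assert mb.discretize_delay(days) == bucket

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            mb.discretize_delay(-1)

    @settings(derandomize=True, max_examples=200)
    @given(days=st.integers(0, 4000))
    def test_buckets_tile_the_nonnegative_days(self, days):
        from mbehrt.cohort import DELAY_BUCKETS
        assert mb.discretize_delay(days) in DELAY_BUCKETS


class TestCohortLevelPreprocessing:
    def test_bio_feature_missingness_filter(self):
        # three markers with missingness 0.1 / 0.25 / 0.35 over 20 lab visits
        visits = []
        for i in range(20):
            bio = {"Z": 1.0}  # every visit is a lab visit
            if i >= 2:
                bio["A"] = 5.0
            if i >= 5:
                bio["B"] = 5.0
            if i >= 7:
                bio["C"] = 5.0
            visits.append(make_visit(dt.date(2016, 3, 1) + dt.timedelta(days=i),
                                     bio_values=bio))
        rec = make_record(visits=visits)
        assert filter_bio_features([rec], ["A", "B", "C"]) == ["A", "B"]

    def test_fully_observed_marker_kept_half_missing_dropped(self):
        visits = [make_visit(dt.date(2016, 3, 1) + dt.timedelta(days=i),
                             bio_values={"A": 1.0} | ({"B": 1.0} if i % 2 else {}))
                  for i in range(10)]
        rec = make_record(visits=visits)
        assert filter_bio_features([rec], ["A", "B"]) == ["A"]

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            filter_bio_features([], ["A"])

    def test_reference_panel_has_the_five_markers(self):
        assert [m.name for m in DEFAULT_MARKERS] == ["MONO", "LEUK", "LYMP", "PN", "CA15-3"]

    def test_normalize_label_synonyms_and_accents(self):
        syn = {"anapath": "anatomo-cyto-pathologie",
               "anatomopathologie": "anatomo-cyto-pathologie"}
        # punctuation/accents removed before the synonym merge
        assert normalize_label("Anapath!", syn) == "anatomo-cyto-pathologie"
        assert normalize_label("Radiothérapie") == "radiotherapie"

    def test_normalize_label_rare_words_dropped(self):
        counts = {"consultation": 250, "service rare": 99}
        assert normalize_label("Consultation", corpus_counts=counts) == "consultation"
        assert normalize_label("Service rare", corpus_counts=counts) is None

    def test_normalize_label_idempotent(self):
        once = normalize_label("Écho-graphie  mammaire")
        assert normalize_label(once) == once


class TestHistoryWindowAndFilters:
    def test_window_bounds(self):
        diagnosis, surgery = dt.date(2016, 3, 1), dt.date(2016, 4, 1)
        visits = [
            make_visit(diagnosis - dt.timedelta(days=200)),   # too early
            make_visit(diagnosis - dt.timedelta(days=30)),    # 1 month before dx
            make_visit(surgery + dt.timedelta(days=365)),     # boundary: kept
            make_visit(surgery + dt.timedelta(days=730)),     # 2 years after
        ]
        rec = make_record(visits=visits)
        window = select_history_window(rec)
        assert [v.date for v in window] == [visits[1].date, visits[2].date]

    def test_empty_visit_list_gives_empty_window(self):
        rec = make_record(visits=[make_visit(dt.date(2010, 1, 1))])
        assert select_history_window(rec) == []

    def test_filter_reasons_and_labels(self):
        records = [
            make_record("A", dfs_event=True, followup_days=200),    # pre-index relapse
            make_record("B", dfs_event=False, followup_days=800),   # censored early
            make_record("C", n_visits=2, dfs_event=False, followup_days=1300),
            make_record("D", dfs_event=False, followup_days=1200),  # kept, negative
            make_record("E", dfs_event=True, followup_days=800),    # kept, positive
            make_record("F", dfs_event=True, followup_days=1500),   # event after horizon
        ]
        kept, excl = apply_cohort_filters(records)
        assert len(kept) + len(excl) == len(records)
        reasons = dict(excl)
        assert reasons == {"A": EXCL_PRE_INDEX_RELAPSE, "B": EXCL_INSUFFICIENT_FOLLOWUP,
                           "C": EXCL_TOO_FEW_VISITS}
        labels = {r.patient_id: r.dfs_event for r in kept}
        assert labels == {"D": False, "E": True, "F": False}


def full_visit(date=dt.date(2016, 3, 5)):
    return mb.VisitEvent(
        date=date, department="oncologie medicale", procedure="rcp",
        therapy="chimiotherapie", subtherapy="taxanes",
        bio_values={m.name: 5.0 for m in DEFAULT_MARKERS},
        tumor_size_cm=2.0)


class TestVisitTokenization:
    def make_context(self):
        rec = make_record()
        return TokenizerContext.for_record(rec, [])

    def test_fully_populated_visit_emits_17_pairs(self):
        ctx = self.make_context()
        # a first visit seeds the previous marker values so deltas can fire
        tokenize_visit(full_visit(), ctx)
        second = full_visit(dt.date(2016, 4, 2))
        second.bio_values = {m.name: 25.0 for m in DEFAULT_MARKERS}
        pairs = tokenize_visit(second, ctx)
        assert len(pairs) == 17
        assert len({modality for _, modality in pairs}) == 17

    def test_sparse_visit_emits_one_pair(self):
        ctx = self.make_context()
        ctx.birth_date = None
        ctx.tumor_grade = None
        ctx.molecular_subtype = None
        pairs = tokenize_visit(mb.VisitEvent(date=dt.date(2016, 3, 5),
                                             department="imagerie"), ctx)
        assert pairs == [("DEPT:imagerie", "department")]

    def test_zero_delta_pair_absent(self):
        ctx = self.make_context()
        tokenize_visit(full_visit(), ctx)
        second = full_visit(dt.date(2016, 4, 2))  # identical marker values
        pairs = tokenize_visit(second, ctx)
        assert len(pairs) == 12  # 17 minus the five zero deltas
        assert not any(mod.startswith("delta_") for _, mod in pairs)

    @settings(derandomize=True, max_examples=30)
    @given(st.booleans(), st.booleans(), st.booleans())
    def test_emits_between_zero_and_17_distinct_modalities(self, dept, proc, bio):
        ctx = self.make_context()
        visit = mb.VisitEvent(
            date=dt.date(2016, 3, 5),
            department="x" if dept else None,
            procedure="y" if proc else None,
            bio_values={"LEUK": 5.0} if bio else {},
            tumor_size_cm=1.0)
        pairs = tokenize_visit(visit, ctx)
        assert 0 <= len(pairs) <= 17
        mods = [m for _, m in pairs]
        assert len(mods) == len(set(mods))


class TestTrajectoryConstruction:
    def five_token_record(self, n_visits=3, spacing_days=10):
        visits = [mb.VisitEvent(date=dt.date(2016, 3, 1) + dt.timedelta(days=spacing_days * k),
                                department="oncologie medicale", procedure="rcp",
                                therapy="chimiotherapie", subtherapy="taxanes")
                  for k in range(n_visits)]
        # age present (birth date), no dNPI inputs, no subtype: 5 tokens/visit
        return make_record(visits=visits, tumor_grade=None, n_nodes=None,
                           molecular_subtype=None)

    def vocab_for(self, record):
        return Vocabulary.build([token_modality_stream(record, [])])

    def test_cls_sep_layout(self):
        rec = self.five_token_record(3)
        traj = build_trajectory(rec, self.vocab_for(rec))
        assert len(traj) == 1 + 3 * 5 + 3
        assert traj.token_ids[0] == SPECIAL_TOKENS["CLS"]
        sep_positions = [i for i, t in enumerate(traj.token_ids) if t == SPECIAL_TOKENS["SEP"]]
        assert sep_positions == [6, 12, 18]
        assert traj.positions == list(range(len(traj)))

    def test_single_visit_delays_all_w0(self):
        rec = self.five_token_record(1)
        traj = build_trajectory(rec, self.vocab_for(rec))
        assert set(traj.delay_ids) == {0}

    def test_truncation_to_512(self):
        # 130 in-window visits x 6 tokens each stream ~780 tokens
        rec = self.five_token_record(130, spacing_days=3)
        traj = build_trajectory(rec, self.vocab_for(rec))
        assert len(traj) == MAX_TOKENS
        assert len(traj.token_ids) == len(traj.modality_ids) == len(traj.delay_ids)

    def test_empty_window_errors(self):
        rec = make_record(visits=[make_visit(dt.date(2000, 1, 1))])
        with pytest.raises(ValueError):
            build_trajectory(rec, self.vocab_for(self.five_token_record()))

    def test_serialization_round_trip(self):
        rec = self.five_token_record(4)
        traj = build_trajectory(rec, self.vocab_for(rec))
        clone = TokenizedTrajectory.from_json(traj.to_json())
        assert clone.token_ids == traj.token_ids
        assert clone.modality_ids == traj.modality_ids
        assert clone.delay_ids == traj.delay_ids
        assert clone.positions == traj.positions
        assert clone.label == traj.label

    def test_unseen_tokens_map_to_unk(self):
        rec = self.five_token_record(1)
        vocab = self.vocab_for(rec)
        other = make_record(visits=[make_visit(dt.date(2016, 3, 5),
                                               department="service inconnu")])
        traj = build_trajectory(other, vocab)
        assert SPECIAL_TOKENS["UNK"] in traj.token_ids


class TestVocabulary:
    def test_special_ids_reserved_and_dense(self):
        vocab = Vocabulary.build([[("DEPT:a", "department"), ("PROC:b", "procedure")]])
        assert vocab.token_to_id["PAD"] == 0
        assert vocab.token_to_id["CLS"] == 1
        ids = sorted(vocab.token_to_id.values())
        assert ids == list(range(len(ids)))
        assert set(vocab.content_ids).isdisjoint(SPECIAL_TOKENS.values())

    def test_json_round_trip(self):
        vocab = Vocabulary.build([[("DEPT:a", "department")]])
        clone = Vocabulary.from_json(vocab.to_json())
        assert clone.token_to_id == vocab.token_to_id
        assert clone.modality_to_id == vocab.modality_to_id
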