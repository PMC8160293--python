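"""Case-definition logic: windows, pairing, patterns, crude estimates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtbi_lca.case_ascertainment import (
    DEFINITIONS,
    AscertainmentWindow,
    ResponsePatternCounts,
    apply_case_definitions,
    build_response_patterns,
    compute_person_time,
    crude_incidence,
    crude_median_time,
    model_dimensions,
    pattern_index,
    pattern_matrix,
)
from rtbi_lca.errors import (
    ArgumentError,
    EmptyInputError,
    ValidationError,
)


def _hits_frame(rows):
    """rows: (patient_id, flags 4-tuple, first_hit_day or None)."""
    df = pd.DataFrame(
        {
            "patient_id": [r[0] for r in rows],
            **{d: [bool(r[1][j]) for r in rows] for j, d in enumerate(DEFINITIONS)},
        }
    )
    df["first_hit_day"] = pd.array([r[2] for r in rows], dtype="Int64")
    return df


class TestApplyCaseDefinitions:
    def test_claim_before_window_ignored(self, tiny_claims, tiny_index):
        claims = tiny_claims([("A", 5, "emergency", "8500", "ICD9")])
        hits = apply_case_definitions(claims, tiny_index(["A"]))
        assert not hits[list(DEFINITIONS)].to_numpy().any()
        assert hits["first_hit_day"].isna().all()

    def test_claim_at_window_start_counts(self, tiny_claims, tiny_index):
        claims = tiny_claims([("A", 7, "emergency", "850.0", "ICD9")])
        hits = apply_case_definitions(claims, tiny_index(["A"]))
        assert hits.loc[0, "er"]
        assert hits.loc[0, "first_hit_day"] == 7

    def test_radiology_trauma_pair_within_one_day(self, tiny_claims, tiny_index):
        claims = tiny_claims(
            [
                ("A", 100, "radiology_billing", "08258", "billing"),
                ("A", 101, "outpatient", "9200", "ICD9"),
            ]
        )
        hits = apply_case_definitions(claims, tiny_index(["A"]))
        assert hits.loc[0, "radiology"]
        assert hits.loc[0, "first_hit_day"] == 100

    def test_radiology_without_trauma_partner_misses(self, tiny_claims, tiny_index):
        claims = tiny_claims(
            [
                ("A", 100, "radiology_billing", "08258", "billing"),
                ("A", 103, "outpatient", "9200", "ICD9"),  # 3 days apart
            ]
        )
        hits = apply_case_definitions(claims, tiny_index(["A"]))
        assert not hits.loc[0, "radiology"]

    def test_hospital_physician_claims_feed_no_definition(
        self, tiny_claims, tiny_index
    ):
        claims = tiny_claims([("A", 100, "hospital_physician", "8500", "ICD9")])
        hits = apply_case_definitions(claims, tiny_index(["A"]))
        assert not hits[list(DEFINITIONS)].to_numpy().any()

    def test_empty_claim_stream_gives_all_negative(self, tiny_claims, tiny_index):
        claims = tiny_claims([("B", 50, "emergency", "8500", "ICD9")])
        hits = apply_case_definitions(claims, tiny_index(["A"]))
        assert len(hits) == 1
        assert not hits[list(DEFINITIONS)].to_numpy().any()

    def test_unknown_source_raises_with_rows(self, tiny_claims, tiny_index):
        claims = tiny_claims([("A", 50, "clinic", "8500", "ICD9")])
        with pytest.raises(ValidationError, match="unknown source"):
            apply_case_definitions(claims, tiny_index(["A"]))

    def test_non_tbi_code_does_not_hit(self, tiny_claims, tiny_index):
        claims = tiny_claims([("A", 50, "emergency", "4019", "ICD9")])
        hits = apply_case_definitions(claims, tiny_index(["A"]))
        assert not hits.loc[0, "er"]


class TestResponsePatterns:
    def test_all_negative_patterns(self):
        hits = _hits_frame([("A", (0, 0, 0, 0), None)] * 3)
        counts = build_response_patterns(hits)
        assert counts.counts[0] == 3
        assert counts.counts[1:].sum() == 0

    def test_bit_encoding(self):
        hits = _hits_frame([("A", (1, 0, 0, 1), 30)])
        counts = build_response_patterns(hits)
        assert counts.counts[0b1001] == 1

    def test_conservation_random(self):
        rng = np.random.default_rng(0)
        flags = rng.random((10_000, 4)) < 0.3
        counts = ResponsePatternCounts.from_flags(flags)
        assert counts.n == 10_000

    @given(st.integers(min_value=0, max_value=15))
    @settings(deadline=None, derandomize=True)
    def test_bit_order_round_trip(self, idx):
        assert pattern_index(pattern_matrix(4)[idx]) == idx

    def test_negative_counts_rejected(self):
        with pytest.raises(ArgumentError):
            ResponsePatternCounts(np.array([1, -1, 0, 0]))


class TestModelDimensions:
    @pytest.mark.parametrize(
        "n_def, n_cls, expected",
        [
            (4, 2, (16, 15, 9)),
            (4, 3, (16, 15, 13)),
            (1, 2, (2, 1, 3)),
        ],
    )
    def test_counting(self, n_def, n_cls, expected):
        assert model_dimensions(n_def, n_cls) == expected

    @pytest.mark.parametrize("args", [(0, 2), (4, 1), (-1, 2)])
    def test_invalid_arguments(self, args):
        with pytest.raises(ArgumentError):
            model_dimensions(*args)


class TestPersonTimeAndCrude:
    def _frame(self, exit_day, first_hit):
        idx = pd.DataFrame(
            {"patient_id": ["A"], "index_date": [pd.Timestamp("2005-01-01")]}
        )
        exits = pd.DataFrame(
            {
                "patient_id": ["A"],
                "exit_date": [pd.Timestamp("2005-01-01") + pd.Timedelta(days=exit_day)],
            }
        )
        hits = _hits_frame([("A", (0, 0, 0, 1) if first_hit else (0, 0, 0, 0), first_hit)])
        return idx, hits, exits

    def test_full_year_no_event(self):
        idx, hits, exits = self._frame(800, None)
        _, total = compute_person_time(idx, hits, exits)
        assert total == pytest.approx(1.0)

    def test_censored_at_first_hit(self):
        idx, hits, exits = self._frame(800, 100)
        _, total = compute_person_time(idx, hits, exits)
        assert total == pytest.approx(100 / 365)

    def test_censored_at_exit(self):
        idx, hits, exits = self._frame(200, None)
        _, total = compute_person_time(idx, hits, exits)
        assert total == pytest.approx(200 / 365)

    def test_exit_before_index_rejected(self):
        idx, hits, exits = self._frame(-5, None)
        with pytest.raises(ValidationError):
            compute_person_time(idx, hits, exits)

    def test_crude_incidence_arithmetic(self):
        assert crude_incidence(10, 250.0) == pytest.approx(4.0)
        assert crude_incidence(0, 100.0) == 0.0
        with pytest.raises(ArgumentError):
            crude_incidence(5, 0.0)

    @pytest.mark.parametrize(
        "days, expected",
        [([98], 98), ([10, 20, 30], 20), ([10, 20, 30, 40], 20)],
    )
    def test_crude_median_lower_convention(self, days, expected):
        hits = _hits_frame([(f"P{i}", (0, 1, 0, 0), d) for i, d in enumerate(days)])
        assert crude_median_time(hits) == expected

    def test_crude_median_empty_rejected(self):
        hits = _hits_frame([("A", (0, 0, 0, 0), None)])
        with pytest.raises(EmptyInputError):
            crude_median_time(hits)


class TestWindowMonotonicity:
    def test_larger_max_day_never_loses_hits(self, noisy_sim):
        cfg, patients, truth, claims, incident, hits365 = noisy_sim
        idx = incident[["patient_id", "index_date"]]
        hits200 = apply_case_definitions(
            claims, idx, window=AscertainmentWindow(7, 200)
        )
        for d in DEFINITIONS:
            assert hits200[d].sum() <= hits365[d].sum()

    def test_thirty_day_start_never_raises_crude_incidence(self, noisy_sim):
        cfg, patients, truth, claims, incident, hits7 = noisy_sim
        idx = incident[["patient_id", "index_date"]]
        w30 = AscertainmentWindow(30, 365)
        hits30 = apply_case_definitions(claims, idx, window=w30)
        _, py7 = compute_person_time(idx, hits7, patients)
        _, py30 = compute_person_time(idx, hits30, patients, window=w30)
        rate7 = crude_incidence(int(hits7[list(DEFINITIONS)].any(axis=1).sum()), py7)
        rate30 = crude_incidence(int(hits30[list(DEFINITIONS)].any(axis=1).sum()), py30)
        assert rate30 <= rate7
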