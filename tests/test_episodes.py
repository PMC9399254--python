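"""Episode reconstruction: gap/overlap rules, switch censoring, eligibility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oatrisk.episodes import (
    build_episodes,
    build_follow_up,
    censor_at_switch,
    clean_prescriptions,
    episode_summaries,
)


def _rx(days, pid="P1", drug="methadone"):
    return pd.DataFrame(
        {"patient_id": pid, "issue_day": days, "drug": drug,
         "product_code": "MTD-ORAL-1MG"}
    )


def _episodes(days, **kwargs):
    out = build_episodes(_rx(days), **kwargs)
    return list(zip(out["start"], out["end"]))


class TestBuildEpisodes:
    def test_gap_at_least_14_days_opens_new_episode(self):
        # day 0 and day 40: gap 40 - 14 = 26 >= 14
        assert _episodes([0, 40]) == [(0, 14), (40, 54)]

    def test_short_gap_is_bridged_within_episode(self):
        # day 0 and day 20: gap 20 - 14 = 6 < 14
        assert _episodes([0, 20]) == [(0, 34)]

    def test_overlap_extends_expiry_from_its_own_issue(self):
        assert _episodes([0, 7]) == [(0, 21)]

    def test_overlap_stack_mode_adds_a_full_supply(self):
        assert _episodes([0, 7], overlap_mode="stack") == [(0, 28)]

    def test_single_prescription_covers_exactly_one_supply(self):
        assert _episodes([5]) == [(5, 19)]

    def test_exact_boundary_gap_breaks_episode(self):
        # gap of exactly max_gap_days (28 - 14 = 14) is a discontinuation
        assert _episodes([0, 28]) == [(0, 14), (28, 42)]
        # one day less is continuous
        assert _episodes([0, 27]) == [(0, 41)]

    def test_duplicate_rows_collapse(self):
        rx = pd.concat([_rx([0, 20]), _rx([0, 20])])
        out = build_episodes(rx)
        assert list(zip(out["start"], out["end"])) == [(0, 34)]
        assert out["n_rx"].iloc[0] == 2

    @given(
        st.lists(st.integers(min_value=0, max_value=400), min_size=1, max_size=25),
        st.integers(min_value=7, max_value=28),
    )
    @settings(max_examples=60, deadline=None)
    def test_shorter_supply_never_extends_coverage(self, days, supply):
        """Every day covered under a 7-day supply is covered under a
        14-day supply (monotonicity of the exposure reconstruction)."""
        days = sorted(set(days))
        short = build_episodes(_rx(days), supply_days=7)
        long_ = build_episodes(_rx(days), supply_days=14)
        covered_long = np.zeros(500, dtype=bool)
        for s, e in zip(long_["start"], long_["end"]):
            covered_long[s:e] = True
        for s, e in zip(short["start"], short["end"]):
            assert covered_long[s:e].all()

    @given(st.lists(st.integers(min_value=0, max_value=400), min_size=1, max_size=25))
    @settings(max_examples=60, deadline=None)
    def test_episode_count_non_increasing_in_max_gap(self, days):
        days = sorted(set(days))
        n = [
            len(build_episodes(_rx(days), max_gap_days=g)) for g in (7, 14, 28)
        ]
        assert n[0] >= n[1] >= n[2]


class TestSwitchCensoring:
    def test_switcher_truncated_at_other_drug_first_issue(self):
        rx = pd.concat(
            [_rx([0, 20]), _rx([50], drug="buprenorphine")]
        ).reset_index(drop=True)
        stream, switches, excluded = censor_at_switch(rx)
        assert excluded.empty
        assert list(stream["issue_day"]) == [0, 20]
        assert set(stream["drug"]) == {"methadone"}
        assert switches["switch_day"].iloc[0] == 50

    def test_single_drug_patient_unchanged(self):
        rx = _rx([0, 20])
        stream, switches, excluded = censor_at_switch(rx)
        assert len(stream) == 2
        assert np.isnan(switches["switch_day"].iloc[0])
        assert excluded.empty

    def test_both_drugs_on_index_date_excluded_as_tie(self):
        rx = pd.concat([_rx([0]), _rx([0], drug="buprenorphine")]).reset_index(drop=True)
        stream, switches, excluded = censor_at_switch(rx)
        assert list(excluded["reason"]) == ["tie"]
        assert stream.empty


class TestCleanPrescriptions:
    def test_analgesia_formulation_removed(self, toy_code_list):
        rx = _rx([0, 10])
        rx.loc[1, "product_code"] = "BUP-PATCH-5"
        out = clean_prescriptions(rx, toy_code_list)
        assert list(out["product_code"]) == ["MTD-ORAL-1MG"]

    def test_oat_formulation_retained_and_empty_list_is_identity(self, toy_code_list):
        rx = _rx([0, 10])
        out = clean_prescriptions(rx, toy_code_list)
        assert len(out) == 2
        from oatrisk.ascertain import CodeList

        empty = CodeList(pd.DataFrame({"code": ["X"], "system": ["ICD10"],
                                       "category": ["nonfatal_overdose"]}))
        pd.testing.assert_frame_equal(clean_prescriptions(rx, empty), rx)


class TestFollowUp:
    def _patients(self, birth_day=-20 * 365, regist_start=-100, regist_end=4000):
        return pd.DataFrame(
            {"patient_id": ["P1"], "birth_day": [birth_day],
             "regist_start_day": [regist_start], "regist_end_day": [regist_end]}
        )

    def _switches(self, switch=np.nan):
        return pd.DataFrame(
            {"patient_id": ["P1"], "drug": ["methadone"], "switch_day": [switch]}
        )

    def test_observation_end_is_earliest_censor(self):
        fu, excl = build_follow_up(
            self._patients(regist_end=3000), _rx([0, 20]), self._switches(2500),
            study_end_day=2800,
        )
        assert excl.empty
        assert fu["obs_end_day"].iloc[0] == 2500

    def test_under_18_excluded(self):
        fu, excl = build_follow_up(
            self._patients(birth_day=-int(17.5 * 365.25)), _rx([0]),
            self._switches(), study_end_day=4000,
        )
        assert fu.empty
        assert "age" in excl["reason"].iloc[0]

    def test_short_registration_excluded(self):
        fu, excl = build_follow_up(
            self._patients(regist_start=-10), _rx([0]), self._switches(),
            study_end_day=4000,
        )
        assert fu.empty
        assert "registration" in excl["reason"].iloc[0]


def test_episode_summary_bands(small_run):
    summary = episode_summaries(small_run.episodes, small_run.follow_up)
    assert set(summary["drug"]) == {"methadone", "buprenorphine"}
    band_cols = ["up to 1 month", "1-3 months", "3-6 months", "6-12 months",
                 "> 12 months"]
    totals = summary[band_cols].sum(axis=1)
    assert (totals == summary["n_episodes"]).all()
    # generator mixes short episodes with a long-retention tail
    assert (summary["up to 1 month"] > summary["> 12 months"]).all()


def test_episode_summary_single_and_empty():
    fu = pd.DataFrame({"patient_id": ["P1"], "index_day": [0], "obs_end_day": [100]})
    eps = pd.DataFrame(
        {"patient_id": ["P1"], "drug": ["methadone"], "start": [0], "end": [14],
         "n_rx": [1]}
    )
    s = episode_summaries(eps, fu)
    assert s["up to 1 month"].iloc[0] == 1
    assert episode_summaries(eps.iloc[0:0], fu).empty
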