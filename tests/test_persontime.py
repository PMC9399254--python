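"""Risk-window splitting, event attribution, aggregation, censor variants."""

import numpy as np
import pandas as pd
import pytest

from oatrisk.persontime import (
    add_age_bands,
    aggregate,
    apply_censor_variant,
    attribute_events,
    first_event_view,
    split_follow_up,
    InvariantError,
)


def _fu(obs_end=200, index=0, pid="P1"):
    return pd.DataFrame(
        {"patient_id": [pid], "drug": ["methadone"], "index_day": [index],
         "obs_end_day": [obs_end]}
    )


def _eps(intervals, pid="P1"):
    return pd.DataFrame(
        {"patient_id": pid, "start": [s for s, _ in intervals],
         "end": [e for _, e in intervals], "drug": "methadone",
         "n_rx": 1}
    )


def _windows(iv):
    return list(zip(iv["window"], iv["start"], iv["end"]))


class TestSplit:
    def test_four_windows_tile_follow_up(self):
        iv = split_follow_up(_eps([(0, 100)]), _fu(200))
        assert _windows(iv) == [
            ("in_1_4", 0, 28), ("in_gt4", 28, 100),
            ("out_1_4", 100, 128), ("out_gt4", 128, 200),
        ]
        assert (iv["end"] - iv["start"]).sum() == 200

    def test_short_episode_has_no_gt4_stratum(self):
        iv = split_follow_up(_eps([(0, 20)]), _fu(20))
        assert _windows(iv) == [("in_1_4", 0, 20)]

    def test_windows_restart_at_each_transition(self):
        iv = split_follow_up(_eps([(0, 50), (60, 120)]), _fu(200))
        assert _windows(iv) == [
            ("in_1_4", 0, 28), ("in_gt4", 28, 50),
            ("out_1_4", 50, 60),  # only 10 days before next episode
            ("in_1_4", 60, 88), ("in_gt4", 88, 120),
            ("out_1_4", 120, 148), ("out_gt4", 148, 200),
        ]

    def test_overlapping_episodes_rejected(self):
        with pytest.raises(InvariantError):
            split_follow_up(_eps([(0, 50), (40, 80)]), _fu(100))


class TestAttribute:
    def test_events_assigned_by_half_open_containment(self):
        iv = split_follow_up(_eps([(0, 100)]), _fu(200))
        events = pd.DataFrame(
            {"patient_id": ["P1", "P1", "P1"], "day": [10, 28, 200]}
        )
        out, attributed = attribute_events(iv, events)
        assert list(attributed["window"]) == ["in_1_4", "in_gt4"]  # day 200 dropped
        assert out["events"].sum() == 2

    def test_first_event_view_truncates_at_event_day(self):
        iv = split_follow_up(_eps([(0, 100)]), _fu(200))
        events = pd.DataFrame({"patient_id": ["P1", "P1"], "day": [40, 150]})
        iv2, attributed = attribute_events(iv, events)
        first = first_event_view(iv2, attributed)
        assert first["end"].max() == 41  # event day contributes person-time
        assert first["event"].sum() == 1
        assert first.loc[first["event"] == 1, "window"].iloc[0] == "in_gt4"


class TestAggregate:
    def test_published_event_rate_arithmetic(self):
        iv = pd.DataFrame(
            {"patient_id": ["P1"], "drug": ["methadone"], "window": ["in_gt4"],
             "start": [0], "end": [int(round(83856 * 365.25))], "events": [12973]}
        )
        out = aggregate(iv, ["window"])
        assert out["rate_per_100py"].iloc[0] == pytest.approx(15.47, abs=0.005)

    def test_one_event_per_person_year_is_rate_100(self):
        iv = pd.DataFrame(
            {"patient_id": ["P1"], "window": ["in_gt4"], "start": [0],
             "end": [365], "events": [1]}
        )
        iv.loc[0, "end"] = int(365.25)  # one person-year at day resolution
        out = aggregate(iv, ["window"])
        assert out["rate_per_100py"].iloc[0] == pytest.approx(100, rel=1e-2)

    def test_rates_invariant_to_rechunking(self, small_run):
        iv = small_run.intervals
        base = aggregate(iv, ["window", "drug"])
        # split every interval longer than 1 day in two
        mask = iv["end"] - iv["start"] > 1
        cut = ((iv["start"] + iv["end"]) // 2).astype(int)
        left = iv[mask].assign(end=cut[mask], events=0)
        right = iv[mask].assign(start=cut[mask])
        rechunked = aggregate(
            pd.concat([iv[~mask], left, right]), ["window", "drug"]
        )
        pd.testing.assert_frame_equal(
            base[["window", "drug", "person_years"]],
            rechunked[["window", "drug", "person_years"]],
            check_exact=False,
        )

    def test_person_time_matches_generator_ledger(self, small_cohort, small_run):
        """Per-window person-time equals the generator's own ledger
        (pre-switch), up to the death-mid-gap edge case (< 0.02%)."""
        from oatrisk.simulate import expected_counts

        exp = expected_counts(small_cohort["truth"], by=("window",), before_switch=True)
        obs = aggregate(small_run.intervals, ["window"])
        merged = exp.merge(obs, on="window")
        assert np.allclose(
            merged["person_years_x"], merged["person_years_y"], rtol=2e-4
        )


class TestCensorVariants:
    def test_one_year_post_treatment(self):
        fu = _fu(2000)
        capped = apply_censor_variant(fu, _eps([(0, 100)]), "one_year_post_treatment")
        assert capped["obs_end_day"].iloc[0] == 100 + 365

    def test_max_followup_years(self):
        fu = _fu(12 * 366, index=0)
        capped = apply_censor_variant(fu, variant="max_followup_years", years=10)
        assert capped["obs_end_day"].iloc[0] == int(round(10 * 365.25))

    def test_none_is_identity_and_never_lengthens(self, small_run):
        fu = small_run.follow_up
        pd.testing.assert_frame_equal(apply_censor_variant(fu, variant="none"), fu)
        for variant, kw in (("one_year_post_treatment", {}),
                            ("max_followup_years", {"years": 2})):
            capped = apply_censor_variant(fu, small_run.episodes, variant, **kw)
            assert (capped["obs_end_day"] <= fu["obs_end_day"]).all()

    def test_conservation_under_every_variant(self, small_cohort, small_run):
        """Interval durations sum to follow-up length for every patient
        under every censor variant."""
        fu0, eps = small_run.follow_up, small_run.episodes
        for variant, kw in (("none", {}), ("one_year_post_treatment", {}),
                            ("max_followup_years", {"years": 3})):
            fu = apply_censor_variant(fu0, eps, variant, **kw)
            iv = split_follow_up(eps, fu)
            dur = iv.assign(d=iv["end"] - iv["start"]).groupby("patient_id")["d"].sum()
            expect = (fu["obs_end_day"] - fu["index_day"]).to_numpy()
            got = dur.reindex(fu["patient_id"]).fillna(0).to_numpy()
            assert (got == expect).all()


def test_age_bands_split_and_conserve():
    fu = _fu(3000).assign(birth_day=-24 * 365 - 200)  # ~24.5y at index
    iv = split_follow_up(_eps([(0, 100)]), fu)
    banded = add_age_bands(iv, fu)
    assert set(banded["age_band"]) == {"18-24", "25-34"}
    assert (banded["end"] - banded["start"]).sum() == 3000
    # the 25th-birthday split day is a band boundary
    cut = int(np.ceil(25 * 365.25)) - (fu["index_day"] - fu["birth_day"]).iloc[0]
    assert cut in set(banded["start"])
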