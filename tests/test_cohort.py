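"""Follow-up construction, eligibility, band splitting, exposure flags."""

import numpy as np
import pandas as pd
import pytest

from mmiburden import (
    apply_eligibility,
    assign_exposure,
    build_segments,
    follow_up_interval,
    split_age_bands,
)
from mmiburden.bands import AGE_BANDS, DAYS_PER_YEAR

from _oracles import brute_force_follow_up

STUDY = (pd.Timestamp("2007-04-01"), pd.Timestamp("2017-07-31"))


def child_record(**overrides):
    base = {
        "child_id": "c1",
        "mother_id": "m1",
        "birth_date": pd.Timestamp("2010-01-01"),
        "death_date": pd.NaT,
        "sex": "F",
        "imd_quintile": 3,
        "registration_start": pd.Timestamp("2010-01-01"),
        "registration_end": pd.Timestamp("2030-01-01"),
        "practice_uts_date": pd.Timestamp("2005-01-01"),
        "practice_collection_end": pd.Timestamp("2030-01-01"),
        "hes_linked": True,
        "mother_death_date": pd.NaT,
    }
    base.update(overrides)
    return base


def mother_record(**overrides):
    base = {
        "mother_id": "m1",
        "registration_start": pd.Timestamp("2000-01-01"),
        "registration_end": pd.Timestamp("2030-01-01"),
        "death_date": pd.NaT,
        "practice_uts_date": pd.Timestamp("2000-01-01"),
    }
    base.update(overrides)
    return base


def test_follow_up_runs_birth_to_study_end():
    """A child born mid-study, registered from birth, is followed from
    birth to the study end (before their 18th birthday)."""
    iv = follow_up_interval(child_record(), STUDY)
    assert iv == (pd.Timestamp("2010-01-01"), pd.Timestamp("2017-07-31"))


def test_follow_up_truncated_by_18th_birthday():
    iv = follow_up_interval(
        child_record(
            birth_date=pd.Timestamp("1994-06-15"),
            registration_start=pd.Timestamp("1994-06-15"),
        ),
        STUDY,
    )
    assert iv == (pd.Timestamp("2007-04-01"), pd.Timestamp("2012-06-15"))


def test_follow_up_none_when_registration_ends_before_study():
    iv = follow_up_interval(
        child_record(
            birth_date=pd.Timestamp("1995-01-01"),
            registration_start=pd.Timestamp("1995-01-01"),
            registration_end=pd.Timestamp("2006-01-01"),
        ),
        STUDY,
    )
    assert iv is None


def test_follow_up_ends_at_mothers_death():
    iv = follow_up_interval(
        child_record(), STUDY, mother_death_date=pd.Timestamp("2013-05-05")
    )
    assert iv[1] == pd.Timestamp("2013-05-05")


def test_missing_birth_date_rejected():
    with pytest.raises(ValueError):
        follow_up_interval(child_record(birth_date=pd.NaT), STUDY)


def test_follow_up_matches_candidate_enumeration():
    """Start/end equal the max/min over explicitly enumerated candidates
    on 1000 random records."""
    rng = np.random.default_rng(5)
    t0 = pd.Timestamp("1995-01-01")

    def rdate(lo=0, hi=9000):
        return t0 + pd.Timedelta(days=int(rng.integers(lo, hi)))

    for _ in range(1000):
        rec = child_record(
            birth_date=rdate(0, 8000),
            registration_start=rdate(),
            registration_end=rdate(),
            practice_uts_date=rdate(),
            practice_collection_end=rdate(),
            death_date=rdate() if rng.random() < 0.2 else pd.NaT,
            mother_death_date=rdate() if rng.random() < 0.2 else pd.NaT,
        )
        got = follow_up_interval(rec, STUDY)
        want = brute_force_follow_up(rec, *STUDY)
        assert got == want


def test_eligibility_rules_and_planted_tally():
    """Each planted violation is excluded under its own rule, in order."""
    ok = child_record(child_id="ok")
    no_hes = child_record(child_id="no_hes", hes_linked=False)
    short = child_record(
        child_id="short",
        registration_end=pd.Timestamp("2010-01-20"),  # 19 days < 30.5
    )
    orphan = child_record(child_id="orphan", mother_id="nobody")
    not_uts = child_record(child_id="not_uts", mother_id="m_lateuts")
    thin_mother = child_record(child_id="thin", mother_id="m_thin")

    children = pd.DataFrame([ok, no_hes, short, orphan, not_uts, thin_mother])
    mothers = pd.DataFrame(
        [
            mother_record(),
            mother_record(mother_id="m_lateuts", practice_uts_date=pd.Timestamp("2015-01-01")),
            mother_record(
                mother_id="m_thin",
                registration_start=pd.Timestamp("2007-01-01"),
                registration_end=pd.Timestamp("2011-01-01"),  # < 2y after start
            ),
        ]
    )
    eligible, tally = apply_eligibility(children, mothers, STUDY)
    assert list(eligible["child_id"]) == ["ok"]
    assert tally["no_hes_linkage"] == 1
    assert tally["insufficient_follow_up"] == 1
    assert tally["orphan_child"] == 1
    assert tally["mother_not_uts"] == 1
    assert tally["mother_insufficient_data"] == 1
    assert tally["eligible"] == 1


def test_mother_needs_two_years_both_sides():
    """A mother registered [start-3y, start+1y] fails the 2-year-after rule."""
    kid = child_record(mother_id="m_a")
    mothers = pd.DataFrame(
        [
            mother_record(
                mother_id="m_a",
                registration_start=pd.Timestamp("2007-01-01"),
                registration_end=pd.Timestamp("2011-01-01"),
                practice_uts_date=pd.Timestamp("2007-01-01"),
            )
        ]
    )
    eligible, tally = apply_eligibility(pd.DataFrame([kid]), mothers, STUDY)
    assert eligible.empty and tally["mother_insufficient_data"] == 1


def test_full_childhood_splits_into_five_bands_summing_18_years():
    birth = pd.Timestamp("1999-04-01")
    seg = split_age_bands((birth, birth + pd.DateOffset(years=18)), birth)
    assert list(seg["age_band"]) == list(AGE_BANDS)
    assert seg["person_years"].sum() == pytest.approx(18.0, abs=0.01)


def test_interval_straddling_first_birthday_splits_in_two():
    birth = pd.Timestamp("2010-01-01")
    start = birth + pd.Timedelta(days=183)
    end = birth + pd.Timedelta(days=548)
    seg = split_age_bands((start, end), birth)
    assert list(seg["age_band"]) == ["<1", "1-4"]
    assert seg["person_years"].iloc[0] == pytest.approx(0.5, abs=0.01)
    assert seg["person_years"].iloc[1] == pytest.approx(0.5, abs=0.01)
    # boundary day belongs to the older band
    assert seg["end_date"].iloc[0] == seg["start_date"].iloc[1]


def test_person_time_is_conserved_on_random_intervals():
    rng = np.random.default_rng(8)
    for _ in range(300):
        birth = pd.Timestamp("2000-01-01") + pd.Timedelta(days=int(rng.integers(0, 5000)))
        a = int(rng.integers(0, 18 * 365))
        b = int(rng.integers(a + 1, 18 * 365 + 1))
        start, end = birth + pd.Timedelta(days=a), birth + pd.Timedelta(days=b)
        seg = split_age_bands((start, end), birth)
        total = seg["person_years"].sum()
        assert total == pytest.approx((end - start).days / DAYS_PER_YEAR, abs=1e-9)


DET = pd.DataFrame(
    [
        {
            "mother_id": "m1",
            "illness": "depression",
            "case_date": pd.Timestamp("2011-06-01"),
            "pathway": "diagnosis",
        }
    ]
)


def _one_segment(band_start, seg_end):
    return pd.DataFrame(
        [
            {
                "child_id": "c1",
                "mother_id": "m1",
                "age_band": "1-4",
                "band_start_date": band_start,
                "start_date": band_start,
                "end_date": seg_end,
                "person_years": 1.0,
                "period": band_start.year,
            }
        ]
    )


def test_case_just_before_band_start_exposes_both_modes():
    seg = _one_segment(pd.Timestamp("2011-06-02"), pd.Timestamp("2012-06-02"))
    for mode in ("main", "sensitivity"):
        out = assign_exposure(seg, DET, mode=mode)
        assert out["exposed_any"].iloc[0]
        assert out["exposed_CMI"].iloc[0]


def test_mid_band_case_exposes_main_mode_only():
    """Ignoring exposure during the age group (reverse-causation check)
    drops a case arising mid-band."""
    seg = _one_segment(pd.Timestamp("2011-01-01"), pd.Timestamp("2012-01-01"))
    assert assign_exposure(seg, DET, mode="main")["exposed_any"].iloc[0]
    assert not assign_exposure(seg, DET, mode="sensitivity")["exposed_any"].iloc[0]


def test_lookback_is_two_years():
    seg = _one_segment(pd.Timestamp("2013-05-31"), pd.Timestamp("2014-05-31"))
    # case 730 days before band start: inside the closed window
    assert assign_exposure(seg, DET, mode="main")["exposed_any"].iloc[0]
    seg2 = _one_segment(pd.Timestamp("2013-06-02"), pd.Timestamp("2014-06-02"))
    assert not assign_exposure(seg2, DET, mode="main")["exposed_any"].iloc[0]


def test_exposure_flags_match_brute_force_scan(small_dataset):
    """Vectorised window flags equal a per-segment literal window check."""
    ds = small_dataset
    seg = ds.segments.head(300)
    det = ds.determinations
    for _, row in seg.iterrows():
        ws = row["band_start_date"] - pd.Timedelta(days=730)
        sub = det[det["mother_id"] == row["mother_id"]]
        want = bool(
            ((sub["case_date"] >= ws) & (sub["case_date"] <= row["end_date"])).any()
        )
        assert row["exposed_any"] == want


def test_sensitivity_exposure_is_subset_of_main(small_dataset):
    ds = small_dataset
    base = ds.segments.drop(columns=[c for c in ds.segments.columns if c.startswith("exposed_")])
    main = assign_exposure(base, ds.determinations, mode="main")
    sens = assign_exposure(base, ds.determinations, mode="sensitivity")
    for cat in ("any", "CMI", "SMI", "addiction"):
        assert not (sens[f"exposed_{cat}"] & ~main[f"exposed_{cat}"]).any()


def test_segments_partition_follow_up(small_dataset):
    ds = small_dataset
    seg = ds.segments
    # within a child: ordered, disjoint, contiguous
    for _, grp in list(seg.groupby("child_id"))[:200]:
        grp = grp.sort_values("start_date")
        assert (grp["end_date"].iloc[:-1].to_numpy() == grp["start_date"].iloc[1:].to_numpy()).all()
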