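"""Cohort eligibility, follow-up construction and person-time splitting.

Follow-up for a child begins at the latest of: date of birth, the date
the practice began contributing up-to-standard (UTS) data, the child's
registration date, or the study start.  It ends at the earliest of:
transfer out of the practice, 18th birthday, child's death, mother's
death, practice data-collection end, or the study end.  Children are
excluded if they lack HES linkage, contribute fewer than 30.5 days of
follow-up, their mother was not UTS-registered at the child's start of
follow-up, or the mother has less than 2 years of data on either side
of that start (needed to ascertain exposure).

The follow-up interval is split at band-boundary birthdays (ages 1, 5,
10, 14, 18) into person-time segments; each segment carries its
person-years (365.25-day years), the calendar year it starts in
(the "period") and, after :func:`assign_exposure`, per-category
exposure flags.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from mmiburden.bands import (
    AGE_BANDS,
    BAND_BOUNDARY_AGES,
    DAYS_PER_YEAR,
    LOOKBACK_DAYS,
    add_years,
    add_years_vec,
)
from mmiburden.phenotyping import EXPOSURE_CATEGORIES, ExposureCategory

#: Minimum in-study follow-up, in days ("at least 30.5 days").
MIN_FOLLOW_UP_DAYS = 30.5

#: Fixed order of exclusion reasons; each child is excluded under the
#: first rule it violates.
EXCLUSION_REASONS: tuple[str, ...] = (
    "missing_birth_date",
    "no_hes_linkage",
    "insufficient_follow_up",
    "orphan_child",
    "mother_not_uts",
    "mother_insufficient_data",
)


def _follow_up_bounds(
    children: pd.DataFrame,
    study_window: tuple[pd.Timestamp, pd.Timestamp],
) -> tuple[pd.Series, pd.Series]:
    """Vectorised (start, end) follow-up candidates for many children.

    Expects date columns ``birth_date``, ``practice_uts_date``,
    ``registration_start``, ``registration_end``, ``death_date``,
    ``mother_death_date``, ``practice_collection_end``.
    """
    study_start, study_end = pd.Timestamp(study_window[0]), pd.Timestamp(study_window[1])
    birth = pd.to_datetime(children["birth_date"])
    start = pd.concat(
        [
            birth,
            pd.to_datetime(children["practice_uts_date"]),
            pd.to_datetime(children["registration_start"]),
            pd.Series(study_start, index=children.index),
        ],
        axis=1,
    ).max(axis=1)
    eighteenth = add_years_vec(birth, 18)
    end = pd.concat(
        [
            pd.to_datetime(children["registration_end"]),
            eighteenth,
            pd.to_datetime(children["death_date"]),
            pd.to_datetime(children["mother_death_date"]),
            pd.to_datetime(children["practice_collection_end"]),
            pd.Series(study_end, index=children.index),
        ],
        axis=1,
    ).min(axis=1, skipna=True)
    return start, end


def follow_up_interval(
    child: Mapping,
    study_window: tuple[pd.Timestamp, pd.Timestamp],
    mother_death_date: pd.Timestamp | None = None,
) -> tuple[pd.Timestamp, pd.Timestamp] | None:
    """Follow-up interval [start, end) for one child, or None if empty.

    ``child`` is a mapping/Series with the ChildRecord date fields; the
    mother's death date may be supplied either as the key
    ``mother_death_date`` or as the explicit argument.
    """
    rec = dict(child)
    if mother_death_date is not None:
        rec["mother_death_date"] = mother_death_date
    rec.setdefault("mother_death_date", pd.NaT)
    if pd.isna(rec.get("birth_date")):
        raise ValueError("missing birth_date")
    frame = pd.DataFrame([rec])
    start, end = _follow_up_bounds(frame, study_window)
    s, e = start.iloc[0], end.iloc[0]
    if e <= s:
        return None
    return s, e


def apply_eligibility(
    children: pd.DataFrame,
    mothers: pd.DataFrame,
    study_window: tuple[pd.Timestamp, pd.Timestamp],
) -> tuple[pd.DataFrame, pd.Series]:
    """Apply the exclusion rules in their fixed order.

    Returns the eligible children (with ``fu_start``/``fu_end`` columns
    attached) and a tally of exclusions per reason plus ``eligible``.
    """
    kids = children.copy()
    for col in ("birth_date", "death_date", "registration_start", "registration_end",
                "practice_uts_date", "practice_collection_end"):
        kids[col] = pd.to_datetime(kids[col])

    mom = mothers.set_index("mother_id")
    mom_death = (
        pd.to_datetime(mom["death_date"])
        if "death_date" in mom.columns
        else pd.Series(pd.NaT, index=mom.index)
    )
    mom_cols = {
        "mother_death_date": mom_death,
        "m_reg_start": pd.to_datetime(mom["registration_start"]),
        "m_reg_end": pd.to_datetime(mom["registration_end"]),
        "m_uts": pd.to_datetime(mom["practice_uts_date"]),
    }
    for name, series in mom_cols.items():
        kids[name] = kids["mother_id"].map(series)
    has_mother = kids["mother_id"].isin(mom.index)

    missing_birth = kids["birth_date"].isna()
    # follow-up bounds are only defined where a birth date exists
    fu_start, fu_end = _follow_up_bounds(kids.assign(
        birth_date=kids["birth_date"].fillna(pd.Timestamp("1900-01-01"))
    ), study_window)
    kids["fu_start"], kids["fu_end"] = fu_start, fu_end
    duration_days = (fu_end - fu_start).dt.days.astype(float)

    hes = kids["hes_linked"].astype(bool)
    long_enough = duration_days >= MIN_FOLLOW_UP_DAYS
    mother_uts = (
        (kids["m_reg_start"] <= fu_start)
        & (fu_start < kids["m_reg_end"])
        & (kids["m_uts"] <= fu_start)
    )
    two_years = pd.Timedelta(days=LOOKBACK_DAYS)
    mother_2y = (kids["m_reg_start"] <= fu_start - two_years) & (
        kids["m_reg_end"] >= fu_start + two_years
    )

    reason = pd.Series("eligible", index=kids.index)
    remaining = pd.Series(True, index=kids.index)
    for name, violated in [
        ("missing_birth_date", missing_birth),
        ("no_hes_linkage", ~hes),
        ("insufficient_follow_up", ~long_enough),
        ("orphan_child", ~has_mother),
        ("mother_not_uts", ~mother_uts.fillna(False)),
        ("mother_insufficient_data", ~mother_2y.fillna(False)),
    ]:
        hit = remaining & violated
        reason[hit] = name
        remaining &= ~hit

    tally = reason.value_counts().reindex(
        list(EXCLUSION_REASONS) + ["eligible"], fill_value=0
    )
    eligible = kids[reason == "eligible"].drop(
        columns=["m_reg_start", "m_reg_end", "m_uts"]
    )
    return eligible.reset_index(drop=True), tally


def split_age_bands(
    interval: tuple[pd.Timestamp, pd.Timestamp],
    birth_date: pd.Timestamp,
) -> pd.DataFrame:
    """Split one follow-up interval [start, end) at band-boundary birthdays.

    Returns a frame with one row per overlapped band: ``age_band``,
    ``band_start_date`` (the nominal band-start birthday),
    ``start_date``, ``end_date``, ``person_years`` and ``period`` (the
    calendar year the segment starts in).
    """
    start, end = pd.Timestamp(interval[0]), pd.Timestamp(interval[1])
    birth = pd.Timestamp(birth_date)
    rows = []
    for i, band in enumerate(AGE_BANDS):
        lo = add_years(birth, BAND_BOUNDARY_AGES[i])
        hi = add_years(birth, BAND_BOUNDARY_AGES[i + 1])
        s, e = max(start, lo), min(end, hi)
        if e > s:
            rows.append(
                {
                    "age_band": band,
                    "band_start_date": lo,
                    "start_date": s,
                    "end_date": e,
                    "person_years": (e - s).days / DAYS_PER_YEAR,
                    "period": int(s.year),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "age_band",
            "band_start_date",
            "start_date",
            "end_date",
            "person_years",
            "period",
        ],
    )


def build_segments(
    children: pd.DataFrame,
    mothers: pd.DataFrame,
    study_window: tuple[pd.Timestamp, pd.Timestamp],
) -> tuple[pd.DataFrame, pd.Series]:
    """Eligibility + follow-up + band splitting for a whole cohort.

    Returns (segments, exclusion tally).  Segments carry child and
    mother ids, demographics, band dates, person-years and period.
    """
    eligible, tally = apply_eligibility(children, mothers, study_window)
    if eligible.empty:
        cols = [
            "child_id", "mother_id", "age_band", "band_start_date",
            "start_date", "end_date", "person_years", "period",
            "sex", "imd_quintile",
        ]
        return pd.DataFrame(columns=cols), tally

    birth = pd.to_datetime(eligible["birth_date"])
    parts = []
    for i, band in enumerate(AGE_BANDS):
        lo = add_years_vec(birth, BAND_BOUNDARY_AGES[i])
        hi = add_years_vec(birth, BAND_BOUNDARY_AGES[i + 1])
        s = np.maximum(eligible["fu_start"].to_numpy(), lo.to_numpy())
        e = np.minimum(eligible["fu_end"].to_numpy(), hi.to_numpy())
        keep = e > s
        if not keep.any():
            continue
        seg = pd.DataFrame(
            {
                "child_id": eligible.loc[keep, "child_id"].to_numpy(),
                "mother_id": eligible.loc[keep, "mother_id"].to_numpy(),
                "age_band": band,
                "band_start_date": lo.to_numpy()[keep],
                "start_date": s[keep],
                "end_date": e[keep],
                "sex": eligible.loc[keep, "sex"].to_numpy(),
                "imd_quintile": eligible.loc[keep, "imd_quintile"].to_numpy(),
            }
        )
        parts.append(seg)
    segments = pd.concat(parts, ignore_index=True)
    segments["person_years"] = (
        (segments["end_date"] - segments["start_date"]).dt.days / DAYS_PER_YEAR
    )
    segments["period"] = segments["start_date"].dt.year.astype(int)
    segments = segments.sort_values(["child_id", "start_date"]).reset_index(drop=True)
    return segments, tally


def assign_exposure(
    segments: pd.DataFrame,
    determinations: pd.DataFrame,
    categories: Iterable[ExposureCategory | str] | None = None,
    mode: str = "main",
) -> pd.DataFrame:
    """Attach per-category exposure flags to person-time segments.

    main mode: a child is exposed for a band if the mother has a
    qualifying case date in the closed window [band_start - 2 years,
    segment_end].  sensitivity mode ignores exposure during the band
    itself: half-open window [band_start - 2 years, band_start).
    """
    if mode not in {"main", "sensitivity"}:
        raise ValueError(f"unknown exposure mode: {mode!r}")
    if categories is None:
        categories = list(EXPOSURE_CATEGORIES.values())
    cats = [
        EXPOSURE_CATEGORIES[c] if isinstance(c, str) else c for c in categories
    ]

    seg = segments.reset_index(drop=True).copy()
    win_start = pd.to_datetime(seg["band_start_date"]) - pd.Timedelta(days=LOOKBACK_DAYS)

    for cat in cats:
        seg[f"exposed_{cat.label}"] = False

    if not determinations.empty and len(seg):
        det = determinations.copy()
        det["case_date"] = pd.to_datetime(det["case_date"])
        merged = (
            seg[["mother_id"]]
            .reset_index(names="_seg")
            .merge(det, on="mother_id", how="inner")
        )
        if len(merged):
            ws = win_start.iloc[merged["_seg"]].to_numpy()
            if mode == "main":
                we = pd.to_datetime(seg["end_date"]).iloc[merged["_seg"]].to_numpy()
                in_win = (merged["case_date"].to_numpy() >= ws) & (
                    merged["case_date"].to_numpy() <= we
                )
            else:
                bs = pd.to_datetime(seg["band_start_date"]).iloc[merged["_seg"]].to_numpy()
                in_win = (merged["case_date"].to_numpy() >= ws) & (
                    merged["case_date"].to_numpy() < bs
                )
            merged = merged[in_win]
            for cat in cats:
                hits = merged.loc[
                    merged["illness"].isin(cat.member_illnesses), "_seg"
                ].unique()
                col = seg.columns.get_loc(f"exposed_{cat.label}")
                seg.iloc[hits, col] = True
    return seg
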