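"""Healthcare-use event counting with same-day deduplication.

Six outcome types are counted per person-time segment: primary care
contacts, prescriptions, referrals, out-patient visits, in-patient
admissions and emergency (A&E) visits, plus a ``total`` record summing
them.  Multiple contacts or prescriptions of the same type on the same
date count once; "same type" is resolved at the level that costing
distinguishes — consultation x staff for primary care, the drug code
for prescriptions, and the outcome itself elsewhere.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from mmiburden.inference import fit_two_group

logger = logging.getLogger(__name__)

OUTCOMES: tuple[str, ...] = (
    "primary_care",
    "prescription",
    "referral",
    "outpatient",
    "inpatient",
    "emergency",
)

TOTAL = "total"

CONSULTATION_TYPES = ("face-to-face", "telephone", "home-visit")
STAFF_TYPES = ("doctor", "nurse", "health-visitor", "other")
EPISODE_TYPES = ("day-case", "regular-day-night", "elective", "non-elective")


def dedup_subtype(events: pd.DataFrame) -> pd.Series:
    """The "same type" granularity for the once-per-day rule.

    primary care -> consultation type x staff; prescription -> the drug
    code; other outcomes -> the outcome alone (empty subtype).
    """
    sub = pd.Series("", index=events.index, dtype=object)
    pc = events["outcome"] == "primary_care"
    if pc.any():
        sub[pc] = (
            events.loc[pc, "consultation_type"].astype(str)
            + "|"
            + events.loc[pc, "staff"].astype(str)
        )
    rx = events["outcome"] == "prescription"
    if rx.any():
        sub[rx] = events.loc[rx, "drug_code"].astype(str)
    return sub


def deduplicate(events: pd.DataFrame) -> pd.DataFrame:
    """Collapse same-day same-type events to one.

    For in-patient duplicates the longest length of stay is kept so the
    collapsed admission is not under-costed.  The number of rows removed
    is recorded in ``result.attrs["n_duplicates_removed"]``.
    """
    ev = events.copy()
    ev["date"] = pd.to_datetime(ev["date"])
    ev["_subtype"] = dedup_subtype(ev)
    if "length_of_stay" in ev.columns:
        ev = ev.sort_values(
            ["child_id", "date", "outcome", "_subtype", "length_of_stay"],
            ascending=[True, True, True, True, False],
            kind="mergesort",
        )
    deduped = ev.drop_duplicates(
        subset=["child_id", "date", "outcome", "_subtype"], keep="first"
    )
    n_removed = len(ev) - len(deduped)
    deduped = deduped.drop(columns="_subtype").reset_index(drop=True)
    deduped.attrs["n_duplicates_removed"] = n_removed
    return deduped


def assign_to_segments(events: pd.DataFrame, segments: pd.DataFrame) -> pd.DataFrame:
    """Attach the containing segment's row index to each event.

    An event belongs to the unique segment with start <= date < end.
    Events outside all segments are dropped; the count is logged and
    stored in ``result.attrs["n_outside_segments"]``.
    """
    seg = segments.reset_index(drop=True).reset_index(names="_seg")
    ev = events.copy()
    ev["date"] = pd.to_datetime(ev["date"])
    merged = ev.merge(
        seg[["_seg", "child_id", "start_date", "end_date"]], on="child_id", how="left"
    )
    inside = (merged["date"] >= merged["start_date"]) & (
        merged["date"] < merged["end_date"]
    )
    matched = merged[inside].drop(columns=["start_date", "end_date"])
    n_outside = len(ev) - len(matched)
    if n_outside:
        logger.info("dropped %d events outside all segments", n_outside)
    matched = matched.reset_index(drop=True)
    matched.attrs["n_outside_segments"] = n_outside
    return matched


_SEGMENT_CARRY = [
    "child_id",
    "mother_id",
    "age_band",
    "person_years",
    "period",
    "imd_quintile",
]


def count_events(events: pd.DataFrame, segments: pd.DataFrame) -> pd.DataFrame:
    """Deduplicated event counts per segment and outcome.

    Returns one row per segment x (six outcomes + total), zeros
    included, carrying the segment's person-years, period, deprivation
    quintile and any ``exposed_*`` flags.
    """
    seg = segments.reset_index(drop=True)
    carry = _SEGMENT_CARRY + [c for c in seg.columns if c.startswith("exposed_")]
    base = seg[carry].reset_index(names="_seg")

    if len(events):
        deduped = deduplicate(events)
        located = assign_to_segments(deduped, seg)
        tallies = (
            located.groupby(["_seg", "outcome"], as_index=False)
            .size()
            .rename(columns={"size": "count"})
        )
    else:
        tallies = pd.DataFrame(columns=["_seg", "outcome", "count"])

    grid = base.loc[base.index.repeat(len(OUTCOMES))].reset_index(drop=True)
    grid["outcome"] = np.tile(OUTCOMES, len(base))
    grid = grid.merge(tallies, on=["_seg", "outcome"], how="left")
    grid["count"] = pd.to_numeric(grid["count"], errors="coerce").fillna(0).astype(int)

    totals = grid.groupby("_seg", as_index=False)["count"].sum()
    total_rows = base.merge(totals, on="_seg", how="left")
    total_rows["count"] = (
        pd.to_numeric(total_rows["count"], errors="coerce").fillna(0).astype(int)
    )
    total_rows["outcome"] = TOTAL

    out = pd.concat([grid, total_rows], ignore_index=True).drop(columns="_seg")
    cols = carry + ["outcome", "count"]
    return out[cols]


def tabulate_by_drug_category(
    events: pd.DataFrame,
    segments: pd.DataFrame,
    exposure_col: str = "exposed_any",
) -> pd.DataFrame:
    """Prescription rates and exposed/unexposed rate ratios per drug category.

    Prescriptions missing a category fall into ``uncategorised``.  Rate
    ratios come from the two-group negative-binomial path with
    mother-clustered robust variance; categories with an empty arm get
    NaN ratios and a degenerate flag.
    """
    seg = segments.reset_index(drop=True)
    rx = events[events["outcome"] == "prescription"].copy()
    if rx.empty:
        return pd.DataFrame(
            columns=[
                "drug_category",
                "n_events",
                "rate_exposed",
                "rate_unexposed",
                "rate_ratio",
                "rr_ci_low",
                "rr_ci_high",
                "degenerate",
            ]
        )
    rx["drug_category"] = (
        rx["drug_category"].fillna("").replace("", "uncategorised")
        if "drug_category" in rx.columns
        else "uncategorised"
    )
    rx = deduplicate(rx)
    located = assign_to_segments(rx, seg)

    py = seg["person_years"]
    exposed = seg[exposure_col].astype(bool)
    py_e, py_u = py[exposed].sum(), py[~exposed].sum()

    rows = []
    for cat, grp in located.groupby("drug_category"):
        counts = grp.groupby("_seg").size()
        per_seg = pd.DataFrame(
            {
                "count": counts.reindex(seg.index, fill_value=0).astype(int),
                "person_years": py,
                exposure_col: exposed,
                "mother_id": seg["mother_id"],
            }
        )
        n_e = per_seg.loc[exposed, "count"].sum()
        n_u = per_seg.loc[~exposed, "count"].sum()
        row = {
            "drug_category": cat,
            "n_events": int(len(grp)),
            "rate_exposed": n_e / py_e if py_e > 0 else np.nan,
            "rate_unexposed": n_u / py_u if py_u > 0 else np.nan,
        }
        if n_e > 0 and n_u > 0:
            fit = fit_two_group(per_seg, exposure_col=exposure_col)
            row.update(
                rate_ratio=fit["rate_ratio"],
                rr_ci_low=fit["ci_low"],
                rr_ci_high=fit["ci_high"],
                degenerate=False,
            )
        else:
            row.update(
                rate_ratio=np.nan, rr_ci_low=np.nan, rr_ci_high=np.nan, degenerate=True
            )
        rows.append(row)
    return pd.DataFrame(rows).sort_values("drug_category").reset_index(drop=True)
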