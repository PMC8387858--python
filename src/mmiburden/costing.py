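"""Tariff-based costing of healthcare events, inflated to a base year.

Unit costs come from annual tariff tables: primary care contacts are
costed by consultation and staff type; referrals, out-patient and A&E
visits by an annual average unit cost; prescriptions by drug-specific
cost with the year's average as fallback when no drug tariff exists;
and hospital admissions by episode type, with elective/non-elective
admissions additionally accruing a per-bed-day cost times length of
stay (a pure bed-day form is available as a switch).  Every cost is
adjusted to base-year (2017) terms with a consumer price index:
``amount * index(base) / index(year)``.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from mmiburden.counting import deduplicate, assign_to_segments

BASE_YEAR = 2017


class CostingError(KeyError):
    """Raised when a tariff or CPI entry needed to cost an event is absent."""


def _cpi_map(cpi: pd.DataFrame, base_year: int) -> Mapping[int, float]:
    idx = dict(zip(cpi["year"].astype(int), cpi["index"].astype(float)))
    if base_year not in idx:
        raise CostingError(f"CPI table lacks the base year {base_year}")
    if any(v <= 0 for v in idx.values()):
        raise CostingError("CPI indices must be positive")
    return idx


def inflate(
    amount: float, year: int, cpi: pd.DataFrame, base_year: int = BASE_YEAR
) -> float:
    """Express a nominal amount from ``year`` in base-year terms."""
    idx = _cpi_map(cpi, base_year)
    if int(year) not in idx:
        raise CostingError(f"CPI table lacks year {year}")
    return float(amount) * idx[base_year] / idx[int(year)]


def _tariff_maps(tariffs: pd.DataFrame):
    t = tariffs.copy()
    t["year"] = t["year"].astype(int)
    t["subtype"] = t["subtype"].fillna("").astype(str)
    unit = {
        (r.year, r.outcome, r.subtype): float(r.unit_cost) for r in t.itertuples()
    }
    bed = {
        (r.year, r.outcome, r.subtype): float(r.per_bed_day_cost)
        for r in t.itertuples()
        if "per_bed_day_cost" in t.columns and pd.notna(r.per_bed_day_cost)
    }
    return unit, bed


def _event_subtype_key(row: Mapping) -> str:
    outcome = row["outcome"]
    if outcome == "primary_care":
        return f"{row['consultation_type']}|{row['staff']}"
    if outcome == "inpatient":
        return str(row["episode_type"])
    if outcome == "prescription":
        return str(row["drug_code"])
    return ""


def _nominal_cost(
    row: Mapping,
    unit: Mapping[tuple, float],
    bed: Mapping[tuple, float],
    admission_form: str,
) -> float:
    year = int(pd.Timestamp(row["date"]).year)
    outcome = row["outcome"]
    sub = _event_subtype_key(row)
    if outcome == "prescription":
        # drug-specific tariff when listed, else the year's average cost
        if (year, outcome, sub) in unit:
            return unit[(year, outcome, sub)]
        if (year, outcome, "") in unit:
            return unit[(year, outcome, "")]
        raise CostingError(f"no prescription tariff (even average) for year {year}")
    if outcome == "inpatient":
        key = (year, outcome, sub)
        if key not in unit:
            raise CostingError(f"missing tariff for {key}")
        admit = unit[key]
        if sub in ("elective", "non-elective"):
            los = float(row.get("length_of_stay", 0) or 0)
            bed_day = bed.get(key, 0.0)
            if admission_form == "additive":
                return admit + bed_day * los
            if admission_form == "bed_day_only":
                return bed_day * max(los, 1.0)
            raise ValueError(f"unknown admission_form: {admission_form!r}")
        return admit
    key = (year, outcome, sub)
    if key not in unit:
        raise CostingError(f"missing tariff for {key}")
    return unit[key]


def cost_event(
    event: Mapping,
    tariffs: pd.DataFrame,
    cpi: pd.DataFrame,
    *,
    base_year: int = BASE_YEAR,
    admission_form: str = "additive",
) -> float:
    """Base-year cost of a single event."""
    unit, bed = _tariff_maps(tariffs)
    nominal = _nominal_cost(event, unit, bed, admission_form)
    return inflate(nominal, int(pd.Timestamp(event["date"]).year), cpi, base_year)


def cost_events(
    events: pd.DataFrame,
    tariffs: pd.DataFrame,
    cpi: pd.DataFrame,
    *,
    base_year: int = BASE_YEAR,
    admission_form: str = "additive",
) -> pd.Series:
    """Base-year cost of every event (aligned with ``events.index``).

    Vectorised equivalent of mapping :func:`cost_event` over the rows.
    """
    unit, bed = _tariff_maps(tariffs)
    idx = _cpi_map(cpi, base_year)
    ev = events
    year = pd.to_datetime(ev["date"]).dt.year.astype(int)
    outcome = ev["outcome"].astype(str)

    sub = pd.Series("", index=ev.index, dtype=object)
    pc = outcome == "primary_care"
    if pc.any():
        sub[pc] = (
            ev.loc[pc, "consultation_type"].astype(str)
            + "|"
            + ev.loc[pc, "staff"].astype(str)
        )
    ip = outcome == "inpatient"
    if ip.any():
        sub[ip] = ev.loc[ip, "episode_type"].astype(str)
    rx = outcome == "prescription"
    if rx.any():
        sub[rx] = ev.loc[rx, "drug_code"].astype(str)

    keys = pd.Series(list(zip(year, outcome, sub)), index=ev.index)
    nominal = keys.map(unit)

    # prescription fallback: the year's average when no drug tariff exists
    rx_missing = rx & nominal.isna()
    if rx_missing.any():
        avg_keys = pd.Series(
            [(y, "prescription", "") for y in year[rx_missing]],
            index=ev.index[rx_missing],
        )
        nominal.loc[rx_missing] = avg_keys.map(unit)

    if nominal.isna().any():
        bad = keys[nominal.isna()].iloc[0]
        raise CostingError(f"missing tariff for {bad}")

    if ip.any():
        los = (
            pd.to_numeric(ev.get("length_of_stay"), errors="coerce")
            .fillna(0.0)
            .astype(float)
            if "length_of_stay" in ev.columns
            else pd.Series(0.0, index=ev.index)
        )
        staylike = ip & sub.isin(["elective", "non-elective"])
        if staylike.any():
            bed_day = keys[staylike].map(lambda k: bed.get(k, 0.0))
            if admission_form == "additive":
                nominal.loc[staylike] = nominal[staylike] + bed_day * los[staylike]
            elif admission_form == "bed_day_only":
                nominal.loc[staylike] = bed_day * np.maximum(los[staylike], 1.0)
            else:
                raise ValueError(f"unknown admission_form: {admission_form!r}")

    missing_years = set(year.unique()) - set(idx)
    if missing_years:
        raise CostingError(f"CPI table lacks years {sorted(missing_years)}")
    factor = year.map(lambda y: idx[base_year] / idx[y])
    return pd.Series(
        nominal.astype(float) * factor.astype(float), index=ev.index, name="cost"
    )


_SEGMENT_CARRY = [
    "child_id",
    "mother_id",
    "age_band",
    "person_years",
    "period",
    "imd_quintile",
]


def cost_rates(
    events: pd.DataFrame,
    segments: pd.DataFrame,
    tariffs: pd.DataFrame,
    cpi: pd.DataFrame,
    *,
    base_year: int = BASE_YEAR,
    admission_form: str = "additive",
) -> pd.DataFrame:
    """Per-segment summed base-year cost and cost per person-year.

    Events are deduplicated with the same once-per-day rule as counting
    before costing.  Returns one row per segment with ``cost`` and
    ``cost_rate`` (pounds per child per year), zeros where a segment has
    no events, carrying exposure flags and covariates.
    """
    seg = segments.reset_index(drop=True)
    carry = _SEGMENT_CARRY + [c for c in seg.columns if c.startswith("exposed_")]
    out = seg[carry].copy()
    out["cost"] = 0.0

    if len(events):
        deduped = deduplicate(events)
        located = assign_to_segments(deduped, seg)
        if len(located):
            located["cost"] = cost_events(
                located, tariffs, cpi, base_year=base_year, admission_form=admission_form
            )
            sums = located.groupby("_seg")["cost"].sum()
            out.loc[sums.index, "cost"] = sums.to_numpy()

    out["cost_rate"] = out["cost"] / out["person_years"]
    return out
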