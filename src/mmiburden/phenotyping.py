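"""Maternal mental illness (MMI) case classification from coded events.

A mother's primary-care record contributes dated, coded events; a code
list maps each code to one of eight illness groups and an event class
(diagnosis, symptom or prescription).  A mother is a case of an illness
through any of three pathways:

(a) *diagnosis* — any diagnosis event qualifies on its own date;
(b) *rx_near_symptom* — a prescription within 91 days (<= 3 months,
    inclusive, either direction by default) of a symptom of the same
    illness qualifies on the later date of the pair;
(c) *event_with_history* — a prescription or symptom with any strictly
    earlier diagnosis of the same illness qualifies on its own date.

Illness groups roll up into exposure categories: common mental illness
(depression, anxiety), serious mental illness (non-affective or
affective psychosis) and addiction (substance or alcohol misuse).
Eating and personality disorders are represented only under ``any``.
Categories are not mutually exclusive: a child may be exposed under
several at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

ILLNESSES: frozenset[str] = frozenset(
    {
        "non-affective psychosis",
        "affective psychosis",
        "depression",
        "anxiety",
        "eating disorder",
        "personality disorder",
        "substance misuse",
        "alcohol misuse",
    }
)

EVENT_CLASSES: frozenset[str] = frozenset({"diagnosis", "symptom", "prescription"})

PATHWAYS: tuple[str, ...] = ("diagnosis", "rx_near_symptom", "event_with_history")


@dataclass(frozen=True)
class ExposureCategory:
    """A named rollup of illness groups used to define child exposure."""

    label: str
    member_illnesses: frozenset[str]


EXPOSURE_CATEGORIES: dict[str, ExposureCategory] = {
    "any": ExposureCategory("any", ILLNESSES),
    "CMI": ExposureCategory("CMI", frozenset({"depression", "anxiety"})),
    "SMI": ExposureCategory(
        "SMI", frozenset({"non-affective psychosis", "affective psychosis"})
    ),
    "addiction": ExposureCategory(
        "addiction", frozenset({"substance misuse", "alcohol misuse"})
    ),
}


class CodeListError(ValueError):
    """Raised for an empty or malformed code list."""


def validate_codelist(codelist: pd.DataFrame) -> pd.DataFrame:
    """Check a code list (columns code, illness, event_class) and return it.

    (code, event_class) pairs must be unique and every illness token must
    come from the closed eight-illness set.
    """
    required = {"code", "illness", "event_class"}
    missing = required - set(codelist.columns)
    if missing:
        raise CodeListError(f"code list missing columns: {sorted(missing)}")
    if len(codelist) == 0:
        raise CodeListError("code list is empty")
    bad_illness = set(codelist["illness"]) - ILLNESSES
    if bad_illness:
        raise CodeListError(f"unknown illness tokens: {sorted(bad_illness)}")
    bad_class = set(codelist["event_class"]) - EVENT_CLASSES
    if bad_class:
        raise CodeListError(f"unknown event classes: {sorted(bad_class)}")
    dup = codelist.duplicated(subset=["code", "event_class"])
    if dup.any():
        raise CodeListError(
            f"duplicate (code, event_class) pairs: "
            f"{codelist.loc[dup, 'code'].unique()[:5].tolist()}"
        )
    return codelist


# Tie-break when several pathways qualify a (mother, illness, date):
# the more direct evidence wins.
_PATHWAY_RANK = {"diagnosis": 0, "rx_near_symptom": 1, "event_with_history": 2}


def classify_cases(
    events: pd.DataFrame,
    codelist: pd.DataFrame,
    *,
    rx_symptom_window_days: int = 91,
    symmetric_window: bool = True,
    rx_date_qualifies: bool = False,
) -> pd.DataFrame:
    """Classify mothers as MMI cases per illness.

    Parameters
    ----------
    events
        Columns ``patient_id``, ``date``, ``code``.  Codes absent from
        the code list are ignored (counted in ``result.attrs``).
    codelist
        Columns ``code``, ``illness``, ``event_class``.
    rx_symptom_window_days
        Width of the prescription-near-symptom window, inclusive.
    symmetric_window
        If True the prescription may precede or follow the symptom;
        if False only symptom-then-prescription pairs qualify.
    rx_date_qualifies
        If True pathway (b) qualifies on the prescription date rather
        than the later date of the pair.

    Returns
    -------
    DataFrame with columns ``mother_id``, ``illness``, ``case_date``,
    ``pathway``, one row per (mother, illness, qualifying date), sorted.
    ``result.attrs["n_unknown_codes"]`` counts ignored events.
    """
    validate_codelist(codelist)
    ev = events.copy()
    ev["date"] = pd.to_datetime(ev["date"])
    merged = ev.merge(codelist, on="code", how="left")
    unknown = merged["illness"].isna()
    n_unknown = int(unknown.sum())
    if n_unknown:
        logger.warning("ignoring %d events with codes outside the code list", n_unknown)
    merged = merged[~unknown]

    out_cols = ["mother_id", "illness", "case_date", "pathway"]
    if merged.empty:
        out = pd.DataFrame(columns=out_cols)
        out.attrs["n_unknown_codes"] = n_unknown
        return out

    diag = merged[merged["event_class"] == "diagnosis"]
    symp = merged[merged["event_class"] == "symptom"]
    rx = merged[merged["event_class"] == "prescription"]

    parts: list[pd.DataFrame] = []

    # (a) any diagnosis qualifies on its date
    if len(diag):
        a = diag[["patient_id", "illness", "date"]].copy()
        a["pathway"] = "diagnosis"
        parts.append(a)

    # (b) prescription within the window of a same-illness symptom
    if len(rx) and len(symp):
        pairs = rx[["patient_id", "illness", "date"]].merge(
            symp[["patient_id", "illness", "date"]],
            on=["patient_id", "illness"],
            suffixes=("_rx", "_sym"),
        )
        delta = (pairs["date_rx"] - pairs["date_sym"]).dt.days
        if symmetric_window:
            ok = delta.abs() <= rx_symptom_window_days
        else:
            ok = (delta >= 0) & (delta <= rx_symptom_window_days)
        pairs = pairs[ok]
        if len(pairs):
            b = pairs[["patient_id", "illness"]].copy()
            if rx_date_qualifies:
                b["date"] = pairs["date_rx"]
            else:
                b["date"] = pairs[["date_rx", "date_sym"]].max(axis=1)
            b["pathway"] = "rx_near_symptom"
            parts.append(b)

    # (c) prescription/symptom with any strictly earlier diagnosis
    if len(diag) and (len(rx) or len(symp)):
        first_diag = (
            diag.groupby(["patient_id", "illness"], as_index=False)["date"]
            .min()
            .rename(columns={"date": "first_diag"})
        )
        trig = pd.concat([rx, symp], ignore_index=True)
        trig = trig.merge(first_diag, on=["patient_id", "illness"], how="inner")
        trig = trig[trig["date"] > trig["first_diag"]]
        if len(trig):
            c = trig[["patient_id", "illness", "date"]].copy()
            c["pathway"] = "event_with_history"
            parts.append(c)

    if not parts:
        out = pd.DataFrame(columns=out_cols)
        out.attrs["n_unknown_codes"] = n_unknown
        return out

    det = pd.concat(parts, ignore_index=True)
    det = det.rename(columns={"patient_id": "mother_id", "date": "case_date"})
    det["_rank"] = det["pathway"].map(_PATHWAY_RANK)
    det = (
        det.sort_values(["mother_id", "illness", "case_date", "_rank"])
        .drop_duplicates(subset=["mother_id", "illness", "case_date"], keep="first")
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    det = det[out_cols]
    det.attrs["n_unknown_codes"] = n_unknown
    return det


def exposure_in_window(
    determinations: pd.DataFrame,
    category: ExposureCategory | str,
    window: tuple[pd.Timestamp, pd.Timestamp],
) -> bool:
    """True iff any member-illness determination falls inside the closed window."""
    if isinstance(category, str):
        category = EXPOSURE_CATEGORIES[category]
    start, end = (pd.Timestamp(window[0]), pd.Timestamp(window[1]))
    if end < start:
        raise ValueError("empty exposure window")
    if determinations.empty:
        return False
    dates = pd.to_datetime(determinations["case_date"])
    member = determinations["illness"].isin(category.member_illnesses)
    return bool((member & (dates >= start) & (dates <= end)).any())
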