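"""Independent brute-force oracles the implementation is checked against.

Each oracle is deliberately naive — O(n^2) pair scans, explicit
candidate enumeration, direct log-likelihood evaluation — and shares no
code with the package internals it verifies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

PATHWAY_RANK = {"diagnosis": 0, "rx_near_symptom": 1, "event_with_history": 2}


def brute_force_classify(
    events: pd.DataFrame,
    codelist: pd.DataFrame,
    window_days: int = 91,
    symmetric: bool = True,
) -> pd.DataFrame:
    """All-pairs scan over one record set applying the three case rules."""
    lookup = {
        (r.code): (r.illness, r.event_class) for r in codelist.itertuples()
    }
    by_patient: dict = {}
    for pid, date, code in zip(events["patient_id"], events["date"], events["code"]):
        if code not in lookup:
            continue
        ill, klass = lookup[code]
        by_patient.setdefault(pid, []).append((pd.Timestamp(date), ill, klass))

    found = {}

    def note(key, pathway):
        found[key] = min(
            found.get(key, "zzz"), pathway, key=lambda p: PATHWAY_RANK.get(p, 9)
        )

    for pid, rows in by_patient.items():
        for date_a, ill_a, klass_a in rows:
            if klass_a == "diagnosis":
                note((pid, ill_a, date_a), "diagnosis")
        for date_a, ill_a, klass_a in rows:
            if klass_a != "prescription":
                continue
            for date_b, ill_b, klass_b in rows:
                if klass_b != "symptom" or ill_b != ill_a:
                    continue
                delta = (date_a - date_b).days
                ok = abs(delta) <= window_days if symmetric else 0 <= delta <= window_days
                if ok:
                    note((pid, ill_a, max(date_a, date_b)), "rx_near_symptom")
        for date_a, ill_a, klass_a in rows:
            if klass_a not in ("prescription", "symptom"):
                continue
            for date_b, ill_b, klass_b in rows:
                if klass_b == "diagnosis" and ill_b == ill_a and date_b < date_a:
                    note((pid, ill_a, date_a), "event_with_history")
    out = pd.DataFrame(
        [
            {"mother_id": m, "illness": ill, "case_date": d, "pathway": p}
            for (m, ill, d), p in found.items()
        ],
        columns=["mother_id", "illness", "case_date", "pathway"],
    )
    return out.sort_values(["mother_id", "illness", "case_date"]).reset_index(drop=True)


def brute_force_follow_up(child: dict, study_start, study_end):
    """Enumerate the four start and six end candidates explicitly."""
    starts = [
        child["birth_date"],
        child["practice_uts_date"],
        child["registration_start"],
        pd.Timestamp(study_start),
    ]
    birth = pd.Timestamp(child["birth_date"])
    eighteenth = birth + pd.DateOffset(years=18)
    ends = [
        child["registration_end"],
        eighteenth,
        child.get("death_date"),
        child.get("mother_death_date"),
        child["practice_collection_end"],
        pd.Timestamp(study_end),
    ]
    s = max(pd.Timestamp(x) for x in starts if pd.notna(x))
    e = min(pd.Timestamp(x) for x in ends if pd.notna(x))
    if e <= s:
        return None
    return s, e


def brute_force_counts(events: pd.DataFrame, segments: pd.DataFrame) -> dict:
    """Group-by-hand count of deduplicated events per (segment, outcome)."""
    seen = set()
    counts: dict = {}
    for _, ev in events.iterrows():
        date = pd.Timestamp(ev["date"])
        outcome = ev["outcome"]
        if outcome == "primary_care":
            sub = (ev["consultation_type"], ev["staff"])
        elif outcome == "prescription":
            sub = (ev["drug_code"],)
        else:
            sub = ()
        key = (ev["child_id"], date, outcome, sub)
        if key in seen:
            continue
        for si, seg in segments.iterrows():
            if (
                seg["child_id"] == ev["child_id"]
                and pd.Timestamp(seg["start_date"]) <= date < pd.Timestamp(seg["end_date"])
            ):
                seen.add(key)
                counts[(si, outcome)] = counts.get((si, outcome), 0) + 1
                break
    return counts


def nb2_loglike(y, mu, alpha):
    """NB2 log-likelihood written directly from the density."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    inv = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + inv)
            - gammaln(inv)
            - gammaln(y + 1)
            + inv * np.log(inv / (inv + mu))
            + y * np.log(mu / (inv + mu))
        )
    )
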