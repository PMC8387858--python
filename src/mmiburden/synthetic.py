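"""Synthetic mother-child linked records with the structure the analysis assumes.

No deposited CPRD/HES extract exists (both are access-restricted), so
this module generates cohorts with the statistical features the
downstream estimators rely on: mother-level gamma frailty shared by all
siblings (sibship clustering, making cluster-robust variance
necessary), a secondary per-child frailty, gamma-Poisson (negative
binomial) event counts per person-time segment and outcome,
multiplicative exposure effects switched on by the same 2-year exposure
window the cohort module applies, log-linear calendar-period effects,
same-day duplicate events (to exercise deduplication), registration
churn, and raw coded clinical events planted so that the phenotyping
module classifies exactly the intended mothers as cases through one of
the three case pathways.

Two entry points:

* :func:`simulate` builds the full dataset (tables shaped like the
  CPRD GOLD / HES extracts, plus code-list, tariff, CPI and population
  fixtures) by running the real phenotyping and cohort modules on its
  own planted events — the exposure-window logic downstream is never
  bypassed.
* :func:`simulate_counts` is the generator's vectorised count layer
  alone (segments, exposure flags and gamma-Poisson counts, no event
  realisation), used for Monte-Carlo calibration studies where
  thousands of replicates are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from mmiburden.bands import AGE_BANDS, BAND_BOUNDARY_AGES, DAYS_PER_YEAR, LOOKBACK_DAYS
from mmiburden.cohort import assign_exposure, build_segments
from mmiburden.counting import OUTCOMES, TOTAL
from mmiburden.phenotyping import ILLNESSES, classify_cases


class ConfigError(ValueError):
    """Raised when a simulation configuration is invalid."""


#: Unexposed event rates per child-year by outcome, before the band
#: multiplier: overall figures a UK child cohort of this period shows.
DEFAULT_BASE_RATES: dict[str, float] = {
    "primary_care": 4.27,
    "prescription": 3.90,
    "referral": 0.30,
    "outpatient": 0.76,
    "inpatient": 0.14,
    "emergency": 0.35,
}

#: Age profile of healthcare use (infancy is by far the heaviest).
DEFAULT_BAND_MULTIPLIERS: dict[str, float] = {
    "<1": 2.6,
    "1-4": 1.3,
    "5-9": 0.75,
    "10-13": 0.65,
    "14-17": 0.75,
}

#: Exposed/unexposed rate ratios by outcome (constant across bands).
DEFAULT_RATE_RATIOS: dict[str, float] = {
    "primary_care": 1.24,
    "prescription": 1.28,
    "referral": 1.30,
    "outpatient": 1.30,
    "inpatient": 1.37,
    "emergency": 1.34,
}

#: Maternal prevalence per illness group; jointly these give roughly a
#: quarter of mothers with any mental illness.
DEFAULT_PREVALENCE: dict[str, float] = {
    "depression": 0.15,
    "anxiety": 0.08,
    "non-affective psychosis": 0.005,
    "affective psychosis": 0.005,
    "substance misuse": 0.02,
    "alcohol misuse": 0.015,
    "eating disorder": 0.01,
    "personality disorder": 0.01,
}

DRUG_CATEGORIES = (
    "infection",
    "respiratory",
    "mental_behavioural",
    "gastrointestinal",
    "musculoskeletal",
    "dermatological",
    "other",
)

#: 2016-style national child counts and MMI prevalence per band.
DEFAULT_POPULATION = pd.DataFrame(
    {
        "age_band": list(AGE_BANDS),
        "n_children": [663_000, 2_705_000, 3_400_000, 2_530_000, 2_400_000],
        "mmi_prevalence": [0.23, 0.23, 0.23, 0.23, 0.23],
    }
)


def _expand_by_band(table: Mapping, default: Mapping | None = None) -> dict:
    """Normalise {outcome: x} or {outcome: {band: x}} to {(outcome, band): x}."""
    out = {}
    for outcome, val in table.items():
        if isinstance(val, Mapping):
            for band, v in val.items():
                out[(outcome, band)] = float(v)
        else:
            for band in AGE_BANDS:
                out[(outcome, band)] = float(val)
    return out


@dataclass
class SimulationConfig:
    """Generative conditions for a synthetic cohort.

    Rates are events per child-year; the exposure rate ratios multiply
    the mean for exposed person-time.  ``overdispersion`` is the
    variance of the mother-level gamma frailty (mean 1) shared by all
    of a mother's children; ``child_overdispersion`` the variance of
    the secondary per-child frailty multiplying it.  The period effect
    is per calendar year on the log scale, centred on 2012.
    """

    n_mothers: int = 20_000
    mean_children_per_mother: float = 1.8
    study_start: str = "2007-04-01"
    study_end: str = "2017-07-31"
    birth_window: tuple[str, str] = ("1993-01-01", "2017-06-30")
    mmi_prevalence_by_category: dict = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    exposure_rate_ratio_by_outcome_and_band: dict = field(
        default_factory=lambda: dict(DEFAULT_RATE_RATIOS)
    )
    baseline_rate_by_outcome_and_band: dict = field(
        default_factory=lambda: {
            o: {b: DEFAULT_BASE_RATES[o] * DEFAULT_BAND_MULTIPLIERS[b] for b in AGE_BANDS}
            for o in OUTCOMES
        }
    )
    overdispersion: float = 0.5
    child_overdispersion: float = 0.2
    period_effect_per_year: float = 0.02
    duplicate_event_prob: float = 0.10
    dropout_hazard: float = 0.05
    hes_linkage_prob: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_mothers <= 0:
            raise ConfigError("n_mothers must be positive")
        if self.mean_children_per_mother < 1:
            raise ConfigError("mean_children_per_mother must be >= 1")
        if pd.Timestamp(self.study_end) <= pd.Timestamp(self.study_start):
            raise ConfigError("study window is empty")
        for name, p in list(self.mmi_prevalence_by_category.items()):
            if not 0 <= p <= 1:
                raise ConfigError(f"prevalence for {name!r} outside [0, 1]")
            if name not in ILLNESSES:
                raise ConfigError(f"unknown illness in prevalence map: {name!r}")
        for key, v in _expand_by_band(self.exposure_rate_ratio_by_outcome_and_band).items():
            if v <= 0:
                raise ConfigError(f"rate ratio for {key} must be > 0")
        for key, v in _expand_by_band(self.baseline_rate_by_outcome_and_band).items():
            if v <= 0:
                raise ConfigError(f"baseline rate for {key} must be > 0")
        for name in ("overdispersion", "child_overdispersion"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("duplicate_event_prob", "hes_linkage_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} outside [0, 1]")
        if self.dropout_hazard < 0:
            raise ConfigError("dropout_hazard must be >= 0")

    def rate_ratio(self, outcome: str, band: str) -> float:
        return _expand_by_band(self.exposure_rate_ratio_by_outcome_and_band)[
            (outcome, band)
        ]

    def baseline_rate(self, outcome: str, band: str) -> float:
        return _expand_by_band(self.baseline_rate_by_outcome_and_band)[(outcome, band)]

    @property
    def p_any_mmi(self) -> float:
        """Probability a mother has at least one illness (independent draws)."""
        p = 1.0
        for q in self.mmi_prevalence_by_category.values():
            p *= 1 - q
        return 1 - p


@dataclass
class SyntheticDataset:
    """A full synthetic extract plus the generative truth behind it."""

    children: pd.DataFrame
    mothers: pd.DataFrame
    clinical_events: pd.DataFrame
    use_events: pd.DataFrame
    codelist: pd.DataFrame
    tariffs: pd.DataFrame
    cpi: pd.DataFrame
    population: pd.DataFrame
    segments: pd.DataFrame
    determinations: pd.DataFrame
    counts: pd.DataFrame
    truth: dict


def _gamma_frailty(rng: np.random.Generator, n: int, variance: float) -> np.ndarray:
    if variance <= 0:
        return np.ones(n)
    shape = 1.0 / variance
    return rng.gamma(shape, variance, size=n)


def _make_codelist() -> pd.DataFrame:
    rows = []
    for ill in sorted(ILLNESSES):
        tag = ill.replace(" ", "_").replace("-", "_")
        for klass, prefix in (
            ("diagnosis", "D"),
            ("symptom", "S"),
            ("prescription", "R"),
        ):
            for k in (1, 2):
                rows.append(
                    {
                        "code": f"{prefix}_{tag}_{k}",
                        "illness": ill,
                        "event_class": klass,
                    }
                )
    return pd.DataFrame(rows)


def _make_cpi() -> pd.DataFrame:
    years = np.arange(2005, 2019)
    return pd.DataFrame(
        {"year": years, "index": np.round(100.0 * 1.025 ** (years - 2017), 4)}
    )


def _make_tariffs(rng: np.random.Generator, n_drugs: int = 30) -> pd.DataFrame:
    """Annual tariff rows for 2005-2018 covering every costable subtype.

    Roughly 30% of drug codes carry no drug-specific tariff, so the
    annual-average fallback is exercised at about the rate seen in
    national prescription cost data.
    """
    years = np.arange(2005, 2019)
    pc_base = {
        ("face-to-face", "doctor"): 37.0,
        ("face-to-face", "nurse"): 12.0,
        ("face-to-face", "health-visitor"): 15.0,
        ("face-to-face", "other"): 20.0,
        ("telephone", "doctor"): 22.0,
        ("telephone", "nurse"): 7.0,
        ("telephone", "health-visitor"): 9.0,
        ("telephone", "other"): 12.0,
        ("home-visit", "doctor"): 92.0,
        ("home-visit", "nurse"): 30.0,
        ("home-visit", "health-visitor"): 38.0,
        ("home-visit", "other"): 50.0,
    }
    drug_costs = np.round(np.exp(rng.normal(2.0, 0.8, size=n_drugs)), 2)
    priced = rng.random(n_drugs) > 0.295  # ~29.5% fall back to the average
    rows = []
    for y in years:
        infl = 1.02 ** (y - 2017)
        for (ct, st), c in pc_base.items():
            rows.append((y, "primary_care", f"{ct}|{st}", round(c * infl, 2), np.nan))
        rows.append((y, "referral", "", round(3.0 * infl, 2), np.nan))
        rows.append((y, "outpatient", "", round(120.0 * infl, 2), np.nan))
        rows.append((y, "emergency", "", round(138.0 * infl, 2), np.nan))
        rows.append((y, "prescription", "", round(8.32 * infl, 2), np.nan))
        for d in range(n_drugs):
            if priced[d]:
                rows.append(
                    (y, "prescription", f"d{d:02d}", round(drug_costs[d] * infl, 2), np.nan)
                )
        rows.append((y, "inpatient", "day-case", round(698.0 * infl, 2), np.nan))
        rows.append((y, "inpatient", "regular-day-night", round(420.0 * infl, 2), np.nan))
        rows.append(
            (y, "inpatient", "elective", round(3180.0 * infl, 2), round(290.0 * infl, 2))
        )
        rows.append(
            (y, "inpatient", "non-elective", round(1520.0 * infl, 2), round(346.0 * infl, 2))
        )
    return pd.DataFrame(
        rows, columns=["year", "outcome", "subtype", "unit_cost", "per_bed_day_cost"]
    )


def _plant_clinical_events(
    rng: np.random.Generator,
    mothers: pd.DataFrame,
    config: SimulationConfig,
    codelist: pd.DataFrame,
    ref_birth: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw coded events so the phenotyper flags exactly the intended mothers.

    For each (mother, illness) case one of the three pathways is chosen
    at random and its minimal event pattern is written inside the
    mother's registration interval.  Onsets cluster around childbearing
    (``ref_birth``, the mother's first recorded delivery): 70% of cases
    start within a normal(0, 1 year) spread of that date — maternal
    mental illness is concentrated perinatally — and the rest are
    uniform over the observable span.  Non-case mothers may receive one
    lone symptom or prescription (never enough to qualify) and a little
    unknown-code noise, so tolerance paths are exercised.

    Returns (clinical events, planted truth per mother x illness).
    """
    study_start = pd.Timestamp(config.study_start)
    study_end = pd.Timestamp(config.study_end)
    onset_lo = study_start - pd.Timedelta(days=3 * 365)

    code_of = {
        (r.illness, r.event_class): r.code
        for r in codelist.drop_duplicates(["illness", "event_class"]).itertuples()
    }

    events = []
    truth_rows = []
    reg_start = pd.to_datetime(mothers["registration_start"])
    reg_end = pd.to_datetime(mothers["registration_end"])
    m_ids = mothers["mother_id"].to_numpy()

    illnesses = sorted(config.mmi_prevalence_by_category)
    prev = np.array([config.mmi_prevalence_by_category[i] for i in illnesses])
    is_case = rng.random((len(mothers), len(illnesses))) < prev[None, :]

    for j, ill in enumerate(illnesses):
        case_idx = np.flatnonzero(is_case[:, j])
        for i in case_idx:
            lo = max(onset_lo, reg_start.iloc[i] + pd.Timedelta(days=1100))
            hi = min(study_end, reg_end.iloc[i] - pd.Timedelta(days=1))
            span = (hi - lo).days
            if span <= 0:
                continue  # registration too short to host a case
            ref = ref_birth.iloc[i] if ref_birth is not None else pd.NaT
            onset = pd.NaT
            if pd.notna(ref) and rng.random() < 0.7:
                cand = ref + pd.Timedelta(days=int(rng.normal(0.0, 365.0)))
                if lo <= cand <= hi:
                    onset = cand
            if pd.isna(onset):
                onset = lo + pd.Timedelta(days=int(rng.integers(0, span + 1)))
            pathway = ("diagnosis", "rx_near_symptom", "event_with_history")[
                rng.integers(0, 3)
            ]
            mid = m_ids[i]
            if pathway == "diagnosis":
                events.append((mid, onset, code_of[(ill, "diagnosis")]))
                case_date = onset
            elif pathway == "rx_near_symptom":
                gap = int(rng.integers(0, 92))
                rx_date = min(onset + pd.Timedelta(days=gap), reg_end.iloc[i])
                events.append((mid, onset, code_of[(ill, "symptom")]))
                events.append((mid, rx_date, code_of[(ill, "prescription")]))
                case_date = max(onset, rx_date)
            else:
                back = int(rng.integers(180, 1096))
                hist = max(onset - pd.Timedelta(days=back), reg_start.iloc[i])
                events.append((mid, hist, code_of[(ill, "diagnosis")]))
                events.append((mid, onset, code_of[(ill, "prescription")]))
                case_date = hist  # the historical diagnosis itself qualifies first
            truth_rows.append(
                {
                    "mother_id": mid,
                    "illness": ill,
                    "pathway": pathway,
                    "onset": onset,
                    "first_case_date": case_date,
                }
            )

    # lone-event noise on mothers with no case at all: never qualifies
    never_case = np.flatnonzero(~is_case.any(axis=1))
    n_noise = int(0.15 * len(never_case))
    if n_noise:
        pick = rng.choice(never_case, size=n_noise, replace=False)
        for i in pick:
            ill = illnesses[rng.integers(0, len(illnesses))]
            klass = ("symptom", "prescription")[rng.integers(0, 2)]
            span = (min(study_end, reg_end.iloc[i]) - reg_start.iloc[i]).days
            if span <= 0:
                continue
            d = reg_start.iloc[i] + pd.Timedelta(days=int(rng.integers(0, span)))
            events.append((m_ids[i], d, code_of[(ill, klass)]))

    # unknown-code noise: must be ignored (and counted) by the phenotyper
    n_unk = max(1, int(0.02 * len(mothers)))
    for i in rng.choice(len(mothers), size=n_unk, replace=False):
        span = (min(study_end, reg_end.iloc[i]) - reg_start.iloc[i]).days
        if span <= 0:
            continue
        d = reg_start.iloc[i] + pd.Timedelta(days=int(rng.integers(0, span)))
        events.append((m_ids[i], d, f"UNK_{int(rng.integers(0, 5))}"))

    ev = pd.DataFrame(events, columns=["patient_id", "date", "code"])
    ev = ev.sort_values(["patient_id", "date", "code"], kind="mergesort").reset_index(
        drop=True
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["mother_id", "illness", "pathway", "onset", "first_case_date"],
    )
    return ev, truth


def _simulate_people(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mother and child tables with registration churn and planted exclusions."""
    study_start = pd.Timestamp(config.study_start)
    study_end = pd.Timestamp(config.study_end)
    n_m = config.n_mothers

    m_ids = np.array([f"M{i:07d}" for i in range(n_m)])
    m_reg_start = study_start - pd.to_timedelta(
        rng.integers(2 * 365, 14 * 365, size=n_m), unit="D"
    )
    late = rng.random(n_m) < 0.04  # registered only after the study began
    m_reg_start = pd.Series(m_reg_start)
    m_reg_start[late] = study_start + pd.to_timedelta(
        rng.integers(0, 5 * 365, size=int(late.sum())), unit="D"
    )
    m_reg_end = pd.Series(study_end + pd.Timedelta(days=365), index=range(n_m))
    early = rng.random(n_m) < 0.06
    m_reg_end[early] = m_reg_start[early] + pd.to_timedelta(
        rng.integers(365, 8 * 365, size=int(early.sum())), unit="D"
    )
    m_uts = m_reg_start.copy()
    uts_late = rng.random(n_m) < 0.03  # practice became research-standard late
    m_uts[uts_late] = study_start + pd.to_timedelta(
        rng.integers(0, 3 * 365, size=int(uts_late.sum())), unit="D"
    )
    m_death = pd.Series(pd.NaT, index=range(n_m), dtype="datetime64[ns]")
    dead = rng.random(n_m) < 0.004
    m_death[dead] = study_start + pd.to_timedelta(
        rng.integers(0, (study_end - study_start).days, size=int(dead.sum())), unit="D"
    )
    mothers = pd.DataFrame(
        {
            "mother_id": m_ids,
            "registration_start": m_reg_start,
            "registration_end": m_reg_end,
            "death_date": m_death,
            "practice_uts_date": m_uts,
        }
    )

    n_kids = 1 + rng.poisson(config.mean_children_per_mother - 1, size=n_m)
    n_c = int(n_kids.sum())
    kid_mother = np.repeat(np.arange(n_m), n_kids)
    birth_lo = max(pd.Timestamp(config.birth_window[0]), study_start - pd.Timedelta(days=16 * 365))
    birth_hi = min(pd.Timestamp(config.birth_window[1]), study_end - pd.Timedelta(days=60))
    # sibships are temporally coherent: first birth uniform in the window,
    # each later sibling 1-4 years after the previous one
    first_birth = rng.integers(0, (birth_hi - birth_lo).days + 1, size=n_m)
    gaps = rng.integers(365, 1461, size=n_c)
    cg = np.cumsum(gaps)
    starts = np.concatenate([[0], np.cumsum(n_kids)[:-1]])
    offsets = cg - np.repeat(cg[starts], n_kids)  # 0 for each first child
    birth_days = np.minimum(
        first_birth[kid_mother] + offsets, (birth_hi - birth_lo).days
    )
    birth = pd.Series(birth_lo + pd.to_timedelta(birth_days, unit="D"))

    c_reg_start = birth + pd.to_timedelta(rng.integers(0, 30, size=n_c), unit="D")
    late_reg = rng.random(n_c) < 0.05
    c_reg_start[late_reg] = birth[late_reg] + pd.to_timedelta(
        rng.integers(365, 3 * 365, size=int(late_reg.sum())), unit="D"
    )
    if config.dropout_hazard > 0:
        stay_years = rng.exponential(1.0 / config.dropout_hazard, size=n_c)
    else:
        stay_years = np.full(n_c, 30.0)
    c_reg_end = c_reg_start + pd.to_timedelta(
        np.minimum(stay_years * DAYS_PER_YEAR, 25 * 365).astype(int), unit="D"
    )
    cap = study_end + pd.Timedelta(days=365)
    c_reg_end = c_reg_end.clip(upper=cap)

    c_death = pd.Series(pd.NaT, index=range(n_c), dtype="datetime64[ns]")
    dead_c = rng.random(n_c) < 0.003
    c_death[dead_c] = birth[dead_c] + pd.to_timedelta(
        rng.integers(1, 10 * 365, size=int(dead_c.sum())), unit="D"
    )

    coll_end = pd.Series(study_end + pd.Timedelta(days=365), index=range(n_c))
    early_coll = rng.random(n_c) < 0.03
    coll_end[early_coll] = study_start + pd.to_timedelta(
        rng.integers(365, 9 * 365, size=int(early_coll.sum())), unit="D"
    )

    children = pd.DataFrame(
        {
            "child_id": [f"C{i:07d}" for i in range(n_c)],
            "mother_id": m_ids[kid_mother],
            "birth_date": birth,
            "death_date": c_death,
            "sex": rng.choice(["F", "M"], size=n_c),
            "imd_quintile": rng.integers(1, 6, size=n_c),
            "registration_start": c_reg_start,
            "registration_end": c_reg_end,
            "practice_uts_date": m_uts.iloc[kid_mother].to_numpy(),
            "practice_collection_end": coll_end,
            "hes_linked": rng.random(n_c) < config.hes_linkage_prob,
        }
    )
    return children, mothers


def _draw_counts(
    rng: np.random.Generator,
    config: SimulationConfig,
    segments: pd.DataFrame,
    mothers: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Gamma-Poisson counts per segment x outcome, with shared frailties."""
    u = _gamma_frailty(rng, len(mothers), config.overdispersion)
    u_of = pd.Series(u, index=mothers["mother_id"])
    kids = segments["child_id"].unique()
    w = _gamma_frailty(rng, len(kids), config.child_overdispersion)
    w_of = pd.Series(w, index=kids)

    seg = segments.reset_index(drop=True)
    u_seg = seg["mother_id"].map(u_of).to_numpy()
    w_seg = seg["child_id"].map(w_of).to_numpy()
    py = seg["person_years"].to_numpy(dtype=float)
    exposed = seg["exposed_any"].astype(bool).to_numpy()
    period = seg["period"].to_numpy(dtype=float)
    period_mult = np.exp(config.period_effect_per_year * (period - 2012.0))

    parts = []
    true_rates = {}
    for outcome in OUTCOMES:
        base = seg["age_band"].map(
            {b: config.baseline_rate(outcome, b) for b in AGE_BANDS}
        ).to_numpy(dtype=float)
        rr = seg["age_band"].map(
            {b: config.rate_ratio(outcome, b) for b in AGE_BANDS}
        ).to_numpy(dtype=float)
        mu = base * np.where(exposed, rr, 1.0) * period_mult * py * u_seg * w_seg
        counts = rng.poisson(mu)
        frame = seg[
            ["child_id", "mother_id", "age_band", "person_years", "period",
             "imd_quintile"]
            + [c for c in seg.columns if c.startswith("exposed_")]
        ].copy()
        frame["outcome"] = outcome
        frame["count"] = counts
        frame["_seg"] = np.arange(len(seg))
        parts.append(frame)
        for b in AGE_BANDS:
            true_rates[(outcome, b)] = (
                config.baseline_rate(outcome, b),
                config.rate_ratio(outcome, b),
            )

    long = pd.concat(parts, ignore_index=True)
    totals = long.groupby("_seg", as_index=False)["count"].sum()
    total_rows = parts[0].drop(columns=["outcome", "count"]).merge(totals, on="_seg")
    total_rows["outcome"] = TOTAL
    long = pd.concat([long, total_rows], ignore_index=True)
    truth = {"true_rates": true_rates, "mother_frailty_var": config.overdispersion}
    return long, truth


def _realize_events(
    rng: np.random.Generator,
    config: SimulationConfig,
    counts: pd.DataFrame,
    segments: pd.DataFrame,
    n_drugs: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dated use events matching the drawn counts, plus duplicates.

    Genuine events get distinct (child, date, outcome, subtype) keys
    wherever possible (colliding dates are re-drawn), then same-day
    duplicates are appended with probability ``duplicate_event_prob``
    each, so deduplicated pipeline counts reproduce the generator's.
    Returns (use events, expected deduplicated counts per segment x outcome).
    """
    seg = segments.reset_index(drop=True)
    nonzero = counts[(counts["outcome"] != TOTAL) & (counts["count"] > 0)]
    idx = np.repeat(nonzero.index.to_numpy(), nonzero["count"].to_numpy())
    ev = nonzero.loc[idx, ["child_id", "outcome", "_seg"]].reset_index(drop=True)

    seg_start = pd.to_datetime(seg["start_date"]).to_numpy().astype("datetime64[D]")
    seg_days = (
        pd.to_datetime(seg["end_date"]) - pd.to_datetime(seg["start_date"])
    ).dt.days.to_numpy()
    s = ev["_seg"].to_numpy()

    def draw_dates(n, which):
        offs = (rng.random(n) * seg_days[which]).astype(int)
        return seg_start[which] + offs

    ev["date"] = draw_dates(len(ev), s)

    n = len(ev)
    ev["consultation_type"] = ""
    ev["staff"] = ""
    ev["episode_type"] = ""
    ev["length_of_stay"] = np.nan
    ev["drug_code"] = ""
    ev["drug_category"] = ""

    pc = (ev["outcome"] == "primary_care").to_numpy()
    if pc.any():
        ev.loc[pc, "consultation_type"] = rng.choice(
            ["face-to-face", "telephone", "home-visit"], size=int(pc.sum()),
            p=[0.72, 0.2, 0.08],
        )
        ev.loc[pc, "staff"] = rng.choice(
            ["doctor", "nurse", "health-visitor", "other"], size=int(pc.sum()),
            p=[0.55, 0.3, 0.1, 0.05],
        )
    rx = (ev["outcome"] == "prescription").to_numpy()
    if rx.any():
        drug_p = 1.0 / (np.arange(n_drugs) + 2.0)
        drug_p /= drug_p.sum()
        drugs = rng.choice(n_drugs, size=int(rx.sum()), p=drug_p)
        ev.loc[rx, "drug_code"] = [f"d{d:02d}" for d in drugs]
        cat_of_drug = [DRUG_CATEGORIES[d % len(DRUG_CATEGORIES)] for d in range(n_drugs)]
        ev.loc[rx, "drug_category"] = [cat_of_drug[d] for d in drugs]
    ip = (ev["outcome"] == "inpatient").to_numpy()
    if ip.any():
        eps = rng.choice(
            ["day-case", "regular-day-night", "elective", "non-elective"],
            size=int(ip.sum()), p=[0.3, 0.08, 0.22, 0.4],
        )
        ev.loc[ip, "episode_type"] = eps
        los = np.zeros(int(ip.sum()))
        los[eps == "regular-day-night"] = 1
        los[eps == "elective"] = rng.poisson(1.5, size=int((eps == "elective").sum()))
        los[eps == "non-elective"] = rng.poisson(
            2.5, size=int((eps == "non-elective").sum())
        )
        ev.loc[ip, "length_of_stay"] = los

    # re-draw dates for accidental same-day same-type collisions so the
    # deduplicated counts equal the drawn counts (residuals are counted)
    sub = _subtype_strings(ev)
    for _ in range(8):
        dup = pd.DataFrame(
            {"c": ev["child_id"], "d": ev["date"], "o": ev["outcome"], "s": sub}
        ).duplicated(keep="first")
        dup &= seg_days[s] > 1  # single-day segments cannot be re-drawn
        if not dup.any():
            break
        which = dup.to_numpy()
        ev.loc[which, "date"] = draw_dates(int(which.sum()), s[which])
        sub = _subtype_strings(ev)

    key = pd.DataFrame(
        {"_seg": ev["_seg"], "c": ev["child_id"], "d": ev["date"],
         "o": ev["outcome"], "s": _subtype_strings(ev)}
    )
    expected = (
        key.drop_duplicates()
        .groupby(["_seg", "o"], as_index=False)
        .size()
        .rename(columns={"o": "outcome", "size": "expected_count"})
    )

    dup_mask = rng.random(len(ev)) < config.duplicate_event_prob
    dups = ev[dup_mask]
    out = pd.concat([ev, dups], ignore_index=True).drop(columns="_seg")
    out["date"] = pd.to_datetime(out["date"])
    out = out.sort_values(
        ["child_id", "date", "outcome", "drug_code", "consultation_type", "staff"],
        kind="mergesort",
    ).reset_index(drop=True)
    cols = ["child_id", "date", "outcome", "consultation_type", "staff",
            "episode_type", "length_of_stay", "drug_code", "drug_category"]
    return out[cols], expected


def _subtype_strings(ev: pd.DataFrame) -> pd.Series:
    sub = pd.Series("", index=ev.index, dtype=object)
    pc = ev["outcome"] == "primary_care"
    sub[pc] = ev.loc[pc, "consultation_type"].astype(str) + "|" + ev.loc[pc, "staff"].astype(str)
    rx = ev["outcome"] == "prescription"
    sub[rx] = ev.loc[rx, "drug_code"].astype(str)
    return sub


def simulate(config: SimulationConfig, realize_events: bool = True) -> SyntheticDataset:
    """Generate a full synthetic mother-child linked dataset.

    Clinical events are planted raw and pushed through the real
    phenotyping and cohort modules to obtain exposure flags; counts are
    gamma-Poisson per segment and outcome; dated use events realise the
    counts (skipped when ``realize_events`` is False, which leaves the
    count layer as ground truth for fast studies).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    codelist = _make_codelist()
    tariff_rng = np.random.default_rng(config.seed + 1)

    children, mothers = _simulate_people(rng, config)
    first_birth = (
        children.groupby("mother_id")["birth_date"].min().reindex(mothers["mother_id"])
    )
    first_birth.index = mothers.index
    clinical_events, planted = _plant_clinical_events(
        rng, mothers, config, codelist, ref_birth=first_birth
    )
    determinations = classify_cases(clinical_events, codelist)

    window = (pd.Timestamp(config.study_start), pd.Timestamp(config.study_end))
    segments, tally = build_segments(children, mothers, window)
    segments = assign_exposure(segments, determinations, mode="main")

    counts, count_truth = _draw_counts(rng, config, segments, mothers)

    if realize_events and len(segments):
        use_events, expected = _realize_events(rng, config, counts, segments)
    else:
        use_events = pd.DataFrame(
            columns=["child_id", "date", "outcome", "consultation_type", "staff",
                     "episode_type", "length_of_stay", "drug_code", "drug_category"]
        )
        expected = pd.DataFrame(columns=["_seg", "outcome", "expected_count"])

    truth = {
        "config": asdict(config),
        "planted_cases": planted,
        "case_mothers": set(planted["mother_id"]) if len(planted) else set(),
        "exclusion_tally": tally,
        "expected_dedup_counts": expected,
        **count_truth,
    }
    counts = counts.drop(columns="_seg")
    return SyntheticDataset(
        children=children,
        mothers=mothers,
        clinical_events=clinical_events,
        use_events=use_events,
        codelist=codelist,
        tariffs=_make_tariffs(tariff_rng),
        cpi=_make_cpi(),
        population=DEFAULT_POPULATION.copy(),
        segments=segments,
        determinations=determinations,
        counts=counts,
        truth=truth,
    )


def simulate_counts(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Vectorised count layer: total-use counts per segment, no events.

    Pure numpy implementation of the same generative model (gamma
    frailties, exposure window, period effect, gamma-Poisson counts)
    for Monte-Carlo studies that need thousands of replicates.  Band
    boundaries use the 365.25-day year here; calendrical boundaries are
    exercised in the full generator.  Returns count records for the
    ``total`` outcome, ready for the inference module.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    epoch = np.datetime64("1970-01-01")
    s0 = (np.datetime64(config.study_start) - epoch).astype(int)
    s1 = (np.datetime64(config.study_end) - epoch).astype(int)

    n_m = config.n_mothers
    n_kids = 1 + rng.poisson(config.mean_children_per_mother - 1, size=n_m)
    n_c = int(n_kids.sum())
    mother_of = np.repeat(np.arange(n_m), n_kids)

    birth = rng.integers(s0 - int(16 * DAYS_PER_YEAR), s1 - 30, size=n_c)
    fu_start = np.maximum(birth, s0)
    fu_end = np.minimum(birth + 18 * DAYS_PER_YEAR, s1).astype(float)
    if config.dropout_hazard > 0:
        stay = rng.exponential(1.0 / config.dropout_hazard, size=n_c) * DAYS_PER_YEAR
        fu_end = np.minimum(fu_end, birth + stay)

    u = _gamma_frailty(rng, n_m, config.overdispersion)
    w = _gamma_frailty(rng, n_c, config.child_overdispersion)
    is_case = rng.random(n_m) < config.p_any_mmi
    case_date = rng.integers(s0 - LOOKBACK_DAYS, s1, size=n_m).astype(float)
    case_date[~is_case] = np.inf

    base_total = {
        b: sum(config.baseline_rate(o, b) for o in OUTCOMES) for b in AGE_BANDS
    }
    rr_total = {
        b: sum(
            config.baseline_rate(o, b) * config.rate_ratio(o, b) for o in OUTCOMES
        )
        / base_total[b]
        for b in AGE_BANDS
    }

    rows = []
    for i, band in enumerate(AGE_BANDS):
        lo = birth + BAND_BOUNDARY_AGES[i] * DAYS_PER_YEAR
        hi = birth + BAND_BOUNDARY_AGES[i + 1] * DAYS_PER_YEAR
        s = np.maximum(fu_start, lo)
        e = np.minimum(fu_end, hi)
        keep = e - s >= 1.0
        if not keep.any():
            continue
        py = (e[keep] - s[keep]) / DAYS_PER_YEAR
        cd = case_date[mother_of[keep]]
        exposed = (cd >= lo[keep] - LOOKBACK_DAYS) & (cd <= e[keep])
        year = 1970 + (s[keep] / 365.2425).astype(int)
        mu = (
            base_total[band]
            * np.where(exposed, rr_total[band], 1.0)
            * np.exp(config.period_effect_per_year * (year - 2012.0))
            * py
            * u[mother_of[keep]]
            * w[keep]
        )
        rows.append(
            pd.DataFrame(
                {
                    "child_id": np.flatnonzero(keep),
                    "mother_id": mother_of[keep],
                    "age_band": band,
                    "person_years": py,
                    "period": year,
                    "exposed_any": exposed,
                    "outcome": TOTAL,
                    "count": rng.poisson(mu),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_cost_records(
    n_mothers: int = 400,
    seed: int | None = None,
    exposure_prob: float = 0.25,
    mean_children_per_mother: float = 1.8,
    base_cost_rate: Mapping[str, float] | None = None,
    cost_difference: Mapping[str, float] | None = None,
    frailty_variance: float = 0.3,
    child_frailty_variance: float = 0.3,
) -> tuple[pd.DataFrame, dict]:
    """Per-segment cost records with a known generative cost difference.

    Children contribute their band's full width of person-time; the
    mean cost rate is the band's base plus, when exposed, the band's
    true difference, multiplied by mother- and child-level gamma
    frailties (mean 1).  Used for bootstrap coverage studies.  Returns
    (records, truth) where truth holds the per-band differences.
    """
    rng = np.random.default_rng(seed)
    base = dict(base_cost_rate or {
        "<1": 2211.0, "1-4": 820.0, "5-9": 610.0, "10-13": 560.0, "14-17": 494.0,
    })
    diff = dict(cost_difference or {
        "<1": 864.0, "1-4": 310.0, "5-9": 210.0, "10-13": 150.0, "14-17": 124.0,
    })
    widths = {b: BAND_BOUNDARY_AGES[i + 1] - BAND_BOUNDARY_AGES[i]
              for i, b in enumerate(AGE_BANDS)}

    n_kids = 1 + rng.poisson(mean_children_per_mother - 1, size=n_mothers)
    n_c = int(n_kids.sum())
    mother_of = np.repeat(np.arange(n_mothers), n_kids)
    exposed_m = rng.random(n_mothers) < exposure_prob
    u = _gamma_frailty(rng, n_mothers, frailty_variance)
    w = _gamma_frailty(rng, n_c, child_frailty_variance)

    rows = []
    for b in AGE_BANDS:
        py = float(widths[b])
        rate = np.where(exposed_m[mother_of], base[b] + diff[b], base[b])
        cost = py * rate * u[mother_of] * w
        rows.append(
            pd.DataFrame(
                {
                    "child_id": np.arange(n_c),
                    "mother_id": mother_of,
                    "age_band": b,
                    "person_years": py,
                    "exposed_any": exposed_m[mother_of],
                    "cost": cost,
                }
            )
        )
    records = pd.concat(rows, ignore_index=True)
    truth = {"band_differences": diff, "base": base}
    return records, truth


# ----------------------------------------------------------------- I/O

_TABLES = {
    "children": "children.csv",
    "mothers": "mothers.csv",
    "clinical_events": "clinical_events.csv",
    "use_events": "use_events.csv",
    "codelist": "codelists.csv",
    "tariffs": "tariffs.csv",
    "cpi": "cpi.csv",
    "population": "population.csv",
}

_DATE_COLS = {
    "children": ["birth_date", "death_date", "registration_start",
                 "registration_end", "practice_uts_date", "practice_collection_end"],
    "mothers": ["registration_start", "registration_end", "death_date",
                "practice_uts_date"],
    "clinical_events": ["date"],
    "use_events": ["date"],
}


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write the dataset's tables as the fixed CSV schemas.

    Dates are ISO-8601; missing dates are empty fields.  Deterministic
    content: the same dataset always produces byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for attr, fname in _TABLES.items():
        df = getattr(dataset, attr).copy()
        for col in _DATE_COLS.get(attr, []):
            if col in df.columns:
                df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        path = directory / fname
        df.to_csv(path, index=False, lineterminator="\n")
        paths[attr] = path
    return paths


def read_dataset(directory: str | Path) -> dict[str, pd.DataFrame]:
    """Read the CSV schemas back; inverse of :func:`write_dataset`."""
    directory = Path(directory)
    out = {}
    for attr, fname in _TABLES.items():
        path = directory / fname
        if not path.exists():
            continue
        df = pd.read_csv(path)
        for col in _DATE_COLS.get(attr, []):
            if col in df.columns:
                df[col] = pd.to_datetime(df[col])
        if attr == "children" and "hes_linked" in df.columns and len(df):
            if df["hes_linked"].dtype == object:
                df["hes_linked"] = df["hes_linked"].astype(str) == "True"
        out[attr] = df
    return out
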