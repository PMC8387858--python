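"""Generator guarantees: determinism, planted truth, structure, round trips."""

import numpy as np
import pandas as pd
import pytest

from mmiburden import (
    SimulationConfig,
    classify_cases,
    count_events,
    read_dataset,
    simulate,
    simulate_counts,
    write_dataset,
)
from mmiburden.counting import OUTCOMES, TOTAL
from mmiburden.synthetic import ConfigError


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        SimulationConfig(n_mothers=0)
    with pytest.raises(ConfigError):
        SimulationConfig(mmi_prevalence_by_category={"depression": 1.5})
    with pytest.raises(ConfigError):
        SimulationConfig(exposure_rate_ratio_by_outcome_and_band={"primary_care": -1})
    with pytest.raises(ConfigError):
        SimulationConfig(study_start="2010-01-01", study_end="2009-01-01")
    with pytest.raises(ConfigError):
        SimulationConfig(duplicate_event_prob=1.4)


def test_same_seed_same_dataset():
    a = simulate(SimulationConfig(n_mothers=150, seed=13))
    b = simulate(SimulationConfig(n_mothers=150, seed=13))
    for attr in ("children", "mothers", "clinical_events", "use_events", "counts"):
        pd.testing.assert_frame_equal(getattr(a, attr), getattr(b, attr))


def test_different_seed_different_dataset():
    a = simulate(SimulationConfig(n_mothers=150, seed=13))
    b = simulate(SimulationConfig(n_mothers=150, seed=14))
    assert not a.use_events.equals(b.use_events)


def test_referential_integrity(small_dataset):
    ds = small_dataset
    assert ds.children["mother_id"].isin(set(ds.mothers["mother_id"])).all()
    assert ds.clinical_events["patient_id"].isin(set(ds.mothers["mother_id"])).all()
    assert ds.use_events["child_id"].isin(set(ds.children["child_id"])).all()


def test_clinical_events_inside_mother_registration(small_dataset):
    ds = small_dataset
    known = ds.clinical_events[
        ds.clinical_events["code"].str.startswith(("D_", "S_", "R_"))
    ]
    merged = known.merge(
        ds.mothers, left_on="patient_id", right_on="mother_id", how="left"
    )
    assert (merged["date"] >= merged["registration_start"]).all()
    assert (merged["date"] <= merged["registration_end"]).all()


def test_use_events_inside_follow_up_segments(small_dataset):
    ds = small_dataset
    seg = ds.segments
    lo = seg.groupby("child_id")["start_date"].min()
    hi = seg.groupby("child_id")["end_date"].max()
    ev = ds.use_events
    assert (ev["date"] >= ev["child_id"].map(lo)).all()
    assert (ev["date"] < ev["child_id"].map(hi)).all()


def test_planted_cases_equal_phenotyper_output(small_dataset):
    """Generator/phenotyper agreement: the classifier flags exactly the
    mothers the generator planted as cases (per illness)."""
    ds = small_dataset
    det = classify_cases(ds.clinical_events, ds.codelist)
    got = set(map(tuple, det[["mother_id", "illness"]].drop_duplicates().itertuples(index=False)))
    planted = set(
        map(tuple, ds.truth["planted_cases"][["mother_id", "illness"]].itertuples(index=False))
    )
    assert got == planted


def test_pipeline_counts_reproduce_generator_counts(small_dataset):
    """End-to-end check: realising events, then deduplicating and counting
    them through the pipeline, reproduces the generator's drawn counts."""
    ds = small_dataset
    counts = count_events(ds.use_events, ds.segments)
    seg = ds.segments.reset_index(drop=True).reset_index(names="_seg")
    got = (
        counts[counts["outcome"] != TOTAL]
        .merge(seg[["_seg", "child_id", "age_band"]], on=["child_id", "age_band"])
        .set_index(["_seg", "outcome"])["count"]
    )
    want = ds.truth["expected_dedup_counts"].set_index(["_seg", "outcome"])[
        "expected_count"
    ]
    aligned = pd.concat([got, want], axis=1).fillna(0)
    assert (aligned["count"] == aligned["expected_count"]).all()


def test_zero_prevalence_means_no_exposed_person_time():
    cfg = SimulationConfig(
        n_mothers=200,
        mmi_prevalence_by_category={k: 0.0 for k in SimulationConfig().mmi_prevalence_by_category},
        seed=5,
    )
    ds = simulate(cfg, realize_events=False)
    assert not ds.segments["exposed_any"].any()
    assert ds.determinations.empty


def test_null_effect_gives_rate_ratio_near_one():
    """With all rate ratios 1 the empirical exposed/unexposed contrast is
    compatible with no effect."""
    from mmiburden import fit_two_group

    cfg = SimulationConfig(
        n_mothers=4000,
        exposure_rate_ratio_by_outcome_and_band={o: 1.0 for o in OUTCOMES},
        seed=3,
    )
    rec = simulate_counts(cfg)
    fit = fit_two_group(rec, covariates=("age_band", "period"))
    assert fit["ci_low"] < 1.0 < fit["ci_high"]
    assert abs(fit["log_rr"]) < 0.1


def test_overdispersion_realised_in_counts():
    """Variance of per-child counts exceeds the Poisson mean when the
    frailty variances are positive."""
    cfg = SimulationConfig(n_mothers=5000, overdispersion=0.5, seed=2)
    rec = simulate_counts(cfg)
    infants = rec[(rec["age_band"] == "1-4") & ~rec["exposed_any"]]
    # compare like-for-like by conditioning on near-full band occupancy
    full = infants[infants["person_years"] > 3.9]
    assert full["count"].var() > 1.5 * full["count"].mean()


def test_mother_frailty_shared_by_siblings():
    """Sibling counts are positively correlated through the shared frailty."""
    cfg = SimulationConfig(
        n_mothers=4000, mean_children_per_mother=2.5, overdispersion=1.0,
        child_overdispersion=0.0, seed=6,
    )
    rec = simulate_counts(cfg)
    band = rec[rec["age_band"] == "5-9"]
    rate = band["count"] / band["person_years"]
    g = pd.DataFrame({"mother_id": band["mother_id"], "rate": rate})
    sib = g.groupby("mother_id")["rate"].agg(["first", "last", "count"])
    sib = sib[sib["count"] >= 2]
    corr = np.corrcoef(sib["first"], sib["last"])[0, 1]
    assert corr > 0.2


def test_round_trip_write_read(tmp_path, small_dataset):
    ds = small_dataset
    write_dataset(ds, tmp_path)
    back = read_dataset(tmp_path)
    pd.testing.assert_frame_equal(
        back["children"], ds.children, check_dtype=False
    )
    pd.testing.assert_frame_equal(
        back["clinical_events"], ds.clinical_events, check_dtype=False
    )
    pd.testing.assert_frame_equal(
        back["use_events"].assign(
            drug_code=back["use_events"]["drug_code"].fillna(""),
            drug_category=back["use_events"]["drug_category"].fillna(""),
            consultation_type=back["use_events"]["consultation_type"].fillna(""),
            staff=back["use_events"]["staff"].fillna(""),
            episode_type=back["use_events"]["episode_type"].fillna(""),
        ),
        ds.use_events,
        check_dtype=False,
    )


def test_same_seed_byte_identical_files(tmp_path):
    a = simulate(SimulationConfig(n_mothers=100, seed=31))
    b = simulate(SimulationConfig(n_mothers=100, seed=31))
    pa = write_dataset(a, tmp_path / "a")
    pb = write_dataset(b, tmp_path / "b")
    for key in pa:
        assert pa[key].read_bytes() == pb[key].read_bytes()


def test_empty_dataset_writes_header_only_csvs(tmp_path):
    from mmiburden.synthetic import SyntheticDataset, _make_codelist, _make_cpi, _make_tariffs, DEFAULT_POPULATION

    empty = SyntheticDataset(
        children=pd.DataFrame(columns=["child_id", "mother_id", "birth_date", "death_date",
                                       "sex", "imd_quintile", "registration_start",
                                       "registration_end", "practice_uts_date",
                                       "practice_collection_end", "hes_linked"]),
        mothers=pd.DataFrame(columns=["mother_id", "registration_start",
                                      "registration_end", "death_date", "practice_uts_date"]),
        clinical_events=pd.DataFrame(columns=["patient_id", "date", "code"]),
        use_events=pd.DataFrame(columns=["child_id", "date", "outcome", "consultation_type",
                                         "staff", "episode_type", "length_of_stay",
                                         "drug_code", "drug_category"]),
        codelist=_make_codelist(),
        tariffs=_make_tariffs(np.random.default_rng(0)),
        cpi=_make_cpi(),
        population=DEFAULT_POPULATION.copy(),
        segments=pd.DataFrame(),
        determinations=pd.DataFrame(),
        counts=pd.DataFrame(),
        truth={},
    )
    paths = write_dataset(empty, tmp_path)
    kids = pd.read_csv(paths["children"])
    assert kids.empty and list(kids.columns)[0] == "child_id"
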