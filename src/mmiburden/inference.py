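"""Rate-ratio and rate-difference estimation for exposed vs unexposed children.

Counts (or costs) per person-time segment are modelled with log-link
negative-binomial (NB2) regression using log person-years as an offset,
so coefficients act on rates.  Models control for period (the calendar
year the age group started, categorical) and age band, and include an
age-band x exposure interaction to give band-specific rate ratios; the
pooled ("all ages") ratio comes from a refit without the interaction.
Standard errors use the cluster-robust Huber-White estimator grouped by
mother, respecting sibship correlation.

Rate differences on the absolute scale come from marginal
standardization: the model-predicted rate averaged (person-year
weighted) over a band's observed covariate rows with exposure switched
on minus off.  The crude two-group difference is reported alongside,
with a mother-level bootstrap CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from mmiburden.bands import AGE_BANDS


@dataclass
class ModelSpec:
    """What to estimate: outcome, exposure definition and adjustments."""

    outcome: str
    exposure_category: str = "any"
    adjust_imd: bool = False
    stratified: bool = False  # per-band fits instead of one interaction model
    admission_note: str = field(default="", repr=False)

    @property
    def exposure_col(self) -> str:
        return f"exposed_{self.exposure_category}"


class ConvergenceError(RuntimeError):
    """NB fit failed even after restarting from Poisson estimates."""


def two_group_rates(
    records: pd.DataFrame,
    exposure_col: str = "exposed_any",
    count_col: str = "count",
) -> dict:
    """Crude arm rates (sum of events over sum of person-years) and difference."""
    exposed = records[exposure_col].astype(bool)
    py_e = records.loc[exposed, "person_years"].sum()
    py_u = records.loc[~exposed, "person_years"].sum()
    out = {
        "rate_exposed": np.nan,
        "rate_unexposed": np.nan,
        "rate_difference": np.nan,
        "empty_arm": py_e <= 0 or py_u <= 0,
    }
    if py_e > 0:
        out["rate_exposed"] = records.loc[exposed, count_col].sum() / py_e
    if py_u > 0:
        out["rate_unexposed"] = records.loc[~exposed, count_col].sum() / py_u
    if not out["empty_arm"]:
        out["rate_difference"] = out["rate_exposed"] - out["rate_unexposed"]
    return out


def _cluster_kwds(records: pd.DataFrame, cluster_col: str) -> dict:
    codes, _ = pd.factorize(records[cluster_col])
    return {"cov_type": "cluster", "cov_kwds": {"groups": codes}}


def _fit_nb(
    endog: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    cov: dict,
    alpha: float | None,
):
    """Fit NB2 (estimating alpha) or fixed-alpha GLM; Poisson-start restart."""
    if alpha is not None:
        model = sm.GLM(
            endog, X, family=sm.families.NegativeBinomial(alpha=max(alpha, 1e-12)),
            offset=offset,
        )
        return model.fit(cov_type=cov["cov_type"], cov_kwds=cov["cov_kwds"]), alpha

    poisson = sm.Poisson(endog, X, offset=offset).fit(disp=0, maxiter=200)
    model = sm.NegativeBinomial(endog, X, offset=offset, loglike_method="nb2")
    start = np.append(poisson.params, 0.1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(
            start_params=start, disp=0, maxiter=500, method="bfgs",
            cov_type=cov["cov_type"], cov_kwds=cov["cov_kwds"],
        )
        if not res.mle_retvals.get("converged", False):
            res = model.fit(
                start_params=np.append(poisson.params, 0.01), disp=0,
                maxiter=2000, method="nm",
                cov_type=cov["cov_type"], cov_kwds=cov["cov_kwds"],
            )
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError("negative binomial fit did not converge")
    return res, float(res.params[-1])


def fit_two_group(
    records: pd.DataFrame,
    exposure_col: str = "exposed_any",
    count_col: str = "count",
    cluster_col: str = "mother_id",
    alpha: float | None = None,
    covariates: tuple[str, ...] = (),
) -> dict:
    """NB fit of ``count ~ exposed (+ categorical covariates)`` with offset.

    With no covariates this is the plain two-group contrast; passing
    ``covariates=("age_band", "period")`` gives the pooled adjusted
    model (exposure windows make exposure prevalence rise with age
    band while baseline rates fall, so the covariates matter whenever
    both are in play).  ``alpha`` fixes the NB2 dispersion (values near
    zero give the Poisson limit, where fitted arm rates equal crude arm
    rates); ``None`` estimates it by maximum likelihood.  CIs are Wald
    on the log scale with mother-clustered robust variance.
    """
    rec = records
    exposed = rec[exposure_col].astype(bool).to_numpy().astype(float)
    cols = [np.ones(len(rec))]
    for cv in covariates:
        levels = np.sort(rec[cv].unique())
        for lev in levels[1:]:
            cols.append((rec[cv] == lev).to_numpy(dtype=float))
    cols.append(exposed)
    X = np.column_stack(cols)
    offset = np.log(rec["person_years"].to_numpy(dtype=float))
    endog = rec[count_col].to_numpy(dtype=float)
    cov = _cluster_kwds(rec, cluster_col)

    res, alpha_hat = _fit_nb(endog, X, offset, cov, alpha)
    log_rr = float(res.params[X.shape[1] - 1])
    se = float(res.bse[X.shape[1] - 1])
    crude = two_group_rates(rec, exposure_col, count_col)
    return {
        "rate_ratio": float(np.exp(log_rr)),
        "ci_low": float(np.exp(log_rr - 1.96 * se)),
        "ci_high": float(np.exp(log_rr + 1.96 * se)),
        "log_rr": log_rr,
        "se_log_rr": se,
        "alpha": alpha_hat,
        "rate_exposed": crude["rate_exposed"],
        "rate_unexposed": crude["rate_unexposed"],
        "intercept_rate": float(np.exp(res.params[0])),
        "n_obs": int(len(rec)),
        "n_clusters": int(rec[cluster_col].nunique()),
    }


def _design(
    rec: pd.DataFrame,
    exposure_col: str,
    bands: list[str],
    interaction: bool,
    adjust_imd: bool,
) -> tuple[np.ndarray, list[str]]:
    """Intercept + period dummies + band dummies (+ IMD) + exposure terms.

    With ``interaction`` the exposure enters as one indicator per band
    (no main effect), so each band's log rate ratio is a single
    coefficient; without it a single exposure indicator is used.
    """
    n = len(rec)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]

    for label, series in [("period", rec["period"])] + (
        [("imd", rec["imd_quintile"])] if adjust_imd else []
    ):
        levels = np.sort(series.unique())
        for lev in levels[1:]:
            cols.append((series == lev).to_numpy(dtype=float))
            names.append(f"{label}[{lev}]")

    if len(bands) > 1:
        for b in bands[1:]:
            cols.append((rec["age_band"] == b).to_numpy(dtype=float))
            names.append(f"band[{b}]")

    exposed = rec[exposure_col].astype(bool).to_numpy(dtype=float)
    if interaction and len(bands) > 1:
        for b in bands:
            cols.append(exposed * (rec["age_band"] == b).to_numpy(dtype=float))
            names.append(f"exposed:band[{b}]")
    else:
        cols.append(exposed)
        names.append("exposed")
    return np.column_stack(cols), names


def _marginal_rate_difference(
    res, X: np.ndarray, names: list[str], exposure_terms: list[str], py: np.ndarray
) -> float:
    """Person-year-weighted standardized rate difference over observed rows."""
    params = np.asarray(res.params)[: len(names)]
    idx = [names.index(t) for t in exposure_terms]
    X1, X0 = X.copy(), X.copy()
    for i in idx:
        X1[:, i] = 1.0 if names[i] == "exposed" else X1[:, i]
        X0[:, i] = 0.0
    # for interaction terms "exposed:band[b]" switching exposure on means
    # setting the indicator of the row's own band to 1
    if any(t.startswith("exposed:band") for t in exposure_terms):
        band_cols = {t: i for t, i in zip(exposure_terms, idx)}
        X1[:, idx] = 0.0
        for t, i in band_cols.items():
            band = t[len("exposed:band["):-1]
            # rows of this band get their interaction switched on
            in_band = _rows_in_band(X, names, band)
            X1[in_band, i] = 1.0
    mu1 = np.exp(X1 @ params)
    mu0 = np.exp(X0 @ params)
    w = py / py.sum()
    return float(np.sum(w * (mu1 - mu0)))


def _rows_in_band(X: np.ndarray, names: list[str], band: str) -> np.ndarray:
    col = f"band[{band}]"
    if col in names:
        return X[:, names.index(col)] == 1.0
    # reference band: rows with all band dummies zero
    dummy_idx = [i for i, n in enumerate(names) if n.startswith("band[")]
    if not dummy_idx:
        return np.ones(len(X), dtype=bool)
    return (X[:, dummy_idx] == 0.0).all(axis=1)


def fit_cell(
    records: pd.DataFrame,
    spec: ModelSpec,
    count_col: str = "count",
    cluster_col: str = "mother_id",
    alpha: float | None = None,
    n_boot_rd: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Band-specific and pooled effect estimates for one outcome x category.

    Returns one row per age band present plus ``all``: crude arm rates,
    rate ratio with cluster-robust Wald CI, standardized and crude rate
    differences (crude-difference CI from a mother-level bootstrap when
    ``n_boot_rd`` > 0), cluster counts and a degenerate flag for bands
    with an all-zero arm.
    """
    # local import: extrapolation provides the shared cluster bootstrap
    from mmiburden.extrapolation import bootstrap_band_differences

    rec = records
    if "outcome" in rec.columns:
        rec = rec[rec["outcome"] == spec.outcome]
    rec = rec.reset_index(drop=True)
    if rec.empty:
        raise ValueError(f"no records for outcome {spec.outcome!r}")
    exposure_col = spec.exposure_col
    bands = [b for b in AGE_BANDS if b in set(rec["age_band"])]

    # a band is degenerate when either arm has zero events
    degenerate: dict[str, bool] = {}
    for b in bands:
        sub = rec[rec["age_band"] == b]
        e = sub[exposure_col].astype(bool)
        degenerate[b] = (
            sub.loc[e, count_col].sum() == 0 or sub.loc[~e, count_col].sum() == 0
        )
    good_bands = [b for b in bands if not degenerate[b]]

    rd_boot = None
    if n_boot_rd > 0:
        rd_boot = bootstrap_band_differences(
            rec, value_col=count_col, exposure_col=exposure_col,
            n_boot=n_boot_rd, seed=seed, cluster_col=cluster_col,
        ).set_index("age_band")

    rows = []

    def _band_row(band, crude, rr=np.nan, lo=np.nan, hi=np.nan, rd_std=np.nan,
                  n_obs=0, n_cl=0, flag=False):
        rd_lo = rd_hi = np.nan
        if rd_boot is not None and band in rd_boot.index:
            sd = rd_boot.loc[band, "sd"]
            rd_lo = crude["rate_difference"] - 1.96 * sd
            rd_hi = crude["rate_difference"] + 1.96 * sd
        rows.append(
            {
                "outcome": spec.outcome,
                "exposure_category": spec.exposure_category,
                "age_band": band,
                "rate_exposed": crude["rate_exposed"],
                "rate_unexposed": crude["rate_unexposed"],
                "rate_ratio": rr,
                "rr_ci_low": lo,
                "rr_ci_high": hi,
                "rate_difference": rd_std,
                "rate_difference_crude": crude["rate_difference"],
                "rd_ci_low": rd_lo,
                "rd_ci_high": rd_hi,
                "n_observations": n_obs,
                "n_clusters": n_cl,
                "degenerate": flag,
            }
        )

    if spec.stratified:
        for b in good_bands:
            sub = rec[rec["age_band"] == b].reset_index(drop=True)
            X, names = _design(sub, exposure_col, [b], False, spec.adjust_imd)
            cov = _cluster_kwds(sub, cluster_col)
            py = sub["person_years"].to_numpy(dtype=float)
            res, _ = _fit_nb(
                sub[count_col].to_numpy(float), X, np.log(py), cov, alpha
            )
            i = names.index("exposed")
            beta, se = float(res.params[i]), float(res.bse[i])
            rd_std = _marginal_rate_difference(res, X, names, ["exposed"], py)
            _band_row(
                b, two_group_rates(sub, exposure_col, count_col),
                np.exp(beta), np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se),
                rd_std, len(sub), sub[cluster_col].nunique(),
            )
    elif good_bands:
        sub = rec[rec["age_band"].isin(good_bands)].reset_index(drop=True)
        X, names = _design(sub, exposure_col, good_bands, True, spec.adjust_imd)
        cov = _cluster_kwds(sub, cluster_col)
        py = sub["person_years"].to_numpy(dtype=float)
        res, _ = _fit_nb(sub[count_col].to_numpy(float), X, np.log(py), cov, alpha)
        exposure_terms = (
            [f"exposed:band[{b}]" for b in good_bands]
            if len(good_bands) > 1
            else ["exposed"]
        )
        for b in good_bands:
            term = (
                f"exposed:band[{b}]" if len(good_bands) > 1 else "exposed"
            )
            i = names.index(term)
            beta, se = float(res.params[i]), float(res.bse[i])
            in_band = sub["age_band"] == b
            rd_std = _marginal_rate_difference(
                res, X[in_band.to_numpy()], names, exposure_terms,
                py[in_band.to_numpy()],
            )
            _band_row(
                b, two_group_rates(sub[in_band], exposure_col, count_col),
                np.exp(beta), np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se),
                rd_std, int(in_band.sum()),
                sub.loc[in_band, cluster_col].nunique(),
            )

    for b in bands:
        if degenerate[b]:
            _band_row(
                b, two_group_rates(rec[rec["age_band"] == b], exposure_col, count_col),
                n_obs=int((rec["age_band"] == b).sum()),
                n_cl=rec.loc[rec["age_band"] == b, cluster_col].nunique(),
                flag=True,
            )

    # pooled ("all ages"): same covariates, no interaction
    crude_all = two_group_rates(rec, exposure_col, count_col)
    if not crude_all["empty_arm"] and rec[count_col].sum() > 0:
        X, names = _design(rec, exposure_col, bands, False, spec.adjust_imd)
        cov = _cluster_kwds(rec, cluster_col)
        py = rec["person_years"].to_numpy(dtype=float)
        res, _ = _fit_nb(rec[count_col].to_numpy(float), X, np.log(py), cov, alpha)
        i = names.index("exposed")
        beta, se = float(res.params[i]), float(res.bse[i])
        rd_std = _marginal_rate_difference(res, X, names, ["exposed"], py)
        _band_row_all = {
            "outcome": spec.outcome,
            "exposure_category": spec.exposure_category,
            "age_band": "all",
            "rate_exposed": crude_all["rate_exposed"],
            "rate_unexposed": crude_all["rate_unexposed"],
            "rate_ratio": float(np.exp(beta)),
            "rr_ci_low": float(np.exp(beta - 1.96 * se)),
            "rr_ci_high": float(np.exp(beta + 1.96 * se)),
            "rate_difference": rd_std,
            "rate_difference_crude": crude_all["rate_difference"],
            "rd_ci_low": np.nan,
            "rd_ci_high": np.nan,
            "n_observations": int(len(rec)),
            "n_clusters": int(rec[cluster_col].nunique()),
            "degenerate": False,
        }
        rows.append(_band_row_all)

    order = {b: i for i, b in enumerate(list(AGE_BANDS) + ["all"])}
    out = pd.DataFrame(rows)
    return out.sort_values("age_band", key=lambda s: s.map(order)).reset_index(
        drop=True
    )
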