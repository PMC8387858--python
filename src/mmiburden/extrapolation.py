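"""National extrapolation of excess healthcare cost, with cluster bootstrap.

The annual excess spend attributable to maternal mental illness is
estimated per age band as::

    excess(band) = cost_difference(band)  [pounds/child/year]
                   x mmi_prevalence(band) x n_children(band)

and summed over the five bands.  Cost differences are the crude
differences in cost rates (exposed minus unexposed, ratio-of-sums form)
by default.  Uncertainty comes from a cluster bootstrap that resamples
mothers with replacement — children travel with their mother, so a
resample never splits a sibship — recomputing the band differences and
the national total for each resample; the normal-approximation CI is
``point +/- 1.96 x SD(bootstrap totals)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from mmiburden.bands import AGE_BANDS


@dataclass
class NationalEstimate:
    """Per-band and total annual excess cost with a bootstrap CI."""

    per_band: dict[str, float]
    total: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    bootstrap_sd: float
    n_invalid_resamples: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(self.total, sum(self.per_band.values()), equal_nan=True):
            raise ValueError("total must equal the sum of per-band excesses")


def _validate_population(population: pd.DataFrame) -> pd.DataFrame:
    pop = population.set_index("age_band")
    missing = set(AGE_BANDS) - set(pop.index)
    if missing:
        raise ValueError(f"population table missing bands: {sorted(missing)}")
    if ((pop["mmi_prevalence"] < 0) | (pop["mmi_prevalence"] > 1)).any():
        raise ValueError("prevalences must lie in [0, 1]")
    if (pop["n_children"] < 0).any():
        raise ValueError("child counts must be non-negative")
    return pop


def national_excess(
    cost_differences: Mapping[str, float],
    population: pd.DataFrame,
) -> NationalEstimate:
    """Point estimate of the national annual excess cost (no CI)."""
    pop = _validate_population(population)
    missing = set(AGE_BANDS) - set(cost_differences)
    if missing:
        raise ValueError(f"cost differences missing bands: {sorted(missing)}")
    per_band = {
        b: float(
            cost_differences[b]
            * pop.loc[b, "mmi_prevalence"]
            * pop.loc[b, "n_children"]
        )
        for b in AGE_BANDS
    }
    total = float(sum(per_band.values()))
    return NationalEstimate(
        per_band=per_band, total=total, ci_low=np.nan, ci_high=np.nan,
        n_bootstrap=0, bootstrap_sd=np.nan,
    )


def band_cost_differences(
    records: pd.DataFrame,
    value_col: str = "cost",
    exposure_col: str = "exposed_any",
) -> dict[str, float]:
    """Crude per-band rate differences, ratio-of-sums form.

    ``sum(value)/sum(person_years)`` in each arm, exposed minus
    unexposed; NaN for a band with an empty arm.
    """
    out: dict[str, float] = {}
    exposed = records[exposure_col].astype(bool)
    for band, grp in records.groupby("age_band"):
        e = exposed.loc[grp.index]
        py_e = grp.loc[e, "person_years"].sum()
        py_u = grp.loc[~e, "person_years"].sum()
        if py_e > 0 and py_u > 0:
            out[band] = float(
                grp.loc[e, value_col].sum() / py_e
                - grp.loc[~e, value_col].sum() / py_u
            )
        else:
            out[band] = np.nan
    return out


def _mother_matrix(
    records: pd.DataFrame,
    value_col: str,
    exposure_col: str,
    cluster_col: str,
) -> tuple[np.ndarray, list[str]]:
    """Per-mother sums of (value, person-years) by band and arm.

    Returns an (n_mothers x 4 * n_bands) matrix with column blocks
    [value_e, py_e, value_u, py_u] per band, and the band order used.
    One matrix product against a resample's mother-count vector yields
    all the sums a bootstrap replicate needs.
    """
    bands = [b for b in AGE_BANDS if b in set(records["age_band"])]
    mothers = pd.Index(records[cluster_col].unique())
    m_pos = {m: i for i, m in enumerate(mothers)}
    M = np.zeros((len(mothers), 4 * len(bands)))
    exposed = records[exposure_col].astype(bool).to_numpy()
    band_pos = {b: j for j, b in enumerate(bands)}
    rows = records[cluster_col].map(m_pos).to_numpy()
    bcol = records["age_band"].map(band_pos).to_numpy()
    val = records[value_col].to_numpy(dtype=float)
    py = records["person_years"].to_numpy(dtype=float)
    arm_off = np.where(exposed, 0, 2)
    np.add.at(M, (rows, 4 * bcol + arm_off), val)
    np.add.at(M, (rows, 4 * bcol + arm_off + 1), py)
    return M, bands


def bootstrap_band_differences(
    records: pd.DataFrame,
    value_col: str = "cost",
    exposure_col: str = "exposed_any",
    n_boot: int = 1000,
    seed: int | None = None,
    cluster_col: str = "mother_id",
) -> pd.DataFrame:
    """Bootstrap SD of each band's crude rate difference (mothers resampled).

    Returns a frame with columns ``age_band``, ``difference`` (the
    observed crude difference), ``sd`` and normal-approximation CI
    bounds.  Shared by the rate-difference CIs of the inference module
    and the national extrapolation.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    M, bands = _mother_matrix(records, value_col, exposure_col, cluster_col)
    n_m = M.shape[0]
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_m, np.full(n_m, 1.0 / n_m), size=n_boot)
    totals = counts.astype(float) @ M  # n_boot x 4*bands
    with np.errstate(divide="ignore", invalid="ignore"):
        diffs = (
            totals[:, 0::4] / totals[:, 1::4] - totals[:, 2::4] / totals[:, 3::4]
        )
    observed = band_cost_differences(records, value_col, exposure_col)
    rows = []
    for j, b in enumerate(bands):
        col = diffs[:, j]
        ok = np.isfinite(col)
        sd = float(col[ok].std(ddof=1)) if ok.sum() >= 2 else np.nan
        d = observed[b]
        rows.append(
            {
                "age_band": b,
                "difference": d,
                "sd": sd,
                "ci_low": d - 1.96 * sd,
                "ci_high": d + 1.96 * sd,
                "n_valid": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows)


def bootstrap_ci(
    records: pd.DataFrame,
    population: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    value_col: str = "cost",
    exposure_col: str = "exposed_any",
    cluster_col: str = "mother_id",
    method: str = "normal",
) -> NationalEstimate:
    """National excess with a mother-level bootstrap CI.

    Each of ``n_boot`` resamples draws mothers with replacement,
    recomputes every band's crude cost-rate difference and the national
    total; the CI is ``point +/- 1.96 x SD`` of the bootstrap totals
    (``method="percentile"`` gives the 2.5/97.5 percentiles instead).
    Deterministic under a fixed seed.  Resamples where some band loses
    an entire arm are dropped and counted.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    pop = _validate_population(population)
    observed = band_cost_differences(records, value_col, exposure_col)
    for b in AGE_BANDS:
        if b not in observed:
            weight = pop.loc[b, "mmi_prevalence"] * pop.loc[b, "n_children"]
            if weight != 0:
                raise ValueError(f"no cost records for band {b!r} with nonzero weight")
            observed[b] = 0.0
    point = national_excess(observed, population)

    M, bands = _mother_matrix(records, value_col, exposure_col, cluster_col)
    weights = np.array(
        [pop.loc[b, "mmi_prevalence"] * pop.loc[b, "n_children"] for b in bands]
    )
    n_m = M.shape[0]
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_m, np.full(n_m, 1.0 / n_m), size=n_boot)
    totals = counts.astype(float) @ M
    with np.errstate(divide="ignore", invalid="ignore"):
        diffs = (
            totals[:, 0::4] / totals[:, 1::4] - totals[:, 2::4] / totals[:, 3::4]
        )
    boot_totals = diffs @ weights
    ok = np.isfinite(boot_totals)
    n_invalid = int((~ok).sum())
    vals = boot_totals[ok]
    sd = float(vals.std(ddof=1)) if len(vals) >= 2 else np.nan
    if method == "normal":
        lo, hi = point.total - 1.96 * sd, point.total + 1.96 * sd
    elif method == "percentile":
        lo, hi = (float(np.percentile(vals, q)) for q in (2.5, 97.5))
    else:
        raise ValueError(f"unknown CI method: {method!r}")
    return NationalEstimate(
        per_band=point.per_band,
        total=point.total,
        ci_low=float(lo),
        ci_high=float(hi),
        n_bootstrap=n_boot,
        bootstrap_sd=sd,
        n_invalid_resamples=n_invalid,
    )
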