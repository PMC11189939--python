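"""Derive the six analysis traits and state covariates from raw observation logs.

Thermal traits per individual-day: T_sel (median body temperature — the
'goal' of thermoregulation), T_Vmax (highest temperature voluntarily
reached — a tolerance proxy) and T_set (width of the central 50% of
readings — precision; smaller is more precise).  Behavioural traits per
trial: movement activity (transitions per minute spent outside the
shelter), sheltering (seconds hiding) and risk-taking (latency to emerge
after a simulated attack).  Quantiles use linear interpolation between
order statistics throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import RawDataset

#: constant added before the natural log of sheltering / risk-taking seconds,
#: guarding zero durations while staying monotone
LOG_OFFSET = 1.0

#: trials where the animal never emerges are recorded at the full recording
#: length (right-censored value used as-is)
RISK_CENSOR_S = 3600.0


def derive_thermal_traits(temps: np.ndarray) -> tuple[float, float, float]:
    """(T_sel, T_set, T_Vmax) of one individual-day temperature series.

    T_sel is the median, T_Vmax the maximum, and T_set the width of the
    central 50% of readings (75th minus 25th percentile, linear
    interpolation).  Reading order is irrelevant.
    """
    temps = np.asarray(temps, dtype=float)
    if temps.size < 4:
        raise ValueError(
            f"need at least 4 readings to resolve quartiles, got {temps.size}"
        )
    if not np.isfinite(temps).all():
        raise ValueError("non-finite temperature reading in series")
    q25, q50, q75 = np.percentile(temps, [25.0, 50.0, 75.0])
    return float(q50), float(q75 - q25), float(temps.max())


def derive_behaviour_traits(
    sheltering_s: float, transitions: int, time_outside_s: float, risk_latency_s: float
) -> tuple[float, float, float]:
    """(activity, sheltering, risk_taking) from one behavioural trial.

    activity = (transitions / seconds outside) * 60, i.e. a per-minute
    transition rate independent of sheltering; it is missing (NaN) when the
    animal never left the shelter.  Sheltering and risk-taking are returned
    in seconds; the log transform is applied at table-building time.
    """
    if not 0.0 <= sheltering_s <= 3600.0:
        raise ValueError(f"sheltering_s out of [0, 3600]: {sheltering_s}")
    if not 0.0 <= time_outside_s <= 3600.0:
        raise ValueError(f"time_outside_s out of [0, 3600]: {time_outside_s}")
    if transitions < 0 or risk_latency_s < 0:
        raise ValueError("transitions and risk_latency_s must be >= 0")
    if time_outside_s == 0:
        if transitions > 0:
            raise ValueError(
                f"inconsistent trial: {transitions} transitions with zero time outside"
            )
        activity = np.nan
    else:
        activity = transitions / time_outside_s * 60.0
    return float(activity), float(sheltering_s), float(risk_latency_s)


def head_size_pca(head_measures: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, float]:
    """First principal component of the three head measures.

    PCA runs on the correlation matrix (the measures differ in scale);
    the component sign is fixed so all loadings are positive.  Returns
    (scores, loadings, fraction of variance explained).
    """
    x = head_measures.to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need >= 3 individuals for the head-size PCA")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = head_measures.columns[sd == 0].tolist()
        raise ValueError(f"constant head-measure column(s): {bad}")
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    loadings = vecs[:, -1]
    if loadings.sum() < 0:
        loadings = -loadings
    scores = z @ loadings
    explained = float(vals[-1] / vals.sum())
    return scores, loadings, explained


def _ols_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def prepare_covariates(raw: RawDataset | pd.DataFrame) -> pd.DataFrame:
    """Individual-level state covariates from the raw measurement table.

    relative_head_size is the residual of the head-size PC on SVL,
    condition the residual of body weight on SVL (raw scales), and
    parasite_intensity the mean infected-cell count over the three smear
    scans.
    """
    cov = raw.covariates if isinstance(raw, RawDataset) else raw
    if len(cov) < 3:
        raise ValueError("need >= 3 individuals with complete measurements")
    heads = cov[["pileus_length_cm", "pileus_width_cm", "head_width_cm"]]
    scores, loadings, explained = head_size_pca(heads)
    svl = cov["SVL_cm"].to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "individual_id": cov["individual_id"].to_numpy(),
            "SVL": svl,
            "head_size_pc": scores,
            "relative_head_size": _ols_residuals(scores, svl),
            "condition": _ols_residuals(cov["BW_g"].to_numpy(dtype=float), svl),
            "parasite_intensity": cov[
                ["parasite_count_1", "parasite_count_2", "parasite_count_3"]
            ].mean(axis=1).to_numpy(),
        }
    )
    out.attrs["head_pc_loadings"] = loadings
    out.attrs["head_pc_explained"] = explained
    return out


@dataclass
class TraitTable:
    """Long-format individual x occasion trait values plus covariates.

    ``data`` holds the natural-scale traits (sheltering and risk_taking
    already log(s+1)-transformed), the standardized ``*_z`` columns, and
    the z-scored occasion index ``time``.  ``transforms`` maps each
    standardized column to its (mean, SD) so fitted intercepts can be
    returned to natural units.
    """

    data: pd.DataFrame
    transforms: dict[str, tuple[float, float]] = field(default_factory=dict)

    def back_transform(self, column: str, value: float) -> float:
        """Natural-scale value of a standardized quantity (e.g. an intercept)."""
        mean, sd = self.transforms[column]
        return mean + sd * value


def standardize_columns(
    df: pd.DataFrame, columns: list[str], suffix: str = "_z"
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Append z-scored copies (sample SD, ddof=1) of the given columns.

    Missing entries are ignored when computing the moments and stay missing
    in the standardized column.  A zero-variance column is an error.
    """
    df = df.copy()
    transforms: dict[str, tuple[float, float]] = {}
    for col in columns:
        vals = df[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if not ok.any():
            raise ValueError(f"column {col!r} has no non-missing values")
        mean = vals[ok].mean()
        sd = vals[ok].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"cannot standardize zero-variance column {col!r}")
        df[col + suffix] = (vals - mean) / sd
        transforms[col] = (float(mean), float(sd))
    return df, transforms


def standardize_traits(
    table: TraitTable | pd.DataFrame,
    trait_columns: list[str] | None = None,
    covariate_columns: list[str] | None = None,
) -> TraitTable:
    """Standardize response and continuous explanatory columns to mean 0, SD 1."""
    df = table.data if isinstance(table, TraitTable) else table
    if trait_columns is None:
        trait_columns = [
            c for c in ("T_sel", "T_set", "T_Vmax", "activity", "sheltering", "risk_taking")
            if c in df.columns
        ]
    if covariate_columns is None:
        covariate_columns = [
            c for c in ("SVL", "relative_head_size", "condition", "parasite_intensity")
            if c in df.columns
        ]
    out, transforms = standardize_columns(df, trait_columns + covariate_columns)
    return TraitTable(data=out, transforms=transforms)


def build_trait_table(raw: RawDataset, *, standardize: bool = True) -> TraitTable:
    """Full derivation: raw logs -> standardized long-format trait table.

    One row per individual x assay day; thermal and behavioural assay days
    are interleaved occasions (thermal on even positions), mirroring the
    alternating-day study design, so each row carries one trait block and
    missing values for the other.  ``time`` is the z-scored occasion index
    within each block.
    """
    thermal_rows = []
    for (ind, day), grp in raw.thermal_log.groupby(["individual_id", "day_index"]):
        t_sel, t_set, t_vmax = derive_thermal_traits(grp["body_temp_C"].to_numpy())
        thermal_rows.append(
            {"individual_id": ind, "block_occasion": day, "block": "thermal",
             "T_sel": t_sel, "T_set": t_set, "T_Vmax": t_vmax}
        )
    thermal = pd.DataFrame(thermal_rows)

    beh_rows = []
    for rec in raw.behaviour_log.itertuples(index=False):
        activity, shel_s, risk_s = derive_behaviour_traits(
            rec.sheltering_s, rec.transitions, rec.time_outside_s, rec.risk_latency_s
        )
        beh_rows.append(
            {"individual_id": rec.individual_id, "block_occasion": rec.day_index,
             "block": "behaviour", "activity": activity,
             "sheltering": np.log(shel_s + LOG_OFFSET),
             "risk_taking": np.log(min(risk_s, RISK_CENSOR_S) + LOG_OFFSET)}
        )
    behaviour = pd.DataFrame(beh_rows)

    long = pd.concat([thermal, behaviour], ignore_index=True, sort=False)
    # interleave: thermal day j -> occasion 2j-1, behaviour day j -> occasion 2j
    long["occasion"] = np.where(
        long["block"] == "thermal",
        2 * long["block_occasion"] - 1,
        2 * long["block_occasion"],
    )
    # time covariate: z-scored assay index within each block, so six thermal
    # and five behavioural assays each span the standardized axis
    long["time"] = np.nan
    for _, idx in long.groupby("block").groups.items():
        occ = long.loc[idx, "block_occasion"].to_numpy(dtype=float)
        long.loc[idx, "time"] = (occ - occ.mean()) / occ.std(ddof=1)

    covs = prepare_covariates(raw)
    long = long.merge(covs, on="individual_id", how="left")
    long = long.sort_values(["individual_id", "occasion"]).reset_index(drop=True)
    long = long.drop(columns=["block_occasion"])

    if not standardize:
        return TraitTable(data=long)
    return standardize_traits(long)


__all__ = [
    "LOG_OFFSET",
    "RISK_CENSOR_S",
    "TraitTable",
    "build_trait_table",
    "derive_behaviour_traits",
    "derive_thermal_traits",
    "head_size_pca",
    "prepare_covariates",
    "standardize_columns",
    "standardize_traits",
]
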