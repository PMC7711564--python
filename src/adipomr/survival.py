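"""Cox proportional-hazards associations and attenuation-based mediation.

Proteins are related to incident vascular events with Cox models (partial
likelihood, Efron handling of tied event times), adjusted for the same
covariate set as the observational protein analyses and excluding
participants with prevalent disease at baseline.  Mediation is quantified
as the percent attenuation of the exposure's log hazard ratio after
simultaneous adjustment for a mediator set; the per-set attenuations are
reported side by side and are not expected to be additive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .observational import Z95, AdjustmentSet, build_design

logger = logging.getLogger(__name__)

__all__ = [
    "HazardResult",
    "AttenuationResult",
    "fit_cox",
    "protein_cvd_assoc",
    "attenuation",
    "percent_attenuation",
]


def percent_attenuation(base_log_hr: float, adjusted_log_hr: float) -> float:
    """``100 * (base - adjusted) / base``: the attenuation definition itself."""
    if base_log_hr == 0:
        raise ValueError("percent attenuation undefined for a zero base log HR")
    return 100.0 * (base_log_hr - adjusted_log_hr) / base_log_hr


@dataclass(frozen=True)
class HazardResult:
    """Hazard ratio of an event per 1-SD higher protein."""

    trait: str
    log_hr: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    adjustment_set: str
    n: int
    n_events: int


@dataclass(frozen=True)
class AttenuationResult:
    """Percent attenuation of an exposure log HR after mediator adjustment.

    Positive values mean the adjusted log HR moved toward zero; the
    percentage is on the log-HR scale unless ``scale == 'hr'`` (in which
    case excess hazard ratios, HR - 1, are compared).
    """

    exposure: str
    mediator_set: str
    base_log_hr: float
    adjusted_log_hr: float
    percent_attenuation: float | None
    absolute_difference: float
    scale: str = "log_hr"


def fit_cox(
    data: pd.DataFrame,
    duration_col: str = "time_years",
    event_col: str = "event",
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Cox partial-likelihood fit (Efron ties) returning per-covariate results.

    Thin wrapper over a Newton-Raphson partial-likelihood maximizer; rows
    with nonpositive times are rejected and a dataset with no events is an
    error.  Returns a DataFrame indexed by covariate with columns
    ``log_hr, se, hr, ci_low, ci_high, p``.
    """
    cols = covariates or [c for c in data.columns if c not in (duration_col, event_col)]
    df = data[[duration_col, event_col] + cols].dropna()
    if (df[duration_col] <= 0).any():
        raise ValueError("all event/censoring times must be positive")
    if df[event_col].sum() < 1:
        raise ValueError("need at least one event")
    cph = CoxPHFitter()
    # tight Newton tolerance so small-sample fits agree with direct
    # partial-likelihood maximization to well below 1e-4
    cph.fit(df, duration_col=duration_col, event_col=event_col,
            fit_options={"precision": 1e-9})
    out = pd.DataFrame(
        {
            "log_hr": cph.params_,
            "se": cph.standard_errors_,
        }
    )
    out["hr"] = np.exp(out["log_hr"])
    out["ci_low"] = np.exp(out["log_hr"] - Z95 * out["se"])
    out["ci_high"] = np.exp(out["log_hr"] + Z95 * out["se"])
    out["p"] = cph.summary["p"].to_numpy()
    out.index.name = "covariate"
    return out


def _design_for_cox(data: pd.DataFrame, adjustment: AdjustmentSet | None) -> pd.DataFrame:
    X = build_design(data, adjustment)
    return X.drop(columns=["const"])  # the baseline hazard absorbs the constant


def protein_cvd_assoc(
    panel: pd.DataFrame,
    records: pd.DataFrame,
    data: pd.DataFrame,
    adjustment: AdjustmentSet | None = None,
    exclude_prevalent: bool = True,
    adjustment_name: str | None = None,
) -> pd.DataFrame:
    """One adjusted Cox fit per protein against incident events.

    ``panel`` must be z-scored; ``records`` carries ``time_years, event``
    and optionally ``prevalent_cvd`` (rows flagged prevalent are removed
    when ``exclude_prevalent``).  Per-protein failures are logged and
    skipped.  Uncorrected p-values are reported.
    """
    idx = panel.index.intersection(records.index)
    if exclude_prevalent and "prevalent_cvd" in records.columns:
        idx = idx[records.loc[idx, "prevalent_cvd"] == 0]
    adj_cols = _design_for_cox(data.loc[idx], adjustment)
    base = pd.concat([records.loc[idx, ["time_years", "event"]], adj_cols], axis=1)
    rows = []
    for prot in panel.columns:
        df = base.copy()
        df[prot] = panel.loc[idx, prot]
        try:
            fit = fit_cox(df)
        except Exception as exc:  # noqa: BLE001 - isolate per-trait failures
            logger.warning("protein_cvd_assoc: skipping %s (%s)", prot, exc)
            continue
        row = fit.loc[prot]
        rows.append(
            HazardResult(
                trait=prot,
                log_hr=float(row["log_hr"]),
                se=float(row["se"]),
                hr=float(row["hr"]),
                ci_low=float(row["ci_low"]),
                ci_high=float(row["ci_high"]),
                p=float(row["p"]),
                adjustment_set=adjustment_name
                or (adjustment.name if adjustment is not None else "unadjusted"),
                n=len(df),
                n_events=int(df["event"].sum()),
            ).__dict__
        )
    return pd.DataFrame(rows)


def attenuation(
    data: pd.DataFrame,
    records: pd.DataFrame,
    exposure: str,
    mediators: list[str],
    adjustment: AdjustmentSet | None = None,
    mediator_data: pd.DataFrame | None = None,
    mediator_set: str = "mediators",
    scale: str = "log_hr",
    exclude_prevalent: bool = True,
) -> AttenuationResult:
    """Percent attenuation of the exposure log HR after mediator adjustment.

    Fits the Cox model twice — exposure plus base adjustment, then with the
    mediators added — and reports ``100 * (base - adjusted) / base`` on the
    log-HR scale (or on the excess-HR scale with ``scale='hr'``).  When the
    base exposure coefficient is indistinguishable from zero (|z| < 0.1) no
    percentage is returned, only the absolute difference.
    """
    if exposure in mediators:
        raise ValueError("mediators must be disjoint from the exposure")
    if scale not in ("log_hr", "hr"):
        raise ValueError("scale must be 'log_hr' or 'hr'")
    med_src = mediator_data if mediator_data is not None else data
    idx = data.index.intersection(records.index).intersection(med_src.index)
    if exclude_prevalent and "prevalent_cvd" in records.columns:
        idx = idx[records.loc[idx, "prevalent_cvd"] == 0]
    adj_cols = _design_for_cox(data.loc[idx], adjustment)
    base_df = pd.concat([records.loc[idx, ["time_years", "event"]], adj_cols], axis=1)
    base_df[exposure] = data.loc[idx, exposure]
    base_fit = fit_cox(base_df)
    full_df = base_df.copy()
    for m in mediators:
        full_df[m] = med_src.loc[idx, m]
    full_fit = fit_cox(full_df)
    b0 = float(base_fit.loc[exposure, "log_hr"])
    b1 = float(full_fit.loc[exposure, "log_hr"])
    z0 = b0 / float(base_fit.loc[exposure, "se"])
    if scale == "hr":
        e0, e1 = np.exp(b0) - 1.0, np.exp(b1) - 1.0
    else:
        e0, e1 = b0, b1
    pct = None
    if abs(z0) >= 0.1 and e0 != 0:
        pct = float(100.0 * (e0 - e1) / e0)
    else:
        logger.warning(
            "attenuation: base exposure log HR indistinguishable from zero; "
            "reporting absolute difference only"
        )
    return AttenuationResult(
        exposure=exposure,
        mediator_set=mediator_set,
        base_log_hr=b0,
        adjusted_log_hr=b1,
        percent_attenuation=pct,
        absolute_difference=float(e0 - e1),
        scale=scale,
    )
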