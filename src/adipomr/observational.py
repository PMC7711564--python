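"""Covariate-adjusted linear associations of adiposity with each protein.

The observational arm of the triangulation: each standardized protein is
regressed on the standardized exposure with a named covariate adjustment
set, and the resulting panel of p-values is controlled at a 5 % false
discovery rate with the Benjamini-Hochberg step-up procedure.  An
ordered-p-value ("Renyi-style") band view of the panel is also provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AssocResult",
    "AdjustmentSet",
    "OBSERVATIONAL_ADJUSTMENT",
    "GENETIC_ADJUSTMENT",
    "standardize",
    "exclude_low_detect",
    "build_design",
    "adjusted_linear_assoc",
    "assoc_panel",
    "bh_fdr",
    "renyi_band",
]

Z95 = 1.959964  # standard-normal 97.5 % quantile


@dataclass(frozen=True)
class AssocResult:
    """One regression estimate: SD difference in outcome per 1-SD exposure."""

    trait: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    adjustment_set: str
    n: int
    p_adjusted: float | None = None
    significant_fdr: bool | None = None


@dataclass(frozen=True)
class AdjustmentSet:
    """A reproducible named covariate set.

    ``continuous`` columns enter linearly (append ``^2`` to a name for a
    quadratic term, e.g. ``"age^2"``); ``categorical`` maps a column name to
    its reference level, expanded to treatment-coded indicators.
    """

    name: str
    continuous: tuple[str, ...] = ()
    categorical: dict[str, object] = field(default_factory=dict)


# covariate sets used by the default pipeline; simulator column names
OBSERVATIONAL_ADJUSTMENT = AdjustmentSet(
    name="observational",
    continuous=("age", "age^2", "sbp", "fasting_time"),
    categorical={
        "sex": 0,
        "region": 0,
        "education": 0,
        "income": 0,
        "alcohol": 0,
        "self_rated_health": 0,
        "diabetes": 0,
        "statin": 0,
        "kidney_disease": 0,
    },
)

# the two-stage (genetic) analyses adjust for a slimmer baseline set
GENETIC_ADJUSTMENT = AdjustmentSet(
    name="genetic",
    continuous=("age", "age^2"),
    categorical={"sex": 0, "region": 0, "education": 0, "smoking": 0, "alcohol": 0},
)


def standardize(values, reference_sd: float | None = None) -> np.ndarray:
    """Mean-centre and scale to unit SD (or to an external reference SD).

    With ``reference_sd`` given, values are centred and divided by that SD —
    the convention for expressing effects per 1-SD of the exposure measured
    in a larger reference cohort.  Idempotent without a reference SD.
    """
    x = np.asarray(values, dtype=float)
    sd = np.std(x, ddof=1)
    if reference_sd is not None:
        if reference_sd <= 0:
            raise ValueError("reference_sd must be positive")
        return (x - x.mean()) / reference_sd
    if sd == 0:
        raise ValueError("cannot standardize a constant vector without reference_sd")
    return (x - x.mean()) / sd


def exclude_low_detect(
    panel: pd.DataFrame,
    lod_flags: pd.DataFrame,
    max_below_frac: float = 0.99,
) -> tuple[list[str], pd.DataFrame]:
    """Drop proteins with a below-LOD fraction exceeding ``max_below_frac``.

    Returns the retained protein names and an exclusion log with the
    offending fractions (strictly greater than the threshold is excluded, so
    the default keeps proteins with exactly 99 % below LOD).
    """
    if list(panel.columns) != list(lod_flags.columns):
        raise ValueError("lod_flags columns must align with the panel")
    frac = lod_flags.mean(axis=0)
    drop = frac > max_below_frac
    log = pd.DataFrame(
        {"protein": frac.index[drop], "below_lod_frac": frac[drop].to_numpy()}
    )
    log["reason"] = f"below-LOD fraction > {max_below_frac}"
    if len(log):
        logger.info("exclude_low_detect: dropped %s", list(log["protein"]))
    return [c for c in panel.columns if not drop[c]], log.reset_index(drop=True)


def build_design(data: pd.DataFrame, adjustment: AdjustmentSet | None) -> pd.DataFrame:
    """Expand an adjustment set into a design matrix (constant included)."""
    cols = {"const": np.ones(len(data))}
    if adjustment is not None:
        for name in adjustment.continuous:
            if name.endswith("^2"):
                base = name[:-2]
                cols[name] = data[base].to_numpy(dtype=float) ** 2
            else:
                cols[name] = data[name].to_numpy(dtype=float)
        for name, ref in adjustment.categorical.items():
            levels = [lv for lv in pd.unique(data[name]) if lv != ref]
            for lv in sorted(levels, key=str):
                cols[f"{name}[{lv}]"] = (data[name] == lv).astype(float).to_numpy()
    return pd.DataFrame(cols, index=data.index)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify offending columns via pivoted QR: small trailing diagonals
        from scipy.linalg import qr

        _, R, piv = qr(arr, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        bad = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] < tol]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def adjusted_linear_assoc(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    adjustment: AdjustmentSet | None = None,
) -> AssocResult:
    """OLS coefficient of a (z-scored) outcome on a (z-scored) exposure.

    Complete-case analysis: rows with any missing value among the outcome,
    exposure or adjustment columns are dropped and the count logged.
    Categorical covariates are expanded with their stated reference levels.
    """
    needed = [outcome, exposure]
    if adjustment is not None:
        needed += [c[:-2] if c.endswith("^2") else c for c in adjustment.continuous]
        needed += list(adjustment.categorical)
    sub = data[list(dict.fromkeys(needed))].dropna()
    n_dropped = len(data) - len(sub)
    if n_dropped:
        logger.info("adjusted_linear_assoc(%s): dropped %d incomplete rows", outcome, n_dropped)
    X = build_design(sub, adjustment)
    if len(sub) < X.shape[1] + 1 + 10:
        raise ValueError("too few complete cases for the requested adjustment")
    X.insert(1, exposure, sub[exposure].to_numpy(dtype=float))
    _check_rank(X)
    fit = sm.OLS(sub[outcome].to_numpy(dtype=float), X.to_numpy(dtype=float)).fit()
    beta, se = float(fit.params[1]), float(fit.bse[1])
    return AssocResult(
        trait=outcome,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        p=float(fit.pvalues[1]),
        adjustment_set=adjustment.name if adjustment is not None else "unadjusted",
        n=len(sub),
    )


def assoc_panel(
    data: pd.DataFrame,
    proteins: list[str],
    exposure: str,
    adjustment: AdjustmentSet | None = None,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Per-protein adjusted associations with BH-FDR control across the panel.

    A failure in one protein's model is logged and skipped rather than
    aborting the panel.
    """
    rows = []
    for prot in proteins:
        try:
            res = adjusted_linear_assoc(data, prot, exposure, adjustment)
        except Exception as exc:  # noqa: BLE001 - isolate per-trait failures
            logger.warning("assoc_panel: skipping %s (%s)", prot, exc)
            continue
        rows.append(res.__dict__)
    out = pd.DataFrame(rows)
    if len(out):
        p_adj, flags = bh_fdr(out["p"].to_numpy(), fdr_q)
        out["p_adjusted"] = p_adj
        out["significant_fdr"] = flags
    return out


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and significance flags."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    flags, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, flags


def renyi_band(
    pvalues, q: float = 0.05, band: str = "bh", alpha: float = 0.05
) -> tuple[pd.DataFrame, int]:
    """Ordered -log10 p-values against their uniform expectation with a band.

    ``band='bh'`` (default) draws the Benjamini-Hochberg step-up line
    ``q * i / m`` and counts traits up to the largest ordered p-value under
    the line — an approximate stand-in for a formal Renyi-plot band, and by
    construction a superset of the BH-significant set at the same ``q``.
    ``band='pointwise'`` uses a flat per-test threshold ``alpha``.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m < 2:
        raise ValueError("need at least two p-values")
    order = np.argsort(p)
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    expected = ranks / (m + 1.0)
    if band == "bh":
        threshold = q * ranks / m
        under = np.nonzero(p_sorted <= threshold)[0]
        n_surpass = int(under[-1] + 1) if under.size else 0
        surpass = ranks <= n_surpass
    elif band == "pointwise":
        threshold = np.full(m, alpha)
        surpass = p_sorted <= alpha
        n_surpass = int(surpass.sum())
    else:
        raise ValueError("band must be 'bh' or 'pointwise'")
    with np.errstate(divide="ignore"):
        df = pd.DataFrame(
            {
                "rank": ranks,
                "p": p_sorted,
                "neglog10_p": -np.log10(np.maximum(p_sorted, 1e-300)),
                "expected_neglog10_p": -np.log10(expected),
                "threshold": threshold,
                "surpass": surpass,
                "index": order,
            }
        )
    return df, n_surpass
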