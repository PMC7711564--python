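"""Mendelian randomization estimators and sensitivity analyses.

The primary estimator is split-sample two-stage least squares (2SLS) with a
genetic score instrument: the exposure is regressed on the score (plus
covariates) in the large genotyped sample, and the outcome is regressed on
the predicted exposure (plus the same covariates) in the proteomics
subcohort.  Summary-statistic estimators — Wald ratio, inverse-variance
weighted (IVW), MR-Egger and the weighted median — plus the Steiger
directionality test and a two-estimate Cochran Q are provided for
sensitivity analysis, along with a cis-window variant exclusion filter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .observational import Z95, AdjustmentSet, build_design

logger = logging.getLogger(__name__)

__all__ = [
    "MRResult",
    "SummaryAssoc",
    "HeterogeneityResult",
    "two_stage_least_squares",
    "tsls_panel",
    "rescale_per_exposure_sd",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "steiger_direction",
    "cochran_q_two_estimates",
    "exclude_nearby_variants",
    "harmonize_summary",
]


@dataclass(frozen=True)
class MRResult:
    """One causal estimate, in SD outcome per SD (or unit) exposure."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_variants: int
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    n_stage1: int | None = None
    n_stage2: int | None = None
    f_stage1: float | None = None


@dataclass(frozen=True)
class SummaryAssoc:
    """Per-variant harmonized exposure and outcome summary statistics."""

    id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    effect_allele: str = "A"

    def __post_init__(self):
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValueError(f"{self.id}: standard errors must be positive")


@dataclass(frozen=True)
class HeterogeneityResult:
    q_statistic: float
    df: int
    p: float


def _result(method: str, est: float, se: float, n_variants: int, **kw) -> MRResult:
    z = est / se if se > 0 else np.inf
    return MRResult(
        method=method,
        estimate=float(est),
        se=float(se),
        ci_low=float(est - Z95 * se),
        ci_high=float(est + Z95 * se),
        p=float(2 * stats.norm.sf(abs(z))),
        n_variants=n_variants,
        **kw,
    )


def two_stage_least_squares(
    data_stage1: pd.DataFrame,
    score_col: str,
    exposure_col: str,
    data_stage2: pd.DataFrame,
    outcome_col: str,
    adjustment: AdjustmentSet | None = None,
    n_boot: int = 0,
    seed: int = 0,
) -> MRResult:
    """Split-sample 2SLS of an outcome on a score-instrumented exposure.

    Stage 1 regresses the exposure on the score and covariates in
    ``data_stage1``; stage 2 applies the stage-1 coefficients to
    ``data_stage2`` (which may be a subset of stage 1) to form predicted
    exposures and regresses the outcome on them with the same adjustment.
    The reported SE is the stage-2 model-based SE, ignoring first-stage
    sampling error — appropriate when the stage-1 sample dwarfs stage 2; set
    ``n_boot > 0`` for a bootstrap SE resampling both stages.
    A first-stage F below 10 triggers a weak-instrument warning.
    """
    X1 = build_design(data_stage1, adjustment)
    X1.insert(1, score_col, data_stage1[score_col].to_numpy(dtype=float))
    y1 = data_stage1[exposure_col].to_numpy(dtype=float)
    coef1, f_stat = _ols_with_partial_f(X1.to_numpy(dtype=float), y1, term_index=1)
    if f_stat < 10:
        warnings.warn(
            f"weak instrument: first-stage F = {f_stat:.2f} < 10", UserWarning, stacklevel=2
        )
    X2_for_pred = build_design(data_stage2, adjustment)
    X2_for_pred.insert(1, score_col, data_stage2[score_col].to_numpy(dtype=float))
    xhat = X2_for_pred.to_numpy(dtype=float) @ coef1
    X2 = build_design(data_stage2, adjustment)
    X2.insert(1, "_xhat", xhat)
    y2 = data_stage2[outcome_col].to_numpy(dtype=float)
    est, se = _ols_coef_se(X2.to_numpy(dtype=float), y2, term_index=1)
    if n_boot > 0:
        se = _tsls_bootstrap_se(
            data_stage1, score_col, exposure_col, data_stage2, outcome_col, adjustment, n_boot, seed
        )
    return _result(
        "tsls",
        est,
        se,
        n_variants=1,
        n_stage1=len(data_stage1),
        n_stage2=len(data_stage2),
        f_stage1=float(f_stat),
    )


def tsls_panel(
    data_stage1: pd.DataFrame,
    score_col: str,
    exposure_col: str,
    data_stage2: pd.DataFrame,
    panel: pd.DataFrame,
    adjustment: AdjustmentSet | None = None,
) -> dict[str, MRResult]:
    """Split-sample 2SLS of every panel column on the same instrumented exposure.

    Identical to calling :func:`two_stage_least_squares` per protein, but the
    first stage is fitted once and reused, which matters when stage 1 is a
    75k-person sample and the panel holds ~90 proteins.
    """
    X1 = build_design(data_stage1, adjustment)
    X1.insert(1, score_col, data_stage1[score_col].to_numpy(dtype=float))
    y1 = data_stage1[exposure_col].to_numpy(dtype=float)
    coef1, f_stat = _ols_with_partial_f(X1.to_numpy(dtype=float), y1, term_index=1)
    if f_stat < 10:
        warnings.warn(
            f"weak instrument: first-stage F = {f_stat:.2f} < 10", UserWarning, stacklevel=2
        )
    X2_for_pred = build_design(data_stage2, adjustment)
    X2_for_pred.insert(1, score_col, data_stage2[score_col].to_numpy(dtype=float))
    xhat = X2_for_pred.to_numpy(dtype=float) @ coef1
    X2 = build_design(data_stage2, adjustment)
    X2.insert(1, "_xhat", xhat)
    X2_arr = X2.to_numpy(dtype=float)
    out: dict[str, MRResult] = {}
    for prot in panel.columns:
        est, se = _ols_coef_se(X2_arr, panel[prot].to_numpy(dtype=float), term_index=1)
        out[prot] = _result(
            "tsls",
            est,
            se,
            n_variants=1,
            n_stage1=len(data_stage1),
            n_stage2=len(data_stage2),
            f_stage1=float(f_stat),
        )
    return out


def _ols_coef_se(X: np.ndarray, y: np.ndarray, term_index: int) -> tuple[float, float]:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[term_index, term_index])
    return float(coef[term_index]), float(se)


def _ols_with_partial_f(X: np.ndarray, y: np.ndarray, term_index: int):
    coef, se = _ols_coef_se(X, y, term_index)
    t = coef / se if se > 0 else np.inf
    full_coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return full_coef, t * t


def _tsls_bootstrap_se(
    data1, score_col, exp_col, data2, out_col, adjustment, n_boot, seed
) -> float:
    rng = np.random.default_rng(seed)
    ests = []
    for _ in range(n_boot):
        idx1 = rng.integers(0, len(data1), len(data1))
        idx2 = rng.integers(0, len(data2), len(data2))
        try:
            res = two_stage_least_squares(
                data1.iloc[idx1], score_col, exp_col, data2.iloc[idx2], out_col, adjustment
            )
        except Exception:  # noqa: BLE001 - degenerate resample
            continue
        ests.append(res.estimate)
    return float(np.std(ests, ddof=1))


def rescale_per_exposure_sd(result: MRResult, exposure_sd: float) -> MRResult:
    """Convert a per-unit-exposure estimate to per-SD-exposure (multiply by SD)."""
    if exposure_sd <= 0:
        raise ValueError("exposure_sd must be positive")
    s = float(exposure_sd)
    return replace(
        result,
        estimate=result.estimate * s,
        se=result.se * s,
        ci_low=result.ci_low * s,
        ci_high=result.ci_high * s,
    )


def wald_ratio(assoc: SummaryAssoc) -> MRResult:
    """Single-variant ratio estimate with first-order delta-method SE."""
    if assoc.beta_exposure == 0:
        raise ValueError("beta_exposure must be nonzero for a Wald ratio")
    est = assoc.beta_outcome / assoc.beta_exposure
    se = assoc.se_outcome / abs(assoc.beta_exposure)
    return _result("wald", est, se, n_variants=1)


def _ratios_and_weights(assocs: list[SummaryAssoc]):
    bx = np.array([a.beta_exposure for a in assocs])
    sy = np.array([a.se_outcome for a in assocs])
    by = np.array([a.beta_outcome for a in assocs])
    if np.any(bx == 0):
        raise ValueError("all exposure betas must be nonzero")
    ratios = by / bx
    se_ratio = sy / np.abs(bx)
    return ratios, 1.0 / se_ratio**2


def ivw(assocs: list[SummaryAssoc], random_effects: bool = False) -> MRResult:
    """Fixed-effect inverse-variance-weighted mean of per-variant Wald ratios.

    With ``random_effects=True`` the SE is inflated multiplicatively by
    sqrt(Q/df) when Q exceeds its degrees of freedom.
    """
    if len(assocs) < 1:
        raise ValueError("need at least one harmonized variant")
    ratios, w = _ratios_and_weights(assocs)
    est = float(np.sum(w * ratios) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    if random_effects and len(assocs) > 1:
        q = float(np.sum(w * (ratios - est) ** 2))
        df = len(assocs) - 1
        se *= max(1.0, np.sqrt(q / df))
    return _result("ivw", est, se, n_variants=len(assocs))


def mr_egger(assocs: list[SummaryAssoc]) -> MRResult:
    """Weighted regression of outcome betas on exposure betas with intercept.

    Exposure betas are oriented positive before fitting (the conventional
    orientation); weights are inverse outcome variances.  The slope is the
    causal estimate and the intercept the average directional pleiotropy.
    SEs use a multiplicative residual scale bounded below by 1.
    """
    if len(assocs) < 3:
        raise ValueError("MR-Egger needs at least 3 variants")
    bx = np.array([a.beta_exposure for a in assocs])
    by = np.array([a.beta_outcome for a in assocs])
    sy = np.array([a.se_outcome for a in assocs])
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtwx_inv = np.linalg.pinv(X.T @ WX)
    coef = xtwx_inv @ (WX.T @ by)
    resid = by - X @ coef
    df = len(assocs) - 2
    scale = max(float(resid @ (w * resid) / df), 1.0)
    cov = xtwx_inv * scale
    slope, slope_se = float(coef[1]), float(np.sqrt(cov[1, 1]))
    icpt, icpt_se = float(coef[0]), float(np.sqrt(cov[0, 0]))
    icpt_p = float(2 * stats.t.sf(abs(icpt / icpt_se), df)) if icpt_se > 0 else 0.0
    return _result(
        "egger",
        slope,
        slope_se,
        n_variants=len(assocs),
        egger_intercept=icpt,
        intercept_se=icpt_se,
        intercept_p=icpt_p,
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def weighted_median(
    assocs: list[SummaryAssoc], n_boot: int = 1000, seed: int = 0
) -> MRResult:
    """Median of the inverse-variance-weighted distribution of Wald ratios.

    Consistent when valid instruments carry more than half of the total
    weight.  The point estimate interpolates the 50 % crossing of the
    cumulative weights; the SE comes from a parametric bootstrap of the
    per-variant betas (``n_boot`` replicates, seeded).
    """
    if len(assocs) < 3:
        raise ValueError("weighted median needs at least 3 variants")
    ratios, w = _ratios_and_weights(assocs)
    est = _weighted_median_point(ratios, w)
    rng = np.random.default_rng(seed)
    bx = np.array([a.beta_exposure for a in assocs])
    by = np.array([a.beta_outcome for a in assocs])
    sx = np.array([a.se_exposure for a in assocs])
    sy = np.array([a.se_outcome for a in assocs])
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        bx_b[bx_b == 0] = np.finfo(float).tiny
        r_b = by_b / bx_b
        w_b = (np.abs(bx_b) / sy) ** 2
        boots[b] = _weighted_median_point(r_b, w_b)
    se = float(np.std(boots, ddof=1))
    return _result("weighted_median", est, se, n_variants=len(assocs))


def steiger_direction(
    r2_exposure: float, n_exposure: int, r2_outcome: float, n_outcome: int
) -> dict:
    """Orient causality by comparing instrument variance explained.

    Orientation is "exposure->outcome" iff the instrument explains more of
    the exposure than of the outcome; the z test compares Fisher-transformed
    correlations across (possibly unequal) sample sizes.
    """
    for r2 in (r2_exposure, r2_outcome):
        if not 0 <= r2 < 1:
            raise ValueError("r2 values must lie in [0, 1)")
    r_exp, r_out = np.sqrt(r2_exposure), np.sqrt(r2_outcome)
    z = (np.arctanh(r_exp) - np.arctanh(r_out)) / np.sqrt(
        1.0 / (n_exposure - 3) + 1.0 / (n_outcome - 3)
    )
    return {
        "orientation": "exposure->outcome" if r2_exposure > r2_outcome else "outcome->exposure",
        "z": float(z),
        "p": float(2 * stats.norm.sf(abs(z))),
    }


def cochran_q_two_estimates(
    beta1: float, se1: float, beta2: float, se2: float
) -> HeterogeneityResult:
    """Cochran Q for the difference between two estimates (df = 1)."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    w = np.array([1.0 / se1**2, 1.0 / se2**2])
    b = np.array([beta1, beta2])
    pooled = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - pooled) ** 2))
    return HeterogeneityResult(q_statistic=q, df=1, p=float(stats.chi2.sf(q, 1)))


def exclude_nearby_variants(
    variants: pd.DataFrame,
    gene_regions: pd.DataFrame,
    window: float = 1_000_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop variants within ``window`` bp of any listed gene span.

    ``gene_regions`` is BED-like (columns ``chrom, start, end`` and
    optionally ``name``; 0-based half-open, converted internally to
    1-based).  Distance is measured from the variant position to the nearest
    span edge (0 inside a span); variants with distance <= window to any
    span on the same chromosome are excluded.  A variant exactly
    ``window + 1`` bp away is retained.
    """
    v_chroms = set(str(c) for c in variants["CHR"].unique())
    g_chroms = set(str(c) for c in gene_regions["chrom"].unique()) if len(gene_regions) else set()
    if g_chroms:
        v_pref = {c.startswith("chr") for c in v_chroms}
        g_pref = {c.startswith("chr") for c in g_chroms}
        if v_pref != g_pref:
            raise ValueError(
                "chromosome naming mismatch between variants and gene regions "
                "(mixed 'chr' prefixes)"
            )
    keep = np.ones(len(variants), dtype=bool)
    reasons = {}
    for g in gene_regions.itertuples(index=False):
        start_1b, end_1b = int(g.start) + 1, int(g.end)
        on_chrom = variants["CHR"].astype(str) == str(g.chrom)
        pos = variants["POS"].to_numpy()
        dist = np.where(
            (pos >= start_1b) & (pos <= end_1b),
            0,
            np.minimum(np.abs(pos - start_1b), np.abs(pos - end_1b)),
        )
        hit = on_chrom.to_numpy() & (dist <= window)
        for i in np.nonzero(hit)[0]:
            name = getattr(g, "name", f"{g.chrom}:{g.start}-{g.end}")
            reasons.setdefault(i, f"within {int(window)} bp of {name}")
        keep &= ~hit
    log = pd.DataFrame(
        {
            "SNP": [variants["SNP"].iloc[i] for i in sorted(reasons)],
            "reason": [reasons[i] for i in sorted(reasons)],
        }
    )
    if len(log):
        logger.info("exclude_nearby_variants: dropped %d variants", len(log))
    return variants.loc[keep].reset_index(drop=True), log


def harmonize_summary(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    palindromic_eaf: tuple[float, float] = (0.42, 0.58),
) -> list[SummaryAssoc]:
    """Harmonize two summary-statistic tables into per-variant pairs.

    Tables need columns ``SNP, EA, OA, BETA, SE`` (and ``EAF`` in the
    exposure table for the palindromic filter).  Matching is on id plus
    alleles; a swapped effect/other allele flips the outcome beta sign;
    palindromic variants with EAF inside ``palindromic_eaf`` are dropped.
    """
    from .score import _PALINDROMIC

    out = outcome_stats.set_index("SNP")
    assocs = []
    lo, hi = palindromic_eaf
    for e in exposure_stats.itertuples(index=False):
        if e.SNP not in out.index:
            continue
        o = out.loc[e.SNP]
        if (str(e.EA), str(e.OA)) in _PALINDROMIC and hasattr(e, "EAF") and lo < e.EAF < hi:
            logger.info("harmonize_summary: dropped palindromic %s (EAF %.2f)", e.SNP, e.EAF)
            continue
        if o["EA"] == e.EA and o["OA"] == e.OA:
            b_out = o["BETA"]
        elif o["EA"] == e.OA and o["OA"] == e.EA:
            b_out = -o["BETA"]
        else:
            logger.info("harmonize_summary: allele mismatch for %s", e.SNP)
            continue
        assocs.append(
            SummaryAssoc(
                id=e.SNP,
                beta_exposure=float(e.BETA),
                se_exposure=float(e.SE),
                beta_outcome=float(b_out),
                se_outcome=float(o["SE"]),
                effect_allele=str(e.EA),
            )
        )
    return assocs
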