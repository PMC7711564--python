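"""Inverse-variance meta-analysis and approximate-Bayes-factor colocalization.

The meta layer pools externally supplied study estimates (betas, log RRs or
log HRs, with an SE or a confidence interval) with in-pipeline estimates:
fixed-effect pooling by default, with a DerSimonian-Laird random-effects
model emitted alongside.  Published relative risks and hazard ratios are
pooled together on the log scale, which merges effect measures — flagged in
the output rather than hidden.

Colocalization is the single-causal-variant approximate-Bayes-factor
method: per-variant Wakefield ABFs for each trait are combined into the
five hypothesis posteriors PP0..PP4 (no association / trait-1 only /
trait-2 only / two distinct causal variants / one shared causal variant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .observational import Z95

__all__ = [
    "StudyEstimate",
    "MetaResult",
    "ColocResult",
    "se_from_ci",
    "meta_fixed",
    "meta_random",
    "coloc_abf",
]


@dataclass(frozen=True)
class StudyEstimate:
    """One study's estimate on a declared scale ('linear' or 'log').

    Exactly one of ``se`` or ``(ci_low, ci_high)`` must be provided; a CI is
    converted with :func:`se_from_ci` at the stated ``level``.  For ratio
    measures (RR/HR/OR) pass the ratio CI with ``scale='log'``; ``beta``
    must already be the log ratio.
    """

    study: str
    beta: float
    scale: str = "linear"
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    level: float = 0.95

    def __post_init__(self):
        if self.scale not in ("linear", "log"):
            raise ValueError("scale must be 'linear' or 'log'")
        has_ci = self.ci_low is not None and self.ci_high is not None
        if (self.se is None) == (not has_ci):
            raise ValueError("provide exactly one of se or (ci_low, ci_high)")
        if not 0 < self.level < 1:
            raise ValueError("level must lie in (0, 1)")

    def resolved_se(self) -> float:
        if self.se is not None:
            return float(self.se)
        return se_from_ci(self.ci_low, self.ci_high, self.level, self.scale)


@dataclass(frozen=True)
class MetaResult:
    pooled: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    model: str  # 'fixed' | 'random'
    q: float
    df: int
    i2: float  # percent
    tau2: float
    k: int


@dataclass(frozen=True)
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_variants: int
    p1: float
    p2: float
    p12: float

    def __post_init__(self):
        total = self.pp0 + self.pp1 + self.pp2 + self.pp3 + self.pp4
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posteriors must sum to 1 (got {total})")


def se_from_ci(low: float, high: float, level: float = 0.95, scale: str = "linear") -> float:
    """Recover a standard error from a symmetric confidence interval.

    ``linear``: (high - low) / (2 z); ``log``: (ln high - ln low) / (2 z)
    for ratio-scale intervals, where z is the standard-normal quantile at
    (1 + level) / 2.
    """
    if high <= low:
        raise ValueError("need high > low")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    if scale == "log":
        if low <= 0:
            raise ValueError("log-scale bounds must be positive")
        return float((np.log(high) - np.log(low)) / (2.0 * z))
    if scale != "linear":
        raise ValueError("scale must be 'linear' or 'log'")
    return float((high - low) / (2.0 * z))


def _extract(estimates: list[StudyEstimate]) -> tuple[np.ndarray, np.ndarray]:
    if len(estimates) == 0:
        raise ValueError("need at least one estimate")
    scales = {e.scale for e in estimates}
    if len(scales) > 1:
        raise ValueError(f"mixed scales in meta-analysis: {sorted(scales)}")
    b = np.array([e.beta for e in estimates], dtype=float)
    s = np.array([e.resolved_se() for e in estimates], dtype=float)
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    return b, s


def _finish(pooled: float, se: float, model: str, q: float, df: int, tau2: float, k: int):
    i2 = max(0.0, 100.0 * (q - df) / q) if q > 0 and df > 0 else 0.0
    z = pooled / se
    return MetaResult(
        pooled=float(pooled),
        se=float(se),
        ci_low=float(pooled - Z95 * se),
        ci_high=float(pooled + Z95 * se),
        p=float(2 * stats.norm.sf(abs(z))),
        model=model,
        q=float(q),
        df=int(df),
        i2=float(i2),
        tau2=float(tau2),
        k=k,
    )


def meta_fixed(estimates: list[StudyEstimate]) -> MetaResult:
    """Fixed-effect inverse-variance pooled estimate with Q and I^2."""
    b, s = _extract(estimates)
    w = 1.0 / s**2
    pooled = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - pooled) ** 2))
    return _finish(pooled, np.sqrt(1.0 / np.sum(w)), "fixed", q, len(b) - 1, 0.0, len(b))


def meta_random(estimates: list[StudyEstimate]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling (reduces to fixed when Q <= df)."""
    if len(estimates) < 2:
        raise ValueError("random-effects pooling needs at least two estimates")
    b, s = _extract(estimates)
    w = 1.0 / s**2
    pooled_f = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - pooled_f) ** 2))
    df = len(b) - 1
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    w_star = 1.0 / (s**2 + tau2)
    pooled = np.sum(w_star * b) / np.sum(w_star)
    return _finish(pooled, np.sqrt(1.0 / np.sum(w_star)), "random", q, df, tau2, len(b))


def _log_abf(beta: np.ndarray, se: np.ndarray, w_prior: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor per variant (H1 vs H0)."""
    v = se**2
    z2 = (beta / se) ** 2
    r = w_prior / (v + w_prior)
    return 0.5 * (np.log1p(-r) + z2 * r)


def coloc_abf(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    w1: float = 0.15**2,
    w2: float = 0.15**2,
) -> ColocResult:
    """Single-causal-variant colocalization of two traits at a locus.

    Each table needs columns ``SNP, BETA, SE``; variants are intersected on
    id.  ``w1``/``w2`` are the prior effect variances (0.15^2 suits
    quantitative traits; use 0.2^2 for log-odds).  Priors ``p1, p2`` are the
    per-variant probabilities of association with each trait alone, ``p12``
    with both.  Returns the five hypothesis posteriors.
    """
    merged = stats1.merge(stats2, on="SNP", suffixes=("_1", "_2"))
    if len(merged) == 0:
        raise ValueError("no shared variants between the two traits")
    l1 = _log_abf(merged["BETA_1"].to_numpy(), merged["SE_1"].to_numpy(), w1)
    l2 = _log_abf(merged["BETA_2"].to_numpy(), merged["SE_2"].to_numpy(), w2)
    lsum_1 = logsumexp(l1)
    lsum_2 = logsumexp(l2)
    lsum_12 = logsumexp(l1 + l2)
    # sum over ordered pairs i != j of l1_i + l2_j (nonnegative by construction)
    lsum_cross, sign = logsumexp(
        [lsum_1 + lsum_2, lsum_12], b=[1.0, -1.0], return_sign=True
    )
    if sign <= 0:
        lsum_cross = -np.inf
    lh = np.array(
        [
            0.0,
            np.log(p1) + lsum_1,
            np.log(p2) + lsum_2,
            np.log(p1) + np.log(p2) + lsum_cross,
            np.log(p12) + lsum_12,
        ]
    )
    pp = np.exp(lh - logsumexp(lh))
    pp = pp / pp.sum()
    return ColocResult(
        pp0=float(pp[0]),
        pp1=float(pp[1]),
        pp2=float(pp[2]),
        pp3=float(pp[3]),
        pp4=float(pp[4]),
        n_variants=len(merged),
        p1=p1,
        p2=p2,
        p12=p12,
    )
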