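"""Weighted and unweighted allele scores and instrument-strength diagnostics.

A genetic score is built from a GWAS summary-statistic weight table
(columns ``SNP, CHR, POS, EA, OA, EAF, BETA, SE``) by summing effect-allele
dosages, optionally weighted by the external per-allele effect sizes.
Instrument strength is quantified by the incremental (partial) R^2 of the
score on the exposure after covariate adjustment and the corresponding
partial F statistic; for a single score with no covariates these satisfy
F = r2 (n - 2) / (1 - r2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "InstrumentDiagnostics",
    "read_weight_table",
    "filter_by_maf",
    "harmonize_weights",
    "compute_score",
    "instrument_strength",
]

WEIGHT_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE"]

# strand-ambiguous allele pairs: complementary on opposite strands
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class VariantRecord:
    """One instrument variant with its external weight."""

    id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    weight_beta: float
    weight_se: float
    gene_proximity: float | None = None

    def __post_init__(self):
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.id}: effect and other allele are identical")
        if not 0 <= self.eaf <= 1:
            raise ValueError(f"{self.id}: EAF must lie in [0, 1]")


@dataclass(frozen=True)
class InstrumentDiagnostics:
    """Instrument strength of a single genetic score."""

    f_statistic: float
    r2: float
    n: int

    def __post_init__(self):
        if self.f_statistic < 0 or not 0 <= self.r2 <= 1:
            raise ValueError("invalid diagnostics: need F >= 0 and r2 in [0, 1]")


def read_weight_table(path: str | Path) -> pd.DataFrame:
    """Read a GWAS summary-statistic weight table (TSV with header)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weight table missing columns: {missing}")
    return df


def filter_by_maf(
    variants: pd.DataFrame, threshold: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop variants whose minor allele frequency falls below ``threshold``.

    Returns the retained table and an exclusion log (one row per dropped
    variant with its MAF and reason).  Idempotent: re-filtering the retained
    set removes nothing.
    """
    if not 0 < threshold < 0.5:
        raise ValueError("threshold must lie in (0, 0.5)")
    if len(variants) == 0:
        logger.warning("filter_by_maf called on an empty variant table")
        return variants.copy(), pd.DataFrame(columns=["SNP", "maf", "reason"])
    maf = np.minimum(variants["EAF"], 1.0 - variants["EAF"])
    keep = maf >= threshold
    excluded = pd.DataFrame(
        {
            "SNP": variants.loc[~keep, "SNP"],
            "maf": maf[~keep],
            "reason": f"MAF < {threshold}",
        }
    )
    if len(excluded):
        logger.info("filter_by_maf: excluded %d of %d variants", len(excluded), len(variants))
    return variants.loc[keep].reset_index(drop=True), excluded.reset_index(drop=True)


def harmonize_weights(
    genotype_variants: pd.DataFrame,
    weights: pd.DataFrame,
    palindromic_maf: float = 0.42,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align a weight table to the allele coding of a genotype file.

    Matches on variant id.  When the weight table's effect allele equals the
    genotype file's other allele (and vice versa) the weight sign is flipped;
    palindromic (A/T, C/G) variants with MAF above ``palindromic_maf`` are
    dropped because their strand cannot be resolved; variants missing from
    the weight table are dropped with a log entry (no proxy lookup).

    Returns the harmonized weight table, aligned to (a subset of)
    ``genotype_variants`` order, plus an exclusion log.
    """
    w = weights.set_index("SNP")
    rows, dropped = [], []
    for g in genotype_variants.itertuples(index=False):
        if g.SNP not in w.index:
            dropped.append((g.SNP, "missing from weight table"))
            continue
        rec = w.loc[g.SNP]
        pair = (str(g.EA), str(g.OA))
        if pair in _PALINDROMIC:
            maf = min(g.EAF, 1 - g.EAF)
            if maf > palindromic_maf:
                dropped.append((g.SNP, f"palindromic with MAF {maf:.3f} > {palindromic_maf}"))
                continue
        if rec["EA"] == g.EA and rec["OA"] == g.OA:
            beta = rec["BETA"]
        elif rec["EA"] == g.OA and rec["OA"] == g.EA:
            beta = -rec["BETA"]
        else:
            dropped.append((g.SNP, "allele mismatch"))
            continue
        rows.append((g.SNP, g.CHR, g.POS, g.EA, g.OA, g.EAF, beta, rec["SE"]))
    log = pd.DataFrame(dropped, columns=["SNP", "reason"])
    if len(log):
        logger.info("harmonize_weights: dropped %d variants", len(log))
    return pd.DataFrame(rows, columns=WEIGHT_COLUMNS), log


def compute_score(
    genotypes: np.ndarray | pd.DataFrame,
    variants: pd.DataFrame,
    weighted: bool = True,
) -> np.ndarray:
    """Per-person allele score: sum of dosages, weighted by ``BETA`` if asked.

    Genotype columns must align with the variant table rows (checked by
    column name when a DataFrame is supplied).  Missing dosages are
    mean-imputed per variant, with a log entry.
    """
    if isinstance(genotypes, pd.DataFrame):
        if list(genotypes.columns) != list(variants["SNP"]):
            raise ValueError("genotype columns are misaligned with the variant table")
        G = genotypes.to_numpy(dtype=float)
    else:
        G = np.asarray(genotypes, dtype=float)
        if G.shape[1] != len(variants):
            raise ValueError(
                f"genotype matrix has {G.shape[1]} columns but {len(variants)} variants given"
            )
    if np.isnan(G).any():
        n_missing = int(np.isnan(G).sum())
        col_means = np.nanmean(G, axis=0)
        idx = np.where(np.isnan(G))
        G = G.copy()
        G[idx] = np.take(col_means, idx[1])
        logger.info("compute_score: mean-imputed %d missing dosages", n_missing)
    w = variants["BETA"].to_numpy(dtype=float) if weighted else np.ones(G.shape[1])
    return G @ w


def instrument_strength(
    score: np.ndarray,
    exposure: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> InstrumentDiagnostics:
    """Partial R^2 and partial F of the score for the exposure.

    ``r2`` is the incremental variance explained by the score after the
    covariates (ordinary R^2 when no covariates are given), and ``F`` the
    partial F test of the score term.
    """
    score = np.asarray(score, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    n = score.size
    if score.std() == 0:
        raise ValueError("constant score: F statistic undefined")
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        C = C.reshape(n, -1)
        X_red = np.column_stack([np.ones(n), C])
    else:
        X_red = np.ones((n, 1))
    if n <= X_red.shape[1] + 2:
        raise ValueError("need n > number of covariates + 2")
    X_full = np.column_stack([X_red, score])
    rss_red = _rss(X_red, exposure)
    rss_full = _rss(X_full, exposure)
    df_resid = n - X_full.shape[1]
    r2 = max((rss_red - rss_full) / rss_red, 0.0) if rss_red > 0 else 0.0
    f = (rss_red - rss_full) / (rss_full / df_resid) if rss_full > 0 else np.inf
    return InstrumentDiagnostics(f_statistic=max(float(f), 0.0), r2=float(min(r2, 1.0)), n=n)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)
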