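"""End-to-end orchestration: simulate -> score -> observational -> MR ->
survival/mediation -> meta/coloc -> triangulation report.

A single :class:`PipelineConfig` (YAML-serializable) drives every stage.
Stages execute in dependency order, each writing a TSV into the run
directory; a manifest with the seed and SHA-256 hashes of every table makes
reruns verifiable bit for bit.  A failure in one protein's model is logged
and skipped rather than aborting the panel.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .meta import StudyEstimate, coloc_abf, meta_fixed, meta_random
from .mr import cochran_q_two_estimates, rescale_per_exposure_sd, tsls_panel
from .observational import (
    GENETIC_ADJUSTMENT,
    OBSERVATIONAL_ADJUSTMENT,
    AdjustmentSet,
    assoc_panel,
    exclude_low_detect,
    renyi_band,
    standardize,
)
from .score import compute_score, filter_by_maf, instrument_strength
from .simulate import SimConfig, make_study
from .survival import attenuation, protein_cvd_assoc

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "triangulation_report", "STAGES"]

STAGES = ("cohort", "score", "observational", "mr", "survival", "meta", "coloc", "report")

# attenuation base model: the full observational set minus the two candidate
# mediators (blood pressure, diabetes), which are added back as mediator sets
ATTENUATION_BASE = AdjustmentSet(
    name="attenuation_base",
    continuous=("age", "age^2", "fasting_time"),
    categorical={
        "sex": 0,
        "region": 0,
        "education": 0,
        "income": 0,
        "alcohol": 0,
        "self_rated_health": 0,
        "statin": 0,
        "kidney_disease": 0,
    },
)


@dataclass
class PipelineConfig:
    """Everything one run needs; validated up front and serialized verbatim."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "run"
    fdr_q: float = 0.05
    maf_threshold: float = 0.01
    unweighted: bool = True  # also run the unweighted-score MR
    max_below_lod: float = 0.99
    n_mediator_proteins: int = 10
    attenuation_scale: str = "log_hr"
    write_genotypes: bool = False
    gene_regions: str | None = None  # BED-like TSV for cis-window exclusion
    cis_window: float = 1_000_000
    meta_estimates: str | None = None  # TSV of external study estimates
    coloc_trait1: str | None = None  # TSV: SNP, BETA, SE
    coloc_trait2: str | None = None

    def __post_init__(self):
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        if not 0 < self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must lie in (0, 0.5)")
        if not 0 <= self.max_below_lod <= 1:
            raise ValueError("max_below_lod must lie in [0, 1]")
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["sim"] = {k: v for k, v in dataclasses.asdict(self.sim).items() if k != "panel"}
        for k in ("maf_range", "rare_maf_range"):
            d["sim"][k] = list(d["sim"][k])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


class _JsonLineFormatter(logging.Formatter):
    def format(self, record):
        return json.dumps(
            {"level": record.levelname, "logger": record.name, "message": record.getMessage()}
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, stages=None) -> Path:
    """Execute the requested stages (all by default); returns the run directory."""
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for path_attr in ("gene_regions", "meta_estimates", "coloc_trait1", "coloc_trait2"):
        p = getattr(config, path_attr)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{path_attr}: no such file: {p}")
    config.to_yaml(out / "config.yaml")

    handler = logging.FileHandler(out / "log.jsonl", mode="w")
    handler.setFormatter(_JsonLineFormatter())
    pkg_logger = logging.getLogger("adipomr")
    pkg_logger.addHandler(handler)
    pkg_logger.setLevel(logging.INFO)
    try:
        _run_stages(config, out, stages)
    finally:
        pkg_logger.removeHandler(handler)
        handler.close()

    manifest = {
        "seed": config.sim.seed,
        "package_version": __version__,
        "config_sha256": _sha256(out / "config.yaml"),
        "tables": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.glob("*.tsv")) + sorted((out / "cohort").glob("*.tsv"))
            if p.is_file()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _zscore_panel(proteins: pd.DataFrame, retained: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {p: standardize(proteins[p]) for p in retained}, index=proteins.index
    )


def _run_stages(config: PipelineConfig, out: Path, stages: list[str]) -> None:
    cfg = config
    cohort, truth = make_study(cfg.sim)
    if "cohort" in stages:
        cohort.write(out / "cohort", include_genotypes=cfg.write_genotypes)
        truth.write(out / "truth")

    # --- genetic score (needed by mr as well) ---
    retained, excl = filter_by_maf(cohort.variants, cfg.maf_threshold)
    if cfg.gene_regions is not None:
        from .mr import exclude_nearby_variants

        regions = pd.read_csv(cfg.gene_regions, sep="\t")
        retained, cis_log = exclude_nearby_variants(retained, regions, cfg.cis_window)
        cis_log.to_csv(out / "cis_exclusions.tsv", sep="\t", index=False)
    idx = cohort.variants.set_index("SNP").index.get_indexer(retained["SNP"])
    G = cohort.genotypes[:, idx]
    covars = cohort.covariates.copy()
    covars["score"] = compute_score(G, retained, weighted=True)
    covars["score_unweighted"] = compute_score(G, retained, weighted=False)
    if "score" in stages:
        excl.to_csv(out / "score_exclusions.tsv", sep="\t", index=False)
        from .observational import build_design

        adj = build_design(covars, GENETIC_ADJUSTMENT).drop(columns="const")
        diag = instrument_strength(covars["score"], covars["bmi"], adj)
        (out / "instrument.json").write_text(
            json.dumps(
                {
                    "f_statistic": diag.f_statistic,
                    "r2": diag.r2,
                    "n": diag.n,
                    "n_variants": len(retained),
                    "n_excluded_maf": len(excl),
                },
                indent=2,
            )
        )

    # --- protein panel preparation ---
    retained_prot, lod_log = exclude_low_detect(
        cohort.proteins, cohort.lod_flags, cfg.max_below_lod
    )
    panel_z = _zscore_panel(cohort.proteins, retained_prot)
    sub_data = covars.loc[cohort.subcohort_ids].copy()
    sub_data["bmi_z_ref"] = standardize(sub_data["bmi"], reference_sd=cfg.sim.exposure_sd)
    obs_path = out / "observational.tsv"

    if "observational" in stages:
        lod_log.to_csv(out / "lod_exclusions.tsv", sep="\t", index=False)
        data = pd.concat([sub_data, panel_z], axis=1)
        obs = assoc_panel(
            data, retained_prot, "bmi_z_ref", OBSERVATIONAL_ADJUSTMENT, fdr_q=cfg.fdr_q
        )
        obs.to_csv(obs_path, sep="\t", index=False)
        band, n_surpass = renyi_band(obs["p"].to_numpy(), q=cfg.fdr_q)
        band["trait"] = obs["trait"].to_numpy()[band["index"]]
        band.to_csv(out / "renyi.tsv", sep="\t", index=False)
        logger.info("renyi band: %d traits surpass the threshold", n_surpass)

    mr_path = out / "mr.tsv"
    if "mr" in stages:
        obs_df = pd.read_csv(obs_path, sep="\t") if obs_path.exists() else None
        rows = []
        score_cols = [("weighted", "score")]
        if cfg.unweighted:
            score_cols.append(("unweighted", "score_unweighted"))
        for tag, score_col in score_cols:
            try:
                results = tsls_panel(
                    covars, score_col, "bmi", sub_data, panel_z, GENETIC_ADJUSTMENT
                )
            except Exception as exc:  # noqa: BLE001 - isolate a whole score variant
                logger.warning("mr stage: skipping score %s (%s)", tag, exc)
                continue
            for prot, res in results.items():
                res = rescale_per_exposure_sd(res, cfg.sim.exposure_sd)
                row = {
                    "trait": prot,
                    "score": tag,
                    "method": res.method,
                    "estimate": res.estimate,
                    "se": res.se,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p,
                    "f_stage1": res.f_stage1,
                    "n_stage1": res.n_stage1,
                    "n_stage2": res.n_stage2,
                }
                if obs_df is not None and tag == "weighted":
                    m = obs_df[obs_df["trait"] == prot]
                    if len(m):
                        het = cochran_q_two_estimates(
                            res.estimate, res.se, float(m["beta"].iloc[0]), float(m["se"].iloc[0])
                        )
                        row["q_vs_observational"] = het.q_statistic
                        row["q_p"] = het.p
                rows.append(row)
        pd.DataFrame(rows).to_csv(mr_path, sep="\t", index=False)

    surv_path = out / "survival.tsv"
    if "survival" in stages:
        surv = protein_cvd_assoc(
            panel_z,
            cohort.survival,
            sub_data,
            OBSERVATIONAL_ADJUSTMENT,
            exclude_prevalent=True,
        )
        surv.to_csv(surv_path, sep="\t", index=False)
        _attenuation_stage(cfg, out, sub_data, panel_z, cohort, surv, obs_path)

    if "meta" in stages and cfg.meta_estimates is not None:
        _meta_stage(cfg, out)

    if "coloc" in stages and cfg.coloc_trait1 is not None and cfg.coloc_trait2 is not None:
        s1 = pd.read_csv(cfg.coloc_trait1, sep="\t")
        s2 = pd.read_csv(cfg.coloc_trait2, sep="\t")
        res = coloc_abf(s1, s2)
        (out / "coloc.json").write_text(json.dumps(dataclasses.asdict(res), indent=2))

    if "report" in stages:
        triangulation_report(out).to_csv(out / "report.tsv", sep="\t", index=False)


def _attenuation_stage(cfg, out, sub_data, panel_z, cohort, surv, obs_path):
    mediators = []
    if obs_path.exists() and len(surv):
        obs = pd.read_csv(obs_path, sep="\t")
        bmi_assoc = set(obs.loc[obs["significant_fdr"].astype(bool), "trait"])
        cand = surv[(surv["p"] < 0.05) & surv["trait"].isin(bmi_assoc)]
        mediators = list(cand.sort_values("p")["trait"].head(cfg.n_mediator_proteins))
    sets = []
    if mediators:
        sets.append(("proteins", mediators, panel_z))
    sets.append(("sbp_diabetes", ["sbp", "diabetes"], sub_data))
    if mediators:
        combined = pd.concat([panel_z[mediators], sub_data[["sbp", "diabetes"]]], axis=1)
        sets.append(("proteins+sbp_diabetes", mediators + ["sbp", "diabetes"], combined))
    rows = []
    for name, meds, med_data in sets:
        try:
            res = attenuation(
                sub_data,
                cohort.survival,
                "bmi_z",
                meds,
                ATTENUATION_BASE,
                mediator_data=med_data,
                mediator_set=name,
                scale=cfg.attenuation_scale,
            )
        except Exception as exc:  # noqa: BLE001
            logger.warning("attenuation: skipping set %s (%s)", name, exc)
            continue
        rows.append(dataclasses.asdict(res) | {"n_mediators": len(meds)})
    pd.DataFrame(rows).to_csv(out / "attenuation.tsv", sep="\t", index=False)


def _meta_stage(cfg, out):
    """Pool externally supplied study estimates per trait (fixed and random)."""
    ext = pd.read_csv(cfg.meta_estimates, sep="\t")
    rows = []
    for trait, grp in ext.groupby("trait"):
        ests = []
        for r in grp.itertuples(index=False):
            kw = {"study": r.study, "beta": float(r.beta), "scale": str(r.scale)}
            if hasattr(r, "se") and pd.notna(r.se):
                kw["se"] = float(r.se)
            else:
                kw.update(ci_low=float(r.ci_low), ci_high=float(r.ci_high))
            ests.append(StudyEstimate(**kw))
        measures = set(grp["measure"]) if "measure" in grp.columns else set()
        fixed = meta_fixed(ests)
        rand = meta_random(ests) if len(ests) >= 2 else None
        for res in filter(None, (fixed, rand)):
            rows.append(
                {
                    "trait": trait,
                    "model": res.model,
                    "pooled": res.pooled,
                    "se": res.se,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p,
                    "q": res.q,
                    "i2": res.i2,
                    "tau2": res.tau2,
                    "k": res.k,
                    "mixed_measures": len(measures) > 1,
                }
            )
    pd.DataFrame(rows).to_csv(out / "meta.tsv", sep="\t", index=False)


def triangulation_report(run_dir: str | Path) -> pd.DataFrame:
    """Per-protein consistency table across the three lines of evidence.

    Merges the observational, MR and survival tables; the concordance flag
    is true when the observational and genetic effects share a sign and the
    genetically implied protein shift points the same way as the protein's
    log hazard ratio.  Missing stages leave their columns empty.
    """
    run_dir = Path(run_dir)
    obs_p, mr_p, surv_p = (run_dir / f"{n}.tsv" for n in ("observational", "mr", "survival"))
    if not obs_p.exists() and not mr_p.exists():
        raise FileNotFoundError("need at least an observational or MR table to report on")
    frames = []
    if obs_p.exists():
        obs = pd.read_csv(obs_p, sep="\t")[["trait", "beta", "se", "p", "significant_fdr"]]
        frames.append(obs.rename(columns=lambda c: f"obs_{c}" if c != "trait" else c))
    if mr_p.exists():
        mr = pd.read_csv(mr_p, sep="\t")
        mr = mr[mr["score"] == "weighted"] if "score" in mr.columns else mr
        keep = ["trait", "estimate", "se", "p"] + (
            ["q_p"] if "q_p" in mr.columns else []
        )
        frames.append(mr[keep].rename(columns=lambda c: f"mr_{c}" if c != "trait" else c))
    if surv_p.exists():
        surv = pd.read_csv(surv_p, sep="\t")[["trait", "log_hr", "hr", "se", "p"]]
        frames.append(surv.rename(columns=lambda c: f"cvd_{c}" if c != "trait" else c))
    report = frames[0]
    for f in frames[1:]:
        report = report.merge(f, on="trait", how="outer")
    if {"obs_beta", "mr_estimate"} <= set(report.columns):
        same_sign = np.sign(report["obs_beta"]) == np.sign(report["mr_estimate"])
        if "cvd_log_hr" in report.columns:
            concord = same_sign & (
                np.sign(report["mr_estimate"]) * np.sign(report["cvd_log_hr"]) > 0
            )
            concord = concord.where(report["cvd_log_hr"].notna() & report["mr_estimate"].notna())
        else:
            concord = same_sign.where(report["mr_estimate"].notna())
        report["direction_concordant"] = concord
    return report
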