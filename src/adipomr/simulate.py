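"""Synthetic cohort generation with known ground truth.

Individual-level biobank data linking genotypes, adiposity, proteomic panels
and incident cardiovascular events are access-restricted, so every stage of
the triangulation analysis in this package is exercised on cohorts generated
here.  The generator emulates the statistical structure the analysis assumes:

* independent bi-allelic instrument variants in Hardy-Weinberg equilibrium,
* a polygenic score explaining a small, controllable fraction of exposure
  (BMI-like) variance,
* a log2-scale "NPX"-like protein panel driven by the exposure, by a shared
  unobserved confounder, and optionally by direct (pleiotropic) variant
  effects, with per-protein below-limit-of-detection censoring,
* proportional-hazards event times over a fixed follow-up window, with the
  hazard loading on the exposure, on selected proteins and on the confounder.

Every generated cohort ships with a :class:`TruthSet` recording the causal
parameters used, so downstream estimators can be tested for recovery.
All randomness flows from the single ``SimConfig.seed`` through named
substreams, making each component reproducible independently of the others.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "TruthSet",
    "CohortData",
    "default_panel",
    "simulate_genotypes",
    "simulate_exposure",
    "simulate_proteins",
    "simulate_survival",
    "make_study",
]

# named substreams derived from the config seed; order is part of the contract
_STREAMS = {
    "variants": 1,
    "genotypes": 2,
    "confounder": 3,
    "exposure": 4,
    "covariates": 5,
    "subcohort": 6,
    "proteins": 7,
    "survival": 8,
    "prevalent": 9,
    "pleiotropy": 10,
}


def _rng(seed, stream: str | int = 0) -> np.random.Generator:
    """Generator for a named substream of ``seed`` (pass-through for Generators)."""
    if isinstance(seed, np.random.Generator):
        return seed
    key = _STREAMS.get(stream, stream) if isinstance(stream, str) else stream
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(int(key),)))


def default_panel() -> pd.DataFrame:
    """Default 92-protein panel with true causal parameters.

    Thirty proteins respond to the exposure (columns ``beta``, SD protein per
    SD exposure); a handful respond negatively while loading positively on the
    confounder, which makes their observational and genetic estimates point in
    opposite directions — the scenario a triangulation analysis exists to
    catch.  Ten proteins carry a direct log hazard ratio on vascular events.
    Two proteins are almost entirely below the limit of detection and should
    be excluded by the downstream >99 %-below-LOD rule.  The remaining sixty
    are null fillers sharing a weak confounder loading.
    """
    affected = [
        # name, beta (SD/SD exposure), gamma (confounder loading), log HR
        ("IL6", 0.35, 0.25, 0.19),
        ("IL18", 0.28, 0.25, 0.22),
        ("CCL3", 0.33, 0.25, 0.0),
        ("MCP1", 0.37, 0.25, 0.0),
        ("MCP3", 0.25, 0.25, 0.25),
        ("TRAIL", 0.50, 0.25, 0.0),
        ("HGF", 0.25, 0.25, 0.20),
        ("GAL9", 0.42, 0.25, 0.0),
        ("CXCL10", 0.22, 0.25, 0.0),
        ("TNFRSF12A", 0.13, 0.25, 0.0),
        ("VEGFR2", 0.18, 0.25, -0.19),
        ("ADA", 0.21, 0.25, 0.0),
        ("GZMB", 0.30, 0.25, 0.0),
        # discordant trio: negative causal effect, strong positive confounding
        ("IL12", -0.22, 0.875, 0.0),
        ("CSF1", -0.18, 0.875, 0.0),
        ("DCN", -0.18, 0.80, 0.0),
        ("CASP8", -0.19, 0.90, 0.34),
        ("FASLG", 0.15, 0.25, -0.26),
        ("TWEAK", 0.12, 0.25, -0.27),
        ("CCL19", 0.15, 0.25, 0.0),
        ("CCL20", 0.18, 0.25, 0.17),
        ("VEGFA", 0.20, 0.25, 0.0),
        ("ARG1", 0.15, 0.25, 0.22),
        ("CAIX", 0.15, 0.25, 0.0),
        ("ADGRG1", 0.12, 0.25, 0.0),
        ("GZMA", 0.18, 0.25, 0.0),
        ("PGF", 0.15, 0.25, 0.0),
        ("TNFSF14", 0.18, 0.25, 0.0),
        ("GAL1", 0.15, 0.25, 0.0),
        ("IL5", 0.12, 0.25, 0.0),
    ]
    rows = [(n, b, g, h, 0.02) for (n, b, g, h) in affected]
    rows += [(f"PROT{j:02d}", 0.0, 0.10, 0.0, 0.02) for j in range(31, 91)]
    # near-fully censored proteins, to be dropped downstream
    rows += [("IL21", 0.0, 0.0, 0.0, 0.995), ("IL35", 0.0, 0.0, 0.0, 0.995)]
    return pd.DataFrame(rows, columns=["protein", "beta", "gamma", "log_hr", "lod_quantile"])


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the design of a large biobank case-subcohort proteomics
    study: ~75 736 genotyped individuals, a simple random subcohort of 628
    with protein measurements and 10-year follow-up, 670 candidate instrument
    variants of which 84 are rare (MAF < 1 %), a weighted allele score
    explaining ~2.06 % of exposure variance, and an exposure with mean 23.9
    and SD 3.4 on its natural (BMI) scale.
    """

    n_gwas: int = 75_736
    n_subcohort: int = 628
    n_variants: int = 670
    n_variants_rare: int = 84
    maf_range: tuple[float, float] = (0.01, 0.50)
    rare_maf_range: tuple[float, float] = (0.001, 0.0095)
    variance_explained_exposure: float = 0.0206
    exposure_mean: float = 23.9
    exposure_sd: float = 3.4
    confounder_exposure_effect: float = 0.40
    panel: pd.DataFrame | None = None  # default_panel() when None
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    shared_factor_loading: float = 0.0
    hazard_exposure_log_hr: float = 0.15
    hazard_confounder_log_hr: float = 0.20
    hazard_age_log_hr: float = 0.50
    hazard_sex_log_hr: float = -0.30
    baseline_hazard: float = 0.020
    weibull_shape: float = 1.0
    followup_years: float = 10.0
    censor_rate: float = 0.10
    prevalent_fraction: float = 0.064
    seed: int = 0

    def __post_init__(self) -> None:
        if self.panel is None:
            self.panel = default_panel()
        if self.n_gwas <= 0 or self.n_subcohort <= 0:
            raise ValueError("sample sizes must be positive")
        if self.n_subcohort > self.n_gwas:
            raise ValueError("n_subcohort must not exceed n_gwas")
        if not 0 <= self.n_variants_rare <= self.n_variants:
            raise ValueError("n_variants_rare must lie in [0, n_variants]")
        for lo, hi in (self.maf_range, self.rare_maf_range):
            if not (0 < lo <= hi <= 0.5):
                raise ValueError("MAF ranges must satisfy 0 < lo <= hi <= 0.5")
        if not 0 < self.variance_explained_exposure <= 1:
            raise ValueError("variance_explained_exposure must lie in (0, 1]")
        if self.exposure_sd <= 0:
            raise ValueError("exposure_sd must be positive")
        if self.followup_years <= 0:
            raise ValueError("followup_years must be positive")
        if not 0 <= self.censor_rate <= 1:
            raise ValueError("censor_rate must lie in [0, 1]")
        lod = np.asarray(self.panel["lod_quantile"], dtype=float)
        if np.any((lod < 0) | (lod >= 1)):
            raise ValueError("lod_quantile values must lie in [0, 1)")

    @property
    def protein_names(self) -> list[str]:
        return list(self.panel["protein"])


@dataclass
class TruthSet:
    """Ground-truth parameters stored alongside every generated cohort."""

    protein: pd.DataFrame  # protein, beta (exposure effect), gamma, log_hr
    variant: pd.DataFrame  # SNP, true_weight, pleiotropy
    confounder: np.ndarray  # per-person latent confounder (genotyped sample)
    exposure_log_hr: float
    confounder_log_hr: float

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.protein.to_csv(outdir / "truth_proteins.tsv", sep="\t", index=False)
        self.variant.to_csv(outdir / "truth_variants.tsv", sep="\t", index=False)
        pd.DataFrame({"confounder": self.confounder}).to_csv(
            outdir / "truth_confounder.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {
                "parameter": ["exposure_log_hr", "confounder_log_hr"],
                "value": [self.exposure_log_hr, self.confounder_log_hr],
            }
        ).to_csv(outdir / "truth_scalars.tsv", sep="\t", index=False)


@dataclass
class CohortData:
    """A generated study: genotyped sample plus proteomics subcohort."""

    variants: pd.DataFrame  # SNP, CHR, POS, EA, OA, EAF, BETA, SE
    genotypes: np.ndarray  # (n_gwas, n_variants) dosages in {0,1,2}
    covariates: pd.DataFrame  # person-level, indexed by integer id
    proteins: pd.DataFrame  # subcohort x proteins, unit variance pre-censoring
    lod_flags: pd.DataFrame  # boolean, aligned to proteins
    survival: pd.DataFrame  # subcohort: time_years, event, prevalent_cvd
    subcohort_ids: np.ndarray

    def write(self, outdir: str | Path, include_genotypes: bool = True) -> None:
        """Write the cohort as one TSV per entity (dosage 'raw' layout for genotypes)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
        self.covariates.to_csv(outdir / "covariates.tsv", sep="\t", index_label="id")
        self.proteins.to_csv(outdir / "proteins.tsv", sep="\t", index_label="id")
        self.lod_flags.astype(int).to_csv(outdir / "lod_flags.tsv", sep="\t", index_label="id")
        self.survival.to_csv(outdir / "survival.tsv", sep="\t", index_label="id")
        if include_genotypes:
            gdf = pd.DataFrame(self.genotypes, columns=self.variants["SNP"])
            gdf.to_csv(outdir / "genotypes.tsv", sep="\t", index_label="id")

    @classmethod
    def read(cls, indir: str | Path) -> "CohortData":
        indir = Path(indir)
        variants = pd.read_csv(indir / "variants.tsv", sep="\t")
        covariates = pd.read_csv(indir / "covariates.tsv", sep="\t", index_col="id")
        proteins = pd.read_csv(indir / "proteins.tsv", sep="\t", index_col="id")
        lod = pd.read_csv(indir / "lod_flags.tsv", sep="\t", index_col="id").astype(bool)
        survival = pd.read_csv(indir / "survival.tsv", sep="\t", index_col="id")
        gpath = indir / "genotypes.tsv"
        if gpath.exists():
            genotypes = (
                pd.read_csv(gpath, sep="\t", index_col="id").to_numpy(dtype=np.int8)
            )
        else:
            genotypes = np.zeros((len(covariates), len(variants)), dtype=np.int8)
        return cls(
            variants=variants,
            genotypes=genotypes,
            covariates=covariates,
            proteins=proteins,
            lod_flags=lod,
            survival=survival,
            subcohort_ids=proteins.index.to_numpy(),
        )

    def export_vcf(self, path: str | Path, sample_ids=None) -> None:
        """Write genotypes as a minimal unphased VCF (GT field only)."""
        ids = np.arange(self.genotypes.shape[0]) if sample_ids is None else sample_ids
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(f"S{i}" for i in ids)
                + "\n"
            )
            for j, row in enumerate(self.variants.itertuples(index=False)):
                gts = "\t".join(gt_codes[int(g)] for g in self.genotypes[:, j])
                fh.write(
                    f"{row.CHR}\t{row.POS}\t{row.SNP}\t{row.OA}\t{row.EA}\t.\tPASS\t.\tGT\t{gts}\n"
                )


def simulate_genotypes(n: int, mafs, seed=0) -> np.ndarray:
    """Draw Hardy-Weinberg genotype dosages.

    Each variant is bi-allelic and independent; the dosage of the effect
    allele is Binomial(2, maf), giving genotype frequencies p^2, 2pq, q^2.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("each MAF must lie in (0, 0.5]")
    rng = _rng(seed, "genotypes")
    return rng.binomial(2, mafs, size=(n, mafs.size)).astype(np.int8)


def simulate_exposure(
    genotypes: np.ndarray,
    weights,
    target_r2: float,
    confounder: np.ndarray | None = None,
    conf_effect: float = 0.0,
    mean: float = 0.0,
    sd: float = 1.0,
    seed=0,
) -> np.ndarray:
    """Generate an exposure with a polygenic score explaining ``target_r2``.

    On the standardized scale the exposure is
    ``sqrt(r2)*z(score) + b*confounder + sqrt(1 - r2 - b^2)*noise``,
    so the weighted allele score explains ``target_r2`` of the exposure
    variance in expectation; the result is rescaled to ``mean``/``sd``
    (BMI-scale by default in :func:`make_study`).
    """
    if not 0 < target_r2 <= 1:
        raise ValueError("target_r2 must lie in (0, 1]")
    if sd <= 0:
        raise ValueError("sd must be positive")
    weights = np.asarray(weights, dtype=float)
    if weights.size != genotypes.shape[1]:
        raise ValueError("weights length must equal the number of variants")
    b = float(conf_effect) if confounder is not None else 0.0
    resid_var = 1.0 - target_r2 - b * b
    if resid_var < -1e-12:
        raise ValueError("target_r2 + conf_effect^2 exceeds 1")
    rng = _rng(seed, "exposure")
    score = genotypes @ weights
    s_sd = score.std()
    score_z = (score - score.mean()) / s_sd if s_sd > 0 else np.zeros_like(score, dtype=float)
    z = np.sqrt(target_r2) * score_z
    if confounder is not None:
        z = z + b * np.asarray(confounder, dtype=float)
    if resid_var > 0:
        z = z + np.sqrt(resid_var) * rng.standard_normal(genotypes.shape[0])
    return mean + sd * z


def simulate_proteins(
    exposure_z: np.ndarray,
    confounder: np.ndarray,
    genotypes: np.ndarray,
    beta,
    gamma,
    pleiotropy=None,
    shared_loading: float = 0.0,
    lod_quantile=0.0,
    names=None,
    seed=0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a standardized protein panel with below-LOD flags.

    Each protein is ``beta*exposure_z + gamma*confounder +
    genotypes@pleiotropy + shared_loading*factor + noise`` with the noise
    variance chosen so columns have unit variance in expectation (the
    "standardized NPX" convention).  The lowest ``lod_quantile`` fraction of
    each column is flagged below-LOD; values are retained, mirroring assays
    that report below-LOD measurements.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    n_prot = beta.size
    if gamma.size != n_prot:
        raise ValueError("beta and gamma must have equal length")
    lod = np.broadcast_to(np.atleast_1d(np.asarray(lod_quantile, dtype=float)), (n_prot,))
    if np.any((lod < 0) | (lod >= 1)):
        raise ValueError("lod_quantile must lie in [0, 1)")
    rng = _rng(seed, "proteins")
    n = exposure_z.shape[0]
    y = np.outer(exposure_z, beta) + np.outer(confounder, gamma)
    direct_var = 0.0
    if pleiotropy is not None:
        alpha = np.asarray(pleiotropy, dtype=float)
        direct = genotypes @ alpha
        y = y + direct[:, None]
        direct_var = float(direct.var())
    if shared_loading:
        y = y + shared_loading * rng.standard_normal(n)[:, None]
    sys_var = beta**2 + gamma**2 + direct_var + shared_loading**2
    noise_sd = np.sqrt(np.maximum(1.0 - sys_var, 0.05))
    y = y + noise_sd * rng.standard_normal((n, n_prot))
    # rescale to exactly unit expected variance when systematic variance > 0.95
    total_sd = np.sqrt(sys_var + noise_sd**2)
    y = y / total_sd
    names = names if names is not None else [f"P{j}" for j in range(n_prot)]
    panel = pd.DataFrame(y, columns=names)
    thresholds = np.array(
        [np.quantile(panel.iloc[:, j], lod[j]) if lod[j] > 0 else -np.inf for j in range(n_prot)]
    )
    flags = pd.DataFrame(panel.to_numpy() < thresholds, columns=names)
    return panel, flags


def simulate_survival(
    covariates: np.ndarray,
    log_hrs,
    followup_years: float,
    censor_rate: float,
    seed=0,
    baseline_hazard: float = 0.020,
    weibull_shape: float = 1.0,
) -> pd.DataFrame:
    """Draw proportional-hazards event times over a fixed follow-up window.

    Baseline hazard is Weibull (exponential when ``weibull_shape == 1``) with
    rate ``baseline_hazard * exp(x'beta)``.  Censoring is independent of the
    event process: an exponential dropout time calibrated so a fraction
    ``censor_rate`` of individuals drop out before administrative censoring
    at ``followup_years``.
    """
    if followup_years <= 0:
        raise ValueError("followup_years must be positive")
    if not 0 <= censor_rate <= 1:
        raise ValueError("censor_rate must lie in [0, 1]")
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] == 1 and np.asarray(log_hrs).size != X.shape[1]:
        X = X.T
    log_hrs = np.asarray(log_hrs, dtype=float)
    if log_hrs.size != X.shape[1]:
        raise ValueError("log_hrs length must equal the covariate count")
    rng = _rng(seed, "survival")
    n = X.shape[0]
    lin = X @ log_hrs
    lin -= lin.mean()  # centre so baseline_hazard is the typical-subject rate
    rate = baseline_hazard * np.exp(lin)
    e = rng.exponential(size=n)
    t_event = (e / rate) ** (1.0 / weibull_shape)
    if censor_rate >= 1.0:
        time = followup_years * rng.uniform(1e-9, 1.0, size=n)
        return pd.DataFrame({"time_years": time, "event": np.zeros(n, dtype=int)})
    if censor_rate > 0:
        drop_rate = -np.log1p(-censor_rate) / followup_years
        t_drop = rng.exponential(1.0 / drop_rate, size=n)
    else:
        t_drop = np.full(n, np.inf)
    t_cens = np.minimum(t_drop, followup_years)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-9)
    return pd.DataFrame({"time_years": time, "event": event})


def _simulate_covariates(n: int, bmi_z: np.ndarray, confounder: np.ndarray, rng) -> pd.DataFrame:
    age = np.clip(rng.normal(52.2, 10.5, n), 30, 79)
    sex = rng.binomial(1, 0.613, n)  # 1 = female
    region = rng.integers(0, 10, n)
    education = rng.binomial(1, 0.234, n)
    income = rng.binomial(1, 0.185, n)
    alcohol = rng.binomial(1, 0.20, n)
    smoking = rng.binomial(1, 0.27, n)
    health = rng.integers(0, 4, n)
    sbp = 131.3 + 4.5 * bmi_z + 2.0 * confounder + rng.normal(0, 20, n)
    p_diab = 1.0 / (1.0 + np.exp(-(-3.55 + 0.35 * bmi_z + 0.2 * confounder)))
    diabetes = rng.binomial(1, p_diab)
    statin = rng.binomial(1, 0.02, n)
    kidney = rng.binomial(1, 0.015, n)
    fasting = rng.uniform(0, 8, n)
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "region": region,
            "education": education,
            "income": income,
            "alcohol": alcohol,
            "smoking": smoking,
            "self_rated_health": health,
            "sbp": sbp,
            "diabetes": diabetes,
            "statin": statin,
            "kidney_disease": kidney,
            "fasting_time": fasting,
        }
    )


_BASES = np.array(["A", "C", "G", "T"])


def _simulate_variants(cfg: SimConfig, rng) -> tuple[pd.DataFrame, np.ndarray]:
    n, n_rare = cfg.n_variants, cfg.n_variants_rare
    mafs = np.empty(n)
    mafs[:n_rare] = rng.uniform(*cfg.rare_maf_range, size=n_rare)
    mafs[n_rare:] = rng.uniform(*cfg.maf_range, size=n - n_rare)
    rng.shuffle(mafs)
    # weights coded to the exposure-raising allele, hence all positive
    w_true = np.abs(rng.normal(0.0, 1.0, n))
    chrom = rng.integers(1, 23, n)
    pos = rng.integers(1_000_000, 240_000_000, n)
    ref_idx = rng.integers(0, 4, n)
    alt_shift = rng.integers(1, 4, n)
    ea = _BASES[(ref_idx + alt_shift) % 4]
    oa = _BASES[ref_idx]
    variants = pd.DataFrame(
        {
            "SNP": [f"snp{j:04d}" for j in range(n)],
            "CHR": chrom,
            "POS": pos,
            "EA": ea,
            "OA": oa,
            "EAF": mafs,
            "BETA": w_true,
            "SE": 0.1 * np.abs(w_true) + 0.01,
        }
    )
    return variants, w_true


def make_study(config: SimConfig) -> tuple[CohortData, TruthSet]:
    """Generate the full nested design plus its truth set.

    Large genotyped sample with exposure and covariates; a simple random
    subcohort with protein panel and survival follow-up; a :class:`TruthSet`
    recording the causal parameters used for each component.
    """
    cfg = config
    seed = cfg.seed
    panel = cfg.panel.reset_index(drop=True)
    variants, w_true = _simulate_variants(cfg, _rng(seed, "variants"))
    genotypes = simulate_genotypes(cfg.n_gwas, variants["EAF"].to_numpy(), seed)
    confounder = _rng(seed, "confounder").standard_normal(cfg.n_gwas)
    bmi = simulate_exposure(
        genotypes,
        w_true,
        cfg.variance_explained_exposure,
        confounder,
        cfg.confounder_exposure_effect,
        mean=cfg.exposure_mean,
        sd=cfg.exposure_sd,
        seed=seed,
    )
    bmi_z = (bmi - cfg.exposure_mean) / cfg.exposure_sd
    covariates = _simulate_covariates(cfg.n_gwas, bmi_z, confounder, _rng(seed, "covariates"))
    covariates["bmi"] = bmi
    covariates["bmi_z"] = bmi_z

    sub = np.sort(
        _rng(seed, "subcohort").choice(cfg.n_gwas, size=cfg.n_subcohort, replace=False)
    )
    pleio = None
    if cfg.pleiotropy_sd > 0 or cfg.pleiotropy_mean != 0:
        pleio = _rng(seed, "pleiotropy").normal(
            cfg.pleiotropy_mean, cfg.pleiotropy_sd, cfg.n_variants
        )
    proteins, lod_flags = simulate_proteins(
        bmi_z[sub],
        confounder[sub],
        genotypes[sub],
        panel["beta"].to_numpy(),
        panel["gamma"].to_numpy(),
        pleiotropy=pleio,
        shared_loading=cfg.shared_factor_loading,
        lod_quantile=panel["lod_quantile"].to_numpy(),
        names=list(panel["protein"]),
        seed=seed,
    )
    proteins.index = sub
    lod_flags.index = sub

    age_z = (covariates["age"].to_numpy()[sub] - 52.2) / 10.5
    haz_X = np.column_stack(
        [
            bmi_z[sub],
            confounder[sub],
            age_z,
            covariates["sex"].to_numpy()[sub],
            proteins.to_numpy(),
        ]
    )
    haz_beta = np.concatenate(
        [
            [
                cfg.hazard_exposure_log_hr,
                cfg.hazard_confounder_log_hr,
                cfg.hazard_age_log_hr,
                cfg.hazard_sex_log_hr,
            ],
            panel["log_hr"].to_numpy(),
        ]
    )
    survival = simulate_survival(
        haz_X,
        haz_beta,
        cfg.followup_years,
        cfg.censor_rate,
        seed=seed,
        baseline_hazard=cfg.baseline_hazard,
        weibull_shape=cfg.weibull_shape,
    )
    survival.index = sub
    survival["prevalent_cvd"] = _rng(seed, "prevalent").binomial(
        1, cfg.prevalent_fraction, cfg.n_subcohort
    )

    truth = TruthSet(
        protein=panel[["protein", "beta", "gamma", "log_hr"]].copy(),
        variant=pd.DataFrame(
            {
                "SNP": variants["SNP"],
                "true_weight": w_true,
                "pleiotropy": pleio if pleio is not None else np.zeros(cfg.n_variants),
            }
        ),
        confounder=confounder,
        exposure_log_hr=cfg.hazard_exposure_log_hr,
        confounder_log_hr=cfg.hazard_confounder_log_hr,
    )
    cohort = CohortData(
        variants=variants,
        genotypes=genotypes,
        covariates=covariates,
        proteins=proteins,
        lod_flags=lod_flags,
        survival=survival,
        subcohort_ids=sub,
    )
    return cohort, truth
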