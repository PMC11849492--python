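"""Synthetic skin-cohort generator with recorded ground truth.

Emulates the data shapes of a cheek-metagenome / skin-imaging-phenome
cohort: ten device-scored skin imaging phenotypes (SIPs) with age and
gender trends, a species relative-abundance table whose alpha diversity
rises with age, per-species gene tables with tight within-species
co-abundance, KO and module structure, and a designated driver species
whose abundance is rank-correlated with one SIP through the KOs of a few
target modules.  Every planted effect is recorded in a TruthRecord so
downstream stages can be scored against a known answer.

The generative model, in order:

* ages ~ Uniform(age_range); gender ~ Bernoulli(female_fraction).
* SIP_j = intercept_j + slope_j * age + offset_j * [male] + sd_j * eps_j,
  truncated at 0.  For the driver's target SIP, eps is a mixture
  w * u + sqrt(1 - w^2) * e of a shared latent u and fresh noise.
* species log-loadings m_s (sorted descending, so species 1 dominates the
  community the way one taxon dominates sebaceous skin) are flattened
  with age -- logit_s = m_s / (1 + diversity_age_effect * age_norm) +
  0.8 * z -- and softmax-normalized, so Shannon diversity increases with
  age.  The driver species' noise term is the same latent mixture as the
  target SIP's, with the mixing weight w calibrated by binary search
  against the empirical Spearman correlation at large n.
* gene g of species s: abundance = species_abundance(s) * baseline_g *
  LogNormal(0, within_species_log_noise_sd), giving within-species
  pairwise Pearson correlations > 0.9 at the default noise.
* modules partition a prefix of the KO universe; each KO carries three
  genes.  KOs of the target modules draw their genes almost entirely
  (>= 90%) from the driver species, with two KOs per target module
  keeping one non-driver gene so the module survives driver removal.
* gene2taxon labels each annotated gene with its true species and a
  percent identity ~ Normal(identity_mean, identity_sd) clipped to
  [70, 100]; a fraction of genes receive no hit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dermalink.stats import spearman_rho

SIP_COLUMNS = (
    "lightening",
    "sebum",
    "porphyrins",
    "texture",
    "melanin",
    "pore",
    "pigment",
    "wrinkle",
    "hemoglobin",
    "uv_spot",
)

# Per-sample spread of the species noise term and of the base log-loadings;
# together with the age flattening they set realistic rank-abundance curves.
_SPECIES_NOISE_SD = 0.8
_SPECIES_LOGMEAN_SD = 1.2
_GENES_PER_KO = 3
_NONDRIVER_KOS_PER_TARGET_MODULE = 2


@dataclass(frozen=True)
class SipTrend:
    """Affine age/gender model of one SIP: score = intercept +
    age_slope * age + gender_offset * [male] + Normal(0, noise_sd)."""

    intercept: float
    age_slope: float
    gender_offset: float
    noise_sd: float


def default_sip_trends() -> dict[str, SipTrend]:
    """Default trends: the qualitative age directions of the ten SIPs
    (pigment, pore, UV spot, melanin, hemoglobin and wrinkle rise with
    age; lightening and texture decline; sebum and porphyrins are flat),
    with noise chosen so |Pearson(SIP, age)| is roughly 0.3-0.45."""
    return {
        "lightening": SipTrend(65.0, -0.35, -2.0, 9.0),
        "sebum": SipTrend(50.0, 0.0, 3.0, 12.0),
        "porphyrins": SipTrend(30.0, 0.0, 0.0, 10.0),
        "texture": SipTrend(55.0, -0.30, 0.0, 9.0),
        "melanin": SipTrend(25.0, 0.30, 0.0, 9.0),
        "pore": SipTrend(30.0, 0.45, 2.0, 11.0),
        "pigment": SipTrend(20.0, 0.50, 1.5, 11.0),
        "wrinkle": SipTrend(12.0, 0.35, -1.0, 8.0),
        "hemoglobin": SipTrend(40.0, 0.25, 0.0, 9.0),
        "uv_spot": SipTrend(15.0, 0.45, 1.0, 11.0),
    }


def default_module_catalog_spec(n_modules: int = 20, kos_per_module: int = 8):
    return [(f"M{i + 1:04d}", kos_per_module) for i in range(n_modules)]


@dataclass(frozen=True)
class DriverSpec:
    """The planted driver: a species whose abundance is rank-correlated
    with ``target_sip`` and which owns >= 90% of the genes behind the KOs
    of ``target_modules``."""

    driver_species_id: str = "sp001"
    target_modules: tuple[str, ...] = ("M0001", "M0002", "M0003")
    target_sip: str = "pore"
    target_correlation: float = 0.5


@dataclass(frozen=True)
class SimConfig:
    n_samples: int = 150
    age_range: tuple[float, float] = (20.0, 60.0)
    female_fraction: float = 0.5
    sip_trends: dict[str, SipTrend] = field(default_factory=default_sip_trends)
    n_species: int = 40
    genes_per_species_range: tuple[int, int] = (90, 130)
    within_species_log_noise_sd: float = 0.1
    n_kos: int = 300
    module_catalog_spec: list[tuple[str, int]] = field(
        default_factory=default_module_catalog_spec
    )
    driver_spec: DriverSpec = field(default_factory=DriverSpec)
    diversity_age_effect: float = 0.5
    annotation: tuple[float, float, float] = (0.05, 98.0, 1.5)  # unannot frac, mean, sd
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 10:
            raise ValueError("n_samples must be at least 10 (downstream statistics undefined)")
        if self.n_species < 1 or self.n_kos < 1:
            raise ValueError("n_species and n_kos must be at least 1")
        lo, hi = self.genes_per_species_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid genes_per_species_range")
        if self.within_species_log_noise_sd < 0:
            raise ValueError("within_species_log_noise_sd must be >= 0")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must lie in [0, 1]")
        if abs(self.driver_spec.target_correlation) > 1:
            raise ValueError("|target_correlation| must be <= 1")
        for name, trend in self.sip_trends.items():
            if name not in SIP_COLUMNS:
                raise ValueError(f"unknown SIP name: {name}")
            if trend.noise_sd < 0:
                raise ValueError(f"negative noise_sd for SIP {name}")
        if set(self.sip_trends) != set(SIP_COLUMNS):
            raise ValueError("sip_trends must cover exactly the ten SIPs")
        demanded = sum(k for _, k in self.module_catalog_spec)
        if demanded > self.n_kos:
            raise ValueError(
                f"module catalog demands {demanded} KOs but the universe has {self.n_kos}"
            )
        module_ids = [m for m, _ in self.module_catalog_spec]
        if len(set(module_ids)) != len(module_ids):
            raise ValueError("duplicate module ids in module_catalog_spec")
        for m in self.driver_spec.target_modules:
            if m not in module_ids:
                raise ValueError(f"target module {m} absent from module_catalog_spec")
        if self.driver_spec.target_sip not in SIP_COLUMNS:
            raise ValueError(f"unknown target SIP: {self.driver_spec.target_sip}")
        frac, _, sd = self.annotation
        if not 0 <= frac <= 1 or sd < 0:
            raise ValueError("invalid annotation spec")


@dataclass
class TruthRecord:
    """Everything needed to score recovery of the planted effects."""

    seed: int
    sip_trends: dict[str, SipTrend]
    species_genes: dict[str, list[str]]
    driver_species_id: str
    target_modules: tuple[str, ...]
    target_sip: str
    target_correlation: float
    mixing_weight: float
    achieved_correlation: float
    per_species_sip_effects: dict[str, dict[str, float]]
    diversity_age_effect: float

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["target_modules"] = list(self.target_modules)
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "TruthRecord":
        d = dict(d)
        d["sip_trends"] = {k: SipTrend(**v) for k, v in d["sip_trends"].items()}
        d["target_modules"] = tuple(d["target_modules"])
        return cls(**d)


@dataclass
class SyntheticStudy:
    metadata: pd.DataFrame  # sample_id, age, gender
    phenome: pd.DataFrame  # samples x 10 SIPs, indexed by sample_id
    species: pd.DataFrame  # species x samples, relative abundance
    genes: pd.DataFrame  # genes x samples, normalized abundance
    gene2ko: pd.DataFrame  # gene_id, ko_id
    gene2taxon: pd.DataFrame  # gene_id, species, identity_pct
    modules: pd.DataFrame  # module_id, ko_id
    lineage: pd.DataFrame  # species, genus, family
    truth: TruthRecord


def _species_logits(
    ages: np.ndarray,
    age_range: tuple[float, float],
    m: np.ndarray,
    noise: np.ndarray,
    diversity_age_effect: float,
) -> np.ndarray:
    a0, a1 = age_range
    span = max(a1 - a0, 1e-12)
    anorm = (ages - a0) / span
    scale = 1.0 / (1.0 + diversity_age_effect * anorm)
    return m[None, :] * scale[:, None] + _SPECIES_NOISE_SD * noise


def _calibrate_mixing(config: SimConfig, m: np.ndarray, driver_idx: int) -> tuple[float, float]:
    """Binary-search the latent mixing weight w so that the empirical
    Spearman correlation between the driver's relative abundance and the
    target SIP matches the requested value at large n.

    Returns (w, achieved correlation at the calibration size).
    """
    target = config.driver_spec.target_correlation
    if target == 0.0:
        return 0.0, 0.0
    sgn = 1.0 if target > 0 else -1.0
    trend = config.sip_trends[config.driver_spec.target_sip]
    n_cal = 4000
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    ages = rng.uniform(*config.age_range, n_cal)
    male = (rng.random(n_cal) >= config.female_fraction).astype(float)
    u = rng.standard_normal(n_cal)
    e_sip = rng.standard_normal(n_cal)
    e_sp = rng.standard_normal(n_cal)
    z = rng.standard_normal((n_cal, config.n_species))

    def achieved(w: float) -> float:
        eps = w * u + np.sqrt(1 - w**2) * e_sip
        sip = np.maximum(
            trend.intercept
            + trend.age_slope * ages
            + trend.gender_offset * male
            + trend.noise_sd * eps,
            0.0,
        )
        zz = z.copy()
        zz[:, driver_idx] = sgn * w * u + np.sqrt(1 - w**2) * e_sp
        logits = _species_logits(ages, config.age_range, m, zz, config.diversity_age_effect)
        ab = np.exp(logits)
        rel = ab[:, driver_idx] / ab.sum(axis=1)
        return spearman_rho(rel, sip).rho

    lo, hi = 0.0, 1.0
    if sgn * achieved(1.0) < abs(target):
        return 1.0, achieved(1.0)
    for _ in range(25):
        mid = 0.5 * (lo + hi)
        if sgn * achieved(mid) < abs(target):
            lo = mid
        else:
            hi = mid
    w = 0.5 * (lo + hi)
    return w, achieved(w)


def generate_cohort(config: SimConfig | None = None) -> SyntheticStudy:
    """Generate a complete synthetic cohort with recorded ground truth.

    Identical config (including seed) yields byte-identical outputs.
    """
    config = config if config is not None else SimConfig()
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (
        rng_meta,
        rng_latent,
        rng_sip,
        rng_species,
        rng_genes,
        rng_ko,
        rng_annot,
    ) = [np.random.default_rng(s) for s in ss.spawn(7)]

    n = config.n_samples
    sample_ids = [f"sample_{i + 1:04d}" for i in range(n)]
    ages = rng_meta.uniform(*config.age_range, n)
    genders = np.where(rng_meta.random(n) < config.female_fraction, "female", "male")
    metadata = pd.DataFrame({"sample_id": sample_ids, "age": ages, "gender": genders})

    species_ids = [f"sp{i + 1:03d}" for i in range(config.n_species)]
    m = np.sort(rng_species.normal(0.0, _SPECIES_LOGMEAN_SD, config.n_species))[::-1]
    driver_idx = species_ids.index(config.driver_spec.driver_species_id)
    w, achieved = _calibrate_mixing(config, m, driver_idx)
    sgn = 1.0 if config.driver_spec.target_correlation >= 0 else -1.0

    u = rng_latent.standard_normal(n)

    # --- phenome ---------------------------------------------------------
    male = (genders == "male").astype(float)
    phen = {}
    for name in SIP_COLUMNS:
        trend = config.sip_trends[name]
        if name == config.driver_spec.target_sip and w > 0:
            eps = w * u + np.sqrt(1 - w**2) * rng_sip.standard_normal(n)
        else:
            eps = rng_sip.standard_normal(n)
        score = (
            trend.intercept
            + trend.age_slope * ages
            + trend.gender_offset * male
            + trend.noise_sd * eps
        )
        phen[name] = np.maximum(score, 0.0)
    phenome = pd.DataFrame(phen, index=pd.Index(sample_ids, name="sample_id"))

    # --- species ---------------------------------------------------------
    z = rng_species.standard_normal((n, config.n_species))
    if w > 0:
        z[:, driver_idx] = sgn * w * u + np.sqrt(1 - w**2) * rng_species.standard_normal(n)
    logits = _species_logits(ages, config.age_range, m, z, config.diversity_age_effect)
    ab = np.exp(logits)
    rel = ab / ab.sum(axis=1, keepdims=True)
    species = pd.DataFrame(
        rel.T, index=pd.Index(species_ids, name="species"), columns=sample_ids
    )

    # --- genes -----------------------------------------------------------
    lo, hi = config.genes_per_species_range
    genes_per_species = rng_genes.integers(lo, hi + 1, config.n_species)
    species_of_gene = np.repeat(np.arange(config.n_species), genes_per_species)
    n_genes = int(genes_per_species.sum())
    gene_ids = [f"g{i + 1:06d}" for i in range(n_genes)]
    baselines = 10.0 ** rng_genes.uniform(-1.0, 1.0, n_genes)
    noise = np.exp(
        rng_genes.normal(0.0, config.within_species_log_noise_sd, (n_genes, n))
    )
    gene_matrix = rel[:, species_of_gene].T * baselines[:, None] * noise
    genes = pd.DataFrame(
        gene_matrix, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids
    )
    species_genes = {
        sp: [gene_ids[i] for i in np.flatnonzero(species_of_gene == idx)]
        for idx, sp in enumerate(species_ids)
    }

    # --- modules and gene -> KO assignment -------------------------------
    ko_ids = [f"K{i + 1:05d}" for i in range(config.n_kos)]
    module_rows = []
    cursor = 0
    module_kos: dict[str, list[str]] = {}
    for module_id, k in config.module_catalog_spec:
        module_kos[module_id] = ko_ids[cursor : cursor + k]
        for ko in module_kos[module_id]:
            module_rows.append((module_id, ko))
        cursor += k
    modules = pd.DataFrame(module_rows, columns=["module_id", "ko_id"])

    driver_gene_pool = list(np.flatnonzero(species_of_gene == driver_idx))
    rng_ko.shuffle(driver_gene_pool)
    other_gene_pool = list(np.flatnonzero(species_of_gene != driver_idx))
    rng_ko.shuffle(other_gene_pool)
    target_modules = config.driver_spec.target_modules

    n_driver_needed = sum(
        _GENES_PER_KO * len(module_kos[mid])
        - _NONDRIVER_KOS_PER_TARGET_MODULE
        for mid in target_modules
    )
    if n_driver_needed > len(driver_gene_pool):
        raise ValueError(
            "driver species has too few genes to own the target modules; "
            "increase genes_per_species_range or shrink the target modules"
        )

    gene_ko_pairs: list[tuple[str, str]] = []
    assigned: set[int] = set()

    def take(pool: list[int], count: int) -> list[int]:
        out = []
        while pool and len(out) < count:
            g = pool.pop()
            if g not in assigned:
                out.append(g)
        if len(out) < count:
            raise ValueError("gene pool exhausted during KO assignment")
        return out

    for mid in target_modules:
        for j, ko in enumerate(module_kos[mid]):
            n_nondriver = 1 if j < _NONDRIVER_KOS_PER_TARGET_MODULE else 0
            members = take(driver_gene_pool, _GENES_PER_KO - n_nondriver)
            members += take(other_gene_pool, n_nondriver)
            for g in members:
                assigned.add(g)
                gene_ko_pairs.append((gene_ids[g], ko))

    background_kos = [k for k in ko_ids if k not in {p[1] for p in gene_ko_pairs}]
    # any gene, any species, may carry a background KO
    general_pool = list(rng_ko.permutation(n_genes))
    for ko in background_kos:
        for g in take(general_pool, _GENES_PER_KO):
            assigned.add(g)
            gene_ko_pairs.append((gene_ids[g], ko))
    gene2ko = pd.DataFrame(gene_ko_pairs, columns=["gene_id", "ko_id"])
    gene2ko = gene2ko.sort_values(["gene_id", "ko_id"], ignore_index=True)

    # --- taxonomy annotations and lineage --------------------------------
    frac_unannot, id_mean, id_sd = config.annotation
    annotated = rng_annot.random(n_genes) >= frac_unannot
    identities = np.clip(rng_annot.normal(id_mean, id_sd, n_genes), 70.0, 100.0)
    gene2taxon = pd.DataFrame(
        {
            "gene_id": np.array(gene_ids)[annotated],
            "species": np.array(species_ids)[species_of_gene[annotated]],
            "identity_pct": identities[annotated],
        }
    )
    lineage = pd.DataFrame(
        {
            "species": species_ids,
            "genus": [f"gen{i // 2 + 1:03d}" for i in range(config.n_species)],
            "family": [f"fam{i // 6 + 1:03d}" for i in range(config.n_species)],
        }
    )

    effects = {sp: {s: 0.0 for s in SIP_COLUMNS} for sp in species_ids}
    effects[config.driver_spec.driver_species_id][config.driver_spec.target_sip] = (
        config.driver_spec.target_correlation
    )
    truth = TruthRecord(
        seed=config.seed,
        sip_trends=dict(config.sip_trends),
        species_genes=species_genes,
        driver_species_id=config.driver_spec.driver_species_id,
        target_modules=tuple(target_modules),
        target_sip=config.driver_spec.target_sip,
        target_correlation=config.driver_spec.target_correlation,
        mixing_weight=float(w),
        achieved_correlation=float(achieved),
        per_species_sip_effects=effects,
        diversity_age_effect=config.diversity_age_effect,
    )
    return SyntheticStudy(
        metadata=metadata,
        phenome=phenome,
        species=species,
        genes=genes,
        gene2ko=gene2ko,
        gene2taxon=gene2taxon,
        modules=modules,
        lineage=lineage,
        truth=truth,
    )


# --------------------------------------------------------------------------
# on-disk representation


def write_study(study: SyntheticStudy, directory, overwrite: bool = False) -> list[Path]:
    """Write a study as the pipeline's TSV/JSON file set.

    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set.  Returns the list of files written.
    """
    if len(study.metadata) == 0:
        raise ValueError("refusing to write a study with an empty sample set")
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} is not empty; pass overwrite=True to replace")
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(df: pd.DataFrame, name: str, index: bool) -> None:
        path = directory / name
        df.to_csv(path, sep="\t", index=index)
        written.append(path)

    _write(study.metadata, "metadata.tsv", index=False)
    _write(study.phenome, "phenome.tsv", index=True)
    _write(study.species, "species.tsv", index=True)
    _write(study.genes, "genes.tsv", index=True)
    _write(study.gene2ko, "gene2ko.tsv", index=False)
    _write(study.gene2taxon, "gene2taxon.tsv", index=False)
    _write(study.modules, "modules.tsv", index=False)
    _write(study.lineage, "lineage.tsv", index=False)
    truth_path = directory / "truth.json"
    truth_path.write_text(json.dumps(study.truth.to_json_dict(), indent=1, sort_keys=True))
    written.append(truth_path)
    return written


def read_study(directory) -> SyntheticStudy:
    """Read back a study written by :func:`write_study`."""
    directory = Path(directory)
    metadata = pd.read_csv(directory / "metadata.tsv", sep="\t")
    phenome = pd.read_csv(directory / "phenome.tsv", sep="\t", index_col="sample_id")
    species = pd.read_csv(directory / "species.tsv", sep="\t", index_col="species")
    genes = pd.read_csv(directory / "genes.tsv", sep="\t", index_col="gene_id")
    gene2ko = pd.read_csv(directory / "gene2ko.tsv", sep="\t")
    gene2taxon = pd.read_csv(directory / "gene2taxon.tsv", sep="\t")
    modules = pd.read_csv(directory / "modules.tsv", sep="\t")
    lineage = pd.read_csv(directory / "lineage.tsv", sep="\t")
    truth = TruthRecord.from_json_dict(json.loads((directory / "truth.json").read_text()))
    return SyntheticStudy(
        metadata=metadata,
        phenome=phenome,
        species=species,
        genes=genes,
        gene2ko=gene2ko,
        gene2taxon=gene2taxon,
        modules=modules,
        lineage=lineage,
        truth=truth,
    )
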