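"""Pipeline orchestration: simulate -> phenome -> ages -> diversity ->
mgs -> modules -> drivers, with a hashed artifact manifest.

A single nested configuration (YAML on disk, plain dict in memory)
drives every stage; unknown keys are rejected, defaults are
materialized, and every output table is recorded in ``manifest.json``
with a SHA-256 content hash, so identical configurations produce
identical manifests.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dermalink import age_index, diversity, drivers, mgs, modules, phenome, simulate

logger = logging.getLogger(__name__)

__all__ = ["default_config", "load_config", "validate_config", "run_pipeline"]

STAGES = ("simulate", "phenome", "ages", "diversity", "mgs", "modules", "drivers")

_DEPENDS = {
    "simulate": (),
    "phenome": ("simulate",),
    "ages": ("simulate",),
    "diversity": ("simulate",),
    "mgs": ("simulate",),
    "modules": ("simulate",),
    "drivers": ("simulate", "mgs", "modules"),
}


def default_config() -> dict:
    """Fully materialized default configuration (every seed explicit)."""
    return {
        "seed": 0,
        "out_dir": "dermalink_out",
        "log_level": "INFO",
        "stages": list(STAGES),
        "simulate": {
            "n_samples": 150,
            "n_species": 40,
            "n_kos": 300,
            "n_modules": 20,
            "kos_per_module": 8,
            "target_sip": "pore",
            "target_correlation": 0.5,
            "diversity_age_effect": 0.5,
            "seed": None,  # falls back to the global seed
        },
        "phenome": {"fdr_threshold": 0.1, "n_age_bins": 5},
        "ages": {"n_folds": 5, "n_trees": 500, "seed": None},
        "diversity": {"n_permutations": 9999, "min_prevalence": 0.1, "seed": None},
        "mgs": {"correlation_threshold": 0.9, "min_genes": 50, "min_samples": 3},
        "modules": {"min_kos": 3, "fdr_threshold": 0.05, "adjust_age": True},
        "drivers": {"module_id": "auto", "sip": "auto"},
    }


def validate_config(config: dict) -> dict:
    """Merge onto defaults, rejecting unknown keys; materialize seeds."""
    merged = default_config()
    for key, value in config.items():
        if key not in merged:
            raise ValueError(f"unknown configuration key: {key!r}")
        if isinstance(merged[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"section {key!r} must be a mapping")
            for sub in value:
                if sub not in merged[key]:
                    raise ValueError(f"unknown configuration key: {key}.{sub}")
            merged[key].update(value)
        else:
            merged[key] = value
    unknown_stages = set(merged["stages"]) - set(STAGES)
    if unknown_stages:
        raise ValueError(f"unknown stages: {sorted(unknown_stages)}")
    for section in ("simulate", "ages", "diversity"):
        if merged[section].get("seed") is None:
            merged[section]["seed"] = merged["seed"]
    return merged


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index)
    return path


def run_pipeline(config: dict) -> dict:
    """Run the requested stages in dependency order.

    Returns the manifest: stage -> {file name -> sha256}, plus the
    configuration used.  A stage failure leaves a partial manifest on
    disk before the exception propagates.
    """
    config = validate_config(copy.deepcopy(config))
    logging.basicConfig(level=getattr(logging, str(config["log_level"]).upper(), 20))
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    requested = [s for s in STAGES if s in config["stages"]]
    data_dir = out_dir / "data"
    for stage in requested:
        for dep in _DEPENDS[stage]:
            if dep not in requested and not (out_dir / f".{dep}.done").exists():
                raise RuntimeError(
                    f"stage {stage!r} requires {dep!r} outputs; run {dep!r} first"
                )

    manifest: dict = {"config": config, "stages": {}}
    manifest_path = out_dir / "manifest.json"
    state: dict = {}

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"][stage] = {f.name: _sha256(f) for f in sorted(files)}
        (out_dir / f".{stage}.done").write_text("")
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))

    try:
        for stage in requested:
            logger.info("running stage %s", stage)
            files = _run_stage(stage, config, out_dir, data_dir, state)
            record(stage, files)
    except Exception:
        manifest["failed"] = True
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise
    return manifest


def _load_study(data_dir: Path, state: dict) -> simulate.SyntheticStudy:
    if "study" not in state:
        state["study"] = simulate.read_study(data_dir)
    return state["study"]


def _run_stage(
    stage: str, config: dict, out_dir: Path, data_dir: Path, state: dict
) -> list[Path]:
    if stage == "simulate":
        sim_cfg = config["simulate"]
        cfg = simulate.SimConfig(
            n_samples=sim_cfg["n_samples"],
            n_species=sim_cfg["n_species"],
            n_kos=sim_cfg["n_kos"],
            module_catalog_spec=simulate.default_module_catalog_spec(
                sim_cfg["n_modules"], sim_cfg["kos_per_module"]
            ),
            driver_spec=simulate.DriverSpec(
                target_sip=sim_cfg["target_sip"],
                target_correlation=sim_cfg["target_correlation"],
            ),
            diversity_age_effect=sim_cfg["diversity_age_effect"],
            seed=sim_cfg["seed"],
        )
        study = simulate.generate_cohort(cfg)
        state["study"] = study
        return simulate.write_study(study, data_dir, overwrite=True)

    study = _load_study(data_dir, state)
    ages_vec = study.metadata.set_index("sample_id").loc[study.phenome.index, "age"]

    if stage == "phenome":
        ph_cfg = config["phenome"]
        trends = phenome.sip_age_regression(
            study.phenome, study.metadata, fdr_threshold=ph_cfg["fdr_threshold"]
        )
        pca = phenome.phenome_pca(study.phenome)
        bins = pd.qcut(ages_vec, ph_cfg["n_age_bins"], duplicates="drop").astype(str)
        separation = phenome.group_separation_test(pca.scores["PC1"], bins)
        explained = pd.DataFrame(
            {
                "component": pca.scores.columns,
                "explained_variance": pca.explained_variance,
            }
        )
        return [
            _write(trends, out_dir / "trends.tsv"),
            _write(pca.scores, out_dir / "pca_scores.tsv", index=True),
            _write(pca.loadings, out_dir / "pca_loadings.tsv", index=True),
            _write(explained, out_dir / "pca_explained.tsv"),
            _write(separation, out_dir / "pc1_group_separation.tsv"),
        ]

    if stage == "ages":
        a_cfg = config["ages"]
        kw = dict(n_folds=a_cfg["n_folds"], n_trees=a_cfg["n_trees"], seed=a_cfg["seed"])
        spa = age_index.fit_age_index(study.phenome, ages_vec, **kw)
        sma = age_index.fit_age_index(study.species.T, ages_vec, **kw)
        sia = age_index.fit_age_index(
            age_index.combine_features(study.phenome, study.species), ages_vec, **kw
        )
        table = pd.DataFrame(
            {
                "sample_id": study.phenome.index,
                "age": ages_vec.to_numpy(),
                "spa": spa.predictions.to_numpy(),
                "sma": sma.predictions.to_numpy(),
                "sia": sia.predictions.to_numpy(),
            }
        )
        summary = pd.DataFrame(
            {
                "index": ["spa", "sma", "sia"],
                "mae_years": [spa.mae, sma.mae, sia.mae],
                "r2_pct_mean": [r.fold_r2.mean() for r in (spa, sma, sia)],
                "r2_pct_sd": [r.fold_r2.std(ddof=1) for r in (spa, sma, sia)],
            }
        )
        return [
            _write(table, out_dir / "ages.tsv"),
            _write(summary, out_dir / "ages_summary.tsv"),
            _write(spa.importances, out_dir / "spa_importance.tsv"),
            _write(sma.importances, out_dir / "sma_importance.tsv"),
        ]

    if stage == "diversity":
        d_cfg = config["diversity"]
        alpha = diversity.shannon(study.species)
        alpha_assoc = diversity.diversity_sip_associations(
            alpha.loc[study.phenome.index], study.phenome, ages_vec
        )
        dist = diversity.bray_curtis(study.species)
        variables = study.phenome.copy()
        variables["age"] = ages_vec
        total, marginals = diversity.permanova_combined(
            dist, variables, n_permutations=d_cfg["n_permutations"], seed=d_cfg["seed"]
        )
        beta = pd.DataFrame(
            [
                (r.variable, r.r2, r.pseudo_f, r.p_value, r.n_permutations)
                for r in [total, *marginals]
            ],
            columns=["variable", "r2", "pseudo_f", "p_value", "n_permutations"],
        )
        assoc = diversity.species_sip_association(
            study.species, study.phenome, ages_vec, min_prevalence=d_cfg["min_prevalence"]
        )
        return [
            _write(
                alpha.rename("shannon").rename_axis("sample_id").reset_index(),
                out_dir / "alpha.tsv",
            ),
            _write(alpha_assoc, out_dir / "alpha_assoc.tsv"),
            _write(beta, out_dir / "beta_permanova.tsv"),
            _write(assoc, out_dir / "species_assoc.tsv"),
        ]

    if stage == "mgs":
        m_cfg = config["mgs"]
        filtered = mgs.filter_genes(study.genes, min_samples=m_cfg["min_samples"])
        cags = mgs.canopy_cluster(
            filtered, correlation_threshold=m_cfg["correlation_threshold"]
        )
        state["cags"] = cags
        selected = mgs.select_mgs(cags, min_genes=m_cfg["min_genes"])
        selected = [
            mgs.assign_taxonomy(m, study.gene2taxon, study.lineage) for m in selected
        ]
        state["mgs"] = selected
        mgs_table = pd.DataFrame(
            [
                (m.mgs_id, m.n_genes, m.taxonomy_rank, m.taxonomy_label or "", m.classified_species)
                for m in selected
            ],
            columns=["mgs_id", "n_genes", "rank", "label", "classified"],
        )
        profiles = pd.DataFrame(
            {m.mgs_id: m.cag.profile for m in selected}, index=filtered.columns
        ).T
        profiles.index.name = "mgs_id"
        return [
            _write(mgs.assignment_frame(cags), out_dir / "cags.tsv"),
            _write(mgs_table, out_dir / "mgs.tsv"),
            _write(profiles, out_dir / "mgs_profiles.tsv", index=True),
        ]

    if stage == "modules":
        mod_cfg = config["modules"]
        ko_table = modules.ko_abundance(study.genes, study.gene2ko)
        scc = modules.ko_sip_scc(
            ko_table, study.phenome, ages_vec, adjust_age=mod_cfg["adjust_age"]
        )
        assoc = modules.module_sip_test(
            scc,
            study.modules,
            min_kos=mod_cfg["min_kos"],
            fdr_threshold=mod_cfg["fdr_threshold"],
        )
        state["module_assoc"] = assoc
        return [
            _write(scc, out_dir / "ko_scc.tsv"),
            _write(assoc, out_dir / "module_assoc.tsv"),
        ]

    if stage == "drivers":
        dr_cfg = config["drivers"]
        assoc = state.get("module_assoc")
        if assoc is None:
            assoc = pd.read_csv(out_dir / "module_assoc.tsv", sep="\t")
        module_id, sip = dr_cfg["module_id"], dr_cfg["sip"]
        if module_id == "auto" or sip == "auto":
            ordered = assoc.sort_values(
                ["q_value", "module_id", "sip"], ignore_index=True
            )
            if ordered.empty:
                raise RuntimeError("no module associations available for driver analysis")
            module_id = ordered.loc[0, "module_id"]
            sip = ordered.loc[0, "sip"]
        if "cags" in state:
            assignment = mgs.assignment_frame(state["cags"])
        else:
            assignment = pd.read_csv(out_dir / "cags.tsv", sep="\t")
        impacts = drivers.leave_one_mgs_out(
            study.genes,
            study.gene2ko,
            assignment,
            study.modules,
            module_id,
            sip,
            study.phenome,
            ages_vec,
        )
        ranked = drivers.rank_drivers(impacts)
        return [_write(ranked, out_dir / "drivers.tsv")]

    raise AssertionError(f"unknown stage {stage}")
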