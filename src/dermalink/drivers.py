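"""Leave-one-MGS-out attribution of module-phenotype correlations.

The contribution of an MGS to a module-SIP correlation is the change in
the module's median KO SCC when that MGS's genes are excluded from the
KO abundance sums.  KOs whose abundance becomes all-zero or constant
after removal are dropped from the post-removal median (a constant
column has no defined rank correlation) and reflected in
``n_kos_retained``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from dermalink.modules import ko_abundance, ko_sip_scc, module_ko_sets

logger = logging.getLogger(__name__)

__all__ = ["leave_one_mgs_out", "rank_drivers"]


def _median_scc(scc: pd.DataFrame, kos: set[str], sip: str) -> float:
    sub = scc[(scc["sip"] == sip) & (scc["ko_id"].isin(kos))]
    if sub.empty:
        return float("nan")
    return float(sub["rho"].median())


def leave_one_mgs_out(
    genes: pd.DataFrame,
    gene2ko: pd.DataFrame,
    mgs_assignment: pd.DataFrame,
    modules: pd.DataFrame | dict[str, set[str]],
    module_id: str,
    sip: str,
    phenome: pd.DataFrame,
    ages,
    candidate_mgs: list[str] | None = None,
    adjust_age: bool = True,
) -> pd.DataFrame:
    """Leave-one-MGS-out deltas for one module-SIP correlation.

    ``mgs_assignment`` is a (gene_id, cag_id/mgs_id) table.  For each
    candidate MGS the KO abundances are recomputed without that MGS's
    genes and the module's KO SCCs against the SIP re-derived; ``delta``
    is (median without) - (full median).  Candidates default to the MGSs
    contributing at least one gene to at least one module KO (any other
    MGS provably has delta = 0).  When every module KO loses all its
    genes the row carries NaN medians and n_kos_retained = 0.
    """
    catalog = modules if isinstance(modules, dict) else module_ko_sets(modules)
    if module_id not in catalog:
        raise KeyError(f"unknown module: {module_id}")
    module_kos = catalog[module_id]
    ages = np.asarray(ages, dtype=float)

    id_col = "mgs_id" if "mgs_id" in mgs_assignment.columns else "cag_id"
    assignment = mgs_assignment.set_index("gene_id")[id_col]

    full_ko = ko_abundance(genes, gene2ko)
    full_scc = ko_sip_scc(full_ko, phenome, ages, adjust_age=adjust_age)
    median_full = _median_scc(full_scc, module_kos, sip)

    module_gene_map = gene2ko[gene2ko["ko_id"].isin(module_kos)]
    contributing = set(
        assignment.reindex(module_gene_map["gene_id"]).dropna().unique()
    )
    if candidate_mgs is None:
        candidates = sorted(contributing)
    else:
        candidates = list(candidate_mgs)

    rows = []
    for mgs_id in candidates:
        removed_genes = set(assignment.index[assignment == mgs_id])
        if not removed_genes & set(module_gene_map["gene_id"]):
            rows.append((mgs_id, module_id, sip, median_full, median_full, 0.0, len(module_kos & set(full_scc["ko_id"]))))
            continue
        kept_genes = genes.loc[~genes.index.isin(removed_genes)]
        reduced_ko = ko_abundance(kept_genes, module_gene_map)
        nonconstant = reduced_ko.loc[np.ptp(reduced_ko.to_numpy(dtype=float), axis=1) > 0]
        n_retained = len(nonconstant)
        if n_retained == 0:
            logger.warning(
                "module %s loses all KOs when %s is removed", module_id, mgs_id
            )
            rows.append((mgs_id, module_id, sip, median_full, np.nan, np.nan, 0))
            continue
        scc_wo = ko_sip_scc(nonconstant, phenome, ages, adjust_age=adjust_age)
        median_wo = _median_scc(scc_wo, module_kos, sip)
        rows.append(
            (
                mgs_id,
                module_id,
                sip,
                median_full,
                median_wo,
                median_wo - median_full,
                n_retained,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mgs_id",
            "module_id",
            "sip",
            "median_scc_full",
            "median_scc_without",
            "delta",
            "n_kos_retained",
        ],
    )


def rank_drivers(impacts: pd.DataFrame) -> pd.DataFrame:
    """Order driver impacts by |delta| descending.

    Rows with an undefined post-removal median (NaN delta) sort last;
    ties break by mgs_id.
    """
    if impacts.empty:
        raise ValueError("impacts table is empty")
    out = impacts.copy()
    abs_delta = out["delta"].abs()
    out["_undefined"] = out["delta"].isna()
    out["_abs"] = abs_delta.fillna(-np.inf)
    out = out.sort_values(
        ["_undefined", "_abs", "mgs_id"], ascending=[True, False, True], ignore_index=True
    )
    return out.drop(columns=["_undefined", "_abs"])
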