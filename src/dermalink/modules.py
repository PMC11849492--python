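"""Functional-module enrichment against skin phenotypes.

KO abundance is the per-sample sum of its member genes' abundances.
For every KO x SIP pair an age-adjusted Spearman correlation (SCC) is
computed; a module is then called against a SIP by a two-sided
Mann-Whitney test of its in-module KO SCCs versus all out-of-module KO
SCCs, with BH FDR across all module x SIP tests and a direction from
the median comparison.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from dermalink.simulate import SIP_COLUMNS
from dermalink.stats import bh_fdr, mann_whitney_u
from dermalink.stats import _t_p_value  # shared t-approximation

logger = logging.getLogger(__name__)

__all__ = ["ko_abundance", "ko_sip_scc", "module_sip_test", "module_ko_sets"]


def ko_abundance(genes: pd.DataFrame, gene2ko: pd.DataFrame) -> pd.DataFrame:
    """KO x sample abundance: the sum of member genes' abundances.

    Genes without a KO are ignored; a gene mapped to more than one KO
    means the catalog is malformed and raises.
    """
    counts = gene2ko["gene_id"].value_counts()
    multi = counts[counts > 1]
    if len(multi):
        raise ValueError(f"genes mapped to multiple KOs: {list(multi.index[:5])}")
    mapping = gene2ko[gene2ko["gene_id"].isin(genes.index)]
    if mapping.empty:
        return pd.DataFrame(columns=genes.columns)
    sub = genes.loc[mapping["gene_id"]]
    sub.index = pd.Index(mapping["ko_id"].to_numpy(), name="ko_id")
    out = sub.groupby(level=0).sum()
    out.index.name = "ko_id"
    return out


def _rank_rows(matrix: np.ndarray) -> np.ndarray:
    return rankdata(matrix, axis=1)


def _center_norm(matrix: np.ndarray) -> np.ndarray:
    c = matrix - matrix.mean(axis=1, keepdims=True)
    norms = np.sqrt((c**2).sum(axis=1, keepdims=True))
    return c / norms


def ko_sip_scc(
    ko_table: pd.DataFrame,
    phenome: pd.DataFrame,
    ages,
    adjust_age: bool = True,
) -> pd.DataFrame:
    """Age-adjusted Spearman correlation of every KO with every SIP.

    Vectorized first-order partial correlation on midranks; equivalent to
    calling :func:`dermalink.stats.adjusted_spearman` per pair.  Constant
    KOs are dropped with a warning.  Returns a long table with columns
    (ko_id, sip, rho, p_value, n).
    """
    ages = np.asarray(ages, dtype=float)
    n = len(ages)
    vals = ko_table.to_numpy(dtype=float)
    constant = np.ptp(vals, axis=1) == 0
    if constant.any():
        dropped = list(ko_table.index[constant])
        logger.warning("dropping %d constant KOs: %s", len(dropped), dropped[:5])
    kept = ko_table.index[~constant]
    vals = vals[~constant]
    if vals.shape[0] == 0:
        return pd.DataFrame(columns=["ko_id", "sip", "rho", "p_value", "n"])
    rk = _center_norm(_rank_rows(vals))  # KO x samples, rank-normalized
    ra = _center_norm(rankdata(ages)[None, :])[0]
    frames = []
    df = n - 3 if adjust_age else n - 2
    for sip in SIP_COLUMNS:
        if sip not in phenome.columns:
            continue
        rs = _center_norm(rankdata(phenome[sip].to_numpy(dtype=float))[None, :])[0]
        r_xy = rk @ rs
        if adjust_age:
            r_xz = rk @ ra
            r_yz = float(rs @ ra)
            denom = np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
            rho = np.clip((r_xy - r_xz * r_yz) / denom, -1.0, 1.0)
        else:
            rho = np.clip(r_xy, -1.0, 1.0)
        p = np.array([_t_p_value(r, df) for r in rho])
        frames.append(
            pd.DataFrame({"ko_id": kept, "sip": sip, "rho": rho, "p_value": p, "n": n})
        )
    return pd.concat(frames, ignore_index=True)


def module_ko_sets(modules: pd.DataFrame) -> dict[str, set[str]]:
    """Module catalog as {module_id: set of KO ids}."""
    return {m: set(g["ko_id"]) for m, g in modules.groupby("module_id")}


def module_sip_test(
    scc: pd.DataFrame,
    modules: pd.DataFrame | dict[str, set[str]],
    min_kos: int = 3,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """In-module vs out-of-module SCC enrichment per (module, SIP).

    Two-sided Mann-Whitney of the module's KO SCCs against all other
    KOs' SCCs for the same SIP; direction = positive iff the in-module
    median exceeds the out-of-module median; BH FDR jointly over all
    tested module x SIP pairs.  Modules with fewer than ``min_kos`` KOs
    present in the SCC table are skipped.
    """
    catalog = modules if isinstance(modules, dict) else module_ko_sets(modules)
    rows = []
    for sip, sub in scc.groupby("sip", sort=True):
        ko_index = sub.set_index("ko_id")["rho"]
        universe = set(ko_index.index)
        for module_id in sorted(catalog):
            in_kos = sorted(catalog[module_id] & universe)
            if len(in_kos) < min_kos:
                logger.info(
                    "module %s has %d KOs with SCCs (< %d); skipped for %s",
                    module_id,
                    len(in_kos),
                    min_kos,
                    sip,
                )
                continue
            out_kos = sorted(universe - set(in_kos))
            if not out_kos:
                raise ValueError(
                    f"module {module_id} covers the entire KO universe; no background"
                )
            rho_in = ko_index.loc[in_kos].to_numpy()
            rho_out = ko_index.loc[out_kos].to_numpy()
            test = mann_whitney_u(rho_in, rho_out)
            med_in = float(np.median(rho_in))
            med_out = float(np.median(rho_out))
            rows.append(
                (
                    module_id,
                    sip,
                    med_in,
                    med_out,
                    "positive" if med_in > med_out else "negative",
                    test.u_statistic,
                    test.p_value,
                    len(in_kos),
                )
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "module_id",
            "sip",
            "median_in",
            "median_out",
            "direction",
            "u_statistic",
            "p_value",
            "n_kos_in",
        ],
    )
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
        out["significant"] = out["q_value"] < fdr_threshold
    return out
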