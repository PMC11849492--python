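"""Temporal dynamics of the skin imaging phenome.

Per-SIP age regression with FDR control, correlation-matrix PCA of the
ten SIP scores, and rank-based separation tests of sample groups along a
principal component.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import linregress

from dermalink.simulate import SIP_COLUMNS
from dermalink.stats import bh_fdr, mann_whitney_u

__all__ = ["sip_age_regression", "phenome_pca", "group_separation_test", "PcaResult"]


def _check_phenome(phenome: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SIP_COLUMNS if c not in phenome.columns]
    if missing:
        raise ValueError(f"phenome table is missing SIP columns: {missing}")
    table = phenome[list(SIP_COLUMNS)]
    if table.isna().any().any():
        raise ValueError("phenome table contains missing values")
    return table


def sip_age_regression(
    phenome: pd.DataFrame, metadata: pd.DataFrame, fdr_threshold: float = 0.1
) -> pd.DataFrame:
    """Ordinary least squares of age on each SIP score.

    The SIP is the independent variable and age the dependent variable,
    so the slope is in years per score unit.  q-values are BH across the
    ten tests; a constant SIP column is reported with an error status and
    NaN statistics while the remaining SIPs are still tested.
    """
    table = _check_phenome(phenome)
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    ages = meta.loc[table.index, "age"].to_numpy(dtype=float)
    if len(table) < 10:
        raise ValueError("need at least 10 samples for the age regressions")
    rows = []
    for sip in SIP_COLUMNS:
        x = table[sip].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append((sip, np.nan, np.nan, "constant column"))
            continue
        fit = linregress(x, ages)
        rows.append((sip, fit.slope, fit.pvalue, ""))
    result = pd.DataFrame(rows, columns=["sip", "slope", "p_value", "status"])
    valid = result["p_value"].notna()
    q = np.full(len(result), np.nan)
    if valid.any():
        q[valid.to_numpy()] = bh_fdr(result.loc[valid, "p_value"].to_numpy())
    result["q_value"] = q
    result["significant"] = result["q_value"] < fdr_threshold
    return result


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # SIPs x components
    explained_variance: np.ndarray  # proportions summing to 1


def phenome_pca(phenome: pd.DataFrame) -> PcaResult:
    """PCA of the z-scored SIP matrix (correlation-matrix PCA).

    SIP units are heterogeneous device scores, so each column is scaled
    to mean 0 / sd 1 before the eigendecomposition.  Component signs are
    fixed so that each loading vector's largest-magnitude entry is
    positive, making plots and tests reproducible.
    """
    table = _check_phenome(phenome)
    if len(table) < 3:
        raise ValueError("need at least 3 samples for PCA")
    X = table.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance SIP column: {SIP_COLUMNS[zero[0]]}")
    Z = (X - X.mean(axis=0)) / sd
    _, svals, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt.T
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = Z @ loadings
    explained = svals**2 / (svals**2).sum()
    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=list(SIP_COLUMNS), columns=comp_names),
        explained_variance=explained,
    )


def group_separation_test(
    scores: pd.Series, groups: pd.Series, fdr_threshold: float = 0.1
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney tests of component scores between
    groups, with BH FDR across the pairs."""
    scores = pd.Series(scores)
    groups = pd.Series(groups, index=scores.index)
    levels = [g for g in pd.unique(groups) if pd.notna(g)]
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    for g in levels:
        if (groups == g).sum() == 0:
            raise ValueError(f"group {g!r} is empty")
    rows = []
    for g1, g2 in combinations(levels, 2):
        res = mann_whitney_u(scores[groups == g1], scores[groups == g2])
        rows.append((g1, g2, res.u_statistic, res.p_value, res.n1, res.n2, res.method))
    out = pd.DataFrame(
        rows, columns=["group1", "group2", "u_statistic", "p_value", "n1", "n2", "method"]
    )
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < fdr_threshold
    return out
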