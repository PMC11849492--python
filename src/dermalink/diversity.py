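"""Taxonomic/functional diversity and its phenotype associations.

Shannon alpha diversity, Bray-Curtis beta diversity, PERMANOVA written
from the McArdle-Anderson pseudo-F definition, age-adjusted rank
correlations of alpha diversity with the ten SIPs, and a per-species
association model (arcsine-square-root linear model with age as a
covariate, standing in for MaAsLin).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations as _iter_permutations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform

from dermalink.simulate import SIP_COLUMNS
from dermalink.stats import adjusted_spearman, bh_fdr, spearman_rho

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "shannon",
    "bray_curtis",
    "permanova",
    "permanova_combined",
    "diversity_sip_associations",
    "species_sip_association",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(v < -1e-12):
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class PermanovaResult:
    variable: str
    r2: float
    pseudo_f: float
    p_value: float
    n_permutations: int


def _relative(profile: pd.DataFrame) -> pd.DataFrame:
    """Renormalize each sample (column) of a feature x sample table to sum 1."""
    vals = profile.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("abundances must be non-negative")
    totals = vals.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"all-zero sample: {profile.columns[zero[0]]}")
    return profile / totals


def shannon(profile: pd.DataFrame) -> pd.Series:
    """Shannon diversity H = -sum p ln p per sample (nats).

    ``profile`` is features x samples with non-negative abundances; each
    sample is renormalized to relative abundance first.
    """
    rel = _relative(profile).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(rel > 0, rel * np.log(rel), 0.0)
    return pd.Series(-terms.sum(axis=0), index=profile.columns, name="shannon")


def bray_curtis(profile: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarities d(i,j) = sum|x-y| / sum(x+y) between
    samples, computed on renormalized relative abundances."""
    rel = _relative(profile)
    mat = squareform(pdist(rel.to_numpy(dtype=float).T, metric="braycurtis"))
    return DistanceMatrix(ids=list(profile.columns), values=mat)


def _design_matrix(variable, name: str) -> np.ndarray:
    """Centered design column(s): dummy coding for categories, the
    centered values for a continuous variable."""
    v = pd.Series(variable)
    if v.dtype.kind in "OUSb" or isinstance(v.dtype, pd.CategoricalDtype):
        dummies = pd.get_dummies(v, dtype=float)
        if dummies.shape[1] < 2:
            raise ValueError(f"zero design variance for variable {name!r}")
        X = dummies.to_numpy()
    else:
        x = v.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"zero design variance for variable {name!r}")
        X = x[:, None]
    return X - X.mean(axis=0)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _permanova_stats(g: np.ndarray, hat: np.ndarray, q: int) -> tuple[float, float]:
    n = g.shape[0]
    tr_g = np.trace(g)
    tr_hgh = float(np.sum(hat * g))  # tr(HG) = tr(HGH) for idempotent H
    r2 = tr_hgh / tr_g
    resid = (tr_g - tr_hgh) / (n - q - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pseudo_f = (tr_hgh / q) / resid
    return r2, pseudo_f


def permanova(
    dist: DistanceMatrix,
    variable,
    n_permutations: int | str = 9999,
    seed: int = 0,
    name: str | None = None,
) -> PermanovaResult:
    """One-variable PERMANOVA from the pseudo-F definition.

    G = -1/2 J D^2 J (double-centered squared distances), H the hat
    matrix of the centered design; R^2 = tr(HGH)/tr(G) and pseudo-F =
    [tr(HGH)/q] / [tr((I-H)G(I-H))/(n-q-1)].  The p-value permutes the
    sample labels of the variable: (1 + #{F_perm >= F_obs}) / (1 + B).
    ``n_permutations="exhaustive"`` enumerates all n! relabelings (n <= 7).
    """
    v = pd.Series(variable)
    name = name or (v.name if v.name is not None else "variable")
    if len(v) != dist.n:
        raise ValueError("variable length must match the distance matrix")
    X = _design_matrix(v, name)
    q = np.linalg.matrix_rank(X)
    hat = X @ np.linalg.pinv(X)
    g = _gower_center(dist.values)
    r2, f_obs = _permanova_stats(g, hat, q)

    if n_permutations == "exhaustive":
        n = dist.n
        if n > 7:
            raise ValueError("exhaustive permutation only supported for n <= 7")
        count = 0
        total = 0
        for perm in _iter_permutations(range(n)):
            idx = np.array(perm)
            g_p = g[np.ix_(idx, idx)]
            _, f_p = _permanova_stats(g_p, hat, q)
            total += 1
            if f_p >= f_obs - 1e-12:
                count += 1
        return PermanovaResult(name, r2, f_obs, count / total, total)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(int(n_permutations)):
        idx = rng.permutation(dist.n)
        g_p = g[np.ix_(idx, idx)]
        _, f_p = _permanova_stats(g_p, hat, q)
        if f_p >= f_obs:
            count += 1
    p = (1 + count) / (1 + int(n_permutations))
    return PermanovaResult(name, r2, f_obs, p, int(n_permutations))


def permanova_combined(
    dist: DistanceMatrix,
    variables: pd.DataFrame,
    n_permutations: int = 9999,
    seed: int = 0,
) -> tuple[PermanovaResult, list[PermanovaResult]]:
    """Joint PERMANOVA of several variables plus marginal one-variable fits.

    The total R^2 comes from the full design matrix (all variables
    jointly); marginal per-variable R^2 from single-variable fits.  A
    rank-deficient joint design raises, listing the offending columns.
    """
    if variables.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    blocks = []
    offending = []
    X = np.empty((dist.n, 0))
    for col in variables.columns:
        b = _design_matrix(variables[col], str(col))
        cand = np.hstack([X, b])
        if np.linalg.matrix_rank(cand) < X.shape[1] + np.linalg.matrix_rank(b):
            offending.append(str(col))
        else:
            X = cand
        blocks.append(b)
    if offending:
        raise ValueError(f"collinear design columns: {offending}")
    q = np.linalg.matrix_rank(X)
    hat = X @ np.linalg.pinv(X)
    g = _gower_center(dist.values)
    r2, f_obs = _permanova_stats(g, hat, q)
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            idx = rng.permutation(dist.n)
            g_p = g[np.ix_(idx, idx)]
            _, f_p = _permanova_stats(g_p, hat, q)
            if f_p >= f_obs:
                count += 1
        p = (1 + count) / (1 + n_permutations)
    else:
        p = float("nan")
    total = PermanovaResult("combined", r2, f_obs, p, n_permutations)
    marginals = [
        permanova(dist, variables[col], n_permutations, seed, name=str(col))
        for col in variables.columns
    ]
    return total, marginals


def diversity_sip_associations(
    diversity: pd.Series, phenome: pd.DataFrame, ages, fdr_threshold: float = 0.1
) -> pd.DataFrame:
    """Rank correlations of alpha diversity with age and each SIP.

    Age uses the plain Spearman correlation; each SIP the age-adjusted
    (partial) Spearman.  q-values are BH across the ten SIP tests.
    """
    div = np.asarray(diversity, dtype=float)
    ages = np.asarray(ages, dtype=float)
    rows = [("age", *_corr_row(spearman_rho(div, ages)))]
    for sip in SIP_COLUMNS:
        res = adjusted_spearman(div, phenome[sip].to_numpy(dtype=float), ages)
        rows.append((sip, *_corr_row(res)))
    out = pd.DataFrame(rows, columns=["variable", "rho", "p_value", "n"])
    q = np.full(len(out), np.nan)
    q[1:] = bh_fdr(out["p_value"].to_numpy()[1:])
    out["q_value"] = q
    out["significant"] = out["q_value"] < fdr_threshold
    return out


def _corr_row(res):
    return res.rho, res.p_value, res.n


def species_sip_association(
    species: pd.DataFrame,
    phenome: pd.DataFrame,
    ages,
    min_prevalence: float = 0.1,
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-species SIP associations: a linear-model stand-in for MaAsLin.

    For each (species, SIP) pair, ordinary least squares of the
    arcsine-square-root-transformed relative abundance on the z-scored
    SIP and z-scored age (the classic default transform/covariate choice
    for compositional microbiome associations).  Species present in
    fewer than ``min_prevalence`` of samples are excluded; q-values are
    BH over all species x SIP tests jointly.
    """
    rel = _relative(species)
    ages = np.asarray(ages, dtype=float)
    prevalence = (rel.to_numpy() > 0).mean(axis=1)
    kept = rel.index[prevalence >= min_prevalence]
    z_age = (ages - ages.mean()) / ages.std(ddof=1)
    rows = []
    for sp in kept:
        y = np.arcsin(np.sqrt(np.clip(rel.loc[sp].to_numpy(dtype=float), 0, 1)))
        if np.ptp(y) == 0:
            logger.warning("species %s has zero variance after transform; skipped", sp)
            continue
        for sip in SIP_COLUMNS:
            x = phenome[sip].to_numpy(dtype=float)
            z_x = (x - x.mean()) / x.std(ddof=1)
            design = sm.add_constant(np.column_stack([z_x, z_age]))
            fit = sm.OLS(y, design).fit()
            rows.append((sp, sip, fit.params[1], fit.pvalues[1]))
    out = pd.DataFrame(rows, columns=["species", "sip", "coefficient", "p_value"])
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
        out["significant"] = out["q_value"] < fdr_threshold
    return out
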