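"""Co-abundance gene groups (CAGs) and metagenomic species (MGSs).

Genes detected in at least three samples are clustered by co-abundance
with a deterministic greedy canopy algorithm: seeds are taken in order
of descending total abundance, a canopy collects all unassigned genes
whose Pearson correlation with the canopy profile exceeds the threshold
(0.9 by default), and the profile -- the per-sample 75th percentile of
the member genes -- is iterated to a fixed point.  CAGs above a gene
count threshold become MGSs and receive a taxonomy label from per-gene
sequence-similarity hits via majority rules at the species (>=95%
identity), genus (>=85%) and family (>=75%) levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CAG",
    "MGS",
    "filter_genes",
    "canopy_cluster",
    "cag_profile",
    "select_mgs",
    "assign_taxonomy",
]


@dataclass
class CAG:
    """A co-abundance gene group with its 75th-percentile profile."""

    cag_id: str
    members: list[str]
    profile: np.ndarray  # per-sample


@dataclass
class MGS:
    """A large CAG, optionally carrying a rule-derived taxonomy label."""

    cag: CAG
    taxonomy_label: str | None = None
    taxonomy_rank: str = "unclassified"  # species | genus | family | unclassified
    classified_species: bool = False

    @property
    def mgs_id(self) -> str:
        return self.cag.cag_id

    @property
    def n_genes(self) -> int:
        return len(self.cag.members)


def filter_genes(genes: pd.DataFrame, min_samples: int = 3) -> pd.DataFrame:
    """Keep genes detected (abundance > 0) in at least ``min_samples``
    samples; row order is preserved."""
    detected = (genes.to_numpy(dtype=float) > 0).sum(axis=1)
    kept = genes.loc[detected >= min_samples]
    if len(kept) == 0:
        logger.warning("gene filter removed every gene (min_samples=%d)", min_samples)
    return kept


def _profile_75(matrix: np.ndarray) -> np.ndarray:
    # np.percentile's default linear interpolation is exactly the
    # (n - 1) * 0.75 convention of stats.percentile_75
    return np.percentile(matrix, 75, axis=0)


def canopy_cluster(
    genes: pd.DataFrame,
    correlation_threshold: float = 0.9,
    max_iterations: int = 10,
) -> list[CAG]:
    """Deterministic greedy canopy clustering of gene abundance profiles.

    Unassigned genes are visited in order of descending total abundance;
    each seeds a canopy whose membership (Pearson r > threshold against
    the canopy profile) and 75th-percentile profile are iterated to a
    fixed point (at most ``max_iterations`` rounds).  Members are then
    assigned and never revisited; singleton canopies are retained.
    Output is sorted by size descending.
    """
    if genes.shape[1] < 3:
        raise ValueError("need at least 3 samples for stable correlations")
    X = genes.to_numpy(dtype=float)
    ids = list(genes.index)
    n_genes = X.shape[0]
    xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((xc**2).sum(axis=1))
    constant = norms == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = xc / norms[:, None]
    # seed order: descending total abundance, stable on ties
    order = np.argsort(-X.sum(axis=1), kind="stable")
    unassigned = np.ones(n_genes, dtype=bool)
    raw_groups: list[list[int]] = []
    for seed in order:
        if not unassigned[seed]:
            continue
        if constant[seed]:
            logger.warning("gene %s has a constant profile; kept as singleton", ids[seed])
            unassigned[seed] = False
            raw_groups.append([seed])
            continue
        profile = X[seed]
        members = np.array([seed])
        for _ in range(max_iterations):
            pc = profile - profile.mean()
            pn = np.sqrt((pc**2).sum())
            if pn == 0:
                members = np.array([seed])
                break
            r = Z @ (pc / pn)
            cand = np.flatnonzero(unassigned & (r > correlation_threshold) & ~constant)
            if seed not in cand:
                members = np.array([seed])
                break
            new_profile = _profile_75(X[cand])
            if len(cand) == len(members) and np.array_equal(cand, members):
                members = cand
                break
            members, profile = cand, new_profile
        unassigned[members] = False
        raw_groups.append(list(members))
    raw_groups.sort(key=lambda g: (-len(g), g[0]))
    cags = []
    for i, group in enumerate(raw_groups):
        cags.append(
            CAG(
                cag_id=f"CAG{i + 1:05d}",
                members=[ids[j] for j in group],
                profile=_profile_75(X[group]),
            )
        )
    return cags


def cag_profile(genes: pd.DataFrame, member_ids) -> pd.Series:
    """Per-sample 75th percentile of the member genes' abundances."""
    member_ids = list(member_ids)
    if not member_ids:
        raise ValueError("member_ids must be non-empty")
    missing = [g for g in member_ids if g not in genes.index]
    if missing:
        raise KeyError(f"unknown gene ids: {missing[:5]}")
    return pd.Series(
        _profile_75(genes.loc[member_ids].to_numpy(dtype=float)),
        index=genes.columns,
        name="profile",
    )


def select_mgs(cags: list[CAG], min_genes: int = 500) -> list[MGS]:
    """CAGs with strictly more than ``min_genes`` members become MGSs
    (taxonomy initially unassigned)."""
    return [MGS(cag=c) for c in cags if len(c.members) > min_genes]


def _majority(labels: list[str]):
    if not labels:
        return None, 0
    series = pd.Series(labels).value_counts()
    top = series.max()
    winners = sorted(series.index[series == top])
    return winners[0], int(top)


def assign_taxonomy(mgs: MGS, hits: pd.DataFrame, lineage: pd.DataFrame) -> MGS:
    """Assign a taxonomy label by the majority-identity rules.

    Species rank if more than half of ALL member genes (unannotated genes
    count in the denominator) hit the same species at >= 95% identity;
    otherwise genus at >= 85%, then family at >= 75%, else unclassified.
    An MGS is flagged as a classified species when >= 80% of its genes
    are annotated to the same species (at the species-level 95% identity
    convention).  Label ties break by supporting gene count, then
    lexicographically.
    """
    members = set(mgs.cag.members)
    n_total = len(members)
    sub = hits[hits["gene_id"].isin(members)]
    lin = lineage.set_index("species")
    missing = sorted(set(sub["species"]) - set(lin.index))
    if missing:
        raise ValueError(f"lineage missing for species: {missing[:5]}")

    def level_call(identity_cutoff: float, column: str):
        ok = sub[sub["identity_pct"] >= identity_cutoff]
        if column == "species":
            labels = list(ok["species"])
        else:
            labels = list(lin.loc[ok["species"], column])
        return _majority(labels)

    sp_label, sp_count = level_call(95.0, "species")
    classified = sp_label is not None and sp_count >= 0.8 * n_total

    for cutoff, column, rank in ((95.0, "species", "species"), (85.0, "genus", "genus"), (75.0, "family", "family")):
        label, count = level_call(cutoff, column)
        if label is not None and count > 0.5 * n_total:
            return replace(
                mgs,
                taxonomy_label=label,
                taxonomy_rank=rank,
                classified_species=bool(classified and rank == "species"),
            )
    return replace(
        mgs, taxonomy_label=None, taxonomy_rank="unclassified", classified_species=False
    )


def assignment_frame(cags: list[CAG]) -> pd.DataFrame:
    """Long (gene_id, cag_id) table of a clustering."""
    rows = [(g, c.cag_id) for c in cags for g in c.members]
    return pd.DataFrame(rows, columns=["gene_id", "cag_id"])
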