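"""Causal network assembly: subnetworks, aptamer dedup, LD blocks, eigenproteins.

A subnetwork is one regulator (A-protein) plus all of its selected
targets. Regulators below the minimum target count are dropped from the
registry (they may persist as targets of others). Genes measured by
several aptamers keep the aptamer with the most targets. Regulators whose
lead instruments coincide or sit in LD (dosage r^2 >= 0.5) form an LD
block; within a block a regulator stays independent only when its
target-set intersection/union ratio I is < 0.6 against every other
member, otherwise the members' targets are collapsed into one unresolved
subnetwork. The subnetwork's summary profile ("eigenprotein") is the
first principal component of the standardized member abundances, retained
when it explains > 15% of the member variance, with its sign oriented to
correlate positively with the mean member profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import GenotypeMatrix, ProteinMatrix

__all__ = [
    "Subnetwork",
    "CausalNetwork",
    "LDBlock",
    "Eigenprotein",
    "assemble_network",
    "dedup_aptamers",
    "resolve_ld_blocks",
    "compute_eigenprotein",
    "target_similarity",
]

logger = logging.getLogger(__name__)


@dataclass
class Eigenprotein:
    weights: np.ndarray
    score: np.ndarray
    variance_fraction: float


@dataclass
class Subnetwork:
    regulator: str
    targets: list[str]
    pp: dict[str, float] = field(default_factory=dict)
    status: str = "independent"  # independent | collapsed | unresolved
    members_collapsed: list[str] = field(default_factory=list)
    eigenprotein: Eigenprotein | None = None

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def summed_pp(self) -> float:
        return float(sum(self.pp.values()))


@dataclass
class CausalNetwork:
    edges: pd.DataFrame  # columns a, b, pp
    fdr_level: float
    subnetworks: list[Subnetwork] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class LDBlock:
    members: list[str]
    lead_snps: list[str]
    pairwise_r2: pd.DataFrame | None = None
    pairwise_jaccard: pd.DataFrame | None = None
    status: dict[str, str] = field(default_factory=dict)


def assemble_network(
    selected_edges: pd.DataFrame,
    min_targets: int = 10,
    fdr_level: float = 0.01,
) -> CausalNetwork:
    """Build the network and its subnetwork registry from selected edges.

    ``selected_edges`` needs columns a, b, pp. Regulators with fewer than
    ``min_targets`` targets are dropped together with their edges; they
    remain eligible as targets of retained regulators.
    """
    if selected_edges.empty:
        logger.warning("empty edge set: returning an empty network")
        return CausalNetwork(edges=selected_edges.copy(), fdr_level=fdr_level, subnetworks=[])
    if (selected_edges["a"] == selected_edges["b"]).any():
        raise ValueError("self-edges in selected edge set")
    sizes = selected_edges.groupby("a")["b"].nunique()
    keep = set(sizes[sizes >= min_targets].index)
    kept_edges = selected_edges[selected_edges["a"].isin(keep)].reset_index(drop=True)
    subnetworks = []
    for reg, grp in kept_edges.groupby("a"):
        subnetworks.append(
            Subnetwork(
                regulator=reg,
                targets=sorted(grp["b"].unique()),
                pp=dict(zip(grp["b"], grp["pp"])),
            )
        )
    subnetworks.sort(key=lambda s: s.regulator)
    return CausalNetwork(edges=kept_edges, fdr_level=fdr_level, subnetworks=subnetworks)


def dedup_aptamers(
    subnetworks: list[Subnetwork],
    aptamer_to_gene: dict[str, str],
) -> list[Subnetwork]:
    """Per gene keep the regulator aptamer with the most targets.

    Ties break by larger summed edge posterior, then lexicographic
    aptamer id.
    """
    by_gene: dict[str, list[Subnetwork]] = {}
    for sub in subnetworks:
        by_gene.setdefault(aptamer_to_gene[sub.regulator], []).append(sub)
    kept = []
    for _, subs in by_gene.items():
        best = sorted(subs, key=lambda s: (-s.n_targets, -s.summed_pp, s.regulator))[0]
        kept.append(best)
    kept.sort(key=lambda s: s.regulator)
    return kept


def _dosage_r2(genotypes: GenotypeMatrix, i: int, j: int) -> float:
    r = np.corrcoef(genotypes.dosages[:, i].astype(float), genotypes.dosages[:, j].astype(float))[0, 1]
    return float(r * r) if np.isfinite(r) else 0.0


def _jaccard(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def resolve_ld_blocks(
    subnetworks: list[Subnetwork],
    lead_snp_of: dict[str, str],
    genotypes: GenotypeMatrix,
    aptamer_to_gene: dict[str, str] | None = None,
    r2_threshold: float = 0.5,
    similarity_threshold: float = 0.6,
) -> tuple[list[LDBlock], list[Subnetwork]]:
    """Group regulators into LD blocks and resolve shared-instrument cases.

    Blocks are the transitive closure of "same lead pSNP or pSNP dosage
    r^2 >= threshold". Within a block a regulator is independent only if
    its target-set ratio I is strictly below the similarity threshold
    against every other member; non-independent members are merged into a
    single collapsed subnetwork (union of targets) labelled with the
    joined gene names and flagged unresolved. Regulator pairs that are
    mutual targets of each other are flagged unresolved wherever they
    occur.
    """
    regs = [s.regulator for s in subnetworks]
    sub_of = {s.regulator: s for s in subnetworks}
    n = len(regs)

    # union-find over regulators
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    snp_idx = {r: genotypes.snp_index(lead_snp_of[r]) for r in regs}
    for i in range(n):
        for j in range(i + 1, n):
            if lead_snp_of[regs[i]] == lead_snp_of[regs[j]]:
                union(i, j)
            elif _dosage_r2(genotypes, snp_idx[regs[i]], snp_idx[regs[j]]) >= r2_threshold:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    blocks: list[LDBlock] = []
    resolved: list[Subnetwork] = []
    gene_of = aptamer_to_gene or {}
    for root in sorted(groups):
        idx = groups[root]
        members = [regs[i] for i in idx]
        if len(members) == 1:
            resolved.append(sub_of[members[0]])
            continue
        tsets = {r: set(sub_of[r].targets) for r in members}
        jac = pd.DataFrame(
            [[_jaccard(tsets[a], tsets[b]) for b in members] for a in members],
            index=members,
            columns=members,
        )
        r2m = pd.DataFrame(
            [[_dosage_r2(genotypes, snp_idx[a], snp_idx[b]) for b in members] for a in members],
            index=members,
            columns=members,
        )
        status: dict[str, str] = {}
        independent, entangled = [], []
        for r in members:
            others = [o for o in members if o != r]
            if all(jac.loc[r, o] < similarity_threshold for o in others):
                independent.append(r)
                status[r] = "independent"
            else:
                entangled.append(r)
                status[r] = "collapsed"
        for r in independent:
            resolved.append(sub_of[r])
        if entangled:
            union_targets = sorted(set().union(*(tsets[r] for r in entangled)))
            pp: dict[str, float] = {}
            for r in entangled:
                for t, w in sub_of[r].pp.items():
                    pp[t] = max(pp.get(t, 0.0), w)
            label = "-".join(sorted(gene_of.get(r, r) for r in entangled))
            resolved.append(
                Subnetwork(
                    regulator=label,
                    targets=union_targets,
                    pp=pp,
                    status="unresolved",
                    members_collapsed=sorted(entangled),
                )
            )
        blocks.append(
            LDBlock(
                members=members,
                lead_snps=[lead_snp_of[r] for r in members],
                pairwise_r2=r2m,
                pairwise_jaccard=jac,
                status=status,
            )
        )

    # mutual-target regulator pairs are unresolved wherever they occur
    target_sets = {s.regulator: set(s.targets) for s in subnetworks}
    for i, a in enumerate(regs):
        for b in regs[i + 1 :]:
            if b in target_sets[a] and a in target_sets[b]:
                for s in resolved:
                    if s.regulator in (a, b) or set((a, b)) & set(s.members_collapsed):
                        s.status = "unresolved"

    resolved.sort(key=lambda s: s.regulator)
    return blocks, resolved


def compute_eigenprotein(
    subnetwork: Subnetwork,
    proteins: ProteinMatrix,
    values: np.ndarray | None = None,
    variance_threshold: float = 0.15,
    include_regulator: bool = True,
) -> Eigenprotein | None:
    """First principal component of the standardized member profiles.

    Members are the regulator plus its targets (regulator skipped for
    collapsed networks whose label is not an aptamer). Rows with any
    missing member value are dropped for the decomposition; the returned
    score is NaN on those rows. Returns None when PC1 explains at most
    ``variance_threshold`` of the member variance. The score sign is
    oriented so its correlation with the mean member profile is positive.
    """
    vals = proteins.values if values is None else np.asarray(values, dtype=float)
    member_ids = list(subnetwork.targets)
    if include_regulator and subnetwork.status != "unresolved":
        try:
            proteins.column(subnetwork.regulator)
            member_ids = [subnetwork.regulator] + member_ids
        except KeyError:
            pass
    cols = [proteins.column(m) for m in member_ids]
    if len(cols) < 2:
        raise ValueError("need at least 2 members for an eigenprotein")
    X = vals[:, cols]
    complete = ~np.isnan(X).any(axis=1)
    Xc = X[complete]
    Xs = (Xc - Xc.mean(axis=0)) / Xc.std(axis=0)
    u, s, vt = np.linalg.svd(Xs, full_matrices=False)
    var_fraction = float(s[0] ** 2 / np.sum(s**2))
    if var_fraction <= variance_threshold:
        return None
    weights = vt[0]
    score_c = Xs @ weights
    mean_profile = Xs.mean(axis=1)
    if np.corrcoef(score_c, mean_profile)[0, 1] < 0:
        weights = -weights
        score_c = -score_c
    score = np.full(X.shape[0], np.nan)
    score[complete] = score_c
    return Eigenprotein(weights=weights, score=score, variance_fraction=var_fraction)


def target_similarity(
    subnetworks: list[Subnetwork],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise target-set Jaccard and eigenprotein Pearson correlation.

    Correlation entries are NaN when either subnetwork lacks an
    eigenprotein.
    """
    if len(subnetworks) < 2:
        raise ValueError("need at least 2 subnetworks")
    names = [s.regulator for s in subnetworks]
    tsets = {s.regulator: set(s.targets) for s in subnetworks}
    jac = pd.DataFrame(
        [[_jaccard(tsets[a], tsets[b]) for b in names] for a in names],
        index=names,
        columns=names,
    )
    corr = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(subnetworks):
        for j, b in enumerate(subnetworks):
            if a.eigenprotein is None or b.eigenprotein is None:
                continue
            sa, sb = a.eigenprotein.score, b.eigenprotein.score
            ok = ~(np.isnan(sa) | np.isnan(sb))
            corr.iloc[i, j] = float(np.corrcoef(sa[ok], sb[ok])[0, 1])
    return jac, corr
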