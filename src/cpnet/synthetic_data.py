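"""Seeded synthetic cohorts for causal protein network inference.

The generator produces the three ingredients the inference pipeline
consumes — genotypes, a ground-truth directed protein network, and protein
abundances — plus a covariate/trait table, with the statistical structure
the method assumes:

* biallelic SNP dosages in Hardy-Weinberg equilibrium;
* a scale-free directed, acyclic protein network in which a subset of
  proteins ("regulators") carry a single cis-acting SNP explaining a
  planted fraction of their variance (mean ~7.4% by default, up to ~84%);
* hidden confounding through global latent Gaussian factors with sparse
  loadings, never exposed to inference;
* six atherosclerosis-style traits (quantitative, prevalent binary,
  incident time-to-event) driven by chosen subnetworks and confounded by
  age and sex.

Every generator derives an independent random stream per component from a
master seed, so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "TruthNetwork",
    "ProteinMatrix",
    "TraitTable",
    "CohortConfig",
    "SyntheticCohort",
    "generate_genotypes",
    "generate_truth_network",
    "simulate_proteins",
    "simulate_traits",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with SNP coordinates.

    ``dosages`` holds minor-allele counts in {0, 1, 2}. ``maf`` is the
    frequency the dosages were drawn under, in (0, 0.5].
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    maf: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if not np.isin(self.dosages, [0, 1, 2]).all():
            raise ValueError("dosages must lie in {0, 1, 2}")
        if np.any(np.asarray(self.pos) <= 0):
            raise ValueError("positions must be strictly positive")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_index(self, snp_id: str) -> int:
        idx = np.flatnonzero(self.snp_ids == snp_id)
        if idx.size == 0:
            raise KeyError(snp_id)
        return int(idx[0])


@dataclass
class TruthNetwork:
    """Planted ground truth: directed edges, cis effects and confounders.

    ``edges`` is an (m, 2) integer array of (parent, child) protein
    indices with standardized linear effect sizes ``betas``. ``cis_snp``
    maps each protein to its cis SNP column (-1 when the protein has no
    instrument) and ``cis_var`` stores the planted cis variance fraction.
    """

    n_proteins: int
    edges: np.ndarray
    betas: np.ndarray
    cis_snp: np.ndarray
    cis_var: np.ndarray
    confounder_loadings: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if self.edges.size and np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-edges are not allowed")
        if np.any((self.cis_var < 0) | (self.cis_var >= 1)):
            raise ValueError("cis variance fractions must lie in [0, 1)")
        self.topological_order()  # raises on cycles

    @property
    def regulators(self) -> np.ndarray:
        """Protein indices that carry a cis instrument."""
        return np.flatnonzero(self.cis_snp >= 0)

    def parents_of(self, child: int) -> np.ndarray:
        return self.edges[self.edges[:, 1] == child, 0]

    def targets_of(self, parent: int) -> np.ndarray:
        return self.edges[self.edges[:, 0] == parent, 1]

    def topological_order(self) -> np.ndarray:
        """Kahn topological sort; raises ValueError if the graph is cyclic."""
        n = self.n_proteins
        indeg = np.zeros(n, dtype=int)
        children: list[list[int]] = [[] for _ in range(n)]
        for p, c in self.edges:
            indeg[c] += 1
            children[p].append(c)
        queue = sorted(np.flatnonzero(indeg == 0).tolist())
        order = []
        while queue:
            u = queue.pop()
            order.append(u)
            for v in children[u]:
                indeg[v] -= 1
                if indeg[v] == 0:
                    queue.append(v)
        if len(order) != n:
            raise ValueError("truth network contains a directed cycle")
        return np.array(order, dtype=int)


@dataclass
class ProteinMatrix:
    """Individuals x aptamers abundance matrix with gene annotation.

    Masked/missing entries are NaN — never silently zero.
    """

    values: np.ndarray
    aptamer_ids: np.ndarray
    gene: np.ndarray
    gene_chrom: np.ndarray
    gene_tss: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = self.values.shape[1]
        for name in ("aptamer_ids", "gene", "gene_chrom", "gene_tss"):
            if len(getattr(self, name)) != p:
                raise ValueError(f"annotation field {name!r} does not match column count")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_aptamers(self) -> int:
        return self.values.shape[1]

    def annotation(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "aptamer_id": self.aptamer_ids,
                "gene": self.gene,
                "chrom": self.gene_chrom,
                "tss": self.gene_tss,
            }
        )

    def column(self, aptamer_id: str) -> int:
        idx = np.flatnonzero(self.aptamer_ids == aptamer_id)
        if idx.size == 0:
            raise KeyError(aptamer_id)
        return int(idx[0])

    def copy_with(self, values: np.ndarray) -> "ProteinMatrix":
        return dataclasses.replace(self, values=np.asarray(values, dtype=float))


@dataclass
class TraitTable:
    """Per-individual covariates and traits.

    ``data`` columns: age, sex, one column per quantitative trait, one per
    prevalent binary trait, and ``<name>_event`` / ``<name>_time`` pairs
    for incident traits (time in years, positive).
    """

    data: pd.DataFrame
    quantitative: list[str]
    prevalent: list[str]
    incident: list[str]
    horizon: float

    def __post_init__(self) -> None:
        for name in self.incident:
            t = self.data[f"{name}_time"].to_numpy()
            e = self.data[f"{name}_event"].to_numpy()
            if np.any(t <= 0):
                raise ValueError("follow-up times must be positive")
            if np.any(t[e == 1] > self.horizon + 1e-9):
                raise ValueError("event times must not exceed the administrative horizon")

    @property
    def n_individuals(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _streams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    """Independent per-component RNG streams derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def generate_genotypes(
    n_individuals: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    *,
    chrom: str = "1",
    pos: np.ndarray | None = None,
    maf: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Draw biallelic dosages under Hardy-Weinberg equilibrium.

    Each SNP's minor-allele frequency is uniform on ``maf_range`` (or
    supplied explicitly via ``maf``); dosages are Binomial(2, maf).
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    lo, hi = maf_range
    if not (0.01 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be a sub-interval of (0.01, 0.5]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if maf is None:
        maf = rng.uniform(lo, hi, size=n_snps)
    else:
        maf = np.asarray(maf, dtype=float)
        if maf.shape != (n_snps,):
            raise ValueError("maf length must equal n_snps")
    dosages = rng.binomial(2, maf, size=(n_individuals, n_snps)).astype(np.int8)
    if pos is None:
        pos = np.arange(1, n_snps + 1, dtype=np.int64) * 10_000
    snp_ids = np.array([f"rs{i:06d}" for i in range(n_snps)], dtype=object)
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=snp_ids,
        chrom=np.array([chrom] * n_snps, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        maf=maf,
    )


def generate_truth_network(
    n_proteins: int,
    n_regulators: int,
    min_targets: int = 10,
    out_degree_tail_exponent: float = 2.0,
    ffl_fraction: float = 0.2,
    cis_var_mean: float = 0.074,
    cis_var_max: float = 0.5,
    n_confounders: int = 5,
    seed: int = 0,
    *,
    effect_size_range: tuple[float, float] = (0.15, 0.35),
    confounder_density: float = 0.3,
    confounder_loading_range: tuple[float, float] = (0.1, 0.3),
    noise_floor: float = 0.15,
) -> TruthNetwork:
    """Plant a scale-free acyclic regulator→target network.

    Regulator out-degrees follow a truncated Pareto law with the given
    tail exponent; a fraction of open two-step paths x→y→z is closed
    into feed-forward loops by adding the x→z shortcut. Each regulator
    receives one cis SNP slot whose planted variance fraction has mean
    ``cis_var_mean`` (rescaled sample mean) and maximum ``cis_var_max``.
    Effect sizes and confounder loadings are jointly budgeted per protein
    so that at least ``noise_floor`` of unit variance remains for noise.
    """
    if n_regulators > n_proteins:
        raise ValueError("n_regulators must not exceed n_proteins")
    if not (0 <= cis_var_mean <= cis_var_max < 1):
        raise ValueError("need cis_var_mean <= cis_var_max < 1")
    if out_degree_tail_exponent <= 1:
        raise ValueError("tail exponent must exceed 1")
    if min_targets >= n_proteins - 1:
        raise ValueError("min_targets incompatible with n_proteins")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # random topological order; edges always point from earlier to later
    topo = rng.permutation(n_proteins)
    rank_of = np.empty(n_proteins, dtype=int)
    rank_of[topo] = np.arange(n_proteins)

    # regulators occupy topological positions that leave room for min_targets
    max_rank = n_proteins - min_targets - 1
    if max_rank < n_regulators:
        raise ValueError("not enough upstream positions for the requested regulators")
    reg_ranks = rng.choice(max_rank, size=n_regulators, replace=False)
    regulators = topo[np.sort(reg_ranks)]

    edges: set[tuple[int, int]] = set()
    alpha = out_degree_tail_exponent
    for r in regulators:
        downstream = topo[rank_of[r] + 1 :]
        avail = downstream.size
        # truncated Pareto out-degree with lower bound min_targets
        u = rng.uniform()
        deg = int(min_targets * u ** (-1.0 / (alpha - 1.0)))
        deg = min(deg, avail, n_proteins - 1)
        targets = rng.choice(downstream, size=deg, replace=False)
        edges.update((int(r), int(t)) for t in targets)

    # FFL content is controlled, not incidental: first strip shortcut edges
    # that closed a 2-path by chance, then close the stated fraction of the
    # remaining open parent->child->grandchild paths
    def _children(es: set[tuple[int, int]]) -> dict[int, set[int]]:
        ch: dict[int, set[int]] = {}
        for p_, c_ in es:
            ch.setdefault(p_, set()).add(c_)
        return ch

    while True:
        children = _children(edges)
        shortcut = None
        for x, ys in children.items():
            for y in ys:
                common = children[x] & children.get(y, set()) - {x, y}
                if common:
                    shortcut = (x, min(common))
                    break
            if shortcut:
                break
        if shortcut is None:
            break
        edges.discard(shortcut)

    if ffl_fraction > 0:
        children = _children(edges)
        open_paths = sorted(
            {
                (x, z)
                for x, ys in children.items()
                for y in ys
                if y in children
                for z in children[y]
                if z != x and z not in children.get(x, ())
            }
        )
        n_close = int(round(ffl_fraction * len(open_paths)))
        if n_close:
            idx = rng.choice(len(open_paths), size=n_close, replace=False)
            edges.update(open_paths[i] for i in idx)

    edge_arr = np.array(sorted(edges), dtype=int).reshape(-1, 2)

    # cis variance fractions: Beta draw scaled to the requested mean/max
    cis_var = np.zeros(n_proteins)
    if n_regulators and cis_var_mean > 0:
        draw = rng.beta(1.2, 1.2 * (cis_var_max / cis_var_mean - 1.0), size=n_regulators)
        draw *= cis_var_max
        draw *= cis_var_mean / draw.mean()  # pin the sample mean
        cis_var[regulators] = np.clip(draw, 1e-4, cis_var_max)
    cis_snp = np.full(n_proteins, -1, dtype=int)
    cis_snp[regulators] = regulators  # provisional identity mapping; cohort
    # assembly rewires this to actual genotype columns

    # effect sizes with random sign
    lo, hi = effect_size_range
    betas = rng.uniform(lo, hi, size=len(edge_arr)) * rng.choice([-1.0, 1.0], size=len(edge_arr))

    # sparse confounder loadings
    loadings = np.zeros((n_proteins, n_confounders))
    if n_confounders:
        mask = rng.uniform(size=loadings.shape) < confounder_density
        llo, lhi = confounder_loading_range
        loadings[mask] = rng.uniform(llo, lhi, size=mask.sum()) * rng.choice(
            [-1.0, 1.0], size=mask.sum()
        )

    # per-protein variance budget: cis + sum b^2 + sum c^2 <= 1 - noise_floor
    budget = 1.0 - noise_floor
    for i in range(n_proteins):
        in_mask = edge_arr[:, 1] == i if edge_arr.size else np.zeros(0, dtype=bool)
        parent_var = float(np.sum(betas[in_mask] ** 2)) if edge_arr.size else 0.0
        conf_var = float(np.sum(loadings[i] ** 2))
        excess = cis_var[i] + parent_var + conf_var
        if excess > budget:
            scale = np.sqrt(max(budget - cis_var[i], 0.0) / max(parent_var + conf_var, 1e-12))
            if edge_arr.size:
                betas[in_mask] *= scale
            loadings[i] *= scale

    return TruthNetwork(
        n_proteins=n_proteins,
        edges=edge_arr,
        betas=betas,
        cis_snp=cis_snp,
        cis_var=cis_var,
        confounder_loadings=loadings,
    )


def simulate_proteins(
    genotypes: GenotypeMatrix,
    truth: TruthNetwork,
    noise_sd: float = 1.0,
    seed: int = 0,
    *,
    scale: str = "linear",
    lognormal_sd: float = 0.5,
    lognormal_mean: float = 8.0,
) -> ProteinMatrix:
    """Generate protein abundances from the planted structural model.

    In topological order each protein is

        z_i = a_i * std(dosage_cis) + sum_parents b * z_parent
              + sum_k c_k * latent_k + eps_i

    with ``a_i = sqrt(cis fraction)`` on the standardized dosage, so the
    realized regression R^2 of a regulator on its cis SNP matches the
    planted fraction up to sampling noise. ``noise_sd`` multiplies the
    residual scale implied by the unit-variance budget. With
    ``scale="lognormal"`` the latent values are mapped through
    ``exp(lognormal_sd * z + lognormal_mean)`` to mimic positive,
    right-skewed assay units (a monotone map, so rank-based downstream
    steps are unaffected).
    """
    n = genotypes.n_individuals
    p = truth.n_proteins
    rngs = _streams(seed, ["latent", "noise"])
    latent = rngs["latent"].standard_normal((n, truth.confounder_loadings.shape[1]))
    eps = rngs["noise"].standard_normal((n, p))

    values = np.zeros((n, p))
    order = truth.topological_order()
    parents: dict[int, list[tuple[int, float]]] = {i: [] for i in range(p)}
    for (a, b), beta in zip(truth.edges, truth.betas):
        parents[b].append((a, beta))

    for i in order:
        z = np.zeros(n)
        if truth.cis_snp[i] >= 0 and truth.cis_var[i] > 0:
            d = genotypes.dosages[:, truth.cis_snp[i]].astype(float)
            f = genotypes.maf[truth.cis_snp[i]]
            d_std = (d - 2 * f) / np.sqrt(2 * f * (1 - f))
            z += np.sqrt(truth.cis_var[i]) * d_std
        for a, beta in parents[i]:
            z += beta * values[:, a]
        z += latent @ truth.confounder_loadings[i]
        explained = (
            truth.cis_var[i]
            + sum(b * b for _, b in parents[i])
            + float(np.sum(truth.confounder_loadings[i] ** 2))
        )
        resid_sd = np.sqrt(max(1.0 - explained, 0.0)) * noise_sd
        z += resid_sd * eps[:, i]
        values[:, i] = z

    if scale == "lognormal":
        values = np.exp(lognormal_sd * values + lognormal_mean)
    elif scale != "linear":
        raise ValueError("scale must be 'linear' or 'lognormal'")

    genes = np.array([f"GENE{i:04d}" for i in range(p)], dtype=object)
    return ProteinMatrix(
        values=values,
        aptamer_ids=np.array([f"APT{i:04d}" for i in range(p)], dtype=object),
        gene=genes,
        gene_chrom=np.array(["1"] * p, dtype=object),
        gene_tss=(np.arange(p, dtype=np.int64) + 1) * 1_000_000,
    )


def _subnetwork_signal(values: np.ndarray, members: np.ndarray) -> np.ndarray:
    """Standardized mean profile of a member set (the trait driver)."""
    sub = values[:, members]
    sub = (sub - sub.mean(axis=0)) / sub.std(axis=0)
    sig = sub.mean(axis=1)
    return (sig - sig.mean()) / sig.std()


def simulate_traits(
    proteins: ProteinMatrix,
    truth: TruthNetwork,
    linked_subnetworks: Sequence[int],
    effect_sizes: Sequence[float],
    censoring_rate: float = 0.2,
    seed: int = 0,
    *,
    trait_types: Sequence[str] = ("quantitative", "quantitative", "prevalent", "prevalent", "incident", "incident"),
    horizon: float = 12.0,
    event_rate: float = 0.15,
    age_mean: float = 76.9,
    age_sd: float = 5.9,
    female_fraction: float = 0.6,
) -> TraitTable:
    """Simulate age, sex and six subnetwork-driven traits.

    Each trait is driven by the standardized mean signal of one planted
    subnetwork (regulator + its true targets), plus age/sex confounding:
    quantitative traits are linear-Gaussian, prevalent traits logistic,
    and incident traits exponential time-to-event with log-hazard linear
    in the signal and independent censoring. ``censoring_rate`` is the
    probability of early uniform censoring before the administrative
    horizon; at 1.0 no events are observed.
    """
    if len(linked_subnetworks) != len(effect_sizes) or len(effect_sizes) != len(trait_types):
        raise ValueError("linked_subnetworks, effect_sizes and trait_types must align")
    for r in linked_subnetworks:
        if truth.cis_snp[r] < 0 and truth.targets_of(r).size == 0:
            raise ValueError(f"protein {r} is not a planted subnetwork regulator")

    rngs = _streams(seed, ["cov", "traits"])
    n = proteins.n_individuals
    age = np.clip(rngs["cov"].normal(age_mean, age_sd, size=n), 66, 96)
    sex = (rngs["cov"].uniform(size=n) < female_fraction).astype(int)
    age_z = (age - age.mean()) / age.std()

    data: dict[str, np.ndarray] = {"age": age, "sex": sex}
    quantitative: list[str] = []
    prevalent: list[str] = []
    incident: list[str] = []
    rng = rngs["traits"]
    counters = {"quantitative": 0, "prevalent": 0, "incident": 0}

    for r, beta, kind in zip(linked_subnetworks, effect_sizes, trait_types):
        members = np.unique(np.concatenate([[r], truth.targets_of(r)]))
        signal = _subnetwork_signal(proteins.values, members)
        lp = beta * signal + 0.2 * age_z + 0.15 * sex
        counters[kind] += 1
        name = {"quantitative": "quant", "prevalent": "prev", "incident": "inc"}[kind] + str(
            counters[kind]
        )
        if kind == "quantitative":
            data[name] = lp + rng.standard_normal(n)
            quantitative.append(name)
        elif kind == "prevalent":
            prob = 1.0 / (1.0 + np.exp(-(-1.8 + lp)))
            data[name] = (rng.uniform(size=n) < prob).astype(int)
            prevalent.append(name)
        elif kind == "incident":
            # baseline rate tuned so the uncensored event fraction over the
            # horizon is ~event_rate at lp = 0
            lam0 = -np.log(1 - event_rate) / horizon
            t_event = rng.exponential(1.0, size=n) / (lam0 * np.exp(lp - lp.mean()))
            event = (t_event <= horizon).astype(int)
            time = np.minimum(t_event, horizon)
            # random loss to follow-up: the selected fraction is truncated at a
            # uniform time before their (potential) event; selection is
            # independent of covariates so hazard estimates stay consistent
            lost = rng.uniform(size=n) < censoring_rate
            t_lost = rng.uniform(1e-6, np.minimum(t_event, horizon))
            event[lost] = 0
            time[lost] = t_lost[lost]
            time = np.maximum(time, 1e-6)
            data[f"{name}_event"] = event
            data[f"{name}_time"] = time
            incident.append(name)
        else:
            raise ValueError(f"unknown trait type {kind!r}")

    return TraitTable(
        data=pd.DataFrame(data),
        quantitative=quantitative,
        prevalent=prevalent,
        incident=incident,
        horizon=horizon,
    )


# ---------------------------------------------------------------------------
# full cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study conditions for a full synthetic cohort.

    Defaults emulate a large population proteogenomic study at reduced
    protein count: n=5,000 individuals, 300 proteins of which ~50 carry a
    cis instrument with mean planted cis R^2 of 7.4%, a scale-free
    regulator network with feed-forward loops and hidden confounders, and
    six cardiometabolic-style traits.
    """

    n_individuals: int = 5000
    n_proteins: int = 300
    n_regulators: int = 50
    min_targets: int = 10
    out_degree_tail_exponent: float = 2.0
    ffl_fraction: float = 0.2
    cis_var_mean: float = 0.074
    cis_var_max: float = 0.5
    n_confounders: int = 5
    maf_range: tuple[float, float] = (0.05, 0.5)
    snps_per_gene: int = 3
    protein_scale: str = "lognormal"
    trait_effect_sizes: tuple[float, ...] = (0.4, 0.4, 0.3, 0.3, 0.3, 0.3)
    censoring_rate: float = 0.2
    effect_size_range: tuple[float, float] = (0.15, 0.35)


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    truth: TruthNetwork
    proteins: ProteinMatrix
    traits: TraitTable
    config: CohortConfig = field(default_factory=CohortConfig)


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Generate a complete seeded cohort under the configured conditions.

    Genome layout: one synthetic chromosome with genes spaced 1 Mb apart,
    so cis windows never overlap. Each gene carries ``snps_per_gene`` SNPs
    inside its cis window; for regulator genes the first of these is the
    causal cis SNP.
    """
    cfg = config or CohortConfig()
    master = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(4)]

    truth = generate_truth_network(
        n_proteins=cfg.n_proteins,
        n_regulators=cfg.n_regulators,
        min_targets=cfg.min_targets,
        out_degree_tail_exponent=cfg.out_degree_tail_exponent,
        ffl_fraction=cfg.ffl_fraction,
        cis_var_mean=cfg.cis_var_mean,
        cis_var_max=cfg.cis_var_max,
        n_confounders=cfg.n_confounders,
        seed=seeds[0],
        effect_size_range=cfg.effect_size_range,
    )

    # SNP layout: snps_per_gene per gene, within +/-100 kb of the TSS
    p, spg = cfg.n_proteins, cfg.snps_per_gene
    tss = (np.arange(p, dtype=np.int64) + 1) * 1_000_000
    offsets = np.linspace(-100_000, 100_000, spg, dtype=np.int64)
    pos = (tss[:, None] + offsets[None, :]).ravel()
    geno = generate_genotypes(
        cfg.n_individuals,
        p * spg,
        maf_range=cfg.maf_range,
        seed=seeds[1],
        pos=pos,
    )
    # causal cis SNP of gene i sits at column i * spg
    truth = dataclasses.replace(
        truth,
        cis_snp=np.where(truth.cis_snp >= 0, truth.cis_snp * spg, -1),
    )

    proteins = simulate_proteins(geno, truth, seed=seeds[2], scale=cfg.protein_scale)

    regs = truth.regulators
    by_size = sorted(regs, key=lambda r: -truth.targets_of(r).size)
    linked = [by_size[i % len(by_size)] for i in range(6)]
    traits = simulate_traits(
        proteins,
        truth,
        linked_subnetworks=linked,
        effect_sizes=list(cfg.trait_effect_sizes),
        censoring_rate=cfg.censoring_rate,
        seed=seeds[3],
    )
    return SyntheticCohort(genotypes=geno, truth=truth, proteins=proteins, traits=traits, config=cfg)
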