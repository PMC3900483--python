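"""Synthetic family study generator for validity experiments.

The generator reproduces a controlled validity design: founder haplotypes
with block-diagonal autoregressive LD are simulated by thresholding
multivariate normal vectors (the HapSim construction), dropped through
replicated pedigrees without recombination, and a binary trait is drawn from
a logistic model on the causal minor-allele counts:

    logit P(Y = 1) = beta0 + sum_c beta_c * X_c.

Defaults describe the package's stated world: 200 independent copies of a
synthetic four-generation, 90-member extended pedigree (22 founders, 68
non-founders, multi-sib nuclear families in every generation, so every
replicate yields many trios and discordant sibpairs); one
gene of 20 SNVs spanning 14.02 kb in 5 position clusters; LD block-diagonal
with 5 independent blocks of 4 SNVs and within-block AR correlation
rho = 0.9; mostly-rare minor allele frequencies (median ~0.02); baseline
prevalence 10% and three causal SNVs drawn among SNVs with MAF >= 0.01 with
per-allele log odds ratios of ln(2) or ln(4).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .pedigree_data import (
    GeneRegion,
    Individual,
    NuclearIndex,
    Pedigree,
    Study,
    build_nuclear_index,
)

__all__ = [
    "DEFAULT_MAFS",
    "DEFAULT_POSITIONS",
    "DEFAULT_BLOCK_SIZES",
    "SimConfig",
    "Replicate",
    "StudyTemplate",
    "ar_block_correlation",
    "simulate_founder_haplotypes",
    "gene_drop",
    "simulate_binary_trait",
    "generate_replicate",
    "build_template",
    "default_template_rows",
]

# 20 mostly-rare minor allele frequencies (5 LD blocks of 4)
DEFAULT_MAFS = np.array(
    [
        0.0025, 0.012, 0.048, 0.0078,
        0.031, 0.0042, 0.095, 0.019,
        0.0063, 0.11, 0.0091, 0.027,
        0.052, 0.0035, 0.011, 0.075,
        0.022, 0.0057, 0.038, 0.016,
    ]
)

DEFAULT_BLOCK_SIZES = (4, 4, 4, 4, 4)

# 5 position clusters of 4 SNVs, 200 bp spacing; total width 14.02 kb
DEFAULT_POSITIONS = np.concatenate(
    [start + np.arange(4) * 200 for start in (1, 3356, 6711, 10066, 13421)]
)

# Pedigree templates are tuples of (person, father, mother, sex) with "0"
# for founders; parents may appear in any order relative to children.

# compact three-generation 12-member family (4 founders, three sibships)
THREE_GENERATION_ROWS = (
    ("gf", "0", "0", 1),
    ("gm", "0", "0", 2),
    ("s1", "0", "0", 2),
    ("s2", "0", "0", 1),
    ("c1", "gf", "gm", 1),
    ("c2", "gf", "gm", 2),
    ("g11", "c1", "s1", 1),
    ("g12", "c1", "s1", 2),
    ("g13", "c1", "s1", 1),
    ("g21", "s2", "c2", 2),
    ("g22", "s2", "c2", 1),
    ("g23", "s2", "c2", 2),
)


def _extended_family_rows() -> tuple[tuple[str, str, str, int], ...]:
    """Synthetic 90-member, four-generation extended pedigree.

    Emulates the scale of the GAW17-style family sample (~87 members, ~25%
    founders, multi-sib nuclear families in every generation): a founding
    couple with 4 married children, 4 grandchildren per second-generation
    couple (each married), and 3 great-grandchildren per third-generation
    couple — 90 members, 22 founders, 68 non-founders.
    """
    rows: list[tuple[str, str, str, int]] = [("gf", "0", "0", 1), ("gm", "0", "0", 2)]
    for i in range(1, 5):
        sex = 1 if i % 2 else 2
        rows.append((f"c{i}", "gf", "gm", sex))
        rows.append((f"s{i}", "0", "0", 3 - sex))
        father, mother = (f"c{i}", f"s{i}") if sex == 1 else (f"s{i}", f"c{i}")
        for j in range(1, 5):
            sex_j = 1 if j % 2 else 2
            rows.append((f"d{i}{j}", father, mother, sex_j))
            rows.append((f"t{i}{j}", "0", "0", 3 - sex_j))
            f2, m2 = (f"d{i}{j}", f"t{i}{j}") if sex_j == 1 else (f"t{i}{j}", f"d{i}{j}")
            for k in range(1, 4):
                rows.append((f"e{i}{j}{k}", f2, m2, 1 if k % 2 else 2))
    return tuple(rows)


EXTENDED_FAMILY_ROWS = _extended_family_rows()


def default_template_rows() -> tuple[tuple[str, str, str, int], ...]:
    """Default pedigree template of the stated world (the extended family)."""
    return EXTENDED_FAMILY_ROWS


@dataclass
class SimConfig:
    """Parameters of one simulation scenario (defaults = the stated world)."""

    n_pedigrees: int = 200
    mafs: np.ndarray = field(default_factory=lambda: DEFAULT_MAFS.copy())
    block_sizes: tuple[int, ...] = DEFAULT_BLOCK_SIZES
    rho: float = 0.9
    causal_indices: tuple[int, ...] = ()
    betas: tuple[float, ...] = ()
    beta0: float = float(np.log(0.1 / 0.9))  # 10% baseline prevalence
    seed: int = 0
    positions: np.ndarray = field(default_factory=lambda: DEFAULT_POSITIONS.copy())
    chromosome: str = "8"
    gene_name: str = "GENE1"
    ascertain: bool = False  # keep only families with >=1 affected non-founder
    template_rows: tuple = EXTENDED_FAMILY_ROWS

    def __post_init__(self) -> None:
        self.mafs = np.asarray(self.mafs, dtype=float)
        if np.any((self.mafs < 0) | (self.mafs > 0.5)):
            raise ValueError("mafs must lie in [0, 0.5]")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if len(self.causal_indices) != len(self.betas):
            raise ValueError("causal_indices and betas must have equal length")
        if sum(self.block_sizes) != self.mafs.size:
            raise ValueError("block sizes must sum to the number of SNVs")

    @property
    def m(self) -> int:
        return int(self.mafs.size)

    def with_betas(self, causal_indices, betas) -> "SimConfig":
        return replace(self, causal_indices=tuple(causal_indices), betas=tuple(betas))


@dataclass
class StudyTemplate:
    """Replicated pedigree structure with fixed genotype-row layout."""

    pedigrees: list[Pedigree]  # affection left unset; structure only
    nuclear: NuclearIndex
    founder_rows: np.ndarray
    sample_ids: list[str]
    n_members: int
    founder_slots: np.ndarray  # member positions of founders within a family
    drop_order: list[tuple[int, int, int]]  # (child, father, mother) member positions

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)


def build_template(config: SimConfig) -> StudyTemplate:
    rows = config.template_rows
    pos_of = {r[0]: k for k, r in enumerate(rows)}
    # parents must precede children for the no-recombination drop
    order: list[tuple[int, int, int]] = []
    placed = {k for k, r in enumerate(rows) if r[1] == "0"}
    pending = [k for k, r in enumerate(rows) if r[1] != "0"]
    while pending:
        progressed = False
        for k in list(pending):
            f, m = pos_of[rows[k][1]], pos_of[rows[k][2]]
            if f in placed and m in placed:
                order.append((k, f, m))
                placed.add(k)
                pending.remove(k)
                progressed = True
        if not progressed:
            raise ValueError("pedigree template contains a cycle")

    pedigrees = []
    sample_ids = []
    nm = len(rows)
    for i in range(config.n_pedigrees):
        fam = f"F{i}"
        members = []
        for k, (person, father, mother, sex) in enumerate(rows):
            ind = Individual(
                person_id=f"{fam}_{person}",
                family_id=fam,
                father_id=None if father == "0" else f"{fam}_{father}",
                mother_id=None if mother == "0" else f"{fam}_{mother}",
                sex=sex,
                affection=None,
                genotype_row=i * nm + k,
            )
            members.append(ind)
            sample_ids.append(ind.person_id)
        pedigrees.append(Pedigree(fam, members))
    founder_slots = np.array([k for k, r in enumerate(rows) if r[1] == "0"], dtype=np.intp)
    founder_rows = (
        np.arange(config.n_pedigrees)[:, None] * nm + founder_slots[None, :]
    ).ravel()
    return StudyTemplate(
        pedigrees=pedigrees,
        nuclear=build_nuclear_index(pedigrees),
        founder_rows=founder_rows,
        sample_ids=sample_ids,
        n_members=nm,
        founder_slots=founder_slots,
        drop_order=order,
    )


def ar_block_correlation(block_sizes, rho: float) -> np.ndarray:
    """Block-diagonal correlation with within-block AR decay ``rho^|j-k|``."""
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must be in [0, 1)")
    m = int(sum(block_sizes))
    corr = np.zeros((m, m))
    offset = 0
    for size in block_sizes:
        j = np.arange(size)
        corr[offset : offset + size, offset : offset + size] = rho ** np.abs(
            j[:, None] - j[None, :]
        )
        offset += size
    return corr


def simulate_founder_haplotypes(
    mafs: np.ndarray,
    correlation: np.ndarray,
    n_haplotypes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Threshold-MVN haplotypes: allele j = 1 iff Z_j < Phi^-1(maf_j)."""
    mafs = np.asarray(mafs, dtype=float)
    try:
        chol = np.linalg.cholesky(np.asarray(correlation, dtype=float))
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive definite") from exc
    z = rng.standard_normal((n_haplotypes, mafs.size)) @ chol.T
    thresholds = norm.ppf(mafs)  # maf = 0 -> -inf -> monomorphic zero column
    return (z < thresholds[None, :]).astype(np.int8)


def gene_drop(
    template: StudyTemplate,
    founder_haplotypes: np.ndarray,
    rng: np.random.Generator,
    n_pedigrees: int | None = None,
) -> np.ndarray:
    """Drop founder haplotypes through the replicated pedigrees.

    ``founder_haplotypes`` has shape (n_pedigrees * n_founders * 2, m); each
    non-founder inherits one complete haplotype from each parent (no
    recombination).  Returns genotypes of shape (n_individuals, m).
    """
    if n_pedigrees is None:
        n_pedigrees = len(template.pedigrees)
    m = founder_haplotypes.shape[1]
    nm = template.n_members
    hap = np.zeros((n_pedigrees, nm, 2, m), dtype=np.int8)
    fh = founder_haplotypes.reshape(n_pedigrees, len(template.founder_slots), 2, m)
    hap[:, template.founder_slots] = fh
    fams = np.arange(n_pedigrees)
    for child, father, mother in template.drop_order:
        pick_f = rng.integers(0, 2, size=n_pedigrees)
        pick_m = rng.integers(0, 2, size=n_pedigrees)
        hap[:, child, 0] = hap[fams, father, pick_f]
        hap[:, child, 1] = hap[fams, mother, pick_m]
    return hap.sum(axis=2, dtype=np.int16).reshape(n_pedigrees * nm, m)


def simulate_binary_trait(
    genotypes: np.ndarray,
    causal_indices,
    betas,
    beta0: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw affection (1/0) per individual from the logistic trait model."""
    eta = np.full(genotypes.shape[0], float(beta0))
    if len(causal_indices):
        eta += genotypes[:, np.asarray(causal_indices, dtype=np.intp)] @ np.asarray(
            betas, dtype=float
        )
    return (rng.random(genotypes.shape[0]) < expit(eta)).astype(np.int8)


@dataclass
class Replicate:
    template: StudyTemplate
    genotypes: np.ndarray  # (n_individuals, m) minor-allele counts
    affection: np.ndarray  # (n_individuals,) 1/0
    region: GeneRegion
    config: SimConfig
    replicate_id: int

    def to_study(self) -> Study:
        """Materialize Pedigree objects (fresh copies) with affection set."""
        pedigrees = []
        for ped in self.template.pedigrees:
            members = [
                Individual(
                    m.person_id,
                    m.family_id,
                    m.father_id,
                    m.mother_id,
                    m.sex,
                    int(self.affection[m.genotype_row]),
                    m.genotype_row,
                )
                for m in ped.members
            ]
            pedigrees.append(Pedigree(ped.family_id, members))
        snv_ids = [f"snv{j + 1}" for j in range(self.config.m)]
        return Study(
            pedigrees=pedigrees,
            genotypes=self.genotypes,
            regions=[self.region],
            sample_ids=list(self.template.sample_ids),
            snv_ids=snv_ids,
        )


def _simulate_families(
    config: SimConfig,
    template: StudyTemplate,
    correlation: np.ndarray,
    rng: np.random.Generator,
    n_fam: int,
) -> tuple[np.ndarray, np.ndarray]:
    n_hap = n_fam * len(template.founder_slots) * 2
    founders = simulate_founder_haplotypes(config.mafs, correlation, n_hap, rng)
    geno = gene_drop(template, founders, rng, n_pedigrees=n_fam)
    aff = simulate_binary_trait(
        geno, config.causal_indices, config.betas, config.beta0, rng
    )
    return geno, aff


def generate_replicate(
    config: SimConfig,
    replicate_id: int = 0,
    template: StudyTemplate | None = None,
) -> Replicate:
    """Generate one fully deterministic replicate of the study.

    The random stream is derived from ``(config.seed, replicate_id)`` so
    replicates are independent and individually reproducible.
    """
    if template is None:
        template = build_template(config)
    rng = np.random.default_rng([int(config.seed), int(replicate_id)])
    correlation = ar_block_correlation(config.block_sizes, config.rho)
    nm = template.n_members
    geno, aff = _simulate_families(config, template, correlation, rng, config.n_pedigrees)
    if config.ascertain:
        nonfounder_slots = np.setdiff1d(np.arange(nm), template.founder_slots)
        for _ in range(1000):
            aff_fam = aff.reshape(config.n_pedigrees, nm)[:, nonfounder_slots]
            bad = np.flatnonzero(aff_fam.sum(axis=1) == 0)
            if bad.size == 0:
                break
            g2, a2 = _simulate_families(config, template, correlation, rng, bad.size)
            rows = (bad[:, None] * nm + np.arange(nm)[None, :]).ravel()
            geno[rows] = g2
            aff[rows] = a2
        else:
            raise RuntimeError("ascertainment resampling did not converge")
    region = GeneRegion(
        config.gene_name,
        config.chromosome,
        config.positions,
        np.arange(config.m),
    )
    return Replicate(template, geno, aff, region, config, replicate_id)
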