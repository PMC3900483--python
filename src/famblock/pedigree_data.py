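"""Pedigree, genotype and gene-region data model and I/O.

The sampling unit throughout the package is the pedigree: an independent
family whose members carry a binary affection status (1 = case, 0 = control)
and a row of minor-allele counts.  Two kinds of informative family units are
extracted from a pedigree for the transmission-based tests:

* a *trio*: two genotyped parents plus an affected child, and
* a *discordant sibpair* (DSP): one affected and one unaffected full sib.

Genotypes are coded as copies of the minor allele (0/1/2, ``-1`` missing),
where "minor" is determined from founder allele frequencies so that related
copies of the same haplotype do not bias the frequency estimate.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MISSING = -1  # genotype sentinel

__all__ = [
    "MISSING",
    "Individual",
    "Pedigree",
    "GeneRegion",
    "InformativeUnit",
    "Study",
    "StudyParseError",
    "load_study",
    "load_ped",
    "load_vcf_genotypes",
    "load_regions",
    "code_minor_alleles",
    "gene_length",
    "extract_informative_units",
    "build_nuclear_index",
    "NuclearIndex",
    "write_ped",
    "write_vcf",
    "write_regions",
]


class StudyParseError(ValueError):
    """Structured parse/consistency error for study inputs."""


@dataclass
class Individual:
    person_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: int | None
    affection: int | None  # 1 case, 0 control, None missing
    genotype_row: int | None = None  # row index into the genotype matrix

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    family_id: str
    members: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {m.person_id: m for m in self.members}

    def member(self, person_id: str) -> Individual:
        return self._by_id[person_id]

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [m for m in self.members if not m.is_founder]

    @property
    def n_nonfounders(self) -> int:
        return len(self.nonfounders)

    def validate(self) -> None:
        """Check parent references and acyclicity of the parent graph."""
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in self._by_id:
                    raise StudyParseError(
                        f"family {self.family_id}: person {m.person_id} "
                        f"references unknown parent {pid}"
                    )
            if (m.father_id is None) != (m.mother_id is None):
                raise StudyParseError(
                    f"family {self.family_id}: person {m.person_id} has "
                    "exactly one known parent; founders must have neither"
                )
        # cycle check via DFS on child -> parent edges
        state: dict[str, int] = {}

        def visit(pid: str) -> None:
            if state.get(pid) == 1:
                raise StudyParseError(
                    f"family {self.family_id}: pedigree cycle involving {pid}"
                )
            if state.get(pid) == 2:
                return
            state[pid] = 1
            m = self._by_id[pid]
            for parent in (m.father_id, m.mother_id):
                if parent is not None:
                    visit(parent)
            state[pid] = 2

        for m in self.members:
            visit(m.person_id)


@dataclass
class GeneRegion:
    gene_name: str
    chromosome: str
    snv_positions: np.ndarray  # sorted 1-based bp coordinates
    snv_indices: np.ndarray  # columns into the genotype matrix

    def __post_init__(self) -> None:
        self.snv_positions = np.asarray(self.snv_positions, dtype=np.int64)
        self.snv_indices = np.asarray(self.snv_indices, dtype=np.intp)
        if self.snv_positions.size == 0:
            raise StudyParseError(f"gene {self.gene_name}: empty region")
        if self.snv_positions.size != self.snv_indices.size:
            raise StudyParseError(
                f"gene {self.gene_name}: positions/indices length mismatch"
            )
        if np.any(np.diff(self.snv_positions) < 0):
            order = np.argsort(self.snv_positions, kind="stable")
            self.snv_positions = self.snv_positions[order]
            self.snv_indices = self.snv_indices[order]

    @property
    def n_snvs(self) -> int:
        return int(self.snv_positions.size)


@dataclass(frozen=True)
class InformativeUnit:
    kind: str  # "trio" | "discordant_sibpair"
    member_ids: tuple[str, ...]  # trio: (father, mother, child); DSP: (affected, unaffected)
    pedigree_id: str


@dataclass
class Study:
    """A loaded study: pedigrees + minor-allele genotype matrix + regions."""

    pedigrees: list[Pedigree]
    genotypes: np.ndarray  # (n_individuals, m_total) minor-allele counts
    regions: list[GeneRegion]
    sample_ids: list[str]
    snv_ids: list[str]


def gene_length(region: GeneRegion) -> int:
    """Gene length in bp: largest minus smallest SNV coordinate (0 for one SNV)."""
    return int(region.snv_positions.max() - region.snv_positions.min())


# ---------------------------------------------------------------------------
# Parsing


def _parse_phenotype(raw: str, family: str, person: str) -> int | None:
    try:
        value = int(float(raw))
    except ValueError as exc:
        raise StudyParseError(
            f"family {family}, person {person}: phenotype {raw!r} not numeric"
        ) from exc
    if value not in (-9, 0, 1, 2):
        raise StudyParseError(
            f"family {family}, person {person}: phenotype {value} not in "
            "{-9, 0, 1, 2} PED conventions"
        )
    return value


def load_ped(ped_path: str | Path) -> list[Pedigree]:
    """Parse a PLINK-style 6-column PED/FAM file into pedigrees.

    Affection coding: if any phenotype equals 2 the file is taken to use the
    1/2 (unaffected/affected) convention with 0 and -9 missing; otherwise
    phenotypes 0/1 are taken as control/case directly with -9 missing.
    """
    rows: list[tuple[str, str, str, str, str, str]] = []
    with open(ped_path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise StudyParseError(
                    f"{ped_path}:{line_no}: expected >=6 PED columns, got {len(fields)}"
                )
            rows.append(tuple(fields[:6]))

    phenos = [_parse_phenotype(r[5], r[0], r[1]) for r in rows]
    uses_12 = any(p == 2 for p in phenos)

    def remap(p: int | None) -> int | None:
        if uses_12:
            return {1: 0, 2: 1}.get(p)  # 0 / -9 -> missing
        return {0: 0, 1: 1}.get(p)  # -9 -> missing

    by_family: dict[str, list[Individual]] = {}
    for (fam, person, father, mother, sex, _), pheno in zip(rows, phenos):
        by_family.setdefault(fam, []).append(
            Individual(
                person_id=person,
                family_id=fam,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=int(sex) if sex in ("1", "2") else None,
                affection=remap(pheno),
            )
        )
    pedigrees = [Pedigree(fam, members) for fam, members in by_family.items()]
    for ped in pedigrees:
        ped.validate()
    return pedigrees


def load_vcf_genotypes(vcf_path: str | Path):
    """Read a biallelic-SNV VCF into raw ALT-allele counts.

    Returns ``(sample_ids, snv_ids, chroms, positions, ref_alleles,
    alt_alleles, alt_counts)`` where ``alt_counts`` is an (n, m) int array of
    ALT-allele dosages with ``-1`` for missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    sample_ids = list(vcf.samples)
    snv_ids, chroms, positions, refs, alts = [], [], [], [], []
    columns = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise StudyParseError(
                f"SNV {variant.ID or variant.POS} has {len(variant.ALT)} ALT "
                "alleles; only biallelic SNVs are supported"
            )
        snv_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chroms.append(variant.CHROM)
        positions.append(variant.POS)
        refs.append(variant.REF)
        alts.append(variant.ALT[0])
        gts = np.asarray(variant.genotypes, dtype=np.int64)[:, :2]
        col = np.where((gts < 0).any(axis=1), MISSING, gts.clip(min=0).sum(axis=1))
        columns.append(col.astype(np.int16))
    vcf.close()
    counts = (
        np.stack(columns, axis=1) if columns else np.zeros((len(sample_ids), 0), np.int16)
    )
    return sample_ids, snv_ids, chroms, positions, refs, alts, counts


def code_minor_alleles(
    alt_counts: np.ndarray,
    founder_rows: np.ndarray,
    ref_alleles: list[str],
    alt_alleles: list[str],
) -> np.ndarray:
    """Recode ALT-allele counts as minor-allele counts.

    The minor allele at each SNV is the one with the lower allele frequency
    among *founders* (non-founders are correlated copies).  Exact 0.5 ties are
    broken toward the lexicographically smaller allele label.  Missing (-1)
    entries stay missing.
    """
    alt_counts = np.asarray(alt_counts)
    coded = alt_counts.copy()
    founder = alt_counts[founder_rows]
    for j in range(alt_counts.shape[1]):
        col = founder[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            alt_freq = 0.0
        else:
            alt_freq = float(obs.sum()) / (2.0 * obs.size)
        if alt_freq > 0.5:
            minor_is_alt = False
        elif alt_freq < 0.5:
            minor_is_alt = True
        else:  # tie: lexicographically smaller label is minor
            minor_is_alt = alt_alleles[j] < ref_alleles[j]
        if not minor_is_alt:
            mask = coded[:, j] != MISSING
            coded[mask, j] = 2 - coded[mask, j]
    return coded


def load_regions(
    regions_path: str | Path, snv_ids: list[str]
) -> list[GeneRegion]:
    """Parse the tab-separated ``gene  chrom  snv_id  position`` regions file."""
    index_of = {s: i for i, s in enumerate(snv_ids)}
    table: dict[str, tuple[str, list[int], list[int]]] = {}
    with open(regions_path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 4:
                raise StudyParseError(
                    f"{regions_path}:{line_no}: expected 4 columns, got {len(fields)}"
                )
            gene, chrom, snv_id, pos = fields
            if snv_id not in index_of:
                raise StudyParseError(
                    f"{regions_path}:{line_no}: SNV {snv_id} not present in genotypes"
                )
            entry = table.setdefault(gene, (chrom, [], []))
            if entry[0] != chrom:
                raise StudyParseError(f"gene {gene}: inconsistent chromosome")
            entry[1].append(int(pos))
            entry[2].append(index_of[snv_id])
    return [
        GeneRegion(gene, chrom, np.array(pos), np.array(idx))
        for gene, (chrom, pos, idx) in table.items()
    ]


def load_study(
    ped_path: str | Path,
    genotype_path: str | Path,
    regions_path: str | Path,
) -> Study:
    """Load pedigrees (PED/FAM), genotypes (VCF) and gene regions (TSV).

    Every genotyped sample must appear in exactly one pedigree; the genotype
    matrix is recoded to founder-minor-allele counts.
    """
    pedigrees = load_ped(ped_path)
    sample_ids, snv_ids, _, _, refs, alts, alt_counts = load_vcf_genotypes(genotype_path)

    by_person: dict[str, Individual] = {}
    for ped in pedigrees:
        for m in ped.members:
            if m.person_id in by_person:
                raise StudyParseError(
                    f"person id {m.person_id} appears in more than one pedigree"
                )
            by_person[m.person_id] = m
    for row, sid in enumerate(sample_ids):
        if sid not in by_person:
            raise StudyParseError(
                f"sample {sid} present in genotypes but absent from the PED file"
            )
        by_person[sid].genotype_row = row

    founder_rows = np.array(
        [
            m.genotype_row
            for ped in pedigrees
            for m in ped.founders
            if m.genotype_row is not None
        ],
        dtype=np.intp,
    )
    genotypes = code_minor_alleles(alt_counts, founder_rows, refs, alts)
    regions = load_regions(regions_path, snv_ids)
    return Study(pedigrees, genotypes, regions, sample_ids, snv_ids)


# ---------------------------------------------------------------------------
# Informative units


def extract_informative_units(pedigree: Pedigree) -> list[InformativeUnit]:
    """Enumerate trios and discordant sibpairs in a pedigree.

    A trio is an affected child with both parents genotyped.  A DSP is a pair
    of full sibs (both parents shared), one affected and one unaffected, both
    genotyped.  A sibship with ``a`` affected and ``u`` unaffected genotyped
    sibs yields ``a * u`` DSPs.  Members with missing affection join no unit.
    Enumeration order follows member order in the pedigree; the resulting set
    does not depend on it.
    """
    units: list[InformativeUnit] = []
    sibships: dict[tuple[str, str], list[Individual]] = {}
    for m in pedigree.members:
        if m.is_founder:
            continue
        sibships.setdefault((m.father_id, m.mother_id), []).append(m)

    for (father_id, mother_id), sibs in sibships.items():
        father = pedigree.member(father_id)
        mother = pedigree.member(mother_id)
        parents_genotyped = (
            father.genotype_row is not None and mother.genotype_row is not None
        )
        for child in sibs:
            if (
                parents_genotyped
                and child.affection == 1
                and child.genotype_row is not None
            ):
                units.append(
                    InformativeUnit(
                        "trio", (father_id, mother_id, child.person_id), pedigree.family_id
                    )
                )
        affected = [s for s in sibs if s.affection == 1 and s.genotype_row is not None]
        unaffected = [s for s in sibs if s.affection == 0 and s.genotype_row is not None]
        for a in affected:
            for u in unaffected:
                units.append(
                    InformativeUnit(
                        "discordant_sibpair",
                        (a.person_id, u.person_id),
                        pedigree.family_id,
                    )
                )
    return units


# ---------------------------------------------------------------------------
# Vectorized index over nuclear structure (used by the fast statistic paths)


@dataclass
class NuclearIndex:
    """Flat index arrays over all children with both parents in the study.

    One slot per (child, father, mother) triple; ``family_ord`` maps slots to
    a dense 0..N-1 pedigree ordinal and ``sibship_ord`` to a dense sibship id.
    """

    child_row: np.ndarray
    father_row: np.ndarray
    mother_row: np.ndarray
    family_ord: np.ndarray
    sibship_ord: np.ndarray
    n_families: int
    n_sibships: int
    family_ids: list[str]


def build_nuclear_index(pedigrees: list[Pedigree]) -> NuclearIndex:
    child, father, mother, fam, sib = [], [], [], [], []
    sib_counter = 0
    for f_ord, ped in enumerate(pedigrees):
        sibships: dict[tuple[str, str], int] = {}
        for m in ped.nonfounders:
            pf = ped.member(m.father_id)
            pm = ped.member(m.mother_id)
            if (
                m.genotype_row is None
                or pf.genotype_row is None
                or pm.genotype_row is None
            ):
                continue
            key = (m.father_id, m.mother_id)
            if key not in sibships:
                sibships[key] = sib_counter
                sib_counter += 1
            child.append(m.genotype_row)
            father.append(pf.genotype_row)
            mother.append(pm.genotype_row)
            fam.append(f_ord)
            sib.append(sibships[key])
    return NuclearIndex(
        child_row=np.array(child, dtype=np.intp),
        father_row=np.array(father, dtype=np.intp),
        mother_row=np.array(mother, dtype=np.intp),
        family_ord=np.array(fam, dtype=np.intp),
        sibship_ord=np.array(sib, dtype=np.intp),
        n_families=len(pedigrees),
        n_sibships=sib_counter,
        family_ids=[p.family_id for p in pedigrees],
    )


# ---------------------------------------------------------------------------
# Writers (plain-text PED / VCF / regions, used for export and round-trips)


def write_ped(study_or_pedigrees, path: str | Path) -> None:
    pedigrees = getattr(study_or_pedigrees, "pedigrees", study_or_pedigrees)
    with open(path, "w") as out:
        for ped in pedigrees:
            for m in ped.members:
                pheno = {1: "2", 0: "1", None: "0"}[m.affection]
                out.write(
                    f"{ped.family_id}\t{m.person_id}\t{m.father_id or 0}\t"
                    f"{m.mother_id or 0}\t{m.sex or 0}\t{pheno}\n"
                )


def write_vcf(study: Study, path: str | Path, chrom_by_snv: list[str] | None = None,
              pos_by_snv: list[int] | None = None) -> None:
    """Write the coded genotype matrix as a minimal VCF 4.2 text file.

    The minor allele is written as ALT (labelled ``A``/REF ``G`` arbitrarily
    unless the study kept real labels), so a round-trip through
    :func:`load_study` reproduces the coded matrix.
    """
    n, m = study.genotypes.shape
    if chrom_by_snv is None or pos_by_snv is None:
        chrom_by_snv = ["1"] * m
        pos_by_snv = [0] * m
        for region in study.regions:
            for pos, idx in zip(region.snv_positions, region.snv_indices):
                chrom_by_snv[idx] = region.chromosome
                pos_by_snv[idx] = int(pos)
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(study.sample_ids)
        + "\n"
    )
    gt_string = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for j in range(m):
        fields = [
            str(chrom_by_snv[j]),
            str(max(pos_by_snv[j], 1)),
            study.snv_ids[j],
            "G",
            "A",
            ".",
            "PASS",
            ".",
            "GT",
        ]
        fields += [gt_string[int(g)] for g in study.genotypes[:, j]]
        buf.write("\t".join(fields) + "\n")
    Path(path).write_text(buf.getvalue())


def write_regions(study: Study, path: str | Path) -> None:
    with open(path, "w") as out:
        for region in study.regions:
            for pos, idx in zip(region.snv_positions, region.snv_indices):
                out.write(
                    f"{region.gene_name}\t{region.chromosome}\t"
                    f"{study.snv_ids[idx]}\t{int(pos)}\n"
                )
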