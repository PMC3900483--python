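"""Per-SNV family-based association statistics: PDT and FBAT.

Both tests condition on parental genotypes and exploit Mendelian
transmission, so they are robust to population stratification.

PDT unit scores
    For a trio (two genotyped parents, one affected child) the score is
    ``d = (# minor alleles transmitted) - (# not transmitted) = 2*c - f - m``.
    For a discordant sibpair it is the affected-minus-unaffected minor-allele
    count.  The per-pedigree statistic ``D_i`` averages the unit scores over
    the pedigree's ``n_T + n_S`` units (a sum is available via ``combine``).

FBAT
    The per-pedigree contribution is ``U_i = sum_c (y_c - offset) *
    (X_c - E[X_c | parents])`` over offspring with both parents genotyped,
    with ``E`` and ``Var`` from Mendelian transmission.  With the binary-trait
    default ``offset = 0`` only affected offspring contribute.

Null variances
    Under the conditional null every unit score is linear in offspring
    genotypes given parental genotypes, so the exact variance of ``D_i``
    (including trio/DSP overlap through a shared child) is
    ``sum_c w_c^2 v_c / n^2`` where ``v_c`` is the Mendelian transmission
    variance of child ``c`` and ``w_c`` its accumulated unit weight.  This
    exact form is the default (``variance="exact"``); ``variance="unit"``
    instead treats unit randomizations as independent, using the label-swap
    variance ``d^2`` for DSPs.  DSPs whose parents are not genotyped at the
    SNV always fall back to the label-swap form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .pedigree_data import (
    MISSING,
    InformativeUnit,
    NuclearIndex,
    Pedigree,
    extract_informative_units,
)

__all__ = [
    "UnitScore",
    "PedigreeStat",
    "SingleSnvTest",
    "pdt_unit_score",
    "pdt_pedigree_stat",
    "fbat_pedigree_stat",
    "classic_pdt_test",
    "classic_fbat_test",
    "pdt_matrix",
    "fbat_matrix",
]


@dataclass(frozen=True)
class UnitScore:
    unit: InformativeUnit
    snv_index: int
    d: float
    null_var: float


@dataclass(frozen=True)
class PedigreeStat:
    pedigree_id: str
    snv_index: int
    value: float
    null_var: float
    n_units: int


@dataclass(frozen=True)
class SingleSnvTest:
    z: float
    p_value: float
    informative: bool


def _geno(pedigree: Pedigree, genotypes: np.ndarray, person_id: str, snv: int) -> int:
    row = pedigree.member(person_id).genotype_row
    if row is None:
        return MISSING
    return int(genotypes[row, snv])


def _mendel_var(f: int, m: int) -> float:
    # Var(X_child | parents) for additive minor-allele coding
    return 0.25 * ((f == 1) + (m == 1))


def pdt_unit_score(
    unit: InformativeUnit, pedigree: Pedigree, genotypes: np.ndarray, snv: int
) -> UnitScore:
    """PDT score of one informative unit at one SNV.

    Trio: ``d = 2*child - father - mother``; null variance is the number of
    heterozygous parents (independent transmissions).  DSP: ``d`` is the
    affected-minus-unaffected count; the unit-level randomization swaps the
    affection labels, giving null variance ``d^2``.
    """
    if unit.kind == "trio":
        father, mother, child = (
            _geno(pedigree, genotypes, pid, snv) for pid in unit.member_ids
        )
        if MISSING in (father, mother, child):
            raise ValueError("unit has missing genotypes; skip upstream")
        d = 2.0 * child - father - mother
        var = float((father == 1) + (mother == 1))
    else:
        affected, unaffected = (
            _geno(pedigree, genotypes, pid, snv) for pid in unit.member_ids
        )
        if MISSING in (affected, unaffected):
            raise ValueError("unit has missing genotypes; skip upstream")
        d = float(affected - unaffected)
        var = d * d
    return UnitScore(unit, snv, d, var)


def _usable(unit: InformativeUnit, pedigree: Pedigree, genotypes: np.ndarray, snv: int) -> bool:
    return all(
        _geno(pedigree, genotypes, pid, snv) != MISSING for pid in unit.member_ids
    )


def pdt_pedigree_stat(
    pedigree: Pedigree,
    genotypes: np.ndarray,
    snv: int,
    combine: str = "average",
    variance: str = "exact",
    units: list[InformativeUnit] | None = None,
) -> PedigreeStat:
    """Per-pedigree PDT statistic ``D_i`` with its conditional null variance."""
    if combine not in ("average", "sum"):
        raise ValueError(f"unknown combine rule {combine!r}")
    if variance not in ("exact", "unit"):
        raise ValueError(f"unknown variance mode {variance!r}")
    if units is None:
        units = extract_informative_units(pedigree)
    units = [u for u in units if _usable(u, pedigree, genotypes, snv)]
    n = len(units)
    if n == 0:
        return PedigreeStat(pedigree.family_id, snv, 0.0, 0.0, 0)

    total = 0.0
    if variance == "unit":
        var = 0.0
        for unit in units:
            score = pdt_unit_score(unit, pedigree, genotypes, snv)
            total += score.d
            var += score.null_var
    else:
        # exact linear form: accumulate per-child weights
        weights: dict[str, float] = {}
        mendel: dict[str, float] = {}
        var_fallback = 0.0
        for unit in units:
            score = pdt_unit_score(unit, pedigree, genotypes, snv)
            total += score.d
            if unit.kind == "trio":
                father_id, mother_id, child_id = unit.member_ids
                weights[child_id] = weights.get(child_id, 0.0) + 2.0
                mendel[child_id] = _mendel_var(
                    _geno(pedigree, genotypes, father_id, snv),
                    _geno(pedigree, genotypes, mother_id, snv),
                )
            else:
                sib_ids = unit.member_ids
                signs = (1.0, -1.0)
                parents = [
                    (pedigree.member(s).father_id, pedigree.member(s).mother_id)
                    for s in sib_ids
                ]
                parent_genos = [
                    (_geno(pedigree, genotypes, f, snv), _geno(pedigree, genotypes, m, snv))
                    for f, m in parents
                ]
                if any(MISSING in pg for pg in parent_genos):
                    var_fallback += score.d * score.d  # label-swap fallback
                    continue
                for sid, sign, (f, m) in zip(sib_ids, signs, parent_genos):
                    weights[sid] = weights.get(sid, 0.0) + sign
                    mendel[sid] = _mendel_var(f, m)
        var = var_fallback + sum(w * w * mendel[c] for c, w in weights.items())

    if combine == "average":
        return PedigreeStat(pedigree.family_id, snv, total / n, var / (n * n), n)
    return PedigreeStat(pedigree.family_id, snv, total, var, n)


def fbat_pedigree_stat(
    pedigree: Pedigree,
    genotypes: np.ndarray,
    snv: int,
    offset: float = 0.0,
) -> PedigreeStat:
    """Per-pedigree FBAT contribution ``U_i`` and its Mendelian null variance."""
    value = 0.0
    var = 0.0
    n_units = 0
    for child in pedigree.nonfounders:
        if child.affection is None or child.genotype_row is None:
            continue
        f = _geno(pedigree, genotypes, child.father_id, snv)
        m = _geno(pedigree, genotypes, child.mother_id, snv)
        x = int(genotypes[child.genotype_row, snv])
        if MISSING in (f, m, x):
            continue
        t = child.affection - offset
        if t == 0.0:
            continue
        v = _mendel_var(f, m)
        value += t * (x - 0.5 * (f + m))
        var += t * t * v
        if v > 0:
            n_units += 1
    return PedigreeStat(pedigree.family_id, snv, value, var, n_units)


def classic_pdt_test(
    pedigrees: list[Pedigree],
    genotypes: np.ndarray,
    snv: int,
    combine: str = "average",
) -> SingleSnvTest:
    """Single-SNV PDT z-test: ``z = sum_i D_i / sqrt(sum_i D_i^2)``.

    The denominator is the empirical (Martin et al.) variance, valid for
    general pedigrees without modelling unit correlations.
    """
    d_values = []
    for ped in pedigrees:
        stat = pdt_pedigree_stat(ped, genotypes, snv, combine=combine)
        if stat.n_units > 0:
            d_values.append(stat.value)
    denom = float(np.sum(np.square(d_values)))
    if denom == 0.0:
        return SingleSnvTest(np.nan, np.nan, False)
    z = float(np.sum(d_values)) / np.sqrt(denom)
    return SingleSnvTest(z, 2.0 * sps.norm.sf(abs(z)), True)


def classic_fbat_test(
    pedigrees: list[Pedigree],
    genotypes: np.ndarray,
    snv: int,
    offset: float = 0.0,
) -> SingleSnvTest:
    """Single-SNV FBAT z-test: ``z = sum_i U_i / sqrt(sum_i Var(U_i))``."""
    total = 0.0
    var = 0.0
    for ped in pedigrees:
        stat = fbat_pedigree_stat(ped, genotypes, snv, offset=offset)
        total += stat.value
        var += stat.null_var
    if var == 0.0:
        return SingleSnvTest(np.nan, np.nan, False)
    z = total / np.sqrt(var)
    return SingleSnvTest(z, 2.0 * sps.norm.sf(abs(z)), True)


# ---------------------------------------------------------------------------
# Vectorized N x m statistic matrices (complete-data fast path)
#
# These operate on a NuclearIndex plus raw arrays and are used by the
# simulation harness; rb_core checks them against the per-pedigree functions.


def _require_complete(geno: np.ndarray, idx: NuclearIndex) -> None:
    rows = np.concatenate([idx.child_row, idx.father_row, idx.mother_row])
    if np.any(geno[rows] == MISSING):
        raise ValueError(
            "vectorized statistic path requires complete genotypes; "
            "use the per-pedigree functions for data with missingness"
        )


def pdt_matrix(
    geno: np.ndarray,
    affection: np.ndarray,
    idx: NuclearIndex,
    combine: str = "average",
) -> tuple[np.ndarray, np.ndarray]:
    """All-pedigree, all-SNV PDT statistics with exact null variances.

    Returns ``(values, null_vars)`` of shape ``(n_families, m)``.  Requires
    complete genotypes and affection coded 1/0 with negative = missing.
    """
    _require_complete(geno, idx)
    m = geno.shape[1]
    nfam = idx.n_families

    aff = affection[idx.child_row]
    known = aff >= 0
    is_case = known & (aff == 1)
    is_ctrl = known & (aff == 0)

    a_sib = np.bincount(idx.sibship_ord[is_case], minlength=idx.n_sibships)
    u_sib = np.bincount(idx.sibship_ord[is_ctrl], minlength=idx.n_sibships)
    u_c = u_sib[idx.sibship_ord]  # unaffected sibs available to each case
    a_c = a_sib[idx.sibship_ord]

    # units per family: one trio per affected child + a*u DSPs per sibship
    n_trio = np.bincount(idx.family_ord[is_case], minlength=nfam)
    fam_of_sib = np.zeros(idx.n_sibships, dtype=np.intp)
    fam_of_sib[idx.sibship_ord] = idx.family_ord  # sibship -> family is unique
    n_dsp = np.bincount(
        fam_of_sib, weights=(a_sib * u_sib).astype(np.float64), minlength=nfam
    ).astype(np.int64)
    n_units = n_trio + n_dsp

    xc = geno[idx.child_row].astype(np.float64)
    xf = geno[idx.father_row].astype(np.float64)
    xm = geno[idx.mother_row].astype(np.float64)

    # per-child signed weight and numerator contribution
    w = np.zeros(len(aff))
    w[is_case] = 2.0 + u_c[is_case]
    w[is_ctrl] = -a_c[is_ctrl].astype(np.float64)
    contrib = w[:, None] * xc
    contrib[is_case] -= xf[is_case] + xm[is_case]  # trio -f-m terms

    v = 0.25 * ((xf == 1).astype(np.float64) + (xm == 1))
    var_contrib = (w**2)[:, None] * v

    values = np.zeros((nfam, m))
    null_vars = np.zeros((nfam, m))
    np.add.at(values, idx.family_ord, contrib)
    np.add.at(null_vars, idx.family_ord, var_contrib)

    informative = n_units > 0
    if combine == "average":
        scale = np.ones(nfam)
        scale[informative] = 1.0 / n_units[informative]
        values *= scale[:, None]
        null_vars *= (scale**2)[:, None]
    elif combine != "sum":
        raise ValueError(f"unknown combine rule {combine!r}")
    values[~informative] = 0.0
    null_vars[~informative] = 0.0
    return values, null_vars


def fbat_matrix(
    geno: np.ndarray,
    affection: np.ndarray,
    idx: NuclearIndex,
    offset: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """All-pedigree, all-SNV FBAT contributions with Mendelian null variances."""
    _require_complete(geno, idx)
    m = geno.shape[1]
    aff = affection[idx.child_row]
    known = aff >= 0
    t = np.where(known, aff - offset, 0.0)

    xc = geno[idx.child_row].astype(np.float64)
    xf = geno[idx.father_row].astype(np.float64)
    xm = geno[idx.mother_row].astype(np.float64)
    v = 0.25 * ((xf == 1).astype(np.float64) + (xm == 1))

    contrib = t[:, None] * (xc - 0.5 * (xf + xm))
    var_contrib = (t**2)[:, None] * v

    values = np.zeros((idx.n_families, m))
    null_vars = np.zeros((idx.n_families, m))
    np.add.at(values, idx.family_ord, contrib)
    np.add.at(null_vars, idx.family_ord, var_contrib)
    return values, null_vars
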