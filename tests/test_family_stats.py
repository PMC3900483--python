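"""PDT/FBAT unit scores, per-pedigree statistics and single-SNV tests.

Null variances are checked against independent enumeration / Monte-Carlo
oracles of the unit-level randomizations (Mendelian transmission for trios
and offspring, affection-label swap for sibpairs).
"""

import itertools

import numpy as np
import pytest
from conftest import build_families

from famblock import family_stats as fs
from famblock.pedigree_data import build_nuclear_index, extract_informative_units


def allele_swap(geno):
    """Recode every genotyped entry to the other allele's count."""
    out = geno.copy()
    mask = out >= 0
    out[mask] = 2 - out[mask]
    return out


class TestPdtUnitScore:
    def test_trio_het_by_hom_parent(self, trio_family):
        pedigrees, geno = trio_family
        units = extract_informative_units(pedigrees[0])
        score = fs.pdt_unit_score(units[0], pedigrees[0], geno, 0)
        assert score.d == 1.0 and score.null_var == 1.0

    def test_trio_both_parents_homozygous_uninformative(self, trio_family):
        pedigrees, geno = trio_family
        units = extract_informative_units(pedigrees[0])
        score = fs.pdt_unit_score(units[0], pedigrees[0], geno, 2)
        assert score.d == 0.0 and score.null_var == 0.0

    def test_dsp_label_swap_variance(self, mixed_family):
        pedigrees, geno = mixed_family
        dsp = [
            u
            for u in extract_informative_units(pedigrees[0])
            if u.kind == "discordant_sibpair"
        ][0]
        score = fs.pdt_unit_score(dsp, pedigrees[0], geno, 0)
        assert score.d == 2.0 and score.null_var == 4.0

    @pytest.mark.parametrize(
        "father,mother", list(itertools.product(range(3), range(3)))
    )
    def test_trio_variance_matches_transmission_enumeration(self, father, mother):
        """Enumerate all Mendelian child genotypes for each parent pair."""
        transmissions = {0: [0], 1: [0, 1], 2: [1]}
        ds = [
            2 * (tf + tm) - father - mother
            for tf in transmissions[father]
            for tm in transmissions[mother]
        ]
        expected_var = np.mean(np.square(ds)) - np.mean(ds) ** 2
        assert abs(np.mean(ds)) < 1e-12  # centered under the null
        pedigrees, geno = build_families(
            {
                "E": [
                    ("f", "0", "0", 0, [father]),
                    ("m", "0", "0", 0, [mother]),
                    ("k", "f", "m", 1, [transmissions[father][0] + transmissions[mother][0]]),
                ]
            }
        )
        unit = extract_informative_units(pedigrees[0])[0]
        score = fs.pdt_unit_score(unit, pedigrees[0], geno, 0)
        assert score.null_var == pytest.approx(expected_var)


class TestPdtPedigreeStat:
    def test_average_of_trio_and_dsp(self, mixed_family):
        pedigrees, geno = mixed_family
        for mode in ("unit", "exact"):  # DSP parents ungenotyped -> same result
            stat = fs.pdt_pedigree_stat(pedigrees[0], geno, 0, variance=mode)
            assert stat.value == pytest.approx(1.5)
            assert stat.null_var == pytest.approx(1.25)
            assert stat.n_units == 2

    def test_sum_combination(self, mixed_family):
        pedigrees, geno = mixed_family
        stat = fs.pdt_pedigree_stat(pedigrees[0], geno, 0, combine="sum")
        assert stat.value == pytest.approx(3.0)
        assert stat.null_var == pytest.approx(5.0)

    def test_no_units_returns_zero(self):
        pedigrees, geno = build_families(
            {"Z": [("a", "0", "0", 0, [1]), ("b", "0", "0", 0, [1]),
                   ("c", "a", "b", 0, [1])]}
        )
        stat = fs.pdt_pedigree_stat(pedigrees[0], geno, 0)
        assert (stat.value, stat.null_var, stat.n_units) == (0.0, 0.0, 0)

    def test_allele_swap_antisymmetry(self, mixed_family):
        pedigrees, geno = mixed_family
        swapped = allele_swap(geno)
        for snv in range(geno.shape[1]):
            a = fs.pdt_pedigree_stat(pedigrees[0], geno, snv)
            b = fs.pdt_pedigree_stat(pedigrees[0], swapped, snv)
            assert b.value == pytest.approx(-a.value)
            assert b.null_var == pytest.approx(a.null_var)

    def test_exact_variance_matches_transmission_simulation(self):
        """Overlapping trio + DSP through a shared affected child.

        The exact linear-form variance must match the Monte-Carlo variance of
        D_i under re-dropped offspring transmissions, while the
        unit-independence combination underestimates it (the units are
        positively correlated through the shared child).
        """
        pedigrees, geno = build_families(
            {
                "O": [
                    ("f", "0", "0", 0, [1]),
                    ("m", "0", "0", 0, [1]),
                    ("aff", "f", "m", 1, [1]),
                    ("una", "f", "m", 0, [0]),
                ]
            }
        )
        ped = pedigrees[0]
        exact = fs.pdt_pedigree_stat(ped, geno, 0, variance="exact")
        unit = fs.pdt_pedigree_stat(ped, geno, 0, variance="unit")

        rng = np.random.default_rng(99)
        n = 40000
        # both parents het: each child's genotype is Binomial(2, 1/2)
        x_aff = rng.integers(0, 2, n) + rng.integers(0, 2, n)
        x_una = rng.integers(0, 2, n) + rng.integers(0, 2, n)
        d_trio = 2 * x_aff - 2
        d_dsp = x_aff - x_una
        d_i = (d_trio + d_dsp) / 2.0
        mc_var = d_i.var()
        se = mc_var * np.sqrt(2.0 / n)  # approximate SE of a variance
        assert exact.null_var == pytest.approx(mc_var, abs=4 * se)
        assert unit.null_var < exact.null_var  # documented approximation


class TestFbat:
    def test_het_het_trio_worked_example(self, fbat_trio):
        pedigrees, geno = fbat_trio
        stat = fs.fbat_pedigree_stat(pedigrees[0], geno, 0)
        assert stat.value == pytest.approx(1.0)
        assert stat.null_var == pytest.approx(0.5)

    def test_homozygous_parents_contribute_nothing(self, trio_family):
        pedigrees, geno = trio_family
        stat = fs.fbat_pedigree_stat(pedigrees[0], geno, 2)
        assert (stat.value, stat.null_var) == (0.0, 0.0)

    def test_offset_brings_in_unaffected_offspring(self):
        pedigrees, geno = build_families(
            {
                "W": [
                    ("f", "0", "0", 0, [1]),
                    ("m", "0", "0", 0, [1]),
                    ("a", "f", "m", 1, [2]),
                    ("u", "f", "m", 0, [2]),
                ]
            }
        )
        zero = fs.fbat_pedigree_stat(pedigrees[0], geno, 0, offset=0.0)
        shifted = fs.fbat_pedigree_stat(pedigrees[0], geno, 0, offset=0.2)
        # offset 0: only the affected child counts
        assert zero.value == pytest.approx(1.0)
        # offset 0.2: affected weight 0.8, unaffected weight -0.2
        assert shifted.value == pytest.approx(0.8 * 1.0 - 0.2 * 1.0)
        assert shifted.null_var == pytest.approx((0.8**2 + 0.2**2) * 0.5)

    def test_value_centered_under_mendelian_simulation(self, fbat_trio):
        pedigrees, _ = fbat_trio
        rng = np.random.default_rng(3)
        n = 100000
        x = rng.integers(0, 2, n) + rng.integers(0, 2, n)  # Aa x Aa child
        values = x - 1.0  # (trait 1) * (X - E[X|parents])
        se = values.std() / np.sqrt(n)
        assert abs(values.mean()) < 3 * se


class TestClassicTests:
    def test_single_pedigree_z_is_one(self, trio_family):
        pedigrees, geno = trio_family
        result = fs.classic_pdt_test(pedigrees, geno, 0)
        assert result.z == pytest.approx(1.0)

    def test_fbat_z_from_worked_example(self, fbat_trio):
        pedigrees, geno = fbat_trio
        result = fs.classic_fbat_test(pedigrees, geno, 0)
        assert result.z == pytest.approx(1.0 / np.sqrt(0.5))

    def test_allele_swap_negates_z_keeps_p(self, mixed_family):
        pedigrees, geno = mixed_family
        a = fs.classic_pdt_test(pedigrees, geno, 0)
        b = fs.classic_pdt_test(pedigrees, allele_swap(geno), 0)
        assert b.z == pytest.approx(-a.z)
        assert b.p_value == pytest.approx(a.p_value)

    def test_uninformative_flag(self):
        pedigrees, geno = build_families(
            {"Z": [("a", "0", "0", 0, [0]), ("b", "0", "0", 0, [0]),
                   ("c", "a", "b", 1, [0])]}
        )
        assert not fs.classic_pdt_test(pedigrees, geno, 0).informative
        assert not fs.classic_fbat_test(pedigrees, geno, 0).informative


class TestVectorizedConsistency:
    def test_matrix_paths_match_per_pedigree_functions(self, small_replicate):
        """The fast array path must agree exactly with the object path."""
        study = small_replicate.to_study()
        idx = build_nuclear_index(study.pedigrees)
        aff_vec = np.full(study.genotypes.shape[0], -1, dtype=np.int8)
        for ped in study.pedigrees:
            for m in ped.members:
                aff_vec[m.genotype_row] = m.affection
        pv, pw = fs.pdt_matrix(study.genotypes, aff_vec, idx)
        fv, fw = fs.fbat_matrix(study.genotypes, aff_vec, idx)
        for i, ped in enumerate(study.pedigrees):
            for j in range(study.genotypes.shape[1]):
                ps = fs.pdt_pedigree_stat(ped, study.genotypes, j)
                assert pv[i, j] == pytest.approx(ps.value)
                assert pw[i, j] == pytest.approx(ps.null_var)
                fsb = fs.fbat_pedigree_stat(ped, study.genotypes, j)
                assert fv[i, j] == pytest.approx(fsb.value)
                assert fw[i, j] == pytest.approx(fsb.null_var)


@pytest.fixture(scope="module")
def null_zs():
    from famblock.family_stats import fbat_matrix, pdt_matrix
    from famblock.simulator import (
        THREE_GENERATION_ROWS,
        SimConfig,
        build_template,
        generate_replicate,
    )

    # enough families that the z lattice is fine relative to the KS
    # resolution at 2500 replicates
    cfg = SimConfig(
        n_pedigrees=300, seed=424242, template_rows=THREE_GENERATION_ROWS
    )
    tpl = build_template(cfg)
    snv = 9  # the most common SNV: plenty of informative units
    zp, zf = [], []
    for r in range(2500):
        rep = generate_replicate(cfg, r, template=tpl)
        v, w = pdt_matrix(rep.genotypes, rep.affection, tpl.nuclear)
        denom = np.sum(v[:, snv] ** 2)
        if denom > 0:
            zp.append(v[:, snv].sum() / np.sqrt(denom))
        v, w = fbat_matrix(rep.genotypes, rep.affection, tpl.nuclear)
        if w[:, snv].sum() > 0:
            zf.append(v[:, snv].sum() / np.sqrt(w[:, snv].sum()))
    return np.array(zp), np.array(zf)


class TestNullCalibration:
    """Gene-drop null: single-SNV z statistics are standard normal."""

    @pytest.mark.parametrize("which", ["pdt", "fbat"])
    def test_z_standard_normal_ks(self, null_zs, which):
        from scipy import stats as sps

        z = null_zs[0] if which == "pdt" else null_zs[1]
        assert len(z) > 2000
        assert sps.kstest(z, "norm").pvalue > 0.01

    @pytest.mark.parametrize("which", ["pdt", "fbat"])
    def test_rejection_rate_within_binomial_ci(self, null_zs, which):
        z = null_zs[0] if which == "pdt" else null_zs[1]
        rate = np.mean(np.abs(z) > 1.959964)
        n = len(z)
        half = 2.576 * np.sqrt(0.05 * 0.95 / n)
        assert abs(rate - 0.05) < half
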