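"""Shared fixtures: tiny hand-built pedigrees and small simulated worlds."""

from __future__ import annotations

import numpy as np
import pytest

from famblock.pedigree_data import Individual, Pedigree
from famblock.simulator import THREE_GENERATION_ROWS, SimConfig


def build_families(specs):
    """Build pedigrees plus a genotype matrix from a compact description.

    ``specs`` maps family id -> list of
    ``(person, father, mother, affection, genotypes-or-None)`` where parents
    are "0" for founders, affection is 1/0/None, and genotypes is a list of
    minor-allele counts (None = not genotyped).  Returns
    ``(pedigrees, genotype_matrix)``.
    """
    pedigrees = []
    rows = []
    for fam, members in specs.items():
        inds = []
        for person, father, mother, aff, geno in members:
            row = None
            if geno is not None:
                row = len(rows)
                rows.append(geno)
            inds.append(
                Individual(
                    person_id=person,
                    family_id=fam,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=None,
                    affection=aff,
                    genotype_row=row,
                )
            )
        ped = Pedigree(fam, inds)
        ped.validate()
        pedigrees.append(ped)
    geno = np.array(rows, dtype=np.int16) if rows else np.zeros((0, 0), np.int16)
    return pedigrees, geno


@pytest.fixture
def trio_family():
    """One trio: father Aa, mother AA, affected child Aa (+2 extra SNVs)."""
    return build_families(
        {
            "T1": [
                ("dad", "0", "0", 0, [1, 2, 0]),
                ("mom", "0", "0", 0, [0, 1, 0]),
                ("kid", "dad", "mom", 1, [1, 2, 0]),
            ]
        }
    )


@pytest.fixture
def mixed_family():
    """A pedigree with one non-overlapping trio and one DSP.

    The trio child R (genotype 1, one het parent) marries an ungenotyped
    spouse; their children form a discordant sibpair (2 vs 0), so the DSP
    uses the label-swap variance in every mode: unit scores
    d = (1, var 1) and (2, var 4).
    """
    return build_families(
        {
            "M1": [
                ("pa", "0", "0", 0, [1, 1, 1]),
                ("pb", "0", "0", 0, [0, 1, 0]),
                ("r", "pa", "pb", 1, [1, 2, 1]),
                ("sp", "0", "0", 0, None),
                ("d1", "r", "sp", 1, [2, 1, 1]),
                ("d2", "r", "sp", 0, [0, 1, 1]),
            ]
        }
    )


@pytest.fixture
def fbat_trio():
    """FBAT worked example: parents Aa x Aa, affected child aa."""
    return build_families(
        {
            "F1": [
                ("dad", "0", "0", 0, [1]),
                ("mom", "0", "0", 0, [1]),
                ("kid", "dad", "mom", 1, [2]),
            ]
        }
    )


@pytest.fixture(scope="session")
def small_world_config():
    """Desk-scale simulation world: 40 compact three-generation families."""
    return SimConfig(
        n_pedigrees=40, seed=20240101, template_rows=THREE_GENERATION_ROWS
    )


@pytest.fixture(scope="session")
def small_replicate(small_world_config):
    from famblock.simulator import generate_replicate

    return generate_replicate(small_world_config, 0)
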