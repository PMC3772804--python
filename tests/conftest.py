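import numpy as np
import pandas as pd
import pytest

from pedimeth.pedigree import (
    Individual,
    Pedigree,
    additive_relationship,
)
from pedimeth.simulate import SyntheticStudyConfig, simulate_pedigree


def I(iid, father=None, mother=None, sex="male", family="F1", twin=None):
    return Individual(
        iid=iid, family=family, father=father, mother=mother, sex=sex,
        twin_group=twin,
    )


@pytest.fixture
def trio():
    """Smallest valid family: two founder parents and one child."""
    return Pedigree(
        [I("P1"), I("P2", sex="female"), I("C", "P1", "P2", sex="female")]
    )


@pytest.fixture
def six_member():
    """Two-generation family: founder couple, two children, their spouses'
    children — GP1 x GP2 -> C1, C2; C1 x S1 -> K1; enumerable by hand."""
    return Pedigree(
        [
            I("GP1"),
            I("GP2", sex="female"),
            I("S1", sex="female"),
            I("C1", "GP1", "GP2"),
            I("C2", "GP1", "GP2", sex="female"),
            I("K1", "C1", "S1"),
        ]
    )


@pytest.fixture
def double_cousins():
    """Two sibling pairs from unrelated founder couples intermarry; their
    children are double first cousins."""
    return Pedigree(
        [
            I("GF1"), I("GM1", sex="female"), I("GF2"), I("GM2", sex="female"),
            I("S1", "GF1", "GM1"), I("S2", "GF1", "GM1", sex="female"),
            I("T1", "GF2", "GM2", sex="female"), I("T2", "GF2", "GM2"),
            I("X1", "S1", "T1"), I("X2", "T2", "S2", sex="female"),
        ]
    )


@pytest.fixture
def three_generation():
    """Founder couple, child couple, grandchild (for grandparent pairs)."""
    return Pedigree(
        [
            I("GF"), I("GM", sex="female"), I("SP", sex="female"),
            I("C", "GF", "GM"),
            I("G", "C", "SP"),
        ]
    )


@pytest.fixture(scope="session")
def cohort():
    """The default synthetic extended-family cohort (187 profiled members)
    with its relationship matrix; shared across tests for speed."""
    cfg = SyntheticStudyConfig(seed=1)
    ped, sampled, census = simulate_pedigree(cfg)
    rel = additive_relationship(ped).subset(sampled)
    return {"config": cfg, "pedigree": ped, "sampled": sampled,
            "census": census, "rel": rel}


@pytest.fixture(scope="session")
def recovery_pedigree():
    """A ~200-member fully observed pedigree for parameter-recovery tests."""
    cfg = SyntheticStudyConfig(seed=1, n_families=12)
    ped, _, _ = simulate_pedigree(cfg)
    return additive_relationship(ped)


def gene_drop_relationship(ped: Pedigree, n_drops: int, seed: int) -> np.ndarray:
    """Monte-Carlo estimate of A by dropping founder allele labels.

    Independent of the tabular recursion: founders get unique allele
    labels, each child inherits one random allele per parent, and A[i,j]
    is estimated as twice the probability that randomly sampled alleles
    from i and j are identical by descent (averaged over the four allele
    pairings).
    """
    rng = np.random.default_rng(seed)
    order = ped.topological_order()
    hap: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    label = 0
    for iid in order:
        fa, mo = ped.parents(iid)
        if fa is None:
            a = np.full(n_drops, label)
            b = np.full(n_drops, label + 1)
            label += 2
        else:
            pick_a = rng.integers(2, size=n_drops).astype(bool)
            pick_b = rng.integers(2, size=n_drops).astype(bool)
            a = np.where(pick_a, hap[fa][0], hap[fa][1])
            b = np.where(pick_b, hap[mo][0], hap[mo][1])
        hap[iid] = (a, b)
    ids = ped.ids
    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        ai, bi = hap[ids[i]]
        for j in range(i, n):
            aj, bj = hap[ids[j]]
            share = (
                (ai == aj).mean() + (ai == bj).mean()
                + (bi == aj).mean() + (bi == bj).mean()
            ) / 4.0
            A[i, j] = A[j, i] = 2.0 * share
    return A
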