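"""Synthetic cohorts: determinism, design truth, gene-drop fidelity."""

import dataclasses

import numpy as np
import pytest

from kincompare.genomic import classify_relationship
from kincompare.simulate import (
    SimScenario,
    founder_frequencies,
    gene_drop,
    hwe_cohort,
    realized_kinship,
    realized_kinship_se,
    simulate_cohort,
    simulate_pedigree,
    write_fixture,
)


def test_same_seed_is_byte_identical(tmp_path):
    sc = SimScenario(n_loci=300, seed=7)
    a, b = simulate_cohort(sc), simulate_cohort(sc)
    assert np.array_equal(a.genotypes.dosage, b.genotypes.dosage)
    assert a.pedigree.ids == b.pedigree.ids
    assert a.sim_pedigree.truth_pairs.equals(b.sim_pedigree.truth_pairs)
    pa = write_fixture(a, tmp_path / "a")
    pb = write_fixture(b, tmp_path / "b")
    for k in pa:
        assert pa[k].read_bytes() == pb[k].read_bytes()


def test_truth_table_contains_designed_relationships():
    sp = simulate_pedigree(SimScenario(seed=1))
    tp = sp.truth_pairs
    assert (tp.loc[tp.relationship == "fullsib", "phi_true"] == 0.25).all()
    assert (tp.loc[tp.relationship == "halfsib", "phi_true"] == 0.125).all()
    assert (tp.loc[tp.relationship == "firstcousin", "phi_true"] == 0.0625).all()
    ti = sp.truth_inbreeding
    assert sorted(ti["F_true"].unique()) == [0.0625, 0.125, 0.25]
    assert (ti.loc[ti.origin == "cousin_mating_offspring", "F_true"] == 0.0625).all()


def test_truth_agrees_with_pedigree_engine():
    """Motifs use fresh unrelated founders, so the recursive engine on
    the full pedigree must reproduce the canonical truth values."""
    sp = simulate_pedigree(SimScenario(seed=5))
    ped = sp.full_pedigree
    for row in sp.truth_pairs.itertuples():
        assert ped.kinship(row.id1, row.id2) == row.phi_true
    for row in sp.truth_inbreeding.itertuples():
        assert ped.inbreeding(row.id) == row.F_true


def test_infeasible_design_rejected():
    with pytest.raises(ValueError, match="infeasible"):
        simulate_pedigree(
            SimScenario(subpop_sizes=(2, 2, 2), n_fullsib=10, seed=0)
        )


def test_cohort_size_and_groups():
    coh = simulate_cohort(SimScenario(n_loci=200, seed=2))
    G = coh.genotypes
    assert G.n_individuals == 99
    assert [G.groups.count(g) for g in ("white", "blackbrown", "grey")] == [
        54,
        31,
        14,
    ]


# -- founder frequencies ----------------------------------------------

def test_zero_drift_keeps_pool_frequencies():
    sc = SimScenario(n_loci=500, drift_generations=0, seed=3)
    f = founder_frequencies(sc)
    assert np.allclose(f[0], f[1]) and np.allclose(f[0], f[2])
    assert (f > 0).all() and (f < 1).all()


def test_balding_nichols_modes():
    sc = SimScenario(n_loci=2000, freq_model="balding-nichols", bn_theta=0.054, seed=4)
    f = founder_frequencies(sc)
    assert (f > 0).all() and (f < 1).all()
    # theta -> 0 limit concentrates at the pool value
    tight = dataclasses.replace(sc, bn_theta=1e-4)
    ft = founder_frequencies(tight)
    assert np.abs(ft[0] - ft[1]).mean() < 0.01
    with pytest.raises(ValueError):
        SimScenario(freq_model="balding-nichols", bn_theta=1.5)


# -- gene dropping -----------------------------------------------------

def test_gene_drop_mendelian_consistency(default_cohort):
    """Every designed parent-offspring pair shares at least one allele
    in state at every locus where both are called."""
    coh = default_cohort
    tp = coh.sim_pedigree.truth_pairs
    G = coh.genotypes
    for row in tp[tp.relationship == "parent_offspring"].itertuples():
        a = G.dosage[G.ids.index(row.id1)]
        b = G.dosage[G.ids.index(row.id2)]
        both = (a >= 0) & (b >= 0)
        assert not ((a[both] == 0) & (b[both] == 2)).any()
        assert not ((a[both] == 2) & (b[both] == 0)).any()


def test_gene_drop_founder_hwe_proportions(rng):
    from kincompare.pedigree import Pedigree

    ped = Pedigree.from_records([(f"f{k}", 0, 0) for k in range(40)])
    freqs = np.full((1, 10000), 0.5)
    drop = gene_drop(ped, {i: "p" for i in ped.ids}, freqs, ("p",), rng=rng)
    counts = [(drop.genotypes.dosage == v).mean() for v in (0, 1, 2)]
    se = 3 * np.sqrt(0.25 * 0.75 / (40 * 10000))
    assert abs(counts[0] - 0.25) < se
    assert abs(counts[1] - 0.5) < 2 * se
    assert abs(counts[2] - 0.25) < se


def test_gene_drop_ibd_audit_matches_design(default_cohort):
    """Realized IBD sharing of designed full-sib pairs sits within
    3 Monte-Carlo standard errors of the design kinship 1/4."""
    coh = default_cohort
    for row in coh.sim_pedigree.truth_pairs.query(
        "relationship == 'fullsib'"
    ).itertuples():
        est = realized_kinship(coh.drop, row.id1, row.id2)
        se = realized_kinship_se(coh.drop, row.id1, row.id2)
        assert abs(est - 0.25) < 3 * se


def test_gene_drop_requires_subpopulation():
    from kincompare.pedigree import Pedigree

    ped = Pedigree.from_records([("a", 0, 0)])
    with pytest.raises(ValueError, match="no subpopulation"):
        gene_drop(ped, {}, np.full((1, 10), 0.5), ("p",))


def test_ld_block_copies_are_pruned(rng):
    """Noisy duplicated columns create high-r2 pairs that LD pruning
    then removes, one member per duplicated pair."""
    from kincompare.genomic import ld_prune

    G = hwe_cohort(np.tile(rng.uniform(0.2, 0.8, 100), (1, 1)), 150, ("a",), rng=rng)
    from kincompare.simulate import add_ld_blocks

    G2 = add_ld_blocks(G, n_copies=10, noise_rate=0.01, rng=rng)
    assert G2.n_loci == 110
    kept_before = len(ld_prune(G))
    kept_after = len(ld_prune(G2))
    assert kept_after <= kept_before + 1  # each copy pair loses a member


def test_hwe_cohort_shape(rng):
    G = hwe_cohort(np.full((2, 100), 0.3), [5, 7], ("a", "b"), rng=rng)
    assert G.n_individuals == 12 and G.groups.count("b") == 7


# -- fixtures round trip ----------------------------------------------

def test_fixture_round_trip(tmp_path):
    from kincompare.io import read_plink_text
    from kincompare.pedigree import Pedigree

    coh = simulate_cohort(SimScenario(n_loci=400, seed=9))
    paths = write_fixture(coh, tmp_path)
    G2 = read_plink_text(paths["ped"], paths["map"])
    assert G2.ids == coh.genotypes.ids
    assert np.array_equal(G2.dosage, coh.genotypes.orient_minor().dosage)
    ped2 = Pedigree.from_csv(paths["pedigree_csv"])
    assert set(ped2.ids) == set(coh.pedigree.ids)
    for rid in coh.pedigree.ids:
        assert ped2.inbreeding(rid) == coh.pedigree.inbreeding(rid)
    # map positions are 1-based and ordered within chromosome
    assert (G2.pos >= 1).all()


def test_truth_degrees_consistent_with_classifier():
    sp = simulate_pedigree(SimScenario(seed=11))
    expected = {
        "fullsib": "1st",
        "parent_offspring": "1st",
        "halfsib": "2nd",
        "avuncular": "2nd",
        "firstcousin": "3rd",
    }
    for row in sp.truth_pairs.itertuples():
        assert classify_relationship(row.phi_true) == expected[row.relationship]
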