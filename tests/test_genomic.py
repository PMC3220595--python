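"""SNP estimators: frequencies, inbreeding, robust kinship, filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kincompare.genomic import (
    DEGREE_CUTOFFS,
    MISSING,
    GenotypeMatrix,
    allele_frequencies,
    classify_relationship,
    estimation_loci,
    hwe_exact_pvalue,
    hwe_filter,
    king_robust_kinship,
    ld_prune,
    mom_inbreeding,
    pairwise_kinship_table,
    zero_ibd_probability,
)


def make_matrix(dosage, chrom=None, pos=None, ids=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, L = dosage.shape
    return GenotypeMatrix(
        dosage=dosage,
        ids=ids or [f"i{k}" for k in range(n)],
        chrom=np.asarray(chrom if chrom is not None else ["1"] * L, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, L + 1)),
    )


def hwe_dosage(p, n, rng):
    return (
        rng.binomial(1, p, size=(n, len(p))) + rng.binomial(1, p, size=(n, len(p)))
    ).astype(np.int8)


# -- frequencies -------------------------------------------------------

def test_allele_frequency_simple_and_monomorphic():
    G = make_matrix([[0, 0], [1, 0], [2, 0]])
    p, n_called = allele_frequencies(G)
    assert p[0] == pytest.approx(0.5)
    assert p[1] == 0.0
    assert n_called.tolist() == [3, 3]
    # monomorphic locus excluded from the estimation set
    assert estimation_loci(G).tolist() == [True, False]


def test_allele_frequency_missing_and_all_missing():
    G = make_matrix([[MISSING, MISSING], [1, MISSING], [2, MISSING]])
    p, n_called = allele_frequencies(G)
    assert p[0] == pytest.approx(3 / 4)  # over the 2 called individuals
    assert n_called[1] == 0 and np.isnan(p[1])
    assert not estimation_loci(G)[1]


def test_allele_frequency_sampling_bound(rng):
    p_true = 0.3
    G = make_matrix(hwe_dosage(np.full(1000, p_true), 1000, rng))
    p, _ = allele_frequencies(G)
    bound = 3 * np.sqrt(p_true * (1 - p_true) / 2000)
    assert abs(p.mean() - p_true) < bound


def test_non_autosomal_loci_flagged():
    G = make_matrix([[0, 1], [1, 2]], chrom=["1", "X"])
    assert estimation_loci(G).tolist() == [True, False]
    assert G.autosomal_mask.tolist() == [True, False]


# -- method-of-moments inbreeding -------------------------------------

def test_mom_inbreeding_fully_homozygous_is_one(rng):
    d = hwe_dosage(np.full(50, 0.4), 20, rng)
    d[0] = np.where(d[0] == 1, 2, d[0])  # individual 0 homozygous throughout
    tab = mom_inbreeding(make_matrix(d))
    assert tab.loc[0, "F_raw"] == pytest.approx(1.0)


def test_mom_inbreeding_all_het_at_half_without_correction():
    # 4 individuals keep p = 0.5 at every locus; focal is fully heterozygous
    d = np.array([[1] * 10, [1] * 10, [0] * 10, [2] * 10], dtype=np.int8)
    tab = mom_inbreeding(make_matrix(d), small_sample_correction=False)
    assert tab.loc[0, "F_raw"] == pytest.approx(-1.0)
    assert tab.loc[0, "F"] == 0.0


def test_mom_inbreeding_null_mean_near_zero(rng):
    p = rng.uniform(0.05, 0.95, 5000)
    G = make_matrix(hwe_dosage(p, 500, rng))
    tab = mom_inbreeding(G)
    assert abs(tab["F_raw"].mean()) < 0.01
    # truncation property
    assert (tab["F"] >= 0).all()
    raw_pos = tab["F_raw"] >= 0
    assert np.allclose(tab.loc[raw_pos, "F"], tab.loc[raw_pos, "F_raw"])


# -- KING-robust kinship and pi0 --------------------------------------

@pytest.fixture(scope="module")
def unrelated_pair_matrix():
    rng = np.random.default_rng(11)
    p = rng.uniform(0.05, 0.95, 20000)
    d = hwe_dosage(p, 2, rng)
    d = np.vstack([d, d[0]])  # third row duplicates the first
    return make_matrix(d, ids=["a", "b", "dup"]), p


def test_king_duplicate_sample_is_half(unrelated_pair_matrix):
    G, _ = unrelated_pair_matrix
    assert king_robust_kinship(G, "a", "dup") == pytest.approx(0.5, abs=0)


def test_king_unrelated_near_zero(unrelated_pair_matrix):
    G, _ = unrelated_pair_matrix
    assert abs(king_robust_kinship(G, "a", "b")) < 0.02


def test_pi0_duplicate_and_unrelated(unrelated_pair_matrix):
    G, p = unrelated_pair_matrix
    assert zero_ibd_probability(G, p, "a", "dup") == 0.0
    assert abs(zero_ibd_probability(G, p, "a", "b") - 1.0) < 0.05


def test_pi0_parent_offspring_exact_zero(rng):
    p = rng.uniform(0.1, 0.9, 5000)
    parent = hwe_dosage(p, 1, rng)[0]
    other = hwe_dosage(p, 1, rng)[0]
    # child inherits one allele from parent, one from the other founder
    child = (
        np.where(parent == 1, rng.integers(0, 2, p.size), parent // 2)
        + np.where(other == 1, rng.integers(0, 2, p.size), other // 2)
    ).astype(np.int8)
    G = make_matrix(np.vstack([parent, child]), ids=["P", "C"])
    assert zero_ibd_probability(G, p, "P", "C") == 0.0


def test_king_orientation_invariance(unrelated_pair_matrix, rng):
    """Flipping which allele is counted at any subset of loci changes
    neither kinship nor pi0 (heterozygote identity is coding-free)."""
    G, p = unrelated_pair_matrix
    flip = rng.random(G.n_loci) < 0.5
    d = G.dosage.copy()
    d[:, flip] = 2 - d[:, flip]
    G2 = make_matrix(d, ids=G.ids)
    p2 = np.where(flip, 1 - p, p)
    assert king_robust_kinship(G2, "a", "b") == pytest.approx(
        king_robust_kinship(G, "a", "b"), abs=0
    )
    assert zero_ibd_probability(G2, p2, "a", "b") == pytest.approx(
        zero_ibd_probability(G, p, "a", "b"), abs=1e-12
    )


def test_king_invariant_to_other_samples(default_cohort):
    """The robust estimator uses only the two genotype vectors, so the
    estimate for a pair is identical in the full cohort and alone."""
    G = default_cohort.genotypes
    a, b = G.ids[0], G.ids[50]
    full = king_robust_kinship(G, a, b)
    alone = king_robust_kinship(G.subset(individuals=[a, b]), a, b)
    assert full == pytest.approx(alone, abs=0)


def test_pairwise_table_shape_and_consistency(default_cohort):
    G = default_cohort.genotypes
    tab = pairwise_kinship_table(G)
    n = G.n_individuals
    assert len(tab) == n * (n - 1) // 2
    ok = tab["phi_raw"].notna()
    assert (tab.loc[ok, "phi"] >= 0).all()
    pos = ok & (tab["phi_raw"] >= 0)
    assert np.allclose(tab.loc[pos, "phi"], tab.loc[pos, "phi_raw"])
    assert tab["pi0"].dropna().between(0, 1).all()
    # spot-check the vectorized table against the scalar estimator
    row = tab.iloc[123]
    assert king_robust_kinship(G, row.id1, row.id2) == pytest.approx(
        row.phi_raw, abs=1e-10
    )


def test_low_overlap_pair_reported_missing():
    d = np.full((2, 120), 1, dtype=np.int8)
    d[0, :50] = MISSING  # only 70 complete loci
    G = make_matrix(d)
    with pytest.warns(UserWarning, match="complete loci"):
        assert np.isnan(king_robust_kinship(G, 0, 1, min_loci=100))


# -- classification ----------------------------------------------------

@pytest.mark.parametrize(
    "phi, expected",
    [
        (0.5, "duplicate/MZ"),
        (2 ** (-1.5) + 1e-9, "duplicate/MZ"),
        (2 ** (-1.5), "1st"),
        (0.25, "1st"),
        (2 ** (-2.5), "2nd"),
        (0.125, "2nd"),
        (2 ** (-3.5), "3rd"),
        (0.0625, "3rd"),
        (2 ** (-4.5), "unrelated"),
        (0.01, "unrelated"),
        (-0.1, "unrelated"),
    ],
)
def test_classifier_boundaries(phi, expected):
    assert classify_relationship(phi) == expected


def test_first_degree_split_on_pi0():
    assert classify_relationship(0.25, pi0=0.0) == "1st (parent-offspring)"
    assert classify_relationship(0.25, pi0=0.25) == "1st (full-sib)"


@given(phi=st.floats(-1, 1, allow_nan=False))
@settings(derandomize=True, max_examples=200)
def test_classifier_total_and_monotone(phi):
    cat = classify_relationship(phi)
    assert cat in {"duplicate/MZ", "1st", "2nd", "3rd", "unrelated"}
    # higher kinship never maps to a more distant degree
    order = {"duplicate/MZ": 0, "1st": 1, "2nd": 2, "3rd": 3, "unrelated": 4}
    assert order[classify_relationship(phi + 0.05)] <= order[cat]


# -- LD pruning --------------------------------------------------------

def test_ld_prune_removes_one_of_identical_pair(rng):
    d = rng.binomial(2, rng.uniform(0.2, 0.8, 20), size=(100, 20)).astype(np.int8)
    d[:, 1] = d[:, 0]
    kept = ld_prune(make_matrix(d))
    assert (0 in kept) != (1 in kept)  # exactly one survives


def test_ld_prune_does_not_span_chromosomes(rng):
    d = rng.binomial(2, rng.uniform(0.2, 0.8, 4), size=(100, 4)).astype(np.int8)
    d[:, 2] = d[:, 1]  # perfect LD across the chromosome boundary
    G = make_matrix(d, chrom=["1", "1", "2", "2"], pos=[1, 2, 1, 2])
    kept = ld_prune(G)
    assert 1 in kept and 2 in kept


def test_ld_prune_retains_most_independent_loci(rng):
    d = rng.binomial(2, rng.uniform(0.2, 0.8, 200), size=(200, 200)).astype(np.int8)
    kept = ld_prune(make_matrix(d))
    assert len(kept) >= 0.95 * 200


# -- HWE test ----------------------------------------------------------

def test_hwe_exact_perfect_proportions_retained():
    assert hwe_exact_pvalue(50, 25, 25) == pytest.approx(1.0, abs=1e-9)


def test_hwe_all_heterozygous_removed():
    d = np.ones((200, 1), dtype=np.int8)
    keep, pv = hwe_filter(make_matrix(d), alpha=0.01)
    assert not keep[0] and pv[0] < 1e-10


def test_hwe_monomorphic_locus_untestable():
    assert hwe_exact_pvalue(0, 30, 0) == 1.0


def test_hwe_exact_matches_bruteforce_enumeration():
    """Cross-check against a direct enumeration of the Levene
    conditional distribution at small counts."""
    from math import factorial

    def brute(n_het, n_hom1, n_hom2):
        # P(h | allele counts) is proportional to 2^h / (h! h1! h2!)
        n = n_het + n_hom1 + n_hom2
        na = 2 * n_hom1 + n_het
        weights = {}
        for h in range(na % 2, min(na, 2 * n - na) + 1, 2):
            h1 = (na - h) // 2
            h2 = n - h - h1
            if h2 < 0:
                continue
            weights[h] = 2**h / (
                factorial(h) * factorial(h1) * factorial(h2)
            )
        z = sum(weights.values())
        obs = weights[n_het] / z
        return sum(w / z for w in weights.values() if w / z <= obs * (1 + 1e-12))

    for counts in [(3, 2, 5), (4, 1, 5), (0, 5, 5), (6, 2, 2)]:
        assert hwe_exact_pvalue(*counts) == pytest.approx(brute(*counts), rel=1e-9)


def test_hwe_null_calibration(rng):
    """Under HWE the exact test at alpha=0.01 removes at most ~1% of
    loci (it is conservative because the null distribution is
    discrete) and still removes some."""
    from scipy.stats import binom

    L, n = 2000, 100
    p = rng.uniform(0.1, 0.5, L)
    G = make_matrix(hwe_dosage(p, n, rng))
    keep, _ = hwe_filter(G, alpha=0.01)
    n_removed = int((~keep).sum())
    assert 0 < n_removed <= binom.ppf(0.995, L, 0.01)
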