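"""SNP-based estimators: allele frequencies, method-of-moments inbreeding,
KING-robust pairwise kinship, zero-IBD probability, LD pruning, HWE
filtering and relationship-degree classification.

Genotypes live in a :class:`GenotypeMatrix`: an individuals x loci
integer dosage matrix counting copies of the per-locus minor allele
(0/1/2), with -1 marking missing calls.  Heterozygote identity is
invariant to which allele is counted, so the kinship and zero-IBD
estimators are robust to allele orientation; the method-of-moments
inbreeding estimator only needs the frequency of the counted allele.

All pairwise statistics use pairwise-complete loci; per-individual
statistics use that individual's non-missing loci.  No imputation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "allele_frequencies",
    "mom_inbreeding",
    "king_robust_kinship",
    "zero_ibd_probability",
    "pairwise_kinship_table",
    "classify_relationship",
    "DEGREE_CATEGORIES",
    "ld_prune",
    "hwe_exact_pvalue",
    "hwe_filter",
]

MISSING = -1

#: relationship-degree categories, closest first
DEGREE_CATEGORIES = ["duplicate/MZ", "1st", "2nd", "3rd", "unrelated"]

#: kinship cutoffs between successive degrees: 2^(-3/2) .. 2^(-9/2)
DEGREE_CUTOFFS = [2.0 ** (-(2 * k + 3) / 2.0) for k in range(4)]

NON_AUTOSOMAL_CODES = {"0", "X", "Y", "XY", "MT", "M"}


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes as minor-allele dosage.

    Attributes
    ----------
    dosage : (n_individuals, n_loci) int8 array
        Copies of the counted allele: 0, 1, 2, or -1 for missing.
    ids : individual identifiers.
    chrom : per-locus chromosome code (str); X/Y/0/MT flagged non-autosomal.
    pos : per-locus 1-based position.
    alleles : per-locus (other, counted) allele pair.
    groups : optional subpopulation label per individual.
    """

    dosage: np.ndarray
    ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    alleles: list[tuple[str, str]] = field(default_factory=list)
    groups: list[str] | None = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2,-1}")
        if self.dosage.shape != (len(self.ids), len(self.chrom)):
            raise ValueError("dosage shape does not match ids/loci")
        if not self.alleles:
            self.alleles = [("A", "B")] * self.n_loci

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.dosage != MISSING

    @property
    def autosomal_mask(self) -> np.ndarray:
        return np.array(
            [str(c).upper() not in NON_AUTOSOMAL_CODES for c in self.chrom]
        )

    def subset(self, individuals=None, loci=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given individual ids /
        boolean-or-integer locus selection."""
        ind_ix = np.arange(self.n_individuals)
        if individuals is not None:
            lookup = {i: k for k, i in enumerate(self.ids)}
            ind_ix = np.array([lookup[str(i)] for i in individuals])
        loc_ix = np.arange(self.n_loci)
        if loci is not None:
            loc_ix = np.asarray(loci)
            if loc_ix.dtype == bool:
                loc_ix = np.flatnonzero(loc_ix)
        return GenotypeMatrix(
            dosage=self.dosage[np.ix_(ind_ix, loc_ix)],
            ids=[self.ids[k] for k in ind_ix],
            chrom=self.chrom[loc_ix],
            pos=self.pos[loc_ix],
            alleles=[self.alleles[k] for k in loc_ix],
            groups=[self.groups[k] for k in ind_ix] if self.groups else None,
        )

    def orient_minor(self) -> "GenotypeMatrix":
        """Flip loci so the counted allele is the sample minor allele.

        Ties (frequency exactly 1/2) keep the current orientation.
        """
        p, _ = allele_frequencies(self)
        flip = p > 0.5
        dosage = self.dosage.copy()
        cols = dosage[:, flip]
        obs = cols != MISSING
        cols[obs] = 2 - cols[obs]
        dosage[:, flip] = cols
        alleles = [
            (b, a) if f else (a, b)
            for (a, b), f in zip(self.alleles, flip)
        ]
        return replace(self, dosage=dosage, alleles=alleles)


# ---------------------------------------------------------------------
# frequencies and inbreeding
# ---------------------------------------------------------------------

def allele_frequencies(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Counted-allele frequency and diploid call count per locus.

    p_l = (counted alleles at l) / (2 * non-missing individuals at l);
    all-missing loci get p = NaN and call count 0 and must be excluded
    downstream.
    """
    obs = G.observed
    n_called = obs.sum(axis=0)
    counts = np.where(obs, G.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, counts / (2.0 * n_called), np.nan)
    return p, n_called


def estimation_loci(G: GenotypeMatrix) -> np.ndarray:
    """Default estimation mask: autosomal, polymorphic, not all-missing."""
    p, n_called = allele_frequencies(G)
    with np.errstate(invalid="ignore"):
        poly = (n_called > 0) & (p > 0) & (p < 1)
    return G.autosomal_mask & poly


def mom_inbreeding(
    G: GenotypeMatrix,
    freqs: np.ndarray | None = None,
    loci: np.ndarray | None = None,
    small_sample_correction: bool = True,
) -> pd.DataFrame:
    """Method-of-moments inbreeding from observed vs expected homozygosity.

    For each individual, over its L_obs non-missing loci in the
    estimation set:

        F = (O(Hom) - E(Hom)) / (L_obs - E(Hom))

    with E(Hom) = sum_l [1 - 2 p_l (1 - p_l) * 2n_l / (2n_l - 1)]; the
    2n/(2n-1) factor is the small-sample correction on expected
    heterozygosity (disable with ``small_sample_correction=False``).
    Frequencies default to sample frequencies, which makes the reference
    population the cohort itself; pass ``freqs`` to use subpopulation
    references instead.

    Returns columns id, n_loci, o_hom, e_hom, F_raw, F where F is the
    raw estimate truncated at zero (negative estimates reflect sampling
    error and are reported as 0 in the truncated column).
    """
    p_all, n_called = allele_frequencies(G)
    if freqs is None:
        freqs = p_all
    mask = estimation_loci(G) if loci is None else np.asarray(loci)
    if mask.dtype != bool:
        m = np.zeros(G.n_loci, dtype=bool)
        m[mask] = True
        mask = m

    p = np.asarray(freqs, dtype=float)[mask]
    n_l = n_called[mask]
    corr = 2.0 * n_l / (2.0 * n_l - 1.0) if small_sample_correction else 1.0
    e_hom_locus = 1.0 - 2.0 * p * (1.0 - p) * corr

    d = G.dosage[:, mask]
    obs = d != MISSING
    o_hom = (obs & ((d == 0) | (d == 2))).sum(axis=1).astype(float)
    l_obs = obs.sum(axis=1).astype(float)
    e_hom = obs @ e_hom_locus

    denom = l_obs - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        f_raw = np.where(denom > 0, (o_hom - e_hom) / denom, np.nan)
    if np.isnan(f_raw).any():
        warnings.warn(
            "inbreeding undefined for some individuals "
            "(non-positive O-E denominator); reported as NaN",
            stacklevel=2,
        )
    return pd.DataFrame(
        {
            "id": G.ids,
            "n_loci": l_obs.astype(int),
            "o_hom": o_hom.astype(int),
            "e_hom": e_hom,
            "F_raw": f_raw,
            "F": np.where(np.isnan(f_raw), np.nan, np.maximum(f_raw, 0.0)),
        }
    )


# ---------------------------------------------------------------------
# pairwise kinship (KING-robust) and zero-IBD
# ---------------------------------------------------------------------

def _pair_counts(G: GenotypeMatrix, i: int, j: int):
    di, dj = G.dosage[i], G.dosage[j]
    complete = (di != MISSING) & (dj != MISSING)
    het_i = int(((di == 1) & complete).sum())
    het_j = int(((dj == 1) & complete).sum())
    het_het = int(((di == 1) & (dj == 1) & complete).sum())
    opp_hom = int((((di == 0) & (dj == 2)) | ((di == 2) & (dj == 0))).sum())
    return complete, het_i, het_j, het_het, opp_hom


def _king_phi(het_i, het_j, het_het, opp_hom):
    m = min(het_i, het_j)
    if m == 0:
        return np.nan
    return (
        (het_het - 2.0 * opp_hom) / (2.0 * m)
        + 0.5
        - (het_i + het_j) / (4.0 * m)
    )


def king_robust_kinship(
    G: GenotypeMatrix, i, j, min_loci: int = 100
) -> float:
    """Allele-frequency-free robust kinship between individuals i, j.

    Over pairwise-complete loci, with N_Aa^i / N_Aa^j the per-individual
    heterozygote counts, N_Aa,Aa the joint-heterozygote count and
    N_AA,aa the opposite-homozygote count:

        phi = (N_Aa,Aa - 2 N_AA,aa) / (2 min(N_Aa^i, N_Aa^j))
              + 1/2 - (N_Aa^i + N_Aa^j) / (4 min(N_Aa^i, N_Aa^j))

    The estimator uses only the two genotype vectors, so it is invariant
    to which other samples are present and to the allele-frequency
    composition of the panel.  Duplicate samples give exactly 0.5.
    Returns NaN (with a warning) if fewer than ``min_loci`` complete
    loci or no heterozygotes in one member.
    """
    ii = G.ids.index(str(i)) if not isinstance(i, (int, np.integer)) else i
    jj = G.ids.index(str(j)) if not isinstance(j, (int, np.integer)) else j
    complete, het_i, het_j, het_het, opp_hom = _pair_counts(G, ii, jj)
    if complete.sum() < min_loci:
        warnings.warn(
            f"pair ({i},{j}): only {int(complete.sum())} pairwise-complete "
            f"loci (< {min_loci}); kinship reported missing",
            stacklevel=2,
        )
        return np.nan
    phi = _king_phi(het_i, het_j, het_het, opp_hom)
    if np.isnan(phi):
        warnings.warn(
            f"pair ({i},{j}): a member has no heterozygous calls; "
            "kinship undefined",
            stacklevel=2,
        )
    return phi


def zero_ibd_probability(
    G: GenotypeMatrix, freqs: np.ndarray, i, j, min_loci: int = 100
) -> float:
    """Estimated probability of sharing zero alleles IBD.

    Only IBD = 0 can produce opposite homozygotes (AA vs aa), whose
    expected count for a fully unrelated pair is sum_l 2 p_l^2 q_l^2
    over pairwise-complete loci, so

        pi0 = N_AA,aa / sum_l 2 p_l^2 (1-p_l)^2,

    clamped to [0, 1].  Parent-offspring pairs give exactly 0.
    """
    ii = G.ids.index(str(i)) if not isinstance(i, (int, np.integer)) else i
    jj = G.ids.index(str(j)) if not isinstance(j, (int, np.integer)) else j
    complete, _, _, _, opp_hom = _pair_counts(G, ii, jj)
    if complete.sum() < min_loci:
        return np.nan
    p = np.asarray(freqs, dtype=float)[complete]
    denom = float(np.nansum(2.0 * p**2 * (1.0 - p) ** 2))
    if denom <= 0:
        raise ValueError("zero-IBD denominator is zero (all loci monomorphic)")
    return float(min(max(opp_hom / denom, 0.0), 1.0))


def pairwise_kinship_table(
    G: GenotypeMatrix,
    freqs: np.ndarray | None = None,
    min_loci: int = 100,
    pi0_split: float = 0.1,
) -> pd.DataFrame:
    """KING-robust kinship, zero-IBD probability and inferred degree for
    every unordered pair (n(n-1)/2 rows).

    Columns: id1, id2, n_loci, het_i, het_j, het_het, opp_hom, phi_raw,
    phi (truncated at 0), pi0, degree.  Pairs with fewer than
    ``min_loci`` pairwise-complete loci are reported missing, not zero.
    """
    if freqs is None:
        freqs, _ = allele_frequencies(G)
    d = G.dosage
    obs = (d != MISSING).astype(np.float32)
    het = (d == 1).astype(np.float32)
    hom0 = (d == 0).astype(np.float32)
    hom2 = (d == 2).astype(np.float32)

    n_complete = obs @ obs.T
    het_het = het @ het.T
    opp_hom = hom0 @ hom2.T + hom2 @ hom0.T
    het_i = het @ obs.T  # het count of row individual over pair-complete loci

    p = np.nan_to_num(np.asarray(freqs, dtype=np.float64), nan=0.0)
    w = 2.0 * p**2 * (1.0 - p) ** 2
    obs64 = obs.astype(np.float64)
    pi0_denom = obs64 @ (obs64 * w).T

    iu, ju = np.triu_indices(G.n_individuals, k=1)
    # counts are exact integers (< 2^24) even in float32; do the ratio
    # arithmetic in float64
    het_i = het_i.astype(np.float64)
    het_het = het_het.astype(np.float64)
    opp_hom = opp_hom.astype(np.float64)
    pi0_denom = pi0_denom.astype(np.float64)
    hi, hj = het_i[iu, ju], het_i[ju, iu]
    m = np.minimum(hi, hj)
    hh, oh, nc = het_het[iu, ju], opp_hom[iu, ju], n_complete[iu, ju]
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_raw = (hh - 2.0 * oh) / (2.0 * m) + 0.5 - (hi + hj) / (4.0 * m)
        pi0 = np.clip(oh / pi0_denom[iu, ju], 0.0, 1.0)
    bad = (nc < min_loci) | (m == 0)
    phi_raw = np.where(bad, np.nan, phi_raw)
    pi0 = np.where(nc < min_loci, np.nan, pi0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} pair(s) reported missing "
            "(insufficient complete loci or no heterozygotes)",
            stacklevel=2,
        )
    degrees = [
        classify_relationship(ph, p0, pi0_split=pi0_split)
        if not np.isnan(ph)
        else "missing"
        for ph, p0 in zip(phi_raw, pi0)
    ]
    ids = G.ids
    return pd.DataFrame(
        {
            "id1": [ids[a] for a in iu],
            "id2": [ids[b] for b in ju],
            "n_loci": nc.astype(int),
            "het_i": hi.astype(int),
            "het_j": hj.astype(int),
            "het_het": hh.astype(int),
            "opp_hom": oh.astype(int),
            "phi_raw": phi_raw.astype(float),
            "phi": np.where(np.isnan(phi_raw), np.nan, np.maximum(phi_raw, 0)),
            "pi0": pi0.astype(float),
            "degree": degrees,
        }
    )


def classify_relationship(
    phi: float, pi0: float | None = None, pi0_split: float = 0.1
) -> str:
    """Map a kinship coefficient to a relationship degree.

    Cutoffs at successive powers of two (upper bound inclusive):
    duplicate/MZ above 2^(-3/2); 1st degree in (2^(-5/2), 2^(-3/2)];
    2nd in (2^(-7/2), 2^(-5/2)]; 3rd in (2^(-9/2), 2^(-7/2)]; otherwise
    unrelated.  Within first degree, pi0 < ``pi0_split`` distinguishes
    parent-offspring (theoretical pi0 = 0) from full sibs (pi0 ~ 1/4):
    the label becomes "1st (parent-offspring)" / "1st (full-sib)" when
    pi0 is supplied.
    """
    if not np.isfinite(phi):
        raise ValueError("phi must be finite")
    c1, c2, c3, c4 = DEGREE_CUTOFFS
    if phi > c1:
        return "duplicate/MZ"
    if phi > c2:
        if pi0 is not None and np.isfinite(pi0):
            sub = "parent-offspring" if pi0 < pi0_split else "full-sib"
            return f"1st ({sub})"
        return "1st"
    if phi > c3:
        return "2nd"
    if phi > c4:
        return "3rd"
    return "unrelated"


def degree_only(label: str) -> str:
    """Collapse a classifier label to its 5-level degree category."""
    return label.split(" ")[0] if label.startswith("1st") else label


# ---------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------

def ld_prune(
    G: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_threshold: float = 0.5,
) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns retained locus indices.

    Within each ``window``-SNP window (never spanning chromosomes) every
    retained pair with squared Pearson dosage correlation above
    ``r2_threshold`` loses one member: the lower-MAF locus, ties going
    to the later position.  The window slides by ``step``.  Monomorphic
    loci have undefined correlation and are skipped (never removed
    here; the MAF filter handles them).
    """
    p, _ = allele_frequencies(G)
    maf = np.minimum(p, 1.0 - p)
    removed = np.zeros(G.n_loci, dtype=bool)
    order = np.lexsort((G.pos, np.asarray([str(c) for c in G.chrom])))
    chroms = np.asarray([str(c) for c in G.chrom])[order]

    for chrom in pd.unique(chroms):
        loci = order[chroms == chrom]
        start = 0
        while start < len(loci):
            block = loci[start : start + window]
            live = [l for l in block if not removed[l] and 0 < maf[l]]
            if len(live) > 1:
                r2 = _pairwise_r2(G, live)
                for a in range(len(live)):
                    if removed[live[a]]:
                        continue
                    for b in range(a + 1, len(live)):
                        la, lb = live[a], live[b]
                        if removed[la] or removed[lb]:
                            continue
                        if r2[a, b] > r2_threshold:
                            if maf[la] < maf[lb]:
                                removed[la] = True
                            elif maf[lb] < maf[la]:
                                removed[lb] = True
                            else:  # tie: drop the later position
                                removed[lb if G.pos[lb] >= G.pos[la] else la] = True
            if start + window >= len(loci):
                break
            start += step
    return np.flatnonzero(~removed)


def _pairwise_r2(G: GenotypeMatrix, loci) -> np.ndarray:
    """Squared correlation between dosage columns, pairwise-complete."""
    d = G.dosage[:, loci].astype(float)
    d[d == MISSING] = np.nan
    if np.isnan(d).any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = np.ma.corrcoef(np.ma.masked_invalid(d.T)).filled(0.0)
    else:
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(d.T)
    r = np.nan_to_num(r, nan=0.0)
    return r**2


# ---------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------

def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact conditional (two-sided) HWE test p-value.

    Enumerates the conditional distribution of the heterozygote count
    given allele counts (Levene/Haldane), summing probabilities of all
    outcomes no more probable than the observed one.  Monomorphic loci
    return p = 1 (no test possible).
    """
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    n = n_het + n_hom1 + n_hom2
    if n == 0 or n_rare == 0:
        return 1.0
    # log-probability of each feasible heterozygote count (same parity)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    valid = hom_c >= 0
    hets, hom_r, hom_c = hets[valid], hom_r[valid], hom_c[valid]
    logp = (
        hets * math.log(2.0)
        + _lgamma(n + 1)
        - _lgamma(hets + 1)
        - _lgamma(hom_r + 1)
        - _lgamma(hom_c + 1)
        + _lgamma(n_rare + 1)
        + _lgamma(2 * n - n_rare + 1)
        - _lgamma(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[hets == n_het][0]
    return float(min(prob[prob <= obs * (1 + 1e-12)].sum(), 1.0))


def _lgamma(x):
    from scipy.special import gammaln

    return gammaln(np.asarray(x, dtype=float))


def hwe_filter(
    G: GenotypeMatrix, alpha: float = 0.01, method: str = "exact"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus HWE test; returns (retained boolean mask, p-values).

    ``method='exact'`` uses the exact conditional test;
    ``method='chisq'`` the 1-df chi-square on genotype counts.  Loci
    with p < ``alpha`` are dropped from the retained mask.
    """
    obs = G.observed
    het = ((G.dosage == 1) & obs).sum(axis=0)
    hom0 = ((G.dosage == 0) & obs).sum(axis=0)
    hom2 = ((G.dosage == 2) & obs).sum(axis=0)
    if method == "exact":
        pvals = np.array(
            [hwe_exact_pvalue(h, a, b) for h, a, b in zip(het, hom0, hom2)]
        )
    elif method == "chisq":
        from scipy.stats import chi2

        n = het + hom0 + hom2
        with np.errstate(invalid="ignore", divide="ignore"):
            p = (2.0 * hom2 + het) / (2.0 * n)
            e = np.stack(
                [n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2]
            )
            o = np.stack([hom0, het, hom2])
            stat = np.where(e > 0, (o - e) ** 2 / np.where(e > 0, e, 1), 0).sum(
                axis=0
            )
        pvals = np.where(
            (p > 0) & (p < 1), chi2.sf(stat, df=1), 1.0
        )
    else:
        raise ValueError(f"unknown HWE method {method!r}")
    return pvals >= alpha, pvals
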