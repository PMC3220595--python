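"""Within-population structure: IBS distance, classical MDS, and
Weir-Cockerham FST with permutation significance.

The genetic distance between two individuals is one minus their mean
allele sharing identical by state (IBS):

    D = 1 - (IBS2 + 0.5 * IBS1) / N

over the N pairwise-complete loci, IBS2/IBS1 counting loci at which the
pair shares two/one allele(s) in state.  Classical (Torgerson) MDS of D
places individuals in k dimensions; subpopulation differentiation is
quantified by the Weir-Cockerham theta estimator of FST combined across
loci as a ratio of sums, with significance from label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic import MISSING, GenotypeMatrix

__all__ = [
    "ibs_distance_matrix",
    "classical_mds",
    "weir_cockerham_fst",
    "fst_permutation_test",
    "FstResult",
]


def ibs_distance_matrix(G: GenotypeMatrix) -> np.ndarray:
    """Symmetric IBS distance matrix with zero diagonal, entries in [0, 1].

    Raises if any pair has no pairwise-complete loci (the distance is
    undefined for such a pair).
    """
    if G.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    d = G.dosage
    obs = (d != MISSING).astype(np.float32)
    ind = [(d == v).astype(np.float32) for v in (0, 1, 2)]
    n = obs @ obs.T
    ibs2 = sum(m @ m.T for m in ind)
    ibs1 = ind[1] @ (ind[0] + ind[2]).T + (ind[0] + ind[2]) @ ind[1].T
    off = ~np.eye(G.n_individuals, dtype=bool)
    if (n[off] == 0).any():
        i, j = np.argwhere((n == 0) & off)[0]
        raise ValueError(
            f"pair ({G.ids[i]}, {G.ids[j]}) has no pairwise-complete loci"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        D = 1.0 - (ibs2 + 0.5 * ibs1) / n
    np.fill_diagonal(D, 0.0)
    return np.clip((D + D.T) / 2.0, 0.0, 1.0).astype(float)


def classical_mds(
    D: np.ndarray, k: int = 2, on_degenerate: str = "error"
) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson classical scaling of a distance matrix.

    Double-centers B = -0.5 * J D^2 J, eigendecomposes, and returns
    ``(coords, eigenvalues)`` where coordinates are the eigenvectors of
    the top-k *positive* eigenvalues scaled by sqrt(eigenvalue)
    (negative eigenvalues are dropped, never truncated into
    coordinates).  Eigenvalues come back in descending order (all n of
    them, for the conservation check sum(lambda) = trace(B)).  Axis
    signs are arbitrary.

    If no positive eigenvalue exists among the top k, raises unless
    ``on_degenerate='zeros'``, which returns an all-zero configuration.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not (1 <= k < n):
        raise ValueError(f"need 1 <= k < n; got k={k}, n={n}")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals[:k] > 1e-12 * max(abs(evals[0]), 1.0)
    if not pos.any():
        if on_degenerate == "zeros":
            return np.zeros((n, k)), evals
        raise ValueError("degenerate geometry: no positive eigenvalue")
    coords = evecs[:, :k][:, pos] * np.sqrt(evals[:k][pos])
    return coords, evals


@dataclass
class FstResult:
    """Multi-locus Weir-Cockerham differentiation estimates.

    ``theta`` is the global ratio-of-sums estimate; ``pairwise`` a
    symmetric DataFrame of between-subpopulation estimates; p-values
    (when a permutation test was run) live in ``p_value`` /
    ``pairwise_p``.
    """

    theta: float
    pairwise: pd.DataFrame
    p_value: float | None = None
    pairwise_p: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [("global", self.theta, self.p_value)]
        labels = list(self.pairwise.index)
        for a in range(len(labels)):
            for b in range(a + 1, len(labels)):
                la, lb = labels[a], labels[b]
                pv = self.pairwise_p.loc[la, lb] if self.pairwise_p is not None else None
                rows.append((f"{la}|{lb}", self.pairwise.loc[la, lb], pv))
        return pd.DataFrame(rows, columns=["scope", "theta", "p_value"])


def _wc_components(dosage, obs, labels_ix, r):
    """Per-locus Weir-Cockerham a, b, c variance components.

    Implements the biallelic random-mating-free estimator from the
    observed heterozygosity form: per subpopulation i at each locus,
    n_i = called diploids, p_i = allele frequency, h_i = observed
    heterozygote proportion.
    """
    onehot = np.zeros((r, dosage.shape[0]), dtype=np.float64)
    onehot[labels_ix, np.arange(dosage.shape[0])] = 1.0
    called = onehot @ obs  # (r, L)
    alt = onehot @ np.where(obs.astype(bool), dosage, 0)
    hets = onehot @ ((dosage == 1) & obs.astype(bool))

    valid_pop = called >= 1
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = np.where(valid_pop, alt / (2.0 * called), 0.0)
        h_i = np.where(valid_pop, hets / called, 0.0)

    n_i = called
    r_eff = valid_pop.sum(axis=0)  # pops represented at this locus
    nbar = n_i.sum(axis=0) / np.maximum(r_eff, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_i.sum(axis=0) - (n_i**2).sum(axis=0) / n_i.sum(axis=0)) / np.maximum(
            r_eff - 1, 1
        )
        pbar = (n_i * p_i).sum(axis=0) / n_i.sum(axis=0)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / (
            np.maximum(r_eff - 1, 1) * nbar
        )
        hbar = (n_i * h_i).sum(axis=0) / n_i.sum(axis=0)

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1 - pbar) - ((r_eff - 1.0) / r_eff) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - ((r_eff - 1.0) / r_eff) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0

    # loci where the estimator is undefined: <2 pops, tiny samples, nc<=0
    bad = (r_eff < 2) | (nbar <= 1) | ~np.isfinite(a + b + c) | (nc <= 0)
    a, b, c = (np.where(bad, 0.0, v) for v in (a, b, c))
    return a, b, c


def _theta(dosage, obs, labels_ix, r) -> float:
    a, b, c = _wc_components(dosage, obs, labels_ix, r)
    denom = (a + b + c).sum()
    if denom == 0:
        return np.nan
    return float(a.sum() / denom)


def weir_cockerham_fst(G: GenotypeMatrix, labels) -> FstResult:
    """Global and pairwise multi-locus Weir-Cockerham theta.

    ``labels`` assigns a subpopulation to each individual; every
    subpopulation needs >= 2 individuals.  The multi-locus estimate is
    the ratio of summed among-population components to summed total
    components; loci where the components are undefined are skipped.
    """
    labels = np.asarray([str(l) for l in labels])
    if len(labels) != G.n_individuals:
        raise ValueError("labels length must match individuals")
    uniq, labels_ix = np.unique(labels, return_inverse=True)
    counts = np.bincount(labels_ix)
    if len(uniq) < 2:
        raise ValueError("need >= 2 subpopulations")
    if (counts < 2).any():
        small = uniq[counts < 2]
        raise ValueError(f"subpopulation(s) with < 2 individuals: {list(small)}")

    dosage = G.dosage.astype(np.float64)
    obs = (G.dosage != MISSING).astype(np.float64)
    theta = _theta(dosage, obs, labels_ix, len(uniq))

    pw = pd.DataFrame(np.zeros((len(uniq), len(uniq))), index=uniq, columns=uniq)
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            sel = np.isin(labels, [uniq[i], uniq[j]])
            sub_ix = (labels[sel] == uniq[j]).astype(int)
            t = _theta(dosage[sel], obs[sel], sub_ix, 2)
            pw.iloc[i, j] = pw.iloc[j, i] = t
    return FstResult(theta=theta, pairwise=pw)


def fst_permutation_test(
    G: GenotypeMatrix,
    labels,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = 0,
) -> FstResult:
    """Permutation significance for global and pairwise theta.

    Individual labels are permuted ``n_perm`` times; the p-value is the
    add-one estimator (1 + #{theta_perm >= theta_obs}) / (n_perm + 1),
    so it can never be exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    result = weir_cockerham_fst(G, labels)
    labels = np.asarray([str(l) for l in labels])
    uniq = list(result.pairwise.index)
    dosage = G.dosage.astype(np.float64)
    obs = (G.dosage != MISSING).astype(np.float64)

    exceed_global = 0
    exceed_pw = np.zeros((len(uniq), len(uniq)))
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        _, perm_ix = np.unique(perm, return_inverse=True)
        t = _theta(dosage, obs, perm_ix, len(uniq))
        if t >= result.theta:
            exceed_global += 1
        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                sel = np.isin(perm, [uniq[i], uniq[j]])
                sub_ix = (perm[sel] == uniq[j]).astype(int)
                tp = _theta(dosage[sel], obs[sel], sub_ix, 2)
                if tp >= result.pairwise.iloc[i, j]:
                    exceed_pw[i, j] += 1

    result.p_value = (1.0 + exceed_global) / (n_perm + 1.0)
    pwp = (1.0 + exceed_pw + exceed_pw.T) / (n_perm + 1.0)
    np.fill_diagonal(pwp, np.nan)
    result.pairwise_p = pd.DataFrame(pwp, index=uniq, columns=uniq)
    return result
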