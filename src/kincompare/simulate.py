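"""Synthetic cohorts: designed pedigrees plus gene-dropped SNP genotypes.

The generator emulates a small, substructured livestock cohort: ~99
individuals in three subpopulations (default sizes 54/31/14, one
singleton allowed on top), a multi-generation pedigree containing
full-sib, half-sib, avuncular, first-cousin and parent-offspring pairs
and first-cousin-mating loops, incomplete parentage records, and
biallelic autosomal SNPs whose between-subpopulation differentiation is
governed either by generations of binomial drift from a common
ancestral pool or by a Balding-Nichols draw.

Genotypes are produced by *gene dropping*: every founder receives two
labelled alleles per locus (allelic state Bernoulli(p) of its
subpopulation), and each non-founder inherits one uniformly random
allele from each parent, independently per locus.  The labels are kept,
so realized identity-by-descent sharing can be audited locus by locus
against the pedigree expectation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic import MISSING, GenotypeMatrix
from .pedigree import Pedigree

__all__ = [
    "SimScenario",
    "SimulatedPedigree",
    "GeneDropResult",
    "simulate_pedigree",
    "founder_frequencies",
    "gene_drop",
    "hwe_cohort",
    "simulate_cohort",
    "write_fixture",
    "realized_kinship",
]


@dataclass(frozen=True)
class SimScenario:
    """Simulator configuration; the seed fixes all randomness.

    Defaults mirror the study cohort: three coat-colour-like
    subpopulations of 54/31/14 animals, differentiation from 11
    generations of drift at subpopulation size N=100 (expected
    FST = 1 - (1 - 1/2N)^t ~ 0.054), ancestral frequencies drawn
    Uniform(0.05, 0.95) per locus, and unlinked loci.  The locus count
    defaults to 5000 for tractability; the array-scale 47693 is just a
    parameter away.
    """

    subpop_sizes: tuple[int, ...] = (54, 31, 14)
    subpop_names: tuple[str, ...] = ("white", "blackbrown", "grey")
    n_loci: int = 5000
    pool_low: float = 0.05
    pool_high: float = 0.95
    freq_model: str = "drift"  # or "balding-nichols"
    drift_generations: int = 11
    drift_size: int = 100
    bn_theta: float = 0.054
    n_fullsib: int = 3
    n_halfsib: int = 3
    n_avuncular: int = 2
    n_firstcousin: int = 3
    n_cousin_mating: int = 2
    n_halfsib_mating: int = 2
    n_fullsib_mating: int = 2
    n_parent_offspring: int = 2
    n_complete_ancestry: int = 18
    parent_missing_rates: tuple[float, ...] = (0.1, 0.2, 0.5)
    genotype_missing_rate: float = 0.005
    n_chromosomes: int = 26
    seed: int = 42

    def __post_init__(self):
        if any(s < 1 for s in self.subpop_sizes):
            raise ValueError("subpopulation sizes must be >= 1")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        for r in (*self.parent_missing_rates, self.genotype_missing_rate):
            if not 0 <= r <= 1:
                raise ValueError(f"rates must be in [0,1], got {r}")
        if self.freq_model not in ("drift", "balding-nichols"):
            raise ValueError(f"unknown freq_model {self.freq_model!r}")
        if self.freq_model == "balding-nichols" and not 0 < self.bn_theta < 1:
            raise ValueError("Balding-Nichols theta must be in (0,1)")


@dataclass
class SimulatedPedigree:
    """Designed pedigree plus its ground truth.

    ``pedigree`` has parent links deleted per the incompleteness rates
    (what an analyst would see); ``full_pedigree`` keeps every true
    link (what gene dropping uses).  ``truth_pairs`` lists every
    designed pair with its class and theoretical kinship;
    ``truth_inbreeding`` every designed inbred individual with its
    theoretical F.  ``founder_subpop`` maps each founder to its
    subpopulation; ``sampled_ids`` are the genotyped cohort.
    """

    pedigree: Pedigree
    full_pedigree: Pedigree
    truth_pairs: pd.DataFrame
    truth_inbreeding: pd.DataFrame
    founder_subpop: dict[str, str]
    sampled_ids: list[str]
    sampled_groups: list[str]


# motif name -> (sampled slots used, designed pairs, theoretical phi)
_MOTIF_SLOTS = {
    "fullsib": 2,
    "halfsib": 2,
    "avuncular": 2,
    "firstcousin": 2,
    "parent_offspring": 2,
    "cousin_mating": 1,
    "halfsib_mating": 1,
    "fullsib_mating": 1,
    "complete_ancestry": 1,
}


def simulate_pedigree(scenario: SimScenario) -> SimulatedPedigree:
    """Build the designed pedigree and record ground truth.

    Relationship motifs are built from fresh, mutually unrelated
    founders inside a single subpopulation, so the theoretical kinship
    of each designed pair is the canonical outbred value (1/4 full sibs,
    1/8 half sibs and avuncular, 1/16 first cousins) and a
    cousin-mating offspring has F = 1/16.  A further set of individuals
    carries a fully recorded 5-generation ancestry (pedigree
    completeness 1).  Motifs are dealt to subpopulations round-robin
    while capacity lasts; remaining sampled slots are filled with
    unrelated founders.  After truth is recorded, parentage records are
    degraded lineage-wise at per-subpopulation rates to emulate
    incomplete herd books (completeness spread from 0 to 1, poorest in
    the smallest subpopulation).
    """
    rng = np.random.default_rng(scenario.seed)
    sizes = scenario.subpop_sizes
    names = scenario.subpop_names[: len(sizes)]

    demand = []
    for motif, count in (
        ("fullsib", scenario.n_fullsib),
        ("halfsib", scenario.n_halfsib),
        ("avuncular", scenario.n_avuncular),
        ("firstcousin", scenario.n_firstcousin),
        ("parent_offspring", scenario.n_parent_offspring),
        ("cousin_mating", scenario.n_cousin_mating),
        ("halfsib_mating", scenario.n_halfsib_mating),
        ("fullsib_mating", scenario.n_fullsib_mating),
        ("complete_ancestry", scenario.n_complete_ancestry),
    ):
        demand += [motif] * count

    capacity = list(sizes)
    assignment: list[list[str]] = [[] for _ in sizes]
    sp = 0
    for motif in demand:
        need = _MOTIF_SLOTS[motif]
        placed = False
        for _ in range(len(sizes)):
            if capacity[sp] >= need:
                assignment[sp].append(motif)
                capacity[sp] -= need
                placed = True
                sp = (sp + 1) % len(sizes)
                break
            sp = (sp + 1) % len(sizes)
        if not placed:
            raise ValueError(
                f"infeasible design: no subpopulation has {need} free "
                f"slots left for motif {motif!r} "
                f"(sizes {sizes}, remaining {capacity})"
            )

    records: list[tuple] = []
    truth_pairs: list[tuple] = []
    truth_inbr: list[tuple] = []
    founder_subpop: dict[str, str] = {}
    sampled: list[str] = []
    sampled_groups: list[str] = []
    counter = [0]

    def new_id(prefix: str) -> str:
        counter[0] += 1
        return f"{prefix}{counter[0]:04d}"

    def founder(group: str) -> str:
        rid = new_id("F")
        records.append((rid, None, None, group))
        founder_subpop[rid] = group
        return rid

    def child(sire: str, dam: str, group: str) -> str:
        rid = new_id("I")
        records.append((rid, sire, dam, group))
        return rid

    for sp_ix, motifs in enumerate(assignment):
        g = names[sp_ix]
        for motif in motifs:
            if motif == "fullsib":
                p1, p2 = founder(g), founder(g)
                a, b = child(p1, p2, g), child(p1, p2, g)
                truth_pairs.append((a, b, "fullsib", 0.25))
                sampled += [a, b]
            elif motif == "halfsib":
                p1, p2, p3 = founder(g), founder(g), founder(g)
                a, b = child(p1, p2, g), child(p1, p3, g)
                truth_pairs.append((a, b, "halfsib", 0.125))
                sampled += [a, b]
            elif motif == "avuncular":
                p1, p2, p3 = founder(g), founder(g), founder(g)
                a = child(p1, p2, g)
                b = child(p1, p2, g)
                c = child(b, p3, g)
                truth_pairs.append((a, c, "avuncular", 0.125))
                sampled += [a, c]
            elif motif == "firstcousin":
                g1, g2 = founder(g), founder(g)
                b1, b2 = child(g1, g2, g), child(g1, g2, g)
                x1, x2 = founder(g), founder(g)
                c1, c2 = child(b1, x1, g), child(b2, x2, g)
                truth_pairs.append((c1, c2, "firstcousin", 0.0625))
                sampled += [c1, c2]
            elif motif == "parent_offspring":
                p1, p2 = founder(g), founder(g)
                a = child(p1, p2, g)
                truth_pairs.append((p1, a, "parent_offspring", 0.25))
                sampled += [p1, a]
            elif motif == "cousin_mating":
                g1, g2 = founder(g), founder(g)
                b1, b2 = child(g1, g2, g), child(g1, g2, g)
                x1, x2 = founder(g), founder(g)
                c1, c2 = child(b1, x1, g), child(b2, x2, g)
                z = child(c1, c2, g)
                truth_inbr.append((z, "cousin_mating_offspring", 0.0625))
                sampled += [z]
            elif motif == "halfsib_mating":
                p1, p2, p3 = founder(g), founder(g), founder(g)
                a, b = child(p1, p2, g), child(p1, p3, g)
                z = child(a, b, g)
                truth_inbr.append((z, "halfsib_mating_offspring", 0.125))
                sampled += [z]
            elif motif == "fullsib_mating":
                p1, p2 = founder(g), founder(g)
                a, b = child(p1, p2, g), child(p1, p2, g)
                z = child(a, b, g)
                truth_inbr.append((z, "fullsib_mating_offspring", 0.25))
                sampled += [z]
            elif motif == "complete_ancestry":
                # fully recorded 5-generation ancestry: 62 outbred
                # ancestors behind one sampled individual (PEC = 1)
                def deep(depth):
                    if depth == 0:
                        return founder(g)
                    return child(deep(depth - 1), deep(depth - 1), g)

                sampled.append(deep(5))
            sampled_groups += [g] * _MOTIF_SLOTS[motif]
        for _ in range(capacity[sp_ix]):
            f = founder(g)
            sampled.append(f)
            sampled_groups.append(g)

    full = Pedigree.from_records(records)

    # Incompleteness clusters by lineage (record quality varies by flock,
    # not per link): each sampled individual is poorly recorded with its
    # subpopulation's rate; every ancestor record reached only through
    # poorly recorded animals loses each parent link with probability 1/2,
    # while ancestors of any well-recorded animal stay fully recorded.
    rates = dict(zip(names, scenario.parent_missing_rates))
    well_recorded = {
        rid: rng.random() >= rates.get(grp, 0.0)
        for rid, grp in zip(sampled, sampled_groups)
    }
    parent_map = {rid: (s, d) for rid, s, d, _ in records}
    protected: set[str] = set()
    stack = [rid for rid in sampled if well_recorded[rid]]
    while stack:
        r = stack.pop()
        if r in protected:
            continue
        protected.add(r)
        stack += [p for p in parent_map[r] if p is not None]
    observed_records = []
    for rid, sire, dam, group in records:
        if rid in protected:
            observed_records.append((rid, sire, dam, group))
            continue
        s = None if (sire is not None and rng.random() < 0.5) else sire
        d = None if (dam is not None and rng.random() < 0.5) else dam
        observed_records.append((rid, s, d, group))
    observed = Pedigree.from_records(observed_records)

    return SimulatedPedigree(
        pedigree=observed,
        full_pedigree=full,
        truth_pairs=pd.DataFrame(
            truth_pairs, columns=["id1", "id2", "relationship", "phi_true"]
        ),
        truth_inbreeding=pd.DataFrame(
            truth_inbr, columns=["id", "origin", "F_true"]
        ),
        founder_subpop=founder_subpop,
        sampled_ids=sampled,
        sampled_groups=sampled_groups,
    )


def founder_frequencies(
    scenario: SimScenario, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Per-subpopulation, per-locus allele frequencies, shape (r, L).

    Drift mode: a common ancestral pool Uniform(pool_low, pool_high) per
    locus, then ``drift_generations`` rounds of binomial resampling of
    2N gametes independently per subpopulation.  Balding-Nichols mode:
    one Beta(p(1-theta)/theta, (1-p)(1-theta)/theta) draw per
    subpopulation and locus.  Loci that fix (frequency exactly 0 or 1
    in any subpopulation) are rejected and redrawn, never clamped.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    r, L = len(scenario.subpop_sizes), scenario.n_loci
    out = np.empty((r, L))
    todo = np.arange(L)
    while todo.size:
        pool = rng.uniform(scenario.pool_low, scenario.pool_high, size=todo.size)
        if scenario.freq_model == "drift":
            freqs = np.tile(pool, (r, 1))
            two_n = 2 * scenario.drift_size
            for _ in range(scenario.drift_generations):
                freqs = rng.binomial(two_n, freqs) / two_n
        else:
            th = scenario.bn_theta
            a = pool * (1 - th) / th
            b = (1 - pool) * (1 - th) / th
            freqs = rng.beta(a[None, :], b[None, :], size=(r, todo.size))
        ok = ((freqs > 0) & (freqs < 1)).all(axis=0)
        out[:, todo[ok]] = freqs[:, ok]
        todo = todo[~ok]
    return out


@dataclass
class GeneDropResult:
    """Gene-dropped genotypes with their IBD audit trail.

    ``genotypes`` covers the requested (sampled) individuals;
    ``paternal_labels`` / ``maternal_labels`` are (n, L) arrays of
    founder-allele labels, two distinct labels having been issued per
    founder, so two equal labels are IBD by construction.
    """

    genotypes: GenotypeMatrix
    paternal_labels: np.ndarray
    maternal_labels: np.ndarray


def gene_drop(
    ped: Pedigree,
    founder_subpop: dict[str, str],
    subpop_freqs: np.ndarray,
    subpop_names: tuple[str, ...],
    n_loci: int | None = None,
    missing_rate: float = 0.0,
    rng: np.random.Generator | int | None = None,
    sample_ids: list[str] | None = None,
    groups: list[str] | None = None,
    n_chromosomes: int = 26,
) -> GeneDropResult:
    """Drop founder alleles through the pedigree, one locus at a time.

    Each founder gets two uniquely labelled alleles per locus whose
    allelic states are Bernoulli(p) draws at its subpopulation's
    frequency; every non-founder inherits one uniformly random allele
    from each parent, independently per locus.  Missing calls are then
    masked uniformly at random.  Loci are unlinked and spread evenly
    over ``n_chromosomes`` autosomes in the emitted metadata.
    """
    rng = (
        rng
        if isinstance(rng, np.random.Generator)
        else np.random.default_rng(rng)
    )
    L = n_loci if n_loci is not None else subpop_freqs.shape[1]
    if subpop_freqs.shape[1] != L:
        raise ValueError("subpop_freqs locus count mismatch")
    n = len(ped.ids)
    name_ix = {g: k for k, g in enumerate(subpop_names)}

    founder_ix = np.flatnonzero((ped.sire < 0) & (ped.dam < 0))
    for k in founder_ix:
        if ped.ids[k] not in founder_subpop:
            raise ValueError(f"founder {ped.ids[k]!r} has no subpopulation")

    # label arrays: per individual, per locus, paternal/maternal allele label
    pat = np.zeros((n, L), dtype=np.int32)
    mat = np.zeros((n, L), dtype=np.int32)
    n_founders = len(founder_ix)
    states = np.zeros((2 * n_founders, L), dtype=np.int8)
    for fnum, k in enumerate(founder_ix):
        p = subpop_freqs[name_ix[founder_subpop[ped.ids[k]]]]
        states[2 * fnum] = rng.random(L) < p
        states[2 * fnum + 1] = rng.random(L) < p
        pat[k] = 2 * fnum
        mat[k] = 2 * fnum + 1

    # topological order guarantees parents are filled before children;
    # an unrecorded parent cannot occur in the full pedigree passed here
    for k in range(n):
        s, d = ped.sire[k], ped.dam[k]
        if s < 0 and d < 0:
            continue
        if s < 0 or d < 0:
            raise ValueError(
                f"gene drop requires both parents known for {ped.ids[k]!r}"
            )
        pick_s = rng.integers(0, 2, size=L, dtype=np.int8).astype(bool)
        pick_d = rng.integers(0, 2, size=L, dtype=np.int8).astype(bool)
        pat[k] = np.where(pick_s, pat[s], mat[s])
        mat[k] = np.where(pick_d, pat[d], mat[d])

    cols = np.arange(L)
    dosage = (
        states[pat, cols[None, :]] + states[mat, cols[None, :]]
    ).astype(np.int8)
    if missing_rate > 0:
        dosage[rng.random(dosage.shape) < missing_rate] = MISSING

    ids = sample_ids if sample_ids is not None else list(ped.ids)
    ix = np.array([ped.index_of(i) for i in ids])
    per_chrom = -(-L // n_chromosomes)  # ceil
    chrom = np.array(
        [str(1 + l // per_chrom) for l in range(L)], dtype=object
    )
    pos = np.array([1 + (l % per_chrom) for l in range(L)], dtype=np.int64)

    G = GenotypeMatrix(
        dosage=dosage[ix],
        ids=[str(i) for i in ids],
        chrom=chrom,
        pos=pos,
        alleles=[("A", "B")] * L,
        groups=list(groups) if groups is not None else None,
    )
    return GeneDropResult(
        genotypes=G, paternal_labels=pat[ix], maternal_labels=mat[ix]
    )


def realized_kinship(drop: GeneDropResult, i, j) -> float:
    """Realized IBD kinship between two sampled individuals.

    Mean over loci of the probability that one random allele from each
    is IBD: (1/4) * sum over the four allele pairings of
    1[labels equal].  Independent unlinked loci make each locus an
    independent replicate of the pedigree's segregation.
    """
    ids = drop.genotypes.ids
    a = ids.index(str(i)) if not isinstance(i, (int, np.integer)) else i
    b = ids.index(str(j)) if not isinstance(j, (int, np.integer)) else j
    pi, mi = drop.paternal_labels[a], drop.maternal_labels[a]
    pj, mj = drop.paternal_labels[b], drop.maternal_labels[b]
    share = (
        (pi == pj).astype(float)
        + (pi == mj)
        + (mi == pj)
        + (mi == mj)
    ) / 4.0
    return float(share.mean())


def realized_kinship_se(drop: GeneDropResult, i, j) -> float:
    """Monte-Carlo standard error of :func:`realized_kinship`."""
    ids = drop.genotypes.ids
    a = ids.index(str(i)) if not isinstance(i, (int, np.integer)) else i
    b = ids.index(str(j)) if not isinstance(j, (int, np.integer)) else j
    pi, mi = drop.paternal_labels[a], drop.maternal_labels[a]
    pj, mj = drop.paternal_labels[b], drop.maternal_labels[b]
    share = (
        (pi == pj).astype(float)
        + (pi == mj)
        + (mi == pj)
        + (mi == mj)
    ) / 4.0
    return float(share.std(ddof=1) / np.sqrt(share.size))


def hwe_cohort(
    subpop_freqs: np.ndarray,
    n_per_subpop,
    subpop_names: tuple[str, ...],
    rng: np.random.Generator | int | None = None,
    n_chromosomes: int = 26,
) -> GenotypeMatrix:
    """Unrelated Hardy-Weinberg individuals drawn straight from the
    subpopulation frequencies (no pedigree): dosage ~ Binomial(2, p)."""
    rng = (
        rng
        if isinstance(rng, np.random.Generator)
        else np.random.default_rng(rng)
    )
    r, L = subpop_freqs.shape
    if np.isscalar(n_per_subpop):
        n_per_subpop = [int(n_per_subpop)] * r
    rows, ids, groups = [], [], []
    for k in range(r):
        n = n_per_subpop[k]
        rows.append(rng.binomial(2, subpop_freqs[k], size=(n, L)).astype(np.int8))
        ids += [f"{subpop_names[k]}_{i + 1:03d}" for i in range(n)]
        groups += [str(subpop_names[k])] * n
    per_chrom = -(-L // n_chromosomes)
    chrom = np.array([str(1 + l // per_chrom) for l in range(L)], dtype=object)
    pos = np.array([1 + (l % per_chrom) for l in range(L)], dtype=np.int64)
    return GenotypeMatrix(
        dosage=np.vstack(rows),
        ids=ids,
        chrom=chrom,
        pos=pos,
        alleles=[("A", "B")] * L,
        groups=groups,
    )


def add_ld_blocks(
    G: GenotypeMatrix,
    n_copies: int,
    noise_rate: float = 0.02,
    rng: np.random.Generator | int | None = None,
) -> GenotypeMatrix:
    """Append ``n_copies`` noisy duplicates of random loci.

    Each copy replicates one existing column, flips every genotype to a
    random value with probability ``noise_rate``, and is placed
    immediately after its template on the same chromosome.  Loci are
    otherwise simulated unlinked; this is the hook for exercising LD
    pruning.
    """
    rng = (
        rng
        if isinstance(rng, np.random.Generator)
        else np.random.default_rng(rng)
    )
    templates = rng.choice(G.n_loci, size=n_copies, replace=False)
    dosage = G.dosage
    new_cols, new_chrom, new_pos, new_alleles = [], [], [], []
    for t in sorted(templates):
        col = dosage[:, t].copy()
        flip = rng.random(col.shape) < noise_rate
        col[flip] = rng.integers(0, 3, size=int(flip.sum()), dtype=np.int8)
        new_cols.append(col)
        new_chrom.append(G.chrom[t])
        new_pos.append(G.pos[t])  # duplicate position: sorts adjacent
        new_alleles.append(G.alleles[t])
    out = GenotypeMatrix(
        dosage=np.hstack([dosage, np.column_stack(new_cols)]),
        ids=list(G.ids),
        chrom=np.concatenate([G.chrom, np.asarray(new_chrom, dtype=object)]),
        pos=np.concatenate([G.pos, np.asarray(new_pos)]),
        alleles=list(G.alleles) + new_alleles,
        groups=G.groups,
    )
    order = np.lexsort((out.pos, np.asarray([str(c) for c in out.chrom])))
    return out.subset(loci=order)


@dataclass
class SimulatedCohort:
    """One fully simulated study: pedigree arm + genomic arm + truth."""

    scenario: SimScenario
    sim_pedigree: SimulatedPedigree
    subpop_freqs: np.ndarray
    drop: GeneDropResult

    @property
    def genotypes(self) -> GenotypeMatrix:
        return self.drop.genotypes

    @property
    def pedigree(self) -> Pedigree:
        return self.sim_pedigree.pedigree


def simulate_cohort(scenario: SimScenario) -> SimulatedCohort:
    """End-to-end simulation under one seed: designed pedigree,
    drifted/BN subpopulation frequencies, gene-dropped genotypes."""
    rng = np.random.default_rng(scenario.seed)
    simped = simulate_pedigree(
        dataclasses.replace(scenario, seed=int(rng.integers(2**31)))
    )
    freqs = founder_frequencies(
        scenario, rng=np.random.default_rng(int(rng.integers(2**31)))
    )
    drop = gene_drop(
        simped.full_pedigree,
        simped.founder_subpop,
        freqs,
        scenario.subpop_names,
        missing_rate=scenario.genotype_missing_rate,
        rng=np.random.default_rng(int(rng.integers(2**31))),
        sample_ids=simped.sampled_ids,
        groups=simped.sampled_groups,
        n_chromosomes=scenario.n_chromosomes,
    )
    return SimulatedCohort(
        scenario=scenario, sim_pedigree=simped, subpop_freqs=freqs, drop=drop
    )


def write_fixture(cohort: SimulatedCohort, out_dir) -> dict[str, Path]:
    """Write PED/MAP, pedigree CSV, labels and truth TSVs to ``out_dir``.

    Everything round-trips: the PED/MAP pair reloads to the same dosage
    matrix (minor-allele oriented) and the pedigree CSV reloads to the
    same structure.
    """
    from .io import write_plink_text

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sp = cohort.sim_pedigree
    G = cohort.genotypes
    if set(sp.sampled_ids) - set(G.ids):
        raise ValueError("sampled ids missing from genotype matrix")

    ped_path, map_path = write_plink_text(G, out / "cohort")

    ped_csv = out / "pedigree.csv"
    with open(ped_csv, "w") as fh:
        fh.write("id,sire,dam,group\n")
        p = sp.pedigree
        for k, rid in enumerate(p.ids):
            s = p.ids[p.sire[k]] if p.sire[k] >= 0 else "0"
            d = p.ids[p.dam[k]] if p.dam[k] >= 0 else "0"
            fh.write(f"{rid},{s},{d},{p.groups.get(rid, '')}\n")

    labels = out / "labels.tsv"
    pd.DataFrame({"id": G.ids, "group": G.groups}).to_csv(
        labels, sep="\t", index=False
    )
    truth_pairs = out / "truth_pairs.tsv"
    sp.truth_pairs.to_csv(truth_pairs, sep="\t", index=False)
    truth_inbr = out / "truth_inbreeding.tsv"
    sp.truth_inbreeding.to_csv(truth_inbr, sep="\t", index=False)
    return {
        "ped": ped_path,
        "map": map_path,
        "pedigree_csv": ped_csv,
        "labels": labels,
        "truth_pairs": truth_pairs,
        "truth_inbreeding": truth_inbr,
    }
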