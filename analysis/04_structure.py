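"""Substructure: IBS distances, classical MDS, Weir-Cockerham FST.

Writes the distance matrix, MDS coordinates/eigenvalues and the FST
table (with permutation p-values) under results/structure/.
"""

from pathlib import Path

import pandas as pd

from kincompare.genomic import estimation_loci
from kincompare.io import read_plink_text
from kincompare.structure import (
    classical_mds,
    fst_permutation_test,
    ibs_distance_matrix,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "structure"
OUT.mkdir(parents=True, exist_ok=True)

G = read_plink_text(ROOT / "cohort" / "cohort.ped", ROOT / "cohort" / "cohort.map")
labels = pd.read_csv(ROOT / "cohort" / "labels.tsv", sep="\t", dtype=str)
groups = [dict(zip(labels["id"], labels["group"]))[i] for i in G.ids]
G = G.subset(loci=estimation_loci(G))

D = ibs_distance_matrix(G)
pd.DataFrame(D, index=G.ids, columns=G.ids).to_csv(OUT / "ibs_distance.tsv", sep="\t")

coords, evals = classical_mds(D, k=2)
mds = pd.DataFrame(coords, columns=["C1", "C2"])
mds.insert(0, "id", G.ids)
mds.insert(1, "group", groups)
mds.to_csv(OUT / "mds.tsv", sep="\t", index=False)
pd.DataFrame({"eigenvalue": evals}).to_csv(OUT / "eigenvalues.tsv", sep="\t", index=False)

fst = fst_permutation_test(G, groups, n_perm=1000, seed=42)
fst.to_frame().to_csv(OUT / "fst.tsv", sep="\t", index=False)

print(f"global FST = {100 * fst.theta:.2f}% (P = {fst.p_value:.4g}); "
      f"within-subpopulation share of variation = {100 * (1 - fst.theta):.1f}%")
print("pairwise FST (%):")
print((100 * fst.pairwise).round(2))
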