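"""Pedigree arm: inbreeding F_PED, completeness PEC, pairwise kinship.

Reads the (incomplete, as-recorded) pedigree written by 01 and writes
per-individual and per-pair tables under results/pedigree/.
"""

from pathlib import Path

import pandas as pd

from kincompare.pedigree import Pedigree, kinship_table

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "pedigree"
OUT.mkdir(parents=True, exist_ok=True)

ped = Pedigree.from_csv(ROOT / "cohort" / "pedigree.csv")
cohort_ids = pd.read_csv(ROOT / "cohort" / "labels.tsv", sep="\t", dtype=str)["id"]

inb = ped.inbreeding_table(cohort_ids)
inb.to_csv(OUT / "inbreeding_ped.tsv", sep="\t", index=False)
kin = kinship_table(ped, cohort_ids)
kin.to_csv(OUT / "kinship_ped.tsv", sep="\t", index=False)

print(f"{len(inb)} individuals: mean F_PED = {inb.F_ped.mean():.4f}, "
      f"{(inb.F_ped > 0.0625).sum()} above the cousin-mating level 6.25%")
print(f"PEC: {(inb.PEC == 1).sum()} complete (PEC = 1), "
      f"{(inb.PEC < 0.6).sum()} poorly recorded (PEC < 0.6)")
print(f"{len(kin)} kinship pairs; "
      f"{(kin.phi_ped > 0).sum()} with positive pedigree kinship")
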