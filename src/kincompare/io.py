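"""Reading and writing the plain-text interchange formats.

PLINK text PED/MAP is the genotype interchange format: each PED row is
``FID IID PAT MAT SEX PHENO`` followed by two allele characters per MAP
locus, ``0 0`` marking a missing call; the MAP file carries one
``chrom snp_id cm pos`` row per locus.  On reading, the counted allele
at each locus is the sample minor allele (ties broken toward the
lexicographically later allele so that writing and re-reading a matrix
is an exact round trip).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic import MISSING, GenotypeMatrix, allele_frequencies

__all__ = ["read_plink_text", "write_plink_text", "write_kinship_outputs"]


def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Parse a PED/MAP pair into a :class:`GenotypeMatrix`.

    The minor allele is determined per locus from sample allele counts;
    non-biallelic loci raise with the locus named, and rows with the
    wrong column count raise with the row number.  Chromosome codes
    X/Y/0 are kept but flagged non-autosomal by the matrix.
    """
    mp = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos"],
        dtype={"chrom": str, "snp": str},
        comment="#",
    )
    n_loci = len(mp)
    expected_cols = 6 + 2 * n_loci

    ids, fids, dosage_rows = [], [], []
    alleles_seen: list[dict[str, int]] = [dict() for _ in range(n_loci)]
    raw_rows = []
    with open(ped_path) as fh:
        for rownum, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != expected_cols:
                raise ValueError(
                    f"PED row {rownum}: expected {expected_cols} columns "
                    f"(6 + 2 x {n_loci} loci), found {len(fields)}"
                )
            fids.append(fields[0])
            ids.append(fields[1])
            calls = np.array(fields[6:], dtype=object).reshape(n_loci, 2)
            raw_rows.append(calls)
            for l in range(n_loci):
                for a in calls[l]:
                    if a != "0":
                        alleles_seen[l][a] = alleles_seen[l].get(a, 0) + 1

    counted: list[str] = []
    allele_pairs: list[tuple[str, str]] = []
    for l, seen in enumerate(alleles_seen):
        al = sorted(seen)
        if len(al) > 2:
            raise ValueError(
                f"locus {mp.snp[l]!r} is not biallelic: alleles {al}"
            )
        if len(al) == 0:
            allele_pairs.append(("A", "B"))
            counted.append("B")
            continue
        if len(al) == 1:
            allele_pairs.append((al[0], "?"))
            counted.append("?")  # counted allele absent -> dosage 0
            continue
        a, b = al
        # counted = minor; tie -> lexicographically later allele
        if seen[a] < seen[b]:
            minor, major = a, b
        elif seen[b] < seen[a]:
            minor, major = b, a
        else:
            minor, major = b, a
        allele_pairs.append((major, minor))
        counted.append(minor)

    dosage = np.full((len(ids), n_loci), MISSING, dtype=np.int8)
    for r, calls in enumerate(raw_rows):
        miss = (calls[:, 0] == "0") | (calls[:, 1] == "0")
        cnt = (calls[:, 0] == counted).astype(np.int8) + (
            calls[:, 1] == counted
        ).astype(np.int8)
        dosage[r] = np.where(miss, MISSING, cnt)

    return GenotypeMatrix(
        dosage=dosage,
        ids=ids,
        chrom=mp.chrom.to_numpy(dtype=object),
        pos=mp.pos.to_numpy(),
        alleles=allele_pairs,
        groups=None,
    )


def write_plink_text(G: GenotypeMatrix, prefix, groups=None) -> tuple[Path, Path]:
    """Write ``prefix.ped`` / ``prefix.map``; returns the two paths.

    The matrix is re-oriented so the written minor allele equals the
    counted allele, guaranteeing dosage round trips exactly through
    :func:`read_plink_text`.  MAP positions are written 1-based in
    locus order.
    """
    prefix = Path(prefix)
    os.makedirs(prefix.parent, exist_ok=True)
    G = G.orient_minor()
    p, _ = allele_frequencies(G)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")

    with open(map_path, "w") as fh:
        for l in range(G.n_loci):
            fh.write(f"{G.chrom[l]}\tsnp{l + 1}\t0\t{int(G.pos[l])}\n")

    groups = groups or (G.groups if G.groups else ["FAM"] * G.n_individuals)
    with open(ped_path, "w") as fh:
        for k, iid in enumerate(G.ids):
            fields = [str(groups[k]), str(iid), "0", "0", "0", "-9"]
            for l in range(G.n_loci):
                major, minor = G.alleles[l]
                d = G.dosage[k, l]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [major, major]
                elif d == 1:
                    fields += [major, minor]
                else:
                    fields += [minor, minor]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def write_kinship_outputs(out_dir, kinship_df=None, inbreeding_df=None) -> None:
    """Write the standard TSV outputs into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if kinship_df is not None:
        kinship_df.to_csv(out / "kinship.tsv", sep="\t", index=False)
    if inbreeding_df is not None:
        inbreeding_df.to_csv(out / "inbreeding.tsv", sep="\t", index=False)
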