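"""Comparing the pedigree arm with the genomic arm.

Given per-individual inbreeding from both arms and per-pair kinship from
both arms, this module computes the summary statistics that quantify
their agreement: the OLS regression of F_SNP on F_PED, per-subpopulation
bias of whole-cohort vs within-subpopulation F_SNP, the cross-tabulation
of inferred relationship degrees, per-degree mean absolute kinship
differences, and the proportions of individuals above the
cousin-mating inbreeding level (6.25%).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genomic import DEGREE_CATEGORIES, degree_only

__all__ = [
    "regress_inbreeding",
    "stratified_bias",
    "agreement_table",
    "threshold_proportions",
    "ComparisonReport",
    "run_comparison",
]

COUSIN_MATING_F = 0.0625


def regress_inbreeding(F_snp, F_ped) -> tuple[float, float, float]:
    """OLS of F_SNP on F_PED; returns (slope, intercept, R^2).

    R^2 is the squared Pearson correlation.  Raises when F_PED has zero
    variance (the regression is undefined) or fewer than 3 individuals.
    """
    x = np.asarray(F_ped, dtype=float)
    y = np.asarray(F_snp, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need >= 3 individuals with both estimates")
    if np.allclose(x, x[0]):
        raise ValueError("pedigree inbreeding has zero variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def stratified_bias(F_full, F_sub, groups) -> pd.Series:
    """Mean per-group shift Delta_g = mean(F_full - F_sub) over group g.

    ``F_full`` is estimated treating the cohort as homogeneous,
    ``F_sub`` with each individual's own subpopulation as the
    allele-frequency reference; both must cover the same individuals.
    """
    F_full = np.asarray(F_full, dtype=float)
    F_sub = np.asarray(F_sub, dtype=float)
    if F_full.shape != F_sub.shape or len(F_full) != len(groups):
        raise ValueError("inputs must cover the same individuals")
    df = pd.DataFrame({"delta": F_full - F_sub, "group": list(groups)})
    counts = df.groupby("group").size()
    if (counts == 0).any():
        raise ValueError("empty group")
    return df.groupby("group")["delta"].mean()


def agreement_table(degrees_ped, degrees_snp) -> pd.DataFrame:
    """5x5 cross-tabulation of relationship degrees between the arms.

    Rows = pedigree degrees, columns = SNP degrees, over the fixed
    category order (duplicate/MZ, 1st, 2nd, 3rd, unrelated); first-
    degree sublabels are collapsed.  The diagonal sum is the number of
    concordant pairs.
    """
    a = pd.Series([degree_only(d) for d in degrees_ped])
    b = pd.Series([degree_only(d) for d in degrees_snp])
    if len(a) != len(b):
        raise ValueError("degree vectors must cover the same pairs")
    tab = pd.crosstab(a, b)
    return tab.reindex(
        index=DEGREE_CATEGORIES, columns=DEGREE_CATEGORIES, fill_value=0
    )


def threshold_proportions(F, threshold: float = COUSIN_MATING_F) -> float:
    """Proportion of individuals with F strictly above ``threshold``."""
    F = np.asarray(F, dtype=float)
    if F.size == 0:
        raise ValueError("empty input")
    return float((F > threshold).mean())


@dataclass
class ComparisonReport:
    """Everything the two-arm comparison produces, JSON/TSV-serializable."""

    slope: float
    intercept: float
    r2: float
    slope_stratified: float | None
    r2_stratified: float | None
    delta_f: pd.DataFrame  # per-individual F_snp - F_ped
    group_bias: pd.Series | None
    degree_agreement: pd.DataFrame
    n_consistent: int
    n_inconsistent: int
    per_degree_abs_diff: pd.DataFrame
    prop_above_snp: float
    prop_above_ped: float
    prop_above_both: float

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["delta_f"] = self.delta_f.to_dict(orient="records")
        d["group_bias"] = (
            self.group_bias.to_dict() if self.group_bias is not None else None
        )
        d["degree_agreement"] = self.degree_agreement.to_dict()
        d["per_degree_abs_diff"] = self.per_degree_abs_diff.to_dict(
            orient="records"
        )
        return d

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "comparison.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)
        self.delta_f.to_csv(out / "delta_f.tsv", sep="\t", index=False)
        self.degree_agreement.to_csv(out / "degree_agreement.tsv", sep="\t")
        self.per_degree_abs_diff.to_csv(
            out / "per_degree_abs_diff.tsv", sep="\t", index=False
        )


def run_comparison(
    inbreeding_ped: pd.DataFrame,
    inbreeding_snp: pd.DataFrame,
    kinship_ped: pd.DataFrame,
    kinship_snp: pd.DataFrame,
    inbreeding_snp_stratified: pd.DataFrame | None = None,
    groups: dict | None = None,
    use_truncated: bool = False,
) -> ComparisonReport:
    """Assemble the full comparison report from the two arms' tables.

    Expects the standard columns: ``id, F_ped`` / ``id, F_raw, F`` for
    inbreeding and ``id1, id2, phi_ped`` / ``id1, id2, phi_raw, degree``
    for kinship.  Regression uses raw (untruncated) genomic estimates
    unless ``use_truncated``.
    """
    fcol = "F" if use_truncated else "F_raw"
    fi = inbreeding_ped.merge(inbreeding_snp[["id", fcol]], on="id")
    slope, intercept, r2 = regress_inbreeding(fi[fcol], fi["F_ped"])

    slope_s = r2_s = None
    group_bias = None
    if inbreeding_snp_stratified is not None:
        fs = fi.merge(
            inbreeding_snp_stratified[["id", fcol]].rename(
                columns={fcol: fcol + "_sub"}
            ),
            on="id",
        )
        slope_s, _, r2_s = regress_inbreeding(fs[fcol + "_sub"], fs["F_ped"])
        if groups:
            group_bias = stratified_bias(
                fs[fcol], fs[fcol + "_sub"], [groups[i] for i in fs["id"]]
            )

    delta = pd.DataFrame(
        {"id": fi["id"], "delta_F": fi[fcol] - fi["F_ped"]}
    )

    from .genomic import classify_relationship

    kp = kinship_ped.merge(kinship_snp, on=["id1", "id2"], how="inner")
    if len(kp) != len(kinship_ped) or len(kp) != len(kinship_snp):
        raise ValueError("kinship tables index different pair sets")
    deg_ped = [classify_relationship(p) for p in kp["phi_ped"]]
    deg_snp = [degree_only(d) for d in kp["degree"]]
    tab = agreement_table(deg_ped, deg_snp)
    n_cons = int(np.diag(tab.to_numpy()).sum())

    kp = kp.assign(degree_ped=[degree_only(d) for d in deg_ped])
    phicol = "phi" if use_truncated else "phi_raw"
    kp["abs_diff"] = (kp["phi_ped"] - kp[phicol]).abs()
    per_degree = (
        kp.groupby("degree_ped")["abs_diff"]
        .agg(["mean", "std", "count"])
        .reindex(DEGREE_CATEGORIES)
        .dropna(how="all")
        .reset_index()
        .rename(columns={"index": "degree"})
    )

    f_snp = fi[fcol].to_numpy()
    f_ped = fi["F_ped"].to_numpy()
    return ComparisonReport(
        slope=slope,
        intercept=intercept,
        r2=r2,
        slope_stratified=slope_s,
        r2_stratified=r2_s,
        delta_f=delta,
        group_bias=group_bias,
        degree_agreement=tab,
        n_consistent=n_cons,
        n_inconsistent=int(len(kp) - n_cons),
        per_degree_abs_diff=per_degree,
        prop_above_snp=threshold_proportions(f_snp),
        prop_above_ped=threshold_proportions(f_ped),
        prop_above_both=float(
            ((f_snp > COUSIN_MATING_F) & (f_ped > COUSIN_MATING_F)).mean()
        ),
    )
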