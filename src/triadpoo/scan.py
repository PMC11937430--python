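"""Genome-scan driver: per-SNP fits, FDR, candidate selection, LD clumping.

Applies the parent-of-origin model independently to every SNP passing
the founder-MAF filter, adjusts the ratio-test p-values for multiple
testing (Benjamini-Hochberg), selects candidates either by FDR or by a
one-parent-only rule (a strong RRcm or RRcf effect without a
significant ratio), and thins correlated hits by greedy LD clumping on
founder-genotype r².  Output mirrors the usual results-table layout,
plus a plot-ready (chrom, pos, -log10 p) companion for Manhattan plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .families import TriadDataset, snp_qc
from .model import TriadPooModel

__all__ = [
    "ClumpSpec",
    "run_scan",
    "bh_adjust",
    "select_candidates",
    "ld_r2",
    "clump",
    "annotate_genes",
    "write_results",
    "format_pvalue",
]

SCAN_COLUMNS = [
    "snp_id", "chrom", "pos", "allele_ref", "allele_eff", "maf", "hwe_p",
    "nearest_gene",
    "rr_cm", "rr_cm_low", "rr_cm_high", "rr_cm_p",
    "rr_cf", "rr_cf_low", "rr_cf_high", "rr_cf_p",
    "ratio", "ratio_low", "ratio_high", "ratio_p",
    "fdr_q", "n_triads", "n_mother_dyads", "n_father_dyads", "converged",
]


@dataclass(frozen=True)
class ClumpSpec:
    """Parameters of greedy LD clumping."""

    p_threshold: float = 1e-5
    r2_threshold: float = 0.1
    window_kb: float = 500.0
    criterion: str = "ratio_p"  # or "min_parent_p"

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold <= 1 or not 0 <= self.r2_threshold <= 1 or self.window_kb <= 0:
            raise ValueError("clump thresholds out of range")
        if self.criterion not in ("ratio_p", "min_parent_p"):
            raise ValueError("criterion must be 'ratio_p' or 'min_parent_p'")


def run_scan(
    dataset: TriadDataset,
    *,
    maf_min: float = 0.05,
    maternal: bool = False,
    child_sex: int | None = None,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-SNP parent-of-origin scan over a dataset.

    Each retained SNP (founder MAF strictly above ``maf_min``) gets an
    independent maximum-likelihood fit; the driver adds no statistical
    behaviour beyond collecting rows.  Non-converged SNPs keep their
    flag and are excluded from the FDR adjustment.  ``child_sex``
    restricts to families whose case child has that sex (1 = boys,
    2 = girls) for sex-stratified sensitivity scans.
    """
    rows = []
    for j, snp in enumerate(dataset.snps):
        units = dataset.units(j)
        if child_sex is not None:
            units = [u for u in units if u.child_sex == child_sex]
        if not units:
            continue
        qc = snp_qc(units)
        if qc.maf <= maf_min:
            continue
        res = TriadPooModel(units, maternal=maternal).fit()
        ci = res.conf_int(ci_level)
        pv = res.pvalues
        params = res.params
        row = {
            "snp_id": snp.snp_id, "chrom": snp.chrom, "pos": snp.pos,
            "allele_ref": snp.allele_ref, "allele_eff": snp.allele_eff,
            "maf": qc.maf, "hwe_p": qc.hwe_p, "nearest_gene": "",
            "rr_cm": params.rr_cm, "rr_cm_low": ci["rr_cm"][0], "rr_cm_high": ci["rr_cm"][1],
            "rr_cm_p": pv["rr_cm"],
            "rr_cf": params.rr_cf, "rr_cf_low": ci["rr_cf"][0], "rr_cf_high": ci["rr_cf"][1],
            "rr_cf_p": pv["rr_cf"],
            "n_triads": res.model.n_triads,
            "n_mother_dyads": res.model.n_mother_dyads,
            "n_father_dyads": res.model.n_father_dyads,
            "converged": res.converged,
        }
        if res.converged:
            r = res.ratio_test(ci_level)
            row.update(ratio=r.ratio, ratio_low=r.ci_low, ratio_high=r.ci_high, ratio_p=r.p_value)
        else:
            row.update(ratio=np.nan, ratio_low=np.nan, ratio_high=np.nan, ratio_p=np.nan)
        rows.append(row)
    if not rows:
        raise ValueError("no SNPs passed the MAF filter")
    df = pd.DataFrame(rows)
    df["fdr_q"] = np.nan
    ok = df["converged"] & df["ratio_p"].notna()
    if ok.any():
        df.loc[ok, "fdr_q"] = bh_adjust(df.loc[ok, "ratio_p"].to_numpy())
    return df[SCAN_COLUMNS]


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1] with no NaN")
    return multipletests(p, method="fdr_bh")[1]


def select_candidates(
    rows: pd.DataFrame,
    *,
    fdr: float = 0.05,
    one_parent_p: float = 1e-5,
) -> pd.DataFrame:
    """Candidate SNPs: significant ratio FDR, or a one-parent-only effect.

    The one-parent rule catches SNPs where one transmitted-allele risk is
    strong (``min(p_rr_cm, p_rr_cf) < one_parent_p``) even though the
    ratio itself is not significant — the ratio misses the case where one
    term is null and the other is not.  Each selected row carries its
    ``selection_reason`` (``"ratio_fdr"``, ``"one_parent"`` or ``"both"``).
    """
    if rows.empty:
        out = rows.copy()
        out["selection_reason"] = pd.Series(dtype=str)
        return out
    by_fdr = rows["fdr_q"].notna() & (rows["fdr_q"] <= fdr)
    by_parent = np.minimum(rows["rr_cm_p"], rows["rr_cf_p"]) < one_parent_p
    sel = rows[by_fdr | by_parent].copy()
    reason = np.where(by_fdr & by_parent, "both", np.where(by_fdr, "ratio_fdr", "one_parent"))
    sel["selection_reason"] = reason[(by_fdr | by_parent).to_numpy()]
    return sel


def ld_r2(g1: Sequence[float], g2: Sequence[float]) -> float:
    """Composite LD: squared Pearson correlation of founder dosage vectors.

    Missing entries (NaN) are dropped pairwise.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 2:
        raise ValueError("need at least two complete founder pairs")
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("zero variance at one of the SNPs; r2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def clump(
    rows: pd.DataFrame,
    founder_dosages: Mapping[str, np.ndarray],
    spec: ClumpSpec = ClumpSpec(),
) -> pd.DataFrame:
    """Greedy LD clumping to an approximately independent set of index SNPs.

    Repeatedly takes the unassigned row with the smallest clumping
    p-value (ties broken by smaller position) among those meeting
    ``p_threshold``, and removes rows on the same chromosome within
    ``window_kb`` whose founder-dosage r² with the index exceeds
    ``r2_threshold``.  Deterministic.
    """
    pcol = (
        rows["ratio_p"]
        if spec.criterion == "ratio_p"
        else np.minimum(rows["rr_cm_p"], rows["rr_cf_p"])
    )
    work = rows.assign(_p=np.asarray(pcol, dtype=float))
    work = work[work["_p"].notna() & (work["_p"] < spec.p_threshold)]
    work = work.sort_values(["_p", "pos"], kind="mergesort")
    kept_ids: list = []
    removed: set = set()
    for row in work.itertuples(index=True):
        if row.Index in removed:
            continue
        kept_ids.append(row.Index)
        g_index = founder_dosages[row.snp_id]
        for other in work.itertuples(index=True):
            if other.Index == row.Index or other.Index in removed or other.Index in kept_ids:
                continue
            if other.chrom != row.chrom or abs(other.pos - row.pos) > spec.window_kb * 1000:
                continue
            if ld_r2(g_index, founder_dosages[other.snp_id]) > spec.r2_threshold:
                removed.add(other.Index)
    return rows.loc[kept_ids].drop(columns=[c for c in ("_p",) if c in rows.columns])


def annotate_genes(rows: pd.DataFrame, bed_path: str | Path) -> pd.DataFrame:
    """Fill ``nearest_gene`` from a BED file (0-based half-open intervals).

    A SNP inside an interval gets that gene; otherwise the nearest gene
    on its chromosome by basepair distance (empty if none).  Pure
    passthrough annotation — no live lookups.
    """
    bed = pd.read_csv(bed_path, sep="\t", header=None, comment="#",
                      names=["chrom", "start", "end", "name"], usecols=range(4),
                      dtype={"chrom": str})
    out = rows.copy()
    genes = []
    for row in out.itertuples(index=False):
        sub = bed[bed["chrom"] == str(row.chrom)]
        if sub.empty:
            genes.append("")
            continue
        pos0 = row.pos - 1  # BED is 0-based
        inside = sub[(sub["start"] <= pos0) & (pos0 < sub["end"])]
        if not inside.empty:
            genes.append(inside.iloc[0]["name"])
        else:
            dist = np.minimum(np.abs(sub["start"] - pos0), np.abs(sub["end"] - 1 - pos0))
            genes.append(sub.iloc[int(np.argmin(dist))]["name"])
    out["nearest_gene"] = genes
    return out


def format_pvalue(p: float) -> str:
    """Table-style scientific notation with 3 significant digits (1.13E-05)."""
    if not np.isfinite(p):
        return "NA"
    return f"{p:.2E}"


def write_results(rows: pd.DataFrame, path: str | Path, manhattan_path: str | Path | None = None) -> None:
    """Write the scan table as TSV, plus an optional Manhattan companion.

    P-value columns are printed in 3-significant-digit scientific
    notation; the companion file holds (chrom, pos, neg_log10_ratio_p).
    """
    out = rows.copy()
    for col in out.columns:
        if col.endswith("_p") or col == "fdr_q" or col == "hwe_p":
            out[col] = out[col].map(format_pvalue)
    out.to_csv(path, sep="\t", index=False)
    if manhattan_path is not None:
        man = rows[["chrom", "pos"]].copy()
        with np.errstate(divide="ignore"):
            man["neg_log10_ratio_p"] = -np.log10(rows["ratio_p"].astype(float))
        man.to_csv(manhattan_path, sep="\t", index=False)
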