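"""Family-linked genotype data: PLINK text input, family units, founder QC.

This module turns hard-call SNP genotypes plus a pedigree into the
case-family units the parent-of-origin likelihood consumes: *triads*
(case child with both parents genotyped), *mother dyads* and *father
dyads* (one parent genotyped).  It also provides the descriptive
founder statistics reported alongside scan results: minor allele
frequency and an exact Hardy-Weinberg equilibrium test, both computed
on parents only, each parent counted once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "SnpRecord",
    "PedigreeRecord",
    "FamilyUnit",
    "SnpQc",
    "FormatError",
    "TriadDataset",
    "read_ped_map",
    "read_triad_tsv",
    "build_family_units",
    "dedupe_siblings",
    "founder_allele_freq",
    "hwe_exact_test",
    "snp_qc",
    "filter_snps",
]

logger = logging.getLogger(__name__)

_VALID_ALLELES = frozenset("ACGT")
_MISSING_ALLELE = "0"


class FormatError(ValueError):
    """Raised when an input file violates the expected text dialect."""


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP with a designated effect allele.

    ``allele_ref`` (A1) and ``allele_eff`` (A2) follow the results-table
    convention: dosages count copies of ``allele_eff``.
    """

    snp_id: str
    chrom: str
    pos: int
    allele_ref: str
    allele_eff: str

    def __post_init__(self) -> None:
        if self.allele_ref == self.allele_eff:
            raise ValueError(f"{self.snp_id}: reference and effect allele identical")
        if self.pos <= 0:
            raise ValueError(f"{self.snp_id}: position must be positive")


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual and its position in the sampling scheme."""

    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    role: Literal["child", "mother", "father"]
    case_status: Literal["case", "control", "unknown"]
    sex: int | None = None  # 1 = male, 2 = female, None = unknown


@dataclass(frozen=True)
class FamilyUnit:
    """One case family's effect-allele dosages at a single SNP.

    A missing (``None``) parent dosage encodes the dyad designs; the
    family type is derived, never stored, so the invariant that a
    mother dyad has no father dosage holds by construction.
    """

    family_id: str
    child: int
    mother: int | None = None
    father: int | None = None
    child_sex: int | None = None

    def __post_init__(self) -> None:
        for name, g in (("child", self.child), ("mother", self.mother), ("father", self.father)):
            if g is not None and g not in (0, 1, 2):
                raise ValueError(f"{name} dosage must be 0, 1, 2 or None; got {g!r}")
        if self.mother is None and self.father is None:
            raise ValueError("a family unit needs at least one genotyped parent")

    @property
    def family_type(self) -> str:
        if self.mother is not None and self.father is not None:
            return "triad"
        return "mother_dyad" if self.mother is not None else "father_dyad"


@dataclass(frozen=True)
class SnpQc:
    """Founder-based descriptive statistics for one SNP."""

    maf: float
    hwe_p: float
    n_founders: int


def _transmissible(g: int | None) -> tuple[int, ...]:
    """Effect-allele counts a parent of genotype ``g`` can transmit."""
    if g is None:
        return (0, 1)
    return {0: (0,), 1: (0, 1), 2: (1,)}[g]


def mendelian_consistent(mother: int | None, father: int | None, child: int) -> bool:
    """Whether a (possibly incomplete) family can arise by Mendelian transmission."""
    return any(mt + ft == child for mt in _transmissible(mother) for ft in _transmissible(father))


# ---------------------------------------------------------------------------
# PLINK text input
# ---------------------------------------------------------------------------

def _read_map(map_path: str | Path) -> list[tuple[str, str, int]]:
    rows = []
    for lineno, line in enumerate(Path(map_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"{map_path}:{lineno}: expected 4 columns (CHR SNP CM POS), got {len(parts)}")
        chrom, snp_id, _cm, pos = parts
        rows.append((chrom, snp_id, int(pos)))
    return rows


def read_ped_map(
    ped_path: str | Path,
    map_path: str | Path,
    effect_allele_rule: Literal["minor"] | Mapping[str, str] = "minor",
) -> tuple[list[SnpRecord], list[PedigreeRecord], np.ndarray]:
    """Read PLINK text ``.ped``/``.map`` files into dosages of the effect allele.

    Parameters
    ----------
    ped_path, map_path
        Whitespace-delimited PLINK 1.x text files.  The ``.ped`` file has
        6 leading columns (FID IID PAT MAT SEX PHENO) followed by two
        allele columns per SNP; allele symbols are A/C/G/T with ``0`` as
        the missing sentinel.
    effect_allele_rule
        ``"minor"`` (default) orients each SNP so the effect allele is
        the minor allele among founders; alternatively a mapping
        ``snp_id -> effect allele letter`` forces a fixed orientation
        (e.g. to match a published table).

    Returns
    -------
    (snps, pedigree, dosages)
        ``dosages`` is an ``(n_individuals, n_snps)`` float array of
        effect-allele counts with ``nan`` where either allele is missing;
        rows follow ``.ped`` order, columns follow ``.map`` order.
    """
    map_rows = _read_map(map_path)
    n_snps = len(map_rows)
    expected_cols = 6 + 2 * n_snps

    pedigree: list[PedigreeRecord] = []
    allele_rows: list[list[str]] = []
    raw: list[tuple[str, str, str, str, int | None, str]] = []
    for lineno, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != expected_cols:
            raise FormatError(
                f"{ped_path}:{lineno}: expected {expected_cols} columns "
                f"(6 + 2 x {n_snps} SNPs), got {len(parts)}"
            )
        fid, iid, pat, mat, sex, pheno = parts[:6]
        alleles = parts[6:]
        for j, a in enumerate(alleles):
            if a != _MISSING_ALLELE and a not in _VALID_ALLELES:
                raise FormatError(f"{ped_path}:{lineno}: unknown allele symbol {a!r} in column {7 + j}")
        raw.append((fid, iid, pat, mat, int(sex) if sex in ("1", "2") else None, pheno))
        allele_rows.append(alleles)

    mother_ids = {mat for _, _, _, mat, _, _ in raw if mat != "0"}
    father_ids = {pat for _, _, pat, _, _, _ in raw if pat != "0"}
    for fid, iid, pat, mat, sex, pheno in raw:
        if pat != "0" or mat != "0":
            role = "child"
        elif iid in mother_ids:
            role = "mother"
        else:
            role = "father" if iid in father_ids else "child"
        status = {"2": "case", "1": "control"}.get(pheno, "unknown")
        pedigree.append(
            PedigreeRecord(fid, iid, pat if pat != "0" else None, mat if mat != "0" else None,
                           role, status, sex)
        )

    founder_rows = [i for i, rec in enumerate(pedigree) if rec.role in ("mother", "father")]
    count_rows = founder_rows if founder_rows else range(len(pedigree))

    snps: list[SnpRecord] = []
    dosages = np.full((len(pedigree), n_snps), np.nan)
    for j, (chrom, snp_id, pos) in enumerate(map_rows):
        col = [(allele_rows[i][2 * j], allele_rows[i][2 * j + 1]) for i in range(len(pedigree))]
        observed = sorted({a for pair in col for a in pair if a != _MISSING_ALLELE})
        if len(observed) > 2:
            raise FormatError(f"{snp_id}: more than two alleles observed: {observed}")
        counts = {a: 0 for a in observed}
        for i in count_rows:
            for a in col[i]:
                if a != _MISSING_ALLELE:
                    counts[a] += 1
        if isinstance(effect_allele_rule, Mapping):
            eff = effect_allele_rule.get(snp_id)
            if eff is None or eff not in _VALID_ALLELES:
                raise FormatError(f"{snp_id}: no valid effect allele in the supplied allele map")
        elif len(observed) == 2:
            # minor among founders; lexicographic tie-break for determinism
            eff = min(observed, key=lambda a: (counts[a], a))
        else:
            eff = observed[0] if observed else "N"
        others = [a for a in observed if a != eff]
        ref = others[0] if others else ("A" if eff != "A" else "C")
        snps.append(SnpRecord(snp_id, chrom, pos, ref, eff))
        for i, (a1, a2) in enumerate(col):
            if a1 != _MISSING_ALLELE and a2 != _MISSING_ALLELE:
                dosages[i, j] = (a1 == eff) + (a2 == eff)
    return snps, pedigree, dosages


def read_triad_tsv(path: str | Path) -> tuple[list[str], dict[str, list[FamilyUnit]]]:
    """Read the simple per-SNP triad TSV dialect.

    Columns: ``snp_id, family_id, child, mother, father`` with empty or
    ``NA`` for a missing parent dosage.  Returns the SNP ids in file
    order and a mapping from SNP id to its family units.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "family_id": str})
    required = {"snp_id", "family_id", "child", "mother", "father"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    units: dict[str, list[FamilyUnit]] = {}
    order: list[str] = []
    for row in df.itertuples(index=False):
        def _g(v):
            return None if pd.isna(v) else int(v)
        if row.snp_id not in units:
            units[row.snp_id] = []
            order.append(row.snp_id)
        units[row.snp_id].append(FamilyUnit(row.family_id, int(row.child), _g(row.mother), _g(row.father)))
    return order, units


# ---------------------------------------------------------------------------
# Family linking
# ---------------------------------------------------------------------------

def build_family_units(
    pedigree: Sequence[PedigreeRecord],
    dosages: np.ndarray,
    snp_index: int = 0,
) -> tuple[list[FamilyUnit], dict[str, int]]:
    """Link case children with their parents' dosages at one SNP.

    One unit is emitted per case child.  A triad whose parent has a
    missing genotype *at this SNP* is downgraded to the corresponding
    dyad rather than dropped, so sporadic missingness costs only the
    missing parent's information.  Children with a missing genotype,
    with neither parent genotyped, or in Mendelian-inconsistent
    families are excluded; the returned counter reports how many of
    each.
    """
    index = {rec.individual_id: i for i, rec in enumerate(pedigree)}
    col = dosages[:, snp_index] if dosages.ndim == 2 else dosages
    units: list[FamilyUnit] = []
    excl = {"child_missing": 0, "no_genotyped_parent": 0, "mendelian_inconsistent": 0}

    def _dosage(iid: str | None) -> int | None:
        if iid is None or iid not in index:
            return None
        v = col[index[iid]]
        return None if np.isnan(v) else int(v)

    for rec in pedigree:
        if rec.role != "child" or rec.case_status != "case":
            continue
        child = _dosage(rec.individual_id)
        if child is None:
            excl["child_missing"] += 1
            continue
        mother, father = _dosage(rec.mother_id), _dosage(rec.father_id)
        if mother is None and father is None:
            excl["no_genotyped_parent"] += 1
            continue
        if not mendelian_consistent(mother, father, child):
            excl["mendelian_inconsistent"] += 1
            continue
        units.append(FamilyUnit(rec.family_id, child, mother, father, rec.sex))
    if any(excl.values()):
        logger.info("build_family_units: excluded %s", excl)
    return units, excl


def dedupe_siblings(units: Sequence[FamilyUnit]) -> list[FamilyUnit]:
    """Keep the first-listed child per family (sibling de-duplication)."""
    seen: set[str] = set()
    out = []
    for u in units:
        if u.family_id not in seen:
            seen.add(u.family_id)
            out.append(u)
    return out


# ---------------------------------------------------------------------------
# Founder statistics
# ---------------------------------------------------------------------------

def _founder_dosage_pairs(units: Iterable[FamilyUnit]) -> list[tuple[int | None, int | None]]:
    # each parent once: a family's parents are shared by all its children
    seen: set[str] = set()
    pairs = []
    for u in units:
        if u.family_id in seen:
            continue
        seen.add(u.family_id)
        pairs.append((u.mother, u.father))
    return pairs


def founder_allele_freq(units: Sequence[FamilyUnit]) -> float:
    """Effect-allele frequency among available parental genotypes."""
    doses = [g for pair in _founder_dosage_pairs(units) for g in pair if g is not None]
    if not doses:
        raise ValueError("no founder genotypes available")
    return sum(doses) / (2 * len(doses))


def hwe_exact_test(n0: int, n1: int, n2: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value for genotype counts.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote counts no more probable than the observed one
    (the standard exact SNP-HWE construction).  Deterministic.
    """
    if min(n0, n1, n2) < 0 or n0 + n1 + n2 < 1:
        raise ValueError("genotype counts must be nonnegative with at least one individual")
    n = n0 + n1 + n2
    n_rare = 2 * min(n0, n2) + n1  # minor allele count
    hets = np.arange(n1 % 2, n_rare + 1, 2)
    homr = (n_rare - hets) // 2
    homc = n - hets - homr
    logp = (
        gammaln(n + 1) - gammaln(homr + 1) - gammaln(hets + 1) - gammaln(homc + 1)
        + hets * np.log(2.0)
        - (gammaln(2 * n + 1) - gammaln(n_rare + 1) - gammaln(2 * n - n_rare + 1))
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    p_obs = prob[hets == n1][0]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def snp_qc(units: Sequence[FamilyUnit]) -> SnpQc:
    """Founder MAF and exact HWE p-value for one SNP's family units."""
    doses = [g for pair in _founder_dosage_pairs(units) for g in pair if g is not None]
    if not doses:
        raise ValueError("no founder genotypes available")
    freq = sum(doses) / (2 * len(doses))
    counts = [doses.count(0), doses.count(1), doses.count(2)]
    return SnpQc(maf=min(freq, 1 - freq), hwe_p=hwe_exact_test(*counts), n_founders=len(doses))


def filter_snps(qc: Sequence[SnpQc], maf_min: float = 0.05) -> list[int]:
    """Indices of SNPs whose founder MAF strictly exceeds ``maf_min``."""
    return [i for i, q in enumerate(qc) if q.maf > maf_min]


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

@dataclass
class TriadDataset:
    """A genotyped cohort of case families, ready for per-SNP analysis."""

    snps: list[SnpRecord]
    pedigree: list[PedigreeRecord]
    dosages: np.ndarray
    exclusions: dict[str, dict[str, int]] = field(default_factory=dict)

    @classmethod
    def from_ped_map(cls, ped_path, map_path, effect_allele_rule="minor") -> "TriadDataset":
        snps, pedigree, dosages = read_ped_map(ped_path, map_path, effect_allele_rule)
        return cls(snps, pedigree, dosages)

    def units(self, snp_index: int) -> list[FamilyUnit]:
        units, excl = build_family_units(self.pedigree, self.dosages, snp_index)
        self.exclusions[self.snps[snp_index].snp_id] = excl
        return units

    def founder_dosages(self, snp_index: int) -> np.ndarray:
        """Parental dosage vector at one SNP (each parent once, nan-free)."""
        units = self.units(snp_index)
        doses = [g for pair in _founder_dosage_pairs(units) for g in pair if g is not None]
        return np.array(doses, dtype=float)

    def qc(self) -> list[SnpQc]:
        return [snp_qc(self.units(j)) for j in range(len(self.snps))]
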