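"""Synthetic case-family generator.

Emulates the study design the parent-of-origin likelihood is built for:
parents drawn under Hardy-Weinberg equilibrium with random mating,
Mendelian transmission, and case children ascertained by rejection
sampling under the multiplicative penetrance

    Pr(case | alleles) = B * RRcm**m_t * RRcf**f_t * RR***(m_t*f_t) * RRm**mother_dosage

where ``m_t``/``f_t`` indicate an effect allele in the maternally /
paternally transmitted slot.  The baseline risk ``B`` scales the
acceptance rate only; the distribution of accepted families depends
only on the relative risks and the allele frequency, which is exactly
the conditional multinomial the model fits.  Dyads are produced by
deleting a parent completely at random according to a triad/dyad
composition, mirroring the ungenotyped-parent mechanism of the sampling
scheme.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .families import FamilyUnit, SnpRecord

__all__ = [
    "SimConfig",
    "SimTruth",
    "COMPOSITION_STUDY",
    "N_FAMILIES_STUDY",
    "simulate_case_families",
    "apply_missingness",
    "simulate_ld_region",
    "chain_haplotype_freqs",
    "write_ped_map",
    "HaploFamily",
]

# the study's family composition: 915 triads, 603 mother dyads, 113 father dyads
N_FAMILIES_STUDY = 1631
COMPOSITION_STUDY = (915 / 1631, 603 / 1631, 113 / 1631)

# childhood-asthma-like baseline risk; affects acceptance rate only (see module docstring)
DEFAULT_BASELINE_RISK = 0.05


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for one synthetic SNP panel."""

    p: float
    rr_cm: float = 1.0
    rr_cf: float = 1.0
    rr_star: float = 1.0
    rr_m: float = 1.0
    baseline_risk: float = DEFAULT_BASELINE_RISK
    n_case_families: int = N_FAMILIES_STUDY
    composition: tuple[float, float, float] = (1.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError("allele frequency must be in (0, 1)")
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")
        max_mult = (
            max(self.rr_cm, 1) * max(self.rr_cf, 1) * max(self.rr_star, 1) * max(self.rr_m, 1) ** 2
        )
        if self.baseline_risk * max_mult > 1.0 + 1e-12:
            raise ValueError("baseline_risk times the maximal risk multiplier exceeds 1")


@dataclass(frozen=True)
class SimTruth:
    """The generating parameter values, recorded for recovery testing."""

    config: dict
    n_drawn: int
    n_accepted: int

    def to_text(self) -> str:
        lines = [f"{k}\t{v}" for k, v in self.config.items()]
        lines += [f"n_drawn\t{self.n_drawn}", f"n_accepted\t{self.n_accepted}"]
        return "\n".join(lines) + "\n"


def _draw_case_slots(rng: np.random.Generator, cfg: SimConfig) -> tuple[np.ndarray, int]:
    """Rejection-sample ordered allele quadruples for case children.

    Returns an ``(n, 4)`` 0/1 array over slots (maternal non-transmitted,
    maternal transmitted, paternal non-transmitted, paternal transmitted)
    plus the total number of candidate families drawn.
    """
    need = cfg.n_case_families
    out = np.empty((need, 4), dtype=np.int8)
    filled = n_drawn = 0
    batch = max(1024, int(2 * need / max(cfg.baseline_risk, 1e-3)))
    while filled < need:
        a = (rng.random((batch, 4)) < cfg.p).astype(np.int8)
        risk = (
            cfg.baseline_risk
            * cfg.rr_cm ** a[:, 1]
            * cfg.rr_cf ** a[:, 3]
            * cfg.rr_star ** (a[:, 1] * a[:, 3])
            * cfg.rr_m ** (a[:, 0] + a[:, 1])
        )
        keep = a[rng.random(batch) < risk]
        n_drawn += batch
        take = min(len(keep), need - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out, n_drawn


def simulate_case_families(cfg: SimConfig) -> tuple[list[FamilyUnit], SimTruth]:
    """Simulate case-ascertained families at one SNP.

    Families start as full triads; :func:`apply_missingness` (called here
    when ``cfg.composition`` requests dyads) deletes parents completely
    at random to reach the requested triad/dyad composition.
    """
    rng = np.random.default_rng(cfg.seed)
    slots, n_drawn = _draw_case_slots(rng, cfg)
    if len(slots) == 0:
        raise RuntimeError("no case families accepted; acceptance probability is zero")
    units = [
        FamilyUnit(f"F{i:06d}", child=int(a[1] + a[3]), mother=int(a[0] + a[1]), father=int(a[2] + a[3]))
        for i, a in enumerate(slots)
    ]
    truth = SimTruth(asdict(cfg), n_drawn=n_drawn, n_accepted=len(units))
    if cfg.composition != (1.0, 0.0, 0.0):
        units = apply_missingness(units, cfg.composition, rng)
    return units, truth


def apply_missingness(
    units: Sequence[FamilyUnit],
    composition: tuple[float, float, float],
    rng: np.random.Generator | int,
) -> list[FamilyUnit]:
    """Reassign triads to dyads by deleting parents completely at random.

    ``composition`` gives (triad, mother-dyad, father-dyad) proportions;
    each family's type is an independent categorical draw, so realised
    counts are multinomial around the expectations.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if abs(sum(composition) - 1.0) > 1e-9:
        raise ValueError("composition must sum to 1")
    kinds = rng.choice(3, size=len(units), p=list(composition))
    out = []
    for u, kind in zip(units, kinds):
        if kind == 0:
            out.append(u)
        elif kind == 1:
            out.append(FamilyUnit(u.family_id, u.child, u.mother, None, u.child_sex))
        else:
            out.append(FamilyUnit(u.family_id, u.child, None, u.father, u.child_sex))
    return out


# ---------------------------------------------------------------------------
# Multi-SNP (LD) regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaploFamily:
    """Per-SNP dosages of one family across a multi-SNP window.

    ``mother``/``father`` are tuples of per-SNP dosages, or ``None`` when
    the parent is not genotyped.
    """

    family_id: str
    child: tuple[int, ...]
    mother: tuple[int, ...] | None = None
    father: tuple[int, ...] | None = None

    @property
    def k(self) -> int:
        return len(self.child)

    def snp_unit(self, s: int) -> FamilyUnit:
        """Single-SNP view of this family at window position ``s``."""
        return FamilyUnit(
            self.family_id,
            self.child[s],
            None if self.mother is None else self.mother[s],
            None if self.father is None else self.father[s],
        )


def chain_haplotype_freqs(p: Sequence[float], r: float) -> np.ndarray:
    """Haplotype frequencies of a first-order Markov allele chain.

    Adjacent SNPs share allele correlation ``r`` (so pairwise LD
    ``r**2``); each SNP ``s`` has effect-allele frequency ``p[s]``.
    Only equal allele frequencies admit an exact stationary chain with
    constant correlation; unequal frequencies bound the feasible ``r``.
    Returns the ``2**k`` haplotype probability vector, haplotypes indexed
    by their bit pattern (SNP 0 = most significant bit).
    """
    p = np.asarray(p, dtype=float)
    k = len(p)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequencies must be interior")
    freqs = np.zeros(2**k)
    for h in range(2**k):
        bits = [(h >> (k - 1 - s)) & 1 for s in range(k)]
        prob = p[0] if bits[0] else 1 - p[0]
        for s in range(1, k):
            p1, p0 = p[s], p[s - 1]
            # conditional P(allele_s = 1 | allele_{s-1}) preserving corr r
            d = r * np.sqrt(p0 * (1 - p0) * p1 * (1 - p1))
            c11 = p1 + d / p0
            c10 = p1 - d / (1 - p0)
            if not (0 <= c11 <= 1 and 0 <= c10 <= 1):
                dmax = min(p0 * (1 - p1), (1 - p0) * p1)
                dmin = -min(p0 * p1, (1 - p0) * (1 - p1))
                rmax = dmax / np.sqrt(p0 * (1 - p0) * p1 * (1 - p1))
                rmin = dmin / np.sqrt(p0 * (1 - p0) * p1 * (1 - p1))
                raise ValueError(
                    f"correlation {r} infeasible for frequencies ({p0}, {p1}); "
                    f"feasible range [{rmin:.4f}, {rmax:.4f}]"
                )
            cond = c11 if bits[s - 1] else c10
            prob *= cond if bits[s] else 1 - cond
        freqs[h] = prob
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise RuntimeError("haplotype frequencies do not sum to 1")
    return freqs


def simulate_ld_region(
    hap_freqs: Sequence[float],
    *,
    rr_cm: float = 1.0,
    rr_cf: float = 1.0,
    risk_snp: int | None = None,
    risk_haplotype: int | None = None,
    baseline_risk: float = DEFAULT_BASELINE_RISK,
    n_case_families: int = N_FAMILIES_STUDY,
    composition: tuple[float, float, float] = (1.0, 0.0, 0.0),
    seed: int = 0,
) -> tuple[list[HaploFamily], SimTruth]:
    """Simulate case families over a window of SNPs in LD.

    Parental haplotypes are drawn i.i.d. from ``hap_freqs`` (length
    ``2**k``); risk attaches either to the effect allele at ``risk_snp``
    or to carrying ``risk_haplotype`` in a transmitted slot.  A ``k=1``
    region with frequencies ``(1-p, p)`` is distributionally identical
    to :func:`simulate_case_families`.
    """
    f = np.asarray(hap_freqs, dtype=float)
    if f.ndim != 1 or len(f) & (len(f) - 1):
        raise ValueError("hap_freqs length must be a power of two")
    if abs(f.sum() - 1.0) > 1e-9 or np.any(f < 0):
        raise ValueError("hap_freqs must be a probability vector")
    k = int(np.log2(len(f)))
    if risk_snp is None and risk_haplotype is None:
        risk_snp = 0
    if risk_snp is not None and risk_haplotype is not None:
        raise ValueError("specify risk_snp or risk_haplotype, not both")
    if baseline_risk * max(rr_cm, 1) * max(rr_cf, 1) > 1 + 1e-12:
        raise ValueError("baseline_risk times the maximal risk multiplier exceeds 1")

    alleles = np.array([[(h >> (k - 1 - s)) & 1 for s in range(k)] for h in range(2**k)], dtype=np.int8)
    if risk_snp is not None:
        carrier = alleles[:, risk_snp].astype(float)  # per-haplotype risk indicator
    else:
        carrier = (np.arange(2**k) == risk_haplotype).astype(float)

    rng = np.random.default_rng(seed)
    out: list[HaploFamily] = []
    n_drawn = 0
    batch = max(1024, int(2 * n_case_families / max(baseline_risk, 1e-3)))
    while len(out) < n_case_families:
        # slots: maternal non-transmitted / transmitted, paternal non-transmitted / transmitted
        q = rng.choice(len(f), size=(batch, 4), p=f)
        risk = baseline_risk * rr_cm ** carrier[q[:, 1]] * rr_cf ** carrier[q[:, 3]]
        keep = q[rng.random(batch) < risk]
        n_drawn += batch
        for row in keep[: n_case_families - len(out)]:
            h_mnt, h_mt, h_fnt, h_ft = (alleles[i] for i in row)
            out.append(
                HaploFamily(
                    f"F{len(out):06d}",
                    child=tuple((h_mt + h_ft).tolist()),
                    mother=tuple((h_mnt + h_mt).tolist()),
                    father=tuple((h_fnt + h_ft).tolist()),
                )
            )
    truth = SimTruth(
        {
            "hap_freqs": f.tolist(),
            "rr_cm": rr_cm,
            "rr_cf": rr_cf,
            "risk_snp": risk_snp,
            "risk_haplotype": risk_haplotype,
            "baseline_risk": baseline_risk,
            "n_case_families": n_case_families,
            "composition": composition,
            "seed": seed,
        },
        n_drawn=n_drawn,
        n_accepted=len(out),
    )
    if composition != (1.0, 0.0, 0.0):
        kinds = rng.choice(3, size=len(out), p=list(composition))
        out = [
            h if kind == 0 else
            HaploFamily(h.family_id, h.child, h.mother, None) if kind == 1 else
            HaploFamily(h.family_id, h.child, None, h.father)
            for h, kind in zip(out, kinds)
        ]
    return out, truth


# ---------------------------------------------------------------------------
# PLINK text output
# ---------------------------------------------------------------------------

def write_ped_map(
    units: Sequence[FamilyUnit] | Sequence[HaploFamily],
    snps: Sequence[SnpRecord],
    ped_path: str | Path,
    map_path: str | Path,
    *,
    include_missing_parents: bool = False,
) -> None:
    """Write family units as PLINK text ``.ped``/``.map``.

    Dosage 0/1/2 maps to allele pairs over (``allele_ref``, ``allele_eff``).
    By default an ungenotyped parent is omitted entirely (the child row
    keeps its pedigree pointers); ``include_missing_parents`` writes the
    parent with all-missing genotypes instead.
    """
    n_snps = len(snps)

    def _geno_cols(doses: Sequence[int | None]) -> list[str]:
        cols = []
        for s, g in enumerate(doses):
            if g is None:
                cols += ["0", "0"]
            else:
                eff, ref = snps[s].allele_eff, snps[s].allele_ref
                cols += [eff] * g + [ref] * (2 - g)
        return cols

    lines = []
    for u in units:
        fid = u.family_id
        child = list(u.child) if isinstance(u, HaploFamily) else [u.child]
        mother = None if u.mother is None else (list(u.mother) if isinstance(u, HaploFamily) else [u.mother])
        father = None if u.father is None else (list(u.father) if isinstance(u, HaploFamily) else [u.father])
        if len(child) != n_snps:
            raise ValueError("unit width does not match the SNP list")
        mid, pid = f"{fid}_M", f"{fid}_P"
        for doses, iid, pat, mat, pheno in (
            (mother, mid, "0", "0", "1"),
            (father, pid, "0", "0", "1"),
            (child, f"{fid}_C", pid, mid, "2"),
        ):
            if doses is None:
                if include_missing_parents:
                    doses = [None] * n_snps
                else:
                    continue
            sex = "2" if iid.endswith("_M") else ("1" if iid.endswith("_P") else "0")
            lines.append(" ".join([fid, iid, pat, mat, sex, pheno] + _geno_cols(doses)))
    Path(ped_path).write_text("\n".join(lines) + "\n")
    Path(map_path).write_text(
        "\n".join(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos}" for s in snps) + "\n"
    )
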