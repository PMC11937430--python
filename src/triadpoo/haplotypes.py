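"""Haplotype-window parent-of-origin analysis.

Generalises the single-SNP model to sliding windows of neighbouring
SNPs (three by default): each case family's latent state is an ordered
quadruple of haplotypes (maternal non-transmitted, maternal transmitted,
paternal non-transmitted, paternal transmitted), with cell weight

    freq(h_mnt) freq(h_mt) freq(h_fnt) freq(h_ft) * RRcm(h_mt) * RRcf(h_ft)

normalised over all quadruples.  Relative risks are contrasts against a
reference haplotype (most frequent by default) whose risks are fixed at 1.
Phase ambiguity and ungenotyped parents are handled by summing the
weights of every quadruple compatible with the observed per-SNP dosages.
Haplotype frequencies are initialised by an EM on parental genotypes
ignoring the risk terms; the full likelihood is then maximised directly
on an unconstrained scale (softmax frequencies, log risks).  Haplotypes
rarer than a floor keep their risks fixed at 1 and are reported as rare.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .families import PedigreeRecord, SnpRecord
from .model import MAX_ABS_LOG_RR, _safe_inverse
from .simulate import HaploFamily

__all__ = [
    "sliding_windows",
    "build_window_units",
    "compatible_haplo_configurations",
    "haplotype_frequency_em",
    "haplotype_label",
    "HaplotypeWindowModel",
    "HaplotypeWindowResults",
    "fit_window",
]

MAX_WINDOW = 5  # 8^4 quadruple enumeration beyond this is refused


def _hap_alleles(k: int) -> np.ndarray:
    """(2**k, k) effect-allele indicator matrix; SNP 0 is the high bit."""
    return np.array(
        [[(h >> (k - 1 - s)) & 1 for s in range(k)] for h in range(2**k)], dtype=np.int8
    )


def haplotype_label(hap: tuple[int, ...], snps: Sequence[SnpRecord] | None = None) -> str:
    """Human-readable allele string for a haplotype, e.g. ``T-A-G``."""
    if snps is None:
        return "".join(str(b) for b in hap)
    return "-".join(s.allele_eff if b else s.allele_ref for s, b in zip(snps, hap))


def sliding_windows(
    snps: Sequence[SnpRecord],
    k: int = 3,
    regions: Sequence[tuple[str, int, int]] | None = None,
) -> list[tuple[int, ...]]:
    """Consecutive k-SNP windows within each chromosome.

    Windows never span chromosomes; SNPs are position-sorted within a
    chromosome first.  ``regions`` (chrom, start, end; 1-based inclusive)
    restricts output to windows fully inside a single region — the usual
    workflow runs windows only over regions flagged by the SNP scan.
    Returns tuples of indices into the input list.
    """
    if k < 1 or k > MAX_WINDOW:
        raise ValueError(f"window size must be between 1 and {MAX_WINDOW}")
    by_chrom: dict[str, list[int]] = {}
    for i, s in enumerate(snps):
        by_chrom.setdefault(s.chrom, []).append(i)
    windows = []
    for chrom in by_chrom:
        idx = sorted(by_chrom[chrom], key=lambda i: snps[i].pos)
        for start in range(len(idx) - k + 1):
            win = tuple(idx[start : start + k])
            if regions is not None and not any(
                chrom == rc and all(rs <= snps[i].pos <= re for i in win)
                for rc, rs, re in regions
            ):
                continue
            windows.append(win)
    return windows


def build_window_units(
    pedigree: Sequence[PedigreeRecord],
    dosages: np.ndarray,
    window: Sequence[int],
) -> list[HaploFamily]:
    """Assemble multi-SNP family units for one window of SNP columns.

    Case children with a missing dosage at any window SNP are dropped;
    a parent's sporadically missing SNPs appear as ``None`` entries.
    """
    index = {rec.individual_id: i for i, rec in enumerate(pedigree)}
    cols = list(window)

    def _tuple(iid: str | None):
        if iid is None or iid not in index:
            return None
        vals = dosages[index[iid], cols]
        tup = tuple(None if np.isnan(v) else int(v) for v in vals)
        return None if all(v is None for v in tup) else tup

    out = []
    for rec in pedigree:
        if rec.role != "child" or rec.case_status != "case":
            continue
        child = _tuple(rec.individual_id)
        if child is None or any(v is None for v in child):
            continue
        mother, father = _tuple(rec.mother_id), _tuple(rec.father_id)
        if mother is None and father is None:
            continue
        out.append(HaploFamily(rec.family_id, child, mother, father))
    return out


# ---------------------------------------------------------------------------
# compatibility machinery
# ---------------------------------------------------------------------------

def _pair_mask(geno, alleles: np.ndarray) -> np.ndarray:
    """(H, H) mask of ordered haplotype pairs matching a genotype tuple.

    ``geno`` may be ``None`` (parent absent: all pairs allowed) or a tuple
    with ``None``/-1 entries for sporadically missing SNPs.
    """
    H = len(alleles)
    if geno is None:
        return np.ones((H, H), dtype=bool)
    mask = np.ones((H, H), dtype=bool)
    for s, g in enumerate(geno):
        if g is None or g < 0:
            continue
        tot = alleles[:, s][:, None] + alleles[:, s][None, :]
        mask &= tot == g
    return mask


def compatible_haplo_configurations(unit: HaploFamily) -> list[tuple[tuple[int, ...], ...]]:
    """All ordered haplotype quadruples matching a family's observed dosages.

    Quadruples are (maternal non-transmitted, maternal transmitted,
    paternal non-transmitted, paternal transmitted), each as an
    effect-allele tuple.
    """
    k = unit.k
    A = _hap_alleles(k)
    M = _pair_mask(unit.mother, A)
    F = _pair_mask(unit.father, A)
    C = _pair_mask(unit.child, A)  # over (h_mt, h_ft)
    out = []
    for h2, h4 in np.argwhere(C):
        for h1 in np.flatnonzero(M[:, h2]):
            for h3 in np.flatnonzero(F[:, h4]):
                out.append((tuple(A[h1]), tuple(A[h2]), tuple(A[h3]), tuple(A[h4])))
    if not out:
        raise ValueError(f"family {unit.family_id}: inconsistent window genotypes")
    return out


# ---------------------------------------------------------------------------
# frequency EM (risk-free initialisation)
# ---------------------------------------------------------------------------

def haplotype_frequency_em(
    genotypes: Sequence[tuple],
    k: int,
    *,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[np.ndarray, list[float]]:
    """EM haplotype-frequency estimate from unphased multilocus genotypes.

    ``genotypes`` are per-SNP dosage tuples (``None``/-1 entries allowed)
    from approximately unrelated individuals — the window parents, each
    once.  Returns the ``2**k`` frequency vector and the log-likelihood
    trace (non-decreasing by EM monotonicity).
    """
    A = _hap_alleles(k)
    H = len(A)
    patterns: dict[tuple, int] = {}
    for g in genotypes:
        key = tuple(-1 if v is None else int(v) for v in g)
        patterns[key] = patterns.get(key, 0) + 1
    masks = [_pair_mask(key, A) for key in patterns]
    counts = np.array(list(patterns.values()), dtype=float)
    n = counts.sum()

    f = np.full(H, 1.0 / H)
    history: list[float] = []
    for _ in range(max_iter):
        expected = np.zeros(H)
        ll = 0.0
        for mask, c in zip(masks, counts):
            P = mask * np.outer(f, f)
            tot = P.sum()
            if tot <= 0:
                raise ValueError("genotype pattern incompatible with positive-frequency haplotypes")
            ll += c * np.log(tot)
            P /= tot
            expected += c * (P.sum(axis=1) + P.sum(axis=0))
        history.append(float(ll))
        f_new = expected / (2 * n)
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    return f, history


# ---------------------------------------------------------------------------
# the window model
# ---------------------------------------------------------------------------

class HaplotypeWindowModel:
    """Joint haplotype-frequency and parent-of-origin risk model for one window.

    Parameters
    ----------
    units
        Multi-SNP family units (see :class:`~triadpoo.simulate.HaploFamily`).
    reference
        ``"auto"`` picks the haplotype with the highest EM-estimated
        frequency; an explicit effect-allele tuple forces the contrast.
    rare_floor
        Haplotypes with initial frequency below this keep RRcm = RRcf = 1
        and are listed in ``rare_haplotypes`` (their frequency is still
        estimated).
    """

    _SUPPORT_FLOOR = 1e-6  # haplotypes below this after EM are removed entirely

    def __init__(
        self,
        units: Sequence[HaploFamily],
        *,
        reference: str | tuple[int, ...] = "auto",
        rare_floor: float = 0.01,
    ) -> None:
        if not units:
            raise ValueError("no family units supplied")
        self.k = units[0].k
        if self.k > MAX_WINDOW:
            raise ValueError(f"window size {self.k} exceeds the supported maximum {MAX_WINDOW}")
        A = self._A = _hap_alleles(self.k)
        H = self.H = len(A)

        patterns: dict[tuple, int] = {}
        for u in units:
            if u.k != self.k:
                raise ValueError("mixed window sizes in unit list")
            key = (
                None if u.mother is None else tuple(-1 if v is None else v for v in u.mother),
                None if u.father is None else tuple(-1 if v is None else v for v in u.father),
                tuple(u.child),
            )
            patterns[key] = patterns.get(key, 0) + 1
        # exclude genotype patterns with no compatible quadruple (inconsistencies)
        self.n_dropped = 0
        counts, keys, Mmasks, Fmasks, Cmasks = [], [], [], [], []
        for (m, fa, c), n in patterns.items():
            M, F, C = _pair_mask(m, A), _pair_mask(fa, A), _pair_mask(c, A)
            feasible = bool((C & np.outer(M.any(axis=0), F.any(axis=0))).any())
            if not feasible:
                self.n_dropped += n
                continue
            counts.append(n)
            keys.append((m, fa, c))
            Mmasks.append(M.astype(float))
            Fmasks.append(F.astype(float))
            Cmasks.append(C.astype(float))
        if not counts:
            raise ValueError("no consistent family units supplied")
        self.nobs = len(units) - self.n_dropped
        self._counts = np.array(counts, dtype=float)
        self._pattern_keys = keys
        self._Mmasks, self._Fmasks, self._Cmasks = Mmasks, Fmasks, Cmasks

        # risk-free EM initialisation on parents (each family's parents once)
        parent_genos = []
        seen = set()
        for u in units:
            if u.family_id in seen:
                continue
            seen.add(u.family_id)
            for g in (u.mother, u.father):
                if g is not None:
                    parent_genos.append(g)
        if not parent_genos:
            parent_genos = [u.child for u in units]
        freq_init, self.em_history = haplotype_frequency_em(parent_genos, self.k)

        support = np.flatnonzero(freq_init > self._SUPPORT_FLOOR)
        if len(support) < 2:
            raise ValueError("fewer than two haplotypes with non-negligible frequency")
        self.support = support
        if reference == "auto":
            ref = int(support[np.argmax(freq_init[support])])
        else:
            ref = int(np.flatnonzero((A == np.asarray(reference, dtype=np.int8)).all(axis=1))[0])
            if ref not in support:
                raise ValueError("requested reference haplotype has (near-)zero frequency")
        self.reference = ref
        self._free_freq = [h for h in support if h != ref]
        self.estimable = [h for h in self._free_freq if freq_init[h] >= rare_floor]
        self.rare_haplotypes = [tuple(A[h]) for h in self._free_freq if h not in self.estimable]
        self._freq_init = freq_init

        self.param_names = (
            [f"freq[{haplotype_label(tuple(A[h]))}]" for h in self._free_freq]
            + [f"rr_cm[{haplotype_label(tuple(A[h]))}]" for h in self.estimable]
            + [f"rr_cf[{haplotype_label(tuple(A[h]))}]" for h in self.estimable]
        )

    def _iter_patterns(self):
        """Distinct (mother, father, child) dosage patterns, aligned with counts."""
        return list(self._pattern_keys)

    # -- parameter transform ---------------------------------------------
    def _unpack(self, theta: np.ndarray):
        nf, ne = len(self._free_freq), len(self.estimable)
        eta = np.full(self.H, -np.inf)
        eta[self.reference] = 0.0
        eta[self._free_freq] = theta[:nf]
        ex = np.exp(eta - eta[np.isfinite(eta)].max())
        f = ex / ex.sum()
        rcm = np.ones(self.H)
        rcf = np.ones(self.H)
        rcm[self.estimable] = np.exp(theta[nf : nf + ne])
        rcf[self.estimable] = np.exp(theta[nf + ne :])
        return f, rcm, rcf

    def _theta0(self) -> np.ndarray:
        f = np.clip(self._freq_init, self._SUPPORT_FLOOR, None)
        eta = np.log(f[self._free_freq] / f[self.reference])
        return np.concatenate([eta, np.zeros(2 * len(self.estimable))])

    # -- likelihood and analytic gradient ---------------------------------
    def _loglike_theta(self, theta: np.ndarray) -> float:
        f, rcm, rcf = self._unpack(theta)
        z = (f @ rcm) * (f @ rcf)
        ll = -self._counts.sum() * np.log(z)
        for M, F, C, c in zip(self._Mmasks, self._Fmasks, self._Cmasks, self._counts):
            mv = (M.T @ f) * f * rcm  # over h_mt
            fv = (F.T @ f) * f * rcf  # over h_ft
            s = mv @ C @ fv
            if s <= 0:
                return -np.inf
            ll += c * np.log(s)
        return float(ll)

    def _score_theta(self, theta: np.ndarray) -> np.ndarray:
        f, rcm, rcf = self._unpack(theta)
        zm, zf = f @ rcm, f @ rcf
        n_tot = self._counts.sum()
        g_f = np.zeros(self.H)      # d ll / d f (before softmax chain rule)
        g_lcm = np.zeros(self.H)    # d ll / d log rcm
        g_lcf = np.zeros(self.H)
        for M, F, C, c in zip(self._Mmasks, self._Fmasks, self._Cmasks, self._counts):
            fm = M.T @ f
            ff = F.T @ f
            mv = fm * f * rcm
            fv = ff * f * rcf
            u = C @ fv      # over h_mt
            v = C.T @ mv    # over h_ft
            s = mv @ u
            w = c / s
            g_lcm += w * mv * u
            g_lcf += w * fv * v
            g_f += w * (M @ (f * rcm * u) + rcm * fm * u + F @ (f * rcf * v) + rcf * ff * v)
        g_f -= n_tot * (rcm / zm + rcf / zf)
        g_lcm -= n_tot * (f * rcm) / zm
        g_lcf -= n_tot * (f * rcf) / zf
        # softmax chain rule: d f / d eta_j = f_j (e_j - f)
        g_eta = f * (g_f - f @ g_f)
        return np.concatenate([g_eta[self._free_freq], g_lcm[self.estimable], g_lcf[self.estimable]])

    def _hessian_theta(self, theta: np.ndarray) -> np.ndarray:
        d = len(theta)
        H = np.empty((d, d))
        for j in range(d):
            h = 1e-5 * max(1.0, abs(theta[j]))
            e = np.zeros(d)
            e[j] = h
            H[:, j] = (self._score_theta(theta + e) - self._score_theta(theta - e)) / (2 * h)
        return (H + H.T) / 2.0

    # -- estimation -------------------------------------------------------
    def fit(self, gtol_per_family: float = 1e-8) -> "HaplotypeWindowResults":
        theta0 = self._theta0()
        gtol = gtol_per_family * max(1.0, self._counts.sum())
        res = optimize.minimize(
            lambda t: -self._loglike_theta(t),
            theta0,
            jac=lambda t: -self._score_theta(t),
            method="BFGS",
            options={"gtol": gtol, "maxiter": 1000},
        )
        theta = res.x
        nf = len(self._free_freq)
        grad_ok = np.max(np.abs(self._score_theta(theta))) <= 10 * gtol
        in_bounds = np.all(np.abs(theta[nf:]) <= MAX_ABS_LOG_RR)
        converged = bool((res.success or grad_ok) and in_bounds)
        cov = _safe_inverse(-self._hessian_theta(theta))
        return HaplotypeWindowResults(self, theta, cov, float(-res.fun), converged, int(res.nit))


class HaplotypeWindowResults:
    """Per-haplotype frequency and parent-of-origin risk estimates."""

    def __init__(self, model: HaplotypeWindowModel, theta, cov, llf, converged, n_iter):
        self.model = model
        self.theta = theta
        self.cov = cov
        self.llf = llf
        self.converged = converged
        self.n_iter = n_iter
        f, rcm, rcf = model._unpack(theta)
        self.freq = {tuple(model._A[h]): float(f[h]) for h in model.support}
        self.rr_cm = {tuple(model._A[h]): float(rcm[h]) for h in model.estimable}
        self.rr_cf = {tuple(model._A[h]): float(rcf[h]) for h in model.estimable}
        self.bse = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    @property
    def reference(self) -> tuple[int, ...]:
        return tuple(self.model._A[self.model.reference])

    def _rr_indices(self, hap: tuple[int, ...]) -> tuple[int, int]:
        m = self.model
        h = int(np.flatnonzero((m._A == np.asarray(hap, dtype=np.int8)).all(axis=1))[0])
        e = m.estimable.index(h)
        nf = len(m._free_freq)
        return nf + e, nf + len(m.estimable) + e

    def ratio_test(self, hap: tuple[int, ...], level: float = 0.95):
        """Wald test of RRcm(h)/RRcf(h) against the reference haplotype."""
        from .model import RatioResult

        if not self.converged:
            raise RuntimeError("fit did not converge; ratio test refused")
        i, j = self._rr_indices(hap)
        log_ratio = self.theta[i] - self.theta[j]
        var = self.cov[i, i] + self.cov[j, j] - 2 * self.cov[i, j]
        se = float(np.sqrt(max(var, 0.0)))
        z = log_ratio / se if se > 0 else np.inf
        zc = stats.norm.ppf(0.5 + level / 2)
        return RatioResult(
            ratio=float(np.exp(log_ratio)),
            ci_low=float(np.exp(log_ratio - zc * se)),
            ci_high=float(np.exp(log_ratio + zc * se)),
            p_value=float(2 * stats.norm.sf(abs(z))),
            se_log=se,
            z=float(z),
        )

    def summary(self, snps: Sequence[SnpRecord] | None = None) -> str:
        m = self.model
        lines = [
            f"Haplotype-window parent-of-origin model (k = {m.k}, {self.model.nobs} families)",
            f"  reference haplotype: {haplotype_label(self.reference, snps)}"
            f"  log-likelihood: {self.llf:.4f}  converged: {self.converged}",
            f"  {'haplotype':<12}{'freq':>8}{'rr_cm':>9}{'rr_cf':>9}{'ratio':>9}{'p(ratio)':>12}",
        ]
        for hap, fr in sorted(self.freq.items(), key=lambda kv: -kv[1]):
            lab = haplotype_label(hap, snps)
            if hap in self.rr_cm and self.converged:
                r = self.ratio_test(hap)
                lines.append(
                    f"  {lab:<12}{fr:>8.4f}{self.rr_cm[hap]:>9.4f}{self.rr_cf[hap]:>9.4f}"
                    f"{r.ratio:>9.4f}{r.p_value:>12.3E}"
                )
            else:
                tag = "ref" if hap == self.reference else "rare"
                lines.append(f"  {lab:<12}{fr:>8.4f}{tag:>9}")
        return "\n".join(lines)


def fit_window(
    units: Sequence[HaploFamily],
    *,
    reference: str | tuple[int, ...] = "auto",
    rare_floor: float = 0.01,
) -> HaplotypeWindowResults:
    """Fit the haplotype-window model; see :class:`HaplotypeWindowModel`."""
    return HaplotypeWindowModel(units, reference=reference, rare_floor=rare_floor).fit()
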