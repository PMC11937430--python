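"""Log-linear parent-of-origin model for case-parent triads and dyads.

The model
---------
For a biallelic SNP, order each case family's four parental alleles as
(maternal non-transmitted, maternal transmitted, paternal non-transmitted,
paternal transmitted).  Writing ``1`` where the slot carries the effect
allele gives 16 *transmission configurations*.  Under Hardy-Weinberg
parental genotypes, random mating and Mendelian transmission, each slot
is an independent Bernoulli(``p``) draw, and conditioning on the child
being a case under a multiplicative penetrance tilts the configuration
probabilities by

    RRcm ** (maternal transmitted allele)
    * RRcf ** (paternal transmitted allele)
    * RR* ** (both transmitted)            [fixed at 1 by default]
    * RRm ** (mother's dosage)             [maternal-effect extension]

The baseline risk and disease prevalence cancel in the normalisation
over the 16 cells, so the case families follow a multinomial whose free
parameters are the allele frequency and the relative risks.  Observed
triads pin the configuration up to the classic double-heterozygote
ambiguity; dyads leave the missing parent's two slots free, which is how
they are marginalised.

The parent-of-origin null (no imprinting-like effect) is RRcm = RRcf;
it is tested by a Wald test of log(RRcm/RRcf).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

from .families import FamilyUnit

__all__ = [
    "Configuration",
    "PooParams",
    "RatioResult",
    "TriadPooModel",
    "TriadPooResults",
    "enumerate_configurations",
    "config_weight",
    "compatible_configurations",
    "family_loglik",
    "posterior_config_weights",
    "fit_poo",
    "fit_maternal",
    "ratio_test",
]

MAX_ABS_LOG_RR = np.log(50.0)  # boundary-divergence detector


class Configuration(NamedTuple):
    """Ordered effect-allele indicators for the four parental allele slots."""

    m_nt: int
    m_t: int
    f_nt: int
    f_t: int

    @property
    def mother(self) -> int:
        return self.m_nt + self.m_t

    @property
    def father(self) -> int:
        return self.f_nt + self.f_t

    @property
    def child(self) -> int:
        return self.m_t + self.f_t


# all 16 configurations, lexicographic in (m_nt, m_t, f_nt, f_t)
_CONF = np.array([[(i >> 3) & 1, (i >> 2) & 1, (i >> 1) & 1, i & 1] for i in range(16)])
_N_EFF = _CONF.sum(axis=1)
_M_T = _CONF[:, 1]
_F_T = _CONF[:, 3]
_BOTH_T = _M_T * _F_T
_MOTHER = _CONF[:, 0] + _CONF[:, 1]
_FATHER = _CONF[:, 2] + _CONF[:, 3]
_CHILD = _CONF[:, 1] + _CONF[:, 3]


def enumerate_configurations() -> list[Configuration]:
    """All 16 transmission configurations in their documented (lexicographic) order."""
    return [Configuration(*(int(v) for v in row)) for row in _CONF]


@dataclass(frozen=True)
class PooParams:
    """Allele frequency and relative risks of the parent-of-origin model.

    ``rr_m`` is ``None`` unless the maternal-genotype extension is active.
    The baseline risk and prevalence are not parameters: they are absorbed
    by the case-family normalisation and unidentifiable from case-only data.
    """

    p: float
    rr_cm: float = 1.0
    rr_cf: float = 1.0
    rr_star: float = 1.0
    rr_m: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"allele frequency must be interior to (0, 1); got {self.p}")
        for name in ("rr_cm", "rr_cf", "rr_star"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.rr_m is not None and self.rr_m <= 0:
            raise ValueError("rr_m must be strictly positive")


def _weights(params: PooParams) -> np.ndarray:
    """Unnormalised weights of the 16 configurations under ``params``."""
    p = params.p
    w = p**_N_EFF * (1 - p) ** (4 - _N_EFF)
    w = w * params.rr_cm**_M_T * params.rr_cf**_F_T * params.rr_star**_BOTH_T
    if params.rr_m is not None:
        w = w * params.rr_m**_MOTHER
    return w


def config_weight(config: Configuration, params: PooParams) -> float:
    """Unnormalised multinomial weight of one configuration."""
    i = config.m_nt * 8 + config.m_t * 4 + config.f_nt * 2 + config.f_t
    return float(_weights(params)[i])


def _compat_mask(mother: int | None, father: int | None, child: int) -> np.ndarray:
    mask = _CHILD == child
    if mother is not None:
        mask = mask & (_MOTHER == mother)
    if father is not None:
        mask = mask & (_FATHER == father)
    return mask


def compatible_configurations(unit: FamilyUnit) -> list[Configuration]:
    """Configurations whose implied genotypes match the observed dosages.

    A missing parent leaves its two slots unconstrained, which is exactly
    the marginalisation the dyad likelihood needs.
    """
    mask = _compat_mask(unit.mother, unit.father, unit.child)
    configs = [Configuration(*(int(v) for v in row)) for row in _CONF[mask]]
    if not configs:
        raise ValueError(f"family {unit.family_id}: Mendelian-inconsistent dosages")
    return configs


def family_loglik(unit: FamilyUnit, params: PooParams) -> float:
    """Log-probability of one family's observed dosages given ``params``."""
    w = _weights(params)
    num = w[_compat_mask(unit.mother, unit.father, unit.child)].sum()
    if num <= 0:
        raise ValueError(f"family {unit.family_id}: Mendelian-inconsistent dosages")
    return float(np.log(num) - np.log(w.sum()))


def posterior_config_weights(unit: FamilyUnit, params: PooParams) -> tuple[list[Configuration], np.ndarray]:
    """Posterior distribution over a family's compatible configurations."""
    configs = compatible_configurations(unit)
    w = _weights(params)
    mask = _compat_mask(unit.mother, unit.father, unit.child)
    post = w[mask] / w[mask].sum()
    return configs, post


@dataclass(frozen=True)
class RatioResult:
    """Wald inference for the parent-of-origin ratio RRcm / RRcf."""

    ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    se_log: float
    z: float


class TriadPooModel:
    """Maximum-likelihood parent-of-origin model for one SNP.

    Parameters
    ----------
    units
        Case-family units at one SNP (triads and/or dyads).
    maternal
        Add the maternal-genotype relative risk ``rr_m`` (one multiplicative
        factor per effect-allele copy carried by the mother).
    fix_rr_star
        Keep the double-dose term at 1 (the multiplicative dose-response
        model, the default); ``False`` frees it.

    The likelihood is maximised on an unconstrained scale
    (logit ``p``, log relative risks) by quasi-Newton iteration with an
    analytic gradient; standard errors come from the inverse numerical
    Hessian (central differences of the gradient) at the optimum.
    """

    def __init__(
        self,
        units: Sequence[FamilyUnit],
        *,
        maternal: bool = False,
        fix_rr_star: bool = True,
        fix_rr_m: bool = False,
    ) -> None:
        if not units:
            raise ValueError("no family units supplied")
        self.maternal = maternal and not fix_rr_m
        self.fix_rr_star = fix_rr_star
        self.param_names = ["p", "rr_cm", "rr_cf"]
        if not fix_rr_star:
            self.param_names.append("rr_star")
        if self.maternal:
            self.param_names.append("rr_m")
        self.nobs = len(units)
        self.n_triads = sum(u.family_type == "triad" for u in units)
        self.n_mother_dyads = sum(u.family_type == "mother_dyad" for u in units)
        self.n_father_dyads = sum(u.family_type == "father_dyad" for u in units)

        # aggregate into distinct (mother, father, child) patterns
        patterns: dict[tuple[int, int, int], int] = {}
        for u in units:
            key = (-1 if u.mother is None else u.mother, -1 if u.father is None else u.father, u.child)
            patterns[key] = patterns.get(key, 0) + 1
        self._counts = np.array(list(patterns.values()), dtype=float)
        self._mask = np.array(
            [
                _compat_mask(None if m < 0 else m, None if f < 0 else f, c)
                for (m, f, c) in patterns
            ],
            dtype=float,
        )
        if np.any(self._mask.sum(axis=1) == 0):
            bad = [k for k, msk in zip(patterns, self._mask) if msk.sum() == 0]
            raise ValueError(f"Mendelian-inconsistent genotype patterns: {bad}")
        # naive allele-frequency start from all observed genotypes
        tot = copies = 0
        for (m, f, c), n in patterns.items():
            for g in (m, f, c):
                if g >= 0:
                    tot += 2 * n
                    copies += g * n
        self._p_start = float(np.clip(copies / max(tot, 1), 0.05, 0.95))

    # -- parameterisation -------------------------------------------------
    def _unpack(self, theta: np.ndarray) -> PooParams:
        p = float(expit(theta[0]))
        rr = np.exp(theta[1:])
        k = 0
        rr_cm, rr_cf = float(rr[k]), float(rr[k + 1])
        k += 2
        rr_star = 1.0
        if not self.fix_rr_star:
            rr_star = float(rr[k])
            k += 1
        rr_m = float(rr[k]) if self.maternal else None
        return PooParams(p, rr_cm, rr_cf, rr_star, rr_m)

    def _pack(self, params: PooParams) -> np.ndarray:
        theta = [logit(params.p), np.log(params.rr_cm), np.log(params.rr_cf)]
        if not self.fix_rr_star:
            theta.append(np.log(params.rr_star))
        if self.maternal:
            theta.append(np.log(params.rr_m if params.rr_m is not None else 1.0))
        return np.array(theta)

    # -- likelihood -------------------------------------------------------
    def loglike(self, params: PooParams) -> float:
        """Observed-data log-likelihood at ``params``."""
        return self._loglike_theta(self._pack(params))

    def _loglike_theta(self, theta: np.ndarray) -> float:
        w = _weights(self._unpack(theta))
        num = self._mask @ w
        return float(self._counts @ np.log(num) - self._counts.sum() * np.log(w.sum()))

    def _score_theta(self, theta: np.ndarray) -> np.ndarray:
        params = self._unpack(theta)
        w = _weights(params)
        # d log w / d theta_j per configuration
        x_cols = [_N_EFF - 4.0 * params.p, _M_T.astype(float), _F_T.astype(float)]
        if not self.fix_rr_star:
            x_cols.append(_BOTH_T.astype(float))
        if self.maternal:
            x_cols.append(_MOTHER.astype(float))
        X = np.column_stack(x_cols)  # (16, d)
        num = self._mask @ w
        g_num = (self._mask * w) @ X  # (n_pat, d)
        grad = (self._counts / num) @ g_num
        grad -= self._counts.sum() * (w @ X) / w.sum()
        return grad

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
    def fit(self, start: PooParams | None = None, gtol_per_family: float = 1e-8) -> "TriadPooResults":
        if start is not None:
            theta0 = self._pack(start)
        else:
            theta0 = np.zeros(len(self.param_names))
            theta0[0] = logit(self._p_start)
        gtol = gtol_per_family * max(1.0, self._counts.sum())
        res = optimize.minimize(
            lambda t: -self._loglike_theta(t),
            theta0,
            jac=lambda t: -self._score_theta(t),
            method="BFGS",
            options={"gtol": gtol, "maxiter": 500},
        )
        theta = res.x
        grad_ok = np.max(np.abs(self._score_theta(theta))) <= 10 * gtol
        in_bounds = np.all(np.abs(theta[1:]) <= MAX_ABS_LOG_RR)
        converged = bool((res.success or grad_ok) and in_bounds)
        H = self._hessian_theta(theta)
        cov = _safe_inverse(-H)
        return TriadPooResults(
            model=self,
            theta=theta,
            cov=cov,
            llf=float(-res.fun),
            converged=converged,
            n_iter=int(res.nit),
        )


def _safe_inverse(A: np.ndarray) -> np.ndarray:
    try:
        cov = np.linalg.inv(A)
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
            raise np.linalg.LinAlgError
        return cov
    except np.linalg.LinAlgError:
        return np.linalg.pinv((A + A.T) / 2.0)


class TriadPooResults:
    """Fitted parent-of-origin model: estimates, uncertainty, diagnostics.

    Estimates live on the unconstrained scale internally (logit allele
    frequency, log relative risks); public accessors report the natural
    scale with exp/expit-transformed Wald intervals.
    """

    def __init__(self, model: TriadPooModel, theta: np.ndarray, cov: np.ndarray,
                 llf: float, converged: bool, n_iter: int) -> None:
        self.model = model
        self.theta = theta
        self.cov = cov
        self.llf = llf
        self.converged = converged
        self.n_iter = n_iter
        self.param_names = model.param_names
        self.bse = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    @property
    def params(self) -> PooParams:
        return self.model._unpack(self.theta)

    @property
    def pvalues(self) -> dict[str, float]:
        """Two-sided Wald p-values for the log relative risks (null: RR = 1)."""
        out = {}
        for j, name in enumerate(self.param_names):
            if name == "p":
                continue
            se = self.bse[j]
            z = self.theta[j] / se if se > 0 else np.inf
            out[name] = float(2 * stats.norm.sf(abs(z)))
        return out

    def conf_int(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        """Natural-scale Wald confidence intervals."""
        z = stats.norm.ppf(0.5 + level / 2)
        out = {}
        for j, name in enumerate(self.param_names):
            lo, hi = self.theta[j] - z * self.bse[j], self.theta[j] + z * self.bse[j]
            tf = expit if name == "p" else np.exp
            out[name] = (float(tf(lo)), float(tf(hi)))
        return out

    def ratio_test(self, level: float = 0.95) -> RatioResult:
        """Wald test of the parent-of-origin ratio RRcm / RRcf."""
        if not self.converged:
            raise RuntimeError("fit did not converge; ratio test refused")
        i, j = self.param_names.index("rr_cm"), self.param_names.index("rr_cf")
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

    def summary(self, level: float = 0.95) -> str:
        """Plain-text summary table of the fit."""
        params = self.params
        values = {"p": params.p, "rr_cm": params.rr_cm, "rr_cf": params.rr_cf,
                  "rr_star": params.rr_star, "rr_m": params.rr_m}
        ci = self.conf_int(level)
        pv = self.pvalues
        lines = [
            "Parent-of-origin log-linear model",
            f"  families: {self.model.n_triads} triads, {self.model.n_mother_dyads} mother dyads, "
            f"{self.model.n_father_dyads} father dyads",
            f"  log-likelihood: {self.llf:.4f}   converged: {self.converged}",
            "",
            f"  {'param':<8}{'estimate':>10}{'se(log)':>10}{'ci_low':>10}{'ci_high':>10}{'p':>12}",
        ]
        for j, name in enumerate(self.param_names):
            lo, hi = ci[name]
            p_str = f"{pv[name]:.3E}" if name in pv else ""
            lines.append(
                f"  {name:<8}{values[name]:>10.4f}{self.bse[j]:>10.4f}{lo:>10.4f}{hi:>10.4f}{p_str:>12}"
            )
        if self.converged:
            r = self.ratio_test(level)
            lines += [
                "",
                f"  RRcm/RRcf = {r.ratio:.4f}  ({r.ci_low:.4f}, {r.ci_high:.4f})  p = {r.p_value:.3E}",
            ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_poo(units: Sequence[FamilyUnit], *, fix_rr_star: bool = True,
            maternal: bool = False, start: PooParams | None = None) -> TriadPooResults:
    """Fit the parent-of-origin model; see :class:`TriadPooModel`."""
    return TriadPooModel(units, maternal=maternal, fix_rr_star=fix_rr_star).fit(start=start)


def fit_maternal(units: Sequence[FamilyUnit], *, fix_rr_star: bool = True,
                 fix_rr_m: bool = False) -> TriadPooResults:
    """Fit the maternal-genotype extension (joint rr_m with the PoO risks)."""
    return TriadPooModel(units, maternal=True, fix_rr_star=fix_rr_star, fix_rr_m=fix_rr_m).fit()


def ratio_test(fit: TriadPooResults, level: float = 0.95) -> RatioResult:
    """Wald test of RRcm / RRcf from a fitted model."""
    return fit.ratio_test(level)
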