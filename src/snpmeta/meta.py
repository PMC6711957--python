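"""Fixed-effect and DerSimonian–Laird random-effects pooling with heterogeneity.

Studies enter as (AE_i, seAE_i) pairs.  The fixed-effect estimate weights by
inverse within-study variance; the random-effects estimate adds the
moment-based between-study variance tau^2 (DerSimonian–Laird) to every
study's variance before weighting.  Heterogeneity is summarised by Cochran's
Q and Higgins's I^2 = 100 * max(0, (Q - df) / Q).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .effects import EffectEstimate, Z_95


class MetaError(ValueError):
    pass


@dataclass(frozen=True)
class MetaResult:
    """Pooled result for one SNP in one population stratum."""

    snp_id: str
    population: str           # All | Asian | Caucasian
    k: int
    pooled_ae_fixed: float
    se_fixed: float
    p_fixed: float
    pooled_ae_random: float
    se_random: float
    p_random: float
    q_stat: float
    i2: float                 # per cent, in [0, 100)
    tau2: float
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None
    degenerate: bool = False  # k == 1: the single study's estimate, not a pool

    @property
    def or_random(self) -> float:
        return math.exp(self.pooled_ae_random)

    @property
    def ci_random(self) -> tuple[float, float]:
        lo = math.exp(self.pooled_ae_random - Z_95 * self.se_random)
        hi = math.exp(self.pooled_ae_random + Z_95 * self.se_random)
        return lo, hi

    @property
    def or_fixed(self) -> float:
        return math.exp(self.pooled_ae_fixed)

    @property
    def ci_fixed(self) -> tuple[float, float]:
        lo = math.exp(self.pooled_ae_fixed - Z_95 * self.se_fixed)
        hi = math.exp(self.pooled_ae_fixed + Z_95 * self.se_fixed)
        return lo, hi


def _check(ae: np.ndarray, se: np.ndarray) -> None:
    if ae.size != se.size or ae.size == 0:
        raise MetaError("need equal-length, non-empty ae and se arrays")
    if np.any(se <= 0) or not np.all(np.isfinite(se)) or not np.all(np.isfinite(ae)):
        raise MetaError("all standard errors must be positive and finite")


def two_sided_p(z: float) -> float:
    return float(2 * stats.norm.sf(abs(z)))


def fixed_effects_meta(ae: Sequence[float], se: Sequence[float]) -> tuple[float, float, float]:
    """Inverse-variance fixed-effect pool: (pooled ae, pooled se, two-sided p)."""
    ae = np.asarray(ae, dtype=float)
    se = np.asarray(se, dtype=float)
    _check(ae, se)
    w = 1.0 / se**2
    pooled = float(np.sum(w * ae) / np.sum(w))
    pooled_se = float(1.0 / math.sqrt(np.sum(w)))
    return pooled, pooled_se, two_sided_p(pooled / pooled_se)


def heterogeneity(q_stat: float, k: int) -> float:
    """Higgins's I^2 (per cent) from Cochran's Q with k - 1 degrees of freedom."""
    if k < 2:
        raise MetaError("heterogeneity needs at least two studies")
    if q_stat <= 0:
        return 0.0
    return max(0.0, (q_stat - (k - 1)) / q_stat) * 100.0


def dl_tau2(ae: Sequence[float], se: Sequence[float]) -> tuple[float, float]:
    """DerSimonian–Laird moment estimate: returns (Q, tau^2)."""
    ae = np.asarray(ae, dtype=float)
    se = np.asarray(se, dtype=float)
    _check(ae, se)
    k = ae.size
    w = 1.0 / se**2
    pooled_fixed = np.sum(w * ae) / np.sum(w)
    q = float(np.sum(w * (ae - pooled_fixed) ** 2))
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    return q, tau2


def dersimonian_laird_meta(
    estimates: Sequence[EffectEstimate],
    *, snp_id: str = "", population: str = "All",
) -> MetaResult:
    """Pool a set of per-study effects under fixed and DL random-effects models.

    A single study is returned as-is, flagged ``degenerate``; pooling proper
    requires k >= 2.
    """
    ests = list(estimates)
    if not ests:
        raise MetaError("no estimates to pool")
    snp = snp_id or ests[0].snp_id
    n_cases = sum(e.k_cases for e in ests if e.k_cases is not None) or None
    n_controls = sum(e.k_controls for e in ests if e.k_controls is not None) or None
    ae = np.array([e.ae for e in ests])
    se = np.array([e.se_ae for e in ests])
    if len(ests) == 1:
        p1 = two_sided_p(float(ae[0] / se[0]))
        return MetaResult(
            snp_id=snp, population=population, k=1,
            pooled_ae_fixed=float(ae[0]), se_fixed=float(se[0]), p_fixed=p1,
            pooled_ae_random=float(ae[0]), se_random=float(se[0]), p_random=p1,
            q_stat=0.0, i2=0.0, tau2=0.0,
            n_cases=n_cases, n_controls=n_controls, degenerate=True,
        )
    pooled_f, se_f, p_f = fixed_effects_meta(ae, se)
    q, tau2 = dl_tau2(ae, se)
    w_star = 1.0 / (se**2 + tau2)
    pooled_r = float(np.sum(w_star * ae) / np.sum(w_star))
    se_r = float(1.0 / math.sqrt(np.sum(w_star)))
    return MetaResult(
        snp_id=snp, population=population, k=len(ests),
        pooled_ae_fixed=pooled_f, se_fixed=se_f, p_fixed=p_f,
        pooled_ae_random=pooled_r, se_random=se_r,
        p_random=two_sided_p(pooled_r / se_r),
        q_stat=q, i2=heterogeneity(q, len(ests)), tau2=tau2,
        n_cases=n_cases, n_controls=n_controls,
    )


def meta_by_stratum(
    estimates: Sequence[EffectEstimate],
    *, snp_id: str = "", min_studies: int = 4,
) -> dict[str, MetaResult | None]:
    """Pool one SNP's studies overall and within Asian/Caucasian strata.

    The "All" stratum takes every study regardless of ancestry.  Strata with
    fewer than ``min_studies`` usable studies are reported as ``None``
    (ineligible) rather than pooled.
    """
    ests = list(estimates)
    out: dict[str, MetaResult | None] = {}
    groups = {
        "All": ests,
        "Asian": [e for e in ests if e.ancestry == "Asian"],
        "Caucasian": [e for e in ests if e.ancestry == "Caucasian"],
    }
    for population, members in groups.items():
        if len(members) >= min_studies:
            out[population] = dersimonian_laird_meta(
                members, snp_id=snp_id, population=population)
        else:
            out[population] = None
    return out
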