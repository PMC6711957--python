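"""Small-study effects: Harbord's score-based asymmetry test and trim-and-fill.

Funnel-plot asymmetry in binary-outcome meta-analyses is tested with
Harbord's modified regression: per study, the efficient score of the log OR
Z_i = a_i - E[a_i | margins] and its hypergeometric variance V_i are computed
from the allele 2x2 table, and Z_i/sqrt(V_i) is regressed on sqrt(V_i); a
non-zero intercept indicates bias.  Studies reporting only summary statistics
have no 2x2 table; when fewer than the gating number of studies carry tables
the test falls back to an Egger-style regression of the standard normal
deviate ae_i/se_i on precision 1/se_i.

When asymmetry is detected, the Duval–Tweedie trim-and-fill procedure (L0
estimator by default) estimates the number of suppressed studies, fills in
their mirror images and re-pools under DerSimonian–Laird.  Both tests are
only applied to SNPs with at least ``bias_min_k`` studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .effects import EffectEstimate
from .meta import MetaResult, dersimonian_laird_meta, fixed_effects_meta


@dataclass(frozen=True)
class HarbordResult:
    intercept: float
    se: float
    p: float
    k: int
    method: str  # "harbord" or "egger_fallback"

    @property
    def biased(self) -> bool:
        return self.p < 0.05


@dataclass(frozen=True)
class TrimFillResult:
    k0: int                    # imputed (filled) studies
    side: str                  # "left" or "right": where studies were missing
    adjusted: MetaResult       # DL random effects on the filled set
    filled_ae: tuple[float, ...]
    filled_se: tuple[float, ...]
    converged: bool


@dataclass(frozen=True)
class BiasAssessment:
    snp_id: str
    population: str
    applicable: bool           # k >= bias_min_k
    k: int
    harbord: Optional[HarbordResult] = None
    trimfill: Optional[TrimFillResult] = None
    funnel: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.applicable and self.harbord is not None:
            raise ValueError("inapplicable assessments carry no test statistics")


def _score_and_variance(table: tuple[float, float, float, float]) -> tuple[float, float]:
    """Efficient score Z = a - E[a|margins] and hypergeometric variance V
    of the log OR, from the allele 2x2 table (case_a, case_b, ctrl_a, ctrl_b)."""
    a, b, c, d = table
    n1, n0 = a + b, c + d
    m1, m0 = a + c, b + d
    n = n1 + n0
    if n <= 1 or m1 == 0 or m0 == 0:
        raise ValueError("degenerate 2x2 table")
    z = a - n1 * m1 / n
    v = n1 * n0 * m1 * m0 / (n**2 * (n - 1))
    return z, v


def _intercept_regression(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """OLS of y on x with intercept; returns (alpha, se_alpha, two-sided p, df=k-2)."""
    k = y.size
    X = np.column_stack([np.ones(k), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = k - 2
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(X.T @ X)
    alpha, se_alpha = float(coef[0]), float(math.sqrt(cov[0, 0]))
    p = 2 * stats.t.sf(abs(alpha / se_alpha), df)
    return alpha, se_alpha, float(p)


def harbord_test(
    estimates: Sequence[EffectEstimate], *, config: PipelineConfig | None = None,
) -> HarbordResult:
    """Harbord's asymmetry test; Egger fallback when too few 2x2 tables exist."""
    cfg = config or PipelineConfig()
    ests = list(estimates)
    if len(ests) < cfg.bias_min_k:
        raise ValueError(
            f"asymmetry test needs at least {cfg.bias_min_k} studies, got {len(ests)}")
    with_tables = [e for e in ests if e.table is not None]
    if len(with_tables) >= cfg.bias_min_k:
        zs, vs = zip(*(_score_and_variance(e.table) for e in with_tables))
        sv = np.sqrt(np.asarray(vs))
        alpha, se, p = _intercept_regression(np.asarray(zs) / sv, sv)
        return HarbordResult(intercept=alpha, se=se, p=p, k=len(with_tables),
                             method="harbord")
    ae = np.array([e.ae for e in ests])
    se_arr = np.array([e.se_ae for e in ests])
    alpha, se, p = _intercept_regression(ae / se_arr, 1.0 / se_arr)
    return HarbordResult(intercept=alpha, se=se, p=p, k=len(ests),
                         method="egger_fallback")


def _estimate_k0(centered: np.ndarray, estimator: str) -> int:
    """Missing-study count from the signed ranks of centered effects.

    L0 = (4*Sr - n(n+1)) / (2n - 1), R0 = gamma* - 1 where gamma* is the
    length of the run of rightmost ranks with positive sign (Duval–Tweedie).
    """
    n = centered.size
    ranks = stats.rankdata(np.abs(centered))
    if estimator == "L0":
        sr = float(ranks[centered > 0].sum())
        return max(0, int(round((4 * sr - n * (n + 1)) / (2 * n - 1))))
    # R0: count the unbroken run of the largest |centered| values that are positive
    order = np.argsort(-np.abs(centered))
    run = 0
    for idx in order:
        if centered[idx] > 0:
            run += 1
        else:
            break
    return max(0, run - 1)


def trim_and_fill(
    estimates: Sequence[EffectEstimate],
    *, side: str | None = None, config: PipelineConfig | None = None,
    population: str = "All",
) -> TrimFillResult:
    """Duval–Tweedie trim-and-fill on the log-OR scale.

    Iteratively: pool the untrimmed studies (fixed effect), centre all effects
    at that pool, estimate the number of asymmetric extreme studies k0 from
    signed ranks, trim the k0 most extreme on the excess side, and repeat
    until k0 stabilises.  Finally the k0 trimmed studies are mirrored about
    the last centre, appended as pseudo-studies, and the full filled set is
    pooled under DL random effects.  ``side`` names where studies are
    *missing* ("left" = suppressed negative effects); when None it is chosen
    by the sign of the rank-based asymmetry at the first iteration.
    """
    cfg = config or PipelineConfig()
    ests = list(estimates)
    ae = np.array([e.ae for e in ests])
    se = np.array([e.se_ae for e in ests])
    k = ae.size
    if k < 3:
        raise ValueError("trim-and-fill needs at least three studies")

    if side is None:
        mu0, *_ = fixed_effects_meta(ae, se)
        # excess on the side with the larger rank mass -> missing on the other
        sr_pos = float(stats.rankdata(np.abs(ae - mu0))[(ae - mu0) > 0].sum())
        sr_neg = float(stats.rankdata(np.abs(ae - mu0))[(ae - mu0) < 0].sum())
        side = "left" if sr_pos >= sr_neg else "right"
    sign = 1.0 if side == "left" else -1.0
    y = sign * ae  # excess now on the positive side

    k0, converged = 0, False
    mu = 0.0
    for _ in range(cfg.trimfill_max_iter):
        keep = np.argsort(-y)[k0:] if k0 else np.arange(k)
        mu, *_ = fixed_effects_meta(y[keep], se[keep])
        k0_new = min(_estimate_k0(y - mu, cfg.trimfill_estimator), k - 1)
        if k0_new == k0:
            converged = True
            break
        k0 = k0_new

    if k0 == 0:
        adjusted = dersimonian_laird_meta(ests, population=population)
        return TrimFillResult(k0=0, side=side, adjusted=adjusted,
                              filled_ae=(), filled_se=(), converged=converged)

    extreme = np.argsort(-y)[:k0]
    filled_y = 2 * mu - y[extreme]
    filled_ae = tuple(float(v) for v in sign * filled_y)
    filled_se = tuple(float(v) for v in se[extreme])
    snp = ests[0].snp_id
    pseudo = [
        EffectEstimate(snp_id=snp, study_id=f"__filled_{i}", ae=a, se_ae=s,
                       route=ests[0].route)
        for i, (a, s) in enumerate(zip(filled_ae, filled_se))
    ]
    adjusted = dersimonian_laird_meta(ests + pseudo, snp_id=snp, population=population)
    return TrimFillResult(k0=k0, side=side, adjusted=adjusted,
                          filled_ae=filled_ae, filled_se=filled_se,
                          converged=converged)


def funnel_data(estimates: Sequence[EffectEstimate]) -> list[tuple[float, float]]:
    """(ae, se) coordinates for a funnel plot; rendering is left to callers."""
    return [(e.ae, e.se_ae) for e in estimates]


def assess_bias(
    estimates: Sequence[EffectEstimate],
    *, population: str = "All", config: PipelineConfig | None = None,
) -> BiasAssessment:
    """Gatekept bias assessment for one SNP stratum.

    Below ``bias_min_k`` studies the assessment is marked inapplicable.
    Trim-and-fill runs only when the Harbord test signals bias at
    ``bias_alpha``, trimming on the side opposite the detected suppression.
    """
    cfg = config or PipelineConfig()
    ests = list(estimates)
    snp = ests[0].snp_id if ests else ""
    if len(ests) < cfg.bias_min_k:
        return BiasAssessment(snp_id=snp, population=population, applicable=False,
                              k=len(ests), funnel=tuple(funnel_data(ests)))
    hb = harbord_test(ests, config=cfg)
    tf = None
    if hb.p < cfg.bias_alpha:
        side = "left" if hb.intercept > 0 else "right"
        tf = trim_and_fill(ests, side=side, config=cfg, population=population)
    return BiasAssessment(snp_id=snp, population=population, applicable=True,
                          k=len(ests), harbord=hb, trimfill=tf,
                          funnel=tuple(funnel_data(ests)))
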