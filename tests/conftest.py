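"""Shared fixtures and independent brute-force oracles.

The oracles re-derive pooled quantities with plain Python loops, independent
of the vectorised implementation they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from snpmeta.effects import EffectEstimate


def make_estimate(ae: float, se: float, study_id: str = "s", snp_id: str = "rs1",
                  ancestry: str = "Asian", table=None) -> EffectEstimate:
    return EffectEstimate(snp_id=snp_id, study_id=study_id, ae=ae, se_ae=se,
                          route="allele_counts", ancestry=ancestry, table=table)


def brute_fixed(ae, se):
    """Fixed-effect pool by direct formula evaluation."""
    w = [1.0 / s**2 for s in se]
    pooled = sum(wi * a for wi, a in zip(w, ae)) / sum(w)
    return pooled, math.sqrt(1.0 / sum(w))


def brute_dl(ae, se):
    """DerSimonian–Laird by direct formula evaluation: returns
    (Q, tau2, pooled_random, se_random)."""
    k = len(ae)
    w = [1.0 / s**2 for s in se]
    mu_f = sum(wi * a for wi, a in zip(w, ae)) / sum(w)
    q = sum(wi * (a - mu_f) ** 2 for wi, a in zip(w, ae))
    c = sum(w) - sum(wi**2 for wi in w) / sum(w)
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    ws = [1.0 / (s**2 + tau2) for s in se]
    mu_r = sum(wi * a for wi, a in zip(ws, ae)) / sum(ws)
    return q, tau2, mu_r, math.sqrt(1.0 / sum(ws))


def brute_hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """HWE exact p by full enumeration of heterozygote configurations."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n - n_a
    support = range(min(n_a, n_b) % 2, min(n_a, n_b) + 1, 2)
    probs = {}
    for h in support:
        aa, bb = (n_a - h) // 2, (n_b - h) // 2
        probs[h] = (2.0**h * math.factorial(n)
                    / (math.factorial(aa) * math.factorial(h) * math.factorial(bb)))
    total = sum(probs.values())
    obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-12)) / total


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def homogeneous_five():
    """Five identical studies: every diagnostic must be exactly null."""
    return [make_estimate(0.2, 0.1, study_id=f"s{i}") for i in range(5)]
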