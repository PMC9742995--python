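"""Shared fixtures: random feasible parameter sets and bisection oracles.

The bisection oracles re-solve the two elemental balances directly from
the constitutive quota relations, independently of the closed-form
quadratic/cubic roots, so algebra errors in the budget coefficients would
show up as oracle disagreement.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from phytoalloc import CfmParams
from phytoalloc.cfm import (
    c_limited_growth,
    check_feasible,
    chlorophyll_quota,
    protein_quota,
    rna_quota,
)
from phytoalloc.errors import InfeasibleParametersError

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def random_feasible_params(rng: np.random.Generator) -> CfmParams:
    """Draw a feasible parameter set by jittering the defaults."""
    base = CfmParams()

    def jitter(v: float, sd: float = 0.3) -> float:
        return v * float(rng.lognormal(0.0, sd))

    while True:
        try:
            p = CfmParams(
                P_max_chl=jitter(base.P_max_chl),
                O_I=jitter(base.O_I),
                I=float(rng.uniform(50.0, 500.0)),
                E=float(rng.uniform(0.05, 0.5)),
                m=jitter(base.m),
                A_pho=jitter(base.A_pho),
                A_plip=jitter(base.A_plip),
                k_bio=jitter(base.k_bio),
                Q_pro_ess_C=jitter(base.Q_pro_ess_C),
                A_rna=jitter(base.A_rna),
                Q_rna_min_C=jitter(base.Q_rna_min_C),
                Q_dna_C=jitter(base.Q_dna_C),
                Q_oth_C=jitter(base.Q_oth_C),
                A_N=jitter(base.A_N),
            )
            p = p.replace(r_bio_pho=p.A_pho / p.k_bio)
            check_feasible(p)
            c_limited_growth(p)
            return p
        except InfeasibleParametersError:
            continue


@pytest.fixture
def feasible_params_batch():
    """100 seeded feasible parameter sets (same draw every run)."""
    rng = np.random.default_rng(240853)
    return [random_feasible_params(rng) for _ in range(100)]


def c_budget_residual(mu: float, p: CfmParams) -> float:
    """1 minus the sum of non-storage C pools, from the quota relations."""
    chl = chlorophyll_quota(mu, p)
    pro = protein_quota(mu, p)[0]
    rna = rna_quota(mu, pro, p)
    return 1.0 - (pro + rna + p.Q_dna_C + chl + p.A_plip * chl
                  + p.Q_nsto_C + p.Q_oth_C)


def n_quota_direct(mu: float, p: CfmParams) -> float:
    """Total N quota from the quota relations and stoichiometry (no storage)."""
    chl = chlorophyll_quota(mu, p)
    pro = protein_quota(mu, p)[0]
    rna = rna_quota(mu, pro, p)
    return (p.Y_pro_NC * pro + p.Y_rna_NC * rna + p.Y_dna_NC * p.Q_dna_C
            + p.Y_chl_NC * chl)


def bisect_root(f, lo: float, hi: float, tol: float = 1e-13,
                max_iter: int = 200) -> float:
    """Plain bisection on a sign change of f over [lo, hi]."""
    flo, fhi = f(lo), f(hi)
    assert flo * fhi <= 0, "no sign change in bracket"
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if hi - lo < tol:
            return mid
        if flo * fm <= 0:
            hi, fhi = mid, fm
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


def bisect_c_limited(p: CfmParams) -> float:
    """C-limited growth rate by bisection on the C-budget residual."""
    hi = 1.0
    while c_budget_residual(hi, p) > 0:
        hi *= 2.0
    return bisect_root(lambda mu: c_budget_residual(mu, p), 0.0, hi)


def bisect_n_limited(p: CfmParams, no3: float) -> float:
    """N-limited growth rate by bisection on the steady-state N balance."""
    if no3 == 0.0:
        return 0.0
    target = p.A_N * no3

    def resid(mu):
        return target - mu * n_quota_direct(mu, p)

    hi = 1.0
    while resid(hi) > 0:
        hi *= 2.0
    return bisect_root(resid, 0.0, hi)
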