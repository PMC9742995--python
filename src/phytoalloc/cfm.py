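"""Steady-state macromolecular allocation model of phytoplankton growth.

The cell's carbon is partitioned among eight pools expressed as quotas
(mol C per mol cell C): protein, RNA, DNA, chlorophyll, thylakoid lipid,
N storage, C storage and other essential C. The quotas of the growth
machinery scale with the growth rate mu through three constitutive
relations:

* chlorophyll is sized so gross C fixation covers growth, biosynthetic
  cost and maintenance:  ``QC_chl = (mu*(1+E) + m) / P(I)``;
* protein is the sum of a photosynthetic part (``A_pho * QC_chl``), a
  biosynthetic part (``k_bio * mu``) and a constant essential part;
* RNA scales with protein and growth: ``QC_rna = Q_rna_min + A_rna*mu*QC_pro``.

Closing the carbon budget (all quotas sum to 1, with C storage empty)
yields a quadratic in mu whose root is the carbon-limited growth rate.
Balancing diffusive nitrate uptake ``A_N*[NO3]`` against the nitrogen
dilution flux ``mu * Q_N(mu)`` at steady state yields a cubic whose root is
the nitrogen-limited growth rate. Realized growth is the minimum of the
two, which produces the saturating growth-versus-nitrate curve: an
increasing N-limited branch followed by a flat C-limited plateau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DomainError, InfeasibleParametersError
from .params import CfmParams

Limitation = Literal["N_limited", "C_limited"]

#: default tolerance for elemental-balance residuals
BALANCE_TOL = 1e-9

_C_POOLS = ("QC_pro", "QC_rna", "QC_dna", "QC_chl",
            "QC_plip_thy", "QC_nsto", "QC_csto", "QC_oth")
_N_POOLS = ("QN_pro", "QN_rna", "QN_dna", "QN_chl", "QN_nsto")


@dataclass(frozen=True)
class MacromolecularState:
    """Full allocation state of the cell at one growth rate.

    All ``QC_*`` fields are carbon quotas in [0, 1] summing to 1; the
    ``QN_*`` fields are nitrogen quotas per mol cell C, so ``QN_total`` is
    also the cellular N:C ratio. ``limitation`` records which elemental
    budget is binding.
    """

    mu: float
    QC_pro: float
    QC_rna: float
    QC_dna: float
    QC_chl: float
    QC_plip_thy: float
    QC_nsto: float
    QC_csto: float
    QC_oth: float
    QN_pro: float
    QN_rna: float
    QN_dna: float
    QN_chl: float
    QN_nsto: float
    QN_total: float
    limitation: Limitation

    @property
    def n_to_c(self) -> float:
        """Cellular N:C ratio (quotas are per mol cell C)."""
        return self.QN_total

    def c_pool_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _C_POOLS}

    def n_pool_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _N_POOLS}


@dataclass(frozen=True)
class BudgetPolynomial:
    """Polynomial in mu encoding an elemental budget.

    ``coefficients`` are ordered highest degree first. Degree 2 encodes the
    carbon budget (C pools sum to 1 with storage empty); degree 3 encodes
    the steady-state nitrogen balance at a given nitrate concentration.
    """

    degree: int
    coefficients: tuple[float, ...]
    regime: Limitation

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.degree + 1:
            raise ValueError("coefficient count does not match degree")

    def evaluate(self, mu: float) -> float:
        return float(np.polyval(self.coefficients, mu))


# ---------------------------------------------------------------------------
# constitutive relations


def photosynthesis_rate(I: float, params: CfmParams) -> float:
    """C fixation per mol chlorophyll C (day⁻¹), saturating in irradiance.

    ``P = P_max_chl * (1 - exp(-O_I * I))`` — zero in the dark, approaching
    ``P_max_chl`` at saturating light.
    """
    if I < 0:
        raise DomainError(f"irradiance must be >= 0, got {I}")
    return params.P_max_chl * (-math.expm1(-params.O_I * I))


def chlorophyll_quota(mu: float, params: CfmParams) -> float:
    """Chlorophyll C quota required to fix C for growth + cost + maintenance."""
    if mu < 0:
        raise DomainError(f"growth rate must be >= 0, got {mu}")
    P = photosynthesis_rate(params.I, params)
    demand = mu * (1.0 + params.E) + params.m
    if P <= 0.0:
        if demand > 0.0:
            raise InfeasibleParametersError(
                "zero photosynthesis (I = 0) cannot meet a positive C demand")
        return 0.0
    return demand / P


def protein_quota(mu: float, params: CfmParams) -> tuple[float, float, float, float]:
    """Protein C quota and its parts: (total, photosynthetic, biosynthetic, essential).

    The photosynthetic part tracks chlorophyll with fixed machinery
    composition; the biosynthetic part is proportional to growth rate; the
    essential part is constant.
    """
    if mu < 0:
        raise DomainError(f"growth rate must be >= 0, got {mu}")
    pho = params.A_pho * chlorophyll_quota(mu, params)
    bio = params.k_bio * mu
    ess = params.Q_pro_ess_C
    return pho + bio + ess, pho, bio, ess


def rna_quota(mu: float, QC_pro: float, params: CfmParams) -> float:
    """RNA C quota: minimum plus the linear RNA–protein–growth coupling."""
    if mu < 0:
        raise DomainError(f"growth rate must be >= 0, got {mu}")
    if QC_pro < 0:
        raise DomainError(f"protein quota must be >= 0, got {QC_pro}")
    return params.Q_rna_min_C + params.A_rna * mu * QC_pro


def _linear_forms(params: CfmParams) -> tuple[float, float, float, float]:
    """Coefficients of the affine quota relations.

    Returns ``(alpha, beta, p1, p0)`` with ``QC_chl = alpha*mu + beta`` and
    ``QC_pro = p1*mu + p0``.
    """
    P = photosynthesis_rate(params.I, params)
    if P <= 0.0:
        raise InfeasibleParametersError(
            "photosynthesis rate is zero; the C budget cannot close")
    alpha = (1.0 + params.E) / P
    beta = params.m / P
    p1 = params.A_pho * alpha + params.k_bio
    p0 = params.A_pho * beta + params.Q_pro_ess_C
    return alpha, beta, p1, p0


def check_feasible(params: CfmParams) -> None:
    """Reject parameter sets whose constant pools already exceed the C budget.

    At mu = 0 the cell still carries essential protein, minimum RNA, DNA,
    other C, replete N-storage C and the maintenance-driven chlorophyll
    (plus its lipid); if those sum to >= 1 no carbon is left for growth.
    """
    alpha, beta, p1, p0 = _linear_forms(params)
    const = (p0 + params.Q_rna_min_C + params.Q_dna_C + params.Q_oth_C
             + params.Q_nsto_C + beta * (1.0 + params.A_plip))
    if const >= 1.0:
        raise InfeasibleParametersError(
            f"constant C pools at mu=0 sum to {const:.4f} >= 1; "
            "no carbon remains for growth machinery")


# ---------------------------------------------------------------------------
# carbon budget (quadratic)


def build_c_budget(params: CfmParams) -> BudgetPolynomial:
    """Quadratic ``a_C*mu^2 + b_C*mu + c_C = 0`` from closing the C budget.

    Substituting the constitutive relations into the unit C budget with C
    storage empty gives a quadratic in mu; the mu² term arises solely from
    the RNA–protein–growth coupling (RNA ∝ mu × protein, protein affine in
    mu).
    """
    alpha, beta, p1, p0 = _linear_forms(params)
    a_c = params.A_rna * p1
    b_c = p1 + params.A_rna * p0 + alpha * (1.0 + params.A_plip)
    c_c = (p0 + params.Q_rna_min_C + params.Q_dna_C
           + beta * (1.0 + params.A_plip)
           + params.Q_nsto_C + params.Q_oth_C - 1.0)
    return BudgetPolynomial(degree=2, coefficients=(a_c, b_c, c_c),
                            regime="C_limited")


def c_limited_growth(params: CfmParams) -> float:
    """Growth rate at which the carbon budget is exactly exhausted.

    Among real roots of the budget quadratic, roots whose allocation state
    is physical (all pools in [0, 1]) are kept; if two remain the larger is
    taken, since growth uses the full C budget.
    """
    check_feasible(params)
    a_c, b_c, c_c = build_c_budget(params).coefficients
    if a_c == 0.0:
        # no RNA-growth coupling: budget is affine in mu
        roots = [-c_c / b_c] if b_c != 0.0 else []
    else:
        disc = b_c * b_c - 4.0 * a_c * c_c
        if disc < 0.0:
            roots = []
        else:
            s = math.sqrt(disc)
            roots = [(-b_c - s) / (2.0 * a_c), (-b_c + s) / (2.0 * a_c)]
    feasible = []
    for r in sorted(roots, reverse=True):
        if r <= 0.0:
            continue
        try:
            allocation_state(r, params, "C_limited")
        except InfeasibleParametersError:
            continue
        feasible.append(r)
    if not feasible:
        raise InfeasibleParametersError(
            "no positive root of the C budget yields a physical allocation "
            "state (all pools in [0, 1])")
    return feasible[0]


# ---------------------------------------------------------------------------
# nitrogen budget (cubic)


def _n_quota_coefficients(params: CfmParams) -> tuple[float, float, float]:
    """Coefficients ``(q2, q1, q0)`` of ``Q_N(mu) = q2*mu² + q1*mu + q0``.

    Total N quota under N limitation (storage empty): N in protein, RNA,
    DNA and chlorophyll, each obtained from its C quota via fixed
    stoichiometry.
    """
    alpha, beta, p1, p0 = _linear_forms(params)
    q2 = params.Y_rna_NC * params.A_rna * p1
    q1 = (params.Y_pro_NC * p1 + params.Y_rna_NC * params.A_rna * p0
          + params.Y_chl_NC * alpha)
    q0 = (params.Y_pro_NC * p0 + params.Y_rna_NC * params.Q_rna_min_C
          + params.Y_dna_NC * params.Q_dna_C + params.Y_chl_NC * beta)
    return q2, q1, q0


def n_quota(mu: float, params: CfmParams) -> float:
    """Total N quota Q_N(mu) under N limitation (no N storage)."""
    q2, q1, q0 = _n_quota_coefficients(params)
    return (q2 * mu + q1) * mu + q0


def build_n_budget(params: CfmParams, no3: float) -> BudgetPolynomial:
    """Cubic ``a_N*mu³ + b_N*mu² + c_N*mu + d_N = 0`` from the N steady state.

    Diffusive uptake ``A_N*[NO3⁻]`` balances growth dilution ``mu*Q_N(mu)``;
    since Q_N is quadratic in mu (through RNA), the balance is cubic. The
    constant term carries ``-A_N*[NO3⁻]``.
    """
    if no3 < 0:
        raise DomainError(f"nitrate concentration must be >= 0, got {no3}")
    q2, q1, q0 = _n_quota_coefficients(params)
    return BudgetPolynomial(degree=3,
                            coefficients=(q2, q1, q0, -params.A_N * no3),
                            regime="N_limited")


def n_limited_growth(params: CfmParams, no3: float) -> float:
    """Nitrogen-limited growth rate at the given nitrate concentration.

    Selects the root branch continuous from mu = 0 at [NO3⁻] = 0 (the
    smallest non-negative real root of the balance cubic). For feasible
    parameters the mu-side of the balance is strictly increasing, so this
    root is unique; a bisection fallback guards degenerate orderings.
    """
    poly = build_n_budget(params, no3)
    if no3 == 0.0:
        return 0.0
    q2, q1, q0 = _n_quota_coefficients(params)
    roots = np.roots(poly.coefficients)
    real = roots[np.abs(roots.imag) < 1e-9 * (1.0 + np.abs(roots.real))].real
    candidates = sorted(r for r in real if r >= -1e-12)
    for r in candidates:
        mu = max(float(r), 0.0)
        if abs(poly.evaluate(mu)) < 1e-7 * (1.0 + params.A_N * no3):
            # Newton polish so the steady-state residual is at solver precision
            for _ in range(3):
                f = poly.evaluate(mu)
                fp = (3.0 * q2 * mu + 2.0 * q1) * mu + q0
                if fp == 0.0:
                    break
                mu -= f / fp
            return max(mu, 0.0)
    # fallback: bisect the monotone balance residual
    q2, q1, q0 = _n_quota_coefficients(params)
    target = params.A_N * no3
    hi = target / q0  # f(mu) >= q0*mu, so the root is below target/q0
    from scipy.optimize import brentq
    return float(brentq(lambda mu: ((q2 * mu + q1) * mu + q0) * mu - target,
                        0.0, hi, xtol=1e-14, rtol=1e-15))


def n_limited_growth_grid(params: CfmParams, no3: np.ndarray) -> np.ndarray:
    """Vectorized N-limited growth over an array of nitrate concentrations.

    Safeguarded Newton iteration on the monotone convex balance
    ``mu*Q_N(mu) = A_N*no3`` starting from the upper bound ``A_N*no3/q0``;
    convergence is monotone from above. Agrees with :func:`n_limited_growth`
    to solver tolerance (asserted in the test suite).
    """
    no3 = np.asarray(no3, dtype=float)
    if np.any(no3 < 0):
        raise DomainError("nitrate concentrations must be >= 0")
    q2, q1, q0 = _n_quota_coefficients(params)
    target = params.A_N * no3
    mu = target / q0
    for _ in range(60):
        f = ((q2 * mu + q1) * mu + q0) * mu - target
        fp = (3.0 * q2 * mu + 2.0 * q1) * mu + q0
        step = f / fp
        mu = mu - step
        if np.all(np.abs(f) <= 1e-14 * (1.0 + target)):
            break
    return np.maximum(mu, 0.0)


# ---------------------------------------------------------------------------
# realized growth and allocation states


def allocation_state(mu: float, params: CfmParams,
                     regime: Limitation) -> MacromolecularState:
    """Reconstruct the full macromolecular state at growth rate mu.

    The C budget closes exactly by construction: C storage absorbs the
    residual of the unit budget. Under N limitation the N-storage pools are
    empty; under C limitation N storage is at its replete level and the
    residual (≈ 0 at the C-limited growth rate) still lands in C storage.
    """
    if regime not in ("N_limited", "C_limited"):
        raise DomainError(f"unknown limitation regime {regime!r}")
    if mu < 0:
        raise DomainError(f"growth rate must be >= 0, got {mu}")
    chl = chlorophyll_quota(mu, params)
    pro, _, _, _ = protein_quota(mu, params)
    rna = rna_quota(mu, pro, params)
    plip = params.A_plip * chl
    nsto_c = 0.0 if regime == "N_limited" else params.Q_nsto_C
    pools = {
        "QC_pro": pro, "QC_rna": rna, "QC_dna": params.Q_dna_C,
        "QC_chl": chl, "QC_plip_thy": plip, "QC_nsto": nsto_c,
        "QC_oth": params.Q_oth_C,
    }
    csto = 1.0 - sum(pools.values())
    if csto < -BALANCE_TOL:
        raise InfeasibleParametersError(
            f"QC_csto would be {csto:.3e} < 0 at mu={mu:.6g}: the non-storage "
            "C pools exceed the budget")
    pools["QC_csto"] = max(csto, 0.0)
    for name, value in pools.items():
        if not (-BALANCE_TOL <= value <= 1.0 + BALANCE_TOL):
            raise InfeasibleParametersError(
                f"pool {name} = {value:.6g} lies outside [0, 1] at mu={mu:.6g}")
    qn = {
        "QN_pro": params.Y_pro_NC * pro,
        "QN_rna": params.Y_rna_NC * rna,
        "QN_dna": params.Y_dna_NC * params.Q_dna_C,
        "QN_chl": params.Y_chl_NC * chl,
        "QN_nsto": params.Y_nsto_NC * nsto_c,
    }
    return MacromolecularState(mu=mu, **pools, **qn,
                               QN_total=sum(qn.values()), limitation=regime)


def realized_growth(params: CfmParams,
                    no3: float) -> tuple[float, MacromolecularState]:
    """Realized growth rate and state: the binding of the two budgets.

    ``mu = min(mu_C, mu_N)``. On the N-limited branch the cell accumulates
    C storage (the budget residual) and holds no N storage; past the
    crossover the C budget binds, growth is flat in nitrate, C storage is
    empty and N storage is replete.
    """
    if no3 < 0:
        raise DomainError(f"nitrate concentration must be >= 0, got {no3}")
    mu_c = c_limited_growth(params)
    mu_n = n_limited_growth(params, no3)
    if mu_n < mu_c:
        state = allocation_state(mu_n, params, "N_limited")
        if state.QC_csto < -BALANCE_TOL:
            raise ConsistencyError("negative C-storage residual under N limitation")
        return mu_n, state
    return mu_c, allocation_state(mu_c, params, "C_limited")


def crossover_no3(params: CfmParams) -> float:
    """Nitrate concentration at which N and C limitation exchange roles.

    From the steady-state balance at mu_C:
    ``no3* = mu_C * Q_N(mu_C) / A_N``.
    """
    mu_c = c_limited_growth(params)
    return mu_c * n_quota(mu_c, params) / params.A_N


def allocation_sweep(params: CfmParams,
                     no3_grid: Sequence[float]) -> pd.DataFrame:
    """Growth, stoichiometry and percentage C allocation along a nitrate grid.

    Returns one row per grid point with columns ``no3_uM``, ``mu_per_day``,
    ``limitation``, ``n_to_c`` and ``pct_<pool>`` for the eight C pools
    (percentages of cellular C, summing to 100).
    """
    grid = np.asarray(list(no3_grid), dtype=float)
    if grid.size == 0:
        raise DomainError("nitrate grid must be non-empty")
    if np.any(grid < 0):
        raise DomainError("nitrate grid values must be >= 0")
    if np.any(np.diff(grid) < 0):
        raise DomainError("nitrate grid must be sorted ascending")
    rows = []
    for no3 in grid:
        mu, state = realized_growth(params, float(no3))
        row = {"no3_uM": float(no3), "mu_per_day": mu,
               "limitation": state.limitation, "n_to_c": state.n_to_c}
        for name, value in state.c_pool_dict().items():
            row[f"pct_{name[3:]}"] = 100.0 * value
        rows.append(row)
    return pd.DataFrame(rows)
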