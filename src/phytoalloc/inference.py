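"""Metropolis–Hastings parameter estimation for the two growth models.

Both fits use a Gaussian random-walk Metropolis–Hastings sampler on the
log-scale of the parameters (which enforces positivity), an iid Gaussian
likelihood on the observed growth rates with fixed error scale sigma, and
flat priors on the log-parameters within broad bounds. An adaptive pre-run
phase tunes the per-parameter proposal scales toward a moderate acceptance
rate and is discarded; the main chain then runs with fixed scales. The
point estimate is the chain state with the highest recorded log-posterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import cfm
from .datasets import GrowthDataset
from .errors import DomainError, InfeasibleParametersError, PhytoallocError
from .monod import monod_growth
from .params import CfmParams, MonodParams

LOG_2PI = math.log(2.0 * math.pi)

#: broad positivity bounds applied to every sampled parameter (log-flat prior)
DEFAULT_BOUNDS = (1e-6, 1e6)


def gaussian_log_likelihood(predicted: Sequence[float],
                            observed: Sequence[float],
                            sigma: float) -> float:
    """Sum of iid Gaussian log-densities of the residuals at scale sigma."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.size == 0:
        raise DomainError("predicted and observed must have equal length >= 1")
    if not sigma > 0:
        raise DomainError(f"sigma must be > 0, got {sigma}")
    resid = pred - obs
    n = pred.size
    return float(-0.5 * n * LOG_2PI - n * math.log(sigma)
                 - 0.5 * np.dot(resid, resid) / sigma ** 2)


@dataclass(frozen=True)
class McmcChain:
    """A Metropolis–Hastings chain: samples, trace and diagnostics."""

    samples: np.ndarray          # (n_iter, n_params), post-accept states
    log_posterior: np.ndarray    # (n_iter,)
    accepted: np.ndarray         # (n_iter,) bool
    acceptance_rate: float
    seed: int
    burn_in: int

    def post_burn(self) -> np.ndarray:
        """Samples with the burn-in prefix removed."""
        return self.samples[self.burn_in:]


@dataclass(frozen=True)
class FitResult:
    """Point estimates and posterior summaries from one fit."""

    param_names: tuple[str, ...]
    estimate: dict[str, float]       # chain argmax of the log-posterior
    posterior_mean: dict[str, float]
    ci95: dict[str, tuple[float, float]]  # central 95% interval
    rss: float                       # residual sum of squares at the estimate
    chain: McmcChain


def metropolis_hastings(logpost: Callable[[np.ndarray], float],
                        init: Sequence[float],
                        proposal_scales: Sequence[float],
                        n_iter: int,
                        seed: int,
                        burn_in: int | None = None,
                        progress: Callable[[int, float, float], None] | None = None,
                        ) -> McmcChain:
    """Gaussian random-walk Metropolis–Hastings.

    Proposals perturb all coordinates jointly with independent Gaussian
    steps of the given per-parameter scales; a move is accepted with
    probability ``min(1, exp(delta log-posterior))``. The chain is fully
    reproducible given ``seed``. ``burn_in`` defaults to 20% of ``n_iter``.
    """
    theta = np.asarray(init, dtype=float).copy()
    scales = np.asarray(proposal_scales, dtype=float)
    if np.any(scales <= 0):
        raise DomainError("proposal scales must be > 0")
    if n_iter < 1:
        raise DomainError("n_iter must be >= 1")
    lp = float(logpost(theta))
    if not math.isfinite(lp):
        raise PhytoallocError(
            "log-posterior is not finite at the initial state; choose a "
            "different initial estimate and re-run")
    rng = np.random.default_rng(seed)
    p = theta.size
    samples = np.empty((n_iter, p))
    trace = np.empty(n_iter)
    accepted = np.zeros(n_iter, dtype=bool)
    for i in range(n_iter):
        prop = theta + scales * rng.normal(size=p)
        lp_prop = float(logpost(prop))
        if math.log(rng.random()) < lp_prop - lp:
            theta, lp = prop, lp_prop
            accepted[i] = True
        samples[i] = theta
        trace[i] = lp
        if progress is not None and (i + 1) % 1000 == 0:
            progress(i + 1, lp, float(accepted[:i + 1].mean()))
    if burn_in is None:
        burn_in = n_iter // 5
    return McmcChain(samples=samples, log_posterior=trace, accepted=accepted,
                     acceptance_rate=float(accepted.mean()), seed=seed,
                     burn_in=int(burn_in))


def _adapt_scales(logpost: Callable[[np.ndarray], float],
                  init: np.ndarray,
                  scales: np.ndarray,
                  n_adapt: int,
                  seed: int,
                  target: float = 0.3) -> tuple[np.ndarray, np.ndarray]:
    """Pre-run phase: tune proposal scales in blocks of 100 iterations.

    Returns the tuned scales and the final chain state; everything run here
    is discarded (it plays the role of extra burn-in).
    """
    theta = init.copy()
    scales = scales.copy()
    block = 100
    for b in range(max(n_adapt // block, 1)):
        chain = metropolis_hastings(logpost, theta, scales, block,
                                    seed=seed + 1000 + b, burn_in=0)
        theta = chain.samples[-1]
        scales *= math.exp(chain.acceptance_rate - target)
        np.clip(scales, 1e-6, 10.0, out=scales)
    return scales, theta


def _log_flat_prior(theta: np.ndarray, bounds: tuple[float, float]) -> float:
    lo, hi = math.log(bounds[0]), math.log(bounds[1])
    if np.any(theta < lo) or np.any(theta > hi):
        return -math.inf
    return 0.0


def _summarize(chain: McmcChain, names: tuple[str, ...],
               rss_at: Callable[[np.ndarray], float]) -> FitResult:
    idx = int(np.argmax(chain.log_posterior))
    best = np.exp(chain.samples[idx])
    post = np.exp(chain.post_burn())
    mean = post.mean(axis=0)
    lo, hi = np.percentile(post, [2.5, 97.5], axis=0)
    return FitResult(
        param_names=names,
        estimate={n: float(v) for n, v in zip(names, best)},
        posterior_mean={n: float(v) for n, v in zip(names, mean)},
        ci95={n: (float(a), float(b)) for n, a, b in zip(names, lo, hi)},
        rss=float(rss_at(best)),
        chain=chain,
    )


# ---------------------------------------------------------------------------
# Monod fit


def fit_monod(data: GrowthDataset,
              n_iter: int = 6000,
              n_adapt: int = 1000,
              sigma: float = 0.05,
              seed: int = 0,
              bounds: tuple[float, float] = DEFAULT_BOUNDS,
              proposal_scale: float = 0.1,
              progress: Callable[[int, float, float], None] | None = None,
              ) -> FitResult:
    """Estimate (mu_max, Ks) from a growth dataset.

    Requires at least 3 points and at least one non-zero growth rate.
    Sampling is on (log mu_max, log Ks) with a flat prior inside ``bounds``.
    """
    if len(data) < 3:
        raise DomainError("fit_monod needs at least 3 data points")
    if np.all(data.mu_obs <= 0):
        raise DomainError("all growth rates are zero; Monod fit is undefined")

    def rss_at(params: np.ndarray) -> float:
        pred = monod_growth(data.no3, MonodParams(*params))
        return float(np.sum((np.asarray(pred) - data.mu_obs) ** 2))

    def logpost(theta: np.ndarray) -> float:
        prior = _log_flat_prior(theta, bounds)
        if not math.isfinite(prior):
            return prior
        pred = monod_growth(data.no3, MonodParams(*np.exp(theta)))
        return prior + gaussian_log_likelihood(pred, data.mu_obs, sigma)

    mu0 = max(float(np.max(data.mu_obs)) * 1.05, 1e-3)
    pos = data.no3[data.no3 > 0]
    ks0 = float(np.median(pos)) if pos.size else 1.0
    init = np.log([mu0, ks0])
    scales, start = _adapt_scales(logpost, init,
                                  np.full(2, proposal_scale), n_adapt, seed)
    chain = metropolis_hastings(logpost, start, scales, n_iter, seed=seed,
                                progress=progress)
    return _summarize(chain, ("mu_max", "Ks"), rss_at)


# ---------------------------------------------------------------------------
# allocation-model fit


def cfm_growth_curve(base: CfmParams, no3: np.ndarray) -> np.ndarray:
    """Realized growth rates over an array of nitrate concentrations."""
    mu_c = cfm.c_limited_growth(base)
    mu_n = cfm.n_limited_growth_grid(base, np.asarray(no3, dtype=float))
    return np.minimum(mu_c, mu_n)


def fit_cfm(data: GrowthDataset,
            base: CfmParams | None = None,
            n_iter: int = 6000,
            n_adapt: int = 1000,
            sigma: float = 0.05,
            seed: int = 0,
            bounds: tuple[float, float] = DEFAULT_BOUNDS,
            proposal_scale: float = 0.1,
            progress: Callable[[int, float, float], None] | None = None,
            ) -> FitResult:
    """Estimate (A_pho, A_N) of the allocation model from a growth dataset.

    ``base`` supplies every other physiological constant; its irradiance is
    overridden by the dataset's experimental irradiance. ``k_bio`` stays
    slaved to ``A_pho`` through the fixed ratio ``r_bio_pho``, so the fit
    has exactly two free parameters. Model growth at each nitrate
    concentration is the realized (min of N- and C-limited) rate.
    """
    if len(data) < 3:
        raise DomainError("fit_cfm needs at least 3 data points")
    base = (base or CfmParams()).replace(I=data.irradiance)
    cfm.check_feasible(base)

    def curve(params: np.ndarray) -> np.ndarray | None:
        try:
            p = base.with_fitted(A_pho=params[0], A_N=params[1])
            return cfm_growth_curve(p, data.no3)
        except (InfeasibleParametersError, DomainError):
            return None

    def rss_at(params: np.ndarray) -> float:
        pred = curve(params)
        if pred is None:
            return math.inf
        return float(np.sum((pred - data.mu_obs) ** 2))

    def logpost(theta: np.ndarray) -> float:
        prior = _log_flat_prior(theta, bounds)
        if not math.isfinite(prior):
            return prior
        pred = curve(np.exp(theta))
        if pred is None:
            return -math.inf
        return prior + gaussian_log_likelihood(pred, data.mu_obs, sigma)

    # order-invariant initial guesses: A_pho from the base physiology, A_N
    # from the median low-nitrate uptake balance mu*Q_N(mu)/no3
    mask = (data.no3 > 0) & (data.mu_obs > 0)
    if np.any(mask):
        ratios = [mu * cfm.n_quota(mu, base) / s
                  for s, mu in zip(data.no3[mask], data.mu_obs[mask])]
        an0 = float(np.median(ratios))
    else:
        an0 = base.A_N
    init = np.log([base.A_pho, max(an0, 1e-6)])
    scales, start = _adapt_scales(logpost, init,
                                  np.full(2, proposal_scale), n_adapt, seed)
    chain = metropolis_hastings(logpost, start, scales, n_iter, seed=seed,
                                progress=progress)
    return _summarize(chain, ("A_pho", "A_N"), rss_at)
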