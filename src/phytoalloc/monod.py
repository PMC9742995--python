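"""Monod kinetics: the classical saturating growth–substrate relation."""

from __future__ import annotations

import numpy as np

from .errors import DomainError
from .params import MonodParams


def monod_growth(S, p: MonodParams):
    """Specific growth rate mu = mu_max * S / (Ks + S).

    ``S`` is the substrate concentration in µM (scalar or array); ``Ks`` is
    the concentration at which growth is exactly half of ``mu_max``.
    Returns day⁻¹, same shape as ``S``.
    """
    S_arr = np.asarray(S, dtype=float)
    if np.any(S_arr < 0):
        raise DomainError("substrate concentration must be >= 0")
    # grouping keeps the half-saturation identity exact: S/(Ks+S) is
    # exactly 0.5 at S = Ks, and mu_max * 0.5 is an exact float product
    mu = p.mu_max * (S_arr / (p.Ks + S_arr))
    return float(mu) if np.isscalar(S) or S_arr.ndim == 0 else mu
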