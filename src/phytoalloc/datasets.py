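"""Growth-versus-nitrate datasets: container, synthetic generators, CSV I/O.

A :class:`GrowthDataset` holds one species' measured points — nitrate
concentration (µM) against specific growth rate (day⁻¹) — together with the
irradiance of the experiment, which the allocation model needs to size the
photosynthetic machinery. The synthetic generators emulate the statistical
structure of such compilations: 5–15 points drawn from a known Monod or
allocation-model curve with additive Gaussian noise truncated at zero.

CSV dialect (UTF-8, comma-separated, "." decimal):
``species, irradiance_umol_m2_s, no3_uM, growth_per_day``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import cfm
from .errors import DomainError
from .monod import monod_growth
from .params import CfmParams, MonodParams

CSV_COLUMNS = ("species", "irradiance_umol_m2_s", "no3_uM", "growth_per_day")


@dataclass(frozen=True)
class GrowthDataset:
    """One species' (NO3⁻, growth-rate) points plus experimental irradiance."""

    species: str
    irradiance: float
    no3: np.ndarray
    mu_obs: np.ndarray
    provenance: Literal["synthetic", "file"] = "synthetic"

    def __post_init__(self) -> None:
        no3 = np.asarray(self.no3, dtype=float)
        mu = np.asarray(self.mu_obs, dtype=float)
        object.__setattr__(self, "no3", no3)
        object.__setattr__(self, "mu_obs", mu)
        if no3.size == 0:
            raise DomainError("a dataset needs at least one point")
        if no3.shape != mu.shape:
            raise DomainError("no3 and mu_obs must have equal length")
        if not np.all(np.isfinite(no3)) or np.any(no3 < 0):
            raise DomainError("no3 values must be finite and >= 0")
        if not np.all(np.isfinite(mu)):
            raise DomainError("growth rates must be finite")
        if self.irradiance < 0:
            raise DomainError("irradiance must be >= 0")

    def __len__(self) -> int:
        return int(self.no3.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "species": self.species,
            "irradiance_umol_m2_s": self.irradiance,
            "no3_uM": self.no3,
            "growth_per_day": self.mu_obs,
        })


def _noisy(mu_true: np.ndarray, noise_sd: float, seed: int) -> np.ndarray:
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    mu = mu_true + rng.normal(0.0, noise_sd, size=mu_true.shape) \
        if noise_sd > 0 else mu_true.copy()
    return np.maximum(mu, 0.0)  # growth rates are reported non-negative


def generate_monod_dataset(true: MonodParams,
                           no3_grid: Sequence[float] | None = None,
                           noise_sd: float = 0.05,
                           seed: int = 0,
                           species: str = "synthetic Monod",
                           irradiance: float = 200.0) -> GrowthDataset:
    """Noisy points on a Monod curve, deterministic under ``seed``.

    The default grid mimics typical culture designs: 10 concentrations
    spanning 0–4×Ks (growth from zero to ~80% of mu_max).
    """
    if no3_grid is None:
        no3_grid = default_no3_grid(4.0 * true.Ks)
    grid = np.asarray(list(no3_grid), dtype=float)
    if grid.size == 0:
        raise DomainError("nitrate grid must be non-empty")
    mu_true = monod_growth(grid, true)
    return GrowthDataset(species=species, irradiance=irradiance, no3=grid,
                         mu_obs=_noisy(np.asarray(mu_true), noise_sd, seed),
                         provenance="synthetic")


def generate_cfm_dataset(true: CfmParams,
                         no3_grid: Sequence[float] | None = None,
                         noise_sd: float = 0.05,
                         seed: int = 0,
                         species: str = "synthetic CFM") -> GrowthDataset:
    """Noisy points on the two-regime allocation-model curve.

    The default grid spans 0–4× the N/C crossover concentration so both the
    rising N-limited branch and the flat C-limited plateau are sampled.
    """
    if no3_grid is None:
        no3_grid = default_no3_grid(4.0 * cfm.crossover_no3(true))
    grid = np.asarray(list(no3_grid), dtype=float)
    if grid.size == 0:
        raise DomainError("nitrate grid must be non-empty")
    mu_true = np.array([cfm.realized_growth(true, float(s))[0] for s in grid])
    return GrowthDataset(species=species, irradiance=true.I, no3=grid,
                         mu_obs=_noisy(mu_true, noise_sd, seed),
                         provenance="synthetic")


def default_no3_grid(no3_max: float, n: int = 10) -> np.ndarray:
    """Evenly spaced nitrate grid from 0 to ``no3_max`` (µM)."""
    if no3_max <= 0:
        raise DomainError("no3_max must be > 0")
    return np.linspace(0.0, no3_max, n)


# ---------------------------------------------------------------------------
# CSV I/O


def write_dataset_csv(dataset: GrowthDataset, path: str | Path) -> None:
    """Write a dataset in the package CSV dialect."""
    dataset.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_dataset_csv(path: str | Path) -> GrowthDataset:
    """Read a dataset CSV, validating columns and every row.

    Raises :class:`DomainError` naming the missing column or the offending
    row (0-based data-row index) on negative nitrate or non-numeric cells.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise DomainError(f"{path.name}: missing required column {col!r}")
    if len(df) == 0:
        raise DomainError(f"{path.name}: no data rows")
    numeric = {}
    for col in ("irradiance_umol_m2_s", "no3_uM", "growth_per_day"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.index[values.isna()]
        if len(bad) > 0:
            raise DomainError(
                f"{path.name}: non-numeric value in column {col!r} "
                f"at row {int(bad[0])}")
        numeric[col] = values.to_numpy(dtype=float)
    neg = np.nonzero(numeric["no3_uM"] < 0)[0]
    if neg.size:
        raise DomainError(
            f"{path.name}: negative no3_uM at row {int(neg[0])}")
    irr = numeric["irradiance_umol_m2_s"]
    return GrowthDataset(species=str(df["species"].iloc[0]),
                         irradiance=float(irr[0]),
                         no3=numeric["no3_uM"],
                         mu_obs=numeric["growth_per_day"],
                         provenance="file")
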