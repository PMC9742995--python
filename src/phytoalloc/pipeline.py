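"""End-to-end experiment runner: fit both models per dataset, export tables.

Mirrors the workflow used to analyse compiled growth-versus-nitrate data:
for each dataset, fit Monod kinetics (mu_max, Ks) and the allocation model
(A_pho, A_N) by Metropolis–Hastings, then export fit tables, model curves
on a nitrate grid, and the allocation sweep of the fitted cell model. All
randomness is seeded from the configuration, so a run is reproducible
byte-for-byte.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import cfm, datasets, inference
from .errors import DomainError, PhytoallocError
from .monod import monod_growth
from .params import CfmParams, MonodParams

log = logging.getLogger("phytoalloc")

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class FitOptions:
    """MCMC settings shared by both fits."""

    iterations: int = 6000
    adapt: int = 1000
    sigma: float = 0.05
    seed: int = 0


@dataclass(frozen=True)
class DatasetSpec:
    """One dataset: a CSV path, or a synthetic-generation block."""

    label: str
    path: Path | None = None
    synthetic: dict | None = None
    irradiance: float | None = None

    def __post_init__(self) -> None:
        if (self.path is None) == (self.synthetic is None):
            raise DomainError(
                f"dataset {self.label!r}: exactly one of 'path' or "
                "'synthetic' must be given")


@dataclass(frozen=True)
class ExperimentConfig:
    """Full experiment description (normally loaded from a YAML file)."""

    datasets: tuple[DatasetSpec, ...]
    output_dir: Path
    fit: FitOptions = field(default_factory=FitOptions)
    no3_grid: np.ndarray | None = None
    base_params: CfmParams = field(default_factory=CfmParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        fit = FitOptions(**raw.get("fit", {}))
        specs = []
        for i, block in enumerate(raw.get("datasets", [])):
            specs.append(DatasetSpec(
                label=str(block.get("label", f"dataset{i}")),
                path=Path(block["path"]) if "path" in block else None,
                synthetic=block.get("synthetic"),
                irradiance=block.get("irradiance"),
            ))
        if not specs:
            raise DomainError("config lists no datasets")
        grid = raw.get("no3_grid")
        if isinstance(grid, dict):
            grid = np.linspace(grid["start"], grid["stop"], int(grid["num"]))
        elif grid is not None:
            grid = np.asarray(grid, dtype=float)
        return cls(datasets=tuple(specs), output_dir=Path(raw["output_dir"]),
                   fit=fit, no3_grid=grid)


def _materialize(spec: DatasetSpec,
                 base: CfmParams) -> datasets.GrowthDataset:
    """Load a CSV dataset or build a synthetic one from its block."""
    if spec.path is not None:
        if not spec.path.exists():
            raise DomainError(f"dataset {spec.label!r}: file not found: {spec.path}")
        ds = datasets.read_dataset_csv(spec.path)
        if spec.irradiance is not None:
            ds = datasets.GrowthDataset(ds.species, float(spec.irradiance),
                                        ds.no3, ds.mu_obs, ds.provenance)
        return ds
    blk = dict(spec.synthetic or {})
    model = blk.pop("model", "monod")
    grid = blk.pop("no3", None)
    if grid is None and "no3_max" in blk:
        grid = datasets.default_no3_grid(blk.pop("no3_max"),
                                         int(blk.pop("n_points", 10)))
    noise_sd = blk.pop("noise_sd", 0.05)
    seed = int(blk.pop("seed", 0))
    if model == "monod":
        true = MonodParams(mu_max=blk.pop("mu_max"), Ks=blk.pop("ks"))
        return datasets.generate_monod_dataset(
            true, grid, noise_sd=noise_sd, seed=seed, species=spec.label,
            irradiance=float(spec.irradiance
                             if spec.irradiance is not None else base.I))
    if model == "cfm":
        true = base.with_fitted(A_pho=blk.pop("a_pho", base.A_pho),
                                A_N=blk.pop("a_n", base.A_N))
        if spec.irradiance is not None:
            true = true.replace(I=float(spec.irradiance))
        return datasets.generate_cfm_dataset(true, grid, noise_sd=noise_sd,
                                             seed=seed, species=spec.label)
    raise DomainError(f"dataset {spec.label!r}: unknown synthetic model {model!r}")


def write_fit_table(results: Sequence[inference.FitResult],
                    labels: Sequence[str],
                    path: str | Path) -> None:
    """One row per dataset: point estimates, 95% intervals, RSS, acceptance.

    Deterministic column order; identical seeds reproduce the file
    byte-identically. An empty result list yields a header-only file.
    """
    rows = []
    for label, res in zip(labels, results):
        row: dict[str, object] = {"dataset": label}
        for name in res.param_names:
            row[f"{name}_estimate"] = res.estimate[name]
            row[f"{name}_mean"] = res.posterior_mean[name]
            row[f"{name}_ci2.5"] = res.ci95[name][0]
            row[f"{name}_ci97.5"] = res.ci95[name][1]
        row["rss"] = res.rss
        row["acceptance_rate"] = res.chain.acceptance_rate
        rows.append(row)
    if rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(columns=["dataset", "rss", "acceptance_rate"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _setup_logging(logfile: Path) -> logging.Handler:
    handler = logging.FileHandler(logfile, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler)
               and getattr(h, "stream", None) is sys.stderr
               for h in log.handlers):
        stream = logging.StreamHandler(sys.stderr)
        stream.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(stream)
    return handler


def run_experiment(config: ExperimentConfig) -> dict[str, Path]:
    """Run both fits on every dataset and write the output bundle.

    Outputs under ``config.output_dir``: ``monod_fits.csv`` and
    ``cfm_fits.csv`` (one row per dataset), per-dataset
    ``<label>_curves.csv`` (observed grid + both fitted model curves) and
    ``<label>_allocation.csv`` (allocation sweep of the fitted cell), plus
    ``run.log`` recording seeds, iterations and acceptance rates.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out / "run.log")
    paths: dict[str, Path] = {"log": out / "run.log"}
    try:
        # materialize all inputs first so a bad reference fails cleanly
        # before any results are written
        loaded = []
        for spec in config.datasets:
            try:
                loaded.append(_materialize(spec, config.base_params))
            except PhytoallocError as exc:
                raise PhytoallocError(f"dataset {spec.label!r}: {exc}") from exc

        monod_results, cfm_results = [], []
        labels = [spec.label for spec in config.datasets]
        for i, (spec, ds) in enumerate(zip(config.datasets, loaded)):
            seed = config.fit.seed + i
            log.info("dataset %s: n=%d irradiance=%g seed=%d iterations=%d",
                     spec.label, len(ds), ds.irradiance, seed,
                     config.fit.iterations)

            def block_logger(tag):
                return lambda it, lp, acc: log.info(
                    "%s %s: iter %d logpost %.4f acc %.3f",
                    spec.label, tag, it, lp, acc)

            try:
                mres = inference.fit_monod(
                    ds, n_iter=config.fit.iterations, n_adapt=config.fit.adapt,
                    sigma=config.fit.sigma, seed=seed,
                    progress=block_logger("monod"))
                cres = inference.fit_cfm(
                    ds, base=config.base_params, n_iter=config.fit.iterations,
                    n_adapt=config.fit.adapt, sigma=config.fit.sigma,
                    seed=seed, progress=block_logger("cfm"))
            except PhytoallocError as exc:
                raise PhytoallocError(f"dataset {spec.label!r}: {exc}") from exc
            log.info("%s fitted: monod acc=%.3f rss=%.4g | cfm acc=%.3f rss=%.4g",
                     spec.label, mres.chain.acceptance_rate, mres.rss,
                     cres.chain.acceptance_rate, cres.rss)
            monod_results.append(mres)
            cfm_results.append(cres)

            grid = config.no3_grid
            if grid is None:
                grid = np.linspace(0.0, 1.25 * float(ds.no3.max() or 1.0), 50)
            fitted = config.base_params.replace(I=ds.irradiance).with_fitted(
                A_pho=cres.estimate["A_pho"], A_N=cres.estimate["A_N"])
            curves = pd.DataFrame({
                "no3_uM": grid,
                "mu_monod_per_day": np.asarray(monod_growth(
                    grid, MonodParams(**mres.estimate))),
                "mu_cfm_per_day": inference.cfm_growth_curve(fitted, grid),
            })
            cpath = out / f"{spec.label}_curves.csv"
            curves.to_csv(cpath, index=False, float_format=_FLOAT_FMT)
            paths[f"{spec.label}_curves"] = cpath
            spath = out / f"{spec.label}_allocation.csv"
            cfm.allocation_sweep(fitted, grid).to_csv(
                spath, index=False, float_format=_FLOAT_FMT)
            paths[f"{spec.label}_allocation"] = spath

        for name, results in (("monod_fits", monod_results),
                              ("cfm_fits", cfm_results)):
            tpath = out / f"{name}.csv"
            write_fit_table(results, labels, tpath)
            paths[name] = tpath
        log.info("experiment complete: %d datasets", len(labels))
        return paths
    finally:
        log.removeHandler(handler)
        handler.close()
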