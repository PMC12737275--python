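"""Configuration-driven orchestration: simulate → risk → pmf → mc → source-risk.

A :class:`RunConfig` selects stages, sizes, seeds and solver settings; a
single global seed fans out to fixed per-stage offsets so any stage can be
re-run independently with identical results.  :func:`run_all` executes the
enabled stages in dependency order and returns a manifest of every artifact
written, with SHA-256 checksums — two runs with the same config and seed
produce identical data artifacts.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import data_io, monte_carlo, pmf as pmf_mod, risk as risk_mod, source_risk, synthetic
from . import registry as _registry

__all__ = ["RunConfig", "run_all", "report"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "risk", "pmf", "mc", "source_risk")

# fixed per-stage seed offsets (global seed + offset, kept below 2**31)
_STAGE_SEED_OFFSET = {"simulate": 1, "risk": 2, "pmf": 3, "mc": 4, "source_risk": 5}


@dataclass
class RunConfig:
    """Settings for one pipeline run (see YAML schema in the docs)."""

    outdir: str = "pahrisk_run"
    seed: int = 42
    stages: tuple[str, ...] = STAGES
    # synthetic data
    n_samples: int = 200
    noise_cv: float = 0.1
    # optional external inputs (used when the simulate stage is disabled)
    concentrations_path: str | None = None
    uncertainties_path: str | None = None
    # risk
    scenario: str = "carcinogenic"
    ed: float | None = None
    # pmf
    k: int = 4
    n_starts: int = 20
    max_iter: int = 2000
    tol: float = 1e-8
    # monte carlo
    mc_iterations: int = 10_000
    mc_counts: tuple[int, ...] = monte_carlo.DEFAULT_ITERATION_COUNTS

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "mc_counts" in d:
            d["mc_counts"] = tuple(int(c) for c in d["mc_counts"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(data_io.load_config(path))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["mc_counts"] = list(self.mc_counts)
        return d

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _STAGE_SEED_OFFSET[stage]) % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _validate(config: RunConfig) -> None:
    if "simulate" not in config.stages:
        needs_conc = {"risk", "pmf", "mc", "source_risk"} & set(config.stages)
        if needs_conc and not config.concentrations_path:
            raise ValueError("concentrations_path required when simulate is disabled")
        if "pmf" in config.stages and not config.uncertainties_path:
            raise ValueError("uncertainties_path required for the pmf stage "
                             "when simulate is disabled")
        for p in (config.concentrations_path, config.uncertainties_path):
            if p and not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")
    if "source_risk" in config.stages and "pmf" not in config.stages:
        raise ValueError("source_risk requires the pmf stage")


def run_all(config: RunConfig) -> pd.DataFrame:
    """Execute the enabled stages in dependency order.

    Returns the artifact manifest (path, stage, sha256).  Any stage failure
    aborts with an exception naming the stage.
    """
    _validate(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    cfg_dict.pop("outdir")  # output location does not affect the data
    registry = _registry.builtin_registry()
    params = _registry.default_exposure(config.scenario, ed=config.ed)

    artifacts: list[tuple[str, Path]] = []
    conc = unc = truth = model = None

    def emit(stage: str, name: str, df: pd.DataFrame, seed: int | None) -> None:
        path = outdir / name
        data_io.write_report(df, path, seed=seed, config=cfg_dict, stage=stage,
                             timestamp=False)
        artifacts.append((stage, path))

    try:
        if "simulate" in config.stages:
            stage = "simulate"
            seed = config.stage_seed(stage)
            conc, unc, truth = synthetic.generate_mixture(
                config.n_samples, noise_cv=config.noise_cv, seed=seed)
            emit(stage, "concentrations.csv", conc.to_frame(), seed)
            unc_df = pd.DataFrame(unc.values, columns=_registry.abbreviations())
            unc_df.insert(0, "sample_id", conc.sample_ids)
            emit(stage, "uncertainties.csv", unc_df, seed)
            truth_f = pd.DataFrame(truth.profiles.profiles,
                                   columns=_registry.abbreviations())
            truth_f.insert(0, "source", list(truth.profiles.labels))
            emit(stage, "true_profiles.csv", truth_f, seed)
            truth_g = pd.DataFrame(truth.contributions,
                                   columns=list(truth.profiles.labels))
            truth_g.insert(0, "sample_id", conc.sample_ids)
            emit(stage, "true_contributions.csv", truth_g, seed)
        else:
            conc = data_io.read_concentrations(config.concentrations_path)
            if config.uncertainties_path:
                unc = data_io.read_uncertainties(config.uncertainties_path)

        if "risk" in config.stages:
            stage = "risk"
            table = risk_mod.assess(conc, params, registry)
            emit(stage, "risk.csv", table, config.stage_seed(stage))

        if "pmf" in config.stages:
            stage = "pmf"
            seed = config.stage_seed(stage)
            model = pmf_mod.fit_pmf(conc, unc, config.k, n_starts=config.n_starts,
                                    seed=seed, max_iter=config.max_iter,
                                    tol=config.tol)
            pmf_mod.label_factors(model)
            prof = pd.DataFrame(model.profiles, columns=_registry.abbreviations())
            prof.insert(0, "factor", model.labels)
            emit(stage, "profiles.csv", prof, seed)
            contrib = pd.DataFrame(model.contributions, columns=model.labels)
            contrib.insert(0, "sample_id", conc.sample_ids)
            emit(stage, "contributions.csv", contrib, seed)
            diag = pd.DataFrame({
                "congener": _registry.abbreviations(),
                "r2": model.congener_r2,
                "max_abs_std_residual": np.abs(model.standardized_residuals).max(axis=0),
            })
            diag["q"] = model.q
            diag["q_expected"] = model.q_expected
            emit(stage, "diagnostics.csv", diag, seed)

        if "mc" in config.stages:
            stage = "mc"
            seed = config.stage_seed(stage)
            specs = monte_carlo.default_specs(conc, registry)
            result = monte_carlo.run_simulation(
                specs, params, registry, n_iterations=config.mc_iterations,
                seed=seed, hq_composition=conc.values.mean(axis=0))
            summary = result.percentiles.reset_index()
            for key, val in result.exceedance.items():
                summary[key] = val
            emit(stage, "mc_summary.csv", summary, seed)
            _, table = monte_carlo.convergence_check(
                specs, params, registry, iteration_counts=config.mc_counts,
                seed=seed, hq_composition=conc.values.mean(axis=0))
            emit(stage, "mc_convergence.csv", table, seed)

        if "source_risk" in config.stages:
            stage = "source_risk"
            attribution = source_risk.attribute_risk(model, params, registry)
            emit(stage, "source_shares.csv", attribution.to_frame(),
                 config.stage_seed(stage))
            rings = source_risk.ring_class_risk_shares(conc, params, registry)
            emit(stage, "ring_shares.csv", rings, config.stage_seed(stage))
    except Exception as err:
        raise RuntimeError(f"stage '{stage}' failed: {err}") from err

    manifest = pd.DataFrame(
        [{"stage": s, "path": str(p), "sha256": _sha256(p)} for s, p in artifacts])
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest


def report(outdir: str | Path) -> str:
    """Human-readable summary of a completed run directory."""
    outdir = Path(outdir)
    lines = [f"pahrisk run summary: {outdir}"]

    risk_path = outdir / "risk.csv"
    if risk_path.exists():
        df = pd.read_csv(risk_path, comment="#")
        lines.append("")
        lines.append("Deterministic risk (per species means):")
        by_sp = df.groupby("species")[["HI", "TILCR"]].mean()
        for sp, row in by_sp.sort_values("TILCR", ascending=False).iterrows():
            lines.append(f"  {sp:15s} HI={row.HI:.3e}  TILCR={row.TILCR:.3e}")
        counts = df["category"].value_counts()
        lines.append("  TILCR categories: "
                     + ", ".join(f"{k}={v}" for k, v in counts.items()))

    prof_path = outdir / "profiles.csv"
    if prof_path.exists():
        df = pd.read_csv(prof_path, comment="#")
        lines.append("")
        lines.append("PMF factors: " + ", ".join(df["factor"].tolist()))

    shares_path = outdir / "source_shares.csv"
    if shares_path.exists():
        df = pd.read_csv(shares_path, comment="#")
        lines.append("")
        lines.append("Source contributions to risk:")
        for _, row in df.iterrows():
            lines.append(f"  {row['factor']:18s} HI {row['hi_share_pct']:5.1f}%"
                         f"  TILCR {row['tilcr_share_pct']:5.1f}%")
    return "\n".join(lines)
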