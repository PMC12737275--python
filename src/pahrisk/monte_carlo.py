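"""Probabilistic (Monte Carlo) dietary risk assessment.

Each iteration draws one value per stochastic input — body weight BW, intake
rate IR, exposure duration ED, exposure frequency EF, the total
BaP-equivalent concentration, and (for the hazard index) the total PAH
concentration — and evaluates the ILCR/TILCR and HQ/HI equations of
:mod:`pahrisk.risk` with the fixed parameters (AT, CSF, RfD) held constant.

The concentration inputs follow the log-normal convention: sample-level
BaP-equivalent totals are log-transformed, screened with the Shapiro–Wilk
test and fitted by :func:`fit_lognormal`, and the simulation draws the
BaP-equivalent total from that fitted distribution (rather than drawing 16
congeners independently).  For the hazard index, the total concentration is
drawn the same way and apportioned over congeners with a fixed composition
vector (the mean congener fractions), since HI is linear in the congener
vector.

Reproducibility: a single seeded generator per run, with a fixed draw order
(bw, ir, ed, ef, bapeq, concentration), so identical seeds give identical
draws.  :func:`convergence_check` grows one common draw stream across the
requested iteration counts (common random numbers), so differences between
counts reflect added iterations only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import registry as _registry
from .data_io import (
    ConcentrationMatrix,
    G_PER_DAY_TO_KG_PER_DAY,
    UG_PER_KG_TO_MG_PER_KG,
)
from .registry import CongenerDescriptor, ExposureParameters
from .risk import compute_bapeq

__all__ = [
    "DistributionSpec",
    "MCResult",
    "fit_lognormal",
    "lognormal_from_mean_cv",
    "default_specs",
    "run_simulation",
    "convergence_check",
    "PERCENTILES",
    "DEFAULT_ITERATION_COUNTS",
]

PERCENTILES = (5, 25, 50, 75, 95)
DEFAULT_ITERATION_COUNTS = (4000, 7000, 10000, 13000)

VARIABLES = ("bw", "ir", "ed", "ef", "bapeq", "concentration")
FAMILIES = ("point", "uniform", "normal", "lognormal", "triangular")

_FAMILY_NPARAMS = {"point": 1, "uniform": 2, "normal": 2, "lognormal": 2,
                   "triangular": 3}


@dataclass(frozen=True)
class DistributionSpec:
    """Distribution assigned to one stochastic input variable.

    Parameter conventions: ``point(value)``, ``uniform(low, high)``,
    ``normal(mean, sd)`` truncated at zero, ``lognormal(meanlog, sdlog)``,
    ``triangular(left, mode, right)``.
    """

    variable: str
    family: str
    parameters: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        p = tuple(float(v) for v in self.parameters)
        object.__setattr__(self, "parameters", p)
        if len(p) != _FAMILY_NPARAMS[self.family]:
            raise ValueError(
                f"{self.family} takes {_FAMILY_NPARAMS[self.family]} parameters")
        if self.family == "uniform" and not p[0] < p[1]:
            raise ValueError("uniform requires low < high")
        if self.family == "normal" and p[1] <= 0:
            raise ValueError("normal requires sd > 0")
        if self.family == "lognormal" and p[1] <= 0:
            raise ValueError("lognormal requires sdlog > 0")
        if self.family == "triangular" and not p[0] <= p[1] <= p[2]:
            raise ValueError("triangular requires left <= mode <= right")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.parameters
        if self.family == "point":
            return np.full(size, p[0])
        if self.family == "uniform":
            return rng.uniform(p[0], p[1], size)
        if self.family == "normal":
            draws = rng.normal(p[0], p[1], size)
            while np.any(draws <= 0):  # truncate at zero (physical quantities)
                bad = draws <= 0
                draws[bad] = rng.normal(p[0], p[1], bad.sum())
            return draws
        if self.family == "lognormal":
            return rng.lognormal(p[0], p[1], size)
        return rng.triangular(p[0], p[1], p[2], size)


@dataclass
class MCResult:
    """Outcome draws and summaries of one Monte Carlo run."""

    n_iterations: int
    seed: int | None
    tilcr_draws: np.ndarray
    hi_draws: np.ndarray | None
    percentiles: pd.DataFrame          # index: percentile; columns: tilcr [, hi]
    exceedance: dict[str, float]       # P(HI > 1), P(TILCR > 1e-6), P(TILCR > 1e-4)
    convergence_table: pd.DataFrame | None = None


def fit_lognormal(values: Sequence[float]) -> tuple[float, float, float]:
    """Fit a log-normal to positive data; return (meanlog, sdlog, shapiro_p).

    The log-scale SD uses the sample (ddof = 1) convention.  The Shapiro–Wilk
    p-value tests normality of the log-transformed values; a large p is
    consistent with the log-normal assumption the simulation makes.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-d sample with n >= 3")
    if np.any(x <= 0):
        raise ValueError("all values must be strictly positive")
    logx = np.log(x)
    if np.allclose(logx, logx[0]):
        raise ValueError("constant sample is degenerate for the Shapiro-Wilk test")
    mu = float(logx.mean())
    sigma = float(logx.std(ddof=1))
    _, p = stats.shapiro(logx)
    return mu, sigma, float(p)


def lognormal_from_mean_cv(mean: float, cv: float) -> tuple[float, float]:
    """(meanlog, sdlog) of the log-normal with the given arithmetic mean and CV."""
    if mean <= 0 or cv <= 0:
        raise ValueError("mean and cv must be positive")
    sigma2 = np.log1p(cv ** 2)
    return float(np.log(mean) - sigma2 / 2.0), float(np.sqrt(sigma2))


def default_specs(matrix: ConcentrationMatrix | None = None,
                  registry: Sequence[CongenerDescriptor] | None = None,
                  ) -> dict[str, DistributionSpec]:
    """Default input distributions for the probabilistic assessment.

    BW ~ normal(60, 6) truncated at zero, IR log-normal moment-matched to
    mean 49.3 g/day with CV 0.3, ED ~ uniform(30, 70) years, EF fixed at 365
    day/year.  When a concentration matrix is supplied, the BaP-equivalent
    and total-concentration inputs are log-normals fitted to its per-sample
    totals; these are modelling assumptions (documented in the methods note),
    overridable per variable.
    """
    registry = registry or _registry.builtin_registry()
    specs = {
        "bw": DistributionSpec("bw", "normal", (60.0, 6.0)),
        "ir": DistributionSpec("ir", "lognormal", lognormal_from_mean_cv(49.3, 0.3)),
        "ed": DistributionSpec("ed", "uniform", (30.0, 70.0)),
        "ef": DistributionSpec("ef", "point", (365.0,)),
    }
    if matrix is not None:
        bapeq_totals = np.array(
            [compute_bapeq(row, registry).sum() for row in matrix.values])
        mu, sigma, _ = fit_lognormal(bapeq_totals)
        specs["bapeq"] = DistributionSpec("bapeq", "lognormal", (mu, sigma))
        mu_c, sigma_c, _ = fit_lognormal(matrix.values.sum(axis=1))
        specs["concentration"] = DistributionSpec(
            "concentration", "lognormal", (mu_c, sigma_c))
    return specs


def _mean_composition(matrix: ConcentrationMatrix) -> np.ndarray:
    mean = matrix.values.mean(axis=0)
    return mean / mean.sum()


def run_simulation(specs: Mapping[str, DistributionSpec],
                   fixed: ExposureParameters | None = None,
                   registry: Sequence[CongenerDescriptor] | None = None,
                   n_iterations: int = 10_000,
                   seed: int | None = None,
                   hq_composition: Sequence[float] | None = None) -> MCResult:
    """Run the probabilistic risk simulation.

    ``specs`` must cover bw, ir, ed and bapeq ("ef" defaults to a point mass
    at 365).  If a "concentration" spec is present, HI draws are produced by
    apportioning each drawn total over congeners with ``hq_composition``
    (default: the survey mean composition).  ``fixed`` supplies AT and CSF.
    """
    registry = registry or _registry.builtin_registry()
    fixed = fixed or _registry.default_exposure("carcinogenic")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    missing = {"bw", "ir", "ed", "bapeq"} - set(specs)
    if missing:
        raise ValueError(f"missing distribution specs for {sorted(missing)}")
    for name, spec in specs.items():
        if spec.variable != name:
            raise ValueError(f"spec for {name!r} declares variable {spec.variable!r}")

    rng = np.random.default_rng(seed)
    # fixed draw order guarantees seed-level reproducibility
    bw = specs["bw"].sample(rng, n_iterations)
    ir = specs["ir"].sample(rng, n_iterations)
    ed = specs["ed"].sample(rng, n_iterations)
    ef_spec = specs.get("ef", DistributionSpec("ef", "point", (365.0,)))
    ef = ef_spec.sample(rng, n_iterations)
    bapeq = specs["bapeq"].sample(rng, n_iterations)

    ir_kg = ir * G_PER_DAY_TO_KG_PER_DAY
    scale = (UG_PER_KG_TO_MG_PER_KG * fixed.csf * ir_kg * ef * ed
             / (bw * fixed.at_days))
    tilcr = bapeq * scale

    hi = None
    if "concentration" in specs:
        conc_total = specs["concentration"].sample(rng, n_iterations)
        if hq_composition is None:
            comp = _registry.survey_mean_vector()
            comp = comp / comp.sum()
        else:
            comp = np.asarray(hq_composition, dtype=float)
            comp = comp / comp.sum()
        rfd = _registry.rfd_vector(registry)
        # HI = C_tot * 1e-3 * IR_kg / BW * sum_j comp_j / RfD_j
        hi = (conc_total * UG_PER_KG_TO_MG_PER_KG * ir_kg / bw
              * float((comp / rfd).sum()))

    pct = {"tilcr": np.percentile(tilcr, PERCENTILES)}
    exceedance = {
        "p_tilcr_gt_1e-6": float(np.mean(tilcr > 1e-6)),
        "p_tilcr_gt_1e-4": float(np.mean(tilcr > 1e-4)),
    }
    if hi is not None:
        pct["hi"] = np.percentile(hi, PERCENTILES)
        exceedance["p_hi_gt_1"] = float(np.mean(hi > 1.0))
    percentiles = pd.DataFrame(pct, index=list(PERCENTILES))
    percentiles.index.name = "percentile"

    return MCResult(n_iterations=n_iterations, seed=seed, tilcr_draws=tilcr,
                    hi_draws=hi, percentiles=percentiles, exceedance=exceedance)


def convergence_check(specs: Mapping[str, DistributionSpec],
                      fixed: ExposureParameters | None = None,
                      registry: Sequence[CongenerDescriptor] | None = None,
                      iteration_counts: Sequence[int] = DEFAULT_ITERATION_COUNTS,
                      seed: int | None = None,
                      tolerance: float = 0.01,
                      hq_composition: Sequence[float] | None = None,
                      ) -> tuple[bool, pd.DataFrame]:
    """Iteration sweep: is the 95th-percentile TILCR stable?

    Runs the simulation at each count on a common growing draw stream and
    reports per-count summaries.  ``stable`` is True when the 95th percentile
    changes by less than ``tolerance`` (relative) between the last two
    counts.
    """
    counts = [int(c) for c in iteration_counts]
    if len(counts) < 2:
        raise ValueError("need at least two iteration counts")
    if any(b <= a for a, b in zip(counts, counts[1:])):
        raise ValueError("iteration counts must be strictly increasing")

    full = run_simulation(specs, fixed, registry, n_iterations=counts[-1],
                          seed=seed, hq_composition=hq_composition)
    rows = []
    p95_values = []
    for n in counts:
        draws = full.tilcr_draws[:n]
        p95 = float(np.percentile(draws, 95))
        p95_values.append(p95)
        rows.append({
            "n_iterations": n,
            "tilcr_mean": float(draws.mean()),
            "tilcr_p50": float(np.percentile(draws, 50)),
            "tilcr_p95": p95,
            "tilcr_se": float(draws.std(ddof=1) / np.sqrt(n)),
        })
    table = pd.DataFrame(rows)
    last, prev = p95_values[-1], p95_values[-2]
    denom = abs(prev) if prev != 0 else 1.0
    table["p95_rel_change"] = [np.nan] + [
        abs(b - a) / (abs(a) if a != 0 else 1.0)
        for a, b in zip(p95_values, p95_values[1:])
    ]
    stable = bool(abs(last - prev) / denom < tolerance)
    return stable, table
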