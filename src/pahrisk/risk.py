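"""Deterministic dietary health-risk engine for PAH mixtures.

Carcinogenic risk follows the BaP-equivalents approach:

    BaPeq_i = C_i × TEF_i
    ILCR_i  = BaPeq_i × CSF × IR × EF × ED / (BW × AT)
    TILCR   = Σ_i ILCR_i

and non-carcinogenic risk the hazard-quotient approach:

    HQ_i = C_i × IR / (RfD_i × BW)
    HI   = Σ_i HQ_i

with C_i in mg/kg wet weight, IR in kg/day, and the single carcinogenic
slope factor CSF applied to every congener's BaP-equivalent dose.
Concentrations enter the public API in µg/kg wet weight (and IR in g/day);
the ×10⁻³ conversions are those defined in :mod:`pahrisk.data_io`.

Risk categories for an ILCR value: negligible below 10⁻⁶, cautionary from
10⁻⁶ to 10⁻⁴ inclusive, unacceptable above 10⁻⁴.

Both TILCR and HI are exactly linear in the concentration vector; this
linearity is what lets :mod:`pahrisk.source_risk` attribute risk shares to
PMF factors with exact 100% closure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import registry as _registry
from .data_io import (
    ConcentrationMatrix,
    G_PER_DAY_TO_KG_PER_DAY,
    UG_PER_KG_TO_MG_PER_KG,
)
from .registry import CongenerDescriptor, ExposureParameters

__all__ = [
    "RiskResult",
    "compute_bapeq",
    "compute_ilcr",
    "compute_hq",
    "classify_ilcr",
    "assess_sample",
    "assess",
    "CATEGORIES",
]

CATEGORIES = ("negligible", "cautionary", "unacceptable")


@dataclass
class RiskResult:
    """Per-congener and aggregate risk metrics for one sample."""

    bapeq: np.ndarray       # µg/kg ww
    ilcr: np.ndarray        # dimensionless lifetime probability
    tilcr: float
    hq: np.ndarray          # dimensionless
    hi: float
    ilcr_category: str


def _as_vector(concentrations: Sequence[float],
               registry: Sequence[CongenerDescriptor]) -> np.ndarray:
    conc = np.asarray(concentrations, dtype=float)
    if conc.shape != (len(registry),):
        raise ValueError(
            f"expected a length-{len(registry)} congener vector, got {conc.shape}")
    if np.any(conc < 0):
        raise ValueError("concentrations must be nonnegative")
    return conc


def compute_bapeq(concentrations: Sequence[float],
                  registry: Sequence[CongenerDescriptor] | None = None) -> np.ndarray:
    """BaP-equivalent concentrations, C_i × TEF_i (units preserved, µg/kg ww)."""
    registry = registry or _registry.builtin_registry()
    conc = _as_vector(concentrations, registry)
    return conc * _registry.tef_vector(registry)


def _ilcr_scale(params: ExposureParameters) -> float:
    """ILCR per unit BaPeq (µg/kg ww): the dose/averaging factor of the ILCR equation."""
    if params.bw <= 0 or params.at_days <= 0:
        raise ValueError("bw and at_days must be positive")
    ir_kg = params.ir * G_PER_DAY_TO_KG_PER_DAY
    return (UG_PER_KG_TO_MG_PER_KG * params.csf * ir_kg * params.ef * params.ed
            / (params.bw * params.at_days))


def compute_ilcr(bapeq: Sequence[float],
                 params: ExposureParameters) -> tuple[np.ndarray, float]:
    """Per-congener incremental lifetime cancer risks and their total.

    ``bapeq`` is in µg/kg wet weight; the result is a dimensionless lifetime
    cancer probability per congener plus TILCR, their exact sum.
    """
    bapeq = np.asarray(bapeq, dtype=float)
    if np.any(bapeq < 0):
        raise ValueError("bapeq must be nonnegative")
    ilcr = bapeq * _ilcr_scale(params)
    return ilcr, float(ilcr.sum())


def compute_hq(concentrations: Sequence[float],
               params: ExposureParameters,
               registry: Sequence[CongenerDescriptor] | None = None
               ) -> tuple[np.ndarray, float]:
    """Per-congener hazard quotients and the hazard index (their exact sum)."""
    registry = registry or _registry.builtin_registry()
    conc = _as_vector(concentrations, registry)
    rfd = _registry.rfd_vector(registry)
    if np.any(rfd <= 0):
        raise ValueError("all reference doses must be positive")
    conc_mg = conc * UG_PER_KG_TO_MG_PER_KG
    ir_kg = params.ir * G_PER_DAY_TO_KG_PER_DAY
    hq = conc_mg * ir_kg / (rfd * params.bw)
    return hq, float(hq.sum())


def classify_ilcr(value: float) -> str:
    """Map an ILCR (or TILCR) value onto the three-level risk scale."""
    if value < 0:
        raise ValueError("ILCR cannot be negative")
    if value < 1e-6:
        return "negligible"
    if value <= 1e-4:
        return "cautionary"
    return "unacceptable"


def assess_sample(concentrations: Sequence[float],
                  params: ExposureParameters | None = None,
                  registry: Sequence[CongenerDescriptor] | None = None) -> RiskResult:
    """Full deterministic risk assessment of one 16-congener sample."""
    registry = registry or _registry.builtin_registry()
    params = params or _registry.default_exposure("carcinogenic")
    bapeq = compute_bapeq(concentrations, registry)
    ilcr, tilcr = compute_ilcr(bapeq, params)
    hq, hi = compute_hq(concentrations, params, registry)
    return RiskResult(bapeq=bapeq, ilcr=ilcr, tilcr=tilcr, hq=hq, hi=hi,
                      ilcr_category=classify_ilcr(tilcr))


def assess(matrix: ConcentrationMatrix,
           params: ExposureParameters | None = None,
           registry: Sequence[CongenerDescriptor] | None = None) -> pd.DataFrame:
    """Per-sample risk table for a whole concentration matrix.

    Columns: sample_id, species, HQ_<abbr>... , HI, ILCR_<abbr>..., TILCR,
    category (classification of the sample TILCR).
    """
    registry = registry or _registry.builtin_registry()
    params = params or _registry.default_exposure("carcinogenic")
    abbrs = _registry.abbreviations(registry)

    tef = _registry.tef_vector(registry)
    rfd = _registry.rfd_vector(registry)
    conc_mg = matrix.values * UG_PER_KG_TO_MG_PER_KG
    ir_kg = params.ir * G_PER_DAY_TO_KG_PER_DAY
    hq = conc_mg * ir_kg / (rfd[None, :] * params.bw)
    ilcr = (matrix.values * tef[None, :]) * _ilcr_scale(params)

    out = pd.DataFrame({"sample_id": matrix.sample_ids, "species": matrix.species})
    for j, a in enumerate(abbrs):
        out[f"HQ_{a}"] = hq[:, j]
    out["HI"] = hq.sum(axis=1)
    for j, a in enumerate(abbrs):
        out[f"ILCR_{a}"] = ilcr[:, j]
    out["TILCR"] = ilcr.sum(axis=1)
    out["category"] = [classify_ilcr(v) for v in out["TILCR"]]
    return out
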