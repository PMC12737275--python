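"""Uncertainty-weighted positive matrix factorization (receptor modelling).

Decomposes an n × p matrix of congener concentrations X, with paired
measurement uncertainties U > 0, into k nonnegative factors

    X ≈ G · F,   G ∈ R^{n×k}_{≥0} (source contributions),
                 F ∈ R^{k×p}_{≥0} (source profiles),

by minimizing the uncertainty-weighted objective

    Q(G, F) = Σ_ij ( (x_ij − Σ_h g_ih f_hj) / u_ij )².

The solver uses multiplicative gradient updates (Lee–Seung-style weighted
NMF), which preserve nonnegativity and never increase Q; each fit is
restarted from ``n_starts`` random initializations and the lowest-Q solution
is kept.  Solutions are reported in the canonical scaling where every
profile row sums to one, with factors ordered by decreasing mean
contribution.

Fit diagnostics follow receptor-modelling practice: per-congener r² between
observed and reconstructed concentrations, standardized residuals
(x − ĝf)/u (well-fit data lie within ±3), and the degrees-of-freedom
reference Q_expected = n·p − k·(n + p) used when scanning factor counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import registry as _registry
from .data_io import ConcentrationMatrix, UncertaintyMatrix

__all__ = [
    "FactorModel",
    "fit_pmf",
    "select_k",
    "profile_percentages",
    "label_factors",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class FactorModel:
    """A fitted PMF solution with run metadata and diagnostics."""

    contributions: np.ndarray          # n × k, >= 0
    profiles: np.ndarray               # k × 16, >= 0, rows sum to 1
    q: float
    q_expected: float
    n_starts: int
    best_start: int
    n_iterations: int
    converged: bool
    congener_r2: np.ndarray            # per congener, in [0, 1]
    standardized_residuals: np.ndarray  # n × 16
    q_history: np.ndarray = field(repr=False, default=None)
    labels: list[str] | None = None

    @property
    def k(self) -> int:
        return self.profiles.shape[0]

    def reconstruction(self) -> np.ndarray:
        return self.contributions @ self.profiles


def _as_arrays(x, u) -> tuple[np.ndarray, np.ndarray]:
    X = x.values if isinstance(x, ConcentrationMatrix) else np.asarray(x, dtype=float)
    U = u.values if isinstance(u, UncertaintyMatrix) else np.asarray(u, dtype=float)
    if X.ndim != 2:
        raise ValueError("x must be a 2-d matrix")
    if U.shape != X.shape:
        raise ValueError(f"uncertainty shape {U.shape} != data shape {X.shape}")
    if np.any(X < 0):
        raise ValueError("concentrations must be nonnegative")
    if np.any(U <= 0):
        raise ValueError("uncertainties must be strictly positive")
    return X, U


def _objective(X, W, G, F) -> float:
    r = X - G @ F
    return float(np.sum(W * r * r))


def _single_start(X, W, k, rng, max_iter, tol):
    """One multiplicative-update run; returns (G, F, q_history, converged)."""
    n, p = X.shape
    scale = np.sqrt(max(X.mean(), _EPS) / k)
    G = rng.uniform(0.1, 1.0, size=(n, k)) * scale
    F = rng.uniform(0.1, 1.0, size=(k, p)) * scale

    WX = W * X
    q_prev = _objective(X, W, G, F)
    history = [q_prev]
    converged = False
    for _ in range(max_iter):
        R = G @ F
        G *= (WX @ F.T) / ((W * R) @ F.T + _EPS)
        R = G @ F
        F *= (G.T @ WX) / (G.T @ (W * R) + _EPS)
        q = _objective(X, W, G, F)
        if q > q_prev * (1 + 1e-9) + 1e-12:
            raise RuntimeError(f"objective increased: {q_prev} -> {q}")
        history.append(q)
        if q_prev - q <= tol * max(q_prev, _EPS):
            converged = True
            q_prev = q
            break
        q_prev = q
    return G, F, np.array(history), converged


def _canonicalize(G, F):
    """Scale profile rows to sum 1 (absorbing scale into G) and order factors
    by decreasing mean contribution.  Leaves Q unchanged."""
    row_sums = F.sum(axis=1)
    row_sums[row_sums <= 0] = 1.0
    F = F / row_sums[:, None]
    G = G * row_sums[None, :]
    order = np.argsort(-G.mean(axis=0))
    return G[:, order], F[order, :]


def fit_pmf(x: ConcentrationMatrix | np.ndarray,
            u: UncertaintyMatrix | np.ndarray,
            k: int,
            n_starts: int = 20,
            seed: int | None = None,
            max_iter: int = 2000,
            tol: float = 1e-8) -> FactorModel:
    """Fit a k-factor PMF model, keeping the best of ``n_starts`` random starts.

    ``k`` must satisfy the identifiability bound k·(n + p) < n·p.  Q is
    non-increasing across iterations within each start (checked every
    iteration); a start counts as converged when the relative Q decrease
    falls below ``tol``.
    """
    X, U = _as_arrays(x, u)
    n, p = X.shape
    if k < 2:
        raise ValueError("k must be >= 2")
    if k * (n + p) >= n * p:
        raise ValueError(f"k={k} too large for identifiability with shape {X.shape}")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    W = 1.0 / (U * U)

    seeds = np.random.SeedSequence(seed).spawn(n_starts)
    best = None
    for s in range(n_starts):
        rng = np.random.default_rng(seeds[s])
        G, F, history, converged = _single_start(X, W, k, rng, max_iter, tol)
        q = history[-1]
        if best is None or q < best[2]:
            best = (G, F, q, history, converged, s)

    G, F, q, history, converged, best_start = best
    G, F = _canonicalize(G, F)
    R = G @ F

    r2 = np.empty(p)
    for j in range(p):
        obs, rec = X[:, j], R[:, j]
        if obs.std() == 0 or rec.std() == 0:
            r2[j] = 0.0
        else:
            r2[j] = np.corrcoef(obs, rec)[0, 1] ** 2
    residuals = (X - R) / U

    return FactorModel(
        contributions=G,
        profiles=F,
        q=float(q),
        q_expected=float(n * p - k * (n + p)),
        n_starts=n_starts,
        best_start=best_start,
        n_iterations=len(history) - 1,
        converged=converged,
        congener_r2=r2,
        standardized_residuals=residuals,
        q_history=history,
    )


def select_k(x, u, k_range: Sequence[int],
             n_starts: int = 20, seed: int | None = None,
             max_iter: int = 2000, tol: float = 1e-8) -> pd.DataFrame:
    """Factor-count scan: fit each k and tabulate Q against Q_expected.

    A sharp drop of Q/Q_expected followed by a flattening marks the
    physically meaningful number of sources.
    """
    ks = [int(k) for k in k_range]
    if not ks:
        raise ValueError("empty k range")
    X = x.values if isinstance(x, ConcentrationMatrix) else np.asarray(x, dtype=float)
    n, p = X.shape
    for k in ks:
        if k >= min(n, p):
            raise ValueError(f"k={k} is not below min(n, p)={min(n, p)}")
    rows = []
    for k in ks:
        model = fit_pmf(x, u, k, n_starts=n_starts, seed=seed,
                        max_iter=max_iter, tol=tol)
        rows.append({"k": k, "q": model.q, "q_expected": model.q_expected,
                     "q_over_q_expected": model.q / model.q_expected,
                     "converged": model.converged})
    return pd.DataFrame(rows)


def profile_percentages(model: FactorModel) -> np.ndarray:
    """k × 16 matrix: percent of each congener's mean reconstructed mass per factor.

    Entry (h, j) = 100 · mean_i(g_ih)·f_hj / Σ_h' mean_i(g_ih')·f_h'j; each
    column sums to 100.  This is the "factor loading in percent" convention
    used when describing source profiles.
    """
    mean_g = model.contributions.mean(axis=0)
    mass = mean_g[:, None] * model.profiles
    totals = mass.sum(axis=0)
    if np.any(totals <= 0):
        bad = [j for j, t in enumerate(totals) if t <= 0]
        raise ValueError(f"all-zero reconstructed mass for congener columns {bad}")
    return 100.0 * mass / totals[None, :]


def label_factors(model: FactorModel,
                  markers: Mapping[str, Sequence[str]] | None = None,
                  registry=None) -> list[str]:
    """Assign each factor the source whose marker congeners it dominates.

    ``markers`` maps source name → marker congener abbreviations (disjoint
    sets).  Each factor gets the source with the largest summed marker
    percentage (from :func:`profile_percentages`); ties break toward the
    first-listed source.  The labels are stored on the model and returned.
    """
    if markers is None:
        from .synthetic import default_markers
        markers = default_markers()
    registry = registry or _registry.builtin_registry()
    abbrs = _registry.abbreviations(registry)

    seen: set[str] = set()
    for src, mk in markers.items():
        mk = list(mk)
        unknown = [m for m in mk if m not in abbrs]
        if unknown:
            raise ValueError(f"unknown marker congeners for {src}: {unknown}")
        if seen & set(mk):
            raise ValueError("marker sets must be disjoint")
        seen |= set(mk)

    if model.k > len(markers):
        raise ValueError(
            f"{model.k} factors but only {len(markers)} marker sets")
    if model.k == 1:
        logger.warning("single-factor model: labeling is degenerate")

    pct = profile_percentages(model)
    idx = {a: j for j, a in enumerate(abbrs)}
    sources = list(markers)
    scores = np.array([[pct[h, [idx[m] for m in markers[s]]].sum()
                        for s in sources] for h in range(model.k)])
    labels = []
    for h in range(model.k):
        best = int(np.argmax(scores[h]))  # argmax takes the first maximum: ties
        labels.append(sources[best])      # break toward the first-listed source
    if len(set(labels)) < len(labels):
        logger.warning("duplicate factor labels assigned: %s", labels)
    model.labels = labels
    return labels
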