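"""pDockQ: predicted DockQ from interface confidence.

pDockQ maps a single combined interface statistic,

    x = IF_plDDT * log(IF_contacts),

through a four-parameter sigmoid

    pDockQ(x) = L / (1 + exp(-k * (x - x0))) + b,

to predict the DockQ quality of a complex model without a native
structure.  The default parameters (L=0.724, x0=152.611, k=0.052,
b=0.018) come from fitting this curve to DockQ scores over a large
benchmark of AlphaFold2 heterodimer models; :func:`fit_pdockq` re-fits
them to new (x, DockQ) data by nonlinear least squares.

The logarithm base is configurable (10 or e) and defaults to base 10,
consistent with the fitted midpoint x0 ≈ 153 for IF_plDDT in [0, 100]
and typical contact counts of 10-1000.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .structure import InterfaceMetrics

__all__ = [
    "PDockQParams",
    "DEFAULT_PARAMS",
    "FitResult",
    "FitError",
    "sigmoid",
    "pdockq_x",
    "pdockq_score",
    "fit_pdockq",
    "RankedModel",
    "rank_models",
]


@dataclass(frozen=True)
class PDockQParams:
    """Sigmoid parameters: amplitude L, midpoint x0, steepness k, offset b."""

    L: float
    x0: float
    k: float
    b: float

    def __post_init__(self) -> None:
        if self.L <= 0 or self.k <= 0:
            raise ValueError("sigmoid requires L > 0 and k > 0")

    def as_dict(self) -> dict:
        return {"L": self.L, "x0": self.x0, "k": self.k, "b": self.b}


DEFAULT_PARAMS = PDockQParams(L=0.724, x0=152.611, k=0.052, b=0.018)


def sigmoid(x, L: float, x0: float, k: float, b: float):
    """The pDockQ sigmoid, vectorised over x."""
    return L / (1.0 + np.exp(-k * (np.asarray(x, dtype=float) - x0))) + b


def pdockq_x(metrics: InterfaceMetrics, log_base: float = 10.0) -> float:
    """Combined interface statistic x = IF_plDDT * log(IF_contacts).

    Undefined (NaN) when the model has no interface contacts; callers
    treating the model as a non-interactor should use
    :func:`pdockq_score`, which maps that case to 0.0.
    """
    if metrics.n_if_contacts == 0:
        return float("nan")
    return metrics.if_plddt * math.log(metrics.n_if_contacts, log_base)


def pdockq_score(
    metrics: InterfaceMetrics,
    params: PDockQParams = DEFAULT_PARAMS,
    log_base: float = 10.0,
) -> float:
    """pDockQ of one model; 0.0 when there is no predicted interface.

    A model without a single inter-chain contact carries no interface
    signal at all, so it scores 0.0 (below the sigmoid floor b) and
    naturally ranks as a non-interactor.
    """
    x = pdockq_x(metrics, log_base)
    if math.isnan(x):
        return 0.0
    return float(sigmoid(x, params.L, params.x0, params.k, params.b))


class FitError(RuntimeError):
    """Sigmoid fit failure; carries the best parameters found so far."""

    def __init__(self, message: str, best: PDockQParams | None = None):
        super().__init__(message)
        self.best_params = best


@dataclass(frozen=True)
class FitResult:
    """Fitted sigmoid parameters with residual summary."""

    params: PDockQParams
    mae: float
    n_points: int
    converged: bool


def fit_pdockq(
    xs: Sequence[float], dockqs: Sequence[float]
) -> FitResult:
    """Fit the four-parameter sigmoid to (x, DockQ) pairs.

    Nonlinear least squares (trust-region reflective) initialised at
    L = max(DockQ), x0 = median(x), k = 0.05, b = min(DockQ), with
    bounds L in (0, 1.5], k in (0, 1], b in [0, 0.5]; parameter-step
    tolerance 1e-12.  Returns the parameters and the mean absolute
    residual.  Degenerate input (constant DockQ, constant x, fewer than
    8 points) or non-convergence raises :class:`FitError`.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(dockqs, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("xs and dockqs must be 1-D and of equal length")
    if len(x) < 8:
        raise FitError(f"need at least 8 points, got {len(x)}")
    if np.ptp(x) == 0:
        raise FitError("all x values identical; sigmoid is unidentifiable")
    if np.ptp(y) == 0:
        raise FitError("all DockQ values identical; objective is flat")

    p0 = np.array(
        [
            min(max(y.max(), 1e-3), 1.5),
            float(np.median(x)),
            0.05,
            min(max(y.min(), 0.0), 0.5),
        ]
    )
    lo = np.array([1e-6, -1e6, 1e-6, 0.0])
    hi = np.array([1.5, 1e6, 1.0, 0.5])

    def resid(p):
        return sigmoid(x, *p) - y

    result = least_squares(
        resid, p0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12
    )
    params = PDockQParams(*result.x)
    if result.status <= 0:
        raise FitError("sigmoid fit did not converge", best=params)
    mae = float(np.mean(np.abs(result.fun)))
    return FitResult(
        params=params, mae=mae, n_points=len(x), converged=True
    )


@dataclass
class RankedModel:
    """One model in a ranked list with its ranking signals."""

    model_label: str
    pdockq: float
    n_if_residues: int
    dockq: object | None = None
    is_top: bool = False


def rank_models(
    models: Sequence[tuple[str, InterfaceMetrics]],
    criterion: str = "pdockq",
    params: PDockQParams = DEFAULT_PARAMS,
    log_base: float = 10.0,
) -> list[RankedModel]:
    """Rank differently-seeded models of one complex, best first.

    ``criterion`` is either ``"pdockq"`` (default) or
    ``"n_if_residues"`` (interface residue count).  The sort is stable:
    ties keep input order.  The first entry is flagged ``is_top``.
    """
    if not models:
        raise ValueError("rank_models requires at least one model")
    if criterion not in ("pdockq", "n_if_residues"):
        raise ValueError(f"unknown ranking criterion {criterion!r}")
    ranked = [
        RankedModel(
            model_label=label,
            pdockq=pdockq_score(m, params, log_base),
            n_if_residues=m.n_if_residues,
        )
        for label, m in models
    ]
    key = (
        (lambda r: r.pdockq)
        if criterion == "pdockq"
        else (lambda r: r.n_if_residues)
    )
    ranked.sort(key=key, reverse=True)  # stable: ties keep input order
    ranked[0].is_top = True
    return ranked
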