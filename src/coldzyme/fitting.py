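"""Shared weighted nonlinear least-squares machinery.

Every model fit in the package goes through :func:`fit_curve`, a thin
deterministic wrapper around :mod:`lmfit` that reports parameter estimates,
standard errors, residuals and the reduced chi-square in a uniform
:class:`FitResult`.  Models are registered by name so the CLI and the
synthetic-data generators can refer to them symbolically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import lmfit

__all__ = [
    "TitrationSeries",
    "FitResult",
    "register_model",
    "get_model",
    "fit_curve",
    "linear_fit",
]


@dataclass
class TitrationSeries:
    """Generic (x, y, sigma) series.

    ``axis`` records the semantics of the independent variable
    (e.g. ``"concentration"``, ``"temperature"``, ``"denaturant"``);
    values are held in SI-consistent units (mol/L, K) by convention.
    """

    x: np.ndarray
    y: np.ndarray
    sigma: np.ndarray | None = None
    axis: str = "x"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same shape")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.x.shape:
                raise ValueError("sigma must match x in shape")

    def __len__(self) -> int:
        return self.x.size


@dataclass
class FitResult:
    """Estimates, uncertainties and goodness-of-fit of one model fit."""

    param_estimates: dict[str, float]
    param_uncertainties: dict[str, float]
    residuals: np.ndarray
    reduced_chi2: float
    converged: bool
    n_obs: int
    n_params: int
    message: str = ""

    def __getitem__(self, name: str) -> float:
        return self.param_estimates[name]

    def stderr(self, name: str) -> float:
        return self.param_uncertainties[name]


_MODEL_REGISTRY: dict[str, Callable] = {}


def register_model(model_id: str, func: Callable) -> None:
    """Register ``func(x, **params) -> y`` under ``model_id``."""
    _MODEL_REGISTRY[model_id] = func


def get_model(model_id: str) -> Callable:
    try:
        return _MODEL_REGISTRY[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model {model_id!r}; registered: {sorted(_MODEL_REGISTRY)}"
        ) from None


def fit_curve(
    model_id: str | Callable,
    data: TitrationSeries,
    init: Mapping[str, float],
    bounds: Mapping[str, tuple[float, float]] | None = None,
    fixed: Mapping[str, float] | None = None,
    weights: np.ndarray | None = None,
) -> FitResult:
    """Weighted least-squares fit of a registered model to a series.

    Minimises sum(((y - yhat)/sigma)^2) with a trust-region reflective
    solver and numerical Jacobians.  Deterministic for identical inputs.
    Non-convergence and singular Jacobians are flagged on the result
    (``converged`` / infinite uncertainties), not raised.
    """
    func = get_model(model_id) if isinstance(model_id, str) else model_id
    if len(data) == 0:
        raise ValueError("empty data series")

    params = lmfit.Parameters()
    bounds = bounds or {}
    for name, value in init.items():
        lo, hi = bounds.get(name, (-np.inf, np.inf))
        if not (lo <= value <= hi):
            raise ValueError(f"initial value for {name} outside bounds")
        params.add(name, value=value, min=lo, max=hi)
    for name, value in (fixed or {}).items():
        params.add(name, value=value, vary=False)

    if weights is None and data.sigma is not None:
        weights = 1.0 / data.sigma

    def residual(p: lmfit.Parameters) -> np.ndarray:
        yhat = func(data.x, **{k: p[k].value for k in p})
        r = data.y - yhat
        return r if weights is None else r * weights

    try:
        out = lmfit.minimize(residual, params, method="least_squares")
        converged = bool(out.success)
        message = str(out.message)
    except Exception as exc:  # pathological model/data: flag, don't raise
        estimates = dict(init)
        return FitResult(
            param_estimates=estimates,
            param_uncertainties={k: np.inf for k in estimates},
            residuals=np.full(len(data), np.nan),
            reduced_chi2=np.inf,
            converged=False,
            n_obs=len(data),
            n_params=len(init),
            message=f"fit aborted: {exc}",
        )

    estimates = {k: out.params[k].value for k in init}
    uncerts = {}
    for k in init:
        se = out.params[k].stderr
        uncerts[k] = float(se) if se is not None and np.isfinite(se) else np.inf

    n_obs, n_params = len(data), len(init)
    resid = data.y - func(data.x, **{k: out.params[k].value for k in out.params})
    if n_obs > n_params:
        redchi = float(out.redchi)
    else:
        redchi = np.nan
    return FitResult(
        param_estimates=estimates,
        param_uncertainties=uncerts,
        residuals=resid,
        reduced_chi2=redchi,
        converged=converged,
        n_obs=n_obs,
        n_params=n_params,
        message=message,
    )


def linear_fit(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """Ordinary least-squares straight line, slope + intercept with stderr."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points for a line")
    A = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope, intercept = coef
    resid = y - (slope * x + intercept)
    dof = x.size - 2
    if dof > 0:
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(A.T @ A)
        se_slope, se_inter = np.sqrt(np.diag(cov))
        redchi = s2
    else:
        se_slope = se_inter = 0.0
        redchi = np.nan
    return FitResult(
        param_estimates={"slope": float(slope), "intercept": float(intercept)},
        param_uncertainties={"slope": float(se_slope), "intercept": float(se_inter)},
        residuals=resid,
        reduced_chi2=redchi,
        converged=True,
        n_obs=int(x.size),
        n_params=2,
    )
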