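"""Bounded multi-start Gaussian mixture fitting of fluorescence profiles.

Each centered profile (inside section only) is modelled as a sum of 1-8
Gaussians ``f(x) = sum_k a_k * exp(-((x - b_k)/c_k)^2)``.  Note the
convention: the exponent carries no factor 2, so the width parameter ``c``
obeys ``c^2 = 4*D*t`` for a freely diffusing band — "variance" throughout
this package means this ``c^2``, not the probabilistic variance (which would
be ``c^2/2``).  Keeping the algebra in this parameterization avoids a
factor-2 error in the recovered radii.

Physical bounds: amplitudes non-negative, centers within +-5 um of the peak
(profiles are peak-centered upstream), widths positive and capped at 100 um
globally; between consecutive measurement points the admissible width window
is narrowed by the theoretical minimum/maximum spreading rates
(:func:`sequential_sigma_bounds`), which also forces the fitted curves to
widen monotonically down the channel.

Fits restart from randomized initial positions until no RMSE improvement is
seen for ``patience`` consecutive attempts (default 5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DomainError, FitFailedError, InfeasibleBoundsError

#: global cap on the Gaussian width parameter (um).
SIGMA_CAP = 100.0
#: lower floor on sigma (um); "positive" made numerical.
SIGMA_EPS = 1e-3
#: half-width of the admissible center interval (um).
CENTER_BOUND = 5.0
#: default multi-start patience: consecutive non-improving restarts allowed.
PATIENCE = 5
#: hard ceiling on restarts, so degenerate profiles cannot loop forever.
MAX_RESTARTS = 200


@dataclass(frozen=True)
class GaussianComponent:
    amplitude: float
    center: float
    sigma: float

    @property
    def variance(self) -> float:
        """The c^2 of the fitting convention (equals 4*D*t for a diffusing band)."""
        return self.sigma**2


@dataclass(frozen=True)
class GoF:
    """Goodness-of-fit metrics of one mixture fit."""

    sse: float
    rmse: float
    r2: float
    adj_r2: float
    dfe: int


@dataclass(frozen=True)
class MixtureFit:
    order: int
    components: tuple[GaussianComponent, ...]
    gof: GoF
    n_restarts: int
    seed: int | None


def mixture_value(
    components: Sequence[GaussianComponent], x: np.ndarray | float
) -> np.ndarray | float:
    """Evaluate the Gaussian mixture at ``x``."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for comp in components:
        out = out + comp.amplitude * np.exp(-(((x - comp.center) / comp.sigma) ** 2))
    return out if out.ndim else float(out)


def gof_metrics(observed: np.ndarray, fitted: np.ndarray, p: int) -> GoF:
    """SSE, RMSE (sse/dfe convention), R^2 and adjusted R^2 for a fit with ``p`` parameters."""
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    n = observed.size
    if fitted.size != n:
        raise ValueError("observed and fitted lengths differ")
    if n <= p:
        raise DomainError(f"need n > p, got n={n}, p={p}")
    resid = observed - fitted
    sse = float(resid @ resid)
    dfe = n - p
    rmse = float(np.sqrt(sse / dfe))
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0:
        raise DomainError("observed data are constant; R^2 undefined")
    r2 = 1.0 - sse / sst
    adj_r2 = 1.0 - (sse / dfe) / (sst / (n - 1))
    return GoF(sse=sse, rmse=rmse, r2=r2, adj_r2=adj_r2, dfe=dfe)


def sequential_sigma_bounds(
    prev: MixtureFit | None,
    dt: float,
    slopes: tuple[float, float],
    order: int,
    global_cap: float = SIGMA_CAP,
    eps: float = SIGMA_EPS,
) -> list[tuple[float, float]]:
    """Per-component sigma bounds for the next measurement point.

    The first profile is only constrained by ``(eps, global_cap]``.  For later
    points, component k (sigma-descending rank) may have widened by at least
    ``slope_min * dt`` and at most ``slope_max * dt`` in variance (c^2), so::

        low_k  = sqrt(c_prev_k^2 + slope_min * dt)
        high_k = min(sqrt(c_prev_k^2 + slope_max * dt), global_cap)

    which guarantees the fitted widths never shrink down the channel.
    """
    if dt < 0:
        raise DomainError(f"dt must be non-negative, got {dt}")
    if prev is None:
        return [(eps, global_cap)] * order
    if prev.order != order:
        raise DomainError("previous fit has a different order")
    slope_min, slope_max = slopes
    bounds: list[tuple[float, float]] = []
    for comp in prev.components:
        low = float(np.sqrt(comp.sigma**2 + slope_min * dt))
        high = float(min(np.sqrt(comp.sigma**2 + slope_max * dt), global_cap))
        if low > high:
            raise InfeasibleBoundsError(
                f"sigma window [{low:.4g}, {high:.4g}] collapsed against the "
                f"global cap {global_cap}; point can be skipped"
            )
        bounds.append((low, high))
    return bounds


def _model(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    y = np.zeros_like(x)
    for a, b, c in params.reshape(-1, 3):
        y = y + a * np.exp(-(((x - b) / c) ** 2))
    return y


def fit_mixture(
    x: np.ndarray,
    y: np.ndarray,
    order: int,
    sigma_bounds: Sequence[tuple[float, float]],
    seed: int | np.random.Generator | None = 0,
    patience: int = PATIENCE,
    max_restarts: int = MAX_RESTARTS,
    center_bound: float = CENTER_BOUND,
) -> MixtureFit:
    """Fit an ``order``-component Gaussian mixture by randomized multi-start.

    Bounded trust-region least squares is started from random initial
    parameters (amplitude uniform in [0, 2*max(y)], center uniform within
    +-``center_bound``, sigma log-uniform within its bounds) until
    ``patience`` consecutive restarts fail to improve the best RMSE.
    Returned components are sorted sigma-descending.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 1 <= order <= 8:
        raise DomainError(f"order must be in 1..8, got {order}")
    if x.size <= 3 * order:
        raise DomainError(
            f"need more than {3 * order} points for an order-{order} fit, got {x.size}"
        )
    if len(sigma_bounds) != order:
        raise DomainError("one sigma bound pair per component required")
    for lo, hi in sigma_bounds:
        if not 0 < lo < hi:
            raise DomainError(f"inconsistent sigma bounds ({lo}, {hi})")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_repr = None if isinstance(seed, np.random.Generator) else seed

    lb = np.ravel([[0.0, -center_bound, lo] for lo, _ in sigma_bounds])
    ub = np.ravel([[np.inf, center_bound, hi] for _, hi in sigma_bounds])
    a_hi = 2.0 * max(float(y.max()), 1e-12)

    best_params: np.ndarray | None = None
    best_rmse = np.inf
    stall = 0
    n_restarts = 0
    failures: list[str] = []
    while stall < patience and n_restarts < max_restarts:
        p0 = np.empty(3 * order)
        for k, (lo, hi) in enumerate(sigma_bounds):
            p0[3 * k] = rng.uniform(0.0, a_hi)
            p0[3 * k + 1] = rng.uniform(-center_bound, center_bound)
            p0[3 * k + 2] = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        n_restarts += 1
        try:
            sol = least_squares(
                lambda p: _model(p, x) - y, p0, bounds=(lb, ub), method="trf"
            )
        except Exception as exc:  # pragma: no cover - optimizer hard failure
            failures.append(str(exc))
            stall += 1
            continue
        resid = sol.fun
        rmse = float(np.sqrt((resid @ resid) / (x.size - 3 * order)))
        if rmse < best_rmse * (1.0 - 1e-12):
            best_rmse = rmse
            best_params = sol.x
            stall = 0
        else:
            stall += 1

    if best_params is None:
        raise FitFailedError(
            f"all {n_restarts} starts failed: {failures[-3:] if failures else 'no convergence'}"
        )

    comps = sorted(
        (
            GaussianComponent(amplitude=float(a), center=float(b), sigma=float(c))
            for a, b, c in best_params.reshape(-1, 3)
        ),
        key=lambda comp: comp.sigma,
        reverse=True,
    )
    gof = gof_metrics(y, _model(best_params, x), p=3 * order)
    return MixtureFit(
        order=order,
        components=tuple(comps),
        gof=gof,
        n_restarts=n_restarts,
        seed=seed_repr,
    )


def order_scan(
    profiles: Sequence[tuple[str, np.ndarray, np.ndarray]],
    max_order: int = 8,
    seed: int = 0,
    patience: int = PATIENCE,
    global_cap: float = SIGMA_CAP,
) -> pd.DataFrame:
    """Goodness-of-fit table over mixture orders 1..``max_order`` per point.

    ``profiles`` are ``(label, x, y)`` triples of centered inside sections.
    Every fit uses the global sigma bounds ``(eps, cap]`` — the scan compares
    model orders, it does not chain the sequential physical bounds.  Fit
    errors are recorded in the ``error`` column, not raised.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(profiles) * max_order)
    rows = []
    i = 0
    for label, x, y in profiles:
        for order in range(1, max_order + 1):
            rng = np.random.default_rng(children[i])
            i += 1
            row = {"point": label, "order": order}
            try:
                fit = fit_mixture(
                    x, y, order, [(SIGMA_EPS, global_cap)] * order, seed=rng,
                    patience=patience,
                )
                row.update(
                    sse=fit.gof.sse,
                    rmse=fit.gof.rmse,
                    r2=fit.gof.r2,
                    adj_r2=fit.gof.adj_r2,
                    n_restarts=fit.n_restarts,
                    error=None,
                )
            except Exception as exc:
                row.update(
                    sse=np.nan, rmse=np.nan, r2=np.nan, adj_r2=np.nan,
                    n_restarts=0, error=str(exc),
                )
            rows.append(row)
    return pd.DataFrame(rows)
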