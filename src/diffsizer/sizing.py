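"""Variance-time regression and radius extraction.

After fitting every measurement point with the same mixture order, the k-th
widest component at each point is collected into a track; its width
parameters squared (c^2) grow linearly with transit time for a freely
diffusing species, with slope 4*D.  An ordinary least-squares line with a
free intercept is fitted (the focused stream starts with a finite width, so
the intercept absorbs c0^2), D = slope/4 converts to a hydrodynamic radius
through Stokes-Einstein, and the amplitude/width pairs give an
intensity-weighted particle-count estimate N = a*c*sqrt(pi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    DomainError,
    InsufficientDataError,
    NonPhysicalSlopeError,
    NoResultError,
)
from .mixturefit import MixtureFit
from .physics import Conditions, M2S_TO_UM2S, radius_from_diffusion

#: reported radii never go below this floor (nm).
RADIUS_FLOOR_NM = 1.0


@dataclass
class ComponentTrack:
    """One component rank followed across measurement points."""

    rank: int
    times: np.ndarray  # s
    variances: np.ndarray  # c^2, um^2
    amplitudes: np.ndarray
    sigmas: np.ndarray  # um


@dataclass
class SizingResult:
    rank: int
    slope: float  # um^2/s
    intercept: float  # um^2
    r2_line: float
    D: float  # um^2/s
    radius_nm: float
    clamped: bool
    n_particles: float


@dataclass
class RadiusReport:
    results: list[SizingResult]
    higher: float
    lower: float
    mean_radius: float
    failures: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def track_components(
    fits: Sequence[MixtureFit], times: Sequence[float]
) -> list[ComponentTrack]:
    """Group the k-th widest component of each fit into one track per rank."""
    if len(fits) != len(times):
        raise DomainError("one transit time per fit required")
    orders = {f.order for f in fits}
    if len(orders) != 1:
        raise DomainError(f"fits have differing orders: {sorted(orders)}")
    order = orders.pop()
    t = np.asarray(times, dtype=float)
    tracks = []
    for rank in range(order):
        sig = np.array([f.components[rank].sigma for f in fits])
        amp = np.array([f.components[rank].amplitude for f in fits])
        tracks.append(
            ComponentTrack(
                rank=rank, times=t, variances=sig**2, amplitudes=amp, sigmas=sig
            )
        )
    return tracks


def fit_variance_time(track: ComponentTrack) -> tuple[float, float, float]:
    """OLS line of c^2 against transit time: (slope um^2/s, intercept um^2, R^2)."""
    if track.times.size < 3:
        raise InsufficientDataError(
            f"variance-time fit needs >= 3 points, got {track.times.size}"
        )
    res = stats.linregress(track.times, track.variances)
    slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    if slope <= 0:
        raise NonPhysicalSlopeError(
            f"rank {track.rank}: non-positive variance-time slope {slope:.4g}"
        )
    return slope, intercept, r2


def diffusion_and_radius(
    slope: float, cond: Conditions, floor_nm: float = RADIUS_FLOOR_NM
) -> tuple[float, float, bool]:
    """Convert a variance-time slope (um^2/s) to (D um^2/s, radius nm, clamped).

    D = slope/4; the Stokes-Einstein radius is clamped below at ``floor_nm``
    and the clamp is flagged so provenance can record it.
    """
    if not slope > 0:
        raise DomainError(f"slope must be positive, got {slope}")
    D = slope / 4.0
    r_nm = radius_from_diffusion(D / M2S_TO_UM2S, cond) * 1e9
    if r_nm < floor_nm:
        return D, floor_nm, True
    return D, r_nm, False


def estimate_particle_count(a: float, c: float) -> float:
    """Intensity-weighted particle count N = a*c*sqrt(pi) for one Gaussian band."""
    if a < 0:
        raise DomainError(f"amplitude must be non-negative, got {a}")
    if not c > 0:
        raise DomainError(f"sigma must be positive, got {c}")
    return a * c * math.sqrt(math.pi)


def summarize(
    tracks: Sequence[ComponentTrack],
    cond: Conditions,
    floor_nm: float = RADIUS_FLOOR_NM,
    provenance: dict | None = None,
) -> RadiusReport:
    """Per-rank sizing results plus the higher/lower/mean radius summary.

    With the default two-component fit the report carries a pair of
    approximate radii per measurement; the headline "approximate radius" is
    the arithmetic mean of the component radii.  Ranks whose variance-time
    slope is non-physical are reported as failures, not fabricated radii.
    """
    results: list[SizingResult] = []
    failures: list[dict] = []
    for track in tracks:
        try:
            slope, intercept, r2 = fit_variance_time(track)
            D, r_nm, clamped = diffusion_and_radius(slope, cond, floor_nm)
        except (NonPhysicalSlopeError, InsufficientDataError) as exc:
            failures.append({"rank": track.rank, "error": str(exc)})
            continue
        n_est = float(
            np.mean(
                [estimate_particle_count(a, c) for a, c in zip(track.amplitudes, track.sigmas)]
            )
        )
        results.append(
            SizingResult(
                rank=track.rank,
                slope=slope,
                intercept=intercept,
                r2_line=r2,
                D=D,
                radius_nm=r_nm,
                clamped=clamped,
                n_particles=n_est,
            )
        )
    if not results:
        raise NoResultError(f"no component produced a radius: {failures}")
    radii = [r.radius_nm for r in results]
    prov = dict(provenance or {})
    prov.setdefault("clamped_ranks", [r.rank for r in results if r.clamped])
    return RadiusReport(
        results=results,
        higher=max(radii),
        lower=min(radii),
        mean_radius=float(np.mean(radii)),
        failures=failures,
        provenance=prov,
    )
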