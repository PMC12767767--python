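"""Profile conditioning: crop, wall localization, normalization, centering.

The raw traces come from images that were rotated to make the measurement
vector perpendicular to the flow, which leaves exact zeros at both ends of
every profile.  Preprocessing removes those ends, finds the two channel
sidewalls in the brightfield trace, splits each profile into inside /
outside-left / outside-right sections, brings all baselines to a common
standard, equalizes the area under the fluorescent curves across measurement
points, and finally zeroes the baseline and centers each fluorescent profile
on its peak.  Only the inside section is later fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dataio import ProfilePair
from .errors import (
    BaselineError,
    DegenerateProfileError,
    NoSignalError,
    WallNotFoundError,
)

#: default intensity standard the baselines are brought to.
DEFAULT_BASELINE = 200.0


@dataclass
class SectionedProfile:
    """A profile pair with located walls and the three derived index sections.

    Sections are half-open ``(start, stop)`` index ranges into ``pair.x``:
    ``outside_left`` before the left wall region, ``inside`` between the wall
    regions, ``outside_right`` after the right wall region.  The excluded
    region around each wall center is ``2 * wall_thickness`` wide (the
    displayed wall-line thickness doubled, to absorb the uncertainty between
    the spike position and the middle of the wall line).
    """

    pair: ProfilePair
    wall_centers: tuple[float, float]
    wall_thickness: float
    inside: tuple[int, int]
    outside_left: tuple[int, int]
    outside_right: tuple[int, int]

    def _sl(self, rng: tuple[int, int]) -> slice:
        return slice(*rng)

    @property
    def x_inside(self) -> np.ndarray:
        return self.pair.x[self._sl(self.inside)]

    @property
    def fluor_inside(self) -> np.ndarray:
        return self.pair.fluorescent[self._sl(self.inside)]

    @property
    def bright_inside(self) -> np.ndarray:
        return self.pair.brightfield[self._sl(self.inside)]

    @property
    def fluor_outside(self) -> np.ndarray:
        return np.concatenate(
            [
                self.pair.fluorescent[self._sl(self.outside_left)],
                self.pair.fluorescent[self._sl(self.outside_right)],
            ]
        )

    def inside_integral(self) -> float:
        """Trapezoidal area under the fluorescent curve inside the channel."""
        return float(np.trapezoid(self.fluor_inside, self.x_inside))


def crop_profile(pair: ProfilePair) -> ProfilePair:
    """Remove the rotation-induced zero ends of a profile.

    A band ``mean +- std`` (population std) of the raw brightfield trace is
    formed; points are dropped from each end until the first one whose
    brightfield intensity exceeds the band's lower limit.  The fluorescent
    trace and x are cropped identically.
    """
    bf = pair.brightfield
    if bf.size == 0:
        raise DegenerateProfileError(f"{pair.label}: empty brightfield trace")
    lower = float(bf.mean() - bf.std())  # population std: ddof=0
    above = bf > lower
    if not above.any():
        raise DegenerateProfileError(
            f"{pair.label}: all brightfield points at or below the crop band "
            f"lower limit ({lower:.4g})"
        )
    start = int(np.argmax(above))
    stop = int(len(bf) - np.argmax(above[::-1]))
    return replace(
        pair,
        x=pair.x[start:stop],
        brightfield=bf[start:stop],
        fluorescent=pair.fluorescent[start:stop],
    )


def _argmax_tiebreak_center(y: np.ndarray, x: np.ndarray) -> int:
    """Index of the maximum of y; ties resolved toward the midpoint of x."""
    m = y.max()
    cand = np.flatnonzero(y == m)
    if cand.size == 1:
        return int(cand[0])
    mid = 0.5 * (x[0] + x[-1])
    return int(cand[np.argmin(np.abs(x[cand] - mid))])


def locate_walls(pair: ProfilePair, wall_thickness: float) -> SectionedProfile:
    """Find the two sidewall spikes and split the profile into three sections.

    Starting from the fluorescent maximum, the brightfield trace is scanned
    in both directions; in each direction the wall center is the sample whose
    intensity deviates most from the brightfield mean (the spike may be
    bright or dark).  A region of width ``2 * wall_thickness`` centered on
    each wall is excluded from all sections.
    """
    x, bf, fl = pair.x, pair.brightfield, pair.fluorescent
    peak = _argmax_tiebreak_center(fl, x)
    bf_mean = bf.mean()
    dev = np.abs(bf - bf_mean)

    left_i = int(np.argmax(dev[: peak + 1]))
    right_i = peak + int(np.argmax(dev[peak:]))
    lw, rw = float(x[left_i]), float(x[right_i])
    if lw - x[0] < wall_thickness or x[-1] - rw < wall_thickness:
        raise WallNotFoundError(
            f"{pair.label}: wall extremum within {wall_thickness} um of the trace end"
        )
    if not lw < rw:
        raise WallNotFoundError(f"{pair.label}: walls not separated (left {lw}, right {rw})")

    ol_stop = int(np.searchsorted(x, lw - wall_thickness, side="left"))
    in_start = int(np.searchsorted(x, lw + wall_thickness, side="right"))
    in_stop = int(np.searchsorted(x, rw - wall_thickness, side="left"))
    or_start = int(np.searchsorted(x, rw + wall_thickness, side="right"))
    return SectionedProfile(
        pair=pair,
        wall_centers=(lw, rw),
        wall_thickness=float(wall_thickness),
        inside=(in_start, in_stop),
        outside_left=(0, ol_stop),
        outside_right=(or_start, len(x)),
    )


def normalize_brightfield(sp: SectionedProfile, standard: float = DEFAULT_BASELINE) -> SectionedProfile:
    """Scale the brightfield so its inside-channel mean equals ``standard``."""
    inside_mean = float(sp.bright_inside.mean())
    if not inside_mean > 0:
        raise DegenerateProfileError(
            f"{sp.pair.label}: non-positive inside brightfield mean"
        )
    factor = standard / inside_mean
    pair = replace(sp.pair, brightfield=sp.pair.brightfield * factor)
    return replace(sp, pair=pair)


def normalize_fluorescent_set(
    sps: list[SectionedProfile],
    standard: float = DEFAULT_BASELINE,
    baseline_region: str = "outside",
) -> list[SectionedProfile]:
    """Two-step fluorescence normalization across a measurement set.

    Step 1 aligns every profile's baseline to ``standard`` (multiplicative).
    Step 2 multiplies each profile by the ratio of the largest inside-channel
    integral across the set to its own, so all inside areas agree; this
    compensates slow illumination / accumulation drift between points.

    ``baseline_region`` selects where the step-1 baseline is measured:
    ``"outside"`` (default; the inside carries analyte signal) or
    ``"inside"``.
    """
    if baseline_region not in ("outside", "inside"):
        raise ValueError(f"baseline_region must be outside|inside, got {baseline_region}")
    step1: list[SectionedProfile] = []
    for sp in sps:
        region = sp.fluor_outside if baseline_region == "outside" else sp.fluor_inside
        if region.size == 0:
            raise BaselineError(
                f"{sp.pair.label}: no {baseline_region} section to estimate the baseline"
            )
        base = float(region.mean())
        if not base > 0:
            raise BaselineError(f"{sp.pair.label}: non-positive baseline estimate")
        pair = replace(sp.pair, fluorescent=sp.pair.fluorescent * (standard / base))
        step1.append(replace(sp, pair=pair))

    integrals = [sp.inside_integral() for sp in step1]
    if any(not i > 0 for i in integrals):
        raise BaselineError("non-positive inside integral; cannot area-normalize")
    target = max(integrals)
    out: list[SectionedProfile] = []
    for sp, integral in zip(step1, integrals):
        pair = replace(sp.pair, fluorescent=sp.pair.fluorescent * (target / integral))
        out.append(replace(sp, pair=pair))
    return out


def zero_and_center(sp: SectionedProfile) -> SectionedProfile:
    """Zero the fluorescent baseline and center the profile on its peak.

    The mean of the outside sections is subtracted from the whole fluorescent
    trace, then x is rigidly shifted so the fluorescent peak sits at x = 0;
    the brightfield shares the x axis so it shifts along, as do the wall
    centers.  Raises :class:`NoSignalError` when no peak rises above
    baseline + 3 standard deviations of the outside samples.
    """
    outside = sp.fluor_outside
    if outside.size == 0:
        raise BaselineError(f"{sp.pair.label}: no outside section to zero against")
    base = float(outside.mean())
    noise = float(outside.std())
    fl = sp.pair.fluorescent
    if fl.max() <= base + 3.0 * noise:
        raise NoSignalError(
            f"{sp.pair.label}: flat fluorescent trace (no peak above baseline + 3 sigma)"
        )
    fl0 = fl - base
    peak = _argmax_tiebreak_center(fl0, sp.pair.x)
    shift = -float(sp.pair.x[peak])
    pair = replace(sp.pair, x=sp.pair.x + shift, fluorescent=fl0)
    return replace(
        sp,
        pair=pair,
        wall_centers=(sp.wall_centers[0] + shift, sp.wall_centers[1] + shift),
    )
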