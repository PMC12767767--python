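"""Stokes-Einstein arithmetic and the device flow model.

Computes the diffusion coefficient of a 2 nm particle in water at 25 C, the
mean carrier speed at the steady-state pump rates, the transit times to the
eleven measurement points, and the admissible variance-time slopes for the
1 nm - 2 um radius range.
"""

from diffsizer import (
    diffusion_from_radius,
    mean_velocity,
    slope_bounds,
    transit_times,
)
from diffsizer.synthetic import default_conditions, default_geometry, steady_state_flow

cond = default_conditions()
geom = default_geometry()
flow = steady_state_flow()

D = diffusion_from_radius(2e-9, cond)
print(f"D(2 nm)            = {D * 1e12:.1f} um^2/s")

v = mean_velocity(flow, geom)
print(f"mean velocity      = {v:.0f} um/s  (total {flow.total} uL/min over "
      f"{geom.channel_height:.0f} x {geom.channel_width:.0f} um)")

times, deltas = transit_times(geom, v)
print(f"transit times      = {times[0]:.3f} .. {times[-1]:.3f} s over "
      f"{len(times)} points (spacing {deltas[0]:.3f} s)")

lo, hi = slope_bounds(1e-9, 2e-6, cond)
print(f"slope bounds (4*D) = [{lo:.3f}, {hi:.1f}] um^2/s for radii in [1 nm, 2 um]")
print("A fitted variance-time slope outside these bounds cannot belong to a "
      "particle in the admissible size range.")
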