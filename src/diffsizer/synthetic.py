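"""Forward Brownian-diffusion simulator for measurement workbooks.

Generates the same kind of data the microscope pipeline produces — one
brightfield/fluorescent profile pair per measurement point along the main
channel — from known ground truth, so every analysis stage and the
end-to-end radius recovery can be tested without laboratory data.

The model: a hydrodynamically focused analyte band starts as a Gaussian of
width c0 at the channel center and spreads by 1-D free diffusion, so at
transit time t a species of diffusion coefficient D contributes
``a(t) * exp(-x^2 / (c0^2 + 4*D*t))`` with ``a(t) = N / sqrt(pi*(c0^2+4*D*t))``
— amplitudes shrink as the band widens, conserving the area (the particle
number N), which makes the N = a*c*sqrt(pi) estimate testable.  On top of
the diffusing band the synthetic camera adds: a flat baseline near intensity
200; two wall spikes in the brightfield trace (narrow Gaussian bumps at the
channel edges, as the imaged wall lines appear); zero-padded profile ends,
as left by image rotation; additive Gaussian noise; and an optional
multiplicative per-point drift emulating fluorophore accumulation on
untreated channel surfaces.

Wall reflection is not modelled; instead the simulator refuses parameter
sets whose diffusion length ``3*sqrt(c0^2 + 4*D*t_max)`` exceeds half the
channel width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dataio import MeasurementSet, Metadata, ProfilePair, write_measurement_workbook
from .errors import DomainError
from .physics import (
    Conditions,
    DeviceGeometry,
    FlowConfig,
    M2S_TO_UM2S,
    diffusion_from_radius,
    mean_velocity,
    transit_times,
)

#: admissible species radius range (nm), matching the analysis assumptions.
R_MIN_NM, R_MAX_NM = 1.0, 2000.0


@dataclass(frozen=True)
class Species:
    radius_nm: float
    abundance: float = 1.0
    sigma0_um: float = 10.0  # width of the focused band at the channel origin

    def __post_init__(self) -> None:
        if not R_MIN_NM <= self.radius_nm <= R_MAX_NM:
            raise DomainError(
                f"species radius {self.radius_nm} nm outside [{R_MIN_NM}, {R_MAX_NM}] nm"
            )
        if not self.abundance > 0:
            raise DomainError("abundance must be positive")
        if not self.sigma0_um > 0:
            raise DomainError("initial sigma must be positive")


@dataclass(frozen=True)
class SpeciesMix:
    species: tuple[Species, ...]

    def __post_init__(self) -> None:
        if not self.species:
            raise DomainError("species mix must not be empty")


@dataclass(frozen=True)
class NoiseModel:
    """Camera and drift model.

    baseline        : flat intensity offset of both traces (camera counts)
    additive_sd     : sd of additive Gaussian noise on both traces (counts)
    drift_per_point : multiplicative accumulation per measurement point on the
                      fluorescent signal (0 = stable; models surface adsorption)
    seed            : RNG seed for the noise draws
    """

    baseline: float = 200.0
    additive_sd: float = 0.0
    drift_per_point: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.baseline < 0:
            raise DomainError("baseline and additive_sd must be non-negative")


def default_geometry() -> DeviceGeometry:
    """The study device: 300 x 20 um main channel, 20 um wall lines, and
    eleven equidistant measurement points from 1 mm to 51 mm downstream."""
    return DeviceGeometry(
        channel_width=300.0,
        channel_height=20.0,
        wall_thickness=20.0,
        positions=tuple(1000.0 + 5000.0 * i for i in range(11)),
    )


def steady_state_flow() -> FlowConfig:
    """Steady-state pump rates: 1 uL/min analyte, 4 uL/min per buffer side."""
    return FlowConfig(analyte_flow=1.0, buffer_flow=4.0)


def default_conditions() -> Conditions:
    """Aqueous buffer at 25 C."""
    return Conditions(temperature=298.15, viscosity=8.9e-4)


def simulate_profiles(
    mix: SpeciesMix,
    geom: DeviceGeometry | None = None,
    flow: FlowConfig | None = None,
    cond: Conditions | None = None,
    noise: NoiseModel | None = None,
    dx: float = 2.0,
    outside_margin: float = 150.0,
    pad_samples: int = 25,
    peak_amplitude: float = 1000.0,
    wall_bright: bool = True,
    exposure: float = 1.0,
) -> MeasurementSet:
    """Simulate a full measurement set with embedded ground truth.

    ``peak_amplitude`` is the summed signal amplitude above baseline at the
    channel origin; species split it according to their abundances.
    ``wall_bright`` selects bright (spikes up) or dark (dips down) wall lines.
    """
    geom = geom or default_geometry()
    flow = flow or steady_state_flow()
    cond = cond or default_conditions()
    noise = noise or NoiseModel()

    v = mean_velocity(flow, geom)
    times, _ = transit_times(geom, v)
    t_max = float(times[-1])

    total_ab = sum(s.abundance for s in mix.species)
    d_um2s = {}
    for s in mix.species:
        D = diffusion_from_radius(s.radius_nm * 1e-9, cond) * M2S_TO_UM2S
        d_um2s[s] = D
        reach = 3.0 * math.sqrt(s.sigma0_um**2 + 4.0 * D * t_max)
        if reach > geom.channel_width / 2.0:
            raise DomainError(
                f"species r={s.radius_nm} nm would reach the sidewalls "
                f"(3 sigma = {reach:.0f} um > half-width {geom.channel_width / 2:.0f} um); "
                "wall reflection is not modelled"
            )

    half_w = geom.channel_width / 2.0
    wall_center = half_w + geom.wall_thickness / 2.0
    half_span = wall_center + geom.wall_thickness / 2.0 + outside_margin
    n_half = int(round(half_span / dx))
    x = np.arange(-n_half, n_half + 1) * dx  # symmetric grid incl. channel center 0
    if 2 * pad_samples >= x.size:
        raise DomainError("pad_samples too large for the grid")

    wall_sd = geom.wall_thickness / 4.0
    wall_amp = noise.baseline if wall_bright else -0.9 * noise.baseline
    bf_clean = noise.baseline + wall_amp * (
        np.exp(-(((x + wall_center) / wall_sd) ** 2) / 2.0)
        + np.exp(-(((x - wall_center) / wall_sd) ** 2) / 2.0)
    )

    rng = np.random.default_rng(noise.seed)
    profiles: list[ProfilePair] = []
    truth_species = []
    for s in mix.species:
        a0 = peak_amplitude * s.abundance / total_ab
        truth_species.append(
            {
                "radius_nm": s.radius_nm,
                "abundance": s.abundance,
                "sigma0_um": s.sigma0_um,
                "D_um2_s": d_um2s[s],
                "N": a0 * s.sigma0_um * math.sqrt(math.pi),
            }
        )

    for i, (pos, t) in enumerate(zip(geom.positions, times)):
        signal = np.zeros_like(x)
        for s in mix.species:
            a0 = peak_amplitude * s.abundance / total_ab
            var = s.sigma0_um**2 + 4.0 * d_um2s[s] * t
            # amplitude scales as N / sqrt(pi * c^2): area is conserved
            a = a0 * s.sigma0_um / math.sqrt(var)
            signal += a * np.exp(-(x**2) / var)
        signal *= (1.0 + noise.drift_per_point) ** i
        fl = noise.baseline + signal
        bf = bf_clean.copy()
        if noise.additive_sd > 0:
            fl = fl + rng.normal(0.0, noise.additive_sd, size=x.size)
            bf = bf + rng.normal(0.0, noise.additive_sd, size=x.size)
        # quantize to 1e-6 counts: far below camera quantization, and exactly
        # representable through the workbook writer's 16-digit decimal cells
        fl = np.round(np.clip(fl, 0.0, None), 6)
        bf = np.round(np.clip(bf, 0.0, None), 6)
        # rotation leaves exact zeros at both profile ends
        if pad_samples:
            fl[:pad_samples] = 0.0
            fl[-pad_samples:] = 0.0
            bf[:pad_samples] = 0.0
            bf[-pad_samples:] = 0.0
        profiles.append(
            ProfilePair(
                label=f"P{i:02d}",
                position=float(pos),
                x=x - x[0],  # workbook x starts at 0 at the left trace edge
                brightfield=bf,
                fluorescent=fl,
            )
        )

    metadata = Metadata(
        geometry=geom, flow=flow, conditions=cond, exposure=exposure, omit=()
    )
    provenance = {
        "generator": "diffsizer.synthetic.simulate_profiles",
        "species": truth_species,
        "noise": {
            "baseline": noise.baseline,
            "additive_sd": noise.additive_sd,
            "drift_per_point": noise.drift_per_point,
            "seed": noise.seed,
        },
        "dx_um": dx,
        "wall_centers_x": [
            float(-wall_center - x[0]),
            float(wall_center - x[0]),
        ],
        "peak_amplitude": peak_amplitude,
    }
    return MeasurementSet(metadata=metadata, profiles=profiles, provenance=provenance)


def make_fixture_suite(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the standard test-fixture workbooks plus a ground-truth manifest.

    Emits: single-species (2 nm), two-species (1.5 + 3 nm), high-noise,
    drifting-baseline and degenerate (flat fluorescent) workbooks.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    specs = {
        "single_2nm": dict(
            mix=SpeciesMix((Species(2.0),)), noise=NoiseModel(seed=seed)
        ),
        "two_species_1p5_3nm": dict(
            mix=SpeciesMix((Species(1.5), Species(3.0))), noise=NoiseModel(seed=seed + 1)
        ),
        "high_noise_2nm": dict(
            mix=SpeciesMix((Species(2.0),)),
            noise=NoiseModel(additive_sd=50.0, seed=seed + 2),
        ),
        "drifting_2nm": dict(
            mix=SpeciesMix((Species(2.0),)),
            noise=NoiseModel(additive_sd=10.0, drift_per_point=0.05, seed=seed + 3),
        ),
        "degenerate_flat": dict(
            mix=SpeciesMix((Species(2.0),)),
            noise=NoiseModel(seed=seed + 4),
            peak_amplitude=0.0,
        ),
    }
    manifest: dict[str, dict] = {}
    paths: dict[str, Path] = {}
    for name, kw in specs.items():
        ms = simulate_profiles(**kw)
        p = outdir / f"{name}.xlsx"
        write_measurement_workbook(ms, p)
        paths[name] = p
        manifest[name] = {
            "file": p.name,
            "radii_nm": [s["radius_nm"] for s in ms.provenance["species"]],
            "provenance": ms.provenance,
        }
    manifest_path = outdir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths
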