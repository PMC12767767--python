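"""End-to-end analysis: read -> preprocess -> fit -> size -> report.

:func:`run_pipeline` executes the whole chain on one measurement workbook
and returns the radius report together with per-point fits, component
tracks, the goodness-of-fit table, and a structured event log.  Everything
is deterministic given the configuration seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import dataio, mixturefit, preprocess, sizing
from .dataio import MeasurementSet
from .errors import InfeasibleBoundsError, InsufficientDataError, DiffsizerError, StageError
from .mixturefit import MixtureFit
from .physics import mean_velocity, slope_bounds, transit_times
from .preprocess import SectionedProfile
from .sizing import ComponentTrack, RadiusReport


class RunConfig(BaseModel):
    """Tunable analysis parameters.

    order                : number of Gaussian components fitted per profile
    r_min_nm, r_max_nm   : admissible hydrodynamic radius range; r_min is
                           also the reporting floor
    baseline             : intensity standard the baselines are brought to
    patience             : multi-start stop rule (consecutive non-improving
                           restarts)
    sigma_cap            : global cap on the Gaussian width parameter (um)
    omit                 : measurement-point labels excluded from evaluation
    fluor_baseline_region: where the step-1 fluorescence baseline is measured
    """

    order: int = Field(default=2, ge=1, le=8)
    r_min_nm: float = 1.0
    r_max_nm: float = 2000.0
    baseline: float = 200.0
    patience: int = Field(default=5, ge=1)
    max_restarts: int = Field(default=mixturefit.MAX_RESTARTS, ge=1)
    sigma_cap: float = mixturefit.SIGMA_CAP
    seed: int = 0
    omit: tuple[str, ...] = ()
    fluor_baseline_region: str = "outside"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if not 0 < self.r_min_nm < self.r_max_nm:
            raise ValueError("need 0 < r_min_nm < r_max_nm")
        if self.fluor_baseline_region not in ("outside", "inside"):
            raise ValueError("fluor_baseline_region must be outside|inside")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    report: RadiusReport
    fits: list[MixtureFit]
    tracks: list[ComponentTrack]
    gof_table: pd.DataFrame
    sections: list[SectionedProfile]
    times: np.ndarray
    events: list[dict] = field(default_factory=list)


def preprocess_set(
    ms: MeasurementSet, config: RunConfig
) -> list[SectionedProfile]:
    """Crop, locate walls, normalize and center every profile of a set."""
    sections: list[SectionedProfile] = []
    wall = ms.metadata.geometry.wall_thickness
    for pair in ms.profiles:
        try:
            cropped = preprocess.crop_profile(pair)
            sp = preprocess.locate_walls(cropped, wall)
            sp = preprocess.normalize_brightfield(sp, config.baseline)
        except DiffsizerError as exc:
            raise StageError("preprocess", pair.label, exc) from exc
        sections.append(sp)
    # fluorescence normalization couples the whole set
    try:
        sections = preprocess.normalize_fluorescent_set(
            sections, config.baseline, config.fluor_baseline_region
        )
        out = []
        for sp in sections:
            try:
                out.append(preprocess.zero_and_center(sp))
            except DiffsizerError as exc:
                raise StageError("preprocess", sp.pair.label, exc) from exc
    except StageError:
        raise
    except DiffsizerError as exc:
        raise StageError("preprocess", None, exc) from exc
    return out


def run_pipeline(
    workbook: str | Path | MeasurementSet,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full sizing analysis on a workbook (path or in-memory set)."""
    config = config or RunConfig()
    events: list[dict] = []

    if isinstance(workbook, MeasurementSet):
        ms = workbook
        source = ms.provenance.get("generator", "<in-memory>")
        if len(ms.profiles) < dataio.MIN_PROFILES:
            raise StageError(
                "read", None,
                InsufficientDataError(
                    f"only {len(ms.profiles)} usable measurement points; "
                    f"need at least {dataio.MIN_PROFILES}"
                ),
            )
        if config.omit:
            keep = [p for p in ms.profiles if p.label not in config.omit]
            if len(keep) < dataio.MIN_PROFILES:
                raise StageError(
                    "read", None,
                    InsufficientDataError(
                        f"only {len(keep)} usable measurement points after omission; "
                        f"need at least {dataio.MIN_PROFILES}"
                    ),
                )
            geom = ms.metadata.geometry
            geom = type(geom)(
                geom.channel_width, geom.channel_height, geom.wall_thickness,
                tuple(p.position for p in keep),
            )
            ms = MeasurementSet(
                metadata=dataio.Metadata(
                    geometry=geom, flow=ms.metadata.flow,
                    conditions=ms.metadata.conditions,
                    exposure=ms.metadata.exposure, omit=config.omit,
                ),
                profiles=keep,
                provenance=ms.provenance,
            )
    else:
        source = str(workbook)
        try:
            ms = dataio.read_measurement_workbook(workbook, omit=config.omit)
        except DiffsizerError as exc:
            raise StageError("read", None, exc) from exc

    cond = ms.metadata.conditions
    geom = ms.metadata.geometry
    v = mean_velocity(ms.metadata.flow, geom)
    times, _deltas = transit_times(geom, v)
    slopes = slope_bounds(config.r_min_nm * 1e-9, config.r_max_nm * 1e-9, cond)
    events.append(
        {"stage": "physics", "mean_velocity_um_s": v, "slope_bounds_um2_s": list(slopes)}
    )

    sections = preprocess_set(ms, config)

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(sections))
    fits: list[MixtureFit] = []
    kept_times: list[float] = []
    kept_labels: list[str] = []
    prev: MixtureFit | None = None
    prev_t: float | None = None
    for sp, t, child in zip(sections, times, children):
        label = sp.pair.label
        dt = 0.0 if prev_t is None else float(t - prev_t)
        try:
            bounds = mixturefit.sequential_sigma_bounds(
                prev, dt, slopes, config.order, global_cap=config.sigma_cap
            )
        except InfeasibleBoundsError as exc:
            events.append({"stage": "fit", "point": label, "skipped": str(exc)})
            continue
        try:
            fit = mixturefit.fit_mixture(
                sp.x_inside,
                sp.fluor_inside,
                config.order,
                bounds,
                seed=np.random.default_rng(child),
                patience=config.patience,
                max_restarts=config.max_restarts,
            )
        except DiffsizerError as exc:
            raise StageError("fit", label, exc) from exc
        fits.append(fit)
        kept_times.append(float(t))
        kept_labels.append(label)
        prev, prev_t = fit, float(t)

    if len(fits) < 3:
        raise StageError(
            "fit", None,
            InsufficientDataError(f"only {len(fits)} fitted points; need >= 3"),
        )

    gof_table = pd.DataFrame(
        {
            "point": kept_labels,
            "order": [f.order for f in fits],
            "sse": [f.gof.sse for f in fits],
            "rmse": [f.gof.rmse for f in fits],
            "r2": [f.gof.r2 for f in fits],
            "adj_r2": [f.gof.adj_r2 for f in fits],
            "n_restarts": [f.n_restarts for f in fits],
        }
    )

    tracks = sizing.track_components(fits, kept_times)
    provenance = {
        "source": source,
        "config": config.model_dump(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "omit": list(config.omit),
    }
    try:
        report = sizing.summarize(
            tracks, cond, floor_nm=config.r_min_nm, provenance=provenance
        )
    except DiffsizerError as exc:
        raise StageError("sizing", None, exc) from exc
    for failure in report.failures:
        events.append({"stage": "sizing", **failure})
    if report.provenance.get("clamped_ranks"):
        events.append(
            {"stage": "sizing", "clamped_ranks": report.provenance["clamped_ranks"]}
        )

    result = PipelineResult(
        report=report,
        fits=fits,
        tracks=tracks,
        gof_table=gof_table,
        sections=sections,
        times=np.asarray(kept_times),
        events=events,
    )
    if outdir is not None:
        _write_diagnostics(result, Path(outdir))
    return result


def _write_diagnostics(result: PipelineResult, outdir: Path) -> None:
    from . import plots

    outdir.mkdir(parents=True, exist_ok=True)
    dataio.write_results(result.report, outdir / "report.json", "json")
    dataio.write_results(result.report, outdir / "report.csv", "csv")
    result.gof_table.to_csv(outdir / "gof_table.csv", index=False)
    (outdir / "events.json").write_text(
        json.dumps(result.events, indent=2, default=dataio._jsonable)
    )
    plots.plot_variance_time(result, outdir / "variance_time.png")
    plots.plot_profiles(result, outdir / "profiles.png")
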