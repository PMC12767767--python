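"""Measurement-workbook I/O and result serialization.

Workbook dialect
----------------
Sheet 1, named ``metadata``, holds key/value rows with these required keys::

    channel_width_um, channel_height_um, wall_thickness_um,
    analyte_flow_ul_min, buffer_flow_ul_min, temperature_K,
    viscosity_Pa_s, exposure_s

Each subsequent sheet is one measurement point (named ``P00``, ``P01``, ...,
front of the channel toward the outlet).  Cell A1 is the literal
``distance_um`` with the point's distance from the channel origin in B1;
row 2 holds the column headers ``position_um | brightfield | fluorescent``
and the data follow.  ``position_um`` is the cross-channel coordinate of each
sample, uniformly spaced.

Deposited workbooks that deviate from this layout get an explicit adapter
written against the actual files; the reader never guesses silently.

Numeric cells are written as decimal text with 16 significant digits (the
XLSX writer's formatting), so values whose shortest decimal form needs at
most 16 digits — in particular all workbooks this package generates, which
quantize intensities to 1e-6 counts — round-trip bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from openpyxl import Workbook, load_workbook

from .errors import FormatError, InsufficientDataError, SchemaError, UsageError
from .physics import Conditions, DeviceGeometry, FlowConfig

REQUIRED_KEYS = (
    "channel_width_um",
    "channel_height_um",
    "wall_thickness_um",
    "analyte_flow_ul_min",
    "buffer_flow_ul_min",
    "temperature_K",
    "viscosity_Pa_s",
    "exposure_s",
)

#: minimum usable measurement points: a line needs >= 2 variance points
#: beyond the first.
MIN_PROFILES = 3

#: relative tolerance for the uniform-spacing check on x.
_SPACING_RTOL = 1e-6


@dataclass
class ProfilePair:
    """Aligned cross-channel traces at one measurement point.

    x : sample positions along the cross-channel vector (um), uniform grid
    brightfield, fluorescent : intensity traces (camera counts), same length
    position : distance of this point from the channel origin (um)
    """

    label: str
    position: float
    x: np.ndarray
    brightfield: np.ndarray
    fluorescent: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.brightfield = np.asarray(self.brightfield, dtype=float)
        self.fluorescent = np.asarray(self.fluorescent, dtype=float)
        if not (len(self.x) == len(self.brightfield) == len(self.fluorescent)):
            raise FormatError(f"{self.label}: trace lengths differ")
        if len(self.x) >= 2 and np.any(np.diff(self.x) <= 0):
            raise FormatError(f"{self.label}: x must be strictly increasing")

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    def shifted(self, delta: float) -> "ProfilePair":
        """Rigid shift of the x axis by ``delta`` um."""
        return replace(self, x=self.x + delta)


@dataclass
class Metadata:
    geometry: DeviceGeometry
    flow: FlowConfig
    conditions: Conditions
    exposure: float
    omit: tuple[str, ...] = ()


@dataclass
class MeasurementSet:
    """A full experiment: metadata plus ordered per-point profile pairs."""

    metadata: Metadata
    profiles: list[ProfilePair]
    provenance: dict = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.profiles]


def _check_uniform(x: np.ndarray, label: str) -> None:
    d = np.diff(x)
    if d.size == 0:
        raise FormatError(f"{label}: profile has fewer than 2 samples")
    if np.any(d <= 0):
        raise FormatError(f"{label}: x not strictly increasing")
    step = d.mean()
    if np.max(np.abs(d - step)) > _SPACING_RTOL * abs(step):
        raise FormatError(f"{label}: non-uniform x spacing")


def read_measurement_workbook(
    path: str | Path, omit: Iterable[str] = ()
) -> MeasurementSet:
    """Read a measurement workbook, dropping the measurement points in ``omit``.

    Sheet order is preserved; omission is by label, never by index.
    """
    omit = tuple(omit)
    wb = load_workbook(Path(path), data_only=True, read_only=True)
    try:
        if "metadata" not in wb.sheetnames:
            raise SchemaError("workbook has no 'metadata' sheet")
        meta_raw: dict[str, float] = {}
        for row in wb["metadata"].iter_rows(values_only=True):
            if row and row[0] is not None:
                meta_raw[str(row[0])] = row[1]
        for key in REQUIRED_KEYS:
            if key not in meta_raw or meta_raw[key] is None:
                raise SchemaError(f"metadata sheet is missing required key '{key}'")
        meta = {k: float(v) for k, v in meta_raw.items() if k in REQUIRED_KEYS}

        sheet_labels = [s for s in wb.sheetnames if s != "metadata"]
        unknown = set(omit) - set(sheet_labels)
        if unknown:
            raise SchemaError(f"omit labels not present in workbook: {sorted(unknown)}")

        profiles: list[ProfilePair] = []
        for label in sheet_labels:
            if label in omit:
                continue
            ws = wb[label]
            rows = ws.iter_rows(values_only=True)
            head = next(rows, None)
            if head is None or head[0] != "distance_um" or head[1] is None:
                raise FormatError(f"{label}: cell A1 must be 'distance_um' with a value in B1")
            position = float(head[1])
            header = next(rows, None)
            if header is None or tuple(header[:3]) != ("position_um", "brightfield", "fluorescent"):
                raise FormatError(f"{label}: expected columns position_um|brightfield|fluorescent")
            data = [
                (float(r[0]), float(r[1]), float(r[2]))
                for r in rows
                if r and r[0] is not None
            ]
            arr = np.asarray(data, dtype=float)
            _check_uniform(arr[:, 0], label)
            if np.any(arr[:, 1:] < 0):
                raise FormatError(f"{label}: negative intensities in raw workbook")
            profiles.append(
                ProfilePair(label, position, arr[:, 0], arr[:, 1], arr[:, 2])
            )
    finally:
        wb.close()

    if len(profiles) < MIN_PROFILES:
        raise InsufficientDataError(
            f"only {len(profiles)} usable measurement points after omission; "
            f"need at least {MIN_PROFILES}"
        )

    geometry = DeviceGeometry(
        channel_width=meta["channel_width_um"],
        channel_height=meta["channel_height_um"],
        wall_thickness=meta["wall_thickness_um"],
        positions=tuple(p.position for p in profiles),
    )
    metadata = Metadata(
        geometry=geometry,
        flow=FlowConfig(meta["analyte_flow_ul_min"], meta["buffer_flow_ul_min"]),
        conditions=Conditions(meta["temperature_K"], meta["viscosity_Pa_s"]),
        exposure=meta["exposure_s"],
        omit=omit,
    )
    return MeasurementSet(metadata=metadata, profiles=profiles)


def write_measurement_workbook(ms: MeasurementSet, path: str | Path) -> Path:
    """Write ``ms`` in the workbook dialect (metadata sheet first, points after)."""
    path = Path(path)
    wb = Workbook()
    meta_ws = wb.active
    meta_ws.title = "metadata"
    m = ms.metadata
    pairs = {
        "channel_width_um": m.geometry.channel_width,
        "channel_height_um": m.geometry.channel_height,
        "wall_thickness_um": m.geometry.wall_thickness,
        "analyte_flow_ul_min": m.flow.analyte_flow,
        "buffer_flow_ul_min": m.flow.buffer_flow,
        "temperature_K": m.conditions.temperature,
        "viscosity_Pa_s": m.conditions.viscosity,
        "exposure_s": m.exposure,
    }
    for k, v in pairs.items():
        meta_ws.append([k, v])
    for p in ms.profiles:
        ws = wb.create_sheet(title=p.label)
        ws.append(["distance_um", p.position])
        ws.append(["position_um", "brightfield", "fluorescent"])
        for xi, bi, fi in zip(p.x, p.brightfield, p.fluorescent):
            ws.append([float(xi), float(bi), float(fi)])
    path.parent.mkdir(parents=True, exist_ok=True)
    wb.save(path)
    return path


def _report_rows(report) -> list[dict]:
    rows = []
    for res in report.results:
        rows.append(
            {
                "rank": res.rank,
                "slope_um2_s": res.slope,
                "intercept_um2": res.intercept,
                "D_um2_s": res.D,
                "radius_nm": res.radius_nm,
                "clamped": res.clamped,
                "n_particles": res.n_particles,
                "r2_line": res.r2_line,
            }
        )
    return rows


def write_results(report, path: str | Path, format: str = "json") -> Path:
    """Serialize a RadiusReport to JSON (full) or CSV (one row per component)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        payload = {
            "components": _report_rows(report),
            "higher_radius_nm": report.higher,
            "lower_radius_nm": report.lower,
            "mean_radius_nm": report.mean_radius,
            "provenance": report.provenance,
        }
        path.write_text(json.dumps(payload, indent=2, default=_jsonable))
    elif format == "csv":
        pd.DataFrame(_report_rows(report)).to_csv(path, index=False)
    else:
        raise UsageError(f"unknown result format '{format}' (expected json or csv)")
    return path


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (tuple, set)):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
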