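"""Config documents and text-based exports.

The full forward-model specification (torso, kidney, electrode array, tissue
resistivities, perfusion cases) round-trips through a single YAML document
with explicit units (lengths mm, resistivities Ohm*m).  Fields and labelled
grids export to legacy ASCII VTK structured-points for inspection; waveforms
to two-column delimited text.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .geometry import ElectrodeArraySpec, KidneySpec, LabelGrid, TorsoSpec
from .tissue_models import PerfusionCase, TissueTable

__all__ = [
    "PatientModel",
    "load_patient_model",
    "save_patient_model",
    "write_vtk_structured_points",
    "write_waveform_csv",
    "read_waveform_csv",
]


@dataclass(frozen=True)
class PatientModel:
    """The complete forward-model specification for one subject."""

    torso: TorsoSpec
    kidney: KidneySpec
    array: ElectrodeArraySpec
    tissues: TissueTable
    perfusion_cases: dict[str, PerfusionCase]

    @classmethod
    def default(cls) -> "PatientModel":
        from .synthetic_data import paper_default_fixture

        torso, kidney, tissues, cases = paper_default_fixture()
        return cls(
            torso=torso,
            kidney=kidney,
            array=ElectrodeArraySpec(center=(kidney.lateral_offset, 0.0)),
            tissues=tissues,
            perfusion_cases=cases,
        )

    def to_dict(self) -> dict:
        return {
            "units": {"length": "mm", "resistivity": "ohm*m"},
            "torso": asdict(self.torso),
            "kidney": {
                "semi_axes": list(self.kidney.semi_axes),
                "h_c": self.kidney.h_c,
                "depth": self.kidney.depth,
                "lateral_offset": self.kidney.lateral_offset,
                "capsule_margin": self.kidney.capsule_margin,
            },
            "array": {
                "spacing_d": self.array.spacing_d,
                "disk_diameter": self.array.disk_diameter,
                "center": list(self.array.center),
                "orientation": list(self.array.orientation),
            },
            "tissues": dict(self.tissues.rho),
            "perfusion_cases": {
                name: {
                    "cortex_blood_fraction": c.cortex_blood_fraction,
                    "before": dict(c.layer_resistivity_before),
                    "after": dict(c.layer_resistivity_after),
                }
                for name, c in self.perfusion_cases.items()
            },
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PatientModel":
        kid = doc["kidney"]
        arr = doc.get("array", {})
        cases = {
            name: PerfusionCase(
                name=name,
                cortex_blood_fraction=c["cortex_blood_fraction"],
                layer_resistivity_before=dict(c["before"]),
                layer_resistivity_after=dict(c["after"]),
            )
            for name, c in doc.get("perfusion_cases", {}).items()
        }
        return cls(
            torso=TorsoSpec(**doc["torso"]),
            kidney=KidneySpec(
                semi_axes=tuple(kid["semi_axes"]),
                h_c=kid["h_c"],
                depth=kid["depth"],
                lateral_offset=kid.get("lateral_offset", 0.0),
                capsule_margin=kid.get("capsule_margin", 10.0),
            ),
            array=ElectrodeArraySpec(
                spacing_d=arr.get("spacing_d", 20.0),
                disk_diameter=arr.get("disk_diameter", 3.0),
                center=tuple(arr.get("center", (0.0, 0.0))),
                orientation=tuple(arr.get("orientation", (0.0, 1.0))),
            ),
            tissues=TissueTable(rho=dict(doc["tissues"])),
            perfusion_cases=cases,
        )


def save_patient_model(model: PatientModel, path) -> None:
    Path(path).write_text(yaml.safe_dump(model.to_dict(), sort_keys=False))


def load_patient_model(path) -> PatientModel:
    return PatientModel.from_dict(yaml.safe_load(Path(path).read_text()))


def write_vtk_structured_points(path, fields: dict[str, np.ndarray], spacing_mm: float, origin_mm) -> None:
    """Write scalar voxel fields to a legacy ASCII VTK structured-points file.

    All fields must share one (nx, ny, nz) shape; VTK expects x-fastest
    ordering, i.e. Fortran raveling of our (x, y, z)-indexed arrays.
    """
    arrays = {k: np.asarray(v) for k, v in fields.items()}
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) != 1:
        raise ValueError("all fields must share one shape")
    nx, ny, nz = shapes.pop()
    lines = [
        "# vtk DataFile Version 3.0",
        "renoimp voxel field",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {origin_mm[0]:.6g} {origin_mm[1]:.6g} {origin_mm[2]:.6g}",
        f"SPACING {spacing_mm:.6g} {spacing_mm:.6g} {spacing_mm:.6g}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    for name, arr in arrays.items():
        is_int = np.issubdtype(arr.dtype, np.integer)
        lines.append(f"SCALARS {name} {'int' if is_int else 'float'} 1")
        lines.append("LOOKUP_TABLE default")
        flat = arr.ravel(order="F")
        fmt = (lambda v: str(int(v))) if is_int else (lambda v: f"{v:.7g}")
        lines.extend(
            " ".join(fmt(v) for v in flat[i : i + 9]) for i in range(0, flat.size, 9)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def export_label_grid_vtk(path, grid: LabelGrid) -> None:
    write_vtk_structured_points(
        path, {"tissue": grid.labels.astype(np.int32)}, grid.voxel_size_h, grid.origin
    )


def write_waveform_csv(path, time_s: np.ndarray, value: np.ndarray, value_name: str, units: str, meta: dict | None = None) -> None:
    """Two-column delimited waveform with a commented header carrying units
    and vessel/channel metadata."""
    head = [f"# {value_name} [{units}]; time [s]"]
    for k, v in (meta or {}).items():
        head.append(f"# {k}: {v}")
    head.append(f"time_s,{value_name}")
    body = "\n".join(f"{t:.9g},{v:.9g}" for t, v in zip(np.asarray(time_s), np.asarray(value)))
    Path(path).write_text("\n".join(head) + "\n" + body + "\n")


def read_waveform_csv(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a waveform written by :func:`write_waveform_csv`; returns
    (time_s, value, metadata)."""
    meta: dict = {}
    rows = []
    header_seen = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" in line:
                k, _, v = line[1:].partition(":")
                meta[k.strip()] = v.strip()
            continue
        if not header_seen and not line[0].isdigit() and not line[0] == "-":
            header_seen = True
            continue
        t, _, v = line.partition(",")
        rows.append((float(t), float(v)))
    arr = np.asarray(rows)
    if arr.size == 0:
        raise ValueError(f"no samples in {path}")
    return arr[:, 0], arr[:, 1], meta
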