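"""In-silico experiments on the patient model.

Reproduces the study protocol: sweep the in-line electrode spacing d from
7 to 40 mm (step 3), solve the static ("before blood-filling") and pulsatile
("after") conduction problems for each perfusion case, and tabulate the base
impedance Z and its cardiac change dZ = Z_before - Z_after.  A depth sweep
models respiratory kidney displacement, and a keyframe interpolator turns a
blood-volume curve Q(t) into a time-resolved impedance waveform dZ(t).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doppler_volume import BloodVolumeCurve
from .forward_solver import CG_RTOL, StimulationPattern, solve_tetrapolar
from .geometry import (
    ElectrodeArraySpec,
    GeometryError,
    KidneySpec,
    PlacementError,
    ResolutionError,
    TorsoSpec,
    build_patient_model,
    set_kidney_depth,
)
from .tissue_models import (
    PerfusionCase,
    TissueTable,
    apply_perfusion_case,
    parallel_conductor_delta,
    to_conductivity_field,
)

__all__ = [
    "SweepTable",
    "ImpedanceWaveform",
    "DEFAULT_SPACINGS_MM",
    "spacing_sweep",
    "depth_sweep",
    "dynamic_delta",
    "simulate_impedance_waveform",
]

#: the study's spacing protocol: 7..40 mm in steps of 3
DEFAULT_SPACINGS_MM = tuple(range(7, 41, 3))
#: per-row resolution policy: spacing must span >= 4 voxels, capped at 2 mm
MAX_H_MM = 2.0


def default_row_h(d_mm: float) -> float:
    return min(MAX_H_MM, d_mm / 4.0)


def _model_hash(*parts) -> str:
    return hashlib.sha256("|".join(repr(p) for p in parts).encode()).hexdigest()[:12]


@dataclass
class SweepTable:
    """Machine-readable sweep result: one row per electrode spacing.

    ``data`` columns: ``d_mm``, ``Z_before_ohm``, then per perfusion case
    ``Z_after_<case>_ohm`` and ``dZ_<case>_ohm``.  ``meta`` carries the model
    hash, per-row grid pitch and any row-level failures, so tables from
    different configurations are never silently compared.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @property
    def case_names(self) -> list[str]:
        return [c[len("dZ_") : -len("_ohm")] for c in self.data.columns if c.startswith("dZ_")]


@dataclass(frozen=True)
class ImpedanceWaveform:
    """Pulsatile impedance dZ(t) in mOhm relative to the end-diastolic
    baseline (dZ(0) = 0); uniform time base in s."""

    time: np.ndarray
    dz_mohm: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "dz_mohm", np.asarray(self.dz_mohm, dtype=float))
        if self.time.shape != self.dz_mohm.shape or self.time.ndim != 1:
            raise ValueError("time and dz_mohm must be matching 1-D arrays")
        if abs(self.dz_mohm[0]) > 1e-9:
            raise ValueError("dZ(0) must be 0 (end-diastolic baseline)")
        if not np.all(np.isfinite(self.dz_mohm)):
            raise ValueError("dZ must be finite")


def _warm_start(phi_field):
    active = ~np.isnan(phi_field.phi)
    return phi_field.phi[active]


def _solve_states(grid, tissue_table, cases, current_ma, rtol):
    """Solve the before state and every after state on one grid.

    Returns (Z_before, {case: Z_after}); after-states are warm-started from
    the before-state potential (the perfusion perturbation is small).
    """
    first = next(iter(cases.values()))
    table_before = apply_perfusion_case(tissue_table, first, "before")
    fld = to_conductivity_field(grid, table_before)
    pattern = StimulationPattern.from_field(fld, current_ma=current_ma)
    z_before, phi = solve_tetrapolar(fld, pattern, rtol=rtol)
    x0 = _warm_start(phi)
    z_after = {}
    for name, case in cases.items():
        fld_a = to_conductivity_field(grid, apply_perfusion_case(tissue_table, case, "after"))
        z_after[name], _ = solve_tetrapolar(fld_a, pattern, x0=x0, rtol=rtol)
    return z_before, z_after


def spacing_sweep(
    torso: TorsoSpec,
    kidney: KidneySpec,
    tissue_table: TissueTable,
    cases: dict[str, PerfusionCase],
    d_values=DEFAULT_SPACINGS_MM,
    h: float | None = None,
    current_ma: float = 3.0,
    rtol: float = CG_RTOL,
) -> SweepTable:
    """Electrode-spacing sweep: solve before/after states at each adjacent
    spacing d (current electrodes at 3 d) and tabulate Z and dZ.

    ``h`` overrides the per-row resolution policy min(2 mm, d/4).  Infeasible
    rows are recorded as NaN and listed in ``meta['failures']``; the sweep
    continues.
    """
    rows = []
    failures = {}
    h_used = {}
    for d in d_values:
        h_d = default_row_h(d) if h is None else float(h)
        row = {"d_mm": float(d), "Z_before_ohm": np.nan}
        for name in cases:
            row[f"Z_after_{name}_ohm"] = np.nan
            row[f"dZ_{name}_ohm"] = np.nan
        try:
            array = ElectrodeArraySpec(spacing_d=float(d), center=(kidney.lateral_offset, 0.0))
            grid = build_patient_model(torso, kidney, array, h_d)
            z_before, z_after = _solve_states(grid, tissue_table, cases, current_ma, rtol)
            row["Z_before_ohm"] = z_before
            for name, za in z_after.items():
                row[f"Z_after_{name}_ohm"] = za
                row[f"dZ_{name}_ohm"] = dynamic_delta(z_before, za)
        except (GeometryError, PlacementError, ResolutionError) as exc:
            failures[float(d)] = str(exc)
        rows.append(row)
        h_used[float(d)] = h_d
    data = pd.DataFrame(rows).sort_values("d_mm", ignore_index=True)
    meta = {
        "model_hash": _model_hash(torso, kidney, tissue_table, sorted(cases)),
        "h_mm": h_used,
        "failures": failures,
        "current_ma": current_ma,
        "rtol": rtol,
    }
    return SweepTable(data=data, meta=meta)


def depth_sweep(
    torso: TorsoSpec,
    kidney: KidneySpec,
    tissue_table: TissueTable,
    case: PerfusionCase,
    depths,
    d: float = 20.0,
    h: float | None = None,
    current_ma: float = 3.0,
    rtol: float = CG_RTOL,
) -> pd.DataFrame:
    """Pulsatile impedance vs kidney depth at a fixed electrode spacing.

    Models respiratory displacement; dZ is expected to fall as the kidney
    sinks away from the array.  Returns columns depth_mm, Z_before_ohm,
    Z_after_ohm, dZ_ohm (NaN rows for infeasible depths).
    """
    h_d = default_row_h(d) if h is None else float(h)
    rows = []
    for depth in depths:
        row = {
            "depth_mm": float(depth),
            "Z_before_ohm": np.nan,
            "Z_after_ohm": np.nan,
            "dZ_ohm": np.nan,
        }
        try:
            moved = set_kidney_depth(torso, kidney, depth)
            array = ElectrodeArraySpec(spacing_d=float(d), center=(moved.lateral_offset, 0.0))
            grid = build_patient_model(torso, moved, array, h_d)
            z_before, z_after = _solve_states(
                grid, tissue_table, {case.name: case}, current_ma, rtol
            )
            row["Z_before_ohm"] = z_before
            row["Z_after_ohm"] = z_after[case.name]
            row["dZ_ohm"] = dynamic_delta(z_before, z_after[case.name])
        except (GeometryError, PlacementError, ResolutionError):
            pass
        rows.append(row)
    return pd.DataFrame(rows)


def dynamic_delta(z_before: float, z_after: float) -> float:
    """Pulsatile impedance dZ = Z_before - Z_after (Ohm); blood filling lowers
    tissue resistivity, so dZ >= 0 for physiological perfusion cases."""
    return float(z_before) - float(z_after)


def _invert_parallel_conductor(rho_before: float, rho_after: float, rho_b: float, m_k: float) -> float:
    """Effective full-cycle blood mass that maps rho_before -> rho_after
    through the parallel-conductor relation (its closed-form inverse)."""
    d1 = rho_before - rho_after
    if d1 == 0:
        return 0.0
    denom = rho_before * (rho_before - rho_b - d1)
    if denom <= 0:
        raise ValueError("after-resistivity below the fully-blood-dominated limit")
    return d1 * m_k * rho_b / denom


def simulate_impedance_waveform(
    torso: TorsoSpec,
    kidney: KidneySpec,
    tissue_table: TissueTable,
    case: PerfusionCase,
    Q: BloodVolumeCurve,
    d: float = 20.0,
    n_keyframes: int = 2,
    h: float | None = None,
    current_ma: float = 3.0,
    rtol: float = CG_RTOL,
) -> ImpedanceWaveform:
    """Time-resolved pulsatile impedance from a blood-volume curve.

    The forward problem is solved at ``n_keyframes`` blood-filling levels
    s in [0, 1]; the layer resistivities at level s follow the
    parallel-conductor relation with blood mass s * m_hat, where m_hat is
    chosen so s = 1 reproduces the case's after-state exactly.  dZ(t) is then
    interpolated at s(t) = Q(t)/max(Q) (clipped to [0, 1]; Q(0) = 0 anchors
    the end-diastolic baseline).  ``n_keyframes = 2`` degenerates to linear
    scaling dZ(t) = dZ_max * Q(t)/max(Q).
    """
    if n_keyframes < 2:
        raise ValueError("need at least 2 keyframes (baseline and full filling)")
    qmax = float(np.max(Q.Q))
    if qmax <= 0:
        return ImpedanceWaveform(time=Q.time.copy(), dz_mohm=np.zeros_like(Q.Q))

    h_d = default_row_h(d) if h is None else float(h)
    array = ElectrodeArraySpec(spacing_d=float(d), center=(kidney.lateral_offset, 0.0))
    grid = build_patient_model(torso, kidney, array, h_d)

    rho_b = tissue_table["blood"]
    m_k = 100.0
    m_hat = {
        layer: _invert_parallel_conductor(
            case.layer_resistivity_before[layer], case.layer_resistivity_after[layer], rho_b, m_k
        )
        for layer in ("cortex", "medulla")
    }

    levels = np.linspace(0.0, 1.0, n_keyframes)
    z_levels = np.empty(n_keyframes)
    x0 = None
    pattern = None
    for j, s in enumerate(levels):
        rho = {
            layer: case.layer_resistivity_before[layer]
            - parallel_conductor_delta(
                case.layer_resistivity_before[layer], rho_b, m_k, s * m_hat[layer]
            )
            for layer in ("cortex", "medulla")
        }
        fld = to_conductivity_field(grid, tissue_table.with_rho(**rho))
        if pattern is None:
            pattern = StimulationPattern.from_field(fld, current_ma=current_ma)
        z_levels[j], phi = solve_tetrapolar(fld, pattern, x0=x0, rtol=rtol)
        if x0 is None:
            x0 = _warm_start(phi)

    dz_levels_mohm = (z_levels[0] - z_levels) * 1e3
    s_t = np.clip(Q.Q / qmax, 0.0, 1.0)
    dz_t = np.interp(s_t, levels, dz_levels_mohm)
    dz_t[0] = 0.0  # Q(0) = 0 by construction; pin the baseline exactly
    return ImpedanceWaveform(time=Q.time.copy(), dz_mohm=dz_t)
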