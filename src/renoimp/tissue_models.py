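"""Tissue resistivities at 100 kHz and the parallel-conductor perfusion model.

At 100 kHz the tissues of the perirenal space behave, to good approximation,
as purely resistive conductors, so each tissue carries a single resistivity
rho (Ohm*m).  Pulsatile blood filling is modelled by treating the inflowing
blood as a conductor in parallel with the kidney parenchyma: adding blood
mass m_b (of resistivity rho_b) to m_k grams of tissue (rho_k) lowers the
bulk resistivity by

    delta_rho = rho_k * m_b * (rho_k - rho_b) / (m_k * rho_b + m_b * rho_k)

so rho_total = rho_k - delta_rho.  Perfusion cases describe how that blood
volume splits between cortex and medulla (normally ~90% cortical) and carry
the corresponding before/after layer resistivities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import TISSUE_BY_NAME, LabelGrid, Tissue

__all__ = [
    "TissueTable",
    "PerfusionCase",
    "ConductivityField",
    "DEFAULT_PERFUSION_CASES",
    "parallel_conductor_delta",
    "blood_mass_per_cycle",
    "apply_perfusion_case",
    "to_conductivity_field",
]

#: baseline kidney parenchyma resistivity (cortex = medulla before filling), Ohm*m
KIDNEY_BASELINE_RHO = 5.84

# Non-renal defaults are literature values for 100 kHz, not model-fitted:
# fat ~40, skeletal muscle (transverse-ish average) ~2.8, whole blood ~1.5,
# mixed abdominal contents ~5 Ohm*m.  All overridable via config.
_DEFAULT_RHO = {
    "subcutaneous_fat": 40.0,
    "muscle": 2.8,
    "perirenal_fat": 40.0,
    "cortex": KIDNEY_BASELINE_RHO,
    "medulla": KIDNEY_BASELINE_RHO,
    "background": 5.0,
    "blood": 1.5,
}


@dataclass(frozen=True)
class TissueTable:
    """Per-tissue electrical resistivity (Ohm*m) at 100 kHz."""

    rho: dict[str, float]

    def __post_init__(self) -> None:
        for name, val in self.rho.items():
            if val <= 0:
                raise ValueError(f"resistivity of {name!r} must be > 0 (got {val})")

    @classmethod
    def default(cls) -> "TissueTable":
        return cls(rho=dict(_DEFAULT_RHO))

    def __getitem__(self, tissue: str) -> float:
        return self.rho[tissue]

    def with_rho(self, **updates: float) -> "TissueTable":
        merged = dict(self.rho)
        merged.update(updates)
        return TissueTable(rho=merged)


@dataclass(frozen=True)
class PerfusionCase:
    """A cortex/medulla blood-flow split with its layer resistivities.

    ``layer_resistivity_before``/``_after`` map ``{"cortex": .., "medulla": ..}``
    to Ohm*m; blood filling can only lower resistivity, so after <= before.
    """

    name: str
    cortex_blood_fraction: float
    layer_resistivity_before: dict[str, float]
    layer_resistivity_after: dict[str, float]

    def __post_init__(self) -> None:
        if not 0 < self.cortex_blood_fraction <= 1:
            raise ValueError("cortex_blood_fraction must lie in (0, 1]")
        for layer in ("cortex", "medulla"):
            if layer not in self.layer_resistivity_before or layer not in self.layer_resistivity_after:
                raise ValueError(f"perfusion case {self.name!r} missing layer {layer!r}")
            before = self.layer_resistivity_before[layer]
            after = self.layer_resistivity_after[layer]
            if not 0 < after <= before:
                raise ValueError(
                    f"case {self.name!r}, layer {layer!r}: need 0 < after <= before "
                    f"(blood lowers resistivity), got {after} vs {before}"
                )


#: the two canonical blood-distribution cases: normal perfusion sends ~90% of
#: renal flow to the cortex; the second case models cortical hypoperfusion.
DEFAULT_PERFUSION_CASES: dict[str, PerfusionCase] = {
    "90-10": PerfusionCase(
        name="90-10",
        cortex_blood_fraction=0.9,
        layer_resistivity_before={"cortex": KIDNEY_BASELINE_RHO, "medulla": KIDNEY_BASELINE_RHO},
        layer_resistivity_after={"cortex": 4.99, "medulla": 5.75},
    ),
    "70-30": PerfusionCase(
        name="70-30",
        cortex_blood_fraction=0.7,
        layer_resistivity_before={"cortex": KIDNEY_BASELINE_RHO, "medulla": KIDNEY_BASELINE_RHO},
        layer_resistivity_after={"cortex": 5.18, "medulla": 5.56},
    ),
}


def parallel_conductor_delta(rho_k: float, rho_b: float, m_k: float, m_b: float) -> float:
    """Resistivity drop (Ohm*m) of tissue after adding blood, by the
    parallel-conductor model.

    Parameters are the tissue and blood resistivities (Ohm*m) and masses (g);
    the returned ``delta_rho`` satisfies ``rho_total = rho_k - delta_rho``.
    """
    if rho_k <= 0 or rho_b <= 0:
        raise ValueError("resistivities must be > 0")
    if m_k <= 0 or m_b < 0:
        raise ValueError("need m_k > 0 and m_b >= 0")
    return rho_k * m_b * (rho_k - rho_b) / (m_k * rho_b + m_b * rho_k)


def blood_mass_per_cycle(
    flow_per_100g: float, cycle_duration: float = 1.0, blood_density: float = 1.05
) -> float:
    """Blood mass (g per 100 g tissue) delivered in one cardiac cycle.

    ``flow_per_100g`` is organ perfusion in mL/min per 100 g (healthy kidney:
    ~400); ``cycle_duration`` in s, ``blood_density`` in g/mL.
    """
    if flow_per_100g < 0 or cycle_duration <= 0 or blood_density <= 0:
        raise ValueError("flow must be >= 0; duration and density > 0")
    return flow_per_100g / 60.0 * cycle_duration * blood_density


def apply_perfusion_case(table: TissueTable, case: PerfusionCase, state: str) -> TissueTable:
    """Return a copy of ``table`` with kidney-layer resistivities set to the
    case's ``"before"`` or ``"after"`` blood-filling values."""
    if state not in ("before", "after"):
        raise ValueError(f"state must be 'before' or 'after', got {state!r}")
    layers = case.layer_resistivity_before if state == "before" else case.layer_resistivity_after
    return table.with_rho(cortex=layers["cortex"], medulla=layers["medulla"])


@dataclass
class ConductivityField:
    """Per-voxel conductivity sigma (S/m) on a label grid.

    Voxels outside the conduction domain carry sigma = 0 and are excluded
    from the solve.  Grid metadata (pitch, dims, origin, electrode
    footprints) mirror the originating :class:`~renoimp.geometry.LabelGrid`.
    """

    voxel_size_h: float
    dims: tuple[int, int, int]
    origin: tuple[float, float, float]
    sigma: np.ndarray
    electrodes: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.sigma = np.ascontiguousarray(self.sigma, dtype=np.float64)
        if self.sigma.shape != tuple(self.dims):
            raise ValueError("sigma shape does not match dims")
        active = self.sigma > 0
        if not active.any():
            raise ValueError("empty conduction domain")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be >= 0 (0 marks outside)")

    @property
    def active(self) -> np.ndarray:
        return self.sigma > 0


def to_conductivity_field(grid: LabelGrid, table: TissueTable) -> ConductivityField:
    """Realize a label grid as per-voxel conductivity sigma = 1/rho (S/m).

    Every tissue present in the grid (other than ``outside``) must appear in
    ``table``; missing tissues raise ``KeyError``.
    """
    lut = np.zeros(len(Tissue), dtype=np.float64)
    present = np.unique(grid.labels)
    from .geometry import TISSUE_NAMES  # local import to avoid cycle noise

    for code in present:
        tissue = Tissue(int(code))
        if tissue is Tissue.OUTSIDE:
            continue
        name = TISSUE_NAMES[tissue]
        if name not in table.rho:
            raise KeyError(f"tissue {name!r} missing from the resistivity table")
        lut[code] = 1.0 / table[name]
    return ConductivityField(
        voxel_size_h=grid.voxel_size_h,
        dims=grid.dims,
        origin=grid.origin,
        sigma=lut[grid.labels],
        electrodes=dict(grid.electrodes),
    )
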