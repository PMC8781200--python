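"""Synthetic inputs with the structure the analysis assumes.

Real renal Doppler traces and measured impedance waveforms are not shipped;
these generators produce their stand-ins: an arterial velocity cycle
(diastolic floor plus a half-sine systolic peak), a weakly pulsatile venous
return, and an impedance waveform proportional to the blood-volume curve
plus seeded Gaussian noise.  Default amplitudes are set so the per-cycle
arterial volume matches healthy renal perfusion (~400 mL/min per 100 g,
scaled to a 130 g kidney at a 1 s cycle, i.e. ~8.7 cm^3 per beat).

Everything is reproducible from (params, seed); changing only the seed
changes only the noise realization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .doppler_volume import (
    DEFAULT_RATE_HZ,
    DEFAULT_S_ARTERY,
    DEFAULT_S_VEIN,
    BloodVolumeCurve,
    VelocityWaveform,
)
from .experiments import ImpedanceWaveform
from .geometry import KidneySpec, TorsoSpec
from .tissue_models import DEFAULT_PERFUSION_CASES, PerfusionCase, TissueTable

__all__ = [
    "WaveformParams",
    "synth_velocity_pair",
    "synth_impedance_from_volume",
    "paper_default_fixture",
]


@dataclass(frozen=True)
class WaveformParams:
    """Shape parameters of one synthetic cardiac cycle.

    Velocities in cm/s.  ``artery_peak`` is the absolute systolic peak;
    ``systolic_fraction`` the fraction of the cycle occupied by the systolic
    half-sine; ``noise_sd`` is additive Gaussian noise as a fraction of each
    signal's own standard deviation.
    """

    cycle_T: float = 1.0
    artery_peak: float = 77.4
    systolic_fraction: float = 0.35
    diastolic_floor: float = 15.0
    vein_mean: float = 22.8
    vein_pulsatility: float = 0.1
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycle_T <= 0:
            raise ValueError("cycle_T must be > 0")
        for name in ("systolic_fraction", "vein_pulsatility", "noise_sd"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("artery_peak", "diastolic_floor", "vein_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.artery_peak < self.diastolic_floor:
            raise ValueError("artery_peak must be >= diastolic_floor")

    def cycle_arterial_volume(self, s_artery: float = DEFAULT_S_ARTERY) -> float:
        """Closed-form per-cycle arterial volume (cm^3): floor plus the
        half-sine systolic bump integrated over the cycle."""
        amp = self.artery_peak - self.diastolic_floor
        return s_artery * (
            self.diastolic_floor * self.cycle_T
            + amp * (2.0 / np.pi) * self.systolic_fraction * self.cycle_T
        )


def synth_velocity_pair(
    p: WaveformParams,
    rate: float = DEFAULT_RATE_HZ,
    s_artery: float = DEFAULT_S_ARTERY,
    s_vein: float = DEFAULT_S_VEIN,
) -> tuple[VelocityWaveform, VelocityWaveform]:
    """Generate one cycle of renal artery and vein velocity.

    Artery: diastolic floor plus a half-sine systolic peak over the first
    ``systolic_fraction`` of the cycle.  Vein: mean * (1 + pulsatility *
    sin(2 pi t/T)), clipped at zero.  Deterministic for a fixed seed.
    """
    n_sys = p.systolic_fraction * p.cycle_T * rate
    if n_sys < 20:
        raise ValueError(
            f"rate {rate} Hz resolves the systolic peak with only {n_sys:.0f} samples (< 20)"
        )
    n = int(round(p.cycle_T * rate)) + 1
    t = np.arange(n) / rate
    t[-1] = p.cycle_T

    t_sys = p.systolic_fraction * p.cycle_T
    artery = np.full(n, p.diastolic_floor, dtype=float)
    sys_mask = t < t_sys
    artery[sys_mask] += (p.artery_peak - p.diastolic_floor) * np.sin(np.pi * t[sys_mask] / t_sys)
    vein = p.vein_mean * (1.0 + p.vein_pulsatility * np.sin(2 * np.pi * t / p.cycle_T))

    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        artery = artery + rng.normal(0.0, p.noise_sd * artery.std(), n)
        vein = vein + rng.normal(0.0, p.noise_sd * vein.std(), n)
    artery = np.clip(artery, 0.0, None)
    vein = np.clip(vein, 0.0, None)
    return (
        VelocityWaveform(time=t, velocity=artery, cross_section=s_artery, role="artery"),
        VelocityWaveform(time=t.copy(), velocity=vein, cross_section=s_vein, role="vein"),
    )


def synth_impedance_from_volume(
    Q: BloodVolumeCurve, gain: float = 1.0, noise_sd: float = 0.0, seed: int = 0
) -> ImpedanceWaveform:
    """Impedance waveform with known ground truth: dZ = gain * Q plus noise.

    ``gain`` in mOhm/cm^3; ``noise_sd`` is the Gaussian noise level as a
    fraction of sd(gain * Q).  The waveform is re-anchored so dZ(0) = 0
    (a constant offset, invisible to correlation).  Deterministic per seed.
    """
    if gain <= 0:
        raise ValueError("gain must be > 0")
    dz = gain * Q.Q
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        dz = dz + rng.normal(0.0, noise_sd * dz.std(), dz.shape)
    dz = dz - dz[0]
    return ImpedanceWaveform(time=Q.time.copy(), dz_mohm=dz)


def paper_default_fixture() -> tuple[TorsoSpec, KidneySpec, TissueTable, dict[str, PerfusionCase]]:
    """The default patient model: measured trunk/layer dimensions
    (2a1 = 253.7, 2b1 = 166.71, h_subc = 5.54, h_m = 10.74, h_c = 5 mm),
    the two canonical perfusion cases, and the default tissue table.

    Kidney axes, depth and capsule thickness are typical-adult defaults
    (config-overridable); the trunk and cortex values are subject-specific.
    """
    return TorsoSpec(), KidneySpec(), TissueTable.default(), dict(DEFAULT_PERFUSION_CASES)
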