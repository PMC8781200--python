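"""Renal blood-volume change from Doppler velocity curves.

The kidney's blood-volume change over one cardiac cycle is the difference of
cumulative volumetric inflow and outflow,

    Q(t) = int_0^t V_a(t) S_a dt - int_0^t V_v(t) S_v dt   [cm^3],

with V the spatially averaged renal artery/vein velocity (cm/s) and S the
lumen cross-section (cm^2).  Integration uses the trapezoid rule (second
order, exact for piecewise-linear velocity traces).  The module also aligns
an impedance waveform with Q(t) and reports their Pearson correlation — the
check used to attribute the pulsatile impedance signal to renal blood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.stats import pearsonr

__all__ = [
    "VelocityWaveform",
    "BloodVolumeCurve",
    "volumetric_flow",
    "blood_volume_change",
    "align_and_resample",
    "pearson_correlation",
]

#: renal artery / vein cross-sections (cm^2) used throughout as defaults
DEFAULT_S_ARTERY = 0.30
DEFAULT_S_VEIN = 0.38
#: impedance-system acquisition rate (Hz)
DEFAULT_RATE_HZ = 500.0

_UNIFORM_RTOL = 1e-6


def _check_uniform(time: np.ndarray) -> float:
    dt = np.diff(time)
    if time.ndim != 1 or time.size < 2 or np.any(dt <= 0):
        raise ValueError("time must be 1-D, length >= 2, strictly increasing")
    if np.ptp(dt) > _UNIFORM_RTOL * dt.mean():
        raise ValueError("time base is not uniform; resample first (align_and_resample)")
    return float(dt.mean())


@dataclass(frozen=True)
class VelocityWaveform:
    """One cardiac cycle of spatially averaged vessel velocity.

    ``time`` in s (uniform), ``velocity`` in cm/s, ``cross_section`` the
    lumen area in cm^2, ``role`` either ``"artery"`` or ``"vein"``.
    """

    time: np.ndarray
    velocity: np.ndarray
    cross_section: float
    role: str = "artery"

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "velocity", np.asarray(self.velocity, dtype=float))
        if self.time.shape != self.velocity.shape:
            raise ValueError("time and velocity must have the same shape")
        _check_uniform(self.time)
        if self.cross_section <= 0:
            raise ValueError("cross_section must be > 0 cm^2")
        if self.role not in ("artery", "vein"):
            raise ValueError("role must be 'artery' or 'vein'")
        if self.role == "artery" and np.any(self.velocity < 0):
            raise ValueError("arterial velocity must be >= 0 over the cycle")


@dataclass(frozen=True)
class BloodVolumeCurve:
    """Cumulative blood-volume change Q(t) in cm^3 since cycle start; Q(0)=0."""

    time: np.ndarray
    Q: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "Q", np.asarray(self.Q, dtype=float))
        if self.time.shape != self.Q.shape:
            raise ValueError("time and Q must have the same shape")
        if abs(self.Q[0]) > 1e-12:
            raise ValueError("Q(0) must be 0")
        if not np.all(np.isfinite(self.Q)):
            raise ValueError("Q must be finite")


def volumetric_flow(w: VelocityWaveform) -> np.ndarray:
    """Pointwise volumetric flow rate velocity * cross_section (cm^3/s)."""
    return w.velocity * w.cross_section


def blood_volume_change(artery: VelocityWaveform, vein: VelocityWaveform) -> BloodVolumeCurve:
    """Trapezoid-integrated arterio-venous volume balance Q(t).

    Both waveforms must share one uniform time base; Q(0) = 0 by
    construction and Q(T) is the net volume stored over the cycle.
    """
    if artery.time.shape != vein.time.shape or not np.allclose(
        artery.time, vein.time, rtol=0, atol=1e-9
    ):
        raise ValueError("artery and vein waveforms must share a common time base")
    net = volumetric_flow(artery) - volumetric_flow(vein)
    q = cumulative_trapezoid(net, artery.time, initial=0.0)
    return BloodVolumeCurve(time=artery.time.copy(), Q=q)


def align_and_resample(
    t_x: np.ndarray,
    x: np.ndarray,
    t_y: np.ndarray,
    y: np.ndarray,
    rate: float = DEFAULT_RATE_HZ,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearly interpolate two time series onto a common uniform grid.

    The grid covers the overlap of the two supports at ``rate`` Hz (default
    500, the impedance system's sampling rate).  Returns (t, x, y).
    """
    t_x, t_y = np.asarray(t_x, float), np.asarray(t_y, float)
    if rate <= 0:
        raise ValueError("rate must be > 0")
    lo = max(t_x[0], t_y[0])
    hi = min(t_x[-1], t_y[-1])
    if hi <= lo:
        raise ValueError("time supports do not overlap")
    n = int(np.ceil((hi - lo) * rate)) + 1
    t = lo + np.arange(n) / rate
    t[-1] = min(t[-1], hi)
    return t, np.interp(t, t_x, np.asarray(x, float)), np.interp(t, t_y, np.asarray(y, float))


def pearson_correlation(q: np.ndarray, dz: np.ndarray) -> float:
    """Sample Pearson correlation between aligned Q(t) and impedance change.

    Requires equal lengths >= 3 and nonzero variance in both inputs.
    """
    q, dz = np.asarray(q, float), np.asarray(dz, float)
    if q.shape != dz.shape or q.ndim != 1 or q.size < 3:
        raise ValueError("need two aligned 1-D series of equal length >= 3")
    if np.std(q) == 0 or np.std(dz) == 0:
        raise ValueError("correlation undefined: an input has zero variance")
    return float(pearsonr(q, dz).statistic)
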