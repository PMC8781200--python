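"""Quasi-static conduction forward solver and tetrapolar transfer impedance.

Solves div(sigma grad phi) = 0 on the voxel model with a 7-point cell-centered
finite-volume stencil and harmonic-mean face conductivities (exact for layered
media normal to the face).  All outer boundaries are insulating except the
current-electrode footprints, where the total current +/- I is spread
uniformly over the footprint faces.  The gauge is zero mean potential over
the conduction domain.  At 100 kHz the solve is real-valued: resistance is
the dominant impedance component in this tissue set.

Two solution paths share the same discrete system:

* a conjugate-gradient solve (Jacobi preconditioner, relative residual 1e-8)
  for arbitrary heterogeneous, irregularly-masked domains;
* an exact DCT-II spectral direct solve for homogeneous full-box domains
  (the cell-centered Neumann Laplacian is diagonal in the DCT-II basis),
  used by the half-space oracle experiments where grids get large.

The analytic companion is the symmetric tetrapolar half-space formula
Z = 2*rho*b / (pi*(a^2 - b^2)) for point electrodes (a, b = half the
current- and measuring-electrode separations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.fft
import scipy.ndimage
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import ElectrodeArraySpec, LabelGrid, PlacementError, Tissue, place_electrode_array
from .tissue_models import ConductivityField, TissueTable

__all__ = [
    "AssemblyError",
    "SolverError",
    "StimulationPattern",
    "PotentialField",
    "ConductionSystem",
    "assemble_conduction_system",
    "solve_potential",
    "transfer_impedance",
    "solve_tetrapolar",
    "analytic_tetrapolar",
    "reciprocity_error",
    "homogeneous_block_field",
]

MM = 1e-3  # mm -> m

#: default solver controls
CG_RTOL = 1e-8
CG_MAXITER = 100_000
DEFAULT_CURRENT_MA = 3.0


class AssemblyError(RuntimeError):
    """The conduction domain cannot be assembled (e.g. it is disconnected)."""


class SolverError(RuntimeError):
    """The iterative solve failed to reach tolerance within the iteration cap."""


@dataclass(frozen=True)
class StimulationPattern:
    """Tetrapolar drive: current pair (C1, C2) and measurement pair (M1, M2).

    Footprints are (m, 2) arrays of (i, k) skin-face voxel indices (j = 0).
    """

    current_pair: tuple[np.ndarray, np.ndarray]
    measurement_pair: tuple[np.ndarray, np.ndarray]
    current_ma: float = DEFAULT_CURRENT_MA

    def __post_init__(self) -> None:
        if self.current_ma <= 0:
            raise ValueError("current_ma must be > 0")
        cells: set[tuple[int, int]] = set()
        for fp in (*self.current_pair, *self.measurement_pair):
            fp = np.asarray(fp)
            if fp.ndim != 2 or fp.shape[1] != 2 or fp.shape[0] == 0:
                raise ValueError("each footprint must be a nonempty (m, 2) index array")
            this = {tuple(c) for c in fp}
            if this & cells:
                raise ValueError("electrode footprints must be pairwise disjoint")
            cells |= this

    @property
    def current_amps(self) -> float:
        return self.current_ma * 1e-3

    @classmethod
    def from_field(cls, fld: ConductivityField, current_ma: float = DEFAULT_CURRENT_MA) -> "StimulationPattern":
        """Standard in-line pattern from the footprints recorded on the field."""
        try:
            c1, m1, m2, c2 = (fld.electrodes[k] for k in ("C1", "M1", "M2", "C2"))
        except KeyError as exc:
            raise PlacementError("field carries no placed electrode array") from exc
        return cls(current_pair=(c1, c2), measurement_pair=(m1, m2), current_ma=current_ma)

    def swapped(self) -> "StimulationPattern":
        """Current and measurement roles exchanged (reciprocal drive)."""
        return StimulationPattern(
            current_pair=self.measurement_pair,
            measurement_pair=self.current_pair,
            current_ma=self.current_ma,
        )


@dataclass
class PotentialField:
    """Solved potential phi (V) on the voxel grid; NaN outside the domain.

    The potential is defined up to a constant; the solver fixes the gauge to
    zero mean over the conduction domain.  ``info`` records iterations and
    the final relative residual.
    """

    voxel_size_h: float
    dims: tuple[int, int, int]
    origin: tuple[float, float, float]
    phi: np.ndarray
    info: dict = field(default_factory=dict)

    def footprint_mean(self, fp: np.ndarray) -> float:
        """Area-averaged potential over a skin footprint (ideal pickup)."""
        fp = np.asarray(fp)
        vals = self.phi[fp[:, 0], 0, fp[:, 1]]
        if np.isnan(vals).any():
            raise ValueError("measurement footprint lies outside the conduction domain")
        return float(vals.mean())


@dataclass
class ConductionSystem:
    """Assembled sparse system A phi = b on the active voxels.

    ``index`` maps voxel (i,j,k) -> row (or -1 outside); ``uniform_sigma`` is
    set when the domain is a full homogeneous box (enables the spectral path).
    """

    A: sp.csr_matrix
    b: np.ndarray
    index: np.ndarray
    field: ConductivityField
    pattern: StimulationPattern
    uniform_sigma: float | None = None

    @property
    def n(self) -> int:
        return self.b.shape[0]


def _footprint_rows(index: np.ndarray, fp: np.ndarray) -> np.ndarray:
    rows = index[np.asarray(fp)[:, 0], 0, np.asarray(fp)[:, 1]]
    if np.any(rows < 0):
        raise AssemblyError("electrode footprint touches voxels outside the conduction domain")
    return rows


def assemble_conduction_system(
    fld: ConductivityField, pattern: StimulationPattern
) -> ConductionSystem:
    """Build the finite-volume system for div(sigma grad phi) = 0.

    Face conductance between voxels with sigma1, sigma2 at pitch h is
    ``g = h * 2*sigma1*sigma2/(sigma1+sigma2)`` (harmonic mean; h in meters,
    g in siemens).  Insulating outer boundaries; the drive current enters as
    source terms +/- I/n_faces on the cells behind each current footprint.
    The matrix is symmetric positive semi-definite with nullspace = constants.
    """
    active = fld.active
    n_comp = scipy.ndimage.label(active, output=None)[1] if active.ndim == 3 else 0
    if n_comp != 1:
        raise AssemblyError(f"conduction domain has {n_comp} connected components (need 1)")

    index = np.full(fld.dims, -1, dtype=np.int64)
    n = int(active.sum())
    index[active] = np.arange(n)

    h_m = fld.voxel_size_h * MM
    sig = fld.sigma
    rows_list, cols_list, g_list = [], [], []
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        sl_lo, sl_hi = tuple(sl_lo), tuple(sl_hi)
        pair = active[sl_lo] & active[sl_hi]
        s1 = sig[sl_lo][pair]
        s2 = sig[sl_hi][pair]
        g = h_m * 2.0 * s1 * s2 / (s1 + s2)
        rows_list.append(index[sl_lo][pair])
        cols_list.append(index[sl_hi][pair])
        g_list.append(g)

    r = np.concatenate(rows_list).astype(np.int32)
    c = np.concatenate(cols_list).astype(np.int32)
    g = np.concatenate(g_list)
    diag = np.zeros(n)
    np.add.at(diag, r, g)
    np.add.at(diag, c, g)
    arange = np.arange(n, dtype=np.int32)
    A = sp.coo_matrix(
        (
            np.concatenate([-g, -g, diag]),
            (np.concatenate([r, c, arange]), np.concatenate([c, r, arange])),
        ),
        shape=(n, n),
    ).tocsr()

    b = np.zeros(n)
    current = pattern.current_amps
    for fp, sign in zip(pattern.current_pair, (+1.0, -1.0)):
        rows = _footprint_rows(index, fp)
        b[rows] += sign * current / rows.size
    # measurement footprints must also live on the domain
    for fp in pattern.measurement_pair:
        _footprint_rows(index, fp)

    uniform = None
    if active.all():
        smin, smax = float(sig.min()), float(sig.max())
        if smax - smin <= 1e-12 * smax:
            uniform = smax
    return ConductionSystem(A=A, b=b, index=index, field=fld, pattern=pattern, uniform_sigma=uniform)


def _uniform_stencil_apply(phi3: np.ndarray, sigma_h: float) -> np.ndarray:
    """Matrix-free A @ phi for the homogeneous full-box Neumann stencil."""
    p = np.pad(phi3, 1, mode="edge")  # mirror ghost cells = insulating faces
    out = 6.0 * phi3 - (
        p[:-2, 1:-1, 1:-1]
        + p[2:, 1:-1, 1:-1]
        + p[1:-1, :-2, 1:-1]
        + p[1:-1, 2:, 1:-1]
        + p[1:-1, 1:-1, :-2]
        + p[1:-1, 1:-1, 2:]
    )
    # edge padding re-adds the center value on boundary faces, which is
    # exactly the Neumann diagonal correction, so no further adjustment
    return sigma_h * out


def _spectral_solve_box(
    b3: np.ndarray, sigma: float, h_mm: float
) -> tuple[np.ndarray, dict]:
    """Exact direct solve of the homogeneous full-box system via DCT-II.

    The cell-centered Neumann Laplacian factorizes per axis with eigenvalues
    2 - 2 cos(pi k / n); the zero mode is the gauge and is set to zero.
    """
    nx, ny, nz = b3.shape
    sigma_h = sigma * h_mm * MM
    lam = [2.0 - 2.0 * np.cos(np.pi * np.arange(n) / n) for n in (nx, ny, nz)]
    denom = sigma_h * (
        lam[0][:, None, None] + lam[1][None, :, None] + lam[2][None, None, :]
    )
    denom[0, 0, 0] = 1.0  # gauge mode
    bh = scipy.fft.dctn(b3, type=2, norm="ortho", workers=-1)
    bh /= denom
    bh[0, 0, 0] = 0.0
    del denom
    phi = scipy.fft.idctn(bh, type=2, norm="ortho", workers=-1)
    del bh
    res = float(
        np.linalg.norm(_uniform_stencil_apply(phi, sigma_h) - b3) / np.linalg.norm(b3)
    )
    return phi, {"method": "dct", "iterations": 0, "relative_residual": res}


def _solve_spectral(system: ConductionSystem) -> tuple[np.ndarray, dict]:
    b3 = system.b.reshape(system.field.dims)
    phi, info = _spectral_solve_box(b3, system.uniform_sigma, system.field.voxel_size_h)
    return phi.ravel(), info


def solve_potential(
    system: ConductionSystem,
    x0: np.ndarray | None = None,
    rtol: float = CG_RTOL,
    maxiter: int = CG_MAXITER,
) -> PotentialField:
    """Solve the assembled system to relative residual <= ``rtol``.

    Deterministic for fixed input.  Homogeneous full-box systems go through
    the exact spectral path; everything else uses Jacobi-preconditioned
    conjugate gradients (warm-startable through ``x0`` — useful when solving
    a sequence of slightly different perfusion states).
    """
    imbalance = abs(system.b.sum())
    if imbalance > 1e-10 * system.pattern.current_amps:
        raise AssemblyError(f"net injected current {imbalance:g} A != 0")

    if system.uniform_sigma is not None:
        x, info = _solve_spectral(system)
    else:
        dinv = 1.0 / system.A.diagonal()
        M = spla.LinearOperator(system.A.shape, matvec=lambda v: dinv * v)
        iters = 0

        def _count(_):
            nonlocal iters
            iters += 1

        x, flag = spla.cg(
            system.A, system.b, x0=x0, rtol=rtol, atol=0.0, maxiter=maxiter, M=M, callback=_count
        )
        if flag != 0:
            res = float(np.linalg.norm(system.A @ x - system.b) / np.linalg.norm(system.b))
            raise SolverError(
                f"CG did not reach rtol={rtol:g} in {maxiter} iterations "
                f"(flag={flag}, relative residual {res:.3e}, n={system.n})"
            )
        res = float(np.linalg.norm(system.A @ x - system.b) / np.linalg.norm(system.b))
        info = {"method": "cg", "iterations": iters, "relative_residual": res}

    x = x - x.mean()  # zero-mean gauge
    phi = np.full(system.field.dims, np.nan)
    phi[system.field.active] = x[system.index[system.field.active]]
    return PotentialField(
        voxel_size_h=system.field.voxel_size_h,
        dims=system.field.dims,
        origin=system.field.origin,
        phi=phi,
        info=info,
    )


def transfer_impedance(phi: PotentialField, pattern: StimulationPattern) -> float:
    """Tetrapolar transfer impedance Z = (phi(M1) - phi(M2)) / I in Ohm.

    Footprint potentials are area-averaged (ideal, non-shunting pickup).
    With the standard in-line order C1-M1-M2-C2 and +I injected at C1 the
    result is positive.
    """
    m1, m2 = pattern.measurement_pair
    return (phi.footprint_mean(m1) - phi.footprint_mean(m2)) / pattern.current_amps


def _uniform_box_sigma(fld: ConductivityField) -> float | None:
    if not fld.active.all():
        return None
    smin, smax = float(fld.sigma.min()), float(fld.sigma.max())
    return smax if smax - smin <= 1e-12 * smax else None


def solve_tetrapolar(
    fld: ConductivityField,
    pattern: StimulationPattern | None = None,
    x0: np.ndarray | None = None,
    rtol: float = CG_RTOL,
) -> tuple[float, PotentialField]:
    """Assemble, solve and measure in one call; returns (Z, potential).

    Homogeneous full-box fields skip sparse assembly entirely and go through
    the matrix-free spectral direct solve (memory matters on fine oracle
    grids); everything else assembles and runs preconditioned CG.
    """
    if pattern is None:
        pattern = StimulationPattern.from_field(fld)
    sigma = _uniform_box_sigma(fld)
    if sigma is not None:
        b3 = np.zeros(fld.dims)
        current = pattern.current_amps
        for fp, sign in zip(pattern.current_pair, (+1.0, -1.0)):
            fp = np.asarray(fp)
            b3[fp[:, 0], 0, fp[:, 1]] += sign * current / fp.shape[0]
        phi3, info = _spectral_solve_box(b3, sigma, fld.voxel_size_h)
        phi3 -= phi3.mean()
        phi = PotentialField(
            voxel_size_h=fld.voxel_size_h, dims=fld.dims, origin=fld.origin, phi=phi3, info=info
        )
    else:
        system = assemble_conduction_system(fld, pattern)
        phi = solve_potential(system, x0=x0, rtol=rtol)
    return transfer_impedance(phi, pattern), phi


def analytic_tetrapolar(rho: float, a: float, b: float) -> float:
    """Half-space impedance of a symmetric in-line tetrapolar array of point
    electrodes: Z = 2*rho*b / (pi*(a^2 - b^2)).

    ``a`` and ``b`` are HALF the current- and measuring-electrode
    separations, in meters; ``rho`` in Ohm*m.  For an equidistant array with
    adjacent spacing d (a = 1.5 d, b = 0.5 d) this reduces to rho/(2 pi d).
    """
    if rho <= 0:
        raise ValueError("rho must be > 0")
    if not a > b >= 0:
        raise ValueError("need a > b >= 0")
    return 2.0 * rho * b / (math.pi * (a * a - b * b))


def reciprocity_error(fld: ConductivityField, pattern: StimulationPattern, rtol: float = CG_RTOL) -> float:
    """Relative change of Z when current and measurement pairs are swapped.

    The continuum reciprocity theorem makes the two transfer impedances
    identical; the discrete residual-bounded difference is a solver/model
    self-check.
    """
    z_fwd, _ = solve_tetrapolar(fld, pattern, rtol=rtol)
    z_rev, _ = solve_tetrapolar(fld, pattern.swapped(), rtol=rtol)
    return abs(z_fwd - z_rev) / abs(z_fwd)


def homogeneous_block_field(
    extent_mm: tuple[float, float, float],
    voxel_size_h: float,
    rho: float,
    array: ElectrodeArraySpec,
) -> ConductivityField:
    """Homogeneous rectangular block (half-space surrogate) with the array
    placed on its y = 0 face; extents are (x, y-depth, z) in mm.

    The grid phase in (x, z) is shifted (by < h/2) so the first electrode
    center coincides with a cell center: when electrode spacings are
    multiples of h this pins every electrode to a cell center at every
    resolution, so h-refinement studies see a consistent discrete electrode
    geometry instead of rasterization parity jumps.
    """
    h = voxel_size_h
    dims = tuple(int(round(e / h)) for e in extent_mm)
    if any(d < 2 for d in dims):
        raise ValueError("block must span at least 2 voxels per axis")
    origin = [-(dims[0] * h) / 2 + h / 2, h / 2, -(dims[2] * h) / 2 + h / 2]
    c1x, c1z = array.electrode_centers()[0]
    for axis, target in ((0, c1x), (2, c1z)):
        frac = (target - origin[axis]) / h
        origin[axis] += (frac - round(frac)) * h
    origin = tuple(origin)
    labels = np.full(dims, Tissue.BACKGROUND, dtype=np.uint8)
    grid = LabelGrid(voxel_size_h=h, dims=dims, origin=origin, labels=labels)
    place_electrode_array(grid, array)
    table = TissueTable.default().with_rho(background=rho)
    from .tissue_models import to_conductivity_field

    return to_conductivity_field(grid, table)
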