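"""Forward electrostatics for inter-sheet impedance tests.

The tested skin patch is a voxelized two-layer block (resistive stratum
corneum over conductive dermis).  Needle columns are carved out of the block
down to the insertion depth; every exposed needle/skin face couples the
adjacent skin voxel to its sheet's potential through a thin contact-impedance
layer whose conductivity follows the tip's penetration flag:

    sigma_contact = (1 - XY) * sigma_dermis + XY * sigma_sc

with XY = 1 for an unpenetrated tip.  The metal sheets (sigma ~ 1e7 S/m,
5e7 times the dermis) are not meshed: each sheet is a single equipotential
node, which is numerically equivalent and keeps the linear system well
conditioned.  A steady conduction problem div(sigma grad phi) = 0 is solved
with a 7-point finite-volume stencil (harmonic-mean face conductances),
insulating outer boundaries, the source sheet at the drive voltage and the
ground sheet at 0 V; non-tested sheets float (one extra unknown each, zero
net current).  The reported observable is the terminal current in μA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import ArrayGeometry, SkinModel, SolverConfig
from .states import PenetrationState, TransdermalState, canonical_state

__all__ = [
    "GridModel",
    "CurrentRecord",
    "SolverError",
    "contact_conductivity",
    "discretize",
    "solve_pair_current",
    "validate_homogeneous_slab",
]

_UM = 1e-6  # μm → m


class SolverError(RuntimeError):
    """Raised when the conduction system is singular or fails to balance."""


def contact_conductivity(xy: int, skin: SkinModel) -> float:
    """State-dependent conductivity of the needle/skin contact layer (S/m).

    ``xy`` is the penetration flag of the owning tip: 1 (unpenetrated) gives
    the stratum-corneum conductivity, 0 (penetrated) the dermis conductivity.
    Fractional flags are rejected; partial penetration is not modelled.
    """
    if xy not in (0, 1):
        raise ValueError(f"penetration flag must be 0 or 1, got {xy!r}")
    return (1 - xy) * skin.dermis_conductivity + xy * skin.sc_conductivity


@dataclass
class CurrentRecord:
    """One simulated inter-sheet current for a sheet pair."""

    pair: tuple[int, int]
    state: TransdermalState
    combination_index: int
    current_uA: float

    def __post_init__(self) -> None:
        if self.pair[0] == self.pair[1]:
            raise ValueError("pair must name two distinct sheets")
        if self.current_uA < 0:
            raise ValueError("current must be nonnegative")


@dataclass
class GridModel:
    """Voxelized skin block with tagged needle contact faces.

    Geometry is carved once; penetration flags only re-weight the contact
    conductances, so one grid serves a whole exhaustive sweep.
    """

    geometry: ArrayGeometry
    skin: SkinModel
    config: SolverConfig
    dims: tuple[int, int, int]
    n_active: int
    active_index: np.ndarray        # (nx, ny, nz) int32, -1 where carved
    sheets_present: tuple[int, ...]
    # interior 7-point stencil in COO form (voxel-voxel conductances, S)
    lap_rows: np.ndarray = field(repr=False, default=None)
    lap_cols: np.ndarray = field(repr=False, default=None)
    lap_vals: np.ndarray = field(repr=False, default=None)
    # contact faces: owning skin voxel, sheet, tip, geometric factor A/t (m)
    face_voxel: np.ndarray = field(repr=False, default=None)
    face_sheet: np.ndarray = field(repr=False, default=None)
    face_tip: np.ndarray = field(repr=False, default=None)
    face_coeff: np.ndarray = field(repr=False, default=None)

    @property
    def n_contact_faces(self) -> int:
        return len(self.face_voxel)

    def carved_columns(self) -> int:
        """Number of distinct (sheet, tip) needle footprints with contact faces."""
        if self.n_contact_faces == 0:
            return 0
        return len(set(zip(self.face_sheet.tolist(), self.face_tip.tolist())))

    @property
    def skin_area_ratio(self) -> float:
        """Lateral skin area divided by array footprint area."""
        nx, ny, _ = self.dims
        h = self.config.voxel_size
        return (nx * h) * (ny * h) / (self.geometry.extent_x * self.geometry.extent_y)


def _needle_boxes(geometry: ArrayGeometry, ox: float, oy: float, taper: bool):
    """Rectangular boxes (μm) occupied by each inserted needle column.

    Yields (sheet, tip, x0, x1, y0, y1, z0, z1).  With ``taper`` the final
    tip_section_length of the inserted depth is narrowed to half width,
    a stepped stand-in for the sharpened tip.
    """
    g = geometry
    for s in range(g.n_sheets):
        x0 = ox + s * g.sheet_pitch
        x1 = x0 + g.sheet_thickness
        for t in range(g.tips_per_sheet):
            y0 = oy + t * g.tip_pitch
            y1 = y0 + g.tip_width
            if not taper:
                yield s, t, x0, x1, y0, y1, 0.0, g.insertion_depth
                continue
            z_taper = max(g.insertion_depth - g.tip_section_length, 0.0)
            if z_taper > 0:
                yield s, t, x0, x1, y0, y1, 0.0, z_taper
            quarter = g.tip_width / 4
            yield s, t, x0, x1, y0 + quarter, y1 - quarter, z_taper, g.insertion_depth


def discretize(
    geometry: ArrayGeometry,
    skin: SkinModel,
    config: SolverConfig,
    include_sheets: Sequence[int] | None = None,
    taper: bool = False,
) -> GridModel:
    """Build the voxel grid: carve needles, tag contact faces, cache the stencil.

    The skin block spans sqrt(footprint_ratio) times the array extent per
    lateral axis (rounded up to whole voxels, array centered) and the full
    two-layer depth.  Sheets listed in ``include_sheets`` (default: all) have
    their needles carved; others are absent from the model.
    """
    h = config.voxel_size
    if h > geometry.tip_width:
        raise ValueError(
            f"voxel_size {h} μm exceeds tip_width {geometry.tip_width} μm"
        )
    scale = float(np.sqrt(skin.footprint_ratio))
    nx = int(np.ceil(scale * geometry.extent_x / h - 1e-9))
    ny = int(np.ceil(scale * geometry.extent_y / h - 1e-9))
    nz = int(np.round(skin.depth / h))
    if nz < 2 or abs(nz * h - skin.depth) > 1e-6 * skin.depth:
        raise ValueError("voxel_size must divide the total skin depth")
    # snap the (near-centered) array origin to the voxel grid so the carved
    # needle region is identical whatever the lateral margin
    ox = round((nx * h - geometry.extent_x) / 2 / h) * h
    oy = round((ny * h - geometry.extent_y) / 2 / h) * h
    present = tuple(range(geometry.n_sheets)) if include_sheets is None else tuple(include_sheets)

    xc = (np.arange(nx) + 0.5) * h
    yc = (np.arange(ny) + 0.5) * h
    zc = (np.arange(nz) + 0.5) * h

    carved = np.zeros((nx, ny, nz), dtype=bool)
    owner_sheet = np.full((nx, ny, nz), -1, dtype=np.int32)
    owner_tip = np.full((nx, ny, nz), -1, dtype=np.int32)
    for s, t, x0, x1, y0, y1, z0, z1 in _needle_boxes(geometry, ox, oy, taper):
        if s not in present:
            continue
        ix = (xc > x0) & (xc < x1)
        iy = (yc > y0) & (yc < y1)
        iz = (zc > z0) & (zc < z1)
        box = np.ix_(ix, iy, iz)
        carved[box] = True
        owner_sheet[box] = s
        owner_tip[box] = t

    active = ~carved
    active_index = np.full((nx, ny, nz), -1, dtype=np.int32)
    active_index[active] = np.arange(int(active.sum()), dtype=np.int32)
    n_active = int(active.sum())

    # per-voxel conductivity by depth layer
    sigma_z = np.where(zc < skin.sc_thickness, skin.sc_conductivity, skin.dermis_conductivity)
    sigma = np.broadcast_to(sigma_z, (nx, ny, nz))

    h_m = h * _UM
    rows, cols, vals = [], [], []
    f_vox, f_sheet, f_tip, f_coeff = [], [], [], []

    def couple(sl_a, sl_b):
        """Process faces between voxel slab a and its +axis neighbor slab b."""
        act_a, act_b = active[sl_a], active[sl_b]
        both = act_a & act_b
        if both.any():
            ia = active_index[sl_a][both]
            ib = active_index[sl_b][both]
            sa, sb = sigma[sl_a][both], sigma[sl_b][both]
            g = 2.0 * sa * sb / (sa + sb) * h_m  # harmonic mean × A/h
            rows.extend((ia, ib, ia, ib))
            cols.extend((ib, ia, ia, ib))
            vals.extend((-g, -g, g, g))
        # skin voxel facing a carved needle voxel → contact face
        for skin_sl, carved_sl in ((sl_a, sl_b), (sl_b, sl_a)):
            m = active[skin_sl] & carved[carved_sl]
            if m.any():
                f_vox.append(active_index[skin_sl][m])
                f_sheet.append(owner_sheet[carved_sl][m])
                f_tip.append(owner_tip[carved_sl][m])
                f_coeff.append(np.full(int(m.sum()), h_m * h_m / (skin.contact_thickness * _UM)))

    couple((slice(0, -1), slice(None), slice(None)), (slice(1, None), slice(None), slice(None)))
    couple((slice(None), slice(0, -1), slice(None)), (slice(None), slice(1, None), slice(None)))
    couple((slice(None), slice(None), slice(0, -1)), (slice(None), slice(None), slice(1, None)))

    def cat(parts, dtype):
        if not parts:
            return np.empty(0, dtype=dtype)
        return np.concatenate([np.asarray(p, dtype=dtype).ravel() for p in parts])

    return GridModel(
        geometry=geometry,
        skin=skin,
        config=config,
        dims=(nx, ny, nz),
        n_active=n_active,
        active_index=active_index,
        sheets_present=present,
        lap_rows=cat(rows, np.int32),
        lap_cols=cat(cols, np.int32),
        lap_vals=cat(vals, np.float64),
        face_voxel=cat(f_vox, np.int32),
        face_sheet=cat(f_sheet, np.int32),
        face_tip=cat(f_tip, np.int32),
        face_coeff=cat(f_coeff, np.float64),
    )


def _face_conductances(grid: GridModel, state: PenetrationState) -> np.ndarray:
    """Per-contact-face conductance (S) under the given penetration flags."""
    skin = grid.skin
    xy = state.flags[grid.face_sheet, grid.face_tip].astype(np.float64)
    sigma_c = (1.0 - xy) * skin.dermis_conductivity + xy * skin.sc_conductivity
    return sigma_c * grid.face_coeff


def solve_pair_current(
    grid: GridModel,
    state: PenetrationState,
    source: int,
    ground: int,
    config: SolverConfig | None = None,
    combination_index: int = 0,
    floating: bool = True,
) -> CurrentRecord:
    """Terminal current between two sheets under the drive voltage.

    The source sheet is clamped at ``drive_voltage``, the ground sheet at 0;
    the remaining present sheets are floating equipotential nodes unless
    ``floating=False``, in which case their contact faces are dropped
    (equivalent to suppressing them).  Returns the current into ground in μA
    after checking source/ground balance to 1e-6 relative.
    """
    config = config or grid.config
    if source == ground:
        raise ValueError("source and ground must differ")
    for sheet in (source, ground):
        if sheet not in grid.sheets_present:
            raise ValueError(f"sheet {sheet} absent from the grid")
    if state.flags.shape != (grid.geometry.n_sheets, grid.geometry.tips_per_sheet):
        raise ValueError("penetration state does not match the array geometry")

    g_face = _face_conductances(grid, state)
    fs = grid.face_sheet
    fv = grid.face_voxel
    on_source = fs == source
    on_ground = fs == ground
    if not on_source.any() or not on_ground.any():
        raise SolverError("tested sheet has no contact faces (not inserted?)")

    float_sheets = [
        s for s in grid.sheets_present if s not in (source, ground)
    ] if floating else []
    sheet_node = {s: grid.n_active + k for k, s in enumerate(float_sheets)}
    n = grid.n_active + len(float_sheets)

    rows = [grid.lap_rows]
    cols = [grid.lap_cols]
    vals = [grid.lap_vals]

    # contact faces: diagonal load on the skin voxel for every face
    rows.append(fv)
    cols.append(fv)
    vals.append(g_face)

    b = np.zeros(n)
    V = config.drive_voltage
    b[fv[on_source]] += g_face[on_source] * V

    for s in float_sheets:
        m = fs == s
        if not m.any():
            raise SolverError(f"floating sheet {s} has no contact faces")
        node = sheet_node[s]
        iv, gv = fv[m], g_face[m]
        rows.extend((iv, np.full(iv.shape, node, np.int32), np.array([node])))
        cols.extend((np.full(iv.shape, node, np.int32), iv, np.array([node])))
        vals.extend((-gv, -gv, np.array([gv.sum()])))

    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    # SPD system: Jacobi-preconditioned conjugate gradients.  The diagonal
    # preconditioner absorbs the sc/dermis contact-conductance contrast well
    # enough that coarse sweep grids converge in a few hundred iterations.
    diag = A.diagonal()
    if np.any(diag <= 0):
        raise SolverError("singular conduction system (isolated node)")
    M = sp.diags(1.0 / diag)
    phi, info = spla.cg(
        A, b, rtol=config.relative_tolerance * 1e-2, atol=0.0,
        maxiter=config.max_iterations, M=M,
    )
    if info > 0:
        raise SolverError(f"CG failed to converge within {config.max_iterations} iterations")
    if info < 0 or not np.all(np.isfinite(phi)):
        raise SolverError("singular conduction system (all contact paths broken?)")

    i_ground = float(np.sum(g_face[on_ground] * phi[fv[on_ground]]))
    i_source = float(np.sum(g_face[on_source] * (V - phi[fv[on_source]])))
    if abs(i_source - i_ground) > 1e-6 * max(abs(i_source), 1e-300):
        raise SolverError(
            f"current imbalance: source {i_source:.6e} A vs ground {i_ground:.6e} A"
        )

    pair_state = state.pair_state(source, ground)
    return CurrentRecord(
        pair=(source, ground),
        state=pair_state,
        combination_index=combination_index,
        current_uA=i_ground / _UM,
    )


def validate_homogeneous_slab(
    config: SolverConfig | None = None,
    sigma: float = 0.2,
    side_um: float = 1000.0,
    depth_um: float = 1000.0,
) -> float:
    """Relative error of the solver against the analytic slab conductance.

    Two full-width plate electrodes on opposite faces of a homogeneous block
    (no contact impedance): the conductance must match G = sigma * A / L.
    Returns |G_num - G| / G.
    """
    config = config or SolverConfig()
    h = config.voxel_size
    nx = max(int(round(side_um / h)), 1)
    ny = nx
    nz = max(int(round(depth_um / h)), 2)
    h_m = h * _UM
    n = nx * ny * nz

    idx = np.arange(n).reshape(nx, ny, nz)
    g_int = sigma * h_m
    rows, cols, vals = [], [], []
    for sl_a, sl_b in (
        ((slice(0, -1), slice(None), slice(None)), (slice(1, None), slice(None), slice(None))),
        ((slice(None), slice(0, -1), slice(None)), (slice(None), slice(1, None), slice(None))),
        ((slice(None), slice(None), slice(0, -1)), (slice(None), slice(None), slice(1, None))),
    ):
        ia, ib = idx[sl_a].ravel(), idx[sl_b].ravel()
        rows.extend((ia, ib, ia, ib))
        cols.extend((ib, ia, ia, ib))
        g = np.full(ia.shape, g_int)
        vals.extend((-g, -g, g, g))

    # Dirichlet plates at z=0 (V) and z=L (0): half-cell conductance to the face
    g_bc = sigma * h_m * 2.0
    top = idx[:, :, 0].ravel()
    bot = idx[:, :, -1].ravel()
    b = np.zeros(n)
    diag_extra = np.zeros(n)
    V = config.drive_voltage
    diag_extra[top] += g_bc
    diag_extra[bot] += g_bc
    b[top] += g_bc * V
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag_extra)

    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    phi = spla.spsolve(A, b)
    current = float(np.sum(g_bc * (V - phi[top])))
    g_num = current / V
    area = (nx * h_m) * (ny * h_m)
    g_ref = sigma * area / (nz * h_m)
    return abs(g_num - g_ref) / g_ref
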