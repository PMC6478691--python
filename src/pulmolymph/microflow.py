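"""Steady coupled Stokes/Darcy flow on voxel grids with membrane walls.

Model: interstitium is a Darcy porous medium (u = −(k/μ)∇p, ∇·u = 0);
vessel lumens carry incompressible Stokes flow (0 = μ∇²u − ∇p, ∇·u = 0);
each lumen–interstitium voxel face is a permeable membrane with normal
seepage u·n = K (p_lumen − p_interstitium) and tangential no-slip.
External interstitial faces carry Dirichlet pressure, lumen openings are
velocity inlets or pressure outlets, air-adjacent faces are no-flux walls
and gravity is neglected.

Discretization: marker-and-cell staggering on the uniform voxel grid.
Cell pressures are unknown for every fluid cell; face-normal velocities
are unknown on lumen–lumen faces and on pressure-outlet faces.  Membrane
seepage velocities are eliminated through the wall relation, which makes
the reduced pressure system C + BᵀA⁻¹B symmetric positive definite
(A: viscous block, B: discrete gradient, C: Darcy/membrane conductances).
The solver factorizes A sparsely and runs Jacobi-preconditioned CG on the
pressure Schur complement; velocities are recovered afterwards.  Backflow
at pressure outlets is suppressed by converting inflowing outlet faces to
no-slip walls and re-solving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components

from pulmolymph.core import FACE_NAMES, FluidParameters, face_axis_side
from pulmolymph.model_prep import BoundarySpec, ModelVolume

# face-type codes on the per-axis staggered face grids
_F_WALL = 0      # no-slip / no-flux (air, mixed-class, unopened lumen faces)
_F_STOKES = 1    # lumen-lumen interior face: velocity unknown
_F_OUTLET = 2    # boundary lumen face with Dirichlet pressure: unknown
_F_INLET = 3     # boundary lumen face with prescribed normal velocity
_F_MEMBRANE = 4  # lumen-interstitium face: seepage from pressures
_F_DARCY = 5     # interstitium-interstitium face
_F_EXT = 6       # boundary interstitium face (Dirichlet p or sealed)

_CLS_AIR, _CLS_INT, _CLS_BLOOD, _CLS_LYMPH = 0, 1, 2, 3


class SingularSystemError(RuntimeError):
    """The flow problem has no pressure reference anywhere (unforced)."""


class NonConvergenceError(RuntimeError):
    pass


@dataclass
class DiscreteFlowSystem:
    """Assembled sparse steady-flow problem (see module docstring)."""

    model: ModelVolume
    boundaries: BoundarySpec
    params: FluidParameters
    interstitial_bc: dict[str, float | None]
    h: float                      # voxel pitch, m
    cls: np.ndarray               # cell class grid
    active: np.ndarray            # fluid cells coupled to a pressure anchor
    pidx: np.ndarray              # 3D -> pressure unknown index (-1 elsewhere)
    n_p: int = 0
    n_u: int = 0
    A_visc: sp.csr_matrix | None = None
    B: sp.csr_matrix | None = None
    C: sp.csr_matrix | None = None
    b_u: np.ndarray | None = None
    b_p: np.ndarray | None = None
    ftype: list[np.ndarray] = field(default_factory=list)
    fid: list[np.ndarray] = field(default_factory=list)
    fval: list[np.ndarray] = field(default_factory=list)
    fK: list[np.ndarray] = field(default_factory=list)
    fpout: list[np.ndarray] = field(default_factory=list)
    fext: list[np.ndarray] = field(default_factory=list)   # ext dirichlet value (nan=sealed)
    inlet_velocities: dict = field(default_factory=dict)
    outlet_pressures: dict = field(default_factory=dict)
    wall_faces: set = field(default_factory=set)            # suppressed outlets
    n_dropped_cells: int = 0
    groups: np.ndarray | None = None   # strong-coupling component per unknown


@dataclass
class FluxReport:
    Q_L_in: float = 0.0           # net membrane flux into the lymph domain, m³/s
    Q_B_out: float = 0.0          # net membrane flux out of the blood domain
    inlet_flux: dict = field(default_factory=dict)     # class -> m³/s into domain
    outlet_flux: dict = field(default_factory=dict)    # class -> m³/s out of domain
    interstitial_exchange_in: float = 0.0   # net Dirichlet-face inflow, m³/s
    balance_defect: dict = field(default_factory=dict)  # domain -> relative defect


@dataclass
class FlowSolution:
    p: np.ndarray                 # cell pressures, Pa (NaN outside fluid)
    u_cell: np.ndarray            # (3, nz, ny, nx) cell-centred velocity, m/s
    face_velocity: list[np.ndarray]   # per-axis staggered normal velocities
    residuals: dict
    suppressed_outlet_faces: int
    backflow_flagged: bool
    fluxes: FluxReport | None = None
    solver: str = ""


# --------------------------------------------------------------------------
# assembly


def _class_grid(model: ModelVolume) -> np.ndarray:
    cls = np.zeros(model.shape, dtype=np.int8)
    cls[model.interstitium] = _CLS_INT
    cls[model.blood] = _CLS_BLOOD
    cls[model.lymph] = _CLS_LYMPH
    return cls


def _resolve_interstitial_bc(bc, params) -> dict[str, float | None]:
    if bc == "default":
        return {f: params.p_int for f in FACE_NAMES}
    if bc is None:
        return {f: None for f in FACE_NAMES}
    if isinstance(bc, (int, float)):
        return {f: float(bc) for f in FACE_NAMES}
    out = {f: None for f in FACE_NAMES}
    for f, v in bc.items():
        face_axis_side(f)
        out[f] = None if v is None else float(v)
    return out


def _patch_faces(model_shape, patch):
    """(axis, qz, qy, qx) face-grid positions for a boundary patch array."""
    cells = patch[:, :3]
    face = FACE_NAMES[int(patch[0, 3])]
    axis, side = face_axis_side(face)
    pos = cells.copy()
    if side == -1:
        pos[:, axis] += 1
    return axis, pos


def assemble(
    model: ModelVolume,
    boundaries: BoundarySpec,
    params: FluidParameters,
    interstitial_bc="default",
    inlet_velocities: dict | None = None,
    outlet_pressures: dict | None = None,
    wall_faces: set | None = None,
) -> DiscreteFlowSystem:
    """Assemble the discrete coupled system.

    ``interstitial_bc`` is ``"default"`` (Dirichlet ``p_int`` on all six
    faces), a scalar, ``None`` (all sealed), or a per-face dict with
    ``None`` meaning sealed.  ``inlet_velocities`` / ``outlet_pressures``
    optionally override the class defaults per patch, keyed
    ``(cls, patch_index)``.  ``wall_faces`` are outlet voxel-faces already
    converted to walls by backflow suppression.
    """
    cls = _class_grid(model)
    shape = cls.shape
    h = model.voxel_pitch * 1e-6
    A_area = h * h
    mu, k = params.mu, params.k
    ibc = _resolve_interstitial_bc(interstitial_bc, params)
    wall_faces = wall_faces or set()

    cpad = np.pad(cls, 1, constant_values=-1)

    ftype, fid, fval, fK, fpout, fext = [], [], [], [], [], []
    n_u = 0
    for d in range(3):
        sl_lo = [slice(1, -1)] * 3
        sl_hi = [slice(1, -1)] * 3
        sl_lo[d] = slice(0, shape[d] + 1)
        sl_hi[d] = slice(1, shape[d] + 2)
        lo = cpad[tuple(sl_lo)]
        hi = cpad[tuple(sl_hi)]
        ft = np.full(lo.shape, _F_WALL, dtype=np.int8)
        lum_lo = (lo == _CLS_BLOOD) | (lo == _CLS_LYMPH)
        lum_hi = (hi == _CLS_BLOOD) | (hi == _CLS_LYMPH)
        ft[(lo == hi) & lum_lo] = _F_STOKES
        ft[(lo == _CLS_INT) & (hi == _CLS_INT)] = _F_DARCY
        memb = ((lum_lo & (hi == _CLS_INT)) | (lum_hi & (lo == _CLS_INT)))
        ft[memb] = _F_MEMBRANE
        ft[((lo == -1) & (hi == _CLS_INT)) | ((hi == -1) & (lo == _CLS_INT))] = _F_EXT
        # boundary lumen faces default to wall; patches promote them below
        ftype.append(ft)
        fid.append(np.full(ft.shape, -1, dtype=np.int64))
        fval.append(np.zeros(ft.shape))
        Kf = np.zeros(ft.shape)
        Kf[memb & ((lo == _CLS_LYMPH) | (hi == _CLS_LYMPH))] = params.K_L
        Kf[memb & ((lo == _CLS_BLOOD) | (hi == _CLS_BLOOD))] = params.K_B
        fK.append(Kf)
        fpout.append(np.zeros(ft.shape))
        ext = np.full(ft.shape, np.nan)
        fext.append(ext)

    # external interstitial Dirichlet values per cube face
    for face in FACE_NAMES:
        axis, side = face_axis_side(face)
        q = 0 if side == 0 else shape[axis]
        sl = [slice(None)] * 3
        sl[axis] = q
        sel = tuple(sl)
        val = ibc[face]
        if val is not None:
            mask = ftype[axis][sel] == _F_EXT
            plane = fext[axis][sel]
            plane[mask] = val
            fext[axis][sel] = plane

    # promote boundary lumen faces per patch
    inlet_velocities = inlet_velocities or {}
    outlet_pressures = outlet_pressures or {}
    default_u = {"blood": params.u_B, "lymph": params.u_L}
    default_p = {"blood": params.p_B, "lymph": params.p_L}
    for kind, patches_by_cls, code in (
        ("inlet", boundaries.inlets, _F_INLET),
        ("outlet", boundaries.outlets, _F_OUTLET),
    ):
        for cname, patches in patches_by_cls.items():
            for ip, patch in enumerate(patches):
                axis, pos = _patch_faces(shape, patch)
                side = 0 if pos[0, axis] == 0 else -1
                inward = 1.0 if side == 0 else -1.0
                for row in pos:
                    key = (axis, row[0], row[1], row[2])
                    sel = (row[0], row[1], row[2])
                    if kind == "outlet" and key in wall_faces:
                        ftype[axis][sel] = _F_WALL
                        continue
                    if kind == "inlet":
                        u_in = inlet_velocities.get((cname, ip),
                                                    default_u[cname])
                        ftype[axis][sel] = _F_INLET
                        fval[axis][sel] = inward * u_in
                    else:
                        p_out = outlet_pressures.get((cname, ip),
                                                     default_p[cname])
                        ftype[axis][sel] = _F_OUTLET
                        fpout[axis][sel] = p_out

    # velocity unknown ids
    for d in range(3):
        unk = (ftype[d] == _F_STOKES) | (ftype[d] == _F_OUTLET)
        ids = np.flatnonzero(unk)
        fid[d].ravel()[ids] = np.arange(n_u, n_u + len(ids))
        n_u += len(ids)

    system = DiscreteFlowSystem(
        model=model, boundaries=boundaries, params=params,
        interstitial_bc=ibc, h=h, cls=cls,
        active=np.zeros(shape, dtype=bool),
        pidx=np.full(shape, -1, dtype=np.int64),
        ftype=ftype, fid=fid, fval=fval, fK=fK, fpout=fpout, fext=fext,
        inlet_velocities=dict(inlet_velocities),
        outlet_pressures=dict(outlet_pressures),
        wall_faces=set(wall_faces),
    )
    _assemble_matrices(system, A_area, mu, k)
    return system


def _face_cells(shape, d, pos):
    """Flat cell indices (lo, hi) adjacent to face-grid positions; -1 outside."""
    lo = pos.copy()
    lo[:, d] -= 1
    hi = pos
    def flat(c):
        ok = (c[:, d] >= 0) & (c[:, d] < shape[d])
        out = np.full(len(c), -1, dtype=np.int64)
        cc = np.clip(c, 0, np.array(shape) - 1)
        out[ok] = np.ravel_multi_index(
            (cc[ok, 0], cc[ok, 1], cc[ok, 2]), shape)
        return out
    return flat(lo), flat(hi)


def _assemble_matrices(S: DiscreteFlowSystem, A_area, mu, k):
    shape = S.cls.shape
    h = S.h
    n_cells = int(np.prod(shape))
    fluid = S.cls != _CLS_AIR

    # ---- connectivity graph over cells to find pressure-anchored components
    gi, gj = [], []
    si, sj = [], []   # strong edges: Darcy and Stokes only (no membranes)
    anchor = np.zeros(n_cells, dtype=bool)
    for d in range(3):
        ft = S.ftype[d]
        pos_all = np.argwhere((ft == _F_DARCY) | (ft == _F_MEMBRANE)
                              | (ft == _F_STOKES))
        if len(pos_all):
            lo, hi = _face_cells(shape, d, pos_all)
            gi.append(lo)
            gj.append(hi)
        pos_strong = np.argwhere((ft == _F_DARCY) | (ft == _F_STOKES))
        if len(pos_strong):
            lo, hi = _face_cells(shape, d, pos_strong)
            si.append(lo)
            sj.append(hi)
        pos_anchor = np.argwhere(((ft == _F_EXT) & ~np.isnan(S.fext[d]))
                                 | (ft == _F_OUTLET))
        if len(pos_anchor):
            lo, hi = _face_cells(shape, d, pos_anchor)
            anchor[lo[lo >= 0]] = True
            anchor[hi[hi >= 0]] = True
    if not anchor.any():
        raise SingularSystemError(
            "no Dirichlet pressure anywhere (no outlet face, no external "
            "interstitial pressure): the steady problem is singular"
        )
    if gi:
        gi = np.concatenate(gi)
        gj = np.concatenate(gj)
        adj = sp.coo_matrix((np.ones(len(gi)), (gi, gj)),
                            shape=(n_cells, n_cells))
        ncomp, comp = connected_components(adj + adj.T, directed=False)
        anchored_comps = np.zeros(ncomp, dtype=bool)
        anchored_comps[comp[anchor]] = True
        active = fluid.ravel() & anchored_comps[comp]
    else:
        active = fluid.ravel() & anchor
    S.active = active.reshape(shape)
    S.n_dropped_cells = int(fluid.sum() - S.active.sum())
    S.pidx = np.full(shape, -1, dtype=np.int64)
    S.pidx[S.active] = np.arange(int(S.active.sum()))
    S.n_p = int(S.active.sum())
    pidx_flat = S.pidx.ravel()

    # strong-coupling groups (per-lumen / per-interstitium components):
    # these are the stiff pressure-datum modes the coarse correction fixes
    if si:
        si_all = np.concatenate(si)
        sj_all = np.concatenate(sj)
        sadj = sp.coo_matrix((np.ones(len(si_all)), (si_all, sj_all)),
                             shape=(n_cells, n_cells))
        _, scomp = connected_components(sadj + sadj.T, directed=False)
    else:
        scomp = np.arange(n_cells)
    act_flat = np.flatnonzero(S.active.ravel())
    _, S.groups = np.unique(scomp[act_flat], return_inverse=True)

    # drop velocity unknowns attached to inactive cells (whole components)
    n_u = 0
    for d in range(3):
        unk = (S.ftype[d] == _F_STOKES) | (S.ftype[d] == _F_OUTLET)
        pos = np.argwhere(unk)
        if len(pos) == 0:
            S.fid[d][:] = -1
            continue
        lo, hi = _face_cells(shape, d, pos)
        keep = np.zeros(len(pos), dtype=bool)
        for c in (lo, hi):
            ok = c >= 0
            keep[ok] |= pidx_flat[c[ok]] >= 0
        S.fid[d][:] = -1
        kept = pos[keep]
        S.fid[d][kept[:, 0], kept[:, 1], kept[:, 2]] = \
            np.arange(n_u, n_u + keep.sum())
        n_u += int(keep.sum())
    S.n_u = n_u

    # ---- viscous block A and gradient block B ----------------------------
    Ai, Aj, Av = [], [], []
    Bi, Bj, Bv = [], [], []
    b_u = np.zeros(n_u)
    mh = mu * h
    for d in range(3):
        ids = S.fid[d]
        pos = np.argwhere(ids >= 0)
        if len(pos) == 0:
            continue
        rows = ids[pos[:, 0], pos[:, 1], pos[:, 2]]
        ftd = S.ftype[d]
        diag = np.zeros(len(pos))
        for a in range(3):
            for s in (-1, 1):
                npos = pos.copy()
                npos[:, a] += s
                if a == d:
                    in_grid = (npos[:, a] >= 0) & (npos[:, a] <= shape[d])
                else:
                    in_grid = (npos[:, a] >= 0) & (npos[:, a] < ftd.shape[a])
                nc = np.clip(npos, 0, np.array(ftd.shape) - 1)
                ntype = np.where(in_grid,
                                 ftd[nc[:, 0], nc[:, 1], nc[:, 2]], -2)
                nid = np.where(in_grid,
                               ids[nc[:, 0], nc[:, 1], nc[:, 2]], -1)
                nval = np.where(in_grid,
                                S.fval[d][nc[:, 0], nc[:, 1], nc[:, 2]], 0.0)
                unknown = nid >= 0
                known_in = ntype == _F_INLET
                zero_val = (ntype == _F_MEMBRANE) | (ntype == _F_WALL) \
                    | (ntype == _F_DARCY) | (ntype == _F_EXT)
                if a == d:
                    # out of grid along the normal: homogeneous Neumann
                    slot = unknown | known_in | zero_val
                    diag += np.where(slot, mh, 0.0)
                else:
                    # tangential: absent fluid means a no-slip wall at h/2
                    ghost = ~(unknown | known_in)
                    diag += np.where(ghost, 2 * mh, mh)
                Ai.append(rows[unknown])
                Aj.append(nid[unknown])
                Av.append(np.full(unknown.sum(), -mh))
                np.add.at(b_u, rows[known_in], mh * nval[known_in])
        Ai.append(rows)
        Aj.append(rows)
        Av.append(diag)
        # pressure gradient: +A p_hi - A p_lo
        lo, hi = _face_cells(shape, d, pos)
        typ = ftd[pos[:, 0], pos[:, 1], pos[:, 2]]
        pout = S.fpout[d][pos[:, 0], pos[:, 1], pos[:, 2]]
        for cells, sign in ((hi, +1.0), (lo, -1.0)):
            inside = cells >= 0
            pcol = np.where(inside, pidx_flat[np.clip(cells, 0, None)], -1)
            okp = pcol >= 0
            Bi.append(rows[okp])
            Bj.append(pcol[okp])
            Bv.append(np.full(okp.sum(), sign * A_area))
            ghost = ~inside & (typ == _F_OUTLET)
            np.add.at(b_u, rows[ghost], -sign * A_area * pout[ghost])

    A_visc = sp.coo_matrix(
        (np.concatenate(Av) if Av else [],
         (np.concatenate(Ai) if Ai else [],
          np.concatenate(Aj) if Aj else [])),
        shape=(n_u, n_u)).tocsc()
    B = sp.coo_matrix(
        (np.concatenate(Bv) if Bv else [],
         (np.concatenate(Bi) if Bi else [],
          np.concatenate(Bj) if Bj else [])),
        shape=(n_u, S.n_p)).tocsr()

    # ---- pressure block C and RHS ----------------------------------------
    Ci, Cj, Cv = [], [], []
    b_p = np.zeros(S.n_p)
    g_darcy = k * A_area / (mu * h)
    for d in range(3):
        ftd = S.ftype[d]
        # Darcy interior faces
        pos = np.argwhere(ftd == _F_DARCY)
        if len(pos):
            lo, hi = _face_cells(shape, d, pos)
            plo, phi = pidx_flat[lo], pidx_flat[hi]
            ok = (plo >= 0) & (phi >= 0)
            plo, phi = plo[ok], phi[ok]
            Ci += [plo, phi, plo, phi]
            Cj += [plo, phi, phi, plo]
            Cv += [np.full(len(plo), g_darcy), np.full(len(plo), g_darcy),
                   np.full(len(plo), -g_darcy), np.full(len(plo), -g_darcy)]
        # membrane faces
        pos = np.argwhere(ftd == _F_MEMBRANE)
        if len(pos):
            lo, hi = _face_cells(shape, d, pos)
            Kv = S.fK[d][pos[:, 0], pos[:, 1], pos[:, 2]] * A_area
            plo, phi = pidx_flat[lo], pidx_flat[hi]
            ok = (plo >= 0) & (phi >= 0)
            plo, phi, Kv = plo[ok], phi[ok], Kv[ok]
            Ci += [plo, phi, plo, phi]
            Cj += [plo, phi, phi, plo]
            Cv += [Kv, Kv, -Kv, -Kv]
        # external Dirichlet interstitial faces (half-cell gradient)
        pos = np.argwhere((ftd == _F_EXT) & ~np.isnan(S.fext[d]))
        if len(pos):
            lo, hi = _face_cells(shape, d, pos)
            cell = np.where(lo >= 0, lo, hi)
            val = S.fext[d][pos[:, 0], pos[:, 1], pos[:, 2]]
            pc = pidx_flat[cell]
            ok = pc >= 0
            pc, val = pc[ok], val[ok]
            g2 = 2.0 * g_darcy
            Ci.append(pc)
            Cj.append(pc)
            Cv.append(np.full(len(pc), g2))
            np.add.at(b_p, pc, -g2 * val)
        # inlet faces: known inflow
        pos = np.argwhere(ftd == _F_INLET)
        if len(pos):
            lo, hi = _face_cells(shape, d, pos)
            val = S.fval[d][pos[:, 0], pos[:, 1], pos[:, 2]]
            # inflow into the interior cell: +A*val if cell is hi, -A*val if lo
            for cells, sign in ((hi, +1.0), (lo, -1.0)):
                inside = cells >= 0
                pc = pidx_flat[cells[inside]]
                okp = pc >= 0
                np.add.at(b_p, pc[okp],
                          -sign * A_area * val[inside][okp])

    C = sp.coo_matrix(
        (np.concatenate(Cv) if Cv else [],
         (np.concatenate(Ci) if Ci else [],
          np.concatenate(Cj) if Cj else [])),
        shape=(S.n_p, S.n_p)).tocsr()

    S.A_visc, S.B, S.C = A_visc, B, C
    S.b_u, S.b_p = b_u, b_p


# --------------------------------------------------------------------------
# solve


def _solve_linear(S: DiscreteFlowSystem, tol: float):
    """Schur-complement solve; returns (p_vec, u_vec, solver_tag)."""
    C, B, A = S.C, S.B, S.A_visc
    if S.n_u > 0:
        lu = spla.splu(A)
        diagA = A.diagonal()
        rhs = B.T @ lu.solve(S.b_u) - S.b_p

        def matvec(x):
            return C @ x + B.T @ lu.solve(B @ x)

        Sop = spla.LinearOperator((S.n_p, S.n_p), matvec=matvec)
        dS = C.diagonal() + np.asarray(
            (B.power(2).T @ (1.0 / diagA))).ravel()
    else:
        rhs = -S.b_p
        Sop = C
        dS = C.diagonal()
    if S.n_p == 0:
        raise SingularSystemError("no pressure unknowns")
    dS = np.where(dS > 0, dS, 1.0)
    # explicit symmetric Jacobi scaling: rows of wildly different physical
    # scale (Darcy vs membrane vs Stokes) then converge together, which a
    # preconditioner alone does not guarantee with an unscaled stopping rule
    sc = 1.0 / np.sqrt(dS)

    def matvec_scaled(y):
        return sc * (Sop @ (sc * y))

    Ss = spla.LinearOperator((S.n_p, S.n_p), matvec=matvec_scaled)
    rhs_s = sc * rhs
    y, info = spla.cg(Ss, rhs_s, rtol=tol, atol=0.0, maxiter=40000)
    if info != 0:
        raise NonConvergenceError(
            f"pressure CG failed (info={info}); scaled relative residual "
            f"{np.linalg.norm(matvec_scaled(y) - rhs_s) / max(np.linalg.norm(rhs_s), 1e-300):.2e}"
        )
    p = sc * y

    # per-group pressure datum, chosen exactly equal to an outlet pressure
    # of the group where one exists: relative to it, the large parts of
    # b_u - B p cancel exactly and the recovered lumen velocities are
    # accurate at the scale of the actual flow, not of the ambient pressure
    p0 = np.zeros(S.n_p)
    if S.n_u:
        pidx_flat_loc = S.pidx.ravel()
        for d in range(3):
            pos = np.argwhere(S.ftype[d] == _F_OUTLET)
            for row in pos:
                lo, hi = _face_cells(S.cls.shape, d, row[None, :])
                cell = lo[0] if lo[0] >= 0 else hi[0]
                pi = pidx_flat_loc[cell]
                if pi >= 0:
                    p0[S.groups == S.groups[pi]] = \
                        S.fpout[d][row[0], row[1], row[2]]
        b_u0 = S.b_u - B @ p0

    def recover_u(pv):
        # the subtraction must happen before the triangular solves: the two
        # terms cancel to many digits inside lumens
        return lu.solve(b_u0 - B @ (pv - p0)) if S.n_u else np.zeros(0)

    # refinement against the physical continuity defect.  The plain CG norm
    # is blind to rows whose gross flux (membrane seepage) is orders below
    # the dominant scales; the slowly-converging error there is a pressure
    # datum drift of whole strongly-coupled regions, so a coarse Galerkin
    # correction over the strong components removes it, alternated with a
    # short scaled-CG pass for the remainder.
    def apply_S(x):
        return C @ x + (B.T @ lu.solve(B @ x) if S.n_u else 0.0)

    groups = S.groups
    m = int(groups.max()) + 1 if S.n_p else 0
    coarse = None
    if 1 <= m <= 256:
        V = sp.coo_matrix((np.ones(S.n_p), (np.arange(S.n_p), groups)),
                          shape=(S.n_p, m)).tocsr()
        SV = np.column_stack([apply_S(np.asarray(V[:, j].todense()).ravel())
                              for j in range(m)])
        E = V.T @ SV
        coarse = (V, np.asarray(E))

    u = recover_u(p)
    for _ in range(4):
        r = (B.T @ u if S.n_u else 0.0) - C @ p - S.b_p
        gross = (abs(B.T) @ np.abs(u) if S.n_u else 0.0) \
            + abs(C) @ np.abs(p) + np.abs(S.b_p)
        gnorm = max(np.linalg.norm(gross), 1e-300)
        if np.linalg.norm(r) <= max(tol, 1e-12) * gnorm:
            break
        if coarse is not None:
            V, E = coarse
            try:
                c = np.linalg.solve(E, V.T @ r)
            except np.linalg.LinAlgError:
                c = np.linalg.lstsq(E, V.T @ r, rcond=None)[0]
            p = p + V @ c
            u = recover_u(p)
            r = (B.T @ u if S.n_u else 0.0) - C @ p - S.b_p
            if np.linalg.norm(r) <= max(tol, 1e-12) * gnorm:
                break
        dz, info2 = spla.cg(Ss, sc * r, rtol=1e-6, atol=0.0, maxiter=40000)
        if info2 != 0:
            break
        p = p + sc * dz
        u = recover_u(p)
    return p, u, "schur-cg"


def _outlet_backflow(S: DiscreteFlowSystem, u: np.ndarray):
    """Outlet voxel-faces currently carrying inflow, as wall-face keys."""
    bad = []
    for d in range(3):
        pos = np.argwhere(S.ftype[d] == _F_OUTLET)
        for row in pos:
            uid = S.fid[d][row[0], row[1], row[2]]
            if uid < 0:
                continue
            outward = -1.0 if row[d] == 0 else 1.0
            if outward * u[uid] < 0:
                bad.append((d, int(row[0]), int(row[1]), int(row[2])))
    return bad


def solve(
    system: DiscreteFlowSystem,
    tol: float = 1e-10,
    max_backflow_iters: int = 20,
    suppress_backflow: bool = True,
) -> FlowSolution:
    """Solve the assembled system with iterative backflow suppression.

    ``suppress_backflow=False`` solves the plain linear system once
    (useful for pressure-driven validation problems and linearity
    checks)."""
    S = system
    suppressed: set = set(S.wall_faces)
    flagged = False
    for it in range(max_backflow_iters + 1):
        p_vec, u_vec, tag = _solve_linear(S, tol)
        if not suppress_backflow:
            break
        bad = _outlet_backflow(S, u_vec)
        if not bad:
            break
        if it == max_backflow_iters:
            flagged = True
            break
        suppressed.update(bad)
        S = assemble(S.model, S.boundaries, S.params,
                     interstitial_bc={f: v for f, v in S.interstitial_bc.items()},
                     inlet_velocities=S.inlet_velocities,
                     outlet_pressures=S.outlet_pressures,
                     wall_faces=suppressed)
    # copy assembled state back so callers see the final system
    system.__dict__.update(S.__dict__)

    residuals = _residuals(S, p_vec, u_vec)
    sol = _build_solution(S, p_vec, u_vec)
    sol.residuals = residuals
    sol.suppressed_outlet_faces = len(suppressed)
    sol.backflow_flagged = flagged
    sol.solver = tag
    sol.fluxes = domain_fluxes(sol, system)
    return sol


def _residuals(S, p, u):
    # residuals are scaled by the gross (unsigned) term magnitudes so a
    # well-balanced solution reports a small number even when the signed
    # right-hand side vanishes
    out = {}
    absu, absp = np.abs(u), np.abs(p)
    if S.n_u:
        r_u = S.A_visc @ u + S.B @ p - S.b_u
        gross_u = abs(S.A_visc) @ absu + abs(S.B) @ absp + np.abs(S.b_u)
        out["momentum"] = float(np.linalg.norm(r_u)
                                / max(np.linalg.norm(gross_u), 1e-300))
        r_p = S.B.T @ u - S.C @ p - S.b_p
        gross_p = abs(S.B.T) @ absu + abs(S.C) @ absp + np.abs(S.b_p)
    else:
        r_p = -S.C @ p - S.b_p
        gross_p = abs(S.C) @ absp + np.abs(S.b_p)
    out["continuity"] = float(np.linalg.norm(r_p)
                              / max(np.linalg.norm(gross_p), 1e-300))
    return out


def _face_velocity_fields(S: DiscreteFlowSystem, p_vec, u_vec):
    """Normal velocity on every face of each axis grid (signed along +axis)."""
    shape = S.cls.shape
    h = S.h
    kmu = S.params.k / S.params.mu
    pidx_flat = S.pidx.ravel()
    pfull = np.full(int(np.prod(shape)), np.nan)
    pfull[pidx_flat >= 0] = p_vec[pidx_flat[pidx_flat >= 0]]
    fields = []
    for d in range(3):
        ftd = S.ftype[d]
        v = np.zeros(ftd.shape)
        ids = S.fid[d]
        has_id = ids >= 0
        v[has_id] = u_vec[ids[has_id]]
        v[ftd == _F_INLET] = S.fval[d][ftd == _F_INLET]
        for code, which in ((_F_MEMBRANE, "memb"), (_F_DARCY, "darcy"),
                            (_F_EXT, "ext")):
            pos = np.argwhere(ftd == code)
            if len(pos) == 0:
                continue
            lo, hi = _face_cells(shape, d, pos)
            if which == "memb":
                Kv = S.fK[d][pos[:, 0], pos[:, 1], pos[:, 2]]
                p_lo = pfull[np.clip(lo, 0, None)]
                p_hi = pfull[np.clip(hi, 0, None)]
                lo_cls = S.cls.ravel()[np.clip(lo, 0, None)]
                lum_is_lo = (lo_cls == _CLS_BLOOD) | (lo_cls == _CLS_LYMPH)
                p_lum = np.where(lum_is_lo, p_lo, p_hi)
                p_int = np.where(lum_is_lo, p_hi, p_lo)
                sign = np.where(lum_is_lo, 1.0, -1.0)
                vv = sign * Kv * (p_lum - p_int)
            elif which == "darcy":
                vv = -kmu * (pfull[hi] - pfull[lo]) / h
            else:
                val = S.fext[d][pos[:, 0], pos[:, 1], pos[:, 2]]
                cell = np.where(lo >= 0, lo, hi)
                pc = pfull[cell]
                side = np.where(lo >= 0, 1.0, -1.0)  # hi-side boundary => +1
                vv = np.where(np.isnan(val), 0.0,
                              side * kmu * (pc - val) / (h / 2.0))
            vv = np.where(np.isnan(vv), 0.0, vv)
            v[pos[:, 0], pos[:, 1], pos[:, 2]] = vv
        fields.append(v)
    return fields, pfull.reshape(shape)


def _build_solution(S, p_vec, u_vec) -> FlowSolution:
    fields, p_grid = _face_velocity_fields(S, p_vec, u_vec)
    shape = S.cls.shape
    u_cell = np.zeros((3,) + shape)
    for d in range(3):
        v = fields[d]
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[d] = slice(0, shape[d])
        sl_hi[d] = slice(1, shape[d] + 1)
        u_cell[d] = 0.5 * (v[tuple(sl_lo)] + v[tuple(sl_hi)])
    u_cell[:, ~S.active] = np.nan
    return FlowSolution(p=p_grid, u_cell=u_cell, face_velocity=fields,
                        residuals={}, suppressed_outlet_faces=0,
                        backflow_flagged=False)


# --------------------------------------------------------------------------
# flux accounting


def domain_fluxes(solution: FlowSolution, system: DiscreteFlowSystem) -> FluxReport:
    """Membrane, inlet, outlet and external-face volumetric fluxes (m³/s)."""
    S = system
    shape = S.cls.shape
    A_area = S.h * S.h
    cls_flat = S.cls.ravel()
    rep = FluxReport()
    # signed tallies per domain: positive = into the domain
    tally = {"blood": 0.0, "lymph": 0.0, "interstitium": 0.0}
    gross = {"blood": 0.0, "lymph": 0.0, "interstitium": 0.0}
    rep.inlet_flux = {"blood": 0.0, "lymph": 0.0}
    rep.outlet_flux = {"blood": 0.0, "lymph": 0.0}
    names = {_CLS_BLOOD: "blood", _CLS_LYMPH: "lymph", _CLS_INT: "interstitium"}
    for d in range(3):
        ftd = S.ftype[d]
        v = solution.face_velocity[d]
        # membrane faces
        pos = np.argwhere(ftd == _F_MEMBRANE)
        if len(pos):
            lo, hi = _face_cells(shape, d, pos)
            vv = v[pos[:, 0], pos[:, 1], pos[:, 2]] * A_area
            lo_cls = cls_flat[lo]
            lum_is_lo = (lo_cls == _CLS_BLOOD) | (lo_cls == _CLS_LYMPH)
            lum_cls = np.where(lum_is_lo, cls_flat[lo], cls_flat[hi])
            # velocity is signed along +axis; outflow from the lumen is
            # +v when the lumen is on the lo side
            out_of_lumen = np.where(lum_is_lo, vv, -vv)
            for lab in (_CLS_BLOOD, _CLS_LYMPH):
                selm = lum_cls == lab
                q_out = float(out_of_lumen[selm].sum())
                tally[names[lab]] -= q_out
                tally["interstitium"] += q_out
                gross[names[lab]] += float(np.abs(out_of_lumen[selm]).sum())
                gross["interstitium"] += float(np.abs(out_of_lumen[selm]).sum())
                if lab == _CLS_LYMPH:
                    rep.Q_L_in += -q_out
                else:
                    rep.Q_B_out += q_out
        # inlet / outlet faces
        for code in (_F_INLET, _F_OUTLET):
            pos = np.argwhere(ftd == code)
            if len(pos) == 0:
                continue
            lo, hi = _face_cells(shape, d, pos)
            cell = np.where(lo >= 0, lo, hi)
            inward = np.where(lo >= 0, -1.0, 1.0)  # +axis points inward on lo faces
            vv = v[pos[:, 0], pos[:, 1], pos[:, 2]] * A_area
            q_in = inward * vv
            for lab in (_CLS_BLOOD, _CLS_LYMPH):
                selc = cls_flat[cell] == lab
                q = float(q_in[selc].sum())
                tally[names[lab]] += q
                gross[names[lab]] += float(np.abs(q_in[selc]).sum())
                if code == _F_INLET:
                    rep.inlet_flux[names[lab]] += q
                else:
                    rep.outlet_flux[names[lab]] += -q
        # external interstitial faces
        pos = np.argwhere((ftd == _F_EXT) & ~np.isnan(S.fext[d]))
        if len(pos):
            lo, hi = _face_cells(shape, d, pos)
            inward = np.where(lo >= 0, -1.0, 1.0)
            vv = v[pos[:, 0], pos[:, 1], pos[:, 2]] * A_area
            q = inward * vv
            rep.interstitial_exchange_in += float(q.sum())
            tally["interstitium"] += float(q.sum())
            gross["interstitium"] += float(np.abs(q).sum())
    for dom in tally:
        rep.balance_defect[dom] = (abs(tally[dom]) / gross[dom]
                                   if gross[dom] > 0 else 0.0)
    return rep


# --------------------------------------------------------------------------
# export


def export_fields(solution: FlowSolution, model: ModelVolume, path) -> None:
    """Write pressure, velocity and domain labels as legacy-ASCII VTK
    structured points (readable by ParaView and by :func:`read_vtk_fields`)."""
    if solution.p is None or not np.isfinite(solution.p).any():
        raise ValueError("refusing to export an empty solution")
    nz, ny, nx = solution.p.shape
    h = model.voxel_pitch
    cls = _class_grid(model)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("pulmolymph steady flow fields\n")
        f.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        f.write(f"ORIGIN 0 0 0\nSPACING {h} {h} {h}\n")
        f.write(f"POINT_DATA {nx * ny * nz}\n")
        f.write("SCALARS pressure double 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, np.where(np.isfinite(solution.p), solution.p,
                               0.0).ravel(), fmt="%.10e")
        f.write("SCALARS domain int 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, cls.ravel(), fmt="%d")
        f.write("VECTORS velocity double\n")
        vec = np.stack([solution.u_cell[2].ravel(),
                        solution.u_cell[1].ravel(),
                        solution.u_cell[0].ravel()], axis=1)
        np.savetxt(f, np.where(np.isfinite(vec), vec, 0.0), fmt="%.10e")


def read_vtk_fields(path):
    """Read back fields written by :func:`export_fields`."""
    with open(path) as f:
        lines = f.read().splitlines()
    dims = None
    i = 0
    fields = {}
    while i < len(lines):
        tok = lines[i].split()
        if tok and tok[0] == "DIMENSIONS":
            dims = (int(tok[3]), int(tok[2]), int(tok[1]))  # (nz, ny, nx)
        elif tok and tok[0] == "SCALARS":
            name, dtype = tok[1], tok[2]
            n = int(np.prod(dims))
            vals = np.array(" ".join(lines[i + 2:i + 2 + n]).split(),
                            dtype=float if dtype == "double" else int)
            fields[name] = vals.reshape(dims)
            i += 1 + n
        elif tok and tok[0] == "VECTORS":
            n = int(np.prod(dims))
            vals = np.array(" ".join(lines[i + 1:i + 1 + n]).split(),
                            dtype=float).reshape(n, 3)
            fields[tok[1]] = np.stack([
                vals[:, 2].reshape(dims), vals[:, 1].reshape(dims),
                vals[:, 0].reshape(dims)])
            i += n
        i += 1
    return fields
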