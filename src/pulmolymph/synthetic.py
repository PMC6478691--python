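"""Synthetic labelled lung-tissue phantoms and analytic validation geometries.

The phantom generator emulates the structures seen in segmented peripheral
human lung: a pleural slab on one volume face, a sparse bifurcating
blood-vessel tree, and a lymphatic network whose volume fraction decays
with distance from the pleura, including partially collapsed (sheet-like)
lymphatics, perivascular lymphatics and optionally a lymphatic ring fully
encircling a blood vessel.  Vessel lumens open onto specified cube faces
with exact, validated counts so that flow boundary conditions can be
applied downstream.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from pulmolymph.core import (
    FACE_NAMES,
    LABEL_AIR,
    LABEL_BLOOD,
    LABEL_INTERSTITIUM,
    LABEL_LYMPH,
    LABEL_PLEURA,
    LabelVolume,
    face_axis_side,
    face_slicer,
    um_to_vox,
)


class SyntheticInfeasibleError(ValueError):
    """Raised when a requested phantom cannot be realized; names the constraint."""


# --------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class BloodTreeSpec:
    depth: int = 2                 # extra interior branching levels beyond trunks
    root_radius_um: float = 30.0   # trunk radius (vessels >= ~22-30 um diameter)
    taper: float = 0.8             # radius multiplier per branching level


@dataclass(frozen=True)
class LymphNetworkSpec:
    radius_um_range: tuple[float, float] = (10.0, 25.0)
    collapse_fraction: float = 0.3   # fraction of segments drawn as 1-voxel sheets
    perivascular_fraction: float = 0.2
    encircling_ring: bool = False


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one phantom volume.

    ``openings`` maps a face name to the number of lumen openings per
    vessel class, e.g. ``{"+z": {"blood": 2, "lymph": 1}}``.  The first
    lymphatic opening (in face order) anchors the lymphatic spine.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_pitch: float = 13.2      # um; control-tissue scan resolution
    target_lymph_vf_at_pleura: float = 0.04
    lymph_vf_gradient: float = -1e-5   # fraction per um; <= 0 for lung-like tissue
    blood_tree: BloodTreeSpec = field(default_factory=BloodTreeSpec)
    lymph_network: LymphNetworkSpec = field(default_factory=LymphNetworkSpec)
    openings: tuple[tuple[str, tuple[int, int]], ...] = (
        ("+z", (2, 1)),
        ("-y", (1, 0)),
        ("+y", (1, 0)),
        ("-x", (1, 0)),
        ("+x", (0, 1)),
    )  # face -> (n_blood, n_lymph)
    pleura_thickness_vox: int = 2
    air_fraction: float = 0.15
    n_depth_bins: int = 4
    seed: int = 0

    def openings_dict(self) -> dict[str, dict[str, int]]:
        return {
            face: {"blood": int(nb), "lymph": int(nl)}
            for face, (nb, nl) in self.openings
        }

    def validate(self) -> None:
        if min(self.shape) < 32:
            raise SyntheticInfeasibleError("shape must be at least 32 voxels per axis")
        if self.voxel_pitch <= 0:
            raise SyntheticInfeasibleError("voxel_pitch must be positive")
        for name, val in (
            ("target_lymph_vf_at_pleura", self.target_lymph_vf_at_pleura),
            ("air_fraction", self.air_fraction),
            ("collapse_fraction", self.lymph_network.collapse_fraction),
            ("perivascular_fraction", self.lymph_network.perivascular_fraction),
        ):
            if not (0.0 <= val <= 1.0):
                raise SyntheticInfeasibleError(f"{name} must lie in [0, 1]")
        if self.lymph_vf_gradient > 0:
            raise SyntheticInfeasibleError(
                "lymph_vf_gradient must be <= 0 for lung-like tissue"
            )
        depth_um = self.shape[0] * self.voxel_pitch
        if self.target_lymph_vf_at_pleura + self.lymph_vf_gradient * depth_um < 0:
            raise SyntheticInfeasibleError(
                "lymph volume fraction becomes negative within the volume depth; "
                "reduce |lymph_vf_gradient| or increase target_lymph_vf_at_pleura"
            )
        r_lo, r_hi = self.lymph_network.radius_um_range
        if r_lo > r_hi or um_to_vox(r_hi, self.voxel_pitch) < 1:
            raise SyntheticInfeasibleError("lymphatic radius range unresolvable")
        for face, (nb, nl) in self.openings:
            face_axis_side(face)
            if nb < 0 or nl < 0:
                raise SyntheticInfeasibleError("opening counts must be >= 0")
            if face == "-z":
                raise SyntheticInfeasibleError(
                    "openings on the pleural (-z) face are not supported"
                )
        if self.total_openings("lymph") < 1:
            raise SyntheticInfeasibleError(
                "at least one lymphatic opening is required to anchor the network"
            )
        if self.blood_tree.depth < 0 or self.blood_tree.taper <= 0:
            raise SyntheticInfeasibleError("blood tree depth/taper invalid")

    def total_openings(self, cls: str) -> int:
        idx = {"blood": 0, "lymph": 1}[cls]
        return sum(counts[idx] for _, counts in self.openings)


def intralobular_spec(**overrides) -> SyntheticSpec:
    """Phantom emulating an intralobular VOI: 4 blood + 1 lymph inlet openings
    on the three distal faces, one outlet opening per class elsewhere."""
    base = dict(
        openings=(
            ("+z", (2, 1)),
            ("-y", (1, 0)),
            ("+y", (1, 0)),
            ("-x", (1, 0)),
            ("+x", (0, 1)),
        ),
    )
    base.update(overrides)
    return SyntheticSpec(**base)


def subpleural_spec(**overrides) -> SyntheticSpec:
    """Phantom emulating a subpleural VOI: 3 blood + 6 lymph inlet openings
    on the three distal faces, one outlet opening per class elsewhere."""
    base = dict(
        openings=(
            ("+z", (1, 2)),
            ("-y", (1, 2)),
            ("+y", (1, 2)),
            ("-x", (1, 0)),
            ("+x", (0, 1)),
        ),
        target_lymph_vf_at_pleura=0.05,
    )
    base.update(overrides)
    return SyntheticSpec(**base)


@dataclass
class GroundTruth:
    """Generator-known truth for parameter-recovery and fidelity tests."""

    depth_bin_edges_um: np.ndarray            # (n_bins + 1,) from the pleural face
    target_vf_per_bin: np.ndarray             # gradient model evaluated per bin
    realized_vf_per_bin: np.ndarray           # lymph / tissue voxels per bin
    opening_counts: dict[str, dict[str, int]]  # face -> class -> count
    lymph_centrelines: list[np.ndarray]       # (n, 3) voxel coords (z, y, x)
    blood_centrelines: list[np.ndarray]
    realized_lymph_vf: float = 0.0


# --------------------------------------------------------------------------
# rasterization helpers (voxel coordinates are (z, y, x))


def _capsule_voxels(shape, p0, p1, radius, clip_lo, clip_hi):
    """Voxel indices within ``radius`` of segment p0-p1, inside the clip box."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    lo = np.maximum(np.floor(np.minimum(p0, p1) - radius - 1).astype(int), clip_lo)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + radius + 1).astype(int) + 1,
                    clip_hi)
    if np.any(lo >= hi):
        return tuple(np.empty(0, dtype=int) for _ in range(3))
    zz, yy, xx = np.meshgrid(*(np.arange(lo[i], hi[i]) for i in range(3)),
                             indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1).astype(float)
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0.0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / denom, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    sel = dist <= radius
    return zz[sel], yy[sel], xx[sel]


def _polyline_voxels(shape, pts, radius, clip_lo, clip_hi):
    out = [np.empty(0, dtype=int)] * 3
    acc = [[], [], []]
    for a, b in zip(pts[:-1], pts[1:]):
        vox = _capsule_voxels(shape, a, b, radius, clip_lo, clip_hi)
        for i in range(3):
            acc[i].append(vox[i])
    return tuple(np.concatenate(acc[i]) if acc[i] else out[i] for i in range(3))


def _ribbon_voxels(shape, origin, u, v, length, width, clip_lo, clip_hi):
    """A 1-voxel-thick sheet spanned by directions u (length) and v (width)."""
    u = np.asarray(u, dtype=float)
    u /= np.linalg.norm(u)
    v = np.asarray(v, dtype=float)
    v -= (v @ u) * u
    nv = np.linalg.norm(v)
    if nv == 0:
        return tuple(np.empty(0, dtype=int) for _ in range(3))
    v /= nv
    ss = np.arange(0.0, length, 0.5)
    tt = np.arange(-width / 2.0, width / 2.0 + 1e-9, 0.5)
    S, T = np.meshgrid(ss, tt, indexing="ij")
    pts = (np.asarray(origin, dtype=float)[None, None, :]
           + S[..., None] * u + T[..., None] * v)
    vox = np.round(pts).astype(int).reshape(-1, 3)
    ok = np.all((vox >= clip_lo) & (vox < clip_hi), axis=1)
    vox = vox[ok]
    if vox.size == 0:
        return tuple(np.empty(0, dtype=int) for _ in range(3))
    return vox[:, 0], vox[:, 1], vox[:, 2]


def _jittered_path(rng, p0, p1, amplitude, n_steps=6):
    """Polyline from p0 to p1 with perpendicular random jitter."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    ts = np.linspace(0.0, 1.0, n_steps + 1)
    pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    if amplitude > 0 and n_steps > 1:
        jit = rng.normal(0.0, amplitude, size=(n_steps + 1, 3))
        jit *= (np.sin(np.pi * ts) ** 2)[:, None]   # pinned at both ends
        pts = pts + jit
    return pts


def count_face_openings(volume: LabelVolume) -> dict[str, dict[str, int]]:
    """Connected lumen patches (8-connectivity in-plane) on each cube face."""
    out: dict[str, dict[str, int]] = {}
    s8 = np.ones((3, 3), dtype=int)
    for face in FACE_NAMES:
        plane = volume.labels[face_slicer(volume.shape, face)]
        counts = {}
        for cls, lab in (("blood", LABEL_BLOOD), ("lymph", LABEL_LYMPH)):
            counts[cls] = int(ndimage.label(plane == lab, structure=s8)[1])
        out[face] = counts
    return out


def has_encircling_ring(volume: LabelVolume) -> bool:
    """True if some z-slice has a lymphatic loop whose 2D interior holds blood."""
    lab = volume.labels
    for z in range(lab.shape[0]):
        lymph = lab[z] == LABEL_LYMPH
        if lymph.sum() < 8:
            continue
        # flood the complement from the slice border; unreached non-lymph
        # pixels are ring interiors
        free = ~lymph
        seed = np.zeros_like(free)
        seed[0, :] = seed[-1, :] = seed[:, 0] = seed[:, -1] = True
        seed &= free
        reach = ndimage.binary_propagation(seed, mask=free)
        interior = free & ~reach
        if np.any(interior & (lab[z] == LABEL_BLOOD)):
            return True
    return False


# --------------------------------------------------------------------------
# the generator


class _Painter:
    """Accumulates class masks with exact per-depth-bin voxel accounting."""

    def __init__(self, spec: SyntheticSpec):
        self.spec = spec
        self.shape = np.array(spec.shape, dtype=int)
        self.blood = np.zeros(spec.shape, dtype=bool)
        self.lymph = np.zeros(spec.shape, dtype=bool)
        self.air = np.zeros(spec.shape, dtype=bool)
        m = 2  # face margin for interior geometry (keeps faces opening-free)
        self.clip_lo = np.array([spec.pleura_thickness_vox + 1, m, m])
        self.clip_hi = self.shape - m
        self.clip_hi[0] = self.shape[0] - m

    def commit(self, mask: np.ndarray, vox) -> int:
        zz, yy, xx = vox
        if len(zz) == 0:
            return 0
        new = ~mask[zz, yy, xx]
        mask[zz, yy, xx] = True
        return int(new.sum())


def _place_face_points(rng, spec, face, n, radius_vox):
    """Well-separated opening centres on a face; returns (z,y,x) float coords."""
    axis, side = face_axis_side(face)
    shape = spec.shape
    edge = int(max(4, 2 * radius_vox + 2))
    other = [a for a in range(3) if a != axis]
    lo = [edge] * 2
    hi = [shape[a] - edge for a in other]
    if any(h <= l for l, h in zip(lo, hi)):
        raise SyntheticInfeasibleError(
            f"face {face} too small for openings of radius {radius_vox}"
        )
    pts: list[np.ndarray] = []
    min_sep = 4.0 * radius_vox + 6.0
    for _ in range(2000):
        if len(pts) == n:
            break
        cand = np.array([rng.uniform(l, h) for l, h in zip(lo, hi)])
        if all(np.linalg.norm(cand - p) >= min_sep for p in pts):
            pts.append(cand)
    if len(pts) < n:
        raise SyntheticInfeasibleError(
            f"cannot place {n} openings of radius {radius_vox} on face {face} "
            f"with separation {min_sep:.0f} voxels"
        )
    out = []
    for p in pts:
        coord = np.empty(3)
        coord[axis] = 0.0 if side == 0 else shape[axis] - 1.0
        coord[other[0]], coord[other[1]] = p
        out.append(coord)
    return out


def _stub_clip(spec, face, centre, radius_vox, reach):
    """Clip box letting an opening stub touch its own face only."""
    axis, side = face_axis_side(face)
    lo = np.floor(centre - radius_vox - 1).astype(int)
    hi = np.ceil(centre + radius_vox + 2).astype(int)
    if side == 0:
        lo[axis] = 0
        hi[axis] = reach
    else:
        lo[axis] = spec.shape[axis] - reach
        hi[axis] = spec.shape[axis]
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(spec.shape))
    return lo, hi


def generate_voi(spec: SyntheticSpec) -> tuple[LabelVolume, GroundTruth]:
    """Generate one labelled phantom volume plus its ground truth.

    The pleural slab sits on the ``-z`` face.  Blood openings are joined
    through a central hub into one tree; the lymphatic network grows from
    a depth-spanning spine anchored at the first lymphatic opening, and
    side segments are added per depth bin until the realized volume
    fraction matches the gradient model within its budget tolerance.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    P = _Painter(spec)
    nz, ny, nx = spec.shape
    pitch = spec.voxel_pitch
    shape_arr = np.array(spec.shape)

    # --- air blobs (placed first so tissue accounting is stable) ----------
    if spec.air_fraction > 0:
        target_air = spec.air_fraction * np.prod(shape_arr)
        guard = 0
        while P.air.sum() < target_air and guard < 5000:
            guard += 1
            c = np.array([rng.uniform(P.clip_lo[i] + 2, P.clip_hi[i] - 2)
                          for i in range(3)])
            r = rng.uniform(2.0, 4.5)
            P.commit(P.air, _capsule_voxels(spec.shape, c, c, r,
                                            P.clip_lo, P.clip_hi))

    opening_info: list[tuple[str, str, np.ndarray, float]] = []
    for face, (nb, nl) in spec.openings:
        r_b = max(1.0, spec.blood_tree.root_radius_um / pitch)
        r_l = max(1.0, spec.lymph_network.radius_um_range[0] / pitch)
        pts = _place_face_points(rng, spec, face, nb + nl, max(r_b, r_l))
        for i, p in enumerate(pts):
            cls = "blood" if i < nb else "lymph"
            opening_info.append((face, cls, p, r_b if cls == "blood" else r_l))

    # --- blood tree: each opening runs to a central hub -------------------
    hub = np.array([nz * 0.55, ny * 0.5, nx * 0.5])
    blood_lines: list[np.ndarray] = []
    for face, cls, p, r in opening_info:
        if cls != "blood":
            continue
        stub_lo, stub_hi = _stub_clip(spec, face, p, r, reach=4)
        axis, side = face_axis_side(face)
        inward = np.zeros(3)
        inward[axis] = 1.0 if side == 0 else -1.0
        stub_end = p + inward * 3.0
        P.commit(P.blood, _capsule_voxels(spec.shape, p, stub_end, r,
                                          stub_lo, stub_hi))
        path = _jittered_path(rng, stub_end, hub, amplitude=2.5)
        P.commit(P.blood, _polyline_voxels(spec.shape, path, r,
                                           P.clip_lo, P.clip_hi))
        blood_lines.append(np.vstack([p[None, :], path]))

    # extra interior branches for tree depth
    if spec.total_openings("blood") > 0:
        r = max(1.0, spec.blood_tree.root_radius_um / pitch)
        tips = [hub]
        for level in range(spec.blood_tree.depth):
            r *= spec.blood_tree.taper
            new_tips = []
            for tip in tips:
                for _ in range(2):
                    d = rng.normal(size=3)
                    d /= np.linalg.norm(d)
                    end = np.clip(tip + d * rng.uniform(8, 14),
                                  P.clip_lo + 1, P.clip_hi - 2)
                    path = _jittered_path(rng, tip, end, amplitude=1.5,
                                          n_steps=3)
                    P.commit(P.blood, _polyline_voxels(
                        spec.shape, path, max(1.0, r), P.clip_lo, P.clip_hi))
                    blood_lines.append(path)
                    new_tips.append(end)
            tips = new_tips

    # --- lymphatic spine: anchor opening -> near-pleural point ------------
    r_lo_um, r_hi_um = spec.lymph_network.radius_um_range
    # the spine and opening stubs are mandatory connective structure; they
    # use the thinnest lymphatic calibre so that low volume-fraction
    # phantoms remain feasible
    spine_r = max(1.0, r_lo_um / pitch)
    lymph_lines: list[np.ndarray] = []
    lymph_openings = [oi for oi in opening_info if oi[1] == "lymph"]
    face, _, anchor, r_anchor = lymph_openings[0]
    stub_lo, stub_hi = _stub_clip(spec, face, anchor, r_anchor, reach=4)
    axis, side = face_axis_side(face)
    inward = np.zeros(3)
    inward[axis] = 1.0 if side == 0 else -1.0
    stub_end = anchor + inward * 3.0
    P.commit(P.lymph, _capsule_voxels(spec.shape, anchor, stub_end, r_anchor,
                                      stub_lo, stub_hi))
    near_pleura = np.array([float(P.clip_lo[0] + 1),
                            rng.uniform(ny * 0.3, ny * 0.7),
                            rng.uniform(nx * 0.3, nx * 0.7)])
    spine = _jittered_path(rng, stub_end, near_pleura, amplitude=3.0,
                           n_steps=10)
    P.commit(P.lymph, _polyline_voxels(spec.shape, spine, spine_r,
                                       P.clip_lo, P.clip_hi))
    lymph_lines.append(np.vstack([anchor[None, :], spine]))

    # remaining lymph openings connect to the nearest spine point
    for face, _, p, r in lymph_openings[1:]:
        stub_lo, stub_hi = _stub_clip(spec, face, p, r, reach=4)
        axis, side = face_axis_side(face)
        inward = np.zeros(3)
        inward[axis] = 1.0 if side == 0 else -1.0
        stub_end = p + inward * 3.0
        P.commit(P.lymph, _capsule_voxels(spec.shape, p, stub_end, r,
                                          stub_lo, stub_hi))
        j = int(np.argmin(np.linalg.norm(spine - stub_end, axis=1)))
        path = _jittered_path(rng, stub_end, spine[j], amplitude=2.0)
        P.commit(P.lymph, _polyline_voxels(spec.shape, path, spine_r,
                                           P.clip_lo, P.clip_hi))
        lymph_lines.append(np.vstack([p[None, :], path]))

    # --- encircling perivascular ring -------------------------------------
    if spec.lymph_network.encircling_ring:
        ring_done = False
        for path in blood_lines:
            for a, b in zip(path[:-1], path[1:]):
                d = b - a
                n = np.linalg.norm(d)
                if n == 0:
                    continue
                if abs(d[0] / n) < 0.7:
                    continue  # want a segment running mostly along z
                mid = 0.5 * (a + b)
                if np.any(mid < P.clip_lo + 6) or np.any(mid > P.clip_hi - 7):
                    continue
                rb = max(1.0, spec.blood_tree.root_radius_um / pitch)
                inner, outer = rb + 2.0, rb + 4.0
                z0 = int(round(mid[0]))
                for z in range(z0 - 1, z0 + 2):
                    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx),
                                         indexing="ij")
                    rad = np.hypot(yy - mid[1], xx - mid[2])
                    ann = (rad >= inner) & (rad <= outer)
                    ann[:2, :] = ann[-2:, :] = False
                    ann[:, :2] = ann[:, -2:] = False
                    if 0 <= z < nz and z >= P.clip_lo[0]:
                        sel = np.where(ann)
                        P.commit(P.lymph,
                                 (np.full(sel[0].shape, z), sel[0], sel[1]))
                ring_pt = mid + np.array([0.0, inner + 1.0, 0.0])
                j = int(np.argmin(np.linalg.norm(spine - ring_pt, axis=1)))
                P.commit(P.lymph, _polyline_voxels(
                    spec.shape,
                    _jittered_path(rng, ring_pt, spine[j], amplitude=1.0),
                    spine_r, P.clip_lo, P.clip_hi))
                ring_done = True
                break
            if ring_done:
                break
        if not ring_done:
            raise SyntheticInfeasibleError(
                "encircling_ring requested but no z-running blood segment "
                "with interior clearance exists; add a +z or -z blood opening"
            )

    # --- per-depth-bin volume-fraction budget ------------------------------
    edges_vox = np.linspace(0, nz, spec.n_depth_bins + 1)
    edges_um = edges_vox * pitch
    centers_um = 0.5 * (edges_um[:-1] + edges_um[1:])
    target_vf = np.clip(spec.target_lymph_vf_at_pleura
                        + spec.lymph_vf_gradient * centers_um, 0.0, 1.0)
    zidx = np.arange(nz)
    bin_of_z = np.clip(np.digitize(zidx + 0.5, edges_vox) - 1, 0,
                       spec.n_depth_bins - 1)

    def per_bin_counts(mask):
        return np.array([
            mask[bin_of_z == b].sum() for b in range(spec.n_depth_bins)
        ], dtype=float)

    tissue = ~P.air  # blood/lymph/pleura/interstitium all count as tissue
    tissue_per_bin = per_bin_counts(tissue)
    target_counts = target_vf * tissue_per_bin
    if np.any(target_counts > 0.4 * tissue_per_bin):
        raise SyntheticInfeasibleError(
            "target lymph volume fraction exceeds 40% of bin tissue; "
            "unreachable at the configured radii"
        )

    spine_bins = np.clip(np.digitize(spine[:, 0] + 0.5, edges_vox) - 1,
                         0, spec.n_depth_bins - 1)
    blood_pts = (np.vstack(blood_lines) if blood_lines
                 else np.empty((0, 3)))

    for b in range(spec.n_depth_bins):
        if target_counts[b] <= 0:
            continue
        attempts = 0
        while attempts < 400:
            have = per_bin_counts(P.lymph)[b]
            if have >= 0.92 * target_counts[b]:
                break
            attempts += 1
            cand = np.where(spine_bins == b)[0]
            if cand.size:
                start = spine[rng.choice(cand)].copy()
            else:  # nearest spine point to the bin's depth band
                zc = 0.5 * (edges_vox[b] + edges_vox[b + 1])
                start = spine[int(np.argmin(np.abs(spine[:, 0] - zc)))].copy()
            seg_r = max(1.0, rng.uniform(r_lo_um, r_hi_um) / pitch)
            length = rng.uniform(8.0, 16.0)
            perivascular = (blood_pts.shape[0] > 0
                            and rng.random() < spec.lymph_network.perivascular_fraction)
            if perivascular:
                k = int(np.argmin(np.abs(blood_pts[:, 0]
                                         - 0.5 * (edges_vox[b] + edges_vox[b + 1]))))
                tgt = blood_pts[k] + rng.normal(0, 1.5, size=3)
                d = tgt - start
            else:
                d = rng.normal(size=3)
                d[0] *= 0.4   # bias lateral so segments stay in their bin
            nrm = np.linalg.norm(d)
            if nrm == 0:
                continue
            d /= nrm
            end = np.clip(start + d * length, P.clip_lo + 1, P.clip_hi - 2)
            # keep the segment inside its depth bin
            end[0] = np.clip(end[0], edges_vox[b] + 1, edges_vox[b + 1] - 1)
            if rng.random() < spec.lymph_network.collapse_fraction:
                v = rng.normal(size=3)
                vox = _ribbon_voxels(spec.shape, start, end - start, v,
                                     np.linalg.norm(end - start),
                                     width=2 * seg_r + 1,
                                     clip_lo=P.clip_lo, clip_hi=P.clip_hi)
            else:
                vox = _capsule_voxels(spec.shape, start, end, seg_r,
                                      P.clip_lo, P.clip_hi)
            # budget guard: skip segments that would overshoot the bin
            zz = vox[0]
            add = (~P.lymph[vox]).sum() if len(zz) else 0
            add_in_bin = int(np.sum((bin_of_z[zz] == b) & ~P.lymph[vox])) \
                if len(zz) else 0
            if have + add_in_bin > 1.12 * target_counts[b] and add_in_bin > 0:
                continue
            P.commit(P.lymph, vox)
            if add:
                lymph_lines.append(np.vstack([start[None, :], end[None, :]]))
        have = per_bin_counts(P.lymph)[b]
        if not (0.8 * target_counts[b] <= have <= 1.2 * target_counts[b]):
            raise SyntheticInfeasibleError(
                f"depth bin {b}: realized lymph voxel count {have:.0f} "
                f"outside +/-20% of target {target_counts[b]:.0f}"
            )

    # --- compose labels with precedence lymph > blood > air ---------------
    labels = np.full(spec.shape, LABEL_INTERSTITIUM, dtype=np.uint8)
    labels[P.air] = LABEL_AIR
    labels[P.blood] = LABEL_BLOOD
    labels[P.lymph] = LABEL_LYMPH
    labels[: spec.pleura_thickness_vox, :, :] = LABEL_PLEURA

    volume = LabelVolume(labels, pitch, pleural_direction="-z")

    realized = count_face_openings(volume)
    requested = spec.openings_dict()
    for f, want in requested.items():
        got = realized.get(f, {"blood": 0, "lymph": 0})
        if got != want:
            raise SyntheticInfeasibleError(
                f"face {f}: realized openings {got} != requested {want}"
            )
    for f, got in realized.items():
        if f not in requested and (got["blood"] or got["lymph"]):
            raise SyntheticInfeasibleError(
                f"unexpected lumen openings on face {f}: {got}"
            )

    lymph_bin = per_bin_counts(volume.labels == LABEL_LYMPH)
    tissue_bin = per_bin_counts(volume.tissue_mask())
    truth = GroundTruth(
        depth_bin_edges_um=edges_um,
        target_vf_per_bin=target_vf,
        realized_vf_per_bin=lymph_bin / np.maximum(tissue_bin, 1),
        opening_counts=realized,
        lymph_centrelines=lymph_lines,
        blood_centrelines=blood_lines,
        realized_lymph_vf=float((volume.labels == LABEL_LYMPH).sum()
                                / max(volume.tissue_mask().sum(), 1)),
    )
    return volume, truth


# --------------------------------------------------------------------------
# analytic validation geometries


def generate_validation_geometry(kind: str, **params) -> LabelVolume:
    """Analytic geometries used as solver and morphometry oracles.

    Kinds: ``tube`` (straight cylinder through interstitium), ``slab``
    (all interstitium), ``sandwich`` (blood slab | interstitium | lymph
    slab along z), ``y_tube`` (symmetric bifurcation), ``arc_tube``
    (quarter-circle cylinder), ``box`` (air except a tissue block).
    """
    pitch = float(params.pop("voxel_pitch", 13.2))
    if kind == "slab":
        shape = tuple(params.pop("shape", (64, 64, 64)))
        _reject_extra(kind, params)
        return LabelVolume(np.full(shape, LABEL_INTERSTITIUM, dtype=np.uint8),
                           pitch)
    if kind == "box":
        shape = tuple(params.pop("shape", (64, 64, 64)))
        block = params.pop("block", tuple(s // 2 for s in shape))
        _reject_extra(kind, params)
        labels = np.zeros(shape, dtype=np.uint8)
        labels[: block[0], : block[1], : block[2]] = LABEL_INTERSTITIUM
        return LabelVolume(labels, pitch)
    if kind == "tube":
        radius = float(params.pop("radius"))
        if radius < 2:
            raise ValueError("tube radius < 2 voxels is unresolvable")
        axis = int(params.pop("axis", 0))
        length = int(params.pop("length", 64))
        pad = int(params.pop("pad", 4))
        label = int(params.pop("label", LABEL_LYMPH))
        _reject_extra(kind, params)
        side = int(np.ceil(2 * radius)) + 2 * pad + 1
        shape = [side, side, side]
        shape[axis] = length
        labels = np.full(shape, LABEL_INTERSTITIUM, dtype=np.uint8)
        c = (side - 1) / 2.0
        other = [a for a in range(3) if a != axis]
        grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        rad = np.hypot(grids[other[0]] - c, grids[other[1]] - c)
        labels[rad <= radius] = label
        return LabelVolume(labels, pitch)
    if kind == "sandwich":
        t = int(params.pop("thickness"))
        lumen = int(params.pop("lumen_thickness", 8))
        side = int(params.pop("side", 24))
        _reject_extra(kind, params)
        nz = 2 * lumen + t
        labels = np.full((nz, side, side), LABEL_INTERSTITIUM, dtype=np.uint8)
        labels[:lumen] = LABEL_BLOOD
        labels[lumen + t:] = LABEL_LYMPH
        return LabelVolume(labels, pitch)
    if kind == "y_tube":
        radius = float(params.pop("radius", 3.0))
        if radius < 2:
            raise ValueError("tube radius < 2 voxels is unresolvable")
        size = int(params.pop("size", 64))
        label = int(params.pop("label", LABEL_LYMPH))
        _reject_extra(kind, params)
        labels = np.full((size, size, size), LABEL_INTERSTITIUM,
                         dtype=np.uint8)
        # integer-centred axis: thinning collapses even-width tubes whose
        # axis falls between voxel columns
        c = float(size // 2)
        mid = np.array([float(size // 2), c, c])
        stem0 = np.array([0.0, c, c])
        arm = size * 0.42
        tipA = mid + np.array([arm / np.sqrt(2), arm / np.sqrt(2), 0.0])
        tipB = mid + np.array([arm / np.sqrt(2), -arm / np.sqrt(2), 0.0])
        mask = np.zeros_like(labels, dtype=bool)
        lo = np.zeros(3, dtype=int)
        hi = np.array(labels.shape)
        for a, b in ((stem0, mid), (mid, tipA), (mid, tipB)):
            zz, yy, xx = _capsule_voxels(labels.shape, a, b, radius, lo, hi)
            mask[zz, yy, xx] = True
        labels[mask] = label
        return LabelVolume(labels, pitch)
    if kind == "arc_tube":
        arc_radius = float(params.pop("arc_radius", 40.0))
        radius = float(params.pop("radius", 3.0))
        if radius < 2:
            raise ValueError("tube radius < 2 voxels is unresolvable")
        label = int(params.pop("label", LABEL_LYMPH))
        pad = int(params.pop("pad", 6))
        _reject_extra(kind, params)
        size = int(np.ceil(arc_radius + 2 * (radius + pad)))
        shape = (int(2 * (radius + pad) + 1), size, size)
        labels = np.full(shape, LABEL_INTERSTITIUM, dtype=np.uint8)
        zc = (shape[0] - 1) / 2.0
        origin = np.array([zc, float(pad + radius), float(pad + radius)])
        thetas = np.linspace(0.0, np.pi / 2.0, 48)
        pts = np.stack([
            np.full_like(thetas, zc),
            origin[1] + arc_radius * np.sin(thetas),
            origin[2] + arc_radius * np.cos(thetas),
        ], axis=1)
        mask = np.zeros_like(labels, dtype=bool)
        lo = np.zeros(3, dtype=int)
        hi = np.array(shape)
        zz, yy, xx = _polyline_voxels(shape, pts, radius, lo, hi)
        mask[zz, yy, xx] = True
        labels[mask] = label
        return LabelVolume(labels, pitch)
    raise ValueError(f"unknown validation geometry kind {kind!r}")


def _reject_extra(kind, params):
    if params:
        raise TypeError(f"unexpected parameters for {kind!r}: {sorted(params)}")


# --------------------------------------------------------------------------
# cohorts for parameter-recovery statistics


def generate_cohort(
    base_spec: SyntheticSpec,
    n_voi: int,
    gradient: float = -1e-5,
    noise_sd: float = 0.006,
    seed: int = 0,
    distance_range_um: tuple[float, float] = (0.0, 2500.0),
    vf_floor: float = 0.008,
):
    """VOIs at known pleural distances with a linear lymph-VF trend.

    True VF per VOI = intercept + gradient x distance + Gaussian noise,
    truncated to ``[vf_floor, 1]``; the intercept is the base spec's
    pleural VF.  The floor reflects the generator's structural minimum:
    the connective lymphatic spine and opening stubs occupy a small fixed
    volume, below which a phantom cannot be realized.  Returns
    ``(volumes, truth_table)`` where the truth table is a list of
    ``{"voi": i, "distance_um": d, "true_vf": v}`` rows.
    """
    if n_voi < 3:
        raise ValueError("n_voi must be >= 3")
    d0, d1 = distance_range_um
    intercept = base_spec.target_lymph_vf_at_pleura
    if intercept + gradient * d1 < 0 or intercept + gradient * d0 < 0:
        raise SyntheticInfeasibleError(
            "gradient drives the volume fraction negative inside the "
            "sampled distance range"
        )
    root = np.random.default_rng(seed)
    distances = np.linspace(d0, d1, n_voi)
    noise = root.normal(0.0, noise_sd, size=n_voi) if noise_sd > 0 else np.zeros(n_voi)
    volumes: list[LabelVolume] = []
    truth = []
    for i, dist in enumerate(distances):
        true_vf = float(np.clip(intercept + gradient * dist + noise[i],
                                vf_floor, 1.0))
        sub = dataclasses.replace(
            base_spec,
            target_lymph_vf_at_pleura=true_vf,
            lymph_vf_gradient=0.0,
            seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0]
                     % (2**31)),
        )
        vol, _ = generate_voi(sub)
        volumes.append(vol)
        truth.append({"voi": i, "distance_um": float(dist), "true_vf": true_vf})
    return volumes, truth
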