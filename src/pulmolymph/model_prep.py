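"""Turn a labelled VOI into a solver-ready model volume.

The processing chain mirrors the image pipeline used to prepare segmented
tissue for flow simulation: extract a cubic VOI, upsample each class mask
by integer replication, smooth with a 3D median filter, prune lumen
components not connected to a domain face, resolve overlaps with the
precedence lymph > blood > tissue, and optionally rescale the voxel pitch
to compensate fixation shrinkage.
"""

from __future__ import annotations

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
    opposite_face,
)
from pulmolymph.morphometry import VOIRecord

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ModelVolume:
    """Disjoint class masks covering a cubic grid, plus provenance."""

    interstitium: np.ndarray
    blood: np.ndarray
    lymph: np.ndarray
    air: np.ndarray
    voxel_pitch: float      # um, post-scaling
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {m.shape for m in (self.interstitium, self.blood,
                                    self.lymph, self.air)}
        if len(shapes) != 1:
            raise ValueError("class masks must share one shape")
        total = (self.interstitium.astype(int) + self.blood.astype(int)
                 + self.lymph.astype(int) + self.air.astype(int))
        if not np.all(total == 1):
            raise ValueError("class masks must be disjoint and cover the grid")

    @property
    def shape(self):
        return self.interstitium.shape

    def class_mask(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass
class BoundarySpec:
    """Inlet/outlet opening patches per vessel class.

    A patch is an ``(n, 4)`` integer array of ``(z, y, x, face_index)``
    rows: the lumen cell and the cube face its boundary voxel-face lies
    on (face_index indexes ``FACE_NAMES``).  Every boundary lumen
    voxel-face belongs to exactly one patch; inlet patches lie only on
    the distal faces.
    """

    distal_faces: tuple[str, str, str]
    inlets: dict[str, list[np.ndarray]]    # class -> list of patches
    outlets: dict[str, list[np.ndarray]]
    warnings: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, tuple[int, int]]:
        return {cls: (len(self.inlets.get(cls, [])),
                      len(self.outlets.get(cls, [])))
                for cls in ("blood", "lymph")}


def _upsample(mask: np.ndarray, f: int) -> np.ndarray:
    if f == 1:
        return mask.copy()
    return np.repeat(np.repeat(np.repeat(mask, f, axis=0), f, axis=1),
                     f, axis=2)


def _prune_to_faces(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Remove 26-connected components not touching any domain face."""
    if not mask.any():
        return mask, 0
    lab, n = ndimage.label(mask, structure=_STRUCT26)
    if n == 0:
        return mask, 0
    border = np.zeros(mask.shape, dtype=bool)
    for face in FACE_NAMES:
        border[face_slicer(mask.shape, face)] = True
    keep = np.unique(lab[border & mask])
    keep = keep[keep > 0]
    kept = np.isin(lab, keep)
    removed = int(mask.sum() - kept.sum())
    return kept & mask, removed


def prepare_model_volume(
    volume: LabelVolume,
    voi: VOIRecord | None = None,
    upsample: int = 3,
    median_window: int = 3,
    shrinkage_scale: float = 1.0,
) -> ModelVolume:
    """Extract a cubic VOI and process it into disjoint solver masks.

    ``voi=None`` uses the whole volume (which must then be cubic).
    ``median_window=1`` disables smoothing (useful for analytic
    geometries).  Upsampling replicates each voxel ``upsample**3`` times,
    preserving per-class volume fractions exactly; the voxel pitch is
    divided by ``upsample`` and multiplied by ``shrinkage_scale``.
    """
    if upsample < 1 or median_window < 1 or median_window % 2 == 0:
        raise ValueError("upsample must be >= 1 and median_window odd >= 1")
    if voi is None:
        sub = volume.labels
        if len(set(sub.shape)) != 1:
            raise ValueError("whole-volume preparation requires a cubic grid")
    else:
        sly, slx = voi.roi.slicer()
        side = voi.roi.side_vox
        z1 = voi.roi.z0 + side   # cubic VOI: depth equals the ROI side
        if z1 > volume.shape[0]:
            raise ValueError("cubic VOI extends beyond the stack in z")
        sub = volume.labels[voi.roi.z0:z1, sly, slx]
        if len(set(sub.shape)) != 1:
            raise ValueError("requested VOI is not cubic")

    tissue = np.isin(sub, (LABEL_INTERSTITIUM, LABEL_BLOOD, LABEL_LYMPH,
                           LABEL_PLEURA))
    blood = sub == LABEL_BLOOD
    lymph = sub == LABEL_LYMPH

    tissue = _upsample(tissue, upsample)
    blood = _upsample(blood, upsample)
    lymph = _upsample(lymph, upsample)

    if median_window > 1:
        size = (median_window,) * 3
        tissue = ndimage.median_filter(tissue.astype(np.uint8), size=size) > 0
        blood = ndimage.median_filter(blood.astype(np.uint8), size=size) > 0
        lymph = ndimage.median_filter(lymph.astype(np.uint8), size=size) > 0

    blood, removed_b = _prune_to_faces(blood)
    lymph, removed_l = _prune_to_faces(lymph)

    # overlap precedence: lymph over blood over tissue
    blood = blood & ~lymph
    tissue = tissue | blood | lymph
    interstitium = tissue & ~blood & ~lymph
    air = ~tissue

    pitch = volume.voxel_pitch / upsample * shrinkage_scale
    return ModelVolume(
        interstitium=interstitium,
        blood=blood,
        lymph=lymph,
        air=air,
        voxel_pitch=pitch,
        provenance={
            "upsample_factor": upsample,
            "filter_applied": median_window > 1,
            "median_window": median_window,
            "shrinkage_scale": shrinkage_scale,
            "removed_component_voxels": {"blood": removed_b,
                                         "lymph": removed_l},
        },
    )


def model_from_labels(volume: LabelVolume) -> ModelVolume:
    """Build a ModelVolume directly from a labelled volume, with no
    upsampling, filtering or pruning.  Intended for analytic validation
    geometries (which need not be cubic); pleural voxels count as
    interstitium."""
    lab = volume.labels
    blood = lab == LABEL_BLOOD
    lymph = lab == LABEL_LYMPH
    interstitium = (lab == LABEL_INTERSTITIUM) | (lab == LABEL_PLEURA)
    air = lab == LABEL_AIR
    return ModelVolume(interstitium=interstitium, blood=blood, lymph=lymph,
                       air=air, voxel_pitch=volume.voxel_pitch,
                       provenance={"upsample_factor": 1,
                                   "filter_applied": False,
                                   "shrinkage_scale": 1.0,
                                   "removed_component_voxels": {}})


def boundary_patch(model: ModelVolume, cls: str, face: str) -> np.ndarray:
    """All boundary voxel-faces of one class on one cube face, as a patch
    array usable in a BoundarySpec (helper for hand-built boundary specs)."""
    axis, side = face_axis_side(face)
    mask = model.class_mask(cls)
    plane = mask[face_slicer(model.shape, face)]
    uu, vv = np.where(plane)
    other = [a for a in range(3) if a != axis]
    cells = np.empty((len(uu), 4), dtype=int)
    cells[:, axis] = 0 if side == 0 else model.shape[axis] - 1
    cells[:, other[0]] = uu
    cells[:, other[1]] = vv
    cells[:, 3] = FACE_NAMES.index(face)
    return cells


def distal_faces(model_shape, pleural_direction: str,
                 distance_map: np.ndarray | None = None) -> tuple[str, str, str]:
    """The three cube faces used for inlet boundaries.

    These are the face opposite the pleural face plus the two faces
    perpendicular to it with the larger mean pleural distance; ties are
    broken in fixed face order for determinism.  Without a distance map a
    flat pleural plane is assumed (all lateral faces tie).
    """
    opp = opposite_face(pleural_direction)
    axis, _ = face_axis_side(pleural_direction)
    lateral = [f for f in FACE_NAMES
               if f not in (pleural_direction, opp)]
    if distance_map is not None:
        means = {}
        for f in lateral:
            means[f] = float(distance_map[face_slicer(model_shape, f)].mean())
        lateral.sort(key=lambda f: (-means[f], FACE_NAMES.index(f)))
    else:
        lateral.sort(key=FACE_NAMES.index)
    return (opp, lateral[0], lateral[1])


def identify_vessel_openings(
    model: ModelVolume,
    pleural_direction: str,
    distance_map: np.ndarray | None = None,
    require_inlets: bool = True,
) -> BoundarySpec:
    """Partition boundary lumen patches into inlets (distal faces) and outlets.

    Connected lumen patches (8-connectivity within each face plane) on
    the three distal faces become inlets; all remaining boundary lumen
    patches become outlets.  A vessel class present in the model but with
    no inlet patch raises an error (the model would be unforced) unless
    ``require_inlets=False``; a class with inlets but no outlet is only a
    warning, since membrane leakage still admits a steady state.
    """
    dist = distal_faces(model.shape, pleural_direction, distance_map)
    s8 = np.ones((3, 3), dtype=int)
    inlets: dict[str, list[np.ndarray]] = {"blood": [], "lymph": []}
    outlets: dict[str, list[np.ndarray]] = {"blood": [], "lymph": []}
    for cls in ("blood", "lymph"):
        mask = model.class_mask(cls)
        for face in FACE_NAMES:
            plane = mask[face_slicer(model.shape, face)]
            lab, n = ndimage.label(plane, structure=s8)
            if n == 0:
                continue
            axis, side = face_axis_side(face)
            z_of_face = 0 if side == 0 else model.shape[axis] - 1
            for comp in range(1, n + 1):
                uu, vv = np.where(lab == comp)
                cells = np.empty((len(uu), 4), dtype=int)
                other = [a for a in range(3) if a != axis]
                cells[:, axis] = z_of_face
                cells[:, other[0]] = uu
                cells[:, other[1]] = vv
                cells[:, 3] = FACE_NAMES.index(face)
                if face in dist:
                    inlets[cls].append(cells)
                else:
                    outlets[cls].append(cells)
    warnings = []
    for cls in ("blood", "lymph"):
        present = bool(model.class_mask(cls).any())
        if not present:
            continue
        if not inlets[cls] and require_inlets:
            raise ValueError(
                f"vessel class {cls!r} has no inlet patch on the distal "
                f"faces {dist}; the model is unforced"
            )
        if inlets[cls] and not outlets[cls]:
            warnings.append(
                f"vessel class {cls!r} has inlets but no outlet; steady "
                f"state relies on membrane leakage"
            )
    return BoundarySpec(distal_faces=dist, inlets=inlets, outlets=outlets,
                        warnings=warnings)
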