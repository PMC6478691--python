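"""Core containers: labelled voxel volumes and fluid/tissue parameters.

Axis convention is ``(z, y, x)`` with ``z`` the sectioning/depth axis.
All voxel pitches are in micrometres; the flow solver converts to SI at
ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

# Label scheme shared by every stage of the pipeline.
LABEL_AIR = 0          # air / paraffin-filled alveolar space
LABEL_INTERSTITIUM = 1  # alveolar walls, matrix, capillary beds
LABEL_BLOOD = 2        # blood-vessel lumen
LABEL_LYMPH = 3        # lymphatic lumen
LABEL_PLEURA = 4       # pleural-surface voxels

VALID_LABELS = frozenset(
    {LABEL_AIR, LABEL_INTERSTITIUM, LABEL_BLOOD, LABEL_LYMPH, LABEL_PLEURA}
)

#: labels counted as "tissue" for volume-fraction denominators
TISSUE_LABELS = (LABEL_INTERSTITIUM, LABEL_BLOOD, LABEL_LYMPH, LABEL_PLEURA)

#: the six axis-aligned volume faces, named by axis and side.
FACE_NAMES = ("-z", "+z", "-y", "+y", "-x", "+x")


def face_axis_side(face: str) -> tuple[int, int]:
    """Map a face name like ``"-z"`` to ``(axis, side)`` with side 0 or -1."""
    if face not in FACE_NAMES:
        raise ValueError(f"unknown face {face!r}; expected one of {FACE_NAMES}")
    axis = "zyx".index(face[1])
    side = 0 if face[0] == "-" else -1
    return axis, side


def opposite_face(face: str) -> str:
    axis, side = face_axis_side(face)
    return ("+" if face[0] == "-" else "-") + face[1]


@dataclass
class LabelVolume:
    """A 3D integer label grid with physical voxel pitch.

    Parameters
    ----------
    labels
        ``(nz, ny, nx)`` array of small integers drawn from the label
        scheme above.
    voxel_pitch
        Edge length of a voxel in micrometres (isotropic).
    pleural_direction
        The volume face the pleural surface touches (e.g. ``"-z"``);
        ``None`` if the volume carries no pleural reference.
    """

    labels: np.ndarray
    voxel_pitch: float
    pleural_direction: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.voxel_pitch <= 0:
            raise ValueError("voxel_pitch must be positive (μm)")
        present = set(np.unique(self.labels).tolist())
        if not present <= VALID_LABELS:
            raise ValueError(
                f"labels contain values outside the declared set: "
                f"{sorted(present - VALID_LABELS)}"
            )
        if self.pleural_direction is not None:
            face_axis_side(self.pleural_direction)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    def mask(self, *labels: int) -> np.ndarray:
        """Boolean mask of voxels carrying any of the given labels."""
        return np.isin(self.labels, labels)

    def tissue_mask(self) -> np.ndarray:
        return self.mask(*TISSUE_LABELS)

    def validate_pleural_shell(self) -> None:
        """Check pleural voxels form one face-connected shell on the declared face.

        Raises ``ValueError`` when the invariant is violated; a no-op when
        the volume contains no pleural voxels.
        """
        pleura = self.labels == LABEL_PLEURA
        if not pleura.any():
            return
        if self.pleural_direction is None:
            raise ValueError("pleural voxels present but pleural_direction unset")
        n_comp = ndimage.label(pleura, structure=ndimage.generate_binary_structure(3, 1))[1]
        if n_comp != 1:
            raise ValueError(f"pleural shell is not face-connected ({n_comp} components)")
        # a slab covering the pleural face inevitably grazes the lateral
        # face rims, so "touching" is judged by areal coverage per face
        coverage = {
            face: pleura[face_slicer(self.shape, face)].mean()
            for face in FACE_NAMES
        }
        touched = [f for f, c in coverage.items() if c >= 0.25]
        if touched != [self.pleural_direction]:
            raise ValueError(
                f"pleural shell covers faces {touched}, expected only "
                f"{self.pleural_direction} (coverage {coverage})"
            )

    def copy(self) -> "LabelVolume":
        return replace(self, labels=self.labels.copy())


def face_slicer(shape: tuple[int, int, int], face: str) -> tuple:
    """Indexing tuple selecting the 2D boundary plane of ``face``."""
    axis, side = face_axis_side(face)
    idx: list = [slice(None)] * 3
    idx[axis] = side
    return tuple(idx)


@dataclass(frozen=True)
class FluidParameters:
    """Fluid, interstitium and vessel-wall parameters (SI units).

    Defaults are literature values for peripheral human lung at rest:
    interstitial fluid viscosity/density, interstitial Darcy permeability
    and porosity, the (subatmospheric) interstitial pressure, inlet
    velocities and outlet pressures for the lymphatic and blood lumens,
    and the hydraulic conductivity of each vessel wall used by the
    membrane flux condition ``u·n = K (p_lumen − p_interstitium)``.
    """

    mu: float = 1.2e-3          # dynamic viscosity, Pa·s
    rho: float = 1030.0         # mass density, kg·m⁻³
    k: float = 4.4e-18          # interstitial permeability, m²
    phi: float = 0.13           # interstitial porosity (diagnostic only)
    p_int: float = -1064.0      # external interstitial pressure, Pa
    u_L: float = 3e-4           # lymphatic inlet normal velocity, m·s⁻¹
    p_L: float = -1200.0        # lymphatic outlet pressure, Pa
    K_L: float = 1.9e-12        # lymphatic wall conductivity, m·s⁻¹·Pa⁻¹
    u_B: float = 3e-3           # blood inlet normal velocity, m·s⁻¹
    p_B: float = 2000.0         # blood outlet pressure, Pa
    K_B: float = 2.71e-12       # blood wall conductivity, m·s⁻¹·Pa⁻¹

    def __post_init__(self) -> None:
        for name in ("mu", "rho", "k", "K_L", "K_B"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.phi <= 1):
            raise ValueError("phi must lie in (0, 1]")

    def replace(self, **kwargs) -> "FluidParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> Mapping[str, float]:
        return {
            "mu": self.mu, "rho": self.rho, "k": self.k, "phi": self.phi,
            "p_int": self.p_int, "u_L": self.u_L, "p_L": self.p_L,
            "K_L": self.K_L, "u_B": self.u_B, "p_B": self.p_B, "K_B": self.K_B,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "FluidParameters":
        return cls(**{k: float(v) for k, v in d.items()})


def um_to_vox(um: float, pitch_um: float) -> int:
    """Convert a length in μm to a voxel count by round-to-nearest."""
    if pitch_um <= 0:
        raise ValueError("pitch must be positive")
    return max(1, int(round(um / pitch_um)))
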