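import numpy as np
import pytest

from pulmolymph.core import LABEL_BLOOD, LabelVolume
from pulmolymph.model_prep import (
    BoundarySpec,
    boundary_patch,
    model_from_labels,
)
from pulmolymph.synthetic import generate_voi, intralobular_spec


@pytest.fixture(scope="session")
def intralobular_voi():
    """One deterministic intralobular phantom shared across tests."""
    spec = intralobular_spec(shape=(48, 48, 48), seed=7)
    return generate_voi(spec)


def make_tube_model(radius, length, pitch, pad=4, label=LABEL_BLOOD):
    """Straight air-backed cylinder (no-slip walls) for Stokes oracles."""
    side = int(np.ceil(2 * radius)) + 2 * pad + 1
    labels = np.zeros((length, side, side), dtype=np.uint8)
    c = side // 2
    yy, xx = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    labels[:, np.hypot(yy - c, xx - c) <= radius] = label
    return model_from_labels(LabelVolume(labels, pitch))


def pressure_driven_tube_boundaries(model, p_in, p_out, cls="blood"):
    empty = {"blood": [], "lymph": []}
    outlets = {"blood": [], "lymph": []}
    outlets[cls] = [boundary_patch(model, cls, "-z"),
                    boundary_patch(model, cls, "+z")]
    spec = BoundarySpec(distal_faces=("+z", "-y", "+y"),
                        inlets=dict(empty), outlets=outlets)
    overrides = {(cls, 0): p_in, (cls, 1): p_out}
    return spec, overrides
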