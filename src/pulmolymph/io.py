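"""Reading and writing labelled volumes and result tables.

Supported volume formats: multi-page TIFF (uint8 labels, JSON metadata
in the description tag), NRRD (uncompressed, minimal header), and
raw uint8 with a JSON sidecar.  All carry voxel pitch and pleural
metadata; volumes without them are rejected with descriptive errors.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from pulmolymph.core import LabelVolume, VALID_LABELS

_LABEL_MAP = {
    "0": "air/paraffin", "1": "interstitium", "2": "blood lumen",
    "3": "lymphatic lumen", "4": "pleural surface",
}


def _meta(volume: LabelVolume) -> dict:
    return {
        "shape": list(volume.shape),
        "voxel_pitch_um": volume.voxel_pitch,
        "axis_order": "zyx",
        "pleural_direction": volume.pleural_direction,
        "label_map": _LABEL_MAP,
    }


def write_volume(volume: LabelVolume, path) -> None:
    """Write by extension: .tif/.tiff, .nrrd, or .raw (+ .json sidecar)."""
    path = Path(path)
    suffix = path.suffix.lower()
    data = volume.labels.astype(np.uint8)
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, data, description=json.dumps(_meta(volume)))
    elif suffix == ".nrrd":
        _write_nrrd(path, data, volume)
    elif suffix == ".raw":
        data.tofile(path)
        path.with_suffix(".json").write_text(json.dumps(_meta(volume),
                                                        indent=1))
    else:
        raise ValueError(f"unsupported volume format {suffix!r}")


def read_volume(path) -> LabelVolume:
    """Read a labelled volume; validates labels and required metadata."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].tags.get("ImageDescription")
            if desc is None:
                raise ValueError(f"{path}: missing metadata description tag")
            meta = json.loads(desc.value)
    elif suffix == ".nrrd":
        data, meta = _read_nrrd(path)
    elif suffix == ".raw":
        side = path.with_suffix(".json")
        if not side.exists():
            raise ValueError(f"{path}: missing JSON sidecar {side.name}")
        meta = json.loads(side.read_text())
        data = np.fromfile(path, dtype=np.uint8).reshape(meta["shape"])
    else:
        raise ValueError(f"unsupported volume format {suffix!r}")
    if "voxel_pitch_um" not in meta:
        raise ValueError(f"{path}: metadata lacks voxel_pitch_um")
    bad = set(np.unique(data).tolist()) - VALID_LABELS
    if bad:
        raise ValueError(f"{path}: unknown label values {sorted(bad)}")
    return LabelVolume(np.asarray(data, dtype=np.uint8),
                       float(meta["voxel_pitch_um"]),
                       pleural_direction=meta.get("pleural_direction"))


def _write_nrrd(path, data, volume):
    header = [
        "NRRD0004",
        "# pulmolymph label volume",
        "type: uint8",
        "dimension: 3",
        f"sizes: {data.shape[2]} {data.shape[1]} {data.shape[0]}",
        "encoding: raw",
        "endian: little",
        f"space directions: ({volume.voxel_pitch},0,0) "
        f"(0,{volume.voxel_pitch},0) (0,0,{volume.voxel_pitch})",
        "space units: \"um\" \"um\" \"um\"",
        f"pulmolymph:meta:= {json.dumps(_meta(volume))}",
        "",   # blank line separates the NRRD header from the raw data
        "",
    ]
    with open(path, "wb") as f:
        f.write("\n".join(header).encode())
        f.write(data.tobytes())   # C order, sizes listed fastest-first


def _read_nrrd(path):
    raw = Path(path).read_bytes()
    end = raw.index(b"\n\n") if b"\n\n" in raw else raw.index(b"\n\r\n")
    header = raw[:end].decode()
    meta = {}
    sizes = None
    pitch = None
    for line in header.splitlines():
        if line.startswith("sizes:"):
            sizes = [int(t) for t in line.split(":")[1].split()]
        elif line.startswith("space directions:"):
            pitch = float(line.split("(")[1].split(",")[0])
        elif line.startswith("pulmolymph:meta:="):
            meta = json.loads(line.split(":=", 1)[1])
    if sizes is None:
        raise ValueError(f"{path}: NRRD header lacks sizes")
    data = np.frombuffer(raw[end + 2:], dtype=np.uint8).reshape(
        sizes[2], sizes[1], sizes[0]).copy()
    if "voxel_pitch_um" not in meta and pitch is not None:
        meta["voxel_pitch_um"] = pitch
    return data, meta


def write_truth_csv(truth_rows, path) -> None:
    import pandas as pd
    pd.DataFrame(truth_rows).to_csv(path, index=False)


def morphometry_to_frame(records, vois=None):
    """Tabulate MorphometryRecords (plus optional VOI class/distance)."""
    import pandas as pd
    rows = []
    for i, rec in enumerate(records):
        row = dict(rec.__dict__)
        if vois is not None:
            row["region_class"] = vois[i].region_class
            row["median_pleural_distance_um"] = vois[i].median_pleural_distance
        rows.append(row)
    return pd.DataFrame(rows)
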