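"""Readers and writers for the package's on-disk formats.

Recordings and isopotential sequences go to HDF5; electrode layouts to JSON;
torso meshes to Wavefront OBJ (vertex/face records only, via trimesh).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import trimesh

from .isopotential import IsopotentialSequence
from .synthetic import BspmRecording, ElectrodeLayout, TorsoMesh


# -- OBJ ---------------------------------------------------------------------

def save_mesh_obj(mesh: TorsoMesh, path: str | Path) -> None:
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    Path(path).write_text(tm.export(file_type="obj"))


def load_mesh_obj(path: str | Path) -> TorsoMesh:
    tm = trimesh.load(str(path), file_type="obj", process=False)
    vertices = np.asarray(tm.vertices, dtype=float)
    mesh = TorsoMesh(
        vertices=vertices,
        faces=np.asarray(tm.faces, dtype=np.int64),
        front_mask=vertices[:, 2] > 0.0,
    )
    mesh.validate()
    return mesh


# -- layout JSON -------------------------------------------------------------

def save_layout_json(layout: ElectrodeLayout, path: str | Path) -> None:
    doc = {
        "names": layout.names,
        "positions_3d": layout.positions_3d.tolist(),
        "positions_2d": [
            [None if np.isnan(v) else v for v in row] for row in layout.positions_2d
        ],
        "side": layout.side.tolist(),
        "ref_names": layout.ref_names,
        "ref_positions_3d": layout.ref_positions_3d.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_layout_json(path: str | Path) -> ElectrodeLayout:
    doc = json.loads(Path(path).read_text())
    pos2d = np.array(
        [[np.nan if v is None else v for v in row] for row in doc["positions_2d"]]
    )
    layout = ElectrodeLayout(
        names=list(doc["names"]),
        positions_3d=np.asarray(doc["positions_3d"], float),
        positions_2d=pos2d,
        side=np.asarray(doc["side"]),
        ref_names=list(doc["ref_names"]),
        ref_positions_3d=np.asarray(doc["ref_positions_3d"], float),
    )
    layout.validate()
    return layout


# -- recordings / sequences (HDF5) ------------------------------------------

def save_recording_h5(recording: BspmRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data.astype(np.float32))
        f["fs"] = recording.fs
        f["label"] = recording.label
        f["patient_id"] = recording.patient_id
        f.create_dataset(
            "channel_names", data=np.array(recording.channel_names, dtype="S")
        )


def load_recording_h5(path: str | Path) -> BspmRecording:
    with h5py.File(path, "r") as f:
        rec = BspmRecording(
            data=f["data"][()].astype(np.float64),
            fs=float(f["fs"][()]),
            label=f["label"][()].decode(),
            patient_id=f["patient_id"][()].decode(),
            channel_names=[c.decode() for c in f["channel_names"][()]],
        )
    rec.validate()
    return rec


def save_sequence_h5(seq: IsopotentialSequence, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=seq.frames.astype(np.float32))
        f["dt"] = seq.dt_s
        f["label"] = seq.label
        f["patient_id"] = seq.patient_id
        f["start_sample"] = seq.start_sample


def load_sequence_h5(path: str | Path) -> IsopotentialSequence:
    with h5py.File(path, "r") as f:
        return IsopotentialSequence(
            frames=f["frames"][()].astype(np.float64),
            dt_s=float(f["dt"][()]),
            label=f["label"][()].decode(),
            patient_id=f["patient_id"][()].decode(),
            start_sample=int(f["start_sample"][()]),
        )
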