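"""HDF5 + JSON-sidecar persistence for recordings, gains, and estimates.

Numeric arrays live in ``.h5`` files; everything human-readable (channel
tables, annotations, configuration hashes, seeds) goes to a ``.json``
sidecar next to the matrix file.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .geometry import ChannelKind, Modality, SensorArray, SensorChannel, SourceSpace
from .forward import GainMatrix
from .inverse import SourceEstimate
from .simulate import Annotation, Recording

__all__ = [
    "save_recording",
    "load_recording",
    "save_gain",
    "load_gain",
    "save_source_space",
    "load_source_space",
    "save_estimate",
    "load_estimate",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _dump_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def _channel_table(array: SensorArray) -> list[dict]:
    return [
        {
            "name": ch.name,
            "kind": ch.kind.value,
            "position": ch.position.tolist(),
            "orientation": ch.orientation.tolist(),
            "baseline": ch.baseline,
            "unit": ch.unit,
        }
        for ch in array.channels
    ]


def _array_from_table(table: list[dict], modality: str) -> SensorArray:
    channels = [
        SensorChannel(
            name=row["name"],
            kind=ChannelKind(row["kind"]),
            position=np.array(row["position"]),
            orientation=np.array(row["orientation"]),
            baseline=row["baseline"],
            unit=row["unit"],
        )
        for row in table
    ]
    return SensorArray(channels, Modality(modality))


def save_recording(path: str | Path, rec: Recording, extra: dict | None = None) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=rec.values, compression="gzip")
        f.attrs["sampling_rate"] = rec.sampling_rate
    meta = {
        "modality": rec.array.modality.value,
        "channels": _channel_table(rec.array),
        "annotations": [
            {"label": a.label, "onset": a.onset, "duration": a.duration}
            for a in rec.annotations
        ],
        "provenance": rec.provenance,
    }
    if extra:
        meta.update(extra)
    _dump_json(_sidecar(path), meta)


def load_recording(path: str | Path) -> Recording:
    path = Path(path)
    with h5py.File(path, "r") as f:
        values = f["values"][()]
        fs = float(f.attrs["sampling_rate"])
    meta = json.loads(_sidecar(path).read_text())
    return Recording(
        values=values,
        sampling_rate=fs,
        array=_array_from_table(meta["channels"], meta["modality"]),
        annotations=[
            Annotation(a["label"], a["onset"], a["duration"]) for a in meta["annotations"]
        ],
        provenance=meta["provenance"],
    )


def save_gain(path: str | Path, gain: GainMatrix) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=gain.values, compression="gzip")
        f.create_dataset("source_order", data=np.asarray(gain.source_order))
    _dump_json(
        _sidecar(path),
        {"modality": gain.modality.value, "channel_order": list(gain.channel_order)},
    )


def load_gain(path: str | Path) -> GainMatrix:
    path = Path(path)
    with h5py.File(path, "r") as f:
        values = f["values"][()]
        source_order = f["source_order"][()]
    meta = json.loads(_sidecar(path).read_text())
    return GainMatrix(values, meta["channel_order"], source_order, Modality(meta["modality"]))


def save_source_space(path: str | Path, ss: SourceSpace) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=ss.positions)
        f.create_dataset("orientations", data=ss.orientations)
        f.create_dataset(
            "hemisphere", data=np.array([h.encode() for h in ss.hemisphere])
        )
        f.attrs["nominal_spacing"] = ss.nominal_spacing


def load_source_space(path: str | Path) -> SourceSpace:
    with h5py.File(path, "r") as f:
        return SourceSpace(
            positions=f["positions"][()],
            orientations=f["orientations"][()],
            hemisphere=np.array([h.decode() for h in f["hemisphere"][()]]),
            nominal_spacing=float(f.attrs["nominal_spacing"]),
        )


def save_estimate(path: str | Path, est: SourceEstimate, extra: dict | None = None) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=est.values, compression="gzip")
        if est.component_noise_eigvals is not None:
            f.create_dataset("component_noise_eigvals", data=est.component_noise_eigvals)
        f.attrs["sampling_rate"] = est.sampling_rate
    meta = {"modality": est.modality.value, "spindle_id": est.spindle_id}
    if extra:
        meta.update(extra)
    _dump_json(_sidecar(path), meta)


def load_estimate(path: str | Path) -> SourceEstimate:
    path = Path(path)
    with h5py.File(path, "r") as f:
        values = f["values"][()]
        fs = float(f.attrs["sampling_rate"])
        eig = f["component_noise_eigvals"][()] if "component_noise_eigvals" in f else None
    meta = json.loads(_sidecar(path).read_text())
    return SourceEstimate(
        values=values,
        sampling_rate=fs,
        modality=Modality(meta["modality"]),
        spindle_id=meta["spindle_id"],
        component_noise_eigvals=eig,
    )
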