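"""File formats: HDF5 recordings, CSV trajectories/features/reports,
a simple VTK-legacy mesh writer with a JSON sidecar, and YAML configs.

All tabular outputs are plain text (CSV); recordings use an HDF5
container (channels x samples with fs/labels attributes).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .features import EMGRecording, FeatureSeries
from .fem import LipModel, TrajectorySet
from .mapping import ActivationSet


def save_recording(path: str | Path, rec: EMGRecording) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("samples", data=rec.samples)
        d.attrs["fs"] = rec.fs
        d.attrs["labels"] = [s.encode() for s in rec.labels]
        d.attrs["instruction"] = rec.instruction
        d.attrs["repetition"] = rec.repetition


def load_recording(path: str | Path) -> EMGRecording:
    with h5py.File(path, "r") as f:
        d = f["samples"]
        return EMGRecording(
            samples=d[()],
            fs=float(d.attrs["fs"]),
            labels=[s.decode() if isinstance(s, bytes) else str(s)
                    for s in d.attrs["labels"]],
            instruction=str(d.attrs.get("instruction", "")),
            repetition=int(d.attrs.get("repetition", 0)),
        )


def save_trajectories(path: str | Path, traj: TrajectorySet) -> None:
    rows = []
    for m in range(traj.n_markers):
        name = (traj.marker_names[m] if traj.marker_names else str(m))
        for fidx in range(traj.n_frames):
            x, y, z = traj.positions[m, fidx]
            rows.append((fidx, name, x, y, z))
    pd.DataFrame(rows, columns=["frame", "marker_id", "x", "y", "z"]).to_csv(
        path, index=False
    )
    sidecar = {
        "frame_rate": traj.frame_rate,
        "source": traj.source,
        "instruction": traj.instruction,
        "repetition": traj.repetition,
        "marker_names": list(traj.marker_names),
        "units": "mm",
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_trajectories(path: str | Path) -> TrajectorySet:
    df = pd.read_csv(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    names = meta["marker_names"]
    frames = int(df["frame"].max()) + 1
    pos = np.empty((len(names), frames, 3))
    for m, name in enumerate(names):
        sub = df[df["marker_id"] == name].sort_values("frame")
        pos[m] = sub[["x", "y", "z"]].to_numpy()
    return TrajectorySet(
        positions=pos,
        frame_rate=float(meta["frame_rate"]),
        source=meta.get("source", "measured"),
        instruction=meta.get("instruction", ""),
        repetition=int(meta.get("repetition", 0)),
        marker_names=names,
    )


def save_features(path: str | Path, feat: FeatureSeries) -> None:
    rows = []
    for c, label in enumerate(feat.labels):
        for fidx in range(feat.n_frames):
            rows.append((fidx, label, feat.values[c, fidx]))
    pd.DataFrame(rows, columns=["frame", "channel", "value"]).to_csv(
        path, index=False
    )
    sidecar = {
        "window_samples": feat.window,
        "hop_samples": feat.hop,
        "s_lim_mV": feat.s_lim,
        "fs": feat.fs,
        "normalised": feat.normalised,
        "instruction": feat.instruction,
        "repetition": feat.repetition,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def save_activation(path: str | Path, act: ActivationSet) -> None:
    df = pd.DataFrame(act.values.T, columns=act.labels)
    df.insert(0, "frame", np.arange(act.n_frames))
    df.to_csv(path, index=False)
    header = {
        "strategy": act.strategy,
        "instruction": act.instruction,
        "repetition": act.repetition,
        "selected": list(act.selected),
    }
    Path(str(path) + ".json").write_text(json.dumps(header, indent=1))


def save_mesh(path: str | Path, model: LipModel) -> None:
    """Legacy-VTK ASCII unstructured grid plus a JSON sidecar."""
    lines = [
        "# vtk DataFile Version 3.0",
        "reduced lip mesh", "ASCII", "DATASET UNSTRUCTURED_GRID",
        f"POINTS {model.n_nodes} float",
    ]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in model.nodes]
    lines.append(f"CELLS {model.n_elements} {model.n_elements * 9}")
    lines += ["8 " + " ".join(str(i) for i in e) for e in model.elems]
    lines.append(f"CELL_TYPES {model.n_elements}")
    lines += ["12"] * model.n_elements
    Path(path).write_text("\n".join(lines) + "\n")
    sidecar = {
        "layers": model.layers.tolist(),
        "fixed_nodes": model.fixed.tolist(),
        "marker_nodes": model.marker_nodes.tolist(),
        "marker_names": list(model.marker_names),
        "sigma_max_kPa": model.sigma_max,
        "muscles": {
            m.name: {
                "polyline": m.polyline.tolist(),
                "lam_star": m.lam_star, "p1": m.p1, "p2": m.p2,
                "lam_ofl": m.lam_ofl,
                "elements": model.muscle_elems.get(
                    m.name, (np.empty(0, int), None))[0].tolist(),
            }
            for m in model.muscles
        },
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def load_mesh(path: str | Path) -> LipModel:
    """Read back a mesh written by :func:`save_mesh`."""
    from .fem import MaterialParams, MuscleDef

    lines = Path(path).read_text().splitlines()
    npts = int(next(ln for ln in lines if ln.startswith("POINTS"))
               .split()[1])
    start = next(i for i, ln in enumerate(lines)
                 if ln.startswith("POINTS")) + 1
    nodes = np.array([[float(v) for v in ln.split()]
                      for ln in lines[start:start + npts]])
    cstart = next(i for i, ln in enumerate(lines)
                  if ln.startswith("CELLS")) + 1
    ncell = int(lines[cstart - 1].split()[1])
    elems = np.array([[int(v) for v in ln.split()[1:]]
                      for ln in lines[cstart:cstart + ncell]])
    meta = json.loads(Path(str(path) + ".json").read_text())
    muscles = []
    muscle_elems = {}
    for name, m in meta.get("muscles", {}).items():
        muscles.append(MuscleDef(
            name=name, polyline=np.asarray(m["polyline"]),
            lam_star=m["lam_star"], p1=m["p1"], p2=m["p2"],
            lam_ofl=m["lam_ofl"],
        ))
    model = LipModel(
        nodes=nodes, elems=elems,
        layers=np.array(meta["layers"]),
        fixed=np.array(meta["fixed_nodes"], dtype=int),
        marker_nodes=np.array(meta["marker_nodes"], dtype=int),
        marker_names=list(meta["marker_names"]),
        material=MaterialParams(),
        muscles=muscles,
        sigma_max=float(meta.get("sigma_max_kPa", 300.0)),
    )
    from .fem import assign_muscle_elements
    for m in muscles:
        ids = np.asarray(meta["muscles"][m.name]["elements"], dtype=int)
        override = MuscleDef(
            name=m.name, polyline=m.polyline, lam_star=m.lam_star,
            p1=m.p1, p2=m.p2, lam_ofl=m.lam_ofl, elements=ids,
        )
        muscle_elems[m.name] = assign_muscle_elements(model, override)
    model.muscle_elems = muscle_elems
    return model


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return data
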