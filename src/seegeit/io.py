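"""File interfaces: legacy-VTK meshes, TSV electrode tables, HDF5 recording
containers, 4D NIfTI image series and JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import Electrode, HeadModel
from .imaging import ImageSeries
from .signals import DemodulatedBlock, RawRecording, SignalConfig

__all__ = [
    "write_mesh_vtk",
    "read_mesh_vtk",
    "write_electrodes_tsv",
    "read_electrodes_tsv",
    "write_recording_h5",
    "read_recording_h5",
    "write_block_h5",
    "read_block_h5",
    "write_image_series_nifti",
    "write_json",
]


def write_mesh_vtk(model: HeadModel, path: str | Path) -> None:
    """Write the tetrahedral mesh with per-element conductivity (legacy VTK ASCII)."""
    v, t = model.vertices, model.tetrahedra
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nseegeit brain mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(v)} double\n")
        np.savetxt(f, v, fmt="%.6f")
        f.write(f"CELLS {len(t)} {len(t) * 5}\n")
        np.savetxt(f, np.column_stack([np.full(len(t), 4), t]), fmt="%d")
        f.write(f"CELL_TYPES {len(t)}\n")
        np.savetxt(f, np.full(len(t), 10), fmt="%d")  # VTK_TETRA
        f.write(f"CELL_DATA {len(t)}\nSCALARS conductivity double 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, model.element_conductivity, fmt="%.6g")


def read_mesh_vtk(path: str | Path) -> HeadModel:
    with open(path) as f:
        lines = f.read().split("\n")
    i = next(k for k, ln in enumerate(lines) if ln.startswith("POINTS"))
    n_pts = int(lines[i].split()[1])
    verts = np.loadtxt(lines[i + 1 : i + 1 + n_pts])
    j = next(k for k, ln in enumerate(lines) if ln.startswith("CELLS"))
    n_cells = int(lines[j].split()[1])
    cells = np.loadtxt(lines[j + 1 : j + 1 + n_cells], dtype=int)[:, 1:]
    s = next(k for k, ln in enumerate(lines) if ln.startswith("LOOKUP_TABLE"))
    sigma = np.loadtxt(lines[s + 1 : s + 1 + n_cells])
    # boundary table is rebuilt lazily by geometry helpers when needed
    from .geometry import build_brain_mesh  # noqa: F401  (avoid cycle at import)

    model = HeadModel(
        vertices=verts,
        tetrahedra=cells,
        element_conductivity=np.atleast_1d(sigma),
    )
    return model


def write_electrodes_tsv(model: HeadModel, path: str | Path) -> None:
    rows = [
        {
            "id": e.id,
            "kind": e.kind,
            "probe": e.probe_id,
            "x_mm": e.position[0],
            "y_mm": e.position[1],
            "z_mm": e.position[2],
            "vertex": e.vertex,
        }
        for e in model.electrodes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_electrodes_tsv(path: str | Path) -> list[Electrode]:
    df = pd.read_csv(path, sep="\t")
    return [
        Electrode(
            id=r["id"],
            kind=r["kind"],
            probe_id=r["probe"],
            position=np.array([r["x_mm"], r["y_mm"], r["z_mm"]]),
            vertex=int(r["vertex"]),
        )
        for _i, r in df.iterrows()
    ]


def write_recording_h5(raw: RawRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("raw", data=raw.samples, compression="gzip", compression_opts=4)
        meta = f.create_group("meta")
        meta.attrs["fs"] = raw.fs
        meta.attrs["t_start"] = raw.t_start
        meta.create_dataset("contact_ids", data=np.array(raw.contact_ids, dtype="S"))
        meta.create_dataset("carrier_freq", data=[c[0] for c in raw.carrier_table])
        meta.create_dataset("carrier_injection", data=[c[1] for c in raw.carrier_table])


def read_recording_h5(path: str | Path) -> RawRecording:
    with h5py.File(path, "r") as f:
        meta = f["meta"]
        fs = float(meta.attrs["fs"])
        return RawRecording(
            samples=f["raw"][()],
            fs=fs,
            contact_ids=[s.decode() for s in meta["contact_ids"][()]],
            carrier_table=list(
                zip(meta["carrier_freq"][()].tolist(), meta["carrier_injection"][()].tolist())
            ),
            t_start=float(meta.attrs["t_start"]),
            config=SignalConfig(fs=fs),
        )


def write_block_h5(block: DemodulatedBlock, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg", data=block.eeg, compression="gzip", compression_opts=4)
        f.create_dataset("dz", data=block.dz, compression="gzip", compression_opts=4)
        meta = f.create_group("meta")
        meta.attrs["fs_eeg"] = block.fs_eeg
        meta.attrs["fs_dz"] = block.fs_dz
        meta.attrs["t_start"] = block.t_start
        meta.create_dataset("contact_ids", data=np.array(block.contact_ids, dtype="S"))
        meta.create_dataset("channel_injection", data=[d for d, _c in block.channels])
        meta.create_dataset(
            "channel_contact", data=np.array([c for _d, c in block.channels], dtype="S")
        )
        if block.baseline_mean is not None:
            meta.create_dataset("baseline_mean", data=block.baseline_mean)
            meta.create_dataset("baseline_sd", data=block.baseline_sd)


def read_block_h5(path: str | Path) -> DemodulatedBlock:
    with h5py.File(path, "r") as f:
        meta = f["meta"]
        channels = list(
            zip(
                meta["channel_injection"][()].tolist(),
                [c.decode() for c in meta["channel_contact"][()]],
            )
        )
        block = DemodulatedBlock(
            eeg=f["eeg"][()],
            fs_eeg=float(meta.attrs["fs_eeg"]),
            dz=f["dz"][()],
            fs_dz=float(meta.attrs["fs_dz"]),
            channels=channels,
            contact_ids=[s.decode() for s in meta["contact_ids"][()]],
            t_start=float(meta.attrs["t_start"]),
        )
        if "baseline_mean" in meta:
            block.baseline_mean = meta["baseline_mean"][()]
            block.baseline_sd = meta["baseline_sd"][()]
        return block


def write_jacobian_h5(jacobian, path: str | Path) -> None:
    """Dense sensitivity matrix with channel and element index tables."""
    with h5py.File(path, "w") as f:
        f.create_dataset("J", data=jacobian.entries, compression="gzip", compression_opts=4)
        f.create_dataset("baseline_V", data=jacobian.baseline)
        f.create_dataset("channel_injection", data=[d for d, _c in jacobian.channels])
        f.create_dataset(
            "channel_contact", data=np.array([c for _d, c in jacobian.channels], dtype="S")
        )
        f.create_dataset("element_index", data=np.arange(jacobian.n_elements))


def read_jacobian_h5(path: str | Path):
    from .forward import JacobianMatrix

    with h5py.File(path, "r") as f:
        channels = list(
            zip(
                f["channel_injection"][()].tolist(),
                [c.decode() for c in f["channel_contact"][()]],
            )
        )
        return JacobianMatrix(
            entries=f["J"][()], channels=channels, baseline=f["baseline_V"][()]
        )


def write_channel_table_tsv(analysis, path: str | Path) -> None:
    """Per-channel dZ statistics for one analysed block."""
    block = analysis.block
    rej = set(analysis.rejected_dz_channels)
    rows = []
    for i, (inj, contact) in enumerate(block.channels):
        rows.append(
            {
                "channel": i,
                "injection": inj,
                "contact": contact,
                "baseline_mean_V": block.baseline_mean[i],
                "baseline_sd_V": block.baseline_sd[i],
                "rejected": i in rej,
                "n_significant_frames": (
                    int(analysis.significance[i].sum())
                    if analysis.significance is not None
                    else 0
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_frame_table_tsv(series: ImageSeries, path: str | Path) -> None:
    """Per-frame maximum |t| and suprathreshold voxel counts."""
    t = series.tscore
    rows = [
        {
            "time_s": float(series.times[i]),
            "max_abs_t": float(np.abs(t[:, i]).max()),
            "n_voxels_t3": int((np.abs(t[:, i]) >= 3.0).sum()),
        }
        for i in range(series.n_frames)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_image_series_nifti(series: ImageSeries, path: str | Path, kind: str = "tscore") -> None:
    """Export frames as a 4D NIfTI volume in the grid's mm affine."""
    arr = series.tscore if kind == "tscore" else series.delta_sigma
    vols = np.stack([series.grid.embed(arr[:, i]) for i in range(series.n_frames)], axis=-1)
    img = nib.Nifti1Image(vols.astype(np.float32), series.grid.affine)
    img.header.set_zooms((series.grid.voxel_size,) * 3 + (1.0,))
    nib.save(img, str(path))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True))
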