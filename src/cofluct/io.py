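"""File-format glue: NIfTI volumes, BIDS-style physio/events TSV, and
TSV/JSON serializations of curves and components."""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def lattice_for(n_voxels: int) -> np.ndarray:
    """Coordinates of a compact 3D lattice holding ``n_voxels`` voxels."""
    side = int(np.ceil(n_voxels ** (1 / 3)))
    grid = np.stack(np.meshgrid(*([np.arange(side)] * 3), indexing="ij"), axis=-1)
    return grid.reshape(-1, 3)[:n_voxels]


def write_fmri_nifti(path, data: np.ndarray, coords: np.ndarray,
                     voxel_size_mm: float = 3.0, tr_s: float = 1.0) -> None:
    """Write frames x voxels data into a 4D NIfTI on its lattice."""
    coords = np.asarray(coords, dtype=int)
    dims = tuple(coords.max(axis=0) + 1)
    vol = np.zeros(dims + (data.shape[0],), dtype=np.float32)
    vol[coords[:, 0], coords[:, 1], coords[:, 2], :] = data.T
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms((voxel_size_mm,) * 3 + (tr_s,))
    nib.save(img, str(path))


def write_map_nifti(path, values: np.ndarray, coords: np.ndarray,
                    voxel_size_mm: float = 3.0) -> None:
    coords = np.asarray(coords, dtype=int)
    dims = tuple(coords.max(axis=0) + 1)
    vol = np.zeros(dims, dtype=np.float32)
    vol[coords[:, 0], coords[:, 1], coords[:, 2]] = values
    nib.save(nib.Nifti1Image(vol, np.diag([voxel_size_mm] * 3 + [1.0])), str(path))


def write_mask_nifti(path, coords: np.ndarray, voxel_size_mm: float = 3.0) -> None:
    write_map_nifti(path, np.ones(len(coords)), coords, voxel_size_mm)


def read_fmri_nifti(path, mask_path=None):
    """Read a 4D NIfTI (+ optional mask) back to frames x voxels + coords."""
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = np.any(vol != 0, axis=-1)
    coords = np.argwhere(mask)
    data = vol[mask].T  # frames x voxels
    tr_s = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    return data, coords, tr_s


def write_physio(path_stem, columns: dict, fs_hz: float,
                 start_time_s: float = 0.0) -> None:
    """BIDS-style physio: gzipped headerless TSV + JSON sidecar."""
    path_stem = Path(path_stem)
    names = list(columns)
    arr = np.column_stack([np.asarray(columns[c], dtype=float) for c in names])
    with gzip.open(path_stem.with_suffix(".tsv.gz"), "wt") as fh:
        np.savetxt(fh, arr, delimiter="\t", fmt="%.8g")
    sidecar = {"SamplingFrequency": fs_hz, "StartTime": start_time_s,
               "Columns": names}
    path_stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_physio(path_stem):
    path_stem = Path(path_stem)
    meta = json.loads(path_stem.with_suffix(".json").read_text())
    with gzip.open(path_stem.with_suffix(".tsv.gz"), "rt") as fh:
        arr = np.loadtxt(fh, delimiter="\t", ndmin=2)
    cols = {name: arr[:, i] for i, name in enumerate(meta["Columns"])}
    return cols, float(meta["SamplingFrequency"]), float(meta.get("StartTime", 0.0))


def write_events_tsv(path, onsets_s, duration_s=0.0, trial_type="event",
                     response=None) -> None:
    n = len(onsets_s)
    df = pd.DataFrame({
        "onset": np.asarray(onsets_s, dtype=float),
        "duration": np.full(n, duration_s),
        "trial_type": [trial_type] * n if isinstance(trial_type, str) else trial_type,
    })
    if response is not None:
        df["response"] = np.asarray(response).astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path):
    df = pd.read_csv(path, sep="\t")
    return df


def write_feature_tsv(path, feature) -> None:
    with open(path, "w") as fh:
        fh.write(f"# name={feature.name}\n# units={feature.units}\n"
                 f"# tr_s={feature.tr_s}\n")
        pd.DataFrame({"value": feature.values}).to_csv(fh, sep="\t", index=False)


def read_feature_tsv(path):
    from .physio import FeatureSeries

    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return FeatureSeries(values=df["value"].to_numpy(),
                         tr_s=float(meta.get("tr_s", 1.0)),
                         name=meta.get("name", "feature"),
                         units=meta.get("units", "a.u."))


def write_curve_tsv(path, lags_s, values, meta: dict | None = None,
                    value_name: str = "value") -> None:
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        pd.DataFrame({"lag_s": lags_s, value_name: values}).to_csv(
            fh, sep="\t", index=False)


def write_json(path, obj: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
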