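"""Readers and writers for the pipeline's plain-text and NIfTI formats.

ROI matrices travel as TSV (rows = ROIs, columns = frames, header row with
frame indices) with a JSON sidecar for TR and identity; motion as 6-column
whitespace-delimited text; events, masks, cluster models and event logs as
TSV (+ JSON sidecars); voxel data as NIfTI-1 4D with a documented reversible
flattening order.
"""

from __future__ import annotations

import json
import os

import nibabel as nib
import numpy as np
import pandas as pd

from .cluster import ClusterModel
from .detect import TsEvent
from .preprocess import MotionTrace, RoiTimeseries, ScrubMask
from .synthetic import EventLog


def _sidecar(path) -> str:
    return str(path) + ".json"


def write_roi_tsv(ts: RoiTimeseries, path) -> None:
    frames = np.arange(ts.n_frames) + ts.frame_offset
    df = pd.DataFrame(ts.data, index=ts.roi_ids, columns=frames)
    # %.17g round-trips float64 exactly
    df.to_csv(path, sep="\t", index_label="roi", float_format="%.17g")
    with open(_sidecar(path), "w") as fh:
        json.dump({"tr": ts.tr, "subject_id": ts.subject_id,
                   "run_id": ts.run_id, "frame_offset": ts.frame_offset}, fh)


def read_roi_tsv(path, tr: float = None) -> RoiTimeseries:
    if not os.path.exists(path):
        raise FileNotFoundError(f"ROI TSV not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    try:
        data = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if not np.all(np.isfinite(data)):
        rows, cols = np.where(~np.isfinite(data))
        raise ValueError(
            f"non-finite value in {path} at row {df.index[rows[0]]!r}, "
            f"column {df.columns[cols[0]]!r}")
    meta = {"tr": tr, "subject_id": "", "run_id": "", "frame_offset": 0}
    if os.path.exists(_sidecar(path)):
        with open(_sidecar(path)) as fh:
            meta.update(json.load(fh))
    if tr is not None:
        meta["tr"] = tr
    if meta["tr"] is None:
        raise ValueError(f"no TR available for {path}: pass tr= or provide a sidecar")
    return RoiTimeseries(data=data, tr=meta["tr"], roi_ids=list(df.index.astype(str)),
                         subject_id=meta["subject_id"], run_id=meta["run_id"],
                         frame_offset=int(meta["frame_offset"]))


def write_motion(motion: MotionTrace, path) -> None:
    np.savetxt(path, motion.params, fmt="%.8f")


def read_motion(path) -> MotionTrace:
    return MotionTrace(params=np.loadtxt(path, ndmin=2))


def write_mask(mask: ScrubMask, path) -> None:
    np.savetxt(path, mask.mask.astype(int), fmt="%d")


def read_mask(path) -> ScrubMask:
    return ScrubMask(mask=np.loadtxt(path, ndmin=1).astype(bool))


def write_events_tsv(events, path, frame_offset: int = 0) -> None:
    """Events as TSV; TSP vectors appended as tsp_<i> columns."""
    rows = []
    for ev in events:
        row = {"subject_id": ev.subject_id, "run_id": ev.run_id,
               "center_frame": ev.center_frame, "frame_offset": frame_offset,
               "window_start": ev.window_start, "window_end": ev.window_end,
               "explained_variance": ev.explained_variance,
               "sub_cluster": -1 if ev.sub_cluster is None else ev.sub_cluster}
        for i, v in enumerate(ev.tsp):
            row[f"tsp_{i}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    tsp_cols = [c for c in df.columns if c.startswith("tsp_")]
    tsp_cols.sort(key=lambda c: int(c.split("_")[1]))
    events = []
    for _, r in df.iterrows():
        sub = int(r["sub_cluster"])
        events.append(TsEvent(center_frame=int(r["center_frame"]),
                              window_start=int(r["window_start"]),
                              window_end=int(r["window_end"]),
                              explained_variance=float(r["explained_variance"]),
                              tsp=r[tsp_cols].to_numpy(dtype=float),
                              sub_cluster=None if sub < 0 else sub,
                              subject_id=str(r["subject_id"]),
                              run_id=str(r["run_id"])))
    return events


def write_event_log(log: EventLog, path) -> None:
    pd.DataFrame({"pattern_id": log.pattern_ids, "frame": log.center_frames,
                  "amplitude": log.amplitudes}).to_csv(path, sep="\t", index=False)


def read_event_log(path) -> EventLog:
    df = pd.read_csv(path, sep="\t")
    return EventLog(pattern_ids=df["pattern_id"].to_numpy(),
                    center_frames=df["frame"].to_numpy(),
                    amplitudes=df["amplitude"].to_numpy())


def write_cluster_model(model: ClusterModel, path) -> None:
    """Centroid matrix as TSV plus a JSON sidecar (k, pairing, inertia, seed)."""
    pd.DataFrame(model.centroids,
                 index=[f"subcluster_{i}" for i in range(model.k)]).to_csv(
        path, sep="\t", index_label="subcluster")
    pairing = None if model.pairing is None else {str(a): int(c)
                                                  for a, c in model.pairing.items()}
    with open(_sidecar(path), "w") as fh:
        json.dump({"k": model.k, "inertia": model.inertia, "seed": model.seed,
                   "pairing": pairing}, fh)


def read_nifti4d(path):
    """Load a 4-D NIfTI as (voxels x frames, affine, spatial shape).

    Voxels are flattened in C order over the three spatial axes, so
    ``matrix.reshape(shape + (n_frames,))`` reverses the flattening.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path} is {img.ndim}-D; a 4-D NIfTI is required")
    data = np.asarray(img.get_fdata(), dtype=float)
    shape = data.shape[:3]
    matrix = data.reshape(-1, data.shape[3])
    return matrix, img.affine, shape


def write_nifti4d(matrix: np.ndarray, affine: np.ndarray, shape, path) -> None:
    data = np.asarray(matrix).reshape(tuple(shape) + (matrix.shape[1],))
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))


def write_nifti_map(values: np.ndarray, affine: np.ndarray, shape, path) -> None:
    """One statistical map (voxel vector) back into 3-D NIfTI."""
    data = np.asarray(values).reshape(tuple(shape))
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))
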