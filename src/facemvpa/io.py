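"""Readers and writers for the pipeline's on-disk formats.

Events travel as BIDS-dialect tab-separated text (columns onset, duration,
trial_type, trial_id, response, response_time; seconds from run start,
``n/a`` for missing) with a JSON sidecar holding run timing.  BOLD runs are
NIfTI-1 4-D volumes (via nibabel) or a flat float32 binary with a JSON
header; ROI masks are NIfTI or plain JSON index lists.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .design import Event, EventDesign
from .glm import BoldRun, RoiMask
from .synth import BehavioralRecord

__all__ = [
    "write_events_tsv",
    "read_events_tsv",
    "write_bold",
    "read_bold",
    "write_tmap_nifti",
    "write_mask_json",
    "read_mask_json",
]

NA = "n/a"


def write_events_tsv(
    design: EventDesign,
    path: str | Path,
    behavior: list[BehavioralRecord] | None = None,
) -> Path:
    """Write a run's events (and optional behavior) as TSV plus JSON sidecar."""
    path = Path(path)
    resp = {r.trial_id: r for r in behavior} if behavior else {}
    rows = []
    for e in design.events:
        r = resp.get(e.trial_id) if e.trial_id is not None else None
        rows.append(
            {
                "onset": e.onset_s,
                "duration": e.duration_s,
                "trial_type": e.condition,
                "trial_id": e.trial_id if e.trial_id is not None else NA,
                "response": r.response if r else NA,
                "response_time": r.rt_s if (r and r.rt_s is not None) else NA,
            }
        )
    pd.DataFrame(
        rows, columns=["onset", "duration", "trial_type", "trial_id", "response", "response_time"]
    ).to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.17g")
    sidecar = {
        "run_id": design.run_id,
        "tr_s": design.tr_s,
        "n_scans": design.n_scans,
        "lead_in_s": design.lead_in_s,
        "lead_out_s": design.lead_out_s,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_events_tsv(path: str | Path) -> tuple[EventDesign, list[BehavioralRecord]]:
    """Read a TSV + sidecar pair back into a design and behavioral records."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    table = pd.read_csv(
        path, sep="\t", na_values=[NA], keep_default_na=False, float_precision="round_trip"
    )
    events: list[Event] = []
    records: list[BehavioralRecord] = []
    for _, row in table.iterrows():
        tid = None if pd.isna(row["trial_id"]) else int(row["trial_id"])
        events.append(Event(float(row["onset"]), float(row["duration"]), str(row["trial_type"]), tid))
        if tid is not None and not pd.isna(row["response"]):
            rt = None if pd.isna(row["response_time"]) else float(row["response_time"])
            records.append(BehavioralRecord(tid, str(row["trial_type"]), str(row["response"]), rt))
    design = EventDesign(
        run_id=int(meta["run_id"]),
        events=events,
        tr_s=float(meta["tr_s"]),
        n_scans=int(meta["n_scans"]),
        lead_in_s=float(meta.get("lead_in_s", 0.0)),
        lead_out_s=float(meta.get("lead_out_s", 0.0)),
    )
    return design, records


def _affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    return np.diag([*voxel_size_mm, 1.0])


def write_bold(
    bold: BoldRun,
    path: str | Path,
    fmt: str = "nifti",
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 4.0),
) -> Path:
    """Write a run as NIfTI (``.nii``/``.nii.gz``) or flat binary + header."""
    path = Path(path)
    if fmt == "nifti":
        img = nib.Nifti1Image(bold.data.astype(np.float32), _affine(voxel_size_mm))
        img.header.set_zooms((*voxel_size_mm, bold.tr_s))
        nib.save(img, str(path))
        sidecar = {"run_id": bold.run_id, "tr_s": bold.tr_s}
        Path(str(path).split(".nii")[0] + ".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True)
        )
    elif fmt == "flat":
        bold.data.astype(np.float32).tofile(path)
        header = {
            "shape": list(bold.data.shape),
            "dtype": "float32",
            "order": "C",
            "tr_s": bold.tr_s,
            "run_id": bold.run_id,
            "voxel_size_mm": list(voxel_size_mm),
        }
        path.with_suffix(".json").write_text(json.dumps(header, indent=2, sort_keys=True))
    else:
        raise ValueError(f"unknown BOLD format {fmt!r}")
    return path


def read_bold(path: str | Path) -> BoldRun:
    """Read a BOLD run written by :func:`write_bold` (format by extension)."""
    path = Path(path)
    if path.suffix in (".nii", ".gz") or ".nii" in path.name:
        img = nib.load(str(path))
        sidecar_path = Path(str(path).split(".nii")[0] + ".json")
        meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
        tr = float(meta.get("tr_s", img.header.get_zooms()[3] if len(img.header.get_zooms()) > 3 else 0.0))
        return BoldRun(
            data=np.asarray(img.dataobj, dtype=np.float64),
            tr_s=tr,
            run_id=int(meta.get("run_id", 0)),
        )
    header = json.loads(path.with_suffix(".json").read_text())
    data = np.fromfile(path, dtype=header["dtype"]).reshape(header["shape"])
    return BoldRun(data=data.astype(np.float64), tr_s=float(header["tr_s"]), run_id=int(header["run_id"]))


def write_tmap_nifti(
    t_map: np.ndarray, path: str | Path, voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 4.0)
) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(t_map, dtype=np.float32), _affine(voxel_size_mm)), str(path))
    return path


def write_mask_json(mask: RoiMask, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "name": mask.name,
        "threshold_p": mask.threshold_p,
        "component_seed": list(mask.component_seed) if mask.component_seed else None,
        "voxel_indices": mask.voxel_indices.tolist(),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def read_mask_json(path: str | Path) -> RoiMask:
    d = json.loads(Path(path).read_text())
    return RoiMask(
        voxel_indices=np.asarray(d["voxel_indices"], dtype=int),
        name=d["name"],
        threshold_p=float(d["threshold_p"]),
        component_seed=tuple(d["component_seed"]) if d.get("component_seed") else None,
    )
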