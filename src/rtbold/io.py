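"""Reading and writing the pipeline's on-disk formats.

Events are tab-separated, one file per subject per run, in a BIDS-events
compatible dialect with columns onset (s, scanner-referenced), duration
(s), trial_type, response_time (ms), correct, excluded_as.  Time series
are delimited unit-by-volume matrices; ground-truth generative parameters
go to a JSON sidecar.  Volumetric maps use NIfTI via nibabel.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable

import nibabel as nib
import numpy as np
import pandas as pd

from .synth import SubjectDataset

EVENTS_DIALECT = ["onset", "duration", "trial_type", "response_time", "correct", "excluded_as"]


def events_to_bids(events: pd.DataFrame, stimulus_duration: float = 0.5) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "onset": events["onset"],
            "duration": stimulus_duration,
            "trial_type": events["condition"],
            "response_time": events["rt_ms"],
            "correct": events["correct"].astype("boolean"),
            "excluded_as": events["excluded_as"],
        }
    )
    return out


def bids_to_events(table: pd.DataFrame, run_index: int, task: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "run_index": run_index,
            "task": task,
            "onset": table["onset"].astype(float),
            "condition": table["trial_type"],
            "rt_ms": table["response_time"].astype(float),
            "correct": table["correct"].astype("boolean"),
            "excluded_as": table.get("excluded_as", "none"),
        }
    )


def write_subject(ds: SubjectDataset, out_dir: str | Path, stimulus_duration: float = 0.5) -> Path:
    """Write one subject: per-run events/timeseries/motion TSVs plus a
    truth JSON sidecar.  Returns the subject directory."""
    sub_dir = Path(out_dir) / ds.subject_id
    sub_dir.mkdir(parents=True, exist_ok=True)
    for run, task in sorted(ds.run_tasks.items()):
        ev = ds.events[ds.events["run_index"] == run]
        tag = f"task-{task}_run-{run:02d}"
        events_to_bids(ev, stimulus_duration).to_csv(
            sub_dir / f"{tag}_events.tsv", sep="\t", index=False, na_rep="n/a"
        )
        if run in ds.timeseries:
            pd.DataFrame(ds.timeseries[run], index=list(ds.unit_names)).to_csv(
                sub_dir / f"{tag}_timeseries.tsv", sep="\t"
            )
        if run in ds.motion:
            pd.DataFrame(
                ds.motion[run], columns=[f"m{i}" for i in range(6)]
            ).to_csv(sub_dir / f"{tag}_motion.tsv", sep="\t", index=False)
    truth = {"run_tasks": {str(k): v for k, v in ds.run_tasks.items()}}
    truth.update(_jsonable(ds.truth))
    (sub_dir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return sub_dir


def read_subject(sub_dir: str | Path, unit_names: Iterable[str] | None = None) -> SubjectDataset:
    """Read back a subject directory written by :func:`write_subject`."""
    sub_dir = Path(sub_dir)
    truth = json.loads((sub_dir / "truth.json").read_text())
    run_tasks = {int(k): v for k, v in truth.pop("run_tasks").items()}
    frames, timeseries, motion = [], {}, {}
    names: list[str] | None = list(unit_names) if unit_names else None
    for run, task in sorted(run_tasks.items()):
        tag = f"task-{task}_run-{run:02d}"
        table = pd.read_csv(sub_dir / f"{tag}_events.tsv", sep="\t", na_values="n/a")
        frames.append(bids_to_events(table, run, task))
        ts_path = sub_dir / f"{tag}_timeseries.tsv"
        if ts_path.exists():
            ts = pd.read_csv(ts_path, sep="\t", index_col=0)
            timeseries[run] = ts.to_numpy()
            if names is None:
                names = [str(i) for i in ts.index]
        mo_path = sub_dir / f"{tag}_motion.tsv"
        if mo_path.exists():
            motion[run] = pd.read_csv(mo_path, sep="\t").to_numpy()
    return SubjectDataset(
        subject_id=sub_dir.name,
        events=pd.concat(frames, ignore_index=True),
        timeseries=timeseries,
        motion=motion,
        truth=truth,
        unit_names=tuple(names or ()),
        run_tasks=run_tasks,
    )


def save_map(values: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a 3-D statistical map as NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine), str(path))


def load_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
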