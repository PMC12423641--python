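"""On-disk layout: multi-page TIFF stacks with JSON sidecars.

One animal = ``<id>.tif`` (T pages of float32 frames) plus ``<id>.json``
(group, injection frame, baseline window, frame rate).  Saliency maps and
masks are single-page float32 / uint8 TIFFs with small JSON sidecars.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Sequence

import numpy as np
import tifffile

from .containers import GroundTruth, PDFrameSeries, RegionMask, SaliencyMap

__all__ = [
    "save_series",
    "load_series",
    "save_cohort",
    "load_cohort",
    "save_map",
    "save_mask",
    "save_ground_truth",
    "save_displacement_field",
    "load_displacement_field",
    "save_model",
    "load_model",
]


def save_series(series: PDFrameSeries, directory: Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{series.animal_id}.tif"
    tifffile.imwrite(path, np.asarray(series.frames, dtype=np.float32))
    meta = {
        "animal_id": series.animal_id,
        "group": series.group,
        "frame_rate_hz": series.frame_rate_hz,
        "injection_index": series.injection_index,
        "baseline_window": list(series.baseline_window),
    }
    (directory / f"{series.animal_id}.json").write_text(json.dumps(meta, indent=1))
    return path


def load_series(path: Path) -> PDFrameSeries:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    frames = tifffile.imread(path)
    return PDFrameSeries(
        animal_id=meta["animal_id"],
        group=meta["group"],
        frames=frames,
        frame_rate_hz=meta["frame_rate_hz"],
        injection_index=meta["injection_index"],
        baseline_window=tuple(meta["baseline_window"]),
    )


def save_cohort(cohort: Sequence[PDFrameSeries], directory: Path) -> List[Path]:
    return [save_series(s, directory) for s in cohort]


def load_cohort(directory: Path) -> List[PDFrameSeries]:
    return [load_series(p) for p in sorted(Path(directory).glob("*.tif"))]


def save_map(map_: SaliencyMap, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, map_.grid.astype(np.float32))
    meta = {
        "class_label": map_.class_label,
        "source": map_.source,
        "window_index": map_.window_index,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def save_mask(mask: RegionMask, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, mask.mask.astype(np.uint8) * 255)
    meta = {"fraction": mask.fraction, "source": mask.source, "n_true": mask.n_true}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def save_displacement_field(field: np.ndarray, path: Path, animal_id: str = "") -> Path:
    """Per-animal (2, rows, cols) registration field as an HDF5 dataset."""
    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("displacement", data=np.asarray(field, dtype=np.float32))
        ds.attrs["animal_id"] = animal_id
        ds.attrs["axes"] = "component(row,col) x rows x cols"
    return path


def load_displacement_field(path: Path) -> np.ndarray:
    import h5py

    with h5py.File(path, "r") as fh:
        return fh["displacement"][()]


def save_model(model, path: Path, meta: dict | None = None) -> Path:
    """Checkpoint a NumPy model (CNN/ViT) as npz params + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, layer in enumerate(model.all_layers()):
        for k, v in layer.P.items():
            arrays[f"{i}:{k}"] = v
    np.savez(path, **arrays)
    sidecar = {"class": type(model).__name__, "spec": dataclasses.asdict(model.spec)}
    sidecar.update(meta or {})
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_model(model, path: Path):
    """Load checkpointed parameters into a freshly built compatible model."""
    data = np.load(Path(path))
    for i, layer in enumerate(model.all_layers()):
        for k in layer.P:
            layer.P[k] = data[f"{i}:{k}"]
    return model


def save_ground_truth(truth: GroundTruth, directory: Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "truth_mask.tif", truth.effect_mask.astype(np.uint8) * 255)
    (directory / "truth.json").write_text(
        json.dumps({"effect_curve": truth.effect_curve.tolist()})
    )
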