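"""Manifest, triplet-archive, report and image I/O."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from PIL import Image

from .types import (
    DatasetManifest,
    EvalReport,
    InputError,
    ManifestRecord,
    TripletDataset,
)

__all__ = ["read_manifest", "write_manifest", "save_triplets", "load_triplets",
           "export_report", "load_report", "export_heatmap", "load_frames_dir"]

_REQUIRED_COLUMNS = ["sample_id", "subject_id", "label"]
_OPTIONAL_COLUMNS = ["frames_dir", "onset", "apex", "offset"]


def read_manifest(path: Union[str, Path]) -> DatasetManifest:
    """Read a CSV manifest; the label vocabulary is first-appearance order.

    Required columns: sample_id, subject_id, label. Optional: frames_dir,
    onset, apex (blank = unknown, to be located automatically), offset.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str,
                                  "label": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"manifest {path} missing column(s): {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dup:
        raise InputError(f"duplicate sample_id(s) in manifest: {dup}")

    def _int_or_none(val):
        if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
            return None
        return int(val)

    records = []
    vocab: list = []
    for row in df.to_dict("records"):
        label = row["label"]
        if label not in vocab:
            vocab.append(label)
        records.append(ManifestRecord(
            sample_id=row["sample_id"],
            subject_id=row["subject_id"],
            label=label,
            frames_dir=row.get("frames_dir") if isinstance(
                row.get("frames_dir"), str) else None,
            onset=_int_or_none(row.get("onset")),
            apex=_int_or_none(row.get("apex")),
            offset=_int_or_none(row.get("offset")),
        ))
    return DatasetManifest(records=records, label_vocab=vocab)


def write_manifest(manifest: DatasetManifest, path: Union[str, Path]) -> None:
    rows = []
    for r in manifest.records:
        rows.append({
            "sample_id": r.sample_id, "subject_id": r.subject_id,
            "frames_dir": r.frames_dir if r.frames_dir else "",
            "onset": "" if r.onset is None else r.onset,
            "apex": "" if r.apex is None else r.apex,
            "offset": "" if r.offset is None else r.offset,
            "label": r.label,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def save_triplets(data: TripletDataset, path: Union[str, Path],
                  metadata: Optional[dict] = None) -> None:
    """Archive a dataset as .npz with a JSON metadata entry."""
    meta = {"normalization": "per-sample per-channel min-max, constant->0.5",
            "channel_order": ["u", "v", "os"]}
    meta.update(metadata or {})
    np.savez(Path(path), X=data.X.astype(np.float32), y=data.y,
             subjects=data.subjects.astype(str),
             sample_ids=data.sample_ids.astype(str),
             label_vocab=np.array(data.label_vocab, dtype=str),
             metadata=np.array(json.dumps(meta)))


def load_triplets(path: Union[str, Path]) -> TripletDataset:
    with np.load(Path(path), allow_pickle=False) as z:
        return TripletDataset(
            X=z["X"], y=z["y"], subjects=z["subjects"],
            sample_ids=z["sample_ids"], label_vocab=z["label_vocab"].tolist())


def export_report(report: EvalReport, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2,
                                     allow_nan=True))


def load_report(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text())


def export_heatmap(heatmap: np.ndarray, path: Union[str, Path],
                   background: Optional[np.ndarray] = None,
                   alpha: float = 0.5) -> None:
    """Write a [0, 1] heatmap as an 8-bit PNG.

    With ``background`` (a grayscale raster, e.g. the u channel) the heatmap
    is overlaid with the perceptually uniform viridis colormap; without one
    the raw heatmap is written as grayscale.
    """
    import matplotlib.cm as cm

    hm = np.clip(np.asarray(heatmap, dtype=np.float64), 0.0, 1.0)
    if background is None:
        img = (hm * 255).round().astype(np.uint8)
        Image.fromarray(img, mode="L").save(path)
        return
    bg = np.asarray(background, dtype=np.float64)
    bg = (bg - bg.min()) / (bg.max() - bg.min()) if bg.max() > bg.min() else bg * 0
    if bg.shape != hm.shape:
        raise InputError("background and heatmap shapes differ")
    colored = cm.viridis(hm)[..., :3]
    overlay = (1 - alpha) * bg[..., None] + alpha * colored
    Image.fromarray((overlay * 255).round().astype(np.uint8), mode="RGB").save(path)


def load_frames_dir(frames_dir: Union[str, Path]) -> list:
    """Load all PNG/JPG/BMP frames of a directory in lexicographic order."""
    frames_dir = Path(frames_dir)
    exts = {".png", ".jpg", ".jpeg", ".bmp"}
    paths = sorted(p for p in frames_dir.iterdir() if p.suffix.lower() in exts)
    if not paths:
        raise InputError(f"no frames found in {frames_dir}")
    frames = []
    for p in paths:
        img = Image.open(p).convert("L")
        frames.append(np.asarray(img, dtype=np.float64) / 255.0)
    return frames
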