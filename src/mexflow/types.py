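"""Domain containers shared across the pipeline.

Conventions used throughout the package:

* images are row-major numpy arrays with the origin at the top-left;
* frame indices are 0-based;
* optical flow ``u`` is the horizontal displacement (+x to the right,
  along columns) and ``v`` the vertical displacement (+y downward, along
  rows), both in pixels per frame pair;
* optical strain ``os`` is the magnitude of the symmetric gradient of the
  flow field (dimensionless, non-negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FrameSequence",
    "FlowField",
    "StrainMap",
    "FlowTriplet",
    "RoiSpec",
    "NetConfig",
    "TrainConfig",
    "SyntheticSpec",
    "PriorAdjustment",
    "ManifestRecord",
    "DatasetManifest",
    "TripletDataset",
    "EvalReport",
    "InputError",
]


class InputError(ValueError):
    """Raised when an input violates a documented precondition."""


def _as_float_image(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise InputError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InputError("image contains non-finite values")
    return arr


@dataclass
class FrameSequence:
    """An ordered grayscale micro-expression clip with annotated indices.

    ``onset_idx`` is the first frame of the facial action, ``apex_idx`` the
    frame of maximal intensity (may be unknown) and ``offset_idx`` the last
    frame of the action.
    """

    frames: list
    subject_id: str
    onset_idx: int = 0
    apex_idx: Optional[int] = None
    offset_idx: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise InputError("a frame sequence needs at least 2 frames")
        self.frames = [_as_float_image(f) for f in self.frames]
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.shape != shape:
                raise InputError(
                    f"frame {i} has shape {f.shape}, expected {shape}"
                )
        n = len(self.frames)
        if self.offset_idx is None:
            self.offset_idx = n - 1
        lo, hi = self.onset_idx, self.offset_idx
        if not (0 <= lo <= hi < n):
            raise InputError(
                f"need 0 <= onset ({lo}) <= offset ({hi}) < n frames ({n})"
            )
        if self.apex_idx is not None and not (lo <= self.apex_idx <= hi):
            raise InputError(
                f"apex index {self.apex_idx} outside [onset, offset] = [{lo}, {hi}]"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple:
        return self.frames[0].shape


@dataclass
class FlowField:
    """Dense optical flow: per-pixel horizontal (u) and vertical (v) displacement."""

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.u.shape != self.v.shape:
            raise InputError(
                f"u and v must share shape, got {self.u.shape} vs {self.v.shape}"
            )
        if self.u.ndim != 2:
            raise InputError("flow components must be 2-D rasters")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise InputError("flow field contains non-finite values")

    @property
    def shape(self) -> tuple:
        return self.u.shape


@dataclass
class StrainMap:
    """Scalar optical-strain magnitude raster (non-negative)."""

    os: np.ndarray

    def __post_init__(self) -> None:
        self.os = np.asarray(self.os, dtype=np.float64)
        if not np.all(np.isfinite(self.os)):
            raise InputError("strain map contains non-finite values")
        if np.any(self.os < 0):
            raise InputError("strain magnitude must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.os.shape


@dataclass
class FlowTriplet:
    """Normalized 3-channel (u, v, os) network input, each channel in [0, 1]."""

    channels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.channels, dtype=np.float32)
        if arr.ndim != 3 or arr.shape[0] != 3:
            raise InputError(f"expected (3, S, S) channels, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise InputError("triplet contains non-finite values")
        if arr.min() < -1e-6 or arr.max() > 1 + 1e-6:
            raise InputError("triplet channels must lie in [0, 1]")
        self.channels = np.clip(arr, 0.0, 1.0)

    @property
    def size(self) -> int:
        return self.channels.shape[1]


@dataclass
class RoiSpec:
    """Three fractional face sub-regions used for apex spotting.

    Each box is (row0, row1, col0, col1) as fractions of image height/width.
    Defaults place the boxes on the mouth and the two eye+brow regions of a
    cropped, roughly frontal face.
    """

    mouth: tuple = (0.60, 0.95, 0.20, 0.80)
    left_eye: tuple = (0.10, 0.45, 0.05, 0.50)
    right_eye: tuple = (0.10, 0.45, 0.50, 0.95)

    def __post_init__(self) -> None:
        for name in ("mouth", "left_eye", "right_eye"):
            r0, r1, c0, c1 = getattr(self, name)
            ok = 0 <= r0 < r1 <= 1 and 0 <= c0 < c1 <= 1
            if not ok:
                raise InputError(f"invalid fractional box for {name}")

    def boxes(self) -> list:
        return [self.mouth, self.left_eye, self.right_eye]

    def crop(self, img: np.ndarray, box: tuple) -> np.ndarray:
        h, w = img.shape
        r0, r1, c0, c1 = box
        return img[int(round(r0 * h)): int(round(r1 * h)),
                   int(round(c0 * w)): int(round(c1 * w))]


@dataclass
class NetConfig:
    """Architecture hyperparameters for the three-branch flow network."""

    n_classes: int = 5
    input_size: int = 28
    kernels_block1: int = 6
    kernels_block2: int = 16
    sam_kernel: int = 7
    cam_reduction: int = 4
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise InputError("need at least 2 classes")
        if self.sam_kernel % 2 != 1:
            raise InputError("sam_kernel must be odd")
        if min(self.kernels_block1, self.kernels_block2) < 1:
            raise InputError("kernel counts must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainConfig:
    """Optimisation settings: Adam with a fixed epoch budget, no schedule."""

    lr: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 8
    epochs: int = 70
    seed: int = 42
    augment: bool = True
    loss: str = "lasce"
    tau: float = 0.5
    gamma: float = 2.0
    eps: float = 1e-12

    def __post_init__(self) -> None:
        if min(self.lr, self.batch_size, self.epochs) <= 0:
            raise InputError("hyperparameters must be positive")
        if self.loss not in {"ce", "focal", "lasce", "la_focal"}:
            raise InputError(f"unknown loss {self.loss!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PriorAdjustment:
    """Class priors p and logit correction factors a_y = log(p_y^tau + eps)."""

    p: np.ndarray
    a: np.ndarray
    tau: float = 0.5
    eps: float = 1e-12

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        self.a = np.asarray(self.a, dtype=np.float64)
        if self.p.shape != self.a.shape:
            raise InputError("p and a must have equal length")
        if not np.all(np.isfinite(self.a)):
            raise InputError("correction factors must be finite")


@dataclass
class ManifestRecord:
    sample_id: str
    subject_id: str
    label: str
    frames_dir: Optional[str] = None
    onset: Optional[int] = None
    apex: Optional[int] = None
    offset: Optional[int] = None


@dataclass
class DatasetManifest:
    """Sample catalogue with an explicit, ordered label vocabulary."""

    records: list
    label_vocab: list

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise InputError(f"duplicate sample_id(s): {sorted(dup)}")
        vocab = set(self.label_vocab)
        for r in self.records:
            if r.label not in vocab:
                raise InputError(f"label {r.label!r} of {r.sample_id} not in vocabulary")

    @property
    def subjects(self) -> list:
        seen: dict = {}
        for r in self.records:
            seen.setdefault(r.subject_id, None)
        return sorted(seen)

    def label_codes(self) -> np.ndarray:
        index = {l: i for i, l in enumerate(self.label_vocab)}
        return np.array([index[r.label] for r in self.records], dtype=np.int64)


@dataclass
class TripletDataset:
    """In-memory dataset of flow triplets with subject and label metadata."""

    X: np.ndarray                  # (N, 3, S, S) float32 in [0, 1]
    y: np.ndarray                  # (N,) int codes into label_vocab
    subjects: np.ndarray           # (N,) str
    sample_ids: np.ndarray         # (N,) str
    label_vocab: list

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.subjects = np.asarray(self.subjects)
        self.sample_ids = np.asarray(self.sample_ids)
        n = len(self.X)
        if not (len(self.y) == len(self.subjects) == len(self.sample_ids) == n):
            raise InputError("dataset arrays must have equal length")

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, idx) -> "TripletDataset":
        return TripletDataset(self.X[idx], self.y[idx], self.subjects[idx],
                              self.sample_ids[idx], list(self.label_vocab))

    def to_manifest(self) -> DatasetManifest:
        records = [
            ManifestRecord(sample_id=str(s), subject_id=str(sub),
                           label=self.label_vocab[int(lab)])
            for s, sub, lab in zip(self.sample_ids, self.subjects, self.y)
        ]
        return DatasetManifest(records=records, label_vocab=list(self.label_vocab))


@dataclass
class EvalReport:
    """Pooled LOSO evaluation: confusion matrix plus Acc / F1 / UF1 / UAR."""

    confusion: np.ndarray          # (C, C) rows = truth, cols = prediction
    label_vocab: list
    acc: float
    acc_per_class: np.ndarray
    f1_per_class: np.ndarray
    uf1: float
    uar: float
    macro_f1: float
    mean_fold_acc: float
    per_fold: list = field(default_factory=list)
    per_sample: dict = field(default_factory=dict)
    excluded_classes: list = field(default_factory=list)
    seed: Optional[int] = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "confusion": np.asarray(self.confusion, dtype=int).tolist(),
            "label_vocab": list(self.label_vocab),
            "acc": float(self.acc),
            "acc_per_class": [float(x) for x in self.acc_per_class],
            "f1_per_class": [float(x) for x in self.f1_per_class],
            "uf1": float(self.uf1),
            "uar": float(self.uar),
            "macro_f1": float(self.macro_f1),
            "mean_fold_acc": float(self.mean_fold_acc),
            "per_fold": self.per_fold,
            "per_sample": {k: list(v) for k, v in self.per_sample.items()},
            "excluded_classes": list(self.excluded_classes),
            "seed": self.seed,
            "config": self.config,
        }


@dataclass
class SyntheticSpec:
    """Generator settings for synthetic localized facial-motion data.

    Each class is a set of Gaussian displacement bumps ("motion loci") given
    as (row_frac, col_frac, radius_frac, direction_angle_rad). Subjects add a
    small random affine perturbation of the flow so leave-one-subject-out
    generalisation is non-trivial; i.i.d. noise is added per pixel.
    """

    n_classes: int = 3
    motion_loci: Optional[list] = None
    amplitude: float = 2.0         # px at the locus centre
    n_subjects: int = 10
    samples_per_class: Sequence = (30, 30, 30)
    subject_effect_sd: float = 0.2  # px, ~10% of amplitude
    noise_sd: float = 0.2           # px
    seq_len: int = 20
    apex_frac: float = 0.6
    image_size: tuple = (170, 140)
    triplet_size: int = 28
    seed: int = 0

    def __post_init__(self) -> None:
        self.samples_per_class = list(self.samples_per_class)
        if len(self.samples_per_class) != self.n_classes:
            raise InputError("samples_per_class must have one entry per class")
        if sum(self.samples_per_class) < self.n_subjects:
            raise InputError("need at least as many samples as subjects")
        if self.amplitude < 0:
            raise InputError("amplitude must be >= 0")
        if not (0 < self.apex_frac < 1):
            raise InputError("apex_frac must lie in (0, 1)")
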