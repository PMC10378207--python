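"""Synthetic micro-motion data with the structure the method assumes.

Real micro-expression clips are short sequences of a nearly static face in
which one or two small regions (mouth corner, brow) undergo a smooth,
low-amplitude displacement that ramps up to an apex frame and decays again.
The generator emulates exactly that structure:

* each class is a set of Gaussian displacement bumps ("motion loci") with a
  fixed direction — distinct loci make classes geometrically separable, the
  way action units separate emotion categories;
* each subject perturbs the class flow with a small random affine warp, so
  held-out subjects are genuinely out-of-distribution for a LOSO fold;
* pixel-level i.i.d. Gaussian noise models sensor/registration error;
* frame sequences warp a smooth random texture (Gaussian-filtered white
  noise, which gives a dense-flow solver traction everywhere) by the class
  flow scaled with a tent ramp peaking at the ground-truth apex.

Class imbalance is controlled through ``samples_per_class``.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .preprocess import flow_to_triplet, optical_strain
from .types import (
    FlowField,
    FlowTriplet,
    FrameSequence,
    InputError,
    SyntheticSpec,
    TripletDataset,
)

__all__ = ["default_loci", "make_flow_sample", "make_sequence",
           "make_dataset", "true_apex_index", "nearest_template_loso"]

# (row_frac, col_frac, radius_frac, direction_angle_rad) per locus; angles
# measured from +x (rightward), y down. Loci sit where facial action units
# live on a cropped face (mouth, brows, cheeks, chin, forehead). Facial
# actions are roughly bilaterally symmetric, so each class is chosen to be
# invariant as a set under horizontal mirroring (midline loci with vertical
# motion, or symmetric left/right pairs with mirrored directions): the
# horizontal-flip augmentation then preserves class identity instead of
# mapping one class onto another.
_LOCI_BANK = [
    [(0.78, 0.50, 0.12, np.pi / 2)],                      # mouth, downward
    [(0.25, 0.30, 0.10, -np.pi / 2),
     (0.25, 0.70, 0.10, -np.pi / 2)],                     # both brows, upward
    [(0.55, 0.35, 0.11, np.pi),
     (0.55, 0.65, 0.11, 0.0)],                            # cheeks, outward
    [(0.40, 0.50, 0.10, np.pi / 2)],                      # nose bridge, down
    [(0.78, 0.30, 0.09, 3 * np.pi / 4),
     (0.78, 0.70, 0.09, np.pi / 4)],                      # mouth corners, down-out
    [(0.90, 0.50, 0.09, -np.pi / 2)],                     # chin, upward
    [(0.10, 0.50, 0.10, np.pi / 2)],                      # forehead, downward
]


def default_loci(n_classes: int) -> list:
    """Per-class motion loci drawn from a fixed bank of facial regions."""
    if n_classes > len(_LOCI_BANK):
        raise InputError(f"at most {len(_LOCI_BANK)} default classes available")
    return [list(_LOCI_BANK[c]) for c in range(n_classes)]


def _loci(spec: SyntheticSpec) -> list:
    return spec.motion_loci if spec.motion_loci is not None else default_loci(
        spec.n_classes)


def _subject_rng(spec: SyntheticSpec, subject: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(1, subject)))


def _subject_affine(spec: SyntheticSpec, subject: int) -> np.ndarray:
    """Per-subject affine flow perturbation coefficients (2 x 3).

    Produces an additive flow  du = a00*xn + a01*yn + a02  (and likewise dv)
    with xn, yn in [-1, 1]; coefficients are N(0, subject_effect_sd) and
    fixed per subject, so all of a subject's samples share the same bias.
    """
    rng = _subject_rng(spec, subject)
    return rng.normal(0.0, spec.subject_effect_sd, size=(2, 3))


def class_flow(spec: SyntheticSpec, cls: int) -> Tuple[np.ndarray, np.ndarray]:
    """Noise-free class-template flow field (u, v) at ``spec.image_size``."""
    if not (0 <= cls < spec.n_classes):
        raise InputError(f"class {cls} outside [0, {spec.n_classes})")
    h, w = spec.image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    u = np.zeros((h, w))
    v = np.zeros((h, w))
    for (rf, cf, radf, ang) in _loci(spec)[cls]:
        r0, c0 = rf * (h - 1), cf * (w - 1)
        sigma = radf * min(h, w)
        bump = np.exp(-(((yy - r0) ** 2 + (xx - c0) ** 2) / (2 * sigma ** 2)))
        u += spec.amplitude * np.cos(ang) * bump
        v += spec.amplitude * np.sin(ang) * bump
    return u, v


def make_flow_sample(spec: SyntheticSpec, cls: int, subject: int,
                     rng: np.random.Generator
                     ) -> Tuple[FlowField, FlowTriplet]:
    """One sample's ground-truth flow and its preprocessed triplet."""
    u, v = class_flow(spec, cls)
    h, w = spec.image_size
    if spec.subject_effect_sd > 0:
        a = _subject_affine(spec, subject)
        yn = np.linspace(-1, 1, h)[:, None]
        xn = np.linspace(-1, 1, w)[None, :]
        u = u + a[0, 0] * xn + a[0, 1] * yn + a[0, 2]
        v = v + a[1, 0] * xn + a[1, 1] * yn + a[1, 2]
    if spec.noise_sd > 0:
        u = u + rng.normal(0.0, spec.noise_sd, size=(h, w))
        v = v + rng.normal(0.0, spec.noise_sd, size=(h, w))
    flow = FlowField(u=u, v=v)
    triplet = flow_to_triplet(flow, optical_strain(flow), size=spec.triplet_size)
    return flow, triplet


def true_apex_index(spec: SyntheticSpec) -> int:
    return int(round(spec.apex_frac * (spec.seq_len - 1)))


def _warp(img: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Inverse bilinear warp: out(p) = img(p - flow(p)), border replicated."""
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    return map_coordinates(img, [yy - v, xx - u], order=1, mode="nearest")


def make_sequence(spec: SyntheticSpec, cls: int, subject: int,
                  rng: np.random.Generator) -> FrameSequence:
    """A frame sequence whose motion tents up to a known apex frame.

    Frame t warps a fixed smooth random texture by ramp(t) times the class
    flow, with ramp rising linearly from 0 at the onset (frame 0) to 1 at
    the apex and back to 0 at the final frame.
    """
    if spec.seq_len < 5:
        raise InputError("seq_len must be >= 5")
    u, v = class_flow(spec, cls)
    if spec.noise_sd > 0:
        u = u + rng.normal(0.0, spec.noise_sd, size=u.shape)
        v = v + rng.normal(0.0, spec.noise_sd, size=v.shape)
    base = gaussian_filter(rng.standard_normal(spec.image_size), sigma=2.0)
    base = (base - base.min()) / (base.max() - base.min())
    apex = true_apex_index(spec)
    n = spec.seq_len
    frames = []
    for t in range(n):
        if t <= apex:
            ramp = t / apex if apex > 0 else 0.0
        else:
            ramp = (n - 1 - t) / (n - 1 - apex)
        if ramp == 0.0 or spec.amplitude == 0.0:
            frames.append(base.copy())
        else:
            frames.append(_warp(base, ramp * u, ramp * v))
    return FrameSequence(frames=frames, subject_id=f"s{subject:02d}",
                         onset_idx=0, apex_idx=apex, offset_idx=n - 1)


def make_dataset(spec: SyntheticSpec) -> TripletDataset:
    """Full reproducible dataset: triplets, labels, subjects, sample ids.

    Samples are assigned to subjects round-robin across the concatenated
    per-class lists, so every subject sees a mix of classes; counts per
    class are exactly ``spec.samples_per_class``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed,
                                                       spawn_key=(0,)))
    X, y, subjects, ids = [], [], [], []
    counter = 0
    for cls, count in enumerate(spec.samples_per_class):
        for j in range(count):
            subject = counter % spec.n_subjects
            _, triplet = make_flow_sample(spec, cls, subject, rng)
            X.append(triplet.channels)
            y.append(cls)
            subjects.append(f"s{subject:02d}")
            ids.append(f"c{cls}_{j:03d}")
            counter += 1
    vocab = [f"class{c}" for c in range(spec.n_classes)]
    return TripletDataset(X=np.stack(X), y=np.array(y),
                          subjects=np.array(subjects),
                          sample_ids=np.array(ids), label_vocab=vocab)


def nearest_template_loso(data: TripletDataset) -> float:
    """LOSO accuracy of a cosine nearest-class-template classifier.

    Per fold, class templates are the mean triplets of the training
    subjects; each test sample is assigned to the template with the highest
    cosine similarity. A high score certifies that the generated benchmark
    is separable, i.e. that network-training results on it are meaningful.
    """
    correct = 0
    flat = data.X.reshape(len(data), -1).astype(np.float64)
    for subj in np.unique(data.subjects):
        mask = data.subjects == subj
        templates = []
        for c in range(len(data.label_vocab)):
            members = flat[(~mask) & (data.y == c)]
            templates.append(members.mean(axis=0) if len(members)
                             else np.zeros(flat.shape[1]))
        t = np.stack(templates)
        t = t / np.linalg.norm(t, axis=1, keepdims=True)
        q = flat[mask]
        q = q / np.linalg.norm(q, axis=1, keepdims=True)
        pred = np.argmax(q @ t.T, axis=1)
        correct += int(np.sum(pred == data.y[mask]))
    return correct / len(data)
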