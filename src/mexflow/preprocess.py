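"""Onset/apex preprocessing: apex spotting, dense optical flow, optical strain.

The pipeline turns a micro-expression clip into a compact motion summary:

1. locate the apex frame (if unannotated) by divide-and-conquer search over
   LBP-histogram differences in three facial regions of interest;
2. compute dense TV-L1 optical flow between the onset and apex frames;
3. derive the optical-strain magnitude, the norm of the symmetric gradient
   of the flow field, which emphasises fine local deformation;
4. min-max normalise (u, v, os) per channel and resize to a small square
   triplet that the network consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d
from skimage.registration import optical_flow_tvl1
from skimage.transform import resize

from .types import (
    FlowField,
    FlowTriplet,
    FrameSequence,
    InputError,
    RoiSpec,
    StrainMap,
)

__all__ = [
    "compute_optical_flow",
    "optical_strain",
    "flow_to_triplet",
    "lbp_histogram",
    "chi2_distance",
    "locate_apex",
    "preprocess_sample",
    "PreprocessConfig",
    "DegenerateSignalWarning",
    "N_LBP_BINS",
    "FRAME_SIZE",
]

FRAME_SIZE = (170, 140)  # (rows, cols) all face crops are resized to before flow


class DegenerateSignalWarning(UserWarning):
    """Apex spotting ran on a sequence with no measurable texture change."""


@dataclass
class PreprocessConfig:
    triplet_size: int = 28
    frame_size: tuple = FRAME_SIZE
    rois: RoiSpec = field(default_factory=RoiSpec)
    flow_params: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# optical flow and strain
# --------------------------------------------------------------------------

def compute_optical_flow(onset: np.ndarray, apex: np.ndarray,
                         params: Optional[dict] = None) -> FlowField:
    """Dense TV-L1 optical flow from ``onset`` to ``apex``.

    Returns a :class:`FlowField` with ``u`` the horizontal (+right) and ``v``
    the vertical (+down) per-pixel displacement. TV-L1 minimises an L1 data
    term under a total-variation prior, which preserves motion edges and is
    robust to the small displacements typical of micro-expressions; an image
    pair with no texture therefore yields the zero field.
    """
    onset = np.asarray(onset, dtype=np.float64)
    apex = np.asarray(apex, dtype=np.float64)
    if onset.shape != apex.shape:
        raise InputError(
            f"onset and apex shapes differ: {onset.shape} vs {apex.shape}"
        )
    if onset.ndim != 2:
        raise InputError("expected 2-D grayscale images")
    if not (np.all(np.isfinite(onset)) and np.all(np.isfinite(apex))):
        raise InputError("images contain non-finite values")
    if np.ptp(onset) == 0 and np.ptp(apex) == 0:
        # no texture: the TV prior selects the zero minimiser
        z = np.zeros_like(onset)
        return FlowField(u=z, v=z.copy())
    # skimage returns (row, col) displacement such that
    # apex[r, c] ~= onset[r - v, c - u]; rows are v, cols are u.
    v, u = optical_flow_tvl1(onset, apex, **(params or {}))
    return FlowField(u=u.astype(np.float64), v=v.astype(np.float64))


def optical_strain(flow: FlowField) -> StrainMap:
    """Optical-strain magnitude of a flow field.

    The strain tensor is the symmetric part of the flow Jacobian,
    eps = 1/2 (grad Of + grad Of^T) with Of = [u, v]^T, evaluated by central
    finite differences (one-sided at the borders). The scalar map returned is

        os = sqrt(eps_xx^2 + eps_yy^2 + 2 * eps_xy^2)

    i.e. the Frobenius norm of eps with both off-diagonal entries counted.
    A rigid translation (constant u, v) has zero strain everywhere.
    """
    h, w = flow.shape
    if h < 3 or w < 3:
        raise InputError("flow field must be at least 3x3 for finite differences")
    # np.gradient: axis 0 = rows (y), axis 1 = cols (x)
    du_dy, du_dx = np.gradient(flow.u)
    dv_dy, dv_dx = np.gradient(flow.v)
    e_xx = du_dx
    e_yy = dv_dy
    e_xy = 0.5 * (du_dy + dv_dx)
    os_mag = np.sqrt(e_xx ** 2 + e_yy ** 2 + 2.0 * e_xy ** 2)
    return StrainMap(os=os_mag)


def _minmax01(channel: np.ndarray) -> np.ndarray:
    lo, hi = channel.min(), channel.max()
    if hi - lo == 0:
        return np.full_like(channel, 0.5)
    return (channel - lo) / (hi - lo)


def flow_to_triplet(flow: FlowField, strain: StrainMap, size: int = 28) -> FlowTriplet:
    """Assemble the (u, v, os) channels into a normalized ``size``x``size`` triplet.

    Each channel is independently min-max scaled to [0, 1] and bilinearly
    resized. A constant channel (e.g. zero flow) maps to all 0.5, the
    midpoint of the target range.
    """
    if flow.shape != strain.shape:
        raise InputError(
            f"flow {flow.shape} and strain {strain.shape} shapes differ"
        )
    out = np.empty((3, size, size), dtype=np.float64)
    for i, chan in enumerate((flow.u, flow.v, strain.os)):
        norm = _minmax01(chan)
        if norm.shape != (size, size):
            norm = resize(norm, (size, size), order=1, mode="edge",
                          anti_aliasing=False, preserve_range=True)
        out[i] = np.clip(norm, 0.0, 1.0)
    return FlowTriplet(channels=out.astype(np.float32))


# --------------------------------------------------------------------------
# LBP / apex spotting
# --------------------------------------------------------------------------

N_LBP_BINS = 59

# map from 8-bit LBP code to 59-bin index: the 58 uniform patterns
# (<= 2 bit transitions on the circle) in increasing code order, then one
# shared bin for all non-uniform codes.


def _build_uniform_lut() -> np.ndarray:
    lut = np.empty(256, dtype=np.int64)
    uniform = []
    for code in range(256):
        bits = [(code >> i) & 1 for i in range(8)]
        transitions = sum(bits[i] != bits[(i + 1) % 8] for i in range(8))
        if transitions <= 2:
            uniform.append(code)
    index = {c: i for i, c in enumerate(uniform)}
    for code in range(256):
        lut[code] = index.get(code, len(uniform))
    assert len(uniform) == 58
    return lut


_UNIFORM_LUT = _build_uniform_lut()

# neighbour offsets in circular order starting east, counter-clockwise in
# image coordinates (east, north-east, north, ...); bit i of the code is
# neighbour i. The square 8-neighbourhood is used (radius-1 ring).
_NEIGHBOURS = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]


def lbp_histogram(region: np.ndarray) -> np.ndarray:
    """Normalized 59-bin uniform LBP(8, 1) histogram of a grayscale region.

    Each interior pixel is compared with its 8 immediate neighbours
    (neighbour >= centre sets the bit); codes with at most two 0/1
    transitions around the ring fall into 58 dedicated uniform bins, all
    remaining codes share one bin. The histogram sums to 1.
    """
    region = np.asarray(region, dtype=np.float64)
    if region.ndim != 2 or region.shape[0] < 3 or region.shape[1] < 3:
        raise InputError("region must be a 2-D image of at least 3x3 pixels")
    centre = region[1:-1, 1:-1]
    codes = np.zeros(centre.shape, dtype=np.int64)
    for bit, (dr, dc) in enumerate(_NEIGHBOURS):
        neigh = region[1 + dr: region.shape[0] - 1 + dr,
                       1 + dc: region.shape[1] - 1 + dc]
        codes |= (neigh >= centre).astype(np.int64) << bit
    binned = _UNIFORM_LUT[codes]
    hist = np.bincount(binned.ravel(), minlength=N_LBP_BINS).astype(np.float64)
    return hist / hist.sum()


def chi2_distance(h1: np.ndarray, h2: np.ndarray) -> float:
    """Chi-squared distance between two normalized histograms."""
    h1 = np.asarray(h1, dtype=np.float64)
    h2 = np.asarray(h2, dtype=np.float64)
    if h1.shape != h2.shape:
        raise InputError("histograms must have equal length")
    return float(np.sum((h1 - h2) ** 2 / (h1 + h2 + 1e-10)))


def _roi_difference_signal(seq: FrameSequence, rois: RoiSpec) -> np.ndarray:
    """d[r, t] = chi2 distance of ROI r's LBP histogram at frame t vs frame 0."""
    boxes = rois.boxes()
    ref = [lbp_histogram(rois.crop(seq.frames[0], b)) for b in boxes]
    d = np.zeros((len(boxes), len(seq)))
    for t in range(1, len(seq)):
        for r, b in enumerate(boxes):
            d[r, t] = chi2_distance(lbp_histogram(rois.crop(seq.frames[t], b)), ref[r])
    return d


def _dc_search(signal: np.ndarray, lo: int, hi: int) -> int:
    """Divide-and-conquer argmax: recurse into the half with larger mean."""
    if hi - lo + 1 <= 3:
        window = signal[lo: hi + 1]
        return lo + int(np.argmax(window))  # argmax ties -> lower index
    mid = (lo + hi) // 2
    left_mean = signal[lo: mid + 1].mean()
    right_mean = signal[mid + 1: hi + 1].mean()
    if left_mean >= right_mean:
        return _dc_search(signal, lo, mid)
    return _dc_search(signal, mid + 1, hi)


def locate_apex(seq: FrameSequence, rois: Optional[RoiSpec] = None) -> int:
    """Locate the apex (maximal facial action) frame of a clip.

    Texture change is measured per frame as the chi-squared distance of each
    ROI's uniform-LBP histogram from frame 0; the ROI with the largest peak
    difference is selected, and its difference signal is searched by
    divide-and-conquer: the index range is halved toward the half with the
    larger mean difference until at most three frames remain. The search
    runs on a width-3 moving average of the signal — frame noise produces
    local dips that can steer the half-mean decision away from a peak
    sitting next to a split point — and the returned index is refined to
    the raw signal's argmax within one frame of the search result.
    """
    if len(seq) < 3:
        raise InputError("apex spotting needs at least 3 frames")
    rois = rois or RoiSpec()
    d = _roi_difference_signal(seq, rois)
    if np.allclose(d, 0):
        warnings.warn("no texture change between frames; apex is arbitrary",
                      DegenerateSignalWarning, stacklevel=2)
        return 1
    r_star = int(np.argmax(d.max(axis=1)))
    raw = d[r_star]
    # frame 0's difference is identically zero by construction, not data;
    # keep it out of the smoothing window
    smooth = np.concatenate(
        [[0.0], uniform_filter1d(raw[1:], size=3, mode="nearest")])
    # frame 0 is the reference (difference 0 by construction); search 1..n-1
    coarse = _dc_search(smooth, 1, len(seq) - 1)
    lo = max(1, coarse - 1)
    hi = min(len(seq) - 1, coarse + 1)
    return lo + int(np.argmax(raw[lo: hi + 1]))


# --------------------------------------------------------------------------
# composition
# --------------------------------------------------------------------------

def preprocess_sample(seq: FrameSequence,
                      cfg: Optional[PreprocessConfig] = None) -> FlowTriplet:
    """Full preprocessing of one clip: apex -> flow -> strain -> triplet.

    Frames are resized to ``cfg.frame_size`` (default 170x140) before flow is
    computed; the apex is located automatically when the sequence carries no
    apex annotation.
    """
    cfg = cfg or PreprocessConfig()
    apex_idx = seq.apex_idx
    if apex_idx is None:
        apex_idx = locate_apex(seq, cfg.rois)
    onset = seq.frames[seq.onset_idx]
    apex = seq.frames[apex_idx]
    if onset.shape != tuple(cfg.frame_size):
        onset = resize(onset, cfg.frame_size, order=1, mode="edge",
                       anti_aliasing=True, preserve_range=True)
        apex = resize(apex, cfg.frame_size, order=1, mode="edge",
                      anti_aliasing=True, preserve_range=True)
    flow = compute_optical_flow(onset, apex, cfg.flow_params)
    strain = optical_strain(flow)
    return flow_to_triplet(flow, strain, size=cfg.triplet_size)
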