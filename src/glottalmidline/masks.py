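"""Render glottal outlines into binary segmentation-mask sequences.

The pipeline mirrors what real high-speed videoendoscopy segmentation
produces: polygon outlines from the six-mass model are corner-smoothed
(Chaikin), rasterized onto a pixel canvas, roughened with contour noise
(each boundary pixel dropped with probability ``p``), and optionally
subjected to rigid motion (rotation/translation) emulating examination
motion, with the ground-truth midline transformed consistently.

Pixel convention: origin top-left, x rightward (columns), y downward
(rows); the pixel at ``mask[r, c]`` has center ``(x, y) = (c, r)``.
The posterior point is the smaller-y end of the midline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as _MplPath
from scipy import ndimage

from .sixmass import SimulationConfig, TrajectorySet, outline_from_state

__all__ = [
    "MaskSequence",
    "RigidMotion",
    "AnnotationError",
    "chaikin_smooth",
    "rasterize",
    "pa_transform",
    "add_contour_noise",
    "apply_motion",
    "sample_motion",
    "render_sequence",
    "read_annotations",
    "write_annotations",
]

DEFAULT_CANVAS = (256, 256)
#: Fraction of the image height spanned by the posterior-anterior axis.
DEFAULT_PA_SPAN = 0.6


class AnnotationError(ValueError):
    """Malformed keypoint annotation file."""


@dataclass
class MaskSequence:
    """Binary mask stack with per-frame ground-truth midline.

    ``gt_midline[t]`` is ``[[x_P, y_P], [x_A, y_A]]`` in pixel
    coordinates.
    """

    masks: np.ndarray                   # [T, H, W] uint8 in {0, 1}
    gt_midline: np.ndarray              # [T, 2, 2]
    frame_rate: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks)
        self.gt_midline = np.asarray(self.gt_midline, dtype=float)
        if self.masks.ndim != 3:
            raise ValueError("masks must be [T, H, W]")
        if self.gt_midline.shape != (len(self.masks), 2, 2):
            raise ValueError("gt_midline must be [T, 2, 2]")
        vals = np.unique(self.masks)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("masks must be binary {0, 1}")
        H, W = self.masks.shape[1:]
        xy = self.gt_midline.reshape(-1, 2)
        if (xy[:, 0].min() < 0 or xy[:, 0].max() > W - 1
                or xy[:, 1].min() < 0 or xy[:, 1].max() > H - 1):
            raise ValueError("gt_midline endpoints outside image bounds")

    def __len__(self) -> int:
        return len(self.masks)


@dataclass
class RigidMotion:
    """Rigid in-plane motion applied identically to masks and midline."""

    base_rotation: float = 0.0          # degrees, static per sequence
    translations: np.ndarray | None = None   # [T, 2] px (dx, dy) per frame
    rotation_jitter: np.ndarray | None = None  # [T] degrees per frame

    def __post_init__(self) -> None:
        if not -30.0 <= self.base_rotation <= 30.0:
            raise ValueError("base_rotation must be within [-30, 30] degrees")

    def frame_params(self, t: int) -> tuple[float, np.ndarray]:
        ang = self.base_rotation
        if self.rotation_jitter is not None:
            ang += float(self.rotation_jitter[t])
        d = (np.zeros(2) if self.translations is None
             else np.asarray(self.translations[t], dtype=float))
        return ang, d


def chaikin_smooth(polygon: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Chaikin's corner cutting on a closed polygon.

    Each iteration replaces every edge's endpoints by the points at 1/4
    and 3/4 along the edge; the vertex count doubles per iteration and
    the result stays within the convex hull of the input.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    poly = np.asarray(polygon, dtype=float)
    # collapse consecutive duplicates (closed-glottis anchors coincide)
    keep = np.any(poly != np.roll(poly, 1, axis=0), axis=1)
    poly = poly[keep] if keep.any() else poly[:1]
    if len(np.unique(poly, axis=0)) < 3:
        raise ValueError("polygon needs >= 3 distinct vertices")
    for _ in range(iterations):
        nxt = np.roll(poly, -1, axis=0)
        q = 0.75 * poly + 0.25 * nxt
        r = 0.25 * poly + 0.75 * nxt
        poly = np.empty((2 * len(poly), 2))
        poly[0::2] = q
        poly[1::2] = r
    return poly


def pa_transform(shape=DEFAULT_CANVAS, span: float = DEFAULT_PA_SPAN):
    """Scale/offset placing the unit posterior-anterior axis on a canvas.

    Returns ``(scale, offset)`` such that ``px = model * scale + offset``
    maps the model midline (x=0, y in [0, 1]) to a vertical segment
    spanning ``span`` of the image height, horizontally centered.
    """
    H, W = shape
    scale = span * H
    # (W-1)/2 is the pixel-grid center; placing the axis exactly on a
    # pixel-center column would make every on-axis pixel an exact tie
    # in the left/right split
    offset = np.array([(W - 1) / 2.0, (1.0 - span) / 2.0 * H])
    return scale, offset


def rasterize(polygon: np.ndarray, shape=DEFAULT_CANVAS,
              scale: float = 1.0, offset=(0.0, 0.0)) -> np.ndarray:
    """Fill a polygon: pixels whose center lies inside (even-odd rule).

    The polygon is mapped to pixel coordinates via
    ``px = polygon * scale + offset`` first.  A polygon entirely outside
    the canvas yields an all-zero mask with a warning.
    """
    H, W = shape
    poly = np.asarray(polygon, dtype=float) * scale + np.asarray(offset)
    mask = np.zeros(shape, dtype=np.uint8)
    if len(poly) < 3:
        return mask
    x0 = max(int(np.floor(poly[:, 0].min())), 0)
    x1 = min(int(np.ceil(poly[:, 0].max())), W - 1)
    y0 = max(int(np.floor(poly[:, 1].min())), 0)
    y1 = min(int(np.ceil(poly[:, 1].max())), H - 1)
    if x1 < x0 or y1 < y0:
        warnings.warn("polygon entirely outside canvas; returning empty mask")
        return mask
    xs = np.arange(x0, x1 + 1)
    ys = np.arange(y0, y1 + 1)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    # Path(closed=True) treats the final vertex as the CLOSEPOLY
    # placeholder, so the first vertex must be appended explicitly
    path = _MplPath(np.vstack([poly, poly[:1]]), closed=True)
    inside = path.contains_points(pts)
    mask[y0:y1 + 1, x0:x1 + 1] = inside.reshape(gy.shape)
    return mask


def contour_pixels(mask: np.ndarray) -> np.ndarray:
    """Boolean map of foreground pixels with an 8-connected background
    neighbour (image border counts as background)."""
    fg = mask.astype(bool)
    eroded = ndimage.binary_erosion(fg, structure=np.ones((3, 3)),
                                    border_value=0)
    return fg & ~eroded


def add_contour_noise(mask: np.ndarray, p: float,
                      rng_seed: int | np.random.Generator) -> np.ndarray:
    """Drop each boundary pixel to background with probability ``p``.

    Only the 8-connected foreground boundary may flip; the interior is
    untouched.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    out = mask.copy()
    contour = contour_pixels(mask)
    idx = np.flatnonzero(contour.ravel())
    flip = idx[rng.random(len(idx)) < p]
    out.ravel()[flip] = 0
    return out


def _rigid_maps(angle_deg: float, translation: np.ndarray, shape):
    """Forward map p' = R (p - c) + c + d in (x, y) and its inverse
    matrix/offset in (row, col) for scipy.ndimage.affine_transform."""
    H, W = shape
    c = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
    th = np.deg2rad(angle_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])

    def fwd(pts):
        return (np.asarray(pts, dtype=float) - c) @ R.T + c + translation

    Rinv = R.T
    # output (row, col) -> input (row, col): swap axes of the xy map
    M = np.array([[Rinv[1, 1], Rinv[1, 0]], [Rinv[0, 1], Rinv[0, 0]]])
    off_xy = c - Rinv @ (c + translation)
    off = off_xy[::-1]
    return fwd, M, off


def _nn_gather(angle_deg: float, translation: np.ndarray, shape):
    """Nearest-neighbour source indices for the inverse rigid map."""
    H, W = shape
    _, M, off = _rigid_maps(angle_deg, translation, shape)
    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    src_r = M[0, 0] * rr + M[0, 1] * cc + off[0]
    src_c = M[1, 0] * rr + M[1, 1] * cc + off[1]
    ri = np.rint(src_r).astype(np.intp)
    ci = np.rint(src_c).astype(np.intp)
    valid = (ri >= 0) & (ri < H) & (ci >= 0) & (ci < W)
    return ri.clip(0, H - 1), ci.clip(0, W - 1), valid


def apply_motion(seq: MaskSequence, motion: RigidMotion,
                 rng_seed: int = 0) -> MaskSequence:
    """Rotate/translate every frame about the image center.

    Masks are resampled nearest-neighbour (stay binary); the
    ground-truth midline is transformed by the same rigid map.  Raises
    if a transformed midline endpoint leaves the canvas.
    """
    shape = seq.masks.shape[1:]
    out_mid = np.empty_like(seq.gt_midline)
    H, W = shape
    static = motion.translations is None and motion.rotation_jitter is None
    if static:
        ang, d = motion.frame_params(0)
        fwd, _, _ = _rigid_maps(ang, d, shape)
        ri, ci, valid = _nn_gather(ang, d, shape)
        out_masks = seq.masks[:, ri, ci]
        out_masks[:, ~valid] = 0
    else:
        out_masks = np.empty_like(seq.masks)
        for t in range(len(seq)):
            ang, d = motion.frame_params(t)
            ri, ci, valid = _nn_gather(ang, d, shape)
            out_masks[t] = seq.masks[t, ri, ci]
            out_masks[t][~valid] = 0
    for t in range(len(seq)):
        ang, d = motion.frame_params(t)
        fwd, _, _ = _rigid_maps(ang, d, shape)
        mid = fwd(seq.gt_midline[t])
        if (mid[:, 0].min() < 0 or mid[:, 0].max() > W - 1
                or mid[:, 1].min() < 0 or mid[:, 1].max() > H - 1):
            raise ValueError(
                f"midline transformed outside canvas at frame {t}; "
                "use a smaller rotation/translation")
        out_mid[t] = mid
    prov = dict(seq.provenance)
    prov["motion"] = {
        "base_rotation": motion.base_rotation,
        "has_translation": motion.translations is not None,
        "has_jitter": motion.rotation_jitter is not None,
    }
    return MaskSequence(out_masks, out_mid, seq.frame_rate, prov)


def sample_motion(rng_seed: int | np.random.Generator, n_frames: int,
                  frame_rate: float,
                  rotation_range: float = 30.0,
                  translation_amplitude: float = 0.0,
                  translation_freq: float = 10.0) -> RigidMotion:
    """Random per-sequence motion: static base rotation uniform in
    ``[-rotation_range, rotation_range]`` degrees plus optional slow
    sinusoidal translation over time (examination motion artifacts).

    Translation amplitude per axis is uniform in
    ``[0, translation_amplitude]`` px with frequency uniform in
    ``[0, translation_freq]`` Hz and random phase.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    base = rng.uniform(-rotation_range, rotation_range)
    translations = None
    if translation_amplitude > 0:
        t = np.arange(n_frames) / frame_rate
        phase = rng.uniform(0, 2 * np.pi, size=2)
        amp = rng.uniform(0, translation_amplitude, size=2)
        freq = rng.uniform(0, translation_freq, size=2)
        translations = np.column_stack([
            amp[0] * np.sin(2 * np.pi * freq[0] * t + phase[0]),
            amp[1] * np.sin(2 * np.pi * freq[1] * t + phase[1])])
    return RigidMotion(base_rotation=base, translations=translations)


def render_sequence(traj: TrajectorySet, config: SimulationConfig,
                    rng_seed: int | np.random.Generator,
                    shape=DEFAULT_CANVAS, pa_span: float = DEFAULT_PA_SPAN,
                    chaikin_iterations: int = 2,
                    contour_noise_p: float = 0.5) -> MaskSequence:
    """Rasterize a simulated trajectory into a noisy mask sequence.

    Frames are sampled at ``config.frame_rate`` over the retained
    window.  The ground-truth midline maps the model p-a axis into
    pixel coordinates (identical for all frames; motion is applied
    separately via :func:`apply_motion`).
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    t0, t1 = traj.times[0], traj.times[-1]
    n_frames = int(np.floor((t1 - t0) * config.frame_rate)) + 1
    frame_times = t0 + np.arange(n_frames) / config.frame_rate
    outlines = outline_from_state(traj, config, frame_times)
    scale, offset = pa_transform(shape, pa_span)
    gt = np.array([[0.0, 0.0], [0.0, 1.0]]) * scale + offset

    masks = np.zeros((n_frames,) + tuple(shape), dtype=np.uint8)
    for t, outline in enumerate(outlines):
        try:
            poly = chaikin_smooth(outline.vertices, chaikin_iterations)
        except ValueError:          # fully closed glottis -> empty frame
            continue
        m = rasterize(poly, shape, scale, offset)
        if contour_noise_p > 0:
            m = add_contour_noise(m, contour_noise_p, rng)
        masks[t] = m
    prov = {"config": config, "chaikin_iterations": chaikin_iterations,
            "contour_noise_p": contour_noise_p, "pa_span": pa_span}
    return MaskSequence(masks, np.tile(gt, (n_frames, 1, 1)),
                        config.frame_rate, prov)


def write_annotations(seq_or_midlines, path) -> None:
    """Write per-frame P/A keypoints as JSON.

    Schema: a list with one record per frame,
    ``{"posterior": [x, y], "anterior": [x, y]}``.
    """
    mid = (seq_or_midlines.gt_midline
           if isinstance(seq_or_midlines, MaskSequence)
           else np.asarray(seq_or_midlines, dtype=float))
    records = [{"posterior": [float(p[0]), float(p[1])],
                "anterior": [float(a[0]), float(a[1])]}
               for p, a in mid]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


def read_annotations(path) -> np.ndarray:
    """Read per-frame P/A keypoints; returns [T, 2, 2] (P then A)."""
    with open(path) as fh:
        try:
            records = json.load(fh)
        except json.JSONDecodeError as e:
            raise AnnotationError(f"not valid JSON: {e}") from e
    if not isinstance(records, list) or not records:
        raise AnnotationError("annotation file must be a non-empty list")
    out = np.empty((len(records), 2, 2))
    for t, rec in enumerate(records):
        if not isinstance(rec, dict):
            raise AnnotationError(f"frame {t}: record is not an object")
        missing = [k for k in ("posterior", "anterior") if k not in rec]
        if missing:
            raise AnnotationError(
                f"frame {t}: missing key(s) {', '.join(missing)}")
        for j, key in enumerate(("posterior", "anterior")):
            xy = rec[key]
            if not (isinstance(xy, (list, tuple)) and len(xy) == 2):
                raise AnnotationError(f"frame {t}: {key} must be [x, y]")
            out[t, j] = xy
    return out
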