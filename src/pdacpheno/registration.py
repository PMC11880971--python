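"""Rigid alignment of serial-section channel masks.

Serial sections of the same tumor are cut a few μm apart, so their tissue
footprints are nearly identical but each slide lands on the scanner with its
own offset and small rotation. A rigid transform (translation + rotation) is
enough to bring the binary masks of one slide into the frame of a reference
slide; the deformable residual of real tissue is out of scope here.

Convention: a :class:`RigidTransform` maps *moving* coordinates into *fixed*
coordinates, ``p_fixed = R(theta) @ p_moving + (dx, dy)``, with points as
(x, y) = (column, row), origin at the top-left pixel corner, rotation about
the origin, theta counter-clockwise in degrees. Any rotation about another
center is representable by absorbing the difference into (dx, dy).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage, signal


@dataclass(frozen=True)
class RigidTransform:
    dx: float
    dy: float
    theta: float = 0.0  # degrees, CCW, about the origin

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.dx, self.dy, self.theta)):
            raise ValueError("transform parameters must be finite")
        if not -180.0 < self.theta <= 180.0:
            raise ValueError("theta must lie in (-180, 180]")

    @property
    def matrix(self) -> np.ndarray:
        """2x2 rotation matrix acting on (x, y) column vectors."""
        t = math.radians(self.theta)
        c, s = math.cos(t), math.sin(t)
        return np.array([[c, -s], [s, c]])

    @property
    def is_identity(self) -> bool:
        return self.dx == self.dy == self.theta == 0.0

    def inverse(self) -> "RigidTransform":
        R = self.matrix
        t = -R.T @ np.array([self.dx, self.dy])
        theta = -self.theta
        if theta == -180.0:
            theta = 180.0
        return RigidTransform(float(t[0]), float(t[1]), theta)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying `other` first, then self."""
        R = self.matrix
        t = R @ np.array([other.dx, other.dy]) + np.array([self.dx, self.dy])
        theta = (self.theta + other.theta + 180.0) % 360.0 - 180.0
        if theta == -180.0:
            theta = 180.0
        return RigidTransform(float(t[0]), float(t[1]), theta)

    @classmethod
    def about_center(cls, dx: float, dy: float, theta: float,
                     center: tuple[float, float]) -> "RigidTransform":
        """Rotation by theta about `center` followed by (dx, dy) shift,
        re-expressed in the origin-centered convention."""
        t = math.radians(theta)
        c, s = math.cos(t), math.sin(t)
        cx, cy = center
        # p' = R (p - c) + c + d  =  R p + (c - R c + d)
        ox = cx - (c * cx - s * cy) + dx
        oy = cy - (s * cx + c * cy) + dy
        return cls(ox, oy, theta)

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps({"dx": self.dx, "dy": self.dy, "theta": self.theta})
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "RigidTransform":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(float(d["dx"]), float(d["dy"]), float(d.get("theta", 0.0)))


IDENTITY = RigidTransform(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SearchGrid:
    """Exhaustive search bounds for transform estimation."""

    max_shift: float = 50.0   # px, each axis
    shift_step: float = 1.0   # px
    max_theta: float = 5.0    # degrees
    theta_step: float = 0.5   # degrees
    refine: bool = True
    refine_step_px: float = 0.1
    refine_step_deg: float = 0.1

    def __post_init__(self) -> None:
        if self.max_shift < 0 or self.shift_step <= 0 or self.theta_step <= 0:
            raise ValueError("invalid search grid")

    @property
    def thetas(self) -> np.ndarray:
        if self.max_theta == 0:
            return np.array([0.0])
        n = int(round(self.max_theta / self.theta_step))
        return np.arange(-n, n + 1) * self.theta_step


def apply_transform_points(points: np.ndarray, t: RigidTransform) -> np.ndarray:
    """Apply a rigid transform to an (N, 2) array of (x, y) points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array of (x, y)")
    return pts @ t.matrix.T + np.array([t.dx, t.dy])


def apply_transform_mask(mask: np.ndarray, t: RigidTransform,
                         order: int = 0) -> np.ndarray:
    """Warp a 2-D mask so its content moves by `t` (moving → fixed frame).

    Nearest-neighbor by default, which keeps binary masks binary; boundary
    pixels may differ by resampling on round trips.
    """
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    inv = t.inverse()
    # ndimage maps output (row, col) -> input coords; ours act on (x, y).
    R = inv.matrix
    mat = np.array([[R[1, 1], R[1, 0]], [R[0, 1], R[0, 0]]])
    off = np.array([inv.dy, inv.dx])
    out = ndimage.affine_transform(m.astype(float), mat, offset=off,
                                   order=order, mode="constant", cval=0.0)
    if m.dtype == bool:
        return out >= 0.5
    return out.astype(m.dtype) if order == 0 else out


def apply_transform(obj: np.ndarray, t: RigidTransform, order: int = 0) -> np.ndarray:
    """Dispatch on shape: (N, 2) point sets exactly, 2-D masks by resampling."""
    arr = np.asarray(obj)
    if arr.ndim == 2 and arr.shape[1] == 2 and arr.shape[0] != arr.shape[1]:
        return apply_transform_points(arr, t)
    if arr.ndim == 2 and arr.shape == (2, 2):
        # ambiguous; treat as points
        return apply_transform_points(arr, t)
    return apply_transform_mask(arr, t, order=order)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def _rotate_about_center(mask: np.ndarray, theta: float) -> np.ndarray:
    if theta == 0.0:
        return np.asarray(mask, bool)
    center = ((mask.shape[1] - 1) / 2.0, (mask.shape[0] - 1) / 2.0)
    t = RigidTransform.about_center(0.0, 0.0, theta, center)
    return apply_transform_mask(np.asarray(mask, bool), t)


def _best_shift_fft(fixed: np.ndarray, moving: np.ndarray,
                    max_shift: float, step: float) -> tuple[int, int, float]:
    """Integer shift maximizing overlap count, via FFT cross-correlation."""
    f = np.asarray(fixed, float)
    m = np.asarray(moving, float)
    corr = signal.fftconvolve(f, m[::-1, ::-1], mode="full")
    # corr[i, j] = sum_{r,c} f[r, c] * m[r - (i - (H-1)), c - (j - (W-1))]
    H, W = m.shape
    rows = np.arange(corr.shape[0]) - (H - 1)  # dy candidates
    cols = np.arange(corr.shape[1]) - (W - 1)  # dx candidates
    rkeep = np.abs(rows) <= max_shift
    ckeep = np.abs(cols) <= max_shift
    if step > 1:
        rkeep &= (rows % int(step) == 0)
        ckeep &= (cols % int(step) == 0)
    sub = corr[np.ix_(rkeep, ckeep)]
    idx = np.unravel_index(np.argmax(sub), sub.shape)
    best = sub[idx]
    return int(cols[ckeep][idx[1]]), int(rows[rkeep][idx[0]]), float(best)


def _soft_dice(fixed: np.ndarray, moving: np.ndarray, t: RigidTransform) -> float:
    warped = apply_transform_mask(np.asarray(moving, float), t, order=1)
    f = np.asarray(fixed, float)
    denom = f.sum() + warped.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * (f * warped).sum() / denom)


def estimate_rigid_transform(
    fixed: np.ndarray,
    moving: np.ndarray,
    search: SearchGrid | None = None,
) -> tuple[RigidTransform, float]:
    """Estimate the rigid transform aligning `moving` onto `fixed`.

    Exhaustive grid search over rotations (about the image center) and
    integer translations (FFT cross-correlation of foreground), maximizing
    Dice overlap, followed by optional coordinate-wise hill climbing at
    sub-pixel / sub-degree resolution using bilinear interpolation.

    Returns the transform in moving→fixed convention and its Dice score.
    """
    search = search or SearchGrid()
    f = np.asarray(fixed, bool)
    m = np.asarray(moving, bool)
    if f.shape != m.shape:
        raise ValueError("fixed and moving masks must share shape")
    nf, nm = int(f.sum()), int(m.sum())
    if nf == 0 or nm == 0:
        raise ValueError("masks must each contain at least one positive pixel")

    center = ((f.shape[1] - 1) / 2.0, (f.shape[0] - 1) / 2.0)
    best: tuple[float, RigidTransform] | None = None
    for theta in search.thetas:
        rotated = _rotate_about_center(m, float(theta))
        n_rot = int(rotated.sum())
        if n_rot == 0:
            continue
        dx, dy, overlap = _best_shift_fft(f, rotated, search.max_shift,
                                          search.shift_step)
        score = 2.0 * overlap / (nf + n_rot)
        t = RigidTransform.about_center(dx, dy, float(theta), center)
        if best is None or score > best[0] + 1e-12:
            best = (score, t)
    if best is None:
        raise ValueError("search produced no candidate transform")

    score, t = best
    if search.refine:
        score, t = _hill_climb(f, m, t, center, search)
    return t, score


def _hill_climb(fixed, moving, t: RigidTransform, center, search: SearchGrid,
                max_iter: int = 40) -> tuple[float, RigidTransform]:
    """Coordinate-wise local refinement on soft (interpolated) Dice."""
    # re-express t as (shift, rotation-about-image-center) parameters:
    # origin offset o = c - R c + d  ⇒  d = o - c + R c
    rc = t.matrix @ np.asarray(center, float)
    params = np.array([
        t.dx - center[0] + rc[0],
        t.dy - center[1] + rc[1],
        t.theta,
    ])

    def build(p):
        return RigidTransform.about_center(p[0], p[1], p[2], center)

    cur = _soft_dice(fixed, moving, build(params))
    steps = np.array([search.refine_step_px, search.refine_step_px,
                      search.refine_step_deg])
    for _ in range(max_iter):
        improved = False
        for i in range(3):
            for sign in (+1, -1):
                cand = params.copy()
                cand[i] += sign * steps[i]
                if abs(cand[2]) > 180:
                    continue
                s = _soft_dice(fixed, moving, build(cand))
                if s > cur + 1e-9:
                    params, cur = cand, s
                    improved = True
        if not improved:
            break
    t_ref = build(params)
    hard = dice(fixed, apply_transform_mask(moving, t_ref))
    return hard, t_ref


def register_stack(stack, reference_slide: str | None = None,
                   search: SearchGrid | None = None):
    """Align every slide of a :class:`~pdacpheno.synthetic.SlideStack` to a
    reference slide using the per-slide tissue masks, and warp all channel
    masks accordingly.

    Returns ``(aligned_stack, transforms)`` where ``transforms[slide]`` maps
    that slide's frame into the reference frame.
    """
    slides = sorted(set(stack.channel_slide.values()))
    ref = reference_slide or slides[0]
    if ref not in stack.tissue:
        raise ValueError(f"unknown reference slide {ref!r}")
    fixed = stack.tissue[ref]
    transforms: dict[str, RigidTransform] = {}
    for s in slides:
        if s == ref:
            transforms[s] = IDENTITY
            continue
        t, _ = estimate_rigid_transform(fixed, stack.tissue[s], search)
        transforms[s] = t
    new_channels = {
        ch: apply_transform_mask(mask, transforms[stack.channel_slide[ch]])
        for ch, mask in stack.channels.items()
    }
    new_tissue = {s: apply_transform_mask(stack.tissue[s], transforms[s])
                  for s in slides}
    aligned = stack.with_masks(new_channels, new_tissue)
    return aligned, transforms
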