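"""Circle Hough transform detection with radial-symmetry scoring.

The detector runs in three stages:

1. :func:`edge_map` — 3x3 smoothing, central-difference gradients, and an
   edge mask thresholded on gradient magnitude.
2. :func:`hough_accumulate` — every edge pixel votes, weighted by gradient
   magnitude, at candidate centers +/- r along its gradient direction for
   every candidate radius r.  Voting in both polarities makes dark-on-bright
   rings and bright-on-dark spots share one code path.  Each radius slice is
   normalized by the ideal full-circle vote mass (2*pi*r pixels at unit
   weight) so a complete circle scores ~1 regardless of radius.
3. Peak proposal and radial-symmetry scoring inside :func:`find_circles` —
   accumulator local maxima are re-scored by the fraction of evenly spaced
   spokes on which the radial gradient profile has a strong, radially
   aligned maximum close to the candidate radius.  That support fraction is
   the detection score compared against the sensitivity threshold: it is 1
   for a full circle of the candidate size and degrades with missing arc or
   with a size mismatch, which is what rejects undersized debris and the
   lobes of oversized clumps.

Centers are pixel-grid points (origin at the top-left pixel center, x
rightward, y downward); results are reported in μm via the pixel size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates, maximum_filter, uniform_filter

from .config import DetectionParams
from .errors import ValidationError
from .image import ImageFrame

# Edge-mask threshold: a fraction of the strong-gradient scale (99.5th
# percentile), floored at a multiple of the median magnitude so pure noise
# frames do not flood the mask.
EDGE_REL_FRAC = 0.30
EDGE_MEDIAN_FLOOR = 6.0

# Proposal threshold on the normalized accumulator (generous: final
# acceptance is decided by the support score against the sensitivity).
PROPOSAL_SCORE = 0.35
MAX_CANDIDATES = 4000

# Radial support scoring.
N_SPOKES = 32
PROFILE_WINDOW_UM = 1.05  # half-width of the radial search window
PEAK_TOL_UM = 0.38  # max peak offset from the refined radius for a supporting spoke
ALIGN_COS = math.cos(math.radians(30.0))
RADIUS_GATE_SLACK_UM = 0.25  # refined radius may exceed the slice span by half a step


@dataclass(frozen=True)
class Detection:
    """One detected circular object (center and radius in μm)."""

    cx: float
    cy: float
    radius: float
    score: float
    modality: str


@dataclass(frozen=True)
class EdgeMap:
    """Per-pixel gradient field plus the binary edge mask."""

    mag: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    mask: np.ndarray
    threshold: float


def edge_map(image: ImageFrame | np.ndarray, edge_percentile: float | None = None) -> EdgeMap:
    """Gradient magnitude/direction and a binary edge mask.

    The image is smoothed with a 3x3 mean filter before central-difference
    gradients.  With ``edge_percentile`` (fraction in [0, 1]) the mask keeps
    pixels above that percentile of the nonzero magnitudes; by default the
    threshold is contrast-relative (``EDGE_REL_FRAC`` of the 99.5th
    magnitude percentile, floored at ``EDGE_MEDIAN_FLOOR`` x median).  A
    constant image yields an empty mask.
    """
    arr = image.to_float() if isinstance(image, ImageFrame) else np.asarray(image, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 32:
        raise ValidationError("image", "must be a 2-D image of at least 32 x 32 px")
    sm = uniform_filter(arr, size=3, mode="reflect")
    gy, gx = np.gradient(sm)
    mag = np.hypot(gx, gy)
    nz = mag[mag > 0]
    if nz.size == 0:
        return EdgeMap(mag=mag, gx=gx, gy=gy, mask=np.zeros_like(mag, dtype=bool), threshold=0.0)
    if edge_percentile is not None:
        if not 0.0 <= edge_percentile <= 1.0:
            raise ValidationError("edge_percentile", "must lie in [0, 1]")
        thr = float(np.percentile(nz, edge_percentile * 100.0))
    else:
        thr = max(
            EDGE_REL_FRAC * float(np.percentile(mag, 99.5)),
            EDGE_MEDIAN_FLOOR * float(np.median(mag)),
        )
    mask = mag > thr
    return EdgeMap(mag=mag, gx=gx, gy=gy, mask=mask, threshold=thr)


def candidate_radii(params: DetectionParams) -> np.ndarray:
    """Strictly increasing candidate radii (μm) spanning [d_min/2, d_max/2]."""
    lo, hi = params.d_min / 2.0, params.d_max / 2.0
    radii = list(np.arange(lo, hi + 1e-9, params.radius_step))
    if radii[-1] < hi - 1e-9:
        radii.append(hi)
    return np.asarray(radii)


def hough_accumulate(edges: EdgeMap, radii_um: Sequence[float], pixel_size: float) -> np.ndarray:
    """3-D circle Hough accumulator, shape (ny, nx, n_radii).

    Votes are weighted by gradient magnitude (scaled so strong edges carry
    unit weight) and cast at both +r and -r along the gradient direction.
    Each radius slice is divided by 2*pi*r_px, the vote mass of an ideal
    one-pixel-wide full circle, so a perfect circle peaks near 1.
    """
    radii_um = np.asarray(radii_um, dtype=float)
    if radii_um.size == 0 or np.any(np.diff(radii_um) <= 0):
        raise ValidationError("radii", "must be nonempty and strictly increasing")
    ny, nx = edges.mag.shape
    acc = np.zeros((ny, nx, radii_um.size), dtype=np.float32)
    ys, xs = np.nonzero(edges.mask)
    if ys.size == 0:
        return acc
    m = edges.mag[ys, xs]
    ref = float(np.percentile(m, 99.0))
    w = np.clip(m / ref, 0.0, 1.0) if ref > 0 else np.ones_like(m)
    ux = edges.gx[ys, xs] / m
    uy = edges.gy[ys, xs] / m
    for k, r_um in enumerate(radii_um):
        r = r_um / pixel_size
        slice_k = np.zeros(ny * nx, dtype=np.float64)
        for sign in (1.0, -1.0):
            cy = np.rint(ys + sign * r * uy).astype(np.int64)
            cx = np.rint(xs + sign * r * ux).astype(np.int64)
            ok = (cy >= 0) & (cy < ny) & (cx >= 0) & (cx < nx)
            if not ok.any():
                continue
            flat = cy[ok] * nx + cx[ok]
            slice_k += np.bincount(flat, weights=w[ok], minlength=ny * nx)
        acc[:, :, k] = (slice_k / (2.0 * math.pi * r)).reshape(ny, nx)
    return acc


def _spoke_peaks(
    edges: EdgeMap,
    cys: np.ndarray,
    cxs: np.ndarray,
    r_px: np.ndarray,
    win: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-spoke radial gradient peaks around candidate circles.

    Samples the gradient-magnitude profile along ``N_SPOKES`` evenly spaced
    rays over radius +/- ``win`` px and returns, per (candidate, spoke):
    the peak offset from the candidate radius, whether the peak is a strong
    edge (above the mask threshold), and whether its gradient is radially
    aligned within 30 degrees.
    """
    n = cys.size
    n_steps = max(9, int(round(2 * win / 0.35)) + 1)
    offs = np.linspace(-win, win, n_steps)
    thetas = np.linspace(0.0, 2.0 * math.pi, N_SPOKES, endpoint=False)
    ct, st = np.cos(thetas), np.sin(thetas)

    rho = r_px[:, None, None] + offs[None, None, :]
    ys = cys[:, None, None] + rho * st[None, :, None]
    xs = cxs[:, None, None] + rho * ct[None, :, None]
    coords = np.stack([ys.ravel(), xs.ravel()])
    mag = map_coordinates(edges.mag, coords, order=1, mode="nearest").reshape(n, N_SPOKES, n_steps)

    k_best = np.argmax(mag, axis=2)
    peak_mag = np.take_along_axis(mag, k_best[:, :, None], axis=2)[:, :, 0]
    peak_off = offs[k_best]

    ys_p = np.take_along_axis(ys, k_best[:, :, None], axis=2)[:, :, 0]
    xs_p = np.take_along_axis(xs, k_best[:, :, None], axis=2)[:, :, 0]
    pc = np.stack([ys_p.ravel(), xs_p.ravel()])
    gx_p = map_coordinates(edges.gx, pc, order=1, mode="nearest").reshape(n, N_SPOKES)
    gy_p = map_coordinates(edges.gy, pc, order=1, mode="nearest").reshape(n, N_SPOKES)
    gnorm = np.hypot(gx_p, gy_p) + 1e-12
    radial = np.abs(gx_p * ct[None, :] + gy_p * st[None, :]) / gnorm

    strong = peak_mag > edges.threshold
    aligned = radial >= ALIGN_COS
    return peak_off, strong, aligned


def _in_box(
    cys: np.ndarray,
    cxs: np.ndarray,
    r_px: np.ndarray,
    box: tuple[float, float, float, float] | None,
) -> np.ndarray:
    """Which spokes' nominal circle points lie inside the valid image box.

    Spokes reaching outside the true image (into the padding) carry no
    evidence either way and are excluded from the support denominator, so
    cells cut by the frame border are scored on their visible arc.
    """
    thetas = np.linspace(0.0, 2.0 * math.pi, N_SPOKES, endpoint=False)
    ys = cys[:, None] + r_px[:, None] * np.sin(thetas)[None, :]
    xs = cxs[:, None] + r_px[:, None] * np.cos(thetas)[None, :]
    if box is None:
        return np.ones_like(ys, dtype=bool)
    y0, y1, x0, x1 = box
    return (ys >= y0) & (ys <= y1) & (xs >= x0) & (xs <= x1)


def _refine_and_score(
    edges: EdgeMap,
    cys: np.ndarray,
    cxs: np.ndarray,
    r_px: np.ndarray,
    pixel_size: float,
    box: tuple[float, float, float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Subpixel refinement and radial-symmetry score for candidates.

    First pass: locate the strong, radially aligned gradient peak on each
    spoke; the mean peak offset estimates the radius error and the first
    circular harmonic of the offsets estimates the center displacement
    (off(theta) ~ dr + dx cos(theta) + dy sin(theta)).  Second pass:
    re-sample at the refined geometry and count the fraction of in-image
    spokes whose peak is strong, aligned, and within PEAK_TOL of the
    refined radius.  Returns (score, cy_refined, cx_refined, r_refined),
    coordinates in px.
    """
    n = cys.size
    if n == 0:
        z = np.zeros(0)
        return z, z, z, z
    win = PROFILE_WINDOW_UM / pixel_size
    tol = PEAK_TOL_UM / pixel_size
    thetas = np.linspace(0.0, 2.0 * math.pi, N_SPOKES, endpoint=False)
    ct, st = np.cos(thetas), np.sin(thetas)

    off, strong, aligned = _spoke_peaks(edges, cys, cxs, r_px, win)
    valid = strong & aligned & _in_box(cys, cxs, r_px, box)
    n_valid = valid.sum(axis=1)
    w = valid.astype(float)
    denom = np.maximum(n_valid, 1)
    dr = (off * w).sum(axis=1) / denom
    dx = 2.0 * (off * ct[None, :] * w).sum(axis=1) / denom
    dy = 2.0 * (off * st[None, :] * w).sum(axis=1) / denom
    lim = win
    dr, dx, dy = (np.clip(v, -lim, lim) for v in (dr, dx, dy))
    usable = n_valid >= N_SPOKES // 4
    r_ref = np.where(usable, np.maximum(r_px + dr, 1.0), r_px)
    cy_ref = np.where(usable, cys + dy, cys)
    cx_ref = np.where(usable, cxs + dx, cxs)

    off2, strong2, aligned2 = _spoke_peaks(edges, cy_ref, cx_ref, r_ref, win)
    in_box2 = _in_box(cy_ref, cx_ref, r_ref, box)
    supported = strong2 & aligned2 & (np.abs(off2) <= tol) & in_box2
    n_in = in_box2.sum(axis=1)
    score = supported.sum(axis=1) / np.maximum(n_in, 1)
    score[n_in < N_SPOKES // 4] = 0.0
    return score, cy_ref, cx_ref, r_ref


def find_circles(image: ImageFrame, params: DetectionParams | None = None) -> list[Detection]:
    """Detect circular objects in one frame.

    Pipeline: reflect-pad (so cells touching the frame border remain
    detectable) -> edge map -> Hough accumulator over the candidate-radius
    span [d_min/2, d_max/2] -> 3-D local-maximum proposals -> radial support
    scoring -> sensitivity threshold -> greedy non-maximum suppression.
    Output order is deterministic: descending score, ties by accumulator
    value then row-major center.
    """
    params = params or DetectionParams()
    px = image.pixel_size
    ny, nx = image.shape
    d_max_px = params.d_max / px
    if min(ny, nx) < d_max_px:
        raise ValidationError("image", f"frame smaller than d_max ({d_max_px:.0f} px)")

    # Constant (background-level) padding: cells touching the frame border
    # keep their visible arc and are scored on in-image spokes only.
    pad = int(math.ceil(d_max_px)) + 4
    raw = image.to_float()
    arr = np.pad(raw, pad, mode="constant", constant_values=float(np.median(raw)))
    edges = edge_map(arr)
    box = (pad + 1.0, pad + ny - 2.0, pad + 1.0, pad + nx - 2.0)
    radii_um = candidate_radii(params)
    acc = hough_accumulate(edges, radii_um, px)

    # 3x3x1 smoothing: box-sum over centers recollects votes smeared by
    # rounding and gradient-angle noise before peak picking.
    smoothed = np.empty_like(acc)
    for k in range(acc.shape[2]):
        smoothed[:, :, k] = uniform_filter(acc[:, :, k], size=3, mode="constant") * 9.0

    is_peak = (smoothed >= PROPOSAL_SCORE) & (
        smoothed == maximum_filter(smoothed, size=(3, 3, 3), mode="constant")
    )
    cys, cxs, ks = np.nonzero(is_peak)
    if cys.size == 0:
        return []
    vals = smoothed[cys, cxs, ks]
    if cys.size > MAX_CANDIDATES:
        keep = np.argsort(-vals, kind="stable")[:MAX_CANDIDATES]
        cys, cxs, ks, vals = cys[keep], cxs[keep], ks[keep], vals[keep]

    r_px = radii_um[ks] / px
    scores, cy_ref, cx_ref, r_ref = _refine_and_score(
        edges, cys.astype(float), cxs.astype(float), r_px, px, box=box
    )

    # Size gate: the refined radius must stay within the candidate span
    # (undersized debris and oversized clump lobes refine out of band).
    r_um = r_ref * px
    lo, hi = params.d_min / 2.0, params.d_max / 2.0
    in_band = (r_um >= lo - RADIUS_GATE_SLACK_UM) & (r_um <= hi + RADIUS_GATE_SLACK_UM)
    ok = in_band & (scores >= params.sensitivity_threshold)
    cy_ref, cx_ref, r_um, vals, scores = (
        cy_ref[ok], cx_ref[ok], r_um[ok], vals[ok], scores[ok]
    )
    if cy_ref.size == 0:
        return []

    # Greedy NMS in descending (score, accumulator) order, deterministic ties.
    order = np.lexsort((cx_ref, cy_ref, -vals, -scores))
    min_d_px = params.nms_distance / px
    kept: list[int] = []
    ky = np.empty(0)
    kx = np.empty(0)
    for i in order:
        if kept:
            if np.min(np.hypot(ky - cy_ref[i], kx - cx_ref[i])) < min_d_px:
                continue
        kept.append(int(i))
        ky = np.append(ky, cy_ref[i])
        kx = np.append(kx, cx_ref[i])

    detections = []
    for i in kept:
        y, x = cy_ref[i] - pad, cx_ref[i] - pad
        if not (0 <= x < nx and 0 <= y < ny):
            continue  # mirror ghost outside the true field
        detections.append(
            Detection(
                cx=float(x) * px,
                cy=float(y) * px,
                radius=float(np.clip(r_um[i], lo, hi)),
                score=float(scores[i]),
                modality=image.modality,
            )
        )
    return detections


@dataclass(frozen=True)
class MatchResult:
    """One-to-one greedy pairing between two detection lists."""

    pairs: tuple[tuple[int, int, float], ...]  # (index in a, index in b, distance μm)
    unmatched_a: tuple[int, ...]
    unmatched_b: tuple[int, ...]

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def _centers(dets: Sequence) -> np.ndarray:
    out = np.empty((len(dets), 2))
    for i, d in enumerate(dets):
        out[i] = (d.cx, d.cy) if hasattr(d, "cx") else (d[0], d[1])
    return out


def match_detections(a: Sequence, b: Sequence, tol: float) -> MatchResult:
    """Greedy nearest-neighbor pairing of detections (or (x, y) points).

    Pairs are accepted in order of increasing center distance, each item
    used at most once; pairs farther than ``tol`` μm are rejected.
    """
    if tol <= 0:
        raise ValidationError("tol", "must be > 0")
    if len(a) == 0 or len(b) == 0:
        return MatchResult((), tuple(range(len(a))), tuple(range(len(b))))
    pa, pb = _centers(a), _centers(b)
    dist = np.hypot(pa[:, 0:1] - pb[None, :, 0], pa[:, 1:2] - pb[None, :, 1])
    pairs: list[tuple[int, int, float]] = []
    free_a = np.ones(len(a), dtype=bool)
    free_b = np.ones(len(b), dtype=bool)
    flat_order = np.argsort(dist, axis=None, kind="stable")
    for flat in flat_order:
        i, j = divmod(int(flat), len(b))
        d = dist[i, j]
        if d > tol:
            break
        if free_a[i] and free_b[j]:
            pairs.append((i, j, float(d)))
            free_a[i] = False
            free_b[j] = False
    return MatchResult(
        tuple(pairs),
        tuple(np.nonzero(free_a)[0].tolist()),
        tuple(np.nonzero(free_b)[0].tolist()),
    )
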