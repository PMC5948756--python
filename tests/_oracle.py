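"""Independent brute-force circle finder used as a test oracle.

Scores every (cx, cy, r) triple on the integer pixel grid by mean
gradient-aligned edge support: the fraction of evenly spaced points on the
circle whose nearest pixels contain a masked edge with gradient radially
aligned within 30 degrees, weighted by the sampled gradient magnitude for
ranking.  Exhaustive and slow by construction; only usable on small frames.
"""

from __future__ import annotations

import math

import numpy as np

from csfcount.hough import EdgeMap, candidate_radii, edge_map
from csfcount.config import DetectionParams
from csfcount.image import ImageFrame

N_ANGLES = 32
ALIGN_COS = math.cos(math.radians(30.0))


def _support_fields(edges: EdgeMap, theta: float) -> tuple[np.ndarray, np.ndarray]:
    """Edge pixels supporting direction ``theta``: indicator and magnitude."""
    gnorm = edges.mag + 1e-12
    aligned = (
        np.abs(edges.gx * math.cos(theta) + edges.gy * math.sin(theta)) / gnorm
    ) >= ALIGN_COS
    ind = edges.mask & aligned
    return ind, np.where(ind, edges.mag, 0.0)


def _shift(field: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """field evaluated at (y + dy, x + dx), zero outside."""
    ny, nx = field.shape
    out = np.zeros_like(field)
    ys0, ys1 = max(0, -dy), min(ny, ny - dy)
    xs0, xs1 = max(0, -dx), min(nx, nx - dx)
    if ys0 >= ys1 or xs0 >= xs1:
        return out
    out[ys0:ys1, xs0:xs1] = field[ys0 + dy : ys1 + dy, xs0 + dx : xs1 + dx]
    return out


def brute_force_circles(
    image: ImageFrame, params: DetectionParams | None = None
) -> list[tuple[float, float, float, float]]:
    """Exhaustive circle search; returns (cx_um, cy_um, radius_um, score).

    Every integer center and every candidate radius is scored; triples with
    support >= the sensitivity threshold survive greedy NMS (ranked by
    binary support, ties by magnitude-weighted support).
    """
    params = params or DetectionParams()
    px = image.pixel_size
    edges = edge_map(image)
    radii = candidate_radii(params)
    ny, nx = edges.mag.shape

    cand: list[tuple[float, float, int, int, int]] = []  # score, wscore, y, x, k
    for k, r_um in enumerate(radii):
        r = r_um / px
        support = np.zeros((ny, nx))
        wsupport = np.zeros((ny, nx))
        for t in range(N_ANGLES):
            theta = 2.0 * math.pi * t / N_ANGLES
            ind, wmag = _support_fields(edges, theta)
            dy = int(round(r * math.sin(theta)))
            dx = int(round(r * math.cos(theta)))
            support += _shift(ind.astype(float), dy, dx)
            wsupport += _shift(wmag, dy, dx)
        support /= N_ANGLES
        wsupport /= N_ANGLES
        ys, xs = np.nonzero(support >= params.sensitivity_threshold)
        for y, x in zip(ys, xs):
            cand.append((float(support[y, x]), float(wsupport[y, x]), int(y), int(x), k))

    cand.sort(key=lambda c: (-c[0], -c[1], c[2], c[3]))
    min_d = params.nms_distance / px
    kept: list[tuple[float, float, float, float]] = []
    centers: list[tuple[int, int]] = []
    for score, _w, y, x, k in cand:
        if any(math.hypot(y - cy, x - cx) < min_d for cy, cx in centers):
            continue
        centers.append((y, x))
        kept.append((x * px, y * px, float(radii[k]), score))
    return kept
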