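"""Ground-truthed synthetic microscopy scenes.

Generates paired bright-field / fluorescence frames that emulate the
optical scene inside a tall counting chamber: dark ring-like cells on a
bright textured background with the faint grid/shadow artifact left by
3D-printed chamber walls, nuclear-stain fluorescence from WBCs only on a
dye-dependent background, sub-band debris and over-band clumps, and
height-dependent defocus blur for cells that have not yet settled.

The generator is the study-condition oracle for the rest of the package:
object counts follow Poisson loading at the requested concentration over
the per-frame control volume, and every rendered frame is bit-reproducible
from the scene seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import ChamberSpec, OpticsSpec, StainingCondition, StainingModelParams
from .errors import ValidationError
from .image import ImageFrame, quantize

CELL_CLASSES = ("RBC", "WBC", "debris", "clump")

# Apparent (optics-magnified) diameter ranges, μm.  Cells span most of the
# detector's [8.6, 14.2] μm acceptance band; debris sits below it, clump
# lobes well above it so that rejection is a property of the scene, not of
# tuned detector internals.
RBC_DIAMETER_RANGE = (9.0, 14.0)
WBC_DIAMETER_RANGE = (9.0, 14.0)
DEBRIS_DIAMETER_RANGE = (3.0, 7.0)
CLUMP_DIAMETER_RANGE = (18.0, 30.0)

# Bright-field rendering constants (fractions of the background level).
BF_BASE_FRAC = 0.55  # background sits at 55% of full scale
RING_DEPTH_FRAC = 0.45  # membrane-ring contrast of a settled cell
RING_SIGMA_UM = 0.80  # radial half-width of the membrane ring
DEBRIS_DEPTH_FRAC = 0.30
CLUMP_DEPTH_FRAC = 0.40
DISK_EDGE_SIGMA_UM = 0.45  # soft edge of filled debris/clump/fluorescence disks
TEXTURE_FRAC = 0.008  # low-frequency background mottle (relative sd)
TEXTURE_CORR_UM = 12.0
GRID_PERIOD_UM = 47.0  # printing-layer grid artifact
GRID_AMP_FRAC = 0.012
GRID_WIDTH_UM = 1.5
SHADOW_FRAC = 0.01  # gentle illumination ramp across the field
CONTRAST_JITTER_SD = 0.05  # per-object lognormal contrast variation


@dataclass(frozen=True)
class SceneObject:
    """One physical object in the chamber.

    ``z0`` is the initial height above the chamber floor (μm); ``z`` the
    current height after any settling steps.  ``diameter`` is the apparent
    diameter in the image plane (μm).
    """

    x: float
    y: float
    z0: float
    z: float
    cls: str
    diameter: float


@dataclass(frozen=True)
class GroundTruthSample:
    """Simulator truth for one imaged area."""

    objects: tuple[SceneObject, ...]
    c_rbc: float
    c_wbc: float
    seed: int
    optics: OpticsSpec
    chamber: ChamberSpec

    def count(self, cls: str) -> int:
        return sum(1 for o in self.objects if o.cls == cls)

    @property
    def n_cells(self) -> int:
        """Number of true in-band cells (RBC + WBC)."""
        return self.count("RBC") + self.count("WBC")

    def positions(self, classes: Sequence[str] = ("RBC", "WBC")) -> np.ndarray:
        """(n, 2) array of (x, y) μm positions for the given classes."""
        pts = [(o.x, o.y) for o in self.objects if o.cls in classes]
        return np.asarray(pts, dtype=float).reshape(-1, 2)


def frame_volume_ul(optics: OpticsSpec, chamber: ChamberSpec) -> float:
    """Control volume imaged by one frame, in μL (1 μL = 1e9 μm^3)."""
    return optics.fov_x * optics.fov_y * chamber.h_c * 1e-9


def sample_scene(
    c_rbc: float,
    c_wbc: float,
    optics: OpticsSpec | None = None,
    chamber: ChamberSpec | None = None,
    debris_rate: float = 50.0,
    clump_rate: float = 5.0,
    seed: int = 0,
) -> GroundTruthSample:
    """Draw one imaged area at the given concentrations (cells/μL).

    Object counts per class are Poisson with mean = concentration x the
    per-frame control volume; positions are uniform over the field and
    initial heights uniform over [0, h_c].  Identical seeds give identical
    scenes.
    """
    optics = optics or OpticsSpec()
    chamber = chamber or ChamberSpec()
    for name, val in (("c_rbc", c_rbc), ("c_wbc", c_wbc),
                      ("debris_rate", debris_rate), ("clump_rate", clump_rate)):
        if val < 0:
            raise ValidationError(name, "concentration/rate must be >= 0")

    rng = np.random.default_rng(seed)
    vol = frame_volume_ul(optics, chamber)
    ranges = {
        "RBC": RBC_DIAMETER_RANGE,
        "WBC": WBC_DIAMETER_RANGE,
        "debris": DEBRIS_DIAMETER_RANGE,
        "clump": CLUMP_DIAMETER_RANGE,
    }
    objects: list[SceneObject] = []
    placed_xy: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for cls, rate in (("clump", clump_rate), ("RBC", c_rbc), ("WBC", c_wbc),
                      ("debris", debris_rate)):
        n = int(rng.poisson(rate * vol))
        lo, hi = ranges[cls]
        for _ in range(n):
            d = float(rng.uniform(lo, hi))
            z = float(rng.uniform(0.0, chamber.h_c))
            # Hard-disk exclusion: settled objects are solid and cannot
            # interpenetrate in plane, so centers keep at least the sum of
            # the radii apart (rejection sampling; gives up after many
            # tries at unphysical densities).
            for _try in range(200):
                x = float(rng.uniform(0.0, optics.fov_x))
                y = float(rng.uniform(0.0, optics.fov_y))
                ok = True
                for (px_, py_), pr in zip(placed_xy, placed_r):
                    if (x - px_) ** 2 + (y - py_) ** 2 < (d / 2.0 + pr) ** 2:
                        ok = False
                        break
                if ok:
                    break
            placed_xy.append((x, y))
            placed_r.append(d / 2.0)
            objects.append(SceneObject(x=x, y=y, z0=z, z=z, cls=cls, diameter=d))
    return GroundTruthSample(
        objects=tuple(objects), c_rbc=c_rbc, c_wbc=c_wbc, seed=seed,
        optics=optics, chamber=chamber,
    )


def gating_scene(
    seed: int = 0,
    optics: OpticsSpec | None = None,
    chamber: ChamberSpec | None = None,
    n_cells: int = 5,
    n_debris: int = 10,
    n_clumps: int = 2,
    border_margin: float = 16.0,
    clearance: float = 12.0,
) -> GroundTruthSample:
    """Deterministic well-separated QC scene for size/symmetry gating checks.

    Places the requested numbers of in-band cells, sub-band debris, and
    over-band clumps (all settled), keeping every object ``clearance`` μm of
    free space beyond contact and ``border_margin`` μm inside the frame, so
    that any spurious or missing detection reflects the size/symmetry gate
    rather than occlusion or border clipping.
    """
    optics = optics or OpticsSpec()
    chamber = chamber or ChamberSpec()
    rng = np.random.default_rng(seed)
    specs = (
        [("clump", CLUMP_DIAMETER_RANGE)] * n_clumps
        + [("RBC", RBC_DIAMETER_RANGE)] * n_cells
        + [("debris", DEBRIS_DIAMETER_RANGE)] * n_debris
    )
    objects: list[SceneObject] = []
    for cls, (lo, hi) in specs:
        d = float(rng.uniform(lo, hi))
        m = border_margin + d / 2.0
        for _try in range(10000):
            x = float(rng.uniform(m, optics.fov_x - m))
            y = float(rng.uniform(m, optics.fov_y - m))
            if all(
                math.hypot(x - o.x, y - o.y) >= (d + o.diameter) / 2.0 + clearance
                for o in objects
            ):
                break
        objects.append(SceneObject(x=x, y=y, z0=0.0, z=0.0, cls=cls, diameter=d))
    return GroundTruthSample(
        objects=tuple(objects), c_rbc=0.0, c_wbc=0.0, seed=seed,
        optics=optics, chamber=chamber,
    )


def settle(sample: GroundTruthSample, t: float, v: float) -> GroundTruthSample:
    """Advance sedimentation by ``t`` seconds at settling velocity ``v`` μm/s.

    Heights become max(0, z - v*t); object order and classes are unchanged.
    """
    if t < 0:
        raise ValidationError("t", "must be >= 0")
    if v <= 0:
        raise ValidationError("v", "must be > 0")
    objs = tuple(replace(o, z=max(0.0, o.z - v * t)) for o in sample.objects)
    return replace(sample, objects=objs)


def settled(sample: GroundTruthSample) -> GroundTruthSample:
    """All objects on the chamber floor (complete sedimentation)."""
    return replace(sample, objects=tuple(replace(o, z=0.0) for o in sample.objects))


def staining_signal(c_d: float, t_i: float, model: StainingModelParams) -> float:
    """Stained-cell fluorescence amplitude under condition (c_d μM, t_i min).

    Hill dose response times first-order uptake saturation:
    ``s_max * c_d^n / (k_half^n + c_d^n) * (1 - exp(-t_i / tau))``.
    Monotone nondecreasing in both arguments.
    """
    if c_d < 0:
        raise ValidationError("c_d", "must be >= 0")
    if t_i < 0:
        raise ValidationError("t_i", "must be >= 0")
    if c_d == 0:
        return 0.0
    n = model.hill_n
    hill = c_d**n / (model.k_half**n + c_d**n)
    return model.s_max * hill * (1.0 - math.exp(-t_i / model.tau))


def fluorescence_background(staining: StainingCondition, model: StainingModelParams) -> float:
    """Background level of a fluorescence frame (dye-dependent)."""
    return model.bg_floor + model.bg_slope * staining.c_d


def _blur_sigma_px(obj: SceneObject, optics: OpticsSpec) -> float:
    return optics.defocus_blur_coeff * obj.z / optics.pixel_size


def _stamp(canvas: np.ndarray, cx_px: float, cy_px: float, patch_half: int, profile_fn, sigma_blur: float) -> None:
    """Add ``profile_fn(dx, dy)`` around (cx, cy), optionally defocus-blurred."""
    ny, nx = canvas.shape
    margin = int(math.ceil(4.0 * sigma_blur)) + 2
    half = patch_half + margin
    ix, iy = int(round(cx_px)), int(round(cy_px))
    x0, x1 = ix - half, ix + half + 1
    y0, y1 = iy - half, iy + half + 1
    xs = np.arange(x0, x1, dtype=float)
    ys = np.arange(y0, y1, dtype=float)
    dx = xs[None, :] - cx_px
    dy = ys[:, None] - cy_px
    patch = profile_fn(dx, dy)
    if sigma_blur > 0.05:
        patch = gaussian_filter(patch, sigma_blur, mode="constant")
    cx0, cx1 = max(x0, 0), min(x1, nx)
    cy0, cy1 = max(y0, 0), min(y1, ny)
    if cx0 >= cx1 or cy0 >= cy1:
        return
    canvas[cy0:cy1, cx0:cx1] += patch[cy0 - y0 : cy1 - y0, cx0 - x0 : cx1 - x0]


def _soft_disk(dx: np.ndarray, dy: np.ndarray, r_px: float, edge_px: float) -> np.ndarray:
    rho = np.hypot(dx, dy)
    return 1.0 / (1.0 + np.exp(np.clip((rho - r_px) / edge_px, -40, 40)))


def _ring(dx: np.ndarray, dy: np.ndarray, r_px: float, sigma_px: float) -> np.ndarray:
    rho = np.hypot(dx, dy)
    return np.exp(-((rho - r_px) ** 2) / (2.0 * sigma_px**2))


def _background_brightfield(optics: OpticsSpec, base: float, seed: int) -> np.ndarray:
    ny, nx = optics.shape
    px = optics.pixel_size
    rng = np.random.default_rng([seed, 11])
    tex = gaussian_filter(rng.standard_normal((ny, nx)), TEXTURE_CORR_UM / px, mode="reflect")
    sd = tex.std()
    if sd > 0:
        tex *= TEXTURE_FRAC * base / sd
    xs = np.arange(nx) * px
    ys = np.arange(ny) * px
    w = GRID_WIDTH_UM
    # distance to nearest grid line (lines at multiples of the period)
    dx = np.minimum(xs % GRID_PERIOD_UM, GRID_PERIOD_UM - xs % GRID_PERIOD_UM)
    dy = np.minimum(ys % GRID_PERIOD_UM, GRID_PERIOD_UM - ys % GRID_PERIOD_UM)
    gx = np.exp(-(dx**2) / (2 * w**2))
    gy = np.exp(-(dy**2) / (2 * w**2))
    grid = -GRID_AMP_FRAC * base * (gx[None, :] + gy[:, None])
    shadow = -SHADOW_FRAC * base * (xs / max(xs[-1], 1.0))[None, :]
    return base + tex + grid + shadow


def _contrast_jitter(rng: np.random.Generator) -> float:
    return float(np.exp(rng.normal(0.0, CONTRAST_JITTER_SD)))


def render_brightfield(
    sample: GroundTruthSample,
    optics: OpticsSpec | None = None,
    noise_sd: float = 250.0,
    bit_depth: int = 16,
) -> ImageFrame:
    """Render the bright-field channel of a scene.

    Cells appear as dark membrane rings, debris as small dark disks, and
    clumps as overlapping multi-lobed dark blobs, all on a bright textured
    background carrying the faint periodic grid/shadow artifact of a
    3D-printed chamber.  Each object is Gaussian-blurred with radius
    ``defocus_blur_coeff * height``; Gaussian read noise is added last.
    """
    optics = optics or sample.optics
    px = optics.pixel_size
    base = BF_BASE_FRAC * (2**bit_depth - 1)
    canvas = _background_brightfield(optics, base, sample.seed)

    jit_rng = np.random.default_rng([sample.seed, 23])
    for idx, obj in enumerate(sample.objects):
        r_px = obj.diameter / 2.0 / px
        sigma_b = _blur_sigma_px(obj, optics)
        contrast = _contrast_jitter(jit_rng)
        cx, cy = obj.x / px, obj.y / px
        if obj.cls in ("RBC", "WBC"):
            depth = RING_DEPTH_FRAC * base * contrast
            sig = RING_SIGMA_UM / px
            _stamp(canvas, cx, cy, int(math.ceil(r_px + 4 * sig + 2)),
                   lambda dx, dy, r=r_px, s=sig, d=depth: -d * _ring(dx, dy, r, s), sigma_b)
        elif obj.cls == "debris":
            depth = DEBRIS_DEPTH_FRAC * base * contrast
            edge = DISK_EDGE_SIGMA_UM / px
            _stamp(canvas, cx, cy, int(math.ceil(r_px + 6 * edge + 2)),
                   lambda dx, dy, r=r_px, e=edge, d=depth: -d * _soft_disk(dx, dy, r, e), sigma_b)
        else:  # clump: overlapping over-band lobes, low radial symmetry
            lobe_rng = np.random.default_rng([sample.seed, 31, idx])
            n_lobes = int(lobe_rng.integers(2, 4))
            depth = CLUMP_DEPTH_FRAC * base * contrast
            edge = DISK_EDGE_SIGMA_UM / px
            for _ in range(n_lobes):
                lobe_d = lobe_rng.uniform(0.9, 1.0) * obj.diameter
                lr_px = lobe_d / 2.0 / px
                ang = lobe_rng.uniform(0, 2 * math.pi)
                off = lobe_rng.uniform(0.0, 0.35) * lr_px
                lx, ly = cx + off * math.cos(ang), cy + off * math.sin(ang)
                _stamp(canvas, lx, ly, int(math.ceil(lr_px + 6 * edge + 2)),
                       lambda dx, dy, r=lr_px, e=edge, d=depth: -d * _soft_disk(dx, dy, r, e),
                       sigma_b)

    if noise_sd > 0:
        noise_rng = np.random.default_rng([sample.seed, 101])
        canvas = canvas + noise_rng.normal(0.0, noise_sd, canvas.shape)
    return ImageFrame(pixels=quantize(canvas, bit_depth), bit_depth=bit_depth,
                      pixel_size=px, modality="bright_field")


def render_fluorescence(
    sample: GroundTruthSample,
    optics: OpticsSpec | None = None,
    staining: StainingCondition | None = None,
    model: StainingModelParams | None = None,
    noise_sd: float = 150.0,
    bit_depth: int = 16,
) -> ImageFrame:
    """Render the fluorescence channel of a scene.

    Only WBCs carry nuclear-stain signal (the dye's fluorescence is
    DNA-enhanced, so non-nucleated RBCs, debris and clumps are absent from
    this channel).  Spot amplitude follows :func:`staining_signal`; the
    background is affine in dye concentration.  The same height-dependent
    defocus rule as in bright-field applies.
    """
    optics = optics or sample.optics
    staining = staining or StainingCondition()
    model = model or StainingModelParams()
    px = optics.pixel_size
    canvas = np.full(optics.shape, fluorescence_background(staining, model), dtype=float)
    amp = staining_signal(staining.c_d, staining.t_i, model)

    jit_rng = np.random.default_rng([sample.seed, 47])
    for obj in sample.objects:
        if obj.cls != "WBC":
            continue
        contrast = _contrast_jitter(jit_rng)
        if amp <= 0:
            continue
        r_px = obj.diameter / 2.0 / px
        edge = DISK_EDGE_SIGMA_UM / px
        sigma_b = _blur_sigma_px(obj, optics)
        _stamp(canvas, obj.x / px, obj.y / px, int(math.ceil(r_px + 6 * edge + 2)),
               lambda dx, dy, r=r_px, e=edge, a=amp * contrast: a * _soft_disk(dx, dy, r, e),
               sigma_b)

    if noise_sd > 0:
        noise_rng = np.random.default_rng([sample.seed, 103])
        canvas = canvas + noise_rng.normal(0.0, noise_sd, canvas.shape)
    return ImageFrame(pixels=quantize(canvas, bit_depth), bit_depth=bit_depth,
                      pixel_size=px, modality="fluorescence")


def write_scene(
    out_dir: str | Path,
    stem: str,
    sample: GroundTruthSample,
    bf: ImageFrame,
    fl: ImageFrame,
) -> dict[str, Path]:
    """Write an image pair (_bf.tif/_fl.tif), truth CSV, and JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "bf": out / f"{stem}_bf.tif",
        "fl": out / f"{stem}_fl.tif",
        "truth": out / f"{stem}_truth.csv",
        "manifest": out / f"{stem}_manifest.json",
    }
    bf.save(paths["bf"])
    fl.save(paths["fl"])
    lines = ["x_um,y_um,z_um,class,diameter_um"]
    lines += [
        f"{o.x:.3f},{o.y:.3f},{o.z:.3f},{o.cls},{o.diameter:.3f}" for o in sample.objects
    ]
    paths["truth"].write_text("\n".join(lines) + "\n")
    manifest = {
        "seed": sample.seed,
        "c_rbc": sample.c_rbc,
        "c_wbc": sample.c_wbc,
        "fov_x_um": sample.optics.fov_x,
        "fov_y_um": sample.optics.fov_y,
        "pixel_size_um": sample.optics.pixel_size,
        "h_c_um": sample.chamber.h_c,
        "n_objects": len(sample.objects),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
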