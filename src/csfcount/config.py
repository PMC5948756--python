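"""Domain types, units, and configuration handling.

Unit conventions used throughout the package: lengths in micrometres (μm),
times in seconds (minutes only at reporting boundaries), volumes in
nanolitres (nL), concentrations in cells/μL, densities in g/mL, viscosity
in centipoise (cP).  Everything is converted at the edges, never inside the
numerics.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError, InputError, ValidationError

logger = logging.getLogger(__name__)

MIN_IMAGE_WIDTH_PX = 64


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValidationError(name, msg)


@dataclass(frozen=True)
class OpticsSpec:
    """Geometry of the miniaturized microscope's imaging path.

    The default field of view is 0.61 mm x 0.46 mm.  ``pixel_size`` defaults
    to 0.476 μm/px so that a 1280-px sensor row spans the 610 μm FOV width;
    the sensor resolution is configurable because it is not a fixed property
    of the optical design.  ``defocus_blur_coeff`` is only used by the
    simulator: it is the Gaussian blur radius (μm) added per μm of cell
    height above the chamber floor (single flat focal plane at the floor).
    """

    fov_x: float = 610.0
    fov_y: float = 460.0
    pixel_size: float = 0.476
    defocus_blur_coeff: float = 0.02

    def __post_init__(self) -> None:
        _require(self.fov_x > 0, "fov_x", "must be > 0")
        _require(self.fov_y > 0, "fov_y", "must be > 0")
        _require(self.pixel_size > 0, "pixel_size", "must be > 0")
        _require(self.defocus_blur_coeff >= 0, "defocus_blur_coeff", "must be >= 0")
        _require(
            self.nx >= MIN_IMAGE_WIDTH_PX,
            "pixel_size",
            f"image width {self.nx} px is below the minimum {MIN_IMAGE_WIDTH_PX}",
        )

    @property
    def nx(self) -> int:
        """Image width in pixels."""
        return int(round(self.fov_x / self.pixel_size))

    @property
    def ny(self) -> int:
        """Image height in pixels."""
        return int(round(self.fov_y / self.pixel_size))

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, columns) of a rendered frame."""
        return (self.ny, self.nx)


@dataclass(frozen=True)
class ChamberSpec:
    """Counting-chamber geometry.

    ``analysis_volume`` is the total volume covered by the ``n_areas``
    imaged areas of one chamber, in nL.  The default of 588 nL is treated as
    an independent instrument constant: the volume recomputed from
    FOV x h_c x n_areas is ~597 nL, and the two are deliberately not forced
    to agree (a warning is logged when a configuration supplies both).
    """

    h_c: float = 532.0
    n_areas: int = 4
    analysis_volume: float = 588.0

    def __post_init__(self) -> None:
        _require(self.h_c > 0, "h_c", "must be > 0")
        _require(self.n_areas >= 1, "n_areas", "must be >= 1")
        _require(self.analysis_volume > 0, "analysis_volume", "must be > 0")

    def geometric_volume_nl(self, optics: OpticsSpec) -> float:
        """Volume of the imaged areas recomputed from geometry (nL)."""
        return self.n_areas * optics.fov_x * optics.fov_y * self.h_c * 1e-6


@dataclass(frozen=True)
class DetectionParams:
    """Circle-Hough detection settings.

    ``sensitivity_threshold`` is the minimum normalized accumulator score
    (radial-symmetry evidence) for a detection: raising it accepts fewer
    objects.  ``d_min``/``d_max`` are the lower/upper apparent-diameter
    cut-offs in μm that separate cells from debris and clumps.
    """

    sensitivity_threshold: float = 0.9
    d_min: float = 8.6
    d_max: float = 14.2
    radius_step: float = 0.5
    min_center_distance: Optional[float] = None

    def __post_init__(self) -> None:
        _require(
            0.0 <= self.sensitivity_threshold <= 1.0,
            "sensitivity_threshold",
            "must lie in [0, 1]",
        )
        _require(self.d_min > 0, "d_min", "must be > 0")
        _require(
            self.d_min < self.d_max,
            "d_min/d_max",
            f"diameter band requires d_min < d_max, got [{self.d_min}, {self.d_max}]",
        )
        _require(self.radius_step > 0, "radius_step", "must be > 0")
        if self.min_center_distance is not None:
            _require(self.min_center_distance > 0, "min_center_distance", "must be > 0")

    @property
    def nms_distance(self) -> float:
        """Non-maximum-suppression radius in μm (defaults to d_min)."""
        return self.min_center_distance if self.min_center_distance is not None else self.d_min


@dataclass(frozen=True)
class SedimentationParams:
    """Inputs for the Stokes settling-velocity calculation.

    V_c is the cell volume (μm^3), rho_c / rho_m the cell and medium
    densities (g/mL), mu_m the medium viscosity (cP).  ``v_override``
    (μm/s), when set, is used in place of the computed Stokes velocity; it
    defaults to the reported 0.92 μm/s for RBCs so that wait-time
    predictions match the instrument protocol, while the first-principles
    value (~0.80 μm/s with the same parameters) remains available through
    :func:`csfcount.sedimentation.stokes_velocity`.
    """

    v_c: float = 90.0
    rho_c: float = 1.09
    rho_m: float = 1.04
    mu_m: float = 1.05
    g: float = 9.81
    v_override: Optional[float] = 0.92

    def __post_init__(self) -> None:
        _require(self.v_c > 0, "v_c", "must be > 0")
        _require(self.mu_m > 0, "mu_m", "must be > 0")
        _require(self.g > 0, "g", "must be > 0")
        if self.rho_c < self.rho_m:
            logger.warning(
                "rho_c (%.3f) < rho_m (%.3f): cells float, settling velocity <= 0",
                self.rho_c,
                self.rho_m,
            )


@dataclass(frozen=True)
class StainingCondition:
    """One on-chip staining condition: dye stock concentration c_d (μM)
    and incubation time t_i (min)."""

    c_d: float = 750.0
    t_i: float = 10.0

    def __post_init__(self) -> None:
        _require(self.c_d >= 0, "c_d", "must be >= 0")
        _require(self.t_i >= 0, "t_i", "must be >= 0")


@dataclass(frozen=True)
class StainingModelParams:
    """Parametric model of on-chip staining used by the simulator.

    The stained-cell amplitude follows a Hill curve in dye concentration
    (half-saturation ``k_half``, exponent ``hill_n``) times a first-order
    uptake saturation in time (constant ``tau``, min).  The fluorescence
    background is affine in dye concentration: ``bg_floor + bg_slope*c_d``.
    With ``hill_n=2`` and ``bg_floor`` small, the signal-to-background ratio
    has an interior maximum at exactly ``c_d = k_half``.  Amplitudes are in
    arbitrary 16-bit camera units; only ratios (SNR) are meaningful.

    Defaults are calibrated so that, at the optimum concentration, the
    measured SNR comfortably exceeds 5.4 from 2 min of incubation on and
    the cell signal is within 5% of its plateau at 10 min.
    """

    s_max: float = 77000.0
    k_half: float = 750.0
    hill_n: float = 2.0
    bg_slope: float = 4.0
    tau: float = 3.33
    bg_floor: float = 100.0

    def __post_init__(self) -> None:
        _require(self.s_max > 0, "s_max", "must be > 0")
        _require(self.k_half > 0, "k_half", "must be > 0")
        _require(self.hill_n >= 1, "hill_n", "must be >= 1")
        _require(self.tau > 0, "tau", "must be > 0")
        _require(self.bg_floor >= 0, "bg_floor", "must be >= 0")
        _require(self.bg_slope >= 0, "bg_slope", "must be >= 0")


@dataclass(frozen=True)
class SimulatorParams:
    """Synthetic-scene nuisance parameters.

    ``noise_sd_bf``/``noise_sd_fl`` are additive Gaussian read-noise
    standard deviations (16-bit units).  ``debris_rate`` and ``clump_rate``
    are volumetric loadings (objects/μL) of sub-band debris and over-band
    clumps.  ``staining`` is the dye-response model; ``condition`` the
    staining condition applied when rendering fluorescence frames.
    """

    noise_sd_bf: float = 250.0
    noise_sd_fl: float = 150.0
    debris_rate: float = 50.0
    clump_rate: float = 5.0
    staining: StainingModelParams = field(default_factory=StainingModelParams)
    condition: StainingCondition = field(default_factory=StainingCondition)

    def __post_init__(self) -> None:
        _require(self.noise_sd_bf >= 0, "noise_sd_bf", "must be >= 0")
        _require(self.noise_sd_fl >= 0, "noise_sd_fl", "must be >= 0")
        _require(self.debris_rate >= 0, "debris_rate", "must be >= 0")
        _require(self.clump_rate >= 0, "clump_rate", "must be >= 0")


@dataclass(frozen=True)
class PipelineConfig:
    """Immutable bundle of every stage's parameters for one run."""

    optics: OpticsSpec = field(default_factory=OpticsSpec)
    chamber: ChamberSpec = field(default_factory=ChamberSpec)
    detection: DetectionParams = field(default_factory=DetectionParams)
    sedimentation: SedimentationParams = field(default_factory=SedimentationParams)
    simulator: SimulatorParams = field(default_factory=SimulatorParams)


# Flat configuration key -> (top-level section, dataclass, field name).
_SECTIONS = {
    "optics": OpticsSpec,
    "chamber": ChamberSpec,
    "detection": DetectionParams,
    "sedimentation": SedimentationParams,
}
_NESTED = {
    "staining": StainingModelParams,
    "condition": StainingCondition,
}


def _flat_key_map() -> dict[str, tuple[str, str]]:
    out: dict[str, tuple[str, str]] = {}
    for section, cls in _SECTIONS.items():
        for f in fields(cls):
            out[f.name] = (section, f.name)
    for f in fields(SimulatorParams):
        if f.name in _NESTED:
            for g in fields(_NESTED[f.name]):
                out[g.name] = (f"simulator.{f.name}", g.name)
        else:
            out[f.name] = ("simulator", f.name)
    return out


_KEY_MAP = _flat_key_map()
_OPTIONAL_KEYS = {"min_center_distance", "v_override"}


def _coerce(key: str, value):
    if value is None or (isinstance(value, str) and value.lower() in {"none", "null", ""}):
        if key in _OPTIONAL_KEYS:
            return None
        raise ValidationError(key, "must be a number")
    if key == "n_areas":
        if not float(value).is_integer():
            raise ValidationError(key, f"must be an integer, got {value!r}")
        return int(value)
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(key, f"must be a number, got {value!r}") from None


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a flat key/value configuration file (YAML syntax, ``#`` comments).

    Unspecified fields take the package defaults.  ``path=None`` or an empty
    file yields the all-defaults configuration.

    Raises
    ------
    InputError
        If the file does not exist.
    ConfigError
        On unparseable content or unknown keys.
    ValidationError
        If any field violates its invariant; the message names the field.
    """
    raw: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise InputError(f"configuration file not found: {p}")
        try:
            loaded = yaml.safe_load(p.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"could not parse {p}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{p}: expected flat key-value pairs")
        raw = loaded
    return config_from_mapping(raw)


def config_from_mapping(raw: dict) -> PipelineConfig:
    """Build a validated :class:`PipelineConfig` from a flat mapping."""
    unknown = sorted(set(raw) - set(_KEY_MAP))
    if unknown:
        raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")

    by_section: dict[str, dict] = {}
    for key, value in raw.items():
        section, fname = _KEY_MAP[key]
        by_section.setdefault(section, {})[fname] = _coerce(key, value)

    optics = OpticsSpec(**by_section.get("optics", {}))
    chamber = ChamberSpec(**by_section.get("chamber", {}))
    detection = DetectionParams(**by_section.get("detection", {}))
    sedimentation = SedimentationParams(**by_section.get("sedimentation", {}))
    staining = StainingModelParams(**by_section.get("simulator.staining", {}))
    condition = StainingCondition(**by_section.get("simulator.condition", {}))
    sim_kwargs = by_section.get("simulator", {})
    simulator = SimulatorParams(staining=staining, condition=condition, **sim_kwargs)

    supplied_volume = "analysis_volume" in raw
    supplied_geometry = any(k in raw for k in ("fov_x", "fov_y", "h_c", "n_areas"))
    if supplied_volume and supplied_geometry:
        geo = chamber.geometric_volume_nl(optics)
        if abs(geo - chamber.analysis_volume) / chamber.analysis_volume > 0.01:
            logger.warning(
                "analysis_volume=%.1f nL differs from FOV x h_c x n_areas = %.1f nL; "
                "the configured analysis_volume is used for concentrations",
                chamber.analysis_volume,
                geo,
            )

    return PipelineConfig(
        optics=optics,
        chamber=chamber,
        detection=detection,
        sedimentation=sedimentation,
        simulator=simulator,
    )


def config_to_mapping(cfg: PipelineConfig) -> dict:
    """Flatten a configuration back to the key/value form of the file format."""
    out: dict = {}
    for section in ("optics", "chamber", "detection", "sedimentation"):
        out.update(dataclasses.asdict(getattr(cfg, section)))
    sim = dataclasses.asdict(cfg.simulator)
    staining = sim.pop("staining")
    condition = sim.pop("condition")
    out.update(sim)
    out.update(staining)
    out.update(condition)
    return out


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write the fully resolved configuration; re-loading round-trips."""
    Path(path).write_text(yaml.safe_dump(config_to_mapping(cfg), sort_keys=True))
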