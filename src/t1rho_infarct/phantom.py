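"""Synthetic short-axis left-ventricle phantom with spin-lock (T1ρ) contrast.

The phantom is a stack of identical short-axis slices: a circular blood pool
surrounded by an annular myocardium, with a sectoral infarct of configurable
angular extent and transmural depth. Tissue signal follows mono-exponential
rotating-frame decay ``S(TSL) = s0 · exp(−TSL / T1ρ)``; voxels on tissue
boundaries mix signals in proportion to their tissue fractions, obtained by
rasterizing the geometry on a supersampled grid and block-averaging.

All "true_*" quantities are computed analytically from the configuration,
never from the raster, so they can serve as ground truth for the raster-based
pipeline downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .chords import ContourPair

TISSUES = ("background", "blood", "myocardium", "infarct")

#: spin-lock schedule (ms) used throughout: five durations spanning 6-48 ms
DEFAULT_TSL_MS = (6.0, 18.0, 30.0, 42.0, 48.0)


class ConfigurationError(ValueError):
    """Raised when a phantom configuration is geometrically impossible."""


@dataclass(frozen=True)
class TissueParams:
    """Relaxation constant and equilibrium amplitude of one tissue class.

    t1rho : ms, rotating-frame relaxation time (> 0)
    s0    : equilibrium signal amplitude, arbitrary units (>= 0)
    """

    t1rho: float
    s0: float

    def __post_init__(self) -> None:
        if self.t1rho <= 0:
            raise ConfigurationError(f"t1rho must be > 0, got {self.t1rho}")
        if self.s0 < 0:
            raise ConfigurationError(f"s0 must be >= 0, got {self.s0}")


def default_tissue_params() -> dict[str, TissueParams]:
    """Default tissue constants.

    Myocardium and infarct T1ρ are the remote (47.2 ms) and chronic-scar
    (91.7 ms) values reported for swine at 3 T.  Blood and background values
    are placeholders chosen only to reproduce the qualitative brightness
    ranking blood > infarct > myocardium on T1ρ-weighted images; they are not
    literature values.
    """
    return {
        "background": TissueParams(t1rho=1e3, s0=0.0),
        "blood": TissueParams(t1rho=150.0, s0=130.0),
        "myocardium": TissueParams(t1rho=47.2, s0=100.0),
        "infarct": TissueParams(t1rho=91.7, s0=100.0),
    }


@dataclass(frozen=True)
class PhantomConfig:
    """Full generative description of the synthetic LV.

    Geometry defaults mirror a high-resolution 3 T cardiac protocol:
    192 × 192 matrix at 0.64 mm in-plane, 20 slices of 2.6 mm.
    Angles are degrees counterclockwise from the +x (column) axis.
    """

    matrix: tuple[int, int] = (192, 192)
    n_slices: int = 20
    pixel_spacing: float = 0.64          # mm, isotropic in-plane
    slice_thickness: float = 2.6         # mm
    epi_radius: float = 30.0             # mm
    endo_radius: float = 20.0            # mm
    blood_radius: float | None = None    # mm; defaults to endo_radius
    infarct_center_angle: float = 210.0  # deg
    infarct_angular_extent: float = 0.211 * 360.0  # deg
    infarct_transmural_profile: tuple[float, ...] = (1.0,)
    infarct_profile_edges: tuple[float, ...] | None = None
    apical_extent: tuple[int, int] | None = None   # slice range [start, stop)
    tissue_params: dict[str, TissueParams] = field(
        default_factory=default_tissue_params
    )
    tsl_ms: tuple[float, ...] = DEFAULT_TSL_MS
    spin_lock_amplitude_hz: float = 500.0
    noise_sigma: float = 2.0             # signal units (SNR 50 at s0 = 100)
    supersample_factor: int = 4
    n_contour_points: int = 360
    seed: int = 0

    def __post_init__(self) -> None:
        nx, ny = self.matrix
        if nx < 2 or ny < 2:
            raise ConfigurationError(f"matrix too small: {self.matrix}")
        if self.endo_radius >= self.epi_radius:
            raise ConfigurationError(
                f"endo_radius ({self.endo_radius} mm) must be smaller than "
                f"epi_radius ({self.epi_radius} mm)"
            )
        half_fov = 0.5 * min(nx, ny) * self.pixel_spacing
        if self.epi_radius >= half_fov:
            raise ConfigurationError(
                f"epi_radius ({self.epi_radius} mm) does not fit inside the "
                f"matrix (half field of view {half_fov:.2f} mm)"
            )
        if not 0.0 <= self.infarct_angular_extent <= 360.0:
            raise ConfigurationError(
                f"infarct_angular_extent must be in [0, 360], got "
                f"{self.infarct_angular_extent}"
            )
        if any(not 0.0 <= f <= 1.0 for f in self.infarct_transmural_profile):
            raise ConfigurationError(
                "transmural profile entries must lie in [0, 1]"
            )
        if self.infarct_profile_edges is not None:
            edges = self.infarct_profile_edges
            if len(edges) != len(self.infarct_transmural_profile) + 1:
                raise ConfigurationError(
                    "infarct_profile_edges must have one more entry than the "
                    "transmural profile"
                )
            if edges[0] != 0.0 or edges[-1] != 1.0 or np.any(np.diff(edges) <= 0):
                raise ConfigurationError(
                    "infarct_profile_edges must increase from 0.0 to 1.0"
                )
        if self.supersample_factor < 1:
            raise ConfigurationError("supersample_factor must be >= 1")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.blood_radius is not None and self.blood_radius > self.endo_radius:
            raise ConfigurationError(
                f"blood_radius ({self.blood_radius} mm) exceeds endo_radius"
            )
        start, stop = self.infarct_slices
        if not (0 <= start <= stop <= self.n_slices):
            raise ConfigurationError(
                f"apical_extent {self.apical_extent} outside slice range "
                f"[0, {self.n_slices})"
            )

    # -- derived geometry -------------------------------------------------

    @property
    def infarct_slices(self) -> tuple[int, int]:
        """Slice index range [start, stop) occupied by the infarct."""
        if self.apical_extent is None:
            return (0, self.n_slices)
        return tuple(self.apical_extent)

    @property
    def center_mm(self) -> tuple[float, float]:
        """LV axis position (x, y) in mm, at the matrix center."""
        nx, ny = self.matrix
        return ((nx - 1) / 2.0 * self.pixel_spacing,
                (ny - 1) / 2.0 * self.pixel_spacing)

    @property
    def wall_thickness(self) -> float:
        return self.epi_radius - self.endo_radius

    def profile_edges_deg(self) -> np.ndarray:
        """Angular bin edges of the transmural profile, degrees from arc start."""
        n = len(self.infarct_transmural_profile)
        if self.infarct_profile_edges is not None:
            rel = np.asarray(self.infarct_profile_edges)
        else:
            rel = np.linspace(0.0, 1.0, n + 1)
        return rel * self.infarct_angular_extent

    @property
    def arc_start_deg(self) -> float:
        return self.infarct_center_angle - self.infarct_angular_extent / 2.0


@dataclass
class GroundTruth:
    """Raster labels plus analytically exact summary quantities.

    label_volume        : (n_slices, ny, nx) int8, majority tissue per voxel
    partial_volume_maps : (n_slices, ny, nx, 4) float, tissue fractions
                          ordered as TISSUES, summing to 1 per voxel
    contours            : per-slice epicardial/endocardial polygons
    true_* quantities   : closed-form values from the configuration
    """

    label_volume: np.ndarray
    partial_volume_maps: np.ndarray
    contours: list[ContourPair]
    true_infarct_perimeter_fraction: float
    true_infarct_volume: float        # mL
    true_lv_myocardial_volume: float  # mL (myocardium + infarct)
    true_nontransmural_infarct_fraction: float
    config: PhantomConfig
    tissues: tuple[str, ...] = TISSUES

    def tissue_index(self, name: str) -> int:
        return self.tissues.index(name)

    def tissue_mask(self, name: str) -> np.ndarray:
        return self.label_volume == self.tissue_index(name)

    def pure_tissue_mask(self, name: str, min_fraction: float = 1.0 - 1e-9) -> np.ndarray:
        """Voxels whose partial-volume fraction for ``name`` is (near) one."""
        return self.partial_volume_maps[..., self.tissue_index(name)] >= min_fraction

    @property
    def myocardial_mask(self) -> np.ndarray:
        return self.tissue_mask("myocardium") | self.tissue_mask("infarct")

    @property
    def voxel_volume_mm3(self) -> float:
        c = self.config
        return c.pixel_spacing ** 2 * c.slice_thickness


@dataclass
class TSLSeries:
    """Multi-slice, multi-spin-lock-duration magnitude image stack.

    data indexed (slice, row, col, tsl_index), arbitrary signal units.
    """

    data: np.ndarray
    tsl_ms: tuple[float, ...]
    spin_lock_amplitude_hz: float
    pixel_spacing: float
    slice_thickness: float

    def __post_init__(self) -> None:
        tsl = np.asarray(self.tsl_ms, dtype=float)
        if tsl.ndim != 1 or len(tsl) < 1:
            raise ValueError("tsl_ms must be a non-empty 1-D sequence")
        if np.any(np.diff(tsl) <= 0):
            raise ValueError("tsl_ms must be strictly increasing")
        if self.data.ndim != 4 or self.data.shape[-1] != len(tsl):
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with "
                f"{len(tsl)} spin-lock durations"
            )
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# geometry rasterization
# ---------------------------------------------------------------------------

def _wrap_deg(angle: np.ndarray) -> np.ndarray:
    return np.mod(angle, 360.0)


def _infarct_depth_at(config: PhantomConfig, theta_deg: np.ndarray) -> np.ndarray:
    """Infarcted wall-depth fraction at each angle (0 where outside the arc)."""
    depth = np.zeros_like(theta_deg, dtype=float)
    if config.infarct_angular_extent <= 0:
        return depth
    rel = _wrap_deg(theta_deg - config.arc_start_deg)
    inside = rel < config.infarct_angular_extent
    edges = config.profile_edges_deg()
    profile = np.asarray(config.infarct_transmural_profile)
    idx = np.clip(np.searchsorted(edges, rel[inside], side="right") - 1,
                  0, len(profile) - 1)
    depth[inside] = profile[idx]
    return depth


def _rasterize_slice(config: PhantomConfig, with_infarct: bool) -> np.ndarray:
    """Partial-volume fractions (ny, nx, 4) for one slice pattern."""
    nx, ny = config.matrix
    ss = config.supersample_factor
    cx, cy = config.center_mm
    # supersampled sample positions at sub-pixel centers, mm
    xs = (np.arange(nx * ss) + 0.5) / ss - 0.5
    ys = (np.arange(ny * ss) + 0.5) / ss - 0.5
    X, Y = np.meshgrid(xs * config.pixel_spacing, ys * config.pixel_spacing)
    r = np.hypot(X - cx, Y - cy)
    theta = np.degrees(np.arctan2(Y - cy, X - cx))

    blood_r = config.blood_radius if config.blood_radius is not None else config.endo_radius
    label = np.zeros(r.shape, dtype=np.int8)  # background
    label[r <= config.epi_radius] = TISSUES.index("myocardium")
    label[r <= blood_r] = TISSUES.index("blood")
    if with_infarct and config.infarct_angular_extent > 0:
        depth = _infarct_depth_at(config, theta)
        d_point = (r - config.endo_radius) / config.wall_thickness
        infarcted = (
            (r > config.endo_radius)
            & (r <= config.epi_radius)
            & (d_point < depth)
        )
        label[infarcted] = TISSUES.index("infarct")

    fractions = np.empty((ny, nx, len(TISSUES)))
    for t in range(len(TISSUES)):
        binary = (label == t).astype(float)
        fractions[..., t] = binary.reshape(ny, ss, nx, ss).mean(axis=(1, 3))
    return fractions


def _circle_polygon(cx: float, cy: float, radius: float, n: int,
                    spacing: float) -> np.ndarray:
    """Closed CCW polygon approximating a circle, pixel-center coordinates."""
    theta = np.linspace(0.0, 2.0 * math.pi, n + 1)  # last point repeats first
    x = (cx + radius * np.cos(theta)) / spacing
    y = (cy + radius * np.sin(theta)) / spacing
    pts = np.column_stack([x, y])
    pts[-1] = pts[0]
    return pts


# ---------------------------------------------------------------------------
# analytic ground truth
# ---------------------------------------------------------------------------

def _sector_area_mm2(config: PhantomConfig, depth: float, extent_deg: float) -> float:
    """Area of a wall sector infarcted from the endocardium to depth fraction."""
    r_in = config.endo_radius
    r_out = config.endo_radius + depth * config.wall_thickness
    return 0.5 * math.radians(extent_deg) * (r_out ** 2 - r_in ** 2)


def analytic_infarct_volume_ml(config: PhantomConfig) -> float:
    """Closed-form infarct volume (mL) from the angular depth profile."""
    edges = config.profile_edges_deg()
    widths = np.diff(edges)
    area = sum(
        _sector_area_mm2(config, d, w)
        for d, w in zip(config.infarct_transmural_profile, widths)
    )
    start, stop = config.infarct_slices
    return area * (stop - start) * config.slice_thickness / 1000.0


def analytic_lv_volume_ml(config: PhantomConfig) -> float:
    """Closed-form myocardial (wall) volume of the full stack, mL."""
    area = math.pi * (config.epi_radius ** 2 - config.endo_radius ** 2)
    return area * config.n_slices * config.slice_thickness / 1000.0


def analytic_perimeter_fraction(config: PhantomConfig) -> float:
    """Endocardial arc fraction adjacent to infarct, summed over all slices."""
    if config.infarct_angular_extent <= 0:
        return 0.0
    edges = config.profile_edges_deg()
    widths = np.diff(edges)
    arc = sum(w for d, w in zip(config.infarct_transmural_profile, widths) if d > 0)
    start, stop = config.infarct_slices
    return (arc / 360.0) * (stop - start) / config.n_slices


def analytic_nontransmural_fraction(config: PhantomConfig) -> float:
    """Fraction of infarct volume lying in partial-thickness (depth < 1) arcs."""
    total = analytic_infarct_volume_ml(config)
    if total == 0:
        return 0.0
    edges = config.profile_edges_deg()
    widths = np.diff(edges)
    area_nt = sum(
        _sector_area_mm2(config, d, w)
        for d, w in zip(config.infarct_transmural_profile, widths)
        if 0 < d < 1.0
    )
    start, stop = config.infarct_slices
    vol_nt = area_nt * (stop - start) * config.slice_thickness / 1000.0
    return vol_nt / total


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def generate_phantom(config: PhantomConfig) -> GroundTruth:
    """Rasterize the phantom and assemble analytic ground truth.

    The geometry is rasterized on a grid supersampled in-plane by
    ``config.supersample_factor``; block averages give per-voxel tissue
    fractions and the majority tissue gives the label volume.  Contours are
    traced as closed counterclockwise polygons at the native resolution.
    """
    nx, ny = config.matrix
    with_inf = _rasterize_slice(config, with_infarct=True)
    without_inf = (
        _rasterize_slice(config, with_infarct=False)
        if config.infarct_slices != (0, config.n_slices)
        or config.infarct_angular_extent <= 0
        else with_inf
    )
    start, stop = config.infarct_slices
    pv = np.empty((config.n_slices, ny, nx, len(TISSUES)))
    for z in range(config.n_slices):
        infarcted_slice = start <= z < stop and config.infarct_angular_extent > 0
        pv[z] = with_inf if infarcted_slice else without_inf
    label = np.argmax(pv, axis=-1).astype(np.int8)

    cx, cy = config.center_mm
    contours = [
        ContourPair(
            slice_index=z,
            epicardium=_circle_polygon(cx, cy, config.epi_radius,
                                       config.n_contour_points,
                                       config.pixel_spacing),
            endocardium=_circle_polygon(cx, cy, config.endo_radius,
                                        config.n_contour_points,
                                        config.pixel_spacing),
            pixel_spacing=config.pixel_spacing,
        )
        for z in range(config.n_slices)
    ]
    return GroundTruth(
        label_volume=label,
        partial_volume_maps=pv,
        contours=contours,
        true_infarct_perimeter_fraction=analytic_perimeter_fraction(config),
        true_infarct_volume=analytic_infarct_volume_ml(config),
        true_lv_myocardial_volume=analytic_lv_volume_ml(config),
        true_nontransmural_infarct_fraction=analytic_nontransmural_fraction(config),
        config=config,
    )


def simulate_tsl_series(truth: GroundTruth,
                        config: PhantomConfig | None = None) -> TSLSeries:
    """Noiseless T1ρ-weighted stack across the spin-lock schedule.

    Per-voxel signal is the tissue-fraction-weighted sum of mono-exponential
    decays: ``S(TSL) = Σ_t frac_t · s0_t · exp(−TSL / T1ρ_t)``.  A voxel that
    is 100% one tissue therefore decays exactly mono-exponentially.
    """
    config = config or truth.config
    tsl = np.asarray(config.tsl_ms, dtype=float)
    pv = truth.partial_volume_maps
    data = np.zeros(pv.shape[:3] + (len(tsl),))
    for t, name in enumerate(truth.tissues):
        params = config.tissue_params[name]
        if params.s0 == 0:
            continue
        decay = params.s0 * np.exp(-tsl / params.t1rho)  # (n_tsl,)
        data += pv[..., t, None] * decay
    return TSLSeries(
        data=data,
        tsl_ms=tuple(tsl),
        spin_lock_amplitude_hz=config.spin_lock_amplitude_hz,
        pixel_spacing=config.pixel_spacing,
        slice_thickness=config.slice_thickness,
    )


def add_noise(series: TSLSeries, sigma: float, seed: int,
              model: str = "rician") -> TSLSeries:
    """Add magnitude (Rician) or clipped Gaussian noise, deterministically.

    Rician noise is the magnitude of the true signal perturbed by two
    independent zero-mean Gaussian channels of standard deviation ``sigma``
    (real and imaginary receiver channels); in air (S = 0) this reduces to a
    Rayleigh distribution with mean ``sigma·√(π/2)``.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if model not in ("rician", "gaussian"):
        raise ValueError(f"unknown noise model {model!r}")
    if sigma == 0:
        return replace(series, data=series.data.copy())
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=series.data.shape)
    if model == "rician":
        n2 = rng.normal(0.0, sigma, size=series.data.shape)
        noisy = np.hypot(series.data + n1, n2)
    else:
        noisy = np.clip(series.data + n1, 0.0, None)
    return replace(series, data=noisy)


#: reference-modality tissue means, arbitrary units: scar retains the agent
#: and is brightest, viable myocardium is nulled, blood is intermediate
REFERENCE_TISSUE_MEANS = {
    "background": 0.0,
    "blood": 60.0,
    "myocardium": 20.0,
    "infarct": 100.0,
}


def simulate_reference_modality(truth: GroundTruth,
                                config: PhantomConfig | None = None,
                                seed: int | None = None,
                                sigma: float | None = None,
                                model: str = "rician") -> np.ndarray:
    """Simulate a contrast-enhanced-style reference image of the same geometry.

    Stands in for the second arm of a method comparison: infarct hyperintense,
    myocardium suppressed, blood intermediate.  Same partial-volume mixing and
    noise contract as the T1ρ-weighted stack.
    """
    config = config or truth.config
    sigma = config.noise_sigma if sigma is None else sigma
    seed = config.seed + 1 if seed is None else seed
    pv = truth.partial_volume_maps
    image = np.zeros(pv.shape[:3])
    for t, name in enumerate(truth.tissues):
        image += pv[..., t] * REFERENCE_TISSUE_MEANS[name]
    if sigma > 0:
        rng = np.random.default_rng(seed)
        if model == "rician":
            image = np.hypot(image + rng.normal(0, sigma, image.shape),
                             rng.normal(0, sigma, image.shape))
        else:
            image = np.clip(image + rng.normal(0, sigma, image.shape), 0, None)
    return image


# ---------------------------------------------------------------------------
# configuration solvers (inverse geometry)
# ---------------------------------------------------------------------------

def extent_for_perimeter_fraction(fraction: float) -> float:
    """Angular extent (deg) of a full-arc infarct with a given endocardial
    perimeter fraction, for an infarct spanning every slice."""
    if not 0 <= fraction <= 1:
        raise ConfigurationError("perimeter fraction must be in [0, 1]")
    return fraction * 360.0


def extent_for_infarct_volume(config: PhantomConfig, volume_ml: float) -> float:
    """Angular extent (deg) giving a fully transmural infarct of the requested
    volume within the configured slab of infarct slices."""
    start, stop = config.infarct_slices
    slab_ml = (
        _sector_area_mm2(config, 1.0, 360.0)
        * (stop - start) * config.slice_thickness / 1000.0
    )
    if not 0 <= volume_ml <= slab_ml:
        raise ConfigurationError(
            f"requested volume {volume_ml} mL outside [0, {slab_ml:.2f}] mL"
        )
    return 360.0 * volume_ml / slab_ml


def partial_depth_arc_for_fraction(config: PhantomConfig,
                                   transmural_extent_deg: float,
                                   depth: float,
                                   target_fraction: float) -> float:
    """Width (deg) of a partial-thickness border arc at the given depth such
    that it holds ``target_fraction`` of the total infarct volume.

    Solves θ_n · A(d) / (θ_t · A(1) + θ_n · A(d)) = f for θ_n, where A(d) is
    the wall cross-section area infarcted to depth fraction d per degree.
    """
    if not 0 < depth < 1:
        raise ConfigurationError("depth must be in (0, 1) for a border arc")
    if not 0 <= target_fraction < 1:
        raise ConfigurationError("target_fraction must be in [0, 1)")
    a_full = _sector_area_mm2(config, 1.0, 1.0)
    a_part = _sector_area_mm2(config, depth, 1.0)
    return (target_fraction / (1.0 - target_fraction)
            * transmural_extent_deg * a_full / a_part)
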