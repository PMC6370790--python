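"""Seeded synthetic worlds: climate rasters, species pools, ranges, specimens.

The generator emulates the data-generating context of a continental
butterfly-assemblage study: a projected equal-area plane with a north-south
temperature gradient, insolation and humidity fields tied to temperature,
a species pool whose thermal optima are coupled to true colour lightness
through a configurable slope, climate-threshold range polygons, and rendered
specimen images (body + four wings) in which the thermoregulatorily relevant
region — body plus the proximal third of each wing — carries the species'
true lightness while the distal wing carries a deliberately different value
so that region-of-interest errors are detectable.

Everything is driven by one integer seed; identical configs give
bit-identical rasters, polygons and images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry.base import BaseGeometry

from .lightness import SpecimenImage
from .raster import Raster

FAMILY_NAMES = ("Lycaenidae", "Nymphalidae", "Papilionidae", "Pieridae")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic continent.

    ``beta`` is the slope of a species' thermal optimum (°C) per unit of
    true dorsal lightness (0-255): positive beta places light species in
    warm climates, the pattern expected under thermal melanism.
    """

    seed: int = 0
    extent: tuple[float, float, float, float] = (0.0, 0.0, 2_000_000.0, 1_500_000.0)
    raster_resolution: float = 25_000.0          # metres / pixel
    crs: str = "SYNTH:EA1"                       # synthetic equal-area plane
    n_species: int = 120
    families: tuple[tuple[str, float], ...] = (
        ("Lycaenidae", 0.35), ("Nymphalidae", 0.35),
        ("Papilionidae", 0.10), ("Pieridae", 0.20))
    lightness_range: tuple[float, float] = (60.0, 200.0)
    beta: float = 0.12                            # °C per lightness unit
    response: str = "linear"                      # linear | hump | U
    niche_width: float = 12.0                     # °C
    noise_sd_optimum: float = 2.0                 # °C
    noise_sd_lightness: float = 2.0               # units, quadratic responses
    noise_sd_climate: float = 1.0                 # °C-scale field noise
    pixel_noise_sd: float = 3.0                   # grayscale units
    dorsal_ventral_offset: float = 30.0           # ventral lighter
    distal_offset: float = 40.0                   # distal wing vs ROI
    morph_spread: float = 4.0                     # +/- around true lightness
    morph2_prob: float = 0.15
    # climate construction
    tmp_south: float = 25.0                       # °C at y_min
    tmp_north: float = -5.0                       # °C at y_max
    ins_base: float = 150.0                       # W m^-2 at 0 °C
    ins_per_degc: float = 5.0
    hum_base: float = 75.0                        # % at 0 °C
    hum_per_degc: float = 1.0
    seasonal_amp: dict = field(default_factory=lambda: {
        "TMP": 8.0, "INS": 40.0, "HUM": 4.0})
    noise_smoothness_px: float = 3.0

    def __post_init__(self) -> None:
        lo, hi = self.lightness_range
        if not (0 <= lo <= hi <= 255):
            raise ValueError("lightness_range must satisfy 0 <= low <= high <= 255")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.niche_width <= 0:
            raise ValueError("niche_width must be positive")
        if self.raster_resolution <= 0:
            raise ValueError("raster_resolution must be positive")
        x0, y0, x1, y1 = self.extent
        if x1 <= x0 or y1 <= y0:
            raise ValueError("extent is degenerate")
        props = [p for _, p in self.families]
        if not math.isclose(sum(props), 1.0, abs_tol=1e-9):
            raise ValueError("family proportions must sum to 1")
        if self.response not in ("linear", "hump", "U"):
            raise ValueError(f"unknown response {self.response!r}")

    @property
    def mean_temperature(self) -> float:
        return 0.5 * (self.tmp_south + self.tmp_north)


@dataclass(frozen=True)
class TrueSpecies:
    """Ground-truth species attributes for parameter-recovery checks."""

    species_id: str
    family: str
    true_lightness_dorsal: float
    true_lightness_ventral: float
    thermal_optimum: float
    n_morphs: int = 1

    def true_lightness(self, side: str) -> float:
        if side == "dorsal":
            return self.true_lightness_dorsal
        if side == "ventral":
            return self.true_lightness_ventral
        raise ValueError(f"side must be 'dorsal' or 'ventral', got {side!r}")


@dataclass(frozen=True)
class SpeciesRange:
    species_id: str
    polygon: BaseGeometry | None    # None iff empty
    empty: bool


def _rng(config: SynthConfig, *stream: int) -> np.random.Generator:
    """Deterministic sub-stream of the config's master seed."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, *stream]))


# ---------------------------------------------------------------------------
# climate

_VAR_STREAM = {"TMP": 1, "INS": 2, "HUM": 3}


def _smooth_noise(shape: tuple[int, int], sd: float, smooth_px: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Gaussian-filtered white noise rescaled to sample sd ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    white = rng.normal(size=shape)
    smooth = gaussian_filter(white, sigma=smooth_px, mode="reflect")
    s = smooth.std()
    if s > 0:
        smooth = smooth / s
    return sd * smooth


@dataclass(frozen=True)
class ClimateField:
    """Annual fields plus the 12 monthly layers they were split into."""

    annual: dict[str, Raster]            # var -> raster
    monthly: dict[str, list[Raster]]     # var -> 12 rasters


def gen_climate(config: SynthConfig) -> ClimateField:
    """Generate INS / TMP / HUM as annual fields plus 12 monthly layers.

    TMP is a north-south linear gradient plus smooth correlated noise; INS
    is a positive affine function of TMP plus independent smooth noise; HUM
    a negative affine function of TMP plus noise.  Monthly layers are the
    annual field plus a spatially constant zero-mean seasonal sinusoid, so
    averaging the 12 layers recovers the annual field exactly.
    """
    x0, y0, x1, y1 = config.extent
    res = config.raster_resolution
    nx = int(round((x1 - x0) / res))
    ny = int(round((y1 - y0) / res))
    if nx < 1 or ny < 1:
        raise ValueError("extent smaller than one pixel")

    def make(data: np.ndarray) -> Raster:
        return Raster(data, x0=x0, y_top=y0 + ny * res, res=res, crs=config.crs)

    # southness in [0, 1]: row 0 is the northern edge
    y_centers = (y0 + ny * res) - (np.arange(ny) + 0.5) * res
    southness = (y1 - y_centers) / (y1 - y0)
    tmp = (config.tmp_north
           + (config.tmp_south - config.tmp_north) * southness)[:, None]
    tmp = np.broadcast_to(tmp, (ny, nx)).copy()
    tmp += _smooth_noise((ny, nx), config.noise_sd_climate,
                         config.noise_smoothness_px, _rng(config, _VAR_STREAM["TMP"]))

    ins = config.ins_base + config.ins_per_degc * tmp
    ins += _smooth_noise((ny, nx), 5.0 * config.noise_sd_climate,
                         config.noise_smoothness_px, _rng(config, _VAR_STREAM["INS"]))
    hum = config.hum_base - config.hum_per_degc * tmp
    hum += _smooth_noise((ny, nx), config.noise_sd_climate,
                         config.noise_smoothness_px, _rng(config, _VAR_STREAM["HUM"]))
    hum = np.clip(hum, 0.0, 100.0)

    annual = {"TMP": make(tmp), "INS": make(ins), "HUM": make(hum)}
    monthly: dict[str, list[Raster]] = {}
    months = np.arange(12)
    for var, ras in annual.items():
        amp = config.seasonal_amp.get(var, 0.0)
        sign = -1.0 if var == "HUM" else 1.0   # humid winters, dry summers
        season = sign * amp * np.cos(2 * np.pi * (months + 0.5) / 12.0)
        monthly[var] = [ras.with_data(ras.data + s) for s in season]
    return ClimateField(annual=annual, monthly=monthly)


# ---------------------------------------------------------------------------
# species pool

def gen_species_pool(config: SynthConfig) -> list[TrueSpecies]:
    """Draw the species pool with lightness-coupled thermal optima.

    True dorsal lightness is uniform on integers within ``lightness_range``
    (8-bit scans quantize to integers, and integer truth makes the noiseless
    render -> extract round trip exact); ventral = dorsal +
    ``dorsal_ventral_offset`` clipped to [0, 255].  The thermal optimum is
    ``mean_temperature + beta * (dorsal - midrange) + N(0, noise_sd_optimum)``.

    With ``response`` set to "hump" or "U" the coupling is inverted: thermal
    optima are uniform over the temperature gradient and lightness is a
    concave (hump) or convex (U) quadratic function of the optimum plus
    N(0, noise_sd_lightness), so assemblage mean lightness responds
    quadratically to cell temperature.
    """
    rng = _rng(config, 10)
    lo, hi = config.lightness_range
    mid = 0.5 * (lo + hi)
    half_t = 0.5 * abs(config.tmp_south - config.tmp_north)
    names = [n for n, _ in config.families]
    props = [p for _, p in config.families]
    out: list[TrueSpecies] = []
    for i in range(config.n_species):
        if config.response == "linear":
            dorsal = float(rng.integers(int(math.ceil(lo)),
                                        int(math.floor(hi)), endpoint=True))
            opt = (config.mean_temperature + config.beta * (dorsal - mid)
                   + (rng.normal(0.0, config.noise_sd_optimum)
                      if config.noise_sd_optimum > 0 else 0.0))
        else:
            opt = float(rng.uniform(min(config.tmp_south, config.tmp_north),
                                    max(config.tmp_south, config.tmp_north)))
            u = (opt - config.mean_temperature) / half_t      # in [-1, 1]
            base = hi - (hi - lo) * u * u if config.response == "hump" \
                else lo + (hi - lo) * u * u
            if config.noise_sd_lightness > 0:
                base += rng.normal(0.0, config.noise_sd_lightness)
            dorsal = float(np.clip(round(base), 0, 255))
        ventral = float(np.clip(round(dorsal + config.dorsal_ventral_offset),
                                0, 255))
        fam = str(rng.choice(names, p=props))
        n_morphs = 2 if rng.random() < config.morph2_prob else 1
        out.append(TrueSpecies(
            species_id=f"sp{i:04d}", family=fam,
            true_lightness_dorsal=dorsal, true_lightness_ventral=ventral,
            thermal_optimum=float(opt), n_morphs=n_morphs))
    return out


# ---------------------------------------------------------------------------
# ranges

def _mask_to_polygon(mask: np.ndarray, ras: Raster) -> BaseGeometry | None:
    """Union of pixel squares where ``mask`` is true (row-run rectangles)."""
    boxes = []
    res = ras.res
    for i in range(mask.shape[0]):
        row = mask[i]
        if not row.any():
            continue
        # split true pixels into contiguous runs
        idx = np.flatnonzero(row)
        splits = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], splits + 1))
        ends = np.concatenate((splits, [len(idx) - 1]))
        y_hi = ras.y_top - i * res
        y_lo = ras.y_top - (i + 1) * res
        for s, e in zip(starts, ends):
            j0, j1 = idx[s], idx[e]
            boxes.append(shapely.box(ras.x0 + j0 * res, y_lo,
                                     ras.x0 + (j1 + 1) * res, y_hi))
    if not boxes:
        return None
    return shapely.union_all(boxes)


def range_mask(species: TrueSpecies, tmp: Raster, config: SynthConfig) -> np.ndarray:
    """Boolean presence pixels: |TMP - optimum| <= niche_width / 2."""
    return np.abs(tmp.data - species.thermal_optimum) <= config.niche_width / 2.0


def gen_ranges(pool: list[TrueSpecies], tmp: Raster,
               config: SynthConfig) -> dict[str, SpeciesRange]:
    """Climate-threshold range polygons; empty ranges allowed and flagged."""
    ranges: dict[str, SpeciesRange] = {}
    for sp in pool:
        poly = _mask_to_polygon(range_mask(sp, tmp, config), tmp)
        ranges[sp.species_id] = SpeciesRange(
            species_id=sp.species_id, polygon=poly, empty=poly is None)
    return ranges


# ---------------------------------------------------------------------------
# specimen rendering

IMAGE_SHAPE = (320, 440)  # (height, width)


@dataclass(frozen=True)
class Wing:
    polygon: np.ndarray          # (n, 2) x,y vertices
    base: tuple[float, float]    # junction with body
    tip: tuple[float, float]


@dataclass(frozen=True)
class SpecimenGeometry:
    body: np.ndarray             # (n, 2) polygon approximating the body
    wings: tuple[Wing, ...]


def _ellipse_polygon(cx: float, cy: float, ax: float, ay: float,
                     n: int = 64) -> np.ndarray:
    # phase offset keeps vertices (and hence edges) off pixel centres
    th = 2 * np.pi * (np.arange(n) + 0.37) / n
    return np.column_stack([cx + ax * np.cos(th), cy + ay * np.sin(th)])


def specimen_geometry(image_shape: tuple[int, int] = IMAGE_SHAPE) -> SpecimenGeometry:
    """Canonical body + four-wing layout, scaled to the image.

    Coordinates are (x=column, y=row).  Fractional vertices keep polygon
    edges off pixel centres so point-in-polygon tests are unambiguous.
    """
    h, w = image_shape
    sx, sy = w / 440.0, h / 320.0

    def pt(x: float, y: float) -> tuple[float, float]:
        return (x * sx, y * sy)

    body = _ellipse_polygon(*pt(220.15, 160.23), 20.3 * sx, 95.4 * sy)

    def wing(verts, base, tip) -> Wing:
        return Wing(polygon=np.array([pt(*v) for v in verts]),
                    base=pt(*base), tip=pt(*tip))

    lf = wing([(202.3, 80.2), (30.7, 20.4), (60.2, 120.6), (202.3, 140.1)],
              base=(202.3, 110.15), tip=(45.45, 70.5))
    lh = wing([(202.3, 180.4), (70.6, 210.2), (100.3, 300.8), (202.3, 260.3)],
              base=(202.3, 220.35), tip=(85.45, 255.5))

    def mirror(wg: Wing) -> Wing:
        mx = 440.0 * sx
        return Wing(polygon=np.column_stack([mx - wg.polygon[:, 0],
                                             wg.polygon[:, 1]]),
                    base=(mx - wg.base[0], wg.base[1]),
                    tip=(mx - wg.tip[0], wg.tip[1]))

    return SpecimenGeometry(body=body, wings=(lf, lh, mirror(lf), mirror(lh)))


def _pixel_centers(image_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    return xx + 0.0, yy + 0.0


def _contains(polygon: np.ndarray, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    poly = shapely.Polygon(polygon)
    return shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)


def wing_axis_fraction(wing: Wing, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    """Normalized projection of pixel centres onto the base->tip axis."""
    bx, by = wing.base
    tx, ty = wing.tip
    ax_, ay_ = tx - bx, ty - by
    norm2 = ax_ * ax_ + ay_ * ay_
    if norm2 <= 1e-12:
        raise ValueError("degenerate wing axis (base == tip)")
    return ((xx - bx) * ax_ + (yy - by) * ay_) / norm2


@dataclass(frozen=True)
class SpecimenRender:
    image: SpecimenImage
    geometry: SpecimenGeometry
    distal_mask: np.ndarray


# body/wing layout is shared by all specimens at a given image size, so the
# rasterized ROI/distal masks are computed once per shape
_LAYOUT_CACHE: dict[tuple[int, int],
                    tuple[SpecimenGeometry, np.ndarray, np.ndarray]] = {}


def _layout(image_shape: tuple[int, int]
            ) -> tuple[SpecimenGeometry, np.ndarray, np.ndarray]:
    cached = _LAYOUT_CACHE.get(image_shape)
    if cached is not None:
        return cached
    geom = specimen_geometry(image_shape)
    xx, yy = _pixel_centers(image_shape)
    body = _contains(geom.body, xx, yy)
    roi = body.copy()
    distal = np.zeros_like(body)
    for wg in geom.wings:
        inside = _contains(wg.polygon, xx, yy) & ~body
        frac = wing_axis_fraction(wg, xx, yy)
        roi |= inside & (frac <= 1.0 / 3.0)
        distal |= inside & (frac > 1.0 / 3.0)
    _LAYOUT_CACHE[image_shape] = (geom, roi, distal)
    return geom, roi, distal


def render_specimen(species: TrueSpecies, side: str, config: SynthConfig,
                    morph_id: str = "m0", lightness_offset: float = 0.0,
                    sex: str = "monomorphic",
                    image_shape: tuple[int, int] = IMAGE_SHAPE) -> SpecimenRender:
    """Render one specimen image with its exact ROI mask.

    The ROI (body + proximal wing third along each base->tip axis) carries
    the species' true lightness for the requested side (+ an optional morph
    offset); the distal two thirds carry lightness + ``distal_offset`` so a
    wrong mask shifts the extracted value detectably.  Gaussian pixel noise
    is added inside the specimen, rounded and clipped to [0, 255].
    """
    value = species.true_lightness(side) + lightness_offset
    geom, roi, distal = _layout(image_shape)
    roi, distal = roi.copy(), distal.copy()

    img = np.full(image_shape, 255.0)
    img[roi] = value
    img[distal] = np.clip(value + config.distal_offset, 0, 255)

    if config.pixel_noise_sd > 0:
        side_code = 0 if side == "dorsal" else 1
        rng = _rng(config, 20, int(species.species_id[2:]), side_code,
                   abs(hash(morph_id)) % (2**31))
        spec = roi | distal
        img[spec] += rng.normal(0.0, config.pixel_noise_sd, size=int(spec.sum()))
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    pixels = np.repeat(pixels[:, :, None], 3, axis=2)

    image = SpecimenImage(pixels=pixels, roi_mask=roi,
                          species_id=species.species_id, side=side, sex=sex,
                          morph_id=morph_id, family=species.family)
    return SpecimenRender(image=image, geometry=geom, distal_mask=distal)


def render_species_images(species: TrueSpecies, config: SynthConfig,
                          image_shape: tuple[int, int] = IMAGE_SHAPE
                          ) -> list[SpecimenRender]:
    """All depicted images of a species: both sides, every morph.

    A two-morph species gets symmetric +/- ``morph_spread`` offsets so the
    unweighted morph mean equals the species' true lightness.
    """
    if species.n_morphs == 1:
        offsets = [0.0]
    else:
        offsets = [config.morph_spread, -config.morph_spread]
    out = []
    for side in ("dorsal", "ventral"):
        for k, off in enumerate(offsets):
            out.append(render_specimen(species, side, config,
                                       morph_id=f"m{k}", lightness_offset=off,
                                       image_shape=image_shape))
    return out


# ---------------------------------------------------------------------------
# convenience: one whole world

@dataclass(frozen=True)
class SynthWorld:
    config: SynthConfig
    climate: ClimateField
    pool: list[TrueSpecies]
    ranges: dict[str, SpeciesRange]


def gen_world(config: SynthConfig) -> SynthWorld:
    climate = gen_climate(config)
    pool = gen_species_pool(config)
    ranges = gen_ranges(pool, climate.annual["TMP"], config)
    return SynthWorld(config=config, climate=climate, pool=pool, ranges=ranges)


def with_seed(config: SynthConfig, seed: int) -> SynthConfig:
    return replace(config, seed=seed)
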