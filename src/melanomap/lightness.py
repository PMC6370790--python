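"""Per-species colour lightness from specimen images.

Colour lightness is the mean of the red, green and blue channel values over
a defined region of interest (ROI) — the body plus the third of each wing
closest to the body — ranging from 0 (black) to 255 (white).  Species
values are built from images by (1) keeping only images passing the sex
policy (females and monomorphic species by default), (2) averaging morphs
within each side, (3) requiring both a dorsal and a ventral value, and
(4) optionally collapsing species complexes to single analysis units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as MplPath


class EmptyROIError(ValueError):
    """The specimen's ROI mask selects no pixels — unusable specimen."""


@dataclass(frozen=True)
class SpecimenImage:
    """One scanned specimen: 24-bit RGB pixels plus its ROI mask."""

    pixels: np.ndarray            # (H, W, 3) uint8
    roi_mask: np.ndarray          # (H, W) bool
    species_id: str
    side: str                     # 'dorsal' | 'ventral'
    sex: str = "unknown"          # 'female' | 'male' | 'monomorphic' | 'unknown'
    morph_id: str = "m0"
    family: str | None = None

    def __post_init__(self) -> None:
        if self.side not in ("dorsal", "ventral"):
            raise ValueError(f"side must be dorsal or ventral, got {self.side!r}")
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be (H, W, 3)")
        if self.roi_mask.shape != self.pixels.shape[:2]:
            raise ValueError("roi_mask and pixels dimensions differ")


@dataclass(frozen=True)
class SpeciesTrait:
    """Per-species dorsal and ventral colour lightness, 0-255."""

    species_id: str
    family: str
    lightness_dorsal: float
    lightness_ventral: float
    n_images_dorsal: int
    n_images_ventral: int
    complex_id: str | None = None

    def lightness(self, side: str) -> float:
        return self.lightness_dorsal if side == "dorsal" else self.lightness_ventral


@dataclass(frozen=True)
class ExclusionRecord:
    species_id: str
    reason: str


DEFAULT_SEX_POLICY = ("female", "monomorphic")


def compute_lightness(image: SpecimenImage) -> float:
    """Mean of the R, G and B channels over the ROI, in [0, 255].

    The grand mean over all ROI pixels and all three channels, which equals
    the mean of per-channel means because the channels share the mask.
    Computed in double precision.
    """
    mask = np.asarray(image.roi_mask, dtype=bool)
    if not mask.any():
        raise EmptyROIError(f"empty ROI mask for {image.species_id}/{image.side}")
    return float(np.mean(image.pixels[mask].astype(np.float64)))


def build_roi_mask(body_polygon: np.ndarray,
                   wings: list,
                   image_shape: tuple[int, int]) -> np.ndarray:
    """ROI mask: body polygon plus the proximal third of each wing.

    Each wing carries a base (junction with body) and tip landmark; a wing
    pixel belongs to the ROI when the projection of its centre onto the
    base->tip axis lies within the first third of the axis length.  This is
    a distance-along-axis rule, not an area rule: it is well defined for any
    wing shape and matches "closest to the body".

    ``wings`` is a sequence of objects with ``polygon`` ((n, 2) array),
    ``base`` and ``tip`` ((x, y) tuples), e.g. :class:`melanomap.synth.Wing`.
    """
    h, w = image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)

    body = MplPath(body_polygon).contains_points(pts).reshape(h, w)
    mask = body.copy()
    for wing in wings:
        bx, by = wing.base
        tx, ty = wing.tip
        ax_, ay_ = tx - bx, ty - by
        norm2 = ax_ * ax_ + ay_ * ay_
        if norm2 <= 1e-12:
            raise ValueError("degenerate wing axis (base == tip)")
        inside = MplPath(wing.polygon).contains_points(pts).reshape(h, w) & ~body
        frac = ((xx - bx) * ax_ + (yy - by) * ay_) / norm2
        mask |= inside & (frac <= 1.0 / 3.0)
    return mask


def _morph_side_mean(images: list[SpecimenImage]) -> tuple[float, int]:
    """Unweighted mean over morphs of per-morph mean lightness."""
    by_morph: dict[str, list[float]] = {}
    for img in images:
        by_morph.setdefault(img.morph_id, []).append(compute_lightness(img))
    morph_means = [float(np.mean(v)) for v in by_morph.values()]
    return float(np.mean(morph_means)), len(images)


def species_lightness(images: list[SpecimenImage],
                      sex_policy: tuple[str, ...] = DEFAULT_SEX_POLICY
                      ) -> SpeciesTrait | ExclusionRecord:
    """Collapse a species' images to one dorsal and one ventral value.

    Images failing the sex policy are dropped; morphs are averaged per side
    (unweighted over morphs); a species missing either side after filtering
    is returned as an :class:`ExclusionRecord` rather than a trait.
    """
    if not images:
        raise ValueError("no images supplied")
    species_id = images[0].species_id
    if any(img.species_id != species_id for img in images):
        raise ValueError("images from multiple species supplied")
    families = {img.family for img in images if img.family is not None}
    if len(families) > 1:
        raise ValueError(
            f"conflicting family labels for {species_id}: {sorted(families)}")
    family = families.pop() if families else "unknown"

    kept = [img for img in images if img.sex in sex_policy]
    sides: dict[str, list[SpecimenImage]] = {"dorsal": [], "ventral": []}
    for img in kept:
        sides[img.side].append(img)

    missing = [s for s in ("dorsal", "ventral") if not sides[s]]
    if missing:
        return ExclusionRecord(species_id=species_id,
                               reason="missing " + " and ".join(missing))
    dorsal, n_d = _morph_side_mean(sides["dorsal"])
    ventral, n_v = _morph_side_mean(sides["ventral"])
    return SpeciesTrait(species_id=species_id, family=family,
                        lightness_dorsal=dorsal, lightness_ventral=ventral,
                        n_images_dorsal=n_d, n_images_ventral=n_v)


def complex_average(traits: list[SpeciesTrait],
                    complex_map: dict[str, str]) -> list[SpeciesTrait]:
    """Collapse species complexes to one trait row each.

    Members of a complex (taxa with unstable species/subspecies status) are
    replaced by a single row holding the unweighted mean of their dorsal and
    ventral lightness; non-members pass through unchanged.  Members of one
    complex must share a family.
    """
    by_complex: dict[str, list[SpeciesTrait]] = {}
    out: list[SpeciesTrait] = []
    for t in traits:
        cid = complex_map.get(t.species_id)
        if cid is None:
            out.append(t)
        else:
            by_complex.setdefault(cid, []).append(t)
    for cid, members in by_complex.items():
        fams = {m.family for m in members}
        if len(fams) > 1:
            raise ValueError(
                f"complex {cid} spans families {sorted(fams)}")
        out.append(SpeciesTrait(
            species_id=cid, family=members[0].family,
            lightness_dorsal=float(np.mean([m.lightness_dorsal for m in members])),
            lightness_ventral=float(np.mean([m.lightness_ventral for m in members])),
            n_images_dorsal=sum(m.n_images_dorsal for m in members),
            n_images_ventral=sum(m.n_images_ventral for m in members),
            complex_id=cid))
    return out


@dataclass(frozen=True)
class ValidationResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def cross_source_validation(traits_a: dict[str, float],
                            traits_b: dict[str, float]) -> ValidationResult:
    """OLS of source-b lightness on source-a lightness over shared species.

    Used to check that two independent image sources score the same species
    consistently (ideally slope ~ 1, r-squared near 1).
    """
    shared = sorted(set(traits_a) & set(traits_b))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared species, got {len(shared)}")
    import statsmodels.api as sm
    a = np.array([traits_a[s] for s in shared], dtype=float)
    b = np.array([traits_b[s] for s in shared], dtype=float)
    res = sm.OLS(b, sm.add_constant(a)).fit()
    return ValidationResult(slope=float(res.params[1]),
                            intercept=float(res.params[0]),
                            r2=float(res.rsquared),
                            p=float(res.pvalues[1]),
                            n=len(shared))


def traits_to_frame(traits: list[SpeciesTrait]):
    """Traits as a tidy DataFrame (CSV interface)."""
    import pandas as pd
    return pd.DataFrame([{
        "species_id": t.species_id, "family": t.family,
        "complex_id": t.complex_id or "",
        "lightness_dorsal": t.lightness_dorsal,
        "lightness_ventral": t.lightness_ventral,
        "n_images_dorsal": t.n_images_dorsal,
        "n_images_ventral": t.n_images_ventral,
    } for t in traits])
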