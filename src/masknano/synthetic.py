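"""Synthetic HAADF-STEM-like fiber cross-section images with ground truth.

The generator emulates the imagery the exposure model is calibrated on: a
dark embedding background, a mid-gray fiber disc, and bright near-spherical
TiO2 particles.  Constituent particles have lognormal diameters and are
grouped into agglomerates (clusters of overlapping discs); agglomerate
centers are placed homogeneously over the fiber cross-section by default.
Every image comes with an exact ground-truth table, so segmentation and
sizing can be benchmarked without any real micrographs.

The module also provides the Monte Carlo oracle for the ring-area surface
fraction model: sampling agglomerate centers in the cross-section disc and
counting those whose disc of diameter d_a touches the boundary estimates
exactly the probability the closed form computes.
"""

from __future__ import annotations

import dataclasses
import math
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import PlacementError, ValidationError
from .mask_data import LayerSpec, MaskSpec
from .surface import surface_fraction

PLACEMENTS = ("homogeneous", "surface_enriched", "core_enriched")


@dataclasses.dataclass
class SyntheticImageSpec:
    """Parameters of one synthetic cross-section image.

    Defaults describe a whole fiber imaged at 4 nm/px: a 4.5 µm fiber disc
    in a 1280 px frame, ~60 agglomerates of geometrically distributed
    constituent count (mean 1.6), constituent diameters lognormal with
    median 130 nm and geometric SD 1.6, HAADF-like intensity ordering
    (background 0.05 < fiber 0.45 < particles 0.95), 1 px Gaussian blur
    and additive Gaussian noise of SD 0.03 gray levels.
    """

    width: int = 1280
    height: int = 1280
    pixel_size: float = 4.0  # nm per pixel
    fiber_diameter: float = 4.5  # µm
    background_intensity: float = 0.05
    fiber_intensity: float = 0.45
    particle_intensity: float = 0.95
    n_agglomerates: int = 60
    mean_constituents_per_agglomerate: float = 1.6  # geometric distribution mean
    constituent_median: float = 130.0  # nm
    constituent_gsd: float = 1.6  # geometric standard deviation
    placement: str = "homogeneous"
    noise_sd: float = 0.03
    blur_sigma: float = 1.0  # pixels
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be > 0")
        if self.fiber_diameter <= 0:
            raise ValidationError("fiber_diameter must be > 0")
        if not (
            0.0
            <= self.background_intensity
            < self.fiber_intensity
            < self.particle_intensity
            <= 1.0
        ):
            raise ValidationError(
                "intensities must satisfy 0 <= background < fiber < particle <= 1"
            )
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise ValidationError("noise_sd and blur_sigma must be >= 0")
        if self.n_agglomerates < 0:
            raise ValidationError("n_agglomerates must be >= 0")
        if self.mean_constituents_per_agglomerate < 1:
            raise ValidationError("mean constituents per agglomerate must be >= 1")
        if self.constituent_gsd < 1:
            raise ValidationError("constituent_gsd must be >= 1")
        fiber_px = self.fiber_diameter * 1000.0 / self.pixel_size
        if fiber_px > min(self.width, self.height):
            raise ValidationError(
                f"fiber disc ({fiber_px:.0f} px) does not fit in the "
                f"{self.width}x{self.height} frame"
            )
        if self.constituent_median >= self.fiber_diameter * 1000.0:
            raise ValidationError(
                "constituent median diameter exceeds the fiber diameter"
            )
        if self.placement not in PLACEMENTS:
            raise ValidationError(f"unknown placement {self.placement!r}")


@dataclasses.dataclass
class GroundTruth:
    """Exact rendering truth for one synthetic image.

    ``particles`` has one row per constituent (diameter_nm, x_nm, y_nm,
    agglomerate_id); ``agglomerates`` one row per agglomerate with its
    composite minimum Feret diameter (of the union of member discs) and
    member count.  Coordinates are in nm from the top-left pixel center.
    """

    particles: pd.DataFrame
    agglomerates: pd.DataFrame
    fiber_diameter: float  # µm
    pixel_size: float  # nm per pixel


def _sample_radius(rng: np.random.Generator, n: int, placement: str) -> np.ndarray:
    """Radial positions (as fractions of the fiber radius) for agglomerate
    centers.  ``homogeneous`` is uniform over the disc area; the enriched
    variants bias outward / inward and exist only to probe the sensitivity
    of the homogeneity assumption."""
    u = rng.random(n)
    if placement == "homogeneous":
        return np.sqrt(u)
    if placement == "surface_enriched":
        return u**0.25
    return u  # core_enriched


def _union_min_feret(centers: np.ndarray, radii: np.ndarray, n_angles: int = 180) -> float:
    """Minimum Feret diameter of a union of discs, by angular scan of the
    projection width (exact per angle because disc projections are
    intervals)."""
    angles = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    directions = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    proj = centers @ directions.T  # (n_discs, n_angles)
    upper = (proj + radii[:, None]).max(axis=0)
    lower = (proj - radii[:, None]).min(axis=0)
    return float((upper - lower).min())


def _paint_disc(image: np.ndarray, cx: float, cy: float, radius: float, value: float) -> None:
    """Composite an anti-aliased bright disc (coordinates and radius in px)."""
    h, w = image.shape
    x0, x1 = max(0, int(cx - radius) - 2), min(w, int(cx + radius) + 3)
    y0, y1 = max(0, int(cy - radius) - 2), min(h, int(cy + radius) + 3)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    alpha = np.clip(0.5 + (radius - dist), 0.0, 1.0)
    patch = image[y0:y1, x0:x1]
    image[y0:y1, x0:x1] = alpha * value + (1.0 - alpha) * patch


def generate_image(spec: SyntheticImageSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic cross-section image with its ground truth.

    Deterministic for a given ``spec.seed``.  Raises
    :class:`PlacementError` (reporting the achieved count) if constituents
    cannot be kept inside the fiber disc after bounded retries.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ps = spec.pixel_size
    fiber_radius_nm = spec.fiber_diameter * 1000.0 / 2.0
    center_nm = np.array([spec.width / 2.0 * ps, spec.height / 2.0 * ps])

    mu = math.log(spec.constituent_median)
    sigma = math.log(spec.constituent_gsd)

    particle_rows: list[dict] = []
    agglomerate_rows: list[dict] = []
    for agg_id in range(spec.n_agglomerates):
        n_c = int(rng.geometric(1.0 / spec.mean_constituents_per_agglomerate))
        diameters = rng.lognormal(mu, sigma, size=n_c)
        radii = diameters / 2.0
        # first constituent at the agglomerate center; center must lie in the disc
        for _ in range(200):
            frac = _sample_radius(rng, 1, spec.placement)[0]
            theta = rng.uniform(0.0, 2.0 * math.pi)
            anchor = center_nm + frac * fiber_radius_nm * np.array(
                [math.cos(theta), math.sin(theta)]
            )
            if np.hypot(*(anchor - center_nm)) < fiber_radius_nm:
                break
        centers = [anchor]
        for k in range(1, n_c):
            placed = False
            for _ in range(50):
                parent_idx = int(rng.integers(len(centers)))
                phi = rng.uniform(0.0, 2.0 * math.pi)
                gap = 0.8 * (radii[k] + radii[parent_idx])
                cand = centers[parent_idx] + gap * np.array(
                    [math.cos(phi), math.sin(phi)]
                )
                if np.hypot(*(cand - center_nm)) < fiber_radius_nm:
                    centers.append(cand)
                    placed = True
                    break
            if not placed:
                raise PlacementError(
                    f"could not place constituent {k + 1} of agglomerate "
                    f"{agg_id} inside the fiber disc",
                    achieved=len(particle_rows) + len(centers),
                )
        centers_arr = np.array(centers)
        for (x, y), d in zip(centers_arr, diameters):
            particle_rows.append(
                {
                    "agglomerate_id": agg_id,
                    "diameter_nm": float(d),
                    "x_nm": float(x),
                    "y_nm": float(y),
                }
            )
        agglomerate_rows.append(
            {
                "agglomerate_id": agg_id,
                "n_constituents": n_c,
                "min_feret_nm": _union_min_feret(centers_arr, radii),
                "x_nm": float(centers_arr[:, 0].mean()),
                "y_nm": float(centers_arr[:, 1].mean()),
            }
        )

    image = np.full(
        (spec.height, spec.width), spec.background_intensity, dtype=np.float64
    )
    _paint_disc(
        image,
        center_nm[0] / ps,
        center_nm[1] / ps,
        fiber_radius_nm / ps,
        spec.fiber_intensity,
    )
    for row in particle_rows:
        _paint_disc(
            image,
            row["x_nm"] / ps,
            row["y_nm"] / ps,
            row["diameter_nm"] / 2.0 / ps,
            spec.particle_intensity,
        )
    if spec.blur_sigma > 0:
        image = ndi.gaussian_filter(image, spec.blur_sigma)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    particle_columns = ["agglomerate_id", "diameter_nm", "x_nm", "y_nm"]
    agglomerate_columns = [
        "agglomerate_id",
        "n_constituents",
        "min_feret_nm",
        "x_nm",
        "y_nm",
    ]
    truth = GroundTruth(
        particles=pd.DataFrame(particle_rows, columns=particle_columns),
        agglomerates=pd.DataFrame(agglomerate_rows, columns=agglomerate_columns),
        fiber_diameter=spec.fiber_diameter,
        pixel_size=ps,
    )
    return image, truth


class MCEstimate(NamedTuple):
    fraction: float
    se: float  # binomial standard error
    n: int


def mc_surface_fraction(
    fiber_diameter_um: float,
    agglomerate_diameter_nm: float,
    placement: str = "homogeneous",
    n_samples: int = 100_000,
    seed: int = 0,
) -> MCEstimate:
    """Monte Carlo estimate of the surface-accessible fraction.

    Samples agglomerate centers in the fiber cross-section disc and counts
    those whose distance to the boundary is less than d_a/2 — i.e. whose
    disc of diameter d_a touches or crosses the fiber surface.  For
    homogeneous placement this event's probability equals the closed-form
    ring-area ratio exactly, making the estimator an independent oracle
    for :func:`masknano.surface.surface_fraction`.
    """
    if fiber_diameter_um <= 0 or agglomerate_diameter_nm <= 0:
        raise ValidationError("fiber and agglomerate diameters must be > 0")
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    if placement not in PLACEMENTS:
        raise ValidationError(f"unknown placement {placement!r}")
    rng = np.random.default_rng(seed)
    radius = fiber_diameter_um / 2.0
    half_da = agglomerate_diameter_nm / 1000.0 / 2.0
    r = _sample_radius(rng, int(n_samples), placement) * radius
    hits = r > radius - half_da
    p = float(hits.mean())
    se = math.sqrt(p * (1.0 - p) / n_samples)
    return MCEstimate(p, se, int(n_samples))


def generate_mask_fixture(
    n_masks: int = 12,
    seed: int = 0,
    d_f_range: tuple[float, float] = (7.0, 35.0),
    d_a_range: tuple[float, float] = (110.0, 450.0),
    d_cp_range: tuple[float, float] = (89.0, 184.0),
    m_tot_range: tuple[float, float] = (800.0, 30_000.0),
    max_layers: int = 3,
) -> tuple[list[MaskSpec], pd.DataFrame]:
    """Random descriptor fixtures with analytically known derived columns.

    Every generated layer is a TiO2-containing cylindrical fiber; the
    expected per-layer surface fraction and (equal-split) per-mask surface
    mass are evaluated with the closed-form model and carried in the truth
    frame, for end-to-end pipeline regression tests.
    """
    for name, rng_pair in (
        ("d_f_range", d_f_range),
        ("d_a_range", d_a_range),
        ("d_cp_range", d_cp_range),
        ("m_tot_range", m_tot_range),
    ):
        lo, hi = rng_pair
        if lo <= 0 or hi < lo:
            raise ValidationError(f"{name} must be positive and ordered")
    if n_masks < 1 or max_layers < 1:
        raise ValidationError("n_masks and max_layers must be >= 1")

    rng = np.random.default_rng(seed)
    masks: list[MaskSpec] = []
    truth_rows: list[dict] = []
    positions = ("external", "central", "internal")
    for i in range(n_masks):
        mask_id = f"SynMask{i + 1:02d}"
        mask_type = "single_use" if rng.random() < 0.5 else "reusable"
        n_layers = int(rng.integers(1, max_layers + 1))
        m_tot = float(rng.uniform(*m_tot_range))
        layers = []
        fractions = []
        for j in range(n_layers):
            d_f = float(rng.uniform(*d_f_range))
            d_a = float(rng.uniform(*d_a_range))
            d_cp = float(rng.uniform(*d_cp_range))
            layer = LayerSpec(
                layer_id=positions[j] if n_layers <= 3 else f"layer{j}",
                position=positions[j] if n_layers <= 3 else "whole-mask",
                composition="Polyester",
                fiber_class="cylindrical_synthetic",
                d_f=round(d_f, 2),
                contains_tio2=True,
                d_a=round(d_a, 1),
                d_cp=round(d_cp, 1),
            )
            layers.append(layer)
        masks.append(
            MaskSpec(
                mask_id=mask_id,
                mask_type=mask_type,
                layers=layers,
                m_tot=round(m_tot, 1),
            )
        )
        # expectations use the rounded values actually stored in the spec
        fractions = [
            surface_fraction(layer.d_f, layer.d_a).fraction for layer in layers
        ]
        share = masks[-1].m_tot / n_layers
        expected_m_sf = sum(f * share for f in fractions)
        for layer, fraction in zip(layers, fractions):
            truth_rows.append(
                {
                    "mask_id": mask_id,
                    "layer_id": layer.layer_id,
                    "d_f_um": layer.d_f,
                    "d_a_nm": layer.d_a,
                    "expected_fraction": fraction,
                    "allocated_mass_ug": share,
                    "expected_mask_m_sf_ug": expected_m_sf,
                }
            )
    return masks, pd.DataFrame(truth_rows)
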