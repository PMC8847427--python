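"""Geometric model for the fraction and mass of TiO2 at the fiber surface.

Synthetic textile fibers are treated as cylinders of median diameter d_f.
TiO2 agglomerates (median minimum Feret diameter d_a) are assumed
homogeneously distributed over the fiber cross-section; an agglomerate is
*surface-accessible* when its disc touches the fiber boundary, i.e. when
its center lies in the outer ring of thickness d_a/2.  The surface
fraction is then the ring-to-disc area ratio

    F = (d_f^2 - (d_f - d_a)^2) / d_f^2,

and the mass at the fiber surface per mask is M_sf = sum_l F_l * M_l over
the TiO2-containing layers, where the M_l allocate the measured total mass
M_tot.  Bi-component microfibers expose more perimeter than a plain
cylinder; their ring area is scaled by the ratio of summed wedge
perimeters to the fiber perimeter.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

from .errors import ValidationError
from .mask_data import MaskSpec
from .units import NM_PER_UM

ALLOCATIONS = ("measured", "equal_split", "proportional_to_F")


@dataclasses.dataclass(frozen=True)
class SurfaceFractionResult:
    """Surface fraction F with the areas it is built from (µm²)."""

    fraction: float
    cross_section_area: float  # S_cs, µm²
    ring_area: float  # S_r (or S_r,mf when corrected), µm²
    corrected: bool = False  # bi-component perimeter correction applied


@dataclasses.dataclass(frozen=True)
class ExposureEstimate:
    """Per-mask surface-mass estimate with its per-layer breakdown."""

    mask_id: str
    layer_fractions: dict  # layer_id -> F
    layer_masses: dict  # layer_id -> allocated TiO2 mass, µg
    m_sf: float  # µg at the fiber surface
    m_tot: float  # µg total
    allocation: str


def surface_fraction(
    fiber_diameter_um: float, agglomerate_diameter_nm: float
) -> SurfaceFractionResult:
    """Fraction of homogeneously distributed agglomerates at the fiber surface.

    Parameters
    ----------
    fiber_diameter_um : median fiber diameter d_f (µm), > 0.
    agglomerate_diameter_nm : median agglomerate minimum Feret d_a (nm), > 0.

    Returns the ring-to-cross-section area ratio, clamped to [0, 1]; for
    d_a >= d_f the ring covers the whole disc and F = 1 (with a warning,
    since the homogeneous-cylinder picture degenerates there).
    """
    if fiber_diameter_um is None or fiber_diameter_um <= 0:
        raise ValidationError(f"fiber diameter must be > 0, got {fiber_diameter_um}")
    if agglomerate_diameter_nm is None or agglomerate_diameter_nm <= 0:
        raise ValidationError(
            f"agglomerate diameter must be > 0, got {agglomerate_diameter_nm}"
        )
    d_f = float(fiber_diameter_um)
    d_a = float(agglomerate_diameter_nm) / NM_PER_UM
    s_cs = math.pi / 4.0 * d_f**2
    if d_a >= d_f:
        warnings.warn(
            "agglomerate diameter >= fiber diameter; surface fraction clamped to 1",
            stacklevel=2,
        )
        return SurfaceFractionResult(1.0, s_cs, s_cs)
    fraction = (d_f**2 - (d_f - d_a) ** 2) / d_f**2
    return SurfaceFractionResult(fraction, s_cs, fraction * s_cs)


def bicomponent_correction(
    base: SurfaceFractionResult, perimeter_ratio: float
) -> SurfaceFractionResult:
    """Scale the ring area for bi-component (segmented-pie) microfibers.

    ``perimeter_ratio`` is the sum of the wedge perimeters over the fiber
    perimeter (>= 1: the wedge structure only adds exposed surface).  The
    corrected fraction is min(1, S_r * ratio / S_cs).
    """
    if base.corrected:
        raise ValidationError("surface fraction is already perimeter-corrected")
    if perimeter_ratio < 1:
        raise ValidationError(
            f"perimeter ratio must be >= 1, got {perimeter_ratio}"
        )
    ring_mf = base.ring_area * perimeter_ratio
    fraction = min(1.0, ring_mf / base.cross_section_area)
    return SurfaceFractionResult(
        fraction, base.cross_section_area, ring_mf, corrected=True
    )


def layer_surface_fraction(layer) -> SurfaceFractionResult:
    """Surface fraction for one layer, applying the bi-component
    correction when the fiber class requires it."""
    if layer.d_f is None or layer.d_a is None:
        raise ValidationError(
            f"layer {layer.layer_id!r}: d_f and d_a are required to model the "
            "surface fraction"
        )
    base = surface_fraction(layer.d_f, layer.d_a)
    if layer.fiber_class == "bicomponent":
        return bicomponent_correction(base, layer.perimeter_ratio)
    return base


def surface_mass(mask: MaskSpec, allocation: str = "equal_split") -> ExposureEstimate:
    """Estimate the TiO2 mass at the fiber surface of one mask (M_sf, µg).

    The measured total mass ``mask.m_tot`` is allocated across the
    TiO2-containing layers: per-layer digestion results are used whenever
    ``mask.layer_masses`` is present; otherwise the ``allocation`` strategy
    decides (``equal_split`` among TiO2-containing layers, or
    ``proportional_to_F``).  Layers without TiO2 receive zero mass.
    """
    if allocation not in ALLOCATIONS:
        raise ValidationError(f"unknown allocation strategy {allocation!r}")
    tio2_layers = mask.tio2_layers
    if not tio2_layers:
        if mask.m_tot > 0:
            raise ValidationError(
                f"mask {mask.mask_id!r}: m_tot = {mask.m_tot:g} µg but no layer "
                "contains TiO2"
            )
        fractions = {layer.layer_id: 0.0 for layer in mask.layers}
        masses = dict.fromkeys(fractions, 0.0)
        return ExposureEstimate(mask.mask_id, fractions, masses, 0.0, 0.0, allocation)

    fractions = {}
    for layer in mask.layers:
        fractions[layer.layer_id] = (
            layer_surface_fraction(layer).fraction if layer.contains_tio2 else 0.0
        )

    masses = dict.fromkeys(fractions, 0.0)
    if mask.layer_masses:
        if allocation == "measured" and set(mask.layer_masses) != {
            layer.layer_id for layer in tio2_layers
        }:
            raise ValidationError(
                f"mask {mask.mask_id!r}: measured allocation requires one "
                "layer mass per TiO2-containing layer"
            )
        for layer_id, value in mask.layer_masses.items():
            masses[layer_id] = value
    elif allocation == "measured":
        raise ValidationError(
            f"mask {mask.mask_id!r}: measured allocation requested but no "
            "per-layer masses are available"
        )
    elif allocation == "proportional_to_F":
        total_f = sum(fractions[layer.layer_id] for layer in tio2_layers)
        for layer in tio2_layers:
            masses[layer.layer_id] = (
                mask.m_tot * fractions[layer.layer_id] / total_f if total_f else 0.0
            )
    else:  # equal_split
        share = mask.m_tot / len(tio2_layers)
        for layer in tio2_layers:
            masses[layer.layer_id] = share

    m_sf = sum(fractions[lid] * masses[lid] for lid in fractions)
    return ExposureEstimate(
        mask_id=mask.mask_id,
        layer_fractions=fractions,
        layer_masses=masses,
        m_sf=m_sf,
        m_tot=mask.m_tot,
        allocation=allocation,
    )
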