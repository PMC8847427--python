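"""Domain types and table I/O for face-mask descriptor data.

A *mask descriptor table* is a comma-separated, UTF-8 file with one row per
(mask, layer).  Units are fixed per column and encoded in the column name:
``d_f_um`` (median fiber diameter, µm), ``d_a_nm`` / ``d_cp_nm`` (median
minimum-Feret diameters of agglomerates and constituent particles, nm),
``m_tot_ug`` (total TiO2 mass per mask, µg).  Absent values are written as
``NA``.  Thousands separators ("17,332") are normalized away at ingest.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

POSITIONS = ("external", "central", "internal", "whole-mask")
FIBER_CLASSES = (
    "cylindrical_synthetic",
    "bicomponent",
    "nonwoven_thermobonded",
    "nonwoven_meltblown",
    "cotton",
    "unknown",
)
MASK_TYPES = ("single_use", "reusable")

#: Columns that must be present in every mask descriptor table.
MANDATORY_COLUMNS = (
    "mask_id",
    "mask_type",
    "layer_id",
    "position",
    "composition",
    "fiber_class",
    "d_f_um",
    "contains_tio2",
    "d_a_nm",
    "d_cp_nm",
    "m_tot_ug",
)


@dataclasses.dataclass
class LayerSpec:
    """One textile layer of a face mask.

    ``d_f`` is the median fiber diameter in µm; ``d_a`` and ``d_cp`` are
    the median minimum Feret diameters of TiO2 agglomerates and of the
    constituent particles, in nm.  ``perimeter_ratio`` is the ratio of the
    summed wedge perimeters to the fiber perimeter for bi-component
    microfibers (1 for every other fiber class).
    """

    layer_id: str
    position: str
    composition: str
    fiber_class: str
    d_f: float | None = None
    d_f_iqr: float | None = None
    contains_tio2: bool = False
    d_a: float | None = None
    d_a_iqr: float | None = None
    d_cp: float | None = None
    d_cp_iqr: float | None = None
    perimeter_ratio: float = 1.0
    extras: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise ValidationError(
                f"layer {self.layer_id!r}: unknown position {self.position!r}"
            )
        if self.fiber_class not in FIBER_CLASSES:
            raise ValidationError(
                f"layer {self.layer_id!r}: unknown fiber class {self.fiber_class!r}"
            )
        for name in ("d_f", "d_f_iqr", "d_a", "d_a_iqr", "d_cp", "d_cp_iqr"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValidationError(
                    f"layer {self.layer_id!r}: {name} must be positive, got {value}"
                )
        if self.contains_tio2:
            if self.d_f is None and self.fiber_class != "cotton":
                raise ValidationError(
                    f"layer {self.layer_id!r}: d_f required for TiO2-containing layer"
                )
            if self.d_a is None or self.d_cp is None:
                raise ValidationError(
                    f"layer {self.layer_id!r}: d_a and d_cp required when "
                    "contains_tio2 is true"
                )
        if self.perimeter_ratio < 1:
            raise ValidationError(
                f"layer {self.layer_id!r}: perimeter_ratio must be >= 1"
            )
        if self.fiber_class != "bicomponent" and self.perimeter_ratio != 1.0:
            raise ValidationError(
                f"layer {self.layer_id!r}: perimeter_ratio != 1 is only "
                "meaningful for bicomponent fibers"
            )


@dataclasses.dataclass
class MaskSpec:
    """A face mask: an ordered stack of layers plus its total TiO2 mass.

    ``m_tot`` is the ICP-OES-derived total TiO2 mass per mask (µg) and
    ``m_tot_u`` its combined measurement uncertainty (k = 1, µg).
    ``layer_masses`` optionally maps layer_id -> µg when layers were
    digested separately.
    """

    mask_id: str
    mask_type: str
    layers: list[LayerSpec]
    m_tot: float
    m_tot_u: float = 0.0
    layer_masses: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.mask_type not in MASK_TYPES:
            raise ValidationError(
                f"mask {self.mask_id!r}: unknown mask type {self.mask_type!r}"
            )
        if not self.layers:
            raise ValidationError(f"mask {self.mask_id!r}: at least one layer required")
        if self.m_tot < 0:
            raise ValidationError(f"mask {self.mask_id!r}: m_tot must be >= 0")
        seen: set[str] = set()
        for layer in self.layers:
            if layer.layer_id in seen:
                raise ValidationError(
                    f"mask {self.mask_id!r}: duplicate layer id {layer.layer_id!r}"
                )
            seen.add(layer.layer_id)
        if self.layer_masses is not None:
            unknown = set(self.layer_masses) - seen
            if unknown:
                raise ValidationError(
                    f"mask {self.mask_id!r}: layer_masses refer to unknown "
                    f"layers {sorted(unknown)}"
                )
            total = sum(self.layer_masses.values())
            if self.m_tot > 0 and not math.isclose(
                total, self.m_tot, rel_tol=1e-3
            ):
                raise ValidationError(
                    f"mask {self.mask_id!r}: layer masses sum to {total:g} µg "
                    f"but m_tot is {self.m_tot:g} µg (beyond 1 part in 10^3)"
                )

    @property
    def tio2_layers(self) -> list[LayerSpec]:
        return [layer for layer in self.layers if layer.contains_tio2]


@dataclasses.dataclass(frozen=True)
class MassValue:
    """A mass expressed either as elemental Ti or as TiO2."""

    value: float  # µg
    basis: str  # "as_Ti" | "as_TiO2"

    def __post_init__(self) -> None:
        if self.basis not in ("as_Ti", "as_TiO2"):
            raise ValidationError(f"unknown mass basis {self.basis!r}")
        if self.value < 0:
            raise ValidationError(f"mass must be >= 0, got {self.value}")


def ti_to_tio2(mass: MassValue) -> MassValue:
    """Convert an elemental-Ti mass to the equivalent TiO2 mass.

    Uses exactly the molar-mass ratio 79.88/47.88 (1.668 to four
    significant figures), assuming all titanium is present as TiO2.
    """
    from .units import TIO2_PER_TI

    if mass.basis != "as_Ti":
        raise ValidationError("ti_to_tio2 expects a mass with basis 'as_Ti'")
    return MassValue(mass.value * TIO2_PER_TI, "as_TiO2")


def tio2_to_ti(mass: MassValue) -> MassValue:
    """Inverse of :func:`ti_to_tio2`."""
    from .units import TIO2_PER_TI

    if mass.basis != "as_TiO2":
        raise ValidationError("tio2_to_ti expects a mass with basis 'as_TiO2'")
    return MassValue(mass.value / TIO2_PER_TI, "as_Ti")


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_float(raw, column: str, row: int) -> float | None:
    if raw is None:
        return None
    text = str(raw).strip()
    if text in ("", "NA", "na", "NaN", "nan", "-", "–"):
        return None
    text = text.replace(",", "")  # normalize "17,332"
    try:
        return float(text)
    except ValueError:
        raise ValidationError(
            f"row {row}: cannot parse {column}={raw!r} as a number"
        ) from None


def _parse_bool(raw, column: str, row: int) -> bool:
    text = str(raw).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no", "", "na"):
        return False
    raise ValidationError(f"row {row}: cannot parse {column}={raw!r} as a boolean")


_NONNEGATIVE = ("m_tot_ug", "m_tot_u_ug", "layer_mass_ug")
_POSITIVE = ("d_f_um", "d_f_iqr_um", "d_a_nm", "d_a_iqr_nm", "d_cp_nm", "d_cp_iqr_nm")


def masks_from_frame(frame: pd.DataFrame) -> list[MaskSpec]:
    """Build :class:`MaskSpec` records from a descriptor DataFrame.

    The frame must have the columns of :data:`MANDATORY_COLUMNS`; extra
    columns are preserved per layer in ``LayerSpec.extras``.
    """
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    known = set(MANDATORY_COLUMNS) | {
        "d_f_iqr_um",
        "d_a_iqr_nm",
        "d_cp_iqr_nm",
        "perimeter_ratio",
        "layer_mass_ug",
        "m_tot_u_ug",
    }
    extra_cols = [c for c in frame.columns if c not in known]

    masks: list[MaskSpec] = []
    order: list[str] = []
    grouped: dict[str, list[tuple[int, pd.Series]]] = {}
    for idx, row in frame.iterrows():
        mask_id = str(row["mask_id"]).strip()
        if not mask_id or mask_id.lower() in ("na", "nan"):
            raise ValidationError(f"row {idx}: empty mask_id")
        if mask_id not in grouped:
            grouped[mask_id] = []
            order.append(mask_id)
        grouped[mask_id].append((idx, row))

    for mask_id in order:
        rows = grouped[mask_id]
        layers: list[LayerSpec] = []
        layer_masses: dict[str, float] = {}
        mask_type = str(rows[0][1]["mask_type"]).strip()
        m_tot = m_tot_u = None
        for idx, row in rows:
            if str(row["mask_type"]).strip() != mask_type:
                raise ValidationError(
                    f"row {idx}: inconsistent mask_type for mask {mask_id!r}"
                )
            values: dict[str, float | None] = {}
            for column in _POSITIVE + _NONNEGATIVE + ("perimeter_ratio",):
                if column in frame.columns:
                    values[column] = _parse_float(row[column], column, idx)
                else:
                    values[column] = None
            for column in _POSITIVE:
                if values[column] is not None and values[column] <= 0:
                    raise ValidationError(
                        f"row {idx}: {column} must be positive, got {values[column]}"
                    )
            for column in _NONNEGATIVE:
                if values[column] is not None and values[column] < 0:
                    raise ValidationError(
                        f"row {idx}: {column} must be >= 0, got {values[column]}"
                    )
            contains = _parse_bool(row["contains_tio2"], "contains_tio2", idx)
            try:
                layer = LayerSpec(
                    layer_id=str(row["layer_id"]).strip(),
                    position=str(row["position"]).strip(),
                    composition=str(row["composition"]).strip(),
                    fiber_class=str(row["fiber_class"]).strip(),
                    d_f=values["d_f_um"],
                    d_f_iqr=values["d_f_iqr_um"],
                    contains_tio2=contains,
                    d_a=values["d_a_nm"],
                    d_a_iqr=values["d_a_iqr_nm"],
                    d_cp=values["d_cp_nm"],
                    d_cp_iqr=values["d_cp_iqr_nm"],
                    perimeter_ratio=(
                        1.0
                        if values["perimeter_ratio"] is None
                        else values["perimeter_ratio"]
                    ),
                    extras={c: row[c] for c in extra_cols},
                )
            except ValidationError as exc:
                raise ValidationError(f"row {idx}: {exc}") from None
            layers.append(layer)
            if values["layer_mass_ug"] is not None:
                layer_masses[layer.layer_id] = values["layer_mass_ug"]
            row_m_tot = values["m_tot_ug"]
            if row_m_tot is None:
                raise ValidationError(f"row {idx}: m_tot_ug is mandatory")
            if m_tot is None:
                m_tot = row_m_tot
            elif not math.isclose(m_tot, row_m_tot, rel_tol=1e-9):
                raise ValidationError(
                    f"row {idx}: m_tot_ug differs between rows of mask {mask_id!r}"
                )
            if values["m_tot_u_ug"] is not None:
                m_tot_u = values["m_tot_u_ug"]
        masks.append(
            MaskSpec(
                mask_id=mask_id,
                mask_type=mask_type,
                layers=layers,
                m_tot=float(m_tot),
                m_tot_u=float(m_tot_u) if m_tot_u is not None else 0.0,
                layer_masses=layer_masses or None,
            )
        )
    return masks


def read_mask_table(path: str | Path) -> list[MaskSpec]:
    """Read a mask descriptor CSV into validated :class:`MaskSpec` records.

    Layers keep their file order; an empty file with only a header yields
    an empty list.  Schema problems raise :class:`SchemaError`, value
    problems :class:`ValidationError` with the offending row index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if frame.empty:
        missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        return []
    return masks_from_frame(frame)


def masks_to_frame(masks: Sequence[MaskSpec]) -> pd.DataFrame:
    """Serialize MaskSpec records back to the descriptor-table layout."""
    rows = []
    for mask in masks:
        for layer in mask.layers:
            row = {
                "mask_id": mask.mask_id,
                "mask_type": mask.mask_type,
                "layer_id": layer.layer_id,
                "position": layer.position,
                "composition": layer.composition,
                "fiber_class": layer.fiber_class,
                "d_f_um": layer.d_f,
                "d_f_iqr_um": layer.d_f_iqr,
                "contains_tio2": str(layer.contains_tio2).lower(),
                "d_a_nm": layer.d_a,
                "d_a_iqr_nm": layer.d_a_iqr,
                "d_cp_nm": layer.d_cp,
                "d_cp_iqr_nm": layer.d_cp_iqr,
                "perimeter_ratio": layer.perimeter_ratio,
                "layer_mass_ug": (
                    mask.layer_masses.get(layer.layer_id)
                    if mask.layer_masses
                    else None
                ),
                "m_tot_ug": mask.m_tot,
                "m_tot_u_ug": mask.m_tot_u,
            }
            rows.append(row)
    return pd.DataFrame(rows)


def write_mask_table(masks: Sequence[MaskSpec], path: str | Path) -> None:
    """Write MaskSpec records as a descriptor CSV (``NA`` for absent values)."""
    frame = masks_to_frame(masks)
    frame.to_csv(path, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# result report I/O


def write_report(results: Iterable, path: str | Path) -> None:
    """Write exposure-risk results as a delimited report.

    One row per mask with the modelled per-layer surface fractions (percent,
    ``|``-joined in layer order), the estimated surface mass M_sf (µg), the
    acceptable exposure level per mask (µg) and the exceedance ratio.
    Values are written at 6 significant figures so a write-then-read
    round-trips well beyond the 3-significant-figure contract.
    """
    results = list(results)
    if not results:
        raise ValidationError("refusing to write an empty report")
    rows = []
    for res in results:
        fractions = "|".join(
            f"{100.0 * f:.6g}" for f in res.layer_fractions.values()
        )
        rows.append(
            {
                "mask_id": res.mask_id,
                "mask_type": res.mask_type,
                "layer_fractions_pct": fractions,
                "m_sf_ug": f"{res.m_sf:.6g}",
                "ael_mask_ug": f"{res.ael_mask:.6g}",
                "exceedance": f"{res.exceedance:.6g}",
                "exceedance_reported": int(res.exceedance_reported),
                "note": res.note or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_report(path: str | Path) -> list:
    """Read a report written by :func:`write_report` back into result objects."""
    from .risk import ExposureRiskResult

    frame = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    results = []
    for _, row in frame.iterrows():
        fracs = [
            float(tok) / 100.0
            for tok in str(row["layer_fractions_pct"]).split("|")
            if tok
        ]
        results.append(
            ExposureRiskResult(
                mask_id=row["mask_id"],
                mask_type=row["mask_type"],
                m_sf=float(row["m_sf_ug"]),
                ael_mask=float(row["ael_mask_ug"]),
                exceedance=float(row["exceedance"]),
                exceedance_reported=int(row["exceedance_reported"]),
                layer_fractions={f"layer{i}": f for i, f in enumerate(fracs)},
                note=row.get("note", "") or "",
            )
        )
    return results
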