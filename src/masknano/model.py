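"""Model/Results interface for the mask exposure analysis.

:class:`MaskExposureModel` is built from a mask descriptor table (objects,
DataFrame or CSV) plus a dosimetry configuration; ``fit()`` evaluates the
geometric surface-fraction model and the risk characterization for every
mask and returns a :class:`MaskExposureResults` carrying the estimates, a
tidy results frame, a ``summary()`` table and report/plot helpers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .mask_data import MaskSpec, masks_from_frame, read_mask_table, write_report
from .risk import (
    DosimetryConfig,
    ExposureRiskResult,
    characterize,
    derive_ael_mask,
    summarize_by_type,
)
from .surface import surface_mass
from .units import round_half_away


class MaskExposureModel:
    """Fiber-surface TiO2 exposure model for a collection of face masks.

    Parameters
    ----------
    masks : sequence of MaskSpec
        Validated mask records.
    dosimetry : DosimetryConfig, optional
        Defaults to the packaged configuration (NOAEC 0.5 mg/m³, 2 masks
        per 8-h period, AEL_mask 3.6 µg).
    allocation : {"equal_split", "measured", "proportional_to_F"}
        How the total TiO2 mass is allocated across TiO2-containing layers
        when per-layer digestion results are absent.
    """

    def __init__(
        self,
        masks: Sequence[MaskSpec],
        dosimetry: DosimetryConfig | None = None,
        allocation: str = "equal_split",
    ):
        self.masks = list(masks)
        self.dosimetry = dosimetry if dosimetry is not None else DosimetryConfig()
        self.allocation = allocation

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        dosimetry: DosimetryConfig | str | Path | None = None,
        allocation: str = "equal_split",
    ) -> "MaskExposureModel":
        """Build the model from a mask descriptor CSV (and optionally a
        dosimetry YAML path)."""
        if isinstance(dosimetry, (str, Path)):
            dosimetry = DosimetryConfig.from_yaml(dosimetry)
        return cls(read_mask_table(path), dosimetry=dosimetry, allocation=allocation)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        dosimetry: DosimetryConfig | None = None,
        allocation: str = "equal_split",
    ) -> "MaskExposureModel":
        return cls(masks_from_frame(frame), dosimetry=dosimetry, allocation=allocation)

    def fit(self) -> "MaskExposureResults":
        """Evaluate surface fractions, surface masses and exceedances."""
        estimates = [surface_mass(mask, allocation=self.allocation) for mask in self.masks]
        results = [
            characterize(estimate, self.dosimetry, mask)
            for estimate, mask in zip(estimates, self.masks)
        ]
        return MaskExposureResults(self, estimates, results)


class MaskExposureResults:
    """Fitted exposure and risk estimates for a set of masks."""

    def __init__(self, model: MaskExposureModel, estimates, results):
        self.model = model
        self.estimates = list(estimates)
        self.results: list[ExposureRiskResult] = list(results)
        self.ael_mask = derive_ael_mask(model.dosimetry)

    @property
    def frame(self) -> pd.DataFrame:
        """Tidy per-mask results frame (full precision)."""
        rows = []
        for res, est in zip(self.results, self.estimates):
            rows.append(
                {
                    "mask_id": res.mask_id,
                    "mask_type": res.mask_type,
                    "layer_fractions_pct": "|".join(
                        f"{100 * f:.6g}" for f in res.layer_fractions.values()
                    ),
                    "m_tot_ug": est.m_tot,
                    "m_sf_ug": res.m_sf,
                    "ael_mask_ug": res.ael_mask,
                    "exceedance": res.exceedance,
                    "exceedance_reported": res.exceedance_reported,
                    "note": res.note,
                }
            )
        return pd.DataFrame(rows)

    def by_type(self) -> dict[str, tuple[int, int]]:
        """(min, max) reported exceedance per mask type."""
        return summarize_by_type(self.results)

    def summary(self) -> str:
        """Human-readable summary table, survey-style rounding.

        Fractions are shown as integer percentages and masses as integer
        µg (round half away from zero); full precision stays available in
        :attr:`frame`.
        """
        lines = [
            "Fiber-surface TiO2 exposure and risk characterization",
            f"AEL_mask: {self.ael_mask:g} µg "
            f"(NOAEC {self.model.dosimetry.noaec:g} mg/m³, "
            f"{self.model.dosimetry.masks_per_period} masks per "
            f"{self.model.dosimetry.exposure_period_h:g}-h period)",
            f"mass allocation: {self.model.allocation}",
            "",
        ]
        table = []
        for res, est in zip(self.results, self.estimates):
            table.append(
                {
                    "mask": res.mask_id,
                    "type": res.mask_type,
                    "F (%)": "|".join(
                        f"{round_half_away(100 * f):.0f}"
                        for f in res.layer_fractions.values()
                        if f > 0
                    )
                    or "0",
                    "M_tot (µg)": f"{round_half_away(est.m_tot):.0f}",
                    "M_sf (µg)": f"{round_half_away(res.m_sf):.0f}",
                    "exceeds AEL (x)": res.exceedance_reported,
                }
            )
        lines.append(pd.DataFrame(table).to_string(index=False))
        lines.append("")
        for mask_type, (lo, hi) in self.by_type().items():
            lines.append(f"{mask_type}: exceedance {lo} to {hi} times AEL_mask")
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> None:
        """Write the report CSV (see :func:`masknano.mask_data.write_report`)."""
        write_report(self.results, path)

    def plot_exceedance(self, ax=None):
        """Bar chart of reported exceedance per mask (log scale)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3.5))
        frame = self.frame
        colors = [
            "tab:red" if t == "reusable" else "tab:blue" for t in frame["mask_type"]
        ]
        ax.bar(frame["mask_id"], frame["exceedance"], color=colors)
        ax.axhline(1.0, color="k", lw=1, ls="--", label="AEL_mask")
        ax.set_yscale("log")
        ax.set_ylabel("M_sf / AEL_mask")
        ax.tick_params(axis="x", rotation=60)
        ax.legend()
        return ax
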