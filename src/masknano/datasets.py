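"""Packaged example data.

``load_mask_survey`` returns the descriptor table of a published survey of
twelve face masks (single-use and reusable) whose synthetic fibers carry
fiber-grade TiO2: per layer the composition, the median fiber diameter
(µm, ± IQR), the median minimum Feret diameters of TiO2 agglomerates and
constituent particles (nm, ± IQR), and per mask the ICP-OES total TiO2
mass (µg, ± combined uncertainty at k = 1).

The survey's own derived columns (modelled surface fraction in percent,
estimated surface mass in µg, exceedance over the acceptable exposure
level) are carried alongside as ``printed_*`` reference columns; they are
reported values, not recomputed by this package, and are used in tests as
the comparison surface.

The wedge-perimeter measurements behind the bi-component mask (Mask12)
are not part of the survey table; its ``perimeter_ratio`` of 3.0 is an
assumed nominal value for a segmented-pie microfiber, not a measurement.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .mask_data import MaskSpec, read_mask_table

_DATA = resources.files("masknano") / "data"


def mask_survey_path() -> Path:
    """Filesystem path of the packaged mask descriptor CSV."""
    return Path(str(_DATA / "mask_survey.csv"))


def default_dosimetry_path() -> Path:
    """Filesystem path of the packaged default dosimetry configuration."""
    return Path(str(_DATA / "dosimetry.yaml"))


def load_mask_survey() -> tuple[list[MaskSpec], pd.DataFrame]:
    """Load the packaged 12-mask survey.

    Returns
    -------
    masks : list of MaskSpec
        Validated mask records (12 masks, 31 layer rows).
    reference : pandas.DataFrame
        The raw table including the ``printed_*`` reference columns.
    """
    path = mask_survey_path()
    masks = read_mask_table(path)
    reference = pd.read_csv(path)
    return masks, reference
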