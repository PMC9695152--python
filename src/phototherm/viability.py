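"""MTT colorimetric viability: plate reduction to percent of control.

Living cells reduce the tetrazolium dye to formazan; the optical density at
570 nm, read against a 670 nm reference, is proportional to the number of
metabolically active cells.  Each well's net OD is ``od570 - od670``
(reference subtraction per well, before any averaging); group viability is
the group's mean net OD as a percentage of the untreated control's.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InsufficientDataError

__all__ = ["MttPlate", "compute_viability", "PLATE_COLUMNS"]

PLATE_COLUMNS = ["well", "group", "od570", "od670", "irradiated"]


@dataclass
class MttPlate:
    """An MTT plate table with wells, group labels and dual-wavelength ODs."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PLATE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"plate table missing columns: {missing}")
        df = self.data
        if ((df["od670"] < 0) | (df["od570"] < df["od670"])).any():
            raise ValueError("wells must satisfy od570 >= od670 >= 0")
        sizes = df.groupby(["group", "irradiated"]).size()
        if (sizes < 3).any():
            bad = sizes[sizes < 3].index.tolist()
            raise ValueError(f"each group needs >= 3 replicate wells; too few in {bad}")

    @property
    def net_od(self) -> pd.Series:
        return self.data["od570"] - self.data["od670"]


def compute_viability(plate: MttPlate, control_group: str) -> pd.DataFrame:
    """Percent viability of every (group, irradiated) arm vs the control.

    The control is the *non-irradiated* arm of ``control_group``.  Viability
    is ``100 * mean(net OD, group) / mean(net OD, control)``; the reported
    spread is the group's replicate standard deviation on the same scale.

    Returns
    -------
    DataFrame with columns ``group, irradiated, viability_percent,
    sd_percent, n_wells``.

    Raises
    ------
    InsufficientDataError
        If the control group is absent (non-irradiated arm) or its mean net
        OD is not positive.
    """
    df = plate.data.copy()
    df["net_od"] = plate.net_od
    control = df[(df["group"] == control_group) & (~df["irradiated"].astype(bool))]
    if control.empty:
        raise InsufficientDataError(
            f"control group {control_group!r} (non-irradiated) not present"
        )
    control_mean = control["net_od"].mean()
    if control_mean <= 0:
        raise InsufficientDataError("control mean net OD must be positive")

    out = (
        df.groupby(["group", "irradiated"], as_index=False)
        .agg(
            viability_percent=("net_od", lambda x: 100.0 * x.mean() / control_mean),
            sd_percent=("net_od", lambda x: 100.0 * x.std(ddof=1) / control_mean),
            n_wells=("net_od", "size"),
        )
        .sort_values(["group", "irradiated"])
        .reset_index(drop=True)
    )
    return out
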