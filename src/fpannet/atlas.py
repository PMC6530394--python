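"""The 16-node frontal-parietal attention network (FPAN) atlas.

The FPAN is defined by 16 MNI coordinates covering bilateral intraparietal
sulcus (IPS), inferior parietal lobule (iPL), ventral IPS, frontal eye
fields (FEF), inferior precentral sulcus (IPCL), supplementary motor area
(SMA), dorsolateral prefrontal cortex (DLPFC), ventral occipital cortex
(vOC) and anterior insula (aIns).  Each region of interest is a 6-mm-radius
sphere around its coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["RoiDefinition", "load_fpan_atlas", "load_atlas_table"]


@dataclass(frozen=True)
class RoiDefinition:
    """A spherical region of interest in MNI space (mm)."""

    name: str
    x: int
    y: int
    z: int
    radius: float = 6.0

    def __post_init__(self):
        for c in (self.x, self.y, self.z):
            if not -90 <= c <= 90:
                raise ValueError(f"coordinate {c} outside +/-90 mm for ROI {self.name!r}")
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")

    @property
    def center(self) -> tuple[int, int, int]:
        return (self.x, self.y, self.z)


def load_atlas_table(path=None) -> pd.DataFrame:
    """Read an atlas TSV (columns name, x, y, z, radius) into a DataFrame."""
    if path is None:
        with resources.as_file(
            resources.files("fpannet.data").joinpath("fpan_atlas.tsv")
        ) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")


def load_fpan_atlas() -> list[RoiDefinition]:
    """Load the packaged 16-region FPAN atlas."""
    table = load_atlas_table()
    rois = [
        RoiDefinition(
            name=row["name"],
            x=int(row["x"]),
            y=int(row["y"]),
            z=int(row["z"]),
            radius=float(row["radius"]),
        )
        for _, row in table.iterrows()
    ]
    if len(rois) != 16:
        raise RuntimeError(f"packaged FPAN atlas must have 16 regions, found {len(rois)}")
    return rois
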