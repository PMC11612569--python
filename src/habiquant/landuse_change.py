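"""Land-use transition matrices and class-area accounting between dates.

The transition matrix T cross-tabulates area moving between land-use
classes across two dates: entry (i, j) is the area (km²) of cells mapped
as class i at the first date and class j at the second.  Cells that are
nodata at either date are excluded entirely, so row sums equal per-class
areas at the first date and column sums equal per-class areas at the
second — area is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .raster_io import Grid, LandUseLegend

__all__ = ["TransitionMatrix", "transition_matrix", "area_percentages"]


@dataclass
class TransitionMatrix:
    """Areas (km²) transitioning between classes across two dates."""

    classes: list[int]
    areas: np.ndarray  # (n, n), entry (i, j): class i at date A -> class j at date B

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        n = len(self.classes)
        if self.areas.shape != (n, n):
            raise ValueError("areas must be n x n for n classes")
        if (self.areas < 0).any():
            raise ValueError("transition areas must be non-negative")

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def row_totals(self) -> np.ndarray:
        """Class areas at the first date."""
        return self.areas.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        """Class areas at the second date."""
        return self.areas.sum(axis=0)

    def conversion_rates(self) -> np.ndarray:
        """Row-normalised percentages: of class i's initial area, the
        percent ending up in class j.  Rows with zero initial area are 0."""
        rows = self.row_totals()
        out = np.zeros_like(self.areas)
        nz = rows > 0
        out[nz] = self.areas[nz] / rows[nz, None] * 100.0
        return out

    def to_frame(self, legend: LandUseLegend | None = None) -> pd.DataFrame:
        labels = (
            [legend.name(c) for c in self.classes] if legend is not None else self.classes
        )
        return pd.DataFrame(self.areas, index=labels, columns=labels)


def transition_matrix(
    lu_a: Grid, lu_b: Grid, legend: LandUseLegend
) -> TransitionMatrix:
    """Cross-tabulate the areas transitioning between classes of two dates.

    Parameters
    ----------
    lu_a, lu_b:
        Land-use rasters for the first and second date; same geometry.
    legend:
        Supplies the class universe; any code present in either raster but
        absent from the legend raises an error naming it.
    """
    if not lu_a.same_geometry(lu_b):
        raise ValueError(
            f"shape/cell-size mismatch: {lu_a.values.shape}@{lu_a.cell_size} "
            f"vs {lu_b.values.shape}@{lu_b.cell_size}"
        )
    both = lu_a.valid_mask & lu_b.valid_mask
    a = lu_a.values[both].astype(int)
    b = lu_b.values[both].astype(int)
    legend.check_codes(np.unique(a))
    legend.check_codes(np.unique(b))

    classes = legend.codes
    index = {c: i for i, c in enumerate(classes)}
    n = len(classes)
    counts = np.zeros((n, n), dtype=float)
    ai = np.array([index[c] for c in a], dtype=int)
    bi = np.array([index[c] for c in b], dtype=int)
    np.add.at(counts, (ai, bi), 1.0)
    return TransitionMatrix(classes=classes, areas=counts * lu_a.cell_size**2)


def area_percentages(
    lu: Grid,
    legend: LandUseLegend,
    grouping: Mapping[int, str] | None = None,
) -> pd.Series:
    """Percent of valid landscape area per class (or per group).

    ``grouping`` maps codes to group names (e.g. paddy + dry farmland →
    "arable"); ungrouped codes keep their legend names.  Percentages sum
    to 100 over the valid area.
    """
    valid = lu.valid_mask
    if not valid.any():
        raise ValueError("raster has no valid cells")
    codes = lu.values[valid].astype(int)
    legend.check_codes(np.unique(codes))

    uniq, counts = np.unique(codes, return_counts=True)
    total = counts.sum()
    percents: dict[str, float] = {}
    for code, cnt in zip(uniq, counts):
        label = grouping.get(int(code)) if grouping else None
        if label is None:
            label = legend.name(int(code))
        percents[label] = percents.get(label, 0.0) + cnt / total * 100.0
    return pd.Series(percents, name="percent")
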