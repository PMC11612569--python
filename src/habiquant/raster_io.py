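"""Raster, legend and threat-table data model with plain-text file I/O.

Rasters travel as ESRI ASCII grids (``.asc``): a six-line header
(``ncols``, ``nrows``, ``xllcorner``, ``yllcorner``, ``cellsize``,
``NODATA_value``) followed by row-major cell values with row 0 the
northernmost row.  Cell size is kilometres everywhere in this package, so
threat distances (also km) never need unit conversion.

Parameter tables are CSV: a land-use legend mapping each integer class code
to a habitat-suitability score and a per-threat sensitivity vector, and a
threat table giving each threat's source classes, maximum influence
distance, weight and decay type.  The packaged defaults reproduce the
Songnen Plain parameterisation this package was built around.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Grid",
    "LandUseLegend",
    "ThreatSpec",
    "GridParseError",
    "TableValidationError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_parameter_tables",
    "default_parameter_tables",
    "default_legend_path",
    "default_threats_path",
]

DECAY_KINDS = ("linear", "exponential")


class GridParseError(ValueError):
    """Raised when an ASCII grid file cannot be parsed; names the line."""


class TableValidationError(ValueError):
    """Raised when a legend/threat table violates its invariants."""


@dataclass
class Grid:
    """A rectangular north-up raster of numeric or categorical cell values.

    Attributes
    ----------
    values:
        2-D float array, shape ``(nrows, ncols)``; row 0 is the
        northernmost row.  Nodata cells hold the ``nodata`` sentinel.
    cell_size:
        Edge length of one square cell, in km.
    nodata:
        Sentinel marking cells outside the valid landscape.
    origin:
        ``(x, y)`` of the lower-left corner in map units.
    """

    values: np.ndarray
    cell_size: float = 1.0
    nodata: float = -9999.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells carrying data."""
        return ~np.isclose(self.values, self.nodata, rtol=0.0, atol=1e-9) & np.isfinite(
            self.values
        )

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def like(self, values: np.ndarray) -> "Grid":
        """A new grid sharing this grid's geometry."""
        return Grid(
            values=np.asarray(values, dtype=float),
            cell_size=self.cell_size,
            nodata=self.nodata,
            origin=self.origin,
        )

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.cell_size, other.cell_size)
        )


@dataclass(frozen=True)
class LegendEntry:
    code: int
    name: str
    suitability: float
    sensitivity: Mapping[str, float]


@dataclass
class LandUseLegend:
    """Per-class habitat suitability H_j and sensitivity S_jr to each threat."""

    entries: dict[int, LegendEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        threat_names: tuple[str, ...] | None = None
        for code, entry in self.entries.items():
            if not 0.0 <= entry.suitability <= 1.0:
                raise TableValidationError(
                    f"class {code} ({entry.name}): suitability {entry.suitability} outside [0,1]"
                )
            names = tuple(entry.sensitivity)
            if threat_names is None:
                threat_names = names
            elif set(names) != set(threat_names):
                raise TableValidationError(
                    f"class {code} ({entry.name}): threat names {names} differ from {threat_names}"
                )
            for threat, s in entry.sensitivity.items():
                if not 0.0 <= s <= 1.0:
                    raise TableValidationError(
                        f"class {code} ({entry.name}): sensitivity to {threat!r} is {s}, outside [0,1]"
                    )

    @property
    def codes(self) -> list[int]:
        return sorted(self.entries)

    @property
    def threat_names(self) -> list[str]:
        for entry in self.entries.values():
            return list(entry.sensitivity)
        return []

    def suitability(self, code: int) -> float:
        return self.entries[int(code)].suitability

    def sensitivity(self, code: int, threat: str) -> float:
        return self.entries[int(code)].sensitivity[threat]

    def name(self, code: int) -> str:
        return self.entries[int(code)].name

    def check_codes(self, codes: Iterable[int]) -> None:
        unknown = sorted(set(int(c) for c in codes) - set(self.entries))
        if unknown:
            raise TableValidationError(f"land-use codes not in legend: {unknown}")

    def suitability_array(self) -> tuple[np.ndarray, np.ndarray]:
        """(codes, H) aligned arrays for vectorised lookups."""
        codes = np.array(self.codes, dtype=int)
        h = np.array([self.entries[c].suitability for c in codes])
        return codes, h


@dataclass
class ThreatSpec:
    """One threat factor: its source classes, reach, weight and decay shape."""

    name: str
    source_codes: frozenset[int]
    d_rmax: float  # km
    weight: float
    decay: str

    def __post_init__(self) -> None:
        self.source_codes = frozenset(int(c) for c in self.source_codes)
        if self.d_rmax <= 0:
            raise TableValidationError(f"threat {self.name!r}: d_rmax must be > 0")
        if self.weight < 0:
            raise TableValidationError(f"threat {self.name!r}: weight must be >= 0")
        if self.decay not in DECAY_KINDS:
            raise TableValidationError(
                f"threat {self.name!r}: decay {self.decay!r} not one of {DECAY_KINDS}"
            )


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_ascii_grid(path: str | Path) -> Grid:
    """Parse an ESRI ASCII grid file into a :class:`Grid`.

    Raises :class:`GridParseError` naming the offending line on malformed
    headers, short/long rows, or non-numeric cell tokens.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    lineno = 0
    for lineno, line in enumerate(lines[:6], start=1):
        parts = line.split()
        if len(parts) != 2:
            raise GridParseError(f"{path}:{lineno}: expected 'key value' header line, got {line!r}")
        key = parts[0].lower()
        if key not in _HEADER_KEYS:
            raise GridParseError(f"{path}:{lineno}: unknown header key {parts[0]!r}")
        try:
            header[key] = float(parts[1])
        except ValueError as exc:
            raise GridParseError(f"{path}:{lineno}: non-numeric header value {parts[1]!r}") from exc
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise GridParseError(f"{path}: header missing keys {missing}")

    nrows = int(header["nrows"])
    ncols = int(header["ncols"])
    if nrows <= 0 or ncols <= 0:
        raise GridParseError(f"{path}: nrows/ncols must be positive")

    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[6:], start=7):
        if not line.strip():
            continue
        tokens = line.split()
        row: list[float] = []
        for tok in tokens:
            try:
                row.append(float(tok))
            except ValueError as exc:
                raise GridParseError(f"{path}:{lineno}: non-numeric cell value {tok!r}") from exc
        rows.append(row)
    if len(rows) != nrows:
        raise GridParseError(f"{path}: header declares nrows={nrows} but found {len(rows)} value rows")
    for i, row in enumerate(rows):
        if len(row) != ncols:
            raise GridParseError(
                f"{path}:{7 + i}: header declares ncols={ncols} but row has {len(row)} values"
            )
    return Grid(
        values=np.array(rows, dtype=float),
        cell_size=header["cellsize"],
        nodata=header["nodata_value"],
        origin=(header["xllcorner"], header["yllcorner"]),
    )


def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    """Write a :class:`Grid` as an ESRI ASCII grid.

    Integer-valued grids are emitted as integer tokens so categorical
    rasters round-trip bit-exactly; float grids use ``repr`` precision.
    """
    path = Path(path)
    vals = grid.values
    integral = np.all(vals == np.round(vals))

    def fmt(v: float) -> str:
        if integral:
            return str(int(round(v)))
        return np.format_float_positional(v, trim="0")

    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {fmt_num(grid.origin[0])}\n")
        fh.write(f"yllcorner {fmt_num(grid.origin[1])}\n")
        fh.write(f"cellsize {fmt_num(grid.cell_size)}\n")
        fh.write(f"NODATA_value {fmt(grid.nodata) if integral else fmt_num(grid.nodata)}\n")
        for row in vals:
            fh.write(" ".join(fmt(v) for v in row) + "\n")


def fmt_num(v: float) -> str:
    """Shortest exact decimal for a float header value."""
    if v == int(v):
        return str(int(v))
    return np.format_float_positional(v, trim="0")


# ---------------------------------------------------------------------------
# Parameter tables

def read_parameter_tables(
    legend_path: str | Path, threats_path: str | Path
) -> tuple[LandUseLegend, list[ThreatSpec]]:
    """Read the legend and threat CSVs, validating all invariants.

    Legend CSV columns: ``code,name,H,<one column per threat>``.
    Threats CSV columns: ``name,codes,d_rmax_km,weight,decay`` where
    ``codes`` is a ``;``-separated list of source land-use codes.
    """
    legend_df = pd.read_csv(legend_path)
    threats_df = pd.read_csv(threats_path)

    required = {"code", "name", "H"}
    if not required.issubset(legend_df.columns):
        raise TableValidationError(
            f"legend file missing columns {sorted(required - set(legend_df.columns))}"
        )
    threat_cols = [c for c in legend_df.columns if c not in required]

    if legend_df["code"].duplicated().any():
        dups = sorted(legend_df.loc[legend_df["code"].duplicated(), "code"])
        raise TableValidationError(f"duplicate land-use codes in legend: {dups}")

    entries: dict[int, LegendEntry] = {}
    for _, row in legend_df.iterrows():
        entries[int(row["code"])] = LegendEntry(
            code=int(row["code"]),
            name=str(row["name"]),
            suitability=float(row["H"]),
            sensitivity={t: float(row[t]) for t in threat_cols},
        )
    legend = LandUseLegend(entries)

    required_t = {"name", "codes", "d_rmax_km", "weight", "decay"}
    if not required_t.issubset(threats_df.columns):
        raise TableValidationError(
            f"threats file missing columns {sorted(required_t - set(threats_df.columns))}"
        )
    threats: list[ThreatSpec] = []
    for _, row in threats_df.iterrows():
        codes = frozenset(int(tok) for tok in str(row["codes"]).split(";") if tok.strip())
        threats.append(
            ThreatSpec(
                name=str(row["name"]),
                source_codes=codes,
                d_rmax=float(row["d_rmax_km"]),
                weight=float(row["weight"]),
                decay=str(row["decay"]).strip().lower(),
            )
        )

    table_names = {t.name for t in threats}
    legend_names = set(legend.threat_names)
    if table_names != legend_names:
        raise TableValidationError(
            "threat-name mismatch between files: "
            f"legend has {sorted(legend_names)}, threats file has {sorted(table_names)}"
        )
    for t in threats:
        unknown = t.source_codes - set(legend.entries)
        if unknown:
            raise TableValidationError(
                f"threat {t.name!r}: source codes {sorted(unknown)} not in legend"
            )
    return legend, threats


def default_legend_path() -> Path:
    return Path(str(resources.files("habiquant") / "data" / "legend.csv"))


def default_threats_path() -> Path:
    return Path(str(resources.files("habiquant") / "data" / "threats.csv"))


def default_parameter_tables() -> tuple[LandUseLegend, list[ThreatSpec]]:
    """The packaged Songnen Plain legend and threat tables."""
    return read_parameter_tables(default_legend_path(), default_threats_path())
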