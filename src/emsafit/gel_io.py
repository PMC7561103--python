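"""Reading, validation and summarisation of per-lane EMSA band intensities.

The unit of data is a *lane*: one well of a native gel, characterised by the
nominal complex concentration loaded, a replicate label, and the densitometry
intensities of three bands — free probe (0 complexes bound), single shift
(1 complex) and supershift (2 complexes).  Lanes containing species outside
this three-state model must be pre-aggregated by the user into these classes
before import.

Tables are UTF-8 CSV with the exact header
``condition, conc_nM, replicate, band0, band1, band2``; a thin adapter reads
the same columns from an XLSX sheet.  Normalisation is per lane by the
three-band sum (probe conservation within a lane); no cross-lane loading
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from numpy.typing import NDArray

__all__ = [
    "SchemaError",
    "LaneValidationError",
    "DegenerateLaneError",
    "LaneRecord",
    "TitrationSeries",
    "ReplicateSummary",
    "REQUIRED_COLUMNS",
    "read_titration_table",
    "read_titration_xlsx",
    "write_titration_table",
    "split_conditions",
    "normalize_lane",
    "normalized_fractions",
    "summarize_replicates",
]

REQUIRED_COLUMNS = ("condition", "conc_nM", "replicate", "band0", "band1", "band2")
BAND_COLUMNS = ("band0", "band1", "band2")


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class LaneValidationError(ValueError):
    """One or more lanes violate the data contract (carries row indices)."""

    def __init__(self, message: str, rows: Iterable[int]):
        self.rows = sorted(int(r) for r in rows)
        super().__init__(f"{message} (rows: {self.rows})")


class DegenerateLaneError(ValueError):
    """A lane whose three bands sum to zero cannot be normalised."""


class LaneRecord(NamedTuple):
    """One gel lane: concentration, replicate label and three band intensities."""

    conc_nM: float
    replicate: str
    band0: float
    band1: float
    band2: float

    @property
    def bands(self) -> NDArray[np.float64]:
        return np.array([self.band0, self.band1, self.band2], dtype=float)


@dataclass(frozen=True)
class TitrationSeries:
    """All lanes of one probe/protein condition across a concentration ladder.

    ``lanes`` is a DataFrame with columns ``conc_nM, replicate, band0, band1,
    band2``, one row per lane, ordered as imported.  A series needs at least
    3 distinct concentrations to constrain the three model parameters
    (Kd, C, f).
    """

    condition: str
    lanes: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS[1:] if c not in self.lanes.columns]
        if missing:
            raise SchemaError(f"lane table missing column(s): {missing}")
        lanes = self.lanes.reset_index(drop=True)
        bands = lanes[list(BAND_COLUMNS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(bands)):
            bad = np.where(~np.isfinite(bands).all(axis=1))[0]
            raise LaneValidationError("non-finite band intensity", bad)
        if np.any(bands < 0):
            bad = np.where((bands < 0).any(axis=1))[0]
            raise LaneValidationError("negative band intensity", bad)
        zero = np.where(bands.sum(axis=1) <= 0)[0]
        if zero.size:
            raise LaneValidationError("lane with all-zero bands", zero)
        conc = lanes["conc_nM"].to_numpy(dtype=float)
        if np.any(conc < 0) or not np.all(np.isfinite(conc)):
            bad = np.where((conc < 0) | ~np.isfinite(conc))[0]
            raise LaneValidationError("invalid concentration", bad)
        object.__setattr__(self, "lanes", lanes)

    def __len__(self) -> int:
        return len(self.lanes)

    @property
    def concentrations(self) -> NDArray[np.float64]:
        """Sorted distinct concentrations (nM) present in the series."""
        return np.unique(self.lanes["conc_nM"].to_numpy(dtype=float))

    def n_distinct_concentrations(self) -> int:
        return self.concentrations.size

    def records(self) -> list[LaneRecord]:
        return [
            LaneRecord(float(r.conc_nM), str(r.replicate), float(r.band0),
                       float(r.band1), float(r.band2))
            for r in self.lanes.itertuples(index=False)
        ]

    def to_frame(self) -> pd.DataFrame:
        """Full table including the condition column (CSV schema order)."""
        out = self.lanes.copy()
        out.insert(0, "condition", self.condition)
        return out[list(REQUIRED_COLUMNS)]


@dataclass(frozen=True)
class ReplicateSummary:
    """Per-concentration mean and SD of normalized band fractions.

    ``mean`` and ``sd`` are DataFrames indexed by concentration with columns
    ``band0, band1, band2`` (fractions, so each mean row sums to 1).
    ``n_reps`` maps concentration to replicate count.  ``single_replicate``
    is set when any concentration has only one lane; its SDs are reported
    as 0 and cannot support resampling without a user-supplied noise scale.
    """

    condition: str
    mean: pd.DataFrame
    sd: pd.DataFrame
    n_reps: pd.Series
    single_replicate: bool


def _validate_columns(df: pd.DataFrame, source: str) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required column(s): {missing}")


def _frame_to_series(df: pd.DataFrame, source: str) -> list[TitrationSeries]:
    _validate_columns(df, source)
    out = []
    for cond, grp in df.groupby("condition", sort=False):
        out.append(
            TitrationSeries(str(cond), grp[list(REQUIRED_COLUMNS[1:])].copy())
        )
    if not out:
        raise LaneValidationError(f"{source}: table has no data rows", [])
    return out


def read_titration_table(path: str | Path) -> list[TitrationSeries]:
    """Read a lane-per-row CSV table into one series per condition.

    The file must carry the header ``condition, conc_nM, replicate, band0,
    band1, band2``.  Raises :class:`SchemaError` for a missing column and
    :class:`LaneValidationError` (naming the offending rows) for negative
    intensities or all-zero lanes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    return _frame_to_series(df, str(path))


def read_titration_xlsx(
    path: str | Path,
    sheet: str | int = 0,
    column_map: Mapping[str, str] | None = None,
    condition: str | None = None,
) -> list[TitrationSeries]:
    """Thin XLSX adapter: read one sheet and map its columns onto the schema.

    ``column_map`` maps schema names (``conc_nM`` etc.) to the sheet's column
    headers; omitted entries are assumed to already match.  ``condition``
    supplies a label when the sheet has no condition column (single-condition
    sheets are common in supplementary spreadsheets).
    """
    df = pd.read_excel(path, sheet_name=sheet)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    if condition is not None and "condition" not in df.columns:
        df.insert(0, "condition", condition)
    if "replicate" not in df.columns:
        df["replicate"] = 1
    return _frame_to_series(df, str(path))


def write_titration_table(
    series: TitrationSeries | Iterable[TitrationSeries], path: str | Path
) -> None:
    """Write one or more series to CSV in the canonical schema.

    Numeric content round-trips bit-exactly through
    :func:`read_titration_table` (17 significant digits preserve doubles).
    """
    if isinstance(series, TitrationSeries):
        series = [series]
    frames = [s.to_frame() for s in series]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )


def split_conditions(series_list: list[TitrationSeries]) -> dict[str, TitrationSeries]:
    """Index a list of series by condition label (labels must be unique)."""
    out: dict[str, TitrationSeries] = {}
    for s in series_list:
        if s.condition in out:
            raise LaneValidationError(
                f"duplicate condition label {s.condition!r}", []
            )
        out[s.condition] = s
    return out


def normalize_lane(bands: Iterable[float] | LaneRecord) -> NDArray[np.float64]:
    """Normalised band fractions ``(p0, p1, p2) = bands / sum(bands)``.

    Scale-invariant: multiplying all three intensities by any k > 0 leaves
    the result unchanged.  Raises :class:`DegenerateLaneError` if the bands
    sum to zero.
    """
    if isinstance(bands, LaneRecord):
        arr = bands.bands
    else:
        arr = np.asarray(list(bands), dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"expected 3 band intensities, got shape {arr.shape}")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise LaneValidationError("negative or non-finite band intensity", [0])
    total = arr.sum()
    if total <= 0:
        raise DegenerateLaneError("band intensities sum to zero")
    return arr / total


def normalized_fractions(series: TitrationSeries) -> NDArray[np.float64]:
    """Per-lane normalised fractions, shape ``(n_lanes, 3)``, rows sum to 1."""
    bands = series.lanes[list(BAND_COLUMNS)].to_numpy(dtype=float)
    return bands / bands.sum(axis=1, keepdims=True)


def summarize_replicates(series: TitrationSeries) -> ReplicateSummary:
    """Mean and SD of normalised fractions per concentration across replicates.

    SD is the sample standard deviation (ddof=1).  A single replicate has no
    measurable spread: its SD is reported as 0 and the ``single_replicate``
    flag records that it is unmeasured, not measured to be zero.
    """
    if len(series) == 0:
        raise LaneValidationError("empty series", [])
    frac = normalized_fractions(series)
    df = pd.DataFrame(frac, columns=list(BAND_COLUMNS))
    df["conc_nM"] = series.lanes["conc_nM"].to_numpy(dtype=float)
    grouped = df.groupby("conc_nM", sort=True)
    mean = grouped[list(BAND_COLUMNS)].mean()
    sd = grouped[list(BAND_COLUMNS)].std(ddof=1).fillna(0.0)
    n_reps = grouped.size()
    return ReplicateSummary(
        condition=series.condition,
        mean=mean,
        sd=sd,
        n_reps=n_reps,
        single_replicate=bool((n_reps < 2).any()),
    )
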