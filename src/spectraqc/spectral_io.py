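"""Scan-grouped, missing-aware spectral matrix and response-table I/O.

The on-disk layout mirrors what field spectroradiometer workflows produce:

* spectral matrix — one row per sample, column 1 a free-form code, columns
  2..n reflectances headed by the wavelength in nm; ``k`` consecutive rows
  form one scan (one field plot);
* response table — three code columns (plot, genotype, replication) then one
  numeric trait column per variable, one row per scan.

Missing cells (deleted by a filter, or rows left empty for unmeasured plots)
are blank in files and NaN in memory.  Filters only ever turn values into
missing; nothing in the package invents a reflectance.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DataFormatError,
    GroupingError,
    LayoutError,
    LookupError,
    OrderingError,
)

logger = logging.getLogger(__name__)

#: In-memory sentinel for a missing cell.  Kept as a name so intent is
#: explicit at call sites; it is NaN and must be tested with np.isnan.
MISSING = np.nan


@dataclass
class SpectralDataset:
    """A wavelengths x samples reflectance matrix with scan grouping.

    Parameters
    ----------
    wavelengths
        Strictly increasing band centres in nm, shape ``(n_wl,)``.
    codes
        One free-form label per sample row.
    values
        Reflectances, shape ``(n_rows, n_wl)``; NaN marks a missing cell.
    samples_per_scan
        Number of consecutive rows forming one scan (one plot).
    """

    wavelengths: np.ndarray
    codes: list[str]
    values: np.ndarray
    samples_per_scan: int

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.codes = [str(c) for c in self.codes]
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        wl = self.wavelengths
        if wl.ndim != 1 or wl.size == 0:
            raise OrderingError("wavelength header is empty")
        if not np.all(np.isfinite(wl)):
            raise DataFormatError("non-numeric wavelength header")
        if np.any(np.diff(wl) <= 0):
            raise OrderingError(
                "wavelengths must be strictly increasing with no duplicates"
            )
        if self.values.ndim != 2 or self.values.shape[1] != wl.size:
            raise DataFormatError(
                f"every row must have {wl.size} cells, got shape "
                f"{self.values.shape}"
            )
        if len(self.codes) != self.values.shape[0]:
            raise DataFormatError("one code per sample row required")
        k = self.samples_per_scan
        if k < 1:
            raise GroupingError("samples_per_scan must be a positive integer")
        if self.values.shape[0] % k != 0:
            raise GroupingError(
                f"{self.values.shape[0]} rows is not a multiple of "
                f"samples_per_scan={k}"
            )

    # -- derived structure ----------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    @property
    def n_scans(self) -> int:
        return self.n_rows // self.samples_per_scan

    @property
    def plot_ids(self) -> list[int]:
        """1-based plot index per scan, in file order."""
        return list(range(1, self.n_scans + 1))

    def scan_rows(self, plot_id: int) -> slice:
        """Row slice of the scan with the given 1-based plot id."""
        if not 1 <= plot_id <= self.n_scans:
            raise LookupError(f"no scan with plot id {plot_id}")
        k = self.samples_per_scan
        return slice((plot_id - 1) * k, plot_id * k)

    def scan_values(self, plot_id: int) -> np.ndarray:
        return self.values[self.scan_rows(plot_id)]

    def scan_code(self, plot_id: int) -> str:
        """Code label of the first sample row of a scan."""
        return self.codes[self.scan_rows(plot_id).start]

    def copy(self) -> "SpectralDataset":
        return SpectralDataset(
            wavelengths=self.wavelengths.copy(),
            codes=list(self.codes),
            values=self.values.copy(),
            samples_per_scan=self.samples_per_scan,
        )

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass
class ResponseTable:
    """Per-plot trait values aligned to the scans of a SpectralDataset."""

    codes: pd.DataFrame  # three columns: plot, genotype, replication labels
    variables: pd.DataFrame  # numeric trait columns, NaN = missing

    def __post_init__(self) -> None:
        if self.codes.shape[1] != 3:
            raise LayoutError("exactly three code columns required")
        if self.variables.shape[1] < 1:
            raise LayoutError("at least one response variable required")
        if len(self.variables.columns) != len(set(self.variables.columns)):
            raise LayoutError("response variable names must be unique")
        if len(self.codes) != len(self.variables):
            raise LayoutError("code and variable blocks must align row-wise")

    @property
    def n_rows(self) -> int:
        return len(self.variables)

    @property
    def variable_names(self) -> list[str]:
        return list(self.variables.columns)

    def variable(self, name: str) -> np.ndarray:
        if name not in self.variables.columns:
            raise LookupError(f"unknown response variable {name!r}")
        return self.variables[name].to_numpy(dtype=float)


@dataclass
class ScanAverages:
    """One averaged spectrum per scan (missing-aware arithmetic mean)."""

    wavelengths: np.ndarray
    plot_ids: list[int]
    codes: list[str]
    values: np.ndarray  # (n_scans, n_wl)

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_BLANK = re.compile(r"^\s*$")


def _read_raw(path: str | Path) -> pd.DataFrame:
    """Read CSV or XLSX into an object frame, preserving blanks as NaN."""
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        return pd.read_excel(path, header=None, dtype=object)
    return pd.read_csv(
        path, header=None, dtype=object, skip_blank_lines=False,
        keep_default_na=True,
    )


def _cell_to_float(cell, where: str) -> float:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return MISSING
    if isinstance(cell, str) and _BLANK.match(cell):
        return MISSING
    try:
        return float(cell)
    except (TypeError, ValueError):
        raise DataFormatError(f"non-numeric cell {cell!r} in {where}") from None


def load_spectra(
    path: str | Path,
    samples_per_plot: int,
    transpose: bool = False,
    drop_rows_matching: str | None = None,
) -> SpectralDataset:
    """Load a spectral matrix (CSV or XLSX).

    ``transpose=True`` handles instruments that emit wavelengths in rows:
    the raw table is transposed before interpretation, after which the
    layout must be wavelengths-in-columns.

    ``drop_rows_matching`` is an optional regular expression; sample rows
    whose code matches it (e.g. calibration panels left in the export) are
    removed before scan grouping.
    """
    raw = _read_raw(path)
    if transpose:
        raw = raw.T.reset_index(drop=True)
    if raw.shape[0] < 2 or raw.shape[1] < 2:
        raise DataFormatError("spectral file needs a header row and >=1 band")

    header = raw.iloc[0, 1:].tolist()
    wavelengths = []
    for j, cell in enumerate(header, start=2):
        try:
            wavelengths.append(float(cell))
        except (TypeError, ValueError):
            raise DataFormatError(
                f"wavelength header column {j} is not numeric: {cell!r}"
            ) from None
    wavelengths = np.asarray(wavelengths, dtype=float)
    if np.any(np.diff(wavelengths) <= 0):
        raise OrderingError(
            "wavelength columns must be strictly increasing (no duplicates); "
            "refusing to sort silently"
        )

    body = raw.iloc[1:]
    codes: list[str] = []
    rows: list[list[float]] = []
    pattern = re.compile(drop_rows_matching) if drop_rows_matching else None
    for i, (_, row) in enumerate(body.iterrows(), start=2):
        code = row.iloc[0]
        code = "" if code is None or (isinstance(code, float) and np.isnan(code)) else str(code)
        if pattern is not None and pattern.search(code):
            logger.info("dropping row %d (code %r) per pre-filter", i, code)
            continue
        rows.append(
            [_cell_to_float(c, f"row {i}") for c in row.iloc[1:]]
        )
        codes.append(code)

    values = np.asarray(rows, dtype=float) if rows else np.empty((0, wavelengths.size))
    if values.shape[0] % samples_per_plot != 0:
        raise GroupingError(
            f"{values.shape[0]} sample rows is not a multiple of "
            f"samples per plot = {samples_per_plot}"
        )
    return SpectralDataset(
        wavelengths=wavelengths,
        codes=codes,
        values=values,
        samples_per_scan=samples_per_plot,
    )


def load_responses(path: str | Path) -> ResponseTable:
    """Load a response table: three code columns, traits from column 4."""
    raw = _read_raw(path)
    if raw.shape[1] < 4:
        raise LayoutError(
            "response file needs three code columns and at least one "
            f"variable column; got {raw.shape[1]} columns"
        )
    header = [str(c) for c in raw.iloc[0]]
    body = raw.iloc[1:].reset_index(drop=True)
    codes = body.iloc[:, :3].astype(object)
    codes.columns = header[:3]
    codes = codes.map(lambda c: "" if c is None or (isinstance(c, float) and np.isnan(c)) else str(c))
    var_names = header[3:]
    variables = pd.DataFrame(
        {
            name: [
                _cell_to_float(c, f"variable {name!r}")
                for c in body.iloc[:, 3 + j]
            ]
            for j, name in enumerate(var_names)
        }
    )
    return ResponseTable(codes=codes, variables=variables)


def average_scans(dataset: SpectralDataset) -> ScanAverages:
    """Missing-aware per-scan mean spectrum (all-missing -> missing)."""
    k = dataset.samples_per_scan
    blocks = dataset.values.reshape(dataset.n_scans, k, dataset.n_wavelengths)
    import warnings as _warnings

    with _warnings.catch_warnings():
        # all-NaN slices legitimately yield NaN (empty scans)
        _warnings.simplefilter("ignore", category=RuntimeWarning)
        means = np.nanmean(blocks, axis=1)
    return ScanAverages(
        wavelengths=dataset.wavelengths.copy(),
        plot_ids=dataset.plot_ids,
        codes=[dataset.scan_code(p) for p in dataset.plot_ids],
        values=means,
    )


def _fmt(x: float) -> str:
    """Round-tripping text form of a float; blank for missing."""
    return "" if np.isnan(x) else repr(float(x))


def export_dataset(
    dataset: SpectralDataset,
    path: str | Path,
    mode: str = "per-sample",
    empties: str = "include",
) -> list[float]:
    """Write the dataset back to CSV in the input layout.

    mode ``"average"`` writes one row per scan (the missing-aware scan
    mean); ``"per-sample"`` mirrors the input row-for-row.  empties
    ``"exclude"`` drops wavelength columns that are missing in *every*
    exported row and returns the manifest of dropped wavelengths (also
    logged); ``"include"`` writes missing cells as blank fields.
    """
    if mode not in {"per-sample", "average"}:
        raise ValueError(f"unknown export mode {mode!r}")
    if empties not in {"include", "exclude"}:
        raise ValueError(f"unknown empties policy {empties!r}")

    if mode == "average":
        avg = average_scans(dataset)
        codes, values = avg.codes, avg.values
    else:
        codes, values = dataset.codes, dataset.values

    keep = np.ones(dataset.n_wavelengths, dtype=bool)
    dropped: list[float] = []
    if empties == "exclude":
        all_missing = np.all(np.isnan(values), axis=0)
        keep = ~all_missing
        dropped = [float(w) for w in dataset.wavelengths[all_missing]]
        if dropped:
            logger.info(
                "export: dropping %d all-missing wavelength columns "
                "(%.1f..%.1f nm)", len(dropped), dropped[0], dropped[-1]
            )

    wl = dataset.wavelengths[keep]
    with open(path, "w", newline="") as fh:
        fh.write("code," + ",".join(_fmt(w) for w in wl) + "\n")
        for code, row in zip(codes, values):
            fh.write(
                str(code) + "," + ",".join(_fmt(v) for v in row[keep]) + "\n"
            )
    return dropped
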