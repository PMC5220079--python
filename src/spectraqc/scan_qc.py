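"""Within-scan replicate quality control.

Field spectroradiometers record k replicate samples per plot scan; a change
of aim, wind on the canopy, or operator fatigue can leave one replicate
pointing at soil or sky.  The check is a per-wavelength coefficient of
variation over the k samples: a scan is a problem if CV exceeds the user
threshold at *any* wavelength.  Deletion of offending samples keeps the
k-row block structure — deleted samples become empty (all-missing) rows so
downstream scan indexing never shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, LookupError
from .spectral_io import SpectralDataset


@dataclass(frozen=True)
class ScanQCConfig:
    """max_cv_pct: highest acceptable within-scan CV (%) at any wavelength."""

    max_cv_pct: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.max_cv_pct) and self.max_cv_pct > 0):
            raise ConfigError("max_cv_pct must be finite and positive")


def scan_cv_profile(scan_values: np.ndarray) -> np.ndarray:
    """Per-wavelength CV (%) over the samples of one scan.

    Uses the sample (n-1) standard deviation over non-missing values.
    NaN where fewer than 2 values are present (undefined); +inf where the
    mean is <= 0 with >= 2 values — CV is meaningless there and non-positive
    mean reflectance is itself a symptom, so it exceeds any threshold.
    """
    import warnings as _warnings

    v = np.asarray(scan_values, dtype=float)
    n = np.sum(~np.isnan(v), axis=0)
    with _warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
        # all-NaN / single-value columns legitimately yield NaN here
        _warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(v, axis=0)
        sd = np.nanstd(v, axis=0, ddof=1)
        cv = sd / mean * 100.0
    cv = np.where(n < 2, np.nan, cv)
    cv = np.where((n >= 2) & (mean <= 0), np.inf, cv)
    return cv


@dataclass
class ScanQCResult:
    """Exhaustive, disjoint ok/problem partition of the scans.

    ``empty`` lists all-missing scans; they carry no evidence either way so
    they sit on the ok side of the partition but are reported separately.
    ``table`` has one row per scan: plot, status, worst_cv_pct,
    worst_wavelength_nm.
    """

    ok: list[int] = field(default_factory=list)
    problems: list[int] = field(default_factory=list)
    empty: list[int] = field(default_factory=list)
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def flag_scans(dataset: SpectralDataset, config: ScanQCConfig) -> ScanQCResult:
    """Partition scans by whether any wavelength's CV exceeds the threshold.

    Read-only on the dataset.
    """
    result = ScanQCResult()
    rows = []
    wl = dataset.wavelengths
    for plot in dataset.plot_ids:
        block = dataset.scan_values(plot)
        if np.all(np.isnan(block)):
            result.ok.append(plot)
            result.empty.append(plot)
            rows.append((plot, "empty", np.nan, np.nan))
            continue
        cv = scan_cv_profile(block)
        defined = ~np.isnan(cv)
        if not defined.any():
            result.ok.append(plot)
            rows.append((plot, "degenerate", np.nan, np.nan))
            continue
        worst_j = int(np.nanargmax(np.where(defined, cv, -np.inf)))
        worst = float(cv[worst_j])
        exceeded = bool(np.any(cv[defined] > config.max_cv_pct))
        if exceeded:
            result.problems.append(plot)
            rows.append((plot, "problem", worst, float(wl[worst_j])))
        else:
            result.ok.append(plot)
            rows.append((plot, "ok", worst, float(wl[worst_j])))
    result.table = pd.DataFrame(
        rows, columns=["plot", "status", "worst_cv_pct", "worst_wavelength_nm"]
    )
    return result


def delete_samples(
    dataset: SpectralDataset, plot_id: int, sample_indices: list[int]
) -> SpectralDataset:
    """Blank out chosen samples (1..k) of one scan; block structure kept.

    Even if all k samples are deleted the scan persists as empty rows.
    """
    out = dataset.copy()
    rows = out.scan_rows(plot_id)  # raises LookupError for a bad plot id
    k = out.samples_per_scan
    for idx in sample_indices:
        if not 1 <= idx <= k:
            raise LookupError(
                f"sample index {idx} outside 1..{k} for plot {plot_id}"
            )
        out.values[rows.start + idx - 1, :] = np.nan
    return out
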