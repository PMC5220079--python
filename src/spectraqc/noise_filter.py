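"""Atmospheric-absorption noise detection and deletion.

Water vapour and CO2 absorb strongly in bands near 1350-1400, 1800-1950 and
2350-2500 nm; under humid field conditions the reflectance there degenerates
into large sample-to-sample jitter.  The filter works per wavelength
*segment* with a two-criterion neighbour-change rule:

1. the relative change between two neighbouring wavelengths,
   ``d_i = |r_i - r_{i-1}| / |r_{i-1}| * 100``, exceeds a user maximum (%);
2. criterion 1 holds at ``N size`` or more consecutive wavelengths.

Positions meeting only criterion 1 are *pct* flags; positions inside a
qualifying streak are *run* flags, and only run flags drive deletion.  In
group mode the deleted range per segment is the inclusive envelope of run
flags pooled over all samples (uniform deletion, like a visual cut); in
individual mode each sample is cut to the envelope of its own run flags,
preserving narrow-noise samples measured under drier conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .spectral_io import SpectralDataset

#: flag levels per cell
FLAG_NONE = 0  #: neither criterion
FLAG_PCT = 1   #: % criterion only (plotted as a red cross in the original)
FLAG_RUN = 2   #: % and run-length criteria (black cross; drives deletion)

_ZERO = 1e-12


@dataclass(frozen=True)
class NoiseSegment:
    """One noise-filter rule over an inclusive wavelength window."""

    lower_nm: float
    upper_nm: float
    max_pct_change: float
    n_size: int
    mode: str = "group"  # "group" | "individual"

    def __post_init__(self) -> None:
        if not self.lower_nm < self.upper_nm:
            raise ConfigError("segment lower bound must be < upper bound")
        if not self.max_pct_change > 0:
            raise ConfigError("max_pct_change must be > 0")
        if int(self.n_size) != self.n_size or self.n_size < 1:
            raise ConfigError("n_size must be a positive integer")
        if self.mode not in {"group", "individual"}:
            raise ConfigError(f"unknown mode {self.mode!r}")


def validate_segments(segments: Sequence[NoiseSegment]) -> None:
    if len(segments) > 10:
        raise ConfigError("at most 10 noise segments per filter run")
    ordered = sorted(segments, key=lambda s: s.lower_nm)
    for a, b in zip(ordered, ordered[1:]):
        if b.lower_nm <= a.upper_nm:
            raise ConfigError(
                f"segments [{a.lower_nm},{a.upper_nm}] and "
                f"[{b.lower_nm},{b.upper_nm}] overlap"
            )


def neighbor_pct_change(series: np.ndarray) -> np.ndarray:
    """|r_i - r_{i-1}| / |r_{i-1}| * 100 at indices 1..n-1; NaN where either
    neighbour is missing.

    A near-zero denominator gives +inf (a jump from zero is maximal relative
    change) unless the current value is also near zero, in which case 0.
    """
    series = np.asarray(series, dtype=float)
    d = np.full(series.size, np.nan)
    prev, cur = series[:-1], series[1:]
    valid = ~np.isnan(prev) & ~np.isnan(cur)
    small_prev = np.abs(prev) < _ZERO
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        rel = np.abs(cur - prev) / np.abs(prev) * 100.0
    rel = np.where(small_prev & (np.abs(cur) < _ZERO), 0.0, rel)
    rel = np.where(small_prev & (np.abs(cur) >= _ZERO), np.inf, rel)
    d[1:][valid] = rel[valid]
    return d


def flag_noise(
    sample: np.ndarray,
    wavelengths: np.ndarray,
    segment: NoiseSegment,
) -> np.ndarray:
    """Per-wavelength flag level (0/1/2) for one sample under one segment.

    Missing cells are never flagged and break run streaks.  A segment that
    does not intersect the wavelength grid yields all-zero flags with a
    warning.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    flags = np.zeros(wavelengths.size, dtype=np.int8)
    in_seg = (wavelengths >= segment.lower_nm) & (wavelengths <= segment.upper_nm)
    if not in_seg.any():
        warnings.warn(
            f"noise segment [{segment.lower_nm}, {segment.upper_nm}] nm is "
            "outside the wavelength range; nothing flagged",
            stacklevel=2,
        )
        return flags

    d = neighbor_pct_change(np.asarray(sample, dtype=float))
    with np.errstate(invalid="ignore"):
        pct = in_seg & ~np.isnan(d) & (d > segment.max_pct_change)
    flags[pct] = FLAG_PCT

    # run flags: maximal streaks of consecutive pct indices of length >= n_size
    idx = np.flatnonzero(pct)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        for s, e in zip(starts, ends):
            if e - s + 1 >= segment.n_size:
                flags[idx[s] : idx[e] + 1] = FLAG_RUN
    return flags


def flag_matrix(
    dataset: SpectralDataset, segment: NoiseSegment
) -> np.ndarray:
    """Flags for every sample row; shape (n_rows, n_wl)."""
    return np.vstack(
        [flag_noise(row, dataset.wavelengths, segment) for row in dataset.values]
    )


@dataclass
class NoiseFilterResult:
    dataset: SpectralDataset
    report: pd.DataFrame  # one row per (segment, sample) deletion
    n_negatives_deleted: int


_REPORT_COLS = [
    "segment_lower_nm", "segment_upper_nm", "mode", "row", "plot",
    "deleted_from_nm", "deleted_to_nm",
]


def apply_noise_filter(
    dataset: SpectralDataset,
    segments: Iterable[NoiseSegment],
    drop_negatives: bool = False,
) -> NoiseFilterResult:
    """Delete noise per segment (group or individual mode).

    Group mode: per segment, the inclusive envelope [min, max] of run flags
    pooled over *all* samples is set to missing in every sample.  Individual
    mode: each sample is cut to the envelope of its own run flags; samples
    with no run flags are untouched.  ``drop_negatives`` afterwards sets
    every negative cell in the whole spectrum to missing.

    Deletion never alters a finite surviving cell, and the whole operation
    is idempotent.
    """
    segments = list(segments)
    validate_segments(segments)
    out = dataset.copy()
    wl = out.wavelengths
    k = out.samples_per_scan
    records: list[dict] = []

    def _record(seg: NoiseSegment, row: int, lo: float, hi: float) -> None:
        records.append(
            {
                "segment_lower_nm": seg.lower_nm,
                "segment_upper_nm": seg.upper_nm,
                "mode": seg.mode,
                "row": row,
                "plot": row // k + 1,
                "deleted_from_nm": lo,
                "deleted_to_nm": hi,
            }
        )

    for seg in segments:
        flags = flag_matrix(out, seg)
        run = flags == FLAG_RUN
        if seg.mode == "group":
            cols = np.flatnonzero(run.any(axis=0))
            if cols.size:
                lo, hi = cols.min(), cols.max()
                out.values[:, lo : hi + 1] = np.nan
                for r in range(out.n_rows):
                    _record(seg, r, float(wl[lo]), float(wl[hi]))
        else:
            for r in range(out.n_rows):
                cols = np.flatnonzero(run[r])
                if cols.size:
                    lo, hi = cols.min(), cols.max()
                    out.values[r, lo : hi + 1] = np.nan
                    _record(seg, r, float(wl[lo]), float(wl[hi]))

    n_neg = 0
    if drop_negatives:
        neg = out.values < 0  # NaN compares False
        n_neg = int(neg.sum())
        out.values[neg] = np.nan

    report = pd.DataFrame.from_records(records, columns=_REPORT_COLS)
    return NoiseFilterResult(dataset=out, report=report, n_negatives_deleted=n_neg)
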