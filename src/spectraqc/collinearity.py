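"""Greedy collinearity pruning of wavelengths against a response variable.

Neighbouring wavelengths of a high-resolution spectrum are nearly linearly
dependent, which wrecks multivariable model building.  This module keeps a
subset of wavelengths that (a) individually explain the response best and
(b) are mutually below a pairwise r-squared cutoff:

1. rank all usable wavelengths by simple-linear R^2 against y (descending,
   ties to the lower wavelength);
2. repeatedly retain the top-ranked remaining wavelength and discard every
   remaining wavelength whose squared Pearson correlation with it is >= the
   cutoff, recording the absorber and the pairwise r^2 in an audit trail.

The procedure is deterministic and auditable; correlations use
pairwise-complete observations so filtered (missing) cells do not bias the
selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError


@dataclass(frozen=True)
class CollinearityConfig:
    r2_cutoff: float
    method: str = "linear"

    def __post_init__(self) -> None:
        if not 0 < self.r2_cutoff <= 1:
            raise ConfigError("r2_cutoff must lie in (0, 1]")
        if self.method not in {"linear", "ann"}:
            raise ConfigError(f"unknown method {self.method!r}")


@dataclass
class CollinearityResult:
    retained: list[float]
    audit: pd.DataFrame  # discarded_nm, absorber_nm, pairwise_r2
    excluded: list[float] = field(default_factory=list)  # <3 pairs or zero variance


def _pairwise_r2_vs_y(matrix: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Simple-linear R^2 of each column against y, pairwise-complete.

    NaN where fewer than 3 complete pairs or a degenerate (zero-variance)
    column/response slice.
    """
    n_wl = matrix.shape[1]
    out = np.full(n_wl, np.nan)
    y_ok = ~np.isnan(y)
    for j in range(n_wl):
        col = matrix[:, j]
        ok = y_ok & ~np.isnan(col)
        if ok.sum() < 3:
            continue
        cx, cy = col[ok], y[ok]
        sx, sy = cx.std(), cy.std()
        if sx == 0 or sy == 0:
            continue
        r = float(np.corrcoef(cx, cy)[0, 1])
        out[j] = r * r
    return out


def _r2_against(col: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of one column vs every column of matrix,
    pairwise-complete and vectorized; NaN where undefined (<2 pairs or zero
    variance)."""
    a = col[:, None]
    valid = ~np.isnan(a) & ~np.isnan(matrix)
    n = valid.sum(axis=0).astype(float)
    a_f = np.where(valid, a, 0.0)
    b_f = np.where(valid, matrix, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a = a_f.sum(axis=0) / n
        mean_b = b_f.sum(axis=0) / n
        cov = (a_f * b_f).sum(axis=0) / n - mean_a * mean_b
        var_a = (a_f * a_f).sum(axis=0) / n - mean_a**2
        var_b = (b_f * b_f).sum(axis=0) / n - mean_b**2
        r2 = cov * cov / (var_a * var_b)
    r2 = np.where((n < 2) | (var_a <= 0) | (var_b <= 0), np.nan, r2)
    return np.clip(r2, 0.0, 1.0)


def prune_collinear(
    avg_matrix: np.ndarray,
    wavelengths: np.ndarray,
    y: np.ndarray,
    config: CollinearityConfig,
) -> CollinearityResult:
    """Greedy best-first pruning; see the module docstring for the rule.

    ``avg_matrix`` is the per-scan averaged spectra, shape (n_scans, n_wl);
    ``y`` the aligned response.  Wavelengths with fewer than 3 complete
    pairs against y, or zero variance, are excluded up front and listed in
    the result.  If nothing is usable the result is empty with a warning.
    """
    if config.method == "ann":
        raise NotImplementedError(
            "the ANN collinearity strategy is an extension hook; only the "
            "linear method is implemented"
        )
    matrix = np.asarray(avg_matrix, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    y = np.asarray(y, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != wavelengths.size:
        raise ValueError("avg_matrix columns must match wavelengths")
    if matrix.shape[0] != y.size:
        raise ValueError("y must align with avg_matrix rows")
    if (~np.isnan(y)).sum() < 3:
        raise ConfigError("need >= 3 scans with non-missing y")

    r2_y = _pairwise_r2_vs_y(matrix, y)
    usable = ~np.isnan(r2_y)
    excluded = [float(w) for w in wavelengths[~usable]]
    if not usable.any():
        warnings.warn("all wavelengths degenerate; nothing to retain", stacklevel=2)
        return CollinearityResult(
            retained=[],
            audit=pd.DataFrame(columns=["discarded_nm", "absorber_nm", "pairwise_r2"]),
            excluded=excluded,
        )

    # rank by R^2 vs y descending, ties to the lower wavelength
    idx = np.flatnonzero(usable)
    order = idx[np.lexsort((wavelengths[idx], -r2_y[idx]))]

    remaining = list(order)
    retained: list[int] = []
    audit_rows: list[tuple[float, float, float]] = []
    while remaining:
        top = remaining.pop(0)
        retained.append(top)
        if not remaining:
            break
        rem = np.asarray(remaining)
        r2_pair = _r2_against(matrix[:, top], matrix[:, rem])
        absorb = ~np.isnan(r2_pair) & (r2_pair >= config.r2_cutoff)
        for j, r2 in zip(rem[absorb], r2_pair[absorb]):
            audit_rows.append((float(wavelengths[j]), float(wavelengths[top]), float(r2)))
        remaining = [j for j, a in zip(remaining, absorb) if not a]

    # selection order: the first retained wavelength is the single best
    # linear predictor of y
    retained_nm = [float(wavelengths[j]) for j in retained]
    audit = pd.DataFrame(
        audit_rows, columns=["discarded_nm", "absorber_nm", "pairwise_r2"]
    )
    return CollinearityResult(retained=retained_nm, audit=audit, excluded=excluded)
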