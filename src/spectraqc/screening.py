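"""Batch regression screening and outlier exploration on scan averages.

Everything here works on the missing-aware per-scan mean spectra
(``spectral_io.average_scans``), mirroring the intended workflow: noise and
within-scan QC first, then index/wavelength screening on clean averages.

* ``screen_wavelengths`` — fit chosen models of each response variable on
  each wavelength's reflectance, keep rows where a chosen statistic passes
  an above/below cutoff;
* ``screen_sris`` — same over a registry of spectral indices, reported in
  the "full report" layout (best model block first, then one block per
  tested model), screened on adjusted R^2;
* ``scatter_table`` / ``flag_by_range`` / ``remove_plots`` — the
  programmatic outlier loop: tabulate (index, trait) per plot, flag plots
  by value range, blank out flagged scans;
* ``detailed_index_report`` — per-plot values of chosen indices and traits
  for external plotting/publication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    DomainError,
    InsufficientDataError,
    LookupError,
)
from .model_fitting import MODEL_ORDER, RegressionFit, fit_model
from .spectral_io import (
    ResponseTable,
    ScanAverages,
    SpectralDataset,
)
from .sri_registry import (
    BandMatchPolicy,
    SRIRegistry,
    builtin_registry,
    compute_sri_matrix,
)

_STATS = ("R2", "adjR2", "RMSE", "SSE", "DFE")
_STAT_ATTR = {"R2": "r2", "adjR2": "adj_r2", "RMSE": "rmse", "SSE": "sse", "DFE": "dfe"}


@dataclass(frozen=True)
class ScreeningConfig:
    """Which models to fit and which statistic/cutoff filters the report.

    ``direction`` defaults per statistic: above for R2/adjR2 (bigger is
    better), below for RMSE/SSE (smaller is better); either is allowed.
    """

    models: tuple[str, ...]
    statistic: str = "R2"
    cutoff: float = 0.0
    direction: str | None = None

    def __post_init__(self) -> None:
        if not self.models:
            raise ConfigError("at least one model required")
        for m in self.models:
            if m not in MODEL_ORDER:
                raise ConfigError(f"unknown model {m!r}")
        if self.statistic not in _STATS:
            raise ConfigError(f"statistic must be one of {_STATS}")
        if self.direction is None:
            object.__setattr__(
                self,
                "direction",
                "below" if self.statistic in {"RMSE", "SSE"} else "above",
            )
        if self.direction not in {"above", "below"}:
            raise ConfigError("direction must be 'above' or 'below'")


def _passes(value: float, cutoff: float, direction: str) -> bool:
    if np.isnan(value):
        return False
    return value > cutoff if direction == "above" else value < cutoff


def _try_fit(x, y, model) -> tuple[RegressionFit | None, str | None]:
    try:
        fit = fit_model(x, y, model)
    except DomainError:
        return None, "domain"
    except InsufficientDataError:
        return None, "insufficient-data"
    if not fit.converged:
        return None, "nonconvergence"
    if fit.degenerate:
        return None, "degenerate-response"
    return fit, None


@dataclass
class ScreeningReport:
    table: pd.DataFrame
    skipped: pd.DataFrame  # predictor, variable, model, reason


def screen_wavelengths(
    averages: ScanAverages,
    responses: ResponseTable,
    config: ScreeningConfig,
) -> ScreeningReport:
    """Per-(wavelength, variable, model) fits passing the statistic cutoff."""
    _check_alignment(averages, responses)
    rows, skips = [], []
    for var in responses.variable_names:
        y = responses.variable(var)
        for j, wl in enumerate(averages.wavelengths):
            x = averages.values[:, j]
            for model in config.models:
                fit, reason = _try_fit(x, y, model)
                if fit is None:
                    skips.append((float(wl), var, model, reason))
                    continue
                stat = getattr(fit, _STAT_ATTR[config.statistic])
                if _passes(stat, config.cutoff, config.direction):
                    rows.append(
                        {
                            "variable": var,
                            "wavelength_nm": float(wl),
                            "model": model,
                            "adjR2": fit.adj_r2,
                            "R2": fit.r2,
                            "RMSE": fit.rmse,
                            "SSE": fit.sse,
                            "DFE": fit.dfe,
                            "p1": fit.p1,
                            "p2": fit.p2,
                            "p3": fit.p3,
                        }
                    )
    table = pd.DataFrame(
        rows,
        columns=[
            "variable", "wavelength_nm", "model",
            "adjR2", "R2", "RMSE", "SSE", "DFE", "p1", "p2", "p3",
        ],
    )
    skipped = pd.DataFrame(
        skips, columns=["predictor", "variable", "model", "reason"]
    )
    return ScreeningReport(table=table, skipped=skipped)


# ---------------------------------------------------------------------------
# SRI full report
# ---------------------------------------------------------------------------

_BLOCK_STATS = ["adjR2", "R2", "RMSE", "SSE", "DFE"]


@dataclass
class FullReport:
    """Best-block + per-model-block layout of the SRI screening."""

    table: pd.DataFrame
    skipped: pd.DataFrame
    models: tuple[str, ...]


def _stat_block(fit: RegressionFit | None) -> list[float]:
    if fit is None:
        return [np.nan] * len(_BLOCK_STATS)
    return [fit.adj_r2, fit.r2, fit.rmse, fit.sse, float(fit.dfe)]


def screen_sris(
    averages: ScanAverages,
    responses: ResponseTable,
    models: tuple[str, ...],
    adj_r2_cutoff: float,
    registry: SRIRegistry | None = None,
    policy: BandMatchPolicy = BandMatchPolicy(),
) -> FullReport:
    """Screen every (variable, index) pair on adjusted R^2.

    A row appears iff at least one tested model converged with
    adjR^2 >= cutoff.  The best model is the converged one with the highest
    adjusted R^2 (ties resolve in canonical model order); its statistics
    come first, then one block per tested model.
    """
    _check_alignment(averages, responses)
    models = tuple(models)
    for m in models:
        if m not in MODEL_ORDER:
            raise ConfigError(f"unknown model {m!r}")
    registry = registry if registry is not None else builtin_registry()
    definitions = list(registry)
    values = compute_sri_matrix(averages, definitions, policy)

    rows, skips = [], []
    for var in responses.variable_names:
        y = responses.variable(var)
        for j, definition in enumerate(definitions):
            x = values[:, j]
            if np.all(np.isnan(x)):
                skips.append((definition.name, var, "*", "all-missing-index"))
                continue
            fits: dict[str, RegressionFit | None] = {}
            for model in models:
                fit, reason = _try_fit(x, y, model)
                fits[model] = fit
                if fit is None:
                    skips.append((definition.name, var, model, reason))
            converged = [
                (m, f) for m, f in fits.items() if f is not None
            ]
            if not converged:
                continue
            # ties resolve by canonical model order; max is stable on the
            # first maximal element so iterate in that order
            converged.sort(key=lambda mf: MODEL_ORDER.index(mf[0]))
            best_model, best_fit = max(converged, key=lambda mf: mf[1].adj_r2)
            if best_fit.adj_r2 < adj_r2_cutoff:
                continue
            row: dict[str, object] = {
                "variable": var,
                "sri": definition.name,
                "best_model": best_model,
            }
            for stat, val in zip(_BLOCK_STATS, _stat_block(best_fit)):
                row[f"best_{stat}"] = val
            for model in models:
                for stat, val in zip(_BLOCK_STATS, _stat_block(fits[model])):
                    row[f"{model}_{stat}"] = val
            rows.append(row)

    columns = ["variable", "sri", "best_model"]
    columns += [f"best_{s}" for s in _BLOCK_STATS]
    for model in models:
        columns += [f"{model}_{s}" for s in _BLOCK_STATS]
    table = pd.DataFrame(rows, columns=columns)
    skipped = pd.DataFrame(
        skips, columns=["predictor", "variable", "model", "reason"]
    )
    return FullReport(table=table, skipped=skipped, models=models)


# ---------------------------------------------------------------------------
# detailed report / outlier loop
# ---------------------------------------------------------------------------


def _check_alignment(averages: ScanAverages, responses: ResponseTable) -> None:
    if averages.n_scans != responses.n_rows:
        raise ConfigError(
            f"{averages.n_scans} scans but {responses.n_rows} response rows"
        )


def detailed_index_report(
    averages: ScanAverages,
    responses: ResponseTable,
    sri_names: list[str],
    variable_names: list[str],
    registry: SRIRegistry | None = None,
    policy: BandMatchPolicy = BandMatchPolicy(),
) -> pd.DataFrame:
    """One row per scan: code columns, requested index values, trait values."""
    _check_alignment(averages, responses)
    registry = registry if registry is not None else builtin_registry()
    definitions = [registry.get(name) for name in sri_names]
    for var in variable_names:
        if var not in responses.variable_names:
            raise LookupError(f"unknown response variable {var!r}")
    values = compute_sri_matrix(averages, definitions, policy)
    out = responses.codes.copy().reset_index(drop=True)
    out.insert(0, "plot_id", averages.plot_ids)
    for j, name in enumerate(sri_names):
        out[name] = values[:, j]
    for var in variable_names:
        out[var] = responses.variable(var)
    return out


def scatter_table(
    averages: ScanAverages,
    responses: ResponseTable,
    sri_name: str,
    variable_name: str,
    registry: SRIRegistry | None = None,
    policy: BandMatchPolicy = BandMatchPolicy(),
) -> pd.DataFrame:
    """(plot_id, index value, trait value) for every scan, missing kept."""
    report = detailed_index_report(
        averages, responses, [sri_name], [variable_name], registry, policy
    )
    return report[["plot_id", sri_name, variable_name]].rename(
        columns={sri_name: "index_value", variable_name: "response_value"}
    )


def flag_by_range(
    table: pd.DataFrame,
    axis: str,
    predicate: str,
    lo: float | None = None,
    hi: float | None = None,
) -> list[int]:
    """Plot ids whose index/response value satisfies lt/gt/between.

    Missing values never match (an empty cell is not evidence of anything).
    """
    if axis not in {"index", "response"}:
        raise ConfigError("axis must be 'index' or 'response'")
    col = table["index_value" if axis == "index" else "response_value"]
    v = col.to_numpy(dtype=float)
    if predicate == "lt":
        if lo is None:
            raise ConfigError("lt needs a bound")
        mask = v < lo
    elif predicate == "gt":
        if lo is None:
            raise ConfigError("gt needs a bound")
        mask = v > lo
    elif predicate == "between":
        if lo is None or hi is None or lo > hi:
            raise ConfigError("between needs lo <= hi")
        mask = (v >= lo) & (v <= hi)
    else:
        raise ConfigError(f"unknown predicate {predicate!r}")
    mask &= ~np.isnan(v)
    return [int(p) for p in table["plot_id"].to_numpy()[mask]]


def remove_plots(
    dataset: SpectralDataset, plot_ids: list[int]
) -> SpectralDataset:
    """Blank all samples of the named scans; the k-row blocks persist."""
    out = dataset.copy()
    for plot in plot_ids:
        out.values[out.scan_rows(plot), :] = np.nan  # LookupError on bad id
    return out
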