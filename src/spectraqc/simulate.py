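"""Deterministic synthetic spectral trials with injectable field artifacts.

The generator emulates the data regime of a canopy reflectance breeding
trial measured with a full-range (350-2500 nm, 1 nm) field
spectroradiometer, three samples per plot scan.  Each plot draws a
greenness and a water-status parameter; the spectrum is a piecewise-smooth
vegetation shape (low visible baseline, green bump near 550 nm, logistic
red-edge rise near 715 nm scaled by greenness, NIR plateau, water
absorption dips near 1450 and 1940 nm deepened by water status, gentle
decline to 2500 nm).

Three measurement artifacts can be injected, each with a complete truth
log so recovery tests never re-derive anything:

* **noise bands** — per-wavelength multiplicative jitter uniform in
  +-amplitude over a wavelength window (atmospheric-absorption noise; the
  target of the noise filter);
* **within-scan jitter** — a multiplicative scalar per replicate sample,
  sd = the target CV% (the target of the scan QC);
* **a calibration-drift block** — a contiguous plot range whose
  reflectance above 700 nm is multiplied by a gain < 1, emulating a skipped
  white-reference calibration that suppresses the NIR and drags
  NDVI-family indices down (the target of the outlier loop).  The gain is
  spectrally selective on purpose: a flat gain would cancel in every
  ratio-based index and be invisible to the tool the block is meant to
  exercise.

The response is tied to the *pre-artifact* NDVI
(y = beta0 + beta1 * NDVI_true + Gaussian noise), so QC filters can only
recover — never manufacture — the signal.  Everything is driven by one
integer seed, bit-for-bit reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .spectral_io import ResponseTable, SpectralDataset

import pandas as pd


@dataclass(frozen=True)
class TrialSimConfig:
    """Study conditions of a simulated trial.

    Defaults mirror a realistic single-replicate field campaign: 100 plots,
    3 samples per scan, the full 350-2500 nm range at 1 nm, replicate
    jitter of 0.3 % CV, and a yield-like response (t/ha) spanning roughly
    2-10 as true NDVI spans 0-1 with trait noise sd 0.3.  Artifacts are off
    unless configured.
    """

    n_plots: int = 100
    samples_per_scan: int = 3
    wl_start: float = 350.0
    wl_stop: float = 2500.0
    wl_step: float = 1.0
    seed: int = 0
    greenness_range: tuple[float, float] = (0.4, 0.95)
    water_range: tuple[float, float] = (0.2, 0.8)
    within_scan_cv_pct: float = 0.3
    noise_bands: tuple[tuple[float, float, float], ...] = ()
    drift_block: tuple[int, int, float] | None = None  # (first, last, nir gain)
    response_name: str = "Yield"
    beta0: float = 2.0
    beta1: float = 8.0
    sigma: float = 0.3

    def __post_init__(self) -> None:
        if self.n_plots < 1 or self.samples_per_scan < 1:
            raise ConfigError("n_plots and samples_per_scan must be positive")
        if self.within_scan_cv_pct < 0 or self.sigma < 0:
            raise ConfigError("jitter and noise magnitudes must be >= 0")
        for lo, hi, amp in self.noise_bands:
            if lo >= hi or amp < 0:
                raise ConfigError(f"bad noise band ({lo}, {hi}, {amp})")
        if self.drift_block is not None:
            lo, hi, gain = self.drift_block
            if not (1 <= lo <= hi <= self.n_plots):
                raise ConfigError(
                    f"drift block {lo}..{hi} outside 1..{self.n_plots}"
                )
            if gain <= 0:
                raise ConfigError("drift gain must be > 0")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.wl_start, self.wl_stop + self.wl_step / 2, self.wl_step)


@dataclass
class TruthLog:
    """Everything a recovery test needs, logged at generation time."""

    greenness: np.ndarray
    water: np.ndarray
    ndvi_true: np.ndarray
    y: np.ndarray
    noise_bands: tuple[tuple[float, float, float], ...]
    drift_block: tuple[int, int, float] | None
    beta0: float
    beta1: float
    sigma: float

    @property
    def drift_plot_ids(self) -> list[int]:
        if self.drift_block is None:
            return []
        lo, hi, _ = self.drift_block
        return list(range(lo, hi + 1))


_DRIFT_EDGE_NM = 700.0  # drift gain applies above this wavelength


def simulate_spectrum(
    greenness: float,
    water: float,
    grid: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One smooth vegetation-like reflectance spectrum on ``grid``.

    Strictly inside (0, 1).  The NIR plateau rises with ``greenness``; the
    1450/1940 nm dips deepen with ``water``.  ``rng`` adds a tiny smooth
    low-frequency perturbation (plot-to-plot individuality); the same
    generator state reproduces the same series.
    """
    if not (0 <= greenness <= 1 and 0 <= water <= 1):
        raise ConfigError("greenness and water must lie in [0, 1]")
    wl = np.asarray(grid, dtype=float)

    vis_base = 0.04 + 0.02 * (1.0 - greenness)
    green_bump = 0.05 * np.exp(-(((wl - 550.0) / 35.0) ** 2))
    visible = vis_base + green_bump

    plateau = 0.25 + 0.30 * greenness
    red_edge = 1.0 / (1.0 + np.exp(-(wl - 715.0) / 12.0))
    spectrum = visible * (1.0 - red_edge) + plateau * red_edge

    # gentle SWIR decline beyond 1300 nm
    decline = 1.0 - np.clip((wl - 1300.0) * 1.2e-4, 0.0, None)
    spectrum = spectrum * decline

    # water-absorption dips (weak 1190 nm feature plus the two major ones)
    depth_1190 = 0.05 + 0.10 * water
    depth_1450 = 0.35 + 0.45 * water
    depth_1940 = 0.45 + 0.45 * water
    spectrum = spectrum * (1.0 - depth_1190 * np.exp(-(((wl - 1190.0) / 40.0) ** 2)))
    spectrum = spectrum * (1.0 - depth_1450 * np.exp(-(((wl - 1450.0) / 35.0) ** 2)))
    spectrum = spectrum * (1.0 - depth_1940 * np.exp(-(((wl - 1940.0) / 45.0) ** 2)))

    if rng is not None:
        # smooth low-frequency individuality; amplitude small enough that
        # neighbouring-wavelength changes stay far below noise-filter cutoffs
        phases = rng.uniform(0, 2 * np.pi, size=3)
        amps = rng.uniform(0.0, 0.004, size=3)
        wiggle = sum(
            a * np.cos(2 * np.pi * wl / p_len + ph)
            for a, p_len, ph in zip(amps, (900.0, 1400.0, 2100.0), phases)
        )
        spectrum = spectrum * (1.0 + wiggle)

    return np.clip(spectrum, 0.005, 0.95)


def _ndvi(spectrum: np.ndarray, grid: np.ndarray) -> float:
    r800 = float(spectrum[np.argmin(np.abs(grid - 800.0))])
    r670 = float(spectrum[np.argmin(np.abs(grid - 670.0))])
    return (r800 - r670) / (r800 + r670)


def simulate_trial(
    config: TrialSimConfig,
) -> tuple[SpectralDataset, ResponseTable, TruthLog]:
    """Generate a full trial: spectra, response table and truth log."""
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    n, k = config.n_plots, config.samples_per_scan

    g_lo, g_hi = config.greenness_range
    w_lo, w_hi = config.water_range
    greenness = rng.uniform(g_lo, g_hi, size=n)
    water = rng.uniform(w_lo, w_hi, size=n)

    rows = np.empty((n * k, grid.size))
    codes: list[str] = []
    ndvi_true = np.empty(n)
    for i in range(n):
        clean = simulate_spectrum(greenness[i], water[i], grid, rng)
        ndvi_true[i] = _ndvi(clean, grid)
        jitter = 1.0 + rng.normal(0.0, config.within_scan_cv_pct / 100.0, size=k)
        for s in range(k):
            rows[i * k + s] = clean * jitter[s]
            codes.append(f"G{i + 1:03d}")

    if config.drift_block is not None:
        lo, hi, gain = config.drift_block
        nir = grid > _DRIFT_EDGE_NM
        rows[(lo - 1) * k : hi * k, nir] *= gain

    for band_lo, band_hi, amp in config.noise_bands:
        in_band = (grid >= band_lo) & (grid <= band_hi)
        if in_band.any():
            rows[:, in_band] *= 1.0 + rng.uniform(
                -amp, amp, size=(n * k, int(in_band.sum()))
            )

    y = config.beta0 + config.beta1 * ndvi_true + rng.normal(0.0, config.sigma, size=n)

    dataset = SpectralDataset(
        wavelengths=grid, codes=codes, values=rows, samples_per_scan=k
    )
    responses = ResponseTable(
        codes=pd.DataFrame(
            {
                "Plot": [str(i + 1) for i in range(n)],
                "Genotype": [f"G{i + 1:03d}" for i in range(n)],
                "Replication": ["1"] * n,
            }
        ),
        variables=pd.DataFrame({config.response_name: y}),
    )
    truth = TruthLog(
        greenness=greenness,
        water=water,
        ndvi_true=ndvi_true,
        y=y,
        noise_bands=config.noise_bands,
        drift_block=config.drift_block,
        beta0=config.beta0,
        beta1=config.beta1,
        sigma=config.sigma,
    )
    return dataset, responses, truth
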