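"""Synthetic ATR-FTIR-like spectra with a known informative-wavelength mask.

Emulates a single-analyte calibration series in aqueous buffer under the
Beer-Lambert premise: every spectrum is a sum of concentration-independent
solvent/buffer bands, analyte bands whose amplitude is exactly linear in
concentration, a smooth per-sample baseline drift, and iid Gaussian noise.
Bands are Gaussian in wavenumber — adequate for testing selection methods,
not a spectroscopic claim about any real analyte.

The default configuration mirrors a 47-sample lactate-in-PBS design:
concentrations 0–5 mmol/L in 0.25 steps then 5–18 mmol/L in 0.5 steps,
a 850–4000 cm^-1 axis at 1 cm^-1 spacing (p = 3151), analyte bands in the
fingerprint region (1050–1250 cm^-1) plus a weak high-wavenumber band near
3505 cm^-1, and dominant water/buffer background bands.  The ground-truth
mask marks wavelengths within ``informative_halfwidth_mult`` Gaussian widths
of any analyte band center, enabling parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import SpectraDataset

__all__ = [
    "SimConfig",
    "GroundTruth",
    "lactate_grid",
    "generate",
    "baseline_subtract",
    "reduced_benchmark_config",
]


def lactate_grid() -> np.ndarray:
    """The 47-point calibration grid: 0–5 mmol/L step 0.25, 5–18 step 0.5."""
    low = np.arange(0.0, 5.0 + 1e-9, 0.25)      # 21 values, 0.00 .. 5.00
    high = np.arange(5.5, 18.0 + 1e-9, 0.5)     # 26 values, 5.50 .. 18.00
    return np.concatenate([low, high])


# (center cm^-1, Gaussian width cm^-1, amplitude)
_DEFAULT_ANALYTE = [
    (1125.0, 15.0, 1.5e-3),   # fingerprint C-O/C-C stretching region
    (1215.0, 12.0, 1.0e-3),
    (3505.0, 10.0, 4.0e-4),   # weak high-wavenumber O-H band
]
_DEFAULT_BACKGROUND = [
    (1637.0, 120.0, 0.9),     # water bending
    (3350.0, 220.0, 1.2),     # broad O-H stretch
    (2120.0, 150.0, 0.08),    # water combination band
    (990.0, 300.0, 0.3),      # buffer envelope
]


@dataclass
class SimConfig:
    """Synthetic spectra design.

    Amplitudes are absorbance units (AU); analyte amplitudes are AU per
    mmol/L (molar-absorptivity scale).  ``noise_sd`` is the iid Gaussian
    noise level and ``baseline_drift_amplitude`` scales a smooth random
    cubic baseline per sample.
    """

    wavenumber_start: float = 850.0
    wavenumber_end: float = 4000.0
    spacing: float = 1.0
    analyte_peaks: list = field(default_factory=lambda: list(_DEFAULT_ANALYTE))
    background_peaks: list = field(default_factory=lambda: list(_DEFAULT_BACKGROUND))
    noise_sd: float = 2e-4
    baseline_drift_amplitude: float = 5e-4
    concentration_grid: np.ndarray = field(default_factory=lactate_grid)
    seed: int = 0
    informative_halfwidth_mult: float = 2.0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.wavenumber_end <= self.wavenumber_start:
            raise ValueError("wavenumber range must be non-empty")
        self.concentration_grid = np.asarray(self.concentration_grid, dtype=float)
        if self.concentration_grid.size == 0:
            raise ValueError("concentration grid must be non-empty")
        if np.any(self.concentration_grid < 0):
            raise ValueError("concentrations must be non-negative")
        if self.noise_sd < 0 or self.baseline_drift_amplitude < 0:
            raise ValueError("noise and drift amplitudes must be >= 0")
        lo, hi = self.wavenumber_start, self.wavenumber_end
        for center, width, _ in list(self.analyte_peaks) + list(self.background_peaks):
            if width <= 0:
                raise ValueError("peak widths must be positive")
            if not lo <= center <= hi:
                raise ValueError(f"peak center {center} outside [{lo}, {hi}]")

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.arange(
            self.wavenumber_start, self.wavenumber_end + self.spacing / 2, self.spacing
        )


@dataclass
class GroundTruth:
    """Which wavelengths carry analyte signal (for recovery testing only)."""

    informative_mask: np.ndarray

    def __post_init__(self) -> None:
        self.informative_mask = np.asarray(self.informative_mask, dtype=bool)


def _gaussians(wn: np.ndarray, peaks) -> np.ndarray:
    out = np.zeros_like(wn)
    for center, width, amplitude in peaks:
        out += amplitude * np.exp(-0.5 * ((wn - center) / width) ** 2)
    return out


def generate(cfg: SimConfig) -> tuple[SpectraDataset, GroundTruth]:
    """Generate a spectra dataset and its ground-truth informative mask.

    absorbance[i, k] = background(k) + conc[i] * analyte(k)
                       + drift_i(k) + noise,

    so before noise the analyte contribution is exactly linear in
    concentration.  Deterministic for a given ``cfg.seed``; different seeds
    change only noise and drift, never the expected spectrum.
    """
    rng = np.random.default_rng(cfg.seed)
    wn = cfg.wavenumbers
    p = wn.size
    conc = cfg.concentration_grid
    n = conc.size
    background = _gaussians(wn, cfg.background_peaks)
    analyte = _gaussians(wn, cfg.analyte_peaks)
    absorbance = background[np.newaxis, :] + conc[:, np.newaxis] * analyte[np.newaxis, :]
    if cfg.baseline_drift_amplitude > 0:
        x = np.linspace(-1.0, 1.0, p)
        coeffs = rng.uniform(-1.0, 1.0, size=(n, 4))
        drift = (
            coeffs[:, [0]]
            + coeffs[:, [1]] * x
            + coeffs[:, [2]] * x**2
            + coeffs[:, [3]] * x**3
        )
        absorbance = absorbance + cfg.baseline_drift_amplitude * drift
    if cfg.noise_sd > 0:
        absorbance = absorbance + rng.normal(0.0, cfg.noise_sd, size=(n, p))
    ds = SpectraDataset(
        wavenumbers=wn,
        absorbance=absorbance,
        concentration=conc,
        sample_ids=[f"sim{i:03d}" for i in range(n)],
    )
    mask = np.zeros(p, dtype=bool)
    for center, width, _ in cfg.analyte_peaks:
        mask |= np.abs(wn - center) <= cfg.informative_halfwidth_mult * width
    return ds, GroundTruth(informative_mask=mask)


def reduced_benchmark_config(seed: int = 0, noise_sd: float = 2e-3) -> SimConfig:
    """Reduced-scale two-band benchmark for recovery studies (p = 301).

    900-1500 cm^-1 at 2 cm^-1 with two fingerprint analyte bands and two
    broad background bands.  The noise level puts the peak signal-to-noise
    ratio near 13 (max-concentration band amplitude 2.7e-2 AU vs 2e-3 AU
    noise), which also makes the ground-truth boundary meaningful: beyond
    two Gaussian widths the band tails fall under the noise floor, so the
    informative mask and the truly recoverable wavelengths coincide.
    """
    return SimConfig(
        wavenumber_start=900.0,
        wavenumber_end=1500.0,
        spacing=2.0,
        analyte_peaks=[(1125.0, 15.0, 1.5e-3), (1215.0, 12.0, 1.0e-3)],
        background_peaks=[(990.0, 300.0, 0.3), (1430.0, 120.0, 0.6)],
        noise_sd=noise_sd,
        seed=seed,
    )


def baseline_subtract(ds: SpectraDataset, reference_index: int) -> SpectraDataset:
    """Subtract one spectrum (e.g. the blank) from every spectrum.

    The reference row becomes identically zero; concentrations and ids are
    unchanged.
    """
    if not 0 <= reference_index < ds.n:
        raise IndexError(f"reference_index {reference_index} out of range [0, {ds.n})")
    ref = ds.absorbance[reference_index]
    return SpectraDataset(
        wavenumbers=ds.wavenumbers.copy(),
        absorbance=ds.absorbance - ref,
        concentration=ds.concentration.copy(),
        sample_ids=list(ds.sample_ids),
    )
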