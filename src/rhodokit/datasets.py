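"""Domain containers for flash-photolysis, titration and photocurrent data.

The CSV dialects follow the conventions of time-resolved spectroscopy rigs:
a trace matrix stores times (s) in the first row, wavelengths (nm) in the
first column and absorbance changes in the body; a photocurrent trace is a
plain two-column (t, I) file.  All text I/O is UTF-8 with '.' decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectralState",
    "KineticIntermediate",
    "PhotocycleScheme",
    "NoiseSpec",
    "TransientAbsorptionDataset",
    "TitrationSeries",
    "PhotocurrentTrace",
    "gaussian_band",
]


def gaussian_band(wavelengths: np.ndarray, lambda_max: float, fwhm: float,
                  peak: float = 1.0) -> np.ndarray:
    """Gaussian absorption band in wavelength with the given FWHM."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return peak * np.exp(-0.5 * ((wavelengths - lambda_max) / sigma) ** 2)


@dataclass(frozen=True)
class SpectralState:
    """A spectrally distinct species, modelled as a Gaussian band.

    Parameters
    ----------
    name : str
        Label, e.g. ``"K540"`` or ``"ground"``.
    lambda_max : float
        Absorption maximum in nm; must lie in the probed window [330, 730].
    fwhm : float
        Full width at half maximum of the band, nm.  Retinal-protein bands
        are ~90 nm wide; only the peak position matters downstream.
    peak_amplitude : float
        Peak molar absorbance in arbitrary units.
    """

    name: str
    lambda_max: float
    fwhm: float = 90.0
    peak_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not (330.0 <= self.lambda_max <= 730.0):
            raise ValueError(
                f"lambda_max {self.lambda_max} nm outside [330, 730] nm")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be non-negative")

    def spectrum(self, wavelengths: np.ndarray) -> np.ndarray:
        return gaussian_band(wavelengths, self.lambda_max, self.fwhm,
                             self.peak_amplitude)


@dataclass(frozen=True)
class KineticIntermediate:
    """A kinetic intermediate: a fixed mixture of spectral states.

    ``fractions`` maps each contributing :class:`SpectralState` to its
    occupancy fraction; fractions must sum to one (tolerance 1e-9).
    """

    name: str
    fractions: tuple[tuple[SpectralState, float], ...]

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.fractions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"state fractions of {self.name} sum to {total}, not 1")
        for state, f in self.fractions:
            if not (0.0 <= f <= 1.0):
                raise ValueError(
                    f"fraction {f} of {state.name} outside [0, 1]")

    @classmethod
    def from_mapping(cls, name: str,
                     fractions: Mapping[SpectralState, float]) -> "KineticIntermediate":
        return cls(name, tuple(fractions.items()))

    def spectrum(self, wavelengths: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(wavelengths, dtype=float))
        for state, f in self.fractions:
            out += f * state.spectrum(wavelengths)
        return out


@dataclass(frozen=True)
class PhotocycleScheme:
    """Unidirectional sequential photocycle P1 -> P2 -> ... -> Pn -> ground.

    ``taus[i]`` is the lifetime (s) of the transition out of
    ``intermediates[i]``; list order is temporal order.
    """

    intermediates: tuple[KineticIntermediate, ...]
    taus: tuple[float, ...]
    ground_state: SpectralState

    def __post_init__(self) -> None:
        if len(self.intermediates) != len(self.taus):
            raise ValueError("one lifetime per intermediate transition")
        if any(t <= 0 for t in self.taus):
            raise ValueError("lifetimes must be strictly positive")

    @property
    def n(self) -> int:
        return len(self.intermediates)

    def difference_spectra(self, wavelengths: np.ndarray) -> np.ndarray:
        """|lambda| x n matrix of (intermediate - ground) spectra."""
        g = self.ground_state.spectrum(wavelengths)
        cols = [im.spectrum(wavelengths) - g for im in self.intermediates]
        return np.column_stack(cols)


@dataclass(frozen=True)
class NoiseSpec:
    """i.i.d. Gaussian measurement noise, reduced by pulse averaging.

    The effective per-point standard deviation is ``sigma / sqrt(n_averages)``.
    """

    sigma: float
    seed: int
    n_averages: int = 1

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")


def _check_increasing(x: np.ndarray, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError(f"{what} grid is empty")
    if x.ndim != 1 or (x.size > 1 and np.any(np.diff(x) <= 0)):
        raise ValueError(f"{what} grid must be strictly increasing")
    return x


@dataclass
class TransientAbsorptionDataset:
    """Flash-induced absorbance-change matrix dA(wavelength, time)."""

    wavelengths: np.ndarray
    times: np.ndarray
    delta_a: np.ndarray
    n_averages: int = 1

    def __post_init__(self) -> None:
        self.wavelengths = _check_increasing(self.wavelengths, "wavelength")
        self.times = _check_increasing(self.times, "time")
        self.delta_a = np.asarray(self.delta_a, dtype=float)
        if self.delta_a.shape != (self.wavelengths.size, self.times.size):
            raise ValueError(
                f"delta_a shape {self.delta_a.shape} != "
                f"({self.wavelengths.size}, {self.times.size})")
        if not np.all(np.isfinite(self.delta_a)):
            raise ValueError("delta_a contains non-finite entries")

    def trace_at(self, wavelength: float) -> np.ndarray:
        """Time trace at the grid wavelength nearest to ``wavelength``."""
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return self.delta_a[i]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.delta_a, index=self.wavelengths,
                          columns=self.times)
        df.index.name = "wavelength_nm"
        df.to_csv(path, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path,
                 n_averages: int = 1) -> "TransientAbsorptionDataset":
        df = pd.read_csv(path, index_col=0)
        return cls(wavelengths=df.index.to_numpy(float),
                   times=np.array([float(c) for c in df.columns]),
                   delta_a=df.to_numpy(float),
                   n_averages=n_averages)


@dataclass
class TitrationSeries:
    """An observable (lambda_max in nm, or absorbance at a fixed band) vs pH."""

    ph: np.ndarray
    observable: np.ndarray
    observable_kind: str = "lambda_max"  # or "absorbance_at"

    def __post_init__(self) -> None:
        self.ph = _check_increasing(self.ph, "pH")
        self.observable = np.asarray(self.observable, dtype=float)
        if self.observable.shape != self.ph.shape:
            raise ValueError("ph and observable lengths differ")
        if self.observable_kind not in ("lambda_max", "absorbance_at"):
            raise ValueError(f"unknown observable_kind {self.observable_kind}")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"ph": self.ph, self.observable_kind: self.observable}
                     ).to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TitrationSeries":
        df = pd.read_csv(path)
        kind = df.columns[1]
        return cls(df["ph"].to_numpy(float), df[kind].to_numpy(float), kind)


@dataclass
class PhotocurrentTrace:
    """A flash- or continuous-light photocurrent recording on a planar bilayer."""

    times: np.ndarray
    current: np.ndarray
    illumination: str = "flash"  # or "continuous"

    def __post_init__(self) -> None:
        self.times = _check_increasing(self.times, "time")
        if self.times[0] < 0:
            raise ValueError("times must start at >= 0")
        self.current = np.asarray(self.current, dtype=float)
        if self.current.shape != self.times.shape:
            raise ValueError("times and current lengths differ")
        if self.illumination not in ("flash", "continuous"):
            raise ValueError(f"unknown illumination {self.illumination}")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times, "current": self.current}
                     ).to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path,
                 illumination: str = "flash") -> "PhotocurrentTrace":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float),
                   illumination)
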