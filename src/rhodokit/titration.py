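"""Boltzmann-sigmoid pH titration analysis.

A retinal protein's absorption reports two protonation equilibria: at acidic
pH the counterion/proton acceptor protonates and the absorption maximum
red-shifts (here 514 -> 548 nm); at alkaline pH the retinal Schiff base (RSB)
deprotonates and the 514 nm band collapses into a ~367 nm band.  Both are fit
with the Boltzmann form

    y(pH) = y_high + (y_low - y_high) / (1 + exp((pH - pKa) / dx)),

whose midpoint is the pKa; the sign of dx is free so a single form covers
acid and alkaline transitions.  Standard errors come from the Gauss-Newton
covariance at the optimum ("point of half decay +/- standard error").
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from ._numutil import parabolic_peak
from .datasets import TitrationSeries

__all__ = [
    "SigmoidFit",
    "BoltzmannModel",
    "SpectraByPH",
    "fit_boltzmann",
    "extract_lambda_max",
    "titration_pka",
]


def boltzmann(ph, pka, dx, y_low, y_high):
    ph = np.asarray(ph, dtype=float)
    return y_high + (y_low - y_high) / (1.0 + np.exp((ph - pka) / dx))


@dataclass
class SigmoidFit:
    midpoint_pka: float
    dx: float
    y_low: float
    y_high: float
    se_pka: float
    residual_sse: float
    unidentifiable: bool = False


class BoltzmannModel(BaseEstimator):
    """Least-squares Boltzmann sigmoid with curvature-based standard errors.

    Initial guesses: plateau levels from the first/last-quartile means of the
    observable, midpoint from the half-crossing of the data.  Flat data (no
    resolvable transition) is flagged ``unidentifiable_`` rather than fit.
    """

    def __init__(self, flat_snr_threshold: float = 3.0):
        self.flat_snr_threshold = flat_snr_threshold

    def fit(self, X, y=None) -> "BoltzmannModel":
        if isinstance(X, TitrationSeries):
            ph, obs = X.ph, X.observable
        else:
            ph = np.asarray(X, dtype=float).ravel()
            obs = np.asarray(y, dtype=float)
        if ph.size < 5:
            raise ValueError("need >= 5 pH points spanning the transition")

        q = max(1, ph.size // 4)
        y_lo0 = float(np.mean(obs[:q]))
        y_hi0 = float(np.mean(obs[-q:]))
        half = 0.5 * (y_lo0 + y_hi0)
        cross = np.nonzero(np.diff(np.sign(obs - half)))[0]
        pka0 = float(ph[cross[0]]) if cross.size else float(np.median(ph))
        # with dx > 0 the curve runs from y_low (acid side) to y_high;
        # rising vs falling is absorbed by the free plateau levels
        dx0 = max((ph[-1] - ph[0]) / 10.0, 1e-3)

        def resid(theta):
            return boltzmann(ph, *theta) - obs

        sol = least_squares(resid, [pka0, dx0, y_lo0, y_hi0], method="lm")
        pka, dx, y_low, y_high = sol.x
        sse = float(2.0 * sol.cost)
        dof = ph.size - 4

        rng_span = abs(y_high - y_low)
        noise = np.sqrt(sse / dof) if dof > 0 else 0.0
        unident = bool(
            rng_span < self.flat_snr_threshold * noise
            or not (ph[0] - 1.0 <= pka <= ph[-1] + 1.0))

        se = np.nan
        if dof > 0:
            jtj = sol.jac.T @ sol.jac
            try:
                # near-singular curvature can yield a tiny negative variance
                var = max(float(np.linalg.inv(jtj)[0, 0]) * sse / dof, 0.0)
                se = float(np.sqrt(var))
            except np.linalg.LinAlgError:
                unident = True

        self.pka_ = float(pka)
        self.dx_ = float(dx)
        self.y_low_ = float(y_low)
        self.y_high_ = float(y_high)
        self.se_pka_ = se
        self.residual_sse_ = sse
        self.unidentifiable_ = unident
        return self

    def predict(self, ph) -> np.ndarray:
        return boltzmann(ph, self.pka_, self.dx_, self.y_low_, self.y_high_)

    def result_(self) -> SigmoidFit:
        return SigmoidFit(self.pka_, self.dx_, self.y_low_, self.y_high_,
                          self.se_pka_, self.residual_sse_,
                          self.unidentifiable_)


def fit_boltzmann(series: TitrationSeries) -> SigmoidFit:
    """Functional wrapper around :class:`BoltzmannModel`."""
    return BoltzmannModel().fit(series).result_()


def extract_lambda_max(wavelengths: np.ndarray,
                       spectrum: np.ndarray) -> tuple[float, bool]:
    """Absorption maximum in nm via 3-point parabolic interpolation.

    Returns ``(lambda_max, at_boundary)``; a maximum sitting on the grid edge
    is returned as-is with the boundary flag raised.
    """
    lam, _, boundary = parabolic_peak(wavelengths, spectrum)
    return lam, boundary


@dataclass
class SpectraByPH:
    """Per-pH absorption spectra on a common wavelength grid."""

    wavelengths: np.ndarray
    ph: np.ndarray
    spectra: np.ndarray  # (|pH|, |lambda|)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.ph = np.asarray(self.ph, dtype=float)
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.shape != (self.ph.size, self.wavelengths.size):
            raise ValueError("spectra must be (|pH|, |wavelengths|)")

    def absorbance_at(self, wavelength: float) -> np.ndarray:
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not (lo <= wavelength <= hi):
            raise ValueError(
                f"{wavelength} nm outside spectral coverage [{lo}, {hi}] nm")
        return np.array([np.interp(wavelength, self.wavelengths, s)
                         for s in self.spectra])

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.spectra.T, index=self.wavelengths,
                          columns=self.ph)
        df.index.name = "wavelength_nm"
        df.to_csv(path, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraByPH":
        df = pd.read_csv(path, index_col=0)
        return cls(df.index.to_numpy(float),
                   np.array([float(c) for c in df.columns]),
                   df.to_numpy(float).T)


def titration_pka(spectra: SpectraByPH, mode: str,
                  rsb_wavelength: float = 514.0) -> SigmoidFit:
    """pKa from a pH series of spectra.

    ``mode="acceptor"`` fits lambda_max(pH) (acid-side counterion
    protonation); ``mode="rsb"`` fits the absorbance at 514 nm vs pH
    (alkaline Schiff-base deprotonation).
    """
    if spectra.ph.size < 5:
        raise ValueError("need >= 5 pH points")
    if mode == "acceptor":
        obs = np.array([extract_lambda_max(spectra.wavelengths, s)[0]
                        for s in spectra.spectra])
        kind = "lambda_max"
    elif mode == "rsb":
        obs = spectra.absorbance_at(rsb_wavelength)
        kind = "absorbance_at"
    else:
        raise ValueError(f"mode must be 'acceptor' or 'rsb', got {mode!r}")
    series = TitrationSeries(spectra.ph, obs, kind)
    return fit_boltzmann(series)
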