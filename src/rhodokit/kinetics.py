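"""Global photocycle kinetics: multiexponential fitting and intermediate spectra.

A flash-photolysis dataset dA(lambda, t) from a rhodopsin photocycle is, under
a unidirectional sequential scheme P1 -> P2 -> ... -> Pn -> ground, an exact
sum of n exponential decays whose wavelength-dependent amplitudes are linear
combinations of the intermediate difference spectra.  This module fits the n
lifetimes globally across all wavelengths (variable projection), selects the
model order by a sequential F-test, and inverts the fitted surface for the
absolute intermediate spectra using the closed-form concentrations of the
irreversible first-order chain (Bateman equations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from ._numutil import parabolic_peak
from ._varpro import project_amplitudes, varpro_fit
from .datasets import SpectralState, TransientAbsorptionDataset

__all__ = [
    "GlobalExponentialModel",
    "GlobalFitResult",
    "IntermediateSpectra",
    "bateman_concentrations",
    "fit_global_exponentials",
    "choose_num_exponentials",
    "sequential_intermediate_spectra",
    "decompose_spectrum",
]

#: relative perturbation applied to duplicate lifetimes instead of the
#: confluent limit of the chain solution
_TIE_PERTURBATION = 1e-6

#: refuse spectral inversion when the concentration matrix is worse than this
_MAX_CONDITION = 1e8


def _untie(taus: np.ndarray) -> np.ndarray:
    """Perturb duplicate lifetimes by 1 ppm so the chain solution is regular."""
    taus = np.array(taus, dtype=float)
    if np.any(taus <= 0):
        raise ValueError("lifetimes must be positive")
    for i in range(1, taus.size):
        while np.any(np.isclose(taus[:i], taus[i], rtol=10 * _TIE_PERTURBATION,
                                atol=0.0)):
            taus[i] *= 1.0 + _TIE_PERTURBATION
    return taus


def bateman_concentrations(taus, times) -> np.ndarray:
    """Occupancies of a unidirectional first-order chain, c_1(0) = 1.

    Returns the (n, |t|) matrix of the closed-form solution

        c_i(t) = (prod_{j<i} k_j) * sum_{j<=i} exp(-k_j t) /
                 prod_{l<=i, l!=j} (k_l - k_j),   k_i = 1/tau_i.

    Duplicate lifetimes are perturbed by 1 ppm (never an error).  Columns
    satisfy sum_i c_i(t) <= 1; the deficit is the recovered ground state.
    """
    taus = _untie(np.atleast_1d(taus))
    times = np.asarray(times, dtype=float)
    k = 1.0 / taus
    n = k.size
    out = np.zeros((n, times.size))
    decays = np.exp(-np.outer(k, times))  # row j = exp(-k_j t)
    for i in range(n):
        prefactor = np.prod(k[:i])
        acc = np.zeros(times.size)
        for j in range(i + 1):
            denom = np.prod(np.delete(k[: i + 1], j) - k[j])
            acc += decays[j] / (denom if i > 0 else 1.0)
        out[i] = prefactor * acc
    return out


@dataclass
class GlobalFitResult:
    """Lifetimes and per-wavelength amplitude spectra of a global fit."""

    taus: np.ndarray              # s, ascending
    amplitude_spectra: np.ndarray  # (|lambda|, n)
    residual_sse: float
    dof: int
    covariance_diag: np.ndarray   # per-tau variance
    degenerate: bool = False

    @property
    def tau_se(self) -> np.ndarray:
        return np.sqrt(self.covariance_diag)

    def amplitude_norms(self) -> np.ndarray:
        """L2 norm per component; near-zero norm marks a spectrally silent
        transition (occupancy exchange between look-alike states)."""
        return np.linalg.norm(self.amplitude_spectra, axis=0)


class GlobalExponentialModel(BaseEstimator):
    """Global multiexponential model for dA(lambda, t) matrices.

    Parameters
    ----------
    n_exp : int or "auto"
        Number of exponential components.  ``"auto"`` selects the order by a
        sequential F-test up to ``n_max``.
    tau_init : sequence of float, optional
        Starting lifetimes (s); always included among the multistarts, so the
        fitted SSE never exceeds the SSE at ``tau_init``.
    n_starts : int
        Multistart count over jittered log-spaced lifetime grids.
    n_max : int
        Upper bound for automatic order selection.
    alpha : float
        Significance level of the sequential F-test.
    """

    def __init__(self, n_exp: int | str = "auto", tau_init=None,
                 n_starts: int = 8, n_max: int = 9, alpha: float = 0.01):
        self.n_exp = n_exp
        self.tau_init = tau_init
        self.n_starts = n_starts
        self.n_max = n_max
        self.alpha = alpha

    def fit(self, X: TransientAbsorptionDataset, y=None) -> "GlobalExponentialModel":
        ds = X
        if self.n_exp == "auto":
            n = choose_num_exponentials(ds, self.n_max, self.alpha,
                                        n_starts=self.n_starts)
            if n == 0:
                raise ValueError("no exponential component is significant; "
                                 "the matrix is indistinguishable from noise")
        else:
            n = int(self.n_exp)
        res = varpro_fit(ds.times, ds.delta_a, n, tau_init=self.tau_init,
                         n_starts=self.n_starts)
        self.n_exp_ = n
        self.taus_ = res.taus
        self.amplitude_spectra_ = res.amplitudes
        self.residual_sse_ = res.sse
        self.dof_ = res.dof
        self.covariance_diag_ = res.tau_variance
        self.degenerate_ = res.degenerate
        return self

    def predict(self, X: TransientAbsorptionDataset) -> np.ndarray:
        """Fitted surface on the dataset's grids (amplitudes re-projected)."""
        _, model, _ = project_amplitudes(X.times, self.taus_, X.delta_a)
        return model

    def result_(self) -> GlobalFitResult:
        return GlobalFitResult(self.taus_, self.amplitude_spectra_,
                               self.residual_sse_, self.dof_,
                               self.covariance_diag_, self.degenerate_)


def fit_global_exponentials(ds: TransientAbsorptionDataset, n_exp: int,
                            tau_init=None, n_starts: int = 8) -> GlobalFitResult:
    """Functional wrapper around :class:`GlobalExponentialModel`."""
    return GlobalExponentialModel(n_exp=n_exp, tau_init=tau_init,
                                  n_starts=n_starts).fit(ds).result_()


def _sse_for_order(ds: TransientAbsorptionDataset, n: int,
                   n_starts: int) -> float:
    if n == 0:
        return float(np.sum(ds.delta_a ** 2))
    return varpro_fit(ds.times, ds.delta_a, n, n_starts=n_starts).sse


def choose_num_exponentials(ds: TransientAbsorptionDataset, n_max: int,
                            alpha: float = 0.01, n_starts: int = 8) -> int:
    """Smallest model order beyond which another component is insignificant.

    Sequential F-test: adding component n+1 costs |lambda| + 1 parameters
    (one lifetime plus one amplitude per wavelength); the reduction in SSE is
    compared against the residual variance of the larger model.  Returns 0
    when even a single component fails the test (pure noise).
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    m = ds.wavelengths.size
    n_obs = ds.delta_a.size
    p_step = m + 1
    sse_prev = _sse_for_order(ds, 0, n_starts)
    for n_next in range(1, n_max + 1):
        sse_next = _sse_for_order(ds, n_next, n_starts)
        dof_next = n_obs - n_next * p_step
        if dof_next <= 0 or sse_next <= 0:
            return n_next - 1
        f = ((sse_prev - sse_next) / p_step) / (sse_next / dof_next)
        p_value = stats.f.sf(f, p_step, dof_next)
        if not (p_value < alpha):
            return n_next - 1
        sse_prev = sse_next
    return n_max


@dataclass
class IntermediateSpectra:
    """Absolute spectra of the sequential intermediates on the data grid."""

    wavelengths: np.ndarray
    spectra: np.ndarray        # (n, |lambda|)
    labels: list[str]
    lambda_max: np.ndarray     # nm, parabolic-interpolated
    condition_number: float
    reconstruction_sse: float


def sequential_intermediate_spectra(
        fit: GlobalFitResult, ds: TransientAbsorptionDataset,
        ground_spectrum: np.ndarray) -> IntermediateSpectra:
    """Invert the fitted surface for absolute intermediate spectra.

    With chain occupancies C from the fitted lifetimes, solves
    dA = D C for the difference spectra D in the least-squares sense and
    returns eps_i = eps_ground + D_i.  Refuses ill-conditioned C.
    """
    ground_spectrum = np.asarray(ground_spectrum, dtype=float)
    if ground_spectrum.shape != ds.wavelengths.shape:
        raise ValueError("ground spectrum must be on the dataset grid")
    C = bateman_concentrations(fit.taus, ds.times)
    cond = float(np.linalg.cond(C @ C.T))
    if cond > _MAX_CONDITION:
        raise np.linalg.LinAlgError(
            f"concentration matrix condition number {cond:.3g} exceeds "
            f"{_MAX_CONDITION:.0e}; lifetimes too close for spectral inversion")
    D, _, _, _ = np.linalg.lstsq(C.T, ds.delta_a.T, rcond=None)
    recon = D.T @ C
    sse = float(np.sum((ds.delta_a - recon) ** 2))
    spectra = D + ground_spectrum[np.newaxis, :]
    lmax = np.array([parabolic_peak(ds.wavelengths, s)[0] for s in spectra])
    labels = [f"P{i + 1}" for i in range(spectra.shape[0])]
    return IntermediateSpectra(ds.wavelengths, spectra, labels, lmax,
                               cond, sse)


def decompose_spectrum(spectrum: np.ndarray, basis: list[SpectralState],
                       wavelengths: np.ndarray) -> tuple[np.ndarray, float]:
    """Nonnegative fractions of basis states composing a spectrum.

    Returns the NNLS coefficients renormalized to sum 1 and the NNLS
    residual norm (on the unnormalized scale).
    """
    if not basis:
        raise ValueError("basis must be nonempty")
    spectrum = np.asarray(spectrum, dtype=float)
    if not np.any(spectrum):
        raise ValueError("cannot decompose an all-zero spectrum")
    B = np.column_stack([s.spectrum(wavelengths) for s in basis])
    coef, resid = nnls(B, spectrum)
    total = coef.sum()
    if total == 0:
        raise ValueError("spectrum has no nonnegative projection on the basis")
    return coef / total, float(resid)
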