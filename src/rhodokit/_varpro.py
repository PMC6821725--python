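"""Separable nonlinear least squares for sums of exponential decays.

Fits Y(c, t) ~ sum_i A_i(c) * exp(-t / tau_i) over many channels c at once.
The amplitudes enter linearly and are eliminated analytically (variable
projection), so the nonlinear search runs over the n lifetimes only, in
log space to keep them positive.  Multistart from jittered log-spaced
lifetime grids guards against local minima; the best SSE wins, ties broken
by the lexicographically smaller lifetime vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["exp_basis", "project_amplitudes", "varpro_fit", "VarproResult"]

# internal jitter seed for multistart grids; fixed so fits are deterministic
_MULTISTART_SEED = 1906


def exp_basis(times: np.ndarray, taus: np.ndarray) -> np.ndarray:
    """|t| x n design matrix E[t, i] = exp(-t / tau_i)."""
    times = np.asarray(times, dtype=float)
    taus = np.asarray(taus, dtype=float)
    return np.exp(-np.outer(times, 1.0 / taus))


def project_amplitudes(times: np.ndarray, taus: np.ndarray,
                       y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Exact linear LSQ amplitudes given lifetimes.

    Parameters
    ----------
    y : (m, |t|) array
        One row per channel (wavelength).

    Returns
    -------
    amplitudes : (m, n) array
    model : (m, |t|) fitted surface
    sse : float
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    E = exp_basis(times, taus)
    coef, _, _, _ = np.linalg.lstsq(E, y.T, rcond=None)
    model = (E @ coef).T
    resid = y - model
    return coef.T, model, float(np.sum(resid * resid))


@dataclass
class VarproResult:
    taus: np.ndarray          # ascending, s
    amplitudes: np.ndarray    # (m, n), columns matched to taus
    sse: float
    dof: int
    tau_variance: np.ndarray  # per-tau variance (delta method from log-tau)
    degenerate: bool = False


def _start_grids(times: np.ndarray, n_exp: int, n_starts: int) -> list[np.ndarray]:
    t_pos = times[times > 0]
    lo = np.log10(t_pos.min()) if t_pos.size else -6.0
    hi = np.log10(times.max())
    base = np.linspace(lo, hi, n_exp + 2)[1:-1]
    grids = [10.0 ** base]
    rng = np.random.default_rng(_MULTISTART_SEED)
    for _ in range(n_starts - 1):
        jit = rng.uniform(-0.4, 0.4, size=n_exp)
        grids.append(10.0 ** np.sort(base + jit))
    return grids


def varpro_fit(times: np.ndarray, y: np.ndarray, n_exp: int,
               tau_init: np.ndarray | None = None,
               n_starts: int = 8,
               max_nfev: int | None = None) -> VarproResult:
    """Global multiexponential fit of a (channels x times) matrix.

    ``tau_init``, when given, is added to the start list, so the returned
    SSE can never exceed the SSE of the supplied initial lifetimes.
    """
    times = np.asarray(times, dtype=float)
    y = np.atleast_2d(np.asarray(y, dtype=float))
    m, nt = y.shape
    if nt != times.size:
        raise ValueError("y columns must match the time grid")
    if n_exp < 1:
        raise ValueError("n_exp must be >= 1")
    if nt <= 2 * n_exp:
        raise ValueError(
            f"{nt} time points cannot identify {n_exp} exponentials "
            f"(need > {2 * n_exp})")

    n_params = n_exp * (m + 1)
    dof = m * nt - n_params

    if not np.any(y):
        # all-zero data: any lifetimes fit exactly; flag instead of guessing
        taus = np.sort(_start_grids(times, n_exp, 1)[0])
        return VarproResult(taus, np.zeros((m, n_exp)), 0.0, dof,
                            np.full(n_exp, np.nan), degenerate=True)

    starts = _start_grids(times, n_exp, n_starts)
    if tau_init is not None:
        tau_init = np.asarray(tau_init, dtype=float)
        if tau_init.size != n_exp or np.any(tau_init <= 0):
            raise ValueError("tau_init must hold n_exp positive lifetimes")
        starts.insert(0, tau_init)

    def residuals(log_tau: np.ndarray) -> np.ndarray:
        _, model, _ = project_amplitudes(times, np.exp(log_tau), y)
        return (y - model).ravel()

    best = None
    for tau0 in starts:
        sol = least_squares(residuals, np.log(tau0), method="lm"
                            if m * nt >= n_exp else "trf",
                            max_nfev=max_nfev)
        sse = float(2.0 * sol.cost)
        key = (sse, tuple(np.sort(np.exp(sol.x))))
        if best is None or key < (best[0], tuple(np.sort(np.exp(best[1].x)))):
            best = (sse, sol)

    sse, sol = best
    taus = np.exp(sol.x)
    order = np.argsort(taus)
    taus = taus[order]
    amplitudes, _, sse = project_amplitudes(times, taus, y)

    # covariance of log-tau from the projected-residual jacobian at optimum
    tau_var = np.full(n_exp, np.nan)
    if dof > 0:
        jac = sol.jac[:, order]
        jtj = jac.T @ jac
        try:
            cov_log = np.linalg.inv(jtj) * (sse / dof)
            tau_var = np.clip(np.diag(cov_log), 0, None) * taus ** 2
        except np.linalg.LinAlgError:
            pass

    return VarproResult(taus, amplitudes, sse, dof, tau_var)
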