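"""Flash photocurrent decomposition for planar-bilayer (BLM) recordings.

A rhodopsin proteoliposome adsorbed to a black lipid membrane couples
capacitively: each electrogenic step of the photocycle appears as an
exponential current component a_i * exp(-t / tau_i), and the displaced charge
of a component is its analytic time integral q_i = a_i * tau_i.  Components
are fit with the same variable-projection engine as the photocycle kinetics
and assigned to photocycle transitions by nearest lifetime on a log scale.
The slowest component (here ~950 ms) reflects the unspecific discharge of
the membrane itself and is excluded from transition assignment by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from ._varpro import varpro_fit
from .datasets import PhotocurrentTrace

__all__ = [
    "CurrentFit",
    "PhotocurrentModel",
    "fit_current",
    "component_charges",
    "assign_to_photocycle",
]


@dataclass
class CurrentFit:
    """Signed exponential components of a flash photocurrent, tau ascending."""

    amplitudes: np.ndarray
    taus: np.ndarray
    se_taus: np.ndarray
    residual_sse: float
    dof: int


class PhotocurrentModel(BaseEstimator):
    """Sum-of-exponentials model for a flash-induced BLM current.

    Shares the variable-projection code path with the photocycle global fit;
    a single-channel special case of the same separable least squares.
    """

    def __init__(self, n_components: int = 4, tau_init=None,
                 n_starts: int = 8):
        self.n_components = n_components
        self.tau_init = tau_init
        self.n_starts = n_starts

    def fit(self, X: PhotocurrentTrace, y=None) -> "PhotocurrentModel":
        if X.illumination != "flash":
            raise ValueError(
                "exponential decomposition applies to flash traces; "
                f"got a {X.illumination!r}-light recording")
        res = varpro_fit(X.times, X.current[np.newaxis, :],
                         self.n_components, tau_init=self.tau_init,
                         n_starts=self.n_starts)
        self.taus_ = res.taus
        self.amplitudes_ = res.amplitudes[0]
        self.se_taus_ = np.sqrt(res.tau_variance)
        self.residual_sse_ = res.sse
        self.dof_ = res.dof
        return self

    def predict(self, times) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        return np.exp(-np.outer(times, 1.0 / self.taus_)) @ self.amplitudes_

    def result_(self) -> CurrentFit:
        return CurrentFit(self.amplitudes_, self.taus_, self.se_taus_,
                          self.residual_sse_, self.dof_)


def fit_current(trace: PhotocurrentTrace, n_components: int,
                tau_init=None) -> CurrentFit:
    """Functional wrapper around :class:`PhotocurrentModel`."""
    return PhotocurrentModel(n_components, tau_init=tau_init
                             ).fit(trace).result_()


def component_charges(fit: CurrentFit) -> tuple[np.ndarray, float]:
    """Displaced charge per component and net charge.

    q_i = a_i * tau_i is the exact integral of a_i exp(-t/tau_i) over
    [0, inf); the net charge of a purely capacitive signal is zero.
    """
    q = np.asarray(fit.amplitudes, dtype=float) * np.asarray(fit.taus,
                                                             dtype=float)
    return q, float(q.sum())


def assign_to_photocycle(current_taus, photocycle_taus, labels=None,
                         exclude_discharge: bool = True
                         ) -> list[dict]:
    """Map each electrogenic component to the nearest photocycle step.

    Nearest is measured as |log10(tau' / tau)|, so the mapping is invariant
    under a common rescaling of both lifetime lists.  With
    ``exclude_discharge`` the slowest current component is reported with a
    null assignment (membrane discharge, not a photocycle transition).
    """
    current_taus = np.atleast_1d(np.asarray(current_taus, dtype=float))
    photocycle_taus = np.atleast_1d(np.asarray(photocycle_taus, dtype=float))
    if current_taus.size == 0 or photocycle_taus.size == 0:
        raise ValueError("both lifetime lists must be nonempty")
    if labels is None:
        labels = [f"tau{i + 1}" for i in range(photocycle_taus.size)]
    if len(labels) != photocycle_taus.size:
        raise ValueError("one label per photocycle lifetime")

    i_discharge = int(np.argmax(current_taus)) if exclude_discharge else -1
    out = []
    for i, tp in enumerate(current_taus):
        if i == i_discharge:
            out.append({"current_tau": float(tp), "photocycle_tau": None,
                        "label": "membrane discharge", "log_distance": None})
            continue
        d = np.abs(np.log10(tp / photocycle_taus))
        j = int(np.argmin(d))
        out.append({"current_tau": float(tp),
                    "photocycle_tau": float(photocycle_taus[j]),
                    "label": labels[j], "log_distance": float(d[j])})
    return out
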