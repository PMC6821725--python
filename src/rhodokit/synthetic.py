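"""Synthetic measurements with the statistical structure of the real assays.

Every pipeline input can be generated here: flash-photolysis dA(lambda, t)
matrices from a sequential photocycle (Bateman occupancies x Gaussian state
bands), pH titration series and spectra, multi-component capacitive
photocurrents, ideal C5 pentamer structures with an axial water pentagon,
and cylinder-confined particle ensembles with a prescribed axial density.
All randomness is seeded and bit-reproducible.

The default parameter sets are the measured ones for the viral rhodopsin
OLPVRII: seven lifetimes (1, 16, 61, 340 us, 10, 25, 73 ms), spectral states
K540 / M410 / N525 / O550 over a 514 nm ground state, pKa midpoints 10.36
(Schiff base, alkaline) and 3.34 (proton acceptor, acidic), and BLM current
constants 24 us / 6 ms / 90 ms / 950 ms.
"""

from __future__ import annotations

import numpy as np

import biotite.structure as struc

from .datasets import (KineticIntermediate, NoiseSpec, PhotocycleScheme,
                       PhotocurrentTrace, SpectralState,
                       TitrationSeries, TransientAbsorptionDataset)
from .energetics import ParticleSamples
from .kinetics import bateman_concentrations
from .structure import StructureModel
from .titration import SpectraByPH, boltzmann

__all__ = [
    "GROUND_514", "K540", "M410", "N525", "O550",
    "FIG5C_TAUS", "BLM_TAUS",
    "default_wavelength_grid", "default_time_grid", "default_blm_time_grid",
    "olpvr2_scheme", "olpvr2_blm_components", "zero_net_charge_amplitudes",
    "gen_photocycle_dataset", "photocycle_peak_signal",
    "gen_titration_series", "gen_titration_spectra",
    "gen_photocurrent",
    "gen_ideal_pentamer",
    "gen_pore_particles",
]

# spectrally distinct states of the OLPVRII photocycle (lambda_max in nm;
# Gaussian bands, FWHM 90 nm typical of retinal proteins)
GROUND_514 = SpectralState("ground", 514.0)
K540 = SpectralState("K540", 540.0)
M410 = SpectralState("M410", 410.0)
N525 = SpectralState("N525", 525.0)
O550 = SpectralState("O550", 550.0)

#: the seven photocycle lifetimes (s)
FIG5C_TAUS = (1e-6, 16e-6, 61e-6, 340e-6, 10e-3, 25e-3, 73e-3)
#: the four electrogenic time constants of the BLM photocurrent (s)
BLM_TAUS = (24e-6, 6e-3, 90e-3, 950e-3)


def default_wavelength_grid() -> np.ndarray:
    """330-730 nm in 10 nm steps (the probed window)."""
    return np.arange(330.0, 731.0, 10.0)


def default_time_grid(t_start: float = 7e-7, t_end: float = 1.0,
                      per_decade: int = 10) -> np.ndarray:
    """Logarithmic time grid from 700 ns after the flash to 1 s."""
    n = int(round(per_decade * np.log10(t_end / t_start))) + 1
    return np.logspace(np.log10(t_start), np.log10(t_end), n)


def default_blm_time_grid(t_start: float = 1e-5, t_end: float = 20.0,
                          per_decade: int = 100) -> np.ndarray:
    """Merged-oscilloscope-window emulation for photocurrent traces.

    Raw electrical recordings carry 1e4-1e5 samples; the standard reduction
    is logarithmic decimation of the merged windows, here 100 points per
    decade over 1e-5 - 20 s.
    """
    return default_time_grid(t_start, t_end, per_decade)


def olpvr2_scheme() -> PhotocycleScheme:
    """Sequential 7-intermediate scheme with the measured lifetimes.

    The composition of P1 (pure K540) and the K/M character of P2-P4 and the
    M/N/O character of P5-P7 follow the reported state assignments; the
    numeric mixing fractions are package assumptions (not measured values),
    chosen as monotone ramps through each phase.
    """
    mk = KineticIntermediate.from_mapping
    intermediates = (
        mk("P1", {K540: 1.0}),
        mk("P2", {K540: 0.7, M410: 0.3}),
        mk("P3", {K540: 0.5, M410: 0.5}),
        mk("P4", {K540: 0.3, M410: 0.7}),
        mk("P5", {M410: 0.6, N525: 0.2, O550: 0.2}),
        mk("P6", {M410: 0.4, N525: 0.3, O550: 0.3}),
        mk("P7", {M410: 0.2, N525: 0.4, O550: 0.4}),
    )
    return PhotocycleScheme(intermediates, FIG5C_TAUS, GROUND_514)


def gen_photocycle_dataset(scheme: PhotocycleScheme,
                           wavelength_grid=None, time_grid=None,
                           noise: NoiseSpec | None = None
                           ) -> TransientAbsorptionDataset:
    """Flash-photolysis matrix dA(lambda, t) from a sequential scheme.

    dA(lambda, t) = sum_i [eps_i(lambda) - eps_ground(lambda)] c_i(t) plus
    i.i.d. Gaussian noise of sd sigma/sqrt(n_averages).
    """
    wl = default_wavelength_grid() if wavelength_grid is None \
        else np.asarray(wavelength_grid, dtype=float)
    t = default_time_grid() if time_grid is None \
        else np.asarray(time_grid, dtype=float)
    noise = noise if noise is not None else NoiseSpec(0.0, 0)

    D = scheme.difference_spectra(wl)            # (|wl|, n)
    C = bateman_concentrations(scheme.taus, t)   # (n, |t|)
    y = D @ C
    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        y = y + rng.normal(0.0, noise.sigma / np.sqrt(noise.n_averages),
                           size=y.shape)
    return TransientAbsorptionDataset(wl, t, y, noise.n_averages)


def photocycle_peak_signal(scheme: PhotocycleScheme,
                           wavelength_grid=None, time_grid=None) -> float:
    """max |dA| of the noiseless surface; used to set sigma for a target SNR."""
    ds = gen_photocycle_dataset(scheme, wavelength_grid, time_grid)
    return float(np.max(np.abs(ds.delta_a)))


def gen_titration_series(pka: float, slope_dx: float, y_low: float,
                         y_high: float, ph_grid, noise_sigma: float = 0.0,
                         seed: int = 0,
                         observable_kind: str = "lambda_max"
                         ) -> TitrationSeries:
    """Observable-vs-pH series on an exact Boltzmann curve (plus noise).

    ``y_low`` is the acid-side plateau (pH << pKa) when ``slope_dx > 0``.
    """
    if slope_dx == 0:
        raise ValueError("slope_dx must be nonzero")
    ph = np.asarray(ph_grid, dtype=float)
    if ph.size == 0:
        raise ValueError("ph_grid is empty")
    y = boltzmann(ph, pka, slope_dx, y_low, y_high)
    if noise_sigma > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sigma, ph.size)
    return TitrationSeries(ph, y, observable_kind)


def gen_titration_spectra(ph_grid, pka: float, dx: float,
                          state_neutral: SpectralState = GROUND_514,
                          state_shifted: SpectralState | None = None,
                          transition: str = "acid",
                          wavelengths=None, noise_sigma: float = 0.0,
                          seed: int = 0) -> SpectraByPH:
    """Per-pH spectra of a two-state protonation equilibrium.

    ``transition="acid"`` puts the shifted form (default the 548 nm
    acceptor-protonated species) at low pH; ``"alkaline"`` puts it (default
    the 367 nm deprotonated-RSB species) at high pH.  The shifted-state
    fraction follows the Boltzmann curve with midpoint ``pka``.
    """
    ph = np.asarray(ph_grid, dtype=float)
    wl = default_wavelength_grid() if wavelengths is None \
        else np.asarray(wavelengths, dtype=float)
    if state_shifted is None:
        state_shifted = SpectralState("acid548", 548.0) \
            if transition == "acid" else SpectralState("deprot367", 367.0)
    if transition == "acid":
        f_shift = 1.0 / (1.0 + np.exp((ph - pka) / abs(dx)))
    elif transition == "alkaline":
        f_shift = 1.0 / (1.0 + np.exp(-(ph - pka) / abs(dx)))
    else:
        raise ValueError("transition must be 'acid' or 'alkaline'")
    base = state_neutral.spectrum(wl)
    shifted = state_shifted.spectrum(wl)
    spectra = np.outer(1.0 - f_shift, base) + np.outer(f_shift, shifted)
    if noise_sigma > 0:
        spectra = spectra + np.random.default_rng(seed).normal(
            0.0, noise_sigma, spectra.shape)
    return SpectraByPH(wl, ph, spectra)


def olpvr2_blm_components() -> list[tuple[float, float]]:
    """Default (amplitude, tau) components of the flash photocurrent.

    Lifetimes are the measured constants; amplitudes are free parameters
    (the absolute current scale is not reported) chosen so the fast rise is
    positive and the slow return components are clearly visible, as in the
    recorded traces.
    """
    return [(1.0, BLM_TAUS[0]), (0.6, BLM_TAUS[1]),
            (-0.35, BLM_TAUS[2]), (-0.15, BLM_TAUS[3])]


def zero_net_charge_amplitudes(taus, leading_amplitudes) -> np.ndarray:
    """Complete an amplitude vector so that sum a_i tau_i = 0.

    The last component's amplitude is solved from the purely capacitive
    (zero net displaced charge) constraint.
    """
    taus = np.asarray(taus, dtype=float)
    lead = np.asarray(leading_amplitudes, dtype=float)
    if lead.size != taus.size - 1:
        raise ValueError("need one fewer leading amplitude than lifetimes")
    last = -float(lead @ taus[:-1]) / taus[-1]
    return np.concatenate([lead, [last]])


def gen_photocurrent(components, time_grid=None, noise_sigma: float = 0.0,
                     seed: int = 0) -> PhotocurrentTrace:
    """Sum-of-exponentials flash photocurrent I(t) = sum a_i exp(-t/tau_i)."""
    t = default_blm_time_grid() if time_grid is None \
        else np.asarray(time_grid, dtype=float)
    current = np.zeros_like(t)
    for a, tau in components:
        if tau <= 0:
            raise ValueError(f"lifetime {tau} must be positive")
        current += a * np.exp(-t / tau)
    if noise_sigma > 0:
        current = current + np.random.default_rng(seed).normal(
            0.0, noise_sigma, t.size)
    return PhotocurrentTrace(t, current, "flash")


def gen_ideal_pentamer(helix_ring_radius: float = 15.0,
                       pentagon_radius: float = 2.212,
                       atoms_per_chain: int = 120,
                       seed: int = 0) -> StructureModel:
    """Exactly C5-symmetric five-chain structure with an axial water pentagon.

    Chain A is a jittered helical backbone (N/CA/C/O per residue) winding
    about a local axis at ``helix_ring_radius`` from z; chains B-E are exact
    72-degree rotations of it.  One water oxygen per protomer sits on a
    regular pentagon of ``pentagon_radius`` in a single z-plane, so the
    adjacent O-O distance is 2 r sin(36 deg).
    """
    if helix_ring_radius <= 0 or pentagon_radius <= 0:
        raise ValueError("radii must be positive")
    rng = np.random.default_rng(seed)
    n_res = max(1, atoms_per_chain // 4)
    names = ["N", "CA", "C", "O"]
    elements = ["N", "C", "C", "O"]

    # local helix of chain A, axis parallel to z at (R, 0)
    local = []
    res_ids, atom_names, elems = [], [], []
    i = 0
    for r in range(n_res):
        for k in range(4):
            if i >= atoms_per_chain:
                break
            phi = 0.55 * i
            p = np.array([helix_ring_radius + 2.3 * np.cos(phi),
                          2.3 * np.sin(phi),
                          0.38 * i])
            local.append(p + rng.normal(0.0, 0.08, 3))
            res_ids.append(r + 1)
            atom_names.append(names[k])
            elems.append(elements[k])
            i += 1
    local = np.array(local)
    z_mid = float(local[:, 2].mean())

    chains = ["A", "B", "C", "D", "E"]
    all_coord, all_chain, all_res, all_name, all_elem = [], [], [], [], []
    all_resname, all_hetero = [], []
    for ci, ch in enumerate(chains):
        ang = np.deg2rad(72.0 * ci)
        rot = np.array([[np.cos(ang), -np.sin(ang), 0.0],
                        [np.sin(ang), np.cos(ang), 0.0],
                        [0.0, 0.0, 1.0]])
        all_coord.append(local @ rot.T)
        all_chain += [ch] * len(local)
        all_res += res_ids
        all_name += atom_names
        all_elem += elems
        all_resname += ["ALA"] * len(local)
        all_hetero += [False] * len(local)
        # the protomer's pentagon water, offset half a step between chains
        wang = ang + np.deg2rad(36.0)
        all_coord.append(np.array([[pentagon_radius * np.cos(wang),
                                    pentagon_radius * np.sin(wang),
                                    z_mid]]))
        all_chain.append(ch)
        all_res.append(n_res + 1)
        all_name.append("O")
        all_elem.append("O")
        all_resname.append("HOH")
        all_hetero.append(True)

    coord = np.vstack(all_coord)
    atoms = struc.AtomArray(coord.shape[0])
    atoms.coord = coord
    atoms.chain_id = np.array(all_chain)
    atoms.res_id = np.array(all_res)
    atoms.res_name = np.array(all_resname)
    atoms.atom_name = np.array(all_name)
    atoms.element = np.array(all_elem)
    atoms.hetero = np.array(all_hetero)
    atoms.set_annotation("occupancy", np.ones(coord.shape[0]))
    atoms.set_annotation("b_factor", np.zeros(coord.shape[0]))
    return StructureModel(atoms)


def gen_pore_particles(target_profile, cylinder_radius: float,
                       n_particles: int, n_frames: int,
                       seed: int = 0, species: str = "water"
                       ) -> ParticleSamples:
    """i.i.d. particle ensemble with a prescribed axial density.

    ``target_profile`` is ``(bin_edges, weights)``: per frame, each
    particle's z is drawn from the piecewise-constant density (uniform
    within a bin) and (x, y) uniformly over the cylinder cross-section.
    """
    edges, weights = target_profile
    edges = np.asarray(edges, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("density profile must be non-negative")
    if weights.sum() <= 0:
        raise ValueError("density profile is identically zero")
    if cylinder_radius <= 0:
        raise ValueError("cylinder_radius must be positive")
    # weights are per-bin probabilities scaled by bin width
    widths = np.diff(edges)
    p = weights * widths
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        if n_particles == 0:
            frames.append(np.empty((0, 3)))
            continue
        bins = rng.choice(weights.size, size=n_particles, p=p)
        z = rng.uniform(edges[bins], edges[bins + 1])
        r = cylinder_radius * np.sqrt(rng.uniform(0.0, 1.0, n_particles))
        phi = rng.uniform(0.0, 2.0 * np.pi, n_particles)
        frames.append(np.column_stack([r * np.cos(phi), r * np.sin(phi), z]))
    return ParticleSamples(frames, species)
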