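"""Axial densities and potentials of mean force for pore permeation.

Equilibrium particle densities n(z) inside a cylinder along the pore axis
are Boltzmann-inverted into a free-energy profile

    G(z) = -R T ln( n(z) / n_bulk ),

with R = 1.9872e-3 kcal/(mol K).  The bulk density is estimated from the
outermost slabs of the axial range; bins with zero counts are masked and
reported against the resolvable cap G_cap = R T ln(total count) instead of
infinity.  Uncertainties come from block bootstrap over frames, which
respects the serial correlation of simulation trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "R_KCAL",
    "ParticleSamples",
    "AxialDensity",
    "PMFProfile",
    "axial_density",
    "pmf_profile",
    "block_bootstrap_sd",
    "selectivity_summary",
    "samples_from_mdanalysis",
]

R_KCAL = 1.9872e-3   # kcal / (mol K)
R_KJ = 8.31446e-3    # kJ / (mol K)

#: default analysis cylinder radius (A): cross-section equal to the area of
#: the pentamer in the membrane plane
DEFAULT_CYLINDER_RADIUS = 36.23
DEFAULT_TEMPERATURE = 310.0
DEFAULT_BIN_WIDTH = 0.5
#: width (A) of the outermost slabs on each z-end used as the bulk reference
BULK_MARGIN = 5.0


@dataclass
class ParticleSamples:
    """Per-frame particle positions; (x, y, z) in A, or z-only."""

    frames: list[np.ndarray]
    species: str = "water"

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("need at least one frame")
        clean = []
        for f in self.frames:
            f = np.asarray(f, dtype=float)
            if f.ndim == 1:
                f = f[:, np.newaxis]
            if f.shape[1] not in (1, 3):
                raise ValueError("frames must be (n, 3) or (n, 1)/(n,) arrays")
            if not np.all(np.isfinite(f)):
                raise ValueError("non-finite particle positions")
            clean.append(f)
        dims = {f.shape[1] for f in clean}
        if len(dims) > 1:
            raise ValueError("all frames must share dimensionality")
        self.frames = clean

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def has_xy(self) -> bool:
        return self.frames[0].shape[1] == 3

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for i, f in enumerate(self.frames):
            for p in f:
                rows.append((i, self.species, *p))
        cols = ["frame", "species"] + (["x", "y", "z"] if self.has_xy
                                       else ["z"])
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False,
                                                float_format="%.6g")

    @classmethod
    def from_csv(cls, path: str | Path,
                 species: str | None = None) -> "ParticleSamples":
        df = pd.read_csv(path)
        if species is not None and "species" in df.columns:
            df = df[df["species"] == species]
        sp = species or (str(df["species"].iloc[0])
                         if "species" in df.columns else "water")
        pos_cols = [c for c in ("x", "y", "z") if c in df.columns]
        n_frames = int(df["frame"].max()) + 1 if len(df) else 0
        frames = []
        for i in range(n_frames):
            sub = df[df["frame"] == i]
            frames.append(sub[pos_cols].to_numpy(float))
        return cls(frames, sp)


@dataclass
class AxialDensity:
    """Time-averaged particle counts per axial bin inside the cylinder."""

    bin_edges: np.ndarray
    counts: np.ndarray            # mean count per frame, per bin
    n_bulk: float                 # per-bin-equivalent bulk count
    cylinder_radius: float
    per_frame_counts: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be ascending")

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _project(frame: np.ndarray, axis) -> tuple[np.ndarray, np.ndarray | None]:
    """(z, radial) coordinates of a frame; radial is None for z-only data."""
    if frame.shape[1] == 1:
        return frame[:, 0], None
    point, direction = (np.asarray(axis[0], dtype=float),
                        np.asarray(axis[1], dtype=float))
    direction = direction / np.linalg.norm(direction)
    rel = frame - point
    z = rel @ direction
    radial = np.linalg.norm(rel - np.outer(z, direction), axis=1)
    return z, radial


_Z_AXIS = (np.zeros(3), np.array([0.0, 0.0, 1.0]))


def axial_density(samples: ParticleSamples, axis=_Z_AXIS,
                  bin_width: float = DEFAULT_BIN_WIDTH,
                  cylinder_radius: float = DEFAULT_CYLINDER_RADIUS,
                  z_range: tuple[float, float] | None = None,
                  bulk_margin: float = BULK_MARGIN) -> AxialDensity:
    """Bin particles along the pore axis within the analysis cylinder.

    ``n_bulk`` is the average per-bin count over the outermost
    ``bulk_margin`` A on both ends of the z-range.  NaN when those slabs are
    empty (PMF conversion then refuses).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if cylinder_radius <= 0:
        raise ValueError("cylinder_radius must be positive")

    projected = []
    for f in samples.frames:
        if f.shape[0] == 0:
            projected.append(np.empty(0))
            continue
        z, radial = _project(f, axis)
        if radial is not None:
            z = z[radial <= cylinder_radius]
        projected.append(z)

    if z_range is None:
        allz = np.concatenate([p for p in projected if p.size])
        if allz.size == 0:
            raise ValueError("no particles inside the cylinder")
        z_range = (float(allz.min()), float(allz.max()))
    n_bins = max(1, int(np.ceil((z_range[1] - z_range[0]) / bin_width)))
    edges = z_range[0] + bin_width * np.arange(n_bins + 1)

    per_frame = np.stack([np.histogram(p, bins=edges)[0] for p in projected])
    counts = per_frame.mean(axis=0)

    centers = 0.5 * (edges[:-1] + edges[1:])
    bulk = (centers <= edges[0] + bulk_margin) | \
           (centers >= edges[-1] - bulk_margin)
    n_bulk = float(counts[bulk].mean()) if np.any(counts[bulk] > 0) else np.nan

    return AxialDensity(edges, counts, n_bulk, cylinder_radius, per_frame)


@dataclass
class PMFProfile:
    """Free-energy profile G(z) with per-bin uncertainties."""

    z: np.ndarray
    g: np.ndarray
    sd: np.ndarray
    temperature: float
    masked: np.ndarray        # True where counts were zero (G > g_cap)
    g_cap: float
    units: str = "kcal/mol"

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"z": self.z, "g": self.g, "sd": self.sd,
                      "masked": self.masked.astype(int)}
                     ).to_csv(path, sep="\t", index=False,
                              float_format="%.6g")


def _gas_constant(units: str) -> float:
    if units == "kcal/mol":
        return R_KCAL
    if units == "kJ/mol":
        return R_KJ
    raise ValueError(f"units must be 'kcal/mol' or 'kJ/mol', got {units!r}")


def pmf_profile(dens: AxialDensity,
                temperature: float = DEFAULT_TEMPERATURE,
                units: str = "kcal/mol") -> PMFProfile:
    """Boltzmann inversion G(z) = -RT ln(n(z)/n_bulk) of an axial density."""
    if not np.isfinite(dens.n_bulk) or dens.n_bulk <= 0:
        raise ValueError("bulk density undefined or non-positive; "
                         "cannot convert counts to a PMF")
    R = _gas_constant(units)
    rt = R * temperature
    masked = dens.counts == 0
    g = np.full_like(dens.counts, np.nan)
    g[~masked] = -rt * np.log(dens.counts[~masked] / dens.n_bulk)
    total = dens.counts.sum() * (dens.per_frame_counts.shape[0]
                                 if dens.per_frame_counts is not None else 1)
    g_cap = rt * np.log(total) if total > 1 else np.nan
    g[masked] = g_cap
    return PMFProfile(dens.z_centers, g, np.full_like(g, np.nan),
                      temperature, masked, float(g_cap), units)


def block_bootstrap_sd(per_frame_profiles, block_length: int,
                       n_resamples: int = 1000, seed: int = 0,
                       temperature: float = DEFAULT_TEMPERATURE,
                       units: str = "kcal/mol",
                       bulk_margin: float = BULK_MARGIN) -> np.ndarray:
    """Per-bin standard deviation of G(z) by block bootstrap over frames.

    Accepts either a single :class:`AxialDensity` carrying per-frame counts
    or a sequence of per-frame :class:`AxialDensity` profiles on a common
    grid.  Contiguous blocks of ``block_length`` frames are resampled with
    replacement; each resample is converted to a PMF and the spread per bin
    is returned.  Reproducible under a fixed seed.
    """
    if isinstance(per_frame_profiles, AxialDensity):
        dens = per_frame_profiles
        counts = dens.per_frame_counts
        if counts is None:
            raise ValueError("AxialDensity lacks per-frame counts")
        edges = dens.bin_edges
    else:
        profiles = list(per_frame_profiles)
        edges = profiles[0].bin_edges
        for p in profiles[1:]:
            if not np.array_equal(p.bin_edges, edges):
                raise ValueError("per-frame profiles must share bin edges")
        counts = np.stack([p.counts for p in profiles])

    n_frames = counts.shape[0]
    if block_length < 1:
        raise ValueError("block_length must be >= 1")
    if n_frames < 2 * block_length:
        raise ValueError(
            f"{n_frames} frames cannot support block length {block_length} "
            f"(need >= {2 * block_length})")

    centers = 0.5 * (edges[:-1] + edges[1:])
    bulk = (centers <= edges[0] + bulk_margin) | \
           (centers >= edges[-1] - bulk_margin)
    R = _gas_constant(units)
    rt = R * temperature

    n_blocks = int(np.ceil(n_frames / block_length))
    starts_max = n_frames - block_length
    rng = np.random.default_rng(seed)
    g_samples = np.full((n_resamples, counts.shape[1]), np.nan)
    for r in range(n_resamples):
        starts = rng.integers(0, starts_max + 1, size=n_blocks)
        idx = (starts[:, None] + np.arange(block_length)[None, :]).ravel()
        idx = idx[:n_frames]
        mean_counts = counts[idx].mean(axis=0)
        n_bulk = mean_counts[bulk].mean()
        if n_bulk <= 0:
            continue
        with np.errstate(divide="ignore"):
            g_samples[r] = -rt * np.log(mean_counts / n_bulk)
    finite = np.isfinite(g_samples)
    sd = np.full(counts.shape[1], np.nan)
    for j in range(counts.shape[1]):
        col = g_samples[finite[:, j], j]
        if col.size > 1:
            sd[j] = col.std(ddof=1)
    return sd


def selectivity_summary(pmf_cation: PMFProfile, pmf_anion: PMFProfile,
                        regions: dict[str, tuple[float, float]] | None = None
                        ) -> dict[str, dict]:
    """Per-region permeation barriers and which species passes more easily.

    Default regions split the axial range into three equal parts named
    cytoplasmic_vestibule / constriction / extracellular_bowl (axis oriented
    cytoplasmic -> extracellular).
    """
    if not np.array_equal(pmf_cation.z, pmf_anion.z):
        raise ValueError("PMF profiles are on different z grids")
    z = pmf_cation.z
    if regions is None:
        lo, hi = z.min(), z.max()
        third = (hi - lo) / 3.0
        regions = {"cytoplasmic_vestibule": (lo, lo + third),
                   "constriction": (lo + third, lo + 2 * third),
                   "extracellular_bowl": (lo + 2 * third, hi)}
    out = {}
    for name, (zlo, zhi) in regions.items():
        sel = (z >= zlo) & (z <= zhi)
        if not np.any(sel):
            raise ValueError(f"region {name} covers no bins")

        def barrier(p):
            vals = p.g[sel & ~p.masked]
            return float(vals.max()) if vals.size else np.inf

        bc, ba = barrier(pmf_cation), barrier(pmf_anion)
        if np.isclose(bc, ba, atol=1e-12):
            verdict = "none"
        else:
            verdict = "anion" if ba < bc else "cation"
        out[name] = {"cation_barrier": bc, "anion_barrier": ba,
                     "barrier_difference": bc - ba, "selective_for": verdict}
    return out


def samples_from_mdanalysis(universe, selection: str,
                            species: str = "water",
                            start: int | None = None,
                            stop: int | None = None) -> ParticleSamples:
    """Extract per-frame positions from an MDAnalysis Universe (optional).

    Core I/O is CSV; this adapter exists for users who already hold binary
    trajectories.  MDAnalysis is imported lazily and never required.
    """
    group = universe.select_atoms(selection)
    frames = [group.positions.astype(float).copy()
              for _ in universe.trajectory[start:stop]]
    return ParticleSamples(frames, species)
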