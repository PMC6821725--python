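# Methods

This note documents the models implemented in rhodokit, the defaults and
their provenance, what the synthetic generators do and do not emulate, and
the numerical choices made where the design was open.

## Sequential photocycle model

After a flash, a retinal protein relaxes through a chain of kinetic
intermediates.  We model the chain as unidirectional and first-order,

    P1 -> P2 -> ... -> Pn -> ground,      rate k_i = 1/tau_i,

with occupancies c_i(t) given by the closed-form solution of the chain
ODEs (Bateman equations), c_1(0) = 1.  Equilibrated back-reactions among
late intermediates are represented only through mixed state compositions
of the P_i, not through reversible rate constants: the published analysis
reports lifetimes and mixed spectra, not a rate matrix, and a sum of n
exponentials fits either way.

Each intermediate is a fixed mixture of spectrally distinct states
(K540, M410, N525, O550 over a 514 nm ground state), each state a Gaussian
band in wavelength.  Defaults:

| parameter | default | why |
|---|---|---|
| lifetimes | 1, 16, 61, 340 µs; 10, 25, 73 ms | measured values for OLPVRII |
| band FWHM | 90 nm | typical retinal band; only peak positions are asserted downstream |
| wavelength grid | 330–730 nm, 10 nm steps | probed window of the instrument |
| time grid | 7×10⁻⁷ – 1 s, 10 pts/decade | recording starts 700 ns after the flash |
| noise | i.i.d. Gaussian, σ/√n_averages | 25 flashes averaged per wavelength |

The mixing fractions of P2–P7 are package assumptions (monotone K→M ramp
through P2–P4; M/N/O mixtures through P5–P7): the published record states
which states contribute but not their numeric fractions.  Anything that
depends on exact fractions (e.g. spectral reconstruction tests) is tested
against the generator's own values, not against published numbers.

"SNR 100" in tests means the single-flash noise level; the 25-pulse
averaging above is always part of the stated measurement protocol, so the
effective per-point noise is σ_peak/100/√25.

## Global multiexponential fitting (variable projection)

ΔA(λ, t) = Σ A_i(λ) e^(−t/τ_i) is separable: conditional on the lifetimes,
the amplitude spectra are an exact linear least-squares solve per
wavelength.  The nonlinear search therefore runs over log τ only (n
parameters instead of n(|λ|+1)), by Levenberg–Marquardt on the projected
residual.  Multistart (default 8) from jittered log-spaced lifetime grids
guards against local minima; the best SSE wins, ties broken toward the
lexicographically smaller lifetime vector.  A user-supplied initial
lifetime vector is always added to the start list, so the returned SSE
never exceeds the SSE at the supplied start.

Lifetime standard errors use the Gauss–Newton covariance of log τ at the
optimum, mapped by the delta method.  Components with near-zero amplitude
norm are spectrally silent transitions (occupancy exchange between
look-alike states); they are reported, never dropped.

Model order: the smallest n such that component n+1 fails a sequential
F-test at α = 0.01, where a component costs |λ|+1 parameters.  Pure noise
returns 0.  The published conclusion for the reference dataset is seven
exponentials; at the defaults above the selector reproduces that.

Equal lifetimes are perturbed by 1 ppm instead of implementing the
confluent limit of the chain solution.  Consequence: mass-conservation
accuracy degrades from ~1e-15 to ~1e-5 for exactly tied lifetimes — an
accepted trade-off, since tied lifetimes are not identifiable by the fit
anyway.

## Intermediate spectra

With fitted lifetimes, ΔA = D·C is solved for the difference spectra D
(least squares against the chain occupancies C), and absolute spectra are
ε_i = ε_ground + D_i.  C·Cᵀ condition numbers above 1e8 are refused rather
than silently inverted.  Peak positions are read by a three-point parabolic
interpolation around the grid maximum (grid-edge maxima are returned
as-is with a boundary flag).  Nonnegative least squares decomposes a
spectrum into state fractions, renormalized to sum to one.

## Titration analysis

Both protonation transitions are fit with one Boltzmann form,
y = y_high + (y_low − y_high)/(1 + exp((pH − pKa)/dx)), dx sign free.
Initial guesses take plateau levels from the first/last quartile means and
the midpoint from the half-crossing.  The s.e. of the midpoint comes from
the local curvature (Gauss–Newton covariance), matching the
"point of half decay ± standard error" convention.  Flat series (range
below 3× the residual noise) or midpoints outside the sampled window are
flagged unidentifiable rather than reported.  The parameterization has a
gauge freedom (dx, y_low, y_high) → (−dx, y_high, y_low); only |dx| and
the signed slope (y_high − y_low)/dx are identifiable.

Synthetic titrations are two-state spectral mixtures: ground (514 nm)
against a 548 nm acid form or a 367 nm deprotonated-Schiff-base form, with
the shifted fraction on the exact Boltzmann curve.  Twelve pH points per
series (the published series span pH 1.93–7.58 and 7.58–12.93 without a
stated count; twelve is a realistic bench titration).  Because the band
separation (34 nm) is small against the bandwidth (90 nm), λ_max of the
blend is nearly linear in the mixing fraction, so the λ_max observable is
Boltzmann-shaped to well within fitting noise (residual bias < 0.001 pH).
The 514 nm observable used on the alkaline side is the uncorrected
absorbance (no baseline model).

## BLM photocurrent decomposition

Flash-induced currents are sums of signed exponentials fit with the same
variable-projection engine (single-channel case).  Defaults of the
synthetic trace: lifetimes 24 µs, 6 ms, 90 ms, 950 ms (measured values);
amplitudes (1.0, 0.6, −0.35, −0.15), free parameters chosen so the fast
rise and the slow return are both clearly visible as in the published
recording; time grid = logarithmic decimation of the merged oscilloscope
windows at 100 points/decade over 10 µs – 20 s; "SNR 50" means
σ = max|I|/50.  Charge per component is the analytic integral a_i·τ_i.
Assignment to photocycle transitions minimizes |log10(τ′/τ)| and is
invariant under common rescaling of both lifetime lists; the slowest
component is excluded by default as the unspecific membrane discharge.
Flash onset is taken at the first sample; no instrument-response
deconvolution.

## Structure geometry

- Parsing: biotite; first model; altlocs resolved to highest occupancy.
  Missing elements are inferred from atom names with a warning.
- Superposition: Kabsch SVD with a determinant correction (proper
  rotations only).  Collinear or mismatched point sets are rejected.
- Protomer RMSD: backbone N/CA/C/O of standard residues, paired by
  (residue number, atom name) intersection — no sequence alignment, so
  cross-protein comparisons are out of scope.
- Pore axis: normal of the best-fit plane through the chain centers of
  mass, through the protein center of mass; orientation toward a caller
  reference (cytoplasmic → extracellular).
- Pore radius: at each axial position the probe center is moved in the
  slab plane to maximize min_a(‖p − x_a‖ − r_a), Nelder–Mead seeded at the
  previous plane's center (continuation) with an on-axis fallback, ties
  broken toward the previous center.  Van der Waals radii are the Bondi
  set (C 1.70, N 1.55, O 1.52, S 1.80 Å; default 1.70 Å); hydrogens are
  ignored (not modeled at this resolution); waters excluded by default.
  Radii are clipped at a 15 Å cap; slabs with no atoms in reach are
  reported at the cap and flagged.  Published vestibule dimensions do not
  state atom-center vs vdW-surface conventions, so no assertion equates
  the profile to those printed diameters.
- Water pentagon: operationally, the five water oxygens radially nearest
  the pore axis, optionally restricted to a ±2 Å slab about a reference
  plane (e.g. the Leu28 carbonyl plane) — a documented proxy for the
  deposited water labels.
- Coordinates are Å; z is signed along the oriented axis with origin at
  the protein center of mass.  PDB storage is float32, which bounds
  round-trip accuracy at ~1e-3 Å (file precision) and exact-symmetry
  checks at ~1e-6 Å.

## Pore energetics

G(z) = −RT ln(n(z)/n_bulk) with R = 1.9872×10⁻³ kcal/(mol·K)
(kJ/mol by flag) and T = 310 K by default (simulation temperature).
Counts are per-bin per-frame averages inside a cylinder of radius 36.23 Å
(cross-section equal to the protein's membrane footprint); bin width
0.5 Å (unstated in the published analysis).  n_bulk is the mean per-bin
count over the outermost 5 Å slabs on both ends of the axial range; since
all bins share one width, per-bin counts and number densities give the
identical ratio.  Empty bins are masked and reported at the resolvability
cap G_cap = RT ln(total count) instead of infinity.

Uncertainties: block bootstrap over frames (blocks of consecutive frames
resampled with replacement, each resample re-inverted to a PMF).  Block
length 1 reduces to the classical bootstrap for i.i.d. frames; serially
correlated trajectories should use blocks longer than the correlation
time.  Trajectory ingestion is CSV in core; an optional MDAnalysis adapter
converts a Universe selection to per-frame samples.

The particle generator draws i.i.d. samples per frame from a prescribed
axial profile, uniform over the cylinder cross-section.  It emulates the
density structure the PMF analysis assumes, not MD physics: no serial
correlation (so block-bootstrap behavior beyond block length 1 is
exercised only structurally), no liquid–vapor oscillations, no
electrostatics.  A green PMF test therefore establishes the correctness of
the density → free-energy inversion and its uncertainty machinery, not
the realism of any simulation.

## Synthetic structures

The ideal pentamer is exactly C5-symmetric: one jittered helical backbone
chain rotated by multiples of 72°, plus one water oxygen per protomer on a
regular pentagon (radius 2.212 Å gives the 2.600 Å adjacent O–O chord) in
a single z-plane.  It validates symmetry-sensitive geometry (axis
recovery, protomer RMSD ≈ 0, ring statistics, profile C5-consistency); it
does not emulate crystallographic disorder, altlocs, or realistic side
chains.

## Known limitations

- The kinetic model is strictly unidirectional; reversible or branched
  schemes are out of scope.
- Noise is i.i.d. Gaussian everywhere: no baseline drift, no shot noise,
  no correlated detector error.
- Uniform weighting across (λ, t) in the global fit; the published
  analysis states no per-point error model.
- Quantities that require microsecond MD ensembles (the simulated pore
  radius minimum, mutant conduction) are outside desk scale and are
  covered only by property-level tests of the machinery.
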