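# Methods

This note documents the models, parameters, numerical choices and known
limitations of `espec`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Units and conventions

All public interfaces exchange Å (length), fs (time), eV (energy), K
(temperature); masses are eV·fs²/Å², charges are elementary charges, and
the Coulomb coupling e²/4πε₀ = 14.3996 eV·Å. Constants are CODATA 2018.
Water sites are ordered O,H,H per molecule everywhere.

## Mixed quantum–classical dynamics

**Water model.** Flexible SPC: harmonic OH stretch (k = 48 eV/Å², r₀ =
1.0 Å, placing the stretch near 3650 cm⁻¹) and harmonic HOH bend (k = 3.29
eV/rad², θ₀ = 109.47°) inside each molecule; O–O Lennard-Jones (ε =
6.74 meV, σ = 3.166 Å) and site–site Coulomb (q_O = −0.82) between
molecules. Intermolecular interactions are switched off per molecule pair
by a cubic-Hermite taper of the O–O distance over [r_c − Δ, r_c] (defaults
9 Å, 1 Å); switching whole charge groups keeps the truncated interaction
neutral. There is no Ewald summation; bulk runs rely on the tapered
cutoff. The stretch/bend constants follow the flexible-SPC literature in
spirit; they are plain harmonic terms, not the original anharmonic
intramolecular surface.

**Excess electron.** One electron on an M³ periodic cubic grid (16³/18.17 Å
during dynamics; the spectral re-solve grid is configurable). The kinetic
operator is applied spectrally by FFT; the electron–water interaction is a
sum of per-site terms

    V_site(r) = −q·e² erf(A r)/r + Σ_j B_j exp(−C_j r²),

an erf-screened Coulomb tail that matches the SPC partial charges at long
range plus Gaussian core terms. The shipped parameter file
(`src/espec/data/pseudopotential.yaml`, version 2) carries, on O, a
repulsive core (30 eV, 2.0 Å⁻²) and a broad attractive Gaussian (−1.8 eV,
0.25 Å⁻²) standing in for the molecular polarization attraction; H carries
a 12 eV, 3.5 Å⁻² core. These constants are this package's own calibration
against physical targets for the hydrated electron — a bound cavity state,
s→p gaps of 1–2 eV, a ground-state radius of gyration near 2–2.5 Å — not a
transcription of any published parameter set. Every solver contract and
oracle test is parameter-agnostic; an alternative file can be dropped in.

**Eigensolver.** LOBPCG (scipy) with an FFT kinetic preconditioner
(T + shift)⁻¹. Ground-state-only solves run single-vector (the ground
state of a real Hamiltonian is non-degenerate); excited-state solves use a
block of K+5 seeded vectors so the near-degenerate p manifold is resolved
(single-vector Lanczos provably misses exact multiplicities). Start
vectors are seeded and warm-restarted from the previous frame's block, so
reruns are bit-stable. Residual tolerances: 1e-9 (relative to the
potential scale) for dynamics, tighter for oracle tests; the solver raises
with the reached residuals if convergence fails.

**Forces and integration.** The quantum force on each site is the
Hellmann–Feynman average −⟨ψ₀|∂V/∂R|ψ₀⟩, evaluated by grid quadrature of
the analytic radial derivative (finite everywhere; the erf screening
removes the Coulomb cusp). Nuclei advance by velocity Verlet at 0.5 fs
(velocities are needed for kinetic temperature, hence the velocity
variant). Equilibration rescales velocities to the target temperature
every 50 steps and then releases the thermostat; production is NVE.

**Grid centering.** The dynamics grid is centered on the initial water
center of mass and then held fixed for the whole NVE segment: a per-frame
floating grid makes the Hamiltonian explicitly time dependent and destroys
energy conservation. The spectral re-solve, which is static, floats its
grid to each frame's center of mass. With the fixed dynamics grid the
total energy (nuclear kinetic + classical potential + E₀) drifts below
1e-4 eV/ps on desk-scale anion runs, which the acceptance suite checks.

## GSTA quantization

The weighting function w(ν) = (hν/2k_BT)·coth(hν/2k_BT) is the
quantum/classical energy ratio of a harmonic oscillator; w(0) = 1 and
w → hν/2k_BT at high frequency. The discrete kernel is built by sampling
√w at the FFT frequencies of the moving window (default 150 fs, an odd
number of samples), inverse transforming, centering and normalizing to
unit sum — by construction its discrete transfer gain equals √w at every
window frequency, and the DC normalization is exact. The √w gain acts on
*coordinates*, so quadratic observables (mode energies, position
variances) scale by w; the test suite pins this with the classical→quantum
harmonic-oscillator variance identity kT/mω² · w = (ℏ/2mω)·coth(ℏω/2k_BT).

Filtering is applied to the dense 0.5 fs trajectory *before* any frame
striding (striding first would alias the OH stretch through the filter);
the spectral pipeline strides afterwards. Half a window is dropped at each
trajectory end rather than padded — padding would fabricate dynamics.
Velocities, when stored, are filtered with the same kernel. At very high
temperature the kernel tends to a discrete delta and the trajectory passes
through unchanged, the classical limit.

## Spectra and statistics

The slow-modulation spectrum is assembled as an oscillator-strength
density: each transition deposits f_k at ΔE_k on a 5 meV grid, averaged
over configurations, with optional 10 meV Gaussian smoothing for fitting;
the raw integral therefore equals the mean summed oscillator strength per
configuration (asserted to 1e-10). Per-transition sub-bands are kept
separately and sum to the total exactly.

Sub-bands are fitted with Gaussians by uniform (unweighted) least squares
with moment-based starts; the fitted total is the sum of the per-band
Gaussians and its maximum and full width at half maximum are measured
numerically, since a Gaussian mixture has no closed form. Moments (m₀, the
mean energy m₁, and the SD) are always computed from the raw transition
list, never from bins. 95% confidence intervals come from a seeded
percentile bootstrap (1000 resamples over configurations) — an ordinary
nonparametric choice made where a specific CI recipe was not prescribed.

Classical-vs-quantized comparisons use the two-sample unpaired Student
*t* test (pooled variance) reported one-sided in the observed direction of
the shift (identical inputs give p = 0.5 exactly), and the variance-ratio
*F* test one-sided toward larger quantized variance. The p-state splitting
is ⟨E₃−E₁⟩ with a bootstrap CI on its classical→quantized change.

## Structure analysis

Electron–site radial distributions use the ground-state wavefunction
centroid as the electron position. Periodic frames normalize by the bulk
site density (minimum image; r_max ≤ box/2 enforced); finite clusters have
no bulk density, so the uniform reference is the same frame's site count
spread over the probed sphere (mode recorded in the output).

The OH-scaling transform multiplies both OH bond vectors (about O) of
every molecule by f — which leaves the HOH angle unchanged — and then
rigidly re-embeds the molecule so its center of mass and principal inertia
axes equal the originals. Holding the angle fixed is a choice: fixing
angle + COM + axes makes the transform well-defined and exactly
invertible, and the tests assert COM/axis preservation to 1e-10 and
f∘(1/f) identity to 1e-9. Principal axes are eigenvectors of the inertia
tensor with geometry-based sign fixing (bisector and H→H references) so
the frame varies continuously.

## Synthetic generators and desk scale

The fixtures module generates harmonic-mode series (deterministic cosines
and classical thermal ensembles with closed-form statistics), relaxed
neutral toy clusters (steepest descent to |F| < 0.05 eV/Å), pre-formed
cavity clusters (one OH per molecule aimed at the shell center — the
standard starting motif for excess-electron runs; a neutral cluster plus a
sub-picosecond equilibration never localizes the electron), and toy
excitation tables with prescribed gap distributions. All are seed-
deterministic and exist to make every stage testable without a production
simulation; they validate mechanics and statistics, not bulk-water
structure.

The default desk-scale protocol — 8 waters at 200 K, 0.4 ps equilibration,
2.2 ps production, 150 fs window, every 40th stored frame re-solved for
K = 4 excited states on a 16³/18.17 Å grid, ~103 paired configurations —
is the package's chosen configuration for end-to-end runs that finish in
minutes on one CPU. At this scale the qualitative NQE signatures (OH
broadening, sub-band and total broadening, F-test direction, deeper
quantized energy levels, the bond-scaling trends) are reproducible and
statistically testable, and that is what the acceptance suite asserts.
Desk runs do *not* reproduce production-scale absolute numbers: those
require hundreds of picoseconds of n = 45–1600 systems with 32³ spectral
grids and 11 excited states (the `paper-n45` / `paper-bulk` presets),
which are multi-day jobs. Small clusters also bind the electron more
variably than bulk; the pre-formed cavity start plus the polarization term
in the shipped potential keep the desk ensemble in the bound, interior-like
regime where the comparison is meaningful.

## Known limitations

- One-electron, adiabatic, ground-state-surface dynamics only; no
  nonadiabatic effects, no many-electron methods. External excitation
  tables (e.g. from TD-DFT) are supported as inputs but never computed.
- The plotted/integrated spectrum is an oscillator-strength density; cross
  sections and absolute intensities are outside scope.
- Transition dipoles use the sawtooth position operator about the
  ground-state centroid; for strongly delocalized (grid-filling) states on
  the periodic grid the dipoles, and hence oscillator strengths, lose
  accuracy. Bound, localized states — the regime of interest — are
  unaffected (the harmonic-well sum rule saturates to 1.000 ± 0.001).
- GSTA is a harmonic, per-coordinate quantization: anharmonic mode
  coupling enters only through the classical trajectory, and the filtered
  trajectory is not a dynamical trajectory (its time correlations beyond
  the window are those of the smoothed classical motion).
- No Ewald summation, barostat, or D₂O; water-only topologies with one
  excess electron.
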