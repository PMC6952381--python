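# Methods

`dynscatter` simulates what an intense femtosecond X-ray pulse does to an
organic nanoparticle *while the particle is being imaged by that same
pulse*, and what the resulting diffraction pattern looks like.  The target
system is a sucrose (C12H22O11) cluster — a benchmark organic sample for
single-particle XFEL imaging — exposed to pulses between the water window
(~284-540 eV) and the keV range.  This note records the model, its
assumptions, the parameters that matter, and the numerical choices.

## Model overview

The cluster is treated as a collection of independent atoms (H, C, O) with
the molecular stoichiometry and geometry retained.  Three coupled layers:

1. **Atomic structure (Hartree-Fock-Slater).**  Every electronic
   configuration C of every atom/ion is solved in a self-consistent
   central field

       V(r) = -Z/r + V_H[rho](r) - (3/2) alpha_x (3 rho/pi)^(1/3),

   with the Latter tail correction V >= -(Z - N + 1)/r.  From the orbitals
   come binding energies, subshell photoionization cross sections
   (length-gauge dipole matrix elements against energy-normalized
   continuum waves in the same potential), core-to-valence oscillator
   strengths, the dispersion-free form factor f0(q) (Fourier transform of
   the radial density), and the anomalous factors: f''(w) from the optical
   theorem (photoabsorption plus resonance Lorentzians), f'(w) by a
   principal-value Kramers-Kronig transform of f'' in the
   scattering-factor convention (f' -> -N_bound as w -> 0).

2. **Ionization dynamics (Monte Carlo).**  Configurations change through
   six channels: photoionization, Auger decay, fluorescence, resonant
   excitation, electron-impact ionization and recombination.  Field-driven
   rates are cross sections times the instantaneous photon flux of a
   Gaussian pulse (energy fluence, FWHM duration, 1% FWHM Gaussian
   bandwidth); Auger rates come from configured core-hole lifetimes
   (C 10 fs, N 7 fs, O 4 fs — a 5 fs oxygen preset is also provided);
   fluorescence yields default to zero for Z <= 8.  Events are sampled per
   time step as Bernoulli trials with p = Gamma dt (the step-size guard
   raises when Gamma dt exceeds 0.2); per-configuration cross sections are
   cached once and rescaled by the flux, so no intensity binning is needed
   and the caching introduces no rate distortion.

3. **Nanoplasma molecular dynamics.**  All nuclei/ions and the freed
   electrons propagate classically (velocity Verlet, softened Coulomb
   forces, direct O(N^2) sum) in 10-attosecond default steps.
   Photo/Auger electrons are born isotropically with the channel's kinetic
   energy.  Impact ionization fires per electron-ion encounter with
   probability sigma_Lotz v dt / V_sphere inside a 0.3 nm encounter
   radius; recombination captures an electron into the lowest vacancy when
   its kinetic-plus-pair energy is below minus half the vacancy binding
   inside 0.1 nm.  Electrons beyond the interaction radius (3x the initial
   cluster radius) with positive total energy are removed as escaped; the
   rest constitute the delocalized population N_e(t).

The observable is the pulse-weighted, bandwidth-averaged scattering
pattern

    dsigma_dam/dOmega(q) ~ dsigma_th/dOmega (1/F) int dw int dt g(w) j(t)
                           [ |F_c(q,t)|^2 + N_e(t) ],

with F_c(q,t) the coherent sum of complex atomic form factors over the
instantaneous configurations and positions, and N_e(t) entering
incoherently (the delocalized electrons' amplitudes do not add in phase
once most have left the cluster volume).  Total cross sections integrate
the pattern over a configurable solid-angle aperture; the Dynamic
Scattering Efficiency is DSE = sigma_dam / sigma_nodam, where sigma_nodam
is the same static evaluation with all atoms neutral.  The experimental
counterpart — the mean fitted incident fluence of the brightest 5% of
size-filtered single-shot hits over the beamline peak fluence F0 — is
implemented in the sphere-model pipeline.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `xalpha` | 0.638 | Slater exchange coefficient; calibrated once so the oxygen K resonance reproduces the resonant (1.2 Mbarn at 530 eV, 1% bandwidth) and valence (0.03 Mbarn) absorption anchors; lands the atomic 1s->2p line at 527.9 eV, close to the known atomic value (~527 eV) |
| core-hole lifetimes | O 4 fs (5 fs preset), C 10 fs, N 7 fs | set Auger rates and natural linewidths |
| `resonance_broadening_ev` | 4.0 eV | width of the 1s->2p band used in the f'/f'' dispersion integrals only; represents the 530-535 eV chemical-shift spread of the molecular 1s->pi* band that the independent-atom model collapses into one line |
| `threshold_mode` | delta-SCF | ionization thresholds from total-energy differences; frozen-eigenvalue thresholds would spuriously open the O K channel below the edge (eigenvalue ~510 eV vs delta-SCF ~546 eV) |
| MD step | 10 as | pulse-coupled dynamics; scaled-down studies use 20 as for the long-pulse runs |
| softening length | 0.01 nm | prevents singular classical collisions |
| interaction radius | 3x initial cluster radius | delocalized vs escaped distinction |
| bandwidth quadrature | 7-node Gauss-Hermite | smooth with the broadened dispersion |
| snapshot cadence | 0.5 fs (1 fs for 180 fs pulses) | convergence-tested against refinement |

## The two-level Rabi estimate

For few-femtosecond pulses the rate picture breaks down; the package
provides the resonant two-level estimate for O 1s <-> 2p: coupling
d = e <2p|r|1s> (the full radial dipole integral from the HFS orbitals),
peak Rabi frequency Omega = d E0 / hbar with E0 the peak field of the
Gaussian envelope at the stated fluence, and excited-state loss at the
neutral-oxygen K-hole Auger rate (tau = 5 fs — the neutral atom's
literature lifetime; the 4 fs value used for the ionic cascade dynamics is
selectable).  At 25 uJ/um^2 and 5 fs FWHM this gives Omega about 81x the
Auger rate: stimulated cycling dominates over Auger depletion.  Fixing the
fluence makes the peak field scale as tau^(-1/2), so shortening the pulse
raises the peak Rabi frequency (quartering the duration doubles it); the
solver is rotating-wave at zero detuning.

## Synthetic data

- **Clusters**: the single-molecule geometry is an idealized ETKDG
  embedding of the sucrose connectivity (fixed seed, MMFF-relaxed);
  clusters pack molecules with random orientations, a 0.55 nm minimum
  center distance, and centers rescaled so the nuclear radius of gyration
  matches a uniform sphere at the bulk density 1581 kg/m^3.  Hydrogens are
  explicit.  What this does *not* emulate: crystalline order, water
  content, non-spherical shapes.
- **Shot ensembles**: sphere-model images with diameters from a normal
  size distribution, fluences from the focal-volume distribution (p(F)
  proportional to 1/F under a transverse Gaussian beam, truncated at a
  configurable minimum fraction), an injected damage factor multiplying
  the expected counts, and Poisson noise.  Passing the recovery tests
  shows the *estimator pipeline* is unbiased at experiment-like counts; it
  says nothing about detector artifacts (charge sharing, gain maps) that
  real pnCCD data would add.

## Numerical choices and degeneracies

- Radial problems use a 3200-point logarithmic grid (1e-5 to 40 a0);
  bound states by Numerov shooting with node-count bisection (integration
  capped where h^2 W exceeds the Numerov stability bound deep in the
  forbidden region); continuum waves on a uniform 4 ma0 grid,
  energy-normalized against the outer WKB envelope.  The hydrogen
  eigenvalue and Stobbe photoionization oracles validate both to <0.1%.
- The s -> 0 limit of the sphere envelope uses the series value 1/9; the
  fit seeds the diameter from a coarse scan finer than the fringe-order
  aliasing scale and refines with bounded scalar minimization; amplitude
  weights are Poisson-motivated with a second pass using model-based
  weights (data-based weights bias the amplitude at low counts).
- Degenerate inputs: bare ions scatter nothing and have no channels; a
  zero-fluence pulse yields no field-driven transitions; empty shot
  selections and zero reference cross sections raise instead of returning
  NaN.
- Energy bookkeeping in the coupled simulation is approximate at the
  (few-eV) level of the eigenvalue-based Auger energies; pure-MD segments
  conserve energy to 1e-4 relative (two-body oracle) and charge exactly.

## Scaled-down study conditions

Full experiment-scale runs (185,193 molecules, 42 million particles) are
supported by the data structures but not by a desktop CPU budget.  The
packaged studies use 8-molecule clusters (2 nm) for the pulse-duration
sweep and the expansion/ionization trends, and 27-molecule clusters
(3 nm) at 30 fs for the photon-energy comparison: the energy selectivity
of the damage (the 530 eV minimum) relies on electron trapping and
recombination, which the very smallest clusters barely exhibit — at 2 nm
per-atom damage saturates at every photon energy (carbon K absorption
alone delivers several photons per atom at 25 uJ/um^2) and the contrast
drowns in Monte-Carlo noise, while at 3 nm the ordering is stable across
seeds.  Absolute DSE values at these sizes are smaller than at 50 nm —
small clusters charge up and expand faster — so only orderings and
limits, not magnitudes, are asserted.

## Known limitations

- Configuration-averaged atomic physics: no LS term structure, no
  molecular orbitals; the 1s->pi* molecular resonance is represented by
  the atomic 1s->2p channel.
- No Compton scattering (negligible total cross section in this range),
  no vibrational broadening beyond the dispersion band width, no shake-off
  or double-Auger channels, no relativistic corrections.
- The focal fluence distribution is an analytic isophote model, not a
  wavefront simulation.
- Recombination uses a classical capture criterion; three-body energy
  partition is not resolved beyond the MD itself.
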