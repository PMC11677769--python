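# Methods

## The model

`lipidmc` coarse-grains the polar surface layer of a phospholipid bilayer
as a two-dimensional system of mobile, rotating electric dipoles — the
zwitterionic headgroups — doped with charged or neutral guest particles.
A dipole of length l = 0.5 nm (the phosphatidylcholine headgroup scale)
carries two opposite point charges of magnitude q_d at
`position ± (l/2)·(cos α, sin α)`; its axis lies in the XY plane and
rotates about the vertical axis through its center.  A dopant is a single
point charge q (q = 0 allowed) with a Lennard-Jones diameter L.

The interaction of any two particles is the signed sum of point-charge
Coulomb terms over their charge sites, screened by a relative
permittivity ε_r, plus a Lennard-Jones term on the center–center
distance d:

    U_C  = Σ_ab  [e²/(4π ε0 ε_r)] · q_a q_b / max(r_ab, r_soft)
    U_LJ = 4 ε [ (σ/d)¹² − (σ/d)⁶ ],   σ = (σ_i + σ_j)/2

For a dipole pair this expands into the four end-charge terms with signs
(+, −, −, +) given by the charge products; for a dipole–dopant pair into
two terms; for a dopant pair into one.  The LJ σ of a dipole is its
diameter (0.5 nm by default), of a dopant its size L, mixed
arithmetically.

Kinetic degrees of freedom (dipole mass and moment of inertia) do not
enter configurational Metropolis sampling; the `DipoleState` type carries
them as optional metadata only.

### Units

Lengths are in nm, charges in elementary charges, and all energies in
k_BT at the configured temperature, so the Metropolis exponent is
dimensionless and parameter-free.  The conversion constant
e²/(4π ε0) = 1.4399645 eV·nm ≈ 56.6 k_BT·nm at 295 K.

### Regularizations

Two guards keep the potential numerically sane; both are config fields:

* **Hard-core floor** (`hard_core_floor`, 1e−4 nm): center–center
  separations below it are treated as overlaps and the move is rejected,
  preventing r⁻¹² overflow.
* **Charge-site soft core** (`coulomb_soft_core`): the Coulomb denominator
  saturates at r_soft, giving every point charge a finite effective size.
  Without it, two opposite end charges can collapse toward the hard floor
  into ~10⁴ k_BT absorbing traps, because the LJ repulsion acts on dipole
  *centers* and cannot protect end sites.  The library default is 0.3 nm
  (bare charge-site contact, ~0.15 nm radius each); the sweep-experiment
  protocol uses 0.4 nm, the contact distance of two *hydrated* charge
  sites, the relevant scale at an aqueous interface (see Calibration).

### Truncation

`dipole_cutoff` optionally truncates *dipole–dipole* pairs beyond a
radius; a neutral dipole pair's far field decays as r⁻³, so a 4 nm cutoff
(the sweep-protocol value) changes pair sums negligibly while cutting the
cost of a Metropolis move by ~5×.  Pairs involving a dopant are always
evaluated in full: the dopant monopole tail (~1/r) is long-ranged and the
dopant–dopant repulsion at large separation is precisely what terminates
the binding-energy descent at higher concentrations.  The library default
is no truncation, and all oracle-equivalence tests run the exact model.

## The Metropolis engine

A *sweep* attempts one move per particle in a freshly randomized order.
Dipoles draw a translation uniform in the square [−dx, dx]² and a
rotation uniform in [−dα, +dα]; dopants translate only (the same dx).
The derived move-range parameter k = π·l/(dx·dα) is reported for
reference; dx and dα are the primary knobs.  Moves that would leave the
open simulation domain (the lattice bounding box padded by half a
spacing) are rejected; under periodic boundaries positions wrap and
separations use the minimum image.

Acceptance is plain Metropolis, min(1, exp(−ΔE)), at the fixed physical
temperature (295 K by default).  The run tracks the best-seen
configuration and its energy — the minimum-binding-energy state — and
stops when the best energy has improved by less than a relative tolerance
over a window of sweeps, or at `max_sweeps`.  Non-convergence within the
budget is a reported flag, not an error.  An optional geometric cooling
schedule (`annealing_factor`, `annealing_stages` on `run_minimization`)
is available but off by default, since the experiments fix a single
temperature.

ΔE for a move is computed in O(N) against all partners and accumulated
into a running total; the total is refreshed from scratch at every
convergence-window boundary (randomized initial placements can relax
through ~10⁴⁰-k_BT LJ overlaps, which would otherwise leave rounding
debris in the accumulator), and the final best-state energy is always
recomputed exactly.

## Concentration-sweep experiments

Concentration is defined as dopant count as a percentage of the dipole
count (400 for the 20×20 lattice), rounded to the nearest whole dopant;
a 0.25 % step on the default lattice is exactly one dopant.

For each replicate r, an undoped baseline run gives Ep0(r); every doped
energy is reported as the signed ratio Ep/|Ep0|, so the undoped level is
exactly −1 and stronger binding (stiffening) is more negative.  Baseline
runs depend on neither q nor L and are shared across the cells of a
charge × size grid; doped runs at the same (replicate, concentration
index) share seeds across cells, as replicated-measurement designs do.

The interior minimum of a mean curve is declared only when the discrete
argmin is interior *and* lies below both endpoints by more than twice the
pooled standard error; its location is the vertex of a local quadratic
fit (5-point window, clipped at edges, clamped to the window), its depth
is the drop of the vertex below the c = 0 level, and the location
uncertainty comes from a 200-resample replicate bootstrap.

### Protocol sizes

The standard experiment protocol (`lipidmc.sweep.experiment_config`) uses
the full 20×20 lattice with a fixed budget of 1000 sweeps per run
(convergence checked over 400-sweep windows at 1e−5 relative tolerance)
and the 4 nm dipole–dipole truncation.  A fixed budget keeps replicate
energies exchangeable across concentrations: every point of a curve is
the best-of-1000-sweeps statistic of the same search process.  Pilot
traces show the normalized curves' shape is stable from roughly 600
sweeps on, while absolute best energies continue to creep slowly
downward — the normalization cancels that common drift.  The acceptance
experiments use ≥10 replicates per concentration; unit tests use smaller
lattices (2×2 to 4×4) where the contract under test is exact rather than
statistical.

## Calibration of the unspecified physics

The published model fixes geometry (20×20 lattice, l = 0.5 nm, spacing
2l, T = 295 K, L = 0.1–0.7 nm, q = 0–6) but not ε_r, ε, σ, q_d, r_soft or
step counts.  Defaults were chosen by a small calibration study against
the three qualitative findings (charged dopants create an interior
binding-energy minimum at a few percent; the minimum shifts to higher
concentration with charge; depth varies non-monotonically with size,
deepest near L = 0.5 nm):

* ε_r = 80 (bulk water).  Halving it to 40 makes dipole shells around
  each dopant screen the dopant–dopant repulsion so effectively that the
  minimum leaves the 0–5 % window entirely.
* ε = 1 k_BT, σ_dipole = 0.5 nm.  Raising ε to 1.5–2 k_BT deepens the
  neutral (LJ) part of dopant binding and pushes the minima toward 4–5 %.
* q_d = 1 e (a single elementary charge per headgroup end).
* r_soft = 0.4 nm in the experiment protocol (hydrated contact
  distance).  At the bare-contact 0.3 nm the smallest dopant
  (L = 0.1 nm) gains disproportionate contact binding: the minima sit
  too high (q = 2 at ~2–3.5 %) and the depth-vs-size curve peaks at
  L = 0.3 nm.  At 0.4 nm the q = 2 minimum falls at ~1.5 % and the
  q = 4 minimum at ~2 %, with the charge-ordering of the locations
  preserved.

One discrepancy survives calibration: with the protocol parameters the
minimum depth grows with dopant size up to L = 0.7 nm (L = 0.5 and 0.7
differ by less than one standard error), whereas the published curves
peak at L = 0.5 nm.  No explored parameter combination reproduced the
L = 0.5 peak without pushing the concentration minima out of their
observed range; the depth comparison across sizes is reported as
computed.  All four knobs are ordinary config fields and none is
hard-coded anywhere.

## EPR spin-probe statistics

The rotational correlation time of a nitroxide probe is computed from the
triplet line amplitudes and the central-line peak-to-peak width:

    τ = 5.95 · ΔH0 · ( √(I0/I+1) + √(I0/I−1) − 2 ) · 10⁻¹⁰ s

ΔH0 is taken in gauss (the convention that yields ~10⁻⁹ s for membrane
probes with ~2 G lines); the unit is an explicit argument so the mT
convention is equally available.  The partition parameter of an
amphiphilic probe whose high-field line splits into a lipid (H) and an
aqueous (P) component is F = H/(H + P).  Concentration series are
normalized to their first point (τ/τ0, F/F0), the same pattern as Ep/Ep0.

The synthetic generator draws first-derivative Lorentzian (default) or
Gaussian lines: a triplet at −a_N, 0, +a_N (a_N = 1.5 mT, a typical
nitrogen hyperfine splitting) with prescribed peak-to-peak amplitudes and
width, optionally splitting the high-field line into H and P components.
Measurement locates each line's peak–trough pair in a window around its
center (known from generator metadata, or estimated from the three
largest peak–trough pairs), then refines all lines by a joint
least-squares fit of the line-shape model, which removes tail overlap and
averages grid noise; sub-grid extrema positions use parabolic
interpolation.  ΔH0 is the central line's extrema separation.

What the generator does *not* emulate: hyperfine anisotropy, slow-motion
lineshape distortion, field modulation artifacts, baseline drift, and
g-strain.  Passing round-trip tests therefore validates the formulas and
the measurement plumbing, not a full spectral simulation of real
instrument data.

## Known limitations

* The surface layer is strictly two-dimensional: no out-of-plane tilt,
  no hydrophobic-core chain interactions, no explicit solvent — the
  model argues Coulomb-driven trends qualitatively, not absolute
  energies.
* Best-of-budget Metropolis at fixed temperature is a stochastic search;
  at 295 K with ~k_BT couplings the "minimum binding energy" is a
  statistic of the search process, which is why every experiment is
  replicated and every extremum call carries an uncertainty.
* All dopants in a run share one sign and magnitude of charge; mixed
  dopant populations are out of scope.
* The interior-minimum detector assumes a single-dip curve; multi-modal
  curves would need a different summary.
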