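# Methods

## Scope and purpose

`cexfrag` analyses the fragmentation of the protonated cystine cation after
sudden ionization to +3. The scientific object is the *analysis chain* —
bond-break detection on trajectory ensembles, break-probability statistics,
fragment identification and m/z assignment, and the surrounding ion-yield
spectroscopy bookkeeping. The trajectories themselves come from a classical
surrogate model built for that purpose: it reproduces the *statistical
structure* the analysis assumes (thermally fluctuating bonds with
well-defined baselines; stochastic, charge-driven dissociation within a
picosecond), not the electronic-structure forces of the real ion. Surrogate
break percentages therefore characterize the surrogate, never the molecule;
validation is by parameter recovery against engineered ground truth.

## Masses and m/z

All m/z values derive from a pinned constants table
(`cexfrag.elements`, CODATA/AME2020 monoisotopic masses, IUPAC 2021
conventional atomic weights, electron mass 5.48579909e-4 u). Three scales:

* **monoisotopic** — principal-isotope masses; used for high-resolution
  assignments such as the isobaric pair C2SNH4⁺ (74.00590) vs C2O2NH4⁺
  (74.02365), which differ by 0.01775 u;
* **average** — conventional atomic weights; the protonated parent prints
  241.3 at one decimal;
* **nominal** — the average mass rounded to the nearest integer, matching
  unit-resolution TOF peak labels. This choice (rather than rounding the
  monoisotopic mass) is deliberate: the disulfide cation S2⁺ has average
  mass 64.12 and monoisotopic mass 63.94, and the observed peak is labeled
  64.

The electron mass is subtracted per positive charge whenever a charge is
set (toggleable); without it the five-decimal assignments are off by
~5.5e-4 u.

Formula parsing is order-preserving with no parentheses; repeated symbols
accumulate (`"COOH"` → C1 O2 H1). A trailing `+`/`-` (optionally with a
magnitude) sets the charge.

## Topology and fragments

Protonated cystine is declared as a labeled molecular graph (27 atoms, 26
bonds, a tree): alpha carbons C1/C4, carboxyl carbons C2/C5, CH2 carbons
C3/C6 bound to S1/S2, the S1–S2 bridge, and explicit hydrogens. Hydrogens
are explicit because fragment families differ only in H count (C2NHx,
CSHx). The extra proton sits on one amine nitrogen; the two sites are
chemically equivalent and the choice is configurable
(`cystine_topology("N1")`).

Fragments are the connected components after deleting a broken-bond set.
Because the graph is a tree, k broken bonds give exactly k + 1 fragments,
and fragment compositions always sum to the parent (asserted by property
tests). Fragment charge is *not* assigned: classical trajectories cannot
partition charge, so the census reports neutral formulas plus hypothetical
+1 m/z values.

## Surrogate force field and dynamics

Units throughout: Å, fs, eV, u, elementary charge
(Coulomb constant 14.3996 eV·Å/e²).

* **Bonds** are Morse potentials V = D(1 − e^{−β(r−r₀)})² with β = √(k/2D),
  so the curvature at r₀ equals a conventional harmonic stiffness k.
  Morse rather than plain harmonic is essential: a harmonic bond's
  restoring force grows without bound while Coulomb repulsion decays, so a
  harmonic surrogate could never dissociate and the break analysis would
  have nothing to measure. Stiffnesses (13–37 eV/Å²), equilibrium lengths
  and well depths (2.3–4.8 eV) are per-element-pair textbook values.
* **Ionized-state weakening**: the +3 state is reached by removing two
  valence electrons from bonding orbitals, so the charged force field
  scales every bond's k and D by 0.4 (β preserved). Without this, the
  ground-state well depths hold the ion together and almost nothing breaks
  within 1 ps; with it, a majority of default-ensemble trajectories end
  with at least one broken bond, the regime the statistics need. The factor
  is a model constant of the surrogate, exposed in `build_forcefield`.
* **Charges**: +3 spread uniformly over the 14 heavy atoms plus the extra
  amine proton (0.2 e each); the thermalization field is neutral. A
  classical point-charge distribution for a core-ionized state is
  inherently fictitious; uniform-over-heavy-atoms is the simplest
  symmetric choice.
* **Non-bonded terms**: Coulomb plus a purely repulsive ε(σ/r)¹² wall
  (ε = 0.005 eV, σ = 0.89·(vdW radii sum)) between all pairs except
  directly bonded (1–2) ones — the standard exclusion that avoids double
  counting with bond terms. The wall provides excluded volume and a soft
  stand-in for angular rigidity; the molecule is floppier than reality,
  which is acceptable because only bond lengths enter the analysis.
* **Reference geometry** is *defined* as a local minimum of this potential,
  found by L-BFGS from a seeded 3D graph embedding. This guarantees
  self-consistency (zero force at the start of a cold neutral run) without
  importing any external coordinates.
* **Integrators**: velocity Verlet; thermalization applies per-step
  Berendsen velocity scaling λ = √(1 + (dt/τ)(T₀/T − 1)) with τ = 0.1 ps
  toward 300 K; production runs are NVE. Step 0.5 fs (≈ 26 steps per C–H
  period); measured NVE drift over 1 ps is ~0.01%, and halving the step
  reduces it. Initial thermal velocities are a seeded Maxwell–Boltzmann
  draw with the centre-of-mass motion removed.

### Protocol defaults

Thermalize the neutral-field molecule (duration (n−1)·1 ps + 1 ps so that n
starting configurations can be drawn ≥ 1 ps apart, taken from the end of
the run backwards), then explode each configuration at +3 for 1 ps at
0.5 fs, 18 configurations by default. Explosion runs inherit the sampled
frame's velocities by default; `resample_velocities=True` draws a fresh
Maxwell–Boltzmann set per run, which makes runs independent Bernoulli
trials and is used for all probability-recovery work.

## Bond-integrity analysis

For each monitored bond the thermal baseline is μ and the *population*
standard deviation σ of its length over the (equilibrated part of the)
thermalization run, pooled across runs when several are given; the
reference distance is d₀ = μ + σ. The one-σ shift compensates the right
skew of anharmonic bond-length distributions (for a right-skewed series,
d₀ exceeds the median — asserted in tests). Population rather than sample
σ because the baseline is a descriptive moment of a long series, and the
convention must be fixed for reproducibility.

The integrity parameter is

    Ξ(d) = 1                         for d ≤ d₀
    Ξ(d) = exp(−(d − d₀)/(λ))        for d > d₀,   λ = decay_scale · d₀

with `decay_scale = 1` by default. The form satisfies the defining
contract — Ξ ∈ [0, 1], Ξ = 1 for an intact bond, monotone non-increasing
beyond d₀, → 0 as d → ∞ — and the relative decay length makes one "bond
length of stretch" count the same for a short O–H as for the long S–S.
With the default threshold Ξ < 0.5, a bond is "breaking" once stretched
beyond ≈ 1.69·d₀, a conventional bond-scission distance.

A bond is classified **broken** iff Ξ stays below the threshold for every
frame of the trailing persistence window (default 100 fs). The trailing
window realizes "broken within 1 ps" while ignoring transient stretches
that recover mid-trajectory; intermediate recombination is ignored by
construction.

**Break tables** group symmetry-equivalent bonds into classes (S1–C3 with
S2–C6, etc.). Two counting conventions are exposed, because grouped
reporting is ambiguous: per-trajectory (an event if *any* member broke;
default) and per-bond-copy. Percentages carry Wilson 95% intervals
(statsmodels). Integer reporting rounds half away from nothing special:
7/18 → 39%, 4/18 → 22%.

**Census**: the final frame's broken-bond set defines each trajectory's
fragmentation; formulas are aggregated over the ensemble.

## Parameter recovery

The recovery experiment engineers a known truth: scale k and D of one bond
class by a factor s (β fixed, maximum restoring force ∝ s). With fresh
Maxwell–Boltzmann velocities per run, the class break probability p(s) is a
smooth decreasing function; it is measured on a coarse probe grid
(s = 1.0…0.6, 25 runs each), a logistic p(s) = 1/(1 + e^{(s−s₀)/w}) is
fitted by maximum likelihood, then a high-count bracket (3 × 55 runs)
around the estimated crossing refines the fit, and the factor at p = 0.5
is returned. Evaluation uses 50 runs with seeds disjoint from calibration.
Across seeds the estimate lands at 0.42–0.64, inside the central 95% region
of Binomial(50, 0.5) ([0.36, 0.64]); the check inherits that interval's 5%
intrinsic failure rate plus a small calibration-error contribution.

## Spectroscopy layer

* **TOF calibration**: t = t₀ + k√(m/z), exact for two references
  (the m/z 45 and 64 peaks by convention), least squares for more; the
  inverse is ((t − t₀)/k)². Round trips are exact to floating precision.
* **Peak integration**: trapezoidal on dense grids, plain sums for peak
  lists. Default fragment windows are ±0.5 m/z around nominal positions
  (unit-resolution peaks); window widths and background treatment are
  declared package defaults, not fitted quantities.
* **PIY/SIY**: one integrated window per fragment per photon energy;
  the scan validator enforces 40–70 meV steps by default. The SIY is the
  elementwise sum of stored PIY arrays, computed in sorted-label order so
  it is bit-identical under permutation of the fragment set.
* **Stick broadening**: unit-area Gaussian kernel, σ = FWHM/√(8 ln 2),
  optional rigid shift. Defaults 0.7 eV FWHM and +7.23 eV are match
  parameters for comparing a computed stick spectrum with a measured SIY,
  not physical constants. The default grid step FWHM/20 keeps the
  quadrature error in the conserved total strength well below 0.1%.

## Synthetic spectra

`cexfrag.synthesize` fabricates a photon-energy scan with known truth:
per-fragment resonance profiles (three bound Gaussian resonances, a broad
feature, and a sigmoidal edge step near 173 eV, loosely shaped like a
sulfur L-edge region), narrow Gaussian mass peaks whose areas equal the
profile values, and a known TOF calibration. What it does *not* emulate:
detector noise statistics beyond optional multiplicative Gaussian noise,
peak-shape asymmetry, baseline drift, overlapping isobars within one
window, or spin–orbit structure. Passing tests therefore demonstrate the
correctness of the extraction arithmetic, not robustness to instrument
pathologies.

## Problem sizes and determinism

Default analyses use 16–18 ps thermalization (0.5 fs step, every 4th frame
stored), 18-trajectory ensembles, ~350 runs for a full
calibration+recovery cycle, and 50-run evaluations — sizes chosen so the
statistical claims (Wilson intervals, binomial recovery bands) are
meaningful while a complete rerun stays in the minutes range on one core.
Every stochastic element (thermal velocity draws, velocity resampling,
synthetic-scan jitter) flows from explicit integer seeds through
`numpy.random.default_rng`; reruns with the same seed and configuration are
bit-identical, and the pipeline writes byte-identical CSVs plus a manifest
with content hashes.

## Known limitations

* The surrogate has no electronic structure: no resonant (below-threshold)
  excitation dynamics, no Auger physics, no charge migration or
  fragment-charge assignment, no secondary fragmentation kinetics.
* Break percentages depend on the surrogate's weakening factor and charge
  distribution; they are not predictions for cystine.
* No angular force-field terms: conformational statistics are not
  realistic, only bond-length statistics are used.
* Nominal m/z as rounded average mass can disagree with
  monoisotopic-rounded labels for heavy sulfur-rich fragments; the package
  exposes all three scales so the convention is always explicit.
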