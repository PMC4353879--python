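# Methods

## Transfer model

The package implements the point-dipole (ideal-dipole) coupling model of
Förster transfer between one excited donor and one ground-state acceptor.
Per trajectory frame at time `t`:

```
kappa(t) = mu_d · mu_a − 3 (Rhat · mu_d)(Rhat · mu_a)
W_F(t)   = 3 kappa²(t) / (2 tau_d) · (R_F / R_da(t))⁶          [ns⁻¹]
E(t)     = 1 / (1 + (W_F(t) tau_d)⁻¹)
```

with `mu_d`, `mu_a` the *normalized* transition-dipole directions, `Rhat`
the unit donor→acceptor separation vector, `R_da` its length, `tau_d` the
donor fluorescence lifetime without the acceptor, and `R_F` the Förster
radius.  Transition-moment magnitudes never appear explicitly: they are
absorbed into `R_F` through the spectral quantities below.  Assumptions
inherited from the model: weak (incoherent, rate-limit) coupling, a single
donor-acceptor pair per analysis, point dipoles (questionable below ~10 Å
separations — the model is applied there regardless, as is standard in
trajectory-based FRET analyses), and the ergodic identification of time
averages with the ensemble averages that experiments measure.

Trajectory averages `⟨R_da⟩, ⟨kappa²⟩, ⟨W_F⟩, ⟨E⟩` are uniform-weight
arithmetic means over equally spaced frames (the simplest quadrature
consistent with a 1/T time integral; no higher-order rule is warranted for
data this noisy), `(kappa²)_max` is the per-trajectory maximum of the
per-frame values (an empirical extreme, not the analytic bound 4), and
`duration_T = N·dt`.

`E` as written is singular at `W_F = 0`; it is evaluated as
`W_F tau_d / (1 + W_F tau_d)`, which is the same function with the
continuous limit `E(0) = 0` built in.  This makes the zero-overlap chain
exact: `J = 0 ⇒ R_F = 0 ⇒ W_F ≡ 0 ⇒ ⟨E⟩ = 0` with no floating-point
residue, matching the physical statement that a donor whose emission a
ground-state acceptor cannot absorb transfers nothing.

## Spectral quantities

```
J   = ∫ f_D(λ) ε_A(λ) λ⁴ dλ        [M⁻¹ cm⁻¹ nm⁴]
R_F = 0.2108 (n⁻⁴ Q_D ⟨kappa²⟩ J)^(1/6)   [Å]
```

`f_D` is the donor emission spectrum area-normalized to 1 over its grid
(units nm⁻¹), `ε_A` the acceptor molar extinction in M⁻¹ cm⁻¹, `λ` in nm.
The 0.2108 prefactor is exact for this unit system; with unit `Q_D`, `n`,
`⟨kappa²⟩` and `J` the radius is 0.2108 Å, which the acceptance script
recomputes.  Numerics: both curves are linearly interpolated onto the union
of their grids restricted to the intersection of their supports and
integrated with the trapezoidal rule; values outside a spectrum's tabulated
support are taken as 0, and disjoint supports yield exactly `J = 0`.
Spectra are read from two-column delimited text (whitespace or commas,
`#` comments), with strictly increasing but not necessarily uniform grids.

## Site and dipole conventions

The donor site is the unweighted centroid of the six tyrosine aromatic-ring
carbons (`CG CD1 CD2 CE1 CE2 CZ`; no hydroxyl oxygen, no mass weighting).
The acceptor site is the midpoint of the two atoms of the bond fusing the
six- and five-membered rings of the formycin bicycle (defaults `C3A`/`C7A`,
the 1PR1-style ligand naming; ligand atom names vary across PDB dialects,
so these are configurable and should be checked against the topology in
use).  Dipole directions are normalized differences of ordered atom pairs;
the shipped defaults (`CG→CZ` for the tyrosine ring, the ring-fusion bond
for the acceptor) are long-axis geometric approximations to
quantum-chemically computed transition moments, adequate for testing the
pipeline but meant to be overridden with better directions when available.
Atom lookup is by (chain, residue number, atom name), so record order in
the file is irrelevant; for alternate-location records the first altloc is
taken with a warning.  Coordinates are Å (PDB convention); frame times are
`index·dt`, 0-based, with `dt` supplied by the user (ns).

## Charge patching

Excited-state (or deprotonated-state) electrostatics are produced by adding
per-atom ESP charge *differences* between the two electronic states to the
base force-field charges, leaving the rest of the parameterization intact:
`q_patched = q_base + Δq`.  Two bookkeeping modes: `excitation` expects the
deltas to sum to ~0 (charge conservation of a neutral excitation; ESP fits
rarely close exactly, tolerance default 0.01 e), `deprotonation` expects
exactly −1 e.  Deviations beyond tolerance flag the patch report but do not
abort — the numbers may still be intentional.  Delta tables are input
files; no rescaling (e.g. for buried vs. solvent-exposed sites) is applied.

## Synthetic trajectory generator

The generator emulates only the *statistical structure* the analysis
consumes: a separation distance process (fixed, uniform in a range, or
strict two-state alternation) and a dipole orientation process (frozen,
isotropic-independent per frame, or uniform within a cone of given
half-angle).  Sphere/cone sampling uses the inverse-CDF scheme
`cosθ = 1 − u(1 − cos α)`, `φ = 2πu'` on `numpy.random.default_rng(seed)`
draws, documented so an independent oracle can replay the exact stream.
Defaults — 5000 frames at `dt = 1 ps` (a 5 ns window), fixed `R = 9.14 Å`,
isotropic orientations — mirror a typical production analysis window and
the wild-type mean separation of the motivating system.  The optional PDB
realization places an idealized phenol hexagon (ring radius 1.39 Å) and a
two-atom bridge (bond length 1.4 Å) so that the spectroscopic site
convention recovers each frame's geometry to PDB coordinate precision
(10⁻³ Å); it claims no chemistry.  What the generator deliberately lacks —
serial correlation, coupled distance/orientation fluctuations, anisotropic
restricted motion of a real binding site, force-field physics — bounds what
green tests mean: they validate the analysis mathematics and plumbing, not
the conformational sampling of any real protein.

## Statistical conventions

SEM is the population standard deviation (`ddof = 0`) over `√N`.  The
`ddof = 0` choice keeps the estimator exactly self-consistent under
trajectory concatenation (duplicating a trajectory leaves all means fixed
and shrinks every SEM by exactly `1/√2`), which the test suite asserts
bit-tightly; at trajectory lengths of interest the difference from
`ddof = 1` is negligible.  No autocorrelation correction is applied by
default — for serially correlated MD data the naive SEM understates the
true uncertainty — but `summarize_trajectory(..., block_size=k)` computes
the SEM over non-overlapping block means instead (means are unaffected).
A constant series short-circuits to SEM = 0 exactly, avoiding the O(ε)
residue of mean subtraction.

## Degenerate inputs and tie-breaks

Zero-length separation or dipole vectors raise degenerate-geometry errors
(no silent clamping); `kappa_sq` outside `[0, 4]` is rejected at the rate
level; fewer than 2 frames raise an insufficient-data error; an all-zero
emission spectrum cannot be normalized and says so.  `R_F = 0` and
`J = 0` are exact sentinel values propagated as exact zeros, never as
small floats.

## Design choices that were genuinely open

* Quadrature for the time averages and for `J`: trapezoidal/arithmetic
  mean, as the least-assumption choice.
* `E(0) := 0` by continuity rather than treating the singularity as an
  error, so zero-overlap systems summarize cleanly.
* Units fixed globally (Å, ns, ns⁻¹, nm, M⁻¹ cm⁻¹ and e) rather than
  carried symbolically; the `0.2108` prefactor pins the unit system.
* The analysis handles exactly one configured donor-acceptor pair per run;
  multi-donor systems are run once per candidate donor.
* CLI exit codes 2 (configuration) / 3 (data), logging to stderr only and
  results to files, so identical configs and seeds give byte-identical
  outputs.

## Problem sizes

Default test and validation sizes: 10⁶ orientation pairs for the
Monte-Carlo isotropic check, a 10⁴×10⁴ symmetry-reduced orientation grid
for the `kappa²` bound, 10⁵ frames for the isotropic trajectory limit and
5·10³ frames for oracle-equivalence checks — sizes at which the Monte-Carlo
standard errors (≈10⁻³ on `⟨kappa²⟩`) are far below the tolerances being
asserted.

## Known limitations

Point-dipole coupling only (no transition-density or line-dipole coupling);
no lifetime fitting, photobleaching kinetics, spectral deconvolution or
inner-filter corrections; no periodic-boundary unwrapping (the donor and
acceptor are assumed whole and in the same image); transition-dipole
directions are geometric atom-pair approximations unless the user supplies
better ones; the naive SEM ignores serial correlation unless block
averaging is requested.
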