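# Methods

## Units and constants

Energies are in eV, lengths in Å, masses in amu everywhere;
`kB = 8.617333262e-5 eV/K` and `1 kcal/mol = 0.0433641 eV`. Angular
frequencies from mass-weighted Hessians come out in `sqrt(eV/(amu Å^2))`
and are also reported in cm⁻¹ for spectroscopic intuition
(1 internal unit ≈ 521.5 cm⁻¹).

## Frequency convention and the amplitude formula

The displacement amplitude of mode *i* at energy `de_i` is
`A_i = sqrt(2 de_i) / w_i`. We interpret `w_i` as the **angular** frequency
in the mass-weighted coordinate system, i.e. the square root of the
mass-weighted Hessian eigenvalue. This is the unique convention under
which a single mode displaced by `A_i` (in mass-weighted coordinates;
Cartesian displacement of atom *a* is `A_i v_i[a] / sqrt(m_a)`) carries
harmonic potential energy exactly `de_i = 1/2 w_i^2 A_i^2`. The test suite
asserts this identity to 1e-9 relative, and additivity over modes via
eigenvector orthogonality.

## Vibrational analysis

`harmonic_analysis` symmetrizes the Cartesian Hessian (rejecting asymmetry
above 1e-6 relative), mass-weights it, and projects out the rigid-body
subspace before diagonalizing: 3 translations plus 3 rotations built from
the geometry, orthonormalized by QR, with numerically null columns dropped.
Linearity is detected from the principal moments of inertia (smallest
moment < 1e-4 amu Å², or N = 2), in which case only 2 rotations exist and
`3N - 5` modes are returned. After diagonalization the `n_projected`
eigenvectors with the largest overlap onto the rigid-body basis are
discarded; this is more robust than an eigenvalue-magnitude cutoff when a
genuine vibration is very soft.

Negative eigenvalues beyond the cutoff mark saddle-point equilibria; those
modes are returned separately as imaginary frequencies and never displaced
— how saddle points should be displaced is genuinely open, and exclusion
(flagged per run) is this package's choice. Real modes below a
10 cm⁻¹ cutoff are likewise excluded from sampling: their amplitude
`sqrt(2 de)/w` diverges as `w -> 0`, so displacing them converts numerical
noise into arbitrarily large displacements.

## Target histogram

The energy window is `[0, f <dE>]` with `f = 4.5` and `<dE> = (3/2) N kB T`,
split into 45 uniform bins (width `0.1 <dE>`; the bin count is a package
choice — it makes the expected per-bin counts small integers at 100
structures). Bin probabilities integrate `exp(-dE/s)` over each bin.

The literal exponential scale `kB T` is dimensionally inconsistent with the
prescribed mean (an exponential of scale `kB T` has mean `kB T`, not
`(3/2) N kB T`), so the default `scale="fitted"` keeps the exponential
shape and solves `s - L/(exp(L/s) - 1) = <dE>` (truncated-exponential
mean, `L = f <dE>`) with Brent's method; a root exists iff `f > 2`, which
the configuration enforces. `scale="literal"` is available for experts;
it concentrates essentially all quota in the first bin.

Integer quotas use largest-remainder rounding (ties to lower bins), which
preserves the non-increasing bin profile and sums exactly to the requested
count. This rounding is why a realized sample's mean sits ~3% below the
continuous mean at the default settings: tail bins with expected counts
below one round to zero. That deficit is deterministic, documented, and
well within the 5% band the distribution tests assert.

## Per-mode energy allocation

The per-mode split of a candidate's total energy is not prescribed beyond
being random; we use unit-exponential weights rescaled to the total —
equivalently a symmetric Dirichlet(1, …, 1), the maximally uninformative
distribution over partitions of a fixed total. Signs are independent fair
coin flips. A Monte-Carlo test checks the per-mode mean share against the
Dirichlet closed form.

## Acceptance loop

Each attempt targets a bin chosen with probability proportional to its
remaining quota and draws the harmonic-estimate total uniformly inside
that bin — this avoids the rejection bottleneck of blind proposals while
leaving the accept/reject decision entirely to the *re-evaluated* backend
energy, so the enforced distribution is exact regardless of how anharmonic
the backend is. Acceptance requires (a) the true `dE` to land in a bin
with remaining quota and (b) minimized RMSD > `0.0075 N` Å to every
previously accepted structure. Failed candidates are redrawn from scratch
(fresh allocation and signs), not rescaled. All randomness comes from one
`numpy` Generator seeded by the run configuration, consumed in a fixed
order (bin, total, mode weights, signs), so runs are bitwise reproducible.

If `max_attempts` (default `200 × n_structures`) is exhausted the run
raises a structured `IncompleteHistogramError` carrying the partial result,
the unfilled bins and the acceptance rate — incomplete molecules are meant
to be excluded, not silently truncated.

Observed behaviour on the 5-atom toy fixture: with the exact harmonic
backend the acceptance rate is ~8%, limited almost entirely by the RMSD
floor in the low-energy bins (small `dE` means small displacements, and
candidates there crowd within `0.0075 N` Å of each other); with the Morse
backend it drops to ~1% because anharmonicity scatters candidates out of
their targeted bins. Both effects are logged per attempt, not asserted.

## Minimized RMSD

Superposition removes the centroids and solves the Kabsch/Wahba problem
via `scipy.spatial.transform.Rotation.align_vectors`, restricted to proper
rotations so enantiomers keep a nonzero RMSD. Coordinates are unweighted
(common conformer-comparison practice) and atoms are matched by index —
permutations of identical atoms are deliberately not searched. The
residual is recomputed explicitly after rotation because the solver's
reported deviation loses precision to cancellation near perfect
superposition. An all-atom/heavy-atom switch is exposed (`heavy_only`);
all-atom is the default. Correctness is checked against a brute-force
Euler-grid + local-refinement oracle to 1e-3 Å.

## Filters

`energy_window_filter` keeps candidates whose RMSD to every kept record is
`>= rmsd_min` (default 0.5 Å) inside a 50 kcal/mol window;
`select_distinct_conformers` uses strict `>` at 1.0 Å ("larger than"), so
a pair at exactly the threshold collapses to one conformer. Both sweep in
ascending energy with ties broken by input index, making them
deterministic and permutation-stable. Duplicate detection compares six
properties (PBE0 energy, MBD energy, HOMO–LUMO gap, HOMO energy, isotropic
molecular polarizability, scalar dipole moment) with an absolute threshold
of 1e-3 in each property's own unit — all six must agree; one
larger-than-threshold difference vetoes the pair. The pairwise relation is
closed transitively (union–find) so keep/drop is well-defined for chains;
the first occurrence in input order is kept.

## HDF5 schema

Records are dict-like bundles keyed by the 42 schema keys with shapes
validated against the atom count (`atNUM` length N; per-atom arrays length
N or N×3; `KSE` variable-length). Two internal identities are enforced at
1e-6 eV whenever the participants are present: `HLgap = eL − eH` and
`ePBE0+MBD = ePBE0 + eMBD`. On disk each molecule prefix
`Geom-m{r}-i{s}-c{t}` is a top-level group with one subgroup per variant
`u`; the reader also accepts a flat one-group-per-label layout, preserves
unknown keys with a warning (forward compatibility), and can apply an
exclusion list in which dropping an `opt` label also drops all variants
sharing its `(r, s, t)` prefix. Units are stored as dataset attributes.

## Toy molecules and what they do (and don't) show

`make_toy_molecule` grows a connected random geometry (elements from
{H, C, N, O, S, Cl}, bonding distances 1.35–1.65 Å, clash floor 1.1 Å) and
equips it with a Morse-bond + harmonic-angle force field whose every term
is minimized at the generated geometry, so the reference is the exact
global minimum. Morse terms sit on *all* atom pairs (stiff wells at
bonding distances, weak 0.35 eV tethers beyond), which guarantees the
curvature spans the full `3N − 6` shape space. The harmonic model's
Hessian is assembled in internal coordinates as
`sum_q V''(q0) (grad q)(grad q)^T` — exact at a stationary point — so
rigid motions are exact null vectors by construction and the
finite-difference Hessian of the anharmonic potential reproduces it.

The synthetic HDF5 fixture generator emulates the *schema and magnitudes*
of real property records (total energies of order −10³..−10⁴ eV, gaps of a
few eV, neutral-molecule Hirshfeld charges), including planted
within-1e-4 duplicate pairs for filter testing. Neither fixture reproduces
real electronic structure: passing tests demonstrate that the sampling,
filtering and bookkeeping machinery is correct, not that any particular
level of theory is well-approximated. Runs at production scale require a
real `EnergyBackend`.

## Problem sizes

The test suite and acceptance script run on 2–9-atom toy molecules,
sampling runs of 25–100 structures, and synthetic datasets of up to a few
hundred records — sizes chosen so every check, including the brute-force
oracles, completes in seconds while still exercising each code path at the
production default parameters (T = 1500 K, 100 structures, 45 bins).
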