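# qm7x-tools

Machinery for building QM7-X-style molecular datasets: harmonic normal-mode
analysis, Boltzmann-histogram-enforced sampling of non-equilibrium
structures around (meta-)stable conformers, conformer and duplicate
filtering rules, the 42-property HDF5 schema, and dataset statistics.

Large quantum-chemistry datasets for machine learning pair each optimized
("equilibrium") small-molecule geometry with on the order of 100 displaced
("non-equilibrium") geometries whose energy rise above the minimum follows a
controlled Boltzmann-like distribution. This package implements that
structure-generation pipeline in a backend-agnostic way: the
electronic-structure method is a pluggable `EnergyBackend` (anything with
`evaluate(structure) -> eV`), and two analytic toy potentials (an exact
harmonic model and an anharmonic Morse + angle force field) make the whole
pipeline runnable and testable without any quantum-chemistry code.

## The sampling model

For an equilibrium structure with `N` atoms, the displaced set is built to
have an average energy rise, in analogy with equipartition, of

    <dE> = (3/2) N kB T,        T = 1500 K by default,

with the individual `dE` values following an exponential (Boltzmann-like)
distribution `P(dE) ~ exp(-dE/s)` truncated to `[0, 4.5 <dE>]`. An
exponential with scale `kB T` cannot average `(3/2) N kB T`, so by default
the scale `s` is root-solved such that the truncated distribution's mean
equals `<dE>` exactly (the literal `kB T` scale is available as an expert
option). The target distribution is enforced through a 45-bin histogram of
integer per-bin quotas summing to the requested structure count.

Candidates are generated by normal-mode displacement: a vibrational
analysis of the mass-weighted Hessian (rigid translations/rotations
projected out) yields angular frequencies `w_i` and mass-weighted
eigenvectors; a random energy partition `de_i` over the modes (symmetric
Dirichlet) gives per-mode amplitudes

    A_i = sqrt(2 de_i) / w_i

applied simultaneously with random signs. Because this trusts the harmonic
approximation, each candidate's true `dE` is re-evaluated with the energy
backend; a candidate is accepted only if its true `dE` falls in a histogram
bin with remaining quota and it differs by a minimized RMSD of more than
`0.0075 N` Å from every structure accepted so far. Sampling ends when every
bin is full.

Around this core the package provides the equilibrium-side selection rules
(50 kcal/mol energy window + 0.5 Å RMSD pruning; distinct conformers at
RMSD > 1.0 Å; duplicate detection via six-property agreement within 1e-3),
the `Geom-m{r}-i{s}-c{t}-{u}` label grammar and HDF5 property schema with
createDB-style duplicate exclusion, and dataset statistics (pairwise
distance distributions, heavy-element composition counts, per-size summary
tables, atomization energies, SCS van der Waals radii).

## Worked example

```python
import numpy as np
from qm7xtools import (
    make_toy_molecule, harmonic_analysis, sample_nonequilibrium,
    SamplingConfig, mean_target_energy,
)
from qm7xtools.calculators import HarmonicBackend

structure, model, topology = make_toy_molecule(5, seed=3)
modes = harmonic_analysis(model.hessian, structure.masses, structure)
print(f"{modes.frequencies.size} modes, "
      f"{np.round(modes.frequencies_cm, 1)} cm^-1")

result = sample_nonequilibrium(
    structure, modes, HarmonicBackend(model), SamplingConfig(seed=0)
)
print(f"accepted {len(result.structures)} structures "
      f"in {len(result.attempts)} attempts")
print(f"mean dE = {np.mean(result.delta_e):.4f} eV, "
      f"target = {mean_target_energy(5, 1500.0):.4f} eV")
```

prints

```
9 modes, [ 413.3  947.4 1110.6 1329.4 2559.7 3142.3 3699.9 4074.2 5009.1] cm^-1
accepted 100 structures in 2492 attempts
mean dE = 0.9370 eV, target = 0.9694 eV
```

The five-atom toy molecule has `3N - 6 = 9` vibrational modes. The run
fills all 45 histogram bins exactly; the accepted structures' mean energy
rise sits within a few percent of the equipartition target `(3/2) N kB T =
0.969 eV` (the small deficit comes from rounding the exponential bin quotas
to integers). Most rejected candidates fail the `0.0075 N` Å RMSD
diversity floor, which is hardest to satisfy in the low-energy bins where
displacements are small.

The same operations are available from a shell via the `qm7x-tools`
command (`sample`, `dedup`, `fixture`, `validate`, `convert`, `distances`,
`composition`, `summary`, `propdist`); see `qm7x-tools --help`.

## Hessian text format

Plain-text Hessians (`read_hessian_text`/`write_hessian_text`, and the
`sample --hessian` option) are whitespace-separated `3N x 3N` matrices in
eV/Å², row-major, one matrix row per line.
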