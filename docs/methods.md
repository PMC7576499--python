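# Methods

This note documents the models, estimators and numerical choices behind
nipflow: what is simulated, how the permeability coefficients and activation
energies are estimated, what the structural and conservation procedures
compute, and where the design was genuinely open.

## 1. Osmotic-shock forward models

A yeast cell loaded with a self-quenching fluorophore and equilibrated in an
iso-osmotic buffer (default 1.4 osmol L⁻¹) is mixed with a hyperosmotic
solution (default final osmolarity 2.1 osmol L⁻¹).  With an impermeant
solute (sorbitol) the cell shrinks monotonically; with a permeant solute
(glycerol) it shrinks and then re-swells as glycerol enters and water
follows.

### Mechanistic ("ode") mode

State variables: relative volume `v = V/V0` and internal glycerol amount
`n` (mol per cm³ of initial cell volume).  With `A/V0` the area-to-volume
ratio, `Vw` the molar volume of water and all concentrations in mol cm⁻³:

    dv/dt = −Pf · (A/V0) · Vw · (C_out − C_in),   C_in = (a_imp + n) / v
    dn/dt =  Pgly · (A/V0) · (C_gly,out − n / v)

`a_imp` is the conserved internal impermeant osmolyte amount, initialized to
the equilibration osmolarity; every internal solute is osmotically active by
default (an osmotically inactive volume fraction `1 − active_fraction` is
supported and defaults to 0).  For a sorbitol shock the external medium is
entirely impermeant (`C_gly,out = 0`); the system then settles at the
closed-form equilibrium `v∞ = osm_in/osm_out` (0.6667 for 1.4/2.1).  For a
glycerol shock the final external osmolarity is carried entirely by
glycerol.  This composition is the only one under which the operational
slope formula below returns `Pgly` rather than a scaled-down value: if a
fraction `f` of the external osmolarity were impermeant, the re-swelling
slope would be reduced by `(1 − f)`.

Integration uses LSODA with `rtol 1e-9`, `atol 1e-12`; the active volume is
floored at `1e-9` to keep the right-hand side defined for extreme inputs.

### Exponential mode

The exact inverse of the estimator chain, used for exact-recovery tests and
for the reported recovery experiments:

* water shock: `v(t) = v∞ + (1 − v∞)·exp(−k t)` with
  `k = Pf · Vw · (osm_out)∞ · (A/V0)` (the inversion of the `Pf` formula);
* glycerol shock: the same exponential until the residual shrinkage
  amplitude reaches 2% (`t_on = ln(50)/k`), after which the volume rises
  exactly linearly with slope `m = Pgly · (A/V0)`.

### Signal transduction and noise

Fluorescence is linear in relative volume, `F = baseline + span·v`
(self-quenching: shrinkage lowers the signal; defaults baseline 0, span 1),
plus i.i.d. Gaussian noise of SD `noise_sd · |span|` per sample.  No dye
loading/leakage kinetics or instrument dead time are modelled, and a single
representative cell geometry is used per run (no population heterogeneity).

### Temperature

Both permeabilities scale as `exp(−Ea/R·(1/T − 1/T_ref))`, with
`R = 1.987e-3 kcal mol⁻¹ K⁻¹` and reference temperature 23 °C.

### Acquisition windows (generator defaults)

The trace duration is set by stopping rules expressed in the physics, not in
samples: a water shock is recorded for `ln(10)/k` seconds (until the signal
is within 10% of its plateau), a glycerol shock for `ln(50)/k + 0.12/m`
seconds (shrinkage complete, then 12% of relative volume re-swollen).  A
temperature series dilates both the window and the sampling step by the
inverse Arrhenius factor of the shock-relevant permeability, emulating the
experimenter's record-until-plateau practice at each bath temperature.  This
makes the trace shape — and therefore any estimator bias — temperature
invariant, so Arrhenius slopes are unbiased even where the single-exponential
approximation biases the absolute rate.  Default sampling: 1500 points per
trace.

## 2. Estimator chain

* **Shrinkage rate.**  Nonlinear least squares of
  `signal = baseline + amplitude·exp(−k t)` (floating baseline, amplitude
  sign from the data).  Initial guesses: baseline from the last sample, `k`
  from a log-linearized fit of the first third of the decay.  A trace whose
  apparent amplitude is below five noise floors (noise floor estimated from
  first differences) is rejected as degenerate.  For glycerol traces only
  the samples up to the smoothed volume minimum are fit.
* **Water permeability.**  `Pf = k·(V0/A) / (Vw·(osm_out)∞)` with the final
  osmolarity converted to mol cm⁻³.  Default geometry `V0/A = 8.3e-5 cm`
  (sphere of radius 2.5 µm; `r/3`), `Vw = 18.07 cm³ mol⁻¹`.
* **Re-swelling slope.**  The turning point is the global minimum of a
  moving-average copy (window 5% of samples); ordinary least squares is then
  fit from a guard gap (2% of samples) past the minimum over a window of 40%
  of samples (or to the trace end).  The fit runs on the relative-volume
  series — the exact inverse of the linear transduction — which makes the
  slope independent of signal scale and sign.  A post-minimum rise smaller
  than both four smoothed noise floors and 5% of the shrinkage amplitude is
  reported as "no re-swelling" (e.g. a water-only channel under a glycerol
  shock).  Whether the original analyses fit fluorescence or converted
  volume is not documented anywhere we know of; both are equivalent up to
  the linear transduction, and the volume-domain fit is the default.
* **Glycerol permeability.**  `Pgly = m·(V0/A)`.  A negative slope is
  returned flagged (`reverse_flux`), not raised.
* **Activation energy.**  OLS of `ln P` against `1/T` (kelvin) over at least
  three distinct temperatures; `Ea = −slope·R`.
* **Strain comparison.**  Two-sided Welch (unequal-variance) t-test with the
  conventional labels: `**` for p < 0.01, `***` for p < 0.001, `ns`
  otherwise.  Replicates are aggregated as mean ± SD per temperature, with
  technical replicates averaged before the Arrhenius fit.

### Known estimator bias (documented, not corrected)

The single-exponential fit of the mechanistic shrinkage trace carries a
duration-dependent bias (the true relaxation rate varies from `k` at the
start to `k/v∞` near equilibrium): about −12% of `k` when only one
relaxation time is recorded, +3% at two, +18% at five.  Under the default
window (`ln(10)/k ≈ 2.3` relaxation times) the Pf bias is ≈ +7%.  The
mechanistic re-swelling slope never exceeds `0.91·m` for the default
conditions, because glycerol entering during the ~10 s shrinkage phase
depletes the inward gradient before the volume minimum; the recovered
`Pgly` is therefore systematically ≈ 11–12% low in mechanistic mode, for
any admissible window placement.  Exponential-mode recovery is exact by
construction; mechanistic-mode recovery documents the approximation error a
real analysis of this kind inherits.  Estimates from either mode should be
read as effective coefficients of the standard operational formulas.

## 3. Pore profiling

The pore radius at axial position `z` is the largest sphere centred in that
plane touching no van der Waals surface:

    r(z) = max_c min_atoms ( ‖atom − (c, z)‖ − vdw_atom )

* **Radii**: C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å; unknown elements get
  1.70 Å with a warning (or raise in strict mode).  Radius sets are plain
  dicts and can be loaded from JSON.
* **Grid search** (the oracle): exhaustive lattice-aligned 0.1 Å grid over
  the xy bounding box of atoms within a thin slab around the plane
  (half-width `max(2 Å, 2·z_step)`).  Restricting the candidate box to the
  slab prevents the exhaustive maximum from escaping into bulk solvent
  outside the channel wall; the objective still sees every atom within the
  capture radius.
* **Anneal search**: 200 Gaussian proposals (step 0.3 Å) with geometric
  cooling from T = 0.5 to 0.01, seeded per plane from the run seed and
  started from the previous plane's centre, followed by a deterministic
  Nelder–Mead polish.  Agreement with the grid oracle on the synthetic
  fixtures is at machine precision.
* Planes with no atoms within the capture radius (default 10 Å) are marked
  open at the capture radius; planes where every centre overlaps an atom are
  flagged blocked with radius 0.  Default plane spacing 0.5 Å.
* **Axis**: models are assumed pre-oriented with the channel along z
  (periplasmic side = +z).  A principal-axis mode (largest-variance
  eigenvector of the coordinate covariance, sign fixed by the axial skewness)
  handles arbitrarily oriented structures and is rigid-motion invariant.
* **Constriction**: global radius minimum, ties broken toward smaller z.
* **Profile differences** are taken plane-by-plane after linear
  interpolation onto the first profile's grid, summarized by the mean
  difference and the difference at the first profile's constriction.

## 4. Hydropathy of pore-lining residues

Grid-based hydrophobicity maps of commercial packages are not
re-implemented.  Instead, hydropathy is computed at residue level over the
pore-lining set (residues owning an atom whose vdW surface lies within
1.5 Å of any inscribed-sphere surface):

* binary scale (default): hydrophobic = {A, V, L, I, M, F, W, C, P};
* Kyte–Doolittle mode: hydrophobic where the index ≥ threshold (default 0).

The ratio is `n_hydrophobic / n_hydrophilic` (+∞ flagged when no hydrophilic
residues), reported for the whole pore and for the regions above/below the
ar/R constriction (`upper` = periplasmic side, membership by residue
centroid z).  Because this is a residue-count procedure, published ratios
computed from proprietary volumetric grids on unreleased homology models are
motivating references, not numeric targets; the property suite instead
verifies internal consistency (whole = upper + lower, designed fixtures).

## 5. Conservation analysis

Alignments are inputs (no de novo alignment is computed).  Channel columns
are classified as identical / similar / dissimilar; "chemical similarity"
defaults to *all pairwise BLOSUM62 scores > 0*, with a pluggable
physicochemical-group alternative ({ILVMA}, {FWY}, {ST}, {DE}, {KRH}, {NQ},
{GP}, {C}).  Gapped columns are dissimilar; all-gap columns are excluded
with a warning.  Pairwise identity is computed over columns where neither
sequence is gapped.  Mutation specs (`W86T`) validate the wild-type residue
before substituting and compose sequentially for double mutants; positions
are 1-based in the ungapped reference numbering.

## 6. Synthetic data: what it does and does not emulate

The generator reproduces the *structure* of the real experiments — shock
kinetics with Arrhenius temperature dependence, replicate noise, hourglass
channel geometry with a designed constriction, homolog families with known
column-level conservation — with known ground truth, so every estimator can
be validated by round trip.  It does not emulate: cell-size distributions,
dye-loading kinetics or dead time, fitting-window ambiguity of a human
operator, real homology-model coordinates, or real NIP sequences (the toy
alignment generator draws columns from rule-consistent residue sets rather
than evolutionary processes).  Passing round-trip tests therefore
demonstrates correctness of the estimators and procedures under the stated
models, not accuracy on any particular laboratory dataset.

Toy channels place pseudo-atoms (carbon vdW 1.7 Å) on rings of radius
`wall(z) + vdw` at 1 Å axial spacing, 12 atoms per ring, one residue per
ring, so the designed wall radius *is* the inscribed-sphere radius at every
ring plane by construction.  The wall is a base cylinder (4 Å) with an
optional triangular constriction notch.

## 7. Reported recovery experiments

The acceptance script (`scripts/acceptance.py`) recovers, from
exponential-mode simulations with the native aquaglyceroporin parameters
(`Pf = 6.78e-4 cm/s`, `Pgly = 24.5e-8 cm/s`, `Ea = 9.80 / 6.93 kcal/mol`):
the mean `Pgly` and `Pf` at 23 °C over 10 noisy replicates, and both
activation energies from a 6-temperature × 3-replicate series over
10–35 °C — problem sizes chosen to match the reported experimental designs
(three independent experiments, 10 technical replicates, shocks from 10 to
35 °C).  Whether published SDs were taken across experiments or across all
traces is ambiguous in the sources; the pipeline reports mean ± SD across
whatever replicate set it is given.

## 8. Known limitations

* Reflection coefficients and solvent–solute coupling are not modelled; the
  two-parameter model treats water and glycerol fluxes as independent except
  through osmolarity.
* The mechanistic-mode `Pgly` deficit (§2) is inherent to the operational
  slope formula under these conditions and is left uncorrected by design.
* The pore profiler has no energetic component (no water placement, grids,
  or molecular dynamics); "blocked" means steric overlap of the probe centre
  everywhere in the plane.
* Region splitting and hydropathy centroids use the structure's own z axis;
  use principal-axis mode (or pre-orient) for arbitrarily oriented models.
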