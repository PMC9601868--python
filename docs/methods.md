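# Methods

`pinmap` implements the computational workflow used to characterize the
binding interface of a 2:1 protein complex predicted by a structure
predictor — here, the antiparallel Trim28 coiled-coil homodimer with a
single KRAB domain docked across its two-fold axis — together with the
quantitative SPR binding analysis used to validate such a model by
mutagenesis. This note records the models, the parameters that matter,
the synthetic data the package generates for itself, and the numerical
choices made where the design was genuinely open.

## Confidence handling

Predicted models carry a per-residue confidence score (pLDDT, 0–100) in
the B-factor column; the per-residue value is taken from the CA atom
(falling back to the mean atom B-factor for CA-less residues). Before any
geometric interpretation, residues with pLDDT strictly below a threshold
(default 50, the conventional "very low" boundary) are removed whole —
confidence is a residue-level quantity, so pruning never removes single
atoms. Residues exactly at the threshold are retained. Pruning is
idempotent and monotone in the threshold, and refuses models whose
B-factors do not look like confidences (values outside [0, 100]).

The predicted aligned error (PAE) matrix is read from the AlphaFold
database JSON layout (`predicted_aligned_error`, either top-level or in a
one-element list). Because PAE is asymmetric, rectangular block summaries
report both the directional mean (rows aligned on columns) and the
symmetrized mean of the two directions; the symmetrized mean is the
headline statistic for judging the relative placement of two domains.

## Superposition and RMSD

Rigid-body superposition is the SVD form of the Kabsch algorithm with the
determinant sign correction, so a proper rotation is always returned;
degenerate (collinear) point sets are rejected. "All equivalent atoms"
means heavy atoms paired by (chain id, author residue number, insertion
code, atom name); unmatched atoms are dropped and hydrogens are excluded
because predicted models carry none. The transform may be fitted on one
selection and the RMSD reported over another (the fit needs at least
three points; the report selection may be as small as one atom, which is
how the displacement of a single atom is quantified after fitting on the
rest). Chain correspondence across differently labelled models is by
explicit renaming, never guessed. Tests validate the minimized RMSD
against an independent quaternion characteristic-polynomial oracle to
1e-8.

## Surface areas and interface description

Solvent-accessible surface area uses the Shrake–Rupley construction: each
heavy atom gets a sphere of radius (vdW + probe) sampled with a
deterministic golden-spiral lattice (default 960 points, probe 1.4 Å);
a sample point is accessible when outside every neighbouring expanded
sphere. There is no randomness anywhere in the geometry stack. Radii are
C 1.70, N 1.55, O 1.52, S/P 1.80, Se 1.90 Å (overridable); these and the
probe are field-standard values, not fitted. Quadrature error at 960
points is below 0.5% against closed forms; the engine is cross-checked
against an independent implementation (biotite) at matched radii.

Buried surface area of each molecule of a partition is its isolated SASA
minus its SASA contribution inside the complex, so the identity
`bsa1 + bsa2 = SASA1 + SASA2 − SASA12` holds to rounding. The molecule
partition is explicit — for a homodimer binding one domain, the two
dimer chains count as one molecule — with a per-chain breakdown also
reported.

A residue is interfacial when its per-residue SASA drops by more than
0.1 Å² on complex formation or any of its heavy atoms lies within 5.0 Å
of the partner molecule; per-chain spans are the min/max author numbers
of that list. The asymmetry flag is set when the spans of the two chains
of a multi-chain group differ, which is how a domain binding across a
homodimer's two-fold axis manifests.

Cross-molecule contacts are typed by distance only (predicted models have
no hydrogens, so no angular terms): salt bridge — sidechain N of
Lys/Arg/His against a sidechain carboxylate O of Asp/Glu within 4.0 Å;
hydrogen bond — any remaining N/O pair within 3.5 Å; hydrophobic —
sidechain carbon pair within 4.5 Å with both residues apolar
(A/V/L/I/M/F/W/Y/P). Each atom pair is reported once under the highest-
priority kind it satisfies (salt bridge > hydrogen bond > hydrophobic),
so a salt-bridging pair is not double-counted as a hydrogen bond. The
cutoffs are conventional values exposed as options.

Hydrophobic clusters on one molecule are connected components of the
graph whose nodes are that molecule's hydrophobic interface residues and
whose edges join residues sharing a common contact partner or lying
within four sequence positions of each other. A cluster's "partner pins"
are the partner-molecule residues contacting at least half of its
members. A residue is a pin when its sidechain loses at least 75% of its
isolated sidechain SASA to the partner and touches at least four
distinct partner residues hydrophobically. The 75%/4 thresholds are
heuristics calibrated on the synthetic fixture so that the designed pin
qualifies and no surface residue does; they are not taken from any
measurement.

## SPR binding models

Steady-state analysis fits plateau responses to the 1:1 isotherm
`Req = Rmax·C/(Kd + C)`. Rmax is profiled out analytically (the model is
linear in it) and Kd is optimized in log space from eight log-spaced
starts spanning the concentration window; the fit is flagged
non-converged when the estimate lands far outside the measured window,
where the isotherm carries no curvature. A valid series needs at least
three concentrations spanning a factor of ten.

Kinetic analysis uses the two-state (conformational change) scheme
`A + B ⇌ AB ⇌ AB*` with response `R = AB + AB*`:

    d[AB]/dt  = ka1·C·(Rmax − AB − AB*) − kd1·AB − ka2·AB + kd2·AB*
    d[AB*]/dt = ka2·AB − kd2·AB*

and apparent affinity `Kd_app = (kd1/ka1)·kd2/(kd2 + ka2)`. For
piecewise-constant analyte concentration the system is linear, so each
injection/dissociation phase is propagated with the exact eigen-solution
(machine precision, verified against the closed-form 1:1 limit when
ka2 = kd2 = 0 to 1e-6); an adaptive integrator covers degenerate rate
combinations. Global fits share all five parameters across sensorgrams,
optimize log-parameters (all rates positive) inside generous physical
bounds with trust-region least squares, and start from eight log-spaced
encounter-affinity seeds. Poorly identified directions are reported as
wide standard errors with a warning, not hidden: with a 60 s injection
the individual rate constants are often weakly determined while Kd_app
remains well constrained, which is the quantity of record.

Fold-decreases divide a mutant Kd by the reference Kd and round half-up
to an integer, the convention of SPR mutagenesis tables. Tables computed
from published rounded Kd values can disagree by a few counts with folds
that were originally computed from unrounded estimates; such rows are
flagged with the recomputed ratio rather than silently echoed
(`pinmap.datasets` carries the published Trim28/ZFP932 values used by the
acceptance script).

## Synthetic data generators

The structure generator emulates the study system's architecture: two
antiparallel straight α-helices of 108 residues (30 turns at 1.5 Å rise,
100°/residue, CA–CA 3.8 Å), numbered 248–355 and centred on residue
301.5, with 20-residue low-confidence (pLDDT 30) linker tails; a third
chain of four short helices (residues 4–47) docks asymmetrically at the
dimer midpoint (chain B is shifted 5.5 Å axially). Sidechains are
reduced to CB plus one typed tip pseudo-atom with correct element typing
(amine N for Lys/Arg, carboxylate O for Asp/Glu/Asn, apolar C for the
hydrophobic types), so the contact rules and SASA radii apply unchanged;
tip reach limits approximate real sidechain extents. The designed
inventory mirrors the study's interface: a leucine pin at residue 301 of
each dimer chain seated in a five-residue hydrophobic pocket of the
small domain (rings at exactly 4.0 Å), salt bridges K290–E16, K297–E17,
R312–E35 (chain A) and K305–D8 (chain B) at 3.4 Å, a hydrogen bond from
the Asn308(B) tip to a backbone oxygen at 3.3 Å, and an extra
hydrophobic pair V294(B)–L47. Designed spans are 290–312 (A), 294–308
(B) and 4–47 (C), so the dock is genuinely asymmetric.

Helix phases of the small domain are chosen by a deterministic grid
search so that every designed sidechain stays within reach of its
target while all segment atoms (tips included) stay clear of dimer
residues outside the designed spans; pocket tips are placed collectively
so they wrap around the pin rather than stacking on the side the
helices happen to face. A hard audit then verifies that no unintended
contact-qualifying atom pair exists anywhere and that no cross-molecule
atom sits within the SASA coupling shell (6.3 Å) of an out-of-span
residue — the generator raises on any violation rather than emitting a
fixture whose ground truth could drift. Residues inside the designed
spans that become interfacial only through probe-shell proximity to
designed sites are enumerated at build time and recorded separately as
"incidental"; detectors are tested for exact set equality against
designed ∪ incidental, and exactly against the designed contacts,
clusters, pins and spans. The PAE matrix is two-level by construction:
zero diagonal, 2 Å within ordered chains, 5 Å between ordered regions of
different chains, 25 Å wherever a linker is involved.

What the generator does not emulate: supercoil pitch (helices are
straight), full rotamers, real sequences, packing of the dimer core, or
the magnitude of the real interface (the synthetic complex buries
~510/360 Å² per side versus ~1,040 Å² in the study system). Passing the
recovery tests therefore demonstrates the detectors' correctness against
known geometry, not numerical agreement with any deposited model; for
user-supplied model files the pipeline emits the same reports in the
same units, with no numeric expectations attached.

The SPR generator simulates one sensorgram per concentration and
replicate on a 1 Hz grid with a 60 s injection and 600 s wash (the
instrument protocol of the study), adds seeded Gaussian noise and
optional linear drift, and embeds the metadata in the CSV header. The
default parameters (ka1 2×10⁵ M⁻¹s⁻¹, kd1 10⁻² s⁻¹, ka2 5×10⁻³ s⁻¹,
kd2 2.062×10⁻³ s⁻¹, Rmax 100 RU) give Kd_app = 14.6 nM, the wild-type
affinity of the study system, with Rmax matching the ~100 RU capture
level; the default concentration series brackets Kd two-fold from 3.65
to 233.6 nM. The steady-state generator defaults to the eight-point
0.1–100×Kd design. All randomness flows through one seeded generator;
identical spec and seed give byte-identical output.

## Problem sizes and tolerances

The test suite and acceptance script work at the scale the generators
define: a 297-residue, ~1,470-atom complex (SASA at 960 points per
atom), 20–50-point clouds for superposition oracles, and 50-replicate
noise studies for each fitting route (2% of Rmax for steady state, 1 RU
for kinetics). Numerical tolerances follow the source of error: 1e-8 for
superposition algebra, 0.5% for SASA quadrature against closed forms,
1e-3 Å² for the buried-surface identity, 1e-6 RU for the kinetic
nesting limit, 1% for noiseless parameter recovery. Fold-decreases are
exact integers.

## Known limitations

* Hydrogen bonds are distance-only; without hydrogens, donor/acceptor
  geometry cannot be checked, so some reported "hydrogen bonds" would not
  survive an angular criterion.
* The pin thresholds (75% burial, ≥4 partners) are calibrated heuristics;
  on real structures with full sidechains they may need adjustment.
* The two-state fit reports honest but potentially wide standard errors;
  only Kd_app should be quoted when the rates are weakly identified.
* mmCIF is read-only; output is fixed-column PDB (residue numbers ≤ 9999,
  coordinates within ±1000 Å).
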