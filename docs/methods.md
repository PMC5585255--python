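# Methods

This note documents the models, conventions and numerical choices behind
`trpgate`, and what the synthetic generators do and do not emulate.

## Structural model and units

A system is a `Topology` (atoms with subunit, residue number/name, atom
name, and a role in {protein, ligand, water} assigned from residue names:
HOH/WAT/TIP3/SOL → water, the configurable ligand code, "EET" by default →
ligand) plus a `Trajectory` of frames. Coordinates are Å, time ns, frames
0-indexed with `time = frame_index × frame_interval_ns`. Multi-model PDB is
the on-disk dialect (read and written through biotite); binary trajectory
formats are not shipped. Selections are AND-combined keyword filters over
subunit / residue number / residue name / atom name / role; they are
deterministic, order-stable and may be empty.

## Contact occupancy and binding site

Contact is defined per residue and frame as minimum heavy-atom distance to
any ligand atom ≤ cutoff. Defaults: 3.5 Å for trajectory occupancy, with a
5 Å preset (`DOCKING_SHELL_CUTOFF_A`) matching the wider shell used to
summarise docking poses. Occupancy is counted from frame 0 by default; a
`start_frame` argument discards an equilibration window when wanted. The
binding site uses *strict* inequality (occupancy > threshold, default
0.6), so a residue at exactly 60% is excluded. Residues are reported per
subunit — occupancies are never pooled across the tetramer, because a
binding pocket belongs to one inter-subunit interface. The salt-bridge
criterion is the conventional 4 Å N–O distance (Lys NZ to Asp OD1/OD2);
persistence is the mean of the per-frame bridged indicator.

## Gate geometry

The four gate Cα corners of a real frame are never exactly coplanar, so
"area of the square" is made well-defined by: per-frame total-least-squares
plane fit (SVD), projection of the corners onto the plane, azimuthal
ordering about the centroid, shoelace area. This is exact (s²) for a
square, invariant to corner input order and to rigid motion (tested to
1e-9), and degrades gracefully for warped quadrilaterals. Non-planarity is
reported per frame as the maximum out-of-plane deviation rather than being
silently absorbed. Series summaries use the population SD over a
configurable window (default: all frames; a single frame reports SD 0);
segment summaries (e.g. first/last halves of a closed→open schedule) are
available for schedules.

The pore axis is the fitted plane normal, refit per frame, which removes
any dependence on global trajectory alignment. Its sign is chosen toward an
explicit extracellular reference selection when given; otherwise it points
away from the centroid of the non-gate protein atoms — in TRP-channel
architecture the cytosolic domains dominate the protein mass below the
lower gate, so "away from that mass" is extracellular. This default is a
design choice and is overridable.

## Water permeation

A water's axial coordinate is its projection onto the pore axis relative to
the gate center. Two planes at ±d (default 5 Å, configurable) define a
slab; a completed up-crossing is a passage from below −d to above +d
without first returning below −d after entering the slab, and symmetrically
for down-crossings. The hysteresis means flicker around a single plane can
never create or double-count events. Events carry the water id, slab entry
frame, exit frame and direction. Water presence near the gate is a simple
per-frame count within a radius of the gate centroid; the 6 Å default is a
package choice (no canonical value exists) and is exposed as a parameter.

## Superposition and RMSD

Kabsch superposition uses scipy's `Rotation.align_vectors` (proper
rotations only — mirror images keep a strictly positive residual) with the
RMSD recomputed from the aligned residuals at full precision; it is
validated in the tests against a direct numerical minimization over
rotation vector + translation to 1e-6. The default RMSD selection is all
protein Cα (pseudo-)atoms, the same selection for fit and measurement;
frame 0 is the default reference. Replicates are reduced to their time
means first; the across-replicate summary is mean ± sample SD (n−1),
matching the "mean ± S.D., n" convention of replicate reporting.

## Binding isotherm

The default model is exact 1:1 mass action with total protein fixed at the
assay concentration (20 nM default): bound fraction from the quadratic
root, so ligand depletion is represented even where negligible. The simple
hyperbola is retained for comparison; at protein ≪ Kd the two fits differ
by < 1% (tested). Fitting is nonlinear least squares (Levenberg–Marquardt)
over (log Kd, amplitude, baseline) with a 7-point multi-start grid of Kd
values log-spaced over [min(c)/10, max(c)×10]; log-Kd parameterisation
keeps the search positive and well-scaled, and the Kd standard error is
mapped back by the delta method. Identifiability guard: a fit is flagged
and *no Kd reported* when (i) the amplitude's 95% CI spans zero, (ii) the
fitted amplitude does not clear 3× the residual noise floor, or (iii) the
optimal Kd sits at the upper search boundary (binding outside the tested
range). These three cover both readings of a "did not fit" mutant —
amplitude ≈ 0 and Kd far above the highest tested concentration.

MST windows default to cold = the 5 s immediately before IR-on and hot =
the last 5 s before IR-off; the evaluation window is not standardised
across instruments, so both windows are parameters. ΔF_norm is reported as
a dimensionless difference referenced to each replicate's lowest-ligand
condition (multiply by 1000 for the per-mille display convention).

## Functional assay reductions

Calcium responses are integrated trapezoidally over the response window
after subtracting the mean pre-stimulus baseline; the value is linear in
the response amplitude and may be negative. Ramp current density is the
interpolated current at the reference voltage (+100 mV default) divided by
capacitance. NPo idealizes a gap-free record by half-amplitude thresholds
at (k − ½)·i_single above the closed baseline, taken as the most-closed
dominant mode of the all-points histogram (lowest-current bin holding ≥ 5%
of samples, refined to the local mean) — picking the *lowest* dominant mode
rather than the global mode keeps multi-channel records with a busy open
level correctly baselined. Upstream filtering of recordings is assumed
done and out of scope.

## Statistics

ANOVA uses the textbook sums-of-squares decomposition (p from the F
distribution); identical constant groups report F = 0, p = 1 by convention.
Pairwise post hoc t comparisons are pooled-variance with Bonferroni
multiplication over the requested pairs, capped at 1. Kruskal–Wallis is
tie-corrected (scipy); the Dunn post hoc is built from pooled mean ranks
with variance N(N+1)/12 − Σ(t³−t)/(12(N−1)) and two-sided normal p values,
Bonferroni-adjusted. The unpaired t test defaults to pooled variance (Welch
available); the one-tailed direction defaults to the observed direction
unless specified, matching how directional mutant-vs-WT reductions are
reported. Mann–Whitney uses exact enumeration for total n ≤ 12 without
ties, otherwise the tie-corrected normal approximation with continuity
correction; the two agree to ~0.015 at the exact/asymptotic boundary.

## Synthetic generators

The generators emulate the *statistical* structure the analyses assume, not
physics: no force fields, membrane, solvent or dynamics. A seed fully
determines every output.

- **Tetramer**: four subunits × 12 pseudo-atoms (one Cα per residue of
  interest, plus NZ for K535 and OD1 for D743), a four-atom ligand with a
  carboxylate head (C1), and n free waters. Defaults: 600 frames at 0.2 ns
  (a 120 ns trajectory), positional noise σ = 0.1 Å.
- **Contacts**: scheduled residues are placed 2.5 Å from the ligand head in
  an exact-count random subset of frames and 8 Å otherwise. The 2.5 Å
  placement sits strictly inside the 3.5 Å cutoff so noise cannot flip the
  state; fractions are recovered exactly. The residue moves relative to the
  fixed ligand head because one head cannot simultaneously satisfy
  arbitrary independent schedules for spatially separate residues.
- **Gate**: per frame the corners form a square with side drawn from the
  active segment's Gaussian; `gate_sides_for_area` inverts
  E[s²] = m² + σ², Var[s²] = 4m²σ² + 2σ⁴ in closed form, so a requested
  area mean ± SD (e.g. 55.5 ± 2.9 Å² closed, 63.8 ± 4.2 Å² open) is matched
  exactly in expectation.
- **Waters**: piecewise-linear axial paths realize requested up/down
  crossing counts exactly (travel legs run 3 Å beyond the hysteresis
  planes); eventless waters perform "touch and retreat" excursions into the
  slab to exercise the counter's state machine without producing events.
- Every frame is finally carried through a random rigid rotation +
  translation (shared by all atoms, so distances and axial projections are
  preserved) and iid Gaussian noise.
- **Assays**: titrations apply multiplicative noise to the mass-action
  response; calcium traces carry a triangular pulse whose grid-aligned
  vertices make the trapezoidal integral exact; ramps anchor the +100 mV
  sample at the target density; gap-free records superpose enough
  independent channels to keep per-channel open probability ≤ 0.5, with
  per-channel open-sample counts set exactly.

Because the generators are coarse, passing tests demonstrate the
correctness of the measurement layer (counting, geometry, fitting,
statistics) under the stated noise models — not the behaviour of the
analyses on real force-field trajectories, with their correlated motions,
anisotropic fluctuations and crowded solvent, nor on raw instrument data
with drift and bleaching.

## Problem sizes

Default problem sizes were chosen so every check is desk-scale: 600-frame
trajectories, 400-atom RMSD clouds, 50-titration Kd recovery, 2000-replicate
null simulations for test calibration (n = 20/group, all four tests within
a 3.5–6.5% rejection band at α = 0.05). The full suite runs in well under a
minute.

## Known limitations

- The coarse tetramer's inter-residue geometry is schematic; pair distances
  (e.g. W733–R594) are measured faithfully but their synthetic values are
  scaffold artifacts, not calibrated targets.
- `estimate_npo` assumes a stable baseline and equal single-channel
  amplitudes; drifting or sub-conductance-rich records need upstream
  idealization.
- The crossing counter assumes waters are point particles sampled densely
  enough that a slab traversal spans at least one frame inside or beyond
  the slab; extremely sparse sampling can merge events (the generators
  never produce such paths).
- The unidentifiability guard is conservative by design: very noisy genuine
  titrations may be flagged rather than fitted.
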