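# Methods

This note records the models implemented in `hydroshape`, the parameter
choices that matter, the numerical details, and what the synthetic-data
generators do and do not emulate.

## Hydration thermodynamics

The hydration free energy of a spherical solute of radius *R* is modelled as

ΔG_hydration(R) = ΔG_water_water + ΔG_DDAA · (4·r_H2O/R) · n_HB.

The interfacial term uses the number ratio of top-layer interfacial water to
volume, 4·r_H2O/R for a sphere, multiplied by the free energy ΔG_DDAA of a
tetrahedral (DDAA) hydrogen-bonding environment per lost bond and by n_HB,
the number of bonds lost per interfacial molecule.

**Units.** All internal arithmetic is in kJ/mol.  The bulk-water constant is
commonly quoted in cal/mol; it is converted on entry at 1 cal = 4.184 J.  A
single canonical unit keeps the critical-radius ratio from silently mixing
unit systems.

**Sign conventions.**  Both constants are negative (bound states).  The
critical radius is evaluated as a ratio of magnitudes,
Rc = 8·|ΔG_DDAA|·r_H2O/|ΔG_water_water|; with both constants negative the
raw and magnitude ratios coincide, and mixed-sign constant sets are rejected
at construction.  With the ambient defaults (ΔG_DDAA = −2.66 kJ/mol,
ΔG_water_water = −1500 cal/mol = −6.276 kJ/mol, r_H2O = 1.9 Å) the package
computes Rc = 6.44 Å.

**n_HB default.**  n_HB defaults to 2, which makes the interfacial term
equal 8·ΔG_DDAA·r_H2O/R — the form in which the model is usually written.
It stays an explicit parameter so the sensitivity to the lost-bond count can
be explored.

**Parameters and defaults**

| parameter | default | units | meaning |
|---|---|---|---|
| ΔG_DDAA | −2.66 | kJ/mol | tetrahedral H-bond environment free energy (293 K, 0.1 MPa) |
| ΔG_water_water | −1500 | cal/mol | bulk-water free energy |
| r_H2O | 1.9 | Å | effective water radius; (3V/4π)^{1/3} of the 3×10⁻²⁹ m³ molecular volume |
| T, P | 293, 0.1 | K, MPa | carried for bookkeeping; no T/P dependence is modelled |

**Geometric factor.**  γ = (SA/V)_aggregate / (SA/V)_separate quantifies the
interfacial area lost on contact; by definition it is exactly 1 whenever the
solute separation exceeds the hydrophobic radius R_H (no shared surface),
and the implementation returns the constant 1 in that regime rather than the
ratio of whatever inputs were supplied.

**Hyperbolic water-induced decay.**  ΔG(r) = a + γ·b/(r − r₀) is fitted by
linear least squares in the transformed variable x = γ/(r − r₀), with r₀
held fixed (it is determined independently as the vacuum contact-minimum
distance) and γ supplied.  Standard errors come from the unbiased residual
variance and (XᵀX)⁻¹.  Points at r ≤ r₀ are outside the model domain and
excluded; fewer than three valid points or a degenerate abscissa raise.

**Packing parameter.**  p = v₀/(a·l₀) maps to an aggregate shape by the
classical intervals (sphere ≤ 1/3 < cylinder ≤ 1/2 < bilayer ≤ 1).  The
printed intervals overlap at their endpoints, so exact boundary values are
deterministically assigned to the smaller class; p > 1 is out of range.

## Water structure

**Hydrogen-bond criterion.**  A bond i→j exists when the oxygen–oxygen
distance is below 3.5 Å and the angle at the donor oxygen between the O→O
axis and a donating O→H bond is below 30°.  The angle is measured at the
donor — the standard reading of this family of geometric criteria.  When two
acceptors satisfy the criterion for the same donated hydrogen, the nearest
oxygen wins, so each hydrogen is donated at most once (the criterion alone
does not guarantee this; the tie-break makes the donor bookkeeping well
defined).  Neighbour search uses a KD-tree, with minimum-image distances
when an orthorhombic box is present; solute shapes are never imaged (the
intended setup is a slab or pocket plus probe inside a large box).  The
KD-tree path is validated against an exhaustive all-pairs oracle in the
suite.

**Local network classes.**  A molecule's (donor, acceptor) counts, capped at
2 each, map to DDAA (2,2), DDA (2,1), DAA (1,2), DA (1,1) or free (0,0).
Combinations outside those five (e.g. a double donor with no acceptor) are
reported as `other` rather than forced into a named class — silently
misclassifying them would corrupt DDAA statistics.

**Interfacial layer.**  A water is interfacial when its oxygen's signed
distance to the solute surface lies in [0, cutoff].  The cutoff defaults to
3.5 Å — one water diameter (≈ 2·r_H2O), the same scale as the H-bond O–O
cutoff — because "the top layer" fixes only the intent, not a thickness; the
value is configurable.  The boundary itself is interfacial (deterministic
tie-break).  Waters at negative signed distance (inside the solid) indicate
a malformed configuration; they are flagged, logged, and counted as
interfacial so the partition stays total.  Layer counts over a trajectory
are reported for the whole frame; the association generator additionally
records a between-solutes sub-region count (waters within one layer of both
solutes), since either counting convention may be wanted.

## Solute geometry

Solutes are implicit solids: signed-distance functions, negative inside.
Primitives (sphere, finite slab, slab with a spherical pocket carved into
the face, slab with a spherical bump on the face) have exact sign-correct
fields and closed-form surface area and volume via spherical-cap formulas.
Unions take the pointwise minimum of member fields — sign-correct
everywhere, only approximately metric near re-entrant intersections, which
is sufficient for layer classification and shell-volume bookkeeping because
generator and classifier evaluate the *same* field.  Union SA/V are
estimated by scrambled-Sobol quasi-Monte-Carlo over the bounding box
(volume by indicator, area by a centred shell of half-width 0.25 Å); the
sample size grows until the replicate standard error is ≤ 0.5% of the
estimate or a cap of 8×2¹⁶ points is reached, and both estimates carry their
standard errors.

## Umbrella sampling and WHAM

**Sampler.**  Window samples are drawn by Metropolis walkers targeting
exp(−[U(r) + ½k(r−c)²]/k_BT): a batch of independent walkers (default 64)
per window, burn-in 5000 sweeps with the step size auto-tuned toward 30–50%
acceptance, production collecting every 10th sweep.  Walker count, burn-in,
stride, final step and acceptance rate are recorded in the window metadata.
Any correctly targeted sampler suffices here — the samples only exist to
validate the estimator.

**WHAM.**  The self-consistent equations are iterated in log space
(log-sum-exp) on a shared grid.  Convergence is declared when the window
free-energy constants change by less than the tolerance (default 1e−7
kJ/mol, an explicit metric for the conventional tolerance figure) between
iterations; non-convergence raises with the residual attached.  Bin width
defaults to 0.1 Å with 1.0 Å bias-center spacing (several bins of overlap
per window).  The grid divides [min sample, max sample] evenly at the width
closest to nominal: a trailing partial bin would under-count near a domain
boundary and distort the boundary free energy by ~k_BT·ln(coverage).  Empty
bins inside the sampled range are masked (NaN), never interpolated —
interpolation happens only when resampling a vacuum profile in the
water-induced decomposition.  All windows must share one temperature;
mixed-temperature input is rejected rather than silently reweighted.
Windows whose sampled ranges do not chain together raise a connectivity
error naming the gap.

Profiles are defined up to an additive constant and are pinned to zero at
the largest sampled separation (the physical zero of an interaction PMF).
When comparing a reconstruction against an analytic truth, the free constant
is removed by subtracting the mean difference before computing RMSE.

A subtlety worth recording: WHAM output is exactly invariant under window
reordering and under duplicating a *single* window, but duplicating one of
several windows double-weights that window's finite-sample histogram in the
pooled maximum-likelihood estimate, moving the converged profile at the
per-window statistical-noise scale.  The suite tests the exact case exactly
and bounds the multi-window case by that noise scale.

**Features.**  Minima are interior local minima with topographic prominence
above a threshold (default 0.5 kJ/mol, below which sampling noise at the
default problem sizes generates spurious wells), reported in position order
— rank 1 at the smallest separation is the contact minimum, rank 2 the
solvent-separated minimum.  Each barrier is the highest point between two
adjacent minima, measured above the preceding minimum, hence never
negative.  Surface ranking orders labelled water-induced profiles by
contact-minimum depth (ascending: strongest attraction first) and by first
barrier height (descending); exact ties are reported as groups, and
profiles with no detected minimum are excluded with a warning.

## Synthetic data: what it emulates, what it does not

**Water boxes** place oxygens by rejection packing at the ambient number
density 0.0334 Å⁻³ with a 2.4 Å minimum O–O distance, hydrogens at 0.96 Å
and 104.5° internal angle with uniformly random orientations.  This is a
*geometric* stand-in: correct density, excluded volume and bond geometry,
but no orientational correlations, no energetics, no dynamics.  Tests on
these fixtures therefore validate geometric bookkeeping (e.g. the wall-
truncation inequality: interfacial waters average no more H-bonds than bulk
waters, because a wall removes neighbours), not water physics; mean H-bond
counts are lower than in real water, where orientations are correlated.

**Ground-truth PMFs.**  The default validation curve is a repulsive
1/(r − 2 Å) tail carrying two Gaussian wells (depths 12 and 5 kJ/mol at 3.2
and 5.8 Å, widths 0.45 and 0.6 Å) on the domain [2.4, 13] Å — a double-well
with a contact-like and a solvent-separated-like minimum, chosen so minima
and barrier detection have known answers.  Extrema are located by
root-finding on the derivative (grid bracketing plus Brent refinement, with
exact-zero grid hits handled separately), so they are solver-precision
references.

**Association trajectories.**  A probe sphere (radius 3.5 Å, a
fullerene-scale probe) approaches a target surface — flat slab, concave
pocket (radius = depth = 4.5 Å, so the pocket wraps the probe), or convex
hemispherical bump (radius 4.5 Å) on a 36×36 Å patch — along the surface
normal through the patch centre; probe placement uses the exact geometry of
each kind (face plane, pocket wall/rim, bump cap).  The generator tracks the
capacity of the shared interfacial shell (points within one layer of the
union surface inside a fixed axial corridor) with a Sobol cloud shared
across frames, converts it to a molecule count at 0.8× ambient density (the
packing fraction achievable in a ~3 Å shell under the 2.4 Å O–O floor), and
enforces monotonicity by running minimum.  As separation shrinks, excess
"mobile" waters are relocated from the shell to the bulk region, and the
cumulative relocation count is the planted interfacial→bulk transition
count.  All waters are placed with a 0.3 Å safety margin inside their band
of the same signed-distance field the classifier uses, so
`classify_layers` reproduces the planted labels *exactly* — by construction,
not approximately.  The concave ≥ flat ≥ convex ordering of planted counts
is a geometric consequence of the construction: a pocket's shell volume is
consumed by the entering probe, a flat face loses a contact lens, a bump
only a small cap overlap.  Default schedule: separations 8 → 1 Å over 8
frames, 40 static interfacial and 80 static bulk waters outside the
corridor.

These trajectories emulate the *counting structure* of an association run —
interfacial count falling, bulk count rising, dewetting as the last layer is
expelled — not the forces that drive it.  Passing tests show the
classification, transition counting and correlation machinery is correct;
they say nothing about the free-energy surface of any real solute pair.

## Problem sizes and numerical choices

The suite's WHAM validation uses 11 windows at 1.0 Å spacing, spring
constant 15 kJ/mol/Å² (bias width ≈ 0.4 Å at 300 K, ample overlap at 1 Å
spacing); the end-to-end check draws 5×10⁴ samples per window and requires
RMSE < 0.5 kJ/mol against the analytic truth, while unit tests use
10³–10⁴ samples.  All generators are bit-reproducible from a single integer
seed via spawned seed sequences; reruns of any CLI stage with the same
config and seed produce byte-identical primary outputs.

## Known limitations

* The thermodynamic model is closed-form bookkeeping: no temperature or
  pressure dependence beyond the configured constants, no prediction of the
  constants themselves, no force-field or quantum energetics.
* Single-temperature WHAM only; no multistate reweighting, no 2-D reaction
  coordinates.  Uncertainty beyond the residual-based fit errors (e.g.
  block bootstrap over samples) is not computed by default.
* Union signed-distance fields understate distances in re-entrant corners;
  metric-accurate fields would require exact CSG distance evaluation, which
  nothing in the pipeline needs.
* Generated water has no orientational structure; absolute H-bond statistics
  on fixtures are not comparable to simulated or experimental water, only
  the geometric contrasts (wall truncation, layer membership) are.
* PMF minima positions are reported as surface-to-surface separations on
  the reconstruction grid; absolute positions tied to any external
  coordinate origin are out of scope.
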