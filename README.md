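# hydroshape

Analysis toolkit for **shape-dependent hydrophobic interactions**: how
strongly two non-polar solutes attract each other in water depends on the
curvature of the surfaces that meet — concave pockets bind a spherical probe
more strongly than flat patches, which bind more strongly than convex bumps.
The package is aimed at molecular-modelling practitioners who want the
thermodynamic bookkeeping, water-structure statistics and umbrella-sampling
analysis behind that statement as reusable, tested code, exercised entirely
on synthetic configurations with known ground truth.

## The model

Hydration of a spherical solute of radius *R* is written as a bulk term plus
an interfacial term.  Interfacial water (the top layer at the solute–water
interface) cannot form tetrahedral (DDAA) hydrogen bonds, and for a sphere
the interfacial-to-volume number ratio is 4·r<sub>H₂O</sub>/R, so

ΔG<sub>hydration</sub>(R) = ΔG<sub>water–water</sub> + ΔG<sub>DDAA</sub> · (4 r<sub>H₂O</sub>/R) · n<sub>HB</sub>,

with n<sub>HB</sub> = 2 lost bonds per interfacial molecule.  The two terms
balance at the **critical radius**

R<sub>c</sub> = 8 |ΔG<sub>DDAA</sub>| r<sub>H₂O</sub> / |ΔG<sub>water–water</sub>|,

above which solutes aggregate to minimise their surface-area-to-volume
ratio.  Aggregation is tracked by the geometric factor
γ = (SA/V)<sub>aggregate</sub> / (SA/V)<sub>separate</sub> (exactly 1 until
surfaces touch at the hydrophobic radius R<sub>H</sub>) and by the count of
water molecules expelled from the interface into the bulk, each worth
ΔG<sub>DDAA</sub>.  The water-induced part of a potential of mean force
(PMF) follows the hyperbolic decay ΔG(r) = a + γ·b/(r − r₀).

Around this model the package provides:

* **`thermo`** — the closed-form relations above, the surfactant
  packing-parameter shape rule, and least-squares fitting of the hyperbolic
  decay;
* **`hbonds` / `layers`** — geometric hydrogen-bond detection
  (R<sub>OO</sub> < 3.5 Å, ∠OOH < 30°), DDAA/DDA/DAA/DA/free local-network
  classes, interfacial/bulk partitioning against implicit (signed-distance)
  solute surfaces, and interfacial→bulk transition counting;
* **`pmf`** — self-consistent WHAM reconstruction of PMFs from harmonically
  biased umbrella windows, water-induced decomposition (total minus vacuum),
  minima/barrier location, and the transition-count correlation;
* **`synth`** — generators with planted ground truth: water-like packings,
  Metropolis-biased umbrella samples from an analytic PMF, and association
  trajectories whose interfacial→bulk transition counts are known by
  construction;
* **`hydroshape`** — a CLI exposing each stage as a subcommand with a shared
  YAML config and seeded reproducibility.

## Worked example

Critical radius from the literature constants (ΔG<sub>DDAA</sub> = −2.66
kJ/mol, ΔG<sub>water–water</sub> = −1500 cal/mol, r<sub>H₂O</sub> = 1.9 Å):

```sh
$ hydroshape thermo --out thermo.json
{"Rc_A": 6.44231994901211, "constants": {"dG_DDAA_kJ_mol": -2.66, "dG_water_water_kJ_mol": -6.276, "r_H2O_A": 1.9, "T_K": 293.0, "P_MPa": 0.1}}
```

A solute smaller than ≈6.4 Å is dominated by the interfacial term (dispersed
solutes); larger ones by the bulk term (aggregation).

Reconstruct a PMF from synthetic umbrella windows and locate its features:

```sh
$ hydroshape gen-umbrella --n-samples 20000 --out win.tsv
$ hydroshape wham --windows win.tsv --out prof.tsv
$ hydroshape features --profile prof.tsv --prominence-min 1.0 --out feat.json
```

`feat.json` reports a contact minimum near 3.41 Å, a solvent-separated
minimum near 6.02 Å, and a 3.25 kJ/mol barrier between them at 4.11 Å — the
analytic extrema of the generating double-well curve sit at 3.44 and 5.92 Å,
so the reconstruction is grid-resolution accurate.

Association of a 3.5 Å probe sphere with a concave pocket, planted
transition bookkeeping included:

```sh
$ hydroshape gen-assoc --surface concave --out-frames assoc.xyz --out-schedule sched.json
$ python -c "import json; print(json.load(open('sched.json'))['cumulative_transitions'])"
[0, 1, 2, 5, 9, 14, 20, 32]
```

As the surface-to-surface separation shrinks from 8 Å to 1 Å the interfacial
count falls (113 → 81) while the bulk count rises by the same amount; the
same run against `--surface flat` and `--surface convex` plants fewer
transitions (concave ≥ flat ≥ convex), which is the geometric origin of the
shape dependence.

## Layout

```
src/hydroshape/   library (thermo, shapes, frames, hbonds, layers, pmf, synth, io, config, cli)
tests/            pytest suite, including end-to-end acceptance checks
docs/methods.md   models, parameter choices, numerical details, limitations
scripts/          acceptance script
```
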