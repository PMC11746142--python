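# pspatools

Quantitative analysis of bacterial ESCRT-III (PspA) rod assemblies and the
membrane vesicles they remodel, from cryo-EM derived inputs.

PspA homo-oligomerizes into helical rods whose outer diameter varies in
discrete ~5 Å classes (≈180–365 Å). Each class is a helical lattice defined
by a screw operation — axial rise Δz (Å) and twist Δφ (°) per step — plus an
n-fold cyclic symmetry Cn, so the rise per asymmetric unit is Δz/n and the
mass-per-length of the polymer is

    MPL = n · m / Δz        (kDa/Å, monomer mass m = 25.3 kDa)

Rod plasticity is carried by three hinge regions of the monomer (the α2/α3
transition, the α3/α4 loop and the α4/α5 loop) and by inter-subunit residue
contacts that are either *fixed* (s.d. of Cα-distance changes across the
diameter series < 1 Å) or *switching* (> 1 Å). On the membrane side, vesicle
morphology is quantified from segmentation masks: skeletonized membranes,
perimeters, nested (double-membrane) vesicle detection with enclosure
distances, and bilayer thickness as the distance between the two leaflet
minima of the radially averaged intensity profile. ATPase activity follows

    A = Δ[Pi] / ([Protein] · Δt)        (h⁻¹)

with Δ[Pi] from a linear phosphate standard curve.

The package provides five library modules plus a CLI:

| module | contents |
| --- | --- |
| `pspatools.synthetic` | seeded generators: vesicle fields with exact ground truth, rod radial profiles, idealized helical assemblies, hinge perturbations |
| `pspatools.morphometrics` | skeletonization, closed-vesicle selection, perimeter, nesting/enclosure, bilayer thickness, summaries |
| `pspatools.helical` | radial profiles, diameter at the 0.3 intensity cutoff, leaflet radii, per-ASU rise, mass-per-length, monomer counts, lattice neighbor offsets |
| `pspatools.plasticity` | Kabsch superposition, hinge displacement angles, Cα82–Cα187 bow distance, fixed/switching contact classification, helix extent |
| `pspatools.biochem` | ATPase activity, standard curves, relative activities, Welch t-test, boxplot-style summaries |

## Worked example

```python
import numpy as np
from pspatools import helical, morphometrics as mm, synthetic

# lattice arithmetic for the 215 Å diameter class (C1, rise 2.52 Å)
sym = helical.HelicalSymmetry(n=1, rise=2.52, twist=130.2)
print(helical.per_asu_rise(sym))              # 2.52  (Å per monomer)
print(helical.mass_per_length(sym))           # 10.04 (kDa/Å)
print(helical.monomer_count(2.6, sym, sig_figs=1))  # 10000.0 monomers in a 2.6 µm rod
print(helical.local_turnover(3.0, 1000.0))    # (3000.0, 50.0)  h⁻¹ and min⁻¹

# vesicle morphometrics on a generated field with known ground truth
field = synthetic.generate_vesicle_field(60, nested_fraction=0.3, seed=2024,
                                         image_shape=(1800, 1800))
records = mm.analyze_field(field.mask, field.pixel_size, field.intensity)
summary = mm.summarize(records).summary
print(summary["n"])                           # 60
print(summary["double_membrane_fraction"])    # 0.3
print(round(summary["mean_bilayer_thickness_A"], 1))  # 38.1 (generator mean 38 Å)
```

A 100 nm mean perimeter corresponds to a mean equivalent diameter of
100/π ≈ 32 nm; the 2.6 µm rod of the 215 Å class holds ~10,000 monomers; a
3 h⁻¹ bulk ATPase rate concentrated 1,000-fold locally is 50 ATP per minute.

The same analyses are scriptable from the shell:

```sh
pspatools simulate vesicles --n 60 --nested-fraction 0.3 --seed 2024 --out-dir out/sim
pspatools morphometrics --mask out/sim/field_mask.tif --image out/sim/field_intensity.tif --out out/morph
pspatools rods mpl                   # per-ASU rise and MPL of the 11 shipped classes
pspatools run --config examples/demo.yaml   # full pipeline with manifest
```

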