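# osteogeom

Automated cross-sectional geometry analysis of long-bone diaphyses.

Given a watertight triangle mesh of a femur-like bone (STL) plus three
anatomical landmarks, the pipeline cleans, decimates (default 20,000 faces)
and orients the mesh, extracts 60 evenly spaced cross-sections between 20%
and 80% of the biomechanical length, places 21 equiangular semilandmarks on
the periosteal and endosteal contour of every section, and computes the full
beam-theory property set per section (areas, perimeters, cortical thickness,
second moments of area, principal moments, section moduli, polar quantities).
Cohort-level tooling compares healthy against osteoporotic groups per
property and location and maps regional cortical thinning.

Because real CT-derived specimens are not distributable, the package ships a
first-class synthetic bone generator: tubular phantoms with elliptical
periosteal/endosteal profiles whose section properties have closed forms,
including an osteoporosis mode (uniform medullary expansion, or regional
anterior/lateral thinning of the distal diaphysis). Every pipeline stage is
validated against this analytic ground truth and against an independent
grid-quadrature oracle.

## CLI

```sh
# 1. simulate a cohort (STL + landmark sidecars + analytic ground truth)
osteogeom simulate --out data/sim --seed 1 --n-healthy 15 --n-osteo 15 \
    --variation 0.05 --ca-ratio 0.70

# 2. process every specimen (clean -> decimate -> orient -> section -> properties)
osteogeom process --in data/sim --out data/proc

# 3. group comparisons, headline summary, regional thickness contrast
osteogeom compare --in data/proc --out data/results
```

All commands accept `--config <yaml>` (see `RunConfig`) and `--seed`; every
output CSV embeds the package version and a hash of the effective
configuration, and reruns with the same inputs are byte-identical.

## Conventions

* Anatomical frame: +z proximal along the long axis, +x mediolateral
  (towards the lateral condyle), +y anteroposterior; origin at the condyle
  midpoint. Sampling levels are fractions of biomechanical length from the
  distal origin.
* Semilandmark rays: angle `2*pi*k / n` from +x, counterclockwise, origin at
  the medullary-cavity centroid. Thickness on a ray spans from the nearest
  endosteal crossing to the farthest periosteal crossing.
* Moments are about the cortical-region area centroid, axes parallel to
  x/y; `theta` is the major-principal-axis angle folded into (-pi/4, pi/4].

## Per-section data dictionary (`*.properties.csv`)

| column | units | meaning |
| --- | --- | --- |
| `level_fraction` | – | section position as a fraction of biomechanical length (distal origin) |
| `z_height` | mm | section plane height in the anatomical frame |
| `total_area` / `medullary_area` / `cortical_area` | mm² | periosteal area / endosteal area / their difference |
| `periosteal_perimeter`, `endosteal_perimeter` | mm | contour lengths |
| `thickness_min`, `thickness_mean`, `thickness_max` | mm | per-ray cortical thickness statistics (21 rays) |
| `centroid_x`, `centroid_y` | mm | cortical-region centroid in the section plane |
| `Ix`, `Iy`, `Ixy` | mm⁴ | second moments about centroidal x/y axes |
| `Imin`, `Imax` | mm⁴ | principal moments |
| `J` | mm⁴ | polar moment, `Ix + Iy` |
| `theta` | rad | major principal axis angle from +x |
| `dx`, `dy` | mm | max outer-fibre distances from the y/x axes |
| `dx_theta`, `dy_theta` | mm | same after rotating by `-theta` |
| `rmax` | mm | max radial distance, centroid to periosteal contour |
| `Zx`, `Zy` | mm³ | section moduli `Ix/dy`, `Iy/dx` |
| `Zmin`, `Zmax` | mm³ | `Imin/dx_theta`, `Imax/dy_theta` |
| `Zpol` | mm³ | polar section modulus `J/rmax` |
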