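# scaffoldmech

Desk-scale design and mechanoregulation analysis of 0/90 strand-lattice
hydrogel scaffolds under dynamic compression.

Extrusion-printed (direct-ink-writing, DIW) hydrogel scaffolds for cartilage
tissue engineering are cultured under cyclic compression: the seeded cells
on the strand surfaces feel both the solid deformation of the lattice and
the shear of the culture medium squeezed through the pores.  Which tissue
the cells are predicted to form depends on the combined biophysical
stimulus

```
S = OSS / a + WSS / b ,        a = 0.0375 ,  b = 10 mPa
```

where `OSS = (2/3) sqrt((e1-e2)^2 + (e2-e3)^2 + (e3-e1)^2)` is the
octahedral shear strain of the scaffold surface (from the elastic principal
strains `e_i`) and `WSS = mu du/dn` is the fluid wall shear stress.  The
stimulus maps to predicted phenotypes by fixed intervals (upper bounds
inclusive): `S <= 0.01` very low stimulus, `(0.01, 1]` bone, `(1, 3]`
cartilage, `(3, 6]` fibrous tissue, `S > 6` very high stimulus.

The package provides, as importable modules and a thin CLI:

* **geometry** — parametric strand lattices in a cylindrical envelope
  (default 10 mm x 4.8 mm, 700 um strands), voxel/Monte-Carlo porosity,
  minimal equivalent pore diameter `D_pore = 2 (Y - D_strand) / sqrt(pi)`,
  STL/VTK surface export;
* **mechanics** — one-term Ogden hydrogel (`mu_1 = -5.8 kPa`,
  `alpha_1 = -1.3`, incompressible), octahedral shear strain, and the
  single raised-cosine compression cycle (1 Hz, 5 % amplitude);
* **synthetic_fields** — a calibrated reduced-order surrogate that emits
  conformal per-node OSS/WSS surface fields over the cycle in place of a
  transient FE/CFD co-simulation (strain concentrated at strand
  junctions, WSS driven by the squeeze-flow pore velocity, seeded
  lognormal heterogeneity);
* **mechanoreg** — surface-average stimulus curves, the compression- and
  release-phase maxima `S_Max1`/`S_Max2`, per-node phenotype maps at the
  `S_Max2` time, area-weighted phenotype percentages and design deltas;
* **design_sweep** — the two-step modification strategy: vary the strands
  per layer (porosity sweep), then rescale the selected design at constant
  porosity and envelope (pore-size sweep, `N_H = N_V`), with the
  one-percentage-point stopping rule on cartilage improvement.

## Worked example

A minimal configuration (`demo.yaml`):

```yaml
designs:
  - {name: S0-H7-V9}
seed: 1
sweep: {nh_range: [6, 10], reference: S0-H7-V9}
```

```
$ scaffoldmech design --spec demo.yaml
S0-H7-V9: porosity 51.8 %  D_pore 827 um  D_strand 700 um  Y 1.433 mm  h 0.533 mm

$ scaffoldmech sweep --config demo.yaml --out sweep.json
6-design report written to sweep.json; selected S1-H8-V9

$ scaffoldmech report --sweep-json sweep.json
design            poro%  Dpore   very_low      bone cartilage   fibrous very_high
S0-H7-V9           51.8    827       0.00     15.09     84.73      0.18      0.00
S1-H6-V9           59.1   1151       0.00     27.23     72.76      0.01      0.00
S1-H7-V9           51.8    827       0.00     15.09     84.73      0.18      0.00
S1-H8-V9           44.8    596       0.00      6.75     92.05      1.20      0.00
S1-H9-V9           37.7    423       0.00      1.96     91.46      6.57      0.00
S1-H10-V9          31.1    288       0.00      0.09     79.75     20.15      0.01
reference: S0-H7-V9  selected: S1-H8-V9
```

Reading the table: removing a strand per layer (H6) raises porosity to
59 % and shifts the surface toward bone differentiation; adding strands
lowers porosity, strengthens both the junction strain concentrations and
the pore shear stress, and moves the surface through the cartilage window
into fibrous territory (20 % of the H10 surface exceeds `S = 3`).  The
sweep selects the design with the largest cartilage area whose successor
improves it by less than one percentage point.

`scaffoldmech fields` writes the per-node OSS/WSS CSV for a design, and
`scaffoldmech stimulate` scores any nodal field CSV matching that schema
(including a real solver export) into a phenotype map and summary.

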