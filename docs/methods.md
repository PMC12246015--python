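# Methods

## Scope and model overview

`scaffoldmech` analyses 0/90 strand-lattice hydrogel scaffolds under a
single cycle of dynamic compression and predicts the tissue phenotype
distribution on the strand surfaces from a two-channel mechanoregulation
stimulus.  The full fluid–structure co-simulation that such an analysis
normally requires is replaced by a calibrated reduced-order surrogate for
the two surface fields; everything upstream (lattice geometry, porosity,
pore metrics, material law, loading kinematics) and downstream (stimulus
scoring, phenotype mapping, design sweep) is computed exactly as defined
below.

## Lattice geometry

A design is `N_V` horizontal layers of `N_H` parallel cylindrical strands
(diameter `D_strand`) inside a cylindrical envelope (`D_scaffold` x
`H_scaffold`, defaults 10 mm x 4.8 mm with 700 um strands).  Layers
alternate between 0° and 90°; same-orientation layers are laterally
aligned.  Strands are chords clipped to the envelope circle; zero-length
(tangent) chords are dropped.

Span conventions (overridable per design via `Y_mm` / `h_mm`):

* horizontal `Y = (D_scaffold − 2 D_strand) / (N_H − 1)`: the outermost
  strand centers are inset one strand diameter from the envelope, a
  printing margin of half a strand diameter at the rim.  Among the simple
  closed-form span rules this is the one that reproduces the porosity
  series of the study designs (see limitations);
* vertical `h = H_scaffold / N_V`: layers repeat at a uniform period, the
  stack is height-centred, and the outermost strand surfaces protrude by
  `(D_strand − h)/2` and are trimmed by the envelope.  Adjacent layers
  interpenetrate by `D_strand − h`, as fused extruded strands do.

**Porosity** is `1 − V_solid / (π R² H)` with `V_solid` the volume of the
union of clipped cylinders, interpenetration counted once.  The default
estimator voxelises at 25 um (axis-aligned strands let the 3-D occupancy
factorise into two 2-D section masks and one integer matrix product, so a
25 um grid costs milliseconds); a seeded Monte-Carlo sampler is available
as a cross-check.  The reported standard error is the change against a
2x-coarser grid (voxel) or the binomial error (Monte Carlo).  Voxel edges
commensurate with the strand radius can align the cylinder boundary with
whole lattice rows (a Gauss-circle artifact, worth ~0.5 % of volume in the
worst case); the defaults used for the study designs do not sit in such a
degenerate alignment, and the porosity values change by < 0.3 percentage
points under grid halving.

**Minimal equivalent pore diameter.**  In axial projection two parallel
strands of one layer and two orthogonal strands of the next bound a square
window of side `Y − D_strand`; `D_pore = 2 (Y − D_strand)/sqrt(π)` is the
diameter of the equal-area circle.  No corner-rounding correction is
applied.

## Material and loading

The hydrogel (oxidised alginate–gelatin) is a one-term incompressible
Ogden solid, `mu_1 = −5.8 kPa`, `alpha_1 = −1.3`, `d_1 = 0` treated as the
incompressibility sentinel (volumetric term omitted).  The closed-form
uniaxial nominal stress `P = Σ mu_i (λ^{a_i−1} − λ^{−a_i/2−1})` is
verified in the tests against the numerical derivative of the strain
energy.

Loading is one raised-cosine compression cycle,
`d(t) = A/2 (1 − cos 2π f t)` with `f = 1 Hz` and `A = 5 %` of the
scaffold height: displacement and velocity vanish at `t = 0`, peak
compression (0.24 mm) occurs at `t = 0.5 s`, and the release phase mirrors
the compression phase.  "Amplitude" is read as peak compression, not
peak-to-peak.  The published loading figure shows this single
compression–release shape but not its equation; the raised cosine is our
choice.  Default sampling is 0.01 s (101 samples per cycle).

## Synthetic surface fields (the solver surrogate)

`surface_mesh` samples the strand lateral surfaces quasi-uniformly
(`~10^4` nodes by default), assigns each node the area weight
(strand area / nodes on strand), and scores junction proximity
`exp(−dist to nearest strand crossing / D_strand)`.  The identical node
set and weights back both fields — the conformal contract that makes
per-node stimulus evaluation possible.

Solid channel:

```
OSS_node(t) = c(t) · T · (1 + A_j · junction) · ε_node ,
```

with `c(t)` the instantaneous compression fraction, `T` the strain
transfer factor, `A_j` the junction amplification and `ε_node` frozen
unit-mean lognormal noise (σ = 0.2).  The surface mean is exactly linear
in compression and peaks at `t = 0.5 s`.

Fluid channel: the piston expels fluid through the open pore fraction at
superficial velocity `u = v_piston / porosity`; wall stress in a pore
channel grows with `u` and the inverse pore diameter (Poiseuille:
`8 μ u / D_pore`).  The per-design peak is the calibrated power law

```
WSS_peak = g · (μ/μ_ref) · u^p · D_pore^−q      [mPa, u in mm/s, D_pore in mm]
```

and the nodal field scales it by `|v(t)|/v_peak`, an interior-attenuation
pattern `exp(−depth/λ)` with `λ = 1 mm / porosity` (denser lattices
develop flow deeper into the pore network) normalised to unit
area-weighted mean, and frozen noise.  The field is linear in piston
speed and zero at rest.

**Calibration (done once, then frozen; all values live in
`SurrogateParams` and are config-overridable).**  The four reference peak
WSS averages of the extreme step-1 and step-2 designs give
`g = 6.6931 mPa`, `p = 0.4295`, `q = 0.4833` by least squares (reproduced
within 5 %).  For the solid channel the junction-score contrast between
the widest- and narrowest-span designs saturates below the reference peak
OSS ratio, so an exact two-point solve does not exist; `A_j = 8` is fixed
near the saturation knee and `T = 0.14755` is the log-midpoint match,
bracketing the reference peaks within ~10 % while preserving their strict
increase with strand count.

What the surrogate does **not** emulate: the release-phase asymmetry of
the real coupled solution (its WSS peak is symmetric at the two
half-cycle speed maxima, so `S_Max2` equals `S_Max1` and falls in the
release phase only by the late-tie rule); pore-scale flow structures;
strain-field details beyond junction concentration; and the small
pore-size dependence of strain at constant porosity — junction scores are
relative to `D_strand`, so geometric rescaling leaves the step-2 OSS
nearly unchanged (~+1 % instead of a mid-single-digit increase).  Passing
trend tests therefore demonstrate the scoring and sweep machinery on
fields with realistic structure, not solver fidelity.

## Mechanoregulation scoring

`S = OSS/a + WSS/b` with `a = 0.0375`, `b = 10 mPa`.  Phenotype intervals
(upper bounds inclusive): very-low `≤ 0.01`, bone `(0.01, 1]`, cartilage
`(1, 3]`, fibrous `(3, 6]`, very-high `> 6`.

The average curve `S_avg(t)` applies the stimulus to the arithmetic mean
of OSS over all surface nodes and the area-weighted mean of WSS (the
curve is the stimulus *of the averages*; per-node maps use per-node
values).  `S_Max1`/`S_Max2` are the maxima on `[0, T/2)` and `[T/2, T)`,
ties broken toward the later time.  Phenotype maps and percentages are
evaluated at the `S_Max2` time; contribution shares split `S` into its
OSS and WSS terms there.

## Design sweep

Step 1 varies `N_H` (default 6–10) at fixed `N_V`, `D_strand`, `h`.
Step 2 freezes the ratios `x1 = h/D_strand` and `x2 = Y/D_strand` of the
selected design, sets `N_H = N_V` (the constant coupling the two counts),
and for each `N_V` solves `H = N_V · x1 · D_strand` — pure geometric
rescaling at fixed envelope, so porosity is preserved (within 0.2
percentage points in practice, 2 points enforced) and applying step 2
with the base `N_V` reproduces the base exactly.  Default variant set
`{N_V−1, N_V+1, N_V+2}`; strand diameters outside the printable 500–800 um
window are excluded with a logged reason.  The full-factorial enumeration
(all step-1 bases x 3 variants = 15 designs) is provided for the
combinatorial count.

Selection walks the results in order and replaces the incumbent only when
the criterion (cartilage surface %) improves by at least one percentage
point; a smaller improvement records a stop and keeps the earlier,
simpler design.

Each design in a sweep gets a deterministic seed derived from the sweep
seed and the design name (kept below 2^31), so reports are reproducible
and order-independent.

## Numerical and interface choices

* Units: mm, s, kPa (solid), mPa (WSS), strains dimensionless; `D_pore`
  reported in um.  WSS is stored in mPa to match `b`.
* Nodal field CSV schema `scaffoldmech-fields-v1`: columns `node_id, x_mm,
  y_mm, z_mm, area_mm2, t_s, oss, wss_mpa`, header comments carrying the
  design name, seed and parameter hash; any solver export matching it can
  be scored with `scaffoldmech stimulate`.
* Outputs embed the config hash; reruns refuse to overwrite without
  `--force`.  Unknown config keys are rejected; a seed is mandatory for
  stochastic stages.
* Node matching uses a KD-tree with 1e-6 mm tolerance and fails listing
  the offending nodes.

## Problem sizes

The shipped defaults — 25 um voxels (~3 x 10^7 cells, evaluated via the
factorised 2-D masks), 10^4 surface nodes, 101 time samples, 8-design
sweeps — were chosen so a full sweep completes in seconds on one CPU while
porosity is converged to well under half a percentage point.

## Known limitations

* The exact span table and span/pore closed forms of the original study
  are in its supplementary material only; the inset span rule used here
  reproduces three of the four published porosities to the printed percent
  (59 vs 60 % for the widest-span design) but yields step-2 pore diameters
  of 476/346 um against the published 510/380 um.  No single self-
  consistent scaling reproduces both published pore diameters together
  with the published strand diameters (their printed ratios disagree), so
  the geometry keeps the convention that matches porosity and the strand
  diameters and documents the discrepancy rather than special-casing it.
* Single cycle only; no viscoelasticity, no neo-tissue growth, no
  two-way coupling, no mass transport.
* Phenotype percentages depend on the surrogate's spatial stimulus
  distribution and are indicative only; the package's quantitative claims
  are the geometry metrics, the kinematics, the scoring identities and
  the monotone design trends.
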