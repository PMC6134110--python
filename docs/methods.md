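# Methods

## Scope and model

`memtilt` analyses trajectories of a membrane-embedded receptor dimer under
three assumptions: an orthorhombic periodic box, a membrane normal along the
laboratory z axis, and coordinates in nanometres (PDB input is converted from
ångströms on read). Within that scope it computes the dimer's tilt
decomposition, inter-selection contact counts, 1-D electrostatic-potential
profiles, lipid order and thickness, and block-averaged uncertainties.

## Tilt decomposition

The extracellular-domain orientation is reduced to three centroid-based unit
vectors per frame: V1 from the membrane-proximal to the membrane-distal
marker centroid (the long axis), V2 the monomer-A → monomer-B centroid
direction orthogonalised against V1 (the "face" axis), and V3 = V1 × V2.
The marker groups are supplied as atom selections; for real data the user
must state them explicitly, for synthetic data the generator provides them.

With u = V1 in the frame (x, y, n) — n the membrane normal, x the *first
frame's* V2 projected into the membrane plane, y = n × x — the angles are

    overall = arccos|u·n|,  lateral = atan2(u_x, u_n),  forward = atan2(u_y, u_n),

reported in degrees. Fixing x from frame 0 rather than co-rotating it is
deliberate: a co-rotating reference would absorb the tilt it is meant to
measure. The definitions force tan²(overall) = tan²(lateral) + tan²(forward)
on every frame, which the tests assert to 1e-6 relative tolerance. Lateral
and forward are signed; an absolute-value reporting mode exists for
comparison with unsigned published traces. If u lies exactly in the membrane
plane the angles saturate at ±90° and are flagged.

Angle distributions are histogrammed over the trailing fraction of each run
(default 0.5, emulating analysing the last half of a production run),
normalised per run to unit integral, then averaged bin-wise across runs so
each replicate carries equal weight. Default bin width 1°, range auto-fit.

## Contacts

A contact is a pair of atoms, one per selection, with minimum-image distance
≤ cutoff (default 0.6 nm). Ties at exactly the cutoff count (closed
interval) — one convention had to be fixed for exact oracle equality, and
published definitions rarely state it. Atom pairs, not residue pairs, are
counted; hydrogens participate unless excluded by the selection. The
production algorithm is a cell-list search (cells ≥ cutoff, 27-stencil,
falling back to all-pairs when a periodic dimension has fewer than three
cells); it shares its minimum-image arithmetic with the brute-force
all-pairs counter, so the two agree exactly, and a periodic KD-tree provides
a second independent cross-check in the tests. The cutoff must be below half
the smallest box edge when periodic.

## Electrostatic potential

Charges (units of e) are wrapped into the box and histogrammed along z into
ρ(z) in e/nm³, averaged over frames (the box must be constant across the
averaged frames). The potential follows from two cumulative trapezoidal
integrations, ψ(z) = −(1/ε₀)∬ρ, referenced to ψ = dψ/dz = 0 at the lower box
edge (bulk-water side). No implicit dielectric is applied: in an all-atom
setting the explicit solvent carries the screening. The unit constant is
e/(ε₀·nm) = 18.0951 V. Discretizing an ideal charge sheet into one bin
reproduces the far-field potential step σd/ε₀ exactly when sheets sit on bin
centers; generic placement converges at first order in the bin width, and
the tests require < 1% change on halving the bin. `potential_contrast`
compares mean |ψ| between two profiles over an explicit z region — the
averaging region is a required argument because "X% more electronegative"
claims are meaningless without one. A `--symmetrize` option averages ψ(z)
with ψ(−z) for symmetric membranes.

## Bilayer order and thickness

Order parameters S = ⟨(3cos²θ − 1)/2⟩ are averaged over lipids and frames
per carbon position. The default mode uses C(i−1)→C(i+1) skeleton vectors
("cc"), usable without explicit hydrogens; the C–H ("cd", deuterium) mode
takes a carbon→hydrogens map. Any user-supplied ordered atom list is a
"chain", which also covers backbone-style definitions. Thickness is the
separation of mean phosphate z positions of the two leaflets, assigned per
frame by the sign of z relative to the selection's (mass-weighted when
available) mean; sign changes relative to frame 0 are logged as flips, never
silently reassigned.

## Block averaging

For block size b, EE(b) = SD(⌊n/b⌋ consecutive block means, ddof 1)/√n_blocks.
The summary EE is the maximum EE(b) over block sizes retaining ≥ 10 blocks:
the classical plateau criterion involves judgement, and the maximum is a
conservative, deterministic substitute. The default ladder is powers of two
from 1 to n/10. Replicate runs are combined as mean of run means with EE =
SD(run means)/√n_runs; a single run keeps its own EE and is flagged. An AR(1)
process with φ = 0.9 and unit marginal variance has SD of the mean
√((1+φ)/(1−φ))/√n ≈ 4.36×10⁻²·√(10⁴/n)/10 — the analytic oracle used in the
tests at 30% tolerance (block-averaged EEs scatter with roughly χ² spread).

## Synthetic fixtures

The generators define the test conditions; they are geometric constructions,
not simulations.

* **Dimer.** A rigid two-lobe body (marker rings defining the proximal and
  distal centroids 6 nm apart, monomer axes 3 nm apart) is rotated each
  frame about the proximal centroid to a scheduled tilt plus Gaussian noise
  (default SD 2°, the order of frame-to-frame angular fluctuation seen in
  stable stretches of real runs). The tilt azimuth defaults to "forward"
  (perpendicular to the inter-monomer axis), matching the component that
  distinguishes the scenarios being emulated. Engineered inter-monomer
  contact pairs sit on a sparse grid (spacing 1.3 nm) at 0.55 nm separation,
  rigid under rotation, so the contact series is exactly constant.
  Protein–membrane pairs are static by construction (they do not follow the
  schedule) so their count stays exact; an optional mode lowers the pivot as
  the scheduled tilt grows, letting a collapsing domain approach the lipid
  slab. The four presets (tilts 33/15/57/19°, contacts 337/165/322/187,
  runs 3/3/3/1) mirror the reference scenarios' reported levels.
* **Bilayer.** Pseudo-lipids on a grid (0.8 nm spacing), phosphate markers
  at ±separation/2 (default 4.8 nm) and straight chains descending along
  directions drawn from a von Mises–Fisher distribution about the inward
  normal. The vMF moment E[cos²θ] = 1 − 2coth(κ)/κ + 2/κ² gives the analytic
  order parameter; κ = 20 by default (S ≈ 0.86, a liquid-ordered level).
  Default leaflet composition 45/25/10/20 mol% CHOL/SM/GCER/PC; every
  pseudo-lipid carries a P marker regardless of species — the fixture is
  geometric, and species labels only exercise selection logic.
* **Charge sheets.** Each sheet becomes a grid of equal point charges; the
  closed-form ψ(z) = −(1/ε₀)Σσᵢ(z − zᵢ)₊ is emitted alongside.
* **AR(1).** Unit-marginal-variance series with the analytic standard error
  of the mean attached.

What the fixtures do **not** emulate: conformational flexibility (the dimer
is rigid, so angle distributions are unimodally narrow), lipid diffusion and
undulations, solvent and ionic screening, or any energetics. Passing tests
therefore demonstrate the correctness of the measurement pipeline, not the
physics of any particular system.

## Numerical choices and problem sizes

All randomness flows through `numpy.random.default_rng` seeded per task;
derived sub-seeds stay below 2³¹, and generators are bit-reproducible.
Analyses use float64 throughout; degenerate geometry (coincident centroids,
zero-norm bonds) raises rather than returning NaN. Default problem sizes —
200-frame runs, 100–200 lipids per leaflet, 200 z-bins, 10⁵-point AR(1)
series — were chosen so the whole pipeline and test suite run in minutes on
one CPU while keeping sampling errors an order of magnitude below the
tolerances asserted.

## Known limitations

Orthorhombic boxes only (triclinic input is rejected); GRO files do not
carry segment ids, so selections on round-tripped GRO must use residue
names; charge input rides on the in-memory topology or a plain text file,
not on the coordinate formats; no SASA, per-residue contact maps,
area-per-lipid, or 3-D Poisson–Boltzmann — these are out of scope.
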