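# Methods

This note records the models implemented in `ktrkit`, the defaults and
units that matter, the design choices made where the problem was genuinely
open, and what the synthetic generators do and do not emulate.

## Coordinate and unit conventions

Coordinates are ångström everywhere inside the package. DEER distances and
ring diameters are reported in nanometre, matching the conventions of the
EPR and EM communities; the conversion happens only at the reporting
boundary. Times are ns (trajectory labelling), µs (DEER), min (uptake);
temperatures °C; concentrations µM (ITC) or mM (kinetics).

## Trajectory observables (`contacts`)

**Native-contact fraction.** Q uses the logistic switching form with
smoothing β = 5 Å⁻¹ and padding λ = 1.5 over heavy-atom pairs closer than
4.5 Å in the reference frame (frame 0 by default), pairing the IDR
residues 7–13 against the regulator-surface ("partner") segment. The
logistic never reaches 0 or 1, so Q is strictly inside (0, 1). In the
reference frame itself each pair contributes 1/(1 + e^(−0.5 β r⁰)); at
contact distances around 4 Å the exponent is ≤ −10, so the reference
frame's Q exceeds 0.95 by a wide margin.

**Lipid contacts.** A residue and a lipid molecule are in contact when any
heavy-atom pair is within 3.5 Å; the pair counts once per frame no matter
how many atom pairs qualify. The reported series is the total over the
selection; per-residue means are returned alongside.

**Membrane distance.** The reference point of a residue is its heavy-atom
centroid (the underlying data are one-bead-per-residue anyway; a named
atom can be selected for imported all-atom data). z = 0 is the mean
phosphate position of the *proximal* leaflet — the leaflet whose mean z is
nearest the selection — because the IDR approaches the membrane from the
cytosolic side only. Negative z is below the plane.

**Terminus length** is the end-to-end distance between the reference
points of the first and last residues of the range. End-to-end (rather
than contour) length was chosen because the quantity is used as a
conformational-spread indicator, and end-to-end distance is the common
choice for that; this is an operational choice the source data would also
admit differently.

Distances use no periodic wrapping: the toy systems are non-periodic.
All pairwise operations are plain dense computations (trajectories here
are hundreds of particles); they are verified against O(n²) brute-force
oracles in the tests, so any later acceleration must not change results.

## Pore profiling (`pore`)

At each z the pore radius is the largest clearance
max_c min_i (|c − x_i| − vdW_i) over in-plane probe centers c in a search
box around the axis, clamped to [0, r_max] (default 10 Å). The
maximization is a coarse grid (0.25 Å) followed by Nelder–Mead
refinement confined to the box. This 2D-per-slice scan reproduces the
radius-vs-z curve of near-axial channels; it is *not* HOLE's 3D
Monte-Carlo path search, and the default Bondi radii differ slightly from
HOLE's radius set, so absolute constriction sizes on real structures can
differ at the 0.1 Å level. The search half-width defaults to 2.5 Å: wide
enough to follow a modestly drifting lumen, narrow enough that the probe
cannot escape sideways around a thin wall section (the failure mode of
per-slice scans). Reported "diameter" is 2×radius. Ties in the minimum
constriction resolve to the smallest z.

## Shape classification (`shapes`)

Class averages are smoothed (Gaussian, σ = 1 px), binarized with a global
Otsu threshold (class averages are high-contrast single objects), reduced
to the largest connected component, and the ring lumen is filled before
measuring. Filling matters: the second moments of an annulus are larger
than those of the filled ellipse with the same outer boundary, so moment
axes of the unfilled ring would overestimate the outer diameters. With the
filled object, the equivalent-ellipse major/minor axis lengths equal the
outer diameters exactly in the continuum limit; discretization keeps the
error well under one pixel. Feret calipers are available as an option.

The oval/square call compares long/short to the fixed threshold 1.115.
The threshold rule defines strict "less than" as square and "more than"
as oval without naming equality; equality is assigned to oval (a closed
upper set), which only affects ratios exactly at the boundary.

## Biophysical fits (`fits`)

**DSF.** Tm is the argmax of the first derivative of the
Savitzky–Golay-smoothed curve (window 5 points, quadratic — on the 1 °C
acquisition grid this is mild smoothing that leaves a noiseless logistic's
peak position unchanged), refined by parabolic interpolation through the
discrete peak. The estimate is invariant under positive affine transforms
of the fluorescence. A curve whose derivative is nowhere positive raises a
no-transition error rather than returning a number.

**ITC.** Per-injection heats follow the single-site (Wiseman) model with
perfusion dilution: injecting v µL into the fixed cell volume V₀ updates
total concentrations by C → C_in + (C − C_in)·e^(−v/V₀); the bound complex
solves the binding quadratic exactly; the heat of injection i is
ΔH·V₀·(MX_i − MX_{i−1}e^(−v/V₀)) normalized per mole injectant. The same
forward model generates synthetic thermograms and serves as the fit
residual, so noiseless round trips are exact by construction — which is
precisely what the round-trip tests are meant to certify about the solver,
not about the model. The fit optimizes log K_D (conditioning), ΔH and n by
Levenberg–Marquardt from a small ladder of K_D starts; near-zero total
heat raises a degenerate-fit error. Standard defaults mirror a 20 × 2 µL
titration into a 280 µL cell (60 µM sites, 800 µM syringe).

**Uptake kinetics.** Initial velocities are OLS slopes over the early
window (points before 50% of the plateau rise or the first 4 points,
whichever is smaller; sampling defaults 1, 2, 3, 4, 7, 10 min). The
Michaelis–Menten fit is unweighted nonlinear least squares of
Y = V_max·X/(K_M + X) (inverse-variance weighting optional); a K_M
estimate collapsing more than three orders of magnitude below the lowest
substrate level is flagged as a boundary fit (saturated data).

## DEER (`deer`)

The kernel is evaluated in closed form through Fresnel integrals,
K = √(π/6φ)[cos φ·C(z) + sin φ·S(z)] with φ = ω_dd t, z = √(6φ/π) — exact
and cheaper than numerical quadrature; the tests verify it against
adaptive quadrature to 10⁻⁶. The dipolar constant 52.04 MHz·nm³ is the
standard free-electron value.

Background correction fits log V linearly in t^(d/3) over the trace tail
(default: the second half), giving the stretched-exponential rate k and
the modulation depth Δ = 1 − e^intercept; F = (V/B − (1 − Δ))/Δ is
normalized to F(0) = 1. A trace with Δ ≈ 0 has no defined form factor and
is rejected. The tail of the intramolecular signal is not exactly constant
(the kernel's powder oscillation decays only as t^(−1/2)), so k and Δ
carry a small bias that shrinks with longer traces; for the default 3 µs
traces the bias is within a few percent and does not move distribution
modes by more than the grid step.

Inversion solves the non-negative Tikhonov problem per α by NNLS on the
stacked system [K; αL], with L the second-difference operator and the
kernel columns carrying trapezoid quadrature weights. The α ladder is
10⁻³–10³, 61 log-spaced points (validated to span ≥ 4 decades with ≥ 3
points); the corner is the most negative signed curvature of the
(log ρ, log η) curve traversed with increasing α — with this
parametrization the corner is a clockwise bend for both noisy and
noiseless data, whereas the noiseless L-curve has no positive-curvature
corner at all. Ladder endpoints are excluded (one-sided derivative
artifacts). The returned distribution is renormalized to unit trapezoid
integral; mode, mean and central-95% width are reported, the mode refined
parabolically. Error bands in the style of background-variation envelopes
are out of scope; the report carries the background parameters so a
jackknife over fit windows can be scripted externally.

## Synthetic generators (`synthetic`)

All generators take an explicit seed and use their own `default_rng`
stream, so outputs are bit-identical for identical parameters and adding
one generator call cannot shift another's stream. Noise σ = 0 gives
deterministic output.

**Toy trajectory.** One bead per residue (bond length 3.8 Å), because the
contact statistics depend only on inter-particle distances, not
chemistry. The tail numbers residues 2–21 (default length 20) with the
hydrophobic patch at 9–13 and the basic cluster at 16/17/19/21; both
groups are "tagged" and feel the membrane attraction. The membrane is two
phosphate-bead leaflets 38 Å apart on a 4 Å grid (80 Å across) with acyl
beads between; each grid site is one lipid molecule, and its charge
character stands in for a 45% POPE / 40% POPG / 15% cardiolipin leaflet in
the single attraction parameter rather than in per-species detail. Frame 0
is a docked reference pose lying along the partner patch (4 Å away, so
residues 7–13 define native contacts); each further frame is an
*independent* tethered chain growth — a fresh biased random walk from the
anchor 30 Å below the plane — rather than a time-correlated walk. The
per-step Metropolis filter accepts moves against the attraction
U = a·depth/bond with probability e^(−ΔU), where the effective a for the
step placing bead k is the overall affinity scaled by the fraction of
tagged beads at or beyond k (tether tension); beads reflect at the
phosphate plane. Independent frames make per-frame contact statistics
i.i.d., which the monotonicity sign tests rely on; the cost is that the
generator cannot emulate autocorrelation times. With affinity 0 the tail
touches the membrane in <5% of frames; with affinity 50 in >90%.

What the toy trajectories do *not* emulate: force-field energetics,
secondary structure, lipid diffusion and order parameters, periodic
boundaries, or microsecond autocorrelation. Tests passing on them certify
the *analysis* code (cutoffs, counting rules, invariances), not any
biophysical conclusion about real trajectories.

**Melt curves** are logistic between two baselines — any two-state form
with an inflection at Tm would do for a derivative-peak extractor — on the
25–80 °C, 1 °C grid; transition width 2 °C.

**Uptake courses** rise exactly linearly at the Michaelis–Menten velocity
through the 4-min early window and then relax C¹-continuously toward a
plateau at 1.5× the linear rise, so the OLS initial-velocity stage is
exact on noiseless data and the full pipeline round trip is machine-precision.

**Class images** are elliptical rings rendered 4× supersampled and
block-averaged, so edges carry partial-volume intensities like real class
averages; ground-truth axes, angle and ring thickness ride along in the
metadata. Default geometry: 7.8 × 6.3 nm outer axes, 1 nm ring, 0.05
nm/px, 220 px.

**DEER traces** are V(t) = [(1 − Δ) + Δ·F(t)]·e^(−kt^(d/3)) with Δ = 0.3,
k = 0.05 µs⁻¹, d = 3, t ≤ 3 µs at 8 ns steps; additive Gaussian noise
spares t = 0 so V(0) = 1 exactly.

## Problem sizes

The defaults were chosen as the smallest sizes at which every estimator is
comfortably inside its tolerance: 60–200 trajectory frames with ~1800
particles, 56-point melt curves, 20-injection thermograms, 4 substrate
levels × 6 timepoints, 220 px images, 376-point DEER traces on a 326-point
distance grid with a 61-point α ladder. The complete test suite and the
acceptance script each run in well under a minute on one CPU.

## Known limitations

* The pore scan is per-slice 2D; strongly tilted or branched channels
  need an explicit axis or a true 3D path search.
* The DEER background fit window is a fixed fraction of the trace;
  datasets with very long-period oscillations need a manual window.
* The ITC model assumes one independent site class; cooperative octamer
  binding is deliberately out of scope.
* Shape measurement assumes one ring per image (largest component wins);
  crowded montages must be split upstream.
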