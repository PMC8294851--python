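# Methods

`fusepore` has two halves: an analysis pipeline for single fusion-pore
conductance recordings (with a synthetic-recording generator standing in
for raw patch-clamp data), and an equilibrium mechanical model of how
SNARE proteins and the Synaptotagmin-1 C2B domain dilate a fusion pore
when calcium is added.  This note records the models, the parameter
choices, the numerical decisions, and what the synthetic data can and
cannot establish.

## 1. Synthetic recordings (`fusepore.synthdata`)

The generator emulates the nanodisc-to-cell fusion assay: a voltage-
clamped patch in which each fusion event opens a single pore whose
current reports the pore conductance.

Generative structure, per patch:

- **Pore nucleation** is a Poisson process at `nucleation_rate`
  (default 0.4 pores/min, scaled per condition), truncated at
  `max_pores_per_patch` (default 3) over a `patch_duration` of 10 min.
  The cap emulates the experimental reality that only a few pores can be
  analyzed per patch; it is what makes naive rate estimates biased
  (Section 3).  Candidate nucleations that fall while a pore is already
  open (or within a 1 s refractory gap) are thinned, so bursts never
  overlap: real recordings can in principle contain overlapping pores,
  and this is a deliberate simplification that keeps single-pore
  idealization well-posed.
- **Burst structure.**  The burst lifetime T_o is drawn exponential
  (`burst_mean_duration`, default 2000 ms) and the number of transient
  full closures (flickers) N_flickers is geometric
  (`flicker_success_prob`, default 0.25; support {0, 1, ...}, so a
  square-pulse burst with no flicker is possible).  These are exactly
  the two distributional facts the assay established, so they are taken
  as the generative definitions.  Flicker closed dwells are exponential
  (`flicker_mean_closed`, 15 ms), capped in total at half of T_o; the
  remaining open time is split into N+1 open dwells with exponential
  weights (`open_mean_dwell`, 500 ms).  A consequence of drawing T_o
  first is that open-dwell durations are conditionally rescaled rather
  than independent; the marginals of T_o and N_flickers are exact.
- **Conductance levels.**  Open-pore conductance is the condition mean
  plus white Gaussian noise (`conductance_noise_sd`, 20 pS); baseline
  Gaussian noise (4 pS) is added everywhere.  Flickers close fully to
  baseline; sub-conductance states are not generated (the assay does not
  parameterize them).  The condition mean follows the published Hill
  titration f(x) = a/(1+(K/x)^n) + c with a = 343.7 pS, c = 164.2 pS,
  n = 2.3, K = 23 uM when the condition has functional Syt1 C2AB and
  PI(4,5)P2; otherwise it stays at the SNARE-alone mean (200 pS).
  (The printed form of the Hill legend is typographically garbled; the
  form used here is fixed by its printed asymptotes f(0) = c and
  f(inf) = a + c.)  Condition presets reproduce the direction of the
  published mutant effects (calcium-binding, SNARE-binding and
  loop-insertion mutants collapse to SNARE-alone; the polybasic mutant
  is reduced; the 4W mutant behaves like wild type).
- Sampling: 0.1 ms (10 kHz); holding potential recorded as 15 mV (the
  assay states only <20 mV).  Traces are emitted unfiltered.  One master
  seed spawns per-patch streams, so every recording is bit-reproducible.

What passing tests on this generator do **not** show about real data:
real recordings have baseline drift, seal instabilities, capacitance
transients, correlated (filtered) noise, sub-conductance states and
occasionally overlapping pores.  The idealization defaults below were
chosen against the generator and must be re-examined on real traces.

## 2. Idealization and per-pore metrics (`fusepore.traces`)

Bursts are detected by threshold crossing: contiguous supra-threshold
activity separated by sub-threshold gaps shorter than `min_burst_gap`
(500 ms) is one burst; within a burst, sub-threshold intervals of at
least `min_dwell` (1 ms) are blocked dwells (flickers).  The open
threshold is 25 pS (>5 baseline SDs, ~1/8 of the smallest condition
mean).  These three defaults are package choices, exposed in the
config; they recover >=95% of generator ground-truth bursts with <5 ms
boundary error at default noise.

Per burst: G_po is the mean of open-dwell samples; P_o the open
fraction of [t_on, t_off]; T_o the burst span; flicker rate
N_flickers/T_o; "conductance fluctuation" is defined here as the RMS of
open-pore points about G_po.  Pooled point-by-point open conductances
feed the pore-size PDFs.

**Expansion rate** follows the published definition: bursts aligned at
the first supra-threshold sample and averaged point-wise; with G100 the
averaged conductance 100 ms after opening, the rate is 0.8*G100
divided by the time between the first crossings of 10% and 90% of
G100.  For an instantaneous step this collapses to 0.8*G100 per sample
interval (documented edge behaviour).

**Nucleation rate**: the naive estimate divides total pores by total
patch time.  Because patches stop being informative once the analysis
cap is reached, the censoring-aware estimate ends a capped patch's
exposure at the onset of its last countable pore (the Poisson MLE for
event-stopped observation).  Simulation shows the naive estimator
underestimates at high true rates while the corrected one does not.
Zero-pore data get the exact (Garwood) Poisson 95% interval, whose
upper limit is 3.69/T.

## 3. Pore statistics (`fusepore.porestats`)

Conductance maps to lumen radius through a cylindrical pore of length
L = 15 nm: G = sigma*pi*r^2/L.  The conductivity default
sigma = 1.65 S/m is derived by solving this model jointly against the
two published correspondences (200 pS <-> 0.76 nm and 1 nS <-> 1.7 nm),
which agree to three figures only for the cylinder-only form — hence
access resistance defaults off (it is implemented, with the closed-form
quadratic inversion, for sensitivity analyses).

Radius PDFs are built by converting conductance *samples* and then
binning (no Jacobian is applied to binned densities).  Default bin
widths, 20 pS and 0.05 nm, resolve the ~200 pS SNARE-alone peak without
empty interior bins at 10^3-10^4 samples.  Boltzmann inversion reports
U = -ln(P/P_max) in kT, only on bins with at least 5 counts (inversion
noise grows as 1/sqrt(count)); the vertical shift is a convention.
Forces use kT = 4.114 pN nm (298 K), so 2 kT over 1->2.5 nm is 5.5 pN
and 6-7 kT is 16.5-19.2 pN.

Hill titrations are least-squares fits of f(x) = a/(1+(K/x)^n)+c via
`lmfit`, with n and/or K optionally fixed (as the published
expansion-rate fit does); 95% bounds come from the asymptotic
covariance with a t critical value.  A 500-replicate coverage study
(8 calcium levels x 10 replicates, 30 pS noise) keeps every parameter's
coverage at or above 90%.

## 4. The lever model (`fusepore.lever`)

### Geometry and membrane energy

The fused nanodisc-cell system is axisymmetric: the nanodisc membrane
(a disc of radius 12.5 nm held at its rim by the ApoE scaffold) sits a
height h above the flat cell membrane and connects to it through a pore
of waist radius r.  All shapes track the bilayer midplane; h is
midplane-to-midplane.  The *lumen* radius that conductance measures is
smaller than the midplane waist by one monolayer thickness:
r_po = r_waist - t_half with t_half = 2 nm.  This distinction matters:
at the sub-nanometre lumen radii the assay reports, the midplane waist
is 2-3 nm, where the Helfrich description is still sensible.

For given (r, h) the minimum-energy profile minimizes

    E = integral (kappa/2)(2H - c0)^2 dA + gamma * (excess area),

with 2H the mean curvature of the surface of revolution and excess area
measured relative to the projected flat annuli.  The profile's tangent
angle is expanded in a sine series on two arc-length segments meeting at
the waist (turning angle 0 at a clamped disc edge, pi/2 at the waist, pi
at the flat remote end); SLSQP minimizes the collocated energy under the
waist-radius and height equality constraints.  The remote end has zero
slope at z = 0 with a free endpoint radius — the profile "joins the
cell membrane at a remote location", and moving the nominal remote
boundary further out provably changes nothing.  The scaffold edge is
clamped (meets the ring flat) by default; an elastic/hinged variant
exposes a torsional ring stiffness.  Spontaneous curvature defaults to
zero.  Solver checks: the energy agrees within 2% with an independent
dense pointwise-collocation minimization; with vanishing tension and a
hinged edge a shallow neck relaxes to a minimal surface (bending energy
-> 0, the catenoid limit); energies are insensitive to doubling the
remote boundary.

### SNAREs and crowding

N = 4 SNARE complexes are each trans (free to roam an area
`trans_area`) or cis (fully zippered at the waist, gaining `dG_zip`).
Zippered SNARE-C2B rods crowd the waist circumference 2*pi*r_waist as
labelled one-dimensional hard rods (Tonks gas), configuration integral
l(l - n b)^(n-1) with footprint b; states whose rods do not fit carry
zero weight.  Translational measures use a 1 nm reference length, whose
arbitrary choice is absorbed by the calibrated dG_zip.  Crowding
pressure falls with radius, so the SNARE subsystem always pushes the
pore open — more SNAREs, larger pores.

### The C2B lever

Each zippered complex carries a C2B domain whose calcium-binding loops
bury with Hill probability p = 1/(1+(K/Ca)^n), n = 2.3 and K = 20 uM
(the membrane affinity of C2AB on PI(4,5)P2 bilayers; the titration fit
of conductance gives the close experimental analogue K = 23 uM).
Burial is independent Bernoulli(p) across the zippered complexes, and a
state needs the *tilted* clearance iff at least one zippered complex is
buried (the strongest constraint dominates; the coupling between
complexes is not otherwise specified by the biology).

Clearance is a geometric test against the solved shape: the SNARE-C2B
complex is a rigid capsule (length 14 nm, diameter 4.0 nm) anchored
near the waist with its axis along the waist chord, between the two
leaflet surfaces (midplane offset by t_half on each side).  Untilted,
the capsule lies parallel at `patch_height` = 0.5 nm above the cell
leaflet; tilted, the C2B end is held `loop_depth` = 1 nm inside the
cell membrane and the axis rises at 15 degrees, so the distal end needs
roughly (length - diameter)*sin(15 deg) of extra headroom.  Between
flat plates these reduce to closed-form thresholds (8.5 and 9.6 nm
midplane separation at the defaults); against real funnel-shaped pores
the requirements are substantially stronger at small radii — the gap
between the two sheets opens slowly along the 10 nm rod — which is
exactly the lever coupling: a tilted complex forces extra height where
extra height is most expensive, biasing the ensemble toward larger
pores.  Whether the *untilted* complex also enforces its thickness as a
minimum separation is genuinely ambiguous in the source material; both
behaviours are implemented (`untilted_sets_separation`).  The default
treats the parallel complex as imposing no shape constraint: measured
against solved funnels, its in-funnel requirement at small radii would
otherwise dominate the zero-calcium ensemble and pull it far from the
calibration anchors.

### State sum and observables

For each radius, exp(-F(r,h)) sums Boltzmann weights over heights on a
0.25 nm grid, zippering numbers 0..N, and burial patterns, with
excluded states removed; the pore height takes the minimizing value
h*(r).  P(r) ~ exp(-U(r)) on a 0.05 nm lumen-radius grid over
0.3-4 nm (experimental sampling of larger pores is too sparse to
compare against).  Reported observables: Boltzmann means of r, h*(r),
and the cylinder-model conductance, and their fold changes relative to
zero calcium.  By construction the clearance rule is the *only* calcium
coupling: removing it collapses the calcium dependence exactly, which is
tested.

### Calibration

Pinned from the source biology: N = 4, Hill n = 2.3, K = 20 uM, tilt
15 deg, loop depth 1 nm, patch height 0.5 nm, disc radius 12.5 nm.
Calibrated within literature ranges against the zero-calcium anchors
(mean lumen radius ~0.9 nm, mean height ~9.0 nm, a several-kT rise from
1 to 2.5 nm): bending modulus kappa = 10 kT, tension gamma =
0.059 kT/nm^2 (membrane length scale sqrt(kappa/gamma) = 13 nm),
zippering gain dG_zip = 18 kT, rod footprint b = 3.7 nm (a SNARE
bundle with its laterally bound C2B), trans area 450 nm^2, capsule
14 x 4.0 nm.  The frozen defaults live in `fusepore.lever.calibrated`
and are also the dataclass defaults.  With-calcium outputs (mean radius
and the radius/conductance fold increases) are predictions, not fit
targets.  One known residual: with kappa at the literature floor the
solved landscape is somewhat steeper over lumen radii 1-2.5 nm than
the published apparent profiles, so the model's free-energy *rise* over
that window runs ~2 kT high at both calcium extremes even though the
means and fold-changes match; tests assert the published rise bands and
this is documented rather than hidden.

### Numerical choices and degenerate inputs

Ritz basis: 5 sine modes per segment, 41 Simpson points; warm starts
along the height grid.  Non-convergence returns a flagged shape (and
that grid point is dropped); geometrically infeasible requests (waist
outside the disc, non-positive dimensions) raise immediately.  Radii
whose constraints exclude every state are excluded from the profile, as
are heights below the bilayer contact distance.  Energies are reported
relative to each profile's minimum; only energy *differences* are
meaningful, since boundary terms (Gaussian curvature, scaffold
assembly) are constants absorbed by calibration.

## 5. Workflow

`RunConfig` mirrors the parameter dataclasses and validates every block
(each violation names the field and rule).  `run_reproduction` executes
simulate -> idealize -> pore statistics -> lever model under one master
seed (`numpy.random.SeedSequence` spawning per-patch streams) and
writes delimited-text tables, a results JSON, and a report table with
stored tolerances.  Problem sizes in the shipped defaults (8 patches x
2 conditions, coarse titration) are chosen so a full reproduction is a
few minutes of desk compute; all sizes are config fields.

## 6. Known limitations

- The generator's noise is white; real recordings are low-pass filtered
  (a Bessel corner), which correlates samples and biases flicker
  detection at short dwells.  An optional low-pass is left as an
  extension point.
- The scaffold is a boundary condition, not an elastic annulus; ApoE
  belt mechanics beyond the clamped/hinged dichotomy are not modelled.
- The capsule clearance replaces an atomistic space-filling check; a
  sphere-union mode reading coordinate files would refine the
  thresholds by fractions of a nanometre.
- Equilibrium only: pore expansion kinetics (and hence expansion-rate
  magnitudes in nS/s) are outside the model; the analysis pipeline
  measures them on data, synthetic or real.
- C2A-domain mechanics and membrane-curvature generation by loop
  insertion are deliberately absent; the lever acts through geometry
  alone.
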