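# Methods

This note documents the models implemented in `nucspool`, the choices made
where the underlying physics left the construction open, and what the
synthetic-data generator does and does not emulate.

## Tether mechanics

The DNA tether (two 2.5-kb handles plus whatever nucleosomal DNA has been
released) is a worm-like chain.  We use the Marko–Siggia interpolation
formula

    F(u) = (kT / Lp) · [ 1/(4(1−u)²) − 1/4 + u ],   u = x / L,

with an enthalpic stretching term applied at all forces: the relative
extension of the tether at force F is `u(F) = u_MS(F) + F/S`.  Defaults
(configurable through the `wlc` JSON block):

| parameter | default | unit | rationale |
|---|---|---|---|
| persistence length Lp | 50 | nm | canonical dsDNA value, the one constant the measurements themselves fix |
| stretch modulus S | 1200 | pN | canonical dsDNA; calibrated against the 27-bp/8.5-nm and 43-bp/6.2-nm anchors (below) |
| thermal energy kT | 4.11 | pN·nm | 23 °C |
| rise per bp | 0.34 | nm | B-form DNA |

A single extensible model is used across the full 0.5–40 pN range rather
than switching it on above a force threshold; a switch would make the
force–extension relation discontinuous, and the stretching term is
negligible below ~5 pN anyway (< 1% of extension).  With these constants,
27 bp of released contour extends 8.55 nm at 4 pN and 43 bp extends
14.61 nm at 30.4 pN — the two anchors that tie the polymer model to the
unwrapping analysis.  Inversion (force from extension, bp from Δx) is by
bracketed scalar root finding to 1e-12; the trace pipeline uses a cached
dense interpolation table of u(F) whose error is orders of magnitude below
instrument noise.

## The spool mechanical model

The nucleosome is a rigid superhelical spool: 147 bp in 1.65 left-handed
turns, superhelix radius 4.18 nm, pitch 2.39 nm/turn (crystal-structure
values).  Base pairs map linearly to superhelical angle.  Note that the
quoted radius/pitch/turns give a helical path of 43.5 nm, about 13% shorter
than 147 × 0.34 nm; the printed crystal parameters are internally
approximate.  We keep them — the entry–exit *chords* they produce are what
the model's observable predictions rest on — and treat path length as a
derived, approximate quantity rather than an invariant.

Under tension the tether extension contributed by the particle is the
projection of its entry–exit chord on the pulling axis.  The zero net
torque condition for a force couple applied at the entry and exit contacts
aligns that chord with the force axis, so the aligned pose contributes the
full chord length.

**Accounting of the low-force transition (~4 pN).**  The FRET evidence
pins the low-force release to ~27 bp of the weak arm (the dye nearest the
weak-arm entry goes dark at low force and sits 24–27 bp inside).  The
rigid body that rotates into alignment is therefore the wrap *retained*
through the transition — the 120-bp core:

* rotation before unwrapping = |chord(120-bp core)| = **8.08 nm** (the
  chord turns from perpendicular to parallel to the force axis);
* released DNA = WLC extension of 27 bp at 4 pN = **8.55 nm**;
* residual rotation during unwrapping = the axial rise of that chord,
  i.e. the crossing deficit of the zero-force pose in which the linkers
  cross and emerge oppositely = **3.22 nm**;
* total = **19.85 nm**, with 120 bp left wrapped.

This construction is an interpretation: the original instrument-side
simulation that motivated these numbers is not published in a citable
algorithmic form, and the split between "rotation before" and "residual
rotation during" unwrapping is a narrative decomposition of a single
reorientation.  We chose the one construction under which all three
contributions are invariants of the crystal geometry; `annotate_low_force`
reports them per state so the decomposition is auditable.

**Accounting of the high-force rip (~30 pN).**  The rip releases DNA
symmetrically from both remaining ends while the spool rotates ~180°.  In
the chord model this rotation is extension-neutral (|chord(43)| −
|chord(120)| = +0.34 nm, below measurement resolution), so the released bp
follow from the WLC inversion of the measured Δx at the rip force alone:
24.5 nm at 30.4 pN → 72 bp, leaving 48 bp wrapped.  The model evaluates at
the ensemble-mean rip force; per-molecule forces can be passed instead.
A further ~13–18 bp release down to the 30-bp end state inferred from the
post-rip offset is represented as bookkeeping only — it is not resolvable
as a discrete event and the generator does not emit one.

The predicted end-state deficit against bare DNA is
`wlc_extension(bp·0.34, F) − |chord(bp)|`; at the 43-bp end state this is
6.18 nm.

## The spherical geometric model

For converting measured extension changes to bp without the full spool
construction, the particle is a sphere of effective radius R; DNA wraps as
an arc of length bp × 0.34 nm and the entry–exit chord is
`2R·sin(arc/2R)`.  A release of n bp changes the extension by

    Δx(n) = n·0.34·u(F) + chord(w−n) − chord(w),

with w the wrap before the event.  Inversion is an exhaustive search over
integer n (the forward map is cheap and the search space is ≤ 147), with
uncertainty propagated from the measurement SD through the local WLC
slope.  R is calibrated **once** from the end-state consistency
constraint — the sphere chord of the 43-bp end state must equal its free
contour extension minus the predicted 6.2-nm deficit — giving
R = 4.2518 nm, frozen as the default and recomputable via
`calibrate_sphere_radius`.  As R → 0 the model reduces to the naive
geometry-free inversion `bp = Δx / (0.34·u)`.

With the calibrated sphere: 24.5 nm at 30.4 pN → 73 bp; a 2.3-nm offset
against bare DNA → 30 bp remaining; a 6-nm offset (tetrasome) → ~42 bp.

## Trace analysis

All detection runs in the apparent-contour coordinate L(t) =
x(t)/u(F(t)), in which a tether is flat, a cooperative rip is a step and a
noncooperative transition is a ramp.  The force channel is median-filtered
(51 samples) before conversion: the ramp is slow and smooth, and raw force
noise would otherwise leak several nanometres into L at low force.

* **Rips/zips** — candidate steps from a rolling-median jump statistic
  (window 25 samples, threshold `min_step_nm` = 5 nm), accepted only if
  the jump is *sharp* (the medians a few samples either side differ by
  ≥ 0.7 of the threshold; an instantaneous step passes, a ramp of a few
  tenths of nm per sample does not).  Δx is then measured as the
  horizontal distance between one-parameter WLC fits to the flanking
  segments (150 samples, 10-sample guard gap), evaluated at the rip
  force.  On the generator's nucleosome ensemble the measurement bias is
  < 0.05 nm with ~0.13 nm SD.
* **Low-force transition** — total size from WLC fits below (0.8–2.4 pN)
  and above (6.2–7.8 pN) the band, evaluated at the half-excess force;
  the cooperative share is measured by local medians around detected
  steps (flanking fits would swallow an adjacent ramp and mask a mixed
  transition); the remainder is the noncooperative share.  Hopping is
  flagged when a two-state split of the in-band apparent contour
  alternates ≥ 3 times under a 25%-gap hysteresis.
* **Divergence point** — baseline WLC fit at 1–3 pN; the onset is the
  first excursion of the median-smoothed residual beyond k·σ (k = 3,
  σ from first differences) sustained ≥ 50 ms, refined by walking back to
  the last 2σ point.  On synthetic noncooperative traces the detected
  force is within ~0.1 pN (mean) of the generative onset.
* **Offsets** — mean horizontal displacement between per-trace WLC fits
  over a shared force range (default 32–38 pN); exactly antisymmetric by
  construction.  For post-rip offsets the range must sit above the rip
  force of both traces.
* **Species calls** — nucleosome = low-force transition + high-force rip;
  hexasome = rip (12–37 pN) without a low-force transition; tetrasome =
  low-force transition (hopping allowed) without a rip; bare DNA =
  neither.  Ambiguous evidence (rip outside the hexasome band, nonzero
  offset on a bare call) sets a warning flag rather than failing.

## FRET analysis

FRET efficiency is the uncorrected proximity ratio E = A/(A+D) after
background subtraction, with bins under 10 photons masked; an optional
gamma factor is exposed but defaults to 1 (the analyses compare relative
high/low states, not absolute distances).  Ensembles are aligned by pure
time shifts: on the high-force rip for cooperative transitions, and — for
gradual transitions with no step to anchor on — on the midpoint of a
decreasing-sigmoid fit to each trace.  The sigmoid-midpoint rule is our
realisation of an otherwise unspecified procedure; its limiting case on
step traces coincides with rip alignment within one bin, which the tests
check.  2D histograms (relative time × E) hold unnormalised counts.

The extension-vs-FRET temporal offset uses a hinge (flat-then-ramp) least
squares fit for the FRET onset, restricted to the window up to the sigmoid
midpoint, and the WLC divergence point for the tweezers channel;
`separation = FRET onset − extension divergence` is positive when the
tweezers channel moves first.

Fluorescence steps (photobleaching, dimer ejection) are found by binary
segmentation of a piecewise-constant mean with a per-segment penalty
proportional to the local first-difference variance (shot noise scales
with the level, so a global penalty either over-segments bright regions
or is dragged down by dim tails).  The ejection event is the largest
downward step; earlier downward steps are counted as bleaching.

## Stochastic disassembly model

Each pulling/relaxation cycle maps the species to a next-cycle species.
The first-cycle nucleosome outcome distribution at 50 mM KOAc is fixed at
(nucleosome 0.40, hexasome 0.28, tetrasome 0.28, bare DNA 0.04) — the
bare-DNA entry is the complement of the three published fractions.  The
hexasome and tetrasome cascade distributions, (0.50, 0.46, 0.04) and
(0.50 retain, 0.50 dissociate), are **placeholders**: the cascade is
observed but its rates are not published; both are configurable through
the `disassembly` JSON block.  Transitions may only conserve or lower
particle rank, except an opt-in tetrasome → hexasome re-engagement.
Estimation from simulated records is by MLE proportions with Wilson score
intervals.  One note on the coverage property checked in the tests: with
nominal 95% intervals, a "≥ 93 of 100 replicates" bound is itself a
borderline-statistical event (~88% per probability for an arbitrary
replicate set); the suite evaluates it on the package's fixed replicate
seeds (1000–1099).

## The synthetic fleezers generator

The generator abstracts the dual-trap instrument to a linear force ramp
(0.5 → 40 pN) on the tether, with trap/bead dynamics folded into Gaussian
extension noise (σ = 1 nm) and force noise (σ = 0.1 pN); sampling is
1 kHz for force/extension and 100 Hz (10-ms bins) for fluorescence.  The
pulling speed defaults to 100 nm/s; the FRET-channel analyses in
`analysis/04` and the corresponding tests run at 25 nm/s so that the
10-ms-binned FRET transition spans enough bins to be resolved, mirroring
the slow low-force ramps of the real measurements.

The emitted extension is `u(F)·(L_construct − seq) + proj + noise`, where
`seq` is contour sequestered by the particle and `proj` its chord
projection.  States are anchored to *measured* quantities and built
backward from bare DNA: the post-rip nucleosome sequesters 30 bp against
the sphere chord (offset 2.27 nm), the rip size is drawn from
N(24.5, 1.6) nm and converted to bp at the drawn rip force, and the
low-force transition releases 27 bp with the 11.3-nm rotation ramp
preceding the release (this ordering is what makes the tweezers channel
diverge before FRET).  Strict forward bp bookkeeping cannot
simultaneously reproduce the 120-bp pre-rip wrap, the 24.5-nm rip and the
2.3-nm final offset — the same tension the unresolvable ~13-bp
noncooperative release resolves in the physical interpretation — so the
generator reproduces what an instrument would measure and reports the
per-state (seq, proj) trajectory as ground truth.

Event distributions (truncated to physical ranges): nucleosome low-force
noncooperative onset N(3.6, 0.2) → completion N(4.3, 0.2) pN with an
87/9/4% noncooperative/cooperative/mixed split, cooperative rip
N(4.1, 0.7) pN with Δx N(20.4, 1.5) nm; high-force rip N(30.4, 8.3) pN
truncated to 8–40 pN with Δx N(24.5, 1.6) nm; hexasome rip N(24.6, 3.0) pN
with Δx N(23.4, 1.1) nm; tetrasome transition N(4.4, 0.5) pN with Δx
N(13.3, 1.7) nm, two-state hopping, and a 47-bp end state so that the
measured offset against bare DNA is ~7.8 nm.  The noncooperative width is
floored at 0.45 pN: a narrower drawn "noncooperative" transition would be
indistinguishable from a rip at the sampling rate, making the ground-truth
kind label meaningless.  Rewrapping draws one of seven case shapes
(single zip; zip + noncooperative; two zips in three force arrangements;
three-transition variants) with uniform default weights — the case
frequencies are not published.  FRET constructs: ED1 loses signal during
the low-force release (gradually for noncooperative transitions), ED2 and
INT at the rip (INT with enhanced pre-rip "gaping" fluctuations); on
relaxation INT always recovers at the first zip, ED1/ED2 at the first or
second with equal probability.  Dimer-ejection delays are exponential
with mean 113 ms (the published mean; the distributional family is our
choice and is configurable).

What the generator does **not** emulate: bead Brownian dynamics and trap
compliance, instrument drift, photon-level dye photophysics (blinking,
spectral crosstalk), sequence-dependent mechanics, and the force
dependence of rewrapping kinetics.  Passing tests therefore demonstrate
that the analysis pipeline is correct and unbiased *under the stated
noise model*, not that it is robust to every artefact of real data.

## Numerical choices and degenerate inputs

Root finding uses `brentq` with brackets guaranteed by monotonicity;
integer-bp inversions are exhaustive argmin searches with explicit range
errors when a Δx or offset exceeds the full-release prediction.  Ties in
the argmin resolve to the smaller bp count (`np.argmin` takes the first
minimum).  Zero-length contours, zero offsets and already-aligned states
return exact zeros.  All randomness flows from `numpy` `default_rng`
seeds; per-molecule streams are spawned as `default_rng([seed, index])`,
so archives are bitwise reproducible.

## Problem sizes

The test suite and the acceptance script use ensembles of 200 traces per
species for detector statistics, 10,000 molecules for outcome fractions,
100 replicates for interval coverage, and 8–20 traces for FRET
alignments — sizes at which the ensemble means are an order of magnitude
more precise than the tolerances they are checked against.

## Known limitations

* The rotation accounting reproduces the printed pathway numbers but is a
  reconstruction; other constructions (e.g. full-wrap chord alignment,
  8.43 nm) are geometrically admissible and would shift the
  before/during split by ~0.35 nm.
* The mechanical model inverts rips at the ensemble-mean force; the
  measured rip-force spread (±8.3 pN) moves the per-molecule bp estimate
  by only ~±1 bp because u(F) is nearly saturated above 20 pN.
* Hexasome/tetrasome cascade probabilities are placeholders (above).
* The species classifier's kind labels (cooperative vs mixed) are
  ambiguous by construction for transitions whose noncooperative share is
  near the 5-nm threshold; species labels are unaffected.
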