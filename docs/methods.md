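# Methods

`ripfit` analyzes constant-velocity optical-tweezers pulling experiments on
a tandem-repeat protein (a 15-HEAT-repeat, 589-residue scaffold of the kind
used as a PP2A subunit) tethered between beads via two 600 bp dsDNA
handles, and the two ensemble binding assays that accompany such a study
(nanoDSF thermal shifts and fluorescence-polarization titrations).  Because
no raw pulling data are distributed with such studies, the package ships a
first-class synthetic-data generator that emulates the experiment at its
stated conditions; every analysis stage is validated by recovering the
generator's ground truth.

## Polymer mechanics

Each elastic element follows the extensible worm-like chain in the
Marko–Siggia interpolation with an enthalpic stretch term,

    F = (kBT / Lp) [ 1/(4 (1 − x/Lc + F/K)²) − 1/4 + x/Lc − F/K ].

Substituting `z = x/Lc − F/K` makes extension-given-force a scalar cubic
solved by vectorized bisection to 2⁻⁶⁴ interval width; force-given-extension
is a bracketed Brent solve with a 200 pN cap and 1e−9 nm tolerance.

Fixed mechanical constants (all configurable):

| parameter | value | origin |
|---|---|---|
| handle Lp | 30 nm | fixed fit parameter of the analysis |
| handle Lc | 2 × 600 bp × 0.34 nm/bp = 408 nm | B-DNA rise convention |
| handle K | 500 pN | midpoint of the quoted 400–600 pN range |
| protein Lp | 0.5 nm | fixed fit parameter |
| protein K | 300 pN | fixed fit parameter |
| contour per residue | 0.365 nm | peptide contour convention |
| folded N–C span | 15 nm | rigid-core treatment (below) |
| kBT | 4.114 pN·nm | 298 K; instrument temperature not otherwise specified |

The folded core is a rigid 15 nm offset, not an elastic element.  The
protein state is parameterized by a single coordinate ℓ ∈ [0, 200]: the
contour-length gain recovered so far.  The unfolded-chain contour is
ℓ·(215/200) (215 nm = 589 × 0.365) and the rigid offset shrinks as
15·(1 − ℓ/200), so complete unfolding yields ΔLc = 215 − 15 = 200 nm, the
construct's expected full gain.  Because WLC extension is linear in contour
length at fixed force, this parameterization is exactly linear in ℓ, and ℓ
is what branch fits report ("absolute contour length", protein only — the
408 nm of handles are excluded and noted in output metadata).

## The pulling simulator

Cooperative unfolding blocks are re-drawn each cycle: the 15 repeats are
partitioned into 2–4 contiguous blocks with uniformly random boundaries
(flanks of a misfolded core use 1–2), reproducing the observed
heterogeneity in the number and size of intermediates between consecutive
pulls.  Blocks flip with Bell rates

    k_u(F) = k0_u · exp(+F·Δx_u / kBT),   k_r(F) = k0_r · exp(−F·Δx_r / kBT),

with Δx_u = Δx_r = 8 nm, k0_u = 3e−5 s⁻¹ (calibratable, below) and
k0_r = 2000 s⁻¹; refolding is gated below 5 pN.  These kinetic constants
are synthetic stand-ins — no per-intermediate rates are published for this
system — chosen so that unfolding concentrates near 6–8 pN and refolding
near 3–4 pN, giving the clear stretch–relax hysteresis the experiment
shows.  The gate keeps a freshly refolded block from sitting above its
unfolding regime and hopping.

Each sweep ramps the trap separation at 100 nm/s; at every 0.1 ms kinetics
step the tension solves the quasi-static balance `F = k_trap (D − x(F))`
(combined trap stiffness 0.3 pN/nm), tabulated per tether state and
interpolated, so no per-step root find is needed.  The 78 kHz → 100 Hz
averaging of the real instrument justifies ignoring sub-millisecond bead
dynamics.  Output is decimated to 100 Hz by block averaging; Gaussian force
noise (σ = 0.2 pN, a choice — no instrument noise figure is stated) is
added at the output stage and propagated into the measured extension
through `x = D − F/k`.  Sweeps span from 0.25 pN (folded) to the separation
where the fully unfolded tether reaches 30 pN, so every stretch crosses the
20 pN high-force criterion used in classification.

Ground truth records every flip (time, force, signed ΔLc, and the branch
offset at matched force — the physically detectable rip size) plus the
cycle's condition events.

### Conditions

* **no ligand (`no_smap`)** — from the second pull onward a stretch
  misfolds with probability 0.22: a contiguous run of 3–8 repeats becomes
  non-unfoldable up to the force cap, subtracting its contour from the
  recoverable gain.  The 3-repeat floor reflects that the experimentally
  scored misfolded traces are visibly shorter than full ones; a 1-repeat
  core (~13 nm) would be indistinguishable from complete unfolding under
  the 90% classification threshold.
* **stabilizer (`atux`)** — no misfolding; all unfolding rates scaled by
  0.1, raising every transition force by ~kBT/Δx·ln10 ≈ 1.2 pN
  (chaperone-like global stabilization).
* **blocker (`dbk`)** — 33% of molecules lock after their first complete
  unfolding: refolding is disabled from that relax onward, so subsequent
  cycles start unfolded and show no transitions.  The lock is a
  per-molecule property; both per-molecule and per-trace tallies are
  implied by the truth records since the engaging cycle is recorded.

Condition events are assigned by randomized systematic sampling: the number
of misfolding stretches (among eligible cycles) and of locked molecules is
the nominal rate times the number of eligible units, randomly rounded, with
units drawn uniformly.  Each unit keeps its nominal marginal probability,
but the realized fraction matches the rate to within one unit.  At the
small sample sizes these experiments use (tens of molecules), i.i.d.
Bernoulli assignment would let binomial noise dominate any recovery
benchmark (e.g. ±9 points on a 33% fraction at 20 molecules); systematic
assignment makes the benchmarks measure pipeline error instead.  What the
generator does **not** emulate: instrument drift and creep, bead-in-trap
hydrodynamics, DNA overstretching, per-intermediate kinetic diversity, and
the blocker's weak first-pull stabilization of a few repeats.  Passing
recovery tests therefore demonstrate correctness of the analysis chain
under the stated statistical structure, not robustness to every instrument
pathology.

### Kinetic calibration

`calibrate_unfold_kinetics` bisects log10(k0_u) until the simulated mean
force of the final unfolding rip per stretch matches a target (7.2 pN at
100 nm/s).  The mean is measured through the same detector and
window-average estimator used downstream, so estimator bias cancels; common
random numbers keep the objective monotone; bisection runs to a fixed
resolution of 0.02 in log10(k0) (~0.024 pN) rather than stopping at the
first in-tolerance measurement, which would lock in that evaluation's
sampling error.  With 400 calibration cycles the calibrated-then-verified
mean lands within ~0.15 pN of target across independent seeds.

## Rip detection

Along an elastic branch the measured extension and force move together,
`dx = C dF` with `C` the local tether compliance — both are driven by the
advancing trap.  With `x = D − F/k` these two channels share one noise
source, so rip detection is fundamentally the detection of a persistent
force step, and the meaningful rip size is the extension offset between
the flanking branches at matched force (the slack gained), not the
instantaneous jump `ΔF/k` — at 0.3 pN/nm combined stiffness the latter is
only ~25% of the slack and the stated 10 nm minimum would discard nearly
every intermediate.

The detector therefore:

1. estimates the local compliance from lag-8 increment ratios smoothed by a
   rolling median (lag differences because per-sample force increments are
   noise-dominated on soft branches), with strictly one-sided past/future
   variants — a centered estimate straddling a rip mixes two branches with
   different loading rates and collapses;
2. slides a matched branch-offset statistic `J[i]`: difference of 4-sample
   side means of extension, compliance-corrected to matched force, with a
   2-sample gap to clear decimation-smeared jumps;
3. flags candidates where `J` deviates from its rolling-median baseline by
   more than 5 rolling MADs, with an absolute floor of 0.5·min_size and a
   cap at 0.95·min_size (wide 121/161-sample windows and clipping keep a
   train of rips from inflating its own threshold), excluding samples below
   2.5 pN (slack tether, no usable elastic reference) and within 25 samples
   of the sweep ends (rolling-estimator padding);
4. reduces candidates by non-maximum suppression at the plateau scale,
   localizes each jump by its largest single-increment residual and the
   monotone force excursion, and
5. re-measures the size with long (up to 12-sample) windows placed a few
   samples away from the trigger — so the ≥ min_size gate is statistically
   independent of the noise excursion that may have raised the candidate —
   extrapolating each side to the flip force along its own branch.

On synthetic data at the default noise this yields ≥ 95% recall for rips of
≥ 12 nm branch offset, a few-percent false-positive rate per sweep on
transition-free traces (zero on noiseless ones), and sizes within ~3 nm
(median) of truth for isolated rips.  Two flips closer than ~0.1 s merge —
unresolvable at 100 Hz.  Transition forces are the mean over the 0.05 s
(5 samples) before the jump onset; at ~10 pN/s loading this sits ~0.35 pN
below the instantaneous flip force, a bias shared by calibration and
analysis.

## Branch fitting and classification

Each inter-transition branch is fit in force space with only ℓ free (all
elastic constants clamped; their configured values are echoed bitwise in
every fit record).  The objective is a soft-L1 cost on force residuals
(δ = 0.6 pN), which behaves as least squares near zero but linearizes
outliers, so a brief excursion into another branch cannot drag the fit.
Samples within 3 of a rip and below 0.2 pN are excluded.  The baseline
(first) branch of a stretch is additionally screened: if the smoothed force
residual exceeds 0.6 pN anywhere, the branch is refit on its clean prefix —
this excises rips too small for the detector, which otherwise bias the
folded-baseline ℓ upward by tens of nm.  Noiseless branches recover ℓ to
0.001 nm; at default noise the median error is well under 2 nm and
per-cycle totals scatter by ~3 nm.

A stretching cycle is classified **locked** if neither sweep has a ≥ 10 nm
transition (checked first — a locked cycle is never counted misfolded),
**full** if its total ΔLc (last minus first fitted branch) reaches 90% of
the expected 200 nm, **misfolded** if it falls short despite ≥ 20 pN
applied, and excluded entirely if the tether validation (cumulative length
vs expectation, single-rupture check) fails.  The 0.9 and 20 pN thresholds
implement the qualitative experimental rule and are exposed as
configuration.  ΔLc distributions use 5 nm bins; the peak is the quadratic
vertex through the three bins around the mode (mode picked on lightly
smoothed counts so a single stray bin cannot claim it).  Label agreement
with ground truth exceeds 95% in all three conditions.

## Binding assays

NanoDSF: the I350/I330 ratio is smoothed and differentiated by
Savitzky–Golay local quadratic regression (window 7 points by default) and
the melting temperature is the global extremum of |dFIR/dT − median|,
refined by quadratic interpolation — locating the extremum of the absolute
deviation makes the result independent of the plotting convention (the
physically rising ratio gives a maximum; negated-derivative plots show a
minimum).  A flat or monotone derivative (no transition) raises an error
rather than returning a spurious extremum.  On noiseless 0.1 °C-grid
sigmoids the midpoint is recovered to < 0.01 °C; with ratio noise the
smoothing window must grow toward the transition width (a 75-point window
holds 0.1 °C at noise σ = 0.001).

Fluorescence polarization: `P = (I∥ − I⊥)/(I∥ + I⊥)` (×1000 for mP), and
titrations are fit to the one-site model `P = Pmax·C/(Kd + C)` by
`scipy.optimize.curve_fit` with standard errors from the fit curvature,
after subtracting the mean of zero-concentration (protein-only background)
wells.  No ligand-depletion correction is applied — the model is used
exactly as the assay quotes it.  Noiseless titrations recover Kd exactly;
at 2 mP noise with triplicates the median error is ~5%.

## Numerical choices and limitations

* All randomness flows from one seed through `numpy` `SeedSequence`
  spawning (one child per molecule-cycle), so partial reruns reproduce.
* Force-balance tables use a 1200-point geometric force grid to 250 pN;
  branch-fit interpolation uses 900 points to 80 pN; both introduce errors
  orders below the noise floor.
* The detector's data-driven compliance carries 10–20% uncertainty, so raw
  rip sizes are screening quantities; contour-length numbers come from the
  WLC fits, as in the experimental analysis.
* Sub-10 nm rips (1–2 repeat blocks at low force) are invisible by
  construction of the 10 nm rule; totals remain correct because they
  difference the first and last branch fits.
* Runtime scales linearly in cycles (~50 ms per analyzed cycle); the
  shipped benchmarks use 30–200 cycles per condition, matching the scale of
  the experimental datasets (21–32 cycles per condition).
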