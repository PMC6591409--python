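# Methods

## Constriction-ring radius

A constriction of a pentameric channel is modelled as the ring of five
symmetry-related probe atoms, one per protomer, of a single pore-lining
residue. The measured quantity is

    r = mean(a1..a5) / f  -  r_vdW

where a1..a5 are the five adjacent-neighbour (pentagon-edge) distances
between the probe atoms, f is the pentagon factor, and r_vdW the probe van
der Waals radius. For a regular pentagon mean-edge/circumradius is
2 sin 36° = 1.1756, so dividing the mean edge by f maps it onto the ring
circumradius; subtracting the probe radius leaves the free radius an ion
sees. Two constant sets are provided:

* **paper-compat (default)**: f = 1.17 exactly, r_vdW = 2.00 Å for a
  united-atom CH₃ carbon and 1.20 Å for an aromatic hydrogen. These
  reproduce the published radii for bestrophin structures and are the
  convention all defaults follow.
* **exact**: f = 2 sin 36°, selectable per call or via
  `--exact-constants`. For a perfect C5 ring this makes r equal to
  circumradius − r_vdW identically.

Adjacency of the five points is recovered geometrically — angular order
about the centroid in the best-fit (SVD) plane, ties broken by centroid
distance then index — so the result is independent of chain naming and
file order. Degenerate rings (coincident points) raise an error;
overclosed rings legitimately yield negative radii and are reported as-is,
because the sign carries information about how far a gate overshoots
closure.

Probe-atom choice per residue type: Ile uses Cδ1. Val and Leu have two
terminal methyls and the published convention names only "Cδ"; the
package picks whichever methyl lies nearer the five-chain ring centroid,
on the reasoning that the pore-lining methyl is the one a permeating ion
touches. Phe rings are measured at a hydrogen position: X-ray models carry
no hydrogens, so ideal ones are constructed in-plane along each ring
carbon's exocyclic bisector at 1.08 Å (standard aromatic C–H), and the
hydrogen nearest the ring centroid is used per chain. The probe centre is
taken at the atom position (carbon centre for methyls), with the
united-atom radius absorbing the C–H extension.

Ring asymmetry is summarised by the five centroid distances, their spread
(max − min) and coefficient of variation. This quantifies "breathing" —
local, asymmetric dilation that can transiently admit ions larger than the
symmetric radius suggests.

Ion accommodation uses dehydrated radii Cl⁻ 1.8, Br⁻ 2.0, I⁻ 2.2, SCN⁻
2.2, CH₃SO₃⁻ 2.6 Å and hydrated radii 3.3 Å (Cl⁻/Br⁻/I⁻), with an
inclusive comparison (a 2.6 Å pore passes the 2.6 Å ion), since a gate
observed to conduct methanesulfonate must be at least that wide.

Structure superposition pairs atoms by (chain, author residue number,
atom name) — default selection Cα, optionally all heavy atoms — and uses
the Kabsch least-squares rotation (reflection-free, no outlier trimming).
No selection convention is claimed beyond this; it is the simplest
reproducible one.

## Electrophysiological derivations

Inputs are steady-state I–V tables per cell and condition (external anion
Cl⁻ or CH₃SO₃⁻; 0 or 1.2 µM free Ca²⁺), in pA with per-cell capacitance.
The default step protocol is −100…+100 mV in 20 mV steps from a 0 mV
holding potential; steady state is the mean of the final 10 % of each step
(the step size and window fraction are configurable, as published
protocols rarely state them). An optional per-condition liquid-junction
offset is subtracted from the voltages before any analysis.

* **Reversal potential**: linear interpolation between the step pair
  bracketing zero current; with several sign changes the crossing nearest
  0 mV is chosen (far-field crossings on noisy tails are artifacts).
* **Relative permeability**: ΔE_rev = E_rev(ex-X) − E_rev(ex-Cl), and
  P_X/P_Cl = (150/120)·10^(−ΔE_rev/59). The Nernst slope is fixed at
  59 mV/decade in paper-compat mode (RT/F·ln10 at 23 °C would be 58.8); a
  right-shifted reversal therefore implies P ratio < 1.25, and a +41.2 mV
  shift gives 0.25.
* **Slope conductance**: least-squares slope over the points within
  ±half-window of the target voltage. The default window just spans the
  two bracketing steps — a two-point secant off-grid, three points
  on-grid — because the published "slope conductance" does not state a
  regression span; pA/mV equals nS.
* **Conductance ratios**: influx branch at each curve's E_rev + 50 mV,
  with the external-CH₃SO₃⁻ current pre-multiplied by 1.2 to compensate
  the 120 vs 150 mM concentration difference; the trans branch at
  E_rev − 50 mV with no compensation.
* **Ca²⁺ fold-stimulation**: current ratio at +100 mV with/without Ca²⁺.
* **Group statistics**: two-tailed unpaired Student's t (equal-variance),
  s.e.m. = SD/√n. Zero-variance degenerate groups are handled explicitly
  (equal means → t = 0, p = 1; unequal → |t| = ∞, p = 0).

All per-cell quantities are computed first and then averaged
(mean ± s.e.m.); cells are never pooled before derivation, matching how
such figures are conventionally built.

## The GHK simulator

Recordings are simulated from the Goldman–Hodgkin–Katz current equation
for monovalent anions (outward-positive; u = V/V_T, V_T = 59/ln10 mV):

    I = P · u · (c_in − c_out e^u) / (1 − e^u)

summed over internal Cl⁻ (150 mM) and the external anion (151 mM Cl⁻ —
the summed chloride content of the external solution — or 120 mM CH₃SO₃⁻
with permeability P_Cl·p_ratio). Although only the GHK *voltage* relation
is used on the analysis side, the current equation is the minimal
electrodiffusion model consistent with those assumptions, and its analytic
reversal potential closes the recovery loop exactly. Note the analysis
constant stays 150/120 per the printed relation even though the simulator
uses 151 mM external Cl⁻.

Additional phenomenology, each with a stated default:

* **Ca²⁺ activation** (`ca_scale`, default 9): channel current without
  Ca²⁺ is the full current divided by this factor, so the +100 mV fold
  recovers it. Genotype presets use 9 (WT), 5 (aperture mutant), 2 (neck
  mutant), 1 (double mutant), following the measured fold pattern.
* **Trans gain** (`trans_gain`, default 1): multiplies the inward-current
  limb of the *net* current under external CH₃SO₃⁻. The gain is sign-gated
  on the net current rather than applied to the internal-Cl⁻ flux
  component because gating modifies conductance, not the ionic
  equilibrium: a component-wise gain would shift the simulated reversal
  potential and corrupt the permeability read-out, which is not how a
  gating effect behaves.
* **Leak** (nS, default 0) adds an ohmic term; **noise** (default 6 pA,
  ≈1 % of the ~600 pA maximal wild-type current) is the standard
  deviation of each steady-state point. Step traces carry per-sample noise
  scaled so the final-window mean has exactly that SD, and the returned
  I–V curve is produced by the same steady-state extractor the analysis
  uses, keeping simulation and analysis noise models consistent.
* **Cell variability**: capacitance ~ N(15, 3²) pF truncated above 5 pF,
  channel density log-normal (σ = 0.15) and proportional to capacitance;
  all conditions of a cell share one scale, as in a real solution-exchange
  experiment.

A quantitative caveat the simulator makes explicit: under bi-ionic
conditions with P ratio 0.25 the raw trans statistic of a *pure* GHK
channel is ≈0.65, not 1 — rectification of the constant-field current
depresses the inward-limb slope at E_rev − 50 mV relative to the
near-ohmic symmetric-Cl⁻ condition. The statistic equals 1 under
independence only when permeation is matched (P_X·[X]out = P_Cl·[Cl]in),
which is the configuration the test suite uses as the independence null.
Consequently an *experimental* trans ratio above 1 for a selective channel
is an even stronger sign of genuine trans-gating than the ratio alone
suggests.

Fixtures: the structural generator emits five chains (A–E) at angles
2πk/5, each ring at its stated circumradius and z, with optional Gaussian
radial jitter and a single-point radial displacement for asymmetry tests.
Val/Leu rings include the second methyl 1.5 Å farther from the axis so the
pore-lining choice is exercised; Phe rings are full planar six-carbon
rings oriented so the inferred inward hydrogen lands exactly at the stated
circumradius; every residue carries a CA atom for superposition tests.
All generators are seed-deterministic down to byte-identical output files.

## What the synthetic data does and does not show

The generators emulate the *measurement geometry* (C5 symmetry, probe
placement, protocol shape, noise level, cell-to-cell scatter) but not
crystallographic error, side-chain conformational heterogeneity, series
resistance, capacitive transients, endogenous background conductances or
time-dependent gating. Passing the recovery tests therefore demonstrates
that the measurement pipeline is correct and unbiased under its stated
model, not that real recordings or crystal structures are free of those
additional effects. Measurements on deposited crystal structures require
the coordinate files, which are not redistributed with the package; the
loader (`load_deposited`) resolves a local `data/deposited/` mirror, and
the corresponding end-to-end checks fail with a clear diagnostic until the
entries are placed there.

## Numerical choices and problem sizes

Interpolation of E_rev on the 20 mV grid carries an O(0.1 mV) curvature
bias for GHK curves (≈1 % on a recovered P ratio of 0.25), and reversal
noise near the crossing dominates the per-cell scatter; recovery tests
therefore average n = 6 cells, the study's typical group size. When a
trans gain is present the steepened inward limb additionally biases the
interpolated crossing upward by ~1–2 mV, so genotype presets that carry a
gain (e.g. the wild type) read back P ratios ≈5 % low on the 20 mV grid —
visible in the worked example (0.229 recovered vs. 0.25 truth). This is a
property of the measurement protocol, not of the estimator; a finer step
protocol removes it. The
adjacency oracle cross-check uses 1000 random non-degenerate rings at
1e-9 Å tolerance; the t-test calibration uses 10,000 null replicates at
n = 5 per group; the unbiasedness check uses 200 replicates at 1 % noise.
These sizes keep the full suite and the acceptance script within a few
seconds while leaving Monte-Carlo error well below the asserted
tolerances.
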