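# Methods

## The generative model

The synthetic heat-ramp generator treats the channel as a two-state
(closed/open) system in thermal equilibrium. The open probability follows
the van't Hoff form

    P(T) = 1 / (1 + exp((ΔH − T·ΔS) / (R·T)))

with activation enthalpy ΔH (kJ/mol) and entropy ΔS (kJ/(mol·K));
P = 1/2 at T_half = ΔH/ΔS, and a large positive ΔH makes activation steep.
The recorded current magnitude is

    |I|(T) = [ leak_ref · q10_leak^((T−25)/10) + i_max · P(T) ] · (1 + ε),
    ε ~ N(0, noise_sd²),

i.e. a weakly temperature-dependent leak plus the gated conductance, under
multiplicative Gaussian noise (recording noise in TEVC scales roughly with
current amplitude). Inward current at −80 mV is stored negative; all
analyses use magnitudes. In Arrhenius coordinates (ln |I| vs 1/T) this
model produces exactly the shape the threshold procedure assumes: a
shallow leak baseline (slope set by q10_leak) that bends into a steep
activation limb whose low-occupancy slope is −ΔH/R.

### Default study conditions

| parameter | default | why |
|---|---|---|
| ΔH | 250 kJ/mol | apparent activation energies of heat-gated TRP currents are of order 100–300 kJ/mol; 250 gives the steep, high-Q10 limb typical of TRPV1 |
| i_max | 4000 nA | µA-scale maximal currents typical of oocyte TEVC |
| leak_ref | 150 nA at 25 °C | a few percent of i_max, as in healthy oocytes |
| q10_leak | 1.3 | near-ohmic leak with mild thermal speed-up |
| noise_sd | 0.03 | 3 % multiplicative noise, a realistic recording CV |
| ramp | 10 → 40 °C, 0.5 °C/s, 2 Hz | 40 °C is the conventional ceiling for oocyte heat stimulation; start low enough that cool-activated channels retain a baseline segment |

Kelvin conversion is fixed at T_K = T_C + 273.15 throughout; user-facing
temperatures are °C, thermodynamic arithmetic is in K. The capsaicin
reference current of a simulated cell defaults to i_max: a saturating
agonist dose opens essentially all channels.

The dose–response generator draws multiplicative-noise replicates around a
Hill curve (acid doses are carried as pH and converted to molar [H+] only
for fitting). The melt generator uses a two-state van't Hoff unfolded
fraction with midpoint T_m on the standard 10–95 °C / 0.5 °C grid; its
noise is additive, expressed as a fraction of the fluorescence amplitude.
Post-peak dye-aggregation decay (typical of SYPRO assays) is off by
default but can be enabled to exercise the truncation rule. Mutant panels
draw ΔΔG uniformly and add Gaussian noise around a linear
threshold-vs-ΔΔG relation; a negative slope emulates destabilizing
mutations lowering the threshold.

### What the generator does not emulate

No desensitization or run-down, no rate dependence of thresholds, no
stochastic single-channel gating, no voltage dependence, no capacitive or
series-resistance artifacts, and no cell-to-cell variation in expression
beyond the seed-to-seed noise. Passing recovery tests therefore shows the
estimators are correct and calibrated *for this data model*; on real
recordings, artifacts outside the model (e.g. desensitizing ramps) still
require the usual experimental quality control.

## Threshold detection

The Arrhenius profile is x = 1/T_K, y = ln |I|, sorted ascending in x;
samples with |I| = 0 are outside the ln domain, dropped and counted.
Analysis caps at t_max (default 40 °C, the oocyte stimulation ceiling).

*Steepest component.* All contiguous windows of `min_points` samples
(default 10) are scanned (vectorized via cumulative sums); windows with
r² ≥ `r2_min` (default 0.90) are candidates and the one maximizing |slope|
is chosen. Ties — which arise only on noiseless, exactly collinear
profiles and are detected with a 1 × 10⁻⁹ relative tolerance — break
toward the *coldest* tied window. This matters: on an exact two-segment
profile every all-steep window has the same slope, and only the window
abutting the breakpoint leaves a clean baseline region below it; any
hotter choice would sweep leftover steep samples into the baseline fit.
With that rule, constructed breakpoints are recovered to better than
10⁻⁶ °C (the package's exactness guarantee).

*Baseline.* Least squares over all samples colder than the steep window,
excluding a `guard_gap` (default 2 samples) against smear at the bend. A
constant baseline with zero residuals is assigned r² = 1 so noiseless flat
segments are not rejected.

*Intersection.* The threshold solves baseline(x) = steep(x) in 1/T
coordinates; fits parallel to within tolerance raise a no-intersection
error, and an intersection outside the profile's temperature range is
flagged rather than silently returned.

The detected threshold marks activation *onset* — where the gated current
emerges from the leak — so it sits below T_half by an amount controlled by
ΔH and the leak-to-gated ratio (≈ 10 °C under the defaults). Both
summaries are reported; their ordering (threshold ≤ half-max) holds on
every monotone-activation trace and is enforced by test.

## Q10 and half-max temperature

Q10 is computed from the steep-segment slope: Ea = −slope·R, then
Q10 = exp(Ea·10/(R·T_ref·(T_ref+10))). The reference temperature defaults
to the steep segment's midpoint (configurable); on pure-exponential
currents the slope route agrees with the direct ratio |I|(T+10)/|I|(T) to
well under 1 %. A non-negative slope yields Q10 ≤ 1 and a warning flag
rather than an error.

The half-maximal activation temperature uses the leak-subtracted current,
gated(T) = |I|(T) − exp(baseline(1/T_K)): subtracting the extrapolated
baseline makes the summary invariant to leak size. A no-subtraction mode
exists for traces without a usable baseline fit. The 50 % crossing is
located by linear interpolation between bracketing samples (error below
one grid step).

## Hill fitting

r(C) = r_max·Cⁿ/(ec50ⁿ + Cⁿ), bounded least squares (lmfit), n free in
[0.3, 10]. Initialization: ec50 at the geometric median dose, n = 1,
r_max at the maximal response; five starts jitter log-ec50 over ±1 decade
and the lowest-RSS converged fit wins. Acid tables are converted
pH → [H+] = 10^(−pH) first and potency is also reported as
pH50 = −log10(ec50). The fit is scale-free in the response, so
pre-normalized and raw responses give identical potency parameters.

## Melt curves

Normalization follows ΔF(t)/ΔF_max = (F(t) − F(20 °C))/(F_max − F(20 °C)),
with the reference taken as the nearest grid sample within 0.25 °C of
20 °C and F_max the global maximum of the raw curve; the formula is affine
invariant, so instrument gain and offset cancel. T_m is, by default, the
midpoint of a Boltzmann sigmoid

    y(T) = lower + (upper − lower) / (1 + exp((tm − T)/k))

fitted to the ascending region between the reference and the maximum. The
plateau levels are left free because the normalized curve is pinned to
single — hence noisy — samples at 0 and 1; fixing the amplitude would
transfer that sample noise into a midpoint bias of several tenths of a
degree at 2 % noise, while the free-plateau fit recovers T_m with a median
error near 0.05 °C under the same conditions. Truncation at the maximum
keeps post-peak aggregation decay out of the fit. Alternatives:
`half_max_interp` (first 0.5-crossing, linear interpolation) and
`derivative_max` (steepest rise, 3-point parabolic refinement); a
non-converging Boltzmann fit falls back to half-max interpolation with a
flag. Replicate curves are fitted independently and summarized as
mean ± SE.

## Statistics

Pearson r on per-mutant (ΔΔG, threshold) pairs (replicates averaged per
mutant upstream), two-sided p from the exact t-transform with n − 2 df,
95 % CI via Fisher z (tanh(atanh r ± z₀.₉₇₅/√(n−3))). NaN pairs are
dropped with a flag; constant variables raise. Two-group contrasts use
Student's two-sided unpaired t (Welch optional); more groups use one-way
ANOVA, with Dunnett (vs control) or Tukey–Kramer (all pairs) adjusted
contrasts delegated to scipy's implementations — the module's contract is
the adjusted-p output shape, not a re-derivation of those procedures.

Calibration is verified by simulation: null (slope-0) panels give Fisher
intervals covering 0 at ≈ 95 %, sample r at generating |ρ| = 0.85 and
n = 16 is unbiased to < 0.05, and the t-test's type-I error at α = 0.05
lies in [0.04, 0.06] over 2000 null replicates.

## Pipeline and I/O

All file I/O lives in one module (tidy CSV/TSV, documented headers, parse
errors name line and column); analysis functions are pure. The pipeline
validates its JSON config against a strict schema (unknown keys rejected),
derives one seed per simulated trace from the base seed, records every
seed and flag in the run report, and serializes the report canonically
(sorted keys) so reruns with the same config hash are byte-identical.
Per-input failures are recorded with a reason and the run continues.
Temperatures are serialized in °C, currents in nA.

## Problem sizes

Recovery studies use 100 seeds per ramp condition (four T_half settings),
200 seeds for EC50 and T_m recovery, 500 panels for correlation
calibration and 2000 replicates for the t-test — sizes at which the
Monte-Carlo error of each summary is comfortably below the margin being
checked, while the full suite and the reproduction script each run in
seconds.

## Known limitations

* The threshold depends on the window rule (`min_points`, `r2_min`): the
  literature defines "baseline" and "steepest component" only informally,
  so absolute thresholds are comparable across traces analysed with one
  configuration, not across configurations.
* Very shallow activators (Q10 ≲ 2) may fail the r² criterion and raise
  a no-steep-component error by design rather than return an unstable
  intersection.
* Hill EC50s for acid assume responses are monotone in [H+]; biphasic
  proton responses are out of scope.
* The ΔΔG values in mutant panels are inputs; the package does not compute
  folding energies.
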