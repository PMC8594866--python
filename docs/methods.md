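# Methods

This note records the models implemented in `dielkin`, the numerical
choices behind them, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Dielectric model

The complex permittivity of one isothermal sweep is

    eps*(w) = eps_inf + sum_i d_eps_i / (1 + (i w tau_HN,i)^a_i)^b_i - i A / w^s,

with angular frequency `w = 2 pi nu` (interfaces always take `nu` in
Hz; `w` exists only internally). Each Havriliak–Negami (HN) component
has a dielectric strength `d_eps > 0`, a time parameter `tau_HN > 0`
and shape exponents `a, b` in (0, 1]; `a = 1` is Cole–Davidson (CD),
`b = 1` Cole–Cole (CC), `a = b = 1` Debye. Complex exponentiation uses
the principal branch, and the loss eps'' is reported positive
everywhere (the imaginary part of the returned complex arrays).

The conductivity term contributes `A / w^s` to the loss only. The
physical prefactor sigma_0/eps_0 is absorbed into the single amplitude
`A` because only the product is identifiable from a loss spectrum;
`s` is bounded to (0.5, 1.2], near 1 for ohmic conduction.

The loss-peak time of an HN component is the closed form

    tau_max = tau_HN [sin(a pi/(2(b+1)))]^(-1/a) [sin(a b pi/(2(b+1)))]^(1/a),

which reduces to `tau_max = tau_HN` for CC and Debye. The test suite
validates it against a brute-force two-stage grid argmax of the
evaluated loss (relative agreement better than 1e-4 over 200 random
shape pairs; typically 1e-6).

## Spectral fitting

Fits minimize the *logarithmic* loss residual
`log eps''_model - log eps''_data`, which balances the many decades of
dynamic range of a broadband sweep; a joint objective adding relative
eps' residuals (`objective="complex"`) is available, with loss-only the
default since loss spectra are what is normally fitted. Parameters are
fitted in log10 for positivity (`log10 tau_HN` in [-12, 6],
`log10 d_eps` in [-4, 3]); shape exponents live in [0.05, 1]. The
optimizer is trust-region least squares (lmfit/`least_squares`), which
proved markedly more robust on the 50–80-parameter global fits than
Levenberg–Marquardt without bound transformations.

Initialization is automatic: local maxima of the 5-point
median-filtered log-loss, ranked by prominence (a weak secondary
shoulder has large log-prominence against the power-law flank of a
strong neighbour, while noise wrinkles do not), seed `tau`; `d_eps`
starts at twice the peak height. Up to five seeded restarts jitter and
then uniformly resample the time parameters inside the window. A
component whose fitted peak lies more than two decades outside the
window, or whose strength collapses to the lower bound, is flagged
`ill_constrained` on its record.

At most two HN components are fitted per window, following standard
practice for these materials (alpha + beta near and above T_g, gamma +
gamma' deep in the glass). `fit_with_selection` implements the 1-vs-2
component choice: two components are kept only if they improve the
residual norm by more than 20%, both peaks are within two decades of
the window, and their loss-peak times differ by more than a factor 3
(closer pairs are merged — overlapping HN pairs are weakly
identifiable).

The window matters: a two-component alpha+beta template is only a
complete model where the gamma processes do not yet contribute. The
tests fit alpha+beta in 10^-2–10^5 Hz (or tighter at low temperature);
pushing the window to 10^6 Hz visibly biases the shared CD exponent
because the gamma flank leaks in.

**Shared-shape series fit.** Time–temperature superposition of the
alpha peak is exploited by making one shape exponent a single global
parameter across all spectra of a series while times and strengths
stay per-temperature. The global fit is seeded by independent
per-spectrum fits; seeds that are flagged, or sit more than half a
decade off the Arrhenius-like trend of `log10 tau` vs 1/T (label swaps
between overlapping processes), are replaced by the trend prediction.
`master_curve` checks superposition model-free: every loss curve is
rescaled by its peak frequency and height (median-smoothed argmax with
parabolic refinement) and the overlap deviation is the maximum
pointwise standard deviation across curves on their common support.

## Relaxation map

Two VFT parameter conventions circulate in the literature and differ
by a factor ln 10 in `D`:

* natural: `log10 tau = log10 tau0 + D T0 / (ln10 (T - T0))`
* decadic: `log10 tau = log10 tau0 + D T0 / (T - T0)`

Both are first-class in `dielkin`; every fit and report states its
convention, and conversion is exact (the evaluated curve, the kinetic
T_g and the fragility are invariant under conversion — a tested
property). The distinction is not pedantry: for the benzodiazepine
parameter set bundled in the presets, the printed kinetic T_g values
are reproduced only under the decadic reading, while the printed
fragility m_p ≈ 32 is reproduced only by applying the
natural-convention derivative formula to the same numbers. The decadic
reading of the same curve gives m_p ≈ 72 — i.e. the published
parameters are internally inconsistent across conventions, and the
package surfaces rather than hides this. Presets adopt the decadic
reading (it reproduces the kinetic T_g, which is the anchored
observable).

Kinetic T_g solves `log10 tau(T) = 2` (tau = 100 s) analytically:
`T_g = T0 + D T0 / (c (2 - log10 tau0))`, `c = ln 10` or 1 by
convention. Fragility is the analytic slope
`m_p = D T0 T_g / (c (T_g - T0)^2)`; a pure Arrhenius process gives
the minimal value `m_p = 2 - log10 tau0`.

`fit_vft` seeds the nonlinear fit by scanning 400 candidate Vogel
temperatures (each leaving a linear subproblem) and refines with
bounded least squares; `T0` is constrained below the coldest data
point, and `D` may grow large so that the Arrhenius limit (T0 → 0 with
`D T0` finite) is representable. Note that the three VFT parameters
are strongly correlated: from a 30–40 K window even percent-level
noise moves the individual parameters while leaving the curve — and
hence T_g and m_p — essentially unchanged. Tests of parameter recovery
therefore use series whose alpha peak stays at least about 1.5 decades
inside the measurement window (T_g+12 to T_g+45 with the default
grid), where the per-temperature times carry no window-edge bias.

Secondary processes use `ln tau` vs `1/T` linear regression
(R = 8.314 J mol^-1 K^-1; Ea in kJ/mol). `detect_kink` fits two
Arrhenius segments with an exhaustive breakpoint search over the data
temperatures (at least three points per side; global optimum
guaranteed on these small grids) and reports the intersection of the
two lines when it falls between the straddling points.

Coupling model: `n = 1 - (ab)^(1/1.23)` from the alpha shape;
`tau_JG = t_c^n tau_alpha^(1-n)` with `t_c = 2 ps` by default,
evaluated in log space. The prediction is reported for comparison with
the measured beta times; experimentally the two can differ by orders
of magnitude, so no quantitative agreement is asserted anywhere.

T_g/T_m ratios are reported truncated (not rounded half-up) to two
decimals, the convention the published benchmark ratios for these
materials follow; the full-precision value is retained alongside.

## Crystallization kinetics

The static permittivity is read as eps' at a low probe frequency
(log-frequency linear interpolation off-grid). Onset detection is a
threshold rule — the first sample below
`plateau_mean - max(3 sd, 0.5% of mean)` persisting for three samples —
with two robustness layers:

1. the plateau statistics are re-estimated from *all* pre-trigger
   samples (a 5-point sd estimate makes a 3-sigma threshold far too
   jittery, and at 0.5% measurement noise the 0.5% floor sits at only
   one sigma);
2. the reported onset is then refined by a direct Avrami fit of the
   raw decay with the onset time free, because the threshold rule has
   a lag/jitter of a few sampling intervals that would otherwise tilt
   the Avrami plot and bias the exponent.

A trace that never leaves its plateau returns a none-sentinel — the
behaviour of a sample that does not recrystallize — and the pipeline
reports "no crystallization detected".

Normalization follows
`eps_n = (eps_s(SL) - eps_s(t)) / (eps_s(SL) - eps_s(C))`;
`eps_s(SL)` is the pre-onset plateau mean and `eps_s(C)` the mean of
the final five points if the tail has flattened (relative change
< 0.2%), otherwise the hold was too short and `eps_s(C)` is left free
in a nonlinear fit of the raw trace. Raw `eps_n` values are used for
fitting; clipping to [0, 1] happens only in reports.

The Avrami fit linearizes `ln(-ln(1 - eps_n))` against
`ln(t - t_onset)` over the band 0.03 ≤ eps_n ≤ 0.97 (the transform
diverges at both ends). The regression is *weighted* by the
delta-method factor `((1 - eps_n) ln(1 - eps_n))^2`: for homoscedastic
eps_s noise the transform amplifies errors by its inverse, enormously
near the band edges, and an unweighted fit would be dominated by the
least informative points. A direct nonlinear fit of
`1 - exp(-Z t^n)` on the same points is attached alongside; on
noise-free data the two agree to 1e-6 (tested). `k = Z^(1/n)` holds by
construction.

## Synthetic-data generator

Material cards bundle per-process temperature laws, lineshapes,
strengths, conductivity, T_g / T_m and (for crystallizing materials)
Avrami parameters. Three presets emulate the benzodiazepines studied
by BDS: `dia_like` (does not recrystallize), `nor_like` and
`tetra_like`. Published values parameterize the alpha process
(decadic VFT triples, CD exponents b = 0.59 / 0.50 / 0.59), T_g / T_m
and the Avrami kinetics (n = 1.01, k = 7e-5 /s for tetra-like at
331 K; n = 1.1, k = 4e-5 /s for nor-like at 375 K). Everything else is
a documented plausible default flagged `paper_derived=False`:

* dielectric strengths (d_eps_alpha ≈ 5–6, secondaries 0.02–0.5,
  eps_inf = 3) are order-of-magnitude choices typical of polar drugs;
* the gamma process gets Arrhenius parameters consistent with its
  assignment to the ring-inversion conformational dynamics
  (~50 kJ/mol, similar times at equal absolute temperature in all
  three materials — which is also why gamma traces do *not* superpose
  in the Angell plot);
* the gamma' process is faster, weaker, and nearly absent in the
  nor-like card;
* the conductivity amplitude is fixed per card (real conductivities
  are temperature dependent; irrelevant for the tested pipeline);
* the beta (Johari–Goldstein) process is coupling-model-tied: above
  T_g, `tau_beta = 10 x t_c^n tau_alpha^(1-n)` (the 10x offset keeps
  the realistic gap between prediction and observation), below T_g an
  Arrhenius continuation (55–60 kJ/mol) anchored at the T_g value.
  This produces the kink at T_g automatically and — unlike a fixed
  above-T_g activation energy — can never cross the alpha trace.
  A plain two-segment `arrhenius_kink` law is also available.

Onset times (5000 s tetra-like, 8000 s nor-like) are typical hold
scales; default crystallization time grids are 60 log-spaced points
from onset/50 to 99.5% completion, leaving roughly half the points on
the supercooled-liquid plateau.

Noise is multiplicative log-normal on the loss (default 1%) and
Gaussian on eps' with sd proportional to the static permittivity
(default 0.2%), independent across frequencies and across spectra
(seed streams spawned from one seed; identical card + seed is
bit-identical). Processes whose peak lies more than four decades
outside the grid are dropped.

What the generator does **not** emulate: electrode polarization and
Maxwell–Wagner interfacial processes, thermal lag, temperature drift
within a sweep, correlated (1/f) instrument noise, partial
recrystallization during cooling, and temperature dependence of
eps_inf or of the conductivity amplitude. Passing recovery tests on
this generator therefore demonstrates the correctness and the
statistical behaviour of the estimators under the stated noise model —
not robustness to every artifact of real cells.

## Numerical choices and degenerate inputs

* Frequencies must be strictly increasing and positive; spectra need
  at least 8 points (readers report offending file and line).
* Fit failure after the restart budget raises an error carrying the
  best residual; degenerate inputs (pure conductivity fitted with an
  HN template) converge with the spurious component flagged.
* Equal-tau component pairs are merged rather than reported (factor-3
  rule, see above).
* `tg_tm_ratio` warns (does not raise) when T_g ≥ T_m.
* Breakpoint and Vogel-temperature searches are exhaustive grids
  before refinement — global optima at these sizes, no luck needed.

## Problem sizes

The bundled tests and the acceptance script run series of 5–10 spectra
with 73 frequency points, crystallization holds of 60 time points, and
Monte-Carlo loops of 40–200 trace-level fits; the full suite completes
in well under a minute on one core.

## Known limitations

* Loss-only fitting cannot separate eps_inf; it is estimated from the
  high-frequency real part after subtracting fitted components.
* The beta process near T_g is a shoulder, not a resolved peak; its
  fitted times are intrinsically less precise than alpha's (records
  carry standard errors and flags for exactly this reason).
* VFT triples from narrow temperature windows are reported with their
  (large, correlated) standard errors; prefer T_g and m_p.
* Above T_g the beta activation energy may in reality vary with
  temperature; neither the analysis nor the generator models this.
* Non-isothermal (Ozawa/Kissinger) crystallization analysis and
  nucleation statistics are out of scope.
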