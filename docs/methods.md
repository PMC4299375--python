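# Methods

## The model

`tetrapulse` studies a control principle in the p53 DNA-damage response:
although the amount of total p53 induced by UV scales with the dose, cells
form transcriptionally active p53 *tetramers* at a rate that is nearly
independent of the input. The package models the minimal kinetic scheme
that produces this behaviour, simulates the two-channel reporter data that
would be collected from it, and implements the trajectory analysis and
statistics used to detect the effect.

Two species are tracked per cell: the p53 homo-dimer pool `D` and the
tetramer pool `Q` (tetramers are dimers of dimers). Dimerization is
co-translational, so no monomer species is modelled. After UV at dose `d`
(J/m²):

    dD/dt = β(t; d) − δ_D·D − 2·J(D)
    dQ/dt = J(D) − δ_Q·Q

with a piecewise-constant production envelope

    β(t; d) = β0 + β1·d   for 0 ≤ t ≤ τ0 + τ1·d,   β0 otherwise,

so both the amplitude and the duration of p53 production grow with dose,
and a saturable tetramerization flux

    J(D) = k_t·D² / (1 + D²/K_A).

`K_A` is the capacity of an ARC-like inhibitory "throttle" that sequesters
dimers: once `D² ≫ K_A` the flux is pinned at the ceiling `k_t·K_A`
regardless of how much p53 the cell makes. ARC knockdown is the limit
`K_A → ∞`, i.e. pure mass action `J = k_t·D²`. Oligomerization mutants
(L344A dimeric, L344P monomeric, M340E/L344K) have `J ≡ 0`.

The two fluorescence observables mirror a split-fluorophore
(protein-fragment complementation) reporter pair: RFP tags every monomer
and reports total p53; YFP is reconstituted only on tetramers, because
homo-dimers carry two copies of the same fragment and stay dark:

    RFP = α·(2D + 4Q) + c_R
    YFP = γ·Q + b·α·(2D + 4Q) + c

`b` is a small unspecific-complementation bleed and `c`, `c_R` are
autofluorescence offsets. The reconstituted fluorophore is irreversible:
YFP decays only through degradation of `Q` (rate `δ_Q`), never by complex
dissociation.

## Default parameters and the regimes they encode

No kinetic constants for this system are available; the defaults are
synthetic constants chosen once so that the model operates in the regimes
the biology implies, with a single pulse playing out over ~24 h of
15-min sampling. All abundances are arbitrary units (a.u.), time in
minutes.

| parameter | default | why |
|---|---|---|
| β0 | 0.002 a.u./min | low basal p53; keeps the resting dimer pool well below the throttle knee so the YFP pulse exists |
| β1 | 1.0 a.u./min per J/m² | dose-proportional production amplitude |
| τ0, τ1 | 180 min, 20 min per J/m² | elevated production for 240/300/420 min at 3/6/12 J/m², giving dose-dependent rise times |
| δ_D = δ_Q | 0.02 /min | ~35 min half-life. Equal decay rates make the total-monomer pool `2D+4Q` obey a closed ODE independent of `J`, so total p53 (RFP) is exactly insensitive to ARC status — the observed knockdown phenotype |
| k_t | 0.01 /(a.u.·min) | with the throttle removed this puts the cell in a conversion-dominated regime (most dimers tetramerize, `J ≈ β/2`), which is what keeps the knockdown tetramer/total ratio flat across doses |
| K_A | 1.0 a.u.² | deep saturation: the dimer pool crosses the knee `√K_A` within ~1 min of UV at every dose, so the flux ceiling `k_t·K_A = 0.01` a.u./min is reached almost immediately and the tetramer slope is dose-independent to ≲1% |
| α, γ | 0.2, 200 | put both channels on a comparable ~100 a.u. scale |
| b | 0.001 | nonzero so mutant YFP tracks total p53 as a pure background, but small enough that the dose-dependent RFP rise does not leak into the YFP slope or shift the YFP peak (at b = 0.005 the leak makes the noiseless YFP peak time non-monotone in dose) |
| c, c_R | 5 | autofluorescence floors |

Population defaults (`PopulationConfig`): n = 200 cells/condition, 1440 min
duration, lognormal mean-1 multipliers with CV 0.3 on `β1` and on `k_t`
(fluorescence amplitudes are positive and right-skewed), additive Gaussian
detection noise σ = 2 a.u. per channel and timepoint, clipped at zero
(a mild bias at very low signal). Each cell's RNG is keyed by
(seed, condition index, cell index), so growing a population never
reshuffles existing cells. Default doses are {3, 6, 12} J/m²: 3 and 6 are
the doses used experimentally; 12 extends the series to a 4-fold range and
is user-overridable.

## What the generator emulates — and what it does not

It emulates: single-pulse two-channel dynamics with dose-dependent
amplitude and rise time; a tetramerization flux that is constant across
doses with the throttle active and input-tracking without it; dark
homo-dimer background for non-tetramerizing mutants; 15-min sampling;
multiplicative cell-to-cell spread plus additive detection noise.

It does not emulate: Mdm2-driven oscillatory dynamics (double-strand-break
responses), cell division or lineage structure, photobleaching, YFP
maturation delay (uncharacterized; omitted — YFP would otherwise lag `Q`
by a maturation time), segmentation/tracking errors, or transcriptional
consequences downstream of tetramer formation. Passing tests therefore
show that the pipeline correctly detects these patterns when the model
generates them — not that real microscopy data are free of the artifacts
above.

## Trajectory analysis

Troughs and peaks are found by a 1-D watershed on a lightly smoothed copy
of each trace (centered moving average, default window 3 samples, shrunken
at the edges): candidate peaks are interior local maxima; a candidate is
kept when its prominence — height above the higher of the two flanking
basins, each basin delimited by the nearest strictly higher point — is at
least `prominence_frac` (default 0.2) of the trace's global range; each
kept peak pairs with the minimum of the trace since the previous kept peak
(or the trace start). Endpoints are never peaks; ties break earlier. The
0.2 default detects noise-free single pulses always and pure-noise traces
almost never.

Features use the first trough/peak pair. Rise time is `t_peak − t_trough`.
Slope is the maximum increase over any 60-min window between trough and
peak, per hour, computed on the **raw** values (smoothing is for extremum
robustness only); when the rise is shorter than 60 min the average rate
over the rise is used instead, since a 1-h window is undefined there. Max
level is baseline-subtracted (peak minus trough) by default; the absolute
peak is available via `baseline_subtract=False`. Cells without a
detectable pulse are flagged invalid, excluded from downstream statistics
and countable from the `valid` column.

## Statistics

Group contrasts use the Mann-Whitney U test with midranks for ties: exact
two-sided p by full enumeration of all rank assignments when n1+n2 ≤ 14
(doubled smaller tail, capped at 1), otherwise the normal approximation
with tie correction and continuity correction. Medians are reported with a
bootstrap SEM (1000 seeded resamples) because the SEM of a median has no
finite-sample closed form. Slope conservation across doses is tested by
the lowest-vs-highest dose contrast — the most powerful two-group reading
of a single reported p-value per channel — with conservation declared at
p ≥ 0.05. No multiple-testing correction is applied; raw p-values are
reported.

## Mechanism discrimination

Both flux mechanisms are fitted to per-dose population-mean traces (the
mechanistic claim is about mean dynamics; hierarchical single-cell fitting
is out of scope). Free parameters: `β1, τ1, k_t` (+`K_A` for the
throttle); everything else is fixed. Residuals of both channels are summed
jointly across doses after scaling each channel by its global data maximum
— both reporters then constrain the fit despite arbitrary gains, while the
cross-dose amplitude pattern, which is what separates the mechanisms, is
preserved. The search is a deterministic log-space grid zoom: a 6-point
coarse grid per dimension, then six shrinking (×0.4) centered 5-point
grids, every candidate point and dose simulated in one vectorized batch.
Candidate points whose ODE diverges (stiff corners of the box at large
`k_t`) are skipped with a warning. Models are compared by
`AIC = n·ln(RSS/n) + 2k` (BIC also reported); exact ties select the
throttle — the biologically inferred mechanism — with a logged warning.

Bounds must be supplied explicitly (`DEFAULT_BOUNDS` provides a vetted box
for the default unit system). The default `K_A` box tops out at 10 a.u.²:
within it the throttle's flux ceiling (≤ 3 a.u./min) genuinely binds at
the highest dose, so a throttle cannot silently impersonate mass action —
keeping the ceiling informative is what gives the AIC comparison its
discriminating power. In the deeply saturated regime only the product
`k_t·K_A` is identifiable (the fit ridge is flat along it), so recovery is
asserted on the product, not the factors.

## Numerical choices

Fixed-step classical RK4, default `dt = 0.1` min, no adaptive stepping —
outputs are bit-reproducible. The production envelope is discontinuous in
time, so the integrator splits steps at the envelope breakpoints and every
RK4 step sees a smooth right-hand side (retaining 4th-order accuracy).
The step default is set by the stiffest feature of the model: after UV the
dimer pool crosses the throttle knee `√K_A` within ~0.2–1 min, and 0.1 min
keeps the trajectory within 1e-6 of a 100×-finer reference (measured
~4e-7 at dose 6; coarser 0.5-min steps leave ~1e-4 errors across the
knee). With production and degradation switched off, RK4 preserves the
linear invariant `2D+4Q` to floating-point roundoff. The pre-damage
steady state is found by 80 bisection iterations on the monotone dimer
balance. Fitting uses a 1.0-min step: its ~0.1% trajectory bias is far
below the population-mean systematic spread and affects both candidate
mechanisms equally. The solver-fidelity check runs a 720-min dose-6
trajectory — long enough to cover the elevated-production window and every
knee crossing — so the 100×-finer reference stays cheap.

## Known limitations

* The damping-flatness of the knockdown ratio and the input-tracking of
  the knockdown flux trade off against each other: a flat tetramer/total
  ratio across doses forces the knockdown flux to scale about
  proportionally with production (conversion-dominated regime), not
  faster. The defaults encode the flat-ratio regime; a degradation-
  dominated choice of `k_t` would instead give a quadratically scaling
  flux and a rising ratio.
* Fitting population means with per-cell nonlinearity leaves a small
  systematic floor in the RSS (the mean of trajectories is not a
  trajectory of the mean); model selection is robust to it because the
  mechanisms differ by large cross-dose signatures, but absolute RSS
  values should not be over-interpreted.
* Several headline contrasts (mutant-vs-mutant background, knockdown
  effect on total p53) are true nulls by construction, so their p ≥ 0.05
  checks carry the test's own ~5% false-positive rate under any seed.
* Negative-value clipping slightly biases very low-signal traces; with the
  default offsets (≥ 5 a.u.) clipping is rare.
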