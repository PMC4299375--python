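# tetrapulse

Simulation and single-cell trace analysis of p53 tetramerization dynamics
after UV damage.

p53 works as a tetramer. In single cells, UV irradiation triggers a pulse
of p53 whose amplitude grows with dose — yet the *rate* at which p53
tetramers form stays nearly constant across doses, because an inhibitory
"throttle" (the ARC protein, which sequesters p53 dimers) caps the
tetramerization flux. This breaks the linear input–output relation and
damps the active fraction of p53 at high damage. `tetrapulse` is a
pipeline for studying that control principle in silico, aimed at
quantitative cell biologists who want a testbed for two-channel
(total vs tetramer) reporter trajectory analysis.

## The model in brief

Per cell, a dimer pool `D` and tetramer pool `Q` evolve as

```
dD/dt = β(t; d) − δ_D·D − 2·J(D)        β(t; d) = β0 + β1·d  for  0 ≤ t ≤ τ0 + τ1·d
dQ/dt = J(D) − δ_Q·Q                    J(D)   = k_t·D² / (1 + D²/K_A)
```

where `d` is the UV dose. With ARC present the flux `J` saturates at the
ceiling `k_t·K_A` (constant tetramerization rate); ARC knockdown is the
mass-action limit `K_A → ∞`. A split-fluorophore reporter pair maps state
to observables: `RFP = α·(2D+4Q) + c_R` (total p53) and
`YFP = γ·Q + b·α·(2D+4Q) + c` (tetramers only — homo-dimers carry two
identical fragments and stay dark). Populations add lognormal cell-to-cell
multipliers on `β1` and `k_t` plus additive detection noise.

The analysis extracts, per cell and channel, the features used in
time-lapse p53 studies: watershed-detected first trough/peak, **rise
time** (trough to peak), **slope** (max increase over a 1-h window, per
hour) and **max level**, then tests *slope conservation* across doses with
Mann-Whitney U statistics and discriminates the throttle from mass action
by AIC model fitting. See `docs/methods.md` for the full account.

## Worked example

Simulate 50 cells at each of three UV doses, extract pulse features, and
test slope conservation per channel:

```
$ cat experiment.yaml
population: {n_cells: 50, duration: 1440, seed: 11}
conditions:
  - {uv_dose: 3}
  - {uv_dose: 6}
  - {uv_dose: 12}

$ tetrapulse simulate --config experiment.yaml --out traces.csv
wrote 150 traces to traces.csv
$ tetrapulse analyze --traces traces.csv --out features.csv
wrote 300 feature rows to features.csv (0 without a detectable pulse)
$ tetrapulse stats --features features.csv --out report.json
wrote slope-conservation report to report.json
```

`report.json` then contains, per channel, dose-sorted median slopes with
bootstrap SEMs and the lowest-vs-highest-dose Mann-Whitney contrast. With
the run above:

* **RFP (total p53)** — median slopes 38.7 / 80.8 / 176.1 a.u./h at
  3 / 6 / 12 J/m², p = 7.1e-18: the accumulation rate of total p53 tracks
  the dose, as expected for dose-proportional production.
* **YFP (tetramers)** — median slopes 67.8 / 69.6 / 67.1 a.u./h,
  p = 0.57, `conserved_at_alpha_0.05: true`: the tetramer formation rate
  is flat across a 4-fold dose range — the throttle at work.

Re-running `simulate` with `arc_status: knockdown` in each condition
breaks the YFP conservation while leaving the RFP dose response unchanged,
and `tetrapulse fit` (given a config with parameter bounds) fits both flux
mechanisms to the per-dose mean traces and reports the AIC-selected one.

The same objects are available as a library
(`tetrapulse.generate_population`, `features_table`,
`slope_conservation_test`, `select_mechanism`, ...); the canned
experiments live in `tetrapulse.protocols`.

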