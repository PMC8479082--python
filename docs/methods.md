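# Methods

## The exchange model and its assumptions

The package models a pair of mice whose circulations are connected in a
closed loop through two fluorescence counters. Each circulation is treated as
a single well-mixed compartment: the intra-mouse blood turnover (cardiac
output of tens of mL/min against a 1.5–2 mL blood volume) is orders of
magnitude faster than the 60 µL/min exchange flow, so the CTC concentration
seen by the sampling cannula is the whole-blood average. Under that
assumption the system is the linear ODE pair given in the README, with four
physical parameters:

| parameter | meaning | units | default |
|---|---|---|---|
| `r_gen` | CTC generation (intravasation) rate into the TBM | CTCs/min | — |
| `t_half_s` / `k_clear` | circulatory half-life / clearance constant | s / 1/min | — |
| `V` | blood volume per mouse | mL | 1.75 |
| `Q` | pump flow rate | µL/min | 60 |
| `transport_delay` | tubing transit time per direction | min | 2 |
| `duration` | experiment length | min | 240 |

`V = 1.75 mL` is the midpoint of the 1.5–2 mL range for an adult mouse; both
mice share one `V` and one `K_clear` (the model is symmetric apart from the
generation term). Clearance is first-order and memoryless — capillary
trapping and cell death are not distinguished. The primary tumor is assumed
to be the sole CTC source, and cells (not clusters) are the counting unit.

Internally all computation uses minutes, mL and cells; seconds appear only
when a half-life is reported. The dimensionless group `k = K_clear·V/q`
(clearance per blood-volume-exchange) controls everything at steady state:
`r1/r2 = 1 + k` and `r2 = r_gen/(k(k+2))`. These two relations invert to the
closed-form estimators `r_gen = (r1 − r2)(1 + r1/r2)` and
`t_1/2 = (V/Q)ln2/(r1/r2 − 1)`; the package verifies the inversion as a
machine-precision round-trip property rather than trusting any transcription
of the algebra.

## Transport delay

The ~2 min tubing transit is modeled as a pure lag: blood sampled at `t`
reaches the downstream counter and the other mouse at `t + τ`, and the cell
is in neither pool meanwhile. The deterministic integrator implements this as
a delay differential equation by the method of steps (segments of length τ,
DOP853 within each segment, rtol 1e-10), with a cell-free-tubing history
before the start. The delay affects transients and end-of-run totals only;
the steady-state closed form is delay-invariant. Setting
`transport_delay = 0` recovers the plain ODE pair.

The integrator's augmented state carries the running integrals of both
counter rates and of the clearance flux, so cumulative detected counts and
the conservation identity
`r_gen·t + n(0) = n1 + n2 + in_transit + cleared` (checked to 1e-6 relative)
come out of the same solve.

## The stochastic simulator (what the synthetic data emulate)

Because the model is linear, cells are independent: each cell in a pool faces
an exponential race between clearance (hazard `K_clear`) and sampling
(hazard `q/V`); sampled cells are detected downstream after τ and join the
other pool. The simulator exploits this to sample per-cell fates in
vectorized waves — one wave per pool dwell — which is distributionally
identical to an exact global next-event (Gillespie) simulation but runs a
4-h, ~100k-cell experiment in tens of milliseconds. Each run records a full
accounting (generated = cleared + pools + in-transit, exact per seed), the
per-pool entry/exit history, and the seed; identical seed and parameters
reproduce the event log bit-for-bit. An optional per-passage
detection-failure probability (default 0, the instrument's verified losses
being below a few percent) thins the log without touching cell fates, and
uses a seed-derived side stream so fates are comparable across settings.

Injection experiments use the empirically motivated two-subpopulation
clearance: a fraction `fast_fraction` (default 0.98) of cultured cells clears
with `t_half_fast_s` (default 5 s) and the rest persists with
`t_half_slow_min` (default 3 h — the persistent population is observed "for
several hours" but its half-life is not pinned down; the value is a declared
assumption). Bolus injections spread 25,000 cells over ~1 min; slow
infusions are a Poisson stream (default 30 cells/min, matching the scale of
endogenous transfer). Scan detections are a Poisson thinning of each cell's
circulating lifetime at hazard `Q_scan/V`, so a persistent cell is recounted
on every pass — which is why cumulative detected/injected fractions, not
instantaneous rates, are the right comparator between infusion and exchange
experiments.

What the synthetic data do *not* emulate: organ-resolved trapping, CTC
clusters, immune interactions, blood rheology, pump pulsation in the event
times (it appears only in the PMT baseline), and stepwise vial replacement
during slow infusion (modeled as a constant rate). Passing tests therefore
demonstrate correctness of the analysis under the model's own law, not that
real CTCs obey first-order kinetics.

## PMT trace synthesis and detection

Traces are synthesized at 30 kHz: a DC offset plus a slow sinusoid (default
4 Hz, emulating peristaltic pulsation), two Gaussian pulses per event
(σ = 0.15 ms) separated by the laser-line transit time, and white Gaussian
noise. The dual-peak separation defaults to the flow-geometry value: mean
velocity `v = Q/(300 µm × 45 µm)` and a 100 µm line spacing give 1.35 ms at
60 µL/min. The line spacing is a configurable assumption.

Detection follows the instrument's offline chain: subtract a trailing
rank-100 median (exact trailing window, prefix medians at the start of the
trace), smooth with a zero-phase Chebyshev type-I lowpass, threshold at 5×
the shot-noise SD, and pair candidate maxima. The Chebyshev design
(order 5, 0.5 dB ripple, 1 kHz cutoff at 30 kHz) and the pairing bounds
(height ratio 0.5–2, separation 0.5–5 ms) are declared calibration defaults:
they preserve millisecond-scale pulses and accept the geometric separation,
but the original instrument's exact values are not public. The noise SD is
estimated by scaled MAD so sparse pulses cannot inflate the threshold.
Pairing is greedy left-to-right with each maximum used in at most one
accepted pair; rejected candidates carry a reason (unpaired, separation out
of bounds, height ratio out of bounds). Raising the threshold can, in
principle, re-partition pathological peak sequences, but on dual-peak traces
the accepted-call count is non-increasing in the threshold (tested).

Note one physical limit: the 1 kHz smoothing merges structure finer than
about a millisecond, so events closer than the filter's resolution appear as
a single dual-peak candidate rather than two rejected ones.

Full-length 4-h traces at 30 kHz (~430 M samples) are deliberately never
materialized; the pipeline synthesizes and verifies bounded windows
(sub-minute to a few minutes), which is where the detection claims are
tested.

## Steady-state estimation

Cumulative counter trajectories are binned at 1 min and fitted by ordinary
least squares over the terminal 30, 45, 60, 75 and 90-min windows (intercept
free). Each window's (r1, r2) is converted to a generation rate and
half-life; the reported value is the across-window mean and the uncertainty
the across-window SD. Per-window conversion (rather than converting the
averaged rates) is the default because it mirrors the experimental
procedure of assessing rates from several steady-state intervals; the pooled
variant is available and agrees on stationary input. Windows with `r2 ≤ 0`
or `r1 ≤ r2` carry no half-life information and are excluded with a warning;
if all are excluded the estimate fails loudly.

A stationarity diagnostic compares terminal count-difference rates across
windows. For nested windows sharing the trajectory end the counting-error
variance of the rate difference has the exact form
`Var(λ_w − λ_W) = λ(1/w − 1/W)`; deviations beyond `z` SDs are flagged. The
default `z = 3.5` is calibrated so that a constant-rate Poisson process is
flagged in well under 5% of runs despite the eight comparisons per
experiment (Poisson tails at window counts of ~15 are noticeably heavier
than Gaussian at `z = 3`).

At the reference regime (r_gen ≈ 406 CTCs/min, t_1/2 ≈ 93 s) the median
relative error of both recovered parameters across 200 simulated 4-h
experiments is about 6%, dominated by the ~500-count return trajectory; the
estimator is unbiased to within 1%.

## Shedding metrics

`shed_per_day = 24·r_gen`, `shed_per_gram_per_day = shed_per_day / mass`,
`percent_per_day = 100·shed_per_day / (mass · cells_per_gram)` with
`cells_per_gram = 1e9` by default. Tumor mass is a direct input; for
ultrasound-measured tumors an empirical linear regression
`mass[mg] = 1.912·volume[mm³] − 50.09` is provided (its fit quality,
R² = 0.84, is metadata from the source data, not recomputed here), and
volumes at or below the regression root are rejected as out of range.

## Numerical and design choices

- Parameter containers are frozen dataclasses validated at construction;
  `t_half_s` and `k_clear` are kept mutually consistent
  (`K·t_1/2 = ln 2`) and supplying an inconsistent pair is an error.
- `Q = 0` is accepted by the model (the no-exchange limit used for
  closed-form decay checks) even though a real experiment requires `Q > 0`;
  steady-state rates are defined only for `Q > 0`, `K_clear > 0`,
  `r_gen > 0`. A pump flow exceeding one blood volume per minute warns but
  does not fail.
- The simulator keeps every random decision on a single `numpy` Generator
  seeded from the experiment seed (plus one derived side stream for counter
  losses), so runs are exactly reproducible and seeds below 2^31 are always
  valid.
- Problem sizes in the test suite are desk-scale by design: 200-replicate
  recovery studies at the full 4-h, ~100k-cell regime (seconds in total,
  thanks to the wave simulator) and PMT traces of 10–60 s at 30 kHz.
- CLI exit codes follow click's convention: 0 success, 1 handled failure,
  2 usage error.

## Known limitations

- The well-mixed, single-compartment assumption ignores first-pass organ
  trapping; a cell returning to the jugular vein is immediately
  representative of the whole circulation.
- One `K_clear` is shared by both mice; a tumor-conditioned circulation
  could in principle clear differently.
- The estimators assume the terminal interval is truly stationary; the
  diagnostic flags gross violations but cannot certify steady state.
- Detection-chain parameters are calibration defaults, not instrument
  ground truth; absolute recall/precision claims hold for the synthetic
  pulse model at the configured SNR.
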