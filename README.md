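# ctckinetics

Circulating tumor cells (CTCs) are the blood-borne intermediaries of
metastasis, but two of their most basic kinetic parameters — the rate at which
a tumor sheds them into the circulation (the intravasation or *generation*
rate, r_gen) and how long they survive there (the circulatory half-life,
t_1/2) — are hard to measure directly. One experimental route is to exchange
blood continuously between a tumor-bearing mouse (TBM) and a healthy
counterpart (HM) through a closed loop carrying two in-line fluorescence
counters, and to read both parameters off the steady-state cell transfer
rates.

`ctckinetics` is a toolkit for designing and analysing such experiments. It
provides, for researchers working on CTC dissemination kinetics:

- the **two-compartment exchange model** and its closed-form estimators,
- a **stochastic event-level simulator** of exchange and of bolus/slow
  cell-injection experiments (the synthetic-data generator for the pipeline),
- the **PMT signal-processing chain** that turns raw photomultiplier traces
  into validated dual-peak CTC detections,
- **steady-state rate estimation** from cumulative count trajectories with
  window-based uncertainties, and
- **tumor-shedding metrics** (cells shed per gram per day, percent of the
  tumor shed per day).

## Model

Each mouse is a well-mixed compartment of blood volume V. CTCs enter the TBM
circulation at constant rate r_gen, clear from both mice with first-order
rate constant K_clear = ln(2)/t_1/2, and are pumped between mice at
volumetric flow Q, so each counter sees rate r_i(t) = C_i(t)·Q with
C_i = n_i/V:

    dn1/dt = −C1·Q + C2·Q − K_clear·n1 + r_gen      (tumor-bearing mouse)
    dn2/dt =  C1·Q − C2·Q − K_clear·n2              (healthy mouse)

At steady state the measured counter rates r1, r2 invert to

    r_gen = (r1 − r2)(1 + r1/r2)                [CTCs/min]
    t_1/2 = (V/Q)·ln(2) / (r1/r2 − 1)           [min]

The stochastic simulator realizes the same law per cell (Poisson generation,
exponential clearance/sampling races, transport delay through the tubing),
so its counter-count expectations match the ODE integrals exactly.

## Worked example

Simulate a 4-h exchange at SCLC-like parameters and re-estimate the kinetics
from the detected events:

```
$ ctckinetics full --r-gen 406.25 --t-half-s 93.3 --seed 7 --mass-g 0.55 \
      --out demo_run
r_gen = 27344 +/- 190 CTCs/hour; t_half = 80.2 +/- 2.5 s; report in demo_run/report.yaml
```

The run transferred 6,929 simulated CTCs to the healthy mouse and returned
470 (`counts:` block of `report.yaml`). Line fits over the terminal 30, 45,
60, 75 and 90-min steady-state windows give r1 = 28.4 ± 0.8 and
r2 = 1.76 ± 0.10 CTCs/min, which the estimators convert to
r_gen = 27,344 ± 190 CTCs/hour (truth: 24,375) and t_1/2 = 80.2 ± 2.5 s
(truth: 93.3 s) — single-experiment counting noise of the expected size, as
the `+/-` spread only captures the window-to-window variability. With the
supplied 0.55 g tumor mass the report also contains the shedding block:
~1.2 M cells/g/day, i.e. ~0.12% of the tumor shed per day.

The same stages are available as library calls (`simulate_exchange`,
`events_to_cumulative`, `estimate_rates`, `shedding_report`) and as the
subcommands `simulate-exchange`, `simulate-injection`, `synth-trace`,
`detect`, `estimate`, `metrics`.

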