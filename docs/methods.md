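# Methods

## Models

Two ordinary-differential-equation models describe a leukemic cell
lineage competing with healthy granulopoiesis. Each lineage has a
mitotic compartment (stem and progenitor cells, marrow-resident) and a
post-mitotic compartment (mature cells): healthy `c1, c2` and leukemic
`l1, l2`, in cells per kg body weight, time in days.

A division in a mitotic pool keeps both progeny mitotic with
probability `a·s` — the fraction of self-renewal `a` modulated by the
cytokine signal `s` for cytokine-responsive cells — and releases them
to the post-mitotic pool with probability `1 − a·s`. Post-mitotic cells
die at constant rates `d_c`, `d_l`; mitotic cells die only through
crowding (see below). The equations are

```
dc1/dt = (2·a_c·s − 1)·p_c·c1 − dbar·(c1 + l1)·c1
dc2/dt = 2·(1 − a_c·s)·p_c·c1 − d_c·c2
dl1/dt = (2·a_l·σ − 1)·p_l·l1 − dbar·(c1 + l1)·l1
dl2/dt = 2·(1 − a_l·σ)·p_l·l1 − d_l·l2
```

with the G-CSF-like quasi-steady-state signal `s = 1/(1 + k·C)`:
receptor-mediated endocytosis by mature cells clears the cytokine, so
`C` is the consuming mature pool. The two variants differ only in the
leukemic response:

* **Cytokine-dependent (Model 1):** `σ = s` and `C = c2 + l2` — both
  lineages consume and respond to the same cytokine.
* **Cytokine-independent (Model 2):** `σ = 1` identically and
  `C = c2` — leukemic self-renewal is autonomous and leukemic mature
  cells are ignored by the healthy feedback loop.

Crowding death `dbar·(c1 + l1)` acts on both mitotic pools, modeling
competition for marrow niche space by the total immature population; it
is the only brake on cytokine-independent expansion. The *effective
growth rate* of a mitotic pool is `(2·a·s − 1)·p` — net cells produced
per cell per day; positive iff `a·s > 1/2`. Different `(a, p)`
combinations can share one effective growth rate; the invasion analysis
below shows why the two quantities are nonetheless not interchangeable.

Exogenous cytokine administration ("priming") is modeled by clamping
the signal experienced by cytokine-responsive compartments to its
maximum `s = 1` during the protocol window (default 30 days). No
explicit cytokine pharmacokinetics are modeled.

## Default parameters

| parameter | value | units | meaning |
|---|---|---|---|
| `a_c` | 0.93 | — | healthy self-renewal fraction |
| `p_c` | 0.42 | 1/day | healthy mitotic proliferation rate |
| `d_c` | 2.3 | 1/day | mature granulocyte death rate (half-life ≈ 7 h) |
| `k` | 1e-9 | kg/cells | feedback strength |
| `dbar` | 1e-12 | kg/(cells·day) | crowding death coefficient |
| `d_l` | 4.6 | 1/day | default blast post-mitotic death rate |

The healthy equilibrium follows in closed form for `dbar = 0`:
`s* = 1/(2a_c)`, `c2* = (2a_c − 1)/k ≈ 8.6e8/kg`,
`c1* = d_c·c2*/p_c ≈ 4.7e9/kg`; with crowding the steady state is found
by bracketed root finding and verified against the right-hand side.

`a_c` is the load-bearing choice. At homeostasis the signal settles at
`s* ≈ 1/(2a_c)`, so the fastest net growth any cytokine-dependent clone
can achieve is `(2·s* − 1)·p_l ≈ (1/a_c − 1)·p_l`: the healthy
self-renewal fraction caps how quickly a feedback-limited leukemia can
expand, and thereby sets the minimum time from one leukemic stem cell
per kg to a 10% marrow blast fraction (≈ 245 days at `a_c = 0.93`; the
cytokine-independent model needs ≈ 20 days at the same proliferation
bound). `dbar` is chosen so crowding death at homeostasis
(`dbar·c1* ≈ 0.005/day`) is negligible against healthy turnover —
raising it perversely *accelerates* cytokine-dependent leukemia, since
the healthy balance then requires a higher `s*` — while still capping
cytokine-independent expansion at `(2a_l − 1)p_l/dbar` cells/kg. `k`
only sets the absolute density scale; all observables used in fitting
are ratios.

### Invasion criteria

Linearising around the healthy equilibrium (with `dbar ≈ 0`): in
Model 1 a seeded clone grows iff `(2·a_l·s* − 1)·p_l > 0`, i.e. iff
`a_l > a_c` — independent of `p_l`. In Model 2 the criterion is a
positive effective growth rate, `(2a_l − 1)·p_l > 0`. Hence
cytokine-dependent relapses are slow (growth at most `(1/a_c − 1)p_l`)
and a marrow relapse reaching 10% blasts much earlier than ~245 days is
only compatible with cytokine-independent expansion.

## Numerics

Integration uses LSODA (stiffness-switching) with relative tolerance
1e-8 and absolute tolerance 1e-6 cells/kg (1e-6/1e-3 inside fitting
loops, where data noise dominates). Threshold crossings (blast-fraction
levels, mature-cell triggers) are located by solver event detection,
not post-hoc interpolation. Stimulation windows are integrated
piecewise so the signal clamp is exact at the window edges. Densities
below 1e-12 cells/kg are treated as extinct to suppress negative
undershoot; the right-hand side clamps tiny negative inputs to zero
before evaluating nonlinear terms. Trajectory correctness is
cross-checked in the test suite against an independently coded
fixed-step RK4 integrator (relative agreement better than 1e-6).

## Stimulation experiment and outcome classification

Disease is seeded (1 LSC/kg at healthy equilibrium) and simulated until
the healthy mature pool first falls to half its homeostatic value —
clinically, cytopenia due to leukemic load. The run then branches into
a 30-day stimulated arm and an unstimulated control, both followed 60
days past the protocol end. The outcome compares the **marrow blast
fraction** of the two arms at protocol end: BENEFICIAL below −5%
relative change, HARMFUL above +5%, NEUTRAL within the band.

The blast fraction, not the absolute blast density, is the right load
measure here: under a clamped signal *both* lineages expand toward the
crowding ceiling `≈ (2a−1)p/dbar`, so absolute densities rise in every
arm; what distinguishes benefit from harm is which lineage wins the
competition for the marrow. It is also the observable used everywhere
else in this analysis. Classification at the protocol end rather than
later is deliberate: in the cytokine-independent beneficial regime the
remission is transient — blasts regrow within weeks of the protocol end
(the test suite asserts this regrowth) — so a later evaluation point
would erase a real, clinically visible reduction.

The analytic counterpart (`predict_stimulation_response`) compares
effective growth rates at `s = 1`: in Model 1, stimulation is
beneficial iff `(2a_c − 1)p_c > (2a_l − 1)p_l` and harmful if reversed;
in Model 2 stimulation cannot boost the blasts (they ignore the
cytokine), so the outcome is beneficial-but-transient when stimulated
healthy cells out-grow the blasts and neutral otherwise. Ties within
0.01/day are classified NEUTRAL. Note the leukemia must first be able
to *trigger* the experiment: in Model 2, coexistence analysis shows the
mature pool only falls below half its homeostatic value for leukemic
effective growth rates above ≈ 0.13/day; weaker clones return
NOT_TRIGGERED.

## Calibration

Per patient and model variant, four parameters are fitted: `a_l`
(linear in [0, 1]), `p_l` (log scale, one division per two years to one
per day), `d_l` (linear, blast half-life 25–100% of the leukocyte
half-life, i.e. `d_c` to `4·d_c`), and the residual leukemic burden at
remission `l1(0)` (log scale, 1e-2 to 1e6 cells/kg). The remission
initial condition is the healthy equilibrium plus `l1(0)`; residual
post-mitotic blasts are taken as cleared (`l2(0) = 0`, their half-life
is hours). The feedback strength `k`, crowding `dbar` and the healthy
lineage are population constants: with a handful of observations of a
single scalar observable they are not identifiable per patient.

Residuals are in blast-fraction units: `model − value` for exact
observations, distance to the interval (zero inside) for censored
reports such as "less than 5% blasts". The objective is minimised by
trust-region-reflective least squares over a unit-cube
reparameterisation, from a seeded Latin-hypercube multistart (default
32 starts; the packaged cohort analysis uses 6, which the recovery
experiments show suffices at these data sizes) plus deterministic
growth-matching starts: a log-linear fit of the blast odds against time
estimates the net growth rate, which is solved for `a_l` at candidate
proliferation rates. The heuristic starts matter because the expanding
regime occupies a small corner of the parameter box (for Model 1 only
`a_l > 1/(2s*) ≈ 0.93` grows) and the objective is flat — every
residual constant — everywhere outside it.

**Model selection.** Model 2 is preferred iff
`RMSE_1 > 1.05·RMSE_2` *and* `RMSE_1 − RMSE_2 > 0.005`, and symmetrically;
otherwise both models are compatible. The absolute floor (half a
percentage point of marrow blasts) guards the relative rule against
comparing numerical jitter when both four-parameter fits essentially
interpolate a sparse record. Patients compatible with the
cytokine-dependent model form group 1 (including both-compatible
patients); patients compatible only with the cytokine-independent model
form group 2; non-converged fits yield UNDETERMINED.

## Synthetic cohort

The generator emulates a retrospective cohort with documented remission
and marrow relapse (default 41 patients, 17 cytokine-independent).
Per patient: leukemic parameters are drawn uniformly —
cytokine-dependent patients `a_l ∈ [0.95, 1]` (they must exceed
`a_c = 0.93` to relapse at all), cytokine-independent patients
`a_l ∈ [0.85, 1]`; both groups `p_l ∈ [0.3, 1]`/day and
`d_l ∈ [1, 4]·d_c`; residual burden `l1(0)` log-uniform over
1e2–1e3 cells/kg (minimal-residual-disease level). The course is
simulated to the relapse-documentation level (25% marrow blasts; draws
not relapsing within 1500 days are redrawn); marrow exams run from
remission at uniform 30–90 day intervals with the documenting exam at
the detection crossing. Measurements add truncated-Gaussian noise
(sd 0.02) and values below 5% are reported as "less than 5%" intervals,
mirroring clinical reporting. These conditions put the two groups on
opposite sides of the expansion-time separation: cytokine-dependent
relapses take ≳ 260 days, cytokine-independent ones 20–100 days.

Overall survival is exponential with group medians 700 days
(cytokine-dependent-compatible) and 350 days (cytokine-independent),
with independent exponential censoring calibrated to a 10% censored
fraction — modest administrative censoring, consistent with a cohort
restricted to patients with documented death or known vital status.
These medians are generator inputs chosen at realistic scale for
relapsed AML, not validated outputs.

What the generator does *not* emulate: treatment courses and
chemotherapy response kinetics, visit-density changes near relapse,
inter-observation correlation beyond the generating ODE, measurement
error that scales with the blast level, or any dependence of survival
on the individual trajectory beyond the group label. Passing recovery
tests therefore show that the pipeline discriminates the two dynamic
regimes under sparse, interval-censored, noisy sampling — not that it
would classify real marrow aspirate series at the same error rates.

## Survival analysis

Kaplan–Meier product-limit curves per assigned group (lifelines), with
the conservative median convention — the earliest time the curve
reaches one half, undefined if never — and the standard two-group
log-rank chi-square (1 df) for the comparison. The time origin is
whatever the input records carry (overall survival by default; survival
after first relapse by shifting times upstream). At the default cohort
size (24 vs 17, hazard ratio 2) the log-rank test has roughly
coin-flip-to-moderate power at α = 0.05; the test suite therefore
checks the *median* p-value over 100 generator replicates rather than
any single draw, and a single 41-patient cohort can legitimately return
p > 0.05.

## Problem sizes used by the packaged analyses

The expansion scan uses 101 self-renewal points per variant (one ODE
solve each, with event detection, horizon 1e4 days). The stimulation
outcome map uses the four regime scenarios plus 50 random draws. The
cohort analysis fits 2 models × 41 patients with 6 multistarts each.

## Known limitations

* The no-overcrowding property of cytokine-dependent disease — total
  mitotic density within 2× its homeostatic value absent stimulation —
  holds over the simulated disease course (through overt relapse, 50%
  marrow blasts). At terminal full takeover, slow-proliferating
  high-turnover blasts can exceed it: the feedback pins the *mature*
  pool at `(2a−1)/k`, so late-stage marrow cellularity scales with
  `(d_l/p_l)` and is bounded only by crowding.
* The models describe the extremes of cytokine dependence; partial
  dependence, multi-clonal dynamics, spatial structure and explicit
  cytokine pharmacokinetics are out of scope.
* Fitted parameters are not individually identifiable from blast
  fractions alone (e.g. `d_l` does not influence the Model 2 blast
  fraction at all); only the model-class decision and the fitted curve
  are interpreted, never single parameter estimates.
* The crowding-induced-differentiation variant and regulation of
  proliferation rates (both reported elsewhere to behave similarly)
  are not implemented.
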