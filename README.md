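# cytoaml

Does it matter, clinically, whether a patient's acute myeloid leukemia
(AML) cells need endogenous cytokines to grow? This package implements
two feedback-regulated ODE models of leukemic expansion competing with
healthy hematopoiesis — **cytokine-dependent** (Model 1: leukemic cells
share the healthy G-CSF-like feedback and compete for the cytokine) and
**cytokine-independent** (Model 2: autonomous self-renewal, limited
only by crowding of the marrow space) — plus the analysis pipeline
built on them: in-silico expansion and cytokine-priming experiments,
least-squares fitting of both models to marrow blast time courses with
an RMSE-based model-selection rule, a synthetic patient cohort
generator, and Kaplan–Meier/log-rank comparison of the resulting
prognostic groups.

It is aimed at systems-biology and mathematical-oncology users who want
to classify relapse kinetics by cytokine dependence, or to explore when
exogenous cytokine administration (priming) helps or harms.

## Model

Each lineage has a mitotic (marrow) and a post-mitotic (mature)
compartment; densities in cells/kg body weight:

```
dc1/dt = (2·a_c·s − 1)·p_c·c1 − d̄·(c1+l1)·c1        healthy mitotic
dc2/dt = 2·(1 − a_c·s)·p_c·c1 − d_c·c2               healthy mature
dl1/dt = (2·a_l·σ − 1)·p_l·l1 − d̄·(c1+l1)·l1        leukemic mitotic (blasts)
dl2/dt = 2·(1 − a_l·σ)·p_l·l1 − d_l·l2               leukemic mature
```

with cytokine signal `s = 1/(1 + k·C)`; Model 1 has `σ = s`,
`C = c2 + l2`, Model 2 has `σ = 1`, `C = c2`. The *effective growth
rate* `(2·a·s − 1)·p` of a mitotic pool governs invasion and the
response to stimulation. Key consequence: a cytokine-dependent clone
invades iff its self-renewal exceeds the healthy one (`a_l > a_c`), and
its expansion speed is capped by the feedback at `≈ (1/a_c − 1)·p_l`,
whereas a cytokine-independent clone invades iff `(2a_l − 1)p_l > 0`
with no feedback cap. Fast relapses therefore imply cytokine
independence. See `docs/methods.md` for the full account.

## Worked example

The analysis is a sequence of numbered drivers (`analysis/01…05`); each
wraps library functions importable from `cytoaml`.

```sh
$ python analysis/01_expansion_scan.py
model1: fastest 10%-blast crossing 244.9 days (15/101 grid points reach the threshold)
model2: fastest 10%-blast crossing 20.2 days (101/101 grid points reach the threshold)
```

One leukemic stem cell per kg is seeded at the healthy equilibrium,
leukemic proliferation is fixed at its biological bound of one division
per day, and self-renewal is scanned over (0.5, 1]. Even the fastest
cytokine-dependent leukemia needs ~245 days to reach a 10% marrow blast
fraction (and only self-renewal above `a_c = 0.93` expands at all: 15
of 101 grid points), while cytokine-independent expansion manages it in
~20 days — so a relapse within a few months of remission can only be
explained by cytokine-independent growth.

```sh
$ python analysis/02_stimulation_outcomes.py
A (model1): beneficial (blast fraction -22.3% vs control at protocol end; EGR rule predicts beneficial)
B (model1): harmful (blast fraction +18.5% vs control at protocol end; EGR rule predicts harmful)
C (model2): neutral (blast fraction -0.3% vs control at protocol end; EGR rule predicts neutral)
D (model2): beneficial (blast fraction -42.3% vs control at protocol end; EGR rule predicts beneficial)
```

A 30-day cytokine course, triggered when leukemic load has halved the
mature healthy pool, is compared to an unstimulated control: the sign
of the outcome is exactly predicted by the ordering of leukemic vs
healthy effective growth rates under stimulation (and in scenario D the
remission is transient — blasts regrow once the protocol ends).

Drivers 03–05 generate the synthetic 41-patient cohort (17
cytokine-independent, fast relapses; noisy, interval-censored marrow
exams every 30–90 days), fit both models to every patient and apply the
5% relative-RMSE selection rule, then compare overall survival of the
two assigned groups (generator medians 700 vs 350 days) by
Kaplan–Meier/log-rank. On the seeded default cohort the pipeline
recovers the generating model class for 41/41 patients; note that at
n = 41 a single cohort draw has limited log-rank power, so the
significance of the survival split is assessed over replicates in the
test suite.

The same stages are available as a CLI for ad-hoc runs
(`cytoaml --help`: `simulate | scan | stimulate | cohort | fit |
survival`), configured by YAML and writing CSV/JSON plus a
reproducibility manifest per stage.

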