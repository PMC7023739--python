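# posttermclinic

Discrete-event simulation and capacity planning for a post-term pregnancy
outpatient clinic.

Hospitals that follow modern induction guidelines examine women in
gestational week 41 at a dedicated outpatient clinic.  Demand at such clinics
is volatile — appointments are frequently missed because the woman has
already given birth — and the clinic is only open for a short morning window
(08:00–10:30), so the planning question is: **how many women can a given
staffing configuration feasibly serve within opening hours?**

This package answers that question with a woman-level discrete-event model.
Each simulated woman flows through

```
check-in (reception) → CTG connection (machine + midwife) → CTG scan
(machine; midwife stays if ≥5 checks) → disconnection (midwife) →
doctor consultation → check-out (reception)
```

with strictly FIFO single-queue multi-server resources.  An alternative
pathway lets a woman see a doctor *before* the CTG stage if one is idle when
her check-in completes (she then skips the post-CTG consultation).

A clinic *configuration* is the decision vector

* **X0** — number of women attending (2–20),
* **X1** — arrival pattern (`All` at 08:00, or `Half` at 08:00 / half at 08:30),
* **X2** — consultation order (`Mid`: midwife first; `Doc`: doctor first if idle),
* **X3/X4/X5** — number of midwives / doctors / CTG machines,

evaluated by seven KPIs: Y1 arrivals, Y2 time the last woman checks out,
Y3 mean length of stay (LoS), Y4 clinic overrun past 10:30, Y5 midwife
waiting time, Y6 doctor waiting time, Y7 CTG-connection waiting time.
Service times come from expert-elicited bounded summaries and are fitted by
moment matching with scaled Beta distributions (see `docs/methods.md`).
A *trial* is a set of independent replications of one configuration
(10,000 by default), summarised by KPI means with 95% confidence
half-widths; the full factorial design spans 2·2·2·2·2·19 = 608
configurations, and the capacity optimiser finds, for each of the 32
resource/pathway combinations, the largest X0 whose trial-mean last
checkout is at or before 10:30.

## Worked example

Attendance statistics for the clinic's scheduled appointments (packaged
counts, before vs after the 2011 guideline change):

```
$ posttermclinic attendance
2010: 200/671 attended (proportion 0.298)
2011-2017: 5787/12266 attended (proportion 0.472)
chi-square(1) = 77.235, p = 1.52e-18
```

Attendance roughly went from 30% to 47% of scheduled appointments — the
difference is highly significant, which is why the model stresses each
configuration with full attendance.

A 1,000-replication trial of the base configuration (all women at 08:00,
midwife first, 2 midwives, 2 doctors, 3 CTG machines, 7 women):

```
$ posttermclinic trial --x0 7 --n-reps 1000 --seed 1
configuration ('All', 'Mid', 2, 2, 3) X0=7, 1000 replications (0 invalid)
  y1_arrivals: 7.00 ± 0.00
  y2_last_checkout: 10:03:58 ± 29 s
  y3_mean_los: 86.92 ± 0.29
  y4_overrun: 0.00 ± 0.00
  y5_midwife_wait: 0.68 ± 0.04
  y6_doctor_wait: 4.91 ± 0.15
  y7_ctg_connection_wait: 23.03 ± 0.11
```

Seven women stay about 87 minutes on average, of which ~23 minutes is
waiting for a free CTG machine and midwife connection — the machines, not
the staff, are the bottleneck.  The last woman leaves around 10:04, before
closing, so demand 7 is feasible for this configuration.

Other subcommands: `simulate` (one day, per-woman CSV), `factorial`
(manifest-driven sweep), `optimise` (capacity search over all 32 combos),
`report` (Markdown tables), `validate-dists` (moment-recovery diagnostics).

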