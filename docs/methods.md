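# Methods

## The model

The clinic is modelled as an open queueing network traversed by one woman
agent per scheduled appointment during a single day.  Time is measured in
decimal minutes since midnight; the clinic opens at 08:00 (480.0), stops
admitting at 10:30 (630.0) but keeps working until every woman present has
departed, and the simulation horizon is 23:59 (1439.0).  The day starts
empty (no overnight carry-over), so no warm-up period is used.  A run in
which a woman is still in the system at the horizon is flagged invalid and
excluded from trial statistics — that configuration simply cannot carry the
offered demand.

Resources are four independent FIFO single-queue multi-server pools:
reception staff (default 1), midwives (X3), doctors (X4) and CTG machines
(X5).  Women are never assigned to a particular server.  The pathway is:

1. **Check-in** at reception.
2. **Doctor-first branch** (`X2 = Doc` only): if at least one doctor is
   idle at the instant check-in completes, the woman has her consultation
   immediately and will skip step 6.  The test is instantaneous — if no
   doctor is free at that moment she joins the ordinary midwife-first flow
   rather than waiting for one.
3. **CTG connection**: seize a machine first, then a midwife, then connect.
   Seizing the machine first makes the reported CTG-connection wait (Y7)
   exactly the machine wait plus the midwife-for-connection wait.
4. **CTG scan**, holding the machine.  The number of CTG checks during the
   scan is drawn per woman; with **5 or more checks the midwife stays for
   the whole scan**, otherwise she is released at connection end and
   re-seized for disconnection.  Checks consume no separate service time —
   their only operational effect is pinning the midwife.
5. **Disconnection**, after which machine and midwife are both released.
6. **Doctor consultation** (skipped if taken at step 2).
7. **Check-out** at reception; the departure timestamp is recorded.

A woman's length of stay is departure minus arrival and equals, to
numerical identity, the sum of her recorded waits and service times; the
test suite asserts this for every simulated woman.

Simultaneous events are dispatched in (event time, woman id) order, which
makes runs fully deterministic under a fixed seed and lets an independent
brute-force list scheduler reproduce the engine's schedules event-for-event
on point-mass instances (`tests/_oracle.py`).

The simulation kernel (`posttermclinic.engine`) is a small purpose-built
process-based event calendar: a heap keyed on (time, priority, insertion
sequence), generator processes, and FIFO resources that hand a released
server straight to the head of the queue.  There is no preemption or
interruption, which the clinic pathway never needs.

## Service-time distributions

No time-stamped activity data exist for the clinic, so every duration is an
expert-elicited summary (min, median, mean, max, SD, kurtosis, skewness),
packaged in `posttermclinic/data/service_times.csv`:

| activity | min | mean | max | SD |
|---|---|---|---|---|
| Check in | 0.130 | 0.457 | 1.000 | 0.249 |
| Connect CTG | 2.000 | 3.410 | 5.000 | 0.863 |
| CTG scan | 20.000 | 26.250 | 45.000 | 4.855 |
| Disconnect CTG | 2.000 | 3.410 | 5.000 | 0.863 |
| Consultation | 10.000 | 22.325 | 45.000 | 4.901 |
| Check out | 0.130 | 1.589 | 5.000 | 0.985 |
| No. of CTG checks | 0 | 2.120 | 10 | 1.462 |

Each duration is fitted as a four-parameter (scaled) Beta on [min, max]
with shape parameters solved in closed form from the mean and SD — the
standard choice for bounded expert-elicited durations.  The fit is exact in
its two matched moments (mean to 1e-6 relative, SD to 1e-3 relative,
asserted per row); the elicited median, skewness and kurtosis are reported
as diagnostics, not imposed, because a two-shape family on a fixed support
has no freedom left.  The moment pair is attainable on [lo, hi] only when
sd² < (mean−lo)(hi−mean); outside that region fitting raises an error
naming the violated bound.  Degenerate rows (min = max) become point
masses.

The CTG-check count is the same Beta fit on [0, 10], discretised by giving
each integer k the Beta mass of [k−0.5, k+0.5] (clipped) and renormalising.
With the elicited moments this lands the discrete mean at 2.113 (within
0.01 of 2.120) and SD at 1.501 (within 0.05 of 1.462), with
P(count ≥ 5) ≈ 0.077, so the midwife-stays rule is exercised in roughly one
woman in thirteen.

## Randomness and reproducibility

All sampling uses numpy PCG64 generators seeded through `SeedSequence`.
Replication *i* of a trial draws from one named substream per activity,
keyed by (master seed, i, activity index) — never by the configuration.
Service times for all women of a replication are pre-drawn in woman-id
order before the day is simulated.  Consequences:

* reruns with the same master seed are bit-identical, regardless of
  execution order of replications;
* configurations compared under the same master seed see **common random
  numbers**: woman *j* receives the same service-time draws in both, so
  paired comparisons are variance-reduced.

## Experiments and optimisation

A trial summarises n independent replications (default 10,000; desk-scale
runs use 1,000) by each KPI's mean and a 95% normal-approximation
half-width, 1.96·sd/√n — the reported "±" values.  The overrun KPI Y4 is
the per-woman average of minutes by which checkout exceeds 10:30; Y5 (the
midwife wait) is the connection plus disconnection wait and Y7 (the CTG
connection wait) the machine plus connection wait, so the connection
component appears in both, deliberately mirroring how the clinic reports
these indicators.

Treatment capacity for a resource/pathway combination is found by running
a trial at **every** demand level X0 = 2..20 and returning the largest
level whose trial-mean last checkout is at or before 10:30.  The exhaustive
scan (no bisection, no early stopping) is cheap at 19 levels and immune to
noise-induced non-monotonicity at the feasibility boundary.  Maximising
demand takes lexicographic priority; the mean overrun at the chosen level
is reported and breaks ties between otherwise equivalent combinations.

## What the generator emulates — and what it does not

The simulator itself is the data generator: its defaults (opening times,
the 2/2/3 base staffing, the elicited service summaries, full attendance,
the two simplified arrival patterns) are the clinic's stated operating
conditions, and stress each configuration maximally because in reality some
women miss their appointment by giving birth first.

The model deliberately represents the clinic **in isolation**:

* Reception is loaded only by the clinic's own women.  A real reception
  desk serves several clinics at once; an optional Poisson background
  arrival stream competing for reception is implemented but **off by
  default** because no arrival-rate data are available for it.
* Physical space — waiting-room chairs, corridors, walking times — is not
  modelled; queues have unlimited waiting capacity.
* Appointment-slot structure is reduced to the two arrival patterns; new
  and returning patients are not distinguished.

These omissions matter most at low demand, where reception and ambient
congestion are a visible share of a visit, so the model's low-demand
waiting times and last-checkout times are optimistic and its feasible
capacities correspondingly generous; the test suite's stochastic headline
check documents this.  At saturation the CTG stage dominates and the
simplifications wash out.  The Beta fits also carry less right skew than
the elicited summaries state (e.g. 0.87 vs 1.56 for the scan), which
slightly thins the tail of the last-checkout distribution.

## Numerical choices

* Feasibility of a demand level uses the trial **mean** of Y2 (not a
  quantile), with a 1e-9 tolerance on the 10:30 boundary.
* Clock rendering rounds to whole seconds; time KPIs print to 2 decimals
  and percentage deltas to 1 decimal.  Comparison percentages are
  100·(a−b)/a with reductions positive, recomputed exactly from the means
  they accompany.
* The attendance chi-square is Pearson's on the 2×2 table without
  continuity correction (equivalently the squared pooled-variance
  two-sample z); attendance growth is quoted as a ratio percentage
  (100·later/earlier).
* Degenerate inputs: empty days, all-invalid trials, zero scheduled
  appointments, out-of-lattice factor levels and infeasible moment pairs
  all raise named errors rather than propagating nonsense.

## Known limitations

Capacity answers are only as good as the elicited durations; a time-stamped
activity log would allow distribution fits with honest tails.  The model
does not represent downstream induction/maternity-ward capacity, costs, or
nuanced appointment templates — the capacity numbers say what the clinic
*can* absorb, not how best to schedule it.
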