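"""One-day simulation of the post-term pregnancy outpatient clinic.

Women flow through check-in (reception), CTG connection / scan / disconnection
(CTG machine + midwife), a doctor consultation, and check-out (reception),
with strictly FIFO single-queue multi-server resources.  Times are decimal
minutes since midnight; by default the clinic opens at 08:00 (480.0), closes
to new work at 10:30 (630.0) but stays open until every woman has departed,
and the run horizon is 23:59 (1439.0).

Pathway per woman:

1. seize reception -> check-in -> release.
2. doctor-first variant only: if a doctor is idle at the instant check-in
   completes, she has her consultation now and skips the post-CTG one.
3. seize a CTG machine, then a midwife; CTG connection.
4. CTG scan, holding the machine.  The number of CTG checks during the scan
   is drawn per woman; with 5 or more checks the midwife stays for the whole
   scan, otherwise she is released after connection and re-seized for
   disconnection.
5. disconnection, then machine and midwife released.
6. if no doctor-first consultation happened: seize a doctor, consultation.
7. seize reception, check-out, departure.

Service times are pre-drawn per woman from one named random substream per
activity, so configurations sharing a master seed see common random numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dataclass_fields
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .engine import Environment, Resource
from .service_distributions import (
    ACTIVITY_KEYS,
    CTG_CHECKS_ACTIVITY,
    FittedDistribution,
    SERVICE_ACTIVITIES,
)

__all__ = [
    "ClinicConfiguration",
    "WomanRecord",
    "DayResult",
    "DayKpis",
    "build_arrival_schedule",
    "replication_streams",
    "run_clinic_day",
    "compute_day_kpis",
    "OPEN_TIME",
    "CLOSE_TIME",
    "HORIZON",
]

OPEN_TIME = 480.0   # 08:00
CLOSE_TIME = 630.0  # 10:30
HORIZON = 1439.0    # 23:59

ARRIVAL_PATTERNS = ("All", "Half")
CONSULT_ORDERS = ("Mid", "Doc")

#: stream names: one per activity, plus the optional background arrival stream
STREAM_KEYS = ACTIVITY_KEYS + ("background",)


@dataclass(frozen=True)
class ClinicConfiguration:
    """The decision vector X0-X5 plus fixed operational parameters.

    X0 arrivals, X1 arrival pattern (``All``: everyone at opening; ``Half``:
    split 08:00/08:30, odd numbers favouring 08:00), X2 consultation order
    (``Mid``: midwife first; ``Doc``: doctor first if one is idle at check-in
    completion), X3 midwives, X4 doctors, X5 CTG machines.  Reception staffing
    is a fixed parameter, not a decision variable.
    """

    arrivals_x0: int = 7
    arrival_pattern_x1: str = "All"
    consult_order_x2: str = "Mid"
    midwives_x3: int = 2
    doctors_x4: int = 2
    ctg_machines_x5: int = 3
    reception_staff: int = 1
    open_time: float = OPEN_TIME
    close_time: float = CLOSE_TIME
    horizon: float = HORIZON
    background_stream_enabled: bool = False
    background_rate: float = 0.0  # arrivals/hour competing for reception

    def __post_init__(self) -> None:
        if not 1 <= self.arrivals_x0 <= 20:
            raise ValueError(f"arrivals_x0 must be in [1, 20], got {self.arrivals_x0}")
        if self.arrival_pattern_x1 not in ARRIVAL_PATTERNS:
            raise ValueError(f"unknown arrival pattern {self.arrival_pattern_x1!r}")
        if self.consult_order_x2 not in CONSULT_ORDERS:
            raise ValueError(f"unknown consultation order {self.consult_order_x2!r}")
        for name in ("midwives_x3", "doctors_x4", "ctg_machines_x5", "reception_staff"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.open_time < self.close_time < self.horizon:
            raise ValueError("need open_time < close_time < horizon")
        if self.background_stream_enabled and self.background_rate <= 0:
            raise ValueError("background stream enabled but rate not positive")

    @property
    def combo(self) -> tuple:
        """The (X1, X2, X3, X4, X5) resource/pathway combination."""
        return (
            self.arrival_pattern_x1,
            self.consult_order_x2,
            self.midwives_x3,
            self.doctors_x4,
            self.ctg_machines_x5,
        )


_WAIT_FIELDS = (
    "checkin_wait",
    "ctg_machine_wait",
    "midwife_connect_wait",
    "midwife_disconnect_wait",
    "doctor_wait",
    "checkout_wait",
)
_SERVICE_FIELDS = (
    "checkin_service",
    "connect_service",
    "scan_service",
    "disconnect_service",
    "consult_service",
    "checkout_service",
)


@dataclass
class WomanRecord:
    """Per-woman timestamps: every wait and service duration of one visit."""

    woman_id: int
    arrival: float
    checkin_wait: float = 0.0
    checkin_service: float = 0.0
    ctg_machine_wait: float = 0.0
    midwife_connect_wait: float = 0.0
    connect_service: float = 0.0
    scan_service: float = 0.0
    n_checks: int = 0
    midwife_disconnect_wait: float = 0.0
    disconnect_service: float = 0.0
    doctor_wait: float = 0.0
    consult_service: float = 0.0
    checkout_wait: float = 0.0
    checkout_service: float = 0.0
    departure: float = math.nan
    doctor_first: bool = False

    @property
    def los(self) -> float:
        """Length of stay: departure minus arrival."""
        return self.departure - self.arrival

    def interval_sum(self) -> float:
        """Sum of all recorded waits and services (equals LoS by construction)."""
        return sum(getattr(self, f) for f in _WAIT_FIELDS + _SERVICE_FIELDS)


@dataclass
class DayResult:
    """Outcome of one simulated clinic day."""

    config: ClinicConfiguration
    records: list[WomanRecord]
    valid: bool
    busy_time: dict[str, float] = field(default_factory=dict)
    traces: Optional[dict] = None

    @property
    def last_checkout(self) -> float:
        return max(r.departure for r in self.records)


@dataclass(frozen=True)
class DayKpis:
    """The seven per-day performance indicators Y1-Y7 (minutes)."""

    y1_arrivals: int
    y2_last_checkout: float
    y3_mean_los: float
    y4_overrun: float
    y5_midwife_wait: float
    y6_doctor_wait: float
    y7_ctg_connection_wait: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


def build_arrival_schedule(
    x0: int, pattern: str, open_time: float = OPEN_TIME
) -> list[float]:
    """Arrival timestamps for ``x0`` women under an arrival pattern.

    ``All``: everyone at opening.  ``Half``: ceil(x0/2) at opening and the
    rest 30 minutes later (odd counts put the larger half first).
    """
    if x0 < 1:
        raise ValueError("x0 must be >= 1")
    if pattern == "All":
        return [open_time] * x0
    if pattern == "Half":
        first = (x0 + 1) // 2
        return [open_time] * first + [open_time + 30.0] * (x0 - first)
    raise ValueError(f"unknown arrival pattern {pattern!r}")


def replication_streams(
    master_seed: int, replication: int
) -> dict[str, np.random.Generator]:
    """One named random substream per activity for a given replication.

    Streams depend only on (master_seed, replication, activity), never on the
    configuration, so trials run with a shared master seed use common random
    numbers across configurations.
    """
    return {
        name: np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(master_seed, spawn_key=(replication, k)))
        )
        for k, name in enumerate(STREAM_KEYS)
    }


def _predraw_services(
    config: ClinicConfiguration,
    dists: Mapping[str, FittedDistribution],
    streams: Mapping[str, np.random.Generator],
) -> dict[str, np.ndarray]:
    """Draw every woman's service times up front, in woman-id order."""
    n = config.arrivals_x0
    draws: dict[str, np.ndarray] = {}
    for key in SERVICE_ACTIVITIES:
        draws[key] = np.asarray(dists[key].sample(streams[key], size=n), dtype=float)
    draws[CTG_CHECKS_ACTIVITY] = np.asarray(
        dists[CTG_CHECKS_ACTIVITY].sample(streams[CTG_CHECKS_ACTIVITY], size=n)
    )
    return draws


def run_clinic_day(
    config: ClinicConfiguration,
    dists: Mapping[str, FittedDistribution],
    rng_stream: Union[Mapping[str, np.random.Generator], np.random.Generator],
    trace_resources: bool = False,
) -> DayResult:
    """Simulate one clinic day and return per-woman records.

    ``rng_stream`` is either a mapping of per-activity generators (see
    :func:`replication_streams`) or a single generator used for everything.
    The clinic stays open past closing until all women depart; a woman still
    in the system at the horizon flags the run invalid.
    """
    missing = [k for k in ACTIVITY_KEYS if k not in dists]
    if missing:
        raise ValueError(f"missing fitted distributions: {missing}")
    if isinstance(rng_stream, np.random.Generator):
        streams = {name: rng_stream for name in STREAM_KEYS}
    else:
        streams = rng_stream

    env = Environment(start=config.open_time)
    reception = Resource(env, config.reception_staff, "reception")
    midwives = Resource(env, config.midwives_x3, "midwife")
    doctors = Resource(env, config.doctors_x4, "doctor")
    ctg_machines = Resource(env, config.ctg_machines_x5, "ctg_machine")
    resources = {
        "reception": reception,
        "midwife": midwives,
        "doctor": doctors,
        "ctg_machine": ctg_machines,
    }
    if trace_resources:
        for res in resources.values():
            res.trace = []

    draws = _predraw_services(config, dists, streams)
    arrivals = build_arrival_schedule(
        config.arrivals_x0, config.arrival_pattern_x1, config.open_time
    )
    records = [WomanRecord(woman_id=i, arrival=t) for i, t in enumerate(arrivals)]
    doc_first_allowed = config.consult_order_x2 == "Doc"

    def woman_flow(w: WomanRecord):
        i = w.woman_id
        t = env.now
        yield reception.request(tag=("checkin", i), priority=i)
        w.checkin_wait = env.now - t
        w.checkin_service = draws["check_in"][i]
        yield env.timeout(w.checkin_service, i)
        reception.release()

        w.consult_service = draws["consultation"][i]
        if doc_first_allowed and doctors.idle_count > 0:
            w.doctor_first = True
            yield doctors.request(tag=("consult", i), priority=i)  # idle doctor: no wait
            yield env.timeout(w.consult_service, i)
            doctors.release()

        t = env.now
        yield ctg_machines.request(tag=("ctg", i), priority=i)
        w.ctg_machine_wait = env.now - t
        t = env.now
        yield midwives.request(tag=("connect", i), priority=i)
        w.midwife_connect_wait = env.now - t
        w.connect_service = draws["connect_ctg"][i]
        yield env.timeout(w.connect_service, i)

        w.n_checks = int(draws["n_ctg_checks"][i])
        midwife_stays = w.n_checks >= 5
        if not midwife_stays:
            midwives.release()
        w.scan_service = draws["ctg_scan"][i]
        yield env.timeout(w.scan_service, i)
        if not midwife_stays:
            t = env.now
            yield midwives.request(tag=("disconnect", i), priority=i)
            w.midwife_disconnect_wait = env.now - t
        w.disconnect_service = draws["disconnect_ctg"][i]
        yield env.timeout(w.disconnect_service, i)
        midwives.release()
        ctg_machines.release()

        if not w.doctor_first:
            t = env.now
            yield doctors.request(tag=("consult", i), priority=i)
            w.doctor_wait = env.now - t
            yield env.timeout(w.consult_service, i)
            doctors.release()

        t = env.now
        yield reception.request(tag=("checkout", i), priority=i)
        w.checkout_wait = env.now - t
        w.checkout_service = draws["check_out"][i]
        yield env.timeout(w.checkout_service, i)
        reception.release()
        w.departure = env.now

    for w in records:
        env.process(woman_flow(w), start_at=w.arrival, priority=w.woman_id)

    if config.background_stream_enabled:
        def background_flow():
            rng = streams["background"]
            rate_per_min = config.background_rate / 60.0
            t = config.open_time + rng.exponential(1.0 / rate_per_min)
            while t < config.close_time:
                yield env.timeout(t - env.now)
                env.process(_background_visit())
                t += rng.exponential(1.0 / rate_per_min)

        def _background_visit():
            yield reception.request(tag=("background", None))
            yield env.timeout(
                dists["check_in"].sample(streams["background"])
            )
            reception.release()

        env.process(background_flow(), start_at=config.open_time)

    env.run(until=config.horizon)
    valid = all(math.isfinite(r.departure) for r in records)
    busy = {
        name: res.busy_time(config.open_time, config.close_time)
        for name, res in resources.items()
    }
    day = DayResult(config=config, records=records, valid=valid, busy_time=busy)
    if trace_resources:
        day.traces = {name: res.trace for name, res in resources.items()}
    return day


def compute_day_kpis(day: DayResult, config: Optional[ClinicConfiguration] = None) -> DayKpis:
    """Compute Y1-Y7 for one simulated day.

    Y4, clinic overrun, is the per-woman average of minutes by which checkout
    exceeds closing time (women leaving on time contribute zero).  Y5 is the
    midwife wait (connection + disconnection), Y7 the CTG connection wait
    (machine + midwife-for-connection); both include the midwife connection
    wait, mirroring how the clinic reports them.
    """
    config = config if config is not None else day.config
    if not day.records:
        raise ValueError("cannot compute KPIs for an empty day")
    if not day.valid:
        raise ValueError("day is invalid (woman still in system at horizon)")
    recs = day.records
    n = len(recs)
    close = config.close_time
    return DayKpis(
        y1_arrivals=n,
        y2_last_checkout=day.last_checkout,
        y3_mean_los=sum(r.los for r in recs) / n,
        y4_overrun=sum(max(0.0, r.departure - close) for r in recs) / n,
        y5_midwife_wait=sum(
            r.midwife_connect_wait + r.midwife_disconnect_wait for r in recs
        ) / n,
        y6_doctor_wait=sum(r.doctor_wait for r in recs) / n,
        y7_ctg_connection_wait=sum(
            r.ctg_machine_wait + r.midwife_connect_wait for r in recs
        ) / n,
    )
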