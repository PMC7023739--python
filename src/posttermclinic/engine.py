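"""Minimal process-based discrete-event simulation kernel.

The kernel advances an event calendar (a binary heap keyed on event time and
an insertion sequence number, so simultaneous events dispatch in the order
they were scheduled) and resumes generator-based processes when the events
they yielded fire.  Resources are single-queue, multi-server and strictly
FIFO: a released server is handed to the head of the waiting queue at the
instant of release.

This is deliberately a small kernel: just enough for entity-flow models in
which processes seize resources, hold them for sampled durations and release
them.  There is no interruption or preemption.

Events carry an integer priority (in the clinic model: the woman id) that
orders simultaneous dispatches, so ties resolve deterministically in
(event time, priority) order regardless of scheduling history.
"""

from __future__ import annotations

import heapq
from collections import deque
from itertools import count
from typing import Callable, Generator, Optional


#: priority used when none is given; sorts after any explicit entity id
DEFAULT_PRIORITY = 2**31


class Event:
    """A one-shot event; processes waiting on it resume when it fires."""

    __slots__ = ("env", "callbacks", "triggered", "priority")

    def __init__(self, env: "Environment", priority: int = DEFAULT_PRIORITY):
        self.env = env
        self.callbacks: list[Callable[["Event"], None]] = []
        self.triggered = False
        self.priority = priority

    def succeed(self) -> "Event":
        """Fire the event at the current simulation time."""
        if self.triggered:
            raise RuntimeError("event already triggered")
        self.triggered = True
        self.env._schedule(self.env.now, self)
        return self


class Timeout(Event):
    """An event that fires ``delay`` time units after creation."""

    __slots__ = ()

    def __init__(self, env: "Environment", delay: float, priority: int = DEFAULT_PRIORITY):
        if delay < 0:
            raise ValueError(f"negative timeout delay: {delay}")
        super().__init__(env, priority)
        self.triggered = True
        env._schedule(env.now + delay, self)


class Process:
    """Wraps a generator that yields :class:`Event` objects."""

    __slots__ = ("env", "_gen", "alive")

    def __init__(
        self,
        env: "Environment",
        gen: Generator,
        start_at: Optional[float] = None,
        priority: int = DEFAULT_PRIORITY,
    ):
        self.env = env
        self._gen = gen
        self.alive = True
        kickoff = Event(env, priority)
        kickoff.callbacks.append(self._resume)
        kickoff.triggered = True
        env._schedule(env.now if start_at is None else start_at, kickoff)

    def _resume(self, _event: Event) -> None:
        try:
            target = next(self._gen)
        except StopIteration:
            self.alive = False
            return
        if not isinstance(target, Event):
            raise TypeError(f"process yielded {target!r}, expected an Event")
        target.callbacks.append(self._resume)


class Environment:
    """Event calendar and simulation clock (time units are arbitrary)."""

    def __init__(self, start: float = 0.0):
        self.now = start
        self._heap: list = []
        self._seq = count()

    def _schedule(self, time: float, event: Event) -> None:
        if time < self.now:
            raise ValueError("cannot schedule into the past")
        heapq.heappush(self._heap, (time, event.priority, next(self._seq), event))

    def timeout(self, delay: float, priority: int = DEFAULT_PRIORITY) -> Timeout:
        return Timeout(self, delay, priority)

    def event(self, priority: int = DEFAULT_PRIORITY) -> Event:
        return Event(self, priority)

    def process(
        self,
        gen: Generator,
        start_at: Optional[float] = None,
        priority: int = DEFAULT_PRIORITY,
    ) -> Process:
        return Process(self, gen, start_at=start_at, priority=priority)

    def run(self, until: Optional[float] = None) -> None:
        """Dispatch events in (time, priority) order, up to ``until`` inclusive."""
        while self._heap:
            time, _, _, event = self._heap[0]
            if until is not None and time > until:
                self.now = until
                return
            heapq.heappop(self._heap)
            self.now = time
            callbacks = event.callbacks
            event.callbacks = []
            for cb in callbacks:
                cb(event)


class Resource:
    """A FIFO multi-server resource.

    ``request()`` returns an event that fires when a server is granted;
    ``release()`` frees one server, handing it straight to the longest-waiting
    requester if any.  Occupancy transitions are logged so that busy time over
    a window (e.g. clinic opening hours) can be integrated afterwards.
    """

    __slots__ = ("env", "capacity", "name", "in_use", "_queue", "_log", "trace")

    def __init__(self, env: Environment, capacity: int, name: str = ""):
        if capacity < 1:
            raise ValueError("resource capacity must be >= 1")
        self.env = env
        self.capacity = capacity
        self.name = name
        self.in_use = 0
        self._queue: deque[Event] = deque()
        self._log: list[tuple[float, int]] = [(env.now, 0)]
        # (request_time, grant_time, tag) triples when tracing is on
        self.trace: Optional[list[tuple[float, float, object]]] = None

    @property
    def idle_count(self) -> int:
        return self.capacity - self.in_use

    def request(self, tag: object = None, priority: int = DEFAULT_PRIORITY) -> Event:
        event = Event(self.env, priority)
        if self.trace is not None:
            req_time = self.env.now
            event.callbacks.append(
                lambda ev, rt=req_time, tg=tag: self.trace.append((rt, self.env.now, tg))
            )
        if self.in_use < self.capacity:
            self.in_use += 1
            self._log.append((self.env.now, self.in_use))
            event.succeed()
        else:
            self._queue.append(event)
        return event

    def release(self) -> None:
        if self._queue:
            # hand the server over; occupancy unchanged
            self._queue.popleft().succeed()
        else:
            if self.in_use == 0:
                raise RuntimeError(f"release of idle resource {self.name!r}")
            self.in_use -= 1
            self._log.append((self.env.now, self.in_use))

    def busy_time(self, window_start: float, window_end: float) -> float:
        """Server-minutes of occupancy within [window_start, window_end]."""
        total = 0.0
        for (t0, level), (t1, _) in zip(self._log, self._log[1:]):
            lo, hi = max(t0, window_start), min(t1, window_end)
            if hi > lo:
                total += level * (hi - lo)
        t_last, level = self._log[-1]
        lo, hi = max(t_last, window_start), min(self.env.now, window_end)
        if hi > lo:
            total += level * (hi - lo)
        return total
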