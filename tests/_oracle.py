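"""Independent brute-force list scheduler for small clinic instances.

A deliberately different implementation of the clinic pathway semantics:
explicit per-woman state machines advanced by repeatedly taking the earliest
pending transition, with FIFO resource queues held as plain lists.  No event
heap, no coroutines.  Simultaneous actions — timed completions and the
continuations of women granted a resource at the same instant — are resolved
in woman-id order, the model's tie-breaking rule.  Used to cross-check the
simulation engine event-for-event on instances of up to a handful of women
with point-mass service times.
"""

import math

INF = math.inf

WAIT_FIELDS = (
    "checkin_wait",
    "ctg_machine_wait",
    "midwife_connect_wait",
    "midwife_disconnect_wait",
    "doctor_wait",
    "checkout_wait",
)


def simulate_oracle(arrivals, svc, n_checks, capacities, doc_first_allowed):
    """Schedule every woman through the clinic pathway.

    arrivals: arrival time per woman; svc: dict activity -> per-woman
    durations; n_checks: per-woman CTG check counts; capacities: dict with
    reception/midwife/doctor/ctg counts.  Returns one record dict per woman.
    """
    n = len(arrivals)
    free = dict(capacities)
    queues = {r: [] for r in free}
    state = ["arriving"] * n
    tnext = list(arrivals)
    qenter = [0.0] * n
    recs = [
        {"woman_id": i, "arrival": arrivals[i], "doctor_first": False,
         "departure": INF, **{f: 0.0 for f in WAIT_FIELDS}}
        for i in range(n)
    ]

    def acquire(i, res, t, queue_state):
        if free[res] > 0:
            free[res] -= 1
            return True
        queues[res].append(i)
        qenter[i] = t
        state[i] = queue_state
        tnext[i] = INF
        return False

    ready = {}  # woman_id -> deferred action at the current instant

    def release(res, t):
        if queues[res]:
            j = queues[res].pop(0)
            # hand-over happens now, but j's continuation runs at her id-turn
            ready[j] = lambda jj=j: granted(jj, t)
        else:
            free[res] += 1

    def start_checkin(i, t):
        state[i] = "checkin"
        tnext[i] = t + svc["check_in"][i]

    def go_ctg(i, t):
        if acquire(i, "ctg", t, "q_ctg"):
            seize_midwife_for_connect(i, t)

    def seize_midwife_for_connect(i, t):
        if acquire(i, "midwife", t, "q_mid_connect"):
            start_connect(i, t)

    def start_connect(i, t):
        state[i] = "connect"
        tnext[i] = t + svc["connect_ctg"][i]

    def start_disconnect(i, t):
        state[i] = "disconnect"
        tnext[i] = t + svc["disconnect_ctg"][i]

    def start_consult(i, t, first):
        recs[i]["doctor_first"] = first
        state[i] = "consult1" if first else "consult2"
        tnext[i] = t + svc["consultation"][i]

    def go_checkout(i, t):
        if acquire(i, "reception", t, "q_rec_out"):
            state[i] = "checkout"
            tnext[i] = t + svc["check_out"][i]

    def granted(j, t):
        s = state[j]
        if s == "q_rec_in":
            recs[j]["checkin_wait"] = t - qenter[j]
            start_checkin(j, t)
        elif s == "q_ctg":
            recs[j]["ctg_machine_wait"] = t - qenter[j]
            seize_midwife_for_connect(j, t)
        elif s == "q_mid_connect":
            recs[j]["midwife_connect_wait"] = t - qenter[j]
            start_connect(j, t)
        elif s == "q_mid_disc":
            recs[j]["midwife_disconnect_wait"] = t - qenter[j]
            start_disconnect(j, t)
        elif s == "q_doc":
            recs[j]["doctor_wait"] = t - qenter[j]
            start_consult(j, t, first=False)
        elif s == "q_rec_out":
            recs[j]["checkout_wait"] = t - qenter[j]
            state[j] = "checkout"
            tnext[j] = t + svc["check_out"][j]
        else:  # pragma: no cover
            raise AssertionError(f"grant in unexpected state {s}")

    def advance(i, t):
        s = state[i]
        if s == "arriving":
            if acquire(i, "reception", t, "q_rec_in"):
                start_checkin(i, t)
        elif s == "checkin":
            release("reception", t)
            if doc_first_allowed and free["doctor"] > 0:
                free["doctor"] -= 1
                start_consult(i, t, first=True)
            else:
                go_ctg(i, t)
        elif s == "consult1":
            release("doctor", t)
            go_ctg(i, t)
        elif s == "connect":
            if n_checks[i] < 5:
                release("midwife", t)
            state[i] = "scan"
            tnext[i] = t + svc["ctg_scan"][i]
        elif s == "scan":
            if n_checks[i] >= 5:
                start_disconnect(i, t)  # midwife stayed, no wait
            elif acquire(i, "midwife", t, "q_mid_disc"):
                start_disconnect(i, t)
        elif s == "disconnect":
            release("midwife", t)
            release("ctg", t)
            if recs[i]["doctor_first"]:
                go_checkout(i, t)
            elif acquire(i, "doctor", t, "q_doc"):
                start_consult(i, t, first=False)
        elif s == "consult2":
            release("doctor", t)
            go_checkout(i, t)
        elif s == "checkout":
            release("reception", t)
            recs[i]["departure"] = t
            state[i] = "done"
            tnext[i] = INF
        else:  # pragma: no cover
            raise AssertionError(f"advance in unexpected state {s}")

    while any(s != "done" for s in state):
        t = min(tnext)
        assert t < INF, "deadlock in oracle"
        for i in range(n):
            if tnext[i] == t:
                tnext[i] = INF
                ready[i] = lambda ii=i, tt=t: advance(ii, tt)
        while ready:
            i = min(ready)
            ready.pop(i)()
    return recs
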