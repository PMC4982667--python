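"""Event-driven kinetic Monte Carlo engine for torque-coupled transcription.

Polymerases occupy a 1-D lattice of nucleotides, each spanning a 35-nt
footprint addressed by its furthest-downstream nucleotide ``n``.  New
polymerases enter at the promoter end with Poisson rate ``alpha * beta`` (one
nucleotide at a time, the body trailing off-lattice), hop forward one
nucleotide at a time with exponentially distributed waiting times, and hop
off the far end as a unit with rate ``gamma * beta``.  Exclusion forbids two
fronts from coming closer than one footprint; a trailing polymerase whose
next site is occupied ceases elongation (a *collision*) until its leader
moves.

In the torque-coupled model each hop twists the DNA segments flanking the
mover.  After every hop the mover's net torque is recomputed from the two
flanking segments, clamped, and mapped through the response set to a new
hop rate ``K V(tau)`` and pause probability ``F(tau)``; with probability
``F(tau)`` the mover enters a pause whose exit rate is ``1 / D(tau)``.  The
response lookup and pause-entry roll happen after every hop, including a hop
that lands in contact with the leader, so a polymerase can be paused and
blocked at once (both intervals then end at its next translocation).  The
two flanking neighbors get fresh waiting-time draws at their updated rates
(a memoryless restart; no new pause-entry roll), which is how a moving
neighbor can shorten a paused polymerase's dwell or push it back into
elongation.  With the ``tasep_constant`` response variant all rates are
torque-independent and the engine reduces to a standard TASEP with
constant-rate pauses.

Every pause and collision interval, initiation/termination time, and
(optionally) every computed net-torque value is recorded for post-hoc
analysis.
"""

from __future__ import annotations

import heapq
import math
import random
from dataclasses import dataclass, field
from math import ceil, log

import numpy as np
import pandas as pd

from .response import ResponseSet, make_response_set
from .torque import TorqueModel

__all__ = [
    "StrandConfig",
    "PolymeraseState",
    "SimulationRecord",
    "run_simulation",
    "schedule_next_move",
    "STATUS_NAMES",
]

# polymerase motion status codes
ELONGATING, PAUSED, BLOCKED, AT_END, DONE = range(5)
STATUS_NAMES = ("elongating", "paused", "blocked", "at_end", "done")

_INIT_EVENT = -1  # sentinel pid for the promoter's initiation clock


@dataclass(frozen=True)
class StrandConfig:
    """Parameters of one simulation run.

    ``alpha`` and ``gamma`` scale the elongation rate ``beta`` (nt/s) to the
    initiation and termination rates.  The 35-nt footprint splits into a
    17-nt anchored transcription bubble with 9 twistable nucleotides on each
    side.  ``pauses_enabled=False`` gives the baseline (collisions-only)
    model.  ``record_intervals=False`` keeps only per-polymerase aggregates,
    which is cheaper for long high-traffic runs; the summary statistics are
    identical either way.
    """

    alpha: float
    t_max: float
    seed: int
    strand_length: int = 5450
    footprint: int = 35
    bubble_len: int = 17
    flank: int = 9
    beta: float = 90.0
    gamma: float = 1.0
    pauses_enabled: bool = True
    responses: ResponseSet = field(
        default_factory=lambda: make_response_set("nonlinear", 90.0)
    )
    torque_model: TorqueModel = field(default_factory=TorqueModel)
    record_intervals: bool = True
    record_torques: bool = True
    validate: bool = False

    def __post_init__(self) -> None:
        if self.footprint != self.bubble_len + 2 * self.flank:
            raise ValueError("footprint must equal bubble_len + 2 * flank")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.beta <= 0 or self.gamma <= 0:
            raise ValueError("beta and gamma must be positive")
        if self.strand_length <= self.footprint:
            raise ValueError("strand must be longer than one footprint")
        if abs(self.responses.scale_K * self.responses.velocity_fn(0.0) - self.beta) > 1e-6 * self.beta:
            raise ValueError(
                "response set is scaled to a different beta than the strand config"
            )


@dataclass(frozen=True)
class PolymeraseState:
    """Final snapshot of one polymerase: the (n, L0, T) triple plus history."""

    index: int
    n: int
    L0_init: int | None
    T_next: float
    status: str
    t_initiated: float
    t_terminated: float  # nan while still on the strand


@dataclass
class SimulationRecord:
    """Everything one run produced, kept raw (censoring is applied downstream).

    Per-polymerase arrays are indexed by initiation order.  ``pause_*`` /
    ``coll_*`` aggregate the closed intervals (count, total duration, total
    squared duration); the full interval tables are present when the run was
    configured with ``record_intervals=True``.  ``torque_counts`` tallies
    every computed clamped net torque into unit-width bins with dedicated
    bins for the exact clamp values.
    """

    config: StrandConfig
    t_init: np.ndarray
    t_term: np.ndarray
    n_final: np.ndarray
    status_final: np.ndarray
    L0_init: np.ndarray  # -1 where no leader existed at initiation
    pause_count: np.ndarray
    pause_time: np.ndarray
    pause_sq: np.ndarray
    coll_count: np.ndarray
    coll_time: np.ndarray
    coll_sq: np.ndarray
    pauses: pd.DataFrame | None
    collisions: pd.DataFrame | None
    torque_counts: np.ndarray | None
    n_events: int
    n_initiation_attempts: int

    @property
    def n_polymerases(self) -> int:
        return len(self.t_init)

    @property
    def completed(self) -> np.ndarray:
        """Mask of polymerases that terminated within the simulated horizon."""
        return np.isfinite(self.t_term)

    def polymerase(self, i: int) -> PolymeraseState:
        return PolymeraseState(
            index=i,
            n=int(self.n_final[i]),
            L0_init=int(self.L0_init[i]) if self.L0_init[i] >= 0 else None,
            T_next=math.nan,
            status=STATUS_NAMES[int(self.status_final[i])],
            t_initiated=float(self.t_init[i]),
            t_terminated=float(self.t_term[i]),
        )


def schedule_next_move(rate: float, now: float, rng: random.Random) -> float:
    """Draw the next event time for an exponential clock with the given rate.

    A nonpositive rate means the polymerase is blocked and no event is
    scheduled (returns +inf).
    """
    if rate <= 0.0:
        return math.inf
    return now + rng.expovariate(rate)


def run_simulation(config: StrandConfig) -> SimulationRecord:
    """Run one seeded realization of the transcription process to ``t_max``.

    Events (initiation attempts, hops, pause exits, terminations) are
    executed in global time order from a priority queue keyed on each
    polymerase's next-event time; stale queue entries are skipped via a
    per-polymerase version counter.  Identical config and seed give an
    identical record.
    """
    rng = random.Random(config.seed)
    expo = rng.expovariate
    unif = rng.random

    resp = config.responses
    tasep = resp.variant == "tasep_constant"
    K = resp.scale_K
    vfn = resp.velocity_fn
    ffn = resp.pause_freq_fn
    dfn = resp.pause_dur_fn
    beta = config.beta
    f0 = ffn(0.0)
    d0 = dfn(0.0)
    inv_d0 = 1.0 / d0

    tmodel = config.torque_model
    pref = tmodel.constants.torque_prefactor
    clo = tmodel.clamp_low
    chi = tmodel.clamp_high
    clamp_seg = tmodel.clamp_segments

    slen = config.strand_length
    fp = config.footprint
    bub = config.bubble_len
    pauses_on = config.pauses_enabled
    init_rate = config.alpha * beta
    exit_rate = config.gamma * beta
    t_max = config.t_max
    validate = config.validate
    rec_int = config.record_intervals

    rec_tau = config.record_torques and not tasep
    tau_counts: list[int] | None = None
    if rec_tau:
        span_f = chi - clo
        if abs(span_f - round(span_f)) > 1e-9:
            raise ValueError("torque histogram requires an integer clamp span")
        span = int(round(span_f))
        tau_counts = [0] * (span + 2)

    # per-polymerase parallel state, indexed by initiation order
    n: list[int] = []
    L0: list[int] = []  # -1 when no leader existed at initiation
    ftau: list[float] = []  # torque of the segment toward the leader; 0 at head
    status: list[int] = []
    version: list[int] = []
    t_init: list[float] = []
    t_term: list[float] = []
    p_cnt: list[int] = []
    p_sum: list[float] = []
    p_sq: list[float] = []
    c_cnt: list[int] = []
    c_sum: list[float] = []
    c_sq: list[float] = []
    open_p: list[float] = []  # pause start time, -1 when not paused
    open_p_pos: list[int] = []
    open_p_exp: list[float] = []
    open_c: list[float] = []  # collision start time, -1 when none open
    open_c_pos: list[int] = []

    if rec_int:
        P_pid: list[int] = []
        P_pos: list[int] = []
        P_t0: list[float] = []
        P_t1: list[float] = []
        P_exp: list[float] = []
        C_pid: list[int] = []
        C_pos: list[int] = []
        C_t0: list[float] = []
        C_t1: list[float] = []

    head = 0  # lowest non-terminated pid; active pids are head..len(n)-1
    heap: list[tuple[float, int, int]] = []
    push = heapq.heappush
    pop = heapq.heappop

    def _close_pause(j: int, now: float) -> None:
        d = now - open_p[j]
        p_cnt[j] += 1
        p_sum[j] += d
        p_sq[j] += d * d
        if rec_int:
            P_pid.append(j)
            P_pos.append(open_p_pos[j])
            P_t0.append(open_p[j])
            P_t1.append(now)
            P_exp.append(open_p_exp[j])
        open_p[j] = -1.0

    def _paused_rate(j: int, tau: float, now: float) -> float:
        # exit clock for a paused polymerase; a recalculated duration of
        # zero (melting anchor) makes the pending translocation immediate
        dd = dfn(tau)
        return 1.0 / dd if dd > 1e-9 else 1e9

    push(heap, (expo(init_rate), _INIT_EVENT, 0))
    n_attempts = 0
    n_events = 0
    t_prev = 0.0

    while heap:
        t, pid, ver = pop(heap)
        if t > t_max:
            break
        if validate:
            assert t >= t_prev, "event times must be non-decreasing"
            t_prev = t

        if pid == _INIT_EVENT:
            # promoter clock keeps firing; blocked attempts are discarded.
            # The polymerase enters one nucleotide at a time with its body
            # trailing off-lattice, so entry only needs the first site free;
            # its relaxed spacing L0 is the bubble gap to the leader now.
            n_attempts += 1
            push(heap, (t + expo(init_rate), _INIT_EVENT, 0))
            last = len(n) - 1
            if last >= head and n[last] < fp + 1:
                continue
            pid = last + 1
            L0v = n[last] - 1 - bub if last >= head else -1
            n.append(1)
            L0.append(L0v)
            ftau.append(0.0)  # L = L0 at initiation, so zero torque
            t_init.append(t)
            t_term.append(math.nan)
            p_cnt.append(0)
            p_sum.append(0.0)
            p_sq.append(0.0)
            c_cnt.append(0)
            c_sum.append(0.0)
            c_sq.append(0.0)
            open_p.append(-1.0)
            open_p_pos.append(0)
            open_p_exp.append(0.0)
            open_c.append(-1.0)
            open_c_pos.append(0)
            version.append(0)
            if last >= head and n[last] - 1 == fp:
                # created in contact with the leader's rear
                status.append(BLOCKED)
                open_c[pid] = t
                open_c_pos[pid] = 1
            else:
                status.append(ELONGATING)
                if rec_tau:
                    tau_counts[_tau_bin(0.0, clo, chi, span)] += 1
                push(heap, (t + expo(beta), pid, 0))
            continue

        if ver != version[pid]:
            continue
        st = status[pid]
        n_events += 1

        if st == AT_END:
            # termination: the polymerase hops off as a unit
            status[pid] = DONE
            t_term[pid] = t
            head = pid + 1
            if head < len(n):
                nh = head
                ftau[nh] = 0.0  # no leader left downstream
                hst = status[nh]
                paused_h = open_p[nh] >= 0.0
                if hst == BLOCKED or (hst == ELONGATING and not tasep):
                    if tasep:
                        rate = inv_d0 if paused_h else beta
                    else:
                        tau = -ftau[nh + 1] if nh + 1 < len(n) else 0.0
                        if tau > chi:
                            tau = chi
                        elif tau < clo:
                            tau = clo
                        if rec_tau:
                            tau_counts[_tau_bin(tau, clo, chi, span)] += 1
                        rate = (
                            _paused_rate(nh, tau, t) if paused_h else K * vfn(tau)
                        )
                    status[nh] = ELONGATING
                    version[nh] = v2 = version[nh] + 1
                    push(heap, (t + expo(rate), nh, v2))
            continue

        # --- elongation of pid ---
        if open_p[pid] >= 0.0:
            _close_pause(pid, t)
        if open_c[pid] >= 0.0:
            # a collision ends when the trailing polymerase translocates
            d = t - open_c[pid]
            c_cnt[pid] += 1
            c_sum[pid] += d
            c_sq[pid] += d * d
            if rec_int:
                C_pid.append(pid)
                C_pos.append(open_c_pos[pid])
                C_t0.append(open_c[pid])
                C_t1.append(t)
            open_c[pid] = -1.0

        npos = n[pid] + 1
        n[pid] = npos
        has_lead = pid > head
        gap = 0
        if has_lead:
            gap = n[pid - 1] - npos
            if validate:
                assert gap >= fp, "exclusion violated: fronts closer than a footprint"
            tau_s = pref * log(L0[pid] / (gap - bub))
            if clamp_seg:
                tau_s = chi if tau_s > chi else (clo if tau_s < clo else tau_s)
            ftau[pid] = tau_s
        trail = pid + 1 if pid + 1 < len(n) else -1
        if trail >= 0:
            if validate:
                assert npos - n[trail] >= fp
            tau_s = pref * log(L0[trail] / (npos - n[trail] - bub))
            if clamp_seg:
                tau_s = chi if tau_s > chi else (clo if tau_s < clo else tau_s)
            ftau[trail] = tau_s

        # schedule the mover
        if npos == slen:
            status[pid] = AT_END
            version[pid] = v2 = version[pid] + 1
            push(heap, (t + expo(exit_rate), pid, v2))
        else:
            # response lookup and the pause-entry roll happen after every
            # hop, including one that lands in contact with the leader
            paused = False
            if tasep:
                if pauses_on and unif() < f0:
                    paused = True
                    open_p[pid] = t
                    open_p_pos[pid] = npos
                    open_p_exp[pid] = d0
                rate = inv_d0 if paused else beta
            else:
                tau = ftau[pid] - (ftau[trail] if trail >= 0 else 0.0)
                if tau > chi:
                    tau = chi
                elif tau < clo:
                    tau = clo
                if rec_tau:
                    tau_counts[_tau_bin(tau, clo, chi, span)] += 1
                if pauses_on and unif() < ffn(tau):
                    paused = True
                    dd = dfn(tau)
                    open_p[pid] = t
                    open_p_pos[pid] = npos
                    open_p_exp[pid] = dd
                    # a zero duration (melting anchor) means the pending
                    # translocation is effectively immediate
                    rate = 1.0 / dd if dd > 1e-9 else 1e9
                else:
                    rate = K * vfn(tau)
            if has_lead and gap == fp:
                # collision: no waiting-time draw while the site ahead is taken
                status[pid] = BLOCKED
                version[pid] += 1
                open_c[pid] = t
                open_c_pos[pid] = npos
            else:
                status[pid] = ELONGATING
                version[pid] = v2 = version[pid] + 1
                push(heap, (t + expo(rate), pid, v2))

        # neighbor updates: fresh draws at the new torque-dependent rates
        if has_lead and not tasep:
            ld = pid - 1
            if status[ld] == ELONGATING:
                tau = ftau[ld] - ftau[pid]
                if tau > chi:
                    tau = chi
                elif tau < clo:
                    tau = clo
                if rec_tau:
                    tau_counts[_tau_bin(tau, clo, chi, span)] += 1
                rate = (
                    _paused_rate(ld, tau, t)
                    if open_p[ld] >= 0.0
                    else K * vfn(tau)
                )
                version[ld] = v2 = version[ld] + 1
                push(heap, (t + expo(rate), ld, v2))
            # a blocked leader stays blocked; termination waits are unaffected
        if trail >= 0:
            tst = status[trail]
            if tst == BLOCKED:
                # the mover just freed the site ahead of its trailer
                if tasep:
                    rate = inv_d0 if open_p[trail] >= 0.0 else beta
                else:
                    tau = ftau[trail] - (ftau[trail + 1] if trail + 1 < len(n) else 0.0)
                    if tau > chi:
                        tau = chi
                    elif tau < clo:
                        tau = clo
                    if rec_tau:
                        tau_counts[_tau_bin(tau, clo, chi, span)] += 1
                    rate = (
                        _paused_rate(trail, tau, t)
                        if open_p[trail] >= 0.0
                        else K * vfn(tau)
                    )
                status[trail] = ELONGATING
                version[trail] = v2 = version[trail] + 1
                push(heap, (t + expo(rate), trail, v2))
            elif not tasep and tst == ELONGATING:
                tau = ftau[trail] - (ftau[trail + 1] if trail + 1 < len(n) else 0.0)
                if tau > chi:
                    tau = chi
                elif tau < clo:
                    tau = clo
                if rec_tau:
                    tau_counts[_tau_bin(tau, clo, chi, span)] += 1
                rate = (
                    _paused_rate(trail, tau, t)
                    if open_p[trail] >= 0.0
                    else K * vfn(tau)
                )
                version[trail] = v2 = version[trail] + 1
                push(heap, (t + expo(rate), trail, v2))

    pauses_df = None
    colls_df = None
    if rec_int:
        pauses_df = pd.DataFrame(
            {
                "pid": np.array(P_pid, dtype=np.int64),
                "pos": np.array(P_pos, dtype=np.int64),
                "start": np.array(P_t0),
                "end": np.array(P_t1),
                "expected": np.array(P_exp),
            }
        )
        colls_df = pd.DataFrame(
            {
                "pid": np.array(C_pid, dtype=np.int64),
                "pos": np.array(C_pos, dtype=np.int64),
                "start": np.array(C_t0),
                "end": np.array(C_t1),
            }
        )

    status_arr = np.array(status, dtype=np.int64)
    if status_arr.size:
        status_arr[(np.array(open_p) >= 0.0) & (status_arr == ELONGATING)] = PAUSED

    return SimulationRecord(
        config=config,
        t_init=np.array(t_init),
        t_term=np.array(t_term),
        n_final=np.array(n, dtype=np.int64),
        status_final=status_arr,
        L0_init=np.array(L0, dtype=np.int64),
        pause_count=np.array(p_cnt, dtype=np.int64),
        pause_time=np.array(p_sum),
        pause_sq=np.array(p_sq),
        coll_count=np.array(c_cnt, dtype=np.int64),
        coll_time=np.array(c_sum),
        coll_sq=np.array(c_sq),
        pauses=pauses_df,
        collisions=colls_df,
        torque_counts=np.array(tau_counts, dtype=np.int64) if rec_tau else None,
        n_events=n_events,
        n_initiation_attempts=n_attempts,
    )


def _tau_bin(tau: float, lo: float, hi: float, span: int) -> int:
    """Histogram bin index for a clamped torque value.

    Bin 0 holds exactly-clamped low values, the last bin exactly-clamped high
    values; interior unit bins are left-open/right-closed, with the bin just
    below the high clamp open on both sides.
    """
    if tau == hi:
        return span + 1
    if tau == lo:
        return 0
    k = ceil(tau - lo)
    return span if k >= span else k
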