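"""Aggregate statistics of simulated transcription runs.

Transcription times are averaged only over polymerases that both initiate
and terminate within the simulated horizon, and pause/collision intervals
are included only when they start before the final recorded termination
(right-censoring of the unfinished tail of the run).  Per-polymerase means
divide the pooled event totals of the censored polymerases by their number,
and duration means are event-weighted, so the delay identity

    total_delay = pauses_per_RNAP * mean_pause_duration
                + collisions_per_RNAP * mean_collision_duration

holds exactly on every summary row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulator import SimulationRecord

__all__ = [
    "CensoredRecord",
    "SummaryStats",
    "censor_records",
    "summarize",
    "delay_decomposition",
    "variability_measures",
    "collision_rate_fit",
    "torque_histogram",
    "torque_histogram_from_counts",
    "coverage",
]


@dataclass
class CensoredRecord:
    """A SimulationRecord restricted to polymerases that completed in time."""

    config: object
    t_init: np.ndarray
    t_term: np.ndarray
    pause_count: np.ndarray
    pause_time: np.ndarray
    pause_sq: np.ndarray
    coll_count: np.ndarray
    coll_time: np.ndarray
    coll_sq: np.ndarray
    pauses: pd.DataFrame | None
    collisions: pd.DataFrame | None
    torque_counts: np.ndarray | None
    final_termination: float
    n_total: int

    @property
    def transcription_times(self) -> np.ndarray:
        return self.t_term - self.t_init


def censor_records(record: SimulationRecord) -> CensoredRecord:
    """Keep completed polymerases and intervals starting before the last exit.

    A pause or collision of a completed polymerase necessarily starts before
    that polymerase's own termination, so restricting the per-polymerase
    aggregates to completed polymerases also enforces the interval-level
    rule; the interval tables are filtered explicitly as well.
    """
    done = record.completed
    final_term = float(np.max(record.t_term[done])) if done.any() else math.nan

    def _filter(df: pd.DataFrame | None) -> pd.DataFrame | None:
        if df is None:
            return None
        keep = done[df["pid"].to_numpy()]
        if not math.isnan(final_term):
            keep &= df["start"].to_numpy() < final_term
        return df.loc[keep].reset_index(drop=True)

    return CensoredRecord(
        config=record.config,
        t_init=record.t_init[done],
        t_term=record.t_term[done],
        pause_count=record.pause_count[done],
        pause_time=record.pause_time[done],
        pause_sq=record.pause_sq[done],
        coll_count=record.coll_count[done],
        coll_time=record.coll_time[done],
        coll_sq=record.coll_sq[done],
        pauses=_filter(record.pauses),
        collisions=_filter(record.collisions),
        torque_counts=record.torque_counts,
        final_termination=final_term,
        n_total=record.n_polymerases,
    )


@dataclass
class SummaryStats:
    """Per-condition aggregates mirroring the standard results-table columns."""

    alpha: float
    n_completed: int
    coverage_pct: float
    mean_transcription_time: float
    pauses_per_rnap: float
    mean_pause_duration: float
    collisions_per_rnap: float
    mean_collision_duration: float
    pause_delay: float
    collision_delay: float
    total_delay: float
    cv_transcription_time: float
    vmr_transcription_time: float
    var_pause_duration: float
    var_collision_duration: float

    def as_row(self) -> dict[str, float]:
        return {
            "alpha": self.alpha,
            "coverage_pct": self.coverage_pct,
            "transcription_time_s": self.mean_transcription_time,
            "collision_delay_s": self.collision_delay,
            "pause_delay_s": self.pause_delay,
            "total_delay_s": self.total_delay,
            "pauses_per_rnap": self.pauses_per_rnap,
            "pause_duration_s": self.mean_pause_duration,
            "collisions_per_rnap": self.collisions_per_rnap,
            "collision_duration_s": self.mean_collision_duration,
            "cv_time": self.cv_transcription_time,
            "vmr_time": self.vmr_transcription_time,
            "var_pause_duration": self.var_pause_duration,
            "var_collision_duration": self.var_collision_duration,
            "n_completed": self.n_completed,
        }


def _pooled_variance(count: float, total: float, total_sq: float) -> float:
    """Unbiased sample variance from (n, sum, sum of squares)."""
    if count < 2:
        return math.nan
    var = (total_sq - total * total / count) / (count - 1)
    return max(var, 0.0)


def summarize(
    records: SimulationRecord | Iterable[SimulationRecord],
) -> SummaryStats:
    """Censor and pool one or more replicate records into one summary row.

    Replicates are pooled at the polymerase level: event totals are summed
    across all censored polymerases of all replicates before any ratio is
    formed.
    """
    if isinstance(records, SimulationRecord):
        records = [records]
    records = list(records)
    if not records:
        raise ValueError("no records to summarize")
    cens = [censor_records(r) for r in records]

    times = np.concatenate([c.transcription_times for c in cens])
    n_done = len(times)
    if n_done == 0:
        raise ValueError(
            "no polymerase completed within t_max; nothing to summarize"
        )

    np_tot = float(sum(c.pause_count.sum() for c in cens))
    pt_tot = float(sum(c.pause_time.sum() for c in cens))
    pq_tot = float(sum(c.pause_sq.sum() for c in cens))
    nc_tot = float(sum(c.coll_count.sum() for c in cens))
    ct_tot = float(sum(c.coll_time.sum() for c in cens))
    cq_tot = float(sum(c.coll_sq.sum() for c in cens))

    pauses_per = np_tot / n_done
    colls_per = nc_tot / n_done
    mean_pause = pt_tot / np_tot if np_tot else 0.0
    mean_coll = ct_tot / nc_tot if nc_tot else 0.0
    pause_delay, coll_delay, total_delay = delay_decomposition(
        pauses_per, mean_pause, colls_per, mean_coll
    )

    mean_time = float(times.mean())
    if n_done >= 2 and mean_time > 0:
        cv, vmr, _ = variability_measures(times)
    else:
        cv = vmr = math.nan

    cov = float(np.mean([coverage(r) for r in records]))

    return SummaryStats(
        alpha=records[0].config.alpha,
        n_completed=n_done,
        coverage_pct=cov,
        mean_transcription_time=mean_time,
        pauses_per_rnap=pauses_per,
        mean_pause_duration=mean_pause,
        collisions_per_rnap=colls_per,
        mean_collision_duration=mean_coll,
        pause_delay=pause_delay,
        collision_delay=coll_delay,
        total_delay=total_delay,
        cv_transcription_time=cv,
        vmr_transcription_time=vmr,
        var_pause_duration=_pooled_variance(np_tot, pt_tot, pq_tot),
        var_collision_duration=_pooled_variance(nc_tot, ct_tot, cq_tot),
    )


def delay_decomposition(
    n_pauses: float,
    mean_pause_dur: float,
    n_collisions: float,
    mean_coll_dur: float,
) -> tuple[float, float, float]:
    """Split the per-polymerase delay into its pause and collision parts."""
    if min(n_pauses, mean_pause_dur, n_collisions, mean_coll_dur) < 0:
        raise ValueError("delay inputs must be nonnegative")
    pause_delay = n_pauses * mean_pause_dur
    coll_delay = n_collisions * mean_coll_dur
    return pause_delay, coll_delay, pause_delay + coll_delay


def variability_measures(samples: Sequence[float]) -> tuple[float, float, float]:
    """Coefficient of variation, variance-to-mean ratio and sample variance.

    Uses the unbiased (n-1) variance convention.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    mean = float(x.mean())
    if mean <= 0:
        raise ValueError("variability measures undefined for nonpositive mean")
    var = float(x.var(ddof=1))
    return math.sqrt(var) / mean, var / mean, var


def collision_rate_fit(
    alphas: Sequence[float], mean_collisions: Sequence[float]
) -> float:
    """Zero-intercept least-squares slope of collisions per RNAP versus alpha."""
    a = np.asarray(alphas, dtype=float)
    y = np.asarray(mean_collisions, dtype=float)
    if a.shape != y.shape or a.size < 2:
        raise ValueError("need two equal-length samples")
    denom = float(np.dot(a, a))
    if denom == 0.0:
        raise ValueError("cannot fit a slope through all-zero alphas")
    return float(np.dot(a, y)) / denom


def _bin_labels(lo: int, hi: int) -> list[str]:
    labels = [str(lo)]
    labels += [str(k) for k in range(lo + 1, hi)]
    labels.append(f"<{hi}")
    labels.append(str(hi))
    return labels


def torque_histogram(
    taus: Sequence[float], clamp_low: float = -10.0, clamp_high: float = 10.0
) -> pd.Series:
    """Percentage of computed torque values falling in each unit-wide bin.

    The exact clamp values get their own bars; interior bins are
    ``(k-1, k]`` and the bin just below the upper clamp is the open interval
    ``(high-1, high)``, labelled ``"<high"``.  Percentages sum to 100.
    """
    x = np.asarray(taus, dtype=float)
    if x.size == 0:
        raise ValueError("empty torque stream")
    if np.any(x < clamp_low) or np.any(x > clamp_high):
        raise ValueError("torque value outside the clamp range")
    lo = int(round(clamp_low))
    hi = int(round(clamp_high))
    span = hi - lo
    counts = np.zeros(span + 2, dtype=np.int64)
    counts[0] = int(np.sum(x == clamp_low))
    counts[-1] = int(np.sum(x == clamp_high))
    interior = x[(x != clamp_low) & (x != clamp_high)]
    k = np.ceil(interior - lo).astype(np.int64)
    k = np.minimum(k, span)
    np.add.at(counts, k, 1)
    return torque_histogram_from_counts(counts, lo, hi)


def torque_histogram_from_counts(
    counts: np.ndarray, clamp_low: int = -10, clamp_high: int = 10
) -> pd.Series:
    """Convert binned torque tallies (engine output) into labelled percentages."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty torque histogram")
    return pd.Series(
        100.0 * counts / total, index=_bin_labels(clamp_low, clamp_high)
    )


def coverage(record: SimulationRecord, t_end: float | None = None) -> float:
    """Time-averaged percent of the strand covered by polymerase footprints.

    Each polymerase contributes one footprint from its initiation until its
    termination (or the end of the window).  The brief entry phase, during
    which part of the footprint still trails off-lattice, is counted at full
    footprint size.
    """
    cfg = record.config
    if t_end is None:
        t_end = cfg.t_max
    if t_end <= 0:
        raise ValueError("coverage window must be positive")
    t0 = np.minimum(record.t_init, t_end)
    t1 = np.minimum(np.nan_to_num(record.t_term, nan=np.inf), t_end)
    occupancy = float(np.sum(np.maximum(t1 - t0, 0.0))) * cfg.footprint
    return 100.0 * occupancy / (t_end * cfg.strand_length)
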