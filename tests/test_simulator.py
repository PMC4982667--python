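"""Event-driven engine: exclusion, scheduling, pauses, collisions, records."""

import math
import random

import numpy as np
import pytest
from scipy import stats

from etamsim.analysis import summarize, torque_histogram_from_counts
from etamsim.simulator import run_simulation, schedule_next_move
from etamsim.workbench import build_config, make_fixture


class TestScheduling:
    def test_exponential_waiting_time_mean(self):
        rng = random.Random(0)
        draws = [schedule_next_move(90.0, 0.0, rng) for _ in range(20000)]
        assert np.mean(draws) == pytest.approx(1 / 90, rel=0.03)

    def test_blocked_polymerase_gets_no_event(self):
        assert schedule_next_move(0.0, 5.0, random.Random(0)) == math.inf
        assert schedule_next_move(-1.0, 5.0, random.Random(0)) == math.inf

    def test_seeded_reproducibility(self):
        a = [schedule_next_move(10.0, 0.0, random.Random(7)) for _ in range(1)]
        b = [schedule_next_move(10.0, 0.0, random.Random(7)) for _ in range(1)]
        assert a == b


class TestDeterminism:
    def test_identical_seed_identical_record(self):
        cfg = build_config(0.01, 60.0, 123, "etam", strand_length=700, validate=True)
        r1, r2 = run_simulation(cfg), run_simulation(cfg)
        np.testing.assert_array_equal(r1.t_init, r2.t_init)
        np.testing.assert_array_equal(r1.t_term, r2.t_term)
        np.testing.assert_array_equal(r1.pause_count, r2.pause_count)
        np.testing.assert_array_equal(r1.torque_counts, r2.torque_counts)
        assert r1.pauses.equals(r2.pauses)
        assert r1.collisions.equals(r2.collisions)

    def test_different_seeds_differ(self):
        c1 = build_config(0.01, 60.0, 1, "etam", strand_length=700)
        c2 = build_config(0.01, 60.0, 2, "etam", strand_length=700)
        assert run_simulation(c1).n_events != run_simulation(c2).n_events


class TestSinglePolymeraseKinetics:
    def test_transit_time_matches_erlang_mean(self):
        """A lone polymerase makes L-1 hops plus one exit wait at rate beta."""
        L = 900
        times = []
        for seed in range(25):
            cfg = build_config(
                0.0001, 400.0, seed, "tasep_baseline", strand_length=L
            )
            rec = run_simulation(cfg)
            times.extend((rec.t_term - rec.t_init)[rec.completed])
        expected = L / 90.0  # (L-1) hops + 1 termination, each mean 1/90
        sem = expected / math.sqrt(L) / math.sqrt(len(times))
        assert np.mean(times) == pytest.approx(expected, abs=4 * sem + 0.05)

    def test_pause_count_matches_binomial_expectation(self):
        """Each hop (except onto the last site) rolls for a pause at F(0)."""
        L = 800
        counts = []
        for seed in range(25):
            cfg = build_config(0.0001, 400.0, seed, "tasep", strand_length=L)
            rec = run_simulation(cfg)
            counts.extend(rec.pause_count[rec.completed])
        expected = (L - 2) * 0.0128
        assert np.mean(counts) == pytest.approx(expected, rel=0.15)

    def test_lone_torque_is_always_zero(self):
        rec = make_fixture("single_runner", seed=3)
        h = torque_histogram_from_counts(rec.torque_counts)
        assert h["0"] == pytest.approx(100.0)


class TestExclusionAndOrder:
    def test_active_fronts_separated_by_footprint(self):
        cfg = build_config(0.05, 80.0, 9, "etam", strand_length=900, validate=True)
        rec = run_simulation(cfg)
        active = rec.status_final != 4  # not DONE
        fronts = rec.n_final[active]
        assert (np.diff(fronts) <= -35).all()  # ordered, non-overlapping

    def test_no_overtaking(self):
        cfg = build_config(0.05, 120.0, 10, "etam", strand_length=900, validate=True)
        rec = run_simulation(cfg)
        done = np.flatnonzero(rec.completed)
        # initiation order equals termination order
        term_times = rec.t_term[done]
        assert (np.diff(term_times) > 0).all()

    def test_event_times_recorded_in_order(self):
        rec = make_fixture("two_polymerase_collision", seed=3)
        for df in (rec.pauses, rec.collisions):
            assert (df["end"] >= df["start"]).all()
            for pid, grp in df.groupby("pid"):
                grp = grp.sort_values("start")
                # intervals of one polymerase never overlap within a category
                assert (grp["start"].values[1:] >= grp["end"].values[:-1] - 1e-12).all()


class TestCollisions:
    def test_collision_recorded_when_trailer_reaches_contact(self):
        rec = make_fixture("two_polymerase_collision", seed=3)
        assert len(rec.collisions) >= 1
        # collision positions: the trailer's stalled front position
        assert (rec.collisions["pos"] >= 1).all()
        assert (rec.collisions["pos"] < rec.config.strand_length).all()

    def test_collision_ends_at_translocation_not_site_vacancy(self):
        # every collision interval has positive length: the trailer's next
        # hop, not the leader's departure, closes it
        rec = make_fixture("two_polymerase_collision", seed=3)
        assert ((rec.collisions["end"] - rec.collisions["start"]) > 0).all()

    def test_baseline_has_no_pauses_but_can_collide(self):
        cfg = build_config(0.05, 120.0, 21, "tasep_baseline", strand_length=600)
        rec = run_simulation(cfg)
        assert rec.pause_count.sum() == 0
        assert rec.pauses is not None and len(rec.pauses) == 0


class TestPauses:
    def test_paused_leader_is_pushed_out_early(self):
        """Neighbor motion shortens a pause below its drawn expectation."""
        rec = make_fixture("paused_leader_pushed", seed=3)
        realized = rec.pauses["end"] - rec.pauses["start"]
        assert (realized < rec.pauses["expected"]).any()

    def test_torque_raises_pause_exit_rate_monotonically(self):
        """A trailer's approach lowers the leader's torque, hence its
        expected pause duration (push from the back)."""
        from etamsim.response import pause_duration_nonlinear
        from etamsim.torque import TorqueModel, net_torque, segment_torque

        m = TorqueModel(clamp_segments=False)
        rear_gaps = [60, 50, 40, 30, 20]  # trailer closing in
        taus = [
            net_torque(m, segment_torque(m, 80, 80), segment_torque(m, 60, g))
            for g in rear_gaps
        ]
        durations = [pause_duration_nonlinear(t) for t in taus]
        assert all(a >= b for a, b in zip(durations, durations[1:]))

    def test_memoryless_restart_preserves_exponential_law(self):
        """Restarting an exponential clock at the same rate whenever an
        independent Poisson event fires leaves the exit law exponential."""
        rng = random.Random(99)
        rate, interrupt = 4.0, 9.0
        samples = []
        for _ in range(4000):
            t = 0.0
            while True:
                exit_in = rng.expovariate(rate)
                kick_in = rng.expovariate(interrupt)
                if exit_in <= kick_in:
                    samples.append(t + exit_in)
                    break
                t += kick_in  # redraw at the same rate: memoryless restart
        ks = stats.kstest(samples, "expon", args=(0, 1 / rate))
        assert ks.pvalue > 0.01

    def test_aggregate_mode_matches_interval_mode(self):
        kw = dict(strand_length=700, validate=True)
        full = run_simulation(build_config(0.02, 80.0, 5, "etam", **kw))
        slim = run_simulation(
            build_config(0.02, 80.0, 5, "etam", record_intervals=False, **kw)
        )
        np.testing.assert_array_equal(full.pause_count, slim.pause_count)
        np.testing.assert_allclose(full.pause_time, slim.pause_time)
        np.testing.assert_array_equal(full.coll_count, slim.coll_count)
        assert slim.pauses is None
        s1, s2 = summarize(full), summarize(slim)
        assert s1.mean_transcription_time == s2.mean_transcription_time
        assert s1.total_delay == s2.total_delay


class TestTasepLimit:
    def oracle_tasep(self, seed, L, alpha, beta, t_max, footprint=35):
        """Direct, independently written TASEP with constant-rate pauses.

        Minimal Gillespie loop over per-polymerase exponential clocks; no
        shared code with the engine beyond the response constants.
        """
        rng = random.Random(seed)
        f0, d0 = 0.0128, 0.5581
        pos, paused, tnext = [], [], []
        born, died = [], []
        next_init = rng.expovariate(alpha * beta)
        t = 0.0
        n_coll = 0
        pause_tot = 0
        while True:
            tmin, who = next_init, -1
            for i, tn in enumerate(tnext):
                if tn < tmin:
                    tmin, who = tn, i
            if tmin > t_max:
                break
            t = tmin
            if who == -1:
                next_init = t + rng.expovariate(alpha * beta)
                last = pos[-1] if pos and pos[-1] < 10**8 else None
                if last is None or last > footprint:
                    pos.append(1)
                    paused.append(False)
                    born.append(t)
                    died.append(math.nan)
                    if last is not None and last == footprint + 1:
                        tnext.append(math.inf)  # created in contact
                        n_coll += 1
                    else:
                        tnext.append(t + rng.expovariate(beta))
                continue
            i = who
            if pos[i] == L:  # exit event
                pos[i] = 10**9
                tnext[i] = math.inf
                died[i] = t
                if i + 1 < len(pos) and tnext[i + 1] == math.inf and pos[i + 1] < 10**8:
                    tnext[i + 1] = t + rng.expovariate(
                        (1 / d0) if paused[i + 1] else beta
                    )
                continue
            pos[i] += 1
            paused[i] = False
            if pos[i] == L:
                tnext[i] = t + rng.expovariate(beta)  # termination wait
            else:
                if rng.random() < f0:
                    paused[i] = True
                    pause_tot += 1
                lead = pos[i - 1] if i > 0 and pos[i - 1] < 10**8 else None
                if lead is not None and lead - pos[i] == footprint:
                    tnext[i] = math.inf  # blocked
                    n_coll += 1
                else:
                    tnext[i] = t + rng.expovariate((1 / d0) if paused[i] else beta)
            # free a blocked trailer
            if i + 1 < len(pos) and tnext[i + 1] == math.inf and pos[i + 1] < 10**8:
                if pos[i] - pos[i + 1] > footprint:
                    tnext[i + 1] = t + rng.expovariate(
                        (1 / d0) if paused[i + 1] else beta
                    )
        times = [d - b for b, d in zip(born, died) if not math.isnan(d)]
        return times, n_coll, pause_tot

    def test_engine_matches_direct_tasep_oracle(self):
        """Dual-route check on a short strand: the torque engine in its
        constant-rate limit against an independently coded TASEP."""
        L, alpha, t_max = 300, 0.02, 400.0
        eng_times, eng_colls = [], 0
        ora_times, ora_colls = [], 0
        for seed in range(12):
            cfg = build_config(
                alpha, t_max, seed, "tasep", strand_length=L, record_intervals=False
            )
            rec = run_simulation(cfg)
            eng_times.extend((rec.t_term - rec.t_init)[rec.completed])
            eng_colls += rec.coll_count.sum()
            times, colls, _ = self.oracle_tasep(seed + 1000, L, alpha, 90.0, t_max)
            ora_times.extend(times)
            ora_colls += colls
        # transit-time distributions agree (two-sample KS at matched n)
        assert np.mean(eng_times) == pytest.approx(np.mean(ora_times), rel=0.05)
        ks = stats.ks_2samp(eng_times, ora_times)
        assert ks.pvalue > 0.001
        # collision pressure of the same magnitude
        assert eng_colls == pytest.approx(ora_colls, rel=0.35)


class TestRecordContents:
    def test_polymerase_state_snapshot(self):
        rec = make_fixture("single_runner", seed=3)
        p = rec.polymerase(0)
        assert p.index == 0
        assert p.L0_init is None  # initiated on an empty strand
        assert p.status == "done"
        assert p.t_terminated > p.t_initiated

    def test_torque_histogram_stream_recorded(self):
        cfg = build_config(0.02, 60.0, 4, "etam", strand_length=700)
        rec = run_simulation(cfg)
        assert rec.torque_counts is not None
        assert rec.torque_counts.sum() > 0
        assert torque_histogram_from_counts(rec.torque_counts).sum() == pytest.approx(
            100.0
        )

    def test_constant_rate_variant_skips_torque_log(self):
        cfg = build_config(0.02, 30.0, 4, "tasep", strand_length=500)
        assert run_simulation(cfg).torque_counts is None
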