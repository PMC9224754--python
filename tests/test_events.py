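import numpy as np
import pytest

from gaitpipe.events import (
    FootfallOverlapError,
    GaitEvent,
    detect_ic,
    detect_to,
    estimate_stride_period,
    psw_events,
    relative_displacement,
    validate_sequence,
)
from gaitpipe.io import FootprintRecord


class TestRelativeDisplacement:
    def test_landmark_equal_pelvis_gives_zero(self):
        y = np.linspace(0, 5, 50)
        np.testing.assert_array_equal(relative_displacement(y, y, 1), 0.0)

    def test_direction_antisymmetry(self):
        rng = np.random.default_rng(0)
        l, p = rng.normal(size=40), rng.normal(size=40)
        np.testing.assert_array_equal(relative_displacement(l, p, -1),
                                      -relative_displacement(l, p, 1))

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        l, p = rng.normal(size=40), rng.normal(size=40)
        np.testing.assert_allclose(relative_displacement(l + 3.7, p + 3.7, 1),
                                   relative_displacement(l, p, 1), atol=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            relative_displacement(np.zeros(5), np.zeros(6), 1)

    def test_bad_direction(self):
        with pytest.raises(ValueError):
            relative_displacement(np.zeros(5), np.zeros(5), 2)


class TestDetectors:
    def test_sinusoid_peaks_and_troughs(self):
        rate, period = 60.0, 1.0
        t = np.arange(int(6 * period * rate)) / rate
        x = np.sin(2 * np.pi * t / period)  # peaks at t = 0.25 + k
        ics = detect_ic(x, rate, side="L")
        tos = detect_to(x, rate, side="L")
        ic_frames = np.array([e.frame for e in ics])
        assert np.all(np.diff(ic_frames) == int(period * rate))
        assert (ic_frames % int(period * rate) == 15).all()
        to_frames = np.array([e.frame for e in tos])
        assert (to_frames % int(period * rate) == 45).all()

    def test_period_estimate_matches_sinusoid(self):
        rate, period = 60.0, 1.1
        t = np.arange(int(8 * period * rate)) / rate
        est = estimate_stride_period(np.sin(2 * np.pi * t / period), rate)
        assert est == pytest.approx(period, abs=1.0 / rate)

    def test_plateau_ties_resolve_to_earliest_frame(self):
        x = np.concatenate([np.zeros(30), np.ones(5), np.zeros(30)])
        (ev,) = detect_ic(x, 60.0, side="L", min_separation_s=0.4)
        assert ev.frame == 30

    def test_brute_force_extrema_equivalence(self):
        rate = 60.0
        rng = np.random.default_rng(5)
        t = np.arange(int(7 * rate)) / rate
        x = (np.sin(2 * np.pi * t) + 0.3 * np.sin(4 * np.pi * t + 0.7)
             + 0.02 * rng.normal(size=t.size))
        w = int(0.5 * rate)  # half the (known) 1 s stride period
        brute = [i for i in range(x.size)
                 if all(x[i] > x[j]
                        for j in range(max(0, i - w), min(x.size, i + w + 1))
                        if j != i)]
        detected = [e.frame for e in
                    detect_ic(x, rate, side="L", min_separation_s=0.5)]
        assert detected == brute

    def test_no_extrema_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert detect_ic(np.linspace(0, 1, 50), 60.0, side="L") == []

    def test_mirrored_pass_gives_identical_events(self, session):
        # walking-direction invariance: flip Y and direction together
        rec = session.mlmc[0]
        track = rec.tracks[0]
        valid = track.valid
        u0, u1 = np.nonzero(valid)[0][[0, -1]]
        pelvis = track.poses["pelvis"].translations[u0:u1, 1]
        heel = track.landmark("heel", "l")[u0:u1, 1]
        fwd = relative_displacement(heel, pelvis, 1)
        mirrored = relative_displacement(-heel, -pelvis, -1)
        a = [e.frame for e in detect_ic(fwd, rec.rate, side="L")]
        b = [e.frame for e in detect_ic(mirrored, rec.rate, side="L")]
        assert a == b


class TestSyntheticRecovery:
    def test_zero_noise_events_within_one_frame(self, session, analysis):
        tol = 1.0 / 60.0 + 1e-9
        detected = {}
        for e in analysis.mlmc_events:
            detected.setdefault((e.kind, e.side), []).append(e.time)
        checked = 0
        for te in session.truth_events:
            track = session.mlmc[te.pass_id].tracks[0]
            f = te.frame
            if not (1 <= f < track.n_frames - 1) or not track.valid[f - 1:f + 2].all():
                continue  # outside the usable interval
            times = np.array(detected[(te.kind, te.side)])
            assert np.min(np.abs(times - te.time)) <= tol
            checked += 1
        assert checked > 20


class TestValidateSequence:
    def test_canonical_synthetic_pass_keeps_all_cycles(self, session):
        evs = [e for e in session.truth_events if e.pass_id == 0]
        runs, discarded = validate_sequence(evs, min_cycles=3)
        sides = sorted(r.side for r in runs)
        assert sides == ["L", "R"]
        assert all(r.n_cycles >= 3 for r in runs)
        # only boundary events that cannot complete a stride are left over
        assert len(discarded) <= 8

    def test_missing_toe_off_splits_run(self, session):
        evs = [e for e in session.truth_events if e.pass_id == 0]
        runs_full, _ = validate_sequence(evs, min_cycles=3)
        n_full = sum(r.n_cycles for r in runs_full)
        mid_to = [e for e in sorted(evs, key=lambda e: e.time)
                  if e.kind == "TO"][len(evs) // 4]
        evs_broken = [e for e in evs if e is not mid_to]
        runs_broken, discarded = validate_sequence(evs_broken, min_cycles=3)
        assert sum(r.n_cycles for r in runs_broken) < n_full
        assert discarded

    def test_exactly_three_cycles_retained(self):
        # hand-built canonical chain: 3 full cycles per side
        events = []
        T, stance = 1.0, 0.65
        t0 = 0.0
        for k in range(5):
            for side, tshift in (("L", 0.0), ("R", 0.5)):
                t_ic = t0 + k * T + tshift
                events.append(GaitEvent("IC", side, t_ic, int(t_ic * 60)))
                events.append(GaitEvent("TO", side, t_ic + stance,
                                        int((t_ic + stance) * 60)))
        events = [e for e in sorted(events, key=lambda e: e.time)
                  if e.time <= 4.2]
        runs, _ = validate_sequence(events, min_cycles=3)
        assert any(r.side == "L" and r.n_cycles >= 3 for r in runs)

    def test_short_runs_discarded(self):
        events = [
            GaitEvent("IC", "L", 0.0, 0), GaitEvent("TO", "R", 0.15, 9),
            GaitEvent("IC", "R", 0.5, 30), GaitEvent("TO", "L", 0.65, 39),
            GaitEvent("IC", "L", 1.0, 60),
        ]
        runs, discarded = validate_sequence(events, min_cycles=3)
        assert runs == []
        assert len(discarded) == 5


class TestPswEvents:
    def _fp(self, side, t_on, t_off, y=0.0, complete=True):
        return FootprintRecord(side, t_on, t_off, (0.06, y), (0.06, y + 0.24),
                               complete=complete)

    def test_alternating_footprints_emit_canonical_events(self):
        fps = [self._fp("L", 0.0, 0.7), self._fp("R", 0.55, 1.25)]
        evs = psw_events(fps)
        assert [(e.kind, e.side) for e in evs] == [
            ("IC", "L"), ("IC", "R"), ("TO", "L"), ("TO", "R")]
        assert all(e.source == "PSW" for e in evs)

    def test_incomplete_footprint_excluded(self):
        fps = [self._fp("L", 0.0, 0.7),
               self._fp("R", 0.55, 1.25, complete=False)]
        evs = psw_events(fps)
        assert {e.side for e in evs} == {"L"}
        assert len(evs) == 2

    def test_overlapping_same_side_contacts_error(self):
        fps = [self._fp("L", 0.0, 0.7), self._fp("L", 0.5, 1.2)]
        with pytest.raises(FootfallOverlapError):
            psw_events(fps)

    def test_zero_latency_psw_ic_matches_truth(self, session):
        truth_ic = sorted(e.time for e in session.truth_events
                          if e.kind == "IC")
        for e in psw_events(session.psw):
            if e.kind != "IC":
                continue
            nearest = min(abs(t - e.time) for t in truth_ic)
            assert nearest <= 1.0 / 100.0 + 1e-9
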