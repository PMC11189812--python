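"""airPLS baseline, z-scoring, event selection, evoked statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from iegmap.errors import (
    ConfigurationError,
    DegenerateInputError,
    EventValidationError,
    FormatError,
)
from iegmap.photometry import (
    AirPLSBaseline,
    PhotometryTrace,
    ZTrace,
    airpls_baseline,
    correct_and_zscore,
    evoked_duration_correlation,
    evoked_response,
    evoked_responses,
    peri_event_matrix,
    select_nonsequential_events,
    session_evoked_summary,
)
from iegmap.simulate import PhotoSimConfig, gen_photometry_session


def _ztrace(z, rate=100.0, t0=0.0):
    z = np.asarray(z, float)
    return ZTrace(time=t0 + np.arange(z.size) / rate, z=z, rate=rate,
                  baseline_interval=(t0, t0 + 1.0), baseline_mean=0.0,
                  baseline_sd=1.0)


class TestAirPLS:
    def test_constant_signal_is_fixed_point(self):
        fit = airpls_baseline(np.full(500, 7.3), lam=1e4)
        np.testing.assert_allclose(fit.baseline, 7.3, atol=1e-8)

    def test_line_in_penalty_null_space(self):
        y = 2.0 + 0.01 * np.arange(2000)
        fit = airpls_baseline(y, lam=1e6, order=2)
        np.testing.assert_allclose(fit.baseline, y, atol=1e-6)

    def test_recovers_drift_under_positive_transients(self):
        # drift + transients, no white noise: the reweighting must ignore
        # the 20 positive transients and return the drift
        cfg = PhotoSimConfig(baseline_minutes=2.0, session_minutes=8.0,
                             noise_sd=0.0, n_events_per_label=10,
                             amplitude_jitter_sd=0.0, seed=21)
        trace, events, truth = gen_photometry_session(cfg)
        y = trace["fluorescence"].to_numpy()
        fit = airpls_baseline(y)
        mask = np.ones(y.size, bool)
        for on in events["onset_s"]:
            i0 = int(round(on * cfg.rate))
            mask[i0:i0 + int(9 * cfg.rate)] = False
        rmse = np.sqrt(np.mean((fit.baseline - truth.drift)[mask] ** 2))
        assert rmse < 0.05 * (truth.drift.max() - truth.drift.min())

    def test_roughness_monotone_in_lambda(self):
        cfg = PhotoSimConfig(baseline_minutes=1.0, session_minutes=6.0,
                             n_events_per_label=5, seed=7)
        y = gen_photometry_session(cfg)[0]["fluorescence"].to_numpy()
        rough = [
            float(np.sum(np.diff(airpls_baseline(y, lam=lam).baseline, 2) ** 2))
            for lam in (1e3, 1e5, 1e7, 1e9, 1e11)
        ]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(rough, rough[1:]))

    def test_input_validation(self):
        with pytest.raises(FormatError):
            airpls_baseline(np.array([1.0, np.nan] * 10))
        with pytest.raises(ConfigurationError):
            airpls_baseline(np.ones(100), lam=0.0)
        with pytest.raises(FormatError):
            airpls_baseline(np.ones(5))

    def test_transformer_facade(self):
        y = np.full(200, 3.0)
        est = AirPLSBaseline(lam=1e4)
        out = est.fit(y).transform(y)
        np.testing.assert_allclose(out, 0.0, atol=1e-8)
        assert est.get_params()["lam"] == 1e4


class TestCorrectAndZScore:
    def _trace(self, f, rate=100.0, baseline=(0.0, 1.0)):
        f = np.asarray(f, float)
        return PhotometryTrace(time=np.arange(f.size) / rate, fluorescence=f,
                               rate=rate, baseline_interval=baseline)

    def test_unit_definition_one_sd_above_mean(self, rng):
        f = rng.normal(10.0, 2.0, size=400)
        tr = self._trace(f, baseline=(0.0, 4.0))
        zt = correct_and_zscore(tr, None)
        mu, sd = f.mean(), f.std(ddof=1)
        i = int(np.argmin(np.abs(f - (mu + sd))))
        probe = f.copy()
        probe[i] = mu + sd
        zt2 = correct_and_zscore(self._trace(probe, baseline=(0.0, 4.0)), None)
        assert zt2.z[i] == pytest.approx(
            (probe[i] - probe.mean()) / probe.std(ddof=1), abs=1e-12)
        np.testing.assert_allclose(zt.z.mean(), 0.0, atol=1e-10)

    def test_baseline_segment_mean_zero_sd_one(self, rng):
        f = 50.0 + rng.normal(size=3000)
        tr = self._trace(f, baseline=(0.0, 10.0))
        zt = correct_and_zscore(tr, None)
        mask = tr.baseline_mask()
        assert abs(zt.z[mask].mean()) < 1e-8
        assert abs(zt.z[mask].std(ddof=1) - 1.0) < 1e-8

    def test_white_noise_session_mean_near_zero(self, rng):
        n = 20000
        f = rng.normal(size=n)
        zt = correct_and_zscore(self._trace(f, baseline=(0.0, 50.0)), None)
        assert abs(zt.z.mean()) < 4.0 / np.sqrt(n) / 0.9  # CLT bound, SD ~1

    def test_constant_signal_degenerate(self):
        with pytest.raises(DegenerateInputError):
            correct_and_zscore(self._trace(np.full(300, 5.0)), None)

    def test_smoothing_preserves_baseline_normalization(self, rng):
        f = rng.normal(size=2000)
        zt = correct_and_zscore(self._trace(f, baseline=(0.0, 10.0)), None,
                                smooth_window=0.5)
        mask = (np.arange(2000) / 100.0) < 10.0
        assert abs(zt.z[mask].mean()) < 1e-8
        assert abs(zt.z[mask].std(ddof=1) - 1.0) < 1e-8


def _events(rows):
    return pd.DataFrame(rows, columns=["onset_s", "offset_s", "label"])


class TestEventSelection:
    def test_documented_example(self):
        ev = _events([(0, 5, "mouse"), (12, 14, "mouse"), (30, 31, "mouse")])
        kept = select_nonsequential_events(ev, min_gap=10.0)
        assert list(kept["onset_s"]) == [0, 30]

    def test_single_event_kept(self):
        kept = select_nonsequential_events(_events([(3, 4, "m")]))
        assert len(kept) == 1

    def test_boundary_gap_inclusive(self):
        ev = _events([(0, 5, "m"), (15, 16, "m"), (26, 27, "m")])
        kept = select_nonsequential_events(ev, min_gap=10.0)
        assert len(kept) == 3

    def test_overlap_rejected(self):
        with pytest.raises(EventValidationError):
            select_nonsequential_events(_events([(0, 5, "m"), (4, 8, "m")]))
        with pytest.raises(EventValidationError):
            select_nonsequential_events(_events([(0, 0, "m")]))

    @given(st.lists(st.tuples(st.floats(0, 50), st.floats(0.1, 5)),
                    max_size=15))
    def test_matches_brute_force_and_idempotent(self, raw):
        # build a valid non-overlapping onset-ordered log
        t, rows = 0.0, []
        for gap, dur in raw:
            t += gap
            rows.append((t, t + dur, "m"))
            t += dur
        ev = _events(rows)
        kept = select_nonsequential_events(ev, min_gap=10.0)
        expect = [i for i in range(len(rows))
                  if i == 0 or rows[i][0] - rows[i - 1][1] >= 10.0]
        assert list(kept.index) == list(range(len(expect)))
        assert list(kept["onset_s"]) == [rows[i][0] for i in expect]
        again = select_nonsequential_events(kept, min_gap=10.0)
        pd.testing.assert_frame_equal(again, kept)


class TestEvokedResponse:
    def test_constant_signal_zero(self):
        zt = _ztrace(np.full(2000, 3.3))
        assert evoked_response(zt, onset=10.0) == 0.0

    def test_step_at_onset_returns_amplitude(self):
        z = np.zeros(2000)
        z[1000:] = 1.7
        assert evoked_response(_ztrace(z), onset=10.0) == pytest.approx(1.7)

    def test_constant_offset_invariance(self, rng):
        z = rng.normal(size=3000)
        zt1, zt2 = _ztrace(z), _ztrace(z + 42.0)
        assert evoked_response(zt1, 15.0) == pytest.approx(
            evoked_response(zt2, 15.0), abs=1e-9)

    def test_truncated_windows_skipped_and_counted(self):
        zt = _ztrace(np.zeros(1000))  # 10 s of trace
        ev = pd.DataFrame({"onset_s": [1.0, 5.0, 9.0],
                           "offset_s": [1.5, 5.5, 9.5],
                           "label": "m", "trial": [1, 2, 3]})
        resp = evoked_responses(zt, ev)
        assert resp.n_skipped == 2
        assert list(resp.responses["trial"]) == [2]

    def test_recovers_planted_kernel_amplitude(self):
        # diff-of-exponentials transients, amplitude a: mean dz over events
        # approaches a x (kernel 3-s window mean)
        cfg = PhotoSimConfig(baseline_minutes=2.0, session_minutes=6.0,
                             noise_sd=0.3, drift_amplitude=0.0,
                             n_events_per_label=10,
                             transient_amplitude={"mouse": 2.0, "object": 2.0},
                             amplitude_jitter_sd=0.0, seed=5)
        trace_df, events, truth = gen_photometry_session(cfg)
        tr = PhotometryTrace.from_frame(trace_df, (0.0, 120.0), rate=cfg.rate)
        zt = correct_and_zscore(tr, None)
        resp = evoked_responses(zt, events)
        expect = 2.0 * truth.kernel_window_mean
        se = np.sqrt(2 / 300) / np.sqrt(20)   # z-noise SD is 1 by construction
        assert resp.responses["delta_z"].mean() == pytest.approx(
            expect, abs=3 * se)

    def test_peri_event_matrix_shape(self):
        zt = _ztrace(np.arange(4000, dtype=float))
        ev = pd.DataFrame({"onset_s": [10.0, 20.0], "offset_s": [11.0, 21.0],
                           "label": ["m", "o"], "trial": [1, 2]})
        mat = peri_event_matrix(zt, ev)
        assert mat.shape == (2, 600)


class TestSessionSummary:
    def _resp(self, per_animal):
        rows = []
        for aid, (m, o) in per_animal.items():
            rows.append({"animal_id": aid, "label": "mouse", "delta_z": m})
            rows.append({"animal_id": aid, "label": "object", "delta_z": o})
        return pd.DataFrame(rows)

    def test_identical_means_give_t_zero_p_one(self):
        c = session_evoked_summary(self._resp(
            {"a": (1.0, 1.0), "b": (2.0, 2.0), "c": (0.5, 0.5)}))
        assert c.t_statistic == 0.0 and c.p_value == 1.0
        assert not c.degenerate

    def test_constant_nonzero_differences_flagged_degenerate(self):
        c = session_evoked_summary(self._resp(
            {a: (x + 1.0, x) for a, x in zip("abcd", [0.0, 1.0, 2.0, 3.0])}))
        assert c.degenerate and np.isnan(c.t_statistic)

    def test_missing_pair_listed(self):
        df = self._resp({"a": (1.0, 0.5), "b": (2.0, 1.0)})
        df = df[~((df.animal_id == "b") & (df.label == "object"))]
        with pytest.raises(DegenerateInputError, match="b"):
            session_evoked_summary(df)

    def test_matches_scipy_paired_t(self, rng):
        from scipy import stats
        vals = {f"a{i}": (rng.normal(), rng.normal()) for i in range(7)}
        c = session_evoked_summary(self._resp(vals))
        a = np.array([v[0] for v in vals.values()])
        b = np.array([v[1] for v in vals.values()])
        ref = stats.ttest_rel(a, b)
        assert c.t_statistic == pytest.approx(ref.statistic)
        assert c.p_value == pytest.approx(ref.pvalue)


class TestSpearman:
    def test_perfect_concordance_and_discordance(self):
        x = np.array([0.1, 0.4, 0.9, 1.5])
        d = np.array([1.0, 2.0, 3.0, 4.0])
        assert evoked_duration_correlation(x, d).rho == pytest.approx(1.0)
        assert evoked_duration_correlation(x, d[::-1]).rho == pytest.approx(-1.0)

    def test_ties_match_average_rank_formula(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
        d = np.array([2.0, 1.0, 1.0, 3.0, 5.0, 4.0])

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j + 1 < len(v) and sv[j + 1] == sv[i]:
                    j += 1
                ranks[order[i:j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        rx, rd = avg_ranks(x), avg_ranks(d)
        expect = np.corrcoef(rx, rd)[0, 1]
        assert evoked_duration_correlation(x, d).rho == pytest.approx(expect)

    def test_constant_vector_flagged(self):
        r = evoked_duration_correlation(np.ones(5), np.arange(5.0))
        assert r.degenerate and np.isnan(r.rho)

    def test_too_few_observations(self):
        with pytest.raises(DegenerateInputError):
            evoked_duration_correlation(np.ones(2), np.ones(2))
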