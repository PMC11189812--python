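"""Reproducibility benchmarks: seeded simulation studies that score every
stage of the package against independent references or planted ground truth.

Each function regenerates its inputs from a seed, runs the package's own
estimators, and returns a scalar summary.  The reference computations
(hand-rolled covariance loops, a dual quadratic-programming SVM solve, an
exhaustive event-filter rule) are deliberately written along independent
code paths from the implementations they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .activation import classify_and_map, fit_linear_svm, haufe_activation
from .photometry import (
    PhotometryTrace,
    airpls_baseline,
    correct_and_zscore,
    evoked_responses,
    select_nonsequential_events,
    session_evoked_summary,
)
from .simulate import CountSimConfig, PhotoSimConfig, gen_cell_counts, \
    gen_photometry_session

__all__ = [
    "haufe_brute_force_max_error",
    "whitened_cosine_min",
    "region_recovery_rate",
    "svm_dual_reference_gap",
    "svm_label_flip_max_deviation",
    "airpls_drift_rmse_fraction",
    "zscore_exactness",
    "event_filter_mismatches",
    "evoked_step_recovery",
    "null_rejection_rate",
]


# ---------------------------------------------------------------------------
# Forward-model transform
# ---------------------------------------------------------------------------

def _pattern_by_loops(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Sigma_x W / (W' Sigma_x W) evaluated element-by-element with explicit
    loops and an independent covariance computation."""
    n, M = X.shape
    mu = [sum(X[:, j]) / n for j in range(M)]
    sigma = np.empty((M, M))
    for j in range(M):
        for k in range(M):
            sigma[j, k] = sum(
                (X[i, j] - mu[j]) * (X[i, k] - mu[k]) for i in range(n)
            ) / (n - 1)
    sw = np.array([sum(sigma[j, k] * w[k] for k in range(M)) for j in range(M)])
    s_s = sum(w[j] * sw[j] for j in range(M))
    return sw / s_s


def haufe_brute_force_max_error(n_datasets: int = 100, seed: int = 0) -> float:
    """Max |A - brute-force A| over random two-class datasets (M<=10, n<=20)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_datasets):
        M = int(rng.integers(2, 11))
        half = int(rng.integers(2, 11))
        X = rng.normal(size=(2 * half, M))
        X[half:] += rng.normal(scale=0.5, size=M)
        y = np.array(["a"] * half + ["b"] * half)
        model = fit_linear_svm(X, y)
        pattern = haufe_activation(model, X)
        ref = _pattern_by_loops(X, model.w)
        worst = max(worst, float(np.max(np.abs(pattern.A - ref))))
    return worst


def whitened_cosine_min(n_cases: int = 50, seed: int = 0) -> float:
    """Min cosine similarity between A and W on exactly whitened data."""
    from .activation import ClassifierModel

    rng = np.random.default_rng(seed)
    worst = 1.0
    for _ in range(n_cases):
        M = int(rng.integers(2, 9))
        n = M + int(rng.integers(5, 20))
        X = rng.normal(size=(n, M))
        Xc = X - X.mean(axis=0)
        L = np.linalg.cholesky(np.cov(Xc, rowvar=False, ddof=1))
        Xw = Xc @ np.linalg.inv(L).T
        w = rng.normal(size=M)
        model = ClassifierModel(w=w, intercept=0.0, positive_label="a",
                                negative_label="b", C=1.0,
                                training_accuracy=1.0,
                                margin=2.0 / np.linalg.norm(w))
        A = haufe_activation(model, Xw).A
        cos = float(A @ w / (np.linalg.norm(A) * np.linalg.norm(w)))
        worst = min(worst, cos)
    return worst


def region_recovery_rate(
    n_reps: int = 200,
    effect_size: float = 2.0,
    seed: int = 0,
    region: str = "IC",
) -> float:
    """Fraction of replicates in which the planted region attains max |A|
    in the drug-vs-vehicle comparison, at the study's 3x5x22 scale."""
    hits = 0
    ss = np.random.SeedSequence(seed).spawn(n_reps)
    for child in ss:
        cfg = CountSimConfig(
            effect_regions=(region,) if effect_size != 0 else (),
            effect_size=effect_size,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        table, _ = gen_cell_counts(cfg)
        results, _ = classify_and_map(table, comparisons=[("R-ket", "saline")])
        hits += results[0].nominated_region == region
    return hits / n_reps


# ---------------------------------------------------------------------------
# SVM reference
# ---------------------------------------------------------------------------

def _dual_qp_objective(X: np.ndarray, y: np.ndarray, C: float) -> float:
    """Optimal soft-margin SVM objective from the dual QP, solved with SLSQP."""
    n = len(y)
    G = (y[:, None] * X) @ (y[:, None] * X).T

    def f(a):
        return 0.5 * a @ G @ a - a.sum()

    def jac(a):
        return G @ a - 1.0

    res = minimize(
        f, np.full(n, 0.5 * C), jac=jac, bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP", options={"maxiter": 2000, "ftol": 1e-14},
    )
    return float(-res.fun)   # = primal optimum by strong duality


def _primal_objective(X, ybin, w, b, C):
    hinge = np.maximum(0.0, 1.0 - ybin * (X @ w + b))
    return 0.5 * float(w @ w) + C * float(hinge.sum())


def svm_dual_reference_gap(n_problems: int = 50, C: float = 1.0,
                           seed: int = 0) -> float:
    """Max |fitted primal objective - dual-QP optimum| over random problems."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_problems):
        M = int(rng.integers(2, 6))
        half = int(rng.integers(3, 9))
        X = rng.normal(size=(2 * half, M))
        X[half:] += rng.normal(scale=1.0, size=M)
        labels = np.array(["a"] * half + ["b"] * half)
        model = fit_linear_svm(X, labels, C=C, positive_label="a")
        ybin = np.where(labels == "a", 1.0, -1.0)
        primal = _primal_objective(X, ybin, model.w, model.intercept, C)
        dual = _dual_qp_objective(X, ybin, C)
        worst = max(worst, abs(primal - dual))
    return worst


def svm_label_flip_max_deviation(n_problems: int = 20, seed: int = 0) -> float:
    """Max |W + W_flipped| over random problems (0 when negation is exact)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_problems):
        X = rng.normal(size=(10, 4))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        m1 = fit_linear_svm(X, labels, positive_label="a")
        m2 = fit_linear_svm(X, labels, positive_label="b")
        worst = max(worst, float(np.max(np.abs(m1.w + m2.w))),
                    abs(m1.intercept + m2.intercept))
    return worst


# ---------------------------------------------------------------------------
# Photometry
# ---------------------------------------------------------------------------

def airpls_drift_rmse_fraction(n_seeds: int = 20, seed: int = 0) -> float:
    """Max over seeds of baseline-recovery RMSE (transient-free samples)
    as a fraction of drift range: cubic drift + 20 positive transients,
    100 Hz, 10-min trace."""
    worst = 0.0
    ss = np.random.SeedSequence(seed).spawn(n_seeds)
    for child in ss:
        cfg = PhotoSimConfig(
            baseline_minutes=2.0, session_minutes=8.0, noise_sd=0.0,
            n_events_per_label=10, amplitude_jitter_sd=0.0,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        trace, events, truth = gen_photometry_session(cfg)
        y = trace["fluorescence"].to_numpy()
        fit = airpls_baseline(y)
        mask = np.ones(y.size, bool)
        for on in events["onset_s"]:
            i0 = int(round(on * cfg.rate))
            mask[i0:i0 + int(9 * cfg.rate)] = False
        rmse = float(np.sqrt(np.mean((fit.baseline - truth.drift)[mask] ** 2)))
        worst = max(worst, rmse / (truth.drift.max() - truth.drift.min()))
    return worst


def zscore_exactness(n_sessions: int = 5, seed: int = 0) -> tuple[float, float]:
    """(max |baseline-z mean|, max |baseline-z SD - 1|) over processed
    sessions, including the airPLS and smoothing paths."""
    worst_mu = worst_sd = 0.0
    ss = np.random.SeedSequence(seed).spawn(n_sessions)
    for k, child in enumerate(ss):
        cfg = PhotoSimConfig(
            baseline_minutes=1.0, session_minutes=4.0, n_events_per_label=5,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        trace_df, _, _ = gen_photometry_session(cfg)
        trace = PhotometryTrace.from_frame(trace_df, (0.0, 60.0), rate=cfg.rate)
        fit = airpls_baseline(trace.fluorescence)
        zt = correct_and_zscore(trace, fit,
                                smooth_window=0.5 if k % 2 else None)
        mask = trace.baseline_mask()
        worst_mu = max(worst_mu, abs(float(zt.z[mask].mean())))
        worst_sd = max(worst_sd, abs(float(zt.z[mask].std(ddof=1)) - 1.0))
    return worst_mu, worst_sd


def event_filter_mismatches(n_lists: int = 1000, seed: int = 0,
                            min_gap: float = 10.0) -> int:
    """Mismatches between the filter and exhaustive rule application (plus
    idempotence violations) over random event logs."""
    rng = np.random.default_rng(seed)
    bad = 0
    for _ in range(n_lists):
        n = int(rng.integers(0, 12))
        t, rows = 0.0, []
        for _ in range(n):
            t += float(rng.uniform(0.0, 25.0))
            d = float(rng.uniform(0.2, 6.0))
            rows.append((round(t, 2), round(t + d, 2), "m"))
            t += d
        ev = pd.DataFrame(rows, columns=["onset_s", "offset_s", "label"])
        kept = select_nonsequential_events(ev, min_gap=min_gap)
        expect = [i for i in range(len(rows))
                  if i == 0 or rows[i][0] - rows[i - 1][1] >= min_gap]
        ok = list(kept["onset_s"]) == [rows[i][0] for i in expect]
        twice = select_nonsequential_events(kept, min_gap=min_gap)
        ok = ok and twice.equals(kept)
        bad += not ok
    return bad


def evoked_step_recovery(
    amplitude: float = 2.0,
    n_events: int = 100,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[float, float]:
    """(mean dz, Monte-Carlo SE) for planted steps of the given amplitude
    at each onset, spread over 5 sessions of 20 events."""
    dzs = []
    ss = np.random.SeedSequence(seed).spawn(max(1, n_events // 20))
    for child in ss:
        cfg = PhotoSimConfig(
            baseline_minutes=5.0, session_minutes=6.0, noise_sd=noise_sd,
            drift_amplitude=0.0,
            transient_amplitude={"mouse": amplitude, "object": amplitude},
            transient_shape="step", step_duration=3.0,
            amplitude_jitter_sd=0.0, n_events_per_label=10,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        trace_df, events, _ = gen_photometry_session(cfg)
        trace = PhotometryTrace.from_frame(trace_df, (0.0, 300.0), rate=cfg.rate)
        zt = correct_and_zscore(trace, None)
        dzs.append(evoked_responses(zt, events).responses["delta_z"].to_numpy())
    dz = np.concatenate(dzs)
    se = noise_sd * np.sqrt(2 / 300) / np.sqrt(dz.size)
    return float(dz.mean()), float(se)


def null_rejection_rate(n_reps: int = 2000, n_animals: int = 7,
                        alpha: float = 0.05, seed: int = 0) -> float:
    """Type-I error of the paired mouse-vs-object contrast on null sessions
    (no planted transients, white-noise traces)."""
    rejections = 0
    reps = np.random.SeedSequence(seed).spawn(n_reps)
    for child in reps:
        animals = child.spawn(n_animals)
        frames = []
        for ai, a_ss in enumerate(animals):
            cfg = PhotoSimConfig(
                baseline_minutes=0.5, session_minutes=2.5, noise_sd=1.0,
                drift_amplitude=0.0,
                transient_amplitude={"mouse": 0.0, "object": 0.0},
                amplitude_jitter_sd=0.0, n_events_per_label=5,
                seed=int(a_ss.generate_state(1)[0] % (2**31)),
            )
            trace_df, events, _ = gen_photometry_session(cfg)
            trace = PhotometryTrace.from_frame(trace_df, (0.0, 30.0),
                                               rate=cfg.rate)
            zt = correct_and_zscore(trace, None)
            resp = evoked_responses(zt, select_nonsequential_events(events))
            r = resp.responses.copy()
            r.insert(0, "animal_id", f"a{ai}")
            frames.append(r)
        contrast = session_evoked_summary(pd.concat(frames, ignore_index=True))
        rejections += contrast.p_value < alpha
    return rejections / n_reps
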