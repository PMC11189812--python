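"""Fiber-photometry preprocessing and contact-evoked response quantification.

Pipeline for single-wavelength GCaMP recordings sampled uniformly (100 Hz in
the emulated design):

1. slow-baseline estimation by airPLS (adaptive iteratively reweighted
   penalized least squares) and subtraction, optionally followed by a short
   centered moving average;
2. z-scoring against a designated pre-session home-cage baseline segment
   (5 min in the emulated design);
3. selection of nonsequential investigation bouts (onset at least 10 s
   after the end of the preceding bout in the full log);
4. per-event evoked response dz = mean z over [onset, onset+3) s minus mean
   z over [onset-3, onset) s, session summaries, the paired mouse-vs-object
   contrast, and the Spearman correlation of dz with contact duration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.linalg import solveh_banded
from scipy.ndimage import uniform_filter1d
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    EventValidationError,
    FormatError,
)

__all__ = [
    "PhotometryTrace",
    "BaselineFit",
    "ZTrace",
    "EvokedResponseSet",
    "AirPLSBaseline",
    "airpls_baseline",
    "correct_and_zscore",
    "select_nonsequential_events",
    "validate_event_log",
    "evoked_response",
    "evoked_responses",
    "peri_event_matrix",
    "session_evoked_summary",
    "evoked_duration_correlation",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhotometryTrace:
    """Uniformly sampled fluorescence with a designated baseline segment."""

    time: np.ndarray              # seconds, uniform
    fluorescence: np.ndarray      # arbitrary units
    rate: float                   # samples / s
    baseline_interval: tuple[float, float]  # (start_s, end_s) of home-cage segment

    def __post_init__(self):
        t, f = np.asarray(self.time, float), np.asarray(self.fluorescence, float)
        if t.shape != f.shape or t.ndim != 1 or t.size < 2:
            raise FormatError("trace needs matching 1-D time and fluorescence")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(f))):
            raise FormatError("non-finite values in trace")
        dt = np.diff(t)
        if np.any(np.abs(dt - 1.0 / self.rate) > 1e-6 / self.rate * 100):
            raise FormatError("trace is not uniformly sampled at the declared rate")
        b0, b1 = self.baseline_interval
        if not (t[0] - 1e-9 <= b0 < b1 <= t[-1] + 1.0 / self.rate + 1e-9):
            raise ConfigurationError("baseline segment must lie within the recording")

    def baseline_mask(self) -> np.ndarray:
        b0, b1 = self.baseline_interval
        return (self.time >= b0) & (self.time < b1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, baseline_interval: tuple[float, float],
                   rate: float | None = None) -> "PhotometryTrace":
        t = df["time_s"].to_numpy(dtype=float)
        if rate is None:
            rate = 1.0 / np.median(np.diff(t))
        return cls(time=t, fluorescence=df["fluorescence"].to_numpy(dtype=float),
                   rate=float(rate), baseline_interval=tuple(baseline_interval))


# ---------------------------------------------------------------------------
# airPLS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaselineFit:
    baseline: np.ndarray
    lam: float
    order: int
    iterations: int
    converged: bool


def _whittaker_banded(lam: float, order: int, n: int) -> np.ndarray:
    """Upper-banded form of lam * D'D for scipy.linalg.solveh_banded."""
    D = sparse.diags(
        [np.ones(n)], [0], shape=(n, n), format="csc"
    )
    for _ in range(order):
        D = D[1:] - D[:-1]
    DtD = (lam * (D.T @ D)).todia()
    ab = np.zeros((order + 1, n))
    for off, data in zip(DtD.offsets, DtD.data):
        if off >= 0:
            ab[order - off, :] = data
    return ab


def airpls_baseline(
    y: np.ndarray,
    lam: float = 1e9,
    order: int = 2,
    max_iter: int = 15,
    ratio: float = 1e-3,
) -> BaselineFit:
    """Estimate a slow drift baseline by airPLS.

    Each iteration solves the weighted Whittaker smoother
    ``(W + lam * D'D) z = W y`` and re-estimates the weights from the
    negative residuals: samples above the current baseline (positive
    transients) get weight ~0, samples below are weighted exponentially in
    the residual magnitude, so the fit hugs the lower envelope of the
    signal.  Iteration stops when the L1 norm of the negative residuals
    drops below ``ratio * |y|_1`` or after ``max_iter`` passes.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 10:
        raise FormatError("airPLS needs a 1-D signal of length >= 10")
    if not np.all(np.isfinite(y)):
        raise FormatError("non-finite input to airPLS")
    if lam <= 0:
        raise ConfigurationError("lam must be > 0")
    if order < 1 or max_iter < 1 or ratio <= 0:
        raise ConfigurationError("invalid airPLS settings")

    n = y.size
    penalty_ab = _whittaker_banded(lam, order, n)
    w = np.ones(n)
    abs_y_l1 = np.abs(y).sum()
    z = y.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ab = penalty_ab.copy()
        ab[-1, :] += w
        z = solveh_banded(ab, w * y, lower=False)
        d = y - z
        neg = d < 0
        dssn = float(np.abs(d[neg]).sum())
        if dssn < ratio * abs_y_l1 or not np.any(neg):
            converged = True
            break
        w[~neg] = 0.0
        w[neg] = np.exp(it * np.abs(d[neg]) / dssn)
        w[0] = np.exp(it * np.abs(d[neg]).max() / dssn)
        w[-1] = w[0]
    return BaselineFit(baseline=z, lam=float(lam), order=int(order),
                       iterations=it, converged=converged)


class AirPLSBaseline(TransformerMixin, BaseEstimator):
    """sklearn-style transformer: fit estimates the airPLS baseline of a
    1-D signal, transform subtracts it.

    Parameters mirror :func:`airpls_baseline`; fitted attributes are
    ``baseline_``, ``n_iter_`` and ``converged_``.
    """

    def __init__(self, lam: float = 1e9, order: int = 2,
                 max_iter: int = 15, ratio: float = 1e-3):
        self.lam = lam
        self.order = order
        self.max_iter = max_iter
        self.ratio = ratio

    def fit(self, X, y=None):
        fit = airpls_baseline(np.ravel(X), self.lam, self.order,
                              self.max_iter, self.ratio)
        self.baseline_ = fit.baseline
        self.n_iter_ = fit.iterations
        self.converged_ = fit.converged
        self.fit_ = fit
        return self

    def transform(self, X):
        X = np.ravel(X)
        if X.shape != self.baseline_.shape:
            raise FormatError("transform input does not match the fitted signal")
        return X - self.baseline_


# ---------------------------------------------------------------------------
# Correction and z-scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZTrace:
    """Baseline-corrected, baseline-segment-z-scored trace."""

    time: np.ndarray
    z: np.ndarray
    rate: float
    baseline_interval: tuple[float, float]
    baseline_mean: float          # fluorescence units, of the corrected signal
    baseline_sd: float


def correct_and_zscore(
    trace: PhotometryTrace,
    fit: BaselineFit | None = None,
    smooth_window: float | None = None,
) -> ZTrace:
    """Subtract the fitted baseline, optionally smooth, and z-score.

    z-scoring uses the mean and sample SD (ddof = 1) of the corrected signal
    over the trace's designated home-cage baseline segment, so the
    baseline-segment z has mean 0 and SD 1 exactly.  ``smooth_window`` is a
    centered moving-average width in seconds (None disables smoothing).
    """
    corrected = trace.fluorescence.astype(float).copy()
    if fit is not None:
        if fit.baseline.shape != corrected.shape:
            raise FormatError("baseline length does not match the trace")
        corrected -= fit.baseline
    if smooth_window is not None and smooth_window > 0:
        width = max(1, int(round(smooth_window * trace.rate)) | 1)
        corrected = uniform_filter1d(corrected, size=width, mode="nearest")
    mask = trace.baseline_mask()
    if mask.sum() < 2:
        raise DegenerateInputError("baseline segment holds < 2 samples")
    mu = float(corrected[mask].mean())
    sd = float(corrected[mask].std(ddof=1))
    if sd == 0:
        raise DegenerateInputError("baseline-segment SD is zero after correction")
    return ZTrace(time=trace.time, z=(corrected - mu) / sd, rate=trace.rate,
                  baseline_interval=trace.baseline_interval,
                  baseline_mean=mu, baseline_sd=sd)


# ---------------------------------------------------------------------------
# Event selection
# ---------------------------------------------------------------------------

EVENT_COLS = ("onset_s", "offset_s", "label")


def validate_event_log(events: pd.DataFrame) -> pd.DataFrame:
    for col in EVENT_COLS:
        if col not in events.columns:
            raise FormatError(f"event log lacks column {col!r}")
    if len(events) == 0:
        return events
    on = events["onset_s"].to_numpy(dtype=float)
    off = events["offset_s"].to_numpy(dtype=float)
    if np.any(off <= on):
        i = int(np.flatnonzero(off <= on)[0])
        raise EventValidationError(
            f"event at row {i + 1} has offset <= onset ({off[i]} <= {on[i]})"
        )
    if np.any(np.diff(on) <= 0) or np.any(on[1:] < off[:-1]):
        raise EventValidationError("events must be onset-ordered and non-overlapping")
    return events


def select_nonsequential_events(
    events: pd.DataFrame, min_gap: float = 10.0
) -> pd.DataFrame:
    """Keep bouts separated from the previous bout's end by >= ``min_gap`` s.

    The reference is always the immediately preceding event in the *full*
    log (not the filtered one); the first event is always kept, and the
    boundary is inclusive ("at least" ``min_gap``).  The operation is
    idempotent.
    """
    validate_event_log(events)
    if len(events) == 0:
        return events.copy()
    on = events["onset_s"].to_numpy(dtype=float)
    off = events["offset_s"].to_numpy(dtype=float)
    keep = np.ones(len(events), dtype=bool)
    keep[1:] = (on[1:] - off[:-1]) >= min_gap
    return events.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Evoked responses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvokedResponseSet:
    """Per-event evoked responses plus bookkeeping for a session."""

    responses: pd.DataFrame       # trial, label, onset_s, duration_s, delta_z
    pre_window: float = 3.0
    post_window: float = 3.0
    n_skipped: int = 0

    def label_means(self) -> pd.Series:
        return self.responses.groupby("label")["delta_z"].mean()


def evoked_response(
    ztrace: ZTrace, onset: float, pre: float = 3.0, post: float = 3.0
) -> float | None:
    """dz = mean z over [onset, onset+post) minus mean z over [onset-pre, onset).

    The onset is aligned to the nearest sample; the pre-window excludes and
    the post-window includes the onset sample.  Returns None (with a logged
    warning) when either window is truncated by the recording edge.
    """
    rate = ztrace.rate
    i0 = int(round((onset - ztrace.time[0]) * rate))
    n_pre = int(round(pre * rate))
    n_post = int(round(post * rate))
    if i0 - n_pre < 0 or i0 + n_post > ztrace.z.size:
        log.warning("event at %.2f s skipped: window truncated by recording edge", onset)
        return None
    return float(ztrace.z[i0:i0 + n_post].mean() - ztrace.z[i0 - n_pre:i0].mean())


def evoked_responses(
    ztrace: ZTrace,
    events: pd.DataFrame,
    pre: float = 3.0,
    post: float = 3.0,
) -> EvokedResponseSet:
    """Per-event evoked responses for every event in the (filtered) log."""
    validate_event_log(events)
    rows, skipped = [], 0
    for _, ev in events.iterrows():
        dz = evoked_response(ztrace, float(ev["onset_s"]), pre=pre, post=post)
        if dz is None:
            skipped += 1
            continue
        rows.append({
            "trial": int(ev["trial"]) if "trial" in ev else len(rows) + 1,
            "label": str(ev["label"]),
            "onset_s": float(ev["onset_s"]),
            "duration_s": float(ev["offset_s"]) - float(ev["onset_s"]),
            "delta_z": dz,
        })
    responses = pd.DataFrame(
        rows, columns=["trial", "label", "onset_s", "duration_s", "delta_z"]
    )
    return EvokedResponseSet(responses=responses, pre_window=pre,
                             post_window=post, n_skipped=skipped)


def peri_event_matrix(
    ztrace: ZTrace,
    events: pd.DataFrame,
    pre: float = 3.0,
    post: float = 3.0,
) -> pd.DataFrame:
    """Events x samples matrix of z on [-pre, +post) s around each onset."""
    rate = ztrace.rate
    n_pre, n_post = int(round(pre * rate)), int(round(post * rate))
    offsets = (np.arange(-n_pre, n_post) + 0.0) / rate
    rows, index = [], []
    for _, ev in events.iterrows():
        i0 = int(round((float(ev["onset_s"]) - ztrace.time[0]) * rate))
        if i0 - n_pre < 0 or i0 + n_post > ztrace.z.size:
            continue
        rows.append(ztrace.z[i0 - n_pre:i0 + n_post])
        index.append((int(ev["trial"]) if "trial" in ev else len(rows),
                      str(ev["label"])))
    mat = pd.DataFrame(rows, columns=[f"{o:+.2f}" for o in offsets])
    if index:
        mat.index = pd.MultiIndex.from_tuples(index, names=["trial", "label"])
    return mat


# ---------------------------------------------------------------------------
# Session statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedContrast:
    labels: tuple[str, str]
    per_animal_means: pd.DataFrame     # animals x labels
    t_statistic: float
    p_value: float
    n_pairs: int
    degenerate: bool = False           # zero-variance paired differences


def session_evoked_summary(
    responses: pd.DataFrame,
    labels: tuple[str, str] = ("mouse", "object"),
) -> PairedContrast:
    """Per-animal per-label mean dz and the paired t contrast between labels.

    ``responses`` must hold columns ``animal_id``, ``label`` and ``delta_z``
    (per event, pooled across animals).  Every animal must contribute both
    labels; otherwise the missing pairs are reported.  Zero-variance paired
    differences are flagged as degenerate rather than yielding infinities.
    """
    for col in ("animal_id", "label", "delta_z"):
        if col not in responses.columns:
            raise FormatError(f"responses table lacks column {col!r}")
    sub = responses[responses["label"].isin(labels)]
    means = sub.pivot_table(index="animal_id", columns="label",
                            values="delta_z", aggfunc="mean")
    missing = [
        (str(a), lab) for a in means.index for lab in labels
        if lab not in means.columns or pd.isna(means.loc[a].get(lab))
    ]
    if missing:
        raise DegenerateInputError(f"unpaired animal/label combinations: {missing}")
    if len(means) < 2:
        raise DegenerateInputError("paired contrast needs >= 2 animals")
    a, b = means[labels[0]].to_numpy(), means[labels[1]].to_numpy()
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs, 0.0):
            t_stat, p = 0.0, 1.0
            degenerate = False
        else:
            t_stat, p = float("nan"), float("nan")
            degenerate = True
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.ttest_rel(a, b)
        t_stat, p = float(res.statistic), float(res.pvalue)
        degenerate = False
    return PairedContrast(
        labels=labels, per_animal_means=means[list(labels)],
        t_statistic=t_stat, p_value=p, n_pairs=len(means),
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    degenerate: bool = False


def evoked_duration_correlation(
    delta_z: np.ndarray, durations: np.ndarray
) -> SpearmanResult:
    """Spearman rank correlation between per-event dz and contact duration.

    Uses average ranks for ties and a two-sided p-value.  Constant input in
    either vector makes the correlation undefined; that is flagged, not
    raised.
    """
    x = np.asarray(delta_z, dtype=float)
    y = np.asarray(durations, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FormatError("delta_z and durations must be matching 1-D vectors")
    if x.size < 3:
        raise DegenerateInputError("Spearman correlation needs >= 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(float("nan"), float("nan"), x.size, degenerate=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(x, y)
    return SpearmanResult(float(rho), float(p), x.size)
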