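"""Seeded synthetic cohorts: cell-count tables, insular-cortex cell clouds,
and fiber-photometry sessions with planted, recoverable ground truth.

Every generator takes an explicit integer seed and is byte-deterministic:
the same configuration and seed always produce the same dataset.  Planted
quantities (effect regions and sizes, the drift curve, per-event transient
amplitudes) are returned alongside the data so downstream estimators can be
scored against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "DEFAULT_REGIONS",
    "CountSimConfig",
    "PhotoSimConfig",
    "SyntheticGroundTruth",
    "gen_cell_counts",
    "gen_ic_coordinates",
    "gen_photometry_session",
    "transient_kernel",
]

#: Default 22 region abbreviations (Allen-atlas style) for simulated tables.
DEFAULT_REGIONS: tuple[str, ...] = (
    "ACC", "PL", "IL", "OFC", "IC", "M1", "M2", "S1", "S2", "AUD", "VIS",
    "RSP", "PIR", "NAc", "CPu", "LS", "BLA", "CeA", "PVT", "MD", "VTA", "DG",
)

#: Anteroposterior extent (mm relative to bregma) of the insular cortex.
IC_AP_RANGE: tuple[float, float] = (2.50, -1.00)
#: Anterior insular cortex: +2.50 to +1.45 mm anterior to bregma.
AIC_AP_RANGE: tuple[float, float] = (2.50, 1.45)


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Planted quantities of a synthetic dataset, for downstream scoring."""

    effect_regions: tuple[str, ...] = ()
    effect_sizes: dict[str, float] = field(default_factory=dict)
    effect_group: str | None = None
    drift: np.ndarray | None = None          # fluorescence units, trace-length
    event_amplitudes: pd.DataFrame | None = None  # per-event planted z size
    kernel_window_mean: float | None = None  # mean of unit kernel over [0, 3) s

    def to_jsonable(self) -> dict:
        out: dict = {
            "effect_regions": list(self.effect_regions),
            "effect_sizes": dict(self.effect_sizes),
            "effect_group": self.effect_group,
        }
        if self.kernel_window_mean is not None:
            out["kernel_window_mean"] = float(self.kernel_window_mean)
        if self.event_amplitudes is not None:
            out["event_amplitudes"] = self.event_amplitudes.to_dict("records")
        return out


# ---------------------------------------------------------------------------
# Cell-count tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountSimConfig:
    """Configuration for a simulated animals x regions IEG count table.

    Counts are negative binomial with per-region mean ``baseline_mean`` and
    dispersion ``dispersion`` (variance = mu + mu^2 / dispersion), so
    between-animal overdispersion is representable.  A group effect is
    planted additively on the mean of ``effect_group`` in ``effect_regions``,
    expressed in units of the within-group SD at baseline.
    """

    n_per_group: int = 5
    groups: tuple[str, ...] = ("saline", "R-ket", "S-ket")
    n_regions: int = 22
    baseline_mean: float | Sequence[float] = 300.0
    dispersion: float = 20.0
    effect_regions: tuple[int | str, ...] = ()
    effect_size: float = 0.0
    effect_group: str = "R-ket"
    region_names: tuple[str, ...] | None = None
    seed: int = 0

    def resolved_regions(self) -> tuple[str, ...]:
        if self.region_names is not None:
            if len(self.region_names) != self.n_regions:
                raise ConfigurationError(
                    f"region_names has {len(self.region_names)} entries, "
                    f"expected n_regions={self.n_regions}"
                )
            return tuple(self.region_names)
        if self.n_regions == len(DEFAULT_REGIONS):
            return DEFAULT_REGIONS
        return tuple(f"R{i + 1:02d}" for i in range(self.n_regions))

    def resolved_effect_indices(self) -> tuple[int, ...]:
        names = self.resolved_regions()
        idx = []
        for r in self.effect_regions:
            if isinstance(r, str):
                if r not in names:
                    raise ConfigurationError(f"unknown effect region {r!r}")
                idx.append(names.index(r))
            else:
                if not 0 <= int(r) < self.n_regions:
                    raise ConfigurationError(
                        f"effect region index {r} outside 0..{self.n_regions - 1}"
                    )
                idx.append(int(r))
        return tuple(idx)

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be >= 1")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        means = np.broadcast_to(
            np.asarray(self.baseline_mean, dtype=float), (self.n_regions,)
        )
        if np.any(means <= 0):
            raise ConfigurationError("all baseline means must be > 0")
        if self.effect_group not in self.groups:
            raise ConfigurationError(
                f"effect_group {self.effect_group!r} not among groups"
            )
        self.resolved_effect_indices()


def _nb_draw(rng: np.random.Generator, mean: float, theta: float, size: int):
    # numpy parameterization: n successes, success prob p; mean = n(1-p)/p
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p, size=size)


def gen_cell_counts(
    config: CountSimConfig,
) -> tuple[pd.DataFrame, SyntheticGroundTruth]:
    """Simulate a per-animal, per-region IEG-positive cell-count table.

    Returns a DataFrame with columns ``animal_id``, ``group`` and one column
    per region, plus the planted ground truth.  For effect regions the
    designated group's mean is shifted by ``effect_size`` x the within-group
    SD implied by the negative-binomial variance at baseline.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    regions = config.resolved_regions()
    means = np.broadcast_to(
        np.asarray(config.baseline_mean, dtype=float), (config.n_regions,)
    ).copy()
    theta = float(config.dispersion)
    base_sd = np.sqrt(means + means**2 / theta)

    effect_idx = config.resolved_effect_indices()
    rows = []
    animal = 0
    for group in config.groups:
        mu = means.copy()
        if group == config.effect_group:
            for j in effect_idx:
                mu[j] = means[j] + config.effect_size * base_sd[j]
                if mu[j] <= 0:
                    raise ConfigurationError(
                        f"planted effect drives region {regions[j]} mean <= 0"
                    )
        counts = np.column_stack(
            [_nb_draw(rng, mu[j], theta, config.n_per_group)
             for j in range(config.n_regions)]
        )
        for i in range(config.n_per_group):
            animal += 1
            rows.append(
                {"animal_id": f"m{animal:03d}", "group": group,
                 **{regions[j]: int(counts[i, j])
                    for j in range(config.n_regions)}}
            )
    table = pd.DataFrame(rows)
    truth = SyntheticGroundTruth(
        effect_regions=tuple(regions[j] for j in effect_idx),
        effect_sizes={regions[j]: float(config.effect_size) for j in effect_idx},
        effect_group=config.effect_group,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Insular-cortex cell coordinates
# ---------------------------------------------------------------------------

def gen_ic_coordinates(
    n_cells: int,
    ap_range: tuple[float, float] = IC_AP_RANGE,
    density_profile: Sequence[float] | Callable[[np.ndarray], np.ndarray] | None = None,
    seed: int = 0,
    animal_id: str = "m001",
    group: str = "saline",
) -> pd.DataFrame:
    """Simulate 3-D coordinates (mm from bregma) of labelled IC cells.

    ``ap_range`` is (anterior, posterior) in decreasing mm and must lie within
    the insular cortex extent (+2.50 to -1.00).  ``density_profile`` shapes
    the anteroposterior distribution: ``None`` is uniform, a sequence gives
    relative weights over equal sub-intervals of ``ap_range``, and a callable
    is evaluated as an unnormalized density on AP positions.
    """
    lo, hi = min(ap_range), max(ap_range)
    if not (IC_AP_RANGE[1] - 1e-9 <= lo and hi <= IC_AP_RANGE[0] + 1e-9):
        raise ConfigurationError(
            f"ap_range {ap_range} outside the IC extent {IC_AP_RANGE}"
        )
    if hi <= lo:
        raise ConfigurationError("ap_range must span a nonempty interval")
    if n_cells < 0:
        raise ConfigurationError("n_cells must be >= 0")
    rng = np.random.default_rng(seed)

    if n_cells == 0:
        ap = np.empty(0)
    elif density_profile is None:
        ap = rng.uniform(lo, hi, size=n_cells)
    elif callable(density_profile):
        # inverse-CDF sampling on a fine grid
        grid = np.linspace(lo, hi, 2049)
        dens = np.asarray(density_profile(grid), dtype=float)
        if np.any(dens < 0) or dens.sum() <= 0:
            raise ConfigurationError("density_profile must be nonnegative, not all zero")
        cdf = np.cumsum(dens)
        cdf = cdf / cdf[-1]
        ap = np.interp(rng.uniform(0, 1, size=n_cells), cdf, grid)
    else:
        w = np.asarray(density_profile, dtype=float)
        if w.ndim != 1 or w.size == 0 or np.any(w < 0) or w.sum() <= 0:
            raise ConfigurationError("density_profile weights must be a nonnegative 1-D array")
        edges = np.linspace(hi, lo, w.size + 1)  # decreasing, anterior first
        which = rng.choice(w.size, size=n_cells, p=w / w.sum())
        u = rng.uniform(0, 1, size=n_cells)
        ap = edges[which] + u * (edges[which + 1] - edges[which])

    # ML/DV: plausible insular envelope; downstream analyses only use AP.
    ml = rng.uniform(2.9, 4.2, size=n_cells)
    dv = rng.uniform(-4.5, -2.0, size=n_cells)
    return pd.DataFrame(
        {"animal_id": animal_id, "group": group,
         "ap_mm": ap, "ml_mm": ml, "dv_mm": dv}
    )


# ---------------------------------------------------------------------------
# Photometry sessions
# ---------------------------------------------------------------------------

def transient_kernel(
    t: np.ndarray, rise: float = 0.2, decay: float = 1.0
) -> np.ndarray:
    """Unit-peak difference-of-exponentials calcium-transient kernel.

    ``k(t) = exp(-t/decay) - exp(-t/rise)`` for t >= 0, scaled to peak 1.
    """
    if rise <= 0 or decay <= rise:
        raise ConfigurationError("need 0 < rise < decay for the transient kernel")
    t = np.asarray(t, dtype=float)
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay)
                 - np.exp(-np.maximum(t, 0) / rise), 0.0)
    t_peak = np.log(decay / rise) * rise * decay / (decay - rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    return k / peak


@dataclass(frozen=True)
class PhotoSimConfig:
    """Configuration for a simulated single-wavelength photometry session.

    The recording starts with a ``baseline_minutes`` home-cage segment that
    contains no events, followed by a ``session_minutes`` behavioural segment.
    The trace is drift + white noise + planted contact-evoked transients whose
    amplitudes are expressed in z units (multiples of the noise SD).
    """

    rate: float = 100.0
    baseline_minutes: float = 5.0
    session_minutes: float = 10.0
    f0: float = 100.0                 # static fluorescence offset
    drift_amplitude: float = 5.0      # peak-to-peak span of the cubic drift
    noise_sd: float = 1.0
    transient_amplitude: dict[str, float] = field(
        default_factory=lambda: {"mouse": 2.0, "object": 2.0}
    )
    transient_rise: float = 0.2
    transient_decay: float = 1.0
    transient_shape: str = "diffexp"  # or "step"
    step_duration: float = 3.0
    event_schedule: tuple[tuple[float, float, str], ...] | None = None
    n_events_per_label: int = 10
    event_duration: float = 2.0
    min_gap: float = 12.0
    # per-event lognormal amplitude jitter (SD of log multiplier); with
    # duration_coupling > 0, auto-scheduled bout durations scale with the
    # same latent multiplier, planting a positive response-duration
    # correlation like the one the evoked/duration analysis estimates
    amplitude_jitter_sd: float = 0.3
    duration_coupling: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.rate <= 0:
            raise ConfigurationError("rate must be > 0")
        if self.baseline_minutes < 0 or self.session_minutes <= 0:
            raise ConfigurationError("segment durations must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.transient_shape not in ("diffexp", "step"):
            raise ConfigurationError(f"unknown transient_shape {self.transient_shape!r}")


def _auto_schedule(config: PhotoSimConfig) -> list[tuple[float, float, str]]:
    """Alternating mouse/object bouts, evenly spaced inside the session."""
    t_base = config.baseline_minutes * 60.0
    t_end = t_base + config.session_minutes * 60.0
    labels = sorted(config.transient_amplitude)
    n_events = config.n_events_per_label * len(labels)
    spacing = config.min_gap + config.event_duration + 1.0
    start = t_base + 5.0
    if start + (n_events - 1) * spacing + config.event_duration + 4.0 > t_end:
        raise ConfigurationError(
            f"{n_events} events at spacing {spacing:.1f}s do not fit in "
            f"the {config.session_minutes:.1f}-min session"
        )
    sched = []
    for i in range(n_events):
        onset = start + i * spacing
        sched.append((onset, onset + config.event_duration, labels[i % len(labels)]))
    return sched


def gen_photometry_session(
    config: PhotoSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticGroundTruth]:
    """Simulate one photometry session.

    Returns ``(trace, events, truth)``: a trace DataFrame (``time_s``,
    ``fluorescence``), an event log (``onset_s``, ``offset_s``, ``label``,
    ``trial``) matching the schedule, and the ground truth (drift curve,
    per-event planted amplitude, kernel 3-s window mean).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rate = config.rate
    t_base = config.baseline_minutes * 60.0
    t_total = t_base + config.session_minutes * 60.0
    n = int(round(t_total * rate))
    t = np.arange(n) / rate

    auto = config.event_schedule is None
    schedule = list(config.event_schedule) if not auto else _auto_schedule(config)

    # per-event latent multiplier: jitters amplitudes and (for auto
    # schedules) couples bout duration to response strength
    if config.amplitude_jitter_sd > 0:
        amp_mult = np.exp(rng.normal(0.0, config.amplitude_jitter_sd, len(schedule)))
    else:
        amp_mult = np.ones(len(schedule))
    if auto and config.duration_coupling != 0 and config.amplitude_jitter_sd > 0:
        schedule = [
            (on, on + (off - on) * mi**config.duration_coupling, lab)
            for (on, off, lab), mi in zip(schedule, amp_mult)
        ]
    prev_off = None
    for onset, offset, label in schedule:
        if offset <= onset:
            raise ConfigurationError(f"event ({onset}, {offset}) has offset <= onset")
        if onset < t_base:
            raise ConfigurationError(
                f"event at {onset:.2f}s overlaps the baseline segment "
                f"(ends {t_base:.0f}s)"
            )
        if offset > t_total:
            raise ConfigurationError(f"event at {onset:.2f}s extends past the recording")
        if prev_off is not None and onset < prev_off:
            raise ConfigurationError("event onsets must be strictly increasing, non-overlapping")
        if label not in config.transient_amplitude:
            raise ConfigurationError(f"no transient amplitude declared for label {label!r}")
        prev_off = offset

    # Cubic drift scaled to span drift_amplitude over the whole recording.
    coefs = rng.standard_normal(4)
    u = t / t_total
    raw_drift = np.polyval(coefs, u)
    span = raw_drift.max() - raw_drift.min()
    drift = (raw_drift - raw_drift.min()) / span * config.drift_amplitude \
        if span > 0 and config.drift_amplitude > 0 else np.zeros(n)

    noise = rng.standard_normal(n) * config.noise_sd if config.noise_sd > 0 else np.zeros(n)
    amp_scale = config.noise_sd if config.noise_sd > 0 else 1.0

    signal = config.f0 + drift + noise
    win = np.arange(int(round(3.0 * rate))) / rate
    if config.transient_shape == "diffexp":
        kernel_window_mean = float(
            transient_kernel(win, config.transient_rise, config.transient_decay).mean()
        )
    else:
        kernel_window_mean = float(np.mean(win < config.step_duration))

    amp_records = []
    for trial, (onset, offset, label) in enumerate(schedule, start=1):
        a = float(config.transient_amplitude[label]) * float(amp_mult[trial - 1])
        amp_records.append(
            {"trial": trial, "onset_s": onset, "offset_s": offset,
             "label": label, "amplitude_z": a}
        )
        if a == 0.0:
            continue
        i0 = int(round(onset * rate))
        if config.transient_shape == "diffexp":
            dur = int(round(8.0 * config.transient_decay * rate))
            idx = np.arange(i0, min(i0 + dur, n))
            signal[idx] += a * amp_scale * transient_kernel(
                t[idx] - onset, config.transient_rise, config.transient_decay
            )
        else:
            i1 = min(int(round((onset + config.step_duration) * rate)), n)
            signal[i0:i1] += a * amp_scale

    trace = pd.DataFrame({"time_s": t, "fluorescence": signal})
    events = pd.DataFrame(
        [{"onset_s": on, "offset_s": off, "label": lab, "trial": k + 1}
         for k, (on, off, lab) in enumerate(schedule)]
    )
    truth = SyntheticGroundTruth(
        drift=config.f0 + drift,
        event_amplitudes=pd.DataFrame(amp_records),
        kernel_window_mean=kernel_window_mean,
    )
    return trace, events, truth


def baseline_interval(config: PhotoSimConfig) -> tuple[float, float]:
    """The (start, end) seconds of the home-cage baseline segment."""
    return (0.0, config.baseline_minutes * 60.0)
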