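"""Synthetic study generator with known ground truth.

Generates observer segmentation logs, hierarchical multi-voxel
"fMRI-like" parcel data and hippocampal time series for a planted set
of event boundaries, so that every downstream stage of the pipeline can
be exercised and validated without access to real data.

Two boundary response profiles are supported for the cortical
generator:

``graded``
    At each planted boundary the latent pattern of every parcel rotates
    toward a new random direction by an angle proportional to the
    planted boundary strength.  The rotation is shared across subjects
    (stimulus-driven); only the additive noise is subject-specific.

``binary``
    Each subject independently either fully replaces the latent pattern
    (boundary "detected", probability given by a detection curve over
    strength) or keeps it unchanged.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .layout import SessionLayout, make_session_layout

__all__ = [
    "GroundTruth",
    "LevelSpec",
    "SimulatedStudy",
    "make_session_layout",
    "random_ground_truth",
    "simulate_observers",
    "simulate_cortex",
    "simulate_hippocampus",
    "simulate_study",
]


@dataclass(frozen=True)
class GroundTruth:
    """Planted boundaries and response-profile parameters."""

    boundary_times: tuple[float, ...]
    strength: tuple[float, ...]
    profile_mode: str = "graded"
    detection_curve: Callable[[np.ndarray], np.ndarray] | None = None
    shift_gain: float = 1.0
    noise_sd: float = 0.1
    hemodynamic_delay_tr: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.boundary_times, float)
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("boundary_times must be strictly increasing")
        s = np.asarray(self.strength, float)
        if s.shape != times.shape:
            raise ValueError("strength must match boundary_times")
        if s.size and (s.min() < 0 or s.max() > 1):
            raise ValueError("strengths must lie in [0, 1]")
        if self.profile_mode not in ("graded", "binary"):
            raise ValueError(f"unknown profile_mode {self.profile_mode!r}")
        if self.shift_gain < 0:
            raise ValueError("shift_gain must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_boundaries(self) -> int:
        return len(self.boundary_times)

    def detection_probability(self, strength: np.ndarray) -> np.ndarray:
        s = np.asarray(strength, float)
        if self.detection_curve is None:
            return s
        p = np.asarray(self.detection_curve(s), float)
        if np.any(np.diff(self.detection_curve(np.linspace(0, 1, 11))) < -1e-12):
            raise ValueError("detection_curve must be monotone non-decreasing")
        return np.clip(p, 0.0, 1.0)


@dataclass(frozen=True)
class LevelSpec:
    """Per-level parcel geometry and boundary responsiveness weight."""

    name: str
    n_parcels: int
    n_voxels: int
    responsiveness: float = 1.0

    def __post_init__(self) -> None:
        if self.n_voxels < 2:
            raise ValueError("voxel counts must be >= 2 per parcel")
        if self.n_parcels < 1:
            raise ValueError("need at least one parcel per level")


DEFAULT_LEVELS = (
    LevelSpec("1_AUD", 3, 16, 1.0),
    LevelSpec("1_VIS", 3, 16, 1.0),
    LevelSpec("2", 4, 16, 0.75),
    LevelSpec("3", 4, 16, 0.55),
    LevelSpec("4", 4, 16, 0.40),
)


@dataclass
class SimulatedStudy:
    """Bundle of everything the synthetic generator produces."""

    layout: SessionLayout
    truth: GroundTruth
    observer_logs: list[dict[str, list[float]]]
    subject_data: dict[str, list[np.ndarray]] = field(default_factory=dict)
    hippocampus_series: list[list[np.ndarray]] = field(default_factory=list)


def random_ground_truth(
    layout: SessionLayout,
    n_boundaries: int = 130,
    min_sep: float = 8.0,
    strength_range: tuple[float, float] = (0.1, 1.0),
    profile_mode: str = "graded",
    seed: int = 0,
    **kwargs,
) -> GroundTruth:
    """Plant boundaries uniformly in the session outside title windows.

    Boundaries are at least ``min_sep`` seconds apart, clear of movie
    title windows and of the first/last ``min_sep`` seconds of each
    run.  Times are snapped to the 0.1 s observer resolution.
    """
    rng = np.random.default_rng(seed)
    valid: list[tuple[float, float]] = []
    for run in layout.runs:
        for m in run:
            lo, hi = layout.movie_interval(m)
            lo += layout.title_duration + 1.5
            run_idx = layout.run_of_time(lo)
            run_end = float(layout.run_starts[run_idx]) + float(
                layout.run_durations[run_idx]
            )
            hi = min(hi, run_end - min_sep)
            if hi > lo:
                valid.append((lo, hi))
    total = sum(hi - lo for lo, hi in valid)
    times: list[float] = []
    for _ in range(200 * n_boundaries):
        if len(times) >= n_boundaries:
            break
        u = rng.uniform(0, total)
        for lo, hi in valid:
            if u < hi - lo:
                t = round(lo + u, 1)
                break
            u -= hi - lo
        else:  # pragma: no cover - float edge
            continue
        if all(abs(t - s) >= min_sep for s in times):
            times.append(t)
    if len(times) < n_boundaries:
        raise ValueError(
            f"could not place {n_boundaries} boundaries with min_sep={min_sep}"
        )
    times = sorted(times)
    strength = rng.uniform(*strength_range, size=n_boundaries)
    return GroundTruth(
        boundary_times=tuple(times),
        strength=tuple(strength),
        profile_mode=profile_mode,
        seed=seed,
        **kwargs,
    )


# --------------------------------------------------------------------------
# Observers
# --------------------------------------------------------------------------
def simulate_observers(
    layout: SessionLayout,
    truth: GroundTruth,
    n_observers: int = 16,
    jitter_sd: float = 0.3,
    false_alarm_rate: float = 0.0,
    enforce_allowance: bool = False,
    seed: int | None = None,
) -> list[dict[str, list[float]]]:
    """Simulate per-observer boundary logs.

    Observer *o* marks planted boundary *i* with probability equal to
    its detection probability (the raw strength unless the truth
    carries a detection curve), at the planted time plus Gaussian
    jitter truncated to the containing movie interval.  Returned times
    are movie-local seconds at 0.1 s resolution.

    ``false_alarm_rate`` is the expected number of spurious marks per
    minute of movie (planted nowhere near consensus); no empirical
    default exists, so it defaults to 0.
    """
    if n_observers < 1:
        raise ValueError("n_observers must be >= 1")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    times = np.asarray(truth.boundary_times, float)
    probs = truth.detection_probability(np.asarray(truth.strength, float))

    from .segmentation import segment_allowance

    logs: list[dict[str, list[float]]] = []
    for _ in range(n_observers):
        marks: dict[str, list[float]] = {mid: [] for mid in layout.movie_ids}
        for t, p in zip(times, probs):
            if rng.random() >= p:
                continue
            movie = layout.movie_of_time(t)
            lo, hi = layout.movie_interval(movie)
            tm = t + rng.normal(0.0, jitter_sd) if jitter_sd > 0 else t
            tm = float(np.clip(tm, lo, hi - 0.1))
            marks[layout.movie_ids[movie]].append(round(tm - lo, 1))
        if false_alarm_rate > 0:
            for movie in range(layout.n_movies):
                lo, hi = layout.movie_interval(movie)
                lam = false_alarm_rate * (hi - lo) / 60.0
                n_fa = rng.poisson(lam)
                fa = rng.uniform(layout.title_duration, hi - lo, size=n_fa)
                marks[layout.movie_ids[movie]].extend(round(v, 1) for v in fa)
        if enforce_allowance:
            for movie in range(layout.n_movies):
                mid = layout.movie_ids[movie]
                lo_n, hi_n = segment_allowance(layout.movie_durations[movie])
                ts = sorted(set(marks[mid]))
                if len(ts) > hi_n:
                    # keep the marks closest to the strongest planted boundaries
                    keep = _strongest_subset(layout, truth, movie, ts, hi_n)
                    ts = keep
                while len(ts) < lo_n:
                    cand = round(
                        rng.uniform(
                            layout.title_duration, layout.movie_durations[movie]
                        ),
                        1,
                    )
                    if cand not in ts:
                        ts.append(cand)
                marks[mid] = sorted(ts)
        logs.append({mid: sorted(v) for mid, v in marks.items()})
    return logs


def _strongest_subset(layout, truth, movie, ts, n_keep):
    lo, _ = layout.movie_interval(movie)
    planted = np.asarray(truth.boundary_times) - lo
    strengths = np.asarray(truth.strength)
    scored = []
    for t in ts:
        d = np.abs(planted - t)
        j = int(np.argmin(d)) if d.size else -1
        s = strengths[j] if (j >= 0 and d[j] <= 1.0) else 0.0
        scored.append((s, t))
    scored.sort(reverse=True)
    return sorted(t for _, t in scored[:n_keep])


# --------------------------------------------------------------------------
# Cortex
# --------------------------------------------------------------------------
def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:  # pragma: no cover - measure-zero
        v = v + 1e-12
        n = np.linalg.norm(v)
    return v / n


def _rotate_toward(u: np.ndarray, target: np.ndarray, angle: float) -> np.ndarray:
    """Rotate unit vector ``u`` toward ``target`` by ``angle`` radians."""
    w = target - np.dot(target, u) * u
    norm = np.linalg.norm(w)
    if norm < 1e-12:  # target parallel to u
        return u.copy()
    w = w / norm
    return np.cos(angle) * u + np.sin(angle) * w


def simulate_cortex(
    layout: SessionLayout,
    truth: GroundTruth,
    levels_spec: Sequence[LevelSpec] = DEFAULT_LEVELS,
    n_subjects: int = 17,
    signal_amplitude: float = 1.0,
    seed: int | None = None,
) -> dict[str, list[np.ndarray]]:
    """Simulate per-subject hierarchical parcel data.

    Returns a mapping ``level name -> list over runs`` of arrays with
    shape ``(n_subjects, n_parcels, n_voxels, run_n_trs)``.  Within each
    event a parcel's voxel pattern is a fixed latent vector plus
    isotropic Gaussian noise; the latent vector changes at the TR of
    each planted boundary (shifted by the truth's hemodynamic delay).
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    b_trs = np.array(
        [
            layout.seconds_to_tr(t, hrf_shift=truth.hemodynamic_delay_tr)
            for t in truth.boundary_times
        ]
    )
    strengths = np.asarray(truth.strength, float)
    n_trs = layout.n_trs
    # event id per session TR: 0 before first boundary, +1 at each boundary TR
    event_of_tr = np.zeros(n_trs, int)
    for tr in b_trs:
        if 0 <= tr < n_trs:
            event_of_tr[tr:] += 1
    n_events = int(event_of_tr.max()) + 1

    if truth.profile_mode == "binary":
        detect_p = truth.detection_probability(strengths)
        # per subject per boundary detection, shared across parcels of a level
        detected = {
            spec.name: rng.random((n_subjects, len(b_trs))) < detect_p
            for spec in levels_spec
        }

    out: dict[str, list[np.ndarray]] = {}
    run_offsets = layout.run_tr_offsets
    run_lengths = layout.run_n_trs
    for spec in levels_spec:
        nv = spec.n_voxels
        sqrt_nv = np.sqrt(nv)
        # latent pattern per parcel per event
        if truth.profile_mode == "graded":
            latents = np.empty((spec.n_parcels, n_events, nv))
            for p in range(spec.n_parcels):
                u = _unit(rng.standard_normal(nv))
                latents[p, 0] = u
                for e in range(1, n_events):
                    target = _unit(rng.standard_normal(nv))
                    angle = (np.pi / 2) * min(
                        1.0,
                        truth.shift_gain * strengths[e - 1] * spec.responsiveness,
                    )
                    u = _rotate_toward(u, target, angle)
                    latents[p, e] = u
            # shared across subjects
            latent_ts = latents[:, event_of_tr, :]  # (parcels, trs, vox)
            signal = np.broadcast_to(
                latent_ts[None], (n_subjects,) + latent_ts.shape
            )
        else:  # binary
            det = detected[spec.name]  # (subjects, boundaries)
            targets = np.empty((spec.n_parcels, n_events, nv))
            for p in range(spec.n_parcels):
                for e in range(n_events):
                    targets[p, e] = _unit(rng.standard_normal(nv))
            signal = np.empty((n_subjects, spec.n_parcels, n_trs, nv))
            for s in range(n_subjects):
                # event index actually adopted by this subject
                adopted = np.zeros(n_events, int)
                for e in range(1, n_events):
                    adopted[e] = e if det[s, e - 1] else adopted[e - 1]
                latent_ts = targets[:, adopted[event_of_tr], :]
                signal[s] = latent_ts
        noise = rng.standard_normal((n_subjects, spec.n_parcels, n_trs, nv))
        data = signal_amplitude * sqrt_nv * signal + truth.noise_sd * noise
        # (subjects, parcels, voxels, trs)
        data = np.moveaxis(data, 3, 2)
        out[spec.name] = [
            np.ascontiguousarray(data[..., off : off + ln])
            for off, ln in zip(run_offsets, run_lengths)
        ]
    return out


# --------------------------------------------------------------------------
# Hippocampus
# --------------------------------------------------------------------------
def default_response_kernel(n_taps: int = 9, peak: int = 3) -> np.ndarray:
    """Smooth non-negative bump over ``n_taps`` TRs peaking at ``peak``."""
    t = np.arange(n_taps, dtype=float)
    k = (t / peak) ** 2 * np.exp(-(t - peak) / 1.5)
    k[0] = 0.0
    return k / k.max()


def simulate_hippocampus(
    layout: SessionLayout,
    truth: GroundTruth,
    amplitude_rule: Callable[[np.ndarray], np.ndarray] | Mapping[int, float] | None = None,
    kernel: np.ndarray | None = None,
    noise_sd: float = 0.05,
    drift_amplitude: float = 0.0,
    n_subjects: int = 17,
    seed: int | None = None,
) -> list[list[np.ndarray]]:
    """Simulate per-subject hippocampal TR series.

    ``series = drift + sum_i amplitude_i * kernel(t - boundary_tr_i) + noise``

    ``amplitude_rule`` maps planted strengths to response amplitudes
    (callable over the strength vector), or maps boundary index to
    amplitude (mapping), or defaults to amplitude = strength.
    Returns a list over subjects of lists over runs of 1-D arrays.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if kernel is None:
        kernel = default_response_kernel()
    kernel = np.asarray(kernel, float)
    if kernel.ndim != 1 or kernel.size == 0:
        raise ValueError("kernel must be a non-empty 1-D array")
    if np.any(kernel < 0):
        raise ValueError("kernel must be non-negative")

    strengths = np.asarray(truth.strength, float)
    if amplitude_rule is None:
        amplitudes = strengths.copy()
    elif callable(amplitude_rule):
        amplitudes = np.asarray(amplitude_rule(strengths), float)
    else:
        amplitudes = np.array(
            [amplitude_rule.get(i, 0.0) for i in range(len(strengths))], float
        )

    rng = np.random.default_rng(truth.seed if seed is None else seed)
    b_trs = [
        layout.seconds_to_tr(t, hrf_shift=truth.hemodynamic_delay_tr)
        for t in truth.boundary_times
    ]
    clean = np.zeros(layout.n_trs)
    run_offsets = layout.run_tr_offsets
    run_lengths = layout.run_n_trs
    for tr, amp in zip(b_trs, amplitudes):
        run = layout.run_of_tr(tr) if 0 <= tr < layout.n_trs else None
        if run is None:
            continue
        run_end = int(run_offsets[run] + run_lengths[run])
        stop = min(tr + kernel.size, run_end)
        clean[tr:stop] += amp * kernel[: stop - tr]
    if drift_amplitude:
        phase = np.linspace(0, 4 * np.pi, layout.n_trs)
        clean = clean + drift_amplitude * np.sin(phase)

    subjects = []
    for _ in range(n_subjects):
        series = clean + noise_sd * rng.standard_normal(layout.n_trs)
        subjects.append(
            [
                series[off : off + ln].copy()
                for off, ln in zip(run_offsets, run_lengths)
            ]
        )
    return subjects


def simulate_study(
    layout: SessionLayout | None = None,
    truth: GroundTruth | None = None,
    levels_spec: Sequence[LevelSpec] = DEFAULT_LEVELS,
    n_subjects: int = 17,
    n_observers: int = 16,
    seed: int = 0,
    **cortex_kwargs,
) -> SimulatedStudy:
    """Convenience wrapper producing a full synthetic study."""
    if layout is None:
        layout = make_session_layout(
            [180.0] * 10, title_duration=4.0, tr=1.5,
            runs=[list(range(5)), list(range(5, 10))],
        )
    if truth is None:
        truth = random_ground_truth(layout, seed=seed)
    logs = simulate_observers(layout, truth, n_observers=n_observers, seed=seed + 1)
    data = simulate_cortex(
        layout, truth, levels_spec, n_subjects=n_subjects, seed=seed + 2,
        **cortex_kwargs,
    )
    hippo = simulate_hippocampus(layout, truth, n_subjects=n_subjects, seed=seed + 3)
    return SimulatedStudy(
        layout=layout,
        truth=truth,
        observer_logs=logs,
        subject_data=data,
        hippocampus_series=hippo,
    )
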