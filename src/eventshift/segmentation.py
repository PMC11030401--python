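"""From observer boundary logs to a categorized, TR-indexed boundary set.

Pipeline: rasterize each observer's marks onto a 0.1 s grid with a 1 s
inclusion window on each side, average across observers into an
agreement time series, smooth with a Gaussian-weighted moving average
(2 s window), concatenate movies, threshold at the 65th percentile to
detect boundary peaks, bin into weak/moderate/strong by agreement,
apply exclusion rules and map times to HRF-shifted TR indices.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .layout import SessionLayout

__all__ = [
    "AgreementSeries",
    "rasterize_observer",
    "agreement_series",
    "smooth_gaussian",
    "concat_movies",
    "detect_boundaries",
    "bin_strength",
    "apply_exclusions",
    "to_tr_indices",
    "segment_allowance",
    "verify_ratings",
    "segment_pipeline",
    "BOUNDARY_COLUMNS",
]

_EPS = 1e-9

#: canonical columns of a boundary table
BOUNDARY_COLUMNS = ["time_s", "agreement", "category", "excluded", "reason", "tr_index"]

CATEGORIES = ("weak", "moderate", "strong")


@dataclass
class AgreementSeries:
    """Across-observer boundary agreement on a regular grid.

    ``values`` may span a single movie or the concatenated session; for
    concatenated series ``movie_offsets`` records the starting sample of
    each movie, in layout order.
    """

    values: np.ndarray
    grid_step: float = 0.1
    movie_offsets: np.ndarray | None = None
    movie_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 1:
            raise ValueError("agreement series must be 1-D")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.grid_step

    def slice_movie(self, index: int) -> np.ndarray:
        if self.movie_offsets is None:
            raise ValueError("series is not concatenated")
        offs = np.concatenate([self.movie_offsets, [self.values.size]])
        return self.values[int(offs[index]) : int(offs[index + 1])]


def _grid_length(duration: float, grid_step: float) -> int:
    return int(round(duration / grid_step))


def rasterize_observer(
    times: np.ndarray,
    movie_duration: float,
    grid_step: float = 0.1,
    window: float = 1.0,
) -> np.ndarray:
    """Binary raster of one observer's marks for one movie.

    A grid sample is 1 iff it lies within ``window`` seconds
    (inclusive) of any marked boundary time.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    times = np.asarray(times, float)
    if times.size and (times.min() < -_EPS or times.max() > movie_duration + _EPS):
        raise ValueError("boundary times outside movie duration")
    n = _grid_length(movie_duration, grid_step)
    raster = np.zeros(n, dtype=float)
    grid = np.arange(n) * grid_step
    for t in times:
        raster[np.abs(grid - t) <= window + _EPS] = 1.0
    return raster


def agreement_series(
    rasters: list[np.ndarray], grid_step: float = 0.1
) -> AgreementSeries:
    """Pointwise mean across observers for one movie."""
    if not rasters:
        raise ValueError("need at least one observer raster")
    lengths = {len(r) for r in rasters}
    if len(lengths) != 1:
        raise ValueError(f"mismatched raster lengths: {sorted(lengths)}")
    return AgreementSeries(np.mean(rasters, axis=0), grid_step=grid_step)


def smooth_gaussian(
    series: AgreementSeries, window: float = 2.0, sigma: float | None = None
) -> AgreementSeries:
    """Gaussian-weighted moving average over a ``window``-second window.

    The kernel is a Gaussian truncated to total width ``window``
    (i.e. +/- window/2), renormalized so that weights sum to one; at
    the series edges the weights are renormalized over the available
    samples.  ``sigma`` defaults to ``window / 5``.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if window < series.grid_step:
        raise ValueError("window smaller than grid step")
    if sigma is None:
        sigma = window / 5.0
    half = int(np.floor(window / 2.0 / series.grid_step + _EPS))
    offsets = np.arange(-half, half + 1) * series.grid_step
    kernel = np.exp(-0.5 * (offsets / sigma) ** 2)
    kernel = kernel / kernel.sum()
    num = np.convolve(series.values, kernel, mode="same")
    den = np.convolve(np.ones_like(series.values), kernel, mode="same")
    return AgreementSeries(
        num / den,
        grid_step=series.grid_step,
        movie_offsets=series.movie_offsets,
        movie_ids=series.movie_ids,
    )


def gaussian_kernel(window: float = 2.0, grid_step: float = 0.1,
                    sigma: float | None = None) -> np.ndarray:
    """The (interior) smoothing kernel used by :func:`smooth_gaussian`."""
    if sigma is None:
        sigma = window / 5.0
    half = int(np.floor(window / 2.0 / grid_step + _EPS))
    offsets = np.arange(-half, half + 1) * grid_step
    k = np.exp(-0.5 * (offsets / sigma) ** 2)
    return k / k.sum()


def concat_movies(
    per_movie: list[AgreementSeries], layout: SessionLayout
) -> AgreementSeries:
    """Concatenate per-movie series in layout order."""
    if len(per_movie) != layout.n_movies:
        raise ValueError(
            f"expected {layout.n_movies} movie series, got {len(per_movie)}"
        )
    steps = {s.grid_step for s in per_movie}
    if len(steps) != 1:
        raise ValueError("grid steps differ across movies")
    step = steps.pop()
    for s, dur in zip(per_movie, layout.movie_durations):
        if len(s.values) != _grid_length(dur, step):
            raise ValueError("movie series length does not match layout duration")
    lengths = [len(s.values) for s in per_movie]
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]]).astype(int)
    return AgreementSeries(
        np.concatenate([s.values for s in per_movie]),
        grid_step=step,
        movie_offsets=offsets,
        movie_ids=layout.movie_ids,
    )


def detect_boundaries(
    smoothed: AgreementSeries,
    percentile: float = 65.0,
    min_peak_separation: float = 1.0,
) -> pd.DataFrame:
    """Detect candidate boundaries as threshold-exceeding local maxima.

    The threshold is the given percentile (linear interpolation) of all
    samples of the concatenated smoothed series.  Local maxima strictly
    above threshold are kept; plateaus are reduced to their earliest
    sample; peaks closer than ``min_peak_separation`` seconds keep only
    the higher one.
    """
    v = smoothed.values
    if v.size == 0:
        raise ValueError("empty series")
    threshold = float(np.percentile(v, percentile))
    peaks = _local_maxima(v)
    peaks = [i for i in peaks if v[i] > threshold]
    if min_peak_separation > 0 and peaks:
        kept: list[int] = []
        # prefer higher peaks; stable on ties via earlier index
        for i in sorted(peaks, key=lambda i: (-v[i], i)):
            if all(
                abs(i - j) * smoothed.grid_step >= min_peak_separation - _EPS
                for j in kept
            ):
                kept.append(i)
        peaks = sorted(kept)
    df = pd.DataFrame(
        {
            "time_s": np.asarray(peaks, float) * smoothed.grid_step,
            "agreement": v[peaks] if peaks else np.empty(0),
        }
    )
    df["category"] = pd.Series([pd.NA] * len(df), dtype="object")
    df["excluded"] = False
    df["reason"] = pd.Series([pd.NA] * len(df), dtype="object")
    df["tr_index"] = pd.Series([pd.NA] * len(df), dtype="Int64")
    df.attrs["threshold"] = threshold
    return df


def _local_maxima(v: np.ndarray) -> list[int]:
    """Indices of local maxima; a plateau yields its earliest sample."""
    n = v.size
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left_ok = i == 0 or v[i - 1] < v[i]
        right_ok = j == n - 1 or v[j + 1] < v[i]
        if left_ok and right_ok and not (i == 0 and j == n - 1):
            peaks.append(i)
        i = j + 1
    return peaks


def bin_strength(candidates: pd.DataFrame) -> pd.DataFrame:
    """Equal-count three-way split by agreement (ascending).

    Remainders are assigned to the stronger bins, so e.g. 10 boundaries
    split 3 weak / 3 moderate / 4 strong.  Ties in agreement keep their
    time order (stable sort).
    """
    n = len(candidates)
    if n < 3:
        raise ValueError("need at least 3 candidate boundaries to bin")
    base, rem = divmod(n, 3)
    sizes = [base, base + (1 if rem == 2 else 0), base + (1 if rem >= 1 else 0)]
    order = candidates["agreement"].to_numpy().argsort(kind="stable")
    cats = np.empty(n, dtype=object)
    start = 0
    for size, cat in zip(sizes, CATEGORIES):
        cats[order[start : start + size]] = cat
        start += size
    out = candidates.copy()
    out["category"] = cats
    return out


def apply_exclusions(
    boundaries: pd.DataFrame,
    layout: SessionLayout,
    min_sep: float = 6.0,
    last_per_run: bool = True,
    onset_pad: float = 1.0,
) -> pd.DataFrame:
    """Flag boundaries for exclusion.

    Rules, applied in order:

    1. every member of a pair closer than ``min_sep`` seconds
       (both flagged, reason ``pair<6s``);
    2. boundaries inside a movie-title onset window
       ``[title_onset, title_onset + title_duration + onset_pad]``
       (reason ``movie_onset``);
    3. the final still-retained boundary of each run
       (reason ``last_in_run``).
    """
    out = boundaries.copy()
    t = out["time_s"].to_numpy()
    if np.any(np.diff(t) < 0):
        raise ValueError("boundaries must be sorted by time")
    n = len(out)
    excluded = out["excluded"].to_numpy(dtype=bool).copy()
    reason = out["reason"].to_numpy(dtype=object).copy()

    for i in range(n):
        for j in range(i + 1, n):
            if t[j] - t[i] >= min_sep:
                break
            for k in (i, j):
                if not excluded[k]:
                    excluded[k] = True
                    reason[k] = f"pair<{min_sep:g}s"

    for lo, hi in layout.title_windows():
        inside = (t >= lo - _EPS) & (t <= hi + onset_pad + _EPS)
        for k in np.nonzero(inside)[0]:
            if not excluded[k]:
                excluded[k] = True
                reason[k] = "movie_onset"

    if last_per_run:
        run_of = np.array([layout.run_of_time(x) for x in t]) if n else np.empty(0, int)
        for run in range(layout.n_runs):
            idx = np.nonzero((run_of == run) & ~excluded)[0]
            if idx.size:
                k = idx[-1]
                excluded[k] = True
                reason[k] = "last_in_run"

    out["excluded"] = excluded
    out["reason"] = reason
    return out


def to_tr_indices(
    boundaries: pd.DataFrame, layout: SessionLayout, hrf_shift: int = 3
) -> pd.DataFrame:
    """Attach run-global, HRF-shifted, 0-based TR indices.

    A boundary whose shifted index falls beyond the end of its run is
    flagged (reason ``beyond_run``) and excluded from windowed analyses.
    """
    out = boundaries.copy()
    trs = np.empty(len(out), dtype=object)
    excluded = out["excluded"].to_numpy(dtype=bool).copy()
    reason = out["reason"].to_numpy(dtype=object).copy()
    for k, t in enumerate(out["time_s"].to_numpy()):
        idx = layout.seconds_to_tr(float(t), hrf_shift=hrf_shift)
        run = layout.run_of_time(float(t))
        run_end = int(layout.run_tr_offsets[run] + layout.run_n_trs[run])
        trs[k] = idx
        if idx >= run_end and not excluded[k]:
            excluded[k] = True
            reason[k] = "beyond_run"
    out["tr_index"] = pd.array(trs, dtype="Int64")
    out["excluded"] = excluded
    out["reason"] = reason
    return out


def segment_allowance(duration_s: float) -> tuple[int, int]:
    """Permitted segment-count range for one movie.

    With ``k`` the smallest integer at least the duration in minutes,
    the target count is ``3 k`` and the permitted range is
    ``(3k - k, 3k + k) = (2k, 4k)``.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    k = int(np.ceil(duration_s / 60.0 - _EPS))
    return 2 * k, 4 * k


def verify_ratings(
    ratings: pd.DataFrame, boundaries: pd.DataFrame
) -> dict:
    """Rank-correlate averaged normalized strength ratings with agreement.

    ``ratings`` has columns ``rater_id``, ``boundary_id``, ``rating``
    (integers 1-5); ``boundary_id`` indexes rows of ``boundaries``.
    Each rater's ratings are standardized (mean 0, sd 1), averaged
    across raters, and Spearman-correlated against the boundaries'
    agreement values.  Raters with constant ratings are dropped with a
    warning.
    """
    required = {"rater_id", "boundary_id", "rating"}
    if not required.issubset(ratings.columns):
        raise ValueError(f"ratings must have columns {sorted(required)}")
    bad = ~ratings["rating"].isin([1, 2, 3, 4, 5])
    if bad.any():
        raise ValueError("ratings must be integers in 1..5")
    zscores = []
    for rater, grp in ratings.groupby("rater_id"):
        sd = grp["rating"].std(ddof=0)
        if sd == 0:
            warnings.warn(f"rater {rater!r} has constant ratings; dropped")
            continue
        z = (grp["rating"] - grp["rating"].mean()) / sd
        zscores.append(pd.Series(z.to_numpy(), index=grp["boundary_id"].to_numpy()))
    if len(zscores) < 2:
        raise ValueError("need at least 2 raters with non-constant ratings")
    avg = pd.concat(zscores, axis=1).mean(axis=1)
    agreement = boundaries["agreement"].reindex(avg.index)
    if agreement.isna().any():
        raise ValueError("ratings reference unknown boundaries")
    rho, p = sps.spearmanr(avg.to_numpy(), agreement.to_numpy())
    return {
        "test": "spearman",
        "rho": float(rho),
        "n": int(len(avg)),
        "df": int(len(avg) - 2),
        "p": float(p),
        "n_raters": len(zscores),
    }


def segment_pipeline(
    observer_logs: list[dict[str, list[float]]],
    layout: SessionLayout,
    grid_step: float = 0.1,
    window: float = 1.0,
    smooth_window: float = 2.0,
    percentile: float = 65.0,
    min_sep: float = 6.0,
    hrf_shift: int = 3,
) -> tuple[pd.DataFrame, AgreementSeries]:
    """Full observer-logs -> boundary-table pipeline.

    Categories are assigned before exclusions, matching the reference
    procedure in which post-exclusion bin counts are unequal.
    """
    per_movie = []
    for m, mid in enumerate(layout.movie_ids):
        duration = layout.movie_durations[m]
        rasters = [
            rasterize_observer(
                np.asarray(log.get(mid, []), float), duration, grid_step, window
            )
            for log in observer_logs
        ]
        per_movie.append(agreement_series(rasters, grid_step))
    concat = concat_movies(per_movie, layout)
    smoothed = smooth_gaussian(concat, window=smooth_window)
    candidates = detect_boundaries(smoothed, percentile=percentile)
    binned = bin_strength(candidates)
    flagged = apply_exclusions(binned, layout, min_sep=min_sep)
    table = to_tr_indices(flagged, layout, hrf_shift=hrf_shift)
    return table, smoothed
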