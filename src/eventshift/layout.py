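"""Session timing layout: movies, title windows, runs, and TR indexing.

All times are expressed in seconds on a single concatenated session
timeline whose origin is the onset of the first movie title.  fMRI
positions are 0-based TR indices that are *run-global*: the index of a
time point in run 2 is offset by the number of TRs in run 1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SessionLayout", "make_session_layout"]

_EPS = 1e-9


@dataclass(frozen=True)
class SessionLayout:
    """Timing map linking observer time (seconds) to fMRI TR indices.

    Parameters
    ----------
    movie_durations
        Total duration of each movie interval in seconds, *including*
        the leading title window.
    title_duration
        Length of the title window at the start of every movie.
    tr
        fMRI repetition time in seconds.
    runs
        Partition of movie indices into scanning runs, in order.
    movie_ids
        Optional movie identifiers; defaults to ``movie00 .. movieNN``.
    """

    movie_durations: tuple[float, ...]
    title_duration: float
    tr: float
    runs: tuple[tuple[int, ...], ...]
    movie_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.movie_durations:
            raise ValueError("empty movie list")
        if any(d <= 0 for d in self.movie_durations):
            raise ValueError("movie durations must be positive")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.title_duration < 0:
            raise ValueError("title_duration must be non-negative")
        flat = [m for run in self.runs for m in run]
        if flat != list(range(len(self.movie_durations))):
            raise ValueError("runs must partition all movies in order")
        if not self.movie_ids:
            object.__setattr__(
                self,
                "movie_ids",
                tuple(f"movie{i:02d}" for i in range(len(self.movie_durations))),
            )
        elif len(self.movie_ids) != len(self.movie_durations):
            raise ValueError("movie_ids length mismatch")

    # ---------------------------------------------------------------- movies
    @property
    def n_movies(self) -> int:
        return len(self.movie_durations)

    @property
    def movie_onsets(self) -> np.ndarray:
        """Global onset (s) of every movie interval (title included)."""
        return np.concatenate([[0.0], np.cumsum(self.movie_durations)[:-1]])

    @property
    def session_duration(self) -> float:
        return float(sum(self.movie_durations))

    def movie_interval(self, movie: int) -> tuple[float, float]:
        onset = float(self.movie_onsets[movie])
        return onset, onset + self.movie_durations[movie]

    def title_windows(self) -> list[tuple[float, float]]:
        """Global ``[onset, onset + title_duration)`` window per movie."""
        return [
            (float(o), float(o) + self.title_duration) for o in self.movie_onsets
        ]

    def movie_of_time(self, time_s: float) -> int:
        if time_s < -_EPS or time_s > self.session_duration + _EPS:
            raise ValueError(f"time {time_s} outside session")
        idx = int(np.searchsorted(self.movie_onsets, time_s + _EPS) - 1)
        return max(idx, 0)

    def in_title(self, time_s: float) -> bool:
        m = self.movie_of_time(time_s)
        onset = float(self.movie_onsets[m])
        return onset - _EPS <= time_s < onset + self.title_duration - _EPS

    # ------------------------------------------------------------------ runs
    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def run_starts(self) -> np.ndarray:
        """Global onset (s) of each run."""
        return self.movie_onsets[[run[0] for run in self.runs]]

    @property
    def run_durations(self) -> np.ndarray:
        return np.array(
            [sum(self.movie_durations[m] for m in run) for run in self.runs]
        )

    @property
    def run_n_trs(self) -> np.ndarray:
        """Number of TRs acquired in each run (full TRs inside the run)."""
        return np.floor(self.run_durations / self.tr + _EPS).astype(int)

    @property
    def run_tr_offsets(self) -> np.ndarray:
        """Run-global TR index of the first TR of each run."""
        return np.concatenate([[0], np.cumsum(self.run_n_trs)[:-1]])

    @property
    def n_trs(self) -> int:
        return int(self.run_n_trs.sum())

    def run_of_time(self, time_s: float) -> int:
        starts = self.run_starts
        if time_s < -_EPS or time_s > self.session_duration + _EPS:
            raise ValueError(f"time {time_s} outside session")
        return max(int(np.searchsorted(starts, time_s + _EPS) - 1), 0)

    def run_of_tr(self, tr_index: int) -> int:
        offs = self.run_tr_offsets
        if tr_index < 0 or tr_index >= self.n_trs:
            raise ValueError(f"TR index {tr_index} outside session")
        return int(np.searchsorted(offs, tr_index + 1) - 1)

    def seconds_to_tr(self, time_s: float, hrf_shift: int = 0) -> int:
        """Run-global TR index of a session time, optionally HRF-shifted.

        The index is computed within the run containing ``time_s`` and
        offset by the TR counts of the preceding runs; the optional
        ``hrf_shift`` is added afterwards.  The result may point past
        the end of the run — callers decide how to handle that.
        """
        run = self.run_of_time(time_s)
        local = time_s - float(self.run_starts[run])
        idx = int(math.floor(local / self.tr + _EPS))
        return int(self.run_tr_offsets[run]) + idx + hrf_shift

    def to_dict(self) -> dict:
        return {
            "movie_durations": list(self.movie_durations),
            "title_duration": self.title_duration,
            "tr": self.tr,
            "runs": [list(r) for r in self.runs],
            "movie_ids": list(self.movie_ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionLayout":
        return cls(
            movie_durations=tuple(float(x) for x in d["movie_durations"]),
            title_duration=float(d["title_duration"]),
            tr=float(d["tr"]),
            runs=tuple(tuple(int(m) for m in r) for r in d["runs"]),
            movie_ids=tuple(d.get("movie_ids") or ()),
        )


def make_session_layout(
    movie_durations,
    title_duration: float = 4.0,
    tr: float = 1.5,
    runs=None,
    movie_ids=None,
) -> SessionLayout:
    """Build a :class:`SessionLayout` from movie durations.

    ``runs`` is a partition of movie indices (defaults to a single run
    covering all movies).  Durations include the leading title window.
    """
    durations = tuple(float(d) for d in movie_durations)
    if runs is None:
        runs = (tuple(range(len(durations))),)
    else:
        runs = tuple(tuple(int(m) for m in r) for r in runs)
    return SessionLayout(
        movie_durations=durations,
        title_duration=float(title_duration),
        tr=float(tr),
        runs=runs,
        movie_ids=tuple(movie_ids) if movie_ids else (),
    )
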