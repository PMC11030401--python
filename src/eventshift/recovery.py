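"""Parameter-recovery utilities on synthetic studies.

These helpers run the pattern-shift machinery directly against planted
ground truth (bypassing the observer-segmentation stage) so that
recovery of boundary-strength effects can be scored cheaply in
validation suites.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import patternshift as ps
from .layout import SessionLayout
from .synthetic import GroundTruth, LevelSpec, simulate_cortex

__all__ = [
    "planted_categories",
    "planted_tr_indices",
    "group_cbc_table",
    "subject_cbc_table",
]

CATEGORIES = ("weak", "moderate", "strong")


def planted_categories(strengths: np.ndarray) -> np.ndarray:
    """Tertile split of planted strengths into weak/moderate/strong."""
    s = np.asarray(strengths, float)
    order = s.argsort(kind="stable")
    n = s.size
    base, rem = divmod(n, 3)
    sizes = [base, base + (1 if rem == 2 else 0), base + (1 if rem >= 1 else 0)]
    cats = np.empty(n, dtype=object)
    start = 0
    for size, cat in zip(sizes, CATEGORIES):
        cats[order[start : start + size]] = cat
        start += size
    return cats


def planted_tr_indices(layout: SessionLayout, truth: GroundTruth) -> np.ndarray:
    return np.array(
        [
            layout.seconds_to_tr(t, hrf_shift=truth.hemodynamic_delay_tr)
            for t in truth.boundary_times
        ]
    )


def _level_series(
    level_runs: list[np.ndarray], halfwin: int
) -> np.ndarray:
    """Normalized level-average shift series from (parcels, vox, trs) runs."""
    n_parcels = level_runs[0].shape[0]
    parcel_series = []
    for p in range(n_parcels):
        per_run = [
            ps.shift_series(ps.standardize_voxels(run[p]), halfwin=halfwin)
            for run in level_runs
        ]
        parcel_series.append(ps.normalize_shift(per_run))
    return np.vstack(parcel_series).mean(axis=0)


def _cbc_rows(
    series_per_level: dict[str, np.ndarray],
    trs: np.ndarray,
    truth: GroundTruth,
    cats: np.ndarray,
    win: int,
    subject: str,
) -> list[dict]:
    rows = []
    for i, tr in enumerate(trs):
        for level, series in series_per_level.items():
            rows.append(
                {
                    "boundary_id": i,
                    "level": level,
                    "subject": subject,
                    "cbc": ps.cross_boundary(series, int(tr), win=win),
                    "strength": truth.strength[i],
                    "category": cats[i],
                }
            )
    return rows


def group_cbc_table(
    layout: SessionLayout,
    truth: GroundTruth,
    levels_spec: Sequence[LevelSpec],
    n_subjects: int = 6,
    halfwin: int = 3,
    win: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Group-average CBC per planted boundary and level.

    Boundaries whose CBC window is undefined (run edges) carry NaN.
    """
    data = simulate_cortex(layout, truth, levels_spec, n_subjects=n_subjects,
                           seed=seed)
    trs = planted_tr_indices(layout, truth)
    cats = planted_categories(truth.strength)
    series = {}
    for spec in levels_spec:
        runs = []
        for run_arr in data[spec.name]:
            std = np.stack(
                [ps.standardize_voxels(run_arr[s]) for s in range(n_subjects)]
            )
            runs.append(ps.group_average(std))
        series[spec.name] = _level_series(runs, halfwin)
    return pd.DataFrame(
        _cbc_rows(series, trs, truth, cats, win, "group")
    )


def subject_cbc_table(
    layout: SessionLayout,
    truth: GroundTruth,
    levels_spec: Sequence[LevelSpec],
    n_subjects: int = 17,
    halfwin: int = 3,
    win: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-subject CBC per planted boundary and level."""
    data = simulate_cortex(layout, truth, levels_spec, n_subjects=n_subjects,
                           seed=seed)
    trs = planted_tr_indices(layout, truth)
    cats = planted_categories(truth.strength)
    rows: list[dict] = []
    for s in range(n_subjects):
        series = {
            spec.name: _level_series(
                [run_arr[s] for run_arr in data[spec.name]], halfwin
            )
            for spec in levels_spec
        }
        rows.extend(_cbc_rows(series, trs, truth, cats, win, f"sub{s:02d}"))
    return pd.DataFrame(rows)
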