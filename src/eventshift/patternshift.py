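"""Multi-voxel pattern-shift time series and cross-boundary correlations.

At each TR *t* the multi-voxel pattern of a parcel is averaged over the
3 TRs immediately before (``t-3..t-1``) and after (``t+1..t+3``) the
focal TR, which is itself excluded; the Pearson correlation between the
two averaged patterns is the raw shift value at *t*.  Per-run series
are concatenated, z-scored over their defined samples, and averaged
across the parcels of each hierarchy level.  The cross-boundary
correlation (CBC) of a boundary is the mean of the normalized series
over the 3 TRs centered on the boundary; a shift is present when the
CBC is strictly below zero.

Undefined samples (window leaving the run, zero-variance pattern) are
NaN and propagate: any mean involving an undefined sample is undefined.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "standardize_voxels",
    "group_average",
    "shift_series",
    "normalize_shift",
    "level_average",
    "cross_boundary",
    "label_shift",
    "cross_boundary_table",
    "level_shift_series",
]


def standardize_voxels(run_array: np.ndarray) -> np.ndarray:
    """z-score each voxel's series within a run (last axis = TR).

    Constant voxels are set to zeros with a warning.
    """
    arr = np.asarray(run_array, float)
    if arr.shape[-1] < 2:
        raise ValueError("need at least 2 TRs to standardize")
    mean = arr.mean(axis=-1, keepdims=True)
    sd = arr.std(axis=-1, keepdims=True)
    flat = sd == 0
    if np.any(flat):
        warnings.warn(f"{int(flat.sum())} constant voxel(s) set to zeros")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    return np.where(np.broadcast_to(flat, z.shape), 0.0, z)


def group_average(subject_arrays: np.ndarray) -> np.ndarray:
    """Voxelwise mean across subjects (first axis = subject)."""
    arr = np.asarray(subject_arrays, float)
    if arr.ndim < 2:
        raise ValueError("expected a stacked (subjects, ...) array")
    return arr.mean(axis=0)


def shift_series(parcel_array: np.ndarray, halfwin: int = 3) -> np.ndarray:
    """Raw pattern-shift correlation series for one parcel, one run.

    ``parcel_array`` is (voxels, TRs).  The value at TR *t* is the
    Pearson correlation (over voxels, both patterns mean-centered)
    between the mean pattern of ``t-halfwin..t-1`` and the mean pattern
    of ``t+1..t+halfwin``.  The first and last ``halfwin`` TRs are NaN,
    as is any TR whose windowed pattern has zero variance.
    """
    arr = np.asarray(parcel_array, float)
    if arr.ndim != 2:
        raise ValueError("parcel array must be (voxels, trs)")
    nv, nt = arr.shape
    if nt <= 2 * halfwin:
        raise ValueError("run length must exceed 2 * halfwin")
    # sliding window means via cumulative sum over TRs
    cs = np.concatenate([np.zeros((nv, 1)), np.cumsum(arr, axis=1)], axis=1)
    win = (cs[:, halfwin:] - cs[:, :-halfwin]) / halfwin  # mean of k..k+halfwin-1
    # pre-pattern at t: TRs t-halfwin..t-1 -> win[:, t-halfwin]
    # post-pattern at t: TRs t+1..t+halfwin -> win[:, t+1]
    t = np.arange(halfwin, nt - halfwin)
    pre = win[:, t - halfwin]
    post = win[:, t + 1]
    pre = pre - pre.mean(axis=0, keepdims=True)
    post = post - post.mean(axis=0, keepdims=True)
    num = (pre * post).sum(axis=0)
    den = np.sqrt((pre**2).sum(axis=0) * (post**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    out = np.full(nt, np.nan)
    out[t] = r
    return out


def normalize_shift(run_series: list[np.ndarray]) -> np.ndarray:
    """Concatenate per-run series and z-score over defined samples.

    Undefined (NaN) samples are preserved.  Returns the concatenated,
    normalized series.
    """
    concat = np.concatenate([np.asarray(s, float) for s in run_series])
    defined = np.isfinite(concat)
    if defined.sum() < 2:
        raise ValueError("need at least 2 defined samples to normalize")
    vals = concat[defined]
    sd = vals.std()
    if sd == 0:
        raise ValueError("constant shift series cannot be z-scored")
    out = concat.copy()
    out[defined] = (vals - vals.mean()) / sd
    return out


def level_average(
    parcel_series: dict, hierarchy: pd.DataFrame | dict
) -> dict[str, np.ndarray]:
    """Pointwise mean of normalized parcel series within each level.

    ``parcel_series`` maps parcel id to a normalized series;
    ``hierarchy`` is either the assignment table from
    :func:`eventshift.hierarchy.assign_parcels` or a mapping
    parcel id -> level.  ``rejected`` parcels are skipped; 1_AUD and
    1_VIS are kept separate.
    """
    if isinstance(hierarchy, pd.DataFrame):
        level_of = dict(zip(hierarchy["parcel_id"], hierarchy["level"]))
    else:
        level_of = dict(hierarchy)
    groups: dict[str, list[np.ndarray]] = {}
    for pid, series in parcel_series.items():
        level = level_of.get(pid)
        if level is None or level == "rejected":
            continue
        groups.setdefault(level, []).append(np.asarray(series, float))
    if not groups:
        raise ValueError("no parcels assigned to any level")
    out = {}
    for level, series_list in groups.items():
        stacked = np.vstack(series_list)
        out[level] = stacked.mean(axis=0)  # NaN edges propagate
    return out


def cross_boundary(series: np.ndarray, tr_index: int, win: int = 1) -> float:
    """Mean of the series over ``tr_index - win .. tr_index + win``.

    Returns NaN when the window leaves the series or touches an
    undefined sample.
    """
    series = np.asarray(series, float)
    lo, hi = tr_index - win, tr_index + win + 1
    if lo < 0 or hi > series.size:
        return float("nan")
    window = series[lo:hi]
    if not np.all(np.isfinite(window)):
        return float("nan")
    return float(window.mean())


def label_shift(cbc: float) -> bool | None:
    """Shift indicator: strictly negative cross-boundary correlation."""
    if cbc is None or not np.isfinite(cbc):
        return None
    return bool(cbc < 0)


def level_shift_series(
    level_data: dict[str, list[np.ndarray]],
    hierarchy: pd.DataFrame | dict | None = None,
    halfwin: int = 3,
    standardized: bool = False,
) -> dict[str, np.ndarray]:
    """End-to-end per-level normalized shift series.

    ``level_data`` maps level name to a list over runs of arrays
    ``(n_parcels, n_voxels, n_trs)`` (a single subject or the group
    average).  Voxel series are standardized per run unless
    ``standardized`` is set, each parcel's per-run raw series are
    concatenated and z-scored, and the parcel z-series are averaged
    within the level.
    """
    out = {}
    for level, runs in level_data.items():
        n_parcels = runs[0].shape[0]
        parcel_series = []
        for p in range(n_parcels):
            per_run = []
            for run_arr in runs:
                arr = run_arr[p]
                if not standardized:
                    arr = standardize_voxels(arr)
                per_run.append(shift_series(arr, halfwin=halfwin))
            parcel_series.append(normalize_shift(per_run))
        out[level] = np.vstack(parcel_series).mean(axis=0)
    return out


def cross_boundary_table(
    level_series: dict[str, np.ndarray],
    boundaries: pd.DataFrame,
    win: int = 1,
    subject: str = "group",
) -> pd.DataFrame:
    """CBC and shift indicator per retained boundary and level.

    Rows of ``boundaries`` that are flagged ``excluded`` are skipped.
    The returned frame has columns ``boundary_id``, ``level``,
    ``subject``, ``cbc`` and ``shift`` (nullable boolean; NA where the
    CBC is undefined).
    """
    rows = []
    retained = boundaries.loc[~boundaries["excluded"].astype(bool)]
    for bid, row in retained.iterrows():
        tr = row["tr_index"]
        if pd.isna(tr):
            continue
        for level, series in level_series.items():
            cbc = cross_boundary(series, int(tr), win=win)
            rows.append(
                {
                    "boundary_id": bid,
                    "level": level,
                    "subject": subject,
                    "cbc": cbc,
                    "shift": label_shift(cbc),
                }
            )
    df = pd.DataFrame(rows, columns=["boundary_id", "level", "subject", "cbc", "shift"])
    df["shift"] = df["shift"].astype("boolean")
    return df
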