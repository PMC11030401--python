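"""Cross-hierarchy alignment scores and boundary-locked ROI responses.

A boundary's shift indicators (one per hierarchy level, true when the
group-level cross-boundary correlation is below zero) are condensed
into three alignment scores:

``strict nesting``
    length of the bottom-up prefix of shifting levels over levels 1-4
    (undefined when a shift occurs above a non-shifting level);
``nesting``
    the same prefix rule over levels 2-4 only;
``summation``
    the count of shifting levels among 2-4, ignoring nesting.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .layout import SessionLayout
from .patternshift import standardize_voxels
from .stats import paired_t, rm_anova, spearman

__all__ = [
    "indicator_matrix",
    "score_strict_nesting",
    "score_nesting",
    "score_summation",
    "score_table",
    "alignment_vs_agreement",
    "roi_series",
    "boundary_locked",
    "grouped_response_tests",
]

LEVEL_ORDER = ("1", "2", "3", "4")


def indicator_matrix(
    cbc: pd.DataFrame, level1_mode: str = "either"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Boundary x level shift indicators from group-level CBC values.

    ``cbc`` is the long group-level table (columns ``boundary_id``,
    ``level``, ``cbc``) with levels ``1_AUD``, ``1_VIS``, ``2``-``4``.
    The level-1 indicator combines the two sensory streams: with
    ``level1_mode='either'`` a shift in either stream counts; with
    ``'both'`` both streams must shift.  Returns ``(indicators,
    dropped)`` where boundaries with an undefined CBC at any assessed
    level are dropped with a reason.
    """
    if level1_mode not in ("either", "both"):
        raise ValueError("level1_mode must be 'either' or 'both'")
    wide = cbc.pivot_table(index="boundary_id", columns="level", values="cbc",
                           dropna=False)
    rows, dropped = [], []
    for bid, row in wide.iterrows():
        l1_parts = [row.get("1_AUD", np.nan), row.get("1_VIS", np.nan)]
        l1_parts = [v for v in l1_parts if v is not None]
        assessed = l1_parts + [row.get(lv, np.nan) for lv in ("2", "3", "4")]
        if any(pd.isna(v) for v in assessed):
            dropped.append({"boundary_id": bid, "reason": "undefined_cbc"})
            continue
        shifts1 = [v < 0 for v in l1_parts]
        l1 = any(shifts1) if level1_mode == "either" else all(shifts1)
        rows.append(
            {
                "boundary_id": bid,
                "L1": bool(l1),
                "L2": bool(row["2"] < 0),
                "L3": bool(row["3"] < 0),
                "L4": bool(row["4"] < 0),
            }
        )
    ind = pd.DataFrame(rows, columns=["boundary_id", "L1", "L2", "L3", "L4"])
    ind = ind.set_index("boundary_id") if len(ind) else ind
    return ind, pd.DataFrame(dropped, columns=["boundary_id", "reason"])


def _prefix_score(bits: tuple[bool, ...]) -> float:
    """Length of the leading run of 1s; NaN if any 1 occurs after a 0."""
    s = 0
    for b in bits:
        if b:
            s += 1
        else:
            break
    if any(bits[s:]):
        return float("nan")
    return float(s)


def score_strict_nesting(indicators) -> float:
    """Bottom-up prefix score over levels 1-4 (0-4, NaN if non-nested)."""
    bits = tuple(bool(b) for b in indicators)
    if len(bits) != 4:
        raise ValueError("strict nesting expects 4 level indicators")
    return _prefix_score(bits)


def score_nesting(indicators) -> float:
    """Bottom-up prefix score over levels 2-4 (0-3, NaN if non-nested)."""
    bits = tuple(bool(b) for b in indicators)
    if len(bits) != 3:
        raise ValueError("nesting expects 3 level indicators (levels 2-4)")
    return _prefix_score(bits)


def score_summation(indicators) -> float:
    """Count of shifting levels among 2-4 (0-3, always defined)."""
    bits = tuple(bool(b) for b in indicators)
    if len(bits) != 3:
        raise ValueError("summation expects 3 level indicators (levels 2-4)")
    return float(sum(bits))


def score_table(indicators: pd.DataFrame) -> pd.DataFrame:
    """All three alignment scores per boundary."""
    rows = []
    for bid, row in indicators.iterrows():
        four = (row["L1"], row["L2"], row["L3"], row["L4"])
        three = four[1:]
        rows.append(
            {
                "boundary_id": bid,
                "strict": score_strict_nesting(four),
                "nesting": score_nesting(three),
                "summation": score_summation(three),
            }
        )
    return pd.DataFrame(
        rows, columns=["boundary_id", "strict", "nesting", "summation"]
    ).set_index("boundary_id")


def alignment_vs_agreement(
    scores: pd.Series, agreement: pd.Series
) -> dict:
    """Spearman correlation of alignment scores with boundary agreement.

    Boundaries with undefined scores are excluded (shrinking the
    degrees of freedom), never imputed.
    """
    joined = pd.concat(
        [scores.rename("score"), agreement.rename("agreement")], axis=1
    ).dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 boundaries with defined scores")
    return spearman(joined["score"].to_numpy(), joined["agreement"].to_numpy())


# --------------------------------------------------------------------------
# Hippocampal boundary-locked responses
# --------------------------------------------------------------------------
def roi_series(
    run_arrays: list[np.ndarray], mask: np.ndarray | None = None
) -> list[np.ndarray]:
    """Mean in-mask voxel series per run, after per-run standardization.

    ``run_arrays`` holds one array per run, either ``(voxels, trs)`` or
    4-D ``(x, y, z, trs)``; for 4-D input a 3-D boolean ``mask`` is
    required and must match the spatial grid.
    """
    out = []
    for arr in run_arrays:
        arr = np.asarray(arr, float)
        if arr.ndim == 4:
            if mask is None:
                raise ValueError("4-D data requires a mask")
            m = np.asarray(mask, bool)
            if m.shape != arr.shape[:3]:
                raise ValueError("mask grid does not match data grid")
            if not m.any():
                raise ValueError("empty mask")
            vox = arr[m]
        elif arr.ndim == 2:
            vox = arr if mask is None else arr[np.asarray(mask, bool)]
            if vox.shape[0] == 0:
                raise ValueError("empty mask")
        else:
            raise ValueError("expected (voxels, trs) or (x, y, z, trs)")
        out.append(standardize_voxels(vox).mean(axis=0))
    return out


def boundary_locked(
    run_series: list[np.ndarray],
    boundaries: pd.DataFrame,
    layout: SessionLayout,
    pre: int = 2,
    post: int = 10,
    baseline: int = 2,
    summary_win: tuple[int, int] = (0, 4),
) -> pd.DataFrame:
    """Baseline-subtracted peri-boundary response per retained boundary.

    For each boundary the series from ``pre`` TRs before to ``post``
    TRs after is extracted within its run; the mean of the ``baseline``
    TRs immediately preceding the boundary is subtracted from every TR.
    The summary is the mean over ``summary_win`` (inclusive) relative
    TRs.  Boundaries whose baseline or summary window leaves the run
    are dropped with a reason in the ``dropped_reason`` attribute.
    """
    series = np.concatenate([np.asarray(s, float) for s in run_series])
    if series.size != layout.n_trs:
        raise ValueError("series length does not match layout TR count")
    offsets = layout.run_tr_offsets
    lengths = layout.run_n_trs
    retained = boundaries.loc[~boundaries["excluded"].astype(bool)]
    rows, dropped = [], []
    for bid, row in retained.iterrows():
        if pd.isna(row["tr_index"]):
            dropped.append({"boundary_id": bid, "reason": "no_tr_index"})
            continue
        tr = int(row["tr_index"])
        run = layout.run_of_tr(tr)
        run_lo = int(offsets[run])
        run_hi = run_lo + int(lengths[run])
        if tr - baseline < run_lo or tr - pre < run_lo:
            dropped.append({"boundary_id": bid, "reason": "window_before_run"})
            continue
        if tr + summary_win[1] >= run_hi:
            dropped.append({"boundary_id": bid, "reason": "window_after_run"})
            continue
        base = float(series[tr - baseline : tr].mean())
        rel = np.arange(-pre, post + 1)
        resp = np.full(rel.size, np.nan)
        for i, dt in enumerate(rel):
            if run_lo <= tr + dt < run_hi:
                resp[i] = series[tr + dt] - base
        lo, hi = summary_win
        summary = float(np.nanmean(resp[(rel >= lo) & (rel <= hi)]))
        rows.append(
            {
                "boundary_id": bid,
                "baseline": base,
                "summary": summary,
                "response": resp,
            }
        )
    out = pd.DataFrame(rows, columns=["boundary_id", "baseline", "summary", "response"])
    out.attrs["dropped"] = pd.DataFrame(dropped, columns=["boundary_id", "reason"])
    return out


def grouped_response_tests(
    responses: pd.DataFrame,
    grouping: pd.Series,
    min_trials_per_bin: int = 15,
) -> dict:
    """Test hippocampal summaries across alignment-score or strength groups.

    ``responses`` is a long per-subject table (columns ``subject``,
    ``boundary_id``, ``summary``); ``grouping`` maps boundary_id to a
    group (alignment score or strength category).  Summaries are
    averaged per subject within group.  With exactly two groups a
    paired t-test is run; with more, a repeated-measures ANOVA.  When
    intermediate score bins hold fewer than ``min_trials_per_bin``
    boundaries, a paired t-test between the extreme scores is reported
    alongside the ANOVA.  Subjects lacking boundaries in some group are
    dropped with a warning.
    """
    df = responses.copy()
    df["group"] = df["boundary_id"].map(grouping)
    df = df.dropna(subset=["group"])
    cell = df.groupby(["subject", "group"])["summary"].mean().unstack("group")
    complete = cell.dropna()
    if len(complete) < len(cell):
        warnings.warn(
            f"{len(cell) - len(complete)} subject(s) lacking boundaries in "
            "some group were dropped"
        )
    if complete.shape[1] < 2:
        raise ValueError("need >= 2 groups with data")
    groups = list(complete.columns)
    report: dict = {"groups": [str(g) for g in groups],
                    "n_subjects": int(len(complete))}
    if complete.shape[1] == 2:
        report["paired_t"] = paired_t(
            complete[groups[0]].to_numpy(), complete[groups[1]].to_numpy()
        )
    else:
        report["rm_anova"] = rm_anova(complete.to_numpy())
        counts = df.groupby("group")["boundary_id"].nunique()
        inner = counts.iloc[1:-1] if len(counts) > 2 else counts.iloc[0:0]
        if len(inner) and (inner < min_trials_per_bin).all():
            try:
                report["extremes_paired_t"] = paired_t(
                    complete[groups[0]].to_numpy(),
                    complete[groups[-1]].to_numpy(),
                )
            except ValueError as exc:
                report["extremes_paired_t"] = {"skipped": str(exc)}
    report["group_means"] = {
        str(g): float(complete[g].mean()) for g in groups
    }
    return report
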