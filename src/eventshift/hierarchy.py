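"""Cortical hierarchy of timescales from ISC under temporal scrambling.

Voxels are labeled short/medium/long timescale from their inter-subject
correlation (ISC) in three scrambling conditions (intact, fine-scramble,
coarse-scramble); parcels inherit the majority voxel label and are
routed to hierarchy levels, with short-timescale parcels split into
early-visual (retinotopic-atlas overlap), early-auditory (hand-picked
list) and non-sensory groups.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "compute_isc",
    "label_voxel",
    "label_voxels",
    "assign_parcel",
    "assign_parcels",
    "VOXEL_LABELS",
    "LEVELS",
]

VOXEL_LABELS = ("short", "medium", "long", "unlabeled")
LEVELS = ("1_AUD", "1_VIS", "2", "3", "4", "rejected")

CONDITIONS = ("intact", "fine", "coarse")


def compute_isc(condition_data: dict[str, np.ndarray]) -> pd.DataFrame:
    """Leave-one-out ISC per voxel and scrambling condition.

    ``condition_data`` maps condition name (``intact``, ``fine``,
    ``coarse``) to an array of shape ``(n_subjects, n_voxels, n_trs)``.
    For each voxel, each subject's time course is correlated with the
    mean time course of all other subjects, and the correlations are
    averaged across subjects.  Voxels with a constant series in any
    subject get NaN (they will end up unlabeled).
    """
    missing = [c for c in CONDITIONS if c not in condition_data]
    if missing:
        raise ValueError(f"missing conditions: {missing}")
    out = {}
    n_voxels = None
    for cond in CONDITIONS:
        data = np.asarray(condition_data[cond], float)
        if data.ndim != 3:
            raise ValueError("condition data must be (subjects, voxels, trs)")
        n_sub = data.shape[0]
        if n_sub < 2:
            raise ValueError("need at least 2 subjects")
        if n_voxels is None:
            n_voxels = data.shape[1]
        elif data.shape[1] != n_voxels:
            raise ValueError("voxel counts differ across conditions")
        total = data.sum(axis=0)
        rs = np.empty((n_sub, n_voxels))
        for s in range(n_sub):
            others = (total - data[s]) / (n_sub - 1)
            rs[s] = _rowwise_corr(data[s], others)
        out[f"r_{cond}"] = rs.mean(axis=0)
    return pd.DataFrame(out)


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation along the last axis, row by row; NaN if flat."""
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    na = np.sqrt((a * a).sum(axis=-1))
    nb = np.sqrt((b * b).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=-1) / (na * nb)
    r[(na == 0) | (nb == 0)] = np.nan
    return r


def label_voxel(
    r_intact: float, r_fine: float, r_coarse: float, thr: float = 0.2
) -> str:
    """Timescale label from the three ISC values.

    short   : above threshold in all three conditions;
    medium  : above threshold intact and coarse-scramble, not fine;
    long    : above threshold only intact;
    anything else (including NaN) is unlabeled.
    """
    vals = (r_intact, r_fine, r_coarse)
    if any(v is None or not np.isfinite(v) for v in vals):
        return "unlabeled"
    hi_i, hi_f, hi_c = (v > thr for v in vals)
    if hi_i and hi_f and hi_c:
        return "short"
    if hi_i and hi_c and not hi_f:
        return "medium"
    if hi_i and not hi_f and not hi_c:
        return "long"
    return "unlabeled"


def label_voxels(isc: pd.DataFrame, thr: float = 0.2) -> np.ndarray:
    """Vectorized :func:`label_voxel` over an ISC table."""
    out = np.array(
        [
            label_voxel(i, f, c, thr)
            for i, f, c in zip(isc["r_intact"], isc["r_fine"], isc["r_coarse"])
        ],
        dtype=object,
    )
    return out


@dataclass(frozen=True)
class ParcelAssignment:
    level: str
    labeled_fraction: float
    label_counts: dict
    visual_fraction: float


def assign_parcel(
    voxel_labels: np.ndarray,
    retino_prob: np.ndarray | None = None,
    is_auditory: bool = False,
    retino_thr: float = 0.25,
    min_labeled_fraction: float = 0.5,
    visual_fraction_thr: float = 0.5,
) -> ParcelAssignment:
    """Hierarchy level of one parcel from its voxel labels.

    The parcel is rejected if fewer than ``min_labeled_fraction`` of its
    voxels carry any timescale label.  Otherwise the majority label
    decides the timescale (ties go to the longer timescale); short
    parcels become ``1_VIS`` if more than ``visual_fraction_thr`` of
    voxels have retinotopic probability >= ``retino_thr``, ``1_AUD`` if
    the parcel is on the auditory list, else level ``2``; medium -> 3;
    long -> 4.
    """
    labels = np.asarray(voxel_labels, dtype=object)
    if labels.size == 0:
        raise ValueError("empty parcel")
    counts = {lab: int(np.sum(labels == lab)) for lab in ("short", "medium", "long")}
    labeled = sum(counts.values())
    frac = labeled / labels.size
    if retino_prob is None:
        vis_frac = 0.0
    else:
        retino_prob = np.asarray(retino_prob, float)
        if retino_prob.shape != labels.shape:
            raise ValueError("retino_prob must match voxel_labels shape")
        vis_frac = float(np.mean(retino_prob >= retino_thr))
    if frac < min_labeled_fraction:
        return ParcelAssignment("rejected", frac, counts, vis_frac)
    # majority label; ties go to the longer timescale
    order = ("long", "medium", "short")
    timescale = max(order, key=lambda lab: (counts[lab], -order.index(lab)))
    if timescale == "short":
        is_visual = vis_frac > visual_fraction_thr
        if is_visual and is_auditory:
            raise ValueError(
                "parcel is on the auditory list but satisfies the visual overlap rule"
            )
        if is_visual:
            level = "1_VIS"
        elif is_auditory:
            level = "1_AUD"
        else:
            level = "2"
    elif timescale == "medium":
        level = "3"
    else:
        level = "4"
    return ParcelAssignment(level, frac, counts, vis_frac)


def assign_parcels(
    voxel_labels: np.ndarray,
    parcel_of_voxel: np.ndarray,
    retino_prob: np.ndarray | None = None,
    auditory_parcels: set | frozenset = frozenset(),
    **kwargs,
) -> pd.DataFrame:
    """Assign every parcel id found in ``parcel_of_voxel`` to a level."""
    parcel_of_voxel = np.asarray(parcel_of_voxel)
    rows = []
    for pid in np.unique(parcel_of_voxel):
        mask = parcel_of_voxel == pid
        a = assign_parcel(
            np.asarray(voxel_labels, dtype=object)[mask],
            retino_prob=None if retino_prob is None else np.asarray(retino_prob)[mask],
            is_auditory=pid in auditory_parcels,
            **kwargs,
        )
        rows.append(
            {
                "parcel_id": pid,
                "level": a.level,
                "labeled_fraction": a.labeled_fraction,
                "visual_fraction": a.visual_fraction,
                "n_short": a.label_counts["short"],
                "n_medium": a.label_counts["medium"],
                "n_long": a.label_counts["long"],
            }
        )
    return pd.DataFrame(rows)
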