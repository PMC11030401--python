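"""File formats and run configuration.

TSV is the canonical tabular format, JSON is used for reports and the
ground-truth sidecar, YAML for configuration, NIfTI for volumetric
data.  All times are seconds; all fMRI positions are 0-based TR
indices.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .layout import SessionLayout

__all__ = [
    "RunConfig",
    "read_layout",
    "write_layout",
    "read_observer_logs",
    "write_observer_logs",
    "read_nifti",
    "write_nifti",
    "read_neuro_inputs",
    "write_table",
    "read_table",
]


@dataclass
class RunConfig:
    """All pipeline tunables, with reference defaults."""

    grid_step: float = 0.1
    inclusion_window: float = 1.0
    smooth_window: float = 2.0
    percentile: float = 65.0
    min_sep: float = 6.0
    hrf_shift: int = 3
    halfwin: int = 3
    cbc_win: int = 1
    isc_threshold: float = 0.2
    retino_threshold: float = 0.25
    level1_mode: str = "either"
    hippo_baseline: int = 2
    nonboundary_per_run: int = 22
    nonboundary_tail_excl: float = 10.0
    dip_n_boot: int = 2000
    seed: int = 0
    input_dir: str = "."
    output_dir: str = "results"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ------------------------------------------------------------------ layout
def write_layout(layout: SessionLayout, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(layout.to_dict()))


def read_layout(path: str | Path) -> SessionLayout:
    return SessionLayout.from_dict(yaml.safe_load(Path(path).read_text()))


# ------------------------------------------------------------- observer logs
def write_observer_logs(
    logs: list[dict[str, list[float]]], path: str | Path
) -> None:
    rows = []
    for o, log in enumerate(logs):
        for movie_id, times in log.items():
            for t in times:
                rows.append((f"obs{o:02d}", movie_id, t))
    df = pd.DataFrame(rows, columns=["observer_id", "movie_id", "time_s"])
    df.to_csv(path, sep="\t", index=False)


def read_observer_logs(
    path: str | Path, layout: SessionLayout
) -> list[dict[str, list[float]]]:
    df = pd.read_csv(path, sep="\t")
    required = {"observer_id", "movie_id", "time_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"observer log must have columns {sorted(required)}")
    logs = []
    for _, grp in df.groupby("observer_id", sort=True):
        log = {mid: [] for mid in layout.movie_ids}
        for _, row in grp.iterrows():
            if row["movie_id"] not in log:
                raise ValueError(f"unknown movie id {row['movie_id']!r}")
            log[row["movie_id"]].append(float(row["time_s"]))
        logs.append({mid: sorted(v) for mid, v in log.items()})
    return logs


# ------------------------------------------------------------------- NIfTI
def write_nifti(data: np.ndarray, path: str | Path,
                affine: np.ndarray | None = None, tr: float | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data, np.float64), affine)
    if tr is not None and data.ndim == 4:
        zooms = list(img.header.get_zooms())
        zooms[3] = tr
        img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    meta = {}
    if data.ndim == 4:
        meta["tr"] = float(img.header.get_zooms()[3])
    return data, img.affine, meta


def read_neuro_inputs(
    data_paths: list[str | Path],
    parcellation_path: str | Path | None = None,
    mask_paths: dict[str, str | Path] | None = None,
    label_table_path: str | Path | None = None,
    tr_override: float | None = None,
) -> dict:
    """Load 4-D data, parcellation and masks onto one consistent grid.

    Raises on affine or grid mismatches; the TR is read from the first
    4-D header unless ``tr_override`` is given.
    """
    out: dict = {"data": [], "tr": tr_override}
    affine = None
    grid = None
    for p in data_paths:
        data, aff, meta = read_nifti(p)
        if affine is None:
            affine, grid = aff, data.shape[:3]
        else:
            if not np.allclose(aff, affine):
                raise ValueError(f"affine mismatch for {p}")
            if data.shape[:3] != grid:
                raise ValueError(f"grid mismatch for {p}")
        if out["tr"] is None and "tr" in meta and meta["tr"] > 0:
            out["tr"] = meta["tr"]
        out["data"].append(data)
    if parcellation_path is not None:
        parc, aff, _ = read_nifti(parcellation_path)
        if affine is not None and not np.allclose(aff, affine):
            raise ValueError("parcellation affine mismatch")
        out["parcellation"] = parc.astype(int)
        if label_table_path is None:
            raise ValueError("parcellation requires a label table")
        out["labels"] = pd.read_csv(label_table_path, sep="\t")
    out["masks"] = {}
    for name, p in (mask_paths or {}).items():
        m, aff, _ = read_nifti(p)
        if affine is not None and not np.allclose(aff, affine):
            raise ValueError(f"mask affine mismatch for {name}")
        out["masks"][name] = m > 0.5
    out["affine"] = affine
    return out


# ------------------------------------------------------------------- tables
def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA")


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], **kwargs)
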