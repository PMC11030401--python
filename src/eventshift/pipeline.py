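"""End-to-end pipeline and the miniature on-disk fixture study.

``make_fixture`` writes a small but complete synthetic study to disk
(layout, observer logs, localizer and movie NIfTIs, atlases, ground
truth); ``run_pipeline`` runs segmentation -> hierarchy -> patternshift
-> stats -> alignment on such a directory and writes all tabular and
JSON outputs plus a provenance record.
"""
from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import alignment as al
from . import hierarchy as hi
from . import io as eio
from . import patternshift as ps
from . import segmentation as seg
from . import stats as st
from . import synthetic as syn
from .layout import SessionLayout, make_session_layout

__all__ = ["make_fixture", "run_pipeline", "PipelineError"]

CONDITIONS = ("intact", "fine", "coarse")

FIXTURE_LEVELS = (
    syn.LevelSpec("1_AUD", 1, 12, 1.0),
    syn.LevelSpec("1_VIS", 1, 12, 1.0),
    syn.LevelSpec("2", 2, 12, 0.8),
    syn.LevelSpec("3", 2, 12, 0.6),
    syn.LevelSpec("4", 2, 12, 0.45),
)

_LEVEL_TO_TIMESCALE = {"1_AUD": "short", "1_VIS": "short", "2": "short",
                       "3": "medium", "4": "long"}


class PipelineError(RuntimeError):
    """Stage-labeled pipeline failure."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def make_fixture(
    outdir: str | Path,
    seed: int = 0,
    n_subjects: int = 4,
    n_observers: int = 8,
    n_localizer_trs: int = 150,
) -> Path:
    """Write a miniature synthetic study suitable for CI to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "localizer").mkdir(exist_ok=True)
    (outdir / "movie").mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)

    layout = make_session_layout(
        [60.0, 60.0, 60.0, 60.0], title_duration=4.0, tr=1.5,
        runs=[(0, 1), (2, 3)],
    )
    truth = syn.random_ground_truth(
        layout, n_boundaries=14, min_sep=8.0, seed=seed,
        shift_gain=1.4, noise_sd=0.2,
    )
    logs = syn.simulate_observers(
        layout, truth, n_observers=n_observers, jitter_sd=0.3, seed=seed + 1
    )
    cortex = syn.simulate_cortex(
        layout, truth, FIXTURE_LEVELS, n_subjects=n_subjects, seed=seed + 2
    )
    amp_rule = lambda s: 0.5 * s  # noqa: E731 - amplitude follows strength
    hippo = syn.simulate_hippocampus(
        layout, truth, amplitude_rule=amp_rule, noise_sd=0.05,
        n_subjects=n_subjects, seed=seed + 3,
    )

    eio.write_layout(layout, outdir / "layout.yaml")
    eio.write_observer_logs(logs, outdir / "observer_logs.tsv")
    (outdir / "truth.json").write_text(
        json.dumps(
            {
                "boundary_times": list(truth.boundary_times),
                "strength": list(truth.strength),
                "profile_mode": truth.profile_mode,
                "shift_gain": truth.shift_gain,
                "noise_sd": truth.noise_sd,
                "hemodynamic_delay_tr": truth.hemodynamic_delay_tr,
                "seed": truth.seed,
            },
            indent=1,
        )
    )

    # spatial grid: x = parcel block (cortex parcels then hippocampus), y =
    # voxel within block, z = 1
    n_vox = FIXTURE_LEVELS[0].n_voxels
    parcel_levels = []
    for spec in FIXTURE_LEVELS:
        parcel_levels.extend([spec.name] * spec.n_parcels)
    n_parcels = len(parcel_levels)
    nx = n_parcels + 1  # final block is hippocampus
    parc = np.zeros((nx, n_vox, 1), int)
    for p in range(n_parcels):
        parc[p, :, 0] = p + 1
    eio.write_nifti(parc, outdir / "parcellation.nii")
    retino = np.zeros((nx, n_vox, 1))
    for p, level in enumerate(parcel_levels):
        if level == "1_VIS":
            retino[p, :, 0] = 0.9
    eio.write_nifti(retino, outdir / "retino_prob.nii")
    hippo_mask = np.zeros((nx, n_vox, 1))
    hippo_mask[n_parcels, :, 0] = 1.0
    eio.write_nifti(hippo_mask, outdir / "hippo_mask.nii")
    eio.write_table(
        pd.DataFrame(
            {
                "parcel_id": np.arange(1, n_parcels + 1),
                "network": ["Synth"] * n_parcels,
            }
        ),
        outdir / "parcel_networks.tsv",
    )
    aud_ids = [p + 1 for p, lv in enumerate(parcel_levels) if lv == "1_AUD"]
    eio.write_table(
        pd.DataFrame({"parcel_id": aud_ids}), outdir / "auditory_parcels.tsv"
    )

    # localizer: shared-signal structure planting the intended ISC pattern
    shared = {c: rng.standard_normal((n_parcels, n_vox, n_localizer_trs))
              for c in CONDITIONS}
    shared_in = {
        "short": CONDITIONS,
        "medium": ("intact", "coarse"),
        "long": ("intact",),
    }
    for s in range(n_subjects):
        for cond in CONDITIONS:
            vol = np.zeros((nx, n_vox, 1, n_localizer_trs))
            for p, level in enumerate(parcel_levels):
                ts = _LEVEL_TO_TIMESCALE[level]
                if cond in shared_in[ts]:
                    sig = shared[cond][p]
                else:
                    sig = rng.standard_normal((n_vox, n_localizer_trs))
                vol[p, :, 0, :] = sig + 0.6 * rng.standard_normal(
                    (n_vox, n_localizer_trs)
                )
            vol[n_parcels, :, 0, :] = rng.standard_normal(
                (n_vox, n_localizer_trs)
            )
            eio.write_nifti(
                vol, outdir / "localizer" / f"sub-{s:02d}_cond-{cond}.nii",
                tr=1.5,
            )

    # movie-viewing data: cortex blocks + hippocampus block
    run_lengths = layout.run_n_trs
    for s in range(n_subjects):
        for r in range(layout.n_runs):
            vol = np.zeros((nx, n_vox, 1, int(run_lengths[r])))
            p = 0
            for spec in FIXTURE_LEVELS:
                arr = cortex[spec.name][r][s]  # (parcels, voxels, trs)
                for q in range(spec.n_parcels):
                    vol[p, :, 0, :] = arr[q]
                    p += 1
            hseries = hippo[s][r]
            vol[n_parcels, :, 0, :] = hseries[None, :] + 0.02 * rng.standard_normal(
                (n_vox, hseries.size)
            )
            eio.write_nifti(
                vol, outdir / "movie" / f"sub-{s:02d}_run-{r}.nii", tr=layout.tr
            )

    cfg = eio.RunConfig(
        seed=seed,
        input_dir=str(outdir),
        output_dir=str(outdir / "results"),
        nonboundary_per_run=6,
        dip_n_boot=200,
    )
    cfg.to_yaml(outdir / "config.yaml")
    return outdir


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------
def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise labeled
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


@_stage("segmentation")
def _run_segmentation(cfg: eio.RunConfig, indir: Path, outdir: Path):
    layout = eio.read_layout(indir / "layout.yaml")
    logs = eio.read_observer_logs(indir / "observer_logs.tsv", layout)
    table, smoothed = seg.segment_pipeline(
        logs, layout,
        grid_step=cfg.grid_step, window=cfg.inclusion_window,
        smooth_window=cfg.smooth_window, percentile=cfg.percentile,
        min_sep=cfg.min_sep, hrf_shift=cfg.hrf_shift,
    )
    out = table.copy()
    out.insert(0, "boundary_id", out.index)
    eio.write_table(out, outdir / "boundaries.tsv")
    eio.write_table(
        pd.DataFrame({"time_s": smoothed.times, "agreement": smoothed.values}),
        outdir / "agreement.tsv",
    )
    return layout, table


@_stage("hierarchy")
def _run_hierarchy(cfg: eio.RunConfig, indir: Path, outdir: Path):
    loc_dir = indir / "localizer"
    parc, _, _ = eio.read_nifti(indir / "parcellation.nii")
    parc = parc.astype(int)
    retino, _, _ = eio.read_nifti(indir / "retino_prob.nii")
    auditory = set(
        eio.read_table(indir / "auditory_parcels.tsv")["parcel_id"].tolist()
    )
    in_parcel = parc > 0
    cond_data = {}
    for cond in CONDITIONS:
        files = sorted(loc_dir.glob(f"*cond-{cond}.nii"))
        if not files:
            raise FileNotFoundError(f"no localizer files for condition {cond}")
        stack = []
        for f in files:
            data, _, _ = eio.read_nifti(f)
            stack.append(data[in_parcel])  # (voxels, trs)
        cond_data[cond] = np.stack(stack)
    isc = hi.compute_isc(cond_data)
    labels = hi.label_voxels(isc, thr=cfg.isc_threshold)
    assignment = hi.assign_parcels(
        labels,
        parc[in_parcel],
        retino_prob=retino[in_parcel],
        auditory_parcels=auditory,
        retino_thr=cfg.retino_threshold,
    )
    eio.write_table(assignment, outdir / "hierarchy.tsv")
    return parc, assignment


@_stage("patternshift")
def _run_patternshift(cfg, indir: Path, outdir: Path, layout, boundaries,
                      parc, assignment):
    movie_files = sorted((indir / "movie").glob("sub-*_run-*.nii"))
    subjects = sorted({f.name.split("_")[0] for f in movie_files})
    level_of = dict(zip(assignment["parcel_id"], assignment["level"]))
    parcel_ids = [
        int(pid) for pid in assignment["parcel_id"]
        if level_of[int(pid)] != "rejected"
    ]

    def load_subject(sub: str) -> dict[int, list[np.ndarray]]:
        per_parcel: dict[int, list[np.ndarray]] = {pid: [] for pid in parcel_ids}
        for r in range(layout.n_runs):
            data, _, _ = eio.read_nifti(indir / "movie" / f"{sub}_run-{r}.nii")
            for pid in parcel_ids:
                per_parcel[pid].append(data[parc == pid])
        return per_parcel

    def level_series_from(per_parcel) -> dict[str, np.ndarray]:
        parcel_z = {}
        for pid, runs in per_parcel.items():
            series = [
                ps.shift_series(ps.standardize_voxels(arr), halfwin=cfg.halfwin)
                for arr in runs
            ]
            parcel_z[pid] = ps.normalize_shift(series)
        return ps.level_average(parcel_z, level_of)

    subject_arrays = {sub: load_subject(sub) for sub in subjects}
    # group average of per-run standardized voxel data
    group: dict[int, list[np.ndarray]] = {}
    for pid in parcel_ids:
        group[pid] = []
        for r in range(layout.n_runs):
            stack = np.stack(
                [
                    ps.standardize_voxels(subject_arrays[sub][pid][r])
                    for sub in subjects
                ]
            )
            group[pid].append(ps.group_average(stack))
    group_series = level_series_from(
        {pid: [run for run in runs] for pid, runs in group.items()}
    )
    cbc_group = ps.cross_boundary_table(group_series, boundaries, win=cfg.cbc_win)
    subject_tables = []
    for sub in subjects:
        series = level_series_from(subject_arrays[sub])
        subject_tables.append(
            ps.cross_boundary_table(series, boundaries, win=cfg.cbc_win,
                                    subject=sub)
        )
    cbc_subjects = pd.concat(subject_tables, ignore_index=True)

    levels = sorted(group_series)
    eio.write_table(
        pd.DataFrame({lv: group_series[lv] for lv in levels}).rename_axis("tr"),
        outdir / "shift_series_group.tsv", index=True,
    )
    eio.write_table(cbc_group, outdir / "cbc_group.tsv")
    eio.write_table(cbc_subjects, outdir / "cbc_subjects.tsv")
    return group_series, cbc_group, cbc_subjects, subjects


def _safe(report_store: dict, key: str, fn, *args, **kwargs):
    try:
        report_store[key] = fn(*args, **kwargs)
    except (ValueError, RuntimeError) as exc:
        report_store[key] = {"skipped": str(exc)}


@_stage("stats")
def _run_stats(cfg, outdir: Path, layout, boundaries, cbc_group, cbc_subjects):
    retained = boundaries.loc[~boundaries["excluded"].astype(bool)]
    cat_of = retained["category"]
    agreement = retained["agreement"]
    levels = sorted(cbc_group["level"].unique())
    group_report: dict = {}
    for lv in levels:
        sub = cbc_group[cbc_group["level"] == lv].dropna(subset=["cbc"])
        vals = sub.set_index("boundary_id")["cbc"]
        cats = cat_of.reindex(vals.index)
        groups = [
            vals[cats == c].to_numpy() for c in seg.CATEGORIES
        ]
        rep: dict = {}
        _safe(rep, "shapiro", st.shapiro_gate, vals.to_numpy())
        if all(len(g) for g in groups):
            _safe(rep, "kruskal_wallis", st.kruskal_wallis, groups)
            _safe(rep, "dunn", st.dunn_pairwise, groups, list(seg.CATEGORIES))
        else:
            rep["kruskal_wallis"] = {"skipped": "empty strength category"}
        _safe(
            rep, "spearman_cbc_agreement", st.spearman,
            vals.to_numpy(), agreement.reindex(vals.index).to_numpy(),
        )
        group_report[lv] = rep

    subject_report: dict = {}
    bsv = st.between_subject_variance(cbc_subjects)
    for lv in levels:
        v = bsv[bsv["level"] == lv].dropna(subset=["variance"])
        cats = cat_of.reindex(v["boundary_id"]).to_numpy()
        rep = {}
        ok = ~pd.isna(cats)
        _safe(
            rep, "bayes_anova", st.bayes_anova_bf01,
            v["variance"].to_numpy()[ok], cats[ok],
        )
        # per-subject mean CBC per category -> repeated measures ANOVA
        sub = cbc_subjects[cbc_subjects["level"] == lv].copy()
        sub["category"] = cat_of.reindex(sub["boundary_id"]).to_numpy()
        cell = (
            sub.dropna(subset=["cbc", "category"])
            .groupby(["subject", "category"])["cbc"].mean().unstack()
        )
        cell = cell.reindex(columns=list(seg.CATEGORIES)).dropna()
        if len(cell) >= 2 and not cell.isna().any().any():
            _safe(rep, "rm_anova", st.rm_anova, cell.to_numpy())
        else:
            rep["rm_anova"] = {"skipped": "incomplete subject x category table"}
        # dip test per subject per category
        dips = []
        for (subject, cat), grp in sub.dropna(subset=["cbc", "category"]).groupby(
            ["subject", "category"]
        ):
            if len(grp) >= 4:
                d = st.dip_test(grp["cbc"].to_numpy(), n_boot=cfg.dip_n_boot,
                                seed=cfg.seed)
                dips.append({"subject": subject, "category": cat, **d})
        rep["dip_tests"] = dips
        subject_report[lv] = rep

    nb = st.sample_non_boundaries(
        layout, boundaries, per_run=cfg.nonboundary_per_run,
        min_sep=cfg.min_sep, tail_excl=cfg.nonboundary_tail_excl,
        seed=cfg.seed,
    )
    eio.write_table(nb, outdir / "nonboundary_points.tsv")
    eio.write_table(bsv, outdir / "between_subject_variance.tsv")
    (outdir / "group_stats.json").write_text(json.dumps(group_report, indent=1))
    (outdir / "subject_stats.json").write_text(
        json.dumps(subject_report, indent=1, default=str)
    )
    return nb


@_stage("alignment")
def _run_alignment(cfg, indir: Path, outdir: Path, layout, boundaries,
                   cbc_group, subjects):
    ind, dropped = al.indicator_matrix(cbc_group, level1_mode=cfg.level1_mode)
    scores = al.score_table(ind) if len(ind) else pd.DataFrame(
        columns=["strict", "nesting", "summation"]
    )
    out = scores.reset_index().merge(
        ind.reset_index(), on="boundary_id", how="left"
    )
    eio.write_table(out, outdir / "alignment.tsv")
    retained = boundaries.loc[~boundaries["excluded"].astype(bool)]
    agreement = retained["agreement"]
    align_report: dict = {"n_dropped": int(len(dropped))}
    for method in ("strict", "nesting", "summation"):
        _safe(
            align_report, f"spearman_{method}", al.alignment_vs_agreement,
            scores[method], agreement,
        )
    (outdir / "alignment_stats.json").write_text(
        json.dumps(align_report, indent=1)
    )

    # hippocampal boundary-locked responses
    mask, _, _ = eio.read_nifti(indir / "hippo_mask.nii")
    mask = mask > 0.5
    resp_rows = []
    for sub in subjects:
        runs = []
        for r in range(layout.n_runs):
            data, _, _ = eio.read_nifti(indir / "movie" / f"{sub}_run-{r}.nii")
            runs.append(data)
        series = al.roi_series(runs, mask)
        responses = al.boundary_locked(
            series, boundaries, layout, baseline=cfg.hippo_baseline
        )
        for _, row in responses.iterrows():
            resp_rows.append(
                {
                    "subject": sub,
                    "boundary_id": row["boundary_id"],
                    "summary": row["summary"],
                    "baseline_mode": cfg.hippo_baseline,
                }
            )
    resp = pd.DataFrame(resp_rows)
    hippo_report: dict = {}
    if len(resp):
        merged = resp.merge(
            scores.reset_index()[["boundary_id", "nesting"]], on="boundary_id",
            how="left",
        ).merge(
            retained.reset_index()[["index", "category"]].rename(
                columns={"index": "boundary_id"}
            ),
            on="boundary_id", how="left",
        )
        eio.write_table(merged, outdir / "hippo_responses.tsv")
        _safe(
            hippo_report, "by_nesting_score", al.grouped_response_tests,
            resp, scores["nesting"],
        )
        _safe(
            hippo_report, "by_strength", al.grouped_response_tests,
            resp, retained["category"],
        )
    (outdir / "hippo_stats.json").write_text(
        json.dumps(hippo_report, indent=1, default=str)
    )
    return align_report, hippo_report


def run_pipeline(config: eio.RunConfig | str | Path) -> dict:
    """Run every stage on the study in ``config.input_dir``.

    Returns a summary dict; all artifacts are written to
    ``config.output_dir``.
    """
    cfg = (
        config
        if isinstance(config, eio.RunConfig)
        else eio.RunConfig.from_yaml(config)
    )
    indir = Path(cfg.input_dir)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    layout, boundaries = _run_segmentation(cfg, indir, outdir)
    parc, assignment = _run_hierarchy(cfg, indir, outdir)
    group_series, cbc_group, cbc_subjects, subjects = _run_patternshift(
        cfg, indir, outdir, layout, boundaries, parc, assignment
    )
    _run_stats(cfg, outdir, layout, boundaries, cbc_group, cbc_subjects)
    _run_alignment(cfg, indir, outdir, layout, boundaries, cbc_group, subjects)

    provenance = {
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.content_hash(),
        "eventshift_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "python_version": platform.python_version(),
        "n_boundaries_retained": int((~boundaries["excluded"]).sum()),
        "n_boundaries_total": int(len(boundaries)),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return provenance
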