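"""Group- and individual-level statistics for cross-boundary correlations.

Every test returns a plain dict ("StatReport") with the test name,
statistic, degrees of freedom, raw and (where applicable) corrected
p-value and an effect size, so reports serialize directly to JSON/TSV.
"""
from __future__ import annotations

import functools
import itertools
import math

import numpy as np
import pandas as pd
from scipy import integrate, special
from scipy import stats as sps

from ._dip import dip_statistic
from .layout import SessionLayout

__all__ = [
    "shapiro_gate",
    "kruskal_wallis",
    "dunn_pairwise",
    "spearman",
    "between_subject_variance",
    "bayes_anova_bf01",
    "dip_test",
    "rm_anova",
    "paired_t",
    "sample_non_boundaries",
    "dip_statistic",
]


def _ranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def shapiro_gate(sample: np.ndarray, alpha: float = 0.05) -> dict:
    """Shapiro-Wilk normality gate.

    Used to log the rationale for the nonparametric route; the pipeline
    runs Kruskal-Wallis regardless of the outcome.
    """
    sample = np.asarray(sample, float)
    n = sample.size
    if n < 3 or n > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    w, p = sps.shapiro(sample)
    return {
        "test": "shapiro-wilk",
        "statistic": float(w),
        "n": int(n),
        "p": float(p),
        "verdict": "normal" if p >= alpha else "non-normal",
    }


def kruskal_wallis(groups: list[np.ndarray]) -> dict:
    """Kruskal-Wallis H with tie correction and rank eta-squared.

    Effect size: ``eta2 = (H - k + 1) / (N - k)``.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        raise ValueError("all values identical")
    ranks = _ranks(pooled)
    sizes = [g.size for g in groups]
    edges = np.cumsum([0] + sizes)
    rank_sums = [ranks[a:b].sum() for a, b in zip(edges[:-1], edges[1:])]
    h = 12.0 / (n_total * (n_total + 1)) * sum(
        rs**2 / n for rs, n in zip(rank_sums, sizes)
    ) - 3.0 * (n_total + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    h /= correction
    k = len(groups)
    df = k - 1
    p = float(sps.chi2.sf(h, df))
    return {
        "test": "kruskal-wallis",
        "statistic": float(h),
        "df": df,
        "n": int(n_total),
        "p": p,
        "eta2": float((h - k + 1) / (n_total - k)),
        "group_summaries": _summaries(groups),
    }


def dunn_pairwise(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    correction: str = "bonferroni",
) -> list[dict]:
    """Dunn's z-tests for all group pairs on the pooled ranks.

    ``z_ij = (meanrank_i - meanrank_j) / sqrt(V * (1/n_i + 1/n_j))``
    with the tie-corrected pooled variance
    ``V = N(N+1)/12 - T / (12 (N-1))``, ``T = sum(t^3 - t)``.
    Two-sided p-values are Bonferroni-multiplied by the number of
    pairs and capped at 1.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = _ranks(pooled)
    sizes = [g.size for g in groups]
    edges = np.cumsum([0] + sizes)
    mean_ranks = [ranks[a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    pooled_var = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    pairs = list(itertools.combinations(range(len(groups)), 2))
    reports = []
    for i, j in pairs:
        se = math.sqrt(pooled_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        if correction == "bonferroni":
            p_corr = min(1.0, p_raw * len(pairs))
        elif correction in (None, "none"):
            p_corr = p_raw
        else:
            raise ValueError(f"unknown correction {correction!r}")
        reports.append(
            {
                "test": "dunn",
                "pair": (labels[i], labels[j]),
                "statistic": float(z),
                "p": p_raw,
                "p_corrected": p_corr,
                "n_comparisons": len(pairs),
            }
        )
    return reports


def spearman(x: np.ndarray, y: np.ndarray) -> dict:
    """Spearman rank correlation with average ranks and t-approximate p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input")
    rho, p = sps.spearmanr(x, y)
    return {
        "test": "spearman",
        "rho": float(rho),
        "n": int(x.size),
        "df": int(x.size - 2),
        "p": float(p),
    }


def between_subject_variance(cbc: pd.DataFrame) -> pd.DataFrame:
    """Unbiased across-subject variance of CBC, per boundary and level.

    ``cbc`` is a long table with columns ``boundary_id``, ``level``,
    ``subject``, ``cbc``.  Cells with fewer than 2 defined subjects are
    NaN.
    """
    def _var(v):
        v = v.dropna()
        return v.var(ddof=1) if len(v) >= 2 else np.nan

    out = (
        cbc.groupby(["boundary_id", "level"])["cbc"]
        .apply(_var)
        .rename("variance")
        .reset_index()
    )
    return out


# --------------------------------------------------------------------------
# Bayesian one-way ANOVA (JZS default priors)
# --------------------------------------------------------------------------
def _bf10_oneway(values: np.ndarray, codes: np.ndarray, rscale: float) -> float:
    """JZS Bayes factor (alternative/null) for a one-way design.

    Effects receive the default g-prior on the sum-to-zero projected
    design, ``g ~ InverseGamma(1/2, rscale^2 / 2)``; the Bayes factor
    is computed by numerical integration over ``log g``.
    """
    n = values.size
    k = int(codes.max()) + 1
    z = np.zeros((n, k))
    z[np.arange(n), codes] = 1.0
    # orthonormal basis of the sum-to-zero space
    q, _ = np.linalg.qr(np.eye(k) - 1.0 / k, mode="reduced")
    x = z @ q[:, : k - 1]
    y = values - values.mean()
    x = x - x.mean(axis=0)
    xtx = x.T @ x
    xty = x.T @ y
    yty = float(y @ y)
    if yty == 0:
        raise ValueError("degenerate data: zero total variance")
    eigval, eigvec = np.linalg.eigh(xtx)
    b = eigvec.T @ xty
    a = rscale**2 / 2.0

    def log_integrand(u: float) -> float:
        g = math.exp(u)
        log_det = float(np.sum(np.log1p(g * eigval)))
        fitted = float(np.sum(b**2 * (g * eigval) / (eigval * (1.0 + g * eigval))))
        resid = max(yty - fitted, 1e-300)
        log_lik = -0.5 * log_det - 0.5 * (n - 1) * (
            math.log(resid) - math.log(yty)
        )
        # InvGamma(1/2, a) density in g, times dg/du = g
        log_prior = (
            0.5 * math.log(a) - special.gammaln(0.5) - 1.5 * u - a / g
        )
        return log_lik + log_prior + u

    # integrate over u = log(g), shifted by the peak for stability
    us = np.linspace(-30, 30, 121)
    peak = float(max(log_integrand(u) for u in us))
    val, _ = integrate.quad(
        lambda u: math.exp(log_integrand(u) - peak), -300, 300, limit=400
    )
    return float(val * math.exp(peak))


def bayes_anova_bf01(
    values: np.ndarray, group_labels: np.ndarray, rscale: float = 0.5
) -> dict:
    """Bayesian one-way ANOVA: evidence for the null over the group model.

    Uses the default JZS prior with fixed-effect Cauchy scale
    ``rscale`` (0.5 by default) and equal prior model odds.  Group
    summaries report posterior means and 95% credible intervals under a
    noninformative within-group prior (numerically these coincide with
    the sample means and t-based intervals).
    """
    values = np.asarray(values, float)
    labels = np.asarray(group_labels)
    if values.size != labels.size:
        raise ValueError("values and labels must align")
    uniq, codes = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("need >= 2 groups")
    if any((codes == c).sum() < 2 for c in range(uniq.size)):
        raise ValueError("each group needs >= 2 observations")
    bf10 = _bf10_oneway(values, codes, rscale)
    summaries = []
    for c, name in enumerate(uniq):
        g = values[codes == c]
        m, sd, n = float(g.mean()), float(g.std(ddof=1)), int(g.size)
        half = float(sps.t.ppf(0.975, n - 1) * sd / math.sqrt(n))
        summaries.append(
            {
                "group": str(name),
                "mean": m,
                "sd": sd,
                "n": n,
                "posterior_mean": m,
                "ci95": [m - half, m + half],
            }
        )
    return {
        "test": "bayes-anova",
        "bf01": float(1.0 / bf10),
        "bf10": float(bf10),
        "rscale": rscale,
        "group_summaries": summaries,
    }


# --------------------------------------------------------------------------
# Hartigan's dip test
# --------------------------------------------------------------------------
@functools.lru_cache(maxsize=64)
def _null_dips(n: int, n_boot: int, seed: int) -> tuple[float, ...]:
    rng = np.random.default_rng(seed)
    return tuple(
        dip_statistic(rng.uniform(size=n)) for _ in range(n_boot)
    )


def dip_test(sample: np.ndarray, n_boot: int = 10000, seed: int = 0) -> dict:
    """Hartigan's dip test with a seeded uniform bootstrap p-value.

    The null distribution of the dip for the sample's size is estimated
    from ``n_boot`` uniform samples; it is cached per ``(n, n_boot,
    seed)`` so repeated tests on equal-sized samples share one null.
    """
    sample = np.asarray(sample, float)
    n = sample.size
    if n < 4:
        raise ValueError("dip test requires n >= 4")
    d = dip_statistic(sample)
    null = np.asarray(_null_dips(n, n_boot, seed))
    p = float((np.sum(null >= d) + 1.0) / (n_boot + 1.0))
    return {"test": "hartigan-dip", "statistic": float(d), "n": int(n),
            "n_boot": int(n_boot), "p": p}


# --------------------------------------------------------------------------
# Repeated measures
# --------------------------------------------------------------------------
def rm_anova(table: pd.DataFrame | np.ndarray) -> dict:
    """One-way repeated-measures ANOVA on a subject x condition table.

    F has ``(k - 1, (k - 1)(n - 1))`` degrees of freedom; the effect
    size is the generalized eta squared
    ``SS_effect / (SS_effect + SS_subjects + SS_error)``.
    """
    arr = np.asarray(table, float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D subject x condition table")
    if np.isnan(arr).any():
        raise ValueError("missing cells in repeated-measures table")
    n, k = arr.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    grand = arr.mean()
    ss_subj = k * float(((arr.mean(axis=1) - grand) ** 2).sum())
    ss_cond = n * float(((arr.mean(axis=0) - grand) ** 2).sum())
    ss_total = float(((arr - grand) ** 2).sum())
    ss_err = ss_total - ss_subj - ss_cond
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_cond == 0:
        f = 0.0
    elif ms_err > 0:
        f = ms_cond / ms_err
    else:
        f = math.inf
    p = float(sps.f.sf(f, df1, df2)) if math.isfinite(f) else 0.0
    return {
        "test": "rm-anova",
        "statistic": float(f),
        "df": (df1, df2),
        "n": int(n),
        "p": p,
        "eta2_g": float(ss_cond / (ss_cond + ss_subj + ss_err)),
    }


def paired_t(
    a: np.ndarray, b: np.ndarray, n_comparisons: int = 1
) -> dict:
    """Paired t-test with optional Bonferroni multiplication."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need equal-length paired samples with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences")
    n = d.size
    t = float(d.mean() / (sd / math.sqrt(n)))
    p_raw = float(2.0 * sps.t.sf(abs(t), n - 1))
    return {
        "test": "paired-t",
        "statistic": t,
        "df": n - 1,
        "n": n,
        "p": p_raw,
        "p_corrected": min(1.0, p_raw * n_comparisons),
        "n_comparisons": n_comparisons,
    }


# --------------------------------------------------------------------------
# Non-boundary control sampler
# --------------------------------------------------------------------------
def sample_non_boundaries(
    layout: SessionLayout,
    boundaries: pd.DataFrame | None = None,
    per_run: int = 22,
    min_sep: float = 6.0,
    tail_excl: float = 10.0,
    exclude_near_boundaries: bool = True,
    seed: int = 0,
    max_tries: int = 20000,
) -> pd.DataFrame:
    """Pseudo-random non-boundary control time points, per run.

    Draws exactly ``per_run`` time points in each run, restricted to
    in-movie periods (title windows excluded), at least ``min_sep``
    seconds from every previously drawn point, outside the final
    ``tail_excl`` seconds of each run, and (by default) at least
    ``min_sep`` seconds from every retained boundary.
    """
    rng = np.random.default_rng(seed)
    if boundaries is not None and exclude_near_boundaries:
        b = boundaries.loc[~boundaries["excluded"].astype(bool), "time_s"]
        boundary_times = b.to_numpy(dtype=float)
    else:
        boundary_times = np.empty(0)
    titles = layout.title_windows()
    rows = []
    for run_idx, run in enumerate(layout.runs):
        start = float(layout.run_starts[run_idx])
        end = start + float(layout.run_durations[run_idx])
        hard_end = end - tail_excl
        chosen: list[float] = []
        tries = 0
        while len(chosen) < per_run:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    f"could not place {per_run} non-boundary points in run "
                    f"{run_idx} after {max_tries} tries"
                )
            t = rng.uniform(start, hard_end)
            if any(lo <= t < hi for lo, hi in titles):
                continue
            if any(abs(t - c) < min_sep for c in chosen):
                continue
            if boundary_times.size and np.any(np.abs(boundary_times - t) < min_sep):
                continue
            chosen.append(t)
        for t in sorted(chosen):
            rows.append({"run": run_idx, "time_s": t})
    df = pd.DataFrame(rows)
    df["tr_index"] = [
        layout.seconds_to_tr(t, hrf_shift=3) for t in df["time_s"]
    ]
    return df


def _summaries(groups: list[np.ndarray]) -> list[dict]:
    return [
        {
            "mean": float(np.mean(g)),
            "sd": float(np.std(g, ddof=1)) if g.size > 1 else 0.0,
            "n": int(g.size),
        }
        for g in groups
    ]
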