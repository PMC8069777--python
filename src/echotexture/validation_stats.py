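"""Validation battery for IMF prediction cohorts.

Receiver-operating-characteristic analysis with the Youden-optimal cutoff
and a DeLong confidence interval, Bland–Altman agreement limits,
Kruskal–Wallis with Bonferroni-corrected Dunn post-hoc comparisons, and
per-group agreement summaries.

Sign convention: Bland–Altman differences are ``IMFqa - IMFpred``
(chemical ground truth minus ultrasound prediction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .imf_model import CohortRecord, GroupingScheme, assign_group, cohort_frame

__all__ = [
    "ROCResult",
    "BlandAltmanResult",
    "KruskalWallisResult",
    "AgreementSummary",
    "roc_analysis",
    "bland_altman",
    "kruskal_wallis",
    "summarize",
    "validation_report",
    "save_figures",
]


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    auc: float
    auc_ci95: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    lr_plus: float
    curve: np.ndarray  # (n_points, 2) of (1 - specificity, sensitivity)


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the Mann-Whitney statistic with midranks for ties."""
    all_scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(all_scores)
    r_pos = ranks[: len(pos)].sum()
    m, n = len(pos), len(neg)
    return float((r_pos - m * (m + 1) / 2) / (m * n))


def _delong_variance(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    """DeLong variance of the AUC via structural components."""
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    tx = stats.rankdata(all_scores)
    v10 = (tx[:m] - stats.rankdata(pos)) / n          # per-positive placement
    v01 = 1.0 - (tx[m:] - stats.rankdata(neg)) / m    # per-negative placement
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_analysis(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """Empirical ROC of ``scores`` for binary ``labels`` (positive when 1).

    A sample is called positive when its score is at or above the threshold.
    The AUC is the Mann-Whitney statistic (trapezoid-equivalent under the
    midrank tie convention); the reported cutoff maximizes Youden's
    J = sensitivity + specificity - 1, ties broken toward the lower
    threshold; the 95% CI uses DeLong's method.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels).astype(int)
    if s.shape != lab.shape:
        raise ValueError("scores and labels must have equal length")
    pos = s[lab == 1]
    neg = s[lab == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ROC analysis needs both classes to be non-empty")

    auc = _mann_whitney_auc(pos, neg)
    var = _delong_variance(pos, neg, auc)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    thresholds = np.unique(s)  # ascending; rule is score >= threshold
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax takes the first (lowest) threshold on ties
    # curve from (0,0) to (1,1): thresholds descending
    fpr = np.concatenate([[0.0], (1.0 - spec)[::-1], [1.0]])
    tpr = np.concatenate([[0.0], sens[::-1], [1.0]])
    curve = np.column_stack([fpr, tpr])

    se, sp = float(sens[best]), float(spec[best])
    lr_plus = float(se / (1.0 - sp)) if sp < 1.0 else float("inf")
    return ROCResult(
        auc=auc,
        auc_ci95=ci,
        cutoff=float(thresholds[best]),
        sensitivity=se,
        specificity=sp,
        lr_plus=lr_plus,
        curve=curve,
    )


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    upper_limit: float
    lower_limit: float
    differences: np.ndarray


def bland_altman(qa: Sequence[float], pred: Sequence[float]) -> BlandAltmanResult:
    """Limits of agreement: mean(qa - pred) +/- 1.96 SD (sample SD, n-1)."""
    qa = np.asarray(qa, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if qa.shape != pred.shape:
        raise ValueError("qa and pred must have equal length")
    if qa.size < 2:
        raise ValueError("Bland-Altman needs at least two pairs")
    d = qa - pred
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        upper_limit=mean + 1.96 * sd,
        lower_limit=mean - 1.96 * sd,
        differences=d,
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis with Dunn post-hoc
# ---------------------------------------------------------------------------

@dataclass
class KruskalWallisResult:
    h_statistic: float
    df: int
    p_value: float
    pairwise: dict[tuple[int, int], float] = field(default_factory=dict)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalWallisResult:
    """Tie-corrected Kruskal-Wallis H with Bonferroni-adjusted Dunn tests.

    Pairwise keys are 0-based group indices; adjusted p-values are
    ``min(1, raw * k(k-1)/2)``.  A pooled sample with no variation yields
    H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    k = len(groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return KruskalWallisResult(h_statistic=0.0, df=k - 1, p_value=1.0,
                                   pairwise={pair: 1.0 for pair in combinations(range(k), 2)})
    h, p = stats.kruskal(*groups)

    # Dunn z-tests on the pooled midranks, with the tie correction term
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(k)]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = k * (k - 1) // 2
    pairwise = {}
    for i, j in combinations(range(k), 2):
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = abs(mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        raw = 2.0 * stats.norm.sf(z)
        pairwise[(i, j)] = min(1.0, raw * n_pairs)
    return KruskalWallisResult(h_statistic=float(h), df=k - 1, p_value=float(p),
                               pairwise=pairwise)


# ---------------------------------------------------------------------------
# agreement summaries
# ---------------------------------------------------------------------------

@dataclass
class AgreementSummary:
    r_squared: float
    overall: pd.DataFrame      # rows mean/sd/min/max, columns IMFqa/IMFpred
    per_group: pd.DataFrame    # MultiIndex (group, stat) x columns


def _stat_table(df: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "IMFqa": [df["IMFqa"].mean(), df["IMFqa"].std(ddof=1),
                      df["IMFqa"].min(), df["IMFqa"].max()],
            "IMFpred": [df["IMFpred"].mean(), df["IMFpred"].std(ddof=1),
                        df["IMFpred"].min(), df["IMFpred"].max()],
        },
        index=["mean", "sd", "min", "max"],
    )


def summarize(
    cohort: Sequence[CohortRecord],
    scheme: GroupingScheme | None = None,
) -> AgreementSummary:
    """Overall and per-group summaries plus R2 between IMFqa and IMFpred.

    R2 is the squared Pearson correlation; if either series is constant the
    correlation is undefined and R2 is reported as 0 with a warning.
    """
    if not len(cohort):
        raise ValueError("cohort must be non-empty")
    scheme = scheme or GroupingScheme.printed()
    df = cohort_frame(cohort)
    df["group"] = [assign_group(v, scheme) for v in df["IMFqa"]]
    if df["IMFqa"].nunique() < 2 or df["IMFpred"].nunique() < 2:
        warnings.warn("correlation undefined on constant input; reporting R2 = 0")
        r2 = 0.0
    else:
        r = float(np.corrcoef(df["IMFqa"], df["IMFpred"])[0, 1])
        r2 = r * r
    per_group = pd.concat(
        {g: _stat_table(sub) for g, sub in df.groupby("group")},
        names=["group", "stat"],
    )
    return AgreementSummary(r_squared=r2, overall=_stat_table(df), per_group=per_group)


def validation_report(
    cohort: Sequence[CohortRecord],
    scheme: GroupingScheme | None = None,
) -> dict:
    """Run the full battery on a cohort and collect a JSON-serializable report."""
    scheme = scheme or GroupingScheme.printed()
    df = cohort_frame(cohort)
    summary = summarize(cohort, scheme)
    # discrimination task: group 1 vs groups 2+3, i.e. positive iff IMFqa
    # exceeds the low cutoff
    labels = (df["IMFqa"] > scheme.low_cutoff).astype(int)
    roc = roc_analysis(df["IMFpred"], labels)
    ba = bland_altman(df["IMFqa"], df["IMFpred"])
    group_vals = [df.loc[df["group"] == g, "IMFqa"].to_numpy() for g in (1, 2, 3)
                  if (df["group"] == g).any()]
    kw = kruskal_wallis(group_vals) if len(group_vals) >= 2 else None
    report = {
        "n": int(len(df)),
        "r_squared": summary.r_squared,
        "roc": {
            "auc": roc.auc,
            "auc_ci95": list(roc.auc_ci95),
            "cutoff": roc.cutoff,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
            "lr_plus": roc.lr_plus,
        },
        "bland_altman": {
            "mean_diff": ba.mean_diff,
            "sd_diff": ba.sd_diff,
            "upper_limit": ba.upper_limit,
            "lower_limit": ba.lower_limit,
        },
        "overall": summary.overall.to_dict(),
        "per_group": {f"{g}.{s}": row.to_dict()
                      for (g, s), row in summary.per_group.iterrows()},
    }
    if kw is not None:
        report["kruskal_wallis"] = {
            "h": kw.h_statistic,
            "df": kw.df,
            "p": kw.p_value,
            "pairwise_bonferroni": {f"{i + 1}-{j + 1}": p for (i, j), p in kw.pairwise.items()},
        }
    return report


def save_figures(cohort: Sequence[CohortRecord], outdir: str | Path,
                 scheme: GroupingScheme | None = None) -> list[Path]:
    """Scatter (with identity line), ROC, and Bland-Altman figures as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scheme = scheme or GroupingScheme.printed()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = cohort_frame(cohort)
    paths = []

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(df["IMFqa"], df["IMFpred"], s=12, alpha=0.6)
    lims = [min(df["IMFqa"].min(), df["IMFpred"].min()),
            max(df["IMFqa"].max(), df["IMFpred"].max())]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("IMFqa (%)")
    ax.set_ylabel("IMFpred (%)")
    p = outdir / "scatter.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    labels = (df["IMFqa"] > scheme.low_cutoff).astype(int)
    roc = roc_analysis(df["IMFpred"], labels)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(roc.curve[:, 0], roc.curve[:, 1], lw=1.5)
    ax.plot([0, 1], [0, 1], "k:", lw=1)
    ax.plot(1 - roc.specificity, roc.sensitivity, "ro", ms=6,
            label=f"cutoff {roc.cutoff:.2f}")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {roc.auc:.4f}")
    ax.legend()
    p = outdir / "roc.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    ba = bland_altman(df["IMFqa"], df["IMFpred"])
    means = (df["IMFqa"] + df["IMFpred"]) / 2
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, ba.differences, s=12, alpha=0.6)
    for y, style in ((ba.mean_diff, "-"), (ba.upper_limit, "--"), (ba.lower_limit, "--")):
        ax.axhline(y, color="r", ls=style, lw=1)
    ax.set_xlabel("mean of IMFqa and IMFpred (%)")
    ax.set_ylabel("IMFqa - IMFpred (%)")
    p = outdir / "bland_altman.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
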