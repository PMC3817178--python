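"""Marker-level confirmation analyses.

Operations that validate a single candidate gene outside the factorization:
probe-level differential expression between tumor groups and normal tissue
(Welch one-sided t per probe, minimum p per gene), an outlier rule flagging
tumors whose expression exceeds the normal range by a log fold-change
margin, delta-Ct statistics for qPCR validation cohorts, and t-tests on
log-transformed normalized read counts for sequencing cohorts.

Welch (unequal-variance) t-tests are used throughout; a pooled-variance
variant is available via ``equal_var=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MarkerReport",
    "probe_differential",
    "outlier_overexpression",
    "delta_ct",
    "group_t_log_counts",
]


@dataclass
class MarkerReport:
    """Per-gene marker summary across probes and group contrasts."""

    gene: str
    probe_p: pd.DataFrame  # probe x contrast one-sided p
    min_p: pd.Series  # per contrast, minimum over probes
    log_fold_change: pd.Series  # per contrast, group mean - normal mean
    outlier_counts: dict = field(default_factory=dict)


def _welch_one_sided(x: np.ndarray, y: np.ndarray, side: str, equal_var: bool) -> float:
    """p for the alternative mean(x) > mean(y) (side='one') or two-sided."""
    alt = "greater" if side == "one" else "two-sided"
    res = stats.ttest_ind(x, y, equal_var=equal_var, alternative=alt)
    return float(res.pvalue)


def probe_differential(
    probe_expr: pd.DataFrame,
    groups: pd.Series,
    normal_label: str = "normal",
    side: str = "one",
    gene: str = "",
    equal_var: bool = False,
) -> MarkerReport:
    """Probe-level differential expression of one gene versus normal.

    ``probe_expr`` is probes x samples (log scale); ``groups`` maps sample
    id to group label.  Each non-normal group is contrasted against the
    normal samples probe by probe; the per-gene summary is the minimum p
    across probes and the fold change is the difference of group means on
    the log scale.
    """
    groups = pd.Series(groups)
    samples = [s for s in probe_expr.columns if s in groups.index]
    probe_expr = probe_expr[samples]
    groups = groups.loc[samples]
    normal = probe_expr.loc[:, groups == normal_label]
    if normal.shape[1] < 2:
        raise ValueError("need >= 2 normal samples")
    contrasts = [g for g in groups.unique() if g != normal_label]
    p_rows = {}
    lfc = {}
    for g in contrasts:
        grp = probe_expr.loc[:, groups == g]
        if grp.shape[1] < 2:
            raise ValueError(f"group {g!r} has a single sample")
        pvals = [
            _welch_one_sided(grp.loc[pr].to_numpy(), normal.loc[pr].to_numpy(), side, equal_var)
            for pr in probe_expr.index
        ]
        p_rows[g] = pvals
        lfc[g] = float(grp.to_numpy().mean() - normal.to_numpy().mean())
    probe_p = pd.DataFrame(p_rows, index=probe_expr.index)
    return MarkerReport(
        gene=gene,
        probe_p=probe_p,
        min_p=probe_p.min(axis=0),
        log_fold_change=pd.Series(lfc),
    )


def outlier_overexpression(
    values: pd.Series,
    normal_samples,
    groups: pd.Series | None = None,
    threshold_log_fc: float = 0.5,
) -> tuple[pd.Series, dict[str, int]]:
    """Flag samples expressing above the normal range plus a margin.

    A sample is flagged iff its (log-scale) value is at least
    ``max(normal values) + threshold_log_fc`` — the boundary is inclusive.
    Returns the per-sample boolean flags (normal samples excluded) and,
    when ``groups`` is given, the count of flagged samples per group.
    """
    normal_samples = list(normal_samples)
    if len(normal_samples) < 2:
        raise ValueError("need >= 2 normal samples")
    cutoff = float(values.loc[normal_samples].max()) + threshold_log_fc
    rest = values.drop(index=normal_samples)
    flags = rest >= cutoff
    counts: dict[str, int] = {}
    if groups is not None:
        groups = pd.Series(groups)
        for g in groups.loc[flags.index].unique():
            counts[g] = int(flags[groups.loc[flags.index] == g].sum())
    return flags, counts


def delta_ct(
    ct_table: pd.DataFrame,
    groups: pd.Series | None = None,
    normal_label: str = "normal",
    side: str = "one",
    equal_var: bool = False,
) -> dict:
    """Relative expression from qPCR cycle thresholds.

    ``ct_table`` needs columns ``sample_id``, ``ct_target``,
    ``ct_reference`` (and ``group`` unless ``groups`` is given).  Per
    sample, dCt = ct_target - ct_reference; ddCt = mean dCt(tumor) - mean
    dCt(normal); fold change = 2**(-ddCt).  Lower dCt means higher target
    expression, so the one-sided test for overexpression in tumors is
    dCt(tumor) < dCt(normal).  Samples missing a reference Ct are dropped
    with a warning.
    """
    df = ct_table.copy()
    if groups is None:
        groups = df.set_index("sample_id")["group"]
    groups = pd.Series(groups)
    missing = df["ct_reference"].isna() | df["ct_target"].isna()
    if missing.any():
        warnings.warn(f"dropped {int(missing.sum())} samples with missing Ct values")
        df = df[~missing]
    df = df.assign(delta_ct=df["ct_target"] - df["ct_reference"]).set_index("sample_id")
    grp = groups.loc[df.index]
    d_norm = df.loc[grp == normal_label, "delta_ct"].to_numpy()
    d_tum = df.loc[grp != normal_label, "delta_ct"].to_numpy()
    if len(d_norm) < 2 or len(d_tum) < 2:
        raise ValueError("need >= 2 samples per group")
    ddct = float(d_tum.mean() - d_norm.mean())
    alt = "less" if side == "one" else "two-sided"  # overexpression: lower dCt
    p = float(stats.ttest_ind(d_tum, d_norm, equal_var=equal_var, alternative=alt).pvalue)
    return {
        "delta_ct": df["delta_ct"],
        "delta_delta_ct": ddct,
        "fold_change": float(2.0 ** (-ddct)),
        "p": p,
    }


def group_t_log_counts(
    counts: pd.DataFrame,
    groups: pd.Series,
    pseudo: float = 1.0,
    side: str = "two",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene t-test on log(count + pseudo) between two groups.

    ``counts`` is genes x samples of non-negative normalized counts;
    ``groups`` must have exactly two levels (first sorted level is the
    baseline; one-sided tests the second level higher).  Genes with zero
    variance in both groups (e.g. all-zero genes) get p = NaN and a flag.
    """
    if pseudo <= 0:
        raise ValueError("pseudo-count must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    groups = pd.Series(groups).loc[counts.columns]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    log_counts = np.log(counts.to_numpy(float) + pseudo)
    a = log_counts[:, (groups == levels[1]).to_numpy()]
    b = log_counts[:, (groups == levels[0]).to_numpy()]
    alt = "greater" if side == "one" else "two-sided"
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var, alternative=alt)
    p = np.asarray(res.pvalue, dtype=float)
    p[degenerate] = np.nan
    return pd.DataFrame(
        {
            "estimate": a.mean(axis=1) - b.mean(axis=1),
            "p": p,
            "degenerate": degenerate,
        },
        index=counts.index,
    )
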