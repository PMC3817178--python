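"""Clinical association of meta-pathway activity, and the clustering comparator.

Two routes to link patterns with phenotypes:

* linear models — each pattern's activity is regressed on one or more
  categorical clinical covariates by ordinary least squares; each non-
  reference level yields a contrast with a one-sided (or two-sided) p-value
  from its t statistic, adjusted family-wise across the simultaneous
  contrasts of that pattern (Bonferroni by default, Holm available);
* hierarchical clustering — samples are clustered on 1 - Pearson
  correlation distance, the tree is cut at k = 2..6, and each cut is tested
  against a clinical variable with a Fisher exact test (exact enumeration
  for small tables, seeded Monte-Carlo permutation otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "associate",
    "cluster_samples",
    "cluster_phenotype_test",
    "validate_clinical",
]

DEFAULT_K_RANGE = range(2, 7)
MC_DRAWS = 100_000
EXACT_TOTAL_LIMIT = 30


@dataclass(frozen=True)
class AssociationResult:
    meta_pathway: str
    contrast: str
    estimate: float
    one_sided_p: float
    adjusted_p: float
    model: str  # univariate | multivariate


def validate_clinical(clinical: pd.DataFrame, sample_ids) -> pd.DataFrame:
    """Index the clinical table by sample_id and align it to the activity."""
    df = clinical.copy()
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    if df.index.duplicated().any():
        raise ValueError("duplicate sample ids in clinical table")
    missing = [s for s in sample_ids if s not in df.index]
    if missing:
        raise ValueError(f"clinical table missing samples: {missing[:5]}")
    return df.loc[list(sample_ids)]


def _design(
    clinical: pd.DataFrame, covariates: list[str], encoding: str
) -> list[tuple[np.ndarray, list[str]]]:
    """Build one or more (design matrix, contrast names) pairs.

    ``reference`` encoding fits a single model with dummies against the
    first sorted level of each covariate.  ``one_vs_rest`` fits one
    univariate model per covariate level (indicator of that level), which
    tests "activity higher in this phenotype than in everything else".
    """
    for cov in covariates:
        values = clinical[cov].astype(str)
        if values.nunique() < 2:
            raise ValueError(f"covariate {cov!r} has fewer than 2 levels")
        counts = values.value_counts()
        if (counts < 3).any():
            small = counts[counts < 3].index.tolist()
            raise ValueError(f"covariate {cov!r} levels with < 3 samples: {small}")
    if encoding == "one_vs_rest":
        designs = []
        for cov in covariates:
            values = clinical[cov].astype(str)
            for lv in sorted(values.unique()):
                X = np.column_stack([np.ones(len(clinical)), (values == lv).to_numpy(float)])
                designs.append((X, ["intercept", f"{cov}[{lv} vs rest]"]))
        return designs
    cols = [np.ones(len(clinical))]
    names = ["intercept"]
    for cov in covariates:
        values = clinical[cov].astype(str)
        levels = sorted(values.unique())
        for lv in levels[1:]:  # first sorted level is the reference
            cols.append((values == lv).to_numpy(float))
            names.append(f"{cov}[{lv} vs {levels[0]}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"singular design: collinear covariates among {covariates}")
    return [(X, names)]


def associate(
    activity,
    clinical: pd.DataFrame,
    covariates: list[str],
    side: str = "one",
    adjust: str = "bonferroni",
    encoding: str = "reference",
) -> pd.DataFrame:
    """OLS of each pattern's activity on clinical covariates.

    ``activity`` is a pattern x sample DataFrame (e.g. the ``rescaled``
    attribute of :class:`~metapathways.activity.MetaPathwayActivity`) or an
    object exposing one.  One-sided p-values test for *higher* activity in
    the contrast level; the family-wise adjustment spans all simultaneous
    contrasts of one pattern.  ``encoding="one_vs_rest"`` tests each
    covariate level against all remaining samples in its own univariate
    model instead of dummy coding against a reference level.  Returns one
    row per (pattern, contrast).
    """
    if side not in ("one", "two"):
        raise ValueError("side must be 'one' or 'two'")
    if adjust not in ("bonferroni", "holm"):
        raise ValueError("adjust must be 'bonferroni' or 'holm'")
    if encoding not in ("reference", "one_vs_rest"):
        raise ValueError("encoding must be 'reference' or 'one_vs_rest'")
    act = getattr(activity, "rescaled", activity)
    act = pd.DataFrame(act)
    clin = validate_clinical(clinical, act.columns)
    designs = _design(clin, covariates, encoding)
    model_kind = "univariate" if len(covariates) == 1 else "multivariate"

    rows = []
    for pat_id, y_row in act.iterrows():
        y = y_row.to_numpy(float)
        fam_names: list[str] = []
        fam_est: list[float] = []
        fam_p: list[float] = []
        for X, names in designs:
            n, q = X.shape
            df_resid = n - q
            if df_resid <= 0:
                raise ValueError("not enough samples for the design")
            if np.ptp(y) == 0.0:  # constant activity: nothing to test
                fam_names += names[1:]
                fam_est += [0.0] * (q - 1)
                fam_p += [1.0] * (q - 1)
                continue
            XtX_inv = np.linalg.inv(X.T @ X)
            beta = XtX_inv @ (X.T @ y)
            resid = y - X @ beta
            s2 = float(resid @ resid) / df_resid
            se = np.sqrt(np.maximum(s2 * np.diag(XtX_inv), 0.0))
            for j in range(1, q):
                fam_names.append(names[j])
                fam_est.append(float(beta[j]))
                if se[j] == 0:
                    fam_p.append(1.0 if beta[j] <= 0 else 0.0)
                elif side == "one":
                    fam_p.append(float(stats.t.sf(beta[j] / se[j], df_resid)))
                else:
                    fam_p.append(float(2 * stats.t.sf(abs(beta[j]) / se[j], df_resid)))
        adj = np.maximum(multipletests(fam_p, method=adjust)[1], fam_p)
        for nm, est, p, ap in zip(fam_names, fam_est, fam_p, adj):
            rows.append((str(pat_id), nm, est, p, float(ap), model_kind))
    return pd.DataFrame(
        rows,
        columns=["meta_pathway", "contrast", "estimate", "one_sided_p", "adjusted_p", "model"],
    )


def cluster_samples(
    X, k_range=DEFAULT_K_RANGE, linkage_method: str = "average"
) -> dict[int, np.ndarray]:
    """Cut the correlation-distance tree of samples at each k.

    ``X`` is rows (genes) x samples; distance between two samples is
    1 - Pearson correlation of their columns.  Returns k -> integer labels
    (1-based, scipy convention) in input sample order.
    """
    M = pd.DataFrame(X).to_numpy(float)
    m = M.shape[1]
    ks = list(k_range)
    if m < max(ks):
        raise ValueError("more clusters requested than samples")
    sd = M.std(axis=0)
    if np.any(sd == 0):
        bad = np.where(sd == 0)[0].tolist()
        raise ValueError(f"zero-variance sample columns: {bad} (correlation undefined)")
    corr = np.corrcoef(M, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    return {k: hierarchy.fcluster(Z, t=k, criterion="maxclust") for k in ks}


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (the route used by
    :func:`cluster_phenotype_test` for 2x2 contingencies)."""
    T = np.asarray(table, dtype=int)
    if T.shape != (2, 2):
        raise ValueError("table must be 2x2")
    return float(stats.fisher_exact(T, alternative="two-sided")[1])


def _log_table_prob(table: np.ndarray) -> float:
    """Log probability of an r x c table under fixed margins (generalized
    hypergeometric)."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
        - gammaln(n + 1) - gammaln(table + 1).sum()
    )


def _enumerate_exact_p(table: np.ndarray) -> float:
    """Exact Fisher p by recursive enumeration of all tables with the
    observed margins: p = total probability of tables no more probable than
    the observed one."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    obs_lp = _log_table_prob(table)
    r, c = table.shape
    total_p = 0.0

    def recurse(i: int, remaining_cols: np.ndarray, partial: list[np.ndarray]) -> None:
        nonlocal total_p
        if i == r - 1:  # last row forced by column margins
            last = remaining_cols.copy()
            if np.any(last < 0):
                return
            t = np.vstack(partial + [last])
            lp = _log_table_prob(t)
            if lp <= obs_lp + 1e-9:
                total_p += np.exp(lp)
            return
        def fill(j: int, left: int, row: list[int]) -> None:
            if j == c - 1:
                if left <= remaining_cols[j]:
                    full = np.array(row + [left])
                    recurse(i + 1, remaining_cols - full, partial + [full])
                return
            for v in range(min(left, int(remaining_cols[j])) + 1):
                fill(j + 1, left - v, row + [v])
        fill(0, int(rows[i]), [])

    recurse(0, cols.astype(int), [])
    return min(total_p, 1.0)


def cluster_phenotype_test(
    labels,
    phenotype,
    n_mc: int = MC_DRAWS,
    seed: int = 0,
    exact_total_limit: int = EXACT_TOTAL_LIMIT,
) -> tuple[float, str]:
    """Fisher exact association of a clustering with a clinical variable.

    Builds the cluster x phenotype contingency table.  2x2 tables use the
    exact hypergeometric two-sided test; larger tables use exact
    enumeration when the total count allows it and otherwise a seeded
    Monte-Carlo permutation null on the table probability.  Degenerate
    tables (a single cluster or a single phenotype level) give p = 1 with
    a warning.  Returns ``(p, method)`` where method is one of
    ``"exact_2x2" | "exact_enum" | "monte_carlo" | "degenerate"``.
    """
    labels = np.asarray(labels)
    phenotype = np.asarray(phenotype)
    if labels.shape != phenotype.shape:
        raise ValueError("labels and phenotype lengths differ")
    tab = pd.crosstab(pd.Series(labels, name="cluster"), pd.Series(phenotype, name="phenotype"))
    tab = tab.loc[(tab.sum(axis=1) > 0), (tab.sum(axis=0) > 0)]
    T = tab.to_numpy(int)
    if T.shape[0] < 2 or T.shape[1] < 2:
        warnings.warn("degenerate contingency margins; returning p = 1")
        return 1.0, "degenerate"
    if T.shape == (2, 2):
        return fisher_exact_2x2(T), "exact_2x2"
    if T.sum() <= exact_total_limit:
        return _enumerate_exact_p(T), "exact_enum"
    # Monte-Carlo: permute phenotype labels, compare table probabilities
    rng = np.random.default_rng(seed)
    lab_codes = pd.factorize(np.asarray(labels))[0]
    phe_codes = pd.factorize(np.asarray(phenotype))[0]
    r = lab_codes.max() + 1
    c = phe_codes.max() + 1
    obs = np.bincount(lab_codes * c + phe_codes, minlength=r * c).reshape(r, c)
    obs_lp = _log_table_prob(obs)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(phe_codes)
        t = np.bincount(lab_codes * c + perm, minlength=r * c).reshape(r, c)
        if _log_table_prob(t) <= obs_lp + 1e-9:
            hits += 1
    return (1.0 + hits) / (n_mc + 1.0), "monte_carlo"
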