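"""Probe-level methylation processing and stacked-matrix assembly.

Converts paired methylated/unmethylated (M/U) probe intensities to beta
values, applies the CpG-count probe filter, summarizes probes to gene level
(maximum beta per gene for methylation, mean estimate per gene for
expression), and stacks expression over log-transformed methylation into a
single data matrix D with a per-element uncertainty matrix Sigma.

Uncertainty model: expression uncertainties are 10% of the signal;
methylation uncertainties come from a normal approximation to the beta
distribution, sd(beta) = sqrt(beta(1-beta)/(1+kappa)), transferred to the
log scale by the delta method.  Both are floored to keep the chi-squared
likelihood bounded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeRecord",
    "CombinedDataset",
    "compute_beta",
    "filter_probes",
    "summarize_methylation",
    "summarize_expression",
    "build_combined",
    "read_matrix_tsv",
    "read_probe_tsv",
]

DEFAULT_OFFSET = 100.0
DEFAULT_EPSILON = 1e-3
DEFAULT_SIGMA_FLOOR = 0.01
DEFAULT_KAPPA = 100.0


@dataclass(frozen=True)
class ProbeRecord:
    """One methylation probe: paired M/U intensities for one CpG region."""

    probe_id: str
    gene: str
    n_cpg: int
    M: float
    U: float


@dataclass
class CombinedDataset:
    """Stacked expression + methylation matrix with uncertainties.

    Rows partition into a contiguous expression block (label ``"E"``)
    followed by a contiguous methylation block (label ``"M"``).
    """

    D: np.ndarray
    Sigma: np.ndarray
    block_of_row: np.ndarray  # "E" or "M" per row
    gene_of_row: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        self.block_of_row = np.asarray(self.block_of_row)
        self.gene_of_row = np.asarray(self.gene_of_row)
        if self.D.shape != self.Sigma.shape:
            raise ValueError("D and Sigma shapes differ")
        if self.D.shape[1] < 2:
            raise ValueError("need at least 2 samples")
        if len(self.sample_ids) != self.D.shape[1]:
            raise ValueError("sample_ids length mismatch")
        if np.any(self.Sigma <= 0):
            raise ValueError("Sigma must be strictly positive")
        labels = list(self.block_of_row)
        n_e = labels.count("E")
        if labels != ["E"] * n_e + ["M"] * (len(labels) - n_e):
            raise ValueError("rows must form a contiguous E block then an M block")

    @property
    def n_expr(self) -> int:
        return int(np.sum(self.block_of_row == "E"))

    @property
    def n_meth(self) -> int:
        return int(np.sum(self.block_of_row == "M"))

    def block(self, label: Literal["E", "M"]) -> np.ndarray:
        return self.D[self.block_of_row == label]


def compute_beta(
    M: float | np.ndarray, U: float | np.ndarray, offset: float = DEFAULT_OFFSET
) -> float | np.ndarray:
    """Methylation fraction beta = max(M,0) / (max(M,0) + max(U,0) + offset).

    Negative intensities (background-subtraction artifacts) are clamped at
    zero.  Scalar in, scalar out; arrays are processed elementwise.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    scalar = np.isscalar(M) and np.isscalar(U)
    Mc = np.maximum(np.asarray(M, dtype=float), 0.0)
    Uc = np.maximum(np.asarray(U, dtype=float), 0.0)
    denom = Mc + Uc + offset
    if np.any(denom == 0):
        raise ValueError("undefined beta: M = U = offset = 0")
    beta = Mc / denom
    return float(beta) if scalar else beta


def filter_probes(
    probes: Iterable[ProbeRecord] | pd.DataFrame, min_cpg: int = 3
):
    """Keep probes interrogating at least ``min_cpg`` CpG sites, in order."""
    if isinstance(probes, pd.DataFrame):
        return probes[probes["n_cpg"] >= min_cpg].copy()
    return [pr for pr in probes if pr.n_cpg >= min_cpg]


def summarize_methylation(beta_by_probe: pd.DataFrame) -> pd.DataFrame:
    """Gene-level beta = the maximum beta over all probes annotated to a gene.

    Parameters
    ----------
    beta_by_probe
        Long table with columns ``gene``, ``sample_id``, ``beta``.

    Returns
    -------
    gene x sample matrix of beta values (genes with no probes are absent).
    """
    if beta_by_probe.empty:
        return pd.DataFrame()
    wide = beta_by_probe.pivot_table(
        index="gene", columns="sample_id", values="beta", aggfunc="max"
    )
    wide.columns.name = None
    wide.index.name = "gene"
    return wide


def summarize_expression(estimates_by_probe: pd.DataFrame) -> pd.DataFrame:
    """Gene-level expression = arithmetic mean of probe-level estimates.

    ``estimates_by_probe``: long table with ``gene``, ``sample_id``,
    ``value`` columns.  Returns a gene x sample matrix.
    """
    if estimates_by_probe.empty:
        return pd.DataFrame()
    wide = estimates_by_probe.pivot_table(
        index="gene", columns="sample_id", values="value", aggfunc="mean"
    )
    wide.columns.name = None
    wide.index.name = "gene"
    return wide


def beta_sd_approx(beta: np.ndarray, kappa: float = DEFAULT_KAPPA) -> np.ndarray:
    """Standard deviation of a Beta(beta*kappa, (1-beta)*kappa) variable."""
    beta = np.asarray(beta, dtype=float)
    return np.sqrt(beta * (1.0 - beta) / (1.0 + kappa))


def build_combined(
    expr: pd.DataFrame,
    meth_beta: pd.DataFrame,
    gene_universe: Sequence[str] | set[str],
    epsilon: float = DEFAULT_EPSILON,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
    kappa: float = DEFAULT_KAPPA,
    sign_convention: Literal["neg_log", "pos_log"] = "neg_log",
) -> CombinedDataset:
    """Stack expression over log-transformed methylation with uncertainties.

    Rows are the expression genes intersected with the universe (E block)
    followed by the methylation genes intersected with the universe (M
    block); a gene may appear in both blocks.  Under the default ``neg_log``
    convention M-block entries are ``-log(max(beta, epsilon))`` so that a
    hypomethylated (re-activated) gene takes a large value that co-varies
    with its re-activated expression, and methylated/silenced states decay
    toward zero.  ``pos_log`` stores ``+log(max(beta, epsilon))`` for
    sensitivity analyses.

    Expression uncertainty is ``max(0.1 * |signal|, sigma_floor)``;
    methylation uncertainty is the beta-distribution sd with precision
    ``kappa`` carried to the log scale by the delta method,
    ``max(sd_approx(beta) / max(beta, epsilon), sigma_floor)``.
    """
    if len(gene_universe) == 0:
        raise ValueError("gene universe is empty")
    universe = set(gene_universe)
    if list(expr.columns) != list(meth_beta.columns):
        raise ValueError("expression and methylation sample lists differ")
    sample_ids = [str(c) for c in expr.columns]

    e_genes = [g for g in expr.index if g in universe]
    m_genes = [g for g in meth_beta.index if g in universe]
    if not e_genes and not m_genes:
        raise ValueError("no genes intersect the universe")

    E = expr.loc[e_genes].to_numpy(dtype=float)
    beta = meth_beta.loc[m_genes].to_numpy(dtype=float)
    if np.any((beta < 0) | (beta > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    beta_c = np.maximum(beta, epsilon)
    logb = np.log(beta_c)
    M = -logb if sign_convention == "neg_log" else logb

    Sigma_E = np.maximum(0.1 * np.abs(E), sigma_floor)
    Sigma_M = np.maximum(beta_sd_approx(beta, kappa) / beta_c, sigma_floor)

    D = np.vstack([E, M]) if len(e_genes) else M
    Sigma = np.vstack([Sigma_E, Sigma_M]) if len(e_genes) else Sigma_M
    return CombinedDataset(
        D=D,
        Sigma=Sigma,
        block_of_row=np.array(["E"] * len(e_genes) + ["M"] * len(m_genes)),
        gene_of_row=np.array(list(e_genes) + list(m_genes)),
        sample_ids=sample_ids,
    )


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a gene x sample TSV (first column = id, header = sample ids)."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def read_probe_tsv(path) -> pd.DataFrame:
    """Read a long probe table: probe_id, gene, n_cpg, sample_id, M, U."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"probe_id", "gene", "n_cpg", "sample_id", "M", "U"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    return df


def probes_to_gene_beta(
    probe_df: pd.DataFrame,
    offset: float = DEFAULT_OFFSET,
    min_cpg: int = 3,
) -> pd.DataFrame:
    """Full probe pipeline: beta conversion, CpG filter, max-per-gene summary."""
    kept = filter_probes(probe_df, min_cpg=min_cpg)
    kept = kept.assign(beta=compute_beta(kept["M"].to_numpy(), kept["U"].to_numpy(), offset))
    return summarize_methylation(kept[["gene", "sample_id", "beta"]])
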