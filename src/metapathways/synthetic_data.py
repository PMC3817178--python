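"""Synthetic paired methylation/expression cohorts with planted structure.

Emulates the data shape of a two-platform head-and-neck cancer study: a
gene-expression matrix and an Infinium-style methylation probe table (M/U
channel intensities) over the same samples, with clinical labels, curated
gene sets, and a known ground truth for every downstream stage.

The planted model: each of ``n_patterns`` patterns is elevated in exactly
one sample group (pattern value 1 in the group, 0.1 background elsewhere).
Expression genes load on one dominant pattern; log expression is
``A_E @ P_true`` plus Gaussian noise whose sd is the planted-signal sd
divided by ``snr``.  A ``silenced_fraction`` of the shared genes is
epigenetically coupled: their methylation mean is low exactly in the
sample group where their expression pattern is high (hypomethylation-driven
re-activation), so beta and log expression are anti-correlated across
samples.  Methylation-only rows (transcription factors measured only on the
methylation platform) carry the same kind of pattern-linked hypomethylation.
Beta values are drawn from a Beta distribution parameterized by mean and
precision ``beta_precision``; M/U intensities are back-computed with a
lognormal total intensity so the probe-processing stage round-trips beta.

The methylation mean uses a log-linear construction,
``mu = beta_high * exp(-a * t)`` with ``t`` the 0-1 normalized pattern, so
that ``-log(mu)`` is exactly affine in the planted pattern and the stacked
matrix's methylation block has the same non-negative factor structure as
the expression block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection, write_gmt

__all__ = ["SimulationConfig", "SyntheticTruth", "generate_dataset", "write_dataset"]

# planted methylation extremes: beta in the gene's active group vs elsewhere
BETA_LOW = 0.1
BETA_HIGH = 0.9
INTENSITY_MEDIAN = 20000.0
INTENSITY_LOG_SD = 0.2


def _default_groups() -> dict[str, int]:
    # discovery-cohort group sizes: normal mucosa, HPV+ and HPV- tumors
    return {"normal": 25, "hpv_positive": 13, "hpv_negative": 31}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults define the study conditions."""

    n_genes_expr: int = 120
    n_genes_meth: int = 100
    n_shared_genes: int = 60
    samples_per_group: dict[str, int] = field(default_factory=_default_groups)
    n_patterns: int = 3
    snr: float = 10.0
    silenced_fraction: float = 0.5
    beta_precision: float = 100.0
    n_gene_sets: int = 50
    set_size: int = 20
    enriched_sets: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes_expr", "n_genes_meth", "n_patterns",
                     "n_gene_sets", "set_size", "enriched_sets"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_shared_genes < 0:
            raise ValueError("n_shared_genes must be non-negative")
        if self.n_shared_genes > min(self.n_genes_expr, self.n_genes_meth):
            raise ValueError("n_shared_genes exceeds block sizes")
        if not 0.0 <= self.silenced_fraction <= 1.0:
            raise ValueError("silenced_fraction must lie in [0, 1]")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.beta_precision <= 0:
            raise ValueError("beta_precision must be positive")
        if not self.samples_per_group:
            raise ValueError("samples_per_group must be nonempty")
        if any(n <= 0 for n in self.samples_per_group.values()):
            raise ValueError("group sizes must be positive")
        if self.n_patterns > len(self.samples_per_group):
            raise ValueError("n_patterns exceeds the number of sample groups")
        if self.enriched_sets > self.n_gene_sets:
            raise ValueError("enriched_sets exceeds n_gene_sets")
        if self.silenced_fraction > 0 and self.n_shared_genes == 0:
            raise ValueError("no shared genes to silence")


@dataclass
class SyntheticTruth:
    """Planted ground truth on the stacked-matrix scale.

    ``A_true`` rows are indexed (block, gene) — expression rows first, then
    methylation rows whose amplitude is the planted pattern loading of
    ``-log(mu)`` (per-gene additive baselines are not part of A_true).
    """

    A_true: pd.DataFrame  # MultiIndex (block, gene) x pattern
    P_true: pd.DataFrame  # pattern x sample
    group_of_sample: pd.Series
    silenced_genes: list[str]
    enriched_set_names: list[str]

    def __post_init__(self) -> None:
        if (self.A_true.to_numpy() < 0).any() or (self.P_true.to_numpy() < 0).any():
            raise ValueError("planted A and P must be non-negative")


def generate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GeneSetCollection, SyntheticTruth]:
    """Generate one cohort.

    Returns ``(expression, probes, clinical, gene_sets, truth)`` where
    expression is gene x sample (positive, exp of the planted log signal),
    probes is a long table (probe_id, gene, n_cpg, sample_id, M, U),
    clinical maps samples to group and randomized covariates, gene_sets
    contains planted enriched plus random sets, and truth carries the
    planted factorization and silenced-gene list.  Same seed, same output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    p = cfg.n_patterns
    groups = list(cfg.samples_per_group)

    sample_ids: list[str] = []
    group_of_sample: list[str] = []
    for g in groups:
        for _ in range(cfg.samples_per_group[g]):
            sample_ids.append(f"S{len(sample_ids):03d}")
            group_of_sample.append(g)
    m = len(sample_ids)
    group_arr = np.array(group_of_sample)

    # patterns: elevated in exactly one group (around 1.0) and decaying to
    # zero elsewhere — inactive samples carry no pattern activity, the
    # structure the uncertainty model is designed to find; in-group jitter
    # gives realistic within-group sample heterogeneity
    P_true = np.zeros((p, m))
    for k in range(p):
        in_group = group_arr == groups[k]
        P_true[k, in_group] = rng.uniform(0.8, 1.2, size=int(in_group.sum()))

    shared_genes = [f"G{i:04d}" for i in range(cfg.n_shared_genes)]
    expr_only = [f"G{i:04d}" for i in range(cfg.n_shared_genes, cfg.n_genes_expr)]
    meth_only = [f"TF{i:04d}" for i in range(cfg.n_genes_meth - cfg.n_shared_genes)]
    expr_genes = shared_genes + expr_only
    meth_genes = shared_genes + meth_only

    # --- expression block ---
    dominant_e = np.arange(cfg.n_genes_expr) % p
    A_E = rng.uniform(0.0, 0.3, size=(cfg.n_genes_expr, p))
    A_E[np.arange(cfg.n_genes_expr), dominant_e] = rng.uniform(2.0, 4.0, cfg.n_genes_expr)
    L = A_E @ P_true
    noise_sd = 0.0 if math.isinf(cfg.snr) else float(np.std(L)) / cfg.snr
    L = L + rng.normal(0.0, 1.0, size=L.shape) * noise_sd
    expression = pd.DataFrame(np.exp(L), index=expr_genes, columns=sample_ids)
    expression.index.name = "gene"

    # --- methylation block ---
    n_sil = int(round(cfg.silenced_fraction * cfg.n_shared_genes))
    silenced = sorted(rng.choice(cfg.n_shared_genes, size=n_sil, replace=False).tolist()) if n_sil else []
    silenced_set = set(silenced)
    dominant_m = np.empty(cfg.n_genes_meth, dtype=int)
    dominant_m[: cfg.n_shared_genes] = dominant_e[: cfg.n_shared_genes]
    dominant_m[cfg.n_shared_genes:] = np.arange(len(meth_only)) % p

    a_slope = math.log(BETA_HIGH / BETA_LOW)  # -log(mu) span over the pattern
    t_norm = np.clip(P_true, 0.0, 1.0)
    structured = np.ones(cfg.n_genes_meth, dtype=bool)
    for i in range(cfg.n_shared_genes):
        if i not in silenced_set:
            structured[i] = False  # shared but unsilenced: flat methylation

    mu = np.empty((cfg.n_genes_meth, m))
    A_M = np.zeros((cfg.n_genes_meth, p))
    flat_mu = rng.uniform(0.3, 0.7, size=cfg.n_genes_meth)  # drawn for all, used where flat
    for i in range(cfg.n_genes_meth):
        if structured[i]:
            mu[i] = BETA_HIGH * np.exp(-a_slope * t_norm[dominant_m[i]])
            A_M[i, dominant_m[i]] = a_slope
        else:
            mu[i] = flat_mu[i]
    kappa = cfg.beta_precision
    beta = rng.beta(mu * kappa, (1.0 - mu) * kappa)
    beta = np.clip(beta, 1e-6, 1.0 - 1e-6)

    # --- probe table: one retained probe per gene, occasional low-CpG probe ---
    records = []
    probe_idx = 0
    for i, gene in enumerate(meth_genes):
        n_cpg = int(rng.integers(3, 9))
        total = rng.lognormal(math.log(INTENSITY_MEDIAN), INTENSITY_LOG_SD, size=m)
        for j, s in enumerate(sample_ids):
            records.append((f"cg{probe_idx:05d}", gene, n_cpg, s,
                            total[j] * beta[i, j], total[j] * (1.0 - beta[i, j])))
        probe_idx += 1
        if rng.random() < 0.5:  # low-CpG probe that the filter must drop
            n_cpg = int(rng.integers(1, 3))
            junk = rng.uniform(0.0, 1.0, size=m)
            total = rng.lognormal(math.log(INTENSITY_MEDIAN), INTENSITY_LOG_SD, size=m)
            for j, s in enumerate(sample_ids):
                records.append((f"cg{probe_idx:05d}", gene, n_cpg, s,
                                total[j] * junk[j], total[j] * (1.0 - junk[j])))
            probe_idx += 1
    probes = pd.DataFrame.from_records(
        records, columns=["probe_id", "gene", "n_cpg", "sample_id", "M", "U"]
    )

    # --- clinical table ---
    sites = np.array(["oral_cavity", "oropharynx", "larynx", "hypopharynx"])
    gender = rng.choice(["female", "male"], size=m)
    smoking = rng.choice(["yes", "no"], size=m)
    site = rng.choice(sites, size=m)
    is_normal = np.array([g == groups[0] or "normal" in g for g in group_of_sample])
    hpv = np.array([
        "positive" if "positive" in g else "negative" if "negative" in g else "NA"
        for g in group_of_sample
    ])
    clinical = pd.DataFrame({
        "sample_id": sample_ids,
        "group": group_of_sample,
        "tumor": np.where(is_normal, "normal", "tumor"),
        "hpv": hpv,
        "gender": gender,
        "smoking": smoking,
        "site": np.where(is_normal, "na", site),
    })

    # --- gene sets: planted enriched (top-decile amplitude) + random nulls ---
    pattern_names = [f"p{k}_{groups[k]}" for k in range(p)]
    blocks = ["E"] * cfg.n_genes_expr + ["M"] * cfg.n_genes_meth
    all_row_genes = expr_genes + meth_genes
    A_stacked = np.vstack([A_E, A_M])
    universe = set(expr_genes) | set(meth_genes)
    gene_amp = pd.DataFrame(A_stacked, columns=pattern_names)
    gene_amp["gene"] = all_row_genes
    per_gene = gene_amp.groupby("gene").max()  # shared genes: max over blocks

    sets: dict[str, list[str]] = {}
    enriched_names = []
    for k in range(cfg.enriched_sets):
        kk = k % p
        col = per_gene[pattern_names[kk]]
        q = col.quantile(0.9)
        candidates = col.index[col.to_numpy() >= q].to_numpy()
        size = min(cfg.set_size, len(candidates))
        pick = rng.choice(len(candidates), size=size, replace=False)
        name = f"ENRICHED_{pattern_names[kk].upper()}_{k}"
        sets[name] = sorted(candidates[pick].tolist())
        enriched_names.append(name)
    uni_list = sorted(universe)
    for i in range(cfg.n_gene_sets - cfg.enriched_sets):
        pick = rng.choice(len(uni_list), size=min(cfg.set_size, len(uni_list)), replace=False)
        sets[f"RANDOM{i:03d}"] = sorted(np.array(uni_list)[pick].tolist())
    gene_sets = GeneSetCollection(sets=sets, universe=universe)

    truth = SyntheticTruth(
        A_true=pd.DataFrame(
            A_stacked,
            index=pd.MultiIndex.from_arrays([blocks, all_row_genes], names=["block", "gene"]),
            columns=pattern_names,
        ),
        P_true=pd.DataFrame(P_true, index=pattern_names, columns=sample_ids),
        group_of_sample=pd.Series(group_of_sample, index=sample_ids, name="group"),
        silenced_genes=[shared_genes[i] for i in silenced],
        enriched_set_names=enriched_names,
    )
    return expression, probes, clinical, gene_sets, truth


def write_dataset(
    expression: pd.DataFrame,
    probes: pd.DataFrame,
    clinical: pd.DataFrame,
    gene_sets: GeneSetCollection,
    truth: SyntheticTruth,
    outdir,
) -> dict[str, Path]:
    """Write the cohort as TSV/GMT files; returns the path of each artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "probes": outdir / "probes.tsv",
        "clinical": outdir / "clinical.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "truth_A": outdir / "truth_A.tsv",
        "truth_P": outdir / "truth_P.tsv",
        "truth_meta": outdir / "truth_meta.tsv",
    }
    expression.to_csv(paths["expression"], sep="\t")
    probes.to_csv(paths["probes"], sep="\t", index=False)
    clinical.to_csv(paths["clinical"], sep="\t", index=False)
    write_gmt(gene_sets, paths["gene_sets"])
    truth.A_true.to_csv(paths["truth_A"], sep="\t")
    truth.P_true.to_csv(paths["truth_P"], sep="\t")
    meta = pd.DataFrame({
        "key": (["silenced_gene"] * len(truth.silenced_genes)
                + ["enriched_set"] * len(truth.enriched_set_names)),
        "value": truth.silenced_genes + truth.enriched_set_names,
    })
    meta.to_csv(paths["truth_meta"], sep="\t", index=False)
    return paths
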