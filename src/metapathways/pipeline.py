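"""End-to-end orchestration: simulate/load -> preprocess -> factorize ->
activity -> associate -> enrich, with deterministic seeding and a
machine-readable summary.

Every stage writes TSV artifacts into the run directory; each output file
carries the configuration hash in a ``#`` header comment so a run can be
traced back to its exact configuration.  Re-running with the same
configuration (any output directory) produces byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activity as activity_mod
from . import association, enrichment, factorization, preprocess, synthetic_data

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger("metapathways")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full run over synthetic or user-supplied data."""

    simulation: synthetic_data.SimulationConfig = field(
        default_factory=synthetic_data.SimulationConfig
    )
    p_range: tuple[int, ...] = (2, 3, 4, 5)
    seeds: tuple[int, ...] = (11, 12)
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    n_burn: int = 5000
    n_sample: int = 5000
    covariates: tuple[str, ...] = ("group",)
    side: str = "one"
    offset: float = preprocess.DEFAULT_OFFSET
    epsilon: float = preprocess.DEFAULT_EPSILON
    sigma_floor: float = preprocess.DEFAULT_SIGMA_FLOOR
    kappa: float = preprocess.DEFAULT_KAPPA
    sign_convention: str = "neg_log"
    n_perm: int = 1000
    robustness_threshold: float = 0.8
    enrichment_alpha: float = 0.05

    def __post_init__(self) -> None:
        m = sum(self.simulation.samples_per_group.values())
        if not self.seeds:
            raise ValueError("seeds must be nonempty")
        if any(p < 1 or p >= m for p in self.p_range):
            raise ValueError(f"p_range must lie within [1, {m - 1}]")
        if max(self.k_range) > m:
            raise ValueError("k_range exceeds the number of samples")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = synthetic_data.SimulationConfig(**raw.pop("simulation", {}))
        for key in ("p_range", "seeds", "k_range", "covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_all(config: RunConfig, outdir) -> dict:
    """Run every stage on a simulated cohort and summarize.

    The summary lists, per p, the robust patterns (cross-seed match
    correlation at least the threshold), and for each robust pattern the
    clinical contrast with the smallest adjusted association p and the
    gene sets enriched at BH < ``enrichment_alpha``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash
    t0 = time.time()

    # --- stage: simulate ---
    expr, probes, clinical, gene_sets, truth = synthetic_data.generate_dataset(config.simulation)
    synthetic_data.write_dataset(expr, probes, clinical, gene_sets, truth, outdir / "data")
    log.info("simulate: %d expr genes, %d probes rows, %d samples (%.1fs)",
             expr.shape[0], len(probes), expr.shape[1], time.time() - t0)

    # --- stage: preprocess ---
    meth_beta = preprocess.probes_to_gene_beta(probes, offset=config.offset)
    meth_beta = meth_beta[expr.columns]
    log_expr = np.log(expr)
    universe = set(expr.index) | set(meth_beta.index)
    dataset = preprocess.build_combined(
        log_expr, meth_beta, universe,
        epsilon=config.epsilon, sigma_floor=config.sigma_floor,
        kappa=config.kappa, sign_convention=config.sign_convention,
    )
    _write_tsv(pd.DataFrame(dataset.D, columns=dataset.sample_ids),
               outdir / "combined" / "D.tsv", cfg_hash)
    _write_tsv(pd.DataFrame(dataset.Sigma, columns=dataset.sample_ids),
               outdir / "combined" / "Sigma.tsv", cfg_hash)
    _write_tsv(pd.DataFrame({"block": dataset.block_of_row, "gene": dataset.gene_of_row}),
               outdir / "combined" / "rows.tsv", cfg_hash)

    # --- stage: factorize over p_range x seeds ---
    results: dict[int, list[factorization.FactorizationResult]] = {}
    for p in config.p_range:
        results[p] = []
        for seed in config.seeds:
            t1 = time.time()
            res = factorization.factorize(
                dataset, p=p, n_burn=config.n_burn, n_sample=config.n_sample, seed=seed
            )
            results[p].append(res)
            log.info("factorize p=%d seed=%d (%.1fs)", p, seed, time.time() - t1)
            tag = f"p{p}_seed{seed}"
            for name, mat in (("A_mean", res.A_mean), ("A_sd", res.A_sd),
                              ("P_mean", res.P_mean), ("P_sd", res.P_sd)):
                _write_tsv(pd.DataFrame(mat), outdir / "factorization" / f"{tag}_{name}.tsv",
                           cfg_hash)
            _write_tsv(pd.DataFrame({"chi2": res.chi2_trace}),
                       outdir / "factorization" / f"{tag}_chi2.tsv", cfg_hash)
    report = factorization.match_patterns(
        [r for group in results.values() for r in group],
        threshold=config.robustness_threshold,
    )

    # --- stages: activity, association, enrichment per p ---
    summary: dict = {"config_hash": cfg_hash, "per_p": {}}
    clin_indexed = clinical.set_index("sample_id").loc[dataset.sample_ids].reset_index()
    e_mask = dataset.block_of_row == "E"
    for p in config.p_range:
        res = results[p][0]
        pattern_ids = [f"pattern{k}" for k in range(p)]
        act = activity_mod.activity_zscores(
            pd.DataFrame(res.P_mean, index=pattern_ids, columns=dataset.sample_ids),
            pd.DataFrame(res.P_sd, index=pattern_ids, columns=dataset.sample_ids),
        )
        _write_tsv(act.rescaled, outdir / "activity" / f"p{p}.tsv", cfg_hash)
        assoc = association.associate(
            act.rescaled, clin_indexed, list(config.covariates),
            side=config.side, encoding="one_vs_rest",
        )
        _write_tsv(assoc, outdir / "associations" / f"p{p}.tsv", cfg_hash, index=False)

        amp_E = pd.DataFrame(res.A_mean[e_mask], index=dataset.gene_of_row[e_mask],
                             columns=pattern_ids)
        sd_E = pd.DataFrame(np.maximum(res.A_sd[e_mask], 1e-6),
                            index=dataset.gene_of_row[e_mask], columns=pattern_ids)
        amp_M = pd.DataFrame(res.A_mean[~e_mask], index=dataset.gene_of_row[~e_mask],
                             columns=pattern_ids)
        sd_M = pd.DataFrame(np.maximum(res.A_sd[~e_mask], 1e-6),
                            index=dataset.gene_of_row[~e_mask], columns=pattern_ids)
        amp, sd = enrichment.combine_amplitude_matrices(amp_E, sd_E, amp_M, sd_M)

        robust = report.robust_patterns(p) if p in report.min_match_corr else []
        summary["per_p"][str(p)] = {
            "robust_patterns": robust,
            "min_match_corr": [round(float(c), 6) for c in
                               report.min_match_corr.get(p, np.array([]))],
            "patterns": {},
        }
        for k in robust:
            pat = pattern_ids[k]
            enr = enrichment.gene_set_test(
                amp[pat], sd[pat], gene_sets,
                n_perm=config.n_perm, seed=config.seeds[0] + 1000 * p + k,
            )
            _write_tsv(enr, outdir / "enrichment" / f"p{p}_{pat}.tsv", cfg_hash, index=False)
            pat_assoc = assoc[assoc["meta_pathway"] == pat]
            best = pat_assoc.loc[pat_assoc["adjusted_p"].idxmin()]
            summary["per_p"][str(p)]["patterns"][pat] = {
                "top_phenotype": str(best["contrast"]),
                "top_adjusted_p": float(best["adjusted_p"]),
                "enriched_sets": enr.loc[
                    enr["adjusted_p"] < config.enrichment_alpha, "name"
                ].tolist(),
            }

    # --- stage: clustering comparator ---
    labels_by_k = association.cluster_samples(dataset.D, k_range=config.k_range)
    rows = []
    for k, labels in labels_by_k.items():
        for col in ("group", "tumor", "hpv", "gender", "smoking"):
            if col not in clinical.columns:
                continue
            pheno = clinical.set_index("sample_id").loc[dataset.sample_ids, col]
            pval, method = association.cluster_phenotype_test(labels, pheno, seed=config.seeds[0])
            rows.append({"k": k, "phenotype": col, "p": pval, "method": method})
    cluster_tests = pd.DataFrame(rows)
    _write_tsv(cluster_tests, outdir / "clusters" / "cluster_tests.tsv", cfg_hash, index=False)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("run_all finished in %.1fs", time.time() - t0)
    return summary
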