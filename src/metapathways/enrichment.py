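"""Gene-set enrichment of meta-pathway amplitudes.

Combines methylation and expression amplitudes of shared genes by
inverse-variance weighting, then scores curated gene sets against a
competitive permutation null: for a set G the statistic is

    Z_G = (1 / sqrt(|G|)) * sum_{g in G} A_g / sd_g

and its null distribution is built from random same-size gene draws from
the scored universe.  Ties count as at least as extreme, so p-values are
valid and lower-bounded by 1/(n_perm + 1).  Benjamini-Hochberg adjustment
is applied across sets (optionally within database strata).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "combine_amplitudes",
    "combine_amplitude_matrices",
    "gene_set_test",
    "read_gmt",
    "write_gmt",
]


@dataclass
class GeneSetCollection:
    """Named gene sets against a declared gene universe.

    Sets are stored intersected with the universe; empty intersections are
    dropped with a warning at construction.
    """

    sets: dict[str, list[str]]
    universe: set[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            inter = [g for g in genes if g in self.universe]
            if not inter:
                warnings.warn(f"gene set {name!r} has empty intersection with universe; skipped")
                continue
            clean[name] = inter
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def sizes(self) -> dict[str, int]:
        return {name: len(g) for name, g in self.sets.items()}


def read_gmt(path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read gene sets from GMT (name <tab> description <tab> gene ...).

    When ``universe`` is None it is taken as the union of all member genes.
    """
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = parts[2:]
            desc[parts[0]] = parts[1]
    uni = set(universe) if universe is not None else {g for gs in sets.values() for g in gs}
    return GeneSetCollection(sets=sets, universe=uni, descriptions=desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def combine_amplitudes(A_E, sd_E, A_M, sd_M):
    """Inverse-variance weighted combination of paired amplitude estimates.

    w = 1/sd^2 per block; the combined amplitude is the weighted mean and
    its sd is 1/sqrt(w_E + w_M) (never exceeding either input sd).
    """
    A_E, sd_E = np.asarray(A_E, float), np.asarray(sd_E, float)
    A_M, sd_M = np.asarray(A_M, float), np.asarray(sd_M, float)
    if np.any(sd_E <= 0) or np.any(sd_M <= 0):
        raise ValueError("standard deviations must be positive")
    w_E = 1.0 / (sd_E * sd_E)
    w_M = 1.0 / (sd_M * sd_M)
    combined = (w_E * A_E + w_M * A_M) / (w_E + w_M)
    sd = 1.0 / np.sqrt(w_E + w_M)
    return combined, sd


def combine_amplitude_matrices(
    amp_E: pd.DataFrame,
    sd_E: pd.DataFrame,
    amp_M: pd.DataFrame,
    sd_M: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene, per-pattern IVW combination of two amplitude matrices.

    Genes present in only one block pass through unchanged; genes in both
    are combined elementwise.  Inputs are gene x pattern frames with
    matching columns.
    """
    if list(amp_E.columns) != list(amp_M.columns):
        raise ValueError("pattern columns differ between blocks")
    shared = amp_E.index.intersection(amp_M.index)
    only_e = amp_E.index.difference(amp_M.index)
    only_m = amp_M.index.difference(amp_E.index)
    rows_amp, rows_sd = [], []
    if len(shared):
        a, s = combine_amplitudes(
            amp_E.loc[shared].to_numpy(), sd_E.loc[shared].to_numpy(),
            amp_M.loc[shared].to_numpy(), sd_M.loc[shared].to_numpy(),
        )
        rows_amp.append(pd.DataFrame(a, index=shared, columns=amp_E.columns))
        rows_sd.append(pd.DataFrame(s, index=shared, columns=amp_E.columns))
    if len(only_e):
        rows_amp.append(amp_E.loc[only_e])
        rows_sd.append(sd_E.loc[only_e])
    if len(only_m):
        rows_amp.append(amp_M.loc[only_m])
        rows_sd.append(sd_M.loc[only_m])
    amp = pd.concat(rows_amp).sort_index()
    sd = pd.concat(rows_sd).sort_index()
    return amp, sd


def gene_set_test(
    amplitudes: Mapping[str, float] | pd.Series,
    sds: Mapping[str, float] | pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
    adjust_within: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Permutation enrichment of gene sets in one pattern's amplitudes.

    Parameters
    ----------
    amplitudes, sds
        Per-gene combined amplitude and its sd; the scored universe is the
        genes present in both and in the collection's universe.
    n_perm
        Random same-size draws (without replacement) from the universe.
    alternative
        ``"greater"`` scores enrichment (high amplitudes); ``"less"``
        scores depletion.
    adjust_within
        Optional map set-name -> stratum (e.g. source database); BH is then
        applied within each stratum instead of across all sets.

    Returns a frame with columns name, size, z, p, adjusted_p sorted by p.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    amp = pd.Series(amplitudes, dtype=float)
    sd = pd.Series(sds, dtype=float)
    genes = amp.index.intersection(sd.index)
    genes = [g for g in genes if g in sets.universe]
    if not genes:
        raise ValueError("no scored genes intersect the universe")
    z_gene = (amp.loc[genes] / sd.loc[genes]).to_numpy()
    pos = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    rng = np.random.default_rng(seed)
    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in sets.sets.items():
        idx = [pos[g] for g in members if g in pos]
        if not idx:
            warnings.warn(f"gene set {name!r} has no scored genes; skipped")
            continue
        size = len(idx)
        z_set = z_gene[idx].sum() / np.sqrt(size)
        if size not in null_cache:
            if size >= n_genes:
                null = np.full(n_perm, z_gene.sum() / np.sqrt(n_genes))
            else:
                keys = rng.random((n_perm, n_genes))
                draw = np.argpartition(keys, size, axis=1)[:, :size]
                null = z_gene[draw].sum(axis=1) / np.sqrt(size)
            null_cache[size] = null
        null = null_cache[size]
        if alternative == "greater":
            n_extreme = int(np.sum(null >= z_set))
        else:
            n_extreme = int(np.sum(null <= z_set))
        p = (1.0 + n_extreme) / (n_perm + 1.0)
        rows.append({"name": name, "size": size, "z": z_set, "p": p})
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(adjusted_p=pd.Series(dtype=float))
    if adjust_within is None:
        out["adjusted_p"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["adjusted_p"] = np.nan
        strata = out["name"].map(lambda s: adjust_within.get(s, "_default"))
        for _, grp in out.groupby(strata):
            out.loc[grp.index, "adjusted_p"] = multipletests(grp["p"], method="fdr_bh")[1]
    return out.sort_values("p", kind="stable").reset_index(drop=True)
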