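"""Meta-pathway activity scores from pattern posterior summaries.

Activity of pattern k in sample s is the Z-score
``Z_ks = P_mean_ks / max(P_sd_ks, sd_floor)``; each pattern row is then
rescaled so its maximum over samples is 1, which puts all patterns on a
common visual scale.  Rows whose maximum Z is not positive cannot be
rescaled and are flagged instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MetaPathwayActivity", "activity_zscores"]

DEFAULT_SD_FLOOR = 1e-6


@dataclass
class MetaPathwayActivity:
    """Per-pattern, per-sample activity (raw Z and max-1 rescaled)."""

    Z: pd.DataFrame
    rescaled: pd.DataFrame
    not_rescaled: list  # pattern ids whose row max Z <= 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.Z.to_numpy())):
            raise ValueError("Z scores must be finite")


def activity_zscores(
    P_mean, P_sd, sd_floor: float = DEFAULT_SD_FLOOR
) -> MetaPathwayActivity:
    """Z = posterior mean / posterior sd per element, rows rescaled to max 1.

    Accepts arrays or DataFrames of identical shape (patterns x samples);
    sds are floored at ``sd_floor`` to keep Z finite.
    """
    if sd_floor <= 0:
        raise ValueError("sd_floor must be positive")
    mean_df = pd.DataFrame(P_mean)
    sd_df = pd.DataFrame(P_sd)
    if mean_df.shape != sd_df.shape:
        raise ValueError("P_mean and P_sd shapes differ")
    sd = sd_df.to_numpy(dtype=float)
    if np.any(sd < 0):
        raise ValueError("P_sd must be non-negative")
    Z = mean_df.to_numpy(dtype=float) / np.maximum(sd, sd_floor)
    rescaled = Z.copy()
    skipped = []
    for i, row_id in enumerate(mean_df.index):
        zmax = Z[i].max()
        if zmax > 0:
            rescaled[i] = Z[i] / zmax
        else:
            skipped.append(row_id)
    if skipped:
        warnings.warn(f"patterns {skipped} have max Z <= 0; left unrescaled")
    return MetaPathwayActivity(
        Z=pd.DataFrame(Z, index=mean_df.index, columns=mean_df.columns),
        rescaled=pd.DataFrame(rescaled, index=mean_df.index, columns=mean_df.columns),
        not_rescaled=skipped,
    )
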