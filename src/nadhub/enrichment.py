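"""Ligand-fishing enrichment ranking of label-free proteomics intensities.

A bait affinity column (immobilised His-GlnZ) and a control column are eluted
in fractions; proteins enriched on the bait column over the control are
candidate interaction partners.  Enrichment is scored per protein per
fraction as log10((bait + c)/(control + c)) with a pseudocount c and ranked
descending.

The pseudocount defaults to the smallest nonzero intensity in the table: a
scale-free choice that keeps zero-intensity controls finite without an
arbitrary constant.  As c -> 0 the ratio diverges only for zero controls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._fitting import DomainError

__all__ = ["enrichment_ranking", "top_candidates"]

_VALUE_COLS = ["bait_f1", "bait_f2", "control_f1", "control_f2"]


def enrichment_ranking(table: pd.DataFrame, pseudocount: float | None = None) -> pd.DataFrame:
    """Rank proteins by bait/control log10 enrichment ratio per fraction.

    ``table`` is wide: protein_id plus bait_f1, bait_f2, control_f1,
    control_f2 intensity columns (missing values treated as 0).  Returns a
    tidy frame (protein_id, fraction, log_ratio) sorted by descending
    log_ratio, with deterministic (protein_id, fraction) tie-breaking so the
    ranking is invariant to input row order.
    """
    df = table.copy()
    for col in _VALUE_COLS:
        if col not in df:
            raise KeyError(f"missing column {col!r}")
        df[col] = df[col].fillna(0.0).astype(float)
        if (df[col] < 0).any():
            raise DomainError(f"negative intensity in {col!r}")
    if pseudocount is None:
        vals = df[_VALUE_COLS].to_numpy().ravel()
        nonzero = vals[vals > 0]
        if nonzero.size == 0:
            raise ValueError("all intensities are zero; supply a pseudocount")
        pseudocount = float(nonzero.min())
    if pseudocount <= 0:
        raise ValueError("pseudocount must be strictly positive")

    parts = []
    for frac in (1, 2):
        ratio = np.log10((df[f"bait_f{frac}"] + pseudocount)
                         / (df[f"control_f{frac}"] + pseudocount))
        parts.append(pd.DataFrame({
            "protein_id": df["protein_id"], "fraction": frac,
            "log_ratio": ratio,
        }))
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["log_ratio", "protein_id", "fraction"],
                           ascending=[False, True, True],
                           kind="mergesort").reset_index(drop=True)


def top_candidates(ranked: pd.DataFrame, k: int = 5) -> list[str]:
    """Top-k protein ids by their best log ratio across fractions."""
    best = (ranked.groupby("protein_id")["log_ratio"].max()
            .sort_values(ascending=False, kind="mergesort"))
    return list(best.index[:k])
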