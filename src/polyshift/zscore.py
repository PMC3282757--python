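"""Intensity-dependent z-scores over A-ordered log-ratios.

Each gene's normalized log-ratio M is standardized against the mean and
sample standard deviation of a window of neighboring genes in A (mean log2
intensity) order: z_i = (M_i - mean(window)) / sd(window). The window always
contains the focal gene. Replicate arrays are z-scored separately and then
combined by averaging.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["sliding_window_zscore", "combine_replicates"]

FLAG_DEGENERATE = "degenerate_window"
FLAG_SINGLE = "single_replicate"
FLAG_DISCORDANT = "discordant"


def _window_bounds(n: int, window_size: int, edge: str) -> tuple[np.ndarray, np.ndarray]:
    """Inclusive [lo, hi] window bounds per rank position.

    ``truncate``: the symmetric window is clipped at the ends of the A-order,
    so edge windows shrink (never below ceil(window_size/2) points).
    ``slide``: edge windows slide inward instead, keeping the full point
    count; with window_size = n every window is the whole table and z reduces
    to the global standardization of M.
    """
    i = np.arange(n)
    half_lo = (window_size - 1) // 2
    half_hi = window_size // 2
    if edge == "truncate":
        lo = np.maximum(i - half_lo, 0)
        hi = np.minimum(i + half_hi, n - 1)
    elif edge == "slide":
        lo = np.clip(i - half_lo, 0, max(n - window_size, 0))
        hi = np.minimum(lo + window_size - 1, n - 1)
    else:
        raise ValueError(f"unknown edge policy {edge!r}")
    return lo, hi


def sliding_window_zscore(
    ma: pd.DataFrame,
    window_size: int = 50,
    edge: str = "slide",
) -> pd.DataFrame:
    """Standardize each M against its A-neighborhood.

    Input must be a normalized MA table (gene_id, M, A). Genes are sorted by
    (A, gene_id) — the lexical tie-break keeps runs reproducible — and each
    gene's window statistics use the sample (n-1) standard deviation. A
    window with zero spread yields z = 0 and a ``degenerate_window`` flag.
    Output keeps the input row order.
    """
    if "normalized" in ma.columns and not bool(ma["normalized"].all()):
        raise ValueError("MA table must be Lowess-normalized before z-scoring")
    n = len(ma)
    if not 2 <= window_size <= n:
        raise ValueError(f"window_size must be in [2, {n}], got {window_size}")

    order = np.lexsort((ma["gene_id"].to_numpy(), ma["A"].to_numpy(float)))
    m = ma["M"].to_numpy(float)[order]
    lo, hi = _window_bounds(n, window_size, edge)

    mean = np.empty(n)
    sd = np.empty(n)
    for i in range(n):
        w = m[lo[i] : hi[i] + 1]
        mean[i] = w.mean()
        sd[i] = w.std(ddof=1)

    degenerate = sd == 0
    z = np.zeros(n)
    np.divide(m - mean, sd, out=z, where=~degenerate)

    out_sorted = pd.DataFrame(
        {
            "gene_id": ma["gene_id"].to_numpy()[order],
            "z": z,
            "window_mean": mean,
            "window_sd": sd,
            "flags": np.where(degenerate, FLAG_DEGENERATE, ""),
        }
    )
    # restore caller's row order
    inverse = np.empty(n, dtype=int)
    inverse[order] = np.arange(n)
    return out_sorted.iloc[inverse].reset_index(drop=True)


def combine_replicates(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Average replicate z-scores per gene.

    Genes present in a single replicate keep that value and are flagged
    ``single_replicate``; genes whose replicates disagree in sign are still
    averaged but flagged ``discordant`` so borderline calls can be audited.
    """
    if not tables:
        raise ValueError("no replicate tables to combine")
    stacked = pd.concat(
        [t[["gene_id", "z"]].assign(_rep=i) for i, t in enumerate(tables)],
        ignore_index=True,
    )
    grouped = stacked.groupby("gene_id", sort=True)["z"]
    combined = grouped.mean().rename("z").reset_index()
    n_reps = grouped.size().to_numpy()
    signs = grouped.agg(lambda s: len(set(np.sign(s[s != 0]))) > 1).to_numpy()

    flags = np.full(len(combined), "", dtype=object)
    flags[n_reps == 1] = FLAG_SINGLE
    flags[(n_reps > 1) & signs] = FLAG_DISCORDANT
    combined["flags"] = flags
    combined["replicate"] = "combined"
    return combined
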