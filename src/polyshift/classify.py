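"""Concomitant-shift classification of combined z-scores.

A transcript is translationally inhibited (group I) when it leaves the
polysomal pool and accumulates in the non-polysomal pool — z_P at or below
-cutoff with z_NP at or above +cutoff — while its total (steady-state) RNA
is unchanged. Group II (translationally enhanced) is the mirror image.
Genes whose total RNA moves past the transcriptome cutoff are transcriptional
calls instead; a gene satisfying both a concomitant shift and a total-RNA
change cannot be attributed to translation and is left indeterminate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ShiftCall", "classify_shifts", "classify_table", "summarize_counts"]

CALLS = (
    "group_I",
    "group_II",
    "transcriptional_up",
    "transcriptional_down",
    "unchanged",
    "indeterminate",
)


@dataclass
class ShiftCall:
    gene_id: str
    z_NP: float
    z_P: float
    z_T: float | None
    call: str
    reasons: tuple[str, ...] = ()


def _is_missing(z) -> bool:
    return z is None or (isinstance(z, float) and math.isnan(z))


def classify_shifts(
    gene_id: str,
    z_np: float,
    z_p: float,
    z_t: float | None = None,
    cutoff_shift: float = 1.5,
    cutoff_total: float = 2.0,
) -> ShiftCall:
    """Classify one gene from its (z_NP, z_P, z_T) triple.

    Cutoff comparisons are inclusive (|z| exactly at the cutoff counts as
    significant). A missing z_T — e.g. a transcript not detected on the
    total-RNA array — is treated as total-unchanged, so a clean concomitant
    shift is still callable.
    """
    if cutoff_shift <= 0 or cutoff_total <= 0:
        raise ValueError("cutoffs must be > 0")
    for name, z in (("z_NP", z_np), ("z_P", z_p)):
        if _is_missing(z) or not math.isfinite(z):
            return ShiftCall(gene_id, z_np, z_p, z_t, "indeterminate",
                             (f"nonfinite_{name}",))
    t_missing = _is_missing(z_t)
    if not t_missing and not math.isfinite(z_t):
        return ShiftCall(gene_id, z_np, z_p, z_t, "indeterminate",
                         ("nonfinite_z_T",))

    total_changed = (not t_missing) and abs(z_t) > cutoff_total
    group_i = z_p <= -cutoff_shift and z_np >= cutoff_shift
    group_ii = z_p >= cutoff_shift and z_np <= -cutoff_shift

    if (group_i or group_ii) and total_changed:
        return ShiftCall(gene_id, z_np, z_p, z_t, "indeterminate",
                         ("concomitant_shift", "total_changed"))
    if group_i:
        return ShiftCall(gene_id, z_np, z_p, z_t, "group_I", ("concomitant_shift",))
    if group_ii:
        return ShiftCall(gene_id, z_np, z_p, z_t, "group_II", ("concomitant_shift",))
    if total_changed:
        call = "transcriptional_up" if z_t > 0 else "transcriptional_down"
        return ShiftCall(gene_id, z_np, z_p, z_t, call, ("total_changed",))
    return ShiftCall(gene_id, z_np, z_p, z_t, "unchanged", ())


def classify_table(
    z: pd.DataFrame,
    cutoff_shift: float = 1.5,
    cutoff_total: float = 2.0,
) -> pd.DataFrame:
    """Vector version over a table with columns gene_id, z_NP, z_P[, z_T]."""
    has_t = "z_T" in z.columns
    calls = [
        classify_shifts(
            row.gene_id,
            row.z_NP,
            row.z_P,
            getattr(row, "z_T", None) if has_t else None,
            cutoff_shift=cutoff_shift,
            cutoff_total=cutoff_total,
        )
        for row in z.itertuples(index=False)
    ]
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "z_NP": [c.z_NP for c in calls],
            "z_P": [c.z_P for c in calls],
            "z_T": [c.z_T for c in calls],
            "call": [c.call for c in calls],
            "reasons": [";".join(c.reasons) for c in calls],
        }
    )


def summarize_counts(
    calls: pd.DataFrame, cutoff_shift: float = 1.5
) -> dict[str, int]:
    """Call counts plus per-fraction tallies.

    The per-fraction entries (np_up, np_down, p_up, p_down) count every gene
    past the cutoff in that single fraction regardless of the other — the
    shape of a transcriptome-wide 'how many moved in NP, how many in P'
    summary — and np_only/p_only count genes past the cutoff in exactly one
    of the two.
    """
    out = {call: 0 for call in CALLS}
    if len(calls):
        out.update(calls["call"].value_counts().to_dict())
    z_np = calls["z_NP"].to_numpy(float) if len(calls) else np.array([])
    z_p = calls["z_P"].to_numpy(float) if len(calls) else np.array([])
    np_hit = np.abs(z_np) >= cutoff_shift
    p_hit = np.abs(z_p) >= cutoff_shift
    out["np_up"] = int((z_np >= cutoff_shift).sum())
    out["np_down"] = int((z_np <= -cutoff_shift).sum())
    out["p_up"] = int((z_p >= cutoff_shift).sum())
    out["p_down"] = int((z_p <= -cutoff_shift).sum())
    out["np_only"] = int((np_hit & ~p_hit).sum())
    out["p_only"] = int((p_hit & ~np_hit).sum())
    return out
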