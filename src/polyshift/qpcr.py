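"""Efficiency-corrected qPCR quantitation.

Implements the Pfaffl-style relative expression ratio, the 2^-ΔCt relative
quantity, signed fold-change conversion, and per-gene percentage profiles
over sucrose-gradient fractions (each fraction's quantity relative to the
sum over all fractions of the same transcript).

Efficiency E is the per-cycle amplification factor, in (1, 2]; E = 2 is
perfect doubling. ΔCt is taken as control minus sample (WT minus mutant), so
R > 1 means the transcript is lower in the mutant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "relative_expression",
    "quantity_2_delta_ct",
    "fraction_distribution",
    "signed_fold_change",
]

DEFAULT_EFFICIENCY = 2.0


def _check_efficiency(e: float, what: str = "efficiency") -> None:
    if not (1.0 < e <= 2.0):
        raise ValueError(f"{what} must be in (1, 2], got {e}")


def relative_expression(
    e_target: float, dct_target: float, e_ref: float, dct_ref: float
) -> float:
    """R = E_target^ΔCt_target / E_ref^ΔCt_ref, ΔCt = Ct(control) - Ct(sample).

    With both efficiencies at 2 this reduces to the classic 2^-ΔΔCt.
    """
    _check_efficiency(e_target, "target efficiency")
    _check_efficiency(e_ref, "reference efficiency")
    return e_target**dct_target / e_ref**dct_ref


def quantity_2_delta_ct(ct: float, ct_ref: float) -> float:
    """Relative quantity 2^-(ct - ct_ref)."""
    return 2.0 ** -(ct - ct_ref)


def signed_fold_change(ratio: float) -> float:
    """Report a ratio the way fold-change tables print it.

    Ratios >= 1 are positive fold changes; ratios < 1 are reported as the
    negative reciprocal (0.25 -> -4.0), so magnitude reads as 'fold' in both
    directions and there are no values in (-1, 1).
    """
    if ratio <= 0:
        raise ValueError(f"ratio must be > 0, got {ratio}")
    return float(ratio) if ratio >= 1.0 else -1.0 / float(ratio)


def fraction_distribution(
    records: pd.DataFrame,
    reference_records: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Percentage of a transcript per gradient fraction.

    ``records`` holds the Ct measurements of ONE gene in ONE line across >= 2
    fractions (columns: gene_id, line, fraction, replicate, ct, efficiency).
    Replicates are averaged on the linear quantity scale (q = E^-ct), then
    each fraction's quantity is expressed as a percentage of the gene's sum
    over all fractions.

    ``reference_records`` optionally carries an unaffected control transcript
    measured over the same fractions; when given, each fraction's quantity is
    divided by the same-fraction control quantity before the percentages are
    taken, correcting for fraction-to-fraction recovery differences.
    """
    if records["gene_id"].nunique() != 1 or records["line"].nunique() != 1:
        raise ValueError("records must cover exactly one gene and one line")
    eff = records["efficiency"].unique()
    if len(eff) != 1:
        raise ValueError("mixed efficiencies across fractions of one primer")
    _check_efficiency(float(eff[0]))
    e = float(eff[0])

    q = (e ** -records["ct"].astype(float)).groupby(records["fraction"]).mean()
    if len(q) < 2:
        raise ValueError("need >= 2 fractions for a distribution")

    if reference_records is not None:
        ref_eff = reference_records["efficiency"].unique()
        if len(ref_eff) != 1:
            raise ValueError("mixed efficiencies in reference records")
        _check_efficiency(float(ref_eff[0]), "reference efficiency")
        e_ref = float(ref_eff[0])
        q_ref = (
            (e_ref ** -reference_records["ct"].astype(float))
            .groupby(reference_records["fraction"])
            .mean()
        )
        missing = set(q.index) - set(q_ref.index)
        if missing:
            raise ValueError(f"reference lacks fractions: {sorted(missing)}")
        q = q / q_ref.reindex(q.index)

    pct = 100.0 * q / q.sum()
    out = pct.rename("percentage").reset_index()
    out.insert(0, "gene_id", records["gene_id"].iloc[0])
    out.insert(1, "line", records["line"].iloc[0])
    return out
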