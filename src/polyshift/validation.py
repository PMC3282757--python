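"""Microarray-vs-qPCR validation of translational-shift calls.

The packaged fixture is the published 23-transcript validation panel: per
transcript, the microarray z-scores (total, NP, P), the qPCR signed fold
changes in NP and P, and the printed verdict (Decrease / Increase / l.c.,
'lack of correspondence').

The validation rule is sign agreement of the POLYSOMAL (P) change between
platforms. NP is deliberately not part of the rule: several panel rows have
a discordant NP fold yet are printed as validated, while every 'l.c.' row
disagrees in P — P-sign agreement is the only rule consistent with all 23
printed labels, and the fixture test pins exactly that.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd

__all__ = [
    "load_table1_fixture",
    "concordance",
    "validate_records",
    "confidence_level",
    "ValidationReport",
]

_FIXTURE = "table1.tsv"
_N_ROWS = 23
# spot checks enforced at load: a corrupted fixture fails loudly
_SPOT_CHECKS = {
    ("At3g23430", "z_T"): 0.59,
    ("At3g23430", "z_NP"): 1.58,
    ("At3g23430", "z_P"): -2.3,
    ("At3g23430", "qpcr_NP"): 1.9,
    ("At3g23430", "qpcr_P"): -15.8,
    ("At2g27940", "z_NP"): -1.98,
    ("At5g15630", "qpcr_P"): 1.4,
}


@dataclass
class ValidationReport:
    n_validated: int
    n_total: int

    @property
    def confidence_percent(self) -> int:
        """Share of panel transcripts reproduced by qPCR, rounded to integer %."""
        return round(100.0 * self.n_validated / self.n_total)


def load_table1_fixture() -> pd.DataFrame:
    """The packaged 23-row validation panel.

    Columns: accession, name, z_T/z_NP/z_P (microarray z-scores; z_T is NaN
    where the transcript was not detected on the total-RNA array), qpcr_NP/
    qpcr_P (signed fold changes), change (printed verdict).
    """
    text = (resources.files("polyshift") / "data" / _FIXTURE).read_text()
    df = pd.read_csv(StringIO(text), sep="\t", na_values=["n.d."])
    if len(df) != _N_ROWS:
        raise RuntimeError(f"fixture corrupted: expected {_N_ROWS} rows, got {len(df)}")
    indexed = df.set_index("accession")
    for (acc, col), expected in _SPOT_CHECKS.items():
        got = indexed.loc[acc, col]
        if not np.isclose(got, expected):
            raise RuntimeError(
                f"fixture corrupted: {acc}.{col} = {got}, expected {expected}"
            )
    return df


def concordance(micro_z_p: float, qpcr_fold_p: float) -> bool:
    """True when the P-fraction change agrees in direction between platforms."""
    if np.isnan(micro_z_p) or np.isnan(qpcr_fold_p):
        raise ValueError("P-fraction values required for concordance")
    if qpcr_fold_p == 0 or micro_z_p == 0:
        raise ValueError("zero change is directionless; concordance indeterminate")
    return np.sign(qpcr_fold_p) == np.sign(micro_z_p)


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the concordance rule to a panel table; adds a ``validated`` column."""
    out = records.copy()
    out["validated"] = [
        concordance(z_p, q_p) for z_p, q_p in zip(records["z_P"], records["qpcr_P"])
    ]
    return out


def confidence_level(records: pd.DataFrame) -> ValidationReport:
    """Validated count and confidence percentage over a panel."""
    if len(records) == 0:
        raise ValueError("no records")
    validated = records["validated"] if "validated" in records else (
        validate_records(records)["validated"]
    )
    return ValidationReport(int(validated.sum()), int(len(records)))
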