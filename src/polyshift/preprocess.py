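"""Two-color array preprocessing: spot table -> normalized per-gene M/A values.

The chain is background correction, intensity filtering, log-ratio (M) and
mean log-intensity (A) computation with duplicate-spot averaging, then Lowess
normalization of M against A to remove intensity-dependent dye bias.

Channel 1 is the mutant sample, channel 2 the wild type, so M > 0 means the
transcript is more abundant in the mutant pool.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "SPOT_COLUMNS",
    "read_spot_table",
    "write_table",
    "subtract_background",
    "intensity_filter",
    "auto_min_intensity",
    "compute_ma",
    "lowess_normalize",
]

SPOT_COLUMNS = ["gene_id", "ch1_fg", "ch1_bg", "ch2_fg", "ch2_bg"]

FLAG_NEGATIVE = "negative_after_bg"
FLAG_LOW = "low_intensity"


def read_spot_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SPOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spot table missing columns: {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """TSV writer; optional ``# ...`` provenance line above the header."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def _add_flag(flags: pd.Series, mask: np.ndarray, flag: str) -> pd.Series:
    flags = flags.copy()
    sel = mask & (flags != "")
    flags.loc[sel] = flags.loc[sel] + ";" + flag
    flags.loc[mask & ~sel.to_numpy(bool)] = flag
    return flags


def subtract_background(raw: pd.DataFrame) -> pd.DataFrame:
    """Local (per-spot) background subtraction.

    Adds ``I1``/``I2`` columns; a spot where either channel is <= 0 after
    subtraction is flagged ``negative_after_bg`` and carries NaN intensities
    rather than a clamped floor — a fabricated ratio is worse than a missing
    one. Flagged spots are excluded downstream, never dropped here.
    """
    df = raw.copy()
    i1 = df["ch1_fg"].to_numpy(float) - df["ch1_bg"].to_numpy(float)
    i2 = df["ch2_fg"].to_numpy(float) - df["ch2_bg"].to_numpy(float)
    bad = (i1 <= 0) | (i2 <= 0)
    df["I1"] = np.where(bad, np.nan, i1)
    df["I2"] = np.where(bad, np.nan, i2)
    flags = df["flags"].fillna("") if "flags" in df else pd.Series("", index=df.index)
    df["flags"] = _add_flag(flags.astype(str), bad, FLAG_NEGATIVE)
    return df


def auto_min_intensity(corrected: pd.DataFrame) -> float:
    """Default filter threshold: twice the median background level."""
    bg = np.concatenate(
        [corrected["ch1_bg"].to_numpy(float), corrected["ch2_bg"].to_numpy(float)]
    )
    return 2.0 * float(np.median(bg))


def intensity_filter(corrected: pd.DataFrame, min_intensity: float) -> pd.DataFrame:
    """Flag spots where BOTH channels fall below ``min_intensity``.

    A spot with one bright channel is kept: a strong ratio against a dim
    partner can be a genuine signal, and dropping it would censor exactly the
    extreme log-ratios the downstream z-score is after.
    """
    if min_intensity < 0:
        raise ValueError("min_intensity must be >= 0")
    df = corrected.copy()
    low = (
        (df["I1"].to_numpy(float) < min_intensity)
        & (df["I2"].to_numpy(float) < min_intensity)
    )
    low &= ~df["flags"].str.contains(FLAG_NEGATIVE).to_numpy(bool)
    df["flags"] = _add_flag(df["flags"], low, FLAG_LOW)
    return df


def compute_ma(filtered: pd.DataFrame) -> pd.DataFrame:
    """Per-gene M = log2(I1/I2) and A = (log2 I1 + log2 I2)/2.

    Flagged spots are excluded; duplicate spots of one gene are averaged on
    the M/A scale (after the log transform), since the log-ratio is the
    modeled quantity. Raises if an unflagged nonpositive intensity slips
    through — that is a preprocessing contract violation, not data.
    """
    ok = filtered["flags"].fillna("") == ""
    df = filtered.loc[ok, ["gene_id", "I1", "I2"]]
    i1 = df["I1"].to_numpy(float)
    i2 = df["I2"].to_numpy(float)
    if np.any(~np.isfinite(i1)) or np.any(i1 <= 0) or np.any(i2 <= 0):
        raise RuntimeError("nonpositive intensity reached compute_ma unflagged")
    ma = pd.DataFrame(
        {
            "gene_id": df["gene_id"].to_numpy(),
            "M": np.log2(i1) - np.log2(i2),
            "A": 0.5 * (np.log2(i1) + np.log2(i2)),
        }
    )
    out = ma.groupby("gene_id", as_index=False, sort=True)[["M", "A"]].mean()
    out["normalized"] = False
    return out


def lowess_normalize(
    ma: pd.DataFrame, span: float = 0.4, iterations: int = 3
) -> pd.DataFrame:
    """Subtract the Lowess trend of M on A.

    span is the Lowess window fraction (default 0.4 with 3 robustness
    iterations, a common two-color choice); A is left untouched.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if len(ma) < 10:
        raise ValueError(
            "need >= 10 points for Lowess normalization; "
            "subtract the global median M instead for tiny tables"
        )
    a = ma["A"].to_numpy(float)
    m = ma["M"].to_numpy(float)
    fit = _sm_lowess(m, a, frac=span, it=iterations, return_sorted=False)
    out = ma.copy()
    out["M"] = m - fit
    out["normalized"] = True
    return out
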