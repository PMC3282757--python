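"""Synthetic data with planted ground truth for the polysome-shift pipeline.

Generates the three kinds of input the analysis consumes:

* two-color array spot tables (mutant vs. wild type, one RNA pool per array),
* qPCR Ct tables over sucrose-gradient fractions,
* 5'/3' UTR sequence sets with planted uAUGs, uORFs and stable hairpins.

Every generator is a pure function of its seed, so closed-loop tests can
compare pipeline output against the planted truth exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "CLASSES",
    "simulate_universe",
    "simulate_array",
    "simulate_ct_table",
    "simulate_utr_set",
]

#: Planted gene classes. ``group_I`` = translationally inhibited (shifted out of
#: polysomes: NP up, P down); ``group_II`` = translationally enhanced (P up,
#: NP down). Transcriptional classes move NP, P and T coherently.
CLASSES = (
    "group_I",
    "group_II",
    "transcriptional_up",
    "transcriptional_down",
    "unchanged",
)

COARSE_FRACTIONS = ("NP", "P", "T")
FINE_FRACTIONS = ("NP", "M", "LP", "HP")

# Sign of the planted log2 shift per (class, pool). Fine gradient pools inherit
# the sign of the coarse pool they belong to (M sediments with NP; LP/HP with P).
_POOL_OF = {"NP": "NP", "M": "NP", "P": "P", "LP": "P", "HP": "P", "T": "T"}
_SHIFT_SIGN = {
    "group_I": {"NP": +1.0, "P": -1.0, "T": 0.0},
    "group_II": {"NP": -1.0, "P": +1.0, "T": 0.0},
    "transcriptional_up": {"NP": +1.0, "P": +1.0, "T": +1.0},
    "transcriptional_down": {"NP": -1.0, "P": -1.0, "T": -1.0},
    "unchanged": {"NP": 0.0, "P": 0.0, "T": 0.0},
}


@dataclass
class SimConfig:
    """Study conditions for the array simulator.

    noise_sd is the per-channel log2-scale standard deviation (lognormal on
    raw intensities). dye_bias = (intercept, slope) of the linear
    intensity-dependent bias added to the log-ratio M as a function of the
    gene's true mean log2 intensity; this is the trend Lowess must remove.
    background_level is an additive constant per array, matching
    subtract-then-ratio preprocessing.
    """

    n_genes: int = 1000
    n_replicates: int = 2
    fractions: tuple[str, ...] = COARSE_FRACTIONS
    noise_sd: float = 0.25
    dye_bias: tuple[float, float] = (0.0, 0.0)
    background_level: float = 50.0
    seed: int = 0
    #: log2-intensity range genes are drawn from (uniform); spans the typical
    #: dynamic range of detected spots, with the floor above the default
    #: low-intensity filter (2x background) so simulated genes model the
    #: expressed, detectable transcriptome.
    abundance_log2_range: tuple[float, float] = (7.0, 13.0)

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        unknown = set(self.fractions) - set(_POOL_OF)
        if unknown:
            raise ValueError(f"unknown fractions: {sorted(unknown)}")


def _rng(seed: int, *stream: int) -> np.random.Generator:
    """Independent child stream of the master seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


def simulate_universe(
    config: SimConfig,
    class_counts: dict[str, int] | None = None,
    effect_size: float = 1.5,
) -> pd.DataFrame:
    """Lay out the gene universe with planted classes.

    Returns a truth table with one row per gene: ``gene_id``, ``true_class``,
    ``base_abundance`` (linear intensity units) and ``shift_effect`` (log2,
    positive; the sign applied per fraction is fixed by the class).
    Genes not claimed by ``class_counts`` are labeled ``unchanged``.
    """
    class_counts = dict(class_counts or {})
    for cls in class_counts:
        if cls not in CLASSES or cls == "unchanged":
            raise ValueError(f"cannot plant class {cls!r}")
    n_special = sum(class_counts.values())
    if n_special > config.n_genes:
        raise ValueError(
            f"class_counts ask for {n_special} genes but n_genes={config.n_genes}"
        )
    if effect_size <= 0:
        raise ValueError("effect_size must be > 0 (a null shift cannot be planted)")

    rng = _rng(config.seed, 1)
    width = max(4, len(str(config.n_genes)))
    gene_ids = np.array([f"g{i:0{width}d}" for i in range(1, config.n_genes + 1)])

    labels = np.full(config.n_genes, "unchanged", dtype=object)
    # Planted genes are scattered over the whole intensity range: assign by
    # seeded permutation, not by block, so windows see a mix of classes.
    order = rng.permutation(config.n_genes)
    pos = 0
    for cls in sorted(class_counts):
        k = class_counts[cls]
        labels[order[pos : pos + k]] = cls
        pos += k

    lo, hi = config.abundance_log2_range
    base = 2.0 ** rng.uniform(lo, hi, size=config.n_genes)
    effect = np.where(labels == "unchanged", 0.0, float(effect_size))
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_class": labels,
            "base_abundance": base,
            "shift_effect": effect,
        }
    )


def simulate_array(
    truth: pd.DataFrame,
    fraction: str,
    replicate: int,
    config: SimConfig,
) -> pd.DataFrame:
    """One two-color array: mutant (channel 1) vs. wild type (channel 2).

    Channel intensities are ``background + base * 2**(shift + bias + noise)``
    with independent lognormal noise per channel; the dye bias enters the
    mutant channel as a linear function of the gene's true mean log2
    intensity, so with noise off the observed log-ratio is exactly
    ``intercept + slope * log2(base_abundance)`` (plus the planted shift).
    """
    if fraction not in config.fractions:
        raise ValueError(f"fraction {fraction!r} not in config.fractions")
    pool = _POOL_OF[fraction]
    frac_index = list(config.fractions).index(fraction)
    rng = _rng(config.seed, 2, frac_index, int(replicate))

    base = truth["base_abundance"].to_numpy(float)
    a_true = np.log2(base)
    sign = truth["true_class"].map(lambda c: _SHIFT_SIGN[c][pool]).to_numpy(float)
    delta = sign * truth["shift_effect"].to_numpy(float)

    b0, b1 = config.dye_bias
    n = len(truth)
    eps_wt = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd else np.zeros(n)
    eps_mut = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd else np.zeros(n)

    bg = float(config.background_level)
    ch_wt = bg + base * 2.0 ** eps_wt
    ch_mut = bg + base * 2.0 ** (delta + b0 + b1 * a_true + eps_mut)
    return pd.DataFrame(
        {
            "gene_id": truth["gene_id"].to_numpy(),
            "ch1_fg": ch_mut,
            "ch1_bg": bg,
            "ch2_fg": ch_wt,
            "ch2_bg": bg,
        }
    )


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

# Mean percentage of a transcript's molecules per gradient pool. The WT-like
# profile puts ~70% of an ordinary message on polysomes, the typical picture
# for an actively translated mRNA in seedlings; planted classes move mass
# between the NP-side and P-side pools.
_PROFILE_MEANS = {
    tuple(FINE_FRACTIONS): {
        "unchanged": (0.15, 0.15, 0.30, 0.40),
        "group_I": (0.40, 0.25, 0.20, 0.15),
        "group_II": (0.05, 0.10, 0.30, 0.55),
        "transcriptional_up": (0.15, 0.15, 0.30, 0.40),
        "transcriptional_down": (0.15, 0.15, 0.30, 0.40),
    },
    ("NP", "P"): {
        "unchanged": (0.30, 0.70),
        "group_I": (0.65, 0.35),
        "group_II": (0.15, 0.85),
        "transcriptional_up": (0.30, 0.70),
        "transcriptional_down": (0.30, 0.70),
    },
}


def simulate_ct_table(
    truth: pd.DataFrame,
    genes: list[str],
    fractions: list[str] | tuple[str, ...] = FINE_FRACTIONS,
    efficiency: dict[str, float] | None = None,
    ct_intercept: float = 40.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    line: str = "iso4E_1",
    profile_concentration: float = 200.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct values from planted per-fraction abundances.

    Per gene, a fraction-weight vector is drawn (seeded Dirichlet around the
    class profile) and ``Ct = ct_intercept - log_E(abundance) + noise`` with
    the primer's efficiency E. Returns ``(records, profiles)`` where
    ``profiles`` holds the planted percentage of each gene per fraction —
    the ground truth the quantitation stage must recover.
    """
    efficiency = dict(efficiency or {})
    for primer, e in efficiency.items():
        if not (1.0 < e <= 2.0):
            raise ValueError(f"efficiency for {primer!r} must be in (1, 2], got {e}")
    fractions = tuple(fractions)
    means = _PROFILE_MEANS.get(fractions)
    rng = _rng(seed, 3)
    truth_by_id = truth.set_index("gene_id")

    records: list[dict] = []
    profile_rows: list[dict] = []
    for gene in genes:
        if gene not in truth_by_id.index:
            raise KeyError(f"gene {gene!r} not in truth table")
        row = truth_by_id.loc[gene]
        if means is None:
            mean_w = np.full(len(fractions), 1.0 / len(fractions))
        else:
            mean_w = np.asarray(means[row["true_class"]], dtype=float)
        weights = rng.dirichlet(mean_w * profile_concentration)
        abundance = row["base_abundance"] * weights
        if np.any(abundance <= 0):
            raise ValueError(f"nonpositive abundance for gene {gene!r}")
        e = efficiency.get(gene, 2.0)
        profile_rows.append(
            {"gene_id": gene, "line": line}
            | {f: 100.0 * w for f, w in zip(fractions, weights)}
        )
        for rep in range(1, n_replicates + 1):
            for frac, ab in zip(fractions, abundance):
                ct = ct_intercept - math.log(ab, e)
                if noise_sd:
                    ct += rng.normal(0.0, noise_sd)
                records.append(
                    {
                        "gene_id": gene,
                        "line": line,
                        "fraction": frac,
                        "replicate": rep,
                        "ct": ct,
                        "efficiency": e,
                    }
                )
    return pd.DataFrame(records), pd.DataFrame(profile_rows)


# ---------------------------------------------------------------------------
# UTR sequences
# ---------------------------------------------------------------------------

UTR_FEATURES = ("uaug", "uorf", "hairpin_stable", "long", "short")

#: Planted hairpin: 10 G:C stem pairs closed over a 4-nt loop. Under the
#: builtin energy model (G:C -3.0 kcal/mol, +4.0 per hairpin loop) this folds
#: to at most -26 kcal/mol, safely below the -20 stability threshold.
_HAIRPIN = "G" * 10 + "AAAA" + "C" * 10


def simulate_utr_set(
    n: int,
    plan: dict[str, int] | None = None,
    seed: int = 0,
    length_range: tuple[int, int] = (40, 250),
    uorf_internal_codons: int = 2,
):
    """Generate ``n`` 5'UTR-like sequences with planted features.

    The background alphabet is {A, C} only, which can form no base pair and
    no AUG/stop codon under the builtin model — every uAUG, uORF and stable
    hairpin present is one the plan planted. Feature counts in ``plan`` are
    assigned to seeded subsets of sequences (a sequence may carry several
    features). Returns ``(records, truth)`` where records are Biopython
    ``SeqRecord`` objects and truth is a per-sequence feature table.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    plan = dict(plan or {})
    unknown = set(plan) - set(UTR_FEATURES)
    if unknown:
        raise ValueError(f"unknown plan features: {sorted(unknown)}")
    for feat, count in plan.items():
        if count < 0 or count > n:
            raise ValueError(f"plan[{feat!r}]={count} inconsistent with n={n}")
    if plan.get("long", 0) + plan.get("short", 0) > n:
        raise ValueError("long + short counts exceed n")

    rng = _rng(seed, 4)
    lo, hi = length_range
    uorf_len = 6 + 3 * uorf_internal_codons

    # Length classes: 'long' sequences first, then 'short', remainder free.
    lengths = np.empty(n, dtype=int)
    n_long = plan.get("long", 0)
    n_short = plan.get("short", 0)
    lengths[:n_long] = rng.integers(max(100, lo), max(101, hi + 1), size=n_long)
    lengths[n_long : n_long + n_short] = rng.integers(lo, 100, size=n_short)
    rest = n - n_long - n_short
    lengths[n_long + n_short :] = rng.integers(lo, hi + 1, size=rest)

    def pick(count: int) -> set[int]:
        return set(rng.choice(n, size=count, replace=False)) if count else set()

    with_uorf = pick(plan.get("uorf", 0))
    with_uaug = pick(plan.get("uaug", 0))
    with_hairpin = pick(plan.get("hairpin_stable", 0))

    records, truth_rows = [], []
    for i in range(n):
        length = int(lengths[i])
        seq = list(rng.choice(["A", "C"], size=length, p=[0.55, 0.45]))
        if i in with_hairpin:
            if length < len(_HAIRPIN) + 4:
                raise ValueError(f"sequence {i} too short for a planted hairpin")
            seq[2 : 2 + len(_HAIRPIN)] = _HAIRPIN
        if i in with_uorf:
            if length < uorf_len:
                raise ValueError(f"sequence {i} too short for a planted uORF")
            start = min(2 * length // 3, length - uorf_len)
            start = max(start, 2 + len(_HAIRPIN) if i in with_hairpin else 0)
            if start + uorf_len > length:
                raise ValueError(f"sequence {i} cannot fit hairpin and uORF")
            body = "".join(rng.choice(["A", "C"], size=3 * uorf_internal_codons))
            seq[start : start + uorf_len] = "ATG" + body + "TAA"
        if i in with_uaug and i not in with_uorf:
            if length < 6:
                raise ValueError(f"sequence {i} too short for a planted uAUG")
            # keep clear of the hairpin block when both are planted
            pos = max(length - 6, 2 + len(_HAIRPIN) if i in with_hairpin else 0)
            if pos + 3 > length:
                raise ValueError(f"sequence {i} cannot fit hairpin and uAUG")
            seq[pos : pos + 3] = "ATG"
        sequence = "".join(seq)
        acc = f"synthUTR{i + 1:04d}"
        records.append(SeqRecord(Seq(sequence), id=acc, description=""))
        truth_rows.append(
            {
                "accession": acc,
                "length": length,
                "length_class": "ge_100" if length >= 100 else "lt_100",
                "has_uaug": i in with_uaug or i in with_uorf,
                "has_uorf": i in with_uorf,
                "hairpin_planted": i in with_hairpin,
            }
        )
    return records, pd.DataFrame(truth_rows, columns=[
        "accession", "length", "length_class", "has_uaug", "has_uorf",
        "hairpin_planted",
    ])
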