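"""UTR feature annotation: length classes, folding stability, uAUG/uORF
scanning and motif hits, with group-level percentage summaries.

Sequences are accepted as DNA or RNA (U and T are interchangeable on input);
internally everything is DNA-alphabet, reported coordinates are 1-based
inclusive, and reported sequences/motifs use RNA letters, the convention of
the UTR literature.

The builtin folding engine is a deliberately simple nearest-pair surrogate
for a full thermodynamic folder (mfold/RNAfold): a Nussinov-style dynamic
program over nested structures with per-pair stacking-free energies
(G:C -3.0, A:U -2.0, G:U -1.0 kcal/mol), a +4.0 kcal/mol penalty per hairpin
loop and a minimum loop of 3 nt. Its ΔG values are NOT interchangeable with
mfold's; the stability threshold is meaningful only per engine, so every
output row records which engine produced it.
"""

from __future__ import annotations

import re
import subprocess
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UTRRecord",
    "read_utr_fasta",
    "filter_full_length",
    "classify_length",
    "find_uaugs",
    "find_uorfs",
    "fold_mfe",
    "PatternRegistry",
    "scan_motifs",
    "annotate",
    "summarize_utr_table",
]

_VALID = set("ACGT")
_STOPS = {"TAA", "TAG", "TGA"}

#: kcal/mol per closing pair; Watson-Crick plus the G:U wobble.
PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "T"): -2.0, ("T", "A"): -2.0,
    ("G", "T"): -1.0, ("T", "G"): -1.0,
}
HAIRPIN_PENALTY = 4.0
MIN_LOOP = 3
STABILITY_THRESHOLD = -20.0  # kcal/mol; "stable" means delta_g strictly below


@dataclass(frozen=True)
class UTRRecord:
    """One UTR sequence; ``side`` is five_prime or three_prime."""

    accession: str
    side: str
    sequence: str = field(repr=False)

    def __post_init__(self):
        if self.side not in ("five_prime", "three_prime"):
            raise ValueError(f"bad side {self.side!r}")
        seq = self.sequence.upper().replace("U", "T")
        if not seq:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"{self.accession}: invalid characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def rna(self) -> str:
        return self.sequence.replace("T", "U")


def read_utr_fasta(path, side: str) -> list[UTRRecord]:
    from Bio import SeqIO

    return [
        UTRRecord(rec.id, side, str(rec.seq))
        for rec in SeqIO.parse(path, "fasta")
    ]


def filter_full_length(
    records: list[UTRRecord],
    reference_list: set[str],
    mode: str = "keep_listed",
) -> list[UTRRecord]:
    """Membership filter against a verified full-length accession list.

    ``keep_listed`` retains only accessions on the list (the default:
    the list names sequences verified to carry complete 5' ends);
    ``drop_listed`` removes them instead. Order is preserved.
    """
    if mode not in ("keep_listed", "drop_listed"):
        raise ValueError(f"bad mode {mode!r}")
    reference_list = set(reference_list)
    if mode == "keep_listed":
        if not reference_list:
            import warnings

            warnings.warn("empty reference list with keep_listed: output is empty")
        return [r for r in records if r.accession in reference_list]
    return [r for r in records if r.accession not in reference_list]


def classify_length(record: UTRRecord, threshold: int = 100) -> str:
    """``ge_100`` iff length >= threshold (boundary inclusive), else ``lt_100``."""
    return "ge_100" if record.length >= threshold else "lt_100"


def find_uaugs(record: UTRRecord) -> list[int]:
    """1-based start positions of every AUG in a 5'UTR, overlaps included."""
    if record.side != "five_prime":
        raise ValueError("uAUG scan is defined on 5'UTRs only")
    return [m.start() + 1 for m in re.finditer(r"(?=ATG)", record.sequence)]


def find_uorfs(
    record: UTRRecord, min_internal_codons: int = 1
) -> list[tuple[int, int, int]]:
    """Upstream ORFs: uAUGs with an in-frame stop wholly inside the UTR.

    Returns (start, stop_end, n_internal_codons) triples, 1-based inclusive;
    a uAUG whose reading frame runs off the end of the UTR is not a uORF
    (it may be the main start, or complete only in the mRNA context).
    """
    seq = record.sequence
    out = []
    for start in find_uaugs(record):
        i = start - 1 + 3  # first codon after the AUG, 0-based
        codons = 0
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if codon in _STOPS:
                if codons >= min_internal_codons:
                    out.append((start, i + 3, codons))
                break
            codons += 1
            i += 3
    return out


# ---------------------------------------------------------------------------
# Folding
# ---------------------------------------------------------------------------


def _fold_builtin(seq: str) -> float:
    """Minimum free energy over nested structures.

    Wp[i, j] = best energy on [i, j] using at least one pair; V[i, j] = best
    energy given i·j paired, where the closed region is either a hairpin loop
    (+4.0) or contains further pairs. Only hairpin loops carry a loop term,
    so the total energy decomposes exactly over the recursion. Unreachable
    states are +inf.
    """
    n = len(seq)
    INF = np.inf
    # pairwise energies e[i, j]
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    emat = np.full((n, n), INF)
    for (a, b), energy in PAIR_ENERGY.items():
        emat[np.ix_(codes == ord(a), codes == ord(b))] = energy

    V = np.full((n, n), INF)
    Wp = np.full((n, n), INF)
    W = np.zeros((n, n))  # min(0, Wp)

    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            if emat[i, j] < INF:
                inner = Wp[i + 1, j - 1]
                V[i, j] = emat[i, j] + min(HAIRPIN_PENALTY, inner)
            # leave i unpaired, or pair i with some k in [i+MIN_LOOP+1, j]
            k_lo = i + MIN_LOOP + 1
            cand = V[i, k_lo : j + 1].copy()
            if j > k_lo:
                cand[:-1] += W[k_lo + 1 : j + 1, j]
            best = min(Wp[i + 1, j], cand.min())
            Wp[i, j] = best
            W[i, j] = min(0.0, best)

    total = Wp[0, n - 1] if n else INF
    return float(min(0.0, total)) if np.isfinite(total) else 0.0


def _fold_external(seq: str, command: tuple[str, ...]) -> float:
    """Delegate to an external folding program (e.g. RNAfold) and parse ΔG."""
    proc = subprocess.run(
        list(command), input=seq + "\n", capture_output=True, text=True, check=True
    )
    match = re.search(r"\((\s*-?\d+\.?\d*)\)\s*$", proc.stdout.strip().splitlines()[-1])
    if not match:
        raise RuntimeError(f"could not parse ΔG from {command[0]} output")
    return float(match.group(1))


def fold_mfe(
    record: UTRRecord,
    engine: str = "builtin",
    external_command: tuple[str, ...] = ("RNAfold", "--noPS"),
) -> float:
    """ΔG (kcal/mol) of the best predicted fold; never positive.

    Sequences shorter than 8 nt return 0.0 (no fold worth scoring under the
    builtin model). ΔG values from different engines are not comparable.
    """
    if engine == "builtin":
        if record.length < 8:
            return 0.0
        return _fold_builtin(record.sequence)
    if engine == "external":
        return _fold_external(record.rna, external_command)
    raise ValueError(f"unknown engine {engine!r}")


# ---------------------------------------------------------------------------
# Motifs
# ---------------------------------------------------------------------------


@dataclass
class PatternRegistry:
    """Named motif patterns, each bound to a UTR side.

    Two builtins ship by default, both documented stand-ins for the original
    web-scanner descriptors (which are not public):

    * ``cpe`` — the canonical cytoplasmic polyadenylation element consensus
      UUUUUAU, matched exactly on 3'UTRs (override with any regex);
    * ``ires_like`` — a pyrimidine-tract proxy on 5'UTRs: any window of >= 25
      nt with >= 80% C/U content; overlapping windows are merged.
    """

    regex_patterns: dict[str, tuple[str, str]] = field(default_factory=dict)
    ires_min_len: int = 25
    ires_min_pyrimidine: float = 0.80
    include_builtin_ires: bool = True

    @classmethod
    def default(cls) -> "PatternRegistry":
        return cls(regex_patterns={"cpe": ("three_prime", "TTTTTAT")})

    def compiled(self) -> dict[str, tuple[str, re.Pattern]]:
        out = {}
        for name, (side, pattern) in self.regex_patterns.items():
            try:
                out[name] = (side, re.compile(pattern.upper().replace("U", "T")))
            except re.error as exc:
                raise ValueError(f"malformed pattern {name!r}: {exc}") from exc
        return out


def _ires_like_hits(seq: str, min_len: int, min_pyr: float) -> list[tuple[int, int]]:
    n = len(seq)
    if n < min_len:
        return []
    pyr = np.array([c in "CT" for c in seq], dtype=int)
    csum = np.concatenate([[0], np.cumsum(pyr)])
    content = (csum[min_len:] - csum[:-min_len]) / min_len
    hit = content >= min_pyr
    # merge overlapping windows into maximal intervals (1-based inclusive)
    intervals = []
    for start in np.flatnonzero(hit):
        lo, hi = start + 1, start + min_len
        if intervals and lo <= intervals[-1][1] + 1:
            intervals[-1] = (intervals[-1][0], hi)
        else:
            intervals.append((lo, hi))
    return intervals


def scan_motifs(
    record: UTRRecord, patterns: PatternRegistry | None = None
) -> dict[str, list[tuple[int, int]]]:
    """All match intervals (1-based inclusive) per pattern on the right side."""
    if patterns is None:
        patterns = PatternRegistry.default()
    hits: dict[str, list[tuple[int, int]]] = {}
    for name, (side, rx) in patterns.compiled().items():
        if side != record.side:
            continue
        hits[name] = [
            (m.start() + 1, m.start() + len(m.group()))
            for m in rx.finditer(record.sequence)
        ]
    if patterns.include_builtin_ires and record.side == "five_prime":
        hits["ires_like"] = _ires_like_hits(
            record.sequence, patterns.ires_min_len, patterns.ires_min_pyrimidine
        )
    return hits


# ---------------------------------------------------------------------------
# Per-record annotation and group summaries
# ---------------------------------------------------------------------------


def annotate(
    record: UTRRecord,
    engine: str = "builtin",
    patterns: PatternRegistry | None = None,
    stability_threshold: float = STABILITY_THRESHOLD,
    min_internal_codons: int = 1,
) -> dict:
    """Full feature set for one UTR record, as a flat dict (one TSV row)."""
    delta_g = fold_mfe(record, engine=engine)
    row = {
        "accession": record.accession,
        "side": record.side,
        "length": record.length,
        "length_class": classify_length(record),
        "delta_g": delta_g,
        "stable": delta_g < stability_threshold,
        "engine": engine,
    }
    if record.side == "five_prime":
        uaugs = find_uaugs(record)
        uorfs = find_uorfs(record, min_internal_codons=min_internal_codons)
        row["n_uaug"] = len(uaugs)
        row["n_uorf"] = len(uorfs)
        row["uaug_positions"] = ",".join(map(str, uaugs))
        row["uorfs"] = ";".join(f"{s}-{e}({c})" for s, e, c in uorfs)
    else:
        row["n_uaug"] = 0
        row["n_uorf"] = 0
        row["uaug_positions"] = ""
        row["uorfs"] = ""
    for name, intervals in scan_motifs(record, patterns).items():
        row[f"n_{name}"] = len(intervals)
    return row


#: Feature -> predicate over an annotation row; the Table-2-style summary
#: reports the percentage of records in each group satisfying each.
_SUMMARY_FEATURES = {
    "ge_100": lambda r: r["length_class"] == "ge_100",
    "lt_100": lambda r: r["length_class"] == "lt_100",
    "stable_structure": lambda r: bool(r["stable"]),
    "uaug": lambda r: r.get("n_uaug", 0) > 0,
    "uorf": lambda r: r.get("n_uorf", 0) > 0,
    "ires_like": lambda r: r.get("n_ires_like", 0) > 0,
    "cpe": lambda r: r.get("n_cpe", 0) > 0,
}


def summarize_utr_table(
    features_by_group: dict[str, pd.DataFrame],
    random_pool: list[UTRRecord] | None = None,
    n_random: int = 80,
    seed: int = 0,
    engine: str = "builtin",
    patterns: PatternRegistry | None = None,
) -> pd.DataFrame:
    """Percentage of records per group carrying each UTR feature.

    Rows are features, columns are groups; an extra ``random`` column is the
    baseline from a seeded sample of ``n_random`` accessions out of
    ``random_pool``, annotated with the same engine and patterns. Length
    classes are complementary so their two percentages sum to 100 per group.
    """
    if not features_by_group:
        raise ValueError("no groups to summarize")
    for name, df in features_by_group.items():
        if len(df) == 0:
            raise ValueError(f"group {name!r} is empty")
    columns = dict(features_by_group)
    if random_pool is not None:
        if n_random > len(random_pool):
            raise ValueError(
                f"n_random={n_random} exceeds pool size {len(random_pool)}"
            )
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(random_pool), size=n_random, replace=False)
        columns["random"] = pd.DataFrame(
            [annotate(random_pool[i], engine=engine, patterns=patterns)
             for i in sorted(chosen)]
        )
    out = {}
    for group, df in columns.items():
        rows = df.to_dict("records")
        out[group] = {
            feat: 100.0 * sum(pred(r) for r in rows) / len(rows)
            for feat, pred in _SUMMARY_FEATURES.items()
        }
    result = pd.DataFrame(out)
    result.index.name = "feature"
    return result
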