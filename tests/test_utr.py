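"""UTR feature scanning and the builtin folding surrogate.

The folding oracle enumerates every nested structure (minimum loop 3) on
short sequences and scores it with the same additive energy model, entirely
independently of the dynamic program.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from polyshift.synthetic import simulate_utr_set
from polyshift.utr import (
    HAIRPIN_PENALTY,
    MIN_LOOP,
    PAIR_ENERGY,
    PatternRegistry,
    UTRRecord,
    classify_length,
    filter_full_length,
    find_uaugs,
    find_uorfs,
    fold_mfe,
    scan_motifs,
    summarize_utr_table,
    annotate,
)


def rec5(seq, acc="x"):
    return UTRRecord(acc, "five_prime", seq)


def rec3(seq, acc="x"):
    return UTRRecord(acc, "three_prime", seq)


# --- independent folding oracle -------------------------------------------


def enumerate_structures(seq):
    """All nested pair sets with minimum loop 3, by brute recursion."""
    n = len(seq)

    def pairable(i, j):
        return (seq[i], seq[j]) in PAIR_ENERGY and j - i > MIN_LOOP

    memo = {}

    def rec(i, j):
        if (i, j) in memo:
            return memo[(i, j)]
        if j - i < MIN_LOOP + 1:
            return [frozenset()]
        out = list(rec(i + 1, j))
        for k in range(i + MIN_LOOP + 1, j + 1):
            if not pairable(i, k):
                continue
            inner = rec(i + 1, k - 1)
            outer = rec(k + 1, j) if k + 1 <= j else [frozenset()]
            for s1 in inner:
                for s2 in outer:
                    out.append(frozenset({(i, k)}) | s1 | s2)
        memo[(i, j)] = out
        return out

    return rec(0, n - 1) if n else [frozenset()]


def oracle_energy(seq, structure):
    total = 0.0
    for a, b in structure:
        total += PAIR_ENERGY[(seq[a], seq[b])]
        is_hairpin = not any(a < c and d < b for c, d in structure if (c, d) != (a, b))
        if is_hairpin:
            total += HAIRPIN_PENALTY
    return total


def oracle_mfe(seq):
    return min((oracle_energy(seq, s) for s in enumerate_structures(seq)), default=0.0)


# --- tests -----------------------------------------------------------------


class TestLengthAndFiltering:
    @pytest.mark.parametrize(
        "length,expected", [(100, "ge_100"), (99, "lt_100"), (1, "lt_100")]
    )
    def test_length_class_boundary(self, length, expected):
        assert classify_length(rec5("A" * length)) == expected

    def test_filter_modes(self):
        records = [rec5("ACA", acc=f"r{i}") for i in range(5)]
        listed = {"r1", "r3"}
        kept = filter_full_length(records, listed, "keep_listed")
        assert [r.accession for r in kept] == ["r1", "r3"]
        dropped = filter_full_length(records, listed, "drop_listed")
        assert [r.accession for r in dropped] == ["r0", "r2", "r4"]
        identity = filter_full_length(records, {"zz"}, "drop_listed")
        assert identity == records

    def test_empty_keep_list_warns_and_empties(self):
        with pytest.warns(UserWarning):
            assert filter_full_length([rec5("ACA")], set(), "keep_listed") == []


class TestUaugUorf:
    def test_uaug_positions(self):
        assert find_uaugs(rec5("CCCAUGCC")) == [4]
        assert find_uaugs(rec5("AUGAUG")) == [1, 4]
        assert find_uaugs(rec5("CCCCCC")) == []
        # overlapping occurrences are all reported
        assert find_uaugs(rec5("ATGATGATG")) == [1, 4, 7]

    def test_uaug_rejects_three_prime(self):
        with pytest.raises(ValueError):
            find_uaugs(rec3("CCCATG"))

    def test_uorf_requires_in_frame_stop_within_utr(self):
        assert find_uorfs(rec5("CCAUGAAAUAGCC")) == [(3, 11, 1)]
        assert find_uorfs(rec5("CCAUGAAACC")) == []

    def test_min_internal_codons_semantics(self):
        assert find_uorfs(rec5("AUGUAA"), min_internal_codons=1) == []
        assert find_uorfs(rec5("AUGUAA"), min_internal_codons=0) == [(1, 6, 0)]

    @given(st.text(alphabet="ACGU", min_size=0, max_size=60))
    def test_uorf_starts_subset_of_uaugs(self, seq):
        if not seq:
            return
        record = rec5(seq)
        starts = {s for s, _, _ in find_uorfs(record, min_internal_codons=0)}
        assert starts <= set(find_uaugs(record))


class TestFolding:
    def test_unpairable_sequence(self):
        assert fold_mfe(rec5("AAAAAAAA")) == 0.0

    def test_gc_hairpin_closed_form(self):
        """Five G:C pairs (-15) closing one hairpin loop (+4)."""
        assert fold_mfe(rec5("GGGGGAAAACCCCC")) == pytest.approx(-11.0)

    def test_short_sequences_score_zero(self):
        assert fold_mfe(rec5("GGGCCCC")) == 0.0  # length 7 < 8

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 13))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            assert fold_mfe(rec5(seq)) == pytest.approx(oracle_mfe(seq), abs=1e-9), seq

    def test_reversal_invariance(self, rng):
        """Reversing a sequence maps each pair (i, j) onto (n-1-j, n-1-i)
        with the same two bases, so the MFE is exactly preserved. (Reverse
        COMPLEMENT is not a symmetry of this model: a G:U wobble pair maps
        onto A:C, which cannot pair.)"""
        for _ in range(25):
            n = int(rng.integers(10, 40))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            assert fold_mfe(rec5(seq)) == pytest.approx(fold_mfe(rec5(seq[::-1])))

    def test_reverse_complement_invariance_without_wobble(self, rng):
        """On G/C-only sequences (no wobble pairs possible) reverse
        complementation is a symmetry."""
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(10):
            n = int(rng.integers(10, 30))
            seq = "".join(rng.choice(list("GC"), size=n))
            rc = seq.translate(comp)[::-1]
            assert fold_mfe(rec5(seq)) == pytest.approx(fold_mfe(rec5(rc)))

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            rec5("ACGTN")


class TestMotifs:
    def test_cpe_literal_match(self):
        hits = scan_motifs(rec3("AAAUUUUUAUGG"))
        assert hits["cpe"] == [(4, 10)]

    def test_pyrimidine_tract_flags_ires_like(self):
        hits = scan_motifs(rec5("CU" * 15))
        assert len(hits["ires_like"]) >= 1

    def test_purine_run_has_no_ires(self):
        hits = scan_motifs(rec5("AG" * 20))
        assert hits["ires_like"] == []

    def test_empty_registry_no_hits(self):
        registry = PatternRegistry(regex_patterns={}, include_builtin_ires=False)
        assert scan_motifs(rec5("CCCAUGCC"), registry) == {}

    def test_malformed_pattern_rejected(self):
        registry = PatternRegistry(regex_patterns={"bad": ("five_prime", "(((")})
        with pytest.raises(ValueError, match="malformed"):
            scan_motifs(rec5("ACGU"), registry)

    def test_side_mismatch_is_silent_skip(self):
        hits = scan_motifs(rec5("UUUUUAU"))  # cpe is a 3'UTR pattern
        assert "cpe" not in hits


class TestSummarize:
    @staticmethod
    def _features(records):
        return pd.DataFrame(
            [annotate(UTRRecord(r.id, "five_prime", str(r.seq))) for r in records]
        )

    def test_planted_fractions_recovered(self):
        records, truth = simulate_utr_set(
            10, {"uorf": 4, "hairpin_stable": 5, "long": 6, "short": 4}, seed=9
        )
        table = summarize_utr_table({"group_I": self._features(records)})
        col = table["group_I"]
        assert col["uorf"] == pytest.approx(40.0)
        assert col["uaug"] == pytest.approx(40.0)
        assert col["stable_structure"] == pytest.approx(50.0)
        assert col["ge_100"] == pytest.approx(60.0)
        assert col["ge_100"] + col["lt_100"] == pytest.approx(100.0)

    def test_all_percentages_in_range(self):
        records, _ = simulate_utr_set(6, {"uaug": 3}, seed=5)
        table = summarize_utr_table({"g": self._features(records)})
        assert ((table >= 0) & (table <= 100)).all().all()

    def test_random_baseline_deterministic(self):
        pool_records, _ = simulate_utr_set(30, {"uaug": 10, "long": 12}, seed=21)
        pool = [UTRRecord(r.id, "five_prime", str(r.seq)) for r in pool_records]
        group_records, _ = simulate_utr_set(4, {"uorf": 2}, seed=22)
        groups = {"group_I": self._features(group_records)}
        t1 = summarize_utr_table(groups, pool, n_random=10, seed=7)
        t2 = summarize_utr_table(groups, pool, n_random=10, seed=7)
        pd.testing.assert_frame_equal(t1, t2)
        assert "random" in t1.columns

    def test_oversized_baseline_rejected(self):
        records, _ = simulate_utr_set(4, {}, seed=1)
        pool = [UTRRecord(r.id, "five_prime", str(r.seq)) for r in records]
        with pytest.raises(ValueError, match="n_random"):
            summarize_utr_table(
                {"g": self._features(records)}, pool, n_random=80, seed=1
            )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            summarize_utr_table({"g": pd.DataFrame()})
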