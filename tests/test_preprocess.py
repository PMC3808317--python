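"""Cleaning, collapsing and library-summary behaviour."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirstress.preprocess import (
    RawRead,
    clean_reads,
    collapse_to_tags,
    merge_tag_sets,
    read_sequences,
    summarize_libraries,
    tags_to_collapsed_fasta,
)

ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"
ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"


def _read(seq: str, name: str = "r") -> RawRead:
    return RawRead(name, seq, "I" * len(seq))


def _random_insert(rng: random.Random, n: int) -> str:
    # rejection-sample inserts that would trip the poly(A) or adapter rules
    while True:
        s = "".join(rng.choice("ACGT") for _ in range(n))
        if s.count("A") / n < 0.8 and "A" * 10 not in s and ADAPTER3[:8] not in s:
            return s


class TestCleaning:
    def test_adapter_dimer_discarded_as_no_insert(self):
        result = clean_reads([_read(ADAPTER3)], ADAPTER3)
        assert result.tally["no_insert"] == 1
        assert result.sequences == []

    def test_clean_insert_retained_with_adapter_removed(self):
        insert = "GCGTATGAGGAGCCAAGCATA"  # 21 nt
        result = clean_reads([_read(insert + ADAPTER3)], ADAPTER3)
        assert result.sequences == [(insert, 1)]
        assert result.tally["kept"] == 1

    def test_planted_violations_match_per_read_oracle(self):
        """A batch with planted rule violations produces the exact tally
        predicted by applying the rules read by read."""
        rng = random.Random(42)
        reads, expected = [], {"polyA": 0, "too_short": 0, "adapter5": 0, "kept": 0}
        for _ in range(10):  # poly(A) inserts
            reads.append(_read("A" * 21 + ADAPTER3))
            expected["polyA"] += 1
        for _ in range(5):  # too-short inserts
            reads.append(_read(_random_insert(rng, 10) + ADAPTER3))
            expected["too_short"] += 1
        for _ in range(5):  # 5'-adapter contaminants
            reads.append(_read(ADAPTER5[-8:] + _random_insert(rng, 21) + ADAPTER3))
            expected["adapter5"] += 1
        for _ in range(80):
            reads.append(_read(_random_insert(rng, 21) + ADAPTER3))
            expected["kept"] += 1
        rng.shuffle(reads)
        result = clean_reads(reads, ADAPTER3, ADAPTER5)
        for rule, n in expected.items():
            assert result.tally[rule] == n

    def test_cleaning_is_idempotent(self):
        rng = random.Random(7)
        reads = [_read(_random_insert(rng, rng.randint(15, 30)) + ADAPTER3) for _ in range(200)]
        first = clean_reads(reads, ADAPTER3, ADAPTER5)
        again = clean_reads(
            [RawRead(f"c{i}", s) for i, (s, _) in enumerate(first.sequences)],
            ADAPTER3,
            ADAPTER5,
        )
        assert [s for s, _ in again.sequences] == [s for s, _ in first.sequences]
        assert again.tally["kept"] == first.tally["kept"]

    def test_empty_input_gives_zeroed_tally(self):
        result = clean_reads([], ADAPTER3)
        assert result.sequences == [] and sum(result.tally.values()) == 0

    def test_u_normalized_to_t(self):
        result = clean_reads([_read("GUGGUGACGGUGGUGGUGCGA" + ADAPTER3)], ADAPTER3)
        assert result.sequences[0][0] == "GTGGTGACGGTGGTGGTGCGA"

    @given(
        st.lists(
            st.text(alphabet="ACGT", min_size=1, max_size=45).filter(bool),
            max_size=60,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_kept_plus_rejected_conserves_input(self, seqs):
        reads = [RawRead(f"r{i}", s) for i, s in enumerate(seqs)]
        result = clean_reads(reads, ADAPTER3, ADAPTER5)
        assert sum(result.tally.values()) == len(seqs)
        assert result.tally["kept"] == len(result.sequences)


class TestCollapse:
    def test_duplicates_collapse_with_counts(self):
        tags = collapse_to_tags(["ACGTACGTACGTACG", "ACGTACGTACGTACG", "TTTACGCGCGCGCGC"], "CK")
        assert tags["ACGTACGTACGTACG"].counts == {"CK": 2}
        assert tags["TTTACGCGCGCGCGC"].counts == {"CK": 1}

    def test_empty_stream(self):
        assert collapse_to_tags([], "CK") == {}

    def test_mass_conservation_against_counting_oracle(self):
        rng = random.Random(3)
        pool = ["".join(rng.choice("ACGT") for _ in range(21)) for _ in range(40)]
        draws = [rng.choice(pool) for _ in range(10_000)]
        tags = collapse_to_tags(draws, "CK")
        oracle = {}
        for s in draws:
            oracle[s] = oracle.get(s, 0) + 1
        assert {s: t.counts["CK"] for s, t in tags.items()} == oracle
        assert sum(t.total for t in tags.values()) == len(draws)


class TestSummaries:
    def test_identical_libraries_are_fully_shared(self):
        tags = collapse_to_tags(["ACGTACGTACGTACG", "CCGGCCGGCCGGCCG"], "CK")
        tags_b = collapse_to_tags(["ACGTACGTACGTACG", "CCGGCCGGCCGGCCG"], "Cd200")
        _, _, overlap = summarize_libraries(tags, tags_b)
        pct = overlap.percentages()
        assert pct["shared_unique"] == 100.0 and pct["shared_total"] == 100.0
        assert overlap.a_specific_unique == overlap.b_specific_unique == 0

    def test_overlap_against_set_intersection_oracle(self):
        rng = random.Random(5)
        common = ["".join(rng.choice("ACGT") for _ in range(20)) for _ in range(20)]
        only_a = ["".join(rng.choice("ACGT") for _ in range(21)) for _ in range(30)]
        only_b = ["".join(rng.choice("ACGT") for _ in range(22)) for _ in range(30)]
        tags_a = collapse_to_tags(common + only_a, "CK")
        tags_b = collapse_to_tags(common + only_b, "Cd200")
        _, _, overlap = summarize_libraries(tags_a, tags_b)
        assert overlap.shared_unique == len(set(common) & (set(common) | set(only_b)))
        assert overlap.shared_unique == 20
        assert (
            overlap.shared_unique + overlap.a_specific_unique + overlap.b_specific_unique
            == len(set(common) | set(only_a) | set(only_b))
        )

    def test_histogram_sums_to_clean_total(self, small_tags):
        from mirstress.preprocess import library_profile

        prof = library_profile(small_tags, "CK")
        assert sum(prof.length_histogram.values()) == prof.total_clean


class TestIO:
    def test_collapsed_fasta_roundtrip(self, tmp_path):
        tags = collapse_to_tags(["ACGTACGTACGTACG"] * 3 + ["CCGGCCGGCCGGCCG"], "CK")
        path = tmp_path / "tags.fa"
        tags_to_collapsed_fasta(tags, path)
        back = list(read_sequences(path))
        assert {(r.sequence, r.count) for r in back} == {
            ("ACGTACGTACGTACG", 3),
            ("CCGGCCGGCCGGCCG", 1),
        }

    def test_fastq_parsing(self, tmp_path):
        path = tmp_path / "r.fastq"
        path.write_text("@r1\nACGT\n+\nIIII\n@r2\nGGCC\n+\nIIII\n")
        reads = list(read_sequences(path))
        assert [r.sequence for r in reads] == ["ACGT", "GGCC"]
        assert reads[0].quality == "IIII"
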