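"""Degradome target calling: scoring, t-plots and category rules."""

from __future__ import annotations

import random

import numpy as np
import pytest

from mirstress.annotate import reverse_complement
from mirstress.degradome import (
    CLEAVE_POS,
    align_mirna_to_transcript,
    build_tplot,
    call_targets,
    categorize_call,
    filter_degradome_reads,
    map_degradome_tags,
)
from mirstress.preprocess import RawRead

MIRNA = "TGAGGTAGTAGGTTGTATAGT"  # 21 nt


def _embed_site(rng: random.Random, mirna: str, flank5: int = 80, flank3: int = 80):
    """Transcript with one perfect antisense site; returns (tx, site_start 1-based)."""
    left = "".join(rng.choice("ACGT") for _ in range(flank5))
    right = "".join(rng.choice("ACGT") for _ in range(flank3))
    return left + reverse_complement(mirna) + right, flank5 + 1


def _score_window_by_hand(mirna: str, window_rev: str) -> tuple:
    """Per-position rescoring oracle: window_rev[k] faces miRNA position
    k+1; returns (score, mismatches, site_ok)."""
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    wobble = {("G", "T"), ("T", "G")}
    score, mism = 0.0, 0
    for k, (m, t) in enumerate(zip(mirna, window_rev), start=1):
        if (m, t) in wc:
            p = 0.0
        elif (m, t) in wobble:
            p = 0.5
        else:
            p = 1.0
            mism += 1
        if 2 <= k <= 13:
            p *= 2
        score += p
    site_ok = all(
        (mirna[k - 1], window_rev[k - 1]) in wc for k in (10, 11)
    )
    return score, mism, site_ok


class TestFiltering:
    def test_length_window(self):
        reads = [
            RawRead("a", "A" * 19, "I" * 19),
            RawRead("b", "ACGTACGTACGTACGTACGT"),  # 20 nt, no quality
            RawRead("c", "ACGTACGTACGTACGTACGTA", "I" * 21),
        ]
        tags = filter_degradome_reads(reads)
        assert set(tags) == {"ACGTACGTACGTACGT" + "ACGT", "ACGTACGTACGTACGTACGTA"}

    def test_low_quality_discarded(self):
        good = RawRead("a", "ACGTACGTACGTACGTACGT", "I" * 20)
        bad = RawRead("b", "TTTTACGTACGTACGTACGT", "#" * 20)  # Q2
        assert set(filter_degradome_reads([good, bad])) == {good.sequence}

    def test_planted_offlength_fraction_removed_exactly(self):
        rng = random.Random(31)
        reads = []
        for i in range(700):
            reads.append(RawRead(f"k{i}", "".join(rng.choice("ACGT") for _ in range(20))))
        for i in range(300):
            reads.append(RawRead(f"o{i}", "".join(rng.choice("ACGT") for _ in range(25))))
        tags = filter_degradome_reads(reads)
        assert sum(tags.values()) == 700


class TestAlignment:
    def test_perfect_complement_scores_zero(self):
        rng = random.Random(1)
        tx, start = _embed_site(rng, MIRNA)
        alns = align_mirna_to_transcript("m", MIRNA, "t", tx)
        exact = [a for a in alns if a.start == start]
        assert exact and exact[0].score == 0.0
        assert exact[0].cleavage_pos == start + len(MIRNA) - CLEAVE_POS

    def test_single_wobble_in_core_scores_one(self):
        rng = random.Random(2)
        tx, start = _embed_site(rng, MIRNA)
        # wobble at miRNA position 5: transcript base faced = start+L-5 (1-based)
        idx = start - 1 + len(MIRNA) - 5
        base = MIRNA[4]
        wob = {"G": "T", "T": "G"}.get(base)
        assert wob is not None, "test miRNA must have G/U at position 5"
        tx = tx[:idx] + wob + tx[idx + 1 :]
        alns = [a for a in align_mirna_to_transcript("m", MIRNA, "t", tx) if a.start == start]
        assert alns and alns[0].score == 1.0  # 0.5 doubled in the core
        assert alns[0].states[4] == "G:U"

    def test_wobble_at_cleavage_site_rejected(self):
        # positions 10 AND 11 must be Watson-Crick; a G:U at 11 disqualifies
        rng = random.Random(3)
        tx, start = _embed_site(rng, MIRNA)
        idx = start - 1 + len(MIRNA) - 11
        base = MIRNA[10]  # position 11 of MIRNA is 'G' -> G:U possible
        wob = {"G": "T", "T": "G"}.get(base)
        assert wob is not None
        tx = tx[:idx] + wob + tx[idx + 1 :]
        assert not [a for a in align_mirna_to_transcript("m", MIRNA, "t", tx) if a.start == start]

    def test_six_mismatches_rejected(self):
        rng = random.Random(4)
        tx, start = _embed_site(rng, MIRNA)
        # mutate 6 faced bases outside the cleavage site to mismatches
        wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
        wobble = {("G", "T"), ("T", "G")}
        for k in [1, 3, 15, 17, 19, 21]:
            idx = start - 1 + len(MIRNA) - k
            m = MIRNA[k - 1]
            repl = next(b for b in "ACGT" if (m, b) not in wc and (m, b) not in wobble)
            tx = tx[:idx] + repl + tx[idx + 1 :]
        hits = [
            a
            for a in align_mirna_to_transcript("m", MIRNA, "t", tx, max_score=100.0)
            if a.start == start
        ]
        assert hits == []

    def test_window_scan_matches_rescoring_oracle(self):
        rng = random.Random(5)
        tx = "".join(rng.choice("ACGT") for _ in range(500))
        L = len(MIRNA)
        alns = {a.start: a for a in align_mirna_to_transcript("m", MIRNA, "t", tx, max_score=30.0, max_mismatch=21)}
        for s in range(0, len(tx) - L + 1):
            window_rev = tx[s : s + L][::-1]
            score, mism, site_ok = _score_window_by_hand(MIRNA, window_rev)
            keep = site_ok and score <= 30.0
            assert (s + 1 in alns) == keep
            if keep:
                assert alns[s + 1].score == pytest.approx(score)
                assert alns[s + 1].mismatches == mism

    def test_mirna_longer_than_transcript(self):
        assert align_mirna_to_transcript("m", MIRNA, "t", "ACGT" * 4) == []


class TestTPlot:
    def test_unit_scale_identity(self):
        tp = build_tplot("t", 50, {10: 1}, 100_000_000)
        assert tp.tp100m[9] == pytest.approx(1.0)

    def test_mass_conservation(self):
        counts = {3: 5, 10: 2, 20: 8}
        tp = build_tplot("t", 30, counts, 1000)
        assert tp.raw.sum() == sum(counts.values())
        assert tp.tp100m.sum() == pytest.approx(sum(counts.values()) * 1e8 / 1000)

    def test_random_placement_matches_truth_table(self):
        rng = random.Random(77)
        tx = {"t1": "".join(rng.choice("ACGT") for _ in range(2000))}
        truth = {}
        tags = {}
        for _ in range(200):
            pos = rng.randrange(0, 2000 - 21)
            seq = tx["t1"][pos : pos + 20]
            count = rng.randint(1, 10)
            tags[seq] = tags.get(seq, 0) + count
        profiles, total = map_degradome_tags(tags, tx)
        for seq, count in tags.items():
            start = tx["t1"].find(seq)
            while start != -1:
                truth[start + 1] = truth.get(start + 1, 0) + count
                start = tx["t1"].find(seq, start + 1)
        assert profiles["t1"] == truth


class TestCategories:
    def test_unique_maximum_is_category_one(self):
        tp = build_tplot("t", 5, {3: 9, 4: 1, 5: 1}, 1000)
        assert categorize_call(tp, 3) == "I"

    def test_above_median_below_max_is_category_two(self):
        tp = build_tplot("t", 5, {1: 9, 3: 5, 4: 1, 5: 1}, 1000)
        assert categorize_call(tp, 3) == "II"

    def test_tied_maximum_is_never_category_one(self):
        tp = build_tplot("t", 5, {1: 9, 2: 9, 3: 1}, 1000)
        assert categorize_call(tp, 1) in {"II", "III"}

    def test_single_read_site_is_category_three(self):
        tp = build_tplot("t", 5, {1: 9, 3: 1}, 1000)
        assert categorize_call(tp, 3) == "III"

    def test_zero_abundance_gives_no_call(self):
        tp = build_tplot("t", 5, {1: 9}, 1000)
        assert categorize_call(tp, 3) is None


class TestCallTargets:
    def test_planted_events_called_and_decoys_silent(self):
        rng = random.Random(9)
        mirnas = {"m1": MIRNA}
        tx1, start = _embed_site(rng, MIRNA, 100, 100)
        decoy = "".join(rng.choice("ACGT") for _ in range(300))
        transcripts = {"target": tx1, "decoy": decoy}
        cp = start + len(MIRNA) - CLEAVE_POS
        signature = tx1[cp - 1 : cp - 1 + 20]
        background = decoy[40:60]
        tags = {signature: 50, background: 10}
        calls, tplots = call_targets(mirnas, transcripts, tags)
        assert len(calls) == 1
        call = calls[0]
        assert (call.alignment.transcript_id, call.alignment.cleavage_pos) == ("target", cp)
        assert call.category == "I" and call.raw == 50

    def test_empty_degradome_gives_no_calls(self):
        calls, _ = call_targets({"m": MIRNA}, {"t": "ACGT" * 100}, {})
        assert calls == []
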