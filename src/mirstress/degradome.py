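"""Degradome (PARE) analysis: miRNA cleavage-target identification.

Degradome tags are the first 20-21 nt of uncapped 5' ends of mRNA
fragments.  miRNA-guided slicing cuts the target between the bases paired
to miRNA positions 10 and 11 (from the miRNA 5' end), so a genuine target
shows a pile-up of degradome 5' ends at the base opposite position 10.

The caller scores miRNA:transcript complementarity over every ungapped
antisense window (mismatch 1.0, G:U wobble 0.5, penalties doubled at
miRNA positions 2-13), requires Watson-Crick pairing at positions 10 and
11, builds per-transcript signature profiles (t-plots, normalized to
transcripts per 100 million mapped reads), and classifies each supported
site:

* category I   -- the site is the single maximum of the transcript profile
                  and carries more than one raw read;
* category II  -- more than one raw read, above the median of occupied
                  positions (but not a unique maximum);
* category III -- everything else with at least one read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .preprocess import RawRead, normalize

# per-position penalties; doubled within the core (miRNA positions 2-13)
MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
GAP_PENALTY = 2.0  # gapped alignment is not scanned; constant kept for scoring parity
CORE_START, CORE_END = 2, 13
CLEAVE_POS = 10  # miRNA position whose partner is the slice site

_BASES = {"A": 0, "C": 1, "G": 2, "T": 3}
# penalty[mirna_base, transcript_base]: WC = 0, G:U wobble = 0.5, else 1
_PENALTY = np.full((4, 4), MISMATCH_PENALTY)
for _m, _t in [("A", "T"), ("C", "G"), ("G", "C"), ("T", "A")]:
    _PENALTY[_BASES[_m], _BASES[_t]] = 0.0
for _m, _t in [("G", "T"), ("T", "G")]:
    _PENALTY[_BASES[_m], _BASES[_t]] = WOBBLE_PENALTY


def _codes(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, code in _BASES.items():
        out[arr == ord(base)] = code
    return out


@dataclass
class TargetAlignment:
    """One scored miRNA:transcript duplex (ungapped, antisense)."""

    mirna_id: str
    mirna_seq: str
    transcript_id: str
    start: int  # 1-based inclusive window on the transcript
    end: int
    score: float
    mismatches: int  # full mismatches only (wobbles tallied separately)
    wobbles: int
    cleavage_pos: int  # transcript base opposite miRNA position 10
    states: Tuple[str, ...] = ()  # per miRNA position: match | G:U | mismatch


@dataclass
class TPlot:
    """Per-position degradome signature abundance on one transcript."""

    transcript_id: str
    raw: np.ndarray  # 1-based positions stored at index pos-1
    total_mapped: int

    @property
    def tp100m(self) -> np.ndarray:
        return self.raw * 1e8 / self.total_mapped

    @property
    def max_raw(self) -> int:
        return int(self.raw.max()) if self.raw.size else 0

    @property
    def median_occupied(self) -> float:
        occupied = self.raw[self.raw >= 1]
        return float(np.median(occupied)) if occupied.size else 0.0


@dataclass
class CleavageCall:
    alignment: TargetAlignment
    raw: int
    tp100m: float
    category: str  # 'I' | 'II' | 'III'


# ---------------------------------------------------------------------------
# read filtering
# ---------------------------------------------------------------------------

def filter_degradome_reads(
    reads: Iterable[RawRead],
    min_len: int = 20,
    max_len: int = 21,
    min_mean_quality: float = 20.0,
    phred_offset: int = 33,
) -> Dict[str, int]:
    """Retain 20-21 nt reads of adequate quality, collapsed to tag counts.

    Reads without quality strings pass the quality rule unconditionally.
    """
    tags: Dict[str, int] = {}
    for read in reads:
        seq = normalize(read.sequence)
        if not (min_len <= len(seq) <= max_len):
            continue
        if read.quality is not None:
            mean_q = sum(ord(c) - phred_offset for c in read.quality) / len(read.quality)
            if mean_q < min_mean_quality:
                continue
        tags[seq] = tags.get(seq, 0) + read.count
    return tags


# ---------------------------------------------------------------------------
# complementarity scoring
# ---------------------------------------------------------------------------

def align_mirna_to_transcript(
    mirna_id: str,
    mirna_seq: str,
    transcript_id: str,
    transcript_seq: str,
    max_score: float = 4.0,
    max_mismatch: int = 5,
) -> List[TargetAlignment]:
    """Scan every ungapped antisense window of the transcript.

    miRNA position k (1-based from its 5' end) faces transcript position
    ``start + L - k`` (1-based), i.e. the duplex is antiparallel.  Windows
    are kept when score <= ``max_score``, full mismatches <=
    ``max_mismatch`` and positions 10 and 11 are Watson-Crick paired.
    """
    mir = normalize(mirna_seq)
    tx = normalize(transcript_seq)
    L, n = len(mir), len(tx)
    if not (15 <= L <= 30):
        raise ValueError(f"miRNA {mirna_id!r}: implausible length {L}")
    if L > n:
        return []
    mcodes = _codes(mir)
    tcodes = _codes(tx)
    windows = np.lib.stride_tricks.sliding_window_view(tcodes, L)
    # column k-1 of rev faces miRNA position k
    rev = windows[:, ::-1]
    valid = (rev >= 0).all(axis=1)
    pen = _PENALTY[np.clip(mcodes[None, :], 0, 3), np.clip(rev, 0, 3)]
    weights = np.ones(L)
    weights[CORE_START - 1 : min(CORE_END, L)] = 2.0
    scores = (pen * weights).sum(axis=1)
    mismatches = (pen == MISMATCH_PENALTY).sum(axis=1)
    wobbles = (pen == WOBBLE_PENALTY).sum(axis=1)
    if L >= CLEAVE_POS + 1:
        wc_site = (pen[:, CLEAVE_POS - 1] == 0.0) & (pen[:, CLEAVE_POS] == 0.0)
    else:
        wc_site = np.zeros(len(windows), dtype=bool)
    keep = valid & wc_site & (scores <= max_score) & (mismatches <= max_mismatch)

    out: List[TargetAlignment] = []
    state_of = {0.0: "match", WOBBLE_PENALTY: "G:U", MISMATCH_PENALTY: "mismatch"}
    for s in np.nonzero(keep)[0]:
        states = tuple(state_of[p] for p in pen[s])
        out.append(
            TargetAlignment(
                mirna_id,
                mir,
                transcript_id,
                start=int(s) + 1,
                end=int(s) + L,
                score=float(scores[s]),
                mismatches=int(mismatches[s]),
                wobbles=int(wobbles[s]),
                cleavage_pos=int(s) + L - CLEAVE_POS + 1,
                states=states,
            )
        )
    return out


# ---------------------------------------------------------------------------
# t-plots and categories
# ---------------------------------------------------------------------------

def map_degradome_tags(
    tags: Mapping[str, int], transcripts: Mapping[str, str]
) -> Tuple[Dict[str, Dict[int, int]], int]:
    """Perfect sense-strand mapping of degradome tags.

    Returns per-transcript {1-based 5'-end position: raw count} and the
    total mapped read count (each tag's count added once if it maps
    anywhere; a multi-site tag contributes its count at every site).
    """
    profiles: Dict[str, Dict[int, int]] = {tid: {} for tid in transcripts}
    total_mapped = 0
    tx_norm = {tid: normalize(seq) for tid, seq in transcripts.items()}
    for tag in sorted(tags):
        count = tags[tag]
        mapped = False
        for tid in sorted(tx_norm):
            seq = tx_norm[tid]
            pos = seq.find(tag)
            while pos != -1:
                profiles[tid][pos + 1] = profiles[tid].get(pos + 1, 0) + count
                mapped = True
                pos = seq.find(tag, pos + 1)
        if mapped:
            total_mapped += count
    return profiles, total_mapped


def build_tplot(
    transcript_id: str,
    length: int,
    five_prime_counts: Mapping[int, int],
    total_mapped: int,
) -> TPlot:
    """Assemble the signature profile of one transcript."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    raw = np.zeros(length, dtype=np.int64)
    for pos, count in five_prime_counts.items():
        raw[pos - 1] += count
    return TPlot(transcript_id, raw, total_mapped)


def categorize_call(tplot: TPlot, cleavage_pos: int) -> Optional[str]:
    """Category of a cleavage site on a t-plot, or None if unsupported."""
    raw = int(tplot.raw[cleavage_pos - 1])
    if raw < 1:
        return None
    maximum = tplot.max_raw
    unique_max = int((tplot.raw == maximum).sum()) == 1
    if raw == maximum and unique_max and raw > 1:
        return "I"
    if raw > 1 and raw > tplot.median_occupied:
        return "II"
    return "III"


def call_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    degradome_tags: Mapping[str, int],
    max_score: float = 4.0,
    max_mismatch: int = 5,
) -> Tuple[List[CleavageCall], Dict[str, TPlot]]:
    """Full target-calling pass.

    For every retained alignment whose cleavage position carries at least
    one degradome read, emit a categorized call.  Calls are ordered by
    (transcript id, cleavage position, miRNA id).
    """
    profiles, total_mapped = map_degradome_tags(degradome_tags, transcripts)
    tplots: Dict[str, TPlot] = {}
    if total_mapped == 0:
        return [], tplots
    for tid, seq in transcripts.items():
        tplots[tid] = build_tplot(tid, len(seq), profiles[tid], total_mapped)

    calls: List[CleavageCall] = []
    for mid in sorted(mirnas):
        for tid in sorted(transcripts):
            for aln in align_mirna_to_transcript(
                mid, mirnas[mid], tid, transcripts[tid], max_score, max_mismatch
            ):
                tplot = tplots[tid]
                category = categorize_call(tplot, aln.cleavage_pos)
                if category is None:
                    continue
                raw = int(tplot.raw[aln.cleavage_pos - 1])
                calls.append(
                    CleavageCall(aln, raw, float(tplot.tp100m[aln.cleavage_pos - 1]), category)
                )
    calls.sort(key=lambda c: (c.alignment.transcript_id, c.alignment.cleavage_pos, c.alignment.mirna_id))
    return calls, tplots


def calls_table(calls: Sequence[CleavageCall]) -> pd.DataFrame:
    """Target-call report: one row per (miRNA, transcript, cleavage site)."""
    rows = [
        {
            "miRNA": c.alignment.mirna_id,
            "target_id": c.alignment.transcript_id,
            "cleavage_site": c.alignment.cleavage_pos,
            "category": c.category,
            "raw_reads": c.raw,
            "TP100M": round(c.tp100m, 3),
            "score": c.alignment.score,
            "mismatches": c.alignment.mismatches,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "miRNA",
            "target_id",
            "cleavage_site",
            "category",
            "raw_reads",
            "TP100M",
            "score",
            "mismatches",
        ],
    )


def tplot_table(tplots: Mapping[str, TPlot]) -> pd.DataFrame:
    """Long-format t-plot export (occupied positions only)."""
    rows = []
    for tid in sorted(tplots):
        tp = tplots[tid]
        for pos in np.nonzero(tp.raw)[0]:
            rows.append(
                {
                    "transcript_id": tid,
                    "position": int(pos) + 1,
                    "raw": int(tp.raw[pos]),
                    "TP100M": round(float(tp.tp100m[pos]), 3),
                }
            )
    return pd.DataFrame(rows, columns=["transcript_id", "position", "raw", "TP100M"])
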