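"""Novel miRNA discovery from unannotated, reference-mapped tags.

Around every perfect hit of a candidate tag, two genomic windows are
excised (tag near the 5' end with a long downstream flank, and the mirror
orientation) and folded.  A window is accepted as a novel miRNA precursor
when the tag sits on one arm of a stem-loop, forms a plausible
miRNA/miRNA* duplex (few unpaired bases, no large asymmetric bulge), the
predicted star sequence -- the duplex partner with 2-nt 3' overhangs -- is
itself observed in the sequenced tags, and the fold is stable enough
(MFE at most -18 kcal/mol by default, i.e. no weaker than the weakest
accepted precursor in comparable plant studies).

Identical mature sequences arising from multiple loci are merged and
numbered serially by descending abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

import numpy as np

from .annotate import Hit, ReferenceDB, map_perfect, reverse_complement
from .degradome import _codes, _PENALTY, MISMATCH_PENALTY
from .folding import HairpinStructure, fold_mfe
from .preprocess import SequenceTag


@dataclass
class PrecursorCandidate:
    """An excised putative pre-miRNA window around a mapped tag."""

    record_id: str
    start: int  # 1-based inclusive, on the reference record
    end: int
    strand: str
    sequence: str  # 5'->3' on the hit strand
    mature: str
    mature_offset: int  # 0-based offset of the mature within `sequence`
    structure: Optional[HairpinStructure] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("precursor window must satisfy end > start")

    @property
    def locus(self) -> Tuple[str, int, str]:
        """Key identifying the mature's genomic position (merges the up-
        and downstream windows excised around the same hit)."""
        if self.strand == "+":
            return (self.record_id, self.start + self.mature_offset, self.strand)
        return (self.record_id, self.end - self.mature_offset - len(self.mature) + 1, self.strand)


@dataclass
class Rejection:
    candidate: PrecursorCandidate
    reason: str


@dataclass
class AcceptedHairpin:
    candidate: PrecursorCandidate
    arm: str  # '5p' | '3p'
    star_seq: str
    star_counts: Dict[str, int]
    mature_counts: Dict[str, int]


@dataclass
class NovelMiRNA:
    """One aggregated novel miRNA (unique mature sequence)."""

    name: str
    mature: str
    precursor_length: int
    mfe: float
    mature_counts: Dict[str, int]
    star_counts: Dict[str, int]
    loci_count: int
    arm: str


# ---------------------------------------------------------------------------
# precursor excision
# ---------------------------------------------------------------------------

def excise_candidate_precursors(
    hit: Hit,
    tag: str,
    reference: ReferenceDB,
    flank_up: int = 20,
    flank_down: int = 160,
    min_precursor: int = 60,
    max_precursor: int = 300,
) -> List[PrecursorCandidate]:
    """Excise up to two candidate windows around a perfect tag hit.

    Window A places the tag near the window 5' end (short upstream flank,
    long downstream flank); window B mirrors it.  Windows are truncated at
    record boundaries and discarded when shorter than ``min_precursor``.
    Flanks are relative to the tag's orientation: for a '-' strand hit the
    excised window is reverse-complemented and up/downstream swap on the
    reference coordinate axis.
    """
    record = reference.records[hit.record_id]
    n = len(record)
    if n < min_precursor:
        return []
    tag_len = len(tag)
    t0 = hit.start  # 1-based
    t1 = hit.start + tag_len - 1
    if hit.strand == "+":
        spans = [(t0 - flank_up, t1 + flank_down), (t0 - flank_down, t1 + flank_up)]
    else:
        spans = [(t0 - flank_down, t1 + flank_up), (t0 - flank_up, t1 + flank_down)]

    out: List[PrecursorCandidate] = []
    seen = set()
    for lo, hi in spans:
        lo, hi = max(1, lo), min(n, hi)
        if not (min_precursor <= hi - lo + 1 <= max_precursor):
            continue
        if (lo, hi) in seen:
            continue
        seen.add((lo, hi))
        window = record[lo - 1 : hi]
        if hit.strand == "+":
            seq = window
            offset = t0 - lo
        else:
            seq = reverse_complement(window)
            offset = hi - t1
        out.append(
            PrecursorCandidate(hit.record_id, lo, hi, hit.strand, seq, tag, offset)
        )
    return out


def has_duplex_partner(
    mature: str, window: str, mature_offset: int, max_unpaired: int = 6
) -> bool:
    """Pre-screen: does the window contain a plausible miRNA* for the
    mature, i.e. an antisense stretch pairing all but ``max_unpaired``
    mature bases (G:U wobbles count as paired)?

    A stem-loop precursor necessarily contains such a stretch outside the
    mature itself, so candidates failing this test cannot satisfy the
    duplex criterion and are skipped before the (much more expensive)
    thermodynamic fold.
    """
    L = len(mature)
    if len(window) < 2 * L:
        return False
    mcodes = _codes(mature)
    wcodes = _codes(window)
    views = np.lib.stride_tricks.sliding_window_view(wcodes, L)[:, ::-1]
    pen = _PENALTY[np.clip(mcodes[None, :], 0, 3), np.clip(views, 0, 3)]
    mism = (pen == MISMATCH_PENALTY).sum(axis=1) + (views < 0).sum(axis=1)
    ok = mism <= max_unpaired
    # exclude starts overlapping the mature's own footprint
    lo = max(0, mature_offset - L + 1)
    hi = min(len(ok), mature_offset + L)
    ok[lo:hi] = False
    return bool(ok.any())


# ---------------------------------------------------------------------------
# hairpin evaluation
# ---------------------------------------------------------------------------

def _nearest_paired(structure: HairpinStructure, pos: int, lo: int, hi: int, step: int) -> Optional[int]:
    """First paired position from ``pos`` walking by ``step`` within [lo, hi]."""
    p = pos
    while lo <= p <= hi:
        if structure.partner(p) is not None:
            return p
        p += step
    return None


def _star_window(
    structure: HairpinStructure, m_start: int, m_end: int
) -> Optional[Tuple[int, int]]:
    """Expected star interval (1-based, inclusive) from the pair table,
    using the canonical 2-nt 3'-overhang duplex geometry."""
    p5 = _nearest_paired(structure, m_start, m_start, m_end, +1)
    p3 = _nearest_paired(structure, m_end - 2, m_start, m_end, -1)
    if p5 is None or p3 is None:
        return None
    a = structure.partner(p5) + 2 - (m_start - p5)
    b = structure.partner(p3) - (m_end - 2 - p3)
    lo, hi = min(a, b), max(a, b)
    return lo, hi


def evaluate_hairpin_candidate(
    candidate: PrecursorCandidate,
    tags: Mapping[str, SequenceTag],
    max_duplex_mismatches: int = 4,
    max_bulge_asymmetry: int = 2,
    max_into_loop: int = 2,
    mfe_max: float = -18.0,
    min_star_reads: int = 1,
    star_slack: int = 2,
) -> AcceptedHairpin | Rejection:
    """Accept or reject a folded precursor candidate.

    Criteria, checked in order (the rejection carries the first failure):

    1. ``loop overlap`` / ``not in stem`` -- the mature must lie on a
       single arm: no self-pairing within the mature, all partners on one
       side, and at most ``max_into_loop`` mature bases protruding past
       the innermost stem pair toward the terminal loop.
    2. ``duplex mismatches`` -- more than ``max_duplex_mismatches``
       unpaired mature bases.
    3. ``asymmetric bulge`` -- an internal loop in the duplex whose two
       sides differ by more than ``max_bulge_asymmetry`` nt.
    4. ``no star evidence`` -- no sequenced tag supports the miRNA* (the
       duplex partner with 2-nt 3' overhangs); tags whose 5' end falls
       within ``star_slack`` nt of the predicted star 5' end count.
    5. ``mfe`` -- folding energy above ``mfe_max`` kcal/mol.
    """
    st = candidate.structure
    if st is None:
        raise ValueError("candidate must be folded before evaluation")
    m_start = candidate.mature_offset + 1  # 1-based on the precursor
    m_end = candidate.mature_offset + len(candidate.mature)

    partners = []
    for pos in range(m_start, m_end + 1):
        q = st.partner(pos)
        if q is not None:
            if m_start <= q <= m_end:
                return Rejection(candidate, "loop overlap")
            partners.append((pos, q))
    if not partners:
        return Rejection(candidate, "not in stem")
    sides = {q > m_end for _, q in partners}
    if len(sides) > 1:
        return Rejection(candidate, "loop overlap")
    arm = "5p" if sides.pop() else "3p"

    # distance from the terminal loop: mature bases past the innermost pair
    if arm == "5p":
        innermost = max(p for p, _ in partners)
        protrusion = m_end - innermost
    else:
        innermost = min(p for p, _ in partners)
        protrusion = innermost - m_start
    if protrusion > max_into_loop:
        return Rejection(candidate, "loop overlap")

    unpaired = (m_end - m_start + 1) - len(partners)
    if unpaired > max_duplex_mismatches:
        return Rejection(candidate, "duplex mismatches")

    for (p1, q1), (p2, q2) in zip(partners, partners[1:]):
        gap_m = p2 - p1 - 1
        gap_s = abs(q1 - q2) - 1
        if abs(gap_m - gap_s) > max_bulge_asymmetry:
            return Rejection(candidate, "asymmetric bulge")

    window = _star_window(st, m_start, m_end)
    if window is None:
        return Rejection(candidate, "not in stem")
    star_lo, star_hi = window
    n = len(candidate.sequence)
    star_counts: Dict[str, int] = {}
    seen_stars: set = set()
    exact_star = candidate.sequence[max(0, star_lo - 1) : min(n, star_hi)]
    for shift in range(-star_slack, star_slack + 1):
        lo = star_lo + shift
        for star_len in range(max(18, star_hi - star_lo + 1 - star_slack),
                              min(26, star_hi - star_lo + 1 + star_slack) + 1):
            hi = lo + star_len - 1
            if lo < 1 or hi > n:
                continue
            seq = candidate.sequence[lo - 1 : hi]
            tag = tags.get(seq)
            if tag is not None and seq != candidate.mature and seq not in seen_stars:
                seen_stars.add(seq)
                for lib, cnt in tag.counts.items():
                    star_counts[lib] = star_counts.get(lib, 0) + cnt
    if sum(star_counts.values()) < min_star_reads:
        return Rejection(candidate, "no star evidence")

    if st.mfe > mfe_max:
        return Rejection(candidate, "mfe")

    mature_tag = tags.get(candidate.mature)
    mature_counts = dict(mature_tag.counts) if mature_tag else {}
    return AcceptedHairpin(candidate, arm, exact_star, star_counts, mature_counts)


# ---------------------------------------------------------------------------
# aggregation and orchestration
# ---------------------------------------------------------------------------

def aggregate_novel(
    accepted: Sequence[AcceptedHairpin], name_prefix: str = "miRn"
) -> List[NovelMiRNA]:
    """Merge accepted hairpins by mature sequence and assign serial names.

    Ordering (hence numbering) is by descending total mature read count,
    then lexicographic mature sequence -- deterministic for a fixed input.
    One representative precursor (the lowest locus key) provides length,
    MFE and arm.
    """
    by_mature: Dict[str, List[AcceptedHairpin]] = {}
    for acc in accepted:
        by_mature.setdefault(acc.candidate.mature, []).append(acc)

    entries = []
    for mature, group in by_mature.items():
        loci = {acc.candidate.locus for acc in group}
        rep = min(group, key=lambda a: a.candidate.locus)
        star_counts: Dict[str, int] = {}
        for lib, cnt in max(
            (a.star_counts for a in group), key=lambda c: sum(c.values())
        ).items():
            star_counts[lib] = cnt
        entries.append(
            (
                sum(rep.mature_counts.values()),
                mature,
                rep,
                star_counts,
                len(loci),
            )
        )
    entries.sort(key=lambda e: (-e[0], e[1]))
    out = []
    for serial, (_, mature, rep, star_counts, n_loci) in enumerate(entries, 1):
        out.append(
            NovelMiRNA(
                f"{name_prefix}{serial}",
                mature,
                len(rep.candidate.sequence),
                rep.candidate.structure.mfe,
                dict(rep.mature_counts),
                star_counts,
                n_loci,
                rep.arm,
            )
        )
    return out


def cluster_hits(
    hit_list: Sequence[Tuple[str, Hit]], cluster_gap: int = 30
) -> List[List[Tuple[str, Hit]]]:
    """Group (tag, hit) pairs into genomic loci.

    Hits on the same record and strand whose footprints are within
    ``cluster_gap`` nt of each other share a locus, so a miRNA, its
    processing variants and its star reads (separated only by the hairpin
    loop) all fall into one cluster.
    """
    ordered = sorted(
        hit_list, key=lambda th: (th[1].record_id, th[1].strand, th[1].start, th[0])
    )
    clusters: List[List[Tuple[str, Hit]]] = []
    cur_key = None
    cur_end = -1
    for tag, hit in ordered:
        key = (hit.record_id, hit.strand)
        end = hit.start + len(tag) - 1
        if key != cur_key or hit.start > cur_end + cluster_gap:
            clusters.append([])
            cur_key = key
            cur_end = end
        clusters[-1].append((tag, hit))
        cur_end = max(cur_end, end)
    return clusters


def discover_novel(
    tags: Mapping[str, SequenceTag],
    unannotated: Iterable[str],
    reference: ReferenceDB,
    min_tag_count: int = 5,
    mature_lengths: Tuple[int, int] = (20, 24),
    flank_up: int = 20,
    flank_down: int = 160,
    min_precursor: int = 60,
    max_precursor: int = 300,
    cluster_gap: int = 30,
    name_prefix: str = "miRn",
    **eval_kwargs,
) -> Tuple[List[NovelMiRNA], List[Rejection]]:
    """End-to-end discovery: select candidate tags, cluster their perfect
    hits into loci, and evaluate the dominant tag of each locus.

    Candidate matures are unannotated tags of mature-like length with at
    least ``min_tag_count`` reads over both libraries.  Each locus is
    represented by its most abundant tag (the presumptive mature product;
    lower-abundance tags at the same locus are processing variants or the
    star and are not folded separately).  The full tag set is still
    consulted for star evidence.
    """
    lo, hi = mature_lengths
    candidates = sorted(
        s
        for s in unannotated
        if lo <= len(s) <= hi and tags[s].total >= min_tag_count
    )
    hits = map_perfect(candidates, reference)
    hit_list = [(seq, h) for seq in candidates for h in hits[seq]]
    accepted: List[AcceptedHairpin] = []
    rejections: List[Rejection] = []
    for cluster in cluster_hits(hit_list, cluster_gap):
        seq, hit = max(cluster, key=lambda th: (tags[th[0]].total, th[0]))
        best: Optional[AcceptedHairpin] = None
        cluster_rejections: List[Rejection] = []
        for cand in excise_candidate_precursors(
            hit, seq, reference, flank_up, flank_down, min_precursor, max_precursor
        ):
            if not has_duplex_partner(seq, cand.sequence, cand.mature_offset):
                cluster_rejections.append(Rejection(cand, "no duplex partner"))
                continue
            cand.structure = fold_mfe(cand.sequence)
            result = evaluate_hairpin_candidate(cand, tags, **eval_kwargs)
            if isinstance(result, AcceptedHairpin):
                if best is None or cand.structure.mfe < best.candidate.structure.mfe:
                    best = result
            else:
                cluster_rejections.append(result)
        if best is not None:
            accepted.append(best)
        else:
            rejections.extend(cluster_rejections)
    return aggregate_novel(accepted, name_prefix), rejections


def novel_table(novel: Sequence[NovelMiRNA], lib_a: str = "CK", lib_b: str = "Cd200") -> pd.DataFrame:
    """Novel-miRNA report (mature shown in RNA alphabet)."""
    rows = [
        {
            "miRNA": nv.name,
            "mature": nv.mature.replace("T", "U"),
            "size": len(nv.mature),
            "precursor_length": nv.precursor_length,
            "MFE": round(nv.mfe, 2),
            f"reads_{lib_a}": nv.mature_counts.get(lib_a, 0),
            f"reads_{lib_b}": nv.mature_counts.get(lib_b, 0),
            "star_reads": sum(nv.star_counts.values()),
            "loci": nv.loci_count,
            "arm": nv.arm,
        }
        for nv in novel
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "miRNA",
            "mature",
            "size",
            "precursor_length",
            "MFE",
            f"reads_{lib_a}",
            f"reads_{lib_b}",
            "star_reads",
            "loci",
            "arm",
        ],
    )
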