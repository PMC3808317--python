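"""Annotation of small-RNA tags: reference mapping, ncRNA removal, and
assignment to known miRNA families.

Tags are first mapped to the reference by perfect (exact-substring) match
on either strand.  Tags matching structural non-coding RNA (rRNA, tRNA,
snRNA, snoRNA) are classified and removed; the remainder are compared to a
set of known mature miRNAs, allowing a configurable number of mismatches
(default 2) under an ungapped end-to-end model.  Whatever is left is
"unannotated" and feeds novel-miRNA discovery.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO

from .preprocess import SequenceTag, normalize

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: tag classes in partition-priority order
NCRNA_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA")
CLASSES = ("known_miRNA",) + NCRNA_PRIORITY + ("unannotated",)

# family numeral with optional letter/arm suffixes: ath-miR156a-5p -> miR156
_FAMILY_RE = re.compile(r"(?:^[a-z]{2,5}-)?((?:miR|let|lin)-?\d+)", re.IGNORECASE)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceDB:
    """Named nucleotide sequences (transcript/genomic, or labelled ncRNA)."""

    records: Dict[str, str]
    kinds: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, seq in self.records.items():
            if not seq:
                raise ValueError(f"reference record {rid!r} is empty")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_fasta(cls, path, kind: str = "transcript") -> "ReferenceDB":
        records, kinds = {}, {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate reference id {rec.id!r}")
            records[rec.id] = normalize(str(rec.seq))
            kinds[rec.id] = kind
        return cls(records, kinds)

    @classmethod
    def ncrna_from_fasta(cls, path) -> "ReferenceDB":
        """Load an ncRNA FASTA whose headers carry the class as a token
        (e.g. ``>rrna_01 rRNA`` or ``>tRNA-Ala-1``)."""
        records, kinds = {}, {}
        for rec in SeqIO.parse(str(path), "fasta"):
            text = rec.description
            cls_label = None
            for label in NCRNA_PRIORITY:
                if re.search(label, text, re.IGNORECASE):
                    cls_label = label
                    break
            if cls_label is None:
                raise ValueError(f"ncRNA record {rec.id!r}: no class token in header")
            records[rec.id] = normalize(str(rec.seq))
            kinds[rec.id] = cls_label
        return cls(records, kinds)


@dataclass(frozen=True)
class Hit:
    """A perfect match of a tag on a reference record (1-based, inclusive)."""

    record_id: str
    start: int
    strand: str  # '+' or '-'


@dataclass
class KnownMiRNAFamily:
    name: str
    members: List[Tuple[str, str]]  # (member id, mature sequence, DNA alphabet)


@dataclass
class AnnotationResult:
    sequence: str
    klass: str
    family: Optional[str] = None
    member: Optional[str] = None
    mismatches: Optional[int] = None
    hits: List[Hit] = field(default_factory=list)


def family_name(member_id: str) -> str:
    """Family of a miRBase-style member name (``ath-miR156a-5p`` -> ``miR156``)."""
    m = _FAMILY_RE.search(member_id)
    if not m:
        raise ValueError(f"cannot parse a miRNA family from {member_id!r}")
    core = m.group(1).replace("-", "")
    return "miR" + core[3:] if core.lower().startswith("mir") else core


def load_known_mirnas(path) -> List[KnownMiRNAFamily]:
    """Group a mature-miRNA FASTA (miRBase-style headers) into families."""
    families: Dict[str, KnownMiRNAFamily] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        fam = family_name(rec.id)
        seq = normalize(str(rec.seq))
        families.setdefault(fam, KnownMiRNAFamily(fam, [])).members.append((rec.id, seq))
    return [families[k] for k in sorted(families)]


# ---------------------------------------------------------------------------
# perfect mapping
# ---------------------------------------------------------------------------

class _ConcatIndex:
    """All reference records joined with separators, for fast exact search
    of many short queries (str.find runs in C)."""

    def __init__(self, db: ReferenceDB):
        self.ids: List[str] = sorted(db.records)
        parts, offsets, off = [], [], 0
        for rid in self.ids:
            seq = db.records[rid]
            parts.append(seq)
            offsets.append(off)
            off += len(seq) + 1  # '#' separator
        self.text = "#".join(parts)
        self.offsets = offsets
        self.lengths = [len(db.records[r]) for r in self.ids]

    def _locate(self, pos: int) -> Tuple[str, int]:
        # binary search over record offsets
        lo, hi = 0, len(self.offsets) - 1
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if self.offsets[mid] <= pos:
                lo = mid
            else:
                hi = mid - 1
        return self.ids[lo], pos - self.offsets[lo]

    def find_all(self, query: str) -> List[Tuple[str, int]]:
        """(record id, 0-based start) of every exact occurrence."""
        hits = []
        pos = self.text.find(query)
        while pos != -1:
            rid, local = self._locate(pos)
            hits.append((rid, local))
            pos = self.text.find(query, pos + 1)
        return hits


def map_perfect(
    tags: Iterable[str], reference: ReferenceDB
) -> Dict[str, List[Hit]]:
    """Map tags to the reference by exact substring match on both strands.

    Returns every tag (tags with no match map to an empty list).  Hit
    coordinates are 1-based on the forward reference strand; a '-' strand
    hit means the reverse complement of the tag matched there.
    """
    result: Dict[str, List[Hit]] = {}
    if len(reference) == 0:
        return {t: [] for t in tags}
    index = _ConcatIndex(reference)
    for tag in tags:
        hits = [Hit(rid, pos + 1, "+") for rid, pos in index.find_all(tag)]
        rc = reverse_complement(tag)
        hits += [Hit(rid, pos + 1, "-") for rid, pos in index.find_all(rc)]
        result[tag] = sorted(hits, key=lambda h: (h.record_id, h.start, h.strand))
    return result


# ---------------------------------------------------------------------------
# ncRNA classification
# ---------------------------------------------------------------------------

def classify_ncrna(
    tags: Iterable[str], ncrna_db: ReferenceDB
) -> Dict[str, Optional[str]]:
    """Assign each tag the class of the ncRNA it matches (exact substring,
    either strand), or None.  Multi-class matches resolve by the fixed
    priority rRNA > tRNA > snRNA > snoRNA.
    """
    by_class = {}
    for label in NCRNA_PRIORITY:
        ids = [r for r, k in ncrna_db.kinds.items() if k == label]
        if ids:
            sub = ReferenceDB({r: ncrna_db.records[r] for r in ids})
            by_class[label] = _ConcatIndex(sub)
    out: Dict[str, Optional[str]] = {}
    for tag in tags:
        rc = reverse_complement(tag)
        cls = None
        for label in NCRNA_PRIORITY:
            idx = by_class.get(label)
            if idx is not None and (idx.text.find(tag) != -1 or idx.text.find(rc) != -1):
                cls = label
                break
        out[tag] = cls
    return out


# ---------------------------------------------------------------------------
# known-miRNA assignment
# ---------------------------------------------------------------------------

def mirna_distance(tag: str, member: str) -> int:
    """Ungapped end-to-end distance: Hamming over the common 5' prefix plus
    one per overhanging base of the longer sequence.  G:U wobbles count as
    mismatches here (unlike degradome target scoring)."""
    k = min(len(tag), len(member))
    d = sum(1 for a, b in zip(tag[:k], member[:k]) if a != b)
    return d + abs(len(tag) - len(member))


def assign_known_mirna(
    tags: Iterable[str],
    families: Sequence[KnownMiRNAFamily],
    max_mismatch: int = 2,
) -> Dict[str, AnnotationResult]:
    """Assign each tag to the known member with the fewest mismatches.

    Ties at equal distance break to the lexicographically smallest member
    id.  Tags whose best distance exceeds ``max_mismatch`` are returned as
    unannotated.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    members = sorted(
        ((mid, seq, fam.name) for fam in families for mid, seq in fam.members),
        key=lambda m: m[0],
    )
    out: Dict[str, AnnotationResult] = {}
    for tag in tags:
        best: Optional[Tuple[int, str, str]] = None  # (distance, member id, family)
        for mid, mseq, fam in members:
            if abs(len(tag) - len(mseq)) > max_mismatch:
                continue
            d = mirna_distance(tag, mseq)
            if d <= max_mismatch and (best is None or d < best[0]):
                best = (d, mid, fam)
        if best is None:
            out[tag] = AnnotationResult(tag, "unannotated")
        else:
            out[tag] = AnnotationResult(tag, "known_miRNA", best[2], best[1], best[0])
    return out


def family_table(
    assignments: Mapping[str, AnnotationResult],
    tags: Mapping[str, SequenceTag],
    lib_a: str = "CK",
    lib_b: str = "Cd200",
) -> pd.DataFrame:
    """Aggregate assigned tags into a per-family abundance table.

    Columns: family, members (distinct members with >= 1 assigned read),
    per-library reads, row-sum total, and the Cd/CK-style read ratio
    rounded to 2 decimals.
    """
    rows: Dict[str, Dict] = {}
    for seq, res in assignments.items():
        if res.klass != "known_miRNA":
            continue
        tag = tags.get(seq)
        if tag is None:
            continue
        row = rows.setdefault(
            res.family, {"members": set(), lib_a: 0, lib_b: 0}
        )
        row["members"].add(res.member)
        row[lib_a] += tag.counts.get(lib_a, 0)
        row[lib_b] += tag.counts.get(lib_b, 0)
    records = []
    for fam in sorted(rows):
        row = rows[fam]
        a, b = row[lib_a], row[lib_b]
        records.append(
            {
                "family": fam,
                "members": len(row["members"]),
                f"reads_{lib_a}": a,
                f"reads_{lib_b}": b,
                "total_reads": a + b,
                "ratio": round(b / a, 2) if a else float("inf"),
            }
        )
    return pd.DataFrame(
        records,
        columns=[
            "family",
            "members",
            f"reads_{lib_a}",
            f"reads_{lib_b}",
            "total_reads",
            "ratio",
        ],
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def annotate_tags(
    tags: Mapping[str, SequenceTag],
    reference: Optional[ReferenceDB] = None,
    ncrna_db: Optional[ReferenceDB] = None,
    families: Sequence[KnownMiRNAFamily] = (),
    max_mismatch: int = 2,
    require_reference_hit: bool = False,
) -> Dict[str, AnnotationResult]:
    """Full annotation pass over a tag set.

    Order of classification: ncRNA classes first (and such tags are
    excluded from miRNA calling), then known miRNAs, then unannotated.
    Known-miRNA assignment does not require a reference hit unless
    ``require_reference_hit`` (strict mode) is set.
    """
    seqs = sorted(tags)
    hits = map_perfect(seqs, reference) if reference is not None else {s: [] for s in seqs}
    nc = classify_ncrna(seqs, ncrna_db) if ncrna_db is not None else {s: None for s in seqs}

    results: Dict[str, AnnotationResult] = {}
    candidates = []
    for seq in seqs:
        if nc[seq] is not None:
            results[seq] = AnnotationResult(seq, nc[seq], hits=hits[seq])
        else:
            candidates.append(seq)

    mirna_pool = [s for s in candidates if hits[s]] if require_reference_hit else candidates
    assigned = assign_known_mirna(mirna_pool, families, max_mismatch) if families else {}
    for seq in candidates:
        res = assigned.get(seq)
        if res is not None and res.klass == "known_miRNA":
            res.hits = hits[seq]
            results[seq] = res
        else:
            results[seq] = AnnotationResult(seq, "unannotated", hits=hits[seq])
    return results


def class_distribution(
    results: Mapping[str, AnnotationResult],
    tags: Mapping[str, SequenceTag],
    libraries: Sequence[str],
) -> pd.DataFrame:
    """Per-class (unique, total) counts per library -- the library
    composition table.  Classes partition the tag set exactly."""
    rows = []
    for cls in CLASSES:
        row: Dict[str, object] = {"class": cls}
        for lib in libraries:
            uniq = total = 0
            for seq, res in results.items():
                if res.klass != cls:
                    continue
                n = tags[seq].counts.get(lib, 0)
                if n > 0:
                    uniq += 1
                    total += n
            row[f"unique_{lib}"] = uniq
            row[f"total_{lib}"] = total
        rows.append(row)
    return pd.DataFrame(rows)
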