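"""Reading, cleaning and collapsing of small-RNA sequencing reads.

A raw small-RNA read is the ligated insert followed by the 3' sequencing
adapter (and possibly preceded by 5'-adapter contamination).  Cleaning
recovers the insert, discards library artefacts, and the surviving inserts
are collapsed into unique sequence tags with per-library read counts --
the unit every downstream stage (annotation, novel-miRNA discovery,
differential expression) operates on.

Rejection rules are applied in a fixed order so that the per-rule tally is
deterministic: 5'-adapter contaminant -> no insert -> poly(A) -> length.
"""

from __future__ import annotations

import gzip
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

_U_TO_T = str.maketrans("Uu", "Tt")
_COLLAPSED_HEADER = re.compile(r"_x(\d+)$")

#: canonical rejection-rule labels, in application order
RULE_ORDER = ("adapter5", "no_insert", "polyA", "too_short", "too_long")


@dataclass
class RawRead:
    """One sequencing read; ``count`` > 1 for collapsed-FASTA input."""

    identifier: str
    sequence: str
    quality: Optional[str] = None
    count: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.identifier!r} has an empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.identifier!r}: quality length != sequence length"
            )


@dataclass
class SequenceTag:
    """A unique small-RNA sequence with read counts per library."""

    sequence: str
    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class OverlapSummary:
    """Shared / library-specific partition of two tag sets.

    ``*_unique`` count distinct sequences, ``*_total`` sum read counts over
    both libraries.  Percentages are of the corresponding union figure,
    rounded to 2 decimals.
    """

    label_a: str
    label_b: str
    shared_unique: int
    a_specific_unique: int
    b_specific_unique: int
    shared_total: int
    a_specific_total: int
    b_specific_total: int

    @property
    def union_unique(self) -> int:
        return self.shared_unique + self.a_specific_unique + self.b_specific_unique

    @property
    def union_total(self) -> int:
        return self.shared_total + self.a_specific_total + self.b_specific_total

    def percentages(self) -> Dict[str, float]:
        pct = lambda v, d: round(100.0 * v / d, 2) if d else 0.0
        return {
            "shared_unique": pct(self.shared_unique, self.union_unique),
            f"{self.label_a}_specific_unique": pct(self.a_specific_unique, self.union_unique),
            f"{self.label_b}_specific_unique": pct(self.b_specific_unique, self.union_unique),
            "shared_total": pct(self.shared_total, self.union_total),
            f"{self.label_a}_specific_total": pct(self.a_specific_total, self.union_total),
            f"{self.label_b}_specific_total": pct(self.b_specific_total, self.union_total),
        }


@dataclass
class LibraryProfile:
    """Composition summary of one cleaned, collapsed library."""

    label: str
    total_clean: int
    total_unique: int
    length_histogram: Dict[int, int]
    class_counts: Optional[Dict[str, Tuple[int, int]]] = None  # class -> (unique, total)
    total_raw: Optional[int] = None


@dataclass
class CleaningResult:
    """Cleaned inserts plus the per-rule rejection tally."""

    sequences: List[Tuple[str, int]]  # (insert, read count)
    tally: Counter

    @property
    def kept(self) -> int:
        return self.tally["kept"]


# ---------------------------------------------------------------------------
# input parsing
# ---------------------------------------------------------------------------

def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_sequences(path) -> Iterator[RawRead]:
    """Stream reads from FASTQ or FASTA.

    FASTA headers in the collapsed dialect ``<name>_x<count>`` set the read
    count; all other headers count 1.  The format is sniffed from the first
    character (``@`` FASTQ, ``>`` FASTA).
    """
    with _open_text(path) as fh:
        first = fh.read(1)
        if not first:
            return
        fh.seek(0)
        if first == "@":
            yield from _read_fastq(fh)
        elif first == ">":
            yield from _read_fasta(fh)
        else:
            raise ValueError(f"{path}: not FASTA or FASTQ (starts with {first!r})")


def _read_fastq(fh) -> Iterator[RawRead]:
    while True:
        header = fh.readline().rstrip()
        if not header:
            return
        seq = fh.readline().rstrip()
        fh.readline()  # '+'
        qual = fh.readline().rstrip()
        yield RawRead(header[1:].split()[0], seq, qual or None)


def _read_fasta(fh) -> Iterator[RawRead]:
    name, chunks = None, []
    for line in fh:
        line = line.rstrip()
        if line.startswith(">"):
            if name is not None:
                yield _fasta_read(name, "".join(chunks))
            name, chunks = line[1:].split()[0] if line[1:] else "", []
        elif line:
            chunks.append(line)
    if name is not None and chunks:
        yield _fasta_read(name, "".join(chunks))


def _fasta_read(name: str, seq: str) -> RawRead:
    m = _COLLAPSED_HEADER.search(name)
    return RawRead(name, seq, None, int(m.group(1)) if m else 1)


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def normalize(seq: str) -> str:
    """Uppercase and normalize U to T (all internal sequences are DNA)."""
    return seq.upper().translate(_U_TO_T).replace("U", "T")


def _is_polya(seq: str, frac: float, run: int) -> bool:
    if not seq:
        return False
    if seq.count("A") / len(seq) >= frac:
        return True
    return "A" * run in seq


def clean_reads(
    reads: Iterable[RawRead],
    adapter3: str,
    adapter5: str = "",
    min_len: int = 15,
    max_len: int = 30,
    seed_len: int = 8,
    polya_frac: float = 0.8,
    polya_run: int = 10,
) -> CleaningResult:
    """Apply the library cleaning rules and return surviving inserts.

    Rules, in order of application (a read is tallied under the first rule
    it fails):

    1. ``adapter5`` -- the read begins with the 3'-terminal ``seed_len``
       bases of the 5' adapter (ligation contaminant).
    2. ``no_insert`` -- the 3' adapter starts at position 0 (adapter dimer,
       empty insert), or the read is shorter than the adapter seed.
    3. ``polyA`` -- the trimmed insert is >= ``polya_frac`` adenine or
       contains an A-homopolymer of length >= ``polya_run``.
    4. ``too_short`` / ``too_long`` -- insert length outside
       [``min_len``, ``max_len``].

    The 3' adapter is located by its first ``seed_len`` bases (leftmost
    occurrence); reads in which the seed never occurs are kept untrimmed,
    which makes cleaning idempotent: re-cleaning the output is a no-op.
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")

    a3 = normalize(adapter3)
    a5 = normalize(adapter5) if adapter5 else ""
    seed3 = a3[: min(seed_len, len(a3))]
    seed5 = a5[-min(seed_len, len(a5)):] if a5 else ""

    tally: Counter = Counter({rule: 0 for rule in RULE_ORDER})
    tally["kept"] = 0
    out: List[Tuple[str, int]] = []

    for read in reads:
        seq = normalize(read.sequence)
        n = read.count
        if seed5 and seq.startswith(seed5):
            tally["adapter5"] += n
            continue
        if len(seq) < len(seed3):
            tally["no_insert"] += n
            continue
        pos = seq.find(seed3)
        if pos == 0:
            tally["no_insert"] += n
            continue
        insert = seq[:pos] if pos > 0 else seq
        if _is_polya(insert, polya_frac, polya_run):
            tally["polyA"] += n
            continue
        if len(insert) < min_len:
            tally["too_short"] += n
            continue
        if len(insert) > max_len:
            tally["too_long"] += n
            continue
        tally["kept"] += n
        out.append((insert, n))

    return CleaningResult(out, tally)


# ---------------------------------------------------------------------------
# collapsing and summaries
# ---------------------------------------------------------------------------

def collapse_to_tags(
    cleaned: Iterable[Tuple[str, int]] | Iterable[str], library: str
) -> Dict[str, SequenceTag]:
    """Collapse cleaned inserts into unique tags keyed by sequence."""
    tags: Dict[str, SequenceTag] = {}
    for item in cleaned:
        seq, n = item if isinstance(item, tuple) else (item, 1)
        tag = tags.get(seq)
        if tag is None:
            tags[seq] = SequenceTag(seq, {library: n})
        else:
            tag.counts[library] = tag.counts.get(library, 0) + n
    return tags


def merge_tag_sets(*tag_sets: Dict[str, SequenceTag]) -> Dict[str, SequenceTag]:
    """Union several per-library tag sets into one multi-library set."""
    merged: Dict[str, SequenceTag] = {}
    for tags in tag_sets:
        for seq, tag in tags.items():
            tgt = merged.setdefault(seq, SequenceTag(seq, {}))
            for lib, n in tag.counts.items():
                tgt.counts[lib] = tgt.counts.get(lib, 0) + n
    return merged


def library_profile(
    tags: Dict[str, SequenceTag],
    library: str,
    classes: Optional[Dict[str, str]] = None,
    total_raw: Optional[int] = None,
) -> LibraryProfile:
    """Length histogram and (optionally) class composition of one library."""
    hist: Counter = Counter()
    total = 0
    per_class: Dict[str, List[int]] = {}
    for seq, tag in tags.items():
        n = tag.counts.get(library, 0)
        if n == 0:
            continue
        hist[len(seq)] += n
        total += n
        if classes is not None:
            cls = classes.get(seq, "unannotated")
            uc = per_class.setdefault(cls, [0, 0])
            uc[0] += 1
            uc[1] += n
    n_unique = sum(1 for t in tags.values() if t.counts.get(library, 0) > 0)
    class_counts = (
        {c: (u, t) for c, (u, t) in per_class.items()} if classes is not None else None
    )
    return LibraryProfile(library, total, n_unique, dict(hist), class_counts, total_raw)


def summarize_libraries(
    tags_a: Dict[str, SequenceTag],
    tags_b: Dict[str, SequenceTag],
    label_a: str = "CK",
    label_b: str = "Cd200",
) -> Tuple[LibraryProfile, LibraryProfile, OverlapSummary]:
    """Per-library profiles plus the shared/specific overlap partition."""
    set_a, set_b = set(tags_a), set(tags_b)
    shared = set_a & set_b
    only_a = set_a - shared
    only_b = set_b - shared

    def reads(seqs, *sets):
        return sum(t.total for s in seqs for t in (ts[s] for ts in sets if s in ts))

    overlap = OverlapSummary(
        label_a,
        label_b,
        shared_unique=len(shared),
        a_specific_unique=len(only_a),
        b_specific_unique=len(only_b),
        shared_total=sum(tags_a[s].total + tags_b[s].total for s in shared),
        a_specific_total=sum(tags_a[s].total for s in only_a),
        b_specific_total=sum(tags_b[s].total for s in only_b),
    )
    return (
        library_profile(tags_a, label_a),
        library_profile(tags_b, label_b),
        overlap,
    )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def tags_to_tsv(tags: Dict[str, SequenceTag], path, libraries: Sequence[str]) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tlength\t" + "\t".join(libraries) + "\n")
        for seq in sorted(tags):
            counts = "\t".join(str(tags[seq].counts.get(l, 0)) for l in libraries)
            fh.write(f"{seq}\t{len(seq)}\t{counts}\n")


def tags_to_collapsed_fasta(tags: Dict[str, SequenceTag], path) -> None:
    """Write ``seqN_xCOUNT`` collapsed FASTA (count summed over libraries)."""
    with open(path, "w") as fh:
        ordered = sorted(tags.values(), key=lambda t: (-t.total, t.sequence))
        for i, tag in enumerate(ordered, 1):
            fh.write(f">seq{i}_x{tag.total}\n{tag.sequence}\n")
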