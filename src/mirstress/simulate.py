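"""Seeded synthetic data with ground truth for every pipeline stage.

The generator emulates a two-condition plant small-RNA study: a transcript
reference with planted miRNA hairpin loci (stem = mature + reverse
complement with a few substitutions, 8-15 nt loop), ncRNA records for the
four structural classes, a small set of "known" mature miRNAs, two
sequencing libraries (control and stressed) whose read pool mixes planted
mature/star species, known-miRNA species, ncRNA fragments and random
degradation fragments with a length profile peaked at 21/24 nt, and a
degradome library whose planted signature tags start at the base opposite
miRNA position 10 of planted target sites.

Everything is drawn from one ``numpy`` generator seeded from the config,
and all iteration orders are fixed, so identical configs produce
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .annotate import ReferenceDB, reverse_complement
from .folding import fold_mfe
from .preprocess import RawRead

_BASES = np.array(list("ACGT"))

#: insert-length profile of the small-RNA libraries (peaks at 21 and 24 nt)
LENGTH_WEIGHTS: Dict[int, float] = {
    15: 1, 16: 1, 17: 1, 18: 2, 19: 2, 20: 3,
    21: 8, 22: 4, 23: 3, 24: 9, 25: 2, 26: 1, 27: 1, 28: 1,
}


@dataclass
class SimConfig:
    """Study-scale parameters of the synthetic experiment."""

    seed: int = 0
    n_transcripts: int = 20
    transcript_length: Tuple[int, int] = (500, 3000)
    n_hairpins: int = 12
    mature_lengths: Tuple[int, ...] = (20, 21, 21, 21, 22, 23, 24)
    loop_length: Tuple[int, int] = (8, 15)
    star_substitutions: Tuple[int, int] = (0, 2)  # uniform inclusive range
    expression_range: Tuple[int, int] = (100, 1500)  # expected CK mature reads
    expression_reference_depth: int = 200_000  # depth at which expression is quoted
    fold_classes: Tuple[float, ...] = (4.0, 0.25, 1.0)  # cycled over hairpins
    star_fraction: float = 0.05
    star_floor: int = 6
    library_depth: int = 200_000
    ncrna_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"rRNA": 0.10, "tRNA": 0.05, "snRNA": 0.01, "snoRNA": 0.01}
    )
    known_fraction: float = 0.05
    n_known_families: int = 5
    adapter3: str = "TCGTATGCCGTCTTCTGCTTG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    n_target_events: int = 8
    signature_reads: int = 50
    degradome_depth: int = 50_000
    background_on_targets: bool = False

    def validate(self) -> List[str]:
        problems = []
        if self.library_depth <= 0 or self.degradome_depth <= 0:
            problems.append("library depths must be positive")
        for cls, frac in self.ncrna_fractions.items():
            if not 0 <= frac <= 1:
                problems.append(f"ncrna fraction for {cls} outside [0, 1]")
        if not 0 <= self.known_fraction <= 1:
            problems.append("known_fraction outside [0, 1]")
        if self.n_target_events > self.n_hairpins:
            problems.append("n_target_events cannot exceed n_hairpins")
        if sum(self.ncrna_fractions.values()) + self.known_fraction >= 0.8:
            problems.append("ncRNA + known fractions leave no room for other reads")
        return problems


@dataclass
class PlantedHairpin:
    name: str
    record_id: str
    start: int  # precursor span, 1-based inclusive
    end: int
    arm: str
    mature: str
    star: str
    mature_start: int  # 1-based on the record
    mfe: float
    expected_ck: float
    expected_cd: float
    fold_change: float
    reads_ck: int = 0
    reads_cd: int = 0
    star_reads_ck: int = 0
    star_reads_cd: int = 0


@dataclass
class PlantedEvent:
    mirna_name: str
    mirna_seq: str
    transcript_id: str
    site_start: int
    site_end: int
    cleavage_pos: int
    signature: int
    expected_category: str = "I"


@dataclass
class KnownSpecies:
    member_id: str
    sequence: str
    expected_ck: float
    expected_cd: float
    reads_ck: int = 0
    reads_cd: int = 0


@dataclass
class TruthTable:
    hairpins: List[PlantedHairpin] = field(default_factory=list)
    events: List[PlantedEvent] = field(default_factory=list)
    known: List[KnownSpecies] = field(default_factory=list)

    def to_frames(self):
        import pandas as pd

        return {
            "hairpins": pd.DataFrame([dataclasses.asdict(h) for h in self.hairpins]),
            "events": pd.DataFrame([dataclasses.asdict(e) for e in self.events]),
            "known": pd.DataFrame([dataclasses.asdict(k) for k in self.known]),
        }


@dataclass
class SimBundle:
    config: SimConfig
    reference: ReferenceDB
    ncrna: ReferenceDB
    truth: TruthTable
    reads_ck: List[RawRead]
    reads_cd: List[RawRead]
    degradome: List[RawRead]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def _plant_hairpin(
    rng: np.random.Generator, cfg: SimConfig, idx: int
) -> Tuple[str, str, str, str, int]:
    """Build one stem-loop insert; returns (precursor, mature, star, arm,
    mature offset within the precursor, 0-based)."""
    m_len = int(rng.choice(cfg.mature_lengths))
    mature = _random_seq(rng, m_len)
    loop = _random_seq(rng, int(rng.integers(cfg.loop_length[0], cfg.loop_length[1] + 1)))
    star = list(reverse_complement(mature))
    n_sub = int(rng.integers(cfg.star_substitutions[0], cfg.star_substitutions[1] + 1))
    # substitutions away from the duplex ends keep the 2-nt overhang geometry
    subs = rng.choice(np.arange(3, m_len - 3), size=n_sub, replace=False) if n_sub else []
    for pos in subs:
        old = star[pos]
        star[pos] = str(rng.choice([b for b in "ACGT" if b != old]))
    star_seq = "".join(star)
    arm = "5p" if idx % 2 == 0 else "3p"
    if arm == "5p":
        precursor = mature + loop + star_seq
        offset = 0
    else:
        precursor = star_seq + loop + mature
        offset = len(star_seq) + len(loop)
    return precursor, mature, star_seq, arm, offset


def simulate_reference(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[ReferenceDB, ReferenceDB, TruthTable]:
    """Transcript reference with planted hairpins and target sites, plus an
    ncRNA database, plus the truth table (expression drawn but reads not
    yet sampled)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    truth = TruthTable()
    lo, hi = config.transcript_length
    lengths = rng.integers(lo, hi + 1, config.n_transcripts)
    records = {f"tx{i + 1:03d}": _random_seq(rng, int(n)) for i, n in enumerate(lengths)}
    ids = sorted(records)

    # hairpins on the first transcripts, one per transcript, mid-sequence
    if config.n_hairpins > len(ids):
        raise ValueError("more hairpins than transcripts")
    for h in range(config.n_hairpins):
        precursor, mature, star, arm, offset = _plant_hairpin(rng, config, h)
        tid = ids[h % len(ids)]
        seq = records[tid]
        if len(precursor) + 40 > len(seq):
            raise ValueError(f"hairpin longer than host transcript {tid}")
        pos = int(rng.integers(20, len(seq) - len(precursor) - 20))  # 0-based
        records[tid] = seq[:pos] + precursor + seq[pos + len(precursor):]
        expected_ck = float(rng.integers(*config.expression_range))
        fc = config.fold_classes[h % len(config.fold_classes)]
        truth.hairpins.append(
            PlantedHairpin(
                name=f"sim-hairpin-{h + 1}",
                record_id=tid,
                start=pos + 1,
                end=pos + len(precursor),
                arm=arm,
                mature=mature,
                star=star,
                mature_start=pos + offset + 1,
                mfe=fold_mfe(precursor).mfe,
                expected_ck=expected_ck,
                expected_cd=expected_ck * fc,
                fold_change=fc,
            )
        )

    # degradome target sites on hairpin-free transcripts
    decoys = [t for t in ids if t not in {h.record_id for h in truth.hairpins}]
    if len(decoys) < 1 and config.n_target_events:
        raise ValueError("no hairpin-free transcripts left for target sites")
    for e in range(config.n_target_events):
        hp = truth.hairpins[e]
        tid = decoys[e % len(decoys)]
        seq = records[tid]
        site = reverse_complement(hp.mature)
        L = len(site)
        pos = int(rng.integers(30, len(seq) - L - 30))  # 0-based site start
        records[tid] = seq[:pos] + site + seq[pos + L:]
        cleavage = pos + 1 + L - 10  # transcript base opposite miRNA position 10
        truth.events.append(
            PlantedEvent(hp.name, hp.mature, tid, pos + 1, pos + L, cleavage, config.signature_reads)
        )

    reference = ReferenceDB(records, {r: "transcript" for r in records})

    nc_records, nc_kinds = {}, {}
    plan = [("rRNA", 2, 1500), ("tRNA", 3, 75), ("snRNA", 2, 150), ("snoRNA", 2, 100)]
    for label, count, length in plan:
        for i in range(count):
            rid = f"{label.lower()}_{i + 1}"
            nc_records[rid] = _random_seq(rng, length)
            nc_kinds[rid] = label
    ncrna = ReferenceDB(nc_records, nc_kinds)

    # known mature miRNAs (miRBase-style families, not tied to the reference)
    for f in range(config.n_known_families):
        fam_serial = 901 + f
        for m in range(int(rng.integers(1, 4))):
            member = f"sim-miR{fam_serial}{'abc'[m]}"
            expected = float(rng.integers(50, 500))
            ratio = float(rng.choice([0.5, 1.0, 2.0]))
            truth.known.append(
                KnownSpecies(member, _random_seq(rng, 21), expected, expected * ratio)
            )
    return reference, ncrna, truth


def shuffled_reference(
    reference: ReferenceDB, rng: np.random.Generator
) -> ReferenceDB:
    """Base-shuffled copy of each record: same composition, no planted
    structure -- the hairpin-free negative control."""
    records = {}
    for rid in sorted(reference.records):
        arr = np.array(list(reference.records[rid]))
        rng.shuffle(arr)
        records[rid] = "".join(arr)
    return ReferenceDB(records, dict(reference.kinds))


# ---------------------------------------------------------------------------
# small-RNA libraries
# ---------------------------------------------------------------------------

def _length_sampler(rng: np.random.Generator, n: int) -> np.ndarray:
    lens = np.array(sorted(LENGTH_WEIGHTS))
    w = np.array([LENGTH_WEIGHTS[l] for l in lens], dtype=float)
    return rng.choice(lens, size=n, p=w / w.sum())


def _fragment_reads(
    rng: np.random.Generator,
    db_records: Mapping[str, str],
    n: int,
    prefix: str,
    start_index: int,
    adapter3: str,
    transcripts_excluded: Sequence[str] = (),
) -> List[RawRead]:
    """Random sub-fragments of the given records with the library length
    profile (models turnover/degradation products)."""
    ids = sorted(t for t in db_records if t not in set(transcripts_excluded))
    lengths = np.array([len(db_records[t]) for t in ids], dtype=float)
    weights = lengths / lengths.sum()
    picks = rng.choice(len(ids), size=n, p=weights)
    frag_lens = _length_sampler(rng, n)
    out = []
    for k in range(n):
        tid = ids[int(picks[k])]
        seq = db_records[tid]
        L = int(frag_lens[k])
        if L >= len(seq):
            L = len(seq) - 1
        start = int(rng.integers(0, len(seq) - L))
        insert = seq[start : start + L]
        out.append(_read(f"{prefix}{start_index + k}", insert, adapter3))
    return out


def _read(identifier: str, insert: str, adapter3: str) -> RawRead:
    seq = insert + adapter3
    return RawRead(identifier, seq, "I" * len(seq))


def simulate_sra_libraries(
    config: SimConfig,
    reference: ReferenceDB,
    ncrna: ReferenceDB,
    truth: TruthTable,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[RawRead], List[RawRead]]:
    """Sample the CK and stressed libraries as multinomial draws at the
    configured depth; realized per-species counts are written back into
    the truth table."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    depth = config.library_depth
    # expression values are expected reads at the reference depth, so the
    # per-read probability of a species is depth-independent
    ref_depth = config.expression_reference_depth

    species: List[Tuple[str, float, float]] = []  # (insert, expected CK, expected Cd)
    star_index: Dict[int, int] = {}
    for i, hp in enumerate(truth.hairpins):
        species.append((hp.mature, hp.expected_ck, hp.expected_cd))
        star_exp = max(config.star_floor, config.star_fraction * hp.expected_ck)
        star_cd = max(config.star_floor, config.star_fraction * hp.expected_cd)
        star_index[len(species)] = i
        species.append((hp.star, star_exp, star_cd))
    known_offset = len(species)
    for ks in truth.known:
        species.append((ks.sequence, ks.expected_ck, ks.expected_cd))

    nc_classes = sorted(config.ncrna_fractions)
    libraries = []
    for lib_idx, lib in enumerate(("CK", "Cd200")):
        probs = [s[1 + lib_idx] / ref_depth for s in species]
        probs += [config.ncrna_fractions[c] for c in nc_classes]
        p_named = sum(probs)
        if p_named >= 1.0:
            raise ValueError("expected species exceed the expression reference depth")
        probs.append(1.0 - p_named)  # degradation fragments
        counts = rng.multinomial(depth, np.array(probs))

        reads: List[RawRead] = []
        serial = 0
        for s_idx, (insert, _, _) in enumerate(species):
            n = int(counts[s_idx])
            for _ in range(n):
                reads.append(_read(f"{lib}_{serial}", insert, config.adapter3))
                serial += 1
            if s_idx % 2 == 0 and s_idx < known_offset:
                hp = truth.hairpins[s_idx // 2]
                setattr(hp, "reads_ck" if lib == "CK" else "reads_cd", n)
            elif s_idx in star_index:
                hp = truth.hairpins[star_index[s_idx]]
                setattr(hp, "star_reads_ck" if lib == "CK" else "star_reads_cd", n)
            elif s_idx >= known_offset:
                ks = truth.known[s_idx - known_offset]
                setattr(ks, "reads_ck" if lib == "CK" else "reads_cd", n)
        for c_idx, cls in enumerate(nc_classes):
            n = int(counts[len(species) + c_idx])
            sub = {r: ncrna.records[r] for r, k in ncrna.kinds.items() if k == cls}
            reads.extend(
                _fragment_reads(rng, sub, n, f"{lib}_", serial, config.adapter3)
            )
            serial += n
        n_deg = int(counts[-1])
        reads.extend(
            _fragment_reads(rng, reference.records, n_deg, f"{lib}_", serial, config.adapter3)
        )
        libraries.append(reads)
    return libraries[0], libraries[1]


# ---------------------------------------------------------------------------
# degradome
# ---------------------------------------------------------------------------

def simulate_degradome(
    config: SimConfig,
    reference: ReferenceDB,
    truth: TruthTable,
    rng: Optional[np.random.Generator] = None,
) -> List[RawRead]:
    """Planted cleavage signatures plus uniform background 5' ends.

    Signature tags start exactly at the planted cleavage position (the
    base opposite miRNA position 10).  Background tags fall on transcripts
    without planted events unless ``background_on_targets`` is set, so
    planted sites stay the unique maxima of their transcripts.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    reads: List[RawRead] = []
    serial = 0
    for ev in truth.events:
        seq = reference.records[ev.transcript_id]
        for k in range(ev.signature):
            L = 20 + (k % 2)
            start = ev.cleavage_pos - 1
            tag = seq[start : start + L]
            if len(tag) < 20:
                tag = seq[start : start + 20]
            reads.append(RawRead(f"deg_{serial}", tag, "I" * len(tag)))
            serial += 1
    n_background = max(0, config.degradome_depth - serial)
    target_ids = {ev.transcript_id for ev in truth.events}
    excluded = () if config.background_on_targets else tuple(sorted(target_ids))
    ids = sorted(t for t in reference.records if t not in set(excluded))
    if ids and n_background:
        lengths = np.array([len(reference.records[t]) for t in ids], dtype=float)
        weights = lengths / lengths.sum()
        picks = rng.choice(len(ids), size=n_background, p=weights)
        tag_lens = rng.integers(20, 22, n_background)
        for k in range(n_background):
            tid = ids[int(picks[k])]
            seq = reference.records[tid]
            L = int(tag_lens[k])
            start = int(rng.integers(0, len(seq) - L))
            reads.append(RawRead(f"deg_{serial}", seq[start : start + L], "I" * L))
            serial += 1
    return reads


# ---------------------------------------------------------------------------
# full study + serialization
# ---------------------------------------------------------------------------

def simulate_study(config: SimConfig, outdir: Optional[Path] = None) -> SimBundle:
    """Generate the complete synthetic study; optionally write all files
    (FASTA/FASTQ, truth TSVs, config YAML) into ``outdir``."""
    problems = config.validate()
    if problems:
        raise ValueError("invalid SimConfig: " + "; ".join(problems))
    rng = np.random.default_rng(config.seed)
    reference, ncrna, truth = simulate_reference(config, rng)
    reads_ck, reads_cd = simulate_sra_libraries(config, reference, ncrna, truth, rng)
    degradome = simulate_degradome(config, reference, truth, rng)
    bundle = SimBundle(config, reference, ncrna, truth, reads_ck, reads_cd, degradome)
    if outdir is not None:
        write_bundle(bundle, Path(outdir))
    return bundle


def _write_fasta(records: Mapping[str, str], path: Path, rna: bool = False) -> None:
    with open(path, "w") as fh:
        for rid in sorted(records):
            seq = records[rid].replace("T", "U") if rna else records[rid]
            fh.write(f">{rid}\n{seq}\n")


def _write_fastq(reads: Sequence[RawRead], path: Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.identifier}\n{r.sequence}\n+\n{r.quality or 'I' * len(r.sequence)}\n")


def write_bundle(bundle: SimBundle, outdir: Path) -> Dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fasta",
        "ncrna": outdir / "ncrna.fasta",
        "known_mirnas": outdir / "known_mirnas.fasta",
        "reads_ck": outdir / "ck.fastq",
        "reads_cd": outdir / "cd200.fastq",
        "degradome": outdir / "degradome.fastq",
        "config": outdir / "sim_config.yaml",
    }
    _write_fasta(bundle.reference.records, paths["reference"])
    with open(paths["ncrna"], "w") as fh:
        for rid in sorted(bundle.ncrna.records):
            fh.write(f">{rid} {bundle.ncrna.kinds[rid]}\n{bundle.ncrna.records[rid]}\n")
    _write_fasta(
        {k.member_id: k.sequence for k in bundle.truth.known},
        paths["known_mirnas"],
        rna=True,
    )
    _write_fastq(bundle.reads_ck, paths["reads_ck"])
    _write_fastq(bundle.reads_cd, paths["reads_cd"])
    _write_fastq(bundle.degradome, paths["degradome"])
    cfg = dataclasses.asdict(bundle.config)
    cfg["ncrna_fractions"] = dict(cfg["ncrna_fractions"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    for name, frame in bundle.truth.to_frames().items():
        p = outdir / f"truth_{name}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        paths[f"truth_{name}"] = p
    return paths
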