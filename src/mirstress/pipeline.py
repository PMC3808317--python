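"""End-to-end pipeline: preprocess -> annotate -> novel discovery ->
differential expression -> degradome target calling.

One config drives all stages; every tabular output is TSV with a
'#'-prefixed, versioned header so reruns are comparable, and a JSON
manifest records parameters, input checksums and per-stage status.
Reruns with identical inputs and config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .annotate import (
    ReferenceDB,
    annotate_tags,
    class_distribution,
    family_table,
    load_known_mirnas,
)
from .degradome import call_targets, calls_table, filter_degradome_reads, tplot_table
from .diffexpr import differential_expression, expression_table
from .novel import discover_novel, novel_table
from .preprocess import (
    clean_reads,
    collapse_to_tags,
    merge_tag_sets,
    read_sequences,
    summarize_libraries,
)

SCHEMA_VERSION = "1"
logger = logging.getLogger("mirstress")


@dataclass
class PipelineConfig:
    """Paths and stage parameters for one pipeline run."""

    library_ck: str
    library_cd: str
    reference: str
    output_dir: str
    known_mirnas: Optional[str] = None
    ncrna: Optional[str] = None
    degradome: Optional[str] = None
    label_ck: str = "CK"
    label_cd: str = "Cd200"
    adapter3: str = "TCGTATGCCGTCTTCTGCTTG"
    adapter5: str = ""
    min_len: int = 15
    max_len: int = 30
    max_mismatch: int = 2
    min_tag_count: int = 5
    flank_up: int = 20
    flank_down: int = 160
    min_precursor: int = 60
    max_precursor: int = 300
    mfe_max: float = -18.0
    min_star_reads: int = 1
    ratio_up: float = 2.0
    ratio_down: float = 0.5
    alpha: float = 0.05
    adjust_pvalues: bool = False
    deg_max_score: float = 4.0
    deg_max_mismatch: int = 5
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def validate_config(config: PipelineConfig) -> List[str]:
    """Rule-by-rule validation; each violation names the offending field."""
    v: List[str] = []
    for name in ("library_ck", "library_cd", "reference"):
        path = getattr(config, name)
        if not path or not Path(path).is_file():
            v.append(f"{name}: file not found ({path})")
    for name in ("known_mirnas", "ncrna", "degradome"):
        path = getattr(config, name)
        if path and not Path(path).is_file():
            v.append(f"{name}: file not found ({path})")
    if not config.adapter3:
        v.append("adapter3: must be non-empty")
    if config.min_len > config.max_len:
        v.append("min_len: must be <= max_len")
    if config.max_mismatch < 0:
        v.append("max_mismatch: must be >= 0")
    if config.min_tag_count < 1:
        v.append("min_tag_count: must be >= 1")
    if config.min_precursor > config.max_precursor:
        v.append("min_precursor: must be <= max_precursor")
    if config.mfe_max > 0:
        v.append("mfe_max: must be <= 0 kcal/mol")
    if config.min_star_reads < 1:
        v.append("min_star_reads: must be >= 1")
    if config.ratio_down >= config.ratio_up:
        v.append("ratio_down: must be < ratio_up")
    if not (0 < config.alpha <= 1):
        v.append("alpha: must be in (0, 1]")
    if config.deg_max_score < 0:
        v.append("deg_max_score: must be >= 0")
    if config.deg_max_mismatch < 0:
        v.append("deg_max_mismatch: must be >= 0")
    return v


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, table_name: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mirstress report\ttable={table_name}\tschema={SCHEMA_VERSION}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%g")


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute all stages; returns the manifest (also written to disk).

    The degradome stage is optional: without a degradome path the pipeline
    stops after differential expression and the manifest marks the stage
    skipped.  On stage failure, outputs of completed stages are retained
    and the manifest records the failure point.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid pipeline config: " + "; ".join(problems))

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log_file = outdir / "run.log"
    handler = logging.FileHandler(log_file, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)

    manifest: Dict = {
        "tool": "mirstress",
        "version": __version__,
        "schema": SCHEMA_VERSION,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "inputs": {},
        "stages": {},
        "outputs": {},
    }
    for name in ("library_ck", "library_cd", "reference", "known_mirnas", "ncrna", "degradome"):
        path = getattr(config, name)
        if path:
            manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    def emit(frame: pd.DataFrame, fname: str, table: str) -> None:
        path = outdir / fname
        _write_tsv(frame, path, table)
        manifest["outputs"][table] = str(path)

    try:
        # --- preprocess -----------------------------------------------------
        logger.info("cleaning %s", config.library_ck)
        clean_ck = clean_reads(
            read_sequences(config.library_ck),
            config.adapter3,
            config.adapter5,
            config.min_len,
            config.max_len,
        )
        clean_cd = clean_reads(
            read_sequences(config.library_cd),
            config.adapter3,
            config.adapter5,
            config.min_len,
            config.max_len,
        )
        tags_ck = collapse_to_tags(clean_ck.sequences, config.label_ck)
        tags_cd = collapse_to_tags(clean_cd.sequences, config.label_cd)
        tags = merge_tag_sets(tags_ck, tags_cd)
        prof_ck, prof_cd, overlap = summarize_libraries(
            tags_ck, tags_cd, config.label_ck, config.label_cd
        )
        pct = overlap.percentages()
        emit(
            pd.DataFrame(
                [
                    {"class": "all", "unique": overlap.union_unique, "total": overlap.union_total,
                     "unique_pct": 100.0, "total_pct": 100.0},
                    {"class": "shared", "unique": overlap.shared_unique, "total": overlap.shared_total,
                     "unique_pct": pct["shared_unique"], "total_pct": pct["shared_total"]},
                    {"class": f"{config.label_ck}_specific", "unique": overlap.a_specific_unique,
                     "total": overlap.a_specific_total,
                     "unique_pct": pct[f"{config.label_ck}_specific_unique"],
                     "total_pct": pct[f"{config.label_ck}_specific_total"]},
                    {"class": f"{config.label_cd}_specific", "unique": overlap.b_specific_unique,
                     "total": overlap.b_specific_total,
                     "unique_pct": pct[f"{config.label_cd}_specific_unique"],
                     "total_pct": pct[f"{config.label_cd}_specific_total"]},
                ]
            ),
            "library_overlap.tsv",
            "library_overlap",
        )
        hist_rows = []
        for prof in (prof_ck, prof_cd):
            for length in sorted(prof.length_histogram):
                hist_rows.append(
                    {"library": prof.label, "length": length, "reads": prof.length_histogram[length]}
                )
        emit(pd.DataFrame(hist_rows), "length_distribution.tsv", "length_distribution")
        manifest["stages"]["preprocess"] = {
            "status": "ok",
            "clean_reads": {config.label_ck: clean_ck.kept, config.label_cd: clean_cd.kept},
            "rejections": {
                config.label_ck: dict(clean_ck.tally),
                config.label_cd: dict(clean_cd.tally),
            },
        }

        # --- annotation -----------------------------------------------------
        logger.info("annotating %d unique tags", len(tags))
        reference = ReferenceDB.from_fasta(config.reference)
        ncrna_db = ReferenceDB.ncrna_from_fasta(config.ncrna) if config.ncrna else None
        families = load_known_mirnas(config.known_mirnas) if config.known_mirnas else []
        results = annotate_tags(
            tags, reference, ncrna_db, families, config.max_mismatch
        )
        emit(
            class_distribution(results, tags, [config.label_ck, config.label_cd]),
            "class_distribution.tsv",
            "class_distribution",
        )
        fam = family_table(results, tags, config.label_ck, config.label_cd)
        emit(fam, "known_families.tsv", "known_families")
        manifest["stages"]["annotate"] = {"status": "ok", "known_families": len(fam)}

        # --- novel discovery ------------------------------------------------
        unannotated = [s for s, r in results.items() if r.klass == "unannotated"]
        logger.info("novel discovery over %d unannotated tags", len(unannotated))
        novel, rejections = discover_novel(
            tags,
            unannotated,
            reference,
            min_tag_count=config.min_tag_count,
            flank_up=config.flank_up,
            flank_down=config.flank_down,
            min_precursor=config.min_precursor,
            max_precursor=config.max_precursor,
            mfe_max=config.mfe_max,
            min_star_reads=config.min_star_reads,
        )
        emit(
            novel_table(novel, config.label_ck, config.label_cd),
            "novel_mirnas.tsv",
            "novel_mirnas",
        )
        manifest["stages"]["novel"] = {
            "status": "ok",
            "accepted": len(novel),
            "rejected": len(rejections),
        }

        # --- differential expression ----------------------------------------
        counts = {}
        for seq, res in results.items():
            if res.klass == "known_miRNA":
                counts[res.member] = tuple(
                    a + b
                    for a, b in zip(
                        counts.get(res.member, (0, 0)),
                        (
                            tags[seq].counts.get(config.label_ck, 0),
                            tags[seq].counts.get(config.label_cd, 0),
                        ),
                    )
                )
        for nv in novel:
            counts[nv.name] = (
                nv.mature_counts.get(config.label_ck, 0),
                nv.mature_counts.get(config.label_cd, 0),
            )
        records = differential_expression(
            counts,
            clean_ck.kept,
            clean_cd.kept,
            config.ratio_up,
            config.ratio_down,
            config.alpha,
            config.adjust_pvalues,
        )
        emit(expression_table(records), "differential_expression.tsv", "differential_expression")
        manifest["stages"]["diff_expr"] = {
            "status": "ok",
            "tested": len(records),
            "significant": sum(r.significant for r in records),
        }

        # --- degradome --------------------------------------------------------
        if config.degradome:
            logger.info("degradome target calling")
            deg_tags = filter_degradome_reads(read_sequences(config.degradome))
            mirnas = {nv.name: nv.mature for nv in novel}
            for fam_obj in families:
                for mid, seq in fam_obj.members:
                    mirnas[mid] = seq
            calls, tplots = call_targets(
                mirnas,
                reference.records,
                deg_tags,
                config.deg_max_score,
                config.deg_max_mismatch,
            )
            emit(calls_table(calls), "target_calls.tsv", "target_calls")
            emit(tplot_table(tplots), "tplots.tsv", "tplots")
            manifest["stages"]["degradome"] = {"status": "ok", "calls": len(calls)}
        else:
            manifest["stages"]["degradome"] = {"status": "skipped", "reason": "no degradome input"}
    except Exception as exc:  # record the failure point, keep partial outputs
        failed = next(
            (s for s in ("preprocess", "annotate", "novel", "diff_expr", "degradome")
             if s not in manifest["stages"]),
            "unknown",
        )
        manifest["stages"][failed] = {"status": "failed", "error": str(exc)}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        logger.removeHandler(handler)
        raise

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.removeHandler(handler)
    handler.close()
    return manifest
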