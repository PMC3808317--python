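"""Bundled reference datasets: published summary tables from the radish
(Raphanus sativus) cadmium-stress small-RNA study whose arithmetic the
package reproduces (per-million normalization, fold changes, family
ratios, library overlap percentages, precursor statistics).

All loaders return pandas DataFrames read from the TSVs under
``mirstress/data``; '#' lines are comments.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# clean-read totals of the two libraries (normalization denominators)
CLEAN_TOTAL_CK = 15_779_290
CLEAN_TOTAL_CD = 13_495_250


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("mirstress").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def load_known_families() -> pd.DataFrame:
    """Known miRNA family read counts per library (CK, Cd200)."""
    return _load("radish_known_families.tsv")


def load_novel_mirnas() -> pd.DataFrame:
    """Reported novel miRNAs: mature sequence, precursor length, MFE,
    per-library reads, loci."""
    return _load("radish_novel_mirnas.tsv")


def load_library_stats() -> pd.DataFrame:
    """Per-library read statistics (raw/clean/mapped/known/unannotated)."""
    return _load("radish_library_stats.tsv")


def load_overlap_summary() -> pd.DataFrame:
    """Shared / library-specific unique and total sequence counts."""
    return _load("radish_overlap_summary.tsv")


def load_de_novel() -> pd.DataFrame:
    """Cadmium-responsive novel miRNAs: raw counts per library."""
    return _load("radish_de_novel.tsv")
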