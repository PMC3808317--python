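"""Differential expression of miRNAs between two sequencing libraries.

One library per condition, so significance comes from an exact test on the
two read counts: the Audic-Claverie conditional distribution of the second
count given the first.  With library depths N1, N2 and r = N2/N1,

    P(y | x) = r**y * (x+y)! / (x! * y! * (1+r)**(x+y+1))

which is the negative binomial NB(x+1, 1/(1+r)) over y; tail sums are
therefore evaluated in log space through ``scipy.stats.nbinom``.  The
two-sided p-value doubles the smaller tail and is capped at 1.

Expression is normalized to reads per million of the library total, zero
normalized values are replaced by 0.001 so fold changes of condition-
specific miRNAs stay finite, and regulation is called on the linear ratio
(up if > 2, down if < 0.5) at p <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from scipy import stats

PSEUDO = 0.001


@dataclass
class ExpressionRecord:
    mirna_id: str
    count_ck: int
    count_cd: int
    total_ck: int
    total_cd: int
    norm_ck: float = 0.0
    norm_cd: float = 0.0
    log2fc: float = 0.0
    pvalue: float = 1.0
    regulation: str = "ns"

    @property
    def significant(self) -> bool:
        return self.regulation != "ns"


def normalize_per_million(count: int, total: int) -> float:
    """Reads-per-million normalization; exact, rounding is presentational."""
    if total <= 0:
        raise ValueError("library total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / total * 1_000_000


def pseudo_adjust(norm: float) -> float:
    """Replace a zero normalized value by 0.001 (keeps ratios finite)."""
    if norm < 0:
        raise ValueError("normalized value must be >= 0")
    return PSEUDO if norm == 0 else norm


def log2_fold_change(norm_ck: float, norm_cd: float) -> float:
    """log2(Cd / CK) on pseudo-adjusted normalized abundances."""
    return log2(pseudo_adjust(norm_cd) / pseudo_adjust(norm_ck))


def count_test_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided Audic-Claverie p-value for counts x (library 1, depth n1)
    and y (library 2, depth n2).

    The two tails are complementary (lower = P(Y <= y), upper = P(Y > y)),
    which makes the doubled-minimum exactly symmetric under swapping
    (x, n1) <-> (y, n2) and gives p = 1 when x == y and n1 == n2.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library depths must be positive")
    r = n2 / n1
    dist = stats.nbinom(x + 1, 1.0 / (1.0 + r))
    lower = dist.cdf(y)
    upper = dist.sf(y)  # P(Y > y) = 1 - lower
    return float(min(1.0, 2.0 * min(lower, upper)))


def classify_regulation(
    log2fc: float,
    pvalue: float,
    ratio_up: float = 2.0,
    ratio_down: float = 0.5,
    alpha: float = 0.05,
) -> str:
    """'up' / 'down' / 'ns' from the linear expression ratio and p-value."""
    if ratio_down >= ratio_up:
        raise ValueError("ratio_down must be < ratio_up")
    ratio = 2.0 ** log2fc
    if pvalue <= alpha and ratio > ratio_up:
        return "up"
    if pvalue <= alpha and ratio < ratio_down:
        return "down"
    return "ns"


def benjamini_hochberg(pvalues: Sequence[float]) -> List[float]:
    """BH-adjusted q-values (optional; off by default in the pipeline)."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    out = [0.0] * m
    prev = 1.0
    for rank_from_top, idx in enumerate(reversed(order)):
        rank = m - rank_from_top
        q = min(prev, pvalues[idx] * m / rank)
        out[idx] = q
        prev = q
    return out


def differential_expression(
    counts: Mapping[str, Tuple[int, int]],
    total_ck: int,
    total_cd: int,
    ratio_up: float = 2.0,
    ratio_down: float = 0.5,
    alpha: float = 0.05,
    adjust: bool = False,
) -> List[ExpressionRecord]:
    """Run the full DE procedure over ``{miRNA id: (count_CK, count_Cd)}``."""
    records: List[ExpressionRecord] = []
    for mid in sorted(counts):
        x, y = counts[mid]
        rec = ExpressionRecord(mid, x, y, total_ck, total_cd)
        rec.norm_ck = normalize_per_million(x, total_ck)
        rec.norm_cd = normalize_per_million(y, total_cd)
        rec.log2fc = log2_fold_change(rec.norm_ck, rec.norm_cd)
        rec.pvalue = count_test_pvalue(x, y, total_ck, total_cd)
        records.append(rec)
    pvals = [r.pvalue for r in records]
    effective = benjamini_hochberg(pvals) if adjust else pvals
    for rec, p in zip(records, effective):
        rec.regulation = classify_regulation(rec.log2fc, p, ratio_up, ratio_down, alpha)
    return records


def _stars(p: float) -> str:
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def expression_table(records: Iterable[ExpressionRecord]) -> pd.DataFrame:
    """Presentation table: normalized abundances to 4 decimals (after the
    0.001 substitution), fold changes to 2, significance stars."""
    rows = []
    for r in records:
        rows.append(
            {
                "miRNA": r.mirna_id,
                "count_CK": r.count_ck,
                "norm_CK": round(pseudo_adjust(r.norm_ck), 4),
                "count_Cd200": r.count_cd,
                "norm_Cd200": round(pseudo_adjust(r.norm_cd), 4),
                "log2fc": round(r.log2fc, 2),
                "regulation": r.regulation,
                "pvalue": r.pvalue,
                "significance": _stars(r.pvalue),
            }
        )
    return pd.DataFrame(rows)
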