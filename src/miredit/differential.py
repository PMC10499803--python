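"""Cohort comparison of editing levels and edited-miRNA expression.

Per-site editing levels (or per-variant TPTM expression values) are
compared between the tumor and normal groups with a two-sided
Mann–Whitney U test — exact enumeration for small tie-free samples,
normal approximation with tie correction otherwise — followed by
Benjamini–Hochberg adjustment across all tested rows. Missing values
(no coverage) are excluded pairwise rather than imputed; an observed
zero level is a real measurement. Direction is called from group means,
falling back to medians on a tie and to "unchanged" if still tied.

TPTM (tags per ten million mapped reads) is the expression unit for
miRNA variants: count * 1e7 / total mapped reads of the sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .sites import bh_adjust

logger = logging.getLogger(__name__)

TUMOR, NORMAL = "tumor", "normal"


@dataclass
class CohortDesign:
    """Sample → group assignment; both groups must be non-empty."""

    groups: dict[str, str]

    def __post_init__(self):
        bad = {g for g in self.groups.values() if g not in (TUMOR, NORMAL)}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if not self.samples(TUMOR) or not self.samples(NORMAL):
            raise ValueError("both tumor and normal groups must be non-empty")

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    @classmethod
    def from_tsv(cls, path) -> "CohortDesign":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"sample_id", "group"} <= set(df.columns):
            raise ValueError("design table needs sample_id and group columns")
        return cls(dict(zip(df.sample_id, df.group)))


@dataclass
class DiffResult:
    id: str  # site name or edited-miRNA variant id
    mean_tumor: float
    mean_normal: float
    direction: str  # increased | decreased | unchanged
    p_raw: float
    p_adj: float = 1.0
    category: str = ""

    @property
    def significant(self) -> bool:
        return self.p_adj < 0.05


def tptm(count: float, total_reads: float) -> float:
    """Tags Per Ten Million sequencing reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return count * 1e7 / total_reads


def _mwu_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    # 'auto' = exact enumeration for small tie-free samples, else the
    # normal approximation with tie and continuity correction
    return float(
        mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue
    )


def _direction(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    mx, my = float(np.mean(x)), float(np.mean(y))
    if mx > my:
        return mx, my, "increased"
    if mx < my:
        return mx, my, "decreased"
    medx, medy = float(np.median(x)), float(np.median(y))
    if medx > medy:
        return mx, my, "increased"
    if medx < medy:
        return mx, my, "decreased"
    return mx, my, "unchanged"


def _diff_table(
    table: pd.DataFrame,
    design: CohortDesign,
    alpha: float,
    categories: dict[str, str] | None,
) -> list[DiffResult]:
    tumor = [s for s in design.samples(TUMOR) if s in table.columns]
    normal = [s for s in design.samples(NORMAL) if s in table.columns]
    results: list[DiffResult] = []
    pvals: list[float] = []
    for row_id, row in table.iterrows():
        x = row[tumor].to_numpy(dtype=float)
        y = row[normal].to_numpy(dtype=float)
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if len(x) < 2 or len(y) < 2:
            logger.warning(
                "%s skipped: fewer than 2 values in a group", row_id
            )
            continue
        mx, my, direction = _direction(x, y)
        p = _mwu_pvalue(x, y)
        results.append(
            DiffResult(
                str(row_id), mx, my, direction, p,
                category=(categories or {}).get(str(row_id), ""),
            )
        )
        pvals.append(p)
    if results:
        for r, pa in zip(results, bh_adjust(pvals)):
            r.p_adj = float(pa)
    return results


def mwu_diff(
    site_table: pd.DataFrame,
    design: CohortDesign,
    alpha: float = 0.05,
    categories: dict[str, str] | None = None,
) -> list[DiffResult]:
    """Differential editing levels per site (rows = sites, columns =
    samples; NaN = no coverage)."""
    return _diff_table(site_table, design, alpha, categories)


def edited_mirna_diff(
    expression: pd.DataFrame,
    design: CohortDesign,
    alpha: float = 0.05,
) -> list[DiffResult]:
    """Differential TPTM expression of edited-miRNA variants.

    Rows absent everywhere (all zero or all missing) are skipped.
    """
    present = expression.fillna(0).sum(axis=1) > 0
    return _diff_table(expression.loc[present], design, alpha, None)


def direction_summary(
    results: list[DiffResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Counts and percentages of significant sites by direction, with a
    per-category breakdown.

    Percentages are over the significant total; with no significant
    sites the frame is empty.
    """
    sig = [r for r in results if r.p_adj < alpha]
    rows = []
    total = len(sig)
    if total == 0:
        return pd.DataFrame(
            columns=["category", "direction", "count", "percent"]
        )
    cats = sorted({r.category for r in sig} | {"all"})
    for cat in cats:
        pool = sig if cat == "all" else [r for r in sig if r.category == cat]
        denom = len(pool)
        for direction in ("increased", "decreased", "unchanged"):
            n = sum(r.direction == direction for r in pool)
            rows.append(
                {
                    "category": cat,
                    "direction": direction,
                    "count": n,
                    "percent": 100.0 * n / total if cat == "all"
                    else (100.0 * n / denom if denom else math.nan),
                }
            )
    return pd.DataFrame(rows)
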