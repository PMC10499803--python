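"""M/E site calling, significance, 9-way classification and cohort merge.

A candidate site is any (hairpin position, alternative base) with read
support. Its editing level is the weighted fraction of reads carrying
the variant. Significance against the sequencing-error null uses a
one-sided binomial upper tail P(X >= k), X ~ Binom(n, e), with e derived
from the mean supporting base quality (floored at the Q30 error rate of
1e-3), followed by Benjamini–Hochberg adjustment across all candidate
sites of the sample. A site counts as significant when simultaneously
its level is >= 5%, its weighted support is >= 10 reads and its adjusted
p-value is < 0.05; cohort-level retention additionally requires
significance in at least 10% of the samples (ceiling convention: 10% of
176 samples means 18).

Categories: A-to-I, C-to-U, 3'-A, 3'-U, 3'-Other, 5'-editing, Other,
SNP and Pseudo. Pseudo marks candidates whose variant-carrying reads are
better explained by a different perfect genomic locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .quantify import DEFAULT_MAX_TAIL, Pileup
from .refio import NUCLEOTIDES, PremiRNA, SiteKey, SnpIndex, format_site_name

CATEGORIES = (
    "A-to-I", "C-to-U", "3'-A", "3'-U", "3'-Other",
    "5'-editing", "Other", "SNP", "Pseudo",
)


@dataclass
class Thresholds:
    """Retention criteria for significant M/E sites."""

    min_level: float = 0.05
    min_reads: float = 10.0
    min_q: int = 30
    alpha: float = 0.05
    min_sample_frac: float = 0.10

    def __post_init__(self):
        if not (0 <= self.min_level <= 1 and 0 < self.alpha < 1
                and 0 < self.min_sample_frac <= 1 and self.min_reads >= 0):
            raise ValueError("thresholds out of range")

    @property
    def error_floor(self) -> float:
        return 10 ** (-self.min_q / 10)


@dataclass
class SiteObservation:
    """One candidate site in one sample."""

    key: SiteKey
    sample_id: str
    edited_weight: float
    total_weight: float
    p_raw: float
    p_adj: float = 1.0
    significant: bool = False

    @property
    def level(self) -> float:
        return self.edited_weight / self.total_weight


@dataclass
class SiteRecord:
    """A cohort-level M/E site with per-sample levels."""

    key: SiteKey
    category: str = "Other"
    levels: dict[str, float] = field(default_factory=dict)  # NaN = no coverage
    n_significant: int = 0

    @property
    def name(self) -> str:
        return format_site_name(self.key)

    @property
    def max_level(self) -> float:
        vals = [v for v in self.levels.values() if not math.isnan(v)]
        return max(vals) if vals else float("nan")


def site_level(edited_weight: float, total_weight: float) -> float:
    """Editing level = edited / total weighted read mass."""
    if total_weight <= 0:
        raise ValueError("total_weight must be positive")
    if edited_weight > total_weight:
        raise ValueError("edited_weight exceeds total_weight")
    return edited_weight / total_weight


def site_pvalue(k: int, n: int, e: float) -> float:
    """One-sided binomial upper tail P(X >= k), X ~ Binom(n, e)."""
    if not 0 < e < 1:
        raise ValueError("error probability must be in (0, 1)")
    if n == 0 or k <= 0:
        return 1.0
    if k > n:
        raise ValueError("k must not exceed n")
    return float(binom.sf(k - 1, n, e))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def central_span(mature) -> tuple[int, int]:
    """Hairpin-local span of the mature central region (positions 2..len-2)."""
    return (mature.start + 1, mature.end - 2)


def classify_site(
    key: SiteKey,
    premirna: PremiRNA,
    alt_locus_share: float = 0.0,
    max_tail: int = DEFAULT_MAX_TAIL,
) -> str:
    """Assign the positional category of a candidate site.

    Pseudo (variant mass better explained by another perfect genomic
    locus, share > 0.5) overrides the positional rules. Otherwise the
    position relative to the mature arms decides: an untemplated offset
    within ``max_tail`` past a mature 3' end is a 3'-addition (3'-A /
    3'-U / 3'-Other by the added base); mature position 1 or any position
    upstream of a mature 5' end is 5'-editing; a central mature position
    (2..len-2) is A-to-I for A→G, C-to-U for C→T, else Other; the last
    two mature positions and anything else fall to Other. SNP status is
    decided separately (:func:`snp_reclassify`) since it needs
    per-sample levels.
    """
    pos = key.pos
    if pos > len(premirna) + max_tail:
        raise ValueError(
            f"{key} unresolvable: past hairpin {premirna.id} tail window"
        )
    if alt_locus_share > 0.5:
        return "Pseudo"
    matures = premirna.matures
    for m in matures:
        if m.start <= pos <= m.end:
            lo, hi = central_span(m)
            if pos == m.start:
                return "5'-editing"
            if lo <= pos <= hi:
                if key.ref == "A" and key.alt == "G":
                    return "A-to-I"
                if key.ref == "C" and key.alt == "T":
                    return "C-to-U"
            return "Other"
    for m in matures:
        if m.end < pos <= m.end + max_tail:
            if key.alt == "A":
                return "3'-A"
            if key.alt == "T":
                return "3'-U"
            return "3'-Other"
    if any(pos < m.start for m in matures):
        return "5'-editing"
    return "Other"


def call_sample_sites(
    pileup: Pileup, thresholds: Thresholds, sample_id: str
) -> list[SiteObservation]:
    """Evaluate every (pos, alt) with coverage in one sample.

    All covered position/alternative pairs enter the BH pool (those with
    no supporting reads at p = 1); observations with support are
    returned, flagged significant per the threshold conjunction.
    """
    cov = pileup.coverage
    covered = np.flatnonzero(cov > 0)
    supported = []  # (key, edited_weight, total, p_raw)
    n_unsupported = 0
    seen: set[tuple[int, str]] = set()
    for (pos, alt), ew in pileup.edited.items():
        if ew <= 0:
            continue
        total = float(cov[pos - 1])
        ref = pileup.ref_base(pos)
        if ref == alt:
            continue
        e = max(10 ** (-pileup.mean_qual(pos, alt) / 10),
                thresholds.error_floor)
        k, n = round(ew), round(total)
        p = site_pvalue(min(k, n), n, e)
        key = SiteKey(pileup.premirna_id, pos, ref, alt)
        supported.append((key, ew, total, p))
        seen.add((pos, alt))
    for pos0 in covered:
        pos = int(pos0) + 1
        ref = pileup.ref_base(pos)
        for alt in NUCLEOTIDES:
            if alt != ref and (pos, alt) not in seen:
                n_unsupported += 1

    if not supported:
        return []
    pool = np.ones(len(supported) + n_unsupported)
    pool[: len(supported)] = [s[3] for s in supported]
    adj = bh_adjust(pool)[: len(supported)]
    out = []
    for (key, ew, total, p), pa in zip(supported, adj):
        level = ew / total
        sig = (
            level >= thresholds.min_level
            and ew >= thresholds.min_reads
            and pa < thresholds.alpha
        )
        out.append(
            SiteObservation(key, sample_id, ew, total, p, float(pa), sig)
        )
    return out


def retention_threshold(n_samples: int, min_sample_frac: float) -> int:
    """Minimum number of significant samples for cohort retention
    (ceiling convention: 10% of 176 samples -> 18)."""
    return math.ceil(min_sample_frac * n_samples)


def combine_cohort(
    observations: list[SiteObservation],
    thresholds: Thresholds,
    n_samples: int,
    pileups_by_sample: dict[str, dict[str, Pileup]] | None = None,
) -> list[SiteRecord]:
    """Merge per-sample observations into retained cohort site records.

    A site is retained when significant in at least
    ``ceil(min_sample_frac * n_samples)`` samples. Per-sample levels are
    0 where the sample covered the position without variant support and
    NaN (missing) where it had no coverage; coverage is taken from
    ``pileups_by_sample`` when provided, else from the observations.
    """
    need = retention_threshold(n_samples, thresholds.min_sample_frac)
    by_key: dict[SiteKey, list[SiteObservation]] = {}
    for obs in observations:
        by_key.setdefault(obs.key, []).append(obs)

    sample_ids = sorted(
        pileups_by_sample.keys()
        if pileups_by_sample is not None
        else {o.sample_id for o in observations}
    )
    records = []
    for key in sorted(by_key, key=format_site_name):
        obs_list = by_key[key]
        n_sig = sum(o.significant for o in obs_list)
        if n_sig < need:
            continue
        levels = {}
        obs_by_sample = {o.sample_id: o for o in obs_list}
        for sid in sample_ids:
            o = obs_by_sample.get(sid)
            if o is not None:
                levels[sid] = o.level
                continue
            covg = 0.0
            if pileups_by_sample is not None:
                pu = pileups_by_sample[sid].get(key.premirna_id)
                if pu is not None and key.pos <= len(pu.coverage):
                    covg = float(pu.coverage[key.pos - 1])
            levels[sid] = 0.0 if covg > 0 else float("nan")
        records.append(SiteRecord(key, levels=levels, n_significant=n_sig))
    return records


def snp_reclassify(
    records: list[SiteRecord],
    snp_index: SnpIndex,
    premirnas: dict[str, PremiRNA] | list[PremiRNA],
) -> list[SiteRecord]:
    """Re-label records as SNP when all four criteria hold: identical
    genomic position to a known SNP, identical alleles, a 100% level in
    at least one sample, and a central mature position."""
    if not isinstance(premirnas, dict):
        premirnas = {p.id: p for p in premirnas}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for rec in records:
        pre = premirnas.get(rec.key.premirna_id)
        if pre is None or rec.key.pos > len(pre):
            continue
        central = any(
            central_span(m)[0] <= rec.key.pos <= central_span(m)[1]
            for m in pre.matures
        )
        if not central:
            continue
        if not (rec.max_level >= 1.0 - 1e-9):
            continue
        chrom, gpos = pre.genomic_position(rec.key.pos)
        ref, alt = rec.key.ref, rec.key.alt
        if pre.locus[3] == "-":
            ref, alt = comp.get(ref, ref), comp.get(alt, alt)
        for snp in snp_index.lookup(chrom, gpos):
            if snp.ref == ref and snp.alt == alt:
                rec.category = "SNP"
                break
    return records


def context_profile(
    records: list[SiteRecord],
    premirnas: dict[str, PremiRNA] | list[PremiRNA],
    offsets: tuple[int, ...] = (-1, 1),
) -> pd.DataFrame:
    """Nucleotide frequencies flanking a set of sites.

    Rows are offsets (e.g. -1 = 5' neighbour, +1 = 3' neighbour), columns
    A/C/G/T; each row sums to 1 over the sites with a templated flank at
    that offset (hairpin-boundary sites are excluded from the
    denominator). Empty input yields an empty frame.
    """
    if not isinstance(premirnas, dict):
        premirnas = {p.id: p for p in premirnas}
    if not records:
        return pd.DataFrame(columns=list(NUCLEOTIDES))
    counts = {off: {nt: 0 for nt in NUCLEOTIDES} for off in offsets}
    for rec in records:
        pre = premirnas[rec.key.premirna_id]
        for off in offsets:
            p = rec.key.pos + off
            if 1 <= p <= len(pre):
                base = pre.base(p)
                if base in counts[off]:
                    counts[off][base] += 1
    rows = {}
    for off in offsets:
        total = sum(counts[off].values())
        rows[off] = (
            {nt: counts[off][nt] / total for nt in NUCLEOTIDES}
            if total else {nt: float("nan") for nt in NUCLEOTIDES}
        )
    return pd.DataFrame.from_dict(rows, orient="index")[list(NUCLEOTIDES)]
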