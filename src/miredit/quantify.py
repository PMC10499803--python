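"""Tag placement on pre-miRNAs, cross-mapping correction and pileups.

Collapsed tags are placed on the hairpin set by seed-and-extend exact
k-mer search (the hairpin set is small, so no external aligner is
needed). A placement aligns a tag prefix with at most ``max_mm``
substitutions; the unaligned 3' suffix, at most ``max_tail`` nt whose
first base differs from the templated genomic continuation, is recorded
as an untemplated tail. Tags mapping to several genomic loci (e.g.
near-identical paralog hairpins) are apportioned by the cross-mapping
correction: iterative proportional allocation of each tag's weight
according to locus expression, run to a fixed point.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from .preprocess import ReadTag
from .refio import PremiRNA, revcomp

logger = logging.getLogger(__name__)

DEFAULT_MAX_MM = 2
DEFAULT_MAX_TAIL = 4
MIN_BODY_LEN = 16
_SEED_K = 6  # pigeonhole: 3 seed pieces of 6 nt cover the first 18 nt


@dataclass
class TagAlignment:
    """A tag placed on a pre-miRNA hairpin.

    ``start`` is the 1-based hairpin position of the first aligned base;
    ``mismatches`` are ``(hairpin_pos, ref, alt)`` triples; ``tail`` is
    the untemplated 3' suffix (may be empty). ``genome_loci`` are exact
    genomic placements of the aligned body and ``weight`` is the
    cross-mapping share assigned to this placement.
    """

    tag: ReadTag
    premirna_id: str
    start: int
    mismatches: list[tuple[int, str, str]]
    tail: str
    genome_loci: list[tuple[str, int, str]] = field(default_factory=list)
    weight: float = 1.0

    @property
    def body_len(self) -> int:
        return len(self.tag.sequence) - len(self.tail)

    @property
    def tail_anchor(self) -> int:
        """1-based hairpin position of the last aligned base."""
        return self.start + self.body_len - 1


class Pileup:
    """Weighted per-position pileup for one pre-miRNA.

    ``coverage[pos]`` accumulates count*weight over every hairpin
    position a placed tag occupies, including its untemplated tail
    offsets (which may run past the hairpin 3' end), so that edited mass
    at a position never exceeds its coverage. ``edited[(pos, alt)]``
    accumulates count*weight of reads supporting the variant, and
    supporting base qualities are tracked count*weight-averaged.
    """

    def __init__(self, premirna: PremiRNA, max_tail: int = DEFAULT_MAX_TAIL):
        self.premirna_id = premirna.id
        self.premirna = premirna
        self.length = len(premirna)
        self.coverage = np.zeros(self.length + max_tail)
        self.edited: dict[tuple[int, str], float] = {}
        self._qual_mass: dict[tuple[int, str], float] = {}

    def add(self, pos: int, alt: str, mass: float, qual: float) -> None:
        k = (pos, alt)
        self.edited[k] = self.edited.get(k, 0.0) + mass
        self._qual_mass[k] = self._qual_mass.get(k, 0.0) + mass * qual

    def mean_qual(self, pos: int, alt: str) -> float:
        mass = self.edited.get((pos, alt), 0.0)
        if mass == 0:
            return 0.0
        return self._qual_mass[(pos, alt)] / mass

    def ref_base(self, pos: int) -> str:
        """Templated base at 1-based ``pos``, '-' beyond the hairpin."""
        return self.premirna.base(pos) if pos <= self.length else "-"


def _evaluate(
    seq: str, hp: str, s0: int, max_mm: int, max_tail: int
) -> tuple[int, list[int]] | None:
    """Split ``seq`` placed at hairpin offset ``s0`` into body + tail.

    Bases running past the hairpin 3' end are forced tail; the
    contiguous trailing-mismatch run extends the tail backwards as long
    as it begins within ``max_tail`` of the read end (trailing
    mismatches further in stay internal mismatches). Returns
    ``(body_len, mismatch_offsets)`` or None if the placement is
    inadmissible (tail too long, body too short or too many internal
    mismatches).
    """
    n = len(seq)
    max_in_hp = min(n, len(hp) - s0)
    if max_in_hp < MIN_BODY_LEN:
        return None
    mism = [i for i in range(max_in_hp) if seq[i] != hp[s0 + i]]
    mism_set = set(mism)
    body = max_in_hp  # bases beyond the hairpin are tail by necessity
    while body - 1 in mism_set and n - (body - 1) <= max_tail:
        body -= 1
    if n - body > max_tail or body < MIN_BODY_LEN:
        return None
    n_mm = bisect_left(mism, body)
    if n_mm > max_mm:
        return None
    return body, mism[:n_mm]


def _kmer_index(premirnas: list[PremiRNA]) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for pi, pre in enumerate(premirnas):
        s = pre.sequence
        for j in range(len(s) - _SEED_K + 1):
            index.setdefault(s[j:j + _SEED_K], []).append((pi, j))
    return index


def align_tags(
    tags: list[ReadTag],
    premirnas: list[PremiRNA],
    max_mm: int = DEFAULT_MAX_MM,
    max_tail: int = DEFAULT_MAX_TAIL,
) -> list[TagAlignment]:
    """Place tags on hairpins; keep all placements that maximize aligned
    length and, among those, minimize mismatches. Unplaceable tags drop."""
    index = _kmer_index(premirnas)
    out: list[TagAlignment] = []
    for tag in tags:
        seq = tag.sequence
        candidates: set[tuple[int, int]] = set()
        # pigeonhole over the first 18 nt: with <=2 mismatches at least
        # one of the three 6-mers is exact
        for off in (0, _SEED_K, 2 * _SEED_K):
            for pi, j in index.get(seq[off:off + _SEED_K], ()):
                s0 = j - off
                if s0 >= 0:
                    candidates.add((pi, s0))
        best: list[tuple[int, int, int, int, list[int]]] = []
        for pi, s0 in candidates:
            res = _evaluate(seq, premirnas[pi].sequence, s0, max_mm, max_tail)
            if res is None:
                continue
            body, mm = res
            best.append((body, -len(mm), pi, s0, mm))
        if not best:
            continue
        top = max(b[:2] for b in best)
        for body, neg_mm, pi, s0, mm in sorted(
            (b for b in best if b[:2] == top), key=lambda b: (b[2], b[3])
        ):
            pre = premirnas[pi]
            out.append(
                TagAlignment(
                    tag=tag,
                    premirna_id=pre.id,
                    start=s0 + 1,
                    mismatches=[
                        (s0 + i + 1, pre.sequence[s0 + i], seq[i]) for i in mm
                    ],
                    tail=seq[body:],
                )
            )
    return out


def genome_hits(
    bodies: list[str], genome: dict[str, str]
) -> dict[str, list[tuple[str, int, str]]]:
    """All exact full-length genomic placements of each body, both strands.

    Loci are ``(chrom, pos0, strand)`` with ``pos0`` the 0-based start of
    the match in forward-genome coordinates.
    """
    hits: dict[str, list[tuple[str, int, str]]] = {}
    for body in set(bodies):
        loci = []
        rc = revcomp(body)
        for chrom, seq in genome.items():
            i = seq.find(body)
            while i != -1:
                loci.append((chrom, i, "+"))
                i = seq.find(body, i + 1)
            i = seq.find(rc)
            while i != -1:
                loci.append((chrom, i, "-"))
                i = seq.find(rc, i + 1)
        hits[body] = sorted(loci)
    return hits


def alignment_locus(
    aln: TagAlignment, premirna: PremiRNA
) -> tuple[str, int, str]:
    """Genomic locus implied by a hairpin placement of the aligned body."""
    chrom, hstart, hend, strand = premirna.locus
    s0 = aln.start - 1
    if strand == "+":
        return (chrom, hstart + s0, "+")
    return (chrom, hstart + (hend - hstart) - s0 - aln.body_len, "-")


def cross_map_correct(
    alignments: list[TagAlignment],
    genome_hits_map: dict[str, list[tuple[str, int, str]]] | None,
    premirnas: list[PremiRNA],
    tol: float = 1e-9,
    max_iter: int = 100,
) -> dict[int, dict[tuple[str, int, str], float]]:
    """Assign cross-mapping weights to alignments in place.

    Each tag's unit weight is spread over its genomic loci (its exact
    full-length hits; tags with no exact hit — e.g. edited reads — use
    the loci implied by their hairpin placements). Iterative proportional
    allocation: weight(tag→locus) ∝ locus expression, where expression is
    the count*weight mass of all tags at the locus; iterated to an L∞
    fixed point. Returns the per-tag locus weight maps (tags identified
    by ``id`` of their ReadTag) for downstream share computations.
    """
    pre_by_id = {p.id: p for p in premirnas}
    by_tag: dict[int, list[TagAlignment]] = {}
    for aln in alignments:
        by_tag.setdefault(id(aln.tag), []).append(aln)

    tag_loci: dict[int, list[tuple[str, int, str]]] = {}
    tag_count: dict[int, int] = {}
    aln_locus: dict[int, tuple[str, int, str]] = {}
    for tid, alns in by_tag.items():
        tag_count[tid] = alns[0].tag.count
        body = alns[0].tag.sequence[: alns[0].body_len]
        loci = list(genome_hits_map.get(body, [])) if genome_hits_map else []
        implied = {
            id(a): alignment_locus(a, pre_by_id[a.premirna_id]) for a in alns
        }
        if not loci:
            loci = sorted(set(implied.values()))
        for a in alns:
            a.genome_loci = loci
            aln_locus[id(a)] = implied[id(a)]
        tag_loci[tid] = loci

    # iterative proportional allocation
    weights = {
        tid: {loc: 1.0 / len(loci) for loc in loci}
        for tid, loci in tag_loci.items()
    }
    for _ in range(max_iter):
        expr: dict[tuple[str, int, str], float] = {}
        for tid, wmap in weights.items():
            c = tag_count[tid]
            for loc, w in wmap.items():
                expr[loc] = expr.get(loc, 0.0) + c * w
        delta = 0.0
        for tid, wmap in weights.items():
            if len(wmap) == 1:
                continue
            e = {loc: expr[loc] for loc in wmap}
            total = sum(e.values())
            for loc in wmap:
                new = e[loc] / total if total > 0 else 1.0 / len(wmap)
                delta = max(delta, abs(new - wmap[loc]))
                wmap[loc] = new
        if delta < tol:
            break
    else:
        warnings.warn(
            "cross-mapping correction did not converge within "
            f"{max_iter} iterations; keeping last iterate",
            RuntimeWarning,
        )

    for alns in by_tag.values():
        for a in alns:
            a.weight = weights[id(a.tag)].get(aln_locus[id(a)], 0.0)
    return weights


def build_pileup(
    alignments: list[TagAlignment],
    premirnas: list[PremiRNA],
    max_tail: int = DEFAULT_MAX_TAIL,
) -> dict[str, Pileup]:
    """Accumulate weighted coverage and per-(pos, alt) edited mass."""
    pre_by_id = {p.id: p for p in premirnas}
    pileups: dict[str, Pileup] = {}
    for aln in alignments:
        mass = aln.tag.count * aln.weight
        if mass == 0:
            continue
        pre = pre_by_id[aln.premirna_id]
        pu = pileups.get(pre.id)
        if pu is None:
            pu = pileups[pre.id] = Pileup(pre, max_tail)
        s0 = aln.start - 1
        end = s0 + aln.body_len + len(aln.tail)
        pu.coverage[s0:end] += mass
        quals = aln.tag.mean_quals
        for pos, ref, alt in aln.mismatches:
            pu.add(pos, alt, mass, quals[pos - aln.start])
        anchor = aln.tail_anchor
        for k, base in enumerate(aln.tail, start=1):
            pos = anchor + k
            pu.add(pos, base, mass, quals[pos - aln.start])
    return pileups
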