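"""PAR-CLIP-based target identification for original and edited miRNAs.

PAR-CLIP reads crosslinked to Argonaute-bound RNA carry diagnostic
T-to-C conversions. Reads are QC-filtered, placed on transcripts
allowing only T(transcript)→C(read) mismatches, merged into coverage
clusters, and searched for exact reverse complements of the miRNA seed
match region (positions 2–8 by default; position 1 usually pairs with an
A-anchor rather than by complementarity). Each seed match is scored with
Ps, the binomial upper-tail probability of observing its converted-read
count under the transcriptome-wide background conversion fraction.
Target sets of the original and a seed-edited miRNA are then compared,
and overlapped with deregulated-gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom

from .preprocess import quality_filter
from .refio import revcomp

DEFAULT_SEED_SPAN = (2, 8)  # 1-based miRNA positions used for matching


@dataclass
class Transcript:
    """A transcript sequence with ordered 5'UTR/CDS/3'UTR regions.

    ``regions`` are ``(label, start, end)`` with 1-based inclusive
    coordinates; they must be non-overlapping, contiguous and cover the
    sequence in order.
    """

    id: str
    sequence: str
    regions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper().replace("U", "T")
        if self.regions:
            expect = 1
            for label, start, end in self.regions:
                if start != expect or end < start:
                    raise ValueError(
                        f"{self.id}: regions not contiguous at {label}"
                    )
                expect = end + 1
            if expect != len(self.sequence) + 1:
                raise ValueError(f"{self.id}: regions do not cover sequence")

    def region_at(self, pos: int) -> str:
        for label, start, end in self.regions:
            if start <= pos <= end:
                return label
        return ""


@dataclass
class AlignedRead:
    transcript_id: str
    start: int  # 1-based
    length: int
    t2c_positions: list[int]  # 1-based transcript positions

    @property
    def end(self) -> int:
        return self.start + self.length - 1

    @property
    def converted(self) -> bool:
        return bool(self.t2c_positions)


@dataclass
class Cluster:
    transcript_id: str
    start: int
    end: int
    n_reads: int
    n_t2c_reads: int


@dataclass
class BindingSite:
    transcript_id: str
    seed_match_start: int
    seed_match_end: int
    region_label: str
    mirna_variant_id: str
    n_reads: int
    n_t2c_reads: int
    ps: float


@dataclass
class TargetComparison:
    common: set[str]
    new_to_edited: set[str]
    lost_by_edited: set[str]


def load_transcripts(
    fasta_path: str | Path, regions_tsv: str | Path | None = None
) -> list[Transcript]:
    """Transcript FASTA plus optional region table
    (transcript_id, region, start, end)."""
    from Bio import SeqIO

    regions: dict[str, list[tuple[str, int, int]]] = {}
    if regions_tsv is not None:
        df = pd.read_csv(regions_tsv, sep="\t")
        for row in df.itertuples():
            regions.setdefault(row.transcript_id, []).append(
                (row.region, int(row.start), int(row.end))
            )
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        out.append(
            Transcript(rec.id, str(rec.seq),
                       sorted(regions.get(rec.id, []), key=lambda r: r[1]))
        )
    return sorted(out, key=lambda t: t.id)


def _t2c_space(seq: str) -> str:
    return seq.replace("T", "C")


def map_parclip(
    fastq: str | Path,
    transcripts: list[Transcript],
    min_q: int = 30,
    first_n: int = 25,
) -> list[AlignedRead]:
    """QC-filter and place PAR-CLIP reads on transcripts.

    A read is placed at its best match in which every mismatch is a
    transcript-T read-C conversion (fewest conversions wins; ties break
    by transcript id then position). Reads with any other mismatch, or
    no placement, are dropped. Candidate placements are found by exact
    search in a reduced alphabet where T and C coincide, then verified.
    """
    reduced = [(t, _t2c_space(t.sequence)) for t in transcripts]
    out = []
    for seq, _qual in quality_filter(fastq, min_q=min_q, first_n=first_n):
        rseq = _t2c_space(seq)
        best: tuple[int, str, int, list[int]] | None = None
        for tx, rtx in reduced:
            i = rtx.find(rseq)
            while i != -1:
                window = tx.sequence[i:i + len(seq)]
                conv = [
                    i + j + 1
                    for j, (a, b) in enumerate(zip(window, seq))
                    if a != b
                ]
                # reduced-space match guarantees mismatches are T/C pairs;
                # keep only transcript-T → read-C
                if all(tx.sequence[p - 1] == "T" and seq[p - i - 1] == "C"
                       for p in conv):
                    cand = (len(conv), tx.id, i + 1, conv)
                    if best is None or cand < best:
                        best = cand
                i = rtx.find(rseq, i + 1)
        if best is not None:
            nconv, tid, start, conv = best
            out.append(AlignedRead(tid, start, len(seq), conv))
    return out


def call_clusters(
    reads: list[AlignedRead], transcripts: list[Transcript],
    min_reads: int = 5,
) -> list[Cluster]:
    """Merge maximal runs of covered positions into read clusters."""
    by_tx: dict[str, list[AlignedRead]] = {}
    for r in reads:
        by_tx.setdefault(r.transcript_id, []).append(r)
    tx_len = {t.id: len(t.sequence) for t in transcripts}
    clusters = []
    for tid, rlist in sorted(by_tx.items()):
        cov = np.zeros(tx_len[tid] + 1, dtype=np.int32)
        for r in rlist:
            cov[r.start - 1:r.end] += 1
        covered = cov > 0
        edges = np.flatnonzero(np.diff(np.concatenate(([0], covered, [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            start, end = int(s) + 1, int(e)
            members = [r for r in rlist if r.start <= end and r.end >= start]
            if len(members) < min_reads:
                continue
            clusters.append(
                Cluster(tid, start, end, len(members),
                        sum(r.converted for r in members))
            )
    return clusters


def background_conversion_rate(reads: list[AlignedRead]) -> float:
    """Transcriptome-wide fraction of reads carrying a T-to-C conversion."""
    if not reads:
        return 0.0
    return sum(r.converted for r in reads) / len(reads)


def site_ps(n_reads: int, n_t2c_reads: int, background_rate: float) -> float:
    """Conversion-enrichment score: upper-tail binomial probability of
    >= n_t2c_reads converted reads among n_reads at the background rate."""
    if n_t2c_reads > n_reads:
        raise ValueError("n_t2c_reads exceeds n_reads")
    if not 0 < background_rate < 1:
        raise ValueError("background_rate must be in (0, 1)")
    if n_reads == 0 or n_t2c_reads == 0:
        return 1.0
    return float(binom.sf(n_t2c_reads - 1, n_reads, background_rate))


def edited_mirna_sequence(mature_seq: str, mature_pos: int, alt: str) -> str:
    """Substitute the edited nucleotide at a 1-based mature position."""
    if not 1 <= mature_pos <= len(mature_seq):
        raise ValueError("edit position outside mature sequence")
    alt = alt.upper().replace("U", "T")
    if mature_seq[mature_pos - 1].upper().replace("U", "T") == alt:
        raise ValueError("edited nucleotide equals the mature reference")
    return mature_seq[:mature_pos - 1] + alt + mature_seq[mature_pos:]


def find_seed_sites(
    mirna_id: str,
    mirna_seq: str,
    clusters: list[Cluster],
    reads: list[AlignedRead],
    transcripts: list[Transcript],
    min_t2c: int = 1,
    seed_span: tuple[int, int] = DEFAULT_SEED_SPAN,
    slack: int = 10,
    background_rate: float | None = None,
) -> list[BindingSite]:
    """Exact reverse-complement seed matches within read clusters.

    Within each cluster span (± ``slack`` nt) the reverse complement of
    miRNA positions ``seed_span`` is searched; each hit becomes a
    binding site with read tallies from reads overlapping the match and
    a Ps score at the transcriptome-wide background conversion rate.
    Sites with fewer than ``min_t2c`` converted reads are discarded.
    """
    mirna_seq = mirna_seq.upper().replace("U", "T")
    if len(mirna_seq) < seed_span[1]:
        raise ValueError("miRNA sequence shorter than the seed span")
    motif = revcomp(mirna_seq[seed_span[0] - 1:seed_span[1]])
    tx_by_id = {t.id: t for t in transcripts}
    reads_by_tx: dict[str, list[AlignedRead]] = {}
    for r in reads:
        reads_by_tx.setdefault(r.transcript_id, []).append(r)
    if background_rate is None:
        background_rate = background_conversion_rate(reads)
    background_rate = min(max(background_rate, 1e-6), 1 - 1e-6)

    sites = []
    seen: set[tuple[str, int]] = set()
    for cl in clusters:
        tx = tx_by_id[cl.transcript_id]
        lo = max(0, cl.start - 1 - slack)
        hi = min(len(tx.sequence), cl.end + slack)
        window = tx.sequence[lo:hi]
        j = window.find(motif)
        while j != -1:
            start = lo + j + 1
            end = start + len(motif) - 1
            if (tx.id, start) not in seen:
                seen.add((tx.id, start))
                members = [
                    r for r in reads_by_tx.get(tx.id, [])
                    if r.start <= end and r.end >= start
                ]
                n_t2c = sum(r.converted for r in members)
                if n_t2c >= min_t2c:
                    sites.append(
                        BindingSite(
                            tx.id, start, end, tx.region_at(start),
                            mirna_id, len(members), n_t2c,
                            site_ps(len(members), n_t2c, background_rate),
                        )
                    )
            j = window.find(motif, j + 1)
    sites.sort(key=lambda s: (s.transcript_id, s.seed_match_start))
    return sites


def compare_target_sets(
    sites_original: list[BindingSite], sites_edited: list[BindingSite]
) -> TargetComparison:
    """Partition target transcripts of the original vs edited miRNA."""
    orig = {s.transcript_id for s in sites_original}
    edit = {s.transcript_id for s in sites_edited}
    return TargetComparison(
        common=orig & edit,
        new_to_edited=edit - orig,
        lost_by_edited=orig - edit,
    )


def filter_by_read_support(
    sites: list[BindingSite], min_t2c_reads: int = 10
) -> list[BindingSite]:
    """Keep sites with strictly more than ``min_t2c_reads`` converted
    reads ("more than 10 PAR-CLIP reads with T-to-C")."""
    return [s for s in sites if s.n_t2c_reads > min_t2c_reads]


def intersect_deg(
    new_targets: set[str],
    deg_lists: list[set[str]],
    expected_direction: str = "",
) -> tuple[set[str], dict[str, int]]:
    """Overlap of new targets with genes deregulated in every list.

    Returns the common overlap and Venn region counts keyed by
    membership pattern (e.g. ``"targets&deg1"``); ``expected_direction``
    is carried for reporting only.
    """
    if not deg_lists:
        raise ValueError("at least one deregulated-gene list required")
    sets = {"targets": set(new_targets)}
    sets.update({f"deg{i + 1}": set(s) for i, s in enumerate(deg_lists)})
    universe = set().union(*sets.values())
    venn: dict[str, int] = {}
    for gene in universe:
        pattern = "&".join(k for k in sets if gene in sets[k])
        venn[pattern] = venn.get(pattern, 0) + 1
    overlap = set(new_targets).intersection(*deg_lists)
    return overlap, venn
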