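"""Synthetic references, cohorts and PAR-CLIP libraries with ground truth.

The generator emulates the inputs of a small-RNA editing study: a set of
pre-miRNA hairpins embedded on both strands of a synthetic genome
(including near-identical paralog pairs that exercise the cross-mapping
correction), cohort FASTQ libraries whose reads are drawn from the
mature arms with planted mutation/editing events at group-specific
levels, Phred-calibrated sequencing errors, untemplated 3' tails and an
exact 3' adapter, and PAR-CLIP libraries whose reads pile up over
planted miRNA complementary sites carrying T-to-C conversions. Every
stochastic choice flows from a single integer seed, so identical
configurations reproduce byte-identical outputs, and every planted
event is recorded in a truth table for downstream validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .refio import MatureMiRNA, PremiRNA, SiteKey, format_site_name, revcomp
from .targets import Transcript

NTS = np.array(list("ACGT"))

# default library layout: 80-nt hairpins with 22-nt arms
HAIRPIN_LEN = 80
MATURE_5P = (10, 31)
MATURE_3P = (48, 69)

# widely used small-RNA library 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    ``coverage_mean`` is the Poisson mean read count per mature arm;
    ``error_rate`` the per-base substitution error probability (base
    qualities are emitted so that 10^(-Q/10) matches it); ``tail_probs``
    the per-read probabilities of an untemplated A / U / other 3' tail.
    The cohort defaults mirror the profiled study: 154 tumor and 22
    normal libraries.
    """

    n_premirnas: int = 30
    paralog_pairs: int = 2
    paralog_identity: float = 0.97
    coverage_mean: float = 300.0
    error_rate: float = 0.001
    tail_probs: dict = field(
        default_factory=lambda: {"A": 0.10, "T": 0.08, "other": 0.02}
    )
    n_tumor: int = 154
    n_normal: int = 22
    seed: int = 0
    adapter: str = DEFAULT_ADAPTER
    genome_len: int | None = None

    def __post_init__(self):
        probs = list(self.tail_probs.values()) + [
            self.paralog_identity, self.error_rate
        ]
        if any(not 0 <= p <= 1 for p in probs) or sum(
            self.tail_probs.values()
        ) > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_premirnas < 1 or self.paralog_pairs < 0:
            raise ValueError("invalid hairpin counts")
        if self.n_premirnas - self.paralog_pairs < self.paralog_pairs:
            raise ValueError("too many paralog pairs for n_premirnas")


@dataclass
class PlantedSite:
    """A ground-truth editing event with group-specific levels."""

    key: SiteKey
    category: str
    level_by_group: dict[str, float]
    in_seed: bool | None = None

    def __post_init__(self):
        if any(not 0 <= v <= 1 for v in self.level_by_group.values()):
            raise ValueError("levels must lie in [0, 1]")
        expect = {"A-to-I": ("A", "G"), "C-to-U": ("C", "T")}
        if self.category in expect and (
            (self.key.ref, self.key.alt) != expect[self.category]
        ):
            raise ValueError(
                f"{self.category} site must be "
                f"{expect[self.category][0]}→{expect[self.category][1]}"
            )


@dataclass
class SimReference:
    premirnas: list[PremiRNA]
    genome: dict[str, str]
    paralog_map: dict[str, str]
    genome_path: Path | None = None
    gff3_path: Path | None = None


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(NTS[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    chars = list(seq)
    for pos in rng.choice(len(chars), size=n_mut, replace=False):
        choices = [c for c in "ACGT" if c != chars[pos]]
        chars[pos] = choices[rng.integers(0, 3)]
    return "".join(chars)


def gen_reference(
    cfg: SimConfig, out_dir: str | Path | None = None
) -> SimReference:
    """Build hairpins, embed them in a synthetic genome, write FASTA/GFF3.

    Hairpins occupy non-overlapping loci alternating between the two
    strands of two synthetic chromosomes. Each paralog pair differs at
    exactly ``ceil((1 - identity) * len)`` positions (0 when identity is
    1). With ``cfg.genome_len`` set, the layout must fit or the call
    fails.
    """
    rng = np.random.default_rng(cfg.seed)
    n_indep = cfg.n_premirnas - cfg.paralog_pairs
    n_mut = math.ceil((1 - cfg.paralog_identity) * HAIRPIN_LEN)

    hairpin_seqs: list[tuple[str, str]] = []
    paralog_map: dict[str, str] = {}
    for i in range(n_indep):
        seq = _random_seq(rng, HAIRPIN_LEN)
        if i < cfg.paralog_pairs:
            id1, id2 = f"syn-mir-{i + 1}-1", f"syn-mir-{i + 1}-2"
            hairpin_seqs.append((id1, seq))
            hairpin_seqs.append((id2, _mutate(rng, seq, n_mut)))
            paralog_map[id1] = id2
            paralog_map[id2] = id1
        else:
            hairpin_seqs.append((f"syn-mir-{i + 1}", seq))

    # layout: alternate strands, random spacers, two chromosomes
    chroms = ["chrS1", "chrS2"]
    parts: dict[str, list[str]] = {c: [] for c in chroms}
    lengths: dict[str, int] = {c: 0 for c in chroms}
    premirnas = []
    for idx, (hid, seq) in enumerate(hairpin_seqs):
        chrom = chroms[idx % 2]
        strand = "+" if (idx // 2) % 2 == 0 else "-"
        spacer = _random_seq(rng, int(rng.integers(120, 200)))
        parts[chrom].append(spacer)
        lengths[chrom] += len(spacer)
        start0 = lengths[chrom]
        parts[chrom].append(seq if strand == "+" else revcomp(seq))
        lengths[chrom] += HAIRPIN_LEN
        matures = [
            MatureMiRNA(f"{hid}-5p", *MATURE_5P, "5p"),
            MatureMiRNA(f"{hid}-3p", *MATURE_3P, "3p"),
        ]
        premirnas.append(
            PremiRNA(hid, seq, (chrom, start0, start0 + HAIRPIN_LEN, strand),
                     matures)
        )
    for chrom in chroms:
        tail = _random_seq(rng, int(rng.integers(120, 200)))
        parts[chrom].append(tail)
        lengths[chrom] += len(tail)
    if cfg.genome_len is not None and sum(lengths.values()) > cfg.genome_len:
        raise ValueError(
            f"genome too small for requested loci: need "
            f"{sum(lengths.values())} > {cfg.genome_len}"
        )
    genome = {c: "".join(parts[c]) for c in chroms}
    premirnas.sort(key=lambda p: p.id)

    ref = SimReference(premirnas, genome, paralog_map)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ref.genome_path = out_dir / "genome.fa"
        ref.gff3_path = out_dir / "mirnas.gff3"
        with open(ref.genome_path, "w") as fh:
            for chrom, seq in genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
        with open(ref.gff3_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for pre in sorted(premirnas, key=lambda p: (p.locus[0], p.locus[1])):
                chrom, s0, e, strand = pre.locus
                fh.write(
                    f"{chrom}\tmiredit_sim\tmiRNA_primary_transcript\t"
                    f"{s0 + 1}\t{e}\t.\t{strand}\t.\t"
                    f"ID={pre.id};Name={pre.id}\n"
                )
                for m in pre.matures:
                    if strand == "+":
                        gs, ge = s0 + m.start, s0 + m.end
                    else:
                        gs, ge = e - m.end + 1, e - m.start + 1
                    fh.write(
                        f"{chrom}\tmiredit_sim\tmiRNA\t{gs}\t{ge}\t.\t"
                        f"{strand}\t.\tID={m.id};Name={m.id};"
                        f"Derives_from={pre.id}\n"
                    )
    return ref


def plant_sites(
    premirnas: list[PremiRNA], planted: list[PlantedSite]
) -> tuple[list[PlantedSite], pd.DataFrame]:
    """Validate planted events against the hairpins and build the truth
    table; the seed-region flag is derived from the mature annotations."""
    by_id = {p.id: p for p in premirnas}
    out = []
    rows = []
    for site in planted:
        pre = by_id.get(site.key.premirna_id)
        if pre is None:
            raise ValueError(f"unknown pre-miRNA {site.key.premirna_id}")
        pos = site.key.pos
        if pos <= len(pre):
            if pre.base(pos) != site.key.ref:
                raise ValueError(
                    f"{format_site_name(site.key)}: reference mismatch "
                    f"(hairpin has {pre.base(pos)})"
                )
        elif site.key.ref != "-":
            raise ValueError(
                f"{format_site_name(site.key)}: position past hairpin "
                "requires ref '-'"
            )
        if site.category.startswith("3'"):
            # only first-offset tail planting is supported, and the added
            # base must be untemplated (differ from the continuation)
            arm_ends = [m.end for m in pre.matures]
            if pos - 1 not in arm_ends:
                raise ValueError(
                    f"{format_site_name(site.key)}: tail planting supported "
                    "only at the first offset past a mature 3' end"
                )
            if pos <= len(pre) and pre.base(pos) == site.key.alt:
                raise ValueError(
                    f"{format_site_name(site.key)}: planted tail base equals "
                    "the templated continuation"
                )
        in_seed = any(
            m.seed_span[0] <= pos <= m.seed_span[1] for m in pre.matures
        )
        site = replace(site, in_seed=in_seed)
        out.append(site)
        row = {
            "site": format_site_name(site.key),
            "premirna_id": site.key.premirna_id,
            "pos": pos,
            "ref": site.key.ref,
            "alt": site.key.alt,
            "category": site.category,
            "in_seed": in_seed,
        }
        row.update(
            {f"level_{g}": v for g, v in site.level_by_group.items()}
        )
        rows.append(row)
    return out, pd.DataFrame(rows)


def _qual_char(error_rate: float) -> str:
    q = 40 if error_rate <= 0 else int(
        np.clip(round(-10 * math.log10(error_rate)), 2, 40)
    )
    return chr(33 + q)


def gen_sample_reads(
    premirnas: list[PremiRNA],
    planted: list[PlantedSite],
    group: str,
    cfg: SimConfig,
    out_path: str | Path,
    rng: np.random.Generator | None = None,
    sample_id: str = "sample",
) -> dict:
    """Write one sample's FASTQ; returns simple per-sample statistics.

    Reads are drawn from each mature arm (Poisson ``coverage_mean``
    depth) with uniform 0–2 nt 3' trimming, planted variants applied
    independently per read at the group's level, per-base errors at
    ``error_rate``, geometric untemplated tails (mean 1.5 nt, capped at
    4) per ``tail_probs``, and the exact 3' adapter appended. Base
    qualities encode ``error_rate`` on the Phred scale.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    qc = _qual_char(cfg.error_rate)
    adapter = cfg.adapter
    tail_kinds = list(cfg.tail_probs.items())
    cum = np.cumsum([p for _, p in tail_kinds])
    n_reads = 0
    n_tailed = 0
    lines: list[str] = []
    for pre in premirnas:
        sites_here = [s for s in planted if s.key.premirna_id == pre.id]
        for m in pre.matures:
            body_sites = [
                (s.key.pos, s.key.alt, s.level_by_group.get(group, 0.0))
                for s in sites_here
                if m.start <= s.key.pos <= m.end
            ]
            tail_sites = [
                (s.key.alt, s.level_by_group.get(group, 0.0))
                for s in sites_here
                if s.key.pos == m.end + 1 and s.category.startswith("3'")
            ]
            n = int(rng.poisson(cfg.coverage_mean))
            for i in range(n):
                planted_tail = ""
                for alt, level in tail_sites:
                    if rng.random() < level:
                        planted_tail = alt
                        break
                trim = 0 if planted_tail else int(rng.integers(0, 3))
                end = m.end - trim
                body = list(pre.sequence[m.start - 1:end])
                for pos, alt, level in body_sites:
                    if pos <= end and rng.random() < level:
                        body[pos - m.start] = alt
                if cfg.error_rate > 0:
                    hits = np.flatnonzero(
                        rng.random(len(body)) < cfg.error_rate
                    )
                    for h in hits:
                        choices = [c for c in "ACGT" if c != body[h]]
                        body[h] = choices[rng.integers(0, 3)]
                tail = planted_tail
                if not tail and tail_kinds:
                    r = rng.random()
                    for (kind, _), c in zip(tail_kinds, cum):
                        if r < c:
                            base = (
                                kind if kind in "ACGT"
                                else "CG"[rng.integers(0, 2)]
                            )
                            tail = base * min(int(rng.geometric(1 / 1.5)), 4)
                            break
                if tail:
                    n_tailed += 1
                insert = "".join(body) + tail
                read = insert + adapter
                lines.append(
                    f"@{sample_id}_{pre.id}_{m.arm}_{i}\n{read}\n+\n"
                    f"{qc * len(read)}\n"
                )
                n_reads += 1
    with open(out_path, "w") as fh:
        fh.writelines(lines)
    return {"n_reads": n_reads, "n_tailed": n_tailed}


def gen_cohort(
    premirnas: list[PremiRNA],
    planted: list[PlantedSite],
    cfg: SimConfig,
    out_dir: str | Path,
) -> tuple[pd.DataFrame, dict[str, Path]]:
    """One FASTQ per sample plus a design table; per-sample seeds are
    spawned deterministically from ``cfg.seed``."""
    if cfg.n_tumor < 1 or cfg.n_normal < 1:
        raise ValueError("both groups need at least one sample")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = [
        (f"tumor_{i + 1:03d}", "tumor") for i in range(cfg.n_tumor)
    ] + [
        (f"normal_{i + 1:03d}", "normal") for i in range(cfg.n_normal)
    ]
    children = np.random.SeedSequence(cfg.seed).spawn(len(names))
    paths: dict[str, Path] = {}
    for (sid, group), child in zip(names, children):
        path = out_dir / f"{sid}.fastq"
        gen_sample_reads(
            premirnas, planted, group, cfg, path,
            rng=np.random.default_rng(child), sample_id=sid,
        )
        paths[sid] = path
    design = pd.DataFrame(names, columns=["sample_id", "group"])
    design.to_csv(out_dir / "design.tsv", sep="\t", index=False)
    return design, paths


# --- PAR-CLIP -------------------------------------------------------------

def gen_transcripts(
    n: int,
    length: int,
    seed: int,
    avoid_motifs: tuple[str, ...] = (),
    utr5_frac: float = 0.2,
    cds_frac: float = 0.5,
) -> list[Transcript]:
    """Random transcripts with 5'UTR/CDS/3'UTR regions, scrubbed of any
    occurrence of the given motifs (so planted binding sites stay the
    only ones)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        seq = _random_seq(rng, length)
        for _ in range(100):
            hit = next(
                (m for m in avoid_motifs if m and m in seq), None
            )
            if hit is None:
                break
            j = seq.index(hit) + len(hit) // 2
            choices = [c for c in "ACGT" if c != seq[j]]
            seq = seq[:j] + choices[rng.integers(0, 3)] + seq[j + 1:]
        else:
            raise RuntimeError("could not scrub motifs from transcript")
        b1 = max(1, int(length * utr5_frac))
        b2 = max(b1 + 1, int(length * (utr5_frac + cds_frac)))
        regions = [
            ("5'UTR", 1, b1), ("CDS", b1 + 1, b2), ("3'UTR", b2 + 1, length),
        ]
        out.append(Transcript(f"TX{i + 1:03d}", seq, regions))
    return out


def embed_motif(tx: Transcript, start: int, motif: str) -> Transcript:
    """Return a copy of ``tx`` with ``motif`` written at 1-based
    ``start``."""
    seq = tx.sequence
    if not 1 <= start <= len(seq) - len(motif) + 1:
        raise ValueError("motif does not fit in transcript")
    return Transcript(
        tx.id, seq[:start - 1] + motif + seq[start - 1 + len(motif):],
        list(tx.regions),
    )


def scrub_unplanned_motifs(
    tx: Transcript,
    motifs: tuple[str, ...],
    keep: set[tuple[int, str]],
    seed: int = 0,
) -> Transcript:
    """Remove chance occurrences of ``motifs`` outside the planted ones.

    Writing a motif into a transcript can create a new occurrence of
    another motif spanning the junction. Any occurrence whose
    ``(1-based start, motif)`` is not in ``keep`` is destroyed by
    mutating one of its bases lying outside every kept span, keeping the
    planted sites byte-identical.
    """
    rng = np.random.default_rng(seed)
    seq = tx.sequence
    protected = [
        range(start - 1, start - 1 + len(m)) for start, m in keep
    ]
    for _ in range(200):
        offender = None
        for m in motifs:
            j = seq.find(m)
            while j != -1:
                if (j + 1, m) not in keep:
                    offender = (j, m)
                    break
                j = seq.find(m, j + 1)
            if offender:
                break
        if offender is None:
            return Transcript(tx.id, seq, list(tx.regions))
        j, m = offender
        mutable = [
            i for i in range(j, j + len(m))
            if not any(i in r for r in protected)
        ]
        if not mutable:
            raise RuntimeError("motif occurrence overlaps only kept spans")
        i = mutable[int(rng.integers(0, len(mutable)))]
        choices = [c for c in "ACGT" if c != seq[i]]
        seq = seq[:i] + choices[int(rng.integers(0, 3))] + seq[i + 1:]
    raise RuntimeError("could not scrub unplanned motif occurrences")


def gen_parclip(
    transcripts: list[Transcript],
    mirna_seqs: dict[str, str],
    planted_sites: list[tuple[str, tuple[int, int], str, int, float]],
    seed: int,
    out_fastq: str | Path,
    read_len: int = 32,
    background_per_kb: float = 1.0,
    background_conversion: float = 0.0,
) -> pd.DataFrame:
    """PAR-CLIP FASTQ with reads piled on planted miRNA complementary
    sites.

    ``planted_sites`` entries are ``(transcript_id, (start, end),
    mirna_id, n_reads, conversion_rate)``; each span must contain the
    reverse complement of the named miRNA's seed-match region (positions
    2–8). Every T in a site read converts to C with the site's
    conversion rate; background reads are scattered uniformly at
    ``background_per_kb`` density. Returns the truth table of planted
    binding sites.
    """
    rng = np.random.default_rng(seed)
    tx_by_id = {t.id: t for t in transcripts}
    qc = chr(33 + 37)
    lines: list[str] = []
    rows = []
    ridx = 0

    def emit(tx: Transcript, start: int, conv_rate: float, tag: str):
        nonlocal ridx
        seq = list(tx.sequence[start - 1:start - 1 + read_len])
        if conv_rate > 0:
            for j, base in enumerate(seq):
                if base == "T" and rng.random() < conv_rate:
                    seq[j] = "C"
        read = "".join(seq)
        lines.append(f"@pc_{tag}_{ridx}\n{read}\n+\n{qc * len(read)}\n")
        ridx += 1

    for tx_id, (start, end), mirna_id, n_reads, conv_rate in planted_sites:
        tx = tx_by_id[tx_id]
        mseq = mirna_seqs[mirna_id].upper().replace("U", "T")
        motif = revcomp(mseq[1:8])
        if motif not in tx.sequence[start - 1:end]:
            raise ValueError(
                f"span {tx_id}:{start}-{end} lacks the seed complement of "
                f"{mirna_id}"
            )
        lo = max(1, end - read_len + 1)
        hi = min(start, len(tx.sequence) - read_len + 1)
        if hi < lo:
            lo = hi = max(1, min(start, len(tx.sequence) - read_len + 1))
        for _ in range(n_reads):
            emit(tx, int(rng.integers(lo, hi + 1)), conv_rate, tx_id)
        rows.append(
            {"transcript_id": tx_id, "start": start, "end": end,
             "mirna_id": mirna_id, "n_reads": n_reads,
             "conversion_rate": conv_rate}
        )

    total_len = sum(len(t.sequence) for t in transcripts)
    n_bg = int(round(background_per_kb * total_len / 1000))
    for _ in range(n_bg):
        tx = transcripts[int(rng.integers(0, len(transcripts)))]
        if len(tx.sequence) <= read_len:
            continue
        emit(tx, int(rng.integers(1, len(tx.sequence) - read_len + 2)),
             background_conversion, "bg")

    with open(out_fastq, "w") as fh:
        fh.writelines(lines)
    return pd.DataFrame(rows)
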