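"""End-to-end orchestration: per-sample detection, cohort merge,
differential testing and target identification, with TSV outputs.

The stages mirror the analysis of a tumor/normal small-RNA cohort:
preprocess (QC, adapter trim, collapse) → quantify (hairpin placement,
cross-mapping weights, pileups) → sites (per-sample calls, cohort
retention, classification) → differential (Mann–Whitney + BH on editing
levels and on edited-miRNA TPTM) → targets (PAR-CLIP seed-match calling
for original vs edited miRNAs). Every output table carries a header
naming the tool version and a hash of the run configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differential import (
    CohortDesign, direction_summary, edited_mirna_diff, mwu_diff, tptm,
)
from .preprocess import collapse, quality_filter, trim_adapter
from .quantify import (
    DEFAULT_MAX_MM, DEFAULT_MAX_TAIL, TagAlignment, align_tags, build_pileup,
    cross_map_correct, genome_hits,
)
from .refio import (
    PremiRNA, SiteKey, SnpIndex, format_edited_mirna_name,
    load_known_snps, load_premirna_set,
)
from .sites import (
    SiteRecord, Thresholds, call_sample_sites, classify_site, combine_cohort,
    context_profile, snp_reclassify,
)
from .targets import (
    compare_target_sets, call_clusters, edited_mirna_sequence,
    filter_by_read_support, find_seed_sites, intersect_deg, load_transcripts,
    map_parclip,
)

logger = logging.getLogger(__name__)


def config_hash(config: dict) -> str:
    """Deterministic short hash of a run configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: Path, cfg_hash: str, **to_csv_kw):
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# miredit v{__version__} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", **to_csv_kw)


def read_table(path: Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


@dataclass
class SampleResult:
    sample_id: str
    n_reads_kept: int
    n_tags: int
    total_mapped: int  # reads (not tags) with at least one placement
    alignments: list[TagAlignment]
    pileups: dict
    observations: list


def detect_sample(
    fastq: str | Path,
    premirnas: list[PremiRNA],
    genome: dict[str, str],
    adapter: str,
    thresholds: Thresholds,
    sample_id: str,
    max_mm: int = DEFAULT_MAX_MM,
    max_tail: int = DEFAULT_MAX_TAIL,
) -> SampleResult:
    """Run preprocess → quantify → per-sample site calling on one FASTQ."""
    reads = quality_filter(fastq, min_q=thresholds.min_q)
    trimmed = trim_adapter(reads, adapter)
    tags = collapse(trimmed)
    n_kept = sum(t.count for t in tags)
    alns = align_tags(tags, premirnas, max_mm=max_mm, max_tail=max_tail)
    bodies = [a.tag.sequence[: a.body_len] for a in alns]
    hits = genome_hits(bodies, genome) if genome else {}
    cross_map_correct(alns, hits, premirnas)
    pileups = build_pileup(alns, premirnas, max_tail=max_tail)
    observations = []
    for pu in pileups.values():
        observations.extend(call_sample_sites(pu, thresholds, sample_id))
    total_mapped = sum(
        t.count for t in {id(a.tag): a.tag for a in alns}.values()
    )
    logger.info(
        "%s: %d reads kept, %d tags, %d mapped reads, %d candidate sites",
        sample_id, n_kept, len(tags), total_mapped, len(observations),
    )
    return SampleResult(
        sample_id, n_kept, len(tags), total_mapped, alns, pileups,
        observations,
    )


def variant_share(alignments: list[TagAlignment], key: SiteKey) -> float:
    """Weighted fraction of a site's supporting read mass that the
    cross-mapping correction assigns to other loci (Pseudo evidence)."""
    total = 0
    away = 0.0
    for aln in alignments:
        if aln.premirna_id != key.premirna_id:
            continue
        supports = any(
            pos == key.pos and alt == key.alt
            for pos, _, alt in aln.mismatches
        )
        if not supports and aln.tail:
            anchor = aln.tail_anchor
            supports = any(
                anchor + k == key.pos and base == key.alt
                for k, base in enumerate(aln.tail, start=1)
            )
        if supports:
            total += aln.tag.count
            away += aln.tag.count * (1.0 - aln.weight)
    return away / total if total else 0.0


@dataclass
class CohortResult:
    records: list[SiteRecord]
    site_table: pd.DataFrame  # sites x samples (levels; NaN = no coverage)
    categories: dict[str, str]
    sample_stats: pd.DataFrame
    edited_tptm: pd.DataFrame  # edited-miRNA variants x samples


def detect_cohort(
    fastq_by_sample: dict[str, Path],
    premirnas: list[PremiRNA],
    genome: dict[str, str],
    adapter: str,
    thresholds: Thresholds | None = None,
    snp_index: SnpIndex | None = None,
    max_mm: int = DEFAULT_MAX_MM,
    max_tail: int = DEFAULT_MAX_TAIL,
) -> CohortResult:
    """Detect and classify cohort-retained M/E sites across samples."""
    thresholds = thresholds or Thresholds()
    pre_by_id = {p.id: p for p in premirnas}
    samples: list[SampleResult] = []
    for sid in sorted(fastq_by_sample):
        samples.append(
            detect_sample(
                fastq_by_sample[sid], premirnas, genome, adapter,
                thresholds, sid, max_mm=max_mm, max_tail=max_tail,
            )
        )
    all_obs = [o for s in samples for o in s.observations]
    pileups_by_sample = {s.sample_id: s.pileups for s in samples}
    records = combine_cohort(
        all_obs, thresholds, len(samples), pileups_by_sample
    )

    all_alns = [a for s in samples for a in s.alignments]
    for rec in records:
        share = variant_share(all_alns, rec.key)
        rec.category = classify_site(
            rec.key, pre_by_id[rec.key.premirna_id],
            alt_locus_share=share, max_tail=max_tail,
        )
    if snp_index is not None:
        snp_reclassify(records, snp_index, pre_by_id)

    sample_ids = [s.sample_id for s in samples]
    site_table = pd.DataFrame(
        {sid: [r.levels.get(sid, np.nan) for r in records]
         for sid in sample_ids},
        index=[r.name for r in records],
    )
    site_table.index.name = "site"

    # edited-miRNA variant expression (TPTM) for substitution sites
    tptm_rows = {}
    for rec in records:
        if rec.key.pos > len(pre_by_id[rec.key.premirna_id]):
            continue
        if rec.key.ref == "-" or rec.key.alt == "-":
            continue
        variant = format_edited_mirna_name(
            rec.key.premirna_id, rec.key.pos, rec.key.alt
        )
        row = {}
        for s in samples:
            pu = s.pileups.get(rec.key.premirna_id)
            ew = pu.edited.get((rec.key.pos, rec.key.alt), 0.0) if pu else 0.0
            row[s.sample_id] = (
                tptm(ew, s.total_mapped) if s.total_mapped else 0.0
            )
        tptm_rows[variant] = row
    edited_tptm = pd.DataFrame.from_dict(tptm_rows, orient="index")
    edited_tptm.index.name = "variant"

    stats = pd.DataFrame(
        [
            {"sample_id": s.sample_id, "reads_kept": s.n_reads_kept,
             "tags": s.n_tags, "mapped_reads": s.total_mapped,
             "candidate_sites": len(s.observations)}
            for s in samples
        ]
    )
    return CohortResult(
        records, site_table, {r.name: r.category for r in records},
        stats, edited_tptm,
    )


# --- config-driven runners ------------------------------------------------

@dataclass
class RunConfig:
    """Declarative run configuration (see the CLI docs for the schema)."""

    raw: dict
    base_dir: Path = field(default_factory=Path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(raw, base_dir=path.parent)

    def path(self, *keys, required=True) -> Path | None:
        node = self.raw
        for k in keys:
            if not isinstance(node, dict) or k not in node:
                if required:
                    raise KeyError(
                        f"config missing required entry {'.'.join(keys)}"
                    )
                return None
            node = node[k]
        p = Path(str(node))
        return p if p.is_absolute() else self.base_dir / p

    def get(self, *keys, default=None):
        node = self.raw
        for k in keys:
            if not isinstance(node, dict) or k not in node:
                return default
            node = node[k]
        return node

    @property
    def out_dir(self) -> Path:
        return self.path("output_dir")

    @property
    def hash(self) -> str:
        return config_hash(self.raw)

    def thresholds(self) -> Thresholds:
        return Thresholds(**self.get("thresholds", default={}))


def _load_references(config: RunConfig):
    from Bio import SeqIO

    genome_path = config.path("references", "genome")
    gff3_path = config.path("references", "gff3")
    for p in (genome_path, gff3_path):
        if not p.exists():
            raise FileNotFoundError(f"missing input: {p}")
    premirnas = load_premirna_set(gff3_path, genome_path)
    genome = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(genome_path), "fasta")
    }
    return premirnas, genome


def _sample_fastqs(config: RunConfig) -> tuple[CohortDesign, dict[str, Path]]:
    design_path = config.path("samples", "design")
    fastq_dir = config.path("samples", "fastq_dir")
    if not design_path.exists():
        raise FileNotFoundError(f"missing design table: {design_path}")
    design = CohortDesign.from_tsv(design_path)
    fastqs = {}
    for sid in design.groups:
        p = fastq_dir / f"{sid}.fastq"
        if not p.exists():
            raise FileNotFoundError(f"missing FASTQ for sample {sid}: {p}")
        fastqs[sid] = p
    return design, fastqs


def run_detect(config: RunConfig) -> CohortResult:
    """preprocess → quantify → sites for every sample, then cohort merge;
    writes per-sample site tables, the cohort site table, the category
    summary and context profiles."""
    premirnas, genome = _load_references(config)
    _design, fastqs = _sample_fastqs(config)
    snp_path = config.path("references", "snps", required=False)
    snp_index = (
        load_known_snps(snp_path)
        if snp_path is not None and snp_path.exists() else None
    )
    adapter = config.get("adapter", default="")
    if not adapter:
        raise KeyError("config missing required entry: adapter")
    result = detect_cohort(
        fastqs, premirnas, genome, adapter, config.thresholds(), snp_index,
        max_mm=config.get("max_mm", default=DEFAULT_MAX_MM),
        max_tail=config.get("max_tail", default=DEFAULT_MAX_TAIL),
    )
    out = config.out_dir
    h = config.hash
    table = result.site_table.copy()
    table.insert(0, "category", [result.categories[s] for s in table.index])
    table.insert(
        1, "n_significant", [r.n_significant for r in result.records]
    )
    write_table(table, out / "cohort_sites.tsv", h)
    write_table(result.sample_stats, out / "sample_stats.tsv", h, index=False)
    write_table(result.edited_tptm, out / "edited_mirna_tptm.tsv", h)
    cat_counts = (
        pd.Series([r.category for r in result.records])
        .value_counts().rename_axis("category").to_frame("n_sites")
    )
    write_table(cat_counts, out / "category_summary.tsv", h)
    pre_by_id = {p.id: p for p in premirnas}
    for cat in ("A-to-I", "C-to-U"):
        recs = [r for r in result.records if r.category == cat]
        prof = context_profile(recs, pre_by_id)
        if not prof.empty:
            prof = prof.rename_axis("offset")
            write_table(
                prof, out / f"context_{cat.replace('-', '_')}.tsv", h
            )
    return result


def run_differential(config: RunConfig):
    """Mann–Whitney + BH on cohort editing levels and edited-miRNA TPTM."""
    out = config.out_dir
    h = config.hash
    design = CohortDesign.from_tsv(config.path("samples", "design"))
    cohort_path = out / "cohort_sites.tsv"
    if not cohort_path.exists():
        raise FileNotFoundError(f"run detect first: missing {cohort_path}")
    table = read_table(cohort_path, index_col=0)
    categories = table["category"].to_dict()
    levels = table.drop(columns=["category", "n_significant"])
    alpha = config.thresholds().alpha
    results = mwu_diff(levels, design, alpha=alpha, categories=categories)
    diff_df = pd.DataFrame(
        [
            {"site": r.id, "category": r.category,
             "mean_tumor": r.mean_tumor, "mean_normal": r.mean_normal,
             "direction": r.direction, "p_raw": r.p_raw, "p_adj": r.p_adj}
            for r in results
        ]
    )
    write_table(diff_df, out / "differential_sites.tsv", h, index=False)
    write_table(
        direction_summary(results, alpha=alpha),
        out / "direction_summary.tsv", h, index=False,
    )
    tptm_path = out / "edited_mirna_tptm.tsv"
    expr_results = []
    if tptm_path.exists():
        expr = read_table(tptm_path, index_col=0)
        expr_results = edited_mirna_diff(expr, design, alpha=alpha)
        expr_df = pd.DataFrame(
            [
                {"variant": r.id, "mean_tumor": r.mean_tumor,
                 "mean_normal": r.mean_normal, "direction": r.direction,
                 "p_raw": r.p_raw, "p_adj": r.p_adj}
                for r in expr_results
            ]
        )
        write_table(
            expr_df, out / "differential_edited_mirnas.tsv", h, index=False
        )
    return results, expr_results


def run_targets(config: RunConfig):
    """PAR-CLIP mapping, cluster/seed-site calling for each configured
    original/edited miRNA pair, target-set comparison and deregulated-
    gene overlaps."""
    out = config.out_dir
    h = config.hash
    fastq = config.path("targets", "parclip_fastq")
    tx_fasta = config.path("targets", "transcripts_fasta")
    if not fastq.exists() or not tx_fasta.exists():
        raise FileNotFoundError("missing PAR-CLIP inputs")
    regions = config.path("targets", "transcripts_regions", required=False)
    transcripts = load_transcripts(
        tx_fasta, regions if regions and regions.exists() else None
    )
    thresholds = config.thresholds()
    reads = map_parclip(fastq, transcripts, min_q=thresholds.min_q)
    clusters = call_clusters(
        reads, transcripts,
        min_reads=config.get("targets", "min_cluster_reads", default=5),
    )
    seed_span = tuple(
        config.get("targets", "seed_span", default=(2, 8))
    )
    comparisons = {}
    site_rows = []
    for variant in config.get("targets", "mirnas", default=[]):
        mid = variant["id"]
        orig_seq = variant["mature_seq"]
        pos = int(variant["mature_pos"])
        alt = variant["alt"]
        edited_seq = edited_mirna_sequence(orig_seq, pos, alt)
        edited_id = format_edited_mirna_name(mid, variant.get(
            "hairpin_pos", pos), alt)
        orig_sites = find_seed_sites(
            mid, orig_seq, clusters, reads, transcripts,
            seed_span=seed_span,
        )
        edit_sites = find_seed_sites(
            edited_id, edited_seq, clusters, reads, transcripts,
            seed_span=seed_span,
        )
        for s in orig_sites + edit_sites:
            site_rows.append(
                {"mirna": s.mirna_variant_id, "transcript": s.transcript_id,
                 "start": s.seed_match_start, "end": s.seed_match_end,
                 "region": s.region_label, "n_reads": s.n_reads,
                 "n_t2c_reads": s.n_t2c_reads, "Ps": s.ps}
            )
        cmp = compare_target_sets(orig_sites, edit_sites)
        comparisons[edited_id] = (cmp, edit_sites)
        cmp_df = pd.DataFrame(
            [
                {"set": name, "transcript": tx}
                for name, members in (
                    ("common", cmp.common),
                    ("new_to_edited", cmp.new_to_edited),
                    ("lost_by_edited", cmp.lost_by_edited),
                )
                for tx in sorted(members)
            ]
        )
        write_table(
            cmp_df, out / f"targets_{edited_id}.tsv", h, index=False
        )
    write_table(
        pd.DataFrame(site_rows), out / "binding_sites.tsv", h, index=False
    )

    deg_paths = config.get("targets", "deg_lists", default=[])
    if deg_paths:
        deg_sets = []
        for p in deg_paths:
            p = Path(p) if Path(p).is_absolute() else config.base_dir / p
            df = pd.read_csv(p, sep="\t")
            deg_sets.append(set(df["gene_id"].astype(str)))
        venn_rows = []
        for edited_id, (cmp, sites) in comparisons.items():
            overlap, venn = intersect_deg(cmp.new_to_edited, deg_sets)
            for pattern, n in sorted(venn.items()):
                venn_rows.append(
                    {"mirna": edited_id, "region": pattern, "count": n}
                )
            venn_rows.append(
                {"mirna": edited_id, "region": "common_overlap",
                 "count": len(overlap)}
            )
            # overlapped targets with strong conversion support
            supported = {
                s.transcript_id for s in filter_by_read_support(sites, 10)
            }
            venn_rows.append(
                {"mirna": edited_id, "region": "overlap_gt10_t2c",
                 "count": len(overlap & supported)}
            )
        write_table(
            pd.DataFrame(venn_rows), out / "deg_overlap.tsv", h, index=False
        )
    else:
        logger.info("no deregulated-gene lists supplied; overlap skipped")
    return comparisons
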