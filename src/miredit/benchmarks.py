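"""Seeded end-to-end validation benchmarks on synthetic data.

These routines run the full pipeline on generated cohorts with known
ground truth and summarize how well it recovers what was planted:
sensitivity and false positives of cohort site detection, accuracy of
editing-level estimates at high depth, the raw type-I error of the
Mann–Whitney stage under a null cohort, and exact recovery of
gained/lost/common targets for a seed-edited miRNA from PAR-CLIP
fixtures. They are deterministic given their seeds and are used both by
the test suite and by the reproduction script.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .differential import CohortDesign, mwu_diff
from .pipeline import detect_cohort, detect_sample
from .refio import PremiRNA, SiteKey, revcomp
from .simulate import (
    PlantedSite, SimConfig, embed_motif, gen_cohort, gen_parclip,
    gen_reference, gen_sample_reads, gen_transcripts, plant_sites,
    scrub_unplanned_motifs,
)
from .sites import Thresholds
from .targets import (
    call_clusters, compare_target_sets, edited_mirna_sequence,
    find_seed_sites, map_parclip,
)

_TRANSITION = {"A": "G", "C": "T", "G": "A", "T": "C"}


def _category_for(ref: str, alt: str) -> str:
    if (ref, alt) == ("A", "G"):
        return "A-to-I"
    if (ref, alt) == ("C", "T"):
        return "C-to-U"
    return "Other"


def _plant_central(
    premirnas: list[PremiRNA], levels: list[float]
) -> list[PlantedSite]:
    """One central substitution per hairpin at the given per-site level
    (same level in both groups)."""
    planted = []
    for pre, level in zip(premirnas, levels):
        m = pre.matures[0]
        pos = m.start + 6  # central, inside the seed region
        ref = pre.base(pos)
        alt = _TRANSITION[ref]
        planted.append(
            PlantedSite(
                SiteKey(pre.id, pos, ref, alt), _category_for(ref, alt),
                {"tumor": level, "normal": level},
            )
        )
    return planted


def recovery_benchmark(
    n_seeds: int = 20,
    base_seed: int = 0,
    coverage: float = 300.0,
    error_rate: float = 0.001,
    levels: tuple[float, ...] = (0.05, 0.1, 0.3),
    n_tumor: int = 8,
    n_normal: int = 4,
    work_dir: str | Path | None = None,
) -> dict:
    """Planted-site recovery across replicate cohorts.

    Each replicate simulates a 12-sample cohort (6 independent hairpins
    plus one paralog pair, 3' tailing off so the planted substitutions
    are the only true events), runs detection end to end and compares
    the retained cohort sites against the truth table. Returns pooled
    sensitivity and the count of significant calls at unplanted sites.
    """
    found = 0
    total = 0
    false_pos = 0
    for k in range(n_seeds):
        seed = (base_seed * 100003 + 7919 * k + 1) % (2**31)
        cfg = SimConfig(
            n_premirnas=7, paralog_pairs=1, paralog_identity=0.97,
            coverage_mean=coverage, error_rate=error_rate, tail_probs={},
            n_tumor=n_tumor, n_normal=n_normal, seed=seed,
        )
        with tempfile.TemporaryDirectory(dir=work_dir) as tmp:
            ref = gen_reference(cfg, tmp)
            plain = [p for p in ref.premirnas if p.id not in ref.paralog_map]
            planted, _truth = plant_sites(
                ref.premirnas, _plant_central(plain[: len(levels)], levels)
            )
            _design, paths = gen_cohort(ref.premirnas, planted, cfg, tmp)
            result = detect_cohort(
                paths, ref.premirnas, ref.genome, cfg.adapter, Thresholds()
            )
        truth_keys = {s.key for s in planted}
        called = {r.key for r in result.records}
        found += len(truth_keys & called)
        total += len(truth_keys)
        false_pos += len(called - truth_keys)
    return {
        "sensitivity": found / total if total else float("nan"),
        "false_positive_sites": false_pos,
        "n_planted": total,
        "n_seeds": n_seeds,
    }


def level_accuracy_benchmark(
    coverage: float = 5000.0,
    levels: tuple[float, ...] = (0.05, 0.1, 0.3),
    seed: int = 0,
    work_dir: str | Path | None = None,
) -> dict:
    """Max absolute error of per-sample editing-level estimates at high
    sequencing depth (one sample, one planted site per hairpin)."""
    cfg = SimConfig(
        n_premirnas=len(levels), paralog_pairs=0, coverage_mean=coverage,
        error_rate=0.001, tail_probs={}, n_tumor=1, n_normal=1,
        seed=seed % (2**31),
    )
    with tempfile.TemporaryDirectory(dir=work_dir) as tmp:
        ref = gen_reference(cfg, tmp)
        planted, _ = plant_sites(
            ref.premirnas, _plant_central(ref.premirnas, list(levels))
        )
        fastq = Path(tmp) / "s1.fastq"
        gen_sample_reads(
            ref.premirnas, planted, "tumor", cfg, fastq,
            rng=np.random.default_rng(cfg.seed), sample_id="s1",
        )
        sample = detect_sample(
            fastq, ref.premirnas, ref.genome, cfg.adapter, Thresholds(), "s1"
        )
    by_key = {o.key: o for o in sample.observations}
    errors = {}
    for site in planted:
        obs = by_key.get(site.key)
        est = obs.level if obs is not None else 0.0
        errors[site.key] = abs(est - site.level_by_group["tumor"])
    return {
        "max_abs_error": max(errors.values()),
        "n_sites": len(errors),
        "coverage": coverage,
    }


def mwu_null_typeI(
    n_tumor: int = 154,
    n_normal: int = 22,
    n_sites: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Raw type-I error of the Mann–Whitney stage under a null cohort:
    both groups drawn from the same Beta level distribution."""
    rng = np.random.default_rng(seed % (2**31))
    cols = [f"t{i}" for i in range(n_tumor)] + [
        f"n{i}" for i in range(n_normal)
    ]
    design = CohortDesign(
        {c: ("tumor" if c.startswith("t") else "normal") for c in cols}
    )
    table = pd.DataFrame(
        rng.beta(2.0, 8.0, size=(n_sites, len(cols))),
        index=[f"s{i}" for i in range(n_sites)], columns=cols,
    )
    results = mwu_diff(table, design, alpha=alpha)
    raw = np.array([r.p_raw for r in results])
    adj = np.array([r.p_adj for r in results])
    return {
        "raw_positive_rate": float(np.mean(raw < alpha)),
        "adj_positive_count": int(np.sum(adj < alpha)),
        "n_sites": len(results),
    }


def parclip_retargeting_benchmark(
    n_seeds: int = 10,
    base_seed: int = 0,
    n_transcripts: int = 6,
    transcript_len: int = 1500,
    reads_per_site: int = 25,
    conversion_rate: float = 0.5,
    work_dir: str | Path | None = None,
) -> dict:
    """Exact recovery of common / gained / lost targets for a seed-edited
    miRNA from planted PAR-CLIP fixtures.

    Per replicate: transcripts are scrubbed of both seed complements,
    binding spans for the original and/or edited miRNA are embedded
    (one transcript with both, two edited-only, one original-only), a
    PAR-CLIP library is generated, and the cluster → seed-site →
    comparison chain must reproduce the planted partition exactly.
    """
    mature = "TGAGGTAGTAGGTTGTATAGTT"
    edited = edited_mirna_sequence(mature, 6, "G")
    m_orig = revcomp(mature[1:8])
    m_edit = revcomp(edited[1:8])
    exact = 0
    for k in range(n_seeds):
        seed = (base_seed * 99991 + 104729 * k + 3) % (2**31)
        txs = gen_transcripts(
            n_transcripts, transcript_len, seed=seed,
            avoid_motifs=(m_orig, m_edit),
        )
        plan = [("both", 0), ("edit", 1), ("edit", 2), ("orig", 3)]
        sites = []
        for kind, i in plan:
            keep = set()
            if kind in ("orig", "both"):
                txs[i] = embed_motif(txs[i], 1200, m_orig)
                keep.add((1200, m_orig))
                sites.append((txs[i].id, (1200, 1206), "orig",
                              reads_per_site, conversion_rate))
            if kind in ("edit", "both"):
                txs[i] = embed_motif(txs[i], 300, m_edit)
                keep.add((300, m_edit))
                sites.append((txs[i].id, (300, 306), "edit",
                              reads_per_site, conversion_rate))
            # embedding can create a junction occurrence of the other motif
            txs[i] = scrub_unplanned_motifs(
                txs[i], (m_orig, m_edit), keep, seed=seed + i
            )
        expected = {
            "common": {txs[0].id},
            "new": {txs[1].id, txs[2].id},
            "lost": {txs[3].id},
        }
        with tempfile.TemporaryDirectory(dir=work_dir) as tmp:
            fastq = Path(tmp) / "parclip.fastq"
            gen_parclip(
                txs, {"orig": mature, "edit": edited}, sites,
                seed=seed, out_fastq=fastq,
            )
            reads = map_parclip(fastq, txs)
        clusters = call_clusters(reads, txs)
        so = find_seed_sites("orig", mature, clusters, reads, txs)
        se = find_seed_sites("edit", edited, clusters, reads, txs)
        cmp = compare_target_sets(so, se)
        if (cmp.common == expected["common"]
                and cmp.new_to_edited == expected["new"]
                and cmp.lost_by_edited == expected["lost"]):
            exact += 1
    return {"exact_recovery_rate": exact / n_seeds, "n_seeds": n_seeds}
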