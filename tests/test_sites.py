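"""Site significance, classification, cohort retention and SNP rules."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from miredit.quantify import Pileup
from miredit.refio import (
    KnownSnp, MatureMiRNA, PremiRNA, SiteKey, SnpIndex,
)
from miredit.sites import (
    SiteObservation, SiteRecord, Thresholds, bh_adjust, call_sample_sites,
    classify_site, combine_cohort, context_profile, retention_threshold,
    site_level, site_pvalue, snp_reclassify,
)


def _premirna(seq=None, seed=3):
    if seq is None:
        rng = np.random.default_rng(seed)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 80)])
    return PremiRNA(
        "hp", seq, ("c", 100, 180, "+"),
        [MatureMiRNA("hp-5p", 10, 31, "5p"),
         MatureMiRNA("hp-3p", 48, 69, "3p")],
    )


# --- level and p-value ----------------------------------------------------

@pytest.mark.parametrize(
    "edited,total,expect", [(5, 50, 0.10), (0, 50, 0.0), (1.5, 3.0, 0.5)]
)
def test_site_level(edited, total, expect):
    assert site_level(edited, total) == pytest.approx(expect)


def test_site_level_invalid():
    with pytest.raises(ValueError):
        site_level(1, 0)
    with pytest.raises(ValueError):
        site_level(5, 4)


def _binom_tail(k, n, e):
    return sum(
        math.comb(n, i) * e**i * (1 - e) ** (n - i) for i in range(k, n + 1)
    )


def test_site_pvalue_closed_forms():
    assert site_pvalue(0, 100, 0.001) == 1.0
    assert site_pvalue(0, 0, 0.001) == 1.0
    assert site_pvalue(5, 5, 0.001) == pytest.approx(1e-15, rel=1e-6)
    assert site_pvalue(2, 10, 0.001) == pytest.approx(
        _binom_tail(2, 10, 0.001), rel=1e-9
    )
    assert site_pvalue(2, 10, 0.001) == pytest.approx(4.476e-5, rel=1e-3)


# --- BH -------------------------------------------------------------------

def test_bh_examples():
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
    assert bh_adjust([]).size == 0


@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_dominates_raw_and_is_permutation_invariant(pvals):
    adj = bh_adjust(pvals)
    assert np.all(adj >= np.asarray(pvals) - 1e-12)
    assert np.all(adj <= 1.0 + 1e-12)
    perm = np.random.default_rng(0).permutation(len(pvals))
    adj_perm = bh_adjust([pvals[i] for i in perm])
    assert np.allclose(adj_perm, adj[perm])


# --- classification -------------------------------------------------------

def test_classify_central_editing_categories():
    pre = _premirna("A" * 80)
    assert classify_site(SiteKey("hp", 15, "A", "G"), pre) == "A-to-I"
    pre_c = _premirna("C" * 80)
    assert classify_site(SiteKey("hp", 15, "C", "T"), pre_c) == "C-to-U"
    assert classify_site(SiteKey("hp", 15, "A", "T"), pre) == "Other"


def test_classify_tail_categories():
    pre = _premirna()
    for alt, cat in (("A", "3'-A"), ("T", "3'-U"), ("C", "3'-Other")):
        if pre.base(32) == alt:
            continue
        assert classify_site(SiteKey("hp", 32, pre.base(32), alt), pre) == cat
    # a tail offset past the hairpin 3' end (mature ends at the hairpin
    # terminus) uses ref '-'
    pre_end = PremiRNA(
        "hp", pre.sequence, pre.locus,
        [MatureMiRNA("hp-3p", 59, 80, "3p")],
    )
    assert classify_site(SiteKey("hp", 81, "-", "A"), pre_end) == "3'-A"


def test_classify_five_prime_and_edges():
    pre = _premirna("A" * 80)
    assert classify_site(SiteKey("hp", 10, "A", "G"), pre) == "5'-editing"
    assert classify_site(SiteKey("hp", 5, "A", "G"), pre) == "5'-editing"
    # last two mature positions are not central
    assert classify_site(SiteKey("hp", 30, "A", "G"), pre) == "Other"
    assert classify_site(SiteKey("hp", 31, "A", "G"), pre) == "Other"


def test_classify_pseudo_overrides():
    pre = _premirna("A" * 80)
    key = SiteKey("hp", 15, "A", "G")
    assert classify_site(key, pre, alt_locus_share=0.8) == "Pseudo"
    assert classify_site(key, pre, alt_locus_share=0.4) == "A-to-I"


def test_classify_unresolvable_position():
    pre = _premirna()
    with pytest.raises(ValueError, match="unresolvable"):
        classify_site(SiteKey("hp", 200, "-", "A"), pre)


# --- per-sample calling ---------------------------------------------------

def _pileup_with(pre, pos, alt, edited, coverage, qual=30.0):
    pu = Pileup(pre)
    pu.coverage[9:31] = coverage
    pu.add(pos, alt, edited, qual)
    return pu


def test_call_sample_sites_significance_conjunction():
    pre = _premirna("A" * 80)
    th = Thresholds()
    # planted-like site: level 0.30 at coverage 200
    obs = call_sample_sites(_pileup_with(pre, 15, "G", 60, 200), th, "s1")
    (o,) = [o for o in obs if o.key.pos == 15]
    assert o.significant and o.p_adj < 1e-10
    # level 4% fails criterion (i)
    obs = call_sample_sites(_pileup_with(pre, 15, "G", 8, 200), th, "s1")
    assert not obs[0].significant
    # 9 supporting reads fail criterion (ii) even at high level
    obs = call_sample_sites(_pileup_with(pre, 15, "G", 9, 20), th, "s1")
    assert not obs[0].significant


def test_call_sample_sites_flag_implies_thresholds():
    pre = _premirna()
    rng = np.random.default_rng(8)
    pu = Pileup(pre)
    pu.coverage[9:31] = 50
    for _ in range(10):
        pos = int(rng.integers(10, 32))
        ref = pre.base(pos)
        alt = rng.choice([c for c in "ACGT" if c != ref])
        pu.add(pos, str(alt), float(rng.integers(1, 30)), 30.0)
    th = Thresholds()
    for o in call_sample_sites(pu, th, "s1"):
        assert o.p_adj >= o.p_raw - 1e-15
        if o.significant:
            assert o.level >= th.min_level
            assert o.edited_weight >= th.min_reads
            assert o.p_adj < th.alpha


# --- cohort combination ---------------------------------------------------

def test_retention_threshold_convention():
    assert retention_threshold(176, 0.10) == 18
    assert retention_threshold(10, 0.10) == 1
    assert retention_threshold(12, 0.10) == 2


def _obs(key, sid, sig):
    return SiteObservation(key, sid, 10.0, 100.0, 1e-8, 1e-6, sig)


def test_combine_cohort_retention_rule():
    key = SiteKey("hp", 15, "A", "G")
    th = Thresholds()
    obs18 = [_obs(key, f"s{i}", i < 18) for i in range(176)]
    kept = combine_cohort(obs18, th, 176)
    assert len(kept) == 1 and kept[0].n_significant == 18
    obs17 = [_obs(key, f"s{i}", i < 17) for i in range(176)]
    assert combine_cohort(obs17, th, 176) == []


def test_combine_cohort_levels_zero_vs_missing():
    pre = _premirna()
    key = SiteKey("hp", 15, pre.base(15), "G" if pre.base(15) != "G" else "A")
    pu_cov = Pileup(pre)
    pu_cov.coverage[9:31] = 40.0
    pileups = {"s1": {"hp": pu_cov}, "s2": {"hp": pu_cov}, "s3": {}}
    obs = [_obs(key, "s1", True)]
    (rec,) = combine_cohort(obs, Thresholds(min_sample_frac=0.10), 3, pileups)
    assert rec.levels["s1"] == pytest.approx(0.1)
    assert rec.levels["s2"] == 0.0  # covered, no variant
    assert math.isnan(rec.levels["s3"])  # no coverage


# --- SNP reclassification -------------------------------------------------

def _snp_record(pre, pos, max_level):
    ref = pre.base(pos)
    alt = "G" if ref != "G" else "A"
    rec = SiteRecord(SiteKey("hp", pos, ref, alt), "A-to-I")
    rec.levels = {"s1": max_level, "s2": 0.2}
    chrom, gpos = pre.genomic_position(pos)
    snp = SnpIndex([KnownSnp(chrom, gpos, ref, alt, "rs1")])
    return rec, snp


def test_snp_reclassify_all_criteria():
    pre = _premirna()
    rec, snp = _snp_record(pre, 15, 1.0)
    snp_reclassify([rec], snp, [pre])
    assert rec.category == "SNP"


def test_snp_reclassify_needs_full_level():
    pre = _premirna()
    rec, snp = _snp_record(pre, 15, 0.6)
    snp_reclassify([rec], snp, [pre])
    assert rec.category == "A-to-I"


def test_snp_reclassify_needs_central_position():
    pre = _premirna()
    rec, snp = _snp_record(pre, 32, 1.0)  # tail offset, not central
    rec.category = "3'-A"
    snp_reclassify([rec], snp, [pre])
    assert rec.category == "3'-A"


def test_snp_reclassify_minus_strand_alleles():
    rng = np.random.default_rng(3)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 80)])
    pre = PremiRNA(
        "hp", seq, ("c", 100, 180, "-"),
        [MatureMiRNA("hp-5p", 10, 31, "5p")],
    )
    ref = pre.base(15)
    alt = "G" if ref != "G" else "A"
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    chrom, gpos = pre.genomic_position(15)
    rec = SiteRecord(SiteKey("hp", 15, ref, alt), "A-to-I",
                     levels={"s1": 1.0})
    snp = SnpIndex([KnownSnp(chrom, gpos, comp[ref], comp[alt], "rs2")])
    snp_reclassify([rec], snp, [pre])
    assert rec.category == "SNP"


# --- context profile ------------------------------------------------------

def test_context_profile_uniform_flank():
    pre = _premirna("TATATATATA" * 8)  # A at even 1-based positions
    recs = [
        SiteRecord(SiteKey("hp", p, "A", "G"), "A-to-I")
        for p in (12, 14, 16)
    ]
    prof = context_profile(recs, [pre])
    assert prof.loc[-1, "T"] == 1.0
    assert prof.loc[1, "T"] == 1.0


def test_context_profile_mixed_and_empty():
    pre = _premirna("A" * 40 + "C" * 40)
    recs = [SiteRecord(SiteKey("hp", p, "C", "T"), "C-to-U")
            for p in (42, 44)] + [
        SiteRecord(SiteKey("hp", p, "A", "G"), "A-to-I") for p in (12, 14)
    ]
    prof = context_profile(recs, [pre])
    assert prof.loc[-1, "A"] == 0.5 and prof.loc[-1, "C"] == 0.5
    assert context_profile([], [pre]).empty


def test_context_profile_boundary_excluded():
    pre = _premirna("A" * 80)
    recs = [SiteRecord(SiteKey("hp", 1, "A", "G"), "A-to-I"),
            SiteRecord(SiteKey("hp", 15, "A", "G"), "A-to-I")]
    prof = context_profile(recs, [pre])
    # position 1 has no 5' flank; denominator excludes it
    assert prof.loc[-1, "A"] == 1.0
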