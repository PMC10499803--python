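"""Tag alignment, cross-mapping weights and pileup accounting."""

import numpy as np
import pytest

from miredit.preprocess import ReadTag
from miredit.quantify import (
    TagAlignment, align_tags, build_pileup, cross_map_correct, genome_hits,
)
from miredit.refio import MatureMiRNA, PremiRNA, revcomp


def tag(seq, count=1, q=35.0):
    return ReadTag(seq, count, np.full(len(seq), q))


def _hairpin(seq, hid="hp1", chrom="c", start=0, strand="+"):
    return PremiRNA(
        hid, seq, (chrom, start, start + len(seq), strand),
        [MatureMiRNA(f"{hid}-5p", 10, 31, "5p")],
    )


@pytest.fixture
def hairpin():
    rng = np.random.default_rng(9)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 80)])
    return _hairpin(seq)


def test_perfect_tag_single_alignment(hairpin):
    arm = hairpin.sequence[9:31]
    (aln,) = align_tags([tag(arm)], [hairpin])
    assert (aln.premirna_id, aln.start) == ("hp1", 10)
    assert aln.mismatches == [] and aln.tail == ""


def test_untemplated_tail_detected():
    # hairpin continuation after the arm is "GG"; appended "AA" is tail
    arm = "TTACGGATCCATTGCAAGGTCCA"
    seq = ("ACGTACGT" + arm + "GG" + "CGTACGTACGTACGTACGTACGTACGTACGTACGT"
           "CGTACGTACGT")[:80]
    pre = _hairpin(seq)
    (aln,) = align_tags([tag(arm + "AA")], [pre])
    assert aln.tail == "AA"
    assert aln.body_len == len(arm)
    assert aln.mismatches == []


def test_distant_trailing_mismatch_stays_internal():
    # a mismatch more than max_tail bases from the read end is internal
    # even though bases beyond it mismatch-free continue to the end
    arm = "TTACGGATCCATTGCAAGGTCCA"
    seq = ("ACGTACGT" + arm + "GG" + "CGTACGTACGTACGTACGTACGTACGTACGTACGT"
           "CGTACGTACGT")[:80]
    pre = _hairpin(seq)
    read = list(arm)
    read[-6] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[-6]]
    (aln,) = align_tags([tag("".join(read))], [pre], max_tail=4)
    assert aln.tail == ""
    assert len(aln.mismatches) == 1


def test_templated_continuation_absorbed_into_body(hairpin):
    arm = hairpin.sequence[9:31]
    nxt = hairpin.sequence[31]  # templated continuation
    (aln,) = align_tags([tag(arm + nxt)], [hairpin])
    assert aln.tail == "" and aln.body_len == 23


def test_too_many_mismatches_unmapped(hairpin):
    arm = list(hairpin.sequence[9:31])
    for i in (3, 9, 15):
        arm[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arm[i]]
    assert align_tags([tag("".join(arm))], [hairpin], max_mm=2) == []


def test_internal_mismatch_recorded(hairpin):
    arm = list(hairpin.sequence[9:31])
    alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[arm[5]]
    ref = arm[5]
    arm[5] = alt
    (aln,) = align_tags([tag("".join(arm))], [hairpin])
    assert aln.mismatches == [(15, ref, alt)]


def test_genome_hits_counts_and_strands(hairpin):
    arm = hairpin.sequence[9:31]
    genome = {
        "c1": "T" * 50 + arm + "T" * 50,
        "c2": "A" * 30 + arm + "A" * 30 + revcomp(arm) + "A" * 20,
    }
    hits = genome_hits([arm], genome)[arm]
    assert ("c1", 50, "+") in hits
    assert ("c2", 30, "+") in hits
    assert any(strand == "-" for _, _, strand in hits)
    assert len(hits) == 3


def _two_locus_instance(shared_count, u1_count, u2_count):
    seq = "".join(
        np.array(list("ACGT"))[np.random.default_rng(2).integers(0, 4, 80)]
    )
    p1 = _hairpin(seq, "p1", start=0)
    p2 = _hairpin(seq, "p2", start=200)
    arm = seq[9:31]
    shared = tag(arm, shared_count)
    alns = [
        TagAlignment(shared, "p1", 10, [], ""),
        TagAlignment(shared, "p2", 10, [], ""),
    ]
    hits = {arm: [("c", 9, "+"), ("c", 209, "+")]}
    b1, b2 = [c for c in "ACGT" if c != arm[0]][:2]
    for body, cnt, pid, locus in (
        (b1 + arm[1:], u1_count, "p1", ("c", 9, "+")),
        (b2 + arm[1:], u2_count, "p2", ("c", 209, "+")),
    ):
        if cnt:
            t = tag(body, cnt)
            alns.append(TagAlignment(t, pid, 10, [(10, arm[0], body[0])], ""))
            hits[body] = [locus]
    return alns, hits, [p1, p2]


def test_cross_map_unique_tag_weight_one(hairpin):
    arm = hairpin.sequence[9:31]
    t = tag(arm, 5)
    aln = TagAlignment(t, "hp1", 10, [], "")
    cross_map_correct([aln], {arm: [("c", 9, "+")]}, [hairpin])
    assert aln.weight == 1.0


def test_cross_map_90_10_fixed_point():
    alns, hits, pres = _two_locus_instance(50, 90, 10)
    cross_map_correct(alns, hits, pres)
    assert abs(alns[0].weight - 0.9) < 1e-6
    assert abs(alns[1].weight - 0.1) < 1e-6


def test_cross_map_symmetric_split_without_unique_support():
    alns, hits, pres = _two_locus_instance(40, 0, 0)
    cross_map_correct(alns, hits, pres)
    assert alns[0].weight == pytest.approx(0.5)
    assert alns[1].weight == pytest.approx(0.5)


def _brute_force_weights(tags, n_steps=10_000):
    """Independent oracle: iterate the proportional-allocation recurrence.

    ``tags``: list of (count, loci tuple). Returns list of per-tag
    weight dicts.
    """
    weights = [
        {loc: 1.0 / len(loci) for loc in loci} for _count, loci in tags
    ]
    for _ in range(n_steps):
        expr = {}
        for (count, _loci), wmap in zip(tags, weights):
            for loc, w in wmap.items():
                expr[loc] = expr.get(loc, 0.0) + count * w
        for (count, loci), wmap in zip(tags, weights):
            if len(loci) == 1:
                continue
            total = sum(expr[loc] for loc in loci)
            for loc in loci:
                wmap[loc] = expr[loc] / total if total else 1 / len(loci)
    return weights


@pytest.mark.parametrize("inst_seed", range(8))
def test_cross_map_matches_brute_force_oracle(inst_seed):
    """Fixed-point weights equal a 10^4-step iteration of the recurrence
    on random instances with <= 3 loci and <= 6 tags."""
    rng = np.random.default_rng(1000 + inst_seed)
    n_loci = int(rng.integers(2, 4))
    loci = [("c", 100 * i, "+") for i in range(n_loci)]
    tags = []
    for i in range(n_loci):  # unique support per locus
        tags.append((int(rng.integers(1, 100)), (loci[i],)))
    for _ in range(int(rng.integers(1, 4))):  # shared tags
        k = int(rng.integers(2, n_loci + 1))
        subset = tuple(loci[j] for j in sorted(
            rng.choice(n_loci, size=k, replace=False)))
        tags.append((int(rng.integers(1, 100)), subset))

    oracle = _brute_force_weights(tags)

    # package path: synthesize hairpins/alignments for the same instance;
    # hairpin starts are chosen so the implied genomic locus of each
    # alignment (start offset 9) lands exactly on the instance's loci
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 80)])
    pres = [
        _hairpin(seq, f"p{i}", start=100 * i - 9) for i in range(n_loci)
    ]
    alns = []
    hits = {}
    tag_objs = []
    bases = "ACGT"
    for idx, (count, tag_loci) in enumerate(tags):
        # unique body string per tag so the hits map has no collisions
        suffix = "".join(bases[int(d)] for d in np.base_repr(idx, 4))
        body = seq[9:31] + suffix
        t = tag(body, count)
        tag_objs.append(t)
        hits[body] = list(tag_loci)
        for loc in tag_loci:
            pid = f"p{loci.index(loc)}"
            alns.append(TagAlignment(t, pid, 10, [], ""))
    weights = cross_map_correct(alns, hits, pres)
    for t, (count, tag_loci), omap in zip(tag_objs, tags, oracle):
        got = weights[id(t)]
        for loc in tag_loci:
            assert got[loc] == pytest.approx(omap[loc], abs=1e-6)
        assert sum(got.values()) == pytest.approx(1.0, abs=1e-9)


def test_pileup_arithmetic(hairpin):
    arm = hairpin.sequence[9:31]
    perfect = tag(arm, 10)
    a1 = TagAlignment(perfect, "hp1", 10, [], "", weight=1.0)
    ref5 = hairpin.sequence[14]
    alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref5]
    var = tag(arm[:5] + alt + arm[6:], 4)
    a2 = TagAlignment(var, "hp1", 10, [(15, ref5, alt)], "", weight=0.5)
    alt2 = next(c for c in "ACGT" if c not in (ref5, alt))
    var2 = tag(arm[:5] + alt2 + arm[6:], 2)
    a3 = TagAlignment(var2, "hp1", 10, [(15, ref5, alt2)], "", weight=1.0)
    pu = build_pileup([a1, a2, a3], [hairpin])["hp1"]
    assert pu.coverage[9:31] == pytest.approx(
        np.full(22, 10 + 4 * 0.5 + 2)
    )
    assert pu.edited[(15, alt)] == pytest.approx(2.0)
    assert pu.edited[(15, alt2)] == pytest.approx(2.0)
    assert np.all(pu.coverage[:9] == 0)


def test_pileup_tail_positions_counted(hairpin):
    arm = hairpin.sequence[9:31]
    t = tag(arm + "AA", 6)
    aln = TagAlignment(t, "hp1", 10, [], "AA", weight=1.0)
    pu = build_pileup([aln], [hairpin])["hp1"]
    ref32 = hairpin.base(32)
    assert pu.edited[(32, "A")] == pytest.approx(6.0)
    assert pu.edited[(33, "A")] == pytest.approx(6.0)
    # tail offsets contribute coverage, so level = 1.0 there
    assert pu.coverage[31] == pytest.approx(6.0)
    assert pu.coverage[32] == pytest.approx(6.0)


def test_pileup_mass_conservation(hairpin):
    arm = hairpin.sequence[9:31]
    alns = [
        TagAlignment(tag(arm, 7), "hp1", 10, [], "", weight=0.6),
        TagAlignment(tag(arm + "AA", 3), "hp1", 10, [], "AA", weight=1.0),
    ]
    pu = build_pileup(alns, [hairpin])["hp1"]
    expected = 7 * 0.6 * 22 + 3 * 1.0 * 24
    assert pu.coverage.sum() == pytest.approx(expected)
    for (pos, alt), ew in pu.edited.items():
        assert ew <= pu.coverage[pos - 1] + 1e-9
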