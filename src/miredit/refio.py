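"""Reference and annotation I/O for miRNA editing analysis.

Conventions used throughout the package:

* The internal nucleotide alphabet is DNA (``T``); ``U`` appears only in
  display names of edited sites/miRNAs (e.g. ``hsa-mir-29c_59_C_u``).
* Genomic intervals are 0-based half-open internally; all user-facing
  pre-miRNA (hairpin) positions are 1-based, so "the 48th nucleotide"
  means ``sequence[47]``.
* Hairpins on the minus strand carry the reverse-complemented genomic
  slice, so hairpin-local coordinates always read 5'→3' along the miRNA.

Site and edited-miRNA names follow the field's convention: an M/E site is
``<pre-miRNA>_<pos>_<REF>_<alt>`` with the reference upper-case and the
edited nucleotide lower-case (``hsa-mir-376c_48_A_g`` is an A-to-I editing
at hairpin position 48), and the corresponding edited mature miRNA is
``<pre-miRNA>_<pos><alt>`` (``hsa-mir-376c_48g``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

NUCLEOTIDES = ("A", "C", "G", "T")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature arm, in 1-based inclusive hairpin-local coordinates."""

    id: str
    start: int
    end: int
    arm: str  # "5p" | "3p"

    def __post_init__(self):
        if not 18 <= self.length <= 26:
            raise ValueError(
                f"mature {self.id}: length {self.length} outside 18..26"
            )
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"mature {self.id}: arm must be 5p or 3p")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def seed_span(self) -> tuple[int, int]:
        """Hairpin-local span of the seed region (mature positions 1-8)."""
        return (self.start, self.start + 7)


@dataclass
class PremiRNA:
    """A pre-miRNA hairpin with its genomic locus and mature arms.

    ``locus`` is ``(chrom, start, end, strand)`` with a 0-based half-open
    genomic interval; ``sequence`` is the hairpin in 5'→3' miRNA
    orientation (reverse complement of the genomic slice on '-').
    """

    id: str
    sequence: str
    locus: tuple[str, int, int, str]
    matures: list[MatureMiRNA] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper().replace("U", "T")
        if len(self.sequence) < 40:
            raise ValueError(f"{self.id}: hairpin shorter than 40 nt")
        for m in self.matures:
            if not (1 <= m.start <= m.end <= len(self.sequence)):
                raise ValueError(
                    f"{self.id}: mature {m.id} ({m.start}-{m.end}) outside "
                    f"hairpin of length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Nucleotide at 1-based hairpin position ``pos``."""
        return self.sequence[pos - 1]

    def genomic_position(self, pos: int) -> tuple[str, int]:
        """Map a 1-based hairpin position to a 1-based genomic position."""
        chrom, start, end, strand = self.locus
        if strand == "+":
            return chrom, start + pos
        return chrom, end - pos + 1


@dataclass(frozen=True)
class KnownSnp:
    chrom: str
    pos: int  # 1-based genomic
    ref: str
    alt: str
    rsid: str

    def __post_init__(self):
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(f"{self.rsid}: non-nucleotide allele")
        if self.ref == self.alt:
            raise ValueError(f"{self.rsid}: ref equals alt")


@dataclass(frozen=True)
class SiteKey:
    """Identity of an M/E site in hairpin coordinates.

    ``pos`` may exceed the hairpin length only for untemplated tail
    offsets past the hairpin 3' end, in which case ``ref`` is ``'-'``.
    ``ref == '-'`` also covers single-base insertions; ``alt == '-'``
    marks deletions.
    """

    premirna_id: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("site position must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        for allele in (self.ref, self.alt):
            if allele not in NUCLEOTIDES and allele != "-":
                raise ValueError(f"invalid allele {allele!r}")


class SnpIndex:
    """Known-SNP lookups keyed by (chrom, 1-based pos)."""

    def __init__(self, snps: Iterable[KnownSnp] = ()):
        self._by_pos: dict[tuple[str, int], list[KnownSnp]] = {}
        for snp in snps:
            self._by_pos.setdefault((snp.chrom, snp.pos), []).append(snp)

    def lookup(self, chrom: str, pos: int) -> list[KnownSnp]:
        return self._by_pos.get((chrom, pos), [])

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_pos.values())


def load_known_snps(tsv_path: str | Path) -> SnpIndex:
    """Load a known-SNP table (chrom, pos, ref, alt, rsid; tab-separated).

    Duplicate positions with different alleles are all retained.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str, "rsid": str})
    required = {"chrom", "pos", "ref", "alt", "rsid"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SNP table missing columns: {sorted(missing)}")
    snps = [
        KnownSnp(row.chrom, int(row.pos), str(row.ref).upper(),
                 str(row.alt).upper(), row.rsid)
        for row in df.itertuples()
    ]
    return SnpIndex(snps)


# --- naming ---------------------------------------------------------------

def _display(allele: str, lower: bool) -> str:
    shown = "U" if allele == "T" else allele
    return shown.lower() if lower else shown.upper()


def _internal(allele: str) -> str:
    up = allele.upper()
    return "T" if up == "U" else up


_SITE_NAME_RE = re.compile(
    r"^(?P<pre>.+)_(?P<pos>\d+)_(?P<ref>[ACGU\-])_(?P<alt>[acgu\-])$"
)


def format_site_name(key: SiteKey) -> str:
    """``(hsa-mir-376c, 48, A, G)`` → ``"hsa-mir-376c_48_A_g"``."""
    return (
        f"{key.premirna_id}_{key.pos}_"
        f"{_display(key.ref, lower=False)}_{_display(key.alt, lower=True)}"
    )


def parse_site_name(name: str) -> SiteKey:
    """Exact inverse of :func:`format_site_name`."""
    m = _SITE_NAME_RE.match(name)
    if m is None:
        # locate the failure for the error message: walk expected fields
        parts = name.rsplit("_", 3)
        if len(parts) < 4:
            raise ValueError(
                f"malformed site name {name!r}: expected "
                "<premirna>_<pos>_<REF>_<alt> (failure at underscore split)"
            )
        pre, pos, ref, alt = parts
        at = len(pre) + 1
        if not pos.isdigit():
            raise ValueError(
                f"malformed site name {name!r}: position field at index {at}"
            )
        at += len(pos) + 1
        if not re.fullmatch(r"[ACGU\-]", ref):
            raise ValueError(
                f"malformed site name {name!r}: reference allele at index {at}"
            )
        at += len(ref) + 1
        raise ValueError(
            f"malformed site name {name!r}: edited allele at index {at}"
        )
    return SiteKey(
        m["pre"], int(m["pos"]), _internal(m["ref"]), _internal(m["alt"])
    )


def format_edited_mirna_name(
    premirna_id: str | PremiRNA, pos: int, alt: str
) -> str:
    """Edited-miRNA name, e.g. ``hsa-mir-376c_48g``.

    If a :class:`PremiRNA` is given, the edited allele is checked against
    the hairpin reference at ``pos``.
    """
    alt_int = _internal(alt)
    if isinstance(premirna_id, PremiRNA):
        pre = premirna_id
        if pos <= len(pre) and pre.base(pos) == alt_int:
            raise ValueError(
                f"{pre.id} position {pos}: edited allele equals reference"
            )
        name = pre.id
    else:
        name = premirna_id
    return f"{name}_{pos}{_display(alt_int, lower=True)}"


# --- GFF3 loading ---------------------------------------------------------

HAIRPIN_FEATURE = "miRNA_primary_transcript"
MATURE_FEATURE = "miRNA"


def _arm_of(name: str, local_start: int, hairpin_len: int) -> str:
    if name.endswith("-5p"):
        return "5p"
    if name.endswith("-3p"):
        return "3p"
    return "5p" if local_start - 1 < hairpin_len / 2 else "3p"


def load_premirna_set(
    gff3_path: str | Path, genome_fasta: str | Path
) -> list[PremiRNA]:
    """Load hairpins + mature arms from a miRBase-style GFF3 and genome.

    Mature (``miRNA``) records attach to their hairpin via the
    ``Derives_from`` attribute; mature coordinates are converted to
    1-based hairpin-local positions (strand aware). Hairpins are returned
    sorted by id. A record referencing a chromosome absent from the FASTA,
    or a mature record outside its hairpin or with no parent hairpin, is a
    fatal error naming the offending record.
    """
    genome = {rec.id: str(rec.seq).upper()
              for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    hairpins: dict[str, dict] = {}
    for feat in db.features_of_type(HAIRPIN_FEATURE):
        if feat.seqid not in genome:
            raise ValueError(
                f"hairpin {feat.id}: chromosome {feat.seqid!r} not in genome FASTA"
            )
        chrom_seq = genome[feat.seqid]
        start0, end = feat.start - 1, feat.end
        if end > len(chrom_seq):
            raise ValueError(f"hairpin {feat.id}: extends past {feat.seqid}")
        seq = chrom_seq[start0:end]
        if feat.strand == "-":
            seq = revcomp(seq)
        hairpins[feat.id] = {
            "id": feat.attributes.get("Name", [feat.id])[0],
            "sequence": seq,
            "locus": (feat.seqid, start0, end, feat.strand),
            "matures": [],
            "gstart": feat.start,
            "gend": feat.end,
            "strand": feat.strand,
        }

    for feat in db.features_of_type(MATURE_FEATURE):
        parents = feat.attributes.get("Derives_from", [])
        if not parents or parents[0] not in hairpins:
            raise ValueError(
                f"mature record {feat.id}: no parent hairpin (Derives_from)"
            )
        h = hairpins[parents[0]]
        if feat.start < h["gstart"] or feat.end > h["gend"]:
            raise ValueError(
                f"mature record {feat.id}: outside hairpin {parents[0]}"
            )
        if h["strand"] == "+":
            local_start = feat.start - h["gstart"] + 1
            local_end = feat.end - h["gstart"] + 1
        else:
            local_start = h["gend"] - feat.end + 1
            local_end = h["gend"] - feat.start + 1
        name = feat.attributes.get("Name", [feat.id])[0]
        h["matures"].append(
            MatureMiRNA(
                name, local_start, local_end,
                _arm_of(name, local_start, len(h["sequence"])),
            )
        )

    out = []
    for h in sorted(hairpins.values(), key=lambda d: d["id"]):
        out.append(
            PremiRNA(h["id"], h["sequence"], h["locus"],
                     sorted(h["matures"], key=lambda m: m.start))
        )
    return out
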