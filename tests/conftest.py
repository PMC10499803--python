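import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from miredit.refio import SiteKey
from miredit.simulate import PlantedSite, SimConfig, gen_reference

TRANSITION = {"A": "G", "C": "T", "G": "A", "T": "C"}


def category_for(ref, alt):
    if (ref, alt) == ("A", "G"):
        return "A-to-I"
    if (ref, alt) == ("C", "T"):
        return "C-to-U"
    return "Other"


def make_planted(premirna, pos, level_tumor, level_normal=None):
    """Plant the transition variant at a hairpin position."""
    if level_normal is None:
        level_normal = level_tumor
    ref = premirna.base(pos)
    alt = TRANSITION[ref]
    return PlantedSite(
        SiteKey(premirna.id, pos, ref, alt),
        category_for(ref, alt),
        {"tumor": level_tumor, "normal": level_normal},
    )


@pytest.fixture(scope="session")
def small_ref(tmp_path_factory):
    """A small written reference: 8 hairpins incl. one paralog pair."""
    cfg = SimConfig(
        n_premirnas=8, paralog_pairs=1, paralog_identity=0.97,
        coverage_mean=300, error_rate=0.001, tail_probs={},
        n_tumor=4, n_normal=2, seed=11,
    )
    ref = gen_reference(cfg, tmp_path_factory.mktemp("ref"))
    return cfg, ref


def write_fastq(path, records):
    """records: iterable of (seq, qual_string)."""
    with open(path, "w") as fh:
        for i, (seq, qual) in enumerate(records):
            fh.write(f"@r{i}\n{seq}\n+\n{qual}\n")
    return path


def qstr(length, q=35):
    return chr(33 + q) * length
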