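import pytest

from armiso.mirbase_io import HairpinRecord, MatureRecord
from armiso.synthetic import SyntheticConfig


@pytest.fixture
def tiny_cfg() -> SyntheticConfig:
    """Small, fast generator configuration for unit tests (not the study conditions)."""
    return SyntheticConfig(
        seed=7,
        n_species=4,
        n_families=5,
        n_samples_disease=4,
        n_samples_control=4,
        library_size_min=5_000,
        library_size_max=10_000,
        n_utrs=30,
        utr_length=300,
    )


@pytest.fixture
def simple_locus() -> tuple[HairpinRecord, MatureRecord]:
    """An 80-nt hairpin with a 22-nt canonical mature at positions 11-32."""
    five = "UGAGGUAGUAGGUUGUAUAGUU"  # 22 nt
    hairpin_seq = "GGGGGCCCCA" + five + "GUAACCGGAUCCGGAAACCGGA" + "ACGUACGUACGUACGUACGUACGUAC"
    hp = HairpinRecord(id="hsa-mir-t1", sequence=hairpin_seq)
    mat = MatureRecord(
        id="hsa-mir-t1-5p", sequence=five, hairpin_ids=["hsa-mir-t1"], start=11, end=32
    )
    return hp, mat


def write_fasta_text(path, entries):
    """entries: list of (header, sequence)."""
    with open(path, "w") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n{seq}\n")
    return path
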