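"""Seed extraction, seed shifting and seed-match target scanning.

The seed — mature miRNA nucleotides 2-8 — is the primary determinant of
target recognition; a 5' end change of one nucleotide shifts the seed frame
and in general redefines the target repertoire ("seed shifting").  Target
scanning here is deliberately minimal: a UTR is a target iff it contains at
least one exact occurrence of the reverse complement of the 7-mer seed.  This
is NOT TargetScan — no 7mer-m8/8mer/A1 site classes, conservation weighting
or context scores — but it makes overlap statistics between the target sets
of two related small RNAs computable and testable from sequence alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .isomir import IsomiRRecord
from .mirbase_io import MatureRecord, normalize_rna

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

SEED_START = 2  # 1-based, inclusive
SEED_END = 8


def reverse_complement(rna: str) -> str:
    return rna.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedSequence:
    source_id: str
    seed: str

    def __post_init__(self) -> None:
        if len(self.seed) != 7:
            raise ValueError(f"seed must be exactly 7 nt, got {len(self.seed)}")
        if set(self.seed) - set("ACGU"):
            raise ValueError(f"seed {self.seed!r} contains non-ACGU symbols")


@dataclass
class TargetSet:
    source_id: str
    utr_ids: set[str] = field(default_factory=set)
    positions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return sum(len(v) for v in self.positions.values())


def extract_seed(sequence: str | MatureRecord, source_id: str = "") -> SeedSequence:
    """Nucleotides 2-8 (1-based) of a mature miRNA or isomiR sequence."""
    if isinstance(sequence, MatureRecord):
        source_id = source_id or sequence.id
        sequence = sequence.sequence
    if len(sequence) < SEED_END:
        raise ValueError(f"sequence of {len(sequence)} nt too short for a 2-8 seed")
    return SeedSequence(source_id=source_id, seed=sequence[SEED_START - 1 : SEED_END])


def detect_seed_shift(
    canonical: MatureRecord | str, isomir: IsomiRRecord
) -> tuple[bool, int, bool]:
    """Whether an isomiR's 5' end moved off the canonical start.

    Returns (shifted, magnitude, seed_changed).  A shift is any nonzero 5'
    offset; whether the 7-mer seed actually differs is reported separately
    because degenerate (e.g. homopolymeric) sequences can shift without
    changing the seed.
    """
    canonical_seq = canonical.sequence if isinstance(canonical, MatureRecord) else canonical
    shifted = isomir.offset5 != 0
    seed_changed = False
    if len(canonical_seq) >= SEED_END and len(isomir.sequence) >= SEED_END:
        seed_changed = (
            extract_seed(canonical_seq).seed != extract_seed(isomir.sequence).seed
        )
    return shifted, abs(isomir.offset5), seed_changed


def _utr_items(utrs: Iterable) -> list[tuple[str, str]]:
    """Normalize UTR input (Biopython records or (id, seq) pairs) to RNA, dedup on id."""
    seen: set[str] = set()
    out: list[tuple[str, str]] = []
    for item in utrs:
        if hasattr(item, "id") and hasattr(item, "seq"):
            uid, seq = item.id, str(item.seq)
        else:
            uid, seq = item
        if uid in seen:
            continue
        seen.add(uid)
        out.append((uid, normalize_rna(seq, context=uid)))
    return out


def scan_targets(seed: SeedSequence, utrs: Iterable) -> TargetSet:
    """All UTRs containing >= 1 exact reverse-complement match of the seed.

    UTRs may be DNA or RNA (T is normalized to U); duplicate UTR ids are
    dropped (first record wins).  Every match interval is recorded 1-based
    inclusive; overlapping occurrences all count.
    """
    site = reverse_complement(seed.seed)
    result = TargetSet(source_id=seed.source_id)
    for uid, seq in _utr_items(utrs):
        hits: list[tuple[int, int]] = []
        pos = seq.find(site)
        while pos >= 0:
            hits.append((pos + 1, pos + len(site)))
            pos = seq.find(site, pos + 1)
        if hits:
            result.utr_ids.add(uid)
            result.positions[uid] = hits
    return result


@dataclass
class OverlapStats:
    shared: int
    fraction_a: float
    fraction_b: float
    jaccard: float


def overlap_stats(a: TargetSet, b: TargetSet) -> OverlapStats:
    """Set overlap between two target repertoires (UTR-id sets).

    fraction_a is the share of a's targets also targeted by b (and vice
    versa); Jaccard is intersection over union.  Empty sets yield zeros.
    """
    inter = a.utr_ids & b.utr_ids
    union = a.utr_ids | b.utr_ids
    return OverlapStats(
        shared=len(inter),
        fraction_a=len(inter) / len(a.utr_ids) if a.utr_ids else 0.0,
        fraction_b=len(inter) / len(b.utr_ids) if b.utr_ids else 0.0,
        jaccard=len(inter) / len(union) if union else 0.0,
    )
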