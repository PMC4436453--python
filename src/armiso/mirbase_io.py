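"""miRBase-dialect FASTA parsing, mature-on-hairpin location and arm assignment.

Mature miRNAs are excised from one of the two arms of a ~60-110 nt stem-loop
precursor (the hairpin).  A mature is a *5p* product when it comes from the
5' arm, *3p* when it comes from the 3' arm; a hairpin annotated with exactly
one mature per arm yields an :class:`ArmPair`.  Arm assignment prefers the
``-5p``/``-3p`` suffix that modern miRBase ids carry; for legacy ids the arm
is called positionally from the mature's midpoint relative to the hairpin
midpoint, with a 1-nt tie band reported as ``ambiguous`` rather than forced.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

_RNA_ALPHABET = set("ACGU")
_ACCESSION_RE = re.compile(r"^MI(MAT)?\d+$")

Arm = Literal["5p", "3p", "ambiguous"]


class MirbaseParseError(ValueError):
    """Raised for malformed FASTA input or records violating miRBase invariants."""


def normalize_rna(seq: str, *, context: str = "") -> str:
    """Uppercase, convert T to U and validate the A/C/G/U alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - _RNA_ALPHABET
    if bad:
        where = f" in {context}" if context else ""
        raise MirbaseParseError(
            f"non-ACGU symbol(s) {sorted(bad)}{where}; input must be nucleotide sequence"
        )
    return s


def species_code(record_id: str) -> str:
    """First hyphen-delimited token of a miRBase id, e.g. ``hsa`` of ``hsa-let-7a``."""
    return record_id.split("-", 1)[0]


@dataclass
class HairpinRecord:
    """A pre-miRNA stem-loop sequence."""

    id: str
    sequence: str
    accession: str = ""
    species_code: str = ""

    def __post_init__(self) -> None:
        if not self.species_code:
            self.species_code = species_code(self.id)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MatureRecord:
    """A mature miRNA, optionally located on its (first) hairpin.

    ``start``/``end`` are 1-based inclusive coordinates on the first hairpin
    listed in ``hairpin_ids``.
    """

    id: str
    sequence: str
    accession: str = ""
    species_code: str = ""
    hairpin_ids: list[str] = field(default_factory=list)
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if not self.species_code:
            self.species_code = species_code(self.id)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ArmAnnotation:
    mature_id: str
    hairpin_id: str
    arm: Arm
    method: Literal["name_suffix", "positional"]
    start: int | None = None
    end: int | None = None


@dataclass
class ArmPair:
    """One hairpin's 5p and 3p mature products."""

    hairpin_id: str
    mature_5p: MatureRecord
    mature_3p: MatureRecord


def _parse_header(description: str) -> tuple[str, str]:
    tokens = description.split()
    rid = tokens[0]
    accession = ""
    if len(tokens) > 1 and _ACCESSION_RE.match(tokens[1]):
        accession = tokens[1]
    return rid, accession


def parse_mirbase_fasta(
    path: str | Path, kind: Literal["hairpin", "mature"]
) -> list[HairpinRecord] | list[MatureRecord]:
    """Parse a miRBase-dialect FASTA file into hairpin or mature records.

    T is normalized to U; ids must be unique; hairpins must be >= 40 nt and
    matures 15-30 nt (miRBase semantics).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise MirbaseParseError(
                        f"{path}:{lineno}: expected FASTA header '>' but got: {line.strip()[:40]!r}"
                    )
                break

    records: list = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid, accession = _parse_header(rec.description)
        if rid in seen:
            raise MirbaseParseError(f"duplicate id {rid!r} in {path}")
        seen.add(rid)
        seq = normalize_rna(str(rec.seq), context=rid)
        if kind == "hairpin":
            if len(seq) < 40:
                raise MirbaseParseError(
                    f"hairpin {rid!r} is {len(seq)} nt; pre-miRNAs must be >= 40 nt"
                )
            records.append(HairpinRecord(id=rid, sequence=seq, accession=accession))
        elif kind == "mature":
            if not 15 <= len(seq) <= 30:
                raise MirbaseParseError(
                    f"mature {rid!r} is {len(seq)} nt; mature miRNAs must be 15-30 nt"
                )
            records.append(MatureRecord(id=rid, sequence=seq, accession=accession))
        else:
            raise ValueError(f"kind must be 'hairpin' or 'mature', got {kind!r}")
    return records


def write_fasta(records: Iterable[HairpinRecord | MatureRecord], path: str | Path) -> None:
    """Write records back to miRBase-dialect FASTA (id [accession] header)."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.accession else f"{rec.id} {rec.accession}"
            fh.write(f">{header}\n{rec.sequence}\n")


def load_coordinates_tsv(path: str | Path) -> dict[str, tuple[str, int, int]]:
    """Read a 3-column TSV (mature_id, hairpin_id, start-end) of location overrides."""
    out: dict[str, tuple[str, int, int]] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            mature_id, hairpin_id, span = row[:3]
            start_s, end_s = span.split("-")
            out[mature_id] = (hairpin_id, int(start_s), int(end_s))
    return out


def locate_mature(mature: MatureRecord, hairpin: HairpinRecord) -> tuple[int, int]:
    """1-based inclusive coordinates of the first exact occurrence of the mature.

    Multiple occurrences are legal on near-palindromic hairpins; the first
    (5'-most) is taken and a warning is logged.
    """
    idx = hairpin.sequence.find(mature.sequence)
    if idx < 0:
        raise ValueError(f"mature {mature.id!r} does not occur on hairpin {hairpin.id!r}")
    if hairpin.sequence.find(mature.sequence, idx + 1) >= 0:
        logger.warning(
            "mature %s occurs more than once on hairpin %s; taking the 5'-most hit",
            mature.id,
            hairpin.id,
        )
    return idx + 1, idx + len(mature.sequence)


_SUFFIX_RE = re.compile(r"-(5p|3p)$")


def assign_arm(
    mature: MatureRecord, hairpin: HairpinRecord | None = None, *, tie_tolerance: float = 1.0
) -> ArmAnnotation:
    """Classify a mature as a 5p or 3p arm product.

    The ``-5p``/``-3p`` id suffix (existing annotation) wins when present.
    Otherwise the call is positional: with mature midpoint m and hairpin
    length L, 5p if m < L/2, 3p if m > L/2, and ``ambiguous`` when
    ``|m - L/2| <= tie_tolerance`` (loop-spanning matures are surfaced, not
    silently forced to an arm).
    """
    m = _SUFFIX_RE.search(mature.id)
    start, end = mature.start, mature.end
    if hairpin is not None and (start is None or end is None):
        try:
            start, end = locate_mature(mature, hairpin)
        except ValueError:
            start = end = None
    if m:
        return ArmAnnotation(
            mature_id=mature.id,
            hairpin_id=hairpin.id if hairpin else (mature.hairpin_ids[0] if mature.hairpin_ids else ""),
            arm=m.group(1),  # type: ignore[arg-type]
            method="name_suffix",
            start=start,
            end=end,
        )
    if hairpin is None or start is None or end is None:
        raise ValueError(
            f"cannot assign arm for {mature.id!r}: no -5p/-3p suffix and no location on a hairpin"
        )
    midpoint = (start + end) / 2.0
    half = len(hairpin) / 2.0
    if abs(midpoint - half) <= tie_tolerance:
        arm: Arm = "ambiguous"
    elif midpoint < half:
        arm = "5p"
    else:
        arm = "3p"
    return ArmAnnotation(
        mature_id=mature.id,
        hairpin_id=hairpin.id,
        arm=arm,
        method="positional",
        start=start,
        end=end,
    )


def annotate_all(
    matures: Sequence[MatureRecord],
    hairpins: Sequence[HairpinRecord],
    *,
    tie_tolerance: float = 1.0,
) -> tuple[list[ArmAnnotation], list[MatureRecord]]:
    """Annotate every locatable mature on its first hairpin.

    A mature on multiple hairpins is annotated on the first hairpin in its
    ``hairpin_ids`` list (multicopy precursors: the first precursor wins).
    Returns (annotations, unlocatable matures).
    """
    by_id = {h.id: h for h in hairpins}
    annotations: list[ArmAnnotation] = []
    unlocatable: list[MatureRecord] = []
    for mat in matures:
        hp = None
        if mat.hairpin_ids:
            hp = by_id.get(mat.hairpin_ids[0])
        if hp is None:
            # fall back to substring search across hairpins, first match wins
            for cand in hairpins:
                if mat.sequence in cand.sequence:
                    hp = cand
                    break
        try:
            annotations.append(assign_arm(mat, hp, tie_tolerance=tie_tolerance))
        except ValueError:
            unlocatable.append(mat)
    return annotations, unlocatable


def pair_arms(
    matures: Sequence[MatureRecord],
    hairpins: Sequence[HairpinRecord],
    *,
    tie_tolerance: float = 1.0,
) -> tuple[list[ArmPair], dict[str, list[MatureRecord]]]:
    """Pair each hairpin's 5p and 3p matures.

    A hairpin yields one :class:`ArmPair` iff exactly one 5p and one 3p
    mature annotate onto it.  Everything else is returned in the unpaired
    report keyed by arm ('5p', '3p', 'ambiguous').
    """
    annotations, unlocatable = annotate_all(matures, hairpins, tie_tolerance=tie_tolerance)
    mat_by_id = {m.id: m for m in matures}
    per_hairpin: dict[str, dict[str, list[str]]] = {}
    for ann in annotations:
        per_hairpin.setdefault(ann.hairpin_id, {"5p": [], "3p": [], "ambiguous": []})[
            ann.arm
        ].append(ann.mature_id)

    pairs: list[ArmPair] = []
    unpaired: dict[str, list[MatureRecord]] = {"5p": [], "3p": [], "ambiguous": []}
    for hid in sorted(per_hairpin):
        arms = per_hairpin[hid]
        if len(arms["5p"]) == 1 and len(arms["3p"]) == 1:
            pairs.append(
                ArmPair(
                    hairpin_id=hid,
                    mature_5p=mat_by_id[arms["5p"][0]],
                    mature_3p=mat_by_id[arms["3p"][0]],
                )
            )
        else:
            for arm in ("5p", "3p"):
                unpaired[arm].extend(mat_by_id[mid] for mid in arms[arm])
        unpaired["ambiguous"].extend(mat_by_id[mid] for mid in arms["ambiguous"])
    if unlocatable:
        logger.info("%d matures could not be located on any hairpin", len(unlocatable))
    return pairs, unpaired


def write_arm_annotations_tsv(annotations: Iterable[ArmAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["mature_id", "hairpin_id", "arm", "method", "start", "end"])
        for a in annotations:
            w.writerow([a.mature_id, a.hairpin_id, a.arm, a.method, a.start or "", a.end or ""])


def write_pairs_tsv(pairs: Iterable[ArmPair], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["hairpin_id", "mature_5p", "mature_3p"])
        for p in pairs:
            w.writerow([p.hairpin_id, p.mature_5p.id, p.mature_3p.id])
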