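"""IsomiR extraction and within-locus expression profiling.

A miRNA locus rarely yields a single sequence: small RNA-seq reads from one
arm differ at their 5'/3' ends (imprecise Drosha/Dicer cleavage, templated
trimming/extension) and may carry non-template 3' additions.  Each distinct
end-variant is an isomiR, identified here by its signed 5' and 3' offsets
relative to the canonical (annotated) mature plus the non-template tail.
Expression is normalized two ways: RPM (reads per million mapped) across the
library, and the relative expression rate — the isomiR's percentage of all
reads assigned to its locus within one sample, which is what makes expression
patterns comparable across samples with different depths.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mirbase_io import HairpinRecord, MatureRecord, locate_mature, normalize_rna

logger = logging.getLogger(__name__)

#: default assignment tolerance: a read's templated start may sit up to this
#: many nt from the canonical start (observed end variability is 1-2 nt;
#: 5 nt leaves margin without crossing into the loop)
DEFAULT_WINDOW = 5
#: default maximum non-template 3' addition length
DEFAULT_MAX_TAIL = 3


@dataclass
class ReadSet:
    """Collapsed small-RNA reads of one sample: (sequence, count) pairs."""

    sample_id: str
    condition: str  # 'disease' or 'control'
    reads: list[tuple[str, int]]
    disease_label: str = ""
    total_mapped: int = 0

    def __post_init__(self) -> None:
        if self.condition not in ("disease", "control"):
            raise ValueError(f"condition must be 'disease' or 'control', got {self.condition!r}")
        for seq, count in self.reads:
            if not seq:
                raise ValueError("empty read sequence")
            if count < 0:
                raise ValueError(f"negative count for read {seq!r}")
        if self.total_mapped <= 0:
            self.total_mapped = sum(c for _, c in self.reads)


@dataclass
class IsomiRRecord:
    """One isomiR of one locus in one sample."""

    locus_id: str
    sequence: str
    offset5: int  # negative = extends 5' of the canonical start
    offset3: int  # positive = templated extension past the canonical 3' end
    tail3: str  # non-template 3' addition, '' for none
    count: int
    rpm: float = 0.0
    percent: float = 0.0

    @property
    def is_canonical(self) -> bool:
        return self.offset5 == 0 and self.offset3 == 0 and self.tail3 == ""

    @property
    def variant_key(self) -> tuple[int, int, str]:
        return (self.offset5, self.offset3, self.tail3)


@dataclass
class LocusProfile:
    """Per-sample isomiR records of one locus across a cohort."""

    locus_id: str
    samples: dict[str, list[IsomiRRecord]] = field(default_factory=dict)
    condition: str = ""

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.samples)


def read_collapsed_tsv(path: str | Path, sample_id: str, condition: str, **kw) -> ReadSet:
    """Load a 2-column (sequence, count) TSV of collapsed reads."""
    reads: list[tuple[str, int]] = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            reads.append((normalize_rna(row[0], context=str(path)), int(row[1])))
    return ReadSet(sample_id=sample_id, condition=condition, reads=reads, **kw)


def read_collapsed_fasta(path: str | Path, sample_id: str, condition: str, **kw) -> ReadSet:
    """Load collapsed reads from FASTA whose ids end in ``-countN``."""
    from Bio import SeqIO

    reads: list[tuple[str, int]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if "-count" not in rid:
            raise ValueError(f"collapsed FASTA id {rid!r} lacks a -countN suffix")
        count = int(rid.rsplit("-count", 1)[1])
        reads.append((normalize_rna(str(rec.seq), context=rid), count))
    return ReadSet(sample_id=sample_id, condition=condition, reads=reads, **kw)


def rpm(count: int, total_mapped: int) -> float:
    """Reads per million mapped reads."""
    if total_mapped <= 0:
        raise ValueError(f"total_mapped must be positive, got {total_mapped}")
    return count * 1_000_000 / total_mapped


def _match_read(
    seq: str, hairpin_seq: str, canonical_start: int, max_tail: int
) -> tuple[int, int, str] | None:
    """Resolve a read against a hairpin.

    Removes the shortest 3' suffix (length <= max_tail) that leaves an exact
    hairpin substring, so fully templated reads carry no tail and the tail is
    non-template by construction.  Among multiple template hits the start
    closest to the canonical start wins (ties: 5'-most).  Returns 0-based
    (template_start, template_len, tail) or None.
    """
    for t in range(0, max_tail + 1):
        core = seq[: len(seq) - t] if t else seq
        if not core:
            break
        starts = []
        pos = hairpin_seq.find(core)
        while pos >= 0:
            starts.append(pos)
            pos = hairpin_seq.find(core, pos + 1)
        if starts:
            best = min(starts, key=lambda s: (abs(s - canonical_start), s))
            return best, len(core), seq[len(seq) - t:] if t else ""
    return None


def extract_isomirs(
    reads: ReadSet,
    hairpin: HairpinRecord,
    canonical: MatureRecord,
    *,
    window: int = DEFAULT_WINDOW,
    max_tail: int = DEFAULT_MAX_TAIL,
    locus_id: str | None = None,
) -> list[IsomiRRecord]:
    """Assign collapsed reads to one miRNA locus and compute offsets/RPM.

    A read belongs to the locus iff its templated portion (after stripping a
    non-template 3' tail of at most ``max_tail`` nt) matches the hairpin with
    a start within +/- ``window`` nt of the canonical start.  Offsets are
    relative to the canonical ends: offset5 = read start - canonical start
    (negative extends 5'), offset3 = templated read end - canonical end.
    Reads matching nowhere are ignored.  Records are aggregated per
    (offset5, offset3, tail3) and sorted by descending count.
    """
    cstart, cend = locate_mature(canonical, hairpin)
    cs0, ce0 = cstart - 1, cend - 1
    lid = locus_id or canonical.id
    agg: dict[tuple[int, int, str], int] = {}
    seq_of: dict[tuple[int, int, str], str] = {}
    for seq, count in reads.reads:
        if count == 0:
            continue
        hit = _match_read(seq, hairpin.sequence, cs0, max_tail)
        if hit is None:
            continue
        start0, tlen, tail = hit
        if abs(start0 - cs0) > window:
            continue
        key = (start0 - cs0, (start0 + tlen - 1) - ce0, tail)
        agg[key] = agg.get(key, 0) + count
        seq_of[key] = seq
    records = [
        IsomiRRecord(
            locus_id=lid,
            sequence=seq_of[key],
            offset5=key[0],
            offset3=key[1],
            tail3=key[2],
            count=count,
            rpm=rpm(count, reads.total_mapped) if reads.total_mapped > 0 else 0.0,
        )
        for key, count in agg.items()
        if count > 0
    ]
    records.sort(key=lambda r: (-r.count, r.offset5, r.offset3, r.tail3))
    return records


def locus_percentages(records: Sequence[IsomiRRecord]) -> list[IsomiRRecord]:
    """Fill each record's within-locus relative expression rate (percent).

    percent = 100 * count / (sum of counts over the locus in this sample).
    A zero locus total yields an empty result with a warning.
    """
    total = sum(r.count for r in records)
    if total <= 0:
        logger.warning("locus total is zero; no percentages computed")
        return []
    for r in records:
        r.percent = 100.0 * r.count / total
    return list(records)


def build_locus_profile(
    readsets: Sequence[ReadSet],
    hairpin: HairpinRecord,
    canonical: MatureRecord,
    *,
    window: int = DEFAULT_WINDOW,
    max_tail: int = DEFAULT_MAX_TAIL,
) -> LocusProfile:
    """Extract and percentage-normalize one locus across a cohort of samples."""
    profile = LocusProfile(locus_id=canonical.id)
    conditions = {rs.condition for rs in readsets}
    if len(conditions) == 1:
        profile.condition = conditions.pop()
    for rs in readsets:
        recs = extract_isomirs(
            rs, hairpin, canonical, window=window, max_tail=max_tail
        )
        profile.samples[rs.sample_id] = locus_percentages(recs)
    return profile


def profile_summary(
    profile: LocusProfile,
    *,
    min_rpm: float = 1.0,
    min_samples: int | None = None,
) -> pd.DataFrame:
    """Mean/SD of each isomiR's relative expression across samples.

    Samples whose locus-level RPM sum is below ``min_rpm`` are dropped
    (abundance filter).  IsomiRs observed in fewer than ``min_samples``
    samples (default: 10% of passing samples, at least 1) are pooled into an
    ``other`` row.  Rows are ranked by mean percent (rank 1 = dominant).
    An isomiR absent from a passing sample contributes percent 0 there, so
    means are comparable across isomiRs.
    """
    passing: dict[str, list[IsomiRRecord]] = {}
    for sid, recs in profile.samples.items():
        if recs and sum(r.rpm for r in recs) >= min_rpm:
            passing[sid] = recs
    if not passing:
        raise ValueError(
            f"locus {profile.locus_id!r}: no sample passes the min_rpm={min_rpm} filter"
        )
    n_pass = len(passing)
    if min_samples is None:
        min_samples = max(1, int(np.ceil(0.10 * n_pass)))

    presence: dict[tuple[int, int, str], int] = {}
    for recs in passing.values():
        for r in recs:
            presence[r.variant_key] = presence.get(r.variant_key, 0) + 1
    kept = {k for k, c in presence.items() if c >= min_samples}
    pooled = set(presence) - kept

    def label(key: tuple[int, int, str]) -> str:
        o5, o3, tail = key
        return f"{o5:+d}|{o3:+d}|{tail or '.'}"

    sample_ids = sorted(passing)
    index = [label(k) for k in sorted(kept)] + (["other"] if pooled else [])
    mat = pd.DataFrame(0.0, index=pd.Index(index, name="variant"), columns=sample_ids)
    seq_of: dict[str, str] = {}
    for sid, recs in passing.items():
        for r in recs:
            if r.variant_key in kept:
                lab = label(r.variant_key)
                seq_of.setdefault(lab, r.sequence)
                mat.at[lab, sid] += r.percent
            else:
                mat.at["other", sid] += r.percent

    n_present = {label(k): c for k, c in presence.items() if k in kept}
    out = pd.DataFrame(
        {
            "mean_percent": mat.mean(axis=1),
            "sd_percent": mat.std(axis=1, ddof=1).fillna(0.0),
            "n_samples": [
                n_present.get(k, len(pooled)) for k in mat.index
            ],
        }
    )
    out["sequence"] = [seq_of.get(k, "") for k in out.index]
    out["rank"] = out["mean_percent"].rank(ascending=False, method="min").astype(int)
    out.attrs["n_passing_samples"] = n_pass
    return out.sort_values("rank")


def _box_stats(values: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo = values[values >= q1 - 1.5 * iqr].min() if len(values) else float("nan")
    hi = values[values <= q3 + 1.5 * iqr].max() if len(values) else float("nan")
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_low": float(lo),
        "whisker_high": float(hi),
        "n": int(len(values)),
    }


def dispersion_compare(
    disease: Sequence[LocusProfile],
    control: Sequence[LocusProfile],
    *,
    min_rpm: float = 1.0,
    min_samples: int | None = None,
) -> dict:
    """Compare between-sample isomiR dispersion of two cohorts.

    For each group the per-isomiR SDs of relative expression (pooled over
    loci) form the dispersion distribution; box summaries (quartiles,
    1.5xIQR whiskers) and a two-tailed rank-sum test of the two SD
    distributions are returned.  Disease cohorts with more flexible isomiR
    expression show systematically larger SDs.
    """
    if not disease or not control:
        raise ValueError("both groups must be nonempty")
    sds: dict[str, np.ndarray] = {}
    for label, group in (("disease", disease), ("control", control)):
        values: list[float] = []
        for profile in group:
            if len(profile.samples) < 2:
                raise ValueError(
                    f"locus {profile.locus_id!r} ({label}): SDs undefined with <2 samples"
                )
            summary = profile_summary(profile, min_rpm=min_rpm, min_samples=min_samples)
            values.extend(summary["sd_percent"].tolist())
        sds[label] = np.asarray(values, dtype=float)
    if np.array_equal(np.sort(sds["disease"]), np.sort(sds["control"])):
        stat, p = 0.0, 1.0
    else:
        res = stats.ranksums(sds["disease"], sds["control"])
        stat, p = float(res.statistic), float(res.pvalue)
    return {
        "disease": _box_stats(sds["disease"]),
        "control": _box_stats(sds["control"]),
        "disease_sds": sds["disease"],
        "control_sds": sds["control"],
        "ranksum_statistic": stat,
        "ranksum_p": p,
    }


def assign_to_loci(
    reads: ReadSet,
    loci: Sequence[tuple[HairpinRecord, MatureRecord]],
    *,
    window: int = DEFAULT_WINDOW,
    max_tail: int = DEFAULT_MAX_TAIL,
) -> dict[str, list[IsomiRRecord]]:
    """Assign each read to at most one of several loci.

    A read eligible for several loci goes to the one whose canonical start is
    closest to the read's templated start; ties go to the 5'-most canonical
    start on the earlier hairpin id (deterministic, logged).
    """
    anchors = []
    for hairpin, canonical in loci:
        cstart, _ = locate_mature(canonical, hairpin)
        anchors.append((hairpin, canonical, cstart - 1))

    per_locus: dict[str, dict[tuple[int, int, str], int]] = {
        c.id: {} for _, c, _ in anchors
    }
    seq_of: dict[str, dict[tuple[int, int, str], str]] = {c.id: {} for _, c, _ in anchors}
    for seq, count in reads.reads:
        if count == 0:
            continue
        candidates = []
        for hairpin, canonical, cs0 in anchors:
            hit = _match_read(seq, hairpin.sequence, cs0, max_tail)
            if hit is None:
                continue
            start0, tlen, tail = hit
            dist = abs(start0 - cs0)
            if dist <= window:
                candidates.append((dist, cs0, hairpin.id, canonical.id, start0, tlen, tail))
        if not candidates:
            continue
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
            logger.info(
                "read %s... equidistant from several loci; assigned to %s",
                seq[:12],
                candidates[0][3],
            )
        _, cs0, _, lid, start0, tlen, tail = candidates[0]
        cstart, cend = next((locate_mature(c, h) for h, c in loci if c.id == lid))
        key = (start0 - (cstart - 1), (start0 + tlen - 1) - (cend - 1), tail)
        per_locus[lid][key] = per_locus[lid].get(key, 0) + count
        seq_of[lid].setdefault(key, seq)

    out: dict[str, list[IsomiRRecord]] = {}
    for lid, agg in per_locus.items():
        recs = [
            IsomiRRecord(
                locus_id=lid,
                sequence=seq_of[lid][key],
                offset5=key[0],
                offset3=key[1],
                tail3=key[2],
                count=count,
                rpm=rpm(count, reads.total_mapped),
            )
            for key, count in agg.items()
        ]
        recs.sort(key=lambda r: (-r.count, r.offset5, r.offset3, r.tail3))
        out[lid] = locus_percentages(recs) if recs else []
    return out


def write_locus_tsv(profile: LocusProfile, path: str | Path) -> None:
    rows = []
    for sid in profile.sample_ids:
        for r in profile.samples[sid]:
            rows.append(
                {
                    "sample_id": sid,
                    "locus": r.locus_id,
                    "sequence": r.sequence,
                    "offset5": r.offset5,
                    "offset3": r.offset3,
                    "tail3": r.tail3,
                    "count": r.count,
                    "rpm": r.rpm,
                    "percent": r.percent,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
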