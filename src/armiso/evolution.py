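"""Cross-species evolutionary analysis of miRNA arms.

Given mature miRNAs from several species this module discovers gene families
shared by every species, infers an unannotated arm of a hairpin from the
homologous human hairpin/mature, trims cross-species alignments to the core
columns free of terminal-length gaps, profiles per-position divergence
(transitions, transversions, indels) against the human reference row, and
computes the classical population-genetic summaries for a set of homologous
miRNA sequences treated as a "population":

* k  — mean number of pairwise nucleotide differences,
* pi — nucleotide diversity, k divided by the core alignment length,
* Hd — haplotype diversity with the n/(n-1) small-sample correction,

with Nei (1987) sampling standard deviations (eq. 10.7 for pi, eq. 8.12 for
Hd), i.e. the values DnaSP prints as "+/-".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import GAP, needleman_wunsch, star_align
from .mirbase_io import HairpinRecord, MatureRecord, locate_mature

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CU")


# ---------------------------------------------------------------------------
# family grouping

_ARM_SUFFIX = re.compile(r"-(5p|3p)$")
_COPY_SUFFIX = re.compile(r"-\d+$")
_VARIANT_SUFFIX = re.compile(r"[a-z]+$")


@dataclass(frozen=True)
class FamilyKey:
    family_name: str  # e.g. "let-7"
    member_name: str  # e.g. "let-7a"


def member_name(mirna_id: str) -> str:
    """Normalize a miRBase id to its gene-member name.

    Strips the species prefix ("hsa-"), the arm suffix ("-5p"/"-3p") and a
    trailing copy number ("-1"/"-2", kept only when removing it would leave a
    name with no digits, so "mir-100" is not truncated to "mir").
    """
    name = mirna_id.split("-", 1)[1] if "-" in mirna_id else mirna_id
    name = name.lower()
    name = _ARM_SUFFIX.sub("", name)
    m = _COPY_SUFFIX.search(name)
    if m:
        stem = name[: m.start()]
        if any(ch.isdigit() for ch in stem):
            name = stem
    return name


def family_name(member: str) -> str:
    """Family of a member name: strip the trailing letter variant ("let-7a" -> "let-7")."""
    stripped = _VARIANT_SUFFIX.sub("", member)
    # don't strip the whole name for letter-only names
    return stripped if any(ch.isdigit() for ch in stripped) else member


@dataclass
class SharedFamily:
    family: str
    members_by_species: dict[str, list[str]]

    @property
    def member_names(self) -> set[str]:
        return {m for ms in self.members_by_species.values() for m in ms}

    def keys(self) -> list[FamilyKey]:
        return [FamilyKey(self.family, m) for m in sorted(self.member_names)]


def find_shared_families(
    per_species_matures: Mapping[str, Iterable[MatureRecord | str]]
) -> list[SharedFamily]:
    """Gene families with at least one member in every surveyed species.

    Ids are normalized with :func:`member_name`/:func:`family_name`; a family
    is shared when every species contributes >= 1 member, and the members are
    reported per species (they need not be the same variant everywhere:
    "let-7a" in one species and "let-7b" in another both witness "let-7").
    """
    if len(per_species_matures) < 2:
        raise ValueError("need matures from at least two species")
    per_species_families: dict[str, dict[str, set[str]]] = {}
    for sp, matures in per_species_matures.items():
        fams: dict[str, set[str]] = {}
        for mat in matures:
            mid = mat.id if hasattr(mat, "id") else str(mat)
            member = member_name(mid)
            fams.setdefault(family_name(member), set()).add(member)
        per_species_families[sp] = fams
    shared_names = set.intersection(
        *(set(fams) for fams in per_species_families.values())
    ) if per_species_families else set()
    out = []
    for fam in sorted(shared_names):
        out.append(
            SharedFamily(
                family=fam,
                members_by_species={
                    sp: sorted(per_species_families[sp][fam]) for sp in per_species_families
                },
            )
        )
    return out


# ---------------------------------------------------------------------------
# alignment containers

@dataclass
class AlignedFamily:
    """A gapped alignment of one miRNA arm across species."""

    name: str
    arm: str  # '5p' or '3p'
    rows: dict[str, str]  # species_code -> gapped sequence
    reference_species: str = "hsa"

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError(f"{self.name}: alignment needs >= 2 rows")
        if self.reference_species not in self.rows:
            raise ValueError(
                f"{self.name}: reference species {self.reference_species!r} missing"
            )
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.name}: rows have unequal lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))


def align_family(
    name: str, arm: str, seqs: Mapping[str, str], reference_species: str = "hsa"
) -> AlignedFamily:
    """Star-align unaligned per-species sequences around the reference species."""
    rows = star_align(dict(seqs), reference_species)
    return AlignedFamily(name=name, arm=arm, rows=rows, reference_species=reference_species)


def trim_core(aln: AlignedFamily) -> AlignedFamily:
    """Strip terminal columns caused by length differences.

    Leading columns are removed up to the first column in which no row has a
    gap, and symmetrically from the 3' end; internal gap columns (true
    indels) are retained.
    """
    cols = list(zip(*aln.rows.values()))
    full = [i for i, col in enumerate(cols) if GAP not in col]
    if not full:
        raise ValueError(f"{aln.name}: no gap-free column; core is empty after trimming")
    lo, hi = full[0], full[-1] + 1
    return AlignedFamily(
        name=aln.name,
        arm=aln.arm,
        rows={sp: seq[lo:hi] for sp, seq in aln.rows.items()},
        reference_species=aln.reference_species,
    )


# ---------------------------------------------------------------------------
# divergence profiling

@dataclass
class DivergenceProfile:
    """Per-position substitution/indel counts against the reference row."""

    name: str
    arm: str
    positions: pd.DataFrame  # columns: position, transitions, transversions, indels, n_compared

    @property
    def substitution_rate(self) -> np.ndarray:
        df = self.positions
        n = df["n_compared"].to_numpy(dtype=float)
        subs = (df["transitions"] + df["transversions"]).to_numpy(dtype=float)
        return np.divide(subs, n, out=np.zeros_like(subs), where=n > 0)

    @property
    def mean_rate(self) -> float:
        total_n = self.positions["n_compared"].sum()
        if total_n == 0:
            return 0.0
        subs = self.positions[["transitions", "transversions"]].to_numpy().sum()
        return float(subs / total_n)


def classify_substitution(ref: str, alt: str) -> str:
    """'transition' (purine<->purine or pyrimidine<->pyrimidine) or 'transversion'."""
    if ref == alt:
        raise ValueError("not a substitution")
    if {ref, alt} <= PURINES or {ref, alt} <= PYRIMIDINES:
        return "transition"
    return "transversion"


def divergence_profile(aln: AlignedFamily) -> DivergenceProfile:
    """Count transitions/transversions/indels per core column vs the reference.

    At each position every non-reference row contributes at most one event;
    gap-vs-gap pairs are excluded from ``n_compared``.
    """
    ref = aln.rows[aln.reference_species]
    others = [seq for sp, seq in aln.rows.items() if sp != aln.reference_species]
    records = []
    for pos in range(aln.length):
        ts = tv = indel = n = 0
        r = ref[pos]
        for seq in others:
            c = seq[pos]
            if r == GAP and c == GAP:
                continue
            n += 1
            if r == GAP or c == GAP:
                indel += 1
            elif r != c:
                if classify_substitution(r, c) == "transition":
                    ts += 1
                else:
                    tv += 1
        records.append(
            {
                "position": pos + 1,
                "transitions": ts,
                "transversions": tv,
                "indels": indel,
                "n_compared": n,
            }
        )
    return DivergenceProfile(name=aln.name, arm=aln.arm, positions=pd.DataFrame(records))


# ---------------------------------------------------------------------------
# diversity statistics

@dataclass
class DiversityStats:
    n: int
    L: int
    pi: float
    pi_sd: float
    hd: float
    hd_sd: float
    k: float


def _pairwise_differences(a: str, b: str) -> int:
    """Differences over columns where both rows are non-gap (gap columns excluded)."""
    return sum(1 for x, y in zip(a, b) if x != y and x != GAP and y != GAP)


def diversity_stats(
    seqs: Sequence[str],
    *,
    aligned: bool = False,
    reference_index: int = 0,
) -> DiversityStats:
    """pi, Hd and k for a set of homologous miRNA sequences.

    If ``aligned`` is false the sequences are star-aligned around
    ``seqs[reference_index]`` and core-trimmed first.  k is the mean count of
    differing non-gap column pairs over all C(n,2) sequence pairs; pi = k/L;
    Hd = (n/(n-1)) (1 - sum p_h^2) over distinct haplotypes.  Sampling SDs
    follow Nei (1987): eq. 10.7 for pi and eq. 8.12 for Hd.
    """
    seqs = list(seqs)
    n = len(seqs)
    if n < 2:
        raise ValueError("diversity statistics need n >= 2 sequences")
    if not aligned:
        keyed = {f"s{i}": s for i, s in enumerate(seqs)}
        fam = AlignedFamily(
            name="adhoc",
            arm="5p",
            rows=star_align(keyed, f"s{reference_index}"),
            reference_species=f"s{reference_index}",
        )
        rows = trim_core(fam).rows
        seqs = [rows[f"s{i}"] for i in range(n)]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("pre-aligned sequences must have equal lengths")
    if L == 0:
        raise ValueError("empty core alignment")

    total_diffs = sum(_pairwise_differences(a, b) for a, b in combinations(seqs, 2))
    n_pairs = n * (n - 1) // 2
    k = total_diffs / n_pairs
    pi = k / L

    haplotype_counts = pd.Series(seqs).value_counts().to_numpy(dtype=float)
    p = haplotype_counts / n
    sum_p2 = float(np.sum(p**2))
    hd = min(1.0, max(0.0, (n / (n - 1)) * (1.0 - sum_p2)))

    # Nei (1987) eq. 8.12 sampling variance of haplotype diversity
    sum_p3 = float(np.sum(p**3))
    var_hd = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sum_p3 - sum_p2**2) + sum_p2 - sum_p2**2
    )
    hd_sd = float(np.sqrt(max(var_hd, 0.0)))

    # Nei (1987) eq. 10.7 total sampling variance of nucleotide diversity
    var_pi = ((n + 1) / (3.0 * (n - 1) * L)) * pi + (
        2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    ) * pi**2
    pi_sd = float(np.sqrt(max(var_pi, 0.0)))

    return DiversityStats(n=n, L=L, pi=pi, pi_sd=pi_sd, hd=hd, hd_sd=hd_sd, k=k)


# ---------------------------------------------------------------------------
# missing-arm inference

def infer_missing_arm(
    hairpin: HairpinRecord,
    human_hairpin: HairpinRecord,
    human_mature: MatureRecord,
    *,
    min_length: int = 15,
    max_gap_fraction: float = 0.5,
) -> str:
    """Predict an unannotated arm from the homologous human hairpin.

    The two hairpins are globally aligned (match +1, mismatch -1, gap -2,
    free end gaps); the prediction is the target-hairpin segment spanning the
    columns of the human mature, with gaps removed.  Conservation across
    species is what makes the consensus transfer meaningful.
    """
    start, end = locate_mature(human_mature, human_hairpin)
    ah, at, _ = needleman_wunsch(human_hairpin.sequence, hairpin.sequence)
    segment: list[str] = []
    hpos = 0
    for ch, ct in zip(ah, at):
        if ch != GAP:
            hpos += 1
            if start <= hpos <= end:
                segment.append(ct)
    gaps = segment.count(GAP)
    predicted = "".join(c for c in segment if c != GAP)
    if not segment or gaps / len(segment) > max_gap_fraction or len(predicted) < min_length:
        raise ValueError(
            f"prediction failed for {hairpin.id!r}: aligned segment "
            f"{len(predicted)} nt with {gaps}/{len(segment) or 1} gap columns"
        )
    return predicted


# ---------------------------------------------------------------------------
# arm comparison statistics

def arm_divergence_compare(
    profiles_5p: Sequence[DivergenceProfile],
    profiles_3p: Sequence[DivergenceProfile],
) -> dict[str, float]:
    """Compare 5p vs 3p divergence with paired Wilcoxon and Spearman tests.

    The Wilcoxon signed-rank pairing unit is each miRNA pair's mean
    substitution rate (positionwise pairing across different-length arms is
    ill-defined); the Spearman correlation is computed on the per-position
    substitution-rate vectors of paired profiles truncated to their common
    length and concatenated.  Both tests are two-tailed; an all-zero
    difference vector yields Z=0, p=1 by convention.
    """
    if len(profiles_5p) != len(profiles_3p) or not profiles_5p:
        raise ValueError("need equal-length nonempty lists of paired profiles")
    mean5 = np.array([p.mean_rate for p in profiles_5p])
    mean3 = np.array([p.mean_rate for p in profiles_3p])
    diffs = mean5 - mean3
    if np.allclose(diffs, 0.0):
        z, p_w = 0.0, 1.0
    else:
        res = stats.wilcoxon(mean5, mean3, method="approx")
        z, p_w = float(res.zstatistic), float(res.pvalue)

    xs: list[float] = []
    ys: list[float] = []
    for p5, p3 in zip(profiles_5p, profiles_3p):
        r5, r3 = p5.substitution_rate, p3.substitution_rate
        m = min(len(r5), len(r3))
        xs.extend(r5[:m])
        ys.extend(r3[:m])
    if np.allclose(xs, ys):
        rho, p_s = 1.0, 0.0
    elif np.ptp(xs) == 0 or np.ptp(ys) == 0:
        rho, p_s = float("nan"), float("nan")
    else:
        sres = stats.spearmanr(xs, ys)
        rho, p_s = float(sres.statistic), float(sres.pvalue)
    return {
        "wilcoxon_z": z,
        "wilcoxon_p": p_w,
        "spearman_rho": rho,
        "spearman_p": p_s,
        "n_pairs": float(len(profiles_5p)),
    }


def diversity_table(
    families: Mapping[str, Mapping[str, Mapping[str, str]]],
    *,
    aligned: bool = True,
) -> pd.DataFrame:
    """Table-2-style summary: one row per (family, arm) with pi, Hd, k and SDs.

    ``families`` maps family name -> arm ('5p'/'3p') -> species -> sequence.
    """
    rows = []
    for fam, arms in families.items():
        for arm, seq_map in arms.items():
            st = diversity_stats(list(seq_map.values()), aligned=aligned)
            rows.append(
                {
                    "family": fam,
                    "arm": arm,
                    "n": st.n,
                    "L": st.L,
                    "pi": st.pi,
                    "pi_sd": st.pi_sd,
                    "hd": st.hd,
                    "hd_sd": st.hd_sd,
                    "k": st.k,
                }
            )
    return pd.DataFrame(rows)
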