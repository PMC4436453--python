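"""Length and nucleotide-composition statistics for mature miRNA groups.

Covers length summaries (mean +/- SEM) with Student's/paired t comparisons,
overall A/U/C/G composition, homopolymer-run composition (overlapping XX/XXX/
XXXX counts, normalized over the four homopolymer labels), per-position
composition along the mature read 5'->3', and Pearson chi-square contingency
comparisons between groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

NUCLEOTIDES = ("A", "U", "C", "G")


def _sequences(group: Iterable) -> list[str]:
    out = []
    for item in group:
        out.append(item.sequence if hasattr(item, "sequence") else str(item))
    if not out:
        raise ValueError("empty group")
    return out


@dataclass
class LengthSummary:
    n: int
    mean: float
    sem: float
    values: list[int]


@dataclass
class CompositionTable:
    """Counts and percents over an ordered label set (A/U/C/G or AA..GGGG)."""

    labels: tuple[str, ...]
    counts: np.ndarray

    @property
    def percents(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros(len(self.labels))
        return 100.0 * self.counts / total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"count": self.counts, "percent": self.percents}, index=list(self.labels)
        )


@dataclass
class PositionalComposition:
    """Per-position nucleotide composition, positions 1..Lmax counted 5'->3'.

    ``counts`` is a positions x 4 matrix (A,U,C,G); a position's coverage is
    the number of sequences long enough to reach it.
    """

    counts: np.ndarray  # shape (Lmax, 4)
    coverage: np.ndarray  # shape (Lmax,)

    @property
    def percents(self) -> np.ndarray:
        cov = np.where(self.coverage > 0, self.coverage, 1)
        return 100.0 * self.counts / cov[:, None]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.percents, columns=list(NUCLEOTIDES))
        df.index = np.arange(1, len(df) + 1)
        df["coverage"] = self.coverage
        return df


def length_summary(group: Iterable) -> LengthSummary:
    """Mean length +/- standard error of the mean for a group of matures."""
    lengths = [len(s) for s in _sequences(group)]
    n = len(lengths)
    mean = float(np.mean(lengths))
    sem = float(np.std(lengths, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return LengthSummary(n=n, mean=mean, sem=sem, values=lengths)


def length_compare(a: Iterable, b: Iterable, *, paired: bool = False) -> tuple[float, float]:
    """Two-tailed t test of length distributions.

    Unpaired mode is Student's t (equal variances) between two independent
    groups, e.g. all 5p-miRNAs vs all 3p-miRNAs.  Paired mode is the paired t
    on per-pair differences, e.g. miR-#-5p vs miR-#-3p of the same hairpin.
    """
    la = [len(s) for s in _sequences(a)]
    lb = [len(s) for s in _sequences(b)]
    if len(la) < 2 or len(lb) < 2:
        raise ValueError("need at least two lengths per group")
    if paired:
        if len(la) != len(lb):
            raise ValueError("paired comparison requires equal-length paired lists")
        diffs = np.asarray(la, float) - np.asarray(lb, float)
        if np.allclose(diffs, diffs[0]) and np.isclose(diffs[0], 0):
            return 0.0, 1.0
        res = stats.ttest_rel(la, lb)
    else:
        if la == lb:
            return 0.0, 1.0
        res = stats.ttest_ind(la, lb, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def nucleotide_composition(group: Iterable) -> CompositionTable:
    """A/U/C/G counts pooled over all sequences in the group."""
    seqs = _sequences(group)
    counts = np.zeros(4, dtype=np.int64)
    for seq in seqs:
        for i, nt in enumerate(NUCLEOTIDES):
            counts[i] += seq.count(nt)
    if counts.sum() != sum(len(s) for s in seqs):
        raise ValueError("sequences contain non-ACGU symbols; normalize input first")
    return CompositionTable(labels=NUCLEOTIDES, counts=counts)


def repeat_run_composition(group: Iterable, k: int) -> CompositionTable:
    """Overlapping homopolymer k-mer counts (XX, XXX or XXXX).

    A run of r identical nucleotides contributes r-k+1 k-mers (overlap
    counting), so count(XXX) <= count(XX) always holds.  Percents are
    normalized over the four homopolymer labels only, matching tables whose
    AA/UU/CC/GG rows sum to 100.
    """
    if k not in (2, 3, 4):
        raise ValueError(f"k must be 2, 3 or 4, got {k}")
    seqs = _sequences(group)
    labels = tuple(nt * k for nt in NUCLEOTIDES)
    counts = np.zeros(4, dtype=np.int64)
    for seq in seqs:
        for i, motif in enumerate(labels):
            n = 0
            pos = seq.find(motif)
            while pos >= 0:
                n += 1
                pos = seq.find(motif, pos + 1)
            counts[i] += n
    return CompositionTable(labels=labels, counts=counts)


def positional_composition(group: Iterable) -> PositionalComposition:
    """Nucleotide percents at each position along the miRNA, 5'->3' from 1."""
    seqs = _sequences(group)
    lmax = max(len(s) for s in seqs)
    counts = np.zeros((lmax, 4), dtype=np.int64)
    coverage = np.zeros(lmax, dtype=np.int64)
    idx = {nt: i for i, nt in enumerate(NUCLEOTIDES)}
    for seq in seqs:
        for pos, nt in enumerate(seq):
            counts[pos, idx[nt]] += 1
        coverage[: len(seq)] += 1
    return PositionalComposition(counts=counts, coverage=coverage)


def _counts_vector(table: CompositionTable | PositionalComposition) -> tuple[np.ndarray, tuple]:
    if isinstance(table, CompositionTable):
        return np.asarray(table.counts, dtype=float), table.labels
    if isinstance(table, PositionalComposition):
        labels = tuple(
            f"pos{p+1}:{nt}" for p in range(table.counts.shape[0]) for nt in NUCLEOTIDES
        )
        return table.counts.astype(float).ravel(), labels
    raise TypeError(f"unsupported table type {type(table).__name__}")


def chi_square_compare(
    table_a: CompositionTable | PositionalComposition,
    table_b: CompositionTable | PositionalComposition,
) -> tuple[float, int, float]:
    """Pearson chi-square on the groups x labels count contingency.

    Positional input is stacked into one positions-x-nucleotide contingency
    (one pooled statistic over all positions).  Categories empty in both
    groups are dropped; a category empty in exactly one group still has a
    positive expected count and is kept.
    """
    ca, la = _counts_vector(table_a)
    cb, lb = _counts_vector(table_b)
    if la != lb:
        raise ValueError("tables have mismatched labels; compare like with like")
    obs = np.vstack([ca, cb])
    keep = obs.sum(axis=0) > 0
    obs = obs[:, keep]
    if obs.shape[1] < 2:
        raise ValueError(
            "fewer than two informative categories; merge categories before testing"
        )
    if np.array_equal(obs[0], obs[1]):
        return 0.0, int(obs.shape[1] - 1), 1.0
    expected = stats.contingency.expected_freq(obs)
    if np.any(expected <= 0):
        raise ValueError("zero expected cell count; merge sparse categories before testing")
    chi2, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(dof), float(p)


def write_composition_tsv(
    tables: dict[str, CompositionTable], path: str | Path
) -> pd.DataFrame:
    """Write a Table-1-style layout: one row per label, one percent column per group."""
    frames = {name: tbl.to_frame()["percent"] for name, tbl in tables.items()}
    df = pd.DataFrame(frames)
    df.to_csv(path, sep="\t", index_label="label", float_format="%.2f")
    return df
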