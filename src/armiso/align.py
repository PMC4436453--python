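"""Global alignment primitives for short (~22-90 nt) miRNA/hairpin sequences.

Needleman-Wunsch with free end gaps (semi-global): terminal gaps cost
nothing, so length differences at the termini do not distort the core
alignment.  Scoring is match +1, mismatch -1, gap -2.  Star alignment merges
pairwise alignments of every sequence against a designated reference into one
multiple alignment in reference coordinates; for the near-identical sequences
this package handles it is a deterministic, auditable stand-in for a general
progressive aligner.
"""

from __future__ import annotations

import numpy as np

GAP = "-"


def needleman_wunsch(
    a: str,
    b: str,
    *,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    free_end_gaps: bool = True,
) -> tuple[str, str, float]:
    """Align two sequences globally; returns (aligned_a, aligned_b, score).

    Tie-break order in traceback is diagonal > up (gap in b) > left (gap in
    a), which makes the result deterministic.
    """
    n, m = len(a), len(b)
    S = np.zeros((n + 1, m + 1))
    if not free_end_gaps:
        S[:, 0] = gap * np.arange(n + 1)
        S[0, :] = gap * np.arange(m + 1)
    sub = np.full((n, m), mismatch)
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    sub[aa[:, None] == bb[None, :]] = match
    for i in range(1, n + 1):
        diag = S[i - 1, :-1] + sub[i - 1]
        up = S[i - 1, 1:] + gap
        row = S[i]
        prev = row[0]
        for j in range(1, m + 1):
            best = diag[j - 1]
            if up[j - 1] > best:
                best = up[j - 1]
            left = prev + gap
            if left > best:
                best = left
            row[j] = best
            prev = best

    # free end gaps: start traceback from the best cell on the last row/column
    if free_end_gaps:
        jmax = int(np.argmax(S[n, :]))
        imax = int(np.argmax(S[:, m]))
        if S[n, jmax] >= S[imax, m]:
            i, j = n, jmax
        else:
            i, j = imax, m
        score = float(S[i, j])
    else:
        i, j = n, m
        score = float(S[n, m])

    out_a: list[str] = []
    out_b: list[str] = []
    # trailing free gaps
    if free_end_gaps:
        for jj in range(m - 1, j - 1, -1):
            out_a.append(GAP)
            out_b.append(b[jj])
        for ii in range(n - 1, i - 1, -1):
            out_a.append(a[ii])
            out_b.append(GAP)
    while i > 0 and j > 0:
        if np.isclose(S[i, j], S[i - 1, j - 1] + sub[i - 1, j - 1]):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif np.isclose(S[i, j], S[i - 1, j] + gap) or (
            free_end_gaps and j == m and np.isclose(S[i, j], S[i - 1, j])
        ):
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
    while i > 0:
        out_a.append(a[i - 1])
        out_b.append(GAP)
        i -= 1
    while j > 0:
        out_a.append(GAP)
        out_b.append(b[j - 1])
        j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), score


def _profile_against_ref(ref: str, aligned_ref: str, aligned_other: str) -> tuple[list[str], list[str]]:
    """Decompose a pairwise alignment into per-reference-slot insertions.

    Returns (ins, chars): ins[i] is the run of other-sequence characters
    inserted before reference position i (i in 0..len(ref), the last slot
    holds the 3' overhang) and chars[i] is the other character aligned to
    ref[i] (or '-').
    """
    ins = ["" for _ in range(len(ref) + 1)]
    chars = [GAP for _ in range(len(ref))]
    ri = 0
    for ca, cb in zip(aligned_ref, aligned_other):
        if ca == GAP:
            ins[ri] += cb
        else:
            if cb != GAP:
                chars[ri] = cb
            ri += 1
    return ins, chars


def star_align(rows: dict[str, str], reference: str) -> dict[str, str]:
    """Multiple alignment of ``rows`` around ``rows[reference]``.

    Each sequence is pairwise aligned to the reference (free end gaps); the
    pairwise alignments are merged on reference coordinates, padding
    insertions to the longest insertion observed at each reference slot.
    Rows already containing '-' are taken as pre-aligned only if all rows
    have equal length (the caller should not mix).
    """
    if reference not in rows:
        raise ValueError(f"reference {reference!r} not among rows")
    ref = rows[reference]
    others = {k: v for k, v in rows.items() if k != reference}
    profiles = {}
    for key, seq in others.items():
        ar, ao, _ = needleman_wunsch(ref, seq)
        profiles[key] = _profile_against_ref(ref, ar, ao)
    max_ins = [0] * (len(ref) + 1)
    for ins, _ in profiles.values():
        for i, run in enumerate(ins):
            max_ins[i] = max(max_ins[i], len(run))

    def build(ins: list[str], chars: list[str]) -> str:
        parts: list[str] = []
        for i in range(len(ref)):
            parts.append(ins[i].rjust(max_ins[i], GAP))
            parts.append(chars[i])
        parts.append(ins[len(ref)].ljust(max_ins[len(ref)], GAP))
        return "".join(parts)

    out = {reference: build(["" for _ in range(len(ref) + 1)], list(ref))}
    for key, (ins, chars) in profiles.items():
        out[key] = build(ins, chars)
    return out
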