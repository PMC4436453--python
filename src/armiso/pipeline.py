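"""End-to-end analyses combining the modules.

:func:`primary_analysis` reproduces, for any miRBase-dialect mature/hairpin
input, the full arm-level census: 5p/3p counts, 5p+3p pairs, length
summaries with t tests, overall/homopolymer/positional composition with
chi-square contingency tests.  Run on the real miRBase files it yields the
published-style tables; run on synthetic input it is the deterministic test
surface.
"""

from __future__ import annotations

from typing import Sequence

from . import composition as comp
from .mirbase_io import (
    ArmPair,
    HairpinRecord,
    MatureRecord,
    annotate_all,
    pair_arms,
)


def primary_analysis(
    matures: Sequence[MatureRecord],
    hairpins: Sequence[HairpinRecord],
    *,
    species: str | None = None,
) -> dict:
    """Arm census and composition statistics for one species' miRNAome.

    Returns a nested dict with:

    * ``counts`` — matures per arm, ambiguous and unlocatable counts, number
      of 5p/3p pairs;
    * ``length`` — per-arm length summaries, the Student's t between all
      5p- and 3p-miRNAs and the paired t over 5p/3p pairs;
    * ``composition`` — A/U/C/G tables per arm with the chi-square test;
    * ``repeats`` — homopolymer-run tables for k = 2, 3, 4 with chi-squares;
    * ``positional`` — per-position composition per arm with the pooled
      positions x nucleotides chi-square.
    """
    if species is not None:
        matures = [m for m in matures if m.species_code == species]
        hairpins = [h for h in hairpins if h.species_code == species]
    annotations, unlocatable = annotate_all(matures, hairpins)
    by_id = {m.id: m for m in matures}
    groups: dict[str, list[MatureRecord]] = {"5p": [], "3p": [], "ambiguous": []}
    for ann in annotations:
        groups[ann.arm].append(by_id[ann.mature_id])
    pairs, unpaired = pair_arms(matures, hairpins)

    result: dict = {
        "counts": {
            "matures": len(matures),
            "5p": len(groups["5p"]),
            "3p": len(groups["3p"]),
            "ambiguous": len(groups["ambiguous"]),
            "unlocatable": len(unlocatable),
            "pairs": len(pairs),
        },
        "annotations": annotations,
        "pairs": pairs,
        "unpaired": {k: len(v) for k, v in unpaired.items()},
    }
    if len(groups["5p"]) < 2 or len(groups["3p"]) < 2:
        return result

    g5, g3 = groups["5p"], groups["3p"]
    t_ind, p_ind = comp.length_compare(g5, g3, paired=False)
    length: dict = {
        "5p": comp.length_summary(g5),
        "3p": comp.length_summary(g3),
        "t_unpaired": t_ind,
        "p_unpaired": p_ind,
    }
    if len(pairs) >= 2:
        p5 = [p.mature_5p for p in pairs]
        p3 = [p.mature_3p for p in pairs]
        t_rel, p_rel = comp.length_compare(p5, p3, paired=True)
        length.update(
            {
                "pair_5p": comp.length_summary(p5),
                "pair_3p": comp.length_summary(p3),
                "t_paired": t_rel,
                "p_paired": p_rel,
            }
        )
    result["length"] = length

    nt5, nt3 = comp.nucleotide_composition(g5), comp.nucleotide_composition(g3)
    chi2, df, p = comp.chi_square_compare(nt5, nt3)
    result["composition"] = {"5p": nt5, "3p": nt3, "chi2": chi2, "df": df, "p": p}

    repeats = {}
    for k in (2, 3, 4):
        r5, r3 = comp.repeat_run_composition(g5, k), comp.repeat_run_composition(g3, k)
        try:
            chi2_k, df_k, p_k = comp.chi_square_compare(r5, r3)
        except ValueError:  # sparse homopolymer table on small inputs
            chi2_k = df_k = p_k = None
        repeats[k] = {"5p": r5, "3p": r3, "chi2": chi2_k, "df": df_k, "p": p_k}
    result["repeats"] = repeats

    pos5, pos3 = comp.positional_composition(g5), comp.positional_composition(g3)
    chi2_p, df_p, p_p = comp.chi_square_compare(pos5, pos3)
    result["positional"] = {"5p": pos5, "3p": pos3, "chi2": chi2_p, "df": df_p, "p": p_p}
    return result


def pairs_analysis(pairs: Sequence[ArmPair]) -> dict:
    """The same composition statistics restricted to 5p/3p pairs of the same hairpin."""
    g5 = [p.mature_5p for p in pairs]
    g3 = [p.mature_3p for p in pairs]
    if len(pairs) < 2:
        raise ValueError("need at least two pairs")
    t_rel, p_rel = comp.length_compare(g5, g3, paired=True)
    nt5, nt3 = comp.nucleotide_composition(g5), comp.nucleotide_composition(g3)
    chi2, df, p = comp.chi_square_compare(nt5, nt3)
    out = {
        "n_pairs": len(pairs),
        "length": {
            "5p": comp.length_summary(g5),
            "3p": comp.length_summary(g3),
            "t_paired": t_rel,
            "p_paired": p_rel,
        },
        "composition": {"5p": nt5, "3p": nt3, "chi2": chi2, "df": df, "p": p},
        "repeats": {},
    }
    for k in (2, 3, 4):
        r5, r3 = comp.repeat_run_composition(g5, k), comp.repeat_run_composition(g3, k)
        try:
            chi2_k, df_k, p_k = comp.chi_square_compare(r5, r3)
        except ValueError:  # sparse homopolymer table on small inputs
            chi2_k = df_k = p_k = None
        out["repeats"][k] = {"5p": r5, "3p": r3, "chi2": chi2_k, "df": df_k, "p": p_k}
    return out
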