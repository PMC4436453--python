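"""Family discovery, alignment, divergence profiling and diversity statistics."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from armiso.align import needleman_wunsch, star_align
from armiso.evolution import (
    AlignedFamily,
    arm_divergence_compare,
    diversity_stats,
    divergence_profile,
    family_name,
    find_shared_families,
    infer_missing_arm,
    member_name,
    trim_core,
)
from armiso.mirbase_io import HairpinRecord, MatureRecord


# ---------------------------------------------------------------------------
# brute-force oracles (kept independent of the implementation path)

def oracle_diversity(seqs):
    """Enumerate all sequence pairs: k, pi and Hd from first principles."""
    n = len(seqs)
    L = len(seqs[0])
    pairs = list(combinations(range(n), 2))
    diffs = []
    different_haplotype = 0
    for i, j in pairs:
        d = sum(
            1
            for x, y in zip(seqs[i], seqs[j])
            if x != y and x != "-" and y != "-"
        )
        diffs.append(d)
        if seqs[i] != seqs[j]:
            different_haplotype += 1
    k = sum(diffs) / len(pairs)
    return {"k": k, "pi": k / L, "hd": different_haplotype / len(pairs)}


def oracle_mismatches(rows, ref):
    """Total ref-vs-row mismatches (both non-gap) by a flat brute-force scan."""
    total = 0
    for sp, seq in rows.items():
        if sp == "hsa":
            continue
        for r, c in zip(ref, seq):
            if r != "-" and c != "-" and r != c:
                total += 1
    return total


# ---------------------------------------------------------------------------
# name normalization and shared families

@pytest.mark.parametrize(
    "mirna_id, member, family",
    [
        ("hsa-let-7a-5p", "let-7a", "let-7"),
        ("hsa-let-7a-1", "let-7a", "let-7"),
        ("mmu-mir-30b", "mir-30b", "mir-30"),
        ("dre-mir-100", "mir-100", "mir-100"),
        ("hsa-mir-30c-2", "mir-30c", "mir-30"),
        ("gga-mir-9-3p", "mir-9", "mir-9"),
    ],
)
def test_name_normalization(mirna_id, member, family):
    assert member_name(mirna_id) == member
    assert family_name(member_name(mirna_id)) == family


def test_shared_family_across_different_variants():
    shared = find_shared_families(
        {"sp1": ["sp1-let-7a"], "sp2": ["sp2-let-7b"]}
    )
    assert [f.family for f in shared] == ["let-7"]
    assert shared[0].member_names == {"let-7a", "let-7b"}


def test_family_absent_from_one_species_is_not_shared():
    assert find_shared_families({"sp1": ["sp1-mir-100"], "sp2": []}) == []


def test_planted_universal_families_recovered_exactly():
    """5 families planted in all 4 species, 3 in proper subsets: exactly 5 shared."""
    species = [f"sp{i}" for i in range(4)]
    universal = [f"mir-{i}" for i in range(1, 6)]
    partial = {"mir-10": species[:2], "mir-11": species[1:], "mir-12": species[:3]}
    per_species = {sp: [] for sp in species}
    for fam in universal:
        for sp in species:
            per_species[sp].append(f"{sp}-{fam}-5p")
    for fam, present in partial.items():
        for sp in present:
            per_species[sp].append(f"{sp}-{fam}-5p")
    # oracle: brute-force set intersection on planted names
    expected = set(universal)
    shared = find_shared_families(per_species)
    assert {f.family for f in shared} == expected


# ---------------------------------------------------------------------------
# alignment and core trimming

class TestAlignment:
    def test_identical_sequences_align_without_gaps(self):
        a, b, score = needleman_wunsch("ACGUACGU", "ACGUACGU")
        assert a == b == "ACGUACGU"
        assert score == 8.0

    def test_terminal_gaps_are_free(self):
        a, b, score = needleman_wunsch("ACGUACGU", "CGUACG")
        assert (a, b) == ("ACGUACGU", "-CGUACG-")
        assert score == 6.0

    def test_star_alignment_rows_equal_length(self):
        rows = star_align(
            {"hsa": "ACGUACGUA", "sp1": "ACGACGUA", "sp2": "ACGUACG"}, "hsa"
        )
        assert len({len(v) for v in rows.values()}) == 1
        assert rows["hsa"].replace("-", "") == "ACGUACGUA"

    def test_trim_core_noop_on_gapless(self):
        aln = AlignedFamily("f", "5p", {"hsa": "ACGU", "sp1": "ACGU"})
        assert trim_core(aln).rows == aln.rows

    def test_trim_core_strips_terminal_gap_columns(self):
        aln = AlignedFamily("f", "5p", {"hsa": "ACGU", "sp1": "-CGU"})
        assert trim_core(aln).rows == {"hsa": "CGU", "sp1": "CGU"}

    def test_trim_core_keeps_internal_gaps(self):
        aln = AlignedFamily("f", "5p", {"hsa": "ACGU", "sp1": "AC-U"})
        assert trim_core(aln).rows == aln.rows


# ---------------------------------------------------------------------------
# divergence profiling

class TestDivergence:
    def test_purine_purine_is_transition(self):
        aln = AlignedFamily("f", "5p", {"hsa": "A", "sp1": "G"})
        row = divergence_profile(aln).positions.iloc[0]
        assert row["transitions"] == 1 and row["transversions"] == 0

    def test_purine_pyrimidine_is_transversion(self):
        aln = AlignedFamily("f", "5p", {"hsa": "A", "sp1": "C"})
        row = divergence_profile(aln).positions.iloc[0]
        assert row["transversions"] == 1 and row["transitions"] == 0

    def test_identical_rows_have_zero_divergence(self):
        aln = AlignedFamily(
            "f", "5p", {"hsa": "ACGUACGU", "sp1": "ACGUACGU", "sp2": "ACGUACGU", "sp3": "ACGUACGU"}
        )
        prof = divergence_profile(aln)
        assert prof.positions[["transitions", "transversions", "indels"]].to_numpy().sum() == 0
        assert np.all(prof.substitution_rate == 0)

    def test_indel_counted_when_one_side_gapped(self):
        aln = AlignedFamily("f", "5p", {"hsa": "AC-U", "sp1": "ACGU"})
        df = divergence_profile(aln).positions
        assert df["indels"].sum() == 1
        assert df.loc[2, "n_compared"] == 1  # gap column still compared

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_substitution_counts_match_brute_force_scan(self, data):
        n_rows = data.draw(st.integers(min_value=2, max_value=5))
        L = data.draw(st.integers(min_value=4, max_value=15))
        alphabet = "ACGU-"
        rows = {}
        for i in range(n_rows):
            name = "hsa" if i == 0 else f"sp{i}"
            rows[name] = "".join(
                data.draw(st.sampled_from(alphabet)) for _ in range(L)
            )
        aln = AlignedFamily("f", "5p", rows)
        prof = divergence_profile(aln)
        counted = prof.positions[["transitions", "transversions"]].to_numpy().sum()
        assert counted == oracle_mismatches(rows, rows["hsa"])
        # per-position bound: events never exceed comparisons
        df = prof.positions
        assert (
            df["transitions"] + df["transversions"] + df["indels"] <= df["n_compared"]
        ).all()


# ---------------------------------------------------------------------------
# diversity statistics

class TestDiversity:
    def test_identical_population_is_monomorphic(self):
        st_ = diversity_stats(["ACGU" * 5] * 10, aligned=True)
        assert (st_.pi, st_.hd, st_.k) == (0.0, 0.0, 0.0)
        assert st_.pi_sd == 0.0 and st_.hd_sd == 0.0

    def test_two_haplotypes_hand_enumerated(self):
        # 4 sequences, two haplotypes at 2/4 each, differing at 3 of 20 sites:
        # 6 pairs, 4 cross pairs x 3 diffs -> k = 12/6 = 2.0; Hd = (4/3)(1-0.5)
        seqs = ["A" * 20, "A" * 20, "A" * 17 + "CCC", "A" * 17 + "CCC"]
        st_ = diversity_stats(seqs, aligned=True)
        oracle = oracle_diversity(seqs)
        assert st_.hd == pytest.approx(2 / 3)
        assert st_.k == pytest.approx(2.0)
        assert st_.k == pytest.approx(oracle["k"])
        assert st_.hd == pytest.approx(oracle["hd"])
        assert st_.pi == pytest.approx(oracle["pi"])

    def test_pi_times_length_equals_k_on_gapfree_core(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGU"), size=22)) for _ in range(6)]
        st_ = diversity_stats(seqs, aligned=True)
        assert st_.pi * st_.L == pytest.approx(st_.k)

    def test_hd_maximal_when_all_distinct_and_relabel_invariant(self):
        seqs = ["AAAA", "CCCC", "GGGG", "UUUU"]
        st_ = diversity_stats(seqs, aligned=True)
        n = 4
        assert st_.hd == pytest.approx((n / (n - 1)) * (1 - 1 / n))
        shuffled = diversity_stats(list(reversed(seqs)), aligned=True)
        assert shuffled.hd == st_.hd and shuffled.k == st_.k

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            diversity_stats(["ACGU"], aligned=True)

    def test_unaligned_input_is_aligned_and_trimmed_first(self):
        # terminal-length differences only: core identical -> zero diversity
        seqs = ["ACGUACGUACGUACGUA", "CGUACGUACGUACGUA", "ACGUACGUACGUACGU"]
        st_ = diversity_stats(seqs, aligned=False)
        assert st_.pi == 0.0 and st_.k == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_oracle_on_random_populations(self, data):
        n = data.draw(st.integers(min_value=2, max_value=8))
        L = data.draw(st.integers(min_value=3, max_value=12))
        seqs = [
            "".join(data.draw(st.sampled_from("ACGU")) for _ in range(L))
            for _ in range(n)
        ]
        st_ = diversity_stats(seqs, aligned=True)
        oracle = oracle_diversity(seqs)
        assert st_.k == pytest.approx(oracle["k"])
        assert st_.pi == pytest.approx(oracle["pi"])
        assert st_.hd == pytest.approx(oracle["hd"])
        assert 0.0 <= st_.pi <= 1.0 and 0.0 <= st_.hd <= 1.0


# ---------------------------------------------------------------------------
# missing-arm inference

def _human_pair():
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGU"), size=80))
    hp = HairpinRecord(id="hsa-mir-9", sequence=seq)
    mat = MatureRecord(id="hsa-mir-9-5p", sequence=seq[10:32], hairpin_ids=[hp.id])
    return hp, mat


class TestInferMissingArm:
    def test_identical_hairpin_recovers_human_mature(self):
        hp, mat = _human_pair()
        target = HairpinRecord(id="mmu-mir-9", sequence=hp.sequence)
        assert infer_missing_arm(target, hp, mat) == mat.sequence

    def test_single_substitution_is_carried(self):
        hp, mat = _human_pair()
        seq = list(hp.sequence)
        assert seq[20] != "A" or True
        seq[20] = {"A": "G", "G": "A", "C": "U", "U": "C"}[seq[20]]
        target = HairpinRecord(id="mmu-mir-9", sequence="".join(seq))
        predicted = infer_missing_arm(target, hp, mat)
        assert len(predicted) == len(mat.sequence)
        diffs = [i for i, (a, b) in enumerate(zip(predicted, mat.sequence)) if a != b]
        assert diffs == [10]  # hairpin position 20 is mature position 10

    def test_deleted_mature_window_fails(self):
        hp, mat = _human_pair()
        target = HairpinRecord(
            id="mmu-mir-9", sequence=hp.sequence[:10] + hp.sequence[32:]
        )
        with pytest.raises(ValueError, match="prediction failed"):
            infer_missing_arm(target, hp, mat)


# ---------------------------------------------------------------------------
# arm comparison statistics

def _profile_from_rows(rows, name="f", arm="5p"):
    return divergence_profile(AlignedFamily(name, arm, rows))


class TestArmCompare:
    def test_identical_profiles_are_null(self):
        profs = [
            _profile_from_rows({"hsa": "ACGUACGU", "sp1": "ACGUACGA", "sp2": "ACGUACGU"})
            for _ in range(5)
        ]
        res = arm_divergence_compare(profs, profs)
        assert res["wilcoxon_z"] == 0.0 and res["wilcoxon_p"] == 1.0
        assert res["spearman_rho"] == 1.0

    def test_shifted_rates_detected(self):
        rng = np.random.default_rng(17)
        profs5, profs3 = [], []
        for _ in range(20):
            base = "".join(rng.choice(list("ACGU"), size=22))
            mutate = lambda s, r: "".join(
                (c if rng.random() > r else rng.choice([x for x in "ACGU" if x != c]))
                for c in s
            )
            profs5.append(
                _profile_from_rows({"hsa": base, "sp1": mutate(base, 0.02), "sp2": mutate(base, 0.02)})
            )
            profs3.append(
                _profile_from_rows({"hsa": base, "sp1": mutate(base, 0.30), "sp2": mutate(base, 0.30)}, arm="3p")
            )
        res = arm_divergence_compare(profs5, profs3)
        assert res["wilcoxon_p"] < 0.05
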