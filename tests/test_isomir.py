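"""IsomiR extraction, RPM/percent normalization and dispersion summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from armiso.isomir import (
    IsomiRRecord,
    LocusProfile,
    ReadSet,
    assign_to_loci,
    build_locus_profile,
    dispersion_compare,
    extract_isomirs,
    locus_percentages,
    profile_summary,
    read_collapsed_fasta,
    read_collapsed_tsv,
    rpm,
)
from armiso.mirbase_io import HairpinRecord, MatureRecord


def _readset(reads, sample_id="s1", condition="control", **kw):
    return ReadSet(sample_id=sample_id, condition=condition, reads=reads, **kw)


class TestRpm:
    @pytest.mark.parametrize(
        "count, total, expected",
        [(500, 1_000_000, 500.0), (0, 123, 0.0), (3, 12, 250_000.0)],
    )
    def test_values(self, count, total, expected):
        assert rpm(count, total) == expected

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            rpm(1, 0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        count=st.integers(min_value=0, max_value=10**6),
        total=st.integers(min_value=1, max_value=10**7),
        scale=st.integers(min_value=1, max_value=50),
    )
    def test_linear_and_scale_invariant(self, count, total, scale):
        assert rpm(scale * count, total) == pytest.approx(scale * rpm(count, total))
        assert rpm(scale * count, scale * total) == pytest.approx(rpm(count, total))


class TestExtraction:
    def test_canonical_read_has_zero_offsets(self, simple_locus):
        hp, mat = simple_locus
        (rec,) = extract_isomirs(_readset([(mat.sequence, 10)]), hp, mat)
        assert (rec.offset5, rec.offset3, rec.tail3) == (0, 0, "")
        assert rec.is_canonical and rec.count == 10

    def test_templated_end_shifts(self, simple_locus):
        # drop the first nt, extend one templated nt at the 3' end
        hp, mat = simple_locus
        start0 = hp.sequence.find(mat.sequence)
        shifted = hp.sequence[start0 + 1 : start0 + len(mat.sequence) + 1]
        (rec,) = extract_isomirs(_readset([(shifted, 4)]), hp, mat)
        assert (rec.offset5, rec.offset3, rec.tail3) == (1, 1, "")

    def test_five_prime_extension_is_negative_offset(self, simple_locus):
        hp, mat = simple_locus
        start0 = hp.sequence.find(mat.sequence)
        extended = hp.sequence[start0 - 2 : start0 + len(mat.sequence)]
        (rec,) = extract_isomirs(_readset([(extended, 1)]), hp, mat)
        assert (rec.offset5, rec.offset3) == (-2, 0)

    def test_nontemplate_tail_detected(self, simple_locus):
        # hairpin continues with GU after the canonical end; "AA" is non-template
        hp, mat = simple_locus
        end0 = hp.sequence.find(mat.sequence) + len(mat.sequence)
        assert hp.sequence[end0 : end0 + 2] == "GU"
        # brute-force check that canonical+AA is nowhere templated
        assert (mat.sequence + "AA") not in hp.sequence
        (rec,) = extract_isomirs(_readset([(mat.sequence + "AA", 7)]), hp, mat)
        assert (rec.offset5, rec.offset3, rec.tail3) == (0, 0, "AA")

    def test_fully_templated_read_carries_no_tail(self, simple_locus):
        # the shortest-suffix rule must not strip templated 3' nucleotides
        hp, mat = simple_locus
        start0 = hp.sequence.find(mat.sequence)
        templated = hp.sequence[start0 : start0 + len(mat.sequence) + 2]
        (rec,) = extract_isomirs(_readset([(templated, 2)]), hp, mat)
        assert rec.tail3 == "" and rec.offset3 == 2

    def test_read_outside_window_ignored(self, simple_locus):
        hp, mat = simple_locus
        far = hp.sequence[40:62]
        assert extract_isomirs(_readset([(far, 5)]), hp, mat, window=5) == []

    def test_unmappable_read_ignored(self, simple_locus):
        hp, mat = simple_locus
        assert extract_isomirs(_readset([("UUUUAAAACCCCGGGGUUUUAA", 5)]), hp, mat) == []

    def test_order_independent_and_idempotent(self, simple_locus):
        hp, mat = simple_locus
        start0 = hp.sequence.find(mat.sequence)
        reads = [
            (mat.sequence, 10),
            (hp.sequence[start0 + 1 : start0 + 23], 5),
            (mat.sequence + "AA", 3),
        ]
        fwd = extract_isomirs(_readset(reads), hp, mat)
        rev = extract_isomirs(_readset(list(reversed(reads))), hp, mat)
        key = lambda recs: [(r.offset5, r.offset3, r.tail3, r.count) for r in recs]
        assert key(fwd) == key(rev)

    def test_counts_conserved_across_loci(self, simple_locus):
        """No read is lost or double-counted when several loci compete."""
        hp, mat = simple_locus
        other_mat = MatureRecord(
            id="hsa-mir-t1-3p", sequence=hp.sequence[44:66], hairpin_ids=[hp.id]
        )
        reads = [(mat.sequence, 10), (other_mat.sequence, 6), (mat.sequence + "AA", 2)]
        rs = _readset(reads)
        per_locus = assign_to_loci(rs, [(hp, mat), (hp, other_mat)])
        total_assigned = sum(r.count for recs in per_locus.values() for r in recs)
        assert total_assigned == 18


class TestPercentages:
    def test_simple_split(self):
        recs = [
            IsomiRRecord("l", "AAA", 0, 0, "", count=c) for c in (60, 30, 10)
        ]
        out = locus_percentages(recs)
        assert [r.percent for r in out] == [60.0, 30.0, 10.0]

    def test_single_isomir_is_everything(self):
        (rec,) = locus_percentages([IsomiRRecord("l", "AAA", 0, 0, "", count=5)])
        assert rec.percent == 100.0

    def test_thirds_sum_to_100(self):
        recs = [IsomiRRecord("l", "AAA", i, 0, "", count=1) for i in range(3)]
        out = locus_percentages(recs)
        assert all(r.percent == pytest.approx(100 / 3) for r in out)
        assert sum(r.percent for r in out) == pytest.approx(100.0)

    def test_zero_total_warns_and_empties(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            out = locus_percentages([IsomiRRecord("l", "AAA", 0, 0, "", count=0)])
        assert out == [] and "zero" in caplog.text


def _profile(percents_by_sample, locus="hsa-mir-t1-5p"):
    """Build a LocusProfile from {sample: {variant_key: percent}} (counts = percents)."""
    prof = LocusProfile(locus_id=locus)
    for sid, variants in percents_by_sample.items():
        recs = [
            IsomiRRecord(locus, "A" * 22, o5, o3, tail, count=int(round(pct * 10)), rpm=pct * 10)
            for (o5, o3, tail), pct in variants.items()
        ]
        prof.samples[sid] = locus_percentages(recs)
    return prof


class TestSummary:
    def test_single_sample_has_zero_sd(self):
        prof = _profile({"s1": {(0, 0, ""): 70, (1, 0, ""): 30}})
        summary = profile_summary(prof, min_samples=1)
        assert (summary["sd_percent"] == 0.0).all()

    def test_two_samples_hand_computed_sd(self):
        prof = _profile(
            {"s1": {(0, 0, ""): 40, (1, 0, ""): 60}, "s2": {(0, 0, ""): 60, (1, 0, ""): 40}}
        )
        summary = profile_summary(prof, min_samples=1)
        assert summary.loc["+0|+0|.", "mean_percent"] == pytest.approx(50.0)
        assert summary.loc["+0|+0|.", "sd_percent"] == pytest.approx(14.142, abs=1e-3)

    def test_rare_variants_pool_into_other(self):
        prof = _profile(
            {
                "s1": {(0, 0, ""): 90, (2, 1, "A"): 10},
                "s2": {(0, 0, ""): 95, (-1, 2, "G"): 5},
                "s3": {(0, 0, ""): 100},
            }
        )
        summary = profile_summary(prof, min_samples=2)
        assert "other" in summary.index
        assert summary.loc["other", "mean_percent"] == pytest.approx(5.0)

    def test_dominance_rank_follows_mean_percent(self):
        prof = _profile(
            {"s1": {(0, 0, ""): 70, (1, 0, ""): 20, (0, 1, ""): 10}},
        )
        summary = profile_summary(prof, min_samples=1)
        assert summary.loc["+0|+0|.", "rank"] == 1
        assert list(summary["rank"]) == sorted(summary["rank"])

    def test_min_rpm_filters_samples(self):
        prof = _profile({"s1": {(0, 0, ""): 70, (1, 0, ""): 30}})
        prof.samples["s2"] = [
            IsomiRRecord("hsa-mir-t1-5p", "A" * 22, 0, 0, "", count=1, rpm=0.01, percent=100.0)
        ]
        summary = profile_summary(prof, min_rpm=1.0, min_samples=1)
        assert summary.attrs["n_passing_samples"] == 1


class TestDispersion:
    def test_identical_groups_are_null(self):
        prof = _profile(
            {"s1": {(0, 0, ""): 70, (1, 0, ""): 30}, "s2": {(0, 0, ""): 60, (1, 0, ""): 40}}
        )
        res = dispersion_compare([prof], [prof])
        assert res["ranksum_p"] == 1.0
        assert res["disease"] == res["control"]

    def test_degenerate_single_isomir_loci_have_zero_sd(self):
        prof = _profile({"s1": {(0, 0, ""): 100}, "s2": {(0, 0, ""): 100}})
        res = dispersion_compare([prof], [prof])
        assert res["disease"]["median"] == 0.0 == res["control"]["median"]

    def test_single_sample_group_rejected(self):
        ok = _profile(
            {"s1": {(0, 0, ""): 70, (1, 0, ""): 30}, "s2": {(0, 0, ""): 50, (1, 0, ""): 50}}
        )
        bad = _profile({"s1": {(0, 0, ""): 70, (1, 0, ""): 30}})
        with pytest.raises(ValueError, match="<2 samples"):
            dispersion_compare([bad], [ok])


class TestIO:
    def test_collapsed_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "reads.tsv"
        path.write_text("UGAGGUAGUAGGUUGUAUAGUU\t12\nACGUACGUACGUACGUACGU\t3\n")
        rs = read_collapsed_tsv(path, "s1", "control")
        assert rs.total_mapped == 15
        assert rs.reads[0] == ("UGAGGUAGUAGGUUGUAUAGUU", 12)

    def test_collapsed_fasta_count_suffix(self, tmp_path):
        path = tmp_path / "reads.fa"
        path.write_text(">read1-count12\nUGAGGUAGUAGGUUGUAUAGUU\n")
        rs = read_collapsed_fasta(path, "s1", "disease")
        assert rs.reads == [("UGAGGUAGUAGGUUGUAUAGUU", 12)]

    def test_bad_condition_rejected(self):
        with pytest.raises(ValueError, match="condition"):
            _readset([("ACGU", 1)], condition="tumour")


def test_profile_percents_always_sum_to_100(simple_locus, tiny_cfg):
    """Within-sample locus percents sum to 100 on generator output (locus total > 0)."""
    from armiso.synthetic import generate_isomir_readsets

    hp, mat = simple_locus
    sim = generate_isomir_readsets(tiny_cfg, [(hp, mat)])
    profile = build_locus_profile(sim.readsets, hp, mat)
    for sid, recs in profile.samples.items():
        if recs:
            assert sum(r.percent for r in recs) == pytest.approx(100.0), sid
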