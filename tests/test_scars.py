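import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_seq
from oracle_utils import mh_by_enumeration, poisson_tail, rc
from polq_scars.pipeline import EventGroup
from polq_scars.scars import (
    EXCLUDED,
    DeletionCall,
    NoiseModel,
    OriginHit,
    call_tmej,
    classify_deletions,
    classify_insertion_origin,
    classify_insertions,
    classify_short_insertion,
    deletion_microhomology,
    estimate_background,
    filter_noise,
    insertion_mh_flags,
    poisson_cutoff,
    summarize_assay,
)


def del_group(start, end, count=1):
    return EventGroup(key=("del", start, end), kind="del", count=count)


def ins_group(pos, seq, count=1):
    return EventGroup(key=("ins", pos, len(seq), seq), kind="ins", count=count)


class TestDeletionMicrohomology:
    def test_example_mh3(self):
        assert deletion_microhomology("GGATCAATCGG", 4, 7) == 3

    def test_no_flanking_identity(self):
        assert deletion_microhomology("AACCGGTT", 3, 6) == 0

    def test_homopolymer(self):
        assert deletion_microhomology("AAAAAA", 2, 3) == 4

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            deletion_microhomology("ACGT", 2, 9)

    @given(data=st.data())
    @settings(max_examples=300, deadline=None)
    def test_matches_placement_enumeration(self, data):
        seq = data.draw(st.text(alphabet="ACGT", min_size=4, max_size=60))
        start = data.draw(st.integers(1, len(seq)))
        end = data.draw(st.integers(start, len(seq)))
        assert deletion_microhomology(seq, start, end) == mh_by_enumeration(
            seq, start, end
        )


class TestCallTmej:
    @pytest.mark.parametrize(
        "mh,expected", [(2, False), (3, True), (4, True), (6, True), (7, False), (0, False)]
    )
    def test_default_window(self, mh, expected):
        assert call_tmej(mh) is expected

    def test_distal_window(self):
        # distal analysis tabulates 0-4
        assert call_tmej(4, window=(0, 4))
        assert not call_tmej(5, window=(0, 4))

    def test_classify_deletions(self):
        ref = "GGATCAATCGG"
        calls = classify_deletions([del_group(4, 7, count=3)], ref)
        assert calls[0].mh_length == 3 and calls[0].tmej

    def test_negative_mh_rejected(self):
        with pytest.raises(ValueError):
            DeletionCall(group=del_group(1, 2), mh_length=-1, tmej=False)


class TestBackgroundEstimate:
    def test_all_ones(self):
        assert estimate_background([del_group(1, 2, 1)] * 4) == 1.0

    def test_median_trimmed(self):
        groups = [del_group(i, i + 1, c) for i, c in enumerate([1, 1, 1, 1, 1000], 1)]
        assert estimate_background(groups) == 1.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            estimate_background([])

    def test_mean_strategy(self):
        groups = [del_group(1, 2, 2), del_group(5, 6, 4)]
        assert estimate_background(groups, strategy="mean") == 3.0


class TestPoissonCutoff:
    def test_lambda_zero(self):
        assert poisson_cutoff(0.0, 0.99) == 1

    def test_lambda1_level99(self):
        assert poisson_cutoff(1.0, 0.99) == 5
        assert poisson_tail(1.0, 5) <= 0.01 < poisson_tail(1.0, 4)

    def test_lambda3_level95(self):
        assert poisson_cutoff(3.0, 0.95) == 7
        assert poisson_tail(3.0, 7) <= 0.05 < poisson_tail(3.0, 6)

    def test_matches_tail_oracle(self):
        for lam in (0.5, 1.0, 2.0, 3.5, 8.0):
            for level in (0.90, 0.95, 0.99):
                c = poisson_cutoff(lam, level)
                assert poisson_tail(lam, c) <= 1 - level
                assert c == 1 or poisson_tail(lam, c - 1) > 1 - level

    @given(
        lam=st.floats(0.0, 20.0),
        lv1=st.sampled_from([0.90, 0.95, 0.99]),
        lv2=st.sampled_from([0.90, 0.95, 0.99]),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_level(self, lam, lv1, lv2):
        if lv1 <= lv2:
            assert poisson_cutoff(lam, lv1) <= poisson_cutoff(lam, lv2)

    @given(
        lam1=st.floats(0.0, 20.0), lam2=st.floats(0.0, 20.0),
        level=st.sampled_from([0.90, 0.95, 0.99]),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_lambda(self, lam1, lam2, level):
        if lam1 <= lam2:
            assert poisson_cutoff(lam1, level) <= poisson_cutoff(lam2, level)

    def test_errors(self):
        with pytest.raises(ValueError):
            poisson_cutoff(-1.0, 0.95)
        with pytest.raises(ValueError):
            poisson_cutoff(1.0, 1.5)
        with pytest.raises(ValueError):
            NoiseModel(lam=1.0, level=0.95, cutoff=0)


class TestFilterNoise:
    def test_split(self):
        groups = [del_group(i, i + 1, 1) for i in range(1, 30, 2)] + [
            del_group(100, 110, 50)
        ]
        kept, noise, model = filter_noise(groups, level=0.99)
        assert model.lam == 1.0 and model.cutoff == 5
        assert [g.count for g in kept] == [50]
        assert len(noise) == len(groups) - 1

    def test_counts_conserved(self):
        groups = [del_group(i, i + 1, i) for i in range(1, 10)]
        kept, noise, _ = filter_noise(groups, level=0.95)
        assert sum(g.count for g in kept) + sum(g.count for g in noise) == sum(
            g.count for g in groups
        )


def _primary(seq):
    return ("amp", seq)


class TestOriginClassification:
    def test_direct_repeat_left_flank(self, rng):
        seq = random_seq(rng, 400)
        jp = 200
        ins = seq[jp - 6 : jp]
        cls, cands = classify_insertion_origin(ins, jp, _primary(seq))
        assert cls == "direct_repeat"
        assert cands[0].end == jp

    def test_snapback_upstream_revcomp(self, rng):
        while True:
            seq = random_seq(rng, 400)
            jp = 200
            ins = rc(seq[jp - 50 : jp - 42])  # 8-mer upstream, reverse complement
            if seq.count(ins) == 0 and seq.count(rc(ins)) == 1:
                break
        cls, cands = classify_insertion_origin(ins, jp, _primary(seq))
        assert cls == "snapback"
        assert cands[0].strand == "-"

    def test_random_absent(self, rng):
        seq = random_seq(rng, 300)
        ins = "TTAACCGGTTAA"
        while ins in seq or rc(ins) in seq:
            seq = random_seq(rng, 300)
        cls, cands = classify_insertion_origin(ins, 150, _primary(seq))
        assert cls == "random" and cands == []

    def test_nearby_vs_distant_window(self, rng):
        seq = random_seq(rng, 1000)
        jp = 500
        probe = seq[550:560]  # 50 bp downstream: nearby
        if seq.count(probe) == 1 and rc(probe) not in seq:
            cls, _ = classify_insertion_origin(probe, jp, _primary(seq))
            assert cls == "nearby"
        probe_far = seq[850:860]  # 350 bp downstream: distant
        if seq.count(probe_far) == 1 and rc(probe_far) not in seq:
            cls, _ = classify_insertion_origin(probe_far, jp, _primary(seq))
            assert cls == "distant"

    def test_ambiguous_excluded(self, rng):
        core = random_seq(rng, 12)
        seq = random_seq(rng, 200) + core + random_seq(rng, 300) + core + random_seq(rng, 200)
        jp = 100
        if seq.count(core) == 2 and rc(core) not in seq:
            cls, cands = classify_insertion_origin(core, jp, _primary(seq))
            assert cls == EXCLUDED and len(cands) == 2

    def test_extra_refs_are_distant(self, rng):
        seq = random_seq(rng, 300)
        other = random_seq(rng, 300)
        ins = other[100:112]
        if ins not in seq and rc(ins) not in seq and other.count(ins) == 1:
            cls, cands = classify_insertion_origin(
                ins, 150, _primary(seq), extra_refs=[("genome", other)]
            )
            assert cls == "distant" and cands[0].ref_name == "genome"

    def test_length_bounds_enforced(self, rng):
        seq = random_seq(rng, 100)
        with pytest.raises(ValueError):
            classify_insertion_origin("ACG", 50, _primary(seq))

    def test_totality_five_way(self, rng):
        seq = random_seq(rng, 600)
        allowed = {"distant", "nearby", "snapback", "direct_repeat", "random", EXCLUDED}
        for _ in range(50):
            length = int(rng.integers(5, 16))
            ins = random_seq(rng, length)
            cls, _ = classify_insertion_origin(ins, 300, _primary(seq))
            assert cls in allowed


class TestShortInsertion:
    def test_single_base_undetermined(self):
        assert classify_short_insertion("T", 50, "ACGT" * 50) == "undetermined"

    def test_template_match(self, rng):
        seq = random_seq(rng, 300)
        ins = seq[120:128]
        if seq.count(ins) == 1 and rc(ins) not in seq:
            assert classify_short_insertion(ins, 150, seq) == "template"

    def test_snapback_match(self, rng):
        while True:
            seq = random_seq(rng, 300)
            ins = rc(seq[120:128])
            if ins not in seq and seq.count(rc(ins)) == 1:
                break
        assert classify_short_insertion(ins, 150, seq) == "snapback"

    def test_undetermined(self, rng):
        seq = random_seq(rng, 300)
        ins = "TTAACCGG"
        while ins in seq or rc(ins) in seq:
            seq = random_seq(rng, 300)
        assert classify_short_insertion(ins, 150, seq) == "undetermined"

    def test_window_limits_search(self, rng):
        seq = random_seq(rng, 1000)
        ins = seq[20:28]  # far upstream of the junction
        if seq.count(ins) == 1 and rc(ins) not in seq:
            assert classify_short_insertion(ins, 500, seq, flank_window=50) == "undetermined"


class TestInsertionMhFlags:
    def _setup(self, rng, mh_init, mh_end, length=10):
        """Engineer a construct with a distant origin with known MH geometry."""
        while True:
            s = list(random_seq(rng, 800))
            jp = 400
            origin = 650
            if mh_init:
                s[origin - 1 - mh_init : origin - 1] = s[jp - mh_init : jp]
            ins = "".join(s[origin - 1 : origin - 1 + length])
            if mh_end:
                ins = ins[:-mh_end] + "".join(s[jp : jp + mh_end])
                s[origin - 1 : origin - 1 + length] = list(ins)
            seq = "".join(s)
            ins = seq[origin - 1 : origin - 1 + length]
            hit = OriginHit("amp", "+", origin, origin + length - 1)
            init, end = insertion_mh_flags(
                ins, jp, hit, {"amp": seq}, "amp", min_mh=1, max_mh=6
            )
            if init == mh_init and end == mh_end:
                return ins, jp, hit, seq

    def test_planted_init_3(self, rng):
        ins, jp, hit, seq = self._setup(rng, mh_init=3, mh_end=0)
        init, end = insertion_mh_flags(ins, jp, hit, {"amp": seq}, "amp")
        assert (init, end) == (3, 0)

    def test_no_flanking_identity(self, rng):
        ins, jp, hit, seq = self._setup(rng, mh_init=0, mh_end=0)
        assert insertion_mh_flags(ins, jp, hit, {"amp": seq}, "amp") == (0, 0)

    def test_planted_both_2(self, rng):
        ins, jp, hit, seq = self._setup(rng, mh_init=2, mh_end=2)
        assert insertion_mh_flags(ins, jp, hit, {"amp": seq}, "amp") == (2, 2)

    def test_below_minimum_reports_zero(self, rng):
        ins, jp, hit, seq = self._setup(rng, mh_init=1, mh_end=0)
        init, _ = insertion_mh_flags(ins, jp, hit, {"amp": seq}, "amp", min_mh=2)
        assert init == 0

    def test_reverse_orientation(self, rng):
        # snapback-style: template is the bottom strand
        while True:
            s = list(random_seq(rng, 600))
            jp, origin, length, k = 300, 450, 8, 3
            # bases 5' of the copy on the bottom strand are revcomp of the
            # forward bases just AFTER the segment
            s[origin + length - 1 : origin + length - 1 + k] = list(
                rc("".join(s[jp - k : jp]))
            )
            seq = "".join(s)
            ins = rc(seq[origin - 1 : origin - 1 + length])
            hit = OriginHit("amp", "-", origin, origin + length - 1)
            init, _ = insertion_mh_flags(ins, jp, hit, {"amp": seq}, "amp")
            if init == k:
                break
        assert init == 3


class TestSummarize:
    def test_all_precise(self):
        out = summarize_assay(100, [], [], assay="proximal")
        assert out["precise_pct"] == 100.0
        assert out["total_reads"] == 100

    def test_percentages_conserve(self, rng):
        ref = "GGATCAATCGG" + random_seq(rng, 100)
        dels = classify_deletions([del_group(4, 7, 10)], ref)
        inss = classify_insertions([ins_group(50, "TTAAC", 5)], ("amp", ref))
        out = summarize_assay(85, dels, inss)
        assert out["total_reads"] == 100
        total_pct = out["precise_pct"] + out["deletion_pct"] + out["insertion_pct"]
        assert total_pct == pytest.approx(100.0)
        assert sum(out["deletions_by_mh_pct"].values()) == pytest.approx(
            out["deletion_pct"]
        )
        assert sum(out["insertions_by_length_pct"].values()) == pytest.approx(
            out["insertion_pct"]
        )
        assert sum(out["origin_composition_pct"].values()) == pytest.approx(100.0)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            summarize_assay(0, [], [])

    def test_bad_assay(self):
        with pytest.raises(ValueError):
            summarize_assay(1, [], [], assay="medial")

    def test_hotspot_notation(self, rng):
        ref = random_seq(rng, 300)
        inss = classify_insertions([ins_group(261, "TTAAC", 5)], ("amp", ref))
        out = summarize_assay(0, [], inss)
        assert "262:261" in out["insertion_hotspots_pct"]
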