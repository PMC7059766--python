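import math

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctfrag.extract import extract_typed_fragments
from ctfrag.simulate import (MAX_FRAG_LEN, MIN_FRAG_LEN, DropletSimSpec,
                             LengthModel, LocusSimSpec, SimulationError,
                             fragments_to_sam, make_reference,
                             simulate_droplets, simulate_fragments)


class TestLengthModel:
    def test_point_mass_is_exact(self):
        rng = np.random.default_rng(0)
        draw = LengthModel.point(167).sample(200, rng)
        assert (draw == 167).all()

    @settings(max_examples=30, derandomize=True)
    @given(mean=st.floats(80, 400), sd=st.floats(1, 60))
    def test_discrete_normal_support_is_bounded_integer(self, mean, sd):
        rng = np.random.default_rng(7)
        draw = LengthModel.discrete_normal(mean, sd).sample(500, rng)
        assert draw.dtype.kind == "i"
        assert draw.min() >= MIN_FRAG_LEN and draw.max() <= MAX_FRAG_LEN

    def test_mixture_samples_all_components(self):
        model = LengthModel.mixture(
            [LengthModel.point(146), LengthModel.point(191)], [0.4, 0.6])
        draw = model.sample(2000, np.random.default_rng(3))
        assert set(np.unique(draw)) == {146, 191}
        assert abs((draw == 191).mean() - 0.6) < 0.05

    @pytest.mark.parametrize("weights", [[0.5, 0.6], [-0.1, 1.1], [0.9]])
    def test_bad_mixture_weights_rejected(self, weights):
        comps = [LengthModel.point(146), LengthModel.point(191)][: len(weights)]
        with pytest.raises(SimulationError):
            LengthModel.mixture(comps, weights)


class TestSimulateFragments:
    def test_deterministic_assignment_hits_exact_count(self, hotspot):
        spec = LocusSimSpec(hotspot=hotspot, true_maf=0.5, n_templates=1000,
                            mutant_model=LengthModel.point(146), seed=1)
        frags = simulate_fragments(spec)
        assert len(frags) == 1000
        assert (frags["allele"] == "mutant").sum() == 500

    def test_point_wild_model_gives_constant_lengths(self, hotspot):
        spec = LocusSimSpec(hotspot=hotspot, true_maf=0.0, n_templates=200,
                            wild_model=LengthModel.point(167), seed=2)
        frags = simulate_fragments(spec)
        assert (frags["length"] == 167).all()

    def test_same_seed_reproduces_byte_identical_table(self, hotspot):
        spec = LocusSimSpec(hotspot=hotspot, true_maf=0.2, n_templates=500,
                            mutant_model=LengthModel.point(146), seed=9)
        a = simulate_fragments(spec).to_csv(sep="\t")
        b = simulate_fragments(spec).to_csv(sep="\t")
        assert a == b

    def test_every_fragment_spans_the_hotspot(self, hotspot):
        spec = LocusSimSpec(hotspot=hotspot, true_maf=0.3, n_templates=800,
                            mutant_model=LengthModel.discrete_normal(150, 20),
                            seed=5)
        frags = simulate_fragments(spec)
        pos0 = hotspot.pos0
        assert (frags["start"] <= pos0).all()
        assert (frags["start"] + frags["length"] > pos0).all()

    def test_binomial_assignment_maf_within_4_se(self, hotspot):
        n, maf = 4000, 0.1
        spec = LocusSimSpec(hotspot=hotspot, true_maf=maf, n_templates=n,
                            mutant_model=LengthModel.point(146),
                            allele_assignment="binomial", seed=17)
        frags = simulate_fragments(spec)
        se = math.sqrt(maf * (1 - maf) / n)
        assert abs((frags["allele"] == "mutant").mean() - maf) <= 4 * se

    def test_missing_mutant_model_with_positive_maf_is_an_error(self, hotspot):
        with pytest.raises(SimulationError, match="mutant_model"):
            LocusSimSpec(hotspot=hotspot, true_maf=0.1, n_templates=10)


class TestSamWriting:
    def test_tlen_sign_and_pos_follow_sam_conventions(self, hotspot, tmp_path):
        spec = LocusSimSpec(hotspot=hotspot, true_maf=0.0, n_templates=3,
                            wild_model=LengthModel.point(167), seed=4)
        frags = simulate_fragments(spec)
        sam = tmp_path / "t.sam"
        fragments_to_sam(frags, hotspot, sam_path=sam)
        with pysam.AlignmentFile(str(sam)) as af:
            recs = list(af.fetch(until_eof=True))
        assert len(recs) == 6
        by_name = {}
        for r in recs:
            by_name.setdefault(r.query_name, []).append(r)
        for i, (name, pair) in enumerate(sorted(by_name.items())):
            left = min(pair, key=lambda r: r.reference_start)
            start = int(frags.iloc[i]["start"])
            assert left.reference_start == start  # SAM POS is start+1, 1-based
            assert left.template_length == 167
            assert {r.template_length for r in pair} == {167, -167}
            assert all(r.is_proper_pair and r.is_paired for r in pair)

    def test_mutant_mates_carry_alt_base_at_walked_offset(self, hotspot, tmp_path):
        # 3-fragment fixture; offsets hand-computed as pos0 - reference_start
        spec = LocusSimSpec(hotspot=hotspot, true_maf=1.0, n_templates=3,
                            mutant_model=LengthModel.point(180), seed=6)
        frags = simulate_fragments(spec)
        sam = tmp_path / "m.sam"
        ref = fragments_to_sam(frags, hotspot, sam_path=sam)
        assert ref[hotspot.pos0] == hotspot.ref_base
        with pysam.AlignmentFile(str(sam)) as af:
            for rec in af.fetch(until_eof=True):
                assert rec.cigarstring == f"{rec.query_length}M"
                if rec.reference_start <= hotspot.pos0 < rec.reference_end:
                    off = hotspot.pos0 - rec.reference_start
                    assert rec.query_sequence[off] == hotspot.alt_base
                    assert rec.get_tag("NM") == 1

    def test_round_trip_recovers_point_146_lengths(self, hotspot, simulate_to_sam):
        spec = LocusSimSpec(hotspot=hotspot, true_maf=1.0, n_templates=50,
                            mutant_model=LengthModel.point(146), seed=8)
        sam, _ = simulate_to_sam(spec)
        typed = extract_typed_fragments(sam, hotspot)
        assert len(typed) == 50
        assert all(t.allele == "mutant" and t.length == 146 for t in typed)

    def test_fragment_outside_reference_is_an_error(self, hotspot):
        spec = LocusSimSpec(hotspot=hotspot, true_maf=0.0, n_templates=5,
                            wild_model=LengthModel.point(400), seed=1)
        frags = simulate_fragments(spec)
        # covers the hotspot (pos0=599) but not fragment ends near 999
        short_ref = make_reference(hotspot, span_end=650, seed=0)
        with pytest.raises(SimulationError, match="outside reference"):
            fragments_to_sam(frags, hotspot, sam_path="/dev/null",
                             reference=short_ref)


class TestSimulateDroplets:
    def test_zero_rate_channel_has_no_positives(self):
        counts = simulate_droplets(DropletSimSpec(
            n_droplets=5000, lambda_mut=0.0, lambda_wt=0.5, seed=1))
        assert counts.n_mut_pos == 0

    def test_huge_rate_saturates_channel(self):
        counts = simulate_droplets(DropletSimSpec(
            n_droplets=5000, lambda_mut=0.1, lambda_wt=50.0, seed=2))
        assert counts.n_wt_pos == 5000

    def test_occupancy_matches_closed_form_within_3_se(self):
        n = 10**6
        counts = simulate_droplets(DropletSimSpec(
            n_droplets=n, lambda_mut=0.0, lambda_wt=1.0, seed=3))
        p = 1 - math.exp(-1.0)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(counts.n_wt_pos / n - p) <= 3 * se

    def test_seeded_determinism(self):
        spec = DropletSimSpec(n_droplets=10000, lambda_mut=0.2,
                              lambda_wt=0.4, seed=11)
        assert simulate_droplets(spec) == simulate_droplets(spec)

    @pytest.mark.parametrize("bad", [dict(lambda_mut=-0.1),
                                     dict(lambda_wt=float("inf")),
                                     dict(n_droplets=0)])
    def test_invalid_specs_rejected(self, bad):
        kwargs = dict(n_droplets=100, lambda_mut=0.1, lambda_wt=0.1, seed=0)
        kwargs.update(bad)
        with pytest.raises(SimulationError):
            DropletSimSpec(**kwargs)
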