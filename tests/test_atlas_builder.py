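import numpy as np
import pytest

from swmclust.atlas_builder import (
    Atlas,
    Bundle,
    bagging_aggregate,
    bundle_centroid,
    fuse_bundles,
    interhemispheric_match,
    load_atlas,
    match_groups,
    reflect_bundle,
    save_atlas,
    symmetrize_atlas,
)
from swmclust.fiber_metrics import d_me, intersection_fractions, pairwise_d_me
from swmclust.tract_io import resample_fiber

from conftest import random_fiber, straight_fiber


def make_bundle(bid, base, n=6, jitter=0.5, rng=None, hemisphere="left"):
    rng = rng or np.random.default_rng(0)
    fibers = [
        (f"s{k}", base + rng.normal(0, jitter, size=3)) for k in range(n)
    ]
    return Bundle(id=bid, fibers=fibers, hemisphere=hemisphere)


def arc(center_y, x=-40.0):
    return resample_fiber(
        straight_fiber([x, center_y - 20.0, 0], [x, center_y + 20.0, 0]), 51
    )


class TestMatchGroups:
    def test_identical_atlases_match_perfectly(self, rng):
        bundles = [make_bundle(f"b{k}", arc(80.0 * k), rng=rng) for k in range(3)]
        a1 = Atlas(bundles=bundles)
        copy = [make_bundle(f"c{k}", arc(80.0 * k), rng=np.random.default_rng(0)) for k in range(3)]
        a2 = Atlas(bundles=copy)
        matches = match_groups(a1, a2)
        assert len(matches) == 3
        for id1, id2, f1, f2 in matches:
            assert id1[1:] == id2[1:]
            assert f1 == 1.0 and f2 == 1.0

    def test_disjoint_atlases_do_not_match(self, rng):
        a1 = Atlas(bundles=[make_bundle("b0", arc(0.0), rng=rng)])
        a2 = Atlas(bundles=[make_bundle("c0", arc(500.0), rng=rng)])
        assert match_groups(a1, a2) == []

    def test_overlap_threshold_boundary(self):
        # bundle of 10 fibers vs a copy sharing 6 (60% -> match) or 4 (40% -> no)
        shared = [arc(8.0 * k) for k in range(10)]
        far = [arc(1000.0 + 50.0 * k) for k in range(10)]
        b_all = Bundle("a", [(f"s{k}", f) for k, f in enumerate(shared)])
        b60 = Bundle(
            "m", [(f"t{k}", f.copy()) for k, f in enumerate(shared[:6] + far[:4])]
        )
        b40 = Bundle(
            "n", [(f"t{k}", f.copy()) for k, f in enumerate(shared[:4] + far[:6])]
        )
        assert match_groups(Atlas(bundles=[b_all]), Atlas(bundles=[b60])) != []
        assert match_groups(Atlas(bundles=[b_all]), Atlas(bundles=[b40])) == []

    def test_symmetric_in_arguments(self, rng):
        a1 = Atlas(bundles=[make_bundle(f"b{k}", arc(60.0 * k), rng=rng) for k in range(3)])
        a2 = Atlas(
            bundles=[make_bundle(f"c{k}", arc(60.0 * k + 1.0), rng=rng) for k in range(3)]
        )
        m12 = {(x, y) for x, y, _, _ in match_groups(a1, a2)}
        m21 = {(y, x) for x, y, _, _ in match_groups(a2, a1)}
        assert m12 == m21


class TestFuseBundles:
    def test_fiber_count_doubles_on_self_fusion(self, rng):
        b = make_bundle("b", arc(0.0), rng=rng)
        fused = fuse_bundles(b, b)
        assert len(fused) == 2 * len(b)

    def test_fused_fully_intersects_parents(self, rng):
        b1 = make_bundle("b1", arc(0.0), rng=rng)
        b2 = make_bundle("b2", arc(2.0), rng=rng)
        fused = fuse_bundles(b1, b2)
        f_parent, _ = intersection_fractions(b1, fused)
        assert f_parent == 1.0

    def test_subject_union(self, rng):
        b1 = Bundle("b1", [("s1", arc(0.0)), ("s2", arc(1.0))])
        b2 = Bundle("b2", [("s2", arc(0.5)), ("s3", arc(1.5))])
        assert fuse_bundles(b1, b2).subjects() == {"s1", "s2", "s3"}


class TestBundleCentroid:
    def test_single_fiber_is_its_own_centroid(self, rng):
        f = resample_fiber(random_fiber(rng), 51)
        b = Bundle("b", [("s", f)])
        assert np.allclose(bundle_centroid(b), f, atol=1e-9)

    def test_reversal_alignment(self, rng):
        f = resample_fiber(random_fiber(rng), 51)
        b = Bundle("b", [("s1", f), ("s2", f[::-1].copy())])
        assert d_me(bundle_centroid(b), f) == pytest.approx(0.0, abs=1e-9)

    def test_mean_of_parallel_offset(self):
        f = resample_fiber(straight_fiber([0, 0, 0], [0, 50, 0]), 51)
        b = Bundle("b", [("s1", f), ("s2", f + [0, 0, 2.0])])
        c = bundle_centroid(b)
        assert np.allclose(c, f + [0, 0, 1.0], atol=1e-9)


class TestBagging:
    def _repetitions(self, present_in, rng):
        """10 repetitions; template k's bundle appears in present_in[k] of them."""
        reps = []
        for rep in range(10):
            bundles = []
            for k, count in enumerate(present_in):
                if rep < count:
                    bundles.append(
                        make_bundle(f"r{rep}b{k}", arc(100.0 * k), rng=rng)
                    )
            if bundles:
                reps.append(Atlas(bundles=bundles, provenance=[f"rep{rep}"]))
            else:
                reps.append(Atlas(bundles=[], provenance=[f"rep{rep}"]))
        return reps

    def test_vote_rule_10_8_7(self, rng):
        # A in 10/10 kept, B in 8/10 kept, C in 7/10 dropped
        final = bagging_aggregate(self._repetitions([10, 8, 7], rng), min_votes=8)
        votes = sorted(b.votes for b in final.bundles)
        assert votes == [8, 10]

    def test_unanimous_bundle_kept_with_full_votes(self, rng):
        final = bagging_aggregate(self._repetitions([10], rng), min_votes=8)
        assert len(final) == 1
        assert final.bundles[0].votes == 10

    def test_identity_limit_single_repetition(self, rng):
        rep = Atlas(
            bundles=[make_bundle(f"b{k}", arc(100.0 * k), rng=rng) for k in range(3)]
        )
        final = bagging_aggregate([rep], min_votes=1)
        assert len(final) == 3
        got = sorted(
            frozenset(map(tuple, np.round(np.mean(b.fiber_arrays(), axis=1), 3)))
            for b in final.bundles
        )
        exp = sorted(
            frozenset(map(tuple, np.round(np.mean(b.fiber_arrays(), axis=1), 3)))
            for b in rep.bundles
        )
        assert got == exp

    def test_planted_template_recovery(self, rng):
        # templates in all 10 reps survive; per-rep unique distractors do not
        reps = []
        for rep in range(10):
            bundles = [
                make_bundle(f"r{rep}t{k}", arc(100.0 * k), jitter=1.0, rng=rng)
                for k in range(4)
            ]
            bundles.append(
                make_bundle(f"r{rep}d", arc(2000.0 + 300.0 * rep), rng=rng)
            )
            reps.append(Atlas(bundles=bundles))
        final = bagging_aggregate(reps, min_votes=8)
        assert len(final) == 4
        assert all(b.votes == 10 for b in final.bundles)

    def test_too_few_repetitions_rejected(self, rng):
        with pytest.raises(ValueError):
            bagging_aggregate([Atlas(bundles=[])] * 3, min_votes=8)


class TestInterhemispheric:
    def test_mirror_atlas_full_correspondence(self, rng):
        left = Atlas(
            bundles=[make_bundle(f"l{k}", arc(80.0 * k), rng=rng) for k in range(3)]
        )
        right = Atlas(
            bundles=[
                reflect_bundle(b)
                for b in [make_bundle(f"r{k}", arc(80.0 * k), rng=rng) for k in range(3)]
            ]
        )
        corr = interhemispheric_match(left, right)
        assert len(corr) == 3

    def test_left_only_bundle_unmatched(self, rng):
        left = Atlas(bundles=[make_bundle("l0", arc(0.0), rng=rng),
                              make_bundle("l1", arc(400.0), rng=rng)])
        right = Atlas(bundles=[reflect_bundle(make_bundle("r0", arc(0.0), rng=rng))])
        corr = interhemispheric_match(left, right)
        assert [c[0] for c in corr] == ["l0"]

    def test_jittered_mirror_still_corresponds(self, rng):
        left = Atlas(bundles=[make_bundle("l0", arc(0.0), rng=rng)])
        jittered = make_bundle("r0", arc(0.0) + rng.normal(0, 1.0 / 3, 3), rng=rng)
        right = Atlas(bundles=[reflect_bundle(jittered)])
        assert len(interhemispheric_match(left, right)) == 1


class TestSymmetrize:
    def _pair(self, rng):
        left = Atlas(bundles=[make_bundle("l0", arc(0.0), rng=rng)])
        right = Atlas(bundles=[reflect_bundle(make_bundle("r0", arc(1.0), rng=rng))])
        return left, right

    def test_right_is_exact_reflection_of_left(self, rng):
        left, right = self._pair(rng)
        corr = interhemispheric_match(left, right)
        sym = symmetrize_atlas(left, right, corr)
        sym_l = sym.get("l0_sym_l")
        sym_r = sym.get("l0_sym_r")
        back = reflect_bundle(sym_r)
        for (_, a), (_, b) in zip(sym_l.fibers, back.fibers):
            assert np.array_equal(a, b)

    def test_common_pair_yields_one_bundle_per_hemisphere(self, rng):
        left, right = self._pair(rng)
        corr = interhemispheric_match(left, right)
        sym = symmetrize_atlas(left, right, corr)
        assert len(sym) == 2
        assert {b.hemisphere for b in sym.bundles} == {"left", "right"}

    def test_reflection_preserves_internal_distances(self, rng):
        left, right = self._pair(rng)
        corr = interhemispheric_match(left, right)
        sym = symmetrize_atlas(left, right, corr)
        dl = pairwise_d_me(sym.get("l0_sym_l").fiber_arrays())
        dr = pairwise_d_me(sym.get("l0_sym_r").fiber_arrays())
        assert np.allclose(dl, dr, atol=1e-9)


class TestAtlasIO:
    def test_save_load_round_trip(self, tmp_path, rng):
        bundles = [
            Bundle(
                id=f"b{k}",
                fibers=[(f"s{i}", resample_fiber(random_fiber(rng), 51)) for i in range(3)],
                hemisphere="left",
                label=f"SF_SF_{k}l",
                votes=9,
            )
            for k in range(2)
        ]
        atlas = Atlas(bundles=bundles, space="template", provenance=["test"])
        save_atlas(atlas, tmp_path / "atlas")
        back = load_atlas(tmp_path / "atlas")
        assert len(back) == 2
        for b in atlas.bundles:
            rb = back.get(b.id)
            assert rb.label == b.label and rb.votes == b.votes
            for (s1, f1), (s2, f2) in zip(b.fibers, rb.fibers):
                assert s1 == s2
                assert np.allclose(f1, f2, atol=1e-4)
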