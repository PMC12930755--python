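import numpy as np
import pytest

from msq import (
    MarkerEffectSet,
    PhasedHaplotypes,
    build_all_R,
    enumerate_gametes,
    gametic_msq,
    genotype_codes,
    lambda_from_proportion,
    phase_indicators,
    selection_index,
    validate_alignment,
    zygotic_msq,
)
from msq.genetic_map import GeneticMap
from msq.mendelian_core import parent_effects

from conftest import random_parent, small_dataset


def make_bundle(haps_array, positions, effects, chrom=None):
    """Bundle from raw arrays (single- or multi-chromosome)."""
    haps_array = np.asarray(haps_array, dtype=np.uint8)
    n, _, L = haps_array.shape
    chrom = np.asarray(chrom if chrom is not None else ["1"] * L, dtype=object)
    mid = np.array([f"m{i}" for i in range(L)], dtype=object)
    gmap = GeneticMap(mid, chrom, np.asarray(positions, dtype=float))
    eff = np.atleast_2d(np.asarray(effects, dtype=float))
    effset = MarkerEffectSet(tuple(f"t{t}" for t in range(eff.shape[0])), eff, mid)
    haps = PhasedHaplotypes(
        np.array([f"p{i}" for i in range(n)], dtype=object), haps_array, mid
    )
    return validate_alignment(gmap, haps, effset)


class TestIndicators:
    @pytest.mark.parametrize(
        "pair,delta,code",
        [((1, 0), 1, 0), ((0, 1), -1, 0), ((0, 0), 0, -1), ((1, 1), 0, 1)],
    )
    def test_phase_and_genotype_coding(self, pair, delta, code):
        haps = PhasedHaplotypes(np.array(["x"], dtype=object), np.array([[[pair[0]], [pair[1]]]]))
        assert phase_indicators(haps).delta[0, 0] == delta
        assert genotype_codes(haps).codes[0, 0] == code

    def test_delta_zero_iff_homozygous(self, bundle):
        delta = phase_indicators(bundle.haps).delta
        hom = bundle.haps.alleles[:, 0, :] == bundle.haps.alleles[:, 1, :]
        assert np.array_equal(delta == 0, hom)
        assert np.all(np.abs(delta[~hom]) == 1)


class TestParentEffects:
    def test_elementwise_product_and_sign(self):
        delta = np.array([1, -1, 0])
        out = parent_effects(delta, np.array([[2.0, 3.0, 5.0]]), np.arange(3))
        assert np.allclose(out, [[2.0, -3.0, 0.0]])

    def test_quadratic_form_invariant_to_global_delta_flip(self):
        rng = np.random.default_rng(5)
        delta = rng.choice([-1, 0, 1], size=6)
        M = rng.normal(size=(2, 6))
        R = np.eye(6) * 0.25
        Mi = parent_effects(delta, M, np.arange(6))
        Mf = parent_effects(-delta, M, np.arange(6))
        assert np.allclose(Mf, -Mi)
        assert np.allclose(Mi @ R @ Mi.T, Mf @ R @ Mf.T)


class TestGameticMsq:
    def test_fully_homozygous_parent_has_zero_msv(self):
        hap = np.ones((1, 2, 4), dtype=np.uint8)
        b = make_bundle(hap, [0, 0.1, 0.2, 0.3], np.ones(4))
        res = gametic_msq(b, build_all_R(b.gmap, "haldane"))[0]
        assert np.all(res.V == 0) and res.msv_aggregate == 0

    def test_single_heterozygous_marker_gives_quarter_m_squared(self):
        b = make_bundle([[[1], [0]]], [0.0], [3.0])
        res = gametic_msq(b, build_all_R(b.gmap, "haldane"))[0]
        assert res.msv_aggregate == pytest.approx(0.25 * 9.0, rel=1e-12)

    def test_matches_enumeration_oracle_multi_trait(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            L, T = 8, 2
            haps = random_parent(rng, L)[None]
            pos = np.sort(rng.uniform(0, 1.2, L))
            M = rng.normal(size=(T, L))
            b = make_bundle(haps, pos, M)
            V = gametic_msq(b, build_all_R(b.gmap, "haldane"))[0].V
            cov = enumerate_gametes(haps[0], pos, M).cov()
            assert np.allclose(V, cov, rtol=1e-10, atol=1e-13)

    def test_single_trait_equals_multi_trait_corner(self, bundle, R_haldane):
        res2 = gametic_msq(bundle, R_haldane, weights=[1.0, 0.0])
        eff1 = MarkerEffectSet(
            (bundle.effects.trait_names[0],),
            bundle.effects.effects[:1],
            bundle.effects.marker_id,
        )
        b1 = validate_alignment(bundle.gmap, bundle.haps, eff1)
        res1 = gametic_msq(b1, R_haldane)
        for r1, r2 in zip(res1, res2):
            assert r1.msv_aggregate == pytest.approx(r2.V[0, 0], rel=1e-12, abs=1e-15)
            assert r1.gebv_aggregate == pytest.approx(r2.gebv[0], rel=1e-12, abs=1e-15)

    def test_gebv_equals_twice_mean_gametic_value(self):
        rng = np.random.default_rng(3)
        haps = random_parent(rng, 6)[None]
        pos = np.sort(rng.uniform(0, 1, 6))
        m = rng.normal(size=6)
        b = make_bundle(haps, pos, m)
        res = gametic_msq(b, build_all_R(b.gmap, "haldane"))[0]
        mean_gamete = enumerate_gametes(haps[0], pos, m).mean()[0]
        assert res.gebv_aggregate == pytest.approx(2 * mean_gamete, rel=1e-10)

    def test_reference_allele_swap_flips_gebv_keeps_variances(self, bundle, dataset, R_haldane):
        res = gametic_msq(bundle, R_haldane)
        swapped = PhasedHaplotypes(
            dataset.haps.individual_id, 1 - dataset.haps.alleles, dataset.haps.marker_id
        )
        bswap = validate_alignment(dataset.gmap, swapped, dataset.effects)
        res_s = gametic_msq(bswap, R_haldane)
        for r, s in zip(res, res_s):
            assert np.array_equal(r.V, s.V)
            assert np.array_equal(r.gebv, -s.gebv)
            assert r.msv_aggregate == s.msv_aggregate

    def test_chromosome_additivity_is_exact(self, bundle, R_haldane):
        whole = gametic_msq(bundle, R_haldane)
        parts = [
            gametic_msq(bundle, R_haldane, chromosomes=[c])
            for c in bundle.gmap.chromosomes
        ]
        for i, r in enumerate(whole):
            V_sum = parts[0][i].V + parts[1][i].V
            g_sum = parts[0][i].gebv + parts[1][i].gebv
            assert np.array_equal(r.V, V_sum)
            assert np.array_equal(r.gebv, g_sum)

    def test_all_variances_nonnegative_and_V_psd(self, bundle, R_haldane):
        for r in gametic_msq(bundle, R_haldane):
            assert r.msv_aggregate >= 0 and np.all(r.msv >= -1e-12)
            eig = np.linalg.eigvalsh(r.V)
            assert eig[0] >= -1e-10 * max(eig[-1], 1.0)

    def test_weights_length_mismatch_rejected(self, bundle, R_haldane):
        with pytest.raises(ValueError, match="weights"):
            gametic_msq(bundle, R_haldane, weights=[1.0, 2.0, 3.0])


class TestZygoticMsq:
    def test_pair_variance_is_sum_of_parents(self, bundle, R_haldane):
        res = gametic_msq(bundle, R_haldane)
        pair = zygotic_msq(bundle, R_haldane, pairs=[("ind1", "ind2")],
                           parent_results=res)[0]
        assert np.array_equal(pair.V, res[0].V + res[1].V)
        assert pair.mean_gebv == pytest.approx(
            0.5 * (res[0].gebv_aggregate + res[1].gebv_aggregate)
        )

    def test_self_pair_doubles_variance(self, bundle, R_haldane):
        res = gametic_msq(bundle, R_haldane, individuals=["ind3"])
        pair = zygotic_msq(bundle, R_haldane, pairs=[("ind3", "ind3")],
                           parent_results=res)[0]
        assert np.array_equal(pair.V, 2 * res[0].V)

    def test_two_homozygous_parents_give_zero(self):
        haps = np.ones((2, 2, 3), dtype=np.uint8)
        haps[1] = 0
        b = make_bundle(haps, [0, 0.1, 0.2], np.ones(3))
        pair = zygotic_msq(b, build_all_R(b.gmap, "haldane"), pairs=[("p0", "p1")])[0]
        assert np.all(pair.V == 0)

    def test_unknown_pair_member_rejected(self, bundle, R_haldane):
        with pytest.raises(KeyError, match="nobody"):
            zygotic_msq(bundle, R_haldane, pairs=[("ind1", "nobody")])


class TestSelectionIndex:
    def test_lambda_zero_gives_gebv(self, bundle, R_haldane):
        res = selection_index(gametic_msq(bundle, R_haldane), 0.0)
        for r in res:
            assert r.index == r.gebv_aggregate

    def test_index_arithmetic(self, bundle, R_haldane):
        r = gametic_msq(bundle, R_haldane, individuals=["ind1"])[0]
        r.gebv_aggregate, r.sd_aggregate = 1.0, 2.0
        selection_index([r], 0.5)
        assert r.index == pytest.approx(2.0)

    def test_negative_lambda_penalizes_variance(self, bundle, R_haldane):
        res = gametic_msq(bundle, R_haldane)
        selection_index(res, -1.0)
        for r in res:
            assert r.index <= r.gebv_aggregate

    def test_zygotic_index_variants(self, bundle, R_haldane):
        pres = gametic_msq(bundle, R_haldane)
        z = zygotic_msq(bundle, R_haldane, pairs=[("ind1", "ind2")], parent_results=pres)
        selection_index(z, 1.0)
        assert z[0].index == pytest.approx(z[0].mean_gebv + z[0].sd_aggregate)
        selection_index(z, 1.0, method="parent_average")
        assert z[0].index == pytest.approx(
            z[0].mean_gebv + 0.5 * (pres[0].sd_aggregate + pres[1].sd_aggregate)
        )


class TestLambdaFromProportion:
    def test_median_truncation_gives_zero(self):
        assert lambda_from_proportion(0.5) == 0.0

    def test_five_percent_value(self):
        assert lambda_from_proportion(0.05) == pytest.approx(np.sqrt(2) * 1.6449, abs=1e-4)

    def test_strictly_decreasing_in_p(self):
        ps = np.linspace(0.01, 0.99, 25)
        lams = [lambda_from_proportion(p) for p in ps]
        assert np.all(np.diff(lams) < 0)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_proportion_rejected(self, p):
        with pytest.raises(ValueError):
            lambda_from_proportion(p)
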