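import numpy as np
import pandas as pd
import pytest

from flowerweb import (
    InteractionMatrix,
    core_periphery,
    degree,
    dependencies,
    dprime,
    push_pull,
    species_strength,
    species_table,
)


class TestDependencies:
    def test_hand_example(self, tiny_web):
        dep = dependencies(tiny_web)
        assert np.allclose(dep.d_lower[0], [0.75, 0.25])
        assert np.allclose(dep.d_upper[:, 0], [1.0, 0.0])

    def test_one_link_web(self, one_link_web):
        dep = dependencies(one_link_web)
        assert np.allclose(dep.d_lower, [[1.0]])
        assert np.allclose(dep.d_upper, [[1.0]])

    def test_normalisation_on_generated_webs(self, random_webs):
        for M in random_webs:
            dep = dependencies(M)
            assert np.allclose(dep.d_lower.sum(axis=1), 1.0)
            assert np.allclose(dep.d_upper.sum(axis=0), 1.0)
            assert np.array_equal(dep.d_lower == 0, M.counts == 0)


class TestDegreeStrength:
    def test_degree_counts_links(self, tiny_web):
        lo, hi = degree(tiny_web)
        assert lo.tolist() == [2, 1] and hi.tolist() == [1, 2]

    def test_strength_hand_example(self, tiny_web):
        lo, hi = species_strength(tiny_web)
        assert hi["b1"] == pytest.approx(0.75)
        assert hi["b2"] == pytest.approx(1.25)

    def test_strength_conservation(self, random_webs):
        # dependencies are conserved: visitor strengths sum to R, plant
        # strengths sum to C
        for M in random_webs:
            lo, hi = species_strength(M)
            assert hi.sum() == pytest.approx(M.R)
            assert lo.sum() == pytest.approx(M.C)


class TestPushPull:
    def test_symmetric_single_link_is_zero(self, one_link_web):
        lo, hi = push_pull(one_link_web)
        assert lo["p1"] == 0 == hi["b1"]

    def test_hand_example(self, tiny_web):
        _lo, hi = push_pull(tiny_web)
        assert hi["b1"] == pytest.approx(-0.25)

    def test_sole_visitor_of_many_plants_is_pusher(self):
        # one visitor spreads evenly over k plants it alone visits: each plant
        # depends on it fully, it depends 1/k on each -> strong pusher
        k = 6
        M = InteractionMatrix(
            tuple(f"p{i}" for i in range(k)), ("b1",), np.ones((k, 1), dtype=int)
        )
        _lo, hi = push_pull(M)
        assert hi["b1"] > 0

    def test_bounded_and_antisymmetric_on_two_species_webs(self, one_link_web, random_webs):
        for M in random_webs:
            lo, hi = push_pull(M)
            assert ((lo >= -1) & (lo <= 1)).all()
            assert ((hi >= -1) & (hi <= 1)).all()
        # a 1x1 web: the two species' asymmetries are exact opposites
        lo, hi = push_pull(one_link_web)
        assert lo["p1"] == pytest.approx(-hi["b1"])


class TestDprime:
    def test_proportional_use_scores_zero(self):
        # visits proportional to partner availability for every species
        M = InteractionMatrix(
            ("p1", "p2"), ("b1", "b2"), np.array([[4, 2], [8, 4]])
        )
        lo, hi = dprime(M)
        assert np.allclose(lo, 0) and np.allclose(hi, 0)

    def test_degenerate_single_link_is_zero(self, one_link_web):
        lo, hi = dprime(one_link_web)
        assert lo["p1"] == 0 == hi["b1"]

    def test_rare_partner_specialist_scores_higher(self):
        # availability q = [0.6, 0.3, 0.1]; a specialist on the rarest plant
        # discriminates more than an equally-busy specialist on the commonest
        M = InteractionMatrix(
            ("common", "mid", "rare"),
            ("on_common", "on_rare", "filler"),
            np.array([[10, 0, 110], [0, 0, 60], [0, 10, 10]]),
        )
        _lo, hi = dprime(M)
        assert hi["on_rare"] > hi["on_common"]

    def test_bounded_on_generated_webs(self, random_webs):
        for M in random_webs:
            lo, hi = dprime(M)
            assert ((lo >= 0) & (lo <= 1)).all()
            assert ((hi >= 0) & (hi <= 1)).all()


class TestCorePeriphery:
    def test_hand_example(self):
        # degrees [5,1,1,1]: mean 2, sample sd 2 -> Gc [1.5,-0.5,-0.5,-0.5]
        M = InteractionMatrix(
            tuple(f"p{i}" for i in range(5)),
            ("hub", "x1", "x2", "x3"),
            np.array(
                [[1, 1, 0, 0], [1, 0, 1, 0], [1, 0, 0, 1], [1, 0, 0, 0], [1, 0, 0, 0]]
            ),
        )
        cp = core_periphery(M, "higher")
        assert cp["Gc"].tolist() == pytest.approx([1.5, -0.5, -0.5, -0.5])
        assert cp["core"].tolist() == [True, False, False, False]

    def test_equal_degrees_no_core(self):
        M = InteractionMatrix(
            ("p1", "p2"), ("b1", "b2"), np.array([[1, 1], [1, 1]])
        )
        cp = core_periphery(M, "higher")
        assert (cp["Gc"] == 0).all() and not cp["core"].any()

    def test_gc_mean_zero(self, random_webs):
        for M in random_webs:
            for guild in ("lower", "higher"):
                gc = core_periphery(M, guild)["Gc"]
                if gc.abs().sum() > 0:
                    assert gc.mean() == pytest.approx(0, abs=1e-10)


def test_species_table_shape_and_columns(random_webs):
    M = random_webs[0]
    tab = species_table(M)
    assert list(tab.columns) == ["guild", "species", "DEG", "ST", "IPP", "dprime", "Gc", "core"]
    assert len(tab) == M.size
    assert tab["species"].is_unique
    assert (tab["DEG"] >= 1).all()
    assert (tab["ST"] >= 0).all()
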