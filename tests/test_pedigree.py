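import numpy as np
import pandas as pd
import pytest

from _oracles import wright_inbreeding
from herdstruct.pedigree import (
    Pedigree,
    PedigreeRecord,
    compare_genomic_pedigree,
    inbreeding,
    pedigree_admixture,
)


def _ped(triples, founder_info=None, year=2000):
    """Build a Pedigree from (id, sire, dam) triples."""
    founder_info = founder_info or {}
    recs = []
    for pid, s, d in triples:
        fracs, pop, by = None, "A", year
        if pid in founder_info:
            fracs, pop, by = founder_info[pid]
        recs.append(PedigreeRecord(pid, s, d, by, pop, fracs))
    return Pedigree(recs)


class TestPedigreeContainer:
    def test_round_trip_tsv(self, tmp_path):
        ped = _ped([("f1", None, None), ("f2", None, None),
                    ("o", "f1", "f2")],
                   {"f1": ({"A": 0.75, "B": 0.25}, "A", 1940)})
        ped.to_tsv(tmp_path / "p.tsv")
        back = Pedigree.from_tsv(tmp_path / "p.tsv")
        assert back.ids == ped.ids
        assert back["o"].sire == "f1" and back["o"].dam == "f2"
        assert back["f1"].founder_fractions == {"A": 0.75, "B": 0.25}
        assert back["f2"].founder_fractions is None

    def test_topological_order_parents_first(self):
        ped = _ped([("o", "f1", "f2"), ("f1", None, None), ("f2", None, None)])
        order = ped.topological_order()
        assert order.index("f1") < order.index("o")
        assert order.index("f2") < order.index("o")

    def test_cycle_detected(self):
        with pytest.raises(ValueError, match="cycle"):
            _ped([("a", "b", None), ("b", "a", None)])

    def test_unknown_parent_reference_detected(self):
        with pytest.raises(ValueError, match="unknown parent"):
            _ped([("a", "ghost", None)])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            _ped([("a", None, None), ("a", None, None)])


class TestInbreeding:
    def test_founders_and_outbred_are_zero(self):
        ped = _ped([("f1", None, None), ("f2", None, None), ("o", "f1", "f2")])
        F = inbreeding(ped)
        assert F["f1"] == 0.0 and F["o"] == 0.0

    def test_full_sib_mating_quarter(self):
        ped = _ped([("f1", None, None), ("f2", None, None),
                    ("s", "f1", "f2"), ("d", "f1", "f2"),
                    ("o", "s", "d")])
        assert inbreeding(ped)["o"] == 0.25

    def test_half_sib_mating_eighth(self):
        ped = _ped([("f1", None, None), ("f2", None, None), ("f3", None, None),
                    ("s", "f1", "f2"), ("d", "f1", "f3"),
                    ("o", "s", "d")])
        assert inbreeding(ped)["o"] == 0.125

    def test_parent_offspring_mating(self):
        ped = _ped([("f1", None, None), ("f2", None, None),
                    ("d", "f1", "f2"), ("o", "f1", "d")])
        assert inbreeding(ped)["o"] == 0.25

    def test_inbred_common_ancestor_raises_f(self):
        # o's parents are full sibs whose sire a is itself inbred
        # (F_a = 0.25).  Wright: path through a contributes
        # (1/2)^3 (1 + 0.25) = 0.15625, path through m (1/2)^3 = 0.125
        ped = _ped([("f1", None, None), ("f2", None, None),
                    ("s0", "f1", "f2"), ("d0", "f1", "f2"),
                    ("a", "s0", "d0"), ("m", None, None),
                    ("c1", "a", "m"), ("c2", "a", "m"),
                    ("o", "c1", "c2")])
        F = inbreeding(ped)
        assert F["a"] == 0.25
        np.testing.assert_allclose(F["o"], 0.15625 + 0.125)

    def test_matches_wright_path_counting_on_random_pedigrees(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            triples = [(f"f{i}", None, None) for i in range(6)]
            ids = [t[0] for t in triples]
            for gen in range(4):
                for k in range(6):
                    s, d = rng.choice(len(ids), size=2, replace=False)
                    triples.append((f"g{gen}_{k}", ids[s], ids[d]))
                ids = ids + [f"g{gen}_{k}" for k in range(6)]
            ped = _ped(triples)
            F = inbreeding(ped)
            parents = {pid: (ped[pid].sire, ped[pid].dam) for pid in ped.ids}
            for pid in ped.ids:
                np.testing.assert_allclose(F[pid],
                                           wright_inbreeding(parents, pid),
                                           atol=1e-12)


class TestPedigreeAdmixture:
    def test_f1_with_one_foreign_parent_is_half(self):
        ped = _ped([("sire", None, None), ("dam", None, None),
                    ("f1", "sire", "dam")],
                   {"sire": ({"B": 1.0}, "B", 1990),
                    "dam": ({"A": 1.0}, "A", 1990)})
        aped = pedigree_admixture(ped, "A")
        assert aped["sire"] == 100.0
        assert aped["dam"] == 0.0
        assert aped["f1"] == 50.0

    def test_backcross_quarter(self):
        ped = _ped([("sire", None, None), ("dam", None, None),
                    ("f1", "sire", "dam"), ("dam2", None, None),
                    ("bc", "f1", "dam2")],
                   {"sire": ({"B": 1.0}, "B", 1990),
                    "dam": ({"A": 1.0}, "A", 1990),
                    "dam2": ({"A": 1.0}, "A", 1991)})
        assert pedigree_admixture(ped, "A")["bc"] == 25.0

    def test_pre_cutoff_founder_counts_as_home_stock(self):
        ped = _ped([("old", None, None), ("dam", None, None),
                    ("o", "old", "dam")],
                   {"old": (None, "B", 1940), "dam": ({"A": 1.0}, "A", 1990)})
        aped = pedigree_admixture(ped, "A", purebred_cutoff_year=1950)
        assert aped["old"] == 0.0 and aped["o"] == 0.0

    def test_unknown_parent_counts_as_home_stock(self):
        ped = _ped([("sire", None, None), ("o", "sire", None)],
                   {"sire": ({"B": 1.0}, "B", 1990)})
        assert pedigree_admixture(ped, "A")["o"] == 50.0

    def test_unlabelled_recent_foreign_founder_raises(self):
        ped = _ped([("x", None, None)], {"x": (None, "B", 1990)})
        with pytest.raises(ValueError, match="no breed fractions"):
            pedigree_admixture(ped, "A")

    def test_fraction_weighted_founder(self):
        ped = _ped([("x", None, None)],
                   {"x": ({"A": 0.8, "B": 0.2}, "A", 1990)})
        np.testing.assert_allclose(pedigree_admixture(ped, "A")["x"], 20.0)


class TestCompareGenomicPedigree:
    def test_perfect_linear_relation(self):
        x = pd.Series([0.0, 1.0, 2.0, 3.0], index=list("abcd"))
        rep = compare_genomic_pedigree(2.0 * x + 1.0, x)
        np.testing.assert_allclose(rep.pearson_r, 1.0)
        np.testing.assert_allclose(rep.slope, 2.0)
        np.testing.assert_allclose(rep.intercept, 1.0)
        np.testing.assert_allclose(rep.r_squared, 1.0)

    def test_matches_numpy_regression(self):
        rng = np.random.default_rng(1)
        x = pd.Series(rng.random(30))
        y = 0.7 * x + rng.normal(0, 0.1, 30)
        rep = compare_genomic_pedigree(y, x)
        slope, intercept = np.polyfit(x, y, 1)
        np.testing.assert_allclose(rep.slope, slope, atol=1e-10)
        np.testing.assert_allclose(rep.intercept, intercept, atol=1e-10)
        np.testing.assert_allclose(rep.r_squared, rep.pearson_r**2, atol=1e-10)

    def test_parent_factors_raise_r_squared(self):
        rng = np.random.default_rng(2)
        sires = np.repeat([f"s{i}" for i in range(5)], 10)
        effect = pd.Series(sires).map({f"s{i}": i * 0.2 for i in range(5)})
        x = pd.Series(rng.random(50))
        y = 0.3 * x + effect.to_numpy() + rng.normal(0, 0.05, 50)
        pf = pd.DataFrame({"sire": sires}, index=x.index)
        rep = compare_genomic_pedigree(y, x, pf)
        assert rep.r_squared_with_parents > rep.r_squared

    def test_misaligned_ids_dropped(self):
        y = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        x = pd.Series([1.0, 2.0, 3.0, 9.9], index=list("abce"))
        rep = compare_genomic_pedigree(y, x)
        assert rep.n == 3

    def test_too_few_pairs_raise(self):
        y = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ValueError, match=">= 3"):
            compare_genomic_pedigree(y, y)
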