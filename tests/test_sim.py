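import numpy as np
import pytest

from herdstruct.pedigree import Pedigree, PedigreeRecord
from herdstruct.sim import (
    Chromosome,
    SimConfig,
    _autozygous_intervals,
    _meiosis,
    gene_drop,
    generate_pedigree,
    simulate,
    simulate_founder_frequencies,
)


class TestFounderFrequencies:
    def test_balding_nichols_moments(self):
        # fixed ancestral p: Beta mean p, variance p(1-p)F
        f = 0.2
        freqs = simulate_founder_frequencies(50_000, (0.3, 0.3), (f,), seed=1)
        np.testing.assert_allclose(freqs.mean(), 0.3, atol=0.01)
        np.testing.assert_allclose(freqs.var(), 0.3 * 0.7 * f, rtol=0.05)

    def test_breeds_are_independent_draws(self):
        freqs = simulate_founder_frequencies(20_000, (0.5, 0.5), (0.3, 0.3),
                                             seed=2)
        r = np.corrcoef(freqs[:, 0], freqs[:, 1])[0, 1]
        assert abs(r) < 0.05

    def test_deterministic_in_seed(self):
        a = simulate_founder_frequencies(100, (0.05, 0.95), (0.1, 0.2), seed=7)
        b = simulate_founder_frequencies(100, (0.05, 0.95), (0.1, 0.2), seed=7)
        np.testing.assert_array_equal(a, b)

    def test_invalid_fst_rejected(self):
        with pytest.raises(ValueError, match="fst"):
            simulate_founder_frequencies(10, (0.1, 0.9), (0.0,), seed=0)


class TestPedigreeGeneration:
    def test_structure_counts_and_parentage(self):
        cfg = SimConfig(n_breeds=2, n_founders_per_breed=10, n_generations=3,
                        fst_per_breed=(0.1, 0.1), seed=0)
        ped = generate_pedigree(cfg)
        assert len(ped) == 2 * 10 * 3
        assert len(ped.founders()) == 20
        for rec in ped.records:
            if rec.sire is not None:
                assert ped[rec.sire].sex == "M"
                assert ped[rec.dam].sex == "F"
                assert ped[rec.sire].birth_year == rec.birth_year - 1

    def test_crossbreds_join_dam_breed(self):
        cfg = SimConfig(n_breeds=2, n_founders_per_breed=10, n_generations=3,
                        fst_per_breed=(0.1, 0.1),
                        crossbreeding_events=((1, "A", "B", 4),), seed=0)
        ped = generate_pedigree(cfg)
        crossbreds = [r for r in ped.records if r.id.startswith("XAB")]
        assert len(crossbreds) == 4
        for r in crossbreds:
            assert r.population == "B"
            assert ped[r.sire].population == "A"
            assert ped[r.dam].population == "B"

    def test_inbred_fraction_produces_sib_matings(self):
        cfg = SimConfig(n_breeds=1, n_founders_per_breed=20, n_generations=4,
                        fst_per_breed=(0.1,), inbred_mating_fraction=1.0,
                        seed=0)
        ped = generate_pedigree(cfg)
        n_sib = 0
        for r in ped.records:
            if r.sire is None or "_g1_" in r.id:
                continue
            s, d = ped[r.sire], ped[r.dam]
            if s.sire in (d.sire, d.dam) or s.dam in (d.sire, d.dam):
                n_sib += 1
        assert n_sib > 0


def _flat_hap(hap_id, length):
    return (np.array([length], dtype=np.int64),
            np.array([hap_id], dtype=np.int64))


class TestMeiosis:
    def test_gamete_covers_chromosome(self):
        chrom = Chromosome("1", 10_000_000, 200.0)  # many crossovers
        rng = np.random.default_rng(0)
        for _ in range(50):
            g = _meiosis(_flat_hap(0, chrom.length_bp),
                         _flat_hap(1, chrom.length_bp), chrom, rng)
            ends, ids = g
            assert ends[-1] == chrom.length_bp
            assert np.all(np.diff(ends) > 0)
            assert set(ids) <= {0, 1}
            # consecutive segments alternate source haplotypes
            assert np.all(ids[1:] != ids[:-1])

    def test_no_crossover_returns_whole_parent_haplotype(self):
        chrom = Chromosome("1", 1_000_000, 1e-9)  # Poisson mean ~0
        rng = np.random.default_rng(1)
        g = _meiosis(_flat_hap(5, chrom.length_bp),
                     _flat_hap(9, chrom.length_bp), chrom, rng)
        assert len(g[1]) == 1 and g[1][0] in (5, 9)

    def test_crossover_count_matches_map_length(self):
        chrom = Chromosome("1", 50_000_000, 100.0)  # 1 Morgan
        rng = np.random.default_rng(2)
        counts = []
        for _ in range(2000):
            g = _meiosis(_flat_hap(0, chrom.length_bp),
                         _flat_hap(1, chrom.length_bp), chrom, rng)
            counts.append(len(g[0]) - 1)
        # segments - 1 slightly undercounts crossovers (coincident/edge
        # events merge), so the observed mean sits just below 1.0
        assert 0.9 < np.mean(counts) <= 1.05


class TestAutozygousIntervals:
    def test_identical_haplotypes_fully_autozygous(self):
        h = _flat_hap(3, 1000)
        assert _autozygous_intervals(h, h) == [(1, 1000)]

    def test_disjoint_ids_nowhere_autozygous(self):
        assert _autozygous_intervals(_flat_hap(0, 1000), _flat_hap(1, 1000)) == []

    def test_partial_overlap(self):
        h1 = (np.array([400, 1000]), np.array([7, 1]))
        h2 = (np.array([600, 1000]), np.array([7, 2]))
        assert _autozygous_intervals(h1, h2) == [(1, 400)]

    def test_adjacent_matching_segments_merge(self):
        h1 = (np.array([500, 1000]), np.array([4, 4]))
        h2 = (np.array([300, 1000]), np.array([4, 4]))
        assert _autozygous_intervals(h1, h2) == [(1, 1000)]


class TestGeneDrop:
    def test_truth_invariants(self):
        cfg = SimConfig(n_breeds=2, n_founders_per_breed=10, n_generations=3,
                        m_snps=500, fst_per_breed=(0.1, 0.1), seed=11,
                        crossbreeding_events=((1, "A", "B", 5),))
        ds, truth, ped = simulate(cfg)
        np.testing.assert_allclose(truth.true_q.sum(axis=1), 1.0)
        assert ((truth.true_autozygosity >= 0)
                & (truth.true_autozygosity <= 1)).all()
        assert ds.n_samples == len(ped)
        assert ds.n_markers == 500

    def test_founders_pure_and_nonautozygous(self):
        cfg = SimConfig(n_breeds=2, n_founders_per_breed=8, n_generations=2,
                        m_snps=200, fst_per_breed=(0.2, 0.2), seed=4)
        _, truth, ped = simulate(cfg)
        for rec in ped.founders():
            assert truth.true_q.loc[rec.id, rec.population] == 1.0
            assert truth.true_autozygosity[rec.id] == 0.0

    def test_f1_cross_is_half_and_half(self):
        # ancestry of a first-generation crossbred is exactly 50/50:
        # one gamete comes entirely from each purebred parent
        cfg = SimConfig(n_breeds=2, n_founders_per_breed=10, n_generations=2,
                        m_snps=200, fst_per_breed=(0.1, 0.1), seed=6,
                        crossbreeding_events=((1, "A", "B", 6),))
        _, truth, _ = simulate(cfg)
        f1 = [i for i in truth.true_q.index if i.startswith("XAB_g1")]
        assert len(f1) == 6
        np.testing.assert_allclose(truth.true_q.loc[f1, "A"], 0.5)
        np.testing.assert_allclose(truth.true_q.loc[f1, "B"], 0.5)

    def test_offspring_ancestry_is_within_parents_span(self):
        cfg = SimConfig(n_breeds=2, n_founders_per_breed=10, n_generations=3,
                        m_snps=200, fst_per_breed=(0.1, 0.1), seed=8,
                        crossbreeding_events=((1, "A", "B", 6),))
        _, truth, ped = simulate(cfg)
        for rec in ped.records:
            if rec.sire is None:
                continue
            lo = 0.5 * np.minimum(truth.true_q.loc[rec.sire],
                                  truth.true_q.loc[rec.dam])
            assert (truth.true_q.loc[rec.id] >= lo - 1e-12).all()

    def test_genotypes_consistent_with_ibd_tracts(self):
        # inside an autozygous tract the genotype is homozygous at every SNP
        cfg = SimConfig(n_breeds=1, n_founders_per_breed=10, n_generations=4,
                        m_snps=1000, fst_per_breed=(0.2,),
                        inbred_mating_fraction=1.0, seed=2)
        ds, truth, _ = simulate(cfg)
        checked = 0
        id_row = {s: i for i, s in enumerate(ds.ids)}
        for pid, tracts in truth.ibd_tracts.items():
            for chrom, s, e in tracts:
                in_chrom = ds.markers["chrom"] == chrom
                hit = in_chrom & ds.markers["bp"].between(s, e)
                cols = np.where(hit)[0]
                g = ds.genotypes[id_row[pid], cols]
                assert not np.any(g == 1)
                checked += cols.size
        assert checked > 100

    def test_deterministic_in_seed(self):
        cfg = SimConfig(n_breeds=2, n_founders_per_breed=6, n_generations=2,
                        m_snps=100, fst_per_breed=(0.1, 0.1), seed=13)
        a = simulate(cfg)
        b = simulate(cfg)
        np.testing.assert_array_equal(a[0].genotypes, b[0].genotypes)
        np.testing.assert_array_equal(a[1].true_q.to_numpy(),
                                      b[1].true_q.to_numpy())

    def test_sib_mating_offspring_autozygosity_mean(self):
        # expected autozygosity of a full-sib offspring is 1/4.  Offspring of
        # one family all inherit that family's *realised* sib kinship, so the
        # mean must be taken over many independent families.
        recs = []
        n_fam = 40
        for f in range(n_fam):
            recs += [
                PedigreeRecord(f"s{f}", None, None, 2000, "A", {"A": 1.0}, "M"),
                PedigreeRecord(f"d{f}", None, None, 2000, "A", {"A": 1.0}, "F"),
                PedigreeRecord(f"b1_{f}", f"s{f}", f"d{f}", 2001, "A", None, "M"),
                PedigreeRecord(f"b2_{f}", f"s{f}", f"d{f}", 2001, "A", None, "F"),
                PedigreeRecord(f"o_{f}", f"b1_{f}", f"b2_{f}", 2002, "A",
                               None, "U"),
            ]
        ped = Pedigree(recs)
        freqs = simulate_founder_frequencies(50, (0.3, 0.7), (0.1,), seed=0)
        chroms = tuple(Chromosome(str(i), 50_000_000, 100.0) for i in range(10))
        _, truth = gene_drop(ped, freqs, chroms, seed=1, m_snps=50,
                             breed_names=["A"])
        vals = truth.true_autozygosity[[f"o_{f}" for f in range(n_fam)]]
        assert abs(vals.mean() - 0.25) < 0.04

    def test_single_known_parent_rejected(self):
        recs = [PedigreeRecord("s", None, None, 2000, "A", {"A": 1.0}, "M"),
                PedigreeRecord("o", "s", None, 2001, "A", None, "U")]
        ped = Pedigree(recs)
        freqs = simulate_founder_frequencies(10, (0.3, 0.7), (0.1,), seed=0)
        with pytest.raises(ValueError, match="one known parent"):
            gene_drop(ped, freqs, (Chromosome("1", 10**6, 1.0),), seed=0,
                      m_snps=10, breed_names=["A"])
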