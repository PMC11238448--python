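"""Gene-dropping simulator for multi-breed SNP datasets with known truth.

Breed allele frequencies diverge from a common ancestral pool under the
Balding-Nichols model: for a breed with divergence parameter F, each SNP
frequency is Beta-distributed with mean equal to the ancestral frequency p
and variance p(1-p)F.  Founder haplotypes are drawn independently per SNP
from their breed's frequencies (no background LD).  Descendant haplotypes
are produced by meiosis with crossovers placed as a Poisson process at one
crossover per 100 cM and no interference, tracking the founder haplotype of
origin of every chromosomal segment.  From that record the simulator
reports, per individual, the true genome fraction inherited from each
breed's founders (``true_q``) and the true autozygosity: the fraction of the
autosome where both haplotypes descend from the same founder haplotype.

These ground truths give every downstream stage a parameter-recovery test:
ROH-based F_ROH against true autozygosity, admixture Q against ``true_q``,
and Weir-Cockerham F_ST against the simulated divergence.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from herdstruct.genotype_io import GenotypeDataset
from herdstruct.pedigree import Pedigree, PedigreeRecord


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    length_cm: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0 or self.length_cm <= 0:
            raise ValueError("chromosome lengths must be positive")


DEFAULT_CHROMOSOMES = tuple(
    Chromosome(str(i + 1), 50_000_000, 50.0) for i in range(5)
)


@dataclass
class SimConfig:
    """Study design of a simulated multi-breed population.

    Defaults give a desk-scale analogue of a multi-breed SNP study: four
    breeds of 30 founders each, six non-overlapping generations, and 20,000
    SNPs spread over five 50 Mb / 50 cM chromosomes.
    """

    n_breeds: int = 4
    n_founders_per_breed: int = 30
    n_generations: int = 6
    m_snps: int = 20_000
    chromosomes: tuple[Chromosome, ...] = DEFAULT_CHROMOSOMES
    fst_per_breed: tuple[float, ...] = (0.1, 0.1, 0.1, 0.1)
    crossbreeding_events: tuple[tuple[int, str, str, int], ...] = ()
    inbred_mating_fraction: float = 0.0
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    base_year: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if len(self.fst_per_breed) != self.n_breeds:
            raise ValueError("fst_per_breed must have one value per breed")
        for f in self.fst_per_breed:
            if not 0.0 < f < 1.0:
                raise ValueError(f"fst must be in (0,1), got {f}")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_freq_range must lie inside (0,1)")
        if not 0.0 <= self.inbred_mating_fraction <= 1.0:
            raise ValueError("inbred_mating_fraction must be in [0,1]")
        names = self.breed_names
        for gen, sb, db, n in self.crossbreeding_events:
            if not 1 <= gen < self.n_generations:
                raise ValueError(f"crossbreeding generation {gen} out of range")
            if sb not in names or db not in names:
                raise ValueError(f"unknown breed in crossbreeding event ({sb},{db})")
            if n < 1:
                raise ValueError("crossbreeding n_offspring must be >= 1")

    @property
    def breed_names(self) -> list[str]:
        return list(string.ascii_uppercase[: self.n_breeds])

    @classmethod
    def from_toml(cls, path) -> "SimConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        if "chromosomes" in raw:
            raw["chromosomes"] = tuple(
                Chromosome(str(c[0]), int(c[1]), float(c[2]))
                for c in raw["chromosomes"]
            )
        if "crossbreeding_events" in raw:
            raw["crossbreeding_events"] = tuple(
                (int(e[0]), str(e[1]), str(e[2]), int(e[3]))
                for e in raw["crossbreeding_events"]
            )
        for key in ("fst_per_breed", "ancestral_freq_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SimTruth:
    """Ground truth recorded during gene dropping."""

    true_q: pd.DataFrame          # individuals x breeds, rows on the simplex
    true_autozygosity: pd.Series  # fraction of autosome autozygous
    ibd_tracts: dict[str, list[tuple[str, int, int]]]

    def to_tsv(self, path) -> None:
        df = self.true_q.add_prefix("q_")
        df.insert(0, "true_autozygosity", self.true_autozygosity)
        df.index.name = "id"
        df.to_csv(path, sep="\t")


def simulate_founder_frequencies(
    m_snps: int,
    ancestral_freq_range: tuple[float, float],
    fst_per_breed: tuple[float, ...],
    seed: int,
) -> np.ndarray:
    """Balding-Nichols breed frequencies, ``(m_snps, n_breeds)``.

    For each SNP an ancestral frequency p is drawn uniformly in
    ``ancestral_freq_range``; breed b's frequency is then
    Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance p(1-p)F.
    """
    lo, hi = ancestral_freq_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("ancestral_freq_range must lie inside (0,1)")
    for f in fst_per_breed:
        if not 0.0 < f < 1.0:
            raise ValueError(f"fst must be in (0,1), got {f}")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=m_snps)
    out = np.empty((m_snps, len(fst_per_breed)))
    for b, f in enumerate(fst_per_breed):
        scale = (1.0 - f) / f
        out[:, b] = rng.beta(p * scale, (1.0 - p) * scale)
    return out


def generate_pedigree(config: SimConfig) -> Pedigree:
    """Multi-breed pedigree with optional cross-breeding and inbred matings.

    Generation 0 holds the founders of each breed.  Each later generation
    replaces a breed with as many offspring as it has founders, mating random
    sires and dams from the previous generation; with probability
    ``inbred_mating_fraction`` a mating is instead between full or half sibs.
    Cross-breeding events insert offspring of a sire from one breed and a dam
    from another; these join the dam's breed for subsequent generations.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    breeds = config.breed_names
    records: list[PedigreeRecord] = []
    # current breeding pool per breed: list of record indices
    pool: dict[str, list[int]] = {b: [] for b in breeds}

    def add(pid, sire, dam, year, breed, fracs, sex):
        records.append(PedigreeRecord(pid, sire, dam, year, breed, fracs, sex))
        return len(records) - 1

    for b in breeds:
        for i in range(config.n_founders_per_breed):
            sex = "M" if i % 2 == 0 else "F"
            idx = add(f"{b}_g0_i{i:03d}", None, None, config.base_year, b,
                      {b: 1.0}, sex)
            pool[b].append(idx)

    crosses = {}
    for gen, sb, db, n in config.crossbreeding_events:
        crosses.setdefault(gen, []).append((sb, db, n))

    def sibs_of(idx: int, candidates: list[int]) -> list[int]:
        r = records[idx]
        out = []
        for c in candidates:
            rc = records[c]
            if c == idx:
                continue
            if (r.sire is not None and r.sire in (rc.sire, rc.dam)) or (
                r.dam is not None and r.dam in (rc.sire, rc.dam)
            ):
                out.append(c)
        return out

    for gen in range(1, config.n_generations):
        year = config.base_year + gen
        new_pool: dict[str, list[int]] = {b: [] for b in breeds}
        for b in breeds:
            males = [i for i in pool[b] if records[i].sex == "M"]
            females = [i for i in pool[b] if records[i].sex == "F"]
            if not males or not females:
                raise RuntimeError(f"breed {b} ran out of sires or dams")
            for k in range(config.n_founders_per_breed):
                dam = int(rng.choice(females))
                sire = None
                if rng.random() < config.inbred_mating_fraction:
                    close = [s for s in sibs_of(dam, males)]
                    if close:
                        sire = int(rng.choice(close))
                if sire is None:
                    sire = int(rng.choice(males))
                sex = "M" if k % 2 == 0 else "F"
                idx = add(f"{b}_g{gen}_i{k:03d}", records[sire].id,
                          records[dam].id, year, b, None, sex)
                new_pool[b].append(idx)
        for sb, db, n in crosses.get(gen, []):
            sires = [i for i in pool[sb] if records[i].sex == "M"]
            dams = [i for i in pool[db] if records[i].sex == "F"]
            for k in range(n):
                sire = int(rng.choice(sires))
                dam = int(rng.choice(dams))
                sex = "M" if k % 2 == 0 else "F"
                idx = add(f"X{sb}{db}_g{gen}_i{k:03d}", records[sire].id,
                          records[dam].id, year, db, None, sex)
                new_pool[db].append(idx)
        pool = new_pool

    return Pedigree(records)


# ---------------------------------------------------------------------------
# Gene dropping


def _snp_positions(chromosomes, m_snps, rng) -> dict[str, np.ndarray]:
    """Assign SNPs to chromosomes proportionally to length, uniform positions."""
    lengths = np.array([c.length_bp for c in chromosomes], dtype=float)
    counts = np.floor(m_snps * lengths / lengths.sum()).astype(int)
    counts[: m_snps - counts.sum()] += 1
    out = {}
    for c, k in zip(chromosomes, counts):
        pos = np.unique(rng.integers(1, c.length_bp + 1, size=k))
        while pos.size < k:  # replace the rare collisions
            extra = rng.integers(1, c.length_bp + 1, size=k - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        out[c.name] = pos
    return out


def _meiosis(hap_a, hap_b, chrom: Chromosome, rng):
    """One gamete from a parent's two haplotypes.

    Haplotypes are breakpoint lists ``(ends_bp, founder_hap_ids)`` covering
    [1, L].  Crossover count is Poisson(length_cM / 100); positions are
    uniform on the cM map, which is linear in bp.
    """
    n_x = rng.poisson(chrom.length_cm / 100.0)
    cur, other = (hap_a, hap_b) if rng.random() < 0.5 else (hap_b, hap_a)
    if n_x == 0:
        return cur
    xovers = np.sort(rng.uniform(0, chrom.length_bp, size=n_x)).astype(np.int64)
    out_ends: list[int] = []
    out_ids: list[int] = []
    prev = 0
    for x in list(xovers) + [chrom.length_bp]:
        if x > prev:
            ends, ids = cur
            i0 = int(np.searchsorted(ends, prev + 1))
            for i in range(i0, len(ends)):
                e = min(int(ends[i]), int(x))
                if out_ids and out_ids[-1] == ids[i] and out_ends:
                    out_ends[-1] = e
                else:
                    out_ends.append(e)
                    out_ids.append(int(ids[i]))
                if ends[i] >= x:
                    break
            prev = int(x)
        cur, other = other, cur
    return np.array(out_ends, dtype=np.int64), np.array(out_ids, dtype=np.int64)


def _autozygous_intervals(h1, h2):
    """bp intervals where the two haplotypes carry the same founder hap id."""
    ends1, ids1 = h1
    ends2, ids2 = h2
    out = []
    i = j = 0
    prev = 0
    while i < len(ends1) and j < len(ends2):
        e = min(ends1[i], ends2[j])
        if ids1[i] == ids2[j]:
            if out and out[-1][1] == prev:
                out[-1] = (out[-1][0], int(e))
            else:
                out.append((prev + 1, int(e)))
        prev = int(e)
        if ends1[i] == e:
            i += 1
        if ends2[j] == e:
            j += 1
    return out


def gene_drop(
    pedigree: Pedigree,
    founder_freqs: np.ndarray,
    chromosomes: tuple[Chromosome, ...],
    seed: int,
    m_snps: int | None = None,
    breed_names: list[str] | None = None,
) -> tuple[GenotypeDataset, SimTruth]:
    """Drop founder haplotypes through a pedigree and genotype the result.

    ``founder_freqs`` is the ``(m_snps, n_breeds)`` Balding-Nichols table;
    founders draw each haplotype allele independently per SNP from their
    breed's column.  Returns the genotype dataset and the ground truth
    (ancestry fractions, autozygosity, IBD tracts).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    m_snps = m_snps or founder_freqs.shape[0]
    if founder_freqs.shape[0] != m_snps:
        raise ValueError("founder_freqs rows must equal m_snps")
    founders = pedigree.founders()
    breeds = breed_names or sorted({f.population for f in founders})
    breed_idx = {b: k for k, b in enumerate(breeds)}
    if founder_freqs.shape[1] != len(breeds):
        raise ValueError("founder_freqs columns must match breed count")

    positions = _snp_positions(chromosomes, m_snps, rng)
    total_bp = float(sum(c.length_bp for c in chromosomes))

    # founder haplotype alleles: (2 * n_founders, m_snps)
    hap_breed: list[int] = []
    founder_hap_of: dict[str, tuple[int, int]] = {}
    for f in founders:
        h0 = len(hap_breed)
        founder_hap_of[f.id] = (h0, h0 + 1)
        hap_breed.extend([breed_idx[f.population]] * 2)
    hap_breed_arr = np.array(hap_breed)
    n_haps = len(hap_breed)
    freqs_per_hap = founder_freqs[:, hap_breed_arr].T  # (n_haps, m)
    hap_alleles = (rng.random((n_haps, m_snps)) < freqs_per_hap).astype(np.int8)

    # drop segments through the pedigree in topological order
    order = pedigree.topological_order()
    haps: dict[str, dict[str, tuple]] = {}  # id -> chrom -> (h1, h2)
    for pid in order:
        rec = pedigree[pid]
        ind: dict[str, tuple] = {}
        if rec.sire is None and rec.dam is None:
            a, b = founder_hap_of[pid]
            for c in chromosomes:
                L = np.array([c.length_bp], dtype=np.int64)
                ind[c.name] = (
                    (L.copy(), np.array([a], dtype=np.int64)),
                    (L.copy(), np.array([b], dtype=np.int64)),
                )
        else:
            if rec.sire is None or rec.dam is None:
                raise ValueError(f"{pid!r} has exactly one known parent; "
                                 "gene dropping needs both or neither")
            for c in chromosomes:
                s1, s2 = haps[rec.sire][c.name]
                d1, d2 = haps[rec.dam][c.name]
                ind[c.name] = (_meiosis(s1, s2, c, rng),
                               _meiosis(d1, d2, c, rng))
        haps[pid] = ind

    # genotypes, ancestry fractions, autozygosity
    ids = pedigree.ids
    n = len(ids)
    geno = np.zeros((n, m_snps), dtype=np.int8)
    true_q = np.zeros((n, len(breeds)))
    autoz = np.zeros(n)
    tracts: dict[str, list[tuple[str, int, int]]] = {}

    chrom_slices = {}
    offset = 0
    for c in chromosomes:
        k = len(positions[c.name])
        chrom_slices[c.name] = slice(offset, offset + k)
        offset += k

    for i, pid in enumerate(ids):
        ind_tracts: list[tuple[str, int, int]] = []
        for c in chromosomes:
            pos = positions[c.name]
            sl = chrom_slices[c.name]
            h1, h2 = haps[pid][c.name]
            for h in (h1, h2):
                ends, hap_ids = h
                seg_of_snp = np.searchsorted(ends, pos)
                alleles = hap_alleles[hap_ids[seg_of_snp], np.arange(sl.start, sl.stop)]
                geno[i, sl] += alleles
                seg_lens = np.diff(np.concatenate([[0], ends]))
                for b_i, ln in zip(hap_breed_arr[hap_ids], seg_lens):
                    true_q[i, b_i] += ln
            for s, e in _autozygous_intervals(h1, h2):
                autoz[i] += e - s + 1
                ind_tracts.append((c.name, int(s), int(e)))
        tracts[pid] = ind_tracts
    true_q /= 2.0 * total_bp
    autoz /= total_bp

    markers = []
    for c in chromosomes:
        for j, p in enumerate(positions[c.name]):
            markers.append((c.name, f"snp_{c.name}_{j}", int(p), "A", "B"))
    markers = pd.DataFrame(markers,
                           columns=["chrom", "id", "bp", "allele_a", "allele_b"])
    samples = pd.DataFrame({
        "id": ids,
        "population": [pedigree[p].population for p in ids],
    })
    dataset = GenotypeDataset(samples, markers, geno)
    truth = SimTruth(
        true_q=pd.DataFrame(true_q, index=ids, columns=breeds),
        true_autozygosity=pd.Series(autoz, index=ids),
        ibd_tracts=tracts,
    )
    return dataset, truth


def simulate(config: SimConfig) -> tuple[GenotypeDataset, SimTruth, Pedigree]:
    """Run the full simulator: frequencies, pedigree, gene drop."""
    freqs = simulate_founder_frequencies(
        config.m_snps, config.ancestral_freq_range, config.fst_per_breed,
        np.random.SeedSequence([config.seed, 0]),
    )
    ped = generate_pedigree(config)
    dataset, truth = gene_drop(
        ped, freqs, config.chromosomes, config.seed,
        m_snps=config.m_snps, breed_names=config.breed_names,
    )
    return dataset, truth, ped
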