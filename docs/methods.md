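# Methods

This note documents the statistical models, algorithms, default parameters,
and numerical choices implemented in `herdstruct`, together with the known
limitations of the bundled simulator.  Coordinates are 1-based and
inclusive throughout; genotypes are B-allele dosages in {0, 1, 2} with -1
for missing.

## 1. Synthetic data: gene-dropping simulator (`herdstruct.sim`)

### Breed allele frequencies

Breeds diverge from a common ancestral gene pool under the Balding–Nichols
model.  For each SNP an ancestral frequency `p` is drawn uniformly from
`ancestral_freq_range` (default `(0.05, 0.95)`).  A breed with divergence
parameter `F` then receives frequency

    f ~ Beta(p(1-F)/F, (1-p)(1-F)/F),

which has mean `p` and variance `p(1-p)F`.  `F` is per-breed
(`fst_per_breed`); the expected Weir–Cockerham F_ST between two breeds with
parameters `F1`, `F2` sampled directly at Hardy–Weinberg equilibrium is
approximately `(F1+F2)/2`.

### Pedigree and meiosis

Generation 0 holds `n_founders_per_breed` founders per breed (alternating
sexes).  Each later generation replaces a breed with the same number of
offspring from random sire × dam matings within the previous generation;
with probability `inbred_mating_fraction` the sire is instead drawn from
the dam's full or half sibs when one exists.  Cross-breeding events
`(generation, sire_breed, dam_breed, n)` insert crossbred offspring
(ids prefixed `X`) that join the dam's breed pool.

Founder chromosomes are labelled with unique founder-haplotype ids.
Descendant gametes are produced by meiosis with a crossover count drawn as
Poisson(length_cM / 100) per chromosome, crossover positions uniform in bp
(the cM map is linear in bp), and no interference or sex differences in
recombination.  Haplotypes are stored as breakpoint lists, so chromosome
length does not affect memory.

### Ground truth

* `true_q`: the bp fraction of an individual's two haplotypes descending
  from each breed's founders (rows sum to 1).  An F1 cross is exactly
  50/50 because each gamete comes wholly from one purebred parent.
* `true_autozygosity`: the bp fraction of the genome where the two
  haplotypes carry the same founder-haplotype id (identity by descent
  relative to the founder generation), with the tract list retained.

SNPs are assigned to chromosomes proportionally to bp length with uniform
unique positions, and founder haplotype alleles are drawn independently
per SNP from the breed frequency.

### Simulator limitations

* No background linkage disequilibrium within founder haplotypes: LD
  arises only from co-inheritance down the simulated pedigree, so
  LD-sensitive methods see less structure than in real panels.
* No mutation, genotyping error, or allelic dropout; missingness must be
  injected by the caller.
* Non-overlapping generations, constant census size per breed, no
  selection or unequal founder contribution beyond random mating and the
  optional sib-mating fraction.
* Poisson crossovers without interference; one global cM/bp ratio per
  chromosome.
* IBD is defined relative to the founder generation; deeper coancestry
  among founders is zero by construction, so `true_autozygosity`
  understates autozygosity relative to an older base population.

## 2. Genotype I/O (`herdstruct.genotype_io`)

PLINK text (`.ped`/`.map`) and VCF are supported.  On PLINK import the B
allele is the lexicographically larger of the two observed alleles;
markers with non-positive positions are dropped with a warning and
reported in `dropped_markers`.  VCF import uses `cyvcf2`; dosage is the
ALT-allele count, `./.` becomes missing.  Marker positions must be
strictly increasing within a chromosome.  The MAF filter retains markers
whose minor-allele frequency among called genotypes is `>=` the threshold
(default 0.05) and raises if no marker survives.

## 3. Relationships, PCA, F_ST (`herdstruct.relationship`)

**IBS matrix.** Entry (i, j) is the mean of `1 - |g_i - g_j| / 2` over
markers called in both individuals (1 for identical genotypes, 0.5 for one
shared allele, 0 for opposite homozygotes).  Without missing data this is
computed via a cityblock `pdist` (O(n² m) in C); with missing data a
per-row masked loop is used.  A pair sharing no called marker is an error,
not a silent NaN.  Genetic distance is `D = 1 - G` with a zeroed diagonal.

**PCA.** The matrix is double-centered (`HGH`), symmetrised, and
eigendecomposed (`numpy.linalg.eigh`).  Eigenvalues are sorted descending;
variance fractions are taken over positive eigenvalues only (negative
eigenvalues from double-centering get fraction 0).  Sign convention: each
eigenvector is oriented so its largest-magnitude loading is positive,
making outputs reproducible across BLAS builds.

**F_ST.** Default estimator is Weir & Cockerham (1984) with sample sizes
r = 2 populations: per-SNP variance components a (among populations), b
(among individuals within populations), c (within individuals) are
combined as a ratio of sums across SNPs — the estimator behind PLINK 1.9's
`--fst`.  Negative per-SNP components are retained; the final ratio is
floored at 0.  A Hudson-style ratio-of-sums estimator is available.
Note that W–C estimates on *pedigree-descended* samples include drift
accumulated over the simulated generations and therefore exceed the
founder-generation Balding–Nichols parameter; the direct-sampling identity
holds only for unrelated HWE samples.

Distance matrices can be exported as NEXUS TAXA/DISTANCES blocks
(lower-triangular with diagonal) for phylogenetic-network software.

## 4. Ancestry estimation (`herdstruct.admixture`)

Genotypes are modelled as `g_ij ~ Binomial(2, sum_k q_ik f_jk)` with
independent SNPs.  Fitting uses multiplicative EM updates (FRAPPE-style),
which keep `Q` rows on the simplex and increase the likelihood
monotonically.  Frequencies are clamped to `[1e-6, 1-1e-6]` to keep the
log-likelihood finite at fixed markers.

* **Supervised:** `F` is fixed to reference-panel allele frequencies and
  only target `Q` rows are updated, from a uniform start (the likelihood
  in Q alone is well-behaved; no restarts needed).  Convergence when the
  log-likelihood gain drops below `tol` (default 1e-4, `max_iter` 2000).
* **Unsupervised:** `Q` and `F` are updated jointly from seeded Dirichlet/
  uniform random starts with `n_restarts` (default 3) restarts; the best
  final likelihood wins.  `K = 1` has a closed form.  Cluster labels are
  arbitrary; `align_columns` matches labels between runs by greedy
  correlation.
* **Model choice:** `cv_error` masks a fraction of called genotype
  entries, refits, and scores the held-out entries by mean binomial
  deviance, returning mean ± sd over folds.
* **A_GEN** = `100 * (1 - q_home)` from a supervised fit: the genomic
  percentage of foreign ancestry.

Supervised estimates are only as good as the reference panels: panels
containing admixed animals bias `q` toward the contaminated breed.  In
simulations, truth-pure foundation animals should form the panels.

## 5. Key contributors (`herdstruct.contributors`)

**Horn's parallel analysis** decides how many PCs of G are significant.
The primary null permutes every genotype column independently across
individuals (preserving allele frequencies, destroying relatedness) and
recomputes the IBS matrix per replicate; `k_significant` is the length of
the leading run of observed eigenvalues exceeding their per-component
`(1 - P)` null quantile (default P = 0.01, 1000 iterations).  A fast
Gaussian null is available when only the matrix exists.  Note that in a
*related* population many PCs are legitimately significant — family
structure is real structure.

**Genetic contribution score.** With `u_i, s_i` the leading singular
vectors/values of G and `w_i = s_i / sum_{i<=k} s_i`,

    gc_j = sum_{i<=k} w_i * |cor(G[:, j], u_i)|.

Individuals whose relationship profile aligns with the dominant axes of
variation (prolific ancestors and their descendant clusters) score high.
Zero-variance columns score 0 with a warning.  Ranks are dense (1 = top).

## 6. Runs of homozygosity (`herdstruct.roh`)

Detection follows PLINK `--homozyg` scanning-window semantics:

1. A window of `window_snps` (default 50) consecutive SNPs *passes* when
   it has at most `window_max_het` (1) heterozygous and
   `window_max_missing` (5) missing calls.
2. A SNP is *eligible* when the fraction of windows covering it that pass
   exceeds `window_threshold` (0.05).
3. Maximal runs of eligible SNPs are split wherever adjacent markers are
   more than `max_gap_bp` (100 kb) apart.
4. Within each run, greedy left-to-right segmentation: a candidate starts
   at the first unconsumed homozygous call and extends while the
   per-segment heterozygote budget (`max_het_per_segment`, default 1)
   allows, with the right endpoint trimmed back to the last homozygous
   non-missing call.
5. A segment is kept if it has `>= min_snps` (80) SNPs, spans
   `>= min_length_bp` (500 kb), and its bp-per-SNP density is
   `<= min_density_bp_per_snp` (50 kb/SNP).

Defaults correspond to a dense (600K-class) array; for sparser panels
scale `min_snps` down.  `F_ROH (%) = 100 * S_ROH / L_AUTO` with
`L_AUTO = 2280.92` Mb by default (configurable); segment lengths use
inclusive bp coordinates (`end - start + 1`).  Length-class profiles use
bins 0.5–1, >1–2, >2–4, >4–6, >6–8, >8–10, >10 Mb (upper-inclusive).

## 7. ROH islands (`herdstruct.islands`)

A marker's *incidence* in a population is the fraction of its individuals
whose ROH cover it (multiple segments of one animal count once).  Islands
are maximal runs of markers with incidence **strictly** above the
threshold (default 0.5: "more than half"), never crossing chromosome
boundaries; support is the maximum incidence inside.  Two islands of
different populations overlap only if they share at least
`min_shared_snps` (2) markers on the common map — bp intersection alone is
not enough; an island overlapping none is private.  Overlap regions are
reported per contiguous run of markers covered by an identical set of >= 2
populations.  BED export converts to 0-based half-open coordinates.

## 8. Pedigree analyses (`herdstruct.pedigree`)

**F_PED** uses the Meuwissen–Luo tabular method: with D_j the Mendelian-
sampling variance term (`1 - 0.25(1+F_s) - 0.25(1+F_d)`, dropping the term
of any unknown parent), `F_i = sum_j L_ij² D_j - 1` accumulated over the
ancestor closure of i.  Unknown parents are unrelated non-inbred
founders; the algorithm is O(pedigree depth) per individual and is tested
against Wright's path-counting formula.

**A_PED** propagates the percentage of foreign ancestry: founders with
explicit breed fractions contribute `100 * (1 - home_fraction)`;
unlabelled founders born before `purebred_cutoff_year` (default 1950)
count as purebred home stock, as do unknown parents; an unlabelled foreign
founder born after the cutoff is an error rather than a silent guess.
Non-founders receive the parental mean, so an F1 with one purebred foreign
parent is exactly 50%.

**Comparison.** `compare_genomic_pedigree` regresses a genomic measure
(e.g. F_ROH or A_GEN) on its pedigree counterpart via least squares,
reporting n, Pearson r, slope, intercept and R²; optional sire/dam factors
are added as dummy-coded covariates with the augmented R² reported
alongside.

## 9. Pipeline and reproducibility (`herdstruct.pipeline`, CLI)

A single TOML config drives simulate-or-load, MAF filter, relationship/
PCA/F_ST, admixture (unsupervised + supervised with A_GEN), parallel
analysis + contribution scores, k-NN network, ROH + islands, and pedigree
analyses.  One master seed derives a deterministic per-stage sub-seed via
BLAKE2b hashing of `"{seed}:{stage}"`, so stages can be rerun in isolation
and a rerun of the same config is bit-identical.  `manifest.json` records
the config, package version, stage seeds, input SHA-256 hashes, stage
timings, and the artifact list.

The k-NN network connects each individual to its `k` (default 10) nearest
neighbours under `D = 1 - IBS`; the default union rule keeps an edge when
either endpoint selects it (guaranteeing minimum degree k), ties broken by
(distance, id).  Edge thickness for rendering is min–max normalised
similarity.

## Numerical choices

* Dosages are `int8`; all statistics are computed in float64.
* PCA eigenvector sign fixing (largest-|loading| positive) and
  deterministic tie-breaks in the k-NN graph remove platform-dependent
  output differences.
* EM log-likelihoods use `log1p` for the `1 - p` branch; allele
  frequencies are clamped at 1e-6 rather than renormalised.
* Seeds: `numpy.random.default_rng` with `SeedSequence([seed, stream])`
  to decouple the frequency, pedigree, and gene-drop streams.
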