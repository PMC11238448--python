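"""Key-contributor identification: Horn's parallel analysis and the
SVD-based genetic contribution score.

Horn's parallel analysis retains the leading principal components of the
relationship matrix whose eigenvalues exceed the (1 - P) quantile of
eigenvalues obtained under a null model.  The primary null permutes each
marker's genotype column independently across individuals before
recomputing the relationship matrix, which preserves the allele-frequency
spectrum while destroying between-individual structure; a Gaussian-data
null is available as a fast fallback when only the matrix is at hand.

The genetic contribution score of individual j is a variance-weighted sum
of the absolute correlations between j's relationship profile (column j of
G) and the first k singular vectors of G:

    gc_j = sum_{i<=k} w_i * |cor(G[:, j], u_i)|,   w_i = s_i / sum_{i<=k} s_i

so that individuals whose relationship patterns align with the dominant
axes of variation - typically prolific ancestors and their families -
receive high scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from herdstruct.genotype_io import GenotypeDataset
from herdstruct.relationship import RelationshipMatrix, ibs_matrix, pca


@dataclass
class ParallelAnalysisResult:
    k_significant: int
    observed_eigenvalues: np.ndarray
    null_quantiles: np.ndarray
    P: float
    iterations: int
    seed: int | None


@dataclass
class ContributionScores:
    scores: pd.Series   # gc_j per individual, >= 0
    ranks: pd.Series    # dense ranking, 1 = highest score
    k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gc": self.scores, "rank": self.ranks})


def parallel_analysis(
    G: RelationshipMatrix,
    dataset: GenotypeDataset | None = None,
    P: float = 0.01,
    iterations: int = 1000,
    seed: int | None = None,
    null: str = "permute",
) -> ParallelAnalysisResult:
    """Number of significant PCs of G by Horn's parallel analysis.

    With ``null="permute"`` (requires ``dataset``) each replicate permutes
    every genotype column independently and recomputes the IBS matrix; with
    ``null="normal"`` replicates are Wishart-type matrices from standard
    Gaussian data rescaled to the observed eigenvalue mass.  ``k_significant``
    counts the leading observed eigenvalues exceeding their per-component
    (1 - P) null quantile, stopping at the first failure.
    """
    if iterations < 100:
        warnings.warn("fewer than 100 iterations makes the null quantile "
                      "unstable", stacklevel=2)
    if null == "permute" and dataset is None:
        raise ValueError('null="permute" needs the genotype dataset')
    rng = np.random.default_rng(seed)
    obs = pca(G).eigenvalues
    n = obs.size
    null_eigs = np.empty((iterations, n))
    if null == "permute":
        geno = dataset.genotypes
        for it in range(iterations):
            perm = geno.copy()
            for j in range(perm.shape[1]):
                rng.shuffle(perm[:, j])
            shuffled = GenotypeDataset(dataset.samples, dataset.markers, perm)
            null_eigs[it] = pca(ibs_matrix(shuffled)).eigenvalues
    elif null == "normal":
        m = dataset.n_markers if dataset is not None else n
        scale = np.clip(obs, 0, None).sum()
        for it in range(iterations):
            X = rng.standard_normal((n, m))
            Gn = X @ X.T / m
            lam = pca(Gn).eigenvalues
            null_eigs[it] = lam * scale / np.clip(lam, 0, None).sum()
    else:
        raise ValueError(f"unknown null model {null!r}")
    quant = np.quantile(null_eigs, 1.0 - P, axis=0)
    k = 0
    for i in range(n):
        if obs[i] > quant[i]:
            k += 1
        else:
            break
    return ParallelAnalysisResult(
        k_significant=k, observed_eigenvalues=obs, null_quantiles=quant,
        P=P, iterations=iterations, seed=seed,
    )


def contribution_scores(G: RelationshipMatrix, k: int) -> ContributionScores:
    """Genetic contribution score gc_j for each individual.

    Uses the SVD of G restricted to the first ``k`` components; individuals
    whose relationship column has zero variance receive score 0.
    """
    vals = G.values
    n = vals.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    U, s, _ = np.linalg.svd(vals)
    w = s[:k] / s[:k].sum() if s[:k].sum() > 0 else np.zeros(k)

    col_sd = vals.std(axis=0)
    zero_var = col_sd == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} individual(s) have a "
                      "zero-variance relationship column; their score is 0",
                      stacklevel=2)
    cols = vals - vals.mean(axis=0)
    scores = np.zeros(n)
    for i in range(k):
        u = U[:, i] - U[:, i].mean()
        u_sd = u.std()
        if u_sd == 0:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (cols.T @ u) / (n * col_sd * u_sd)
        scores += w[i] * np.abs(np.where(zero_var, 0.0, corr))
    ser = pd.Series(scores, index=G.ids, name="gc")
    ranks = ser.rank(method="dense", ascending=False).astype(int)
    return ContributionScores(scores=ser, ranks=ranks, k=k)
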