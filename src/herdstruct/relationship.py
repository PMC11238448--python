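"""Identity-by-state relationships, PCA, and pairwise F_ST.

The relationship matrix G holds, for each pair of individuals, the mean
per-SNP allele-sharing score over markers where both are called: identical
genotypes score 1, genotypes sharing one allele score 0.5, and opposite
homozygotes score 0.  Genetic distance is 1 - G.  Population differentiation
is estimated per pair of populations with Weir & Cockerham's variance
components combined as a ratio of sums across SNPs (the estimator behind
PLINK 1.9's F_ST), with a Hudson-style estimator available as an option.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from herdstruct.genotype_io import MISSING, GenotypeDataset


@dataclass
class RelationshipMatrix:
    """Symmetric matrix of pairwise IBS similarities in [0, 1]."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("relationship matrix must be symmetric")
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


@dataclass
class PCAResult:
    eigenvalues: np.ndarray          # descending
    eigenvectors: np.ndarray         # orthonormal columns
    variance_fraction: np.ndarray    # of positive eigenvalues; sums to 1

    def coordinates(self, n_components: int | None = None) -> np.ndarray:
        """Sample coordinates: eigenvectors scaled by sqrt(eigenvalue)."""
        k = n_components or int((self.eigenvalues > 0).sum())
        lam = np.clip(self.eigenvalues[:k], 0.0, None)
        return self.eigenvectors[:, :k] * np.sqrt(lam)


@dataclass
class FstMatrix:
    populations: list[str]
    values: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.populations,
                            columns=self.populations)


def ibs_matrix(dataset: GenotypeDataset) -> RelationshipMatrix:
    """Pairwise IBS relationship matrix G.

    Entry (i, j) is the mean over markers called in both individuals of
    1 - |g_i - g_j| / 2.  Raises if any pair shares no called marker.
    """
    g = dataset.genotypes
    n = dataset.n_samples
    if (g == MISSING).any():
        gf = dataset.dosage_float()
        obs = ~np.isnan(gf)
        gz = np.nan_to_num(gf)
        vals = np.empty((n, n))
        for i in range(n):
            both = obs[i] & obs  # (n, m)
            shared = both.sum(axis=1)
            if (shared == 0).any():
                j = int(np.where(shared == 0)[0][0])
                raise ValueError(
                    f"individuals {dataset.ids[i]!r} and {dataset.ids[j]!r} "
                    "share no non-missing marker"
                )
            diff = np.abs(gz[i] - gz) * both
            vals[i] = 1.0 - diff.sum(axis=1) / (2.0 * shared)
    else:
        m = dataset.n_markers
        d = squareform(pdist(g.astype(float), metric="cityblock"))
        vals = 1.0 - d / (2.0 * m)
    vals = (vals + vals.T) / 2.0
    return RelationshipMatrix(dataset.ids, vals)


def distance_matrix(G: RelationshipMatrix) -> RelationshipMatrix:
    """Genetic distances D = 1 - G with a zero diagonal."""
    d = 1.0 - G.values
    np.fill_diagonal(d, 0.0)
    return RelationshipMatrix(G.ids, d)


def pca(G: RelationshipMatrix | np.ndarray) -> PCAResult:
    """Eigendecomposition of the double-centered relationship matrix.

    Components are ordered by decreasing eigenvalue; variance fractions are
    taken over positive eigenvalues only.  Each eigenvector is oriented so
    its largest-magnitude loading is positive.
    """
    vals = G.values if isinstance(G, RelationshipMatrix) else np.asarray(G, float)
    if not np.isfinite(vals).all():
        raise ValueError("relationship matrix contains non-finite entries")
    n = vals.shape[0]
    row_mean = vals.mean(axis=1, keepdims=True)
    centered = vals - row_mean - row_mean.T + vals.mean()
    centered = (centered + centered.T) / 2.0
    lam, vec = np.linalg.eigh(centered)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    for i in range(n):
        j = int(np.argmax(np.abs(vec[:, i])))
        if vec[j, i] < 0:
            vec[:, i] = -vec[:, i]
    pos = lam[lam > 0]
    frac = np.where(lam > 0, lam / pos.sum(), 0.0) if pos.size else np.zeros(n)
    return PCAResult(lam, vec, frac)


def _wc_components(g1: np.ndarray, g2: np.ndarray):
    """Weir-Cockerham (1984) per-SNP variance components for two samples.

    ``g1``/``g2`` are dosage matrices (individuals x markers) with NaN for
    missing.  Returns per-SNP arrays (a, b, c): among-population, among
    individuals within populations, and within-individual components.
    """
    r = 2
    comps = []
    for g in (g1, g2):
        obs = ~np.isnan(g)
        n_i = obs.sum(axis=0).astype(float)           # individuals called
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.nansum(g, axis=0) / (2.0 * n_i)
            h_i = np.nansum(g == 1, axis=0) / n_i     # observed het freq
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0
        a = nbar / nc * (s2 - (inner) / (nbar - 1))
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    return a, b, c


def _pair_fst(g1, g2, estimator="wc") -> float:
    if estimator == "wc":
        a, b, c = _wc_components(g1, g2)
        den = a + b + c
        ok = np.isfinite(den) & (den != 0)
        if not ok.any():
            raise ValueError("no informative SNPs for F_ST")
        return max(0.0, float(np.sum(a[ok]) / np.sum(den[ok])))
    if estimator == "hudson":
        num_parts, den_parts = [], []
        for g in (g1, g2):
            obs = ~np.isnan(g)
            n = 2.0 * obs.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.nansum(g, axis=0) / n
            num_parts.append((p, n))
        (p1, n1), (p2, n2) = num_parts
        with np.errstate(invalid="ignore", divide="ignore"):
            num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
            den = p1 * (1 - p2) + p2 * (1 - p1)
        ok = np.isfinite(den) & (den != 0)
        if not ok.any():
            raise ValueError("no informative SNPs for F_ST")
        return max(0.0, float(np.sum(num[ok]) / np.sum(den[ok])))
    raise ValueError(f"unknown estimator {estimator!r}")


def pairwise_fst(
    dataset: GenotypeDataset,
    labels: list[str] | None = None,
    estimator: str = "wc",
) -> FstMatrix:
    """Pairwise F_ST between populations.

    Per-SNP Weir-Cockerham variance components are combined as a ratio of
    sums across SNPs (``estimator="wc"``, the default, matching PLINK 1.9's
    Wright's-F_ST output); ``estimator="hudson"`` gives the Hudson
    ratio-of-averages estimator.  Negative per-SNP components are kept; the
    final estimate is floored at zero.
    """
    pops = labels or list(dict.fromkeys(dataset.samples["population"]))
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    gf = dataset.dosage_float()
    groups = {}
    for p in pops:
        rows = np.where(dataset.samples["population"].to_numpy() == p)[0]
        if rows.size < 2:
            raise ValueError(f"population {p!r} has fewer than 2 individuals")
        sub = gf[rows]
        if np.isnan(sub).all(axis=0).all():
            raise ValueError(f"population {p!r} has no called genotypes")
        groups[p] = sub
    k = len(pops)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = _pair_fst(groups[pops[i]], groups[pops[j]],
                                              estimator)
    return FstMatrix(pops, out)


# ---------------------------------------------------------------------------
# NEXUS distance export (for SplitsTree-class network software)


def _nexus_label(label: str) -> str:
    if re.search(r"[\s(){}\[\]/\\,;:=*'\"`+<>-]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def export_nexus_distances(fst: FstMatrix, path) -> None:
    """Write a NEXUS file with TAXA and DISTANCES (lower-triangular) blocks."""
    n = len(fst.populations)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"  DIMENSIONS NTAX={n};\n  TAXLABELS\n")
        for p in fst.populations:
            fh.write(f"    {_nexus_label(p)}\n")
        fh.write("  ;\nEND;\n\nBEGIN DISTANCES;\n")
        fh.write(f"  DIMENSIONS NTAX={n};\n")
        fh.write("  FORMAT TRIANGLE=LOWER DIAGONAL LABELS;\n  MATRIX\n")
        for i, p in enumerate(fst.populations):
            row = " ".join(f"{fst.values[i, j]:.6f}" for j in range(i + 1))
            fh.write(f"    {_nexus_label(p)} {row}\n")
        fh.write("  ;\nEND;\n")


def read_nexus_distances(path) -> FstMatrix:
    """Parse a NEXUS DISTANCES block written by :func:`export_nexus_distances`."""
    with open(path) as fh:
        text = fh.read()
    m = re.search(r"BEGIN DISTANCES;(.*?)END;", text, re.S | re.I)
    if not m:
        raise ValueError(f"{path}: no DISTANCES block")
    block = m.group(1)
    mm = re.search(r"MATRIX(.*?);", block, re.S | re.I)
    labels, rows = [], []
    for line in mm.group(1).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("'"):
            end = line.index("'", 1)
            while end + 1 < len(line) and line[end + 1] == "'":
                end = line.index("'", end + 2)
            label = line[1:end].replace("''", "'")
            rest = line[end + 1:]
        else:
            label, _, rest = line.partition(" ")
        labels.append(label)
        rows.append([float(x) for x in rest.split()])
    n = len(labels)
    vals = np.zeros((n, n))
    for i, r in enumerate(rows):
        for j, x in enumerate(r):
            vals[i, j] = vals[j, i] = x
    return FstMatrix(labels, vals)
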