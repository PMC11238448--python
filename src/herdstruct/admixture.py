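"""Model-based ancestry estimation (supervised and unsupervised).

The model treats each genotype g_ij as Binomial(2, p_ij) with
p_ij = sum_k q_ik f_jk, where q_i is individual i's ancestry vector on the
K-simplex and f_jk the allele frequency of SNP j in ancestral population k;
SNPs are assumed independent.  Fitting uses monotone multiplicative EM
updates (FRAPPE-style).  In supervised mode the F columns are fixed to
reference-panel frequencies and only the Q rows of the target individuals
are estimated; in unsupervised mode Q and F are estimated jointly from a
seeded random start with restarts.  A masking-based cross-validation error
(mean binomial deviance on held-out genotype entries) scores the choice of
K, and the A_GEN summary converts a supervised fit into the percentage of
non-reference ancestry per individual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from herdstruct.genotype_io import GenotypeDataset

EPS = 1e-6  # allele-frequency clamp keeping the log-likelihood finite


@dataclass
class AdmixtureFit:
    Q: pd.DataFrame          # individuals x populations, rows on the simplex
    F: pd.DataFrame          # markers x populations, clamped to [EPS, 1-EPS]
    loglik: float
    mode: str                # "supervised" | "unsupervised"
    K: int
    n_iter: int
    converged: bool


def _loglik(g: np.ndarray, obs: np.ndarray, Q: np.ndarray, F: np.ndarray) -> float:
    P = Q @ F.T
    ll = np.where(obs, g * np.log(P) + (2.0 - g) * np.log1p(-P), 0.0)
    return float(ll.sum())


def _em_q_step(g, obs, Q, F, update_f: bool):
    """One EM sweep; genotypes ``g`` with mask ``obs`` (missing = excluded)."""
    P = Q @ F.T
    R1 = np.where(obs, g / P, 0.0)
    R0 = np.where(obs, (2.0 - g) / (1.0 - P), 0.0)
    m_obs = obs.sum(axis=1, keepdims=True)
    Q_new = Q * (R1 @ F + R0 @ (1.0 - F)) / (2.0 * m_obs)
    Q_new /= Q_new.sum(axis=1, keepdims=True)
    if update_f:
        num = F * (R1.T @ Q)
        den = num + (1.0 - F) * (R0.T @ Q)
        with np.errstate(invalid="ignore"):
            F_new = np.where(den > 0, num / den, F)
        F_new = np.clip(F_new, EPS, 1.0 - EPS)
    else:
        F_new = F
    return Q_new, F_new


def reference_frequencies(
    dataset: GenotypeDataset, reference_labels: dict[str, str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Per-population allele frequencies of the labelled reference panels.

    ``reference_labels`` maps sample id -> ancestral population; by default
    every sample is a reference for its own population label.
    """
    if reference_labels is None:
        reference_labels = dict(zip(dataset.samples["id"],
                                    dataset.samples["population"]))
    pops = list(dict.fromkeys(reference_labels.values()))
    gf = dataset.dosage_float()
    cols = []
    id_index = {s: i for i, s in enumerate(dataset.ids)}
    for p in pops:
        rows = [id_index[s] for s, lab in reference_labels.items() if lab == p]
        if len(rows) < 2:
            raise ValueError(f"reference population {p!r} needs >= 2 individuals")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            f = np.nanmean(gf[rows], axis=0) / 2.0
        cols.append(f)
    F = np.clip(np.column_stack(cols), EPS, 1.0 - EPS)
    return F, pops


def fit_supervised(
    dataset: GenotypeDataset,
    reference_labels: dict[str, str],
    target_ids: list[str],
    tol: float = 1e-4,
    max_iter: int = 2000,
) -> AdmixtureFit:
    """Estimate ancestry of target individuals against fixed reference panels.

    Ancestral allele frequencies are the reference-panel frequencies
    (clamped away from 0/1); each target's Q row maximises the
    independent-SNP binomial log-likelihood via EM on the simplex.
    """
    overlap = set(target_ids) & set(reference_labels)
    if overlap:
        raise ValueError(f"targets also listed as references: {sorted(overlap)[:5]}")
    F, pops = reference_frequencies(dataset, reference_labels)
    K = len(pops)
    targets = dataset.subset_samples(target_ids)
    gf = targets.dosage_float()
    obs = ~np.isnan(gf)
    # a reference panel monomorphic everywhere carries no ancestry signal
    for k, p in enumerate(pops):
        if np.all((F[:, k] <= EPS) | (F[:, k] >= 1 - EPS)):
            informative = (F[:, k] > EPS) & (F[:, k] < 1 - EPS)
            if not informative.any():
                raise ValueError(f"reference population {p!r} is monomorphic "
                                 "at every SNP")
    g = np.nan_to_num(gf)
    n = len(target_ids)
    Q = np.full((n, K), 1.0 / K)
    ll_prev = _loglik(g, obs, Q, F)
    converged = False
    for it in range(1, max_iter + 1):
        Q, _ = _em_q_step(g, obs, Q, F, update_f=False)
        ll = _loglik(g, obs, Q, F)
        if ll - ll_prev < tol:
            converged = True
            break
        ll_prev = ll
    if not converged:
        warnings.warn(f"supervised EM not converged after {max_iter} iterations")
    return AdmixtureFit(
        Q=pd.DataFrame(Q, index=target_ids, columns=pops),
        F=pd.DataFrame(F, index=dataset.markers["id"], columns=pops),
        loglik=ll, mode="supervised", K=K, n_iter=it, converged=converged,
    )


def fit_unsupervised(
    dataset: GenotypeDataset,
    K: int,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 2000,
    n_restarts: int = 3,
) -> AdmixtureFit:
    """Joint EM estimation of Q and F with random restarts; returns the run
    with the best converged log-likelihood.  Cluster labels are arbitrary
    (label switching is left to the caller)."""
    n = dataset.n_samples
    if K < 1 or K > n:
        raise ValueError(f"K must be in [1, {n}]")
    gf = dataset.dosage_float()
    obs = ~np.isnan(gf)
    g = np.nan_to_num(gf)
    if K == 1:
        with np.errstate(invalid="ignore"):
            f = np.where(obs.sum(axis=0) > 0,
                         g.sum(axis=0) / (2.0 * obs.sum(axis=0)), 0.5)
        F = np.clip(f[:, None], EPS, 1 - EPS)
        Q = np.ones((n, 1))
        return AdmixtureFit(
            Q=pd.DataFrame(Q, index=dataset.ids, columns=["K1"]),
            F=pd.DataFrame(F, index=dataset.markers["id"], columns=["K1"]),
            loglik=_loglik(g, obs, Q, F), mode="unsupervised", K=1,
            n_iter=0, converged=True,
        )
    best = None
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        Q = rng.dirichlet(np.ones(K), size=n)
        F = np.clip(rng.uniform(0.05, 0.95, size=(dataset.n_markers, K)),
                    EPS, 1 - EPS)
        ll_prev = _loglik(g, obs, Q, F)
        converged = False
        for it in range(1, max_iter + 1):
            Q, F = _em_q_step(g, obs, Q, F, update_f=True)
            ll = _loglik(g, obs, Q, F)
            if ll - ll_prev < tol:
                converged = True
                break
            ll_prev = ll
        if not converged:
            warnings.warn(f"unsupervised EM not converged after {max_iter} iterations")
        if best is None or ll > best[0]:
            best = (ll, Q, F, it, converged)
    ll, Q, F, it, converged = best
    cols = [f"K{k + 1}" for k in range(K)]
    return AdmixtureFit(
        Q=pd.DataFrame(Q, index=dataset.ids, columns=cols),
        F=pd.DataFrame(F, index=dataset.markers["id"], columns=cols),
        loglik=ll, mode="unsupervised", K=K, n_iter=it, converged=converged,
    )


def align_columns(Q_a: pd.DataFrame, Q_b: pd.DataFrame) -> pd.DataFrame:
    """Relabel ``Q_b`` columns to best match ``Q_a`` (greedy correlation)."""
    corr = np.corrcoef(Q_a.to_numpy().T, Q_b.to_numpy().T)
    K = Q_a.shape[1]
    cross = corr[:K, K:]
    perm = [-1] * K
    used = set()
    for a in np.argsort(-np.abs(cross).max(axis=1)):
        order = np.argsort(-cross[a])
        for b in order:
            if b not in used:
                perm[a] = int(b)
                used.add(int(b))
                break
    out = Q_b.iloc[:, perm]
    out.columns = Q_a.columns
    return out


def cv_error(
    dataset: GenotypeDataset,
    K: int,
    mask_fraction: float = 0.1,
    n_folds: int = 3,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[float, float]:
    """Masking-based cross-validation error for one K.

    Each fold masks a random ``mask_fraction`` of called genotype entries,
    fits the unsupervised model on the rest, and scores the masked entries
    by their mean binomial deviance.  Returns (mean, sd) over folds.
    """
    if not 0.0 < mask_fraction < 0.5:
        raise ValueError("mask_fraction must be in (0, 0.5)")
    rng = np.random.default_rng(seed)
    gf = dataset.dosage_float()
    called = ~np.isnan(gf)
    scores = []
    for fold in range(n_folds):
        mask = called & (rng.random(gf.shape) < mask_fraction)
        train = dataset.genotypes.copy()
        train[mask] = -1
        masked_ds = GenotypeDataset(dataset.samples.copy(),
                                    dataset.markers.copy(), train)
        fit = fit_unsupervised(masked_ds, K, seed=int(rng.integers(2**31)),
                               **fit_kwargs)
        P = np.clip(fit.Q.to_numpy() @ fit.F.to_numpy().T, EPS, 1 - EPS)
        g = gf[mask]
        p = P[mask]
        dev = -2.0 * (g * np.log(p) + (2.0 - g) * np.log1p(-p))
        scores.append(float(dev.mean()))
    return float(np.mean(scores)), float(np.std(scores))


def agen(fit: AdmixtureFit, reference_population: str) -> pd.Series:
    """Percentage of non-reference ancestry, A_GEN = 100 * (1 - q_ref)."""
    if reference_population not in fit.Q.columns:
        raise KeyError(f"{reference_population!r} not among fit populations "
                       f"{list(fit.Q.columns)}")
    return 100.0 * (1.0 - fit.Q[reference_population])
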