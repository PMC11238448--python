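"""Runs-of-homozygosity detection and F_ROH summaries.

Detection follows the scanning-window semantics of PLINK's ``--homozyg``:
a window of ``window_snps`` consecutive SNPs passes when it contains at most
``window_max_het`` heterozygous and ``window_max_missing`` missing calls;
each SNP's hit rate is the fraction of windows covering it that pass, and
SNPs with hit rate above ``window_threshold`` are ROH-eligible.  Maximal
runs of eligible SNPs, split wherever the gap between adjacent markers
exceeds ``max_gap_bp``, are then scanned left to right: each candidate
segment starts at the first unconsumed homozygous call and is extended as
far as the per-segment heterozygote allowance permits, with endpoints
trimmed to homozygous non-missing calls.  A segment is emitted when it
meets the minimum SNP count, minimum length, and SNP-density constraints.

The genomic inbreeding coefficient F_ROH is the total ROH length S_ROH
divided by the autosomal genome length L_AUTO (default 2280.92 Mb,
configurable), expressed in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from herdstruct.genotype_io import MISSING, GenotypeDataset

L_AUTO_MB = 2280.92

SEGMENT_COLUMNS = ["id", "chrom", "start_bp", "end_bp", "n_snps", "n_het",
                   "length_bp"]


@dataclass(frozen=True)
class ROHParams:
    """Detection parameters; defaults are the standard 600K-panel settings
    (one SNP per 50 kb, 100 kb gap, 500 kb / 80-SNP minimum, one het allowed)
    with PLINK's default scanning window."""

    min_density_bp_per_snp: int = 50_000
    max_gap_bp: int = 100_000
    min_length_bp: int = 500_000
    min_snps: int = 80
    max_het_per_segment: int = 1
    window_snps: int = 50
    window_threshold: float = 0.05
    window_max_het: int = 1
    window_max_missing: int = 5
    strict_min_snps: bool = False  # require n_snps > min_snps instead of >=

    def __post_init__(self) -> None:
        for name in ("min_density_bp_per_snp", "max_gap_bp", "min_length_bp",
                     "min_snps", "window_snps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.window_threshold < 1.0:
            raise ValueError("window_threshold must be in (0,1)")


def _eligible_snps(het: np.ndarray, miss: np.ndarray, params: ROHParams) -> np.ndarray:
    """Hit-rate eligibility of each SNP on one chromosome (vectorised)."""
    m = het.size
    w = min(params.window_snps, m)
    n_win = m - w + 1
    het_c = np.concatenate([[0], np.cumsum(het)])
    mis_c = np.concatenate([[0], np.cumsum(miss)])
    win_het = het_c[w:] - het_c[:-w]
    win_mis = mis_c[w:] - mis_c[:-w]
    passing = (win_het <= params.window_max_het) & (win_mis <= params.window_max_missing)
    # window i covers SNPs [i, i+w-1]; windows covering SNP j: max(0, j-w+1)..min(j, n_win-1)
    pass_c = np.concatenate([[0], np.cumsum(passing)])
    j = np.arange(m)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n_win - 1)
    hits = pass_c[hi + 1] - pass_c[lo]
    total = hi - lo + 1
    return hits / total > params.window_threshold


def _segments_in_run(g: np.ndarray, pos: np.ndarray, params: ROHParams):
    """Greedy left-to-right segmentation of one eligible run.

    ``g`` and ``pos`` are the genotypes and positions of the run's SNPs.
    Yields (start_idx, end_idx) index pairs into the run.
    """
    het = g == 1
    miss = g == MISSING
    m = g.size
    i = 0
    while i < m:
        while i < m and (het[i] or miss[i]):
            i += 1
        if i >= m:
            break
        hets = 0
        k = i
        last_hom = i
        while k + 1 < m:
            nxt = k + 1
            if het[nxt] and hets + 1 > params.max_het_per_segment:
                break
            if het[nxt]:
                hets += 1
            k = nxt
            if not het[k] and not miss[k]:
                last_hom = k
        yield i, last_hom
        i = k + 1


def _segment_ok(start: int, end: int, g: np.ndarray, pos: np.ndarray,
                params: ROHParams) -> bool:
    n_snps = end - start + 1
    length = int(pos[end] - pos[start] + 1)
    min_snps_ok = (n_snps > params.min_snps if params.strict_min_snps
                   else n_snps >= params.min_snps)
    return (min_snps_ok
            and length >= params.min_length_bp
            and length / n_snps <= params.min_density_bp_per_snp)


def detect_roh(dataset: GenotypeDataset, params: ROHParams | None = None) -> pd.DataFrame:
    """Detect ROH segments for every individual.

    Returns a DataFrame with columns ``id, chrom, start_bp, end_bp, n_snps,
    n_het, length_bp`` (1-based inclusive coordinates).
    """
    params = params or ROHParams()
    rows = []
    chrom_groups = [
        (chrom, grp.index.to_numpy(), grp["bp"].to_numpy())
        for chrom, grp in dataset.markers.groupby("chrom", sort=False)
    ]
    for chrom, cols, pos in chrom_groups:
        gaps_over = np.diff(pos) > params.max_gap_bp
        sub = dataset.genotypes[:, cols]
        for i, pid in enumerate(dataset.ids):
            g = sub[i]
            het = g == 1
            miss = g == MISSING
            eligible = _eligible_snps(het, miss, params)
            # maximal eligible runs, split at over-long gaps
            boundaries = np.zeros(g.size + 1, dtype=bool)
            boundaries[0] = boundaries[-1] = True
            boundaries[1:-1] = gaps_over
            start = None
            run_bounds = []
            for j in range(g.size):
                if eligible[j] and (start is None):
                    start = j
                if start is not None:
                    stop = (j + 1 == g.size or not eligible[j + 1]
                            or boundaries[j + 1])
                    if stop:
                        run_bounds.append((start, j))
                        start = None
            for rs, re in run_bounds:
                gr, pr = g[rs:re + 1], pos[rs:re + 1]
                for s, e in _segments_in_run(gr, pr, params):
                    if _segment_ok(s, e, gr, pr, params):
                        seg = gr[s:e + 1]
                        rows.append((
                            pid, chrom, int(pr[s]), int(pr[e]),
                            int(e - s + 1), int((seg == 1).sum()),
                            int(pr[e] - pr[s] + 1),
                        ))
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def summarize_roh(
    segments: pd.DataFrame,
    individuals: pd.DataFrame,
    l_auto_mb: float = L_AUTO_MB,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual and per-population ROH summary statistics.

    ``individuals`` is a DataFrame with ``id`` and ``population`` columns
    (every genotyped individual, so animals without segments are reported
    with N_ROH = 0).  Returns ``(per_individual, per_population)`` tables:
    N_ROH, S_ROH (Mb), L_ROH (mean Mb, NaN when N_ROH = 0) and
    F_ROH (%) = 100 * S_ROH / L_AUTO.
    """
    base = individuals[["id", "population"]].copy()
    if len(segments):
        agg = segments.groupby("id")["length_bp"].agg(["count", "sum"])
    else:
        agg = pd.DataFrame(columns=["count", "sum"])
    base = base.merge(agg, left_on="id", right_index=True, how="left")
    base["N_ROH"] = base.pop("count").astype(float).fillna(0).astype(int)
    s_mb = base.pop("sum").astype(float).fillna(0.0) / 1e6
    base["S_ROH_Mb"] = s_mb
    base["L_ROH_Mb"] = np.where(base["N_ROH"] > 0, s_mb / base["N_ROH"].replace(0, 1),
                                np.nan)
    base["F_ROH_pct"] = 100.0 * s_mb / l_auto_mb

    stats = ["N_ROH", "S_ROH_Mb", "L_ROH_Mb", "F_ROH_pct"]
    per_pop = (
        base.groupby("population", sort=False)[stats]
        .agg(["mean", "std", "median", "min", "max"])
    )
    return base, per_pop


LENGTH_CLASSES_MB = [(0.5, 1.0), (1.0, 2.0), (2.0, 4.0), (4.0, 6.0),
                     (6.0, 8.0), (8.0, 10.0), (10.0, np.inf)]
LENGTH_CLASS_LABELS = ["0.5-1", ">1-2", ">2-4", ">4-6", ">6-8", ">8-10", ">10"]


def length_class_profile(
    segments: pd.DataFrame,
    populations: pd.Series | dict,
) -> pd.DataFrame:
    """Fraction of segments per length class (Mb) for each population.

    Classes are lower-exclusive / upper-inclusive except the first, which
    includes its 0.5 Mb lower bound.  ``populations`` maps individual id to
    population.  Raises if any segment is shorter than 0.5 Mb.
    """
    if not len(segments):
        return pd.DataFrame(columns=LENGTH_CLASS_LABELS)
    pop = pd.Series(populations)
    length_mb = segments["length_bp"] / 1e6
    if (length_mb < 0.5).any():
        raise ValueError("segment shorter than 0.5 Mb violates the minimum-"
                         "length invariant")
    cls = np.searchsorted([c[1] for c in LENGTH_CLASSES_MB], length_mb,
                          side="left")
    df = pd.DataFrame({
        "population": segments["id"].map(pop),
        "class": [LENGTH_CLASS_LABELS[c] for c in cls],
    })
    counts = (df.groupby("population", sort=False)["class"]
              .value_counts().unstack(fill_value=0)
              .reindex(columns=LENGTH_CLASS_LABELS, fill_value=0))
    return counts.div(counts.sum(axis=1), axis=0)
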