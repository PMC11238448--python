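"""ROH islands: consensus homozygous regions within populations.

A marker's incidence in a population is the fraction of its individuals
whose ROH segments cover that marker.  Maximal runs of consecutive markers
whose incidence is strictly above the support threshold (default 0.5, i.e.
"more than half the population") form islands, reported with bp bounds at
their first and last member SNP.  Islands found in only one population are
private; islands of different populations are considered overlapping only
when they share at least ``min_shared_snps`` markers (default 2), counted on
the common marker map rather than by bp intersection alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from herdstruct.genotype_io import GenotypeDataset

ISLAND_COLUMNS = ["population", "chrom", "start_bp", "end_bp", "n_snps",
                  "support", "length_mb", "start_idx", "end_idx"]


def snp_incidence(
    segments: pd.DataFrame,
    dataset: GenotypeDataset,
    population: str,
) -> np.ndarray:
    """Per-marker fraction of a population's individuals lying in a ROH.

    A marker counts as covered for an individual when its position falls
    inside any of that individual's segments (bounds inclusive).
    """
    members = dataset.samples.loc[dataset.samples["population"] == population,
                                  "id"]
    if members.empty:
        raise ValueError(f"no individuals in population {population!r}")
    markers = dataset.markers
    m = len(markers)
    covered = np.zeros(m, dtype=np.int64)
    chrom_idx = {
        chrom: (grp.index.to_numpy(), grp["bp"].to_numpy())
        for chrom, grp in markers.groupby("chrom", sort=False)
    }
    segs = segments[segments["id"].isin(set(members))]
    for pid, grp in segs.groupby("id"):
        mask = np.zeros(m, dtype=bool)
        for _, seg in grp.iterrows():
            cols, pos = chrom_idx[seg["chrom"]]
            lo = np.searchsorted(pos, seg["start_bp"], side="left")
            hi = np.searchsorted(pos, seg["end_bp"], side="right")
            mask[cols[lo:hi]] = True
        covered += mask
    return covered / len(members)


def detect_islands(
    incidence: np.ndarray,
    dataset: GenotypeDataset,
    population: str,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Maximal runs of markers with incidence strictly above ``threshold``.

    A marker at exactly the threshold is excluded ("more than" is strict).
    Runs never span a chromosome boundary.  Returns one row per island with
    bp bounds at the first/last member SNP, the number of member SNPs, the
    island's support (max incidence across its SNPs), and its length in Mb.
    """
    markers = dataset.markers
    above = np.asarray(incidence) > threshold
    rows = []
    for chrom, grp in markers.groupby("chrom", sort=False):
        cols = grp.index.to_numpy()
        pos = grp["bp"].to_numpy()
        a = above[cols]
        if not a.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], a.view(np.int8), [0]])))
        for s, e in zip(edges[::2], edges[1::2] - 1):
            rows.append((
                population, chrom, int(pos[s]), int(pos[e]), int(e - s + 1),
                float(np.max(incidence[cols[s:e + 1]])),
                float(pos[e] - pos[s] + 1) / 1e6,
                int(cols[s]), int(cols[e]),
            ))
    return pd.DataFrame(rows, columns=ISLAND_COLUMNS)


def classify_islands(
    islands_by_population: dict[str, pd.DataFrame],
    min_shared_snps: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split islands into private and shared, and report overlap regions.

    All island tables must come from the same marker map (they carry global
    marker indices).  Two islands overlap when they share at least
    ``min_shared_snps`` markers; an island is private when it overlaps no
    island of any other population.  The overlap table lists, per contiguous
    run of markers covered by the same set of two or more populations, the
    chromosome, bp bounds, length and the sharing populations.
    """
    tables = []
    for pop, df in islands_by_population.items():
        t = df.copy()
        t["population"] = pop
        tables.append(t)
    allisl = (pd.concat(tables, ignore_index=True) if tables
              else pd.DataFrame(columns=ISLAND_COLUMNS))

    private_flags = []
    for i, row in allisl.iterrows():
        shared = False
        for j, other in allisl.iterrows():
            if other["population"] == row["population"]:
                continue
            if other["chrom"] != row["chrom"]:
                continue
            lo = max(row["start_idx"], other["start_idx"])
            hi = min(row["end_idx"], other["end_idx"])
            if hi - lo + 1 >= min_shared_snps:
                shared = True
                break
        private_flags.append(not shared)
    allisl["private"] = private_flags

    # contiguous marker runs covered by an identical set of >= 2 populations
    overlap_rows = []
    if len(allisl):
        for chrom, grp in allisl.groupby("chrom", sort=False):
            lo = int(grp["start_idx"].min())
            hi = int(grp["end_idx"].max())
            cover: list[frozenset] = []
            for j in range(lo, hi + 1):
                pops = frozenset(
                    r["population"] for _, r in grp.iterrows()
                    if r["start_idx"] <= j <= r["end_idx"]
                )
                cover.append(pops)
            pos_by_idx = {}
            for _, r in grp.iterrows():
                pos_by_idx[r["start_idx"]] = r["start_bp"]
                pos_by_idx[r["end_idx"]] = r["end_bp"]
            start = 0
            for j in range(1, len(cover) + 1):
                if j == len(cover) or cover[j] != cover[start]:
                    pops = cover[start]
                    n_run = j - start
                    if len(pops) >= 2 and n_run >= min_shared_snps:
                        overlap_rows.append({
                            "chrom": chrom,
                            "start_idx": lo + start,
                            "end_idx": lo + j - 1,
                            "n_shared_snps": n_run,
                            "populations": ",".join(sorted(pops)),
                        })
                    start = j
    overlaps = pd.DataFrame(
        overlap_rows,
        columns=["chrom", "start_idx", "end_idx", "n_shared_snps", "populations"],
    )
    return allisl, overlaps


def islands_with_positions(overlaps: pd.DataFrame,
                           dataset: GenotypeDataset) -> pd.DataFrame:
    """Attach bp bounds and Mb length to an overlap table."""
    if not len(overlaps):
        out = overlaps.copy()
        out["start_bp"] = out["end_bp"] = out["length_mb"] = []
        return out
    bp = dataset.markers["bp"].to_numpy()
    out = overlaps.copy()
    out["start_bp"] = bp[out["start_idx"].to_numpy()]
    out["end_bp"] = bp[out["end_idx"].to_numpy()]
    out["length_mb"] = (out["end_bp"] - out["start_bp"] + 1) / 1e6
    return out


def write_bed(islands: pd.DataFrame, path) -> None:
    """Islands as BED (0-based half-open; conversion noted in the header)."""
    with open(path, "w") as fh:
        fh.write("# BED coordinates: 0-based half-open "
                 "(start_bp-1, end_bp) from 1-based inclusive island bounds\n")
        for _, r in islands.iterrows():
            name = f"{r['population']}_island"
            fh.write(f"{r['chrom']}\t{int(r['start_bp']) - 1}\t{int(r['end_bp'])}"
                     f"\t{name}\t{r['support']:.3f}\n")
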