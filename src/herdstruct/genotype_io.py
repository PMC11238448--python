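"""Genotype containers, PLINK-text / VCF input-output, and marker filters.

Genotypes are stored as B-allele dosages in an ``int8`` matrix with ``-1``
for missing calls.  Marker coordinates are 1-based inclusive base pairs, as
in PLINK ``.map`` files; chromosome names are kept as strings so both
``"1"`` and ``"ECA1"`` style maps work unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


class GenotypeFormatError(ValueError):
    """A genotype file violates the expected format (message names the line)."""


class EmptyPanelError(ValueError):
    """A filter removed every marker from the panel."""


@dataclass
class GenotypeDataset:
    """SNP genotypes for a set of individuals with population labels.

    Parameters
    ----------
    samples : DataFrame with columns ``id`` and ``population``.
    markers : DataFrame with columns ``chrom``, ``id``, ``bp``, ``allele_a``
        and ``allele_b``, sorted by chromosome then position.
    genotypes : ``(n_samples, n_markers)`` int8 matrix of B-allele dosages
        in {0, 1, 2}; ``-1`` marks a missing call.
    """

    samples: pd.DataFrame
    markers: pd.DataFrame
    genotypes: np.ndarray
    dropped_markers: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.markers = self.markers.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if self.n_samples < 1 or self.n_markers < 1:
            raise ValueError("dataset needs at least one sample and one marker")
        bad = ~np.isin(self.genotypes, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 for missing")
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def ids(self) -> list[str]:
        return self.samples["id"].tolist()

    @property
    def populations(self) -> pd.Series:
        return self.samples.set_index("id")["population"]

    def dosage_float(self) -> np.ndarray:
        """Genotypes as float with NaN for missing calls."""
        g = self.genotypes.astype(float)
        g[self.genotypes == MISSING] = np.nan
        return g

    def subset_markers(self, keep: np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep)
        return GenotypeDataset(
            self.samples.copy(),
            self.markers.iloc[keep].copy(),
            self.genotypes[:, keep].copy(),
        )

    def subset_samples(self, ids: list[str]) -> "GenotypeDataset":
        idx = self.samples.set_index("id").index.get_indexer(ids)
        if (idx < 0).any():
            missing = [i for i, j in zip(ids, idx) if j < 0]
            raise KeyError(f"unknown sample ids: {missing}")
        return GenotypeDataset(
            self.samples.iloc[idx].copy(),
            self.markers.copy(),
            self.genotypes[idx].copy(),
        )


# ---------------------------------------------------------------------------
# PLINK text format


def write_plink_text(dataset: GenotypeDataset, ped_path, map_path) -> None:
    """Write PLINK ``.ped``/``.map`` text files (allele-pair encoding)."""
    mk = dataset.markers
    with open(map_path, "w") as fh:
        for _, row in mk.iterrows():
            fh.write(f"{row['chrom']}\t{row['id']}\t0\t{row['bp']}\n")
    a = mk["allele_a"].to_numpy()
    b = mk["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, (_, s) in enumerate(dataset.samples.iterrows()):
            g = dataset.genotypes[i]
            pairs = np.empty((len(mk), 2), dtype=object)
            pairs[g == 0] = np.stack([a[g == 0], a[g == 0]], axis=1)
            pairs[g == 1] = np.stack([a[g == 1], b[g == 1]], axis=1)
            pairs[g == 2] = np.stack([b[g == 2], b[g == 2]], axis=1)
            pairs[g == MISSING] = ["0", "0"]
            geno = " ".join(" ".join(p) for p in pairs)
            fh.write(f"{s['population']} {s['id']} 0 0 0 -9 {geno}\n")


def read_plink_text(ped_path, map_path) -> GenotypeDataset:
    """Read PLINK text ``.ped``/``.map`` into a :class:`GenotypeDataset`.

    Markers with non-positive (unknown) positions are dropped and recorded in
    ``dropped_markers``.  The first family column of the ``.ped`` file is used
    as the population label.
    """
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise GenotypeFormatError(f"{map_path}:{ln}: expected 4 columns")
            rows.append((parts[0], parts[1], int(parts[3])))
    markers = pd.DataFrame(rows, columns=["chrom", "id", "bp"])
    if markers["id"].duplicated().any():
        dup = markers.loc[markers["id"].duplicated(), "id"].iloc[0]
        raise GenotypeFormatError(f"{map_path}: duplicate marker id {dup!r}")
    m_total = len(markers)

    placed = markers["bp"] > 0
    dropped = markers[~placed].copy()
    if len(dropped):
        warnings.warn(
            f"excluded {len(dropped)} marker(s) with unknown chromosomal position",
            stacklevel=2,
        )

    sample_rows = []
    geno_rows = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m_total:
                raise GenotypeFormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m_total} fields, got {len(parts)}"
                )
            fid, iid = parts[0], parts[1]
            alleles = np.array(parts[6:], dtype=object).reshape(m_total, 2)
            sample_rows.append((iid, fid))
            geno_rows.append(alleles)
    if not sample_rows:
        raise GenotypeFormatError(f"{ped_path}: no individuals")
    samples = pd.DataFrame(sample_rows, columns=["id", "population"])

    # infer the two alleles per marker from the observed calls
    allele_a = np.empty(m_total, dtype=object)
    allele_b = np.empty(m_total, dtype=object)
    geno = np.full((len(samples), m_total), MISSING, dtype=np.int8)
    stacked = np.stack(geno_rows)  # (n, m, 2)
    for j in range(m_total):
        col = stacked[:, j, :]
        obs = col[col != "0"]
        uniq = sorted(set(obs.tolist()))
        if len(uniq) > 2:
            raise GenotypeFormatError(
                f"{ped_path}: marker {markers['id'][j]!r} has >2 alleles {uniq}"
            )
        a = uniq[0] if uniq else "A"
        b = uniq[1] if len(uniq) > 1 else ("B" if a != "B" else "A2")
        allele_a[j], allele_b[j] = a, b
        called = (col[:, 0] != "0") & (col[:, 1] != "0")
        geno[called, j] = (col[called] == b).sum(axis=1)
    markers["allele_a"] = allele_a
    markers["allele_b"] = allele_b

    markers = markers[placed.to_numpy()]
    geno = geno[:, placed.to_numpy()]
    order = _check_sorted(markers, map_path)
    return GenotypeDataset(samples, markers.iloc[order], geno[:, order],
                           dropped_markers=dropped if len(dropped) else None)


def _check_sorted(markers: pd.DataFrame, path) -> np.ndarray:
    """Markers must be sorted by position within chromosome; chromosomes are
    kept in file order."""
    order = []
    start = 0
    for chrom, grp in markers.groupby("chrom", sort=False):
        pos = grp["bp"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            j = int(np.where(np.diff(pos) <= 0)[0][0])
            raise GenotypeFormatError(
                f"{path}: positions not strictly increasing on {chrom} "
                f"near marker {grp['id'].iloc[j + 1]!r}"
            )
        order.extend(range(start, start + len(grp)))
        start += len(grp)
    return np.arange(len(markers))


# ---------------------------------------------------------------------------
# VCF


def write_vcf(dataset: GenotypeDataset, path) -> None:
    """Write a minimal VCF 4.2 file; REF = allele A, ALT = allele B."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dataset.markers["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        ids = "\t".join(dataset.samples["id"])
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{ids}\n")
        for j, (_, row) in enumerate(dataset.markers.iterrows()):
            gts = "\t".join(gt_map[int(g)] for g in dataset.genotypes[:, j])
            fh.write(
                f"{row['chrom']}\t{row['bp']}\t{row['id']}\t{row['allele_a']}"
                f"\t{row['allele_b']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path, populations: dict[str, str] | None = None) -> GenotypeDataset:
    """Read diploid genotypes from a VCF file via cyvcf2.

    Dosage is the ALT-allele count of the GT field; half-called or missing
    genotypes become missing.  ``populations`` optionally maps sample id to a
    population label (default label: ``"unknown"``).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, geno_cols = [], []
    for var in vcf:
        gts = np.asarray(var.genotype.array())
        if gts.shape[1] - 1 != 2:  # last column is the phasing flag
            raise GenotypeFormatError(
                f"{path}: non-diploid record at {var.CHROM}:{var.POS}"
            )
        alleles = gts[:, :2]
        dose = np.where((alleles < 0).any(axis=1), MISSING, alleles.sum(axis=1))
        alt = var.ALT[0] if var.ALT else "B"
        rows.append((var.CHROM, var.ID or f"{var.CHROM}:{var.POS}", var.POS,
                     var.REF, alt))
        geno_cols.append(dose.astype(np.int8))
    markers = pd.DataFrame(rows, columns=["chrom", "id", "bp", "allele_a", "allele_b"])
    pops = populations or {}
    samples = pd.DataFrame(
        {"id": sample_ids,
         "population": [pops.get(s, "unknown") for s in sample_ids]}
    )
    return GenotypeDataset(samples, markers, np.column_stack(geno_cols))


# ---------------------------------------------------------------------------
# Filters and frequencies


def maf_filter(dataset: GenotypeDataset, threshold: float = 0.05) -> GenotypeDataset:
    """Keep markers with minor allele frequency >= ``threshold``.

    The frequency is computed over non-missing calls pooled across all
    individuals.  Markers with MAF strictly below the threshold are removed,
    so a marker sitting exactly at the threshold is retained.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("threshold must be in [0, 0.5]")
    g = dataset.dosage_float()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
        freq = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = np.where(np.nan_to_num(maf, nan=-1.0) >= threshold)[0]
    if keep.size == 0:
        raise EmptyPanelError(
            f"MAF filter at {threshold} removed all {dataset.n_markers} markers"
        )
    return dataset.subset_markers(keep)


def allele_freq(
    dataset: GenotypeDataset,
    marker_ids: list[str] | None = None,
    by_population: bool = True,
) -> pd.DataFrame:
    """Genotype and B-allele frequencies, per population by default.

    Returns a long table with one row per (marker, population):
    genotype counts ``n_AA``/``n_AB``/``n_BB``, their frequencies, and the
    B-allele frequency, all over non-missing calls.
    """
    if marker_ids is None:
        marker_ids = dataset.markers["id"].tolist()
    midx = dataset.markers.set_index("id").index.get_indexer(marker_ids)
    if (midx < 0).any():
        unknown = [m for m, j in zip(marker_ids, midx) if j < 0]
        raise KeyError(f"unknown marker ids: {unknown}")

    if by_population:
        groups = dataset.samples.groupby("population", sort=False).indices
    else:
        groups = {"all": np.arange(dataset.n_samples)}

    out = []
    for pop, rows in groups.items():
        sub = dataset.genotypes[np.asarray(rows)][:, midx]
        n_aa = (sub == 0).sum(axis=0)
        n_ab = (sub == 1).sum(axis=0)
        n_bb = (sub == 2).sum(axis=0)
        n_obs = n_aa + n_ab + n_bb
        with np.errstate(invalid="ignore", divide="ignore"):
            freq_b = (n_ab + 2 * n_bb) / (2 * n_obs)
        for j, mid in enumerate(marker_ids):
            out.append({
                "marker": mid, "population": pop,
                "n_AA": int(n_aa[j]), "n_AB": int(n_ab[j]), "n_BB": int(n_bb[j]),
                "n_obs": int(n_obs[j]),
                "freq_AA": n_aa[j] / n_obs[j] if n_obs[j] else np.nan,
                "freq_AB": n_ab[j] / n_obs[j] if n_obs[j] else np.nan,
                "freq_BB": n_bb[j] / n_obs[j] if n_obs[j] else np.nan,
                "freq_B": freq_b[j] if n_obs[j] else np.nan,
            })
    return pd.DataFrame(out)
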