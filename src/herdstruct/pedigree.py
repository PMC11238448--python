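"""Pedigree container, inbreeding (F_PED), pedigree admixture (A_PED), and
genomic-vs-pedigree comparison.

F_PED is the kinship of an individual's parents, computed with the
Meuwissen-Luo tabular algorithm, which scales with pedigree depth rather
than pedigree size.  A_PED is the percentage of foreign (non home-breed)
ancestry propagated down the pedigree as the parental mean, with founders
anchored either by explicit breed fractions or by a purebred cutoff year
(animals born before the cutoff count as purebred home stock).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = None


@dataclass
class PedigreeRecord:
    id: str
    sire: str | None
    dam: str | None
    birth_year: int
    population: str
    founder_fractions: dict[str, float] | None = None  # founders only
    sex: str = "U"


@dataclass
class Pedigree:
    """Parentage records ordered so that parents precede offspring."""

    records: list[PedigreeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {r.id: i for i, r in enumerate(self.records)}
        if len(self._index) != len(self.records):
            raise ValueError("duplicate ids in pedigree")
        self._order = self._toposort()

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, pid: str) -> PedigreeRecord:
        return self.records[self._index[pid]]

    def __contains__(self, pid: str) -> bool:
        return pid in self._index

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def founders(self) -> list[PedigreeRecord]:
        return [r for r in self.records if r.sire is None and r.dam is None]

    def topological_order(self) -> list[str]:
        return list(self._order)

    def _toposort(self) -> list[str]:
        state: dict[str, int] = {}
        order: list[str] = []

        def visit(pid: str) -> None:
            stack = [(pid, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    state[node] = 2
                    order.append(node)
                    continue
                if state.get(node) == 1:
                    raise ValueError(f"pedigree cycle involving {node!r}")
                if state.get(node) == 2:
                    continue
                state[node] = 1
                stack.append((node, True))
                rec = self.records[self._index[node]]
                for parent in (rec.sire, rec.dam):
                    if parent is not None:
                        if parent not in self._index:
                            raise ValueError(
                                f"{node!r} references unknown parent {parent!r}"
                            )
                        if state.get(parent) != 2:
                            stack.append((parent, False))

        for r in self.records:
            if state.get(r.id) != 2:
                visit(r.id)
        return order

    # -- text round trip ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "id": r.id, "sire": r.sire or "0", "dam": r.dam or "0",
                "birth_year": r.birth_year, "population": r.population,
                "founder_fractions": (
                    ";".join(f"{k}:{v:g}" for k, v in r.founder_fractions.items())
                    if r.founder_fractions else ""
                ),
                "sex": r.sex,
            })
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        recs = []
        for _, row in df.iterrows():
            fracs = None
            if row.get("founder_fractions"):
                fracs = {}
                for part in row["founder_fractions"].split(";"):
                    k, v = part.split(":")
                    fracs[k] = float(v)
            recs.append(PedigreeRecord(
                id=row["id"],
                sire=None if row["sire"] in ("0", "") else row["sire"],
                dam=None if row["dam"] in ("0", "") else row["dam"],
                birth_year=int(row["birth_year"]),
                population=row.get("population", "unknown") or "unknown",
                founder_fractions=fracs,
                sex=row.get("sex", "U") or "U",
            ))
        return cls(recs)


def inbreeding(pedigree: Pedigree) -> pd.Series:
    """Inbreeding coefficient F_PED per individual (Meuwissen-Luo).

    F of an individual is the kinship of its parents; unknown parents are
    treated as unrelated, non-inbred founders, so any animal with a missing
    parent has F = 0.
    """
    order = pedigree.topological_order()
    idx = {pid: i for i, pid in enumerate(order)}
    n = len(order)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for pid in order:
        r = pedigree[pid]
        i = idx[pid]
        sire[i] = idx[r.sire] if r.sire is not None else -1
        dam[i] = idx[r.dam] if r.dam is not None else -1

    F = _ml_inbreeding(sire, dam)
    return pd.Series(F, index=order).reindex(pedigree.ids)


def _ml_inbreeding(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Meuwissen-Luo on parent index arrays (-1 = unknown), topological order."""
    n = sire.size
    F = np.zeros(n)
    D = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        # Mendelian sampling variance: unknown parents contribute as
        # unrelated non-inbred founders
        D[i] = 1.0
        if s >= 0:
            D[i] -= 0.25 * (1.0 + F[s])
        if d >= 0:
            D[i] -= 0.25 * (1.0 + F[d])
        if s < 0 or d < 0:
            continue
        pending: dict[int, float] = {i: 1.0}
        acc = 0.0
        for j in range(i, -1, -1):
            lj = pending.pop(j, None)
            if lj is None:
                continue
            acc += lj * lj * D[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    pending[p] = pending.get(p, 0.0) + lj / 2.0
        F[i] = acc - 1.0
    return F


def pedigree_admixture(
    pedigree: Pedigree,
    home_breed: str,
    purebred_cutoff_year: int = 1950,
) -> pd.Series:
    """Pedigree-based foreign-ancestry percentage A_PED per individual.

    Founders carrying explicit breed fractions contribute
    ``100 * (1 - fraction_of_home_breed)``; unlabelled founders born before
    the cutoff year count as purebred home stock (0% foreign); an unlabelled
    founder born on/after the cutoff raises.  Every non-founder receives the
    mean of its parents, an unknown parent counting as purebred home stock.
    """
    aped: dict[str, float] = {}
    for pid in pedigree.topological_order():
        r = pedigree[pid]
        if r.sire is None and r.dam is None:
            if r.founder_fractions is not None:
                aped[pid] = 100.0 * (1.0 - r.founder_fractions.get(home_breed, 0.0))
            elif r.birth_year < purebred_cutoff_year:
                aped[pid] = 0.0
            elif r.population == home_breed:
                aped[pid] = 0.0
            else:
                raise ValueError(
                    f"founder {pid!r} born {r.birth_year} (>= cutoff "
                    f"{purebred_cutoff_year}) has no breed fractions"
                )
        else:
            vs = aped[r.sire] if r.sire is not None else 0.0
            vd = aped[r.dam] if r.dam is not None else 0.0
            aped[pid] = 0.5 * (vs + vd)
    return pd.Series(aped).reindex(pedigree.ids)


@dataclass
class RegressionReport:
    n: int
    pearson_r: float
    slope: float
    intercept: float
    r_squared: float
    r_squared_with_parents: float | None = None


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return beta, r2


def compare_genomic_pedigree(
    genomic: pd.Series,
    pedigree_based: pd.Series,
    parent_factors: pd.DataFrame | None = None,
) -> RegressionReport:
    """Regress a genomic measure on its pedigree counterpart.

    Both series are aligned on their index (individual ids); rows with a
    missing value on either side are dropped.  ``parent_factors`` may carry
    ``sire``/``dam`` columns which, when given, are added to the model as
    categorical factors and the augmented R^2 reported alongside.
    """
    df = pd.concat({"y": genomic, "x": pedigree_based}, axis=1).dropna()
    if len(df) < 3:
        raise ValueError(f"need >= 3 paired observations, got {len(df)}")
    y = df["y"].to_numpy(float)
    x = df["x"].to_numpy(float)
    r = float(np.corrcoef(x, y)[0, 1])
    X = np.column_stack([np.ones_like(x), x])
    beta, r2 = _ols(y, X)
    r2_parents = None
    if parent_factors is not None:
        pf = parent_factors.reindex(df.index)
        dummies = [X]
        for col in ("sire", "dam"):
            if col in pf.columns:
                d = pd.get_dummies(pf[col].astype(str), drop_first=True)
                if d.shape[1]:
                    dummies.append(d.to_numpy(float))
        Xp = np.column_stack(dummies)
        _, r2_parents = _ols(y, Xp)
    return RegressionReport(
        n=len(df), pearson_r=r, slope=float(beta[1]), intercept=float(beta[0]),
        r_squared=r2, r_squared_with_parents=r2_parents,
    )
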