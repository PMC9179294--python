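"""Cohort container for the twin/sister family design.

A cohort is an ordered table of women with family, twin-pair and zygosity
structure plus the covariates (age, BMI) used throughout the analysis.
Monozygotic (MZ) and dizygotic (DZ) twin pairs are families of two; non-twin
sisters form families of one to a few members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

ZYGOSITIES = ("MZ", "DZ", "SIB")

COHORT_COLUMNS = ["id", "family_id", "pair_id", "zygosity", "age", "bmi"]

DENSITY_COLUMNS = ["cumulus", "altocumulus", "cirrocumulus", "cumulus_white",
                   "total_area"]


@dataclass(frozen=True)
class Individual:
    """One woman in the cohort.

    Parameters
    ----------
    id : str
        Unique identifier.
    family_id : str
        Family identifier shared by sisters and co-twins.
    pair_id : str or None
        Twin-pair identifier; ``None`` for non-twin sisters.
    zygosity : {"MZ", "DZ", "SIB"}
        Twin zygosity, or ``"SIB"`` for a non-twin sister.
    age : float
        Age at mammogram, years.
    bmi : float
        Body mass index, kg/m^2.
    """

    id: str
    family_id: str
    pair_id: Optional[str]
    zygosity: str
    age: float
    bmi: float

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.bmi <= 0:
            raise ValueError("bmi must be positive")


class Cohort:
    """Ordered collection of individuals with a family index.

    Backed by a :class:`pandas.DataFrame` with one row per woman; row order
    is stable across every operation so that genotype and trait matrices can
    be aligned positionally.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in COHORT_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if table["id"].duplicated().any():
            dup = table.loc[table["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate individual id {dup!r}")
        if len(table) == 0:
            raise ValueError("empty cohort")
        # normalize missing pair ids to None (object dtype) so round-trips
        # through TSV compare equal
        table = table.copy()
        table["pair_id"] = table["pair_id"].astype(object).where(
            table["pair_id"].notna(), None)
        bad = ~table["zygosity"].isin(ZYGOSITIES)
        if bad.any():
            raise ValueError(
                f"unknown zygosity values: {sorted(table.loc[bad, 'zygosity'].unique())}")
        # pair_id must be shared by exactly two individuals, within one family
        pairs = table.dropna(subset=["pair_id"]).groupby("pair_id")
        for pid, grp in pairs:
            if len(grp) != 2:
                raise ValueError(f"pair {pid!r} has {len(grp)} members, expected 2")
            if grp["family_id"].nunique() != 1:
                raise ValueError(f"pair {pid!r} spans multiple families")
        self.table = table.reset_index(drop=True)

    # -- basic protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self) -> Iterable[Individual]:
        for row in self.table.itertuples(index=False):
            yield Individual(row.id, row.family_id,
                             None if pd.isna(row.pair_id) else row.pair_id,
                             row.zygosity, row.age, row.bmi)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def family_ids(self) -> np.ndarray:
        return self.table["family_id"].to_numpy()

    @property
    def n_families(self) -> int:
        return self.table["family_id"].nunique()

    def family_index(self) -> dict[str, np.ndarray]:
        """Map family_id -> integer row positions (in table order)."""
        idx: dict[str, list[int]] = {}
        for pos, fid in enumerate(self.table["family_id"]):
            idx.setdefault(fid, []).append(pos)
        return {fid: np.asarray(rows, dtype=int) for fid, rows in idx.items()}

    def mz_pair_index(self) -> dict[str, np.ndarray]:
        """Map pair_id -> row positions for MZ pairs only."""
        tab = self.table
        mask = (tab["zygosity"] == "MZ") & tab["pair_id"].notna()
        out: dict[str, list[int]] = {}
        for pos in np.flatnonzero(mask.to_numpy()):
            out.setdefault(tab.at[pos, "pair_id"], []).append(pos)
        return {pid: np.asarray(rows, dtype=int) for pid, rows in out.items()}

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "Cohort":
        table = pd.read_csv(path, sep="\t", dtype={"id": str, "family_id": str,
                                                   "pair_id": str})
        return cls(table)

    def copy(self) -> "Cohort":
        return Cohort(self.table.copy())
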