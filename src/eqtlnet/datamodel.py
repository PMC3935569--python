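"""Shared domain types for bin-map QTL analysis.

All genomic coordinates are stored internally in base pairs on 1-based
closed intervals; megabases appear only when tables are written.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

GENOTYPE_CODES = ("A", "B", "H", "NA")
PRESENCE_CODES = ("P", "M", "A")

#: numeric coding used throughout the scan machinery: parent-1 homozygote -> -1,
#: parent-2 homozygote -> +1, heterozygote / missing -> NaN (dropped pairwise)
_NUMERIC = {"A": -1.0, "B": 1.0, "H": np.nan, "NA": np.nan}


class BinMap:
    """Ordered recombination bins with physical (bp) and genetic (cM) coordinates.

    Parameters
    ----------
    table
        DataFrame with columns ``bin_id, chrom, phys_start, phys_end,
        genetic_pos``.  Bins are sorted by (chrom, phys_start) on
        construction; within a chromosome they must be non-overlapping and
        the genetic position non-decreasing.
    """

    COLUMNS = ["bin_id", "chrom", "phys_start", "phys_end", "genetic_pos"]

    def __init__(self, table: pd.DataFrame):
        t = table[self.COLUMNS].copy()
        t["phys_start"] = t["phys_start"].astype(np.int64)
        t["phys_end"] = t["phys_end"].astype(np.int64)
        t["genetic_pos"] = t["genetic_pos"].astype(float)
        t = t.sort_values(["chrom", "phys_start"], kind="stable").reset_index(drop=True)
        self.table = t
        self._validate()

    def _validate(self) -> None:
        t = self.table
        if (t["phys_end"] < t["phys_start"]).any():
            bad = t.loc[t["phys_end"] < t["phys_start"], "bin_id"].iloc[0]
            raise ValueError(f"bin {bad}: phys_end < phys_start")
        if t["bin_id"].duplicated().any():
            dup = t.loc[t["bin_id"].duplicated(), "bin_id"].iloc[0]
            raise ValueError(f"duplicated bin_id {dup}")
        for chrom, grp in t.groupby("chrom", sort=False):
            starts = grp["phys_start"].to_numpy()
            ends = grp["phys_end"].to_numpy()
            overlap = starts[1:] <= ends[:-1]
            if overlap.any():
                i = int(np.argmax(overlap))
                a, b = grp["bin_id"].iloc[i], grp["bin_id"].iloc[i + 1]
                raise ValueError(
                    f"overlapping bins on chromosome {chrom}: {a} "
                    f"({starts[i]}-{ends[i]}) and {b} ({starts[i+1]}-{ends[i+1]})"
                )
            cm = grp["genetic_pos"].to_numpy()
            if (np.diff(cm) < -1e-9).any():
                raise ValueError(f"genetic positions decrease on chromosome {chrom}")

    @property
    def n_bins(self) -> int:
        return len(self.table)

    @property
    def bin_ids(self) -> np.ndarray:
        return self.table["bin_id"].to_numpy()

    @property
    def chromosomes(self) -> list:
        return list(self.table["chrom"].unique())

    def midpoints(self) -> np.ndarray:
        """Physical midpoint of each bin in bp."""
        t = self.table
        return ((t["phys_start"].to_numpy() + t["phys_end"].to_numpy()) / 2.0)

    def chrom_sizes_bp(self) -> pd.Series:
        """Chromosome physical extents (sum of bin widths, bp)."""
        t = self.table
        widths = t["phys_end"] - t["phys_start"] + 1
        return widths.groupby(t["chrom"], sort=False).sum()

    def chrom_sizes_cm(self) -> pd.Series:
        """Chromosome genetic extents (max genetic position, cM)."""
        return self.table.groupby("chrom", sort=False)["genetic_pos"].max()

    def index_of(self, bin_id: str) -> int:
        idx = np.flatnonzero(self.bin_ids == bin_id)
        if idx.size == 0:
            raise KeyError(f"unknown bin_id {bin_id}")
        return int(idx[0])

    def __eq__(self, other) -> bool:
        return isinstance(other, BinMap) and self.table.equals(other.table)

    def __repr__(self) -> str:
        return f"BinMap({self.n_bins} bins, {len(self.chromosomes)} chromosomes)"


class GenotypeMatrix:
    """RIL lines x bins genotype calls in {A, B, H, NA}."""

    def __init__(self, calls: pd.DataFrame):
        bad = ~calls.isin(GENOTYPE_CODES)
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"unknown genotype code {calls.iat[r, c]!r} at line "
                f"{calls.index[r]!r}, bin {calls.columns[c]!r}"
            )
        if calls.index.duplicated().any():
            raise ValueError(f"duplicated line label {calls.index[calls.index.duplicated()][0]!r}")
        self.calls = calls

    @property
    def lines(self) -> list:
        return list(self.calls.index)

    @property
    def n_lines(self) -> int:
        return len(self.calls)

    @property
    def n_bins(self) -> int:
        return self.calls.shape[1]

    def numeric(self) -> np.ndarray:
        """Float matrix with A -> -1, B -> +1, H/NA -> NaN."""
        arr = self.calls.to_numpy(dtype=object)
        out = np.full(arr.shape, np.nan)
        out[arr == "A"] = -1.0
        out[arr == "B"] = 1.0
        return out

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_lines} lines x {self.n_bins} bins)"


class ExpressionSet:
    """E-traits x lines log2 expression with genomic anchors and presence calls.

    ``anchors`` is indexed by e-trait id with columns ``gene_id, chrom,
    position`` (bp, midpoint convention); unanchored e-traits carry NaN.
    ``presence`` holds MAS5-style P/M/A flags congruent with ``values``;
    ``None`` means every call is P.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        anchors: Optional[pd.DataFrame] = None,
        presence: Optional[pd.DataFrame] = None,
    ):
        if values.index.duplicated().any():
            raise ValueError("duplicated e-trait id")
        if presence is not None:
            if presence.shape != values.shape or not presence.index.equals(values.index):
                raise ValueError("presence matrix not congruent with values")
            bad = ~presence.isin(PRESENCE_CODES)
            if bad.to_numpy().any():
                raise ValueError("presence calls must be P, M or A")
        if anchors is None:
            anchors = pd.DataFrame(
                {"gene_id": values.index, "chrom": pd.NA, "position": np.nan},
                index=values.index,
            )
        self.values = values
        self.anchors = anchors.reindex(values.index)
        self.presence = presence

    @property
    def etrait_ids(self) -> list:
        return list(self.values.index)

    @property
    def lines(self) -> list:
        return list(self.values.columns)

    @property
    def n_etraits(self) -> int:
        return len(self.values)

    @property
    def n_lines(self) -> int:
        return self.values.shape[1]

    def subset(self, etraits: Sequence) -> "ExpressionSet":
        pres = self.presence.loc[etraits] if self.presence is not None else None
        return ExpressionSet(self.values.loc[etraits], self.anchors.loc[etraits], pres)

    def __repr__(self) -> str:
        return f"ExpressionSet({self.n_etraits} e-traits x {self.n_lines} lines)"


@dataclass
class QtlRecord:
    """One mapped locus for one trait.

    ``additive`` is in trait units per allele substitution; positive means
    the parent-2 allele increases the trait.  ``si_lo``/``si_hi`` bound the
    1.5-LOD-drop support interval in bp (1-based closed).  ``regulation`` is
    ``cis`` if the trait's own genomic anchor falls inside the support
    interval on the same chromosome, ``trans`` otherwise, and
    ``not-applicable`` for unanchored traits or phenotypes.
    """

    trait_id: str
    chromosome: str
    peak_bin: str
    peak_pos: int
    lod: float
    si_lo: int
    si_hi: int
    additive: float
    var_explained: float
    regulation: str = "not-applicable"

    def __post_init__(self):
        if not (self.si_lo <= self.peak_pos <= self.si_hi):
            raise ValueError(
                f"{self.trait_id}: peak position {self.peak_pos} outside "
                f"support interval [{self.si_lo}, {self.si_hi}]"
            )
        if not (0.0 <= self.var_explained <= 1.0):
            raise ValueError(f"{self.trait_id}: var_explained outside [0, 1]")
        if self.regulation not in ("cis", "trans", "not-applicable"):
            raise ValueError(f"invalid regulation flag {self.regulation!r}")


class PhenotypeTable:
    """Lines x named quantitative traits; NA allowed."""

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            raise ValueError("duplicated line label")
        self.values = values.astype(float)

    @property
    def lines(self) -> list:
        return list(self.values.index)

    @property
    def traits(self) -> list:
        return list(self.values.columns)

    def __repr__(self) -> str:
        return f"PhenotypeTable({len(self.values)} lines x {len(self.values.columns)} traits)"


@dataclass
class GeneSet:
    """Named list of gene / e-trait labels (a functional category)."""

    name: str
    members: list = field(default_factory=list)

    def resolve(self, etrait_ids: Sequence) -> tuple[list, list]:
        """Split members into (resolved, unresolved) against an e-trait index.

        Labels match either the e-trait id or its gene_id; unresolvable
        labels are reported, not fatal.
        """
        known = set(etrait_ids)
        resolved = [m for m in self.members if m in known]
        unresolved = [m for m in self.members if m not in known]
        return resolved, unresolved


class AnnotationTable:
    """Gene -> term pairs for enrichment tests."""

    def __init__(self, pairs: pd.DataFrame):
        self.pairs = pairs[["gene", "term"]].drop_duplicates().reset_index(drop=True)

    def genes_for(self, term: str) -> list:
        return list(self.pairs.loc[self.pairs["term"] == term, "gene"])

    @property
    def terms(self) -> list:
        return list(self.pairs["term"].unique())
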