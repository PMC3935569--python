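"""Readers and writers for the pipeline's tab-delimited tables.

Every table is TSV with '#'-prefixed comment lines and a header row;
decimal point, never comma.  Writers and readers round-trip up to printed
precision.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Union

import numpy as np
import pandas as pd

from .datamodel import (
    AnnotationTable,
    BinMap,
    GeneSet,
    GenotypeMatrix,
    PhenotypeTable,
    QtlRecord,
)

log = logging.getLogger("eqtlnet")

_READ_KW = dict(sep="\t", comment="#")


def read_bin_map(path: Union[str, Path]) -> BinMap:
    """Read a bin map from a TSV with header ``chrom, start, end, cM``.

    Bins out of order are re-sorted with a warning; an optional ``bin_id``
    column is honoured, otherwise ordinal ids ``Bin1..BinN`` are assigned
    after sorting.
    """
    raw = pd.read_csv(path, **_READ_KW, dtype={"chrom": str})
    required = {"chrom", "start", "end", "cM"}
    if not required.issubset(raw.columns):
        raise ValueError(f"{path}: bin map needs columns {sorted(required)}")
    for col in ("start", "end", "cM"):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        if coerced.isna().any() and not raw[col].isna().any():
            line = int(np.flatnonzero(coerced.isna())[0]) + 2  # header is line 1
            raise ValueError(f"{path}: non-numeric {col!r} value on line {line}")
        raw[col] = coerced

    sorted_raw = raw.sort_values(["chrom", "start"], kind="stable")
    if not sorted_raw.index.equals(raw.index):
        log.warning("%s: bins were out of order; re-sorted by (chrom, start)", path)
    raw = sorted_raw.reset_index(drop=True)

    if "bin_id" in raw.columns:
        bin_ids = raw["bin_id"].astype(str)
    else:
        bin_ids = pd.Series([f"Bin{i+1}" for i in range(len(raw))])
    table = pd.DataFrame(
        {
            "bin_id": bin_ids.to_numpy(),
            "chrom": raw["chrom"].to_numpy(),
            "phys_start": raw["start"].to_numpy(),
            "phys_end": raw["end"].to_numpy(),
            "genetic_pos": raw["cM"].to_numpy(),
        }
    )
    return BinMap(table)


def write_bin_map(binmap: BinMap, path: Union[str, Path]) -> None:
    t = binmap.table
    out = pd.DataFrame(
        {
            "bin_id": t["bin_id"],
            "chrom": t["chrom"],
            "start": t["phys_start"],
            "end": t["phys_end"],
            "cM": t["genetic_pos"].round(4),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_matrix(path: Union[str, Path], kind: str):
    """Read a labelled matrix: first column row labels, header column labels.

    ``kind`` is one of ``genotype`` (codes validated), ``expression``
    (coerced to reals, NAs counted), ``presence`` (P/M/A flags) or
    ``phenotype``.
    """
    df = pd.read_csv(path, **_READ_KW, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated row label {dup!r}")
    if kind == "genotype":
        df = df.astype(str)
        return GenotypeMatrix(df)
    if kind == "presence":
        return df.astype(str)
    if kind in ("expression", "phenotype"):
        df = df.apply(pd.to_numeric, errors="raise")
        n_na = int(df.isna().sum().sum())
        if n_na:
            log.info("%s: %d NA cells accepted and propagated", path, n_na)
        return PhenotypeTable(df) if kind == "phenotype" else df
    raise ValueError(f"unknown matrix kind {kind!r}")


_QTL_COLUMNS = [
    "trait_id", "chrom", "peak_bin", "peak_Mb", "LOD", "additive",
    "var_explained", "si_lo_Mb", "si_hi_Mb", "regulation",
]


def write_qtl_table(records: List[QtlRecord], path: Union[str, Path]) -> None:
    """Write mapped QTLs as TSV; Mb columns are bp / 1e6 at 6 decimals."""
    rows = [
        {
            "trait_id": r.trait_id,
            "chrom": r.chromosome,
            "peak_bin": r.peak_bin,
            "peak_Mb": round(r.peak_pos / 1e6, 6),
            "LOD": round(r.lod, 4),
            "additive": round(r.additive, 6),
            "var_explained": round(r.var_explained, 6),
            "si_lo_Mb": round(r.si_lo / 1e6, 6),
            "si_hi_Mb": round(r.si_hi / 1e6, 6),
            "regulation": r.regulation,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_QTL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_qtl_table(path: Union[str, Path]) -> List[QtlRecord]:
    df = pd.read_csv(path, **_READ_KW, dtype={"chrom": str, "peak_bin": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(
            QtlRecord(
                trait_id=row.trait_id,
                chromosome=row.chrom,
                peak_bin=row.peak_bin,
                peak_pos=int(round(row.peak_Mb * 1e6)),
                lod=float(row.LOD),
                si_lo=int(round(row.si_lo_Mb * 1e6)),
                si_hi=int(round(row.si_hi_Mb * 1e6)),
                additive=float(row.additive),
                var_explained=float(row.var_explained),
                regulation=row.regulation,
            )
        )
    return records


def read_gene_set(path: Union[str, Path], name: str | None = None) -> GeneSet:
    """One gene / e-trait label per line; blank lines and '#' comments skipped."""
    p = Path(path)
    members = [
        line.strip()
        for line in p.read_text().splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    return GeneSet(name=name or p.stem, members=members)


def read_annotation(path: Union[str, Path]) -> AnnotationTable:
    df = pd.read_csv(path, **_READ_KW)
    if not {"gene", "term"}.issubset(df.columns):
        raise ValueError(f"{path}: annotation needs columns gene, term")
    return AnnotationTable(df)


def read_anchors(path: Union[str, Path]) -> pd.DataFrame:
    """Per-e-trait genomic anchors: columns etrait_id, gene_id, chrom, position."""
    df = pd.read_csv(path, **_READ_KW, dtype={"chrom": str}, index_col="etrait_id")
    return df[["gene_id", "chrom", "position"]]
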